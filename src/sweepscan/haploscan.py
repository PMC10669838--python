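"""Extended haplotype homozygosity (EHH), its integral (iHH) and XP-EHH.

EHH at distance x from a core SNP is the probability that two haplotypes
drawn at random are identical over every SNP between the core (exclusive)
and x (inclusive): EHH(x) = sum_h C(c_h, 2) / C(n, 2) where c_h are the
sizes of the identity classes. The cross-population variant used here is
computed over all haplotypes jointly (no partition by core allele), so
EHH(0) = 1. iHH is the trapezoid integral of the EHH decay curve over
physical distance, summed over both directions; the curve is linearly
interpolated to the point where it crosses the truncation cutoff. Scanning
stops at the cutoff (default 0.05), at an inter-SNP gap larger than
max_gap (default 200 kb), or at the chromosome end.

Raw XP-EHH at a site is ln(iHH_object / iHH_reference); scores are
z-normalized genome-wide.

Two routes exist deliberately: `ehh`/`ihh` are a plain-Python reference
implementation of the definitions, and `_ihh_scan` is the numba kernel the
scan uses; tests hold them equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000


@dataclass
class EhhCurve:
    core_index: int
    direction: str  # "left" | "right"
    points: list[tuple[float, float]]  # (distance bp, EHH), starts at (0, 1)
    crossing: tuple[float, float] | None = None  # first point below cutoff, if hit


def _homozygosity(groups: np.ndarray) -> float:
    n = groups.size
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    direction: str,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
) -> EhhCurve:
    """Reference EHH decay curve in one direction from the core SNP."""
    haps = np.asarray(haplotypes)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    step = 1 if direction == "right" else -1
    points = [(0.0, 1.0)]
    crossing = None
    groups = np.zeros(n, dtype=np.int64)
    j = core_index
    prev_pos = positions[core_index]
    while True:
        j += step
        if j < 0 or j >= haps.shape[1]:
            break  # chromosome end: hard stop
        if abs(int(positions[j]) - int(prev_pos)) > max_gap:
            break
        groups = groups * 2 + haps[:, j]
        _, groups = np.unique(groups, return_inverse=True)
        d = float(abs(int(positions[j]) - int(positions[core_index])))
        e = _homozygosity(groups)
        if e < cutoff:
            crossing = (d, e)
            break
        points.append((d, e))
        prev_pos = positions[j]
    return EhhCurve(core_index=core_index, direction=direction, points=points, crossing=crossing)


def ihh(left: EhhCurve, right: EhhCurve, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Integrated EHH (bp x homozygosity) over both directions.

    NaN when the core has no flanking site on either side. When a curve ends
    below the cutoff, integration runs to the linearly interpolated point
    where EHH = cutoff; at a chromosome end or gap it stops at the last SNP.
    """
    if left.core_index != right.core_index:
        raise ValueError("curves must share the core")

    def one_side(curve: EhhCurve) -> float:
        total = 0.0
        pts = curve.points
        for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
            total += 0.5 * (e0 + e1) * (d1 - d0)
        if curve.crossing is not None:
            d0, e0 = pts[-1]
            d1, e1 = curve.crossing
            x = d0 + (e0 - cutoff) / (e0 - e1) * (d1 - d0)
            total += 0.5 * (e0 + cutoff) * (x - d0)
        return total

    if len(left.points) == 1 and left.crossing is None and len(right.points) == 1 and right.crossing is None:
        return float("nan")
    return one_side(left) + one_side(right)


@njit(cache=True)
def _ihh_scan(haps, positions, cutoff, max_gap):  # pragma: no cover - numba
    n, m = haps.shape
    pair_total = n * (n - 1)
    out = np.empty(m)
    groups = np.empty(n, np.int64)
    keys = np.empty(n, np.int64)
    for core in range(m):
        total = 0.0
        any_flank = False
        for step in (-1, 1):
            for i in range(n):
                groups[i] = 0
            ehh_prev = 1.0
            d_prev = 0.0
            prev_pos = positions[core]
            j = core
            while True:
                j += step
                if j < 0 or j >= m:
                    break
                if abs(positions[j] - prev_pos) > max_gap:
                    break
                any_flank = True
                for i in range(n):
                    keys[i] = groups[i] * 2 + haps[i, j]
                order = np.argsort(keys, kind="mergesort")
                gid = 0
                groups[order[0]] = 0
                pair_sum = 0
                run = 1
                for k in range(1, n):
                    if keys[order[k]] != keys[order[k - 1]]:
                        pair_sum += run * (run - 1)
                        run = 1
                        gid += 1
                    else:
                        run += 1
                    groups[order[k]] = gid
                pair_sum += run * (run - 1)
                e = pair_sum / pair_total
                d = abs(positions[j] - positions[core])
                if e < cutoff:
                    x = d_prev + (ehh_prev - cutoff) / (ehh_prev - e) * (d - d_prev)
                    total += 0.5 * (ehh_prev + cutoff) * (x - d_prev)
                    break
                total += 0.5 * (ehh_prev + e) * (d - d_prev)
                ehh_prev = e
                d_prev = float(d)
                prev_pos = positions[j]
        if any_flank:
            out[core] = total
        else:
            out[core] = np.nan
    return out


def ihh_all_sites(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
) -> np.ndarray:
    """iHH at every site of one chromosome (fast kernel)."""
    haps = np.ascontiguousarray(np.asarray(haplotypes, dtype=np.uint8))
    if haps.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    pos = np.ascontiguousarray(np.asarray(positions, dtype=np.int64))
    return _ihh_scan(haps, pos, float(cutoff), int(max_gap))


def xpehh_scan(
    variants: pd.DataFrame,
    haps_object: np.ndarray,
    haps_reference: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
    phased: bool = True,
) -> pd.DataFrame:
    """Per-site raw XP-EHH = ln(iHH_object / iHH_reference), per chromosome.

    Sites where either iHH is undefined or zero get NaN. The object
    population is the one whose sweep raises the score.
    """
    if not phased:
        raise ValueError("XP-EHH requires phased haplotypes")
    ihh_a = np.empty(len(variants))
    ihh_b = np.empty(len(variants))
    for chrom in variants.chrom.unique():
        idx = np.where(variants.chrom.values == chrom)[0]
        pos = variants.pos.values[idx]
        ihh_a[idx] = ihh_all_sites(np.asarray(haps_object)[:, idx], pos, cutoff, max_gap)
        ihh_b[idx] = ihh_all_sites(np.asarray(haps_reference)[:, idx], pos, cutoff, max_gap)
    # log(a) - log(b) rather than log(a/b): exactly antisymmetric under swap
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log(ihh_a) - np.log(ihh_b)
    raw[~np.isfinite(raw)] = np.nan
    return pd.DataFrame(
        {
            "chrom": variants.chrom.values,
            "pos": variants.pos.values,
            "ihh_a": ihh_a,
            "ihh_b": ihh_b,
            "xpehh_raw": raw,
        }
    )


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Genome-wide z-normalization over finite scores; NaN propagated."""
    raw = np.asarray(raw, dtype=float)
    finite = np.isfinite(raw)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite scores to normalize")
    mu = raw[finite].mean()
    sd = raw[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance: scores cannot be normalized")
    out = np.full(raw.shape, np.nan)
    out[finite] = (raw[finite] - mu) / sd
    return out
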