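"""Two-tier SNP significance classification and seed-and-extend region calling.

Per comparison and per method, every SNP gets a tier:

* FST track — extreme: theta in the top 0.01% of finite values AND
  Bonferroni-adjusted Fisher p < 0.01; significant: theta >= 0.4 AND
  adjusted p < 0.01.
* XP-EHH track — extreme: |normalized score| in the top 0.1%; significant:
  |normalized score| >= 1.

Quantile thresholds are computed genome-wide over finite scores; values
exactly at the cutoff count (>=). NA sites are non-significant and excluded
from the quantiles. The stricter label wins.

Region growing: centering on each extreme SNP, the region extends SNP-by-SNP
in both directions, crossing runs of one or two non-significant SNPs and
stopping at the first run of three or more (or the chromosome end); the
boundary is the outermost significant-or-extreme SNP reached. A maximal
stretch (delimited by the same >=3-non-significant runs) containing more
than five significant SNPs but no extreme SNP is also a region. Because
extension crosses every gap shorter than the stopping run, each such stretch
yields exactly one candidate interval: from its first to its last
significant-or-extreme SNP, kept iff the stretch holds an extreme SNP or
more than five significant ones. Regions sharing a SNP are merged (the
closed form makes that a no-op; merging is still applied for safety).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import natural_chrom_key

TIER_NON = "N"
TIER_SIG = "S"
TIER_EXT = "E"

EXTREME_FST_QUANTILE = 0.0001   # top 0.01% of theta
EXTREME_XPEHH_QUANTILE = 0.001  # top 0.1% of |normalized XP-EHH|
SIG_FST_MIN = 0.4
SIG_XPEHH_MIN = 1.0
ADJ_P_MAX = 0.01
MIN_SIG_RULE_B = 5  # "more than five": strictly greater
STOP_RUN = 3        # "more than two consecutive non-significant SNPs"


@dataclass
class SelectedRegion:
    chrom: str
    start: int  # 1-based inclusive, position of outermost member SNP
    end: int
    method: str
    n_extreme: int
    n_significant: int
    rule: str  # "seed" (>=1 extreme) | "run" (>5 significant) | "window"

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def classify_snps(scores: pd.DataFrame, method: str) -> np.ndarray:
    """Assign E/S/N tiers to every site of one comparison.

    `scores` needs columns fst + fisher_p_adj (method='fst') or xpehh_norm
    (method='xpehh').
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    tiers = np.full(len(scores), TIER_NON, dtype="U1")
    if method == "fst":
        theta = scores["fst"].values.astype(float)
        p_adj = scores["fisher_p_adj"].values.astype(float)
        finite = np.isfinite(theta)
        if not finite.any():
            raise ValueError("no finite FST values")
        thr = np.quantile(theta[finite], 1.0 - EXTREME_FST_QUANTILE)
        p_ok = np.isfinite(p_adj) & (p_adj < ADJ_P_MAX)
        sig = finite & (theta >= SIG_FST_MIN) & p_ok
        ext = finite & (theta >= thr) & p_ok
    elif method == "xpehh":
        z = np.abs(scores["xpehh_norm"].values.astype(float))
        finite = np.isfinite(z)
        if not finite.any():
            raise ValueError("no finite XP-EHH values")
        thr = np.quantile(z[finite], 1.0 - EXTREME_XPEHH_QUANTILE)
        sig = finite & (z >= SIG_XPEHH_MIN)
        ext = finite & (z >= thr)
    else:
        raise ValueError(f"unknown method {method!r}")
    tiers[sig] = TIER_SIG
    tiers[ext] = TIER_EXT
    return tiers


def _merge_index_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge intervals that share at least one index."""
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def grow_region_indices(tiers) -> list[tuple[int, int]]:
    """Region index intervals for one chromosome's tier sequence.

    Closed form of the seed-and-extend rule (see module docstring): split at
    runs of >= STOP_RUN non-significant SNPs; a segment becomes the interval
    [first non-N, last non-N] iff it has an extreme SNP, or more than
    MIN_SIG_RULE_B significant SNPs and no extreme SNP.
    """
    s = "".join(tiers)
    segments: list[tuple[int, int]] = []
    prev = 0
    for m in re.finditer(TIER_NON + "{%d,}" % STOP_RUN, s):
        segments.append((prev, m.start()))
        prev = m.end()
    segments.append((prev, len(s)))

    intervals: list[tuple[int, int]] = []
    for a, b in segments:
        seg = s[a:b]
        first = next((i for i, ch in enumerate(seg) if ch != TIER_NON), None)
        if first is None:
            continue
        last = len(seg) - 1 - next(i for i, ch in enumerate(reversed(seg)) if ch != TIER_NON)
        if seg.count(TIER_EXT) >= 1 or seg.count(TIER_SIG) > MIN_SIG_RULE_B:
            intervals.append((a + first, a + last))
    return _merge_index_intervals(intervals)


def grow_regions(
    positions: np.ndarray, tiers: np.ndarray, chroms: np.ndarray, method: str
) -> list[SelectedRegion]:
    """Call selected regions from per-SNP tiers, per chromosome."""
    positions = np.asarray(positions)
    tiers = np.asarray(tiers)
    chroms = np.asarray(chroms)
    regions: list[SelectedRegion] = []
    for chrom in sorted(set(chroms.tolist()), key=natural_chrom_key):
        idx = np.where(chroms == chrom)[0]
        order = idx[np.argsort(positions[idx], kind="mergesort")]
        t = tiers[order]
        pos = positions[order]
        for lo, hi in grow_region_indices(t):
            sub = t[lo : hi + 1]
            n_ext = int((sub == TIER_EXT).sum())
            regions.append(
                SelectedRegion(
                    chrom=chrom,
                    start=int(pos[lo]),
                    end=int(pos[hi]),
                    method=method,
                    n_extreme=n_ext,
                    n_significant=int((sub == TIER_SIG).sum()),
                    rule="seed" if n_ext else "run",
                )
            )
    return regions


def regions_from_windows(called_windows: pd.DataFrame, method: str = "xpclr") -> list[SelectedRegion]:
    """Merge adjacent called windows (end + 1 == next start) into regions."""
    regions: list[SelectedRegion] = []
    df = called_windows.sort_values(
        ["chrom", "start"], key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s
    )
    for _, row in df.iterrows():
        if (
            regions
            and regions[-1].chrom == row.chrom
            and row.start <= regions[-1].end + 1
        ):
            regions[-1].end = max(regions[-1].end, int(row.end))
            regions[-1].n_significant += 1
        else:
            regions.append(
                SelectedRegion(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    method=method,
                    n_extreme=0,
                    n_significant=1,  # counts member windows on this track
                    rule="window",
                )
            )
    return regions


def regions_to_frame(regions: list[SelectedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "method": r.method,
                "rule": r.rule,
                "n_extreme": r.n_extreme,
                "n_significant": r.n_significant,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "method", "rule", "n_extreme", "n_significant"],
    )
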