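"""Windowed cross-population composite likelihood ratio (XP-CLR style) scan.

The genome is tiled with non-overlapping windows (default 25 kb, tiling from
position 1; a final partial window is kept if it holds at least one SNP).
Within a window, each SNP contributes a weighted log-likelihood-ratio term
contrasting two models of the object-population allele frequency q given the
reference-population frequency p:

* neutral drift: q ~ Normal(p, omega * p(1-p)) truncated to [0,1] with the
  tail mass placed as point masses on the boundaries; the observed object
  allele count is binomial given q. omega is the drift scale, set from
  genome-wide FST as omega = F/(1-F).
* sweep: each sampled lineage at distance d bp from the window center
  hitchhikes with probability c = exp(-alpha * d) onto the swept haplotype
  (carrying the swept allele with certainty) and otherwise segregates
  neutrally; which of the two alleles was swept gets an equal prior. The
  selection strength alpha is maximized over a log grid whose limit
  (alpha -> infinity, c -> 0) recovers the neutral model, so the raw score
  2 * (logL_sweep - logL_neutral) is non-negative.

SNPs are down-weighted for linkage disequilibrium in the reference
population: SNPs are single-linkage clustered on pairwise r^2 above a cutoff
(default 0.95) and each SNP's weight is 1/(cluster size). Windows carry at
most 500 SNPs (deterministic thinning, every k-th by position). Window
scores are z-normalized genome-wide (xpclr_norm) and the windows at or above
the top-1% quantile are called candidates, ties included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from scipy.stats import norm

from .haploscan import normalize_scores

DEFAULT_WINDOW = 25_000
DEFAULT_MAX_SNPS = 500
DEFAULT_LD_CUTOFF = 0.95
DEFAULT_TOP_FRACTION = 0.01
DEFAULT_ALPHA_GRID = np.logspace(-6, -2, 20)  # per-bp selection scale
N_Q_GRID = 64


def estimate_omega(fst: float) -> float:
    """Drift scale from genome-wide FST: omega = F/(1-F)."""
    if not 0.0 < fst < 1.0:
        raise ValueError("genome-wide FST must lie strictly in (0, 1)")
    return fst / (1.0 - fst)


def ld_weights(ref_haps: np.ndarray, r2_cutoff: float = DEFAULT_LD_CUTOFF) -> np.ndarray:
    """Per-SNP weights 1/(cluster size) from single-linkage clustering on r^2.

    r^2 is the squared Pearson correlation of allele indicators in the
    reference population; monomorphic columns have undefined r^2 and are
    treated as unlinked singletons.
    """
    h = np.asarray(ref_haps, dtype=float)
    s = h.shape[1]
    if s == 0:
        return np.empty(0)
    centered = h - h.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    ok = norms > 0
    r2 = np.zeros((s, s))
    if ok.any():
        c = centered[:, ok] / norms[ok]
        sub = (c.T @ c) ** 2
        r2[np.ix_(ok, ok)] = sub
    adj = csr_matrix(r2 > r2_cutoff)
    _, labels = connected_components(adj, directed=False)
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def _neutral_q_prior(p: np.ndarray, omega: float, n_q: int = N_Q_GRID):
    """Per-site discretized density of q: (interior grid, interior mass,
    boundary masses at 0 and 1). p must be strictly inside (0,1)."""
    edges = np.linspace(0.0, 1.0, n_q + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    sd = np.sqrt(omega * p * (1.0 - p))
    cdf = norm.cdf((edges[None, :] - p[:, None]) / sd[:, None])
    interior = np.diff(cdf, axis=1)
    mass0 = cdf[:, 0]
    mass1 = 1.0 - cdf[:, -1]
    return mids, interior, mass0, mass1


def window_cl_ratio(
    p_ref: np.ndarray,
    alt_obj: np.ndarray,
    n_obj_alleles: np.ndarray,
    dist_bp: np.ndarray,
    weights: np.ndarray,
    omega: float,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
) -> float:
    """Raw composite log-likelihood-ratio score of one window (NaN if unusable).

    Sites monomorphic in the reference are dropped (no drift information);
    with none left the window is NaN.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    p_ref = np.asarray(p_ref, dtype=float)
    use = (p_ref > 0.0) & (p_ref < 1.0)
    if not use.any():
        return float("nan")
    p = p_ref[use]
    k = np.asarray(alt_obj, dtype=float)[use]
    m = np.asarray(n_obj_alleles, dtype=float)[use]
    d = np.asarray(dist_bp, dtype=float)[use]
    w = np.asarray(weights, dtype=float)[use]

    mids, interior, mass0, mass1 = _neutral_q_prior(p, omega)
    log_choose = gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    def site_loglik(c: np.ndarray, swept_allele: int) -> np.ndarray:
        # success prob per lineage on the q grid: hitchhike w.p. c, else q
        if swept_allele == 1:
            pi = c[:, None] + (1.0 - c[:, None]) * mids[None, :]
            pi0 = c  # boundary q = 0
            pi1 = np.ones_like(c)  # boundary q = 1
        else:
            pi = (1.0 - c[:, None]) * mids[None, :]
            pi0 = np.zeros_like(c)
            pi1 = 1.0 - c
        eps = 1e-12
        pi = np.clip(pi, eps, 1 - eps)
        pmf = np.exp(log_choose[:, None] + k[:, None] * np.log(pi) + (m - k)[:, None] * np.log1p(-pi))
        lik = (interior * pmf).sum(axis=1)
        for mass, pb in ((mass0, pi0), (mass1, pi1)):
            pb = np.clip(pb, eps, 1 - eps)
            lik = lik + mass * np.exp(log_choose + k * np.log(pb) + (m - k) * np.log1p(-pb))
        return np.log(np.maximum(lik, 1e-300))

    zero_c = np.zeros(p.size)
    ll_neutral = float((w * site_loglik(zero_c, 1)).sum())
    best = ll_neutral
    for alpha in np.asarray(alpha_grid, dtype=float):
        c = np.exp(-alpha * d)
        ll0 = site_loglik(c, 0)
        ll1 = site_loglik(c, 1)
        # equal prior over which allele was swept, mixed in likelihood space
        hi = np.maximum(ll0, ll1)
        ll = hi + np.log(0.5 * (np.exp(ll0 - hi) + np.exp(ll1 - hi)))
        best = max(best, float((w * ll).sum()))
    return 2.0 * max(0.0, best - ll_neutral)


def _thin_indices(n: int, cap: int) -> np.ndarray:
    if n <= cap:
        return np.arange(n)
    k = int(np.ceil(n / cap))
    return np.arange(0, n, k)


def scan_windows(
    variants: pd.DataFrame,
    haps_object: np.ndarray,
    haps_reference: np.ndarray,
    omega: float,
    window: int = DEFAULT_WINDOW,
    max_snps: int = DEFAULT_MAX_SNPS,
    ld_cutoff: float = DEFAULT_LD_CUTOFF,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows and score them.

    Returns chrom, start, end (1-based inclusive on the window grid),
    n_snps, xpclr_raw and the genome-wide z-score xpclr_norm.
    """
    obj = np.asarray(haps_object)
    ref = np.asarray(haps_reference)
    rows = []
    for chrom in variants.chrom.unique():
        cidx = np.where(variants.chrom.values == chrom)[0]
        pos = variants.pos.values[cidx]
        last = int(pos.max())
        n_windows = (last - 1) // window + 1
        for wi in range(n_windows):
            start = wi * window + 1
            end = start + window - 1
            in_w = cidx[(pos >= start) & (pos <= end)]
            if in_w.size == 0:
                rows.append((chrom, start, end, 0, np.nan))
                continue
            in_w = in_w[_thin_indices(in_w.size, max_snps)]
            wpos = variants.pos.values[in_w]
            ref_h = ref[:, in_w]
            obj_h = obj[:, in_w]
            p_ref = ref_h.mean(axis=0)
            alt_obj = obj_h.sum(axis=0)
            m_alleles = np.full(in_w.size, obj_h.shape[0])
            center = 0.5 * (start + end)
            weights = ld_weights(ref_h, ld_cutoff)
            raw = window_cl_ratio(
                p_ref, alt_obj, m_alleles, np.abs(wpos - center), weights, omega, alpha_grid
            )
            rows.append((chrom, start, end, int(in_w.size), raw))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "xpclr_raw"])
    df["xpclr_norm"] = normalize_scores(df.xpclr_raw.values)
    return df


def call_top_windows(windows: pd.DataFrame, top_fraction: float = DEFAULT_TOP_FRACTION) -> pd.DataFrame:
    """Windows with xpclr_norm at or above the (1 - top_fraction) quantile
    of the finite scores; ties at the quantile are all included."""
    scores = windows.xpclr_norm.values
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("no finite window scores")
    thr = np.quantile(scores[finite], 1.0 - top_fraction)
    return windows[finite & (scores >= thr)].reset_index(drop=True)
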