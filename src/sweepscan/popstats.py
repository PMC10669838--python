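"""Per-SNP and genome-wide allele-frequency statistics.

Implements the Weir & Cockerham (1984) variance-component FST estimator
(per-site theta-hat = a/(a+b+c) and the genome-wide ratio-of-sums
sum(a)/sum(a+b+c)), a two-sided Fisher exact allele test with Bonferroni
correction, observed heterozygosity, Nei gene diversity, an IBS distance
matrix, the exact conditional Hardy-Weinberg test, and the SNP QC filters
(MAF / HWE / missingness).

Genotypes are integer dosage matrices (N individuals x M sites) with values
0/1/2 and -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SiteCounts",
    "site_counts",
    "wc_fst_components",
    "wc_fst_site",
    "genomewide_fst",
    "fisher_allele_test",
    "bonferroni",
    "observed_heterozygosity",
    "gene_diversity",
    "ibs_distance_matrix",
    "hwe_exact_test",
    "apply_filters",
]


@dataclass
class SiteCounts:
    """Per-site, per-population genotype counts; all arrays (M sites x P pops)."""

    pops: list[str]
    n: np.ndarray          # diploids with calls
    hom_ref: np.ndarray
    het: np.ndarray
    hom_alt: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hom_ref + self.het + self.hom_alt == self.n).all():
            raise ValueError("genotype counts must sum to n")

    @property
    def alt_count(self) -> np.ndarray:
        return 2 * self.hom_alt + self.het

    @property
    def alt_freq(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.n > 0, self.alt_count / (2.0 * self.n), np.nan)

    @property
    def usable(self) -> np.ndarray:
        """Sites with >= 2 populations carrying at least one called diploid."""
        return (self.n > 0).sum(axis=1) >= 2


def site_counts(genotypes: dict[str, np.ndarray]) -> SiteCounts:
    """Tally genotype counts per site per population (missing = -1, excluded)."""
    pops = list(genotypes)
    cols = []
    for pop in pops:
        g = np.asarray(genotypes[pop])
        cols.append(
            np.stack(
                [(g == 0).sum(axis=0), (g == 1).sum(axis=0), (g == 2).sum(axis=0)],
                axis=1,
            )
        )
    arr = np.stack(cols, axis=2)  # (M, 3, P)
    hom_ref, het, hom_alt = arr[:, 0, :], arr[:, 1, :], arr[:, 2, :]
    return SiteCounts(pops=pops, n=hom_ref + het + hom_alt, hom_ref=hom_ref, het=het, hom_alt=hom_alt)


def wc_fst_components(counts: SiteCounts) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components per site: (a, a+b+c).

    Sites with fewer than two populations carrying data get NaN in both.
    a is the among-population component, b among individuals within
    populations, c within individuals; theta-hat = a/(a+b+c).
    """
    n = counts.n.astype(float)
    present = n > 0
    r = present.sum(axis=1).astype(float)
    ok = r >= 2

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(present, counts.alt_freq, 0.0)
        h = np.where(present, np.where(n > 0, counts.het / n, 0.0), 0.0)

        n_tot = n.sum(axis=1)
        nbar = n_tot / r
        # n_C = (r*nbar - sum(n_i^2)/(r*nbar)) / (r-1)
        n_c = (n_tot - (n * n).sum(axis=1) / n_tot) / (r - 1.0)
        pbar = (n * p).sum(axis=1) / n_tot
        s2 = (n * (p - pbar[:, None]) ** 2 * present).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=1) / n_tot

        pq = pbar * (1.0 - pbar)
        inner = pq - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / n_c * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (pq - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    denom = a + b + c
    a = np.where(ok, a, np.nan)
    denom = np.where(ok, denom, np.nan)
    return a, denom


def wc_fst_site(counts: SiteCounts) -> np.ndarray:
    """Per-site theta-hat; NaN where undefined (monomorphic across populations,
    or < 2 usable populations). Negative estimates are kept as computed."""
    a, denom = wc_fst_components(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / denom
    theta[np.isclose(denom, 0.0) | ~np.isfinite(denom)] = np.nan
    return theta


def genomewide_fst(counts: SiteCounts) -> float:
    """Ratio-of-sums (weighted) FST: sum(a)/sum(a+b+c) over usable sites."""
    a, denom = wc_fst_components(counts)
    use = np.isfinite(a) & np.isfinite(denom) & ~np.isclose(denom, 0.0)
    if not use.any():
        raise ValueError("no usable polymorphic sites for genome-wide FST")
    return float(a[use].sum() / denom[use].sum())


# -- exact tests -------------------------------------------------------------


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_allele_test(
    alt1: np.ndarray, n1: np.ndarray, alt2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 allele-count tables, vectorized.

    Table rows are (ref, alt) counts of `n1` and `n2` total alleles per
    population. Two-sided by the point-probability rule: p is the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table. Tables
    with a zero margin return p = 1.
    """
    alt1 = np.atleast_1d(np.asarray(alt1, dtype=np.int64))
    alt2 = np.atleast_1d(np.asarray(alt2, dtype=np.int64))
    n1 = np.broadcast_to(np.atleast_1d(np.asarray(n1, dtype=np.int64)), alt1.shape)
    n2 = np.broadcast_to(np.atleast_1d(np.asarray(n2, dtype=np.int64)), alt1.shape)

    K = alt1 + alt2                      # total alt alleles
    N = n1 + n2
    p_out = np.ones(alt1.shape, dtype=float)
    nz = (K > 0) & (K < N) & (n1 > 0) & (n2 > 0)
    if not nz.any():
        return p_out

    # support of X = alt alleles in population 1
    max_n1 = int(n1[nz].max())
    x = np.arange(max_n1 + 1)
    xg = x[None, :]
    n1g, n2g, Kg = n1[nz, None], n2[nz, None], K[nz, None]
    valid = (xg <= n1g) & (xg <= Kg) & (Kg - xg <= n2g)
    with np.errstate(invalid="ignore"):
        logpmf = (
            _log_binom(n1g, xg)
            + _log_binom(n2g, np.where(valid, Kg - xg, 0))
            - _log_binom(n1g + n2g, Kg)
        )
    logpmf = np.where(valid, logpmf, -np.inf)
    log_obs = np.take_along_axis(logpmf, alt1[nz, None], axis=1)
    # tolerance guards against ties lost to rounding (same rule as scipy)
    le_obs = logpmf <= log_obs + 1e-7
    p = np.exp(logpmf, where=np.isfinite(logpmf), out=np.zeros_like(logpmf))
    p_out[nz] = np.minimum((p * le_obs).sum(axis=1), 1.0)
    return p_out


def bonferroni(p: np.ndarray, m: int) -> np.ndarray:
    """p_adj = min(1, m * p); m is the number of SNPs tested in the comparison."""
    if m <= 0:
        raise ValueError("m must be a positive test count")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style).

    p is the total probability, conditional on the allele counts, of all
    heterozygote counts no more probable than the observed one. Degenerate
    inputs (no individuals, or a monomorphic site) return 1 by convention.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = hom_ref + het + hom_alt
    rare = min(2 * hom_ref + het, 2 * hom_alt + het)  # rare-allele copies
    if n == 0 or rare == 0:
        return 1.0

    # probabilities over all het counts with the same parity as `rare`
    het_max = min(rare, 2 * n - rare)
    hets = np.arange(rare % 2, het_max + 1, 2)
    logp = np.empty(hets.shape)
    # log P(het | rare, n) up to a constant: rare-hom count = (rare - het)/2
    common = 2 * n - rare
    for i, h in enumerate(hets):
        rr = (rare - h) // 2
        cc = (common - h) // 2
        logp[i] = (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(rr + 1)
            - gammaln(cc + 1)
            - gammaln(h + 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_test_vec(hom_ref: np.ndarray, het: np.ndarray, hom_alt: np.ndarray) -> np.ndarray:
    """Vectorized wrapper over hwe_exact_test with caching on (rare, het, n)."""
    cache: dict[tuple[int, int, int], float] = {}
    out = np.empty(len(hom_ref))
    for i, (r, h, a) in enumerate(zip(hom_ref, het, hom_alt)):
        key = (int(r), int(h), int(a))
        if key not in cache:
            cache[key] = hwe_exact_test(*key)
        out[i] = cache[key]
    return out


# -- diversity ---------------------------------------------------------------


def observed_heterozygosity(genotypes: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-individual heterozygosity (het calls / non-missing calls) and the
    unweighted population mean; individuals with zero calls are excluded."""
    g = np.asarray(genotypes)
    called = (g >= 0).sum(axis=1)
    hets = (g == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(called > 0, hets / called, np.nan)
    finite = rate[np.isfinite(rate)]
    if finite.size == 0:
        raise ValueError("no individual has a called genotype")
    return rate, float(finite.mean())


def gene_diversity(genotypes: np.ndarray, corrected: bool = True) -> float:
    """Mean Nei gene diversity over usable loci.

    Per biallelic locus with allele frequency p over n called diploids:
    D = 1 - p^2 - q^2, times the small-sample correction 2n/(2n-1) when
    `corrected`. Monomorphic loci contribute 0; loci with no calls are
    dropped. Errors when no locus is usable.
    """
    g = np.asarray(genotypes)
    called = (g >= 0).sum(axis=0)
    usable = called > 0
    if not usable.any():
        raise ValueError("no usable loci")
    alt = np.where(g > 0, g, 0).sum(axis=0)[usable]
    n = called[usable].astype(float)
    p = alt / (2.0 * n)
    d = 1.0 - p**2 - (1.0 - p) ** 2
    if corrected:
        d = d * (2.0 * n) / (2.0 * n - 1.0)
    return float(d.mean())


def ibs_distance_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state distance: 1 - mean(shared alleles)/2.

    Shared alleles per site for dosages gi, gj is 2 - |gi - gj| (so het/het
    counts as 2, opposite homozygotes as 0). Complete-case per pair; a pair
    with zero overlapping calls gets NaN.
    """
    g = np.asarray(genotypes, dtype=np.int16)
    n = g.shape[0]
    dist = np.zeros((n, n))
    miss = g < 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            m = ok.sum()
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
                continue
            shared = (2 - np.abs(g[i, ok] - g[j, ok])).mean()
            dist[i, j] = dist[j, i] = 1.0 - shared / 2.0
    return dist


# -- QC filtering ------------------------------------------------------------


def apply_filters(
    genotypes: np.ndarray,
    maf_min: float = 0.0,
    hwe_alpha: float = 1e-6,
    missing_max: float = 0.1,
) -> tuple[np.ndarray, dict[str, int]]:
    """Site QC over the pooled panel: keep a site iff MAF >= maf_min AND
    HWE exact p >= hwe_alpha AND missingness <= missing_max.

    Returns (boolean keep mask over sites, report). The report attributes each
    removed site to the first failing filter, in the order MAF, HWE,
    missingness.
    """
    g = np.asarray(genotypes)
    n_called = (g >= 0).sum(axis=0)
    n_total = g.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_called > 0, np.where(g > 0, g, 0).sum(axis=0) / (2.0 * n_called), 0.0)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    hom_ref = (g == 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    hom_alt = (g == 2).sum(axis=0)
    hwe_p = hwe_exact_test_vec(hom_ref, het, hom_alt)
    missingness = 1.0 - n_called / n_total

    fail_maf = maf < maf_min
    fail_hwe = ~fail_maf & (hwe_p < hwe_alpha)
    fail_miss = ~fail_maf & ~fail_hwe & (missingness > missing_max)
    keep = ~(fail_maf | fail_hwe | fail_miss)
    report = {
        "n_input": int(g.shape[1]),
        "removed_maf": int(fail_maf.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_missing": int(fail_miss.sum()),
        "n_kept": int(keep.sum()),
    }
    return keep, report
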