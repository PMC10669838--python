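"""Synthetic diverged populations with injected selective sweeps.

The neutral model is Balding-Nichols: an ancestral allele frequency p is
drawn uniformly on (maf_floor, 1 - maf_floor); each population draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) where F is that population's
divergence from the ancestor; haplotype alleles are independent Bernoulli
draws at the population frequency. Under this model the expected pairwise
FST between populations with divergences F_i and F_j is approximately
(F_i + F_j)/2, which is how a pairwise target matrix is mapped to per-
population divergences.

A sweep is injected by homogenizing a fraction of the target population's
haplotypes over the sweep span onto one shared core haplotype (extended
haplotype identity is what XP-EHH detects, so frequency shifts alone would
not do), and re-drawing the remaining haplotypes so the core allele lands
near the requested final frequency at every site in the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import HaplotypeSet, natural_chrom_key, write_popmap, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    target_pop: str
    chrom: str
    center: int
    half_width: int
    final_freq: float = 0.95
    carrier_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.5 < self.final_freq <= 1.0):
            raise ValueError("final_freq must be in (0.5, 1]")
        if not (0.0 < self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must be in (0, 1]")

    @property
    def start(self) -> int:  # 1-based inclusive
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width


@dataclass
class SimConfig:
    n_pops: int = 3
    samples_per_pop: tuple[int, ...] | int = 30
    n_snps: int = 20_000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000})
    fst_matrix: np.ndarray | float = 0.10
    maf_floor: float = 0.05
    sweeps: list[SweepSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    pop_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.samples_per_pop, int):
            self.samples_per_pop = tuple([self.samples_per_pop] * self.n_pops)
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        if np.isscalar(self.fst_matrix):
            f = float(self.fst_matrix)
            m = np.full((self.n_pops, self.n_pops), f)
            np.fill_diagonal(m, 0.0)
            self.fst_matrix = m
        else:
            self.fst_matrix = np.asarray(self.fst_matrix, dtype=float)
        m = self.fst_matrix
        if m.shape != (self.n_pops, self.n_pops):
            raise ValueError("fst_matrix must be n_pops x n_pops")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
            raise ValueError("fst_matrix must be symmetric with a zero diagonal")
        if np.any(m < 0) or np.any(m >= 1):
            raise ValueError("fst_matrix entries must lie in [0, 1)")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.pop_labels is None:
            self.pop_labels = tuple(f"pop{i + 1}" for i in range(self.n_pops))
        if len(self.pop_labels) != self.n_pops:
            raise ValueError("pop_labels length must equal n_pops")
        for sw in self.sweeps:
            if sw.target_pop not in self.pop_labels:
                raise ValueError(f"sweep target {sw.target_pop!r} not a population label")
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep chromosome {sw.chrom!r} not simulated")
            if sw.start < 1 or sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError(
                    f"sweep [{sw.start}, {sw.end}] outside {sw.chrom} "
                    f"(length {self.chrom_lengths[sw.chrom]})"
                )


def per_pop_divergence(fst_matrix: np.ndarray) -> np.ndarray:
    """Least-squares F_i so that (F_i + F_j)/2 approximates the pairwise matrix."""
    k = fst_matrix.shape[0]
    if k == 1:
        return np.zeros(1)
    if k == 2:
        f = fst_matrix[0, 1]
        return np.array([f, f])
    rows, targets = [], []
    for i in range(k):
        for j in range(i + 1, k):
            row = np.zeros(k)
            row[i] = row[j] = 0.5
            rows.append(row)
            targets.append(fst_matrix[i, j])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(targets), rcond=None)
    return np.clip(sol, 0.0, 0.95)


@dataclass
class SimulatedPanel:
    variants: pd.DataFrame  # chrom, pos, ref, alt
    haplotypes: dict[str, HaplotypeSet]
    sweeps: list[SweepSpec]
    config: SimConfig
    missing: dict[str, np.ndarray] = field(default_factory=dict)  # pop -> (N x M) bool
    model_freqs: dict[str, np.ndarray] = field(default_factory=dict)  # pre-sweep Balding-Nichols freqs

    @property
    def popmap(self) -> dict[str, str]:
        return {s: p for p, hs in self.haplotypes.items() for s in hs.samples}

    def genotype_matrix(self, pop: str) -> np.ndarray:
        """(N x M) dosages 0/1/2, -1 where a genotype was masked missing."""
        g = self.haplotypes[pop].genotypes().astype(np.int8)
        if pop in self.missing:
            g = np.where(self.missing[pop], np.int8(-1), g)
        return g


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    if n > length:
        raise ValueError(f"cannot place {n} SNPs on a {length} bp chromosome")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.3) + 16))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    keep = np.sort(rng.choice(pos.size, size=n, replace=False))
    return pos[keep]


def simulate_populations(config: SimConfig) -> SimulatedPanel:
    """Draw the panel: variant table, per-population phased haplotypes, truth sweeps."""
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chrom_lengths, key=natural_chrom_key)
    total_len = sum(config.chrom_lengths.values())

    # allocate SNPs to chromosomes proportionally to length
    alloc = {c: int(round(config.n_snps * config.chrom_lengths[c] / total_len)) for c in chroms}
    drift = config.n_snps - sum(alloc.values())
    alloc[chroms[0]] += drift

    chrom_col, pos_col = [], []
    for c in chroms:
        p = _draw_positions(rng, config.chrom_lengths[c], alloc[c])
        chrom_col.extend([c] * len(p))
        pos_col.extend(p.tolist())
    m = len(pos_col)

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": np.asarray(pos_col, dtype=np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )

    p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)
    divergences = per_pop_divergence(config.fst_matrix)

    haplotypes: dict[str, HaplotypeSet] = {}
    pop_freqs: dict[str, np.ndarray] = {}
    for label, n_dip, F in zip(config.pop_labels, config.samples_per_pop, divergences):
        if F <= 0:
            freq = p_anc.copy()
        else:
            shape = (1.0 - F) / F
            freq = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        pop_freqs[label] = freq
        haps = (rng.random((2 * n_dip, m)) < freq).astype(np.uint8)
        samples = [f"{label}_s{i + 1:03d}" for i in range(n_dip)]
        haplotypes[label] = HaplotypeSet(haps, samples)

    for sw in config.sweeps:
        _inject_sweep(rng, variants, haplotypes[sw.target_pop].alleles, sw)

    missing: dict[str, np.ndarray] = {}
    if config.missing_rate > 0:
        # masks genotype calls for QC-filter testing; the phased haplotype
        # panel itself stays complete (haplotype statistics need full data)
        for label, n_dip in zip(config.pop_labels, config.samples_per_pop):
            missing[label] = rng.random((n_dip, m)) < config.missing_rate

    return SimulatedPanel(
        variants=variants,
        haplotypes=haplotypes,
        sweeps=list(config.sweeps),
        config=config,
        missing=missing,
        model_freqs=pop_freqs,
    )


def _inject_sweep(rng: np.random.Generator, variants: pd.DataFrame, haps: np.ndarray, sw: SweepSpec) -> None:
    in_span = (
        (variants.chrom.values == sw.chrom)
        & (variants.pos.values >= sw.start)
        & (variants.pos.values <= sw.end)
    )
    cols = np.where(in_span)[0]
    if cols.size == 0:
        return
    n_hap = haps.shape[0]
    n_car = max(1, int(round(sw.carrier_fraction * n_hap)))
    carriers = rng.choice(n_hap, size=n_car, replace=False)
    core = (rng.random(cols.size) < 0.5).astype(np.uint8)  # core allele per site

    # non-carrier core-allele frequency q' solving cf + (1-cf) q' = final_freq
    cf = n_car / n_hap
    q_rest = 0.0 if cf >= 1.0 else float(np.clip((sw.final_freq - cf) / (1.0 - cf), 0.0, 1.0))

    non_carriers = np.setdiff1d(np.arange(n_hap), carriers)
    block = haps[:, cols]
    block[carriers[:, None], np.arange(cols.size)] = core
    if non_carriers.size:
        draw = rng.random((non_carriers.size, cols.size)) < q_rest
        block[non_carriers[:, None], np.arange(cols.size)] = np.where(draw, core, 1 - core)
    haps[:, cols] = block


def write_truth_bed(path, sweeps: list[SweepSpec]) -> None:
    """Truth intervals as 0-based half-open BED, sorted by chromosome then start."""
    rows = sorted(sweeps, key=lambda s: (natural_chrom_key(s.chrom), s.start))
    with open(path, "w") as fh:
        fh.write("# sweepscan truth sweep intervals (0-based half-open)\n")
        for sw in rows:
            fh.write(f"{sw.chrom}\t{sw.start - 1}\t{sw.end}\t{sw.target_pop}\n")


def write_panel(panel: SimulatedPanel, out_prefix: str) -> dict[str, str]:
    """Write VCF + popmap + truth BED; returns the paths written."""
    paths = {
        "vcf": f"{out_prefix}.vcf",
        "popmap": f"{out_prefix}.popmap.tsv",
        "truth": f"{out_prefix}.truth.bed",
    }
    write_vcf(paths["vcf"], panel.variants, panel.haplotypes)
    write_popmap(paths["popmap"], panel.popmap)
    write_truth_bed(paths["truth"], panel.sweeps)
    return paths


def read_config_file(path) -> SimConfig:
    """Flat key = value simulation config (see docs/methods.md for keys)."""
    kv: dict[str, str] = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        kv[k.strip()] = v.strip()
    n_pops = int(kv.get("n_pops", 3))
    chrom_lengths = {}
    for part in kv.get("chrom_lengths", "chr1:5000000").split(","):
        name, _, ln = part.partition(":")
        chrom_lengths[name.strip()] = int(ln)
    sweeps = []
    for part in kv.get("sweeps", "").split(";"):
        part = part.strip()
        if not part:
            continue
        f = dict(x.split(":", 1) for x in part.split(","))
        sweeps.append(
            SweepSpec(
                target_pop=f["pop"],
                chrom=f["chrom"],
                center=int(f["center"]),
                half_width=int(f["half_width"]),
                final_freq=float(f.get("final_freq", 0.95)),
                carrier_fraction=float(f.get("carrier_fraction", 0.9)),
            )
        )
    return SimConfig(
        n_pops=n_pops,
        samples_per_pop=int(kv.get("samples_per_pop", 30)),
        n_snps=int(kv.get("n_snps", 20000)),
        chrom_lengths=chrom_lengths,
        fst_matrix=float(kv.get("fst", 0.10)),
        maf_floor=float(kv.get("maf_floor", 0.05)),
        sweeps=sweeps,
        pop_labels=tuple(kv["pop_labels"].split(",")) if "pop_labels" in kv else None,
        seed=int(kv.get("seed", 0)),
    )
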