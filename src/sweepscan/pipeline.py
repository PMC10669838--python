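"""End-to-end orchestration: stats -> scans -> regions -> genes -> report.

Every stage is deterministic given its inputs; the only randomness in the
package lives in the simulator. A run writes, per comparison: the per-SNP
score table (FST, Fisher raw/adjusted p, raw/normalized XP-EHH, tier),
the XP-CLR window table, per-method region TSV+BED, gene sets (TSV + JSON),
plus a run manifest and a human-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genio, geneset, haploscan, popstats, regioncall, xpclrscan

log = logging.getLogger("sweepscan")


@dataclass
class Comparison:
    label: str
    object_pop: str      # the population whose sweep raises XP-EHH / XP-CLR
    reference_pop: str


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    out_dir: str
    comparisons: list[Comparison]
    gff3: str | None = None
    merge_groups: dict[str, str] = field(default_factory=dict)
    # thresholds (defaults are the pipeline's published operating point)
    extreme_fst_quantile: float = regioncall.EXTREME_FST_QUANTILE
    extreme_xpehh_quantile: float = regioncall.EXTREME_XPEHH_QUANTILE
    sig_fst_min: float = regioncall.SIG_FST_MIN
    sig_xpehh_min: float = regioncall.SIG_XPEHH_MIN
    adj_p_max: float = regioncall.ADJ_P_MAX
    window: int = xpclrscan.DEFAULT_WINDOW
    max_snps: int = xpclrscan.DEFAULT_MAX_SNPS
    ld_cutoff: float = xpclrscan.DEFAULT_LD_CUTOFF
    top_fraction: float = xpclrscan.DEFAULT_TOP_FRACTION
    ehh_cutoff: float = haploscan.DEFAULT_CUTOFF
    max_gap: int = haploscan.DEFAULT_MAX_GAP
    seed: int = 0

    def thresholds(self) -> dict:
        d = asdict(self)
        for k in ("vcf", "popmap", "out_dir", "comparisons", "gff3", "merge_groups"):
            d.pop(k)
        return d


@dataclass
class ComparisonResult:
    label: str
    scores: pd.DataFrame
    windows: pd.DataFrame
    regions: dict[str, list[regioncall.SelectedRegion]]
    gene_sets: geneset.MethodGeneSets | None
    genomewide_fst: float


@dataclass
class RunResult:
    config: RunConfig
    variants: pd.DataFrame
    populations: list[str]
    diversity: pd.DataFrame     # per population: obs het, gene diversity
    pairwise_fst: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    overlap_genes: set[str] | None


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    popmap = genio.read_popmap(cfg.popmap)
    variants, hapsets = genio.read_vcf(cfg.vcf, popmap, merge_groups=cfg.merge_groups)
    pops = sorted(hapsets)
    log.info("loaded %d SNPs, populations: %s", len(variants), ", ".join(pops))
    genotypes = {p: hapsets[p].genotypes() for p in pops}
    meta_base = {"sweepscan_version": __version__, **cfg.thresholds()}

    # population diversity table
    div_rows = []
    for p in pops:
        _, het = popstats.observed_heterozygosity(genotypes[p])
        div_rows.append(
            {
                "population": p,
                "n_samples": hapsets[p].n_samples,
                "observed_het": het,
                "gene_diversity": popstats.gene_diversity(genotypes[p]),
            }
        )
    diversity = pd.DataFrame(div_rows)

    # pairwise genome-wide FST
    fst_rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            counts = popstats.site_counts({a: genotypes[a], b: genotypes[b]})
            fst_rows.append({"pop_a": a, "pop_b": b, "fst": popstats.genomewide_fst(counts)})
    pairwise = pd.DataFrame(fst_rows)

    genio.write_score_table(out / "diversity.tsv", diversity, meta_base)
    genio.write_score_table(out / "pairwise_fst.tsv", pairwise, meta_base)

    results: dict[str, ComparisonResult] = {}
    genes = genio.read_gff3(cfg.gff3) if cfg.gff3 else None
    for comp in cfg.comparisons:
        for p in (comp.object_pop, comp.reference_pop):
            if p not in hapsets:
                raise ValueError(f"comparison {comp.label}: unknown population {p!r}")
        results[comp.label] = _run_comparison(
            cfg, comp, variants, hapsets, genotypes, genes, out, meta_base
        )

    overlap = None
    if genes is not None and len(cfg.comparisons) >= 2:
        labels = [c.label for c in cfg.comparisons[:2]]
        overlap = geneset.cross_comparison_overlap(
            results[labels[0]].gene_sets.final, results[labels[1]].gene_sets.final
        )
        with open(out / "overlap_genes.json", "w") as fh:
            json.dump({"comparisons": labels, "overlap": sorted(overlap)}, fh, indent=1)

    result = RunResult(
        config=cfg,
        variants=variants,
        populations=pops,
        diversity=diversity,
        pairwise_fst=pairwise,
        comparisons=results,
        overlap_genes=overlap,
    )

    manifest = {
        "sweepscan_version": __version__,
        "parameters": cfg.thresholds(),
        "inputs": {
            "vcf": {"path": str(cfg.vcf), "sha256": _sha256(cfg.vcf)},
            "popmap": {"path": str(cfg.popmap), "sha256": _sha256(cfg.popmap)},
            **(
                {"gff3": {"path": str(cfg.gff3), "sha256": _sha256(cfg.gff3)}}
                if cfg.gff3
                else {}
            ),
        },
        "n_snps": int(len(variants)),
        "populations": pops,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    (out / "report.md").write_text(report(result))
    return result


def _run_comparison(cfg, comp, variants, hapsets, genotypes, genes, out: Path, meta_base) -> ComparisonResult:
    a, b = comp.object_pop, comp.reference_pop
    log.info("comparison %s: object=%s reference=%s", comp.label, a, b)
    counts = popstats.site_counts({a: genotypes[a], b: genotypes[b]})
    theta = popstats.wc_fst_site(counts)
    gw_fst = popstats.genomewide_fst(counts)

    ia, ib = counts.pops.index(a), counts.pops.index(b)
    fisher_p = popstats.fisher_allele_test(
        counts.alt_count[:, ia], 2 * counts.n[:, ia],
        counts.alt_count[:, ib], 2 * counts.n[:, ib],
    )
    p_adj = popstats.bonferroni(fisher_p, m=len(variants))

    xp = haploscan.xpehh_scan(
        variants,
        hapsets[a].alleles,
        hapsets[b].alleles,
        cutoff=cfg.ehh_cutoff,
        max_gap=cfg.max_gap,
        phased=hapsets[a].phased and hapsets[b].phased,
    )
    xp["xpehh_norm"] = haploscan.normalize_scores(xp.xpehh_raw.values)

    scores = pd.DataFrame(
        {
            "chrom": variants.chrom.values,
            "pos": variants.pos.values,
            "fst": theta,
            "fisher_p": fisher_p,
            "fisher_p_adj": p_adj,
            "ihh_a": xp.ihh_a.values,
            "ihh_b": xp.ihh_b.values,
            "xpehh_raw": xp.xpehh_raw.values,
            "xpehh_norm": xp.xpehh_norm.values,
        }
    )
    tiers = {m: regioncall.classify_snps(scores, m) for m in ("fst", "xpehh")}
    scores["tier_fst"] = tiers["fst"]
    scores["tier_xpehh"] = tiers["xpehh"]

    omega = xpclrscan.estimate_omega(gw_fst)
    windows = xpclrscan.scan_windows(
        variants,
        hapsets[a].alleles,
        hapsets[b].alleles,
        omega=omega,
        window=cfg.window,
        max_snps=cfg.max_snps,
        ld_cutoff=cfg.ld_cutoff,
    )
    called = xpclrscan.call_top_windows(windows, cfg.top_fraction)

    regions = {
        m: regioncall.grow_regions(scores.pos.values, tiers[m], scores.chrom.values, m)
        for m in ("fst", "xpehh")
    }
    regions["xpclr"] = regioncall.regions_from_windows(called)

    meta = {**meta_base, "comparison": comp.label, "object": a, "reference": b,
            "genomewide_fst": f"{gw_fst:.6f}", "omega": f"{omega:.6f}"}
    genio.write_score_table(out / f"{comp.label}.scores.tsv", scores, meta)
    genio.write_score_table(out / f"{comp.label}.xpclr_windows.tsv", windows, meta)
    all_regions = [r for m in ("fst", "xpehh", "xpclr") for r in regions[m]]
    genio.write_score_table(
        out / f"{comp.label}.regions.tsv", regioncall.regions_to_frame(all_regions), meta
    )
    genio.write_bed(
        out / f"{comp.label}.regions.bed",
        [(r.chrom, r.start, r.end, r.method) for r in all_regions],
        header_comment=f"selected regions, comparison {comp.label}",
    )

    gene_sets = None
    if genes is not None:
        gene_sets = geneset.method_gene_sets(comp.label, regions, genes)
        payload = {
            "comparison": comp.label,
            "per_method": {m: sorted(s) for m, s in gene_sets.per_method.items()},
            "final_candidates": sorted(gene_sets.final),
        }
        with open(out / f"{comp.label}.genes.json", "w") as fh:
            json.dump(payload, fh, indent=1)

    return ComparisonResult(
        label=comp.label,
        scores=scores,
        windows=windows,
        regions=regions,
        gene_sets=gene_sets,
        genomewide_fst=gw_fst,
    )


def report(result: RunResult) -> str:
    """Human-readable run summary; every number is re-derivable from the TSVs."""
    lines = [f"# sweepscan run report (v{__version__})", ""]
    lines.append("## Populations")
    for _, row in result.diversity.iterrows():
        lines.append(
            f"- {row.population}: n={row.n_samples}, observed heterozygosity="
            f"{row.observed_het:.4f}, gene diversity={row.gene_diversity:.4f}"
        )
    lines.append("")
    lines.append("## Pairwise genome-wide FST (ratio of sums)")
    for _, row in result.pairwise_fst.iterrows():
        lines.append(f"- {row.pop_a} vs {row.pop_b}: FST = {row.fst:.4f}")
    lines.append("")
    for label, comp in result.comparisons.items():
        lines.append(f"## Comparison {label}")
        lines.append(f"- genome-wide FST: {comp.genomewide_fst:.4f}")
        for m in ("fst", "xpehh"):
            t = comp.scores[f"tier_{m}"].values
            lines.append(
                f"- {m} tiers: {int((t == 'E').sum())} extreme, "
                f"{int((t == 'S').sum())} significant"
            )
        for m in ("fst", "xpehh", "xpclr"):
            n = len(comp.regions[m])
            lines.append(f"- {m}: {n} region{'s' if n != 1 else ''}")
        if comp.gene_sets is not None:
            for m, s in comp.gene_sets.per_method.items():
                lines.append(f"- genes ({m}): {len(s)}")
            lines.append(f"- final candidate genes (>=2 methods): {len(comp.gene_sets.final)}")
        lines.append("")
    if result.overlap_genes is not None:
        lines.append(f"## Cross-comparison overlap: {len(result.overlap_genes)} genes")
        lines.append("")
    return "\n".join(lines)
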