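"""Gene annotation of selected regions and the multi-method candidate sets.

A gene is assigned to a region iff its gene body [start, end] overlaps the
region interval by at least one base pair (both intervals 1-based
inclusive); no promoter or flank extension is applied by default. Per
comparison, the final candidate set is the genes found by at least two of
the three methods (FST, XP-EHH, XP-CLR); the cross-comparison overlap is a
plain set intersection of two final sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import GeneModel
from .regioncall import SelectedRegion


@dataclass
class MethodGeneSets:
    comparison: str
    per_method: dict[str, set[str]] = field(default_factory=dict)

    @property
    def final(self) -> set[str]:
        """Genes present in at least two method sets."""
        counts: dict[str, int] = {}
        for genes in self.per_method.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return {g for g, c in counts.items() if c >= 2}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.per_method.values():
            out |= genes
        return out


def annotate_regions(
    regions: list[SelectedRegion], genes: list[GeneModel], flank: int = 0
) -> list[list[GeneModel]]:
    """Per-region lists of overlapping genes (gene-body overlap, >=1 bp).

    Errors if no chromosome name is shared between the two inputs (a naming
    mismatch would otherwise silently annotate nothing).
    """
    if regions and genes:
        rchroms = {r.chrom for r in regions}
        gchroms = {g.chrom for g in genes}
        if not rchroms & gchroms:
            raise ValueError(
                f"no shared chromosome names: regions use {sorted(rchroms)[:3]}, "
                f"annotation uses {sorted(gchroms)[:3]}"
            )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts = {c: np.array([g.start for g in gs]) for c, gs in by_chrom.items()}
    ends = {c: np.array([g.end for g in gs]) for c, gs in by_chrom.items()}

    out: list[list[GeneModel]] = []
    for r in regions:
        gs = by_chrom.get(r.chrom, [])
        if not gs:
            out.append([])
            continue
        hit = (starts[r.chrom] <= r.end + flank) & (ends[r.chrom] >= r.start - flank)
        out.append([gs[i] for i in np.where(hit)[0]])
    return out


def method_gene_sets(
    comparison: str,
    regions_by_method: dict[str, list[SelectedRegion]],
    genes: list[GeneModel],
    flank: int = 0,
) -> MethodGeneSets:
    """Unique gene-id sets per method and the >=2-of-methods final set."""
    sets = MethodGeneSets(comparison=comparison)
    for method, regions in regions_by_method.items():
        hits = annotate_regions(regions, genes, flank=flank)
        sets.per_method[method] = {g.gene_id for lst in hits for g in lst}
    return sets


def cross_comparison_overlap(final_a: set[str], final_b: set[str]) -> set[str]:
    """Genes selected in both comparisons."""
    return set(final_a) & set(final_b)
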