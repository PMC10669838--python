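"""Readers and writers for the external formats the pipeline touches.

One coordinate convention holds throughout the package: positions are
1-based inclusive (the native VCF/GFF3 convention). BED output is converted
to 0-based half-open at the writing boundary only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("sweepscan")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class HaplotypeSet:
    """Phased alleles for one population: (2N haplotypes x M sites) in {0,1}."""

    alleles: np.ndarray
    samples: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] % 2:
            raise ValueError("allele matrix must be 2-D with an even row count")
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise ValueError("row count must equal 2 x number of samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> np.ndarray:
        """(N x M) diploid dosages 0/1/2 (no missing data in phased sets)."""
        return (self.alleles[0::2].astype(np.int8) + self.alleles[1::2]).astype(np.int8)


@dataclass
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def natural_chrom_key(chrom: str):
    """Sort key: numeric chromosome names numerically, others after, lexicographic."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), chrom)
    return (1, 0, chrom)


def read_popmap(path) -> dict[str, str]:
    """TSV with columns sample_id, population (header optional)."""
    popmap: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"popmap line with <2 columns: {line!r}")
        if parts[0].lower() in {"sample_id", "sample"}:
            continue
        popmap[parts[0]] = parts[1]
    if not popmap:
        raise FormatError("empty population map")
    return popmap


def apply_merge_groups(popmap: dict[str, str], merge_groups: dict[str, str] | None) -> dict[str, str]:
    """Relabel populations, e.g. {'BRA': 'BRs', 'BRB': 'BRs'}."""
    if not merge_groups:
        return dict(popmap)
    return {s: merge_groups.get(p, p) for s, p in popmap.items()}


def read_vcf(
    path,
    popmap: dict[str, str],
    merge_groups: dict[str, str] | None = None,
    allow_unphased: bool = False,
    include_chroms: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, HaplotypeSet]]:
    """Load biallelic SNPs from a phased VCF into per-population haplotype sets.

    Multiallelic and non-SNP records are dropped (count logged). Returns the
    variant table (chrom, pos, ref, alt; sorted by natural chromosome order
    then position) and a dict population -> HaplotypeSet.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in popmap]
    if unknown:
        raise FormatError(f"samples absent from population map: {unknown[:5]}")
    popmap = apply_merge_groups(popmap, merge_groups)
    pops = sorted(set(popmap[s] for s in samples))
    sample_pop = np.array([popmap[s] for s in samples])

    records = []
    hap_rows = []
    n_dropped = 0
    for v in vcf:
        if include_chroms is not None and v.CHROM not in include_chroms:
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        if not allow_unphased and not all(g[2] for g in gts):
            raise FormatError(
                f"unphased genotype at {v.CHROM}:{v.POS}; pass allow_unphased to accept"
            )
        row = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            row[2 * i] = g[0]
            row[2 * i + 1] = g[1]
        records.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        hap_rows.append(row)
    if n_dropped:
        log.info("dropped %d multiallelic/non-SNP records", n_dropped)
    if not records:
        raise FormatError("no usable biallelic SNP records in VCF")

    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    haps_all = np.stack(hap_rows, axis=1)  # (2*n_samples, M)
    order = sorted(
        range(len(variants)),
        key=lambda i: (natural_chrom_key(variants.chrom.iloc[i]), variants.pos.iloc[i]),
    )
    variants = variants.iloc[order].reset_index(drop=True)
    haps_all = haps_all[:, order]

    phased = not allow_unphased
    hapsets: dict[str, HaplotypeSet] = {}
    for pop in pops:
        idx = np.where(sample_pop == pop)[0]
        rows = np.sort(np.concatenate([2 * idx, 2 * idx + 1]))
        mat = haps_all[rows]
        if (mat < 0).any():
            if not allow_unphased:
                raise FormatError("missing genotype in phased VCF")
            mat = mat.copy()
        hapsets[pop] = HaplotypeSet(
            np.clip(mat, 0, 1).astype(np.uint8),
            [samples[i] for i in idx],
            phased=phased,
        )
    return variants, hapsets


def write_vcf(path, variants: pd.DataFrame, hapsets: dict[str, HaplotypeSet]) -> None:
    """Write a minimal phased VCF v4.2 (GT-only) for the given panel."""
    pops = sorted(hapsets)
    sample_names = [s for p in pops for s in hapsets[p].samples]
    chroms = sorted(variants.chrom.unique(), key=natural_chrom_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in chroms:
            end = int(variants.loc[variants.chrom == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={end + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        mats = [hapsets[p].alleles for p in pops]
        for j in range(len(variants)):
            row = variants.iloc[j]
            gts = []
            for mat in mats:
                col = mat[:, j]
                gts.extend(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(col) // 2))
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_popmap(path, popmap: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in popmap.items():
            fh.write(f"{s}\t{p}\n")


# -- GFF3 ------------------------------------------------------------------

_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def read_gff3(path) -> list[GeneModel]:
    """Extract gene-type features from a GFF3 file.

    Only ``type == gene`` rows are kept. The display name falls back through
    Name= -> gene_id= -> ID=. Malformed rows are skipped with a log message
    rather than aborting, so a partially damaged annotation remains usable.
    """
    genes: list[GeneModel] = []
    n_bad = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            n_bad += 1
            log.warning("gff3 line %d: %d columns, skipped", lineno, len(parts))
            continue
        if parts[2] != "gene":
            continue
        try:
            start, end = int(parts[3]), int(parts[4])
            attrs = dict(_ATTR_RE.findall(parts[8]))
            raw_id = attrs.get("ID") or attrs.get("gene_id")
            if not raw_id:
                raise ValueError("no ID/gene_id attribute")
            gene_id = raw_id.removeprefix("gene:")
            name = attrs.get("Name") or attrs.get("gene_id") or gene_id
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    name=name,
                    chrom=parts[0],
                    start=start,
                    end=end,
                    strand=parts[6] if parts[6] in "+-." else ".",
                )
            )
        except (ValueError, KeyError) as exc:
            n_bad += 1
            log.warning("gff3 line %d malformed (%s), skipped", lineno, exc)
    if n_bad:
        log.info("skipped %d malformed gff3 lines", n_bad)
    return genes


# -- score tables ----------------------------------------------------------


def write_score_table(path, table: pd.DataFrame, meta: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata header lines; floats at 10 sig digits."""
    with open(path, "w") as fh:
        fh.write("# sweepscan score table\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_score_table(path, expect_columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], dtype={"chrom": str})
    if expect_columns is not None and list(df.columns) != list(expect_columns):
        raise FormatError(
            f"score table header mismatch: got {list(df.columns)}, want {expect_columns}"
        )
    return df


def write_bed(path, intervals, header_comment: str | None = None) -> None:
    """Write (chrom, start_1based, end_1based) intervals as 0-based half-open BED."""
    rows = sorted(intervals, key=lambda r: (natural_chrom_key(r[0]), r[1]))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for chrom, start, end, *rest in rows:
            extra = ("\t" + "\t".join(str(x) for x in rest)) if rest else ""
            fh.write(f"{chrom}\t{start - 1}\t{end}{extra}\n")
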