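"""Readers and writers for the formats the pipeline touches.

VCF 4.2 subset (biallelic SNPs, GT genotypes, a single SRC INFO key for
evidence tags), BED3 regions, and fixed-header TSV tables for genome
layouts, allele counts, marker sets and dosage loci. Readers validate and
reject rather than silently coerce; writers emit sorted, deterministic
output so files diff cleanly. VCF positions are 1-based; BED intervals are
0-based half-open; that convention carries through to the in-memory
containers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .core import (
    AlleleCountTable,
    GenomeLayout,
    MarkerSet,
    RegionSet,
    ValidationError,
    VariantSet,
)
from .dosage import LocusSpec

logger = logging.getLogger(__name__)

_BASES = set("ACGT")


# ---------------------------------------------------------------------------
# Genome layout TSV
# ---------------------------------------------------------------------------

def read_layout(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["chrom", "length"]:
        raise ValidationError(f"layout file needs header 'chrom\\tlength', got {list(df.columns)}")
    return GenomeLayout.from_frame(df)


def write_layout(layout: GenomeLayout, path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, genotype_policy: str = "require",
             layout: GenomeLayout | None = None) -> VariantSet:
    """Read a VCF into a VariantSet.

    Multiallelic and non-SNP records are skipped (count logged and stored on
    the returned set as ``n_skipped``), as are homozygous-reference and
    missing genotypes. ``genotype_policy``:

    * ``require`` - a GT field is mandatory; error if the file has no sample.
    * ``assume_hom_alt`` - no sample column needed; every record is taken as
      homozygous-alt (assembly-vs-reference call sets).
    """
    if genotype_policy not in ("require", "assume_hom_alt"):
        raise ValidationError(f"unknown genotype policy {genotype_policy!r}")
    vcf = VCF(str(path))
    has_sample = len(vcf.samples) > 0
    if genotype_policy == "require" and not has_sample:
        raise ValidationError(f"{path}: no sample column but genotype policy requires GT")
    rows = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        if rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        if genotype_policy == "assume_hom_alt":
            gclass = "hom_alt"
        else:
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = rec.gt_types[0]
            if gt == 1:
                gclass = "het"
            elif gt == 3:
                gclass = "hom_alt"
            else:
                n_skipped += 1
                continue
        src = rec.INFO.get("SRC") or ""
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], gclass, src))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf %s: skipped %d records (non-SNP/multiallelic/no alt evidence)",
                    path, n_skipped)
    vs = VariantSet(pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                                "genotype_class", "evidence"]),
                    layout=layout)
    vs.n_skipped = n_skipped
    return vs


def write_vcf(variants: VariantSet, path, layout: GenomeLayout | None = None,
              sample_name: str = "SAMPLE") -> None:
    """Write a VariantSet as a minimal VCF 4.2 with one sample carrying GT.

    Evidence tags travel in the SRC INFO key (comma-joined).
    """
    layout = layout or variants.layout
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SRC,Number=1,Type=String,Description="Evidence source tags">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if layout is not None:
            for chrom, length in layout.chromosomes:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for _, r in variants.df.iterrows():
            info = f"SRC={r['evidence']}" if r["evidence"] else "."
            gt = "1/1" if r["genotype_class"] == "hom_alt" else "0/1"
            fh.write(f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
                     f"{info}\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, layout: GenomeLayout | None = None) -> RegionSet:
    """Read a 3+ column BED (0-based half-open). Empty files yield an empty set."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{line_no}: BED needs >= 3 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), layout=layout)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.df.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")


# ---------------------------------------------------------------------------
# Allele count TSV
# ---------------------------------------------------------------------------

_COUNT_COLS = ["sample", "chrom", "pos", "ref_count", "alt_count"]


def read_counts(path) -> AlleleCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    if list(df.columns) != _COUNT_COLS:
        raise ValidationError(
            f"counts file needs header {_COUNT_COLS}, got {list(df.columns)}")
    return AlleleCountTable(df)


def write_counts(counts: AlleleCountTable, path) -> None:
    counts.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker TSV
# ---------------------------------------------------------------------------

_MARKER_COLS = ["haplotype", "chrom", "pos", "diagnostic_allele"]


def read_markers(path, reference_id: str | None = None,
                 layout: GenomeLayout | None = None) -> MarkerSet:
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str, "chrom": str})
    if list(df.columns) != _MARKER_COLS:
        raise ValidationError(
            f"marker file needs header {_MARKER_COLS}, got {list(df.columns)}")
    return MarkerSet.from_frame(df, reference_id=reference_id, layout=layout)


def write_markers(markers: MarkerSet, path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dosage locus TSV (long format: one row per haplotype carrier status)
# ---------------------------------------------------------------------------

_LOCUS_COLS = ["locus_id", "chrom", "start", "end", "haplotype", "carrier"]


def read_loci(path, markers: MarkerSet | None = None) -> list[LocusSpec]:
    """Read locus definitions; when a MarkerSet is given, each locus picks up
    the diagnostic markers of its carrier haplotypes inside the interval."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str,
                                            "haplotype": str})
    if list(df.columns) != _LOCUS_COLS:
        raise ValidationError(f"locus file needs header {_LOCUS_COLS}, got {list(df.columns)}")
    loci = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        chrom = grp["chrom"].iloc[0]
        start, end = int(grp["start"].iloc[0]), int(grp["end"].iloc[0])
        carriers = dict(zip(grp["haplotype"], grp["carrier"].astype(int)))
        marker_list: tuple = ()
        if markers is not None:
            pairs = []
            for hap, carrier in carriers.items():
                if carrier and hap in markers.haplotypes:
                    mdf = markers[hap]
                    sel = mdf[(mdf["chrom"] == chrom) & (mdf["pos"] > start) &
                              (mdf["pos"] <= end)]
                    pairs.extend(zip(sel["pos"].astype(int), sel["diagnostic_allele"]))
            marker_list = tuple(sorted(set(pairs)))
        loci.append(LocusSpec(locus_id=str(locus_id), chrom=chrom, start=start,
                              end=end, carriers=carriers, markers=marker_list))
    return loci


def write_loci(loci: list[LocusSpec], path) -> None:
    rows = []
    for loc in loci:
        for hap, carrier in loc.carriers.items():
            rows.append((loc.locus_id, loc.chrom, loc.start, loc.end, hap, carrier))
    pd.DataFrame(rows, columns=_LOCUS_COLS).to_csv(path, sep="\t", index=False)
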