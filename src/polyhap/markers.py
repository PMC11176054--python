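"""Set-algebraic derivation of haplotype-unique SNP markers.

Two-haplotype designs (one inbred genome against the reference) keep
homozygous dual-evidence SNPs of the target that match no SNP seen in the
reference genome's own data. Four-haplotype designs additionally split the
second hybrid into its two assembly haplotypes via heterozygous read SNPs,
and diagnose the reference haplotype at positions where every other genome
is homozygous-alt (reference-supporting reads then indicate presence).

All subtraction steps are position-level, not allele-level: a position seen
in any blocking set is removed regardless of which alternate allele it
carries, so no ambiguous markers remain.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .core import GenomeLayout, MarkerSet, RegionSet, ValidationError, VariantSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Primitive set operations
# ---------------------------------------------------------------------------

def intersect_evidence(a: VariantSet, b: VariantSet) -> VariantSet:
    """Records present in both sets by (chrom, pos, alt) with agreeing genotype.

    Sites found in both but with conflicting genotype class are dropped (and
    counted in the log): conflicting evidence is no evidence. Evidence tags
    of both inputs are merged.
    """
    merged = a.df.merge(b.df, on=["chrom", "pos", "ref", "alt"], how="inner",
                        suffixes=("_a", "_b"))
    agree = merged["genotype_class_a"] == merged["genotype_class_b"]
    n_conflict = int((~agree).sum())
    if n_conflict:
        logger.info("intersect_evidence: dropped %d sites with conflicting genotype class",
                    n_conflict)
    merged = merged[agree]
    tags = merged.apply(
        lambda r: ",".join(sorted({t for t in (r["evidence_a"].split(",") +
                                               r["evidence_b"].split(",")) if t})),
        axis=1) if len(merged) else pd.Series([], dtype=str)
    out = merged[["chrom", "pos", "ref", "alt"]].copy()
    out["genotype_class"] = merged["genotype_class_a"]
    out["evidence"] = tags
    return VariantSet(out, layout=a.layout or b.layout)


def subtract_overlaps(target: VariantSet, blockers: list[VariantSet]) -> VariantSet:
    """Remove target records whose position occurs in any blocker set.

    Position-level exclusion: the blocking allele is irrelevant.
    """
    if not blockers:
        return target
    block = pd.concat([b.df[["chrom", "pos"]] for b in blockers], ignore_index=True)
    block = block.drop_duplicates()
    keep = target.df.merge(block.assign(_blocked=True), on=["chrom", "pos"], how="left")
    out = target.df[keep["_blocked"].isna().to_numpy()]
    return VariantSet(out.reset_index(drop=True), layout=target.layout)


def _match_alleles(a: VariantSet, b: VariantSet) -> pd.DataFrame:
    """Rows of `a` whose (chrom, pos, alt) also occur in `b`."""
    key = b.df[["chrom", "pos", "alt"]].drop_duplicates()
    return a.df.merge(key, on=["chrom", "pos", "alt"], how="inner")


# ---------------------------------------------------------------------------
# Two-way markers
# ---------------------------------------------------------------------------

def derive_two_way_markers(target_dual_evidence: VariantSet,
                           reference_genome_snps: VariantSet,
                           haplotype_id: str,
                           exclusion: RegionSet | None = None,
                           layout: GenomeLayout | None = None) -> MarkerSet:
    """Markers unique to one non-reference genome in a two-haplotype design.

    ``target_dual_evidence`` should already be the intersection of the two
    evidence call sets (see :func:`intersect_evidence`); only its homozygous
    records survive, minus any position reported during the reference
    genome's own data alignment. The diagnostic allele is always alt.
    """
    hom = target_dual_evidence.hom_alt()
    clean = subtract_overlaps(hom, [reference_genome_snps])
    df = clean.df[["chrom", "pos"]].assign(diagnostic_allele="alt")
    markers = MarkerSet({haplotype_id: df}, layout=layout or target_dual_evidence.layout)
    if exclusion is not None and len(exclusion):
        markers = apply_exclusion(markers, exclusion)
    return markers


# ---------------------------------------------------------------------------
# Four-way markers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FourWayInputs:
    """Inputs for the four-haplotype marker derivation.

    One designated reference haplotype, one non-reference inbred genome, and
    the two assembly haplotypes of the second hybrid, all in reference
    coordinates:

    * ``assembly_snps`` - per hybrid haplotype, assembly-vs-reference SNPs;
    * ``hybrid_reads`` - read-based SNP calls of the hybrid (het/hom classes);
    * ``inbred_reads`` - dual-evidence (pre-intersected) calls of the inbred;
    * ``reference_reads`` - residual SNPs from aligning the reference
      genome's own data (noise positions to exclude);
    * ``exclusion`` - regions masked from all marker lists (introgression).
    """

    reference_id: str
    inbred_id: str
    hybrid_hap_ids: tuple[str, str]
    assembly_snps: dict[str, VariantSet]
    hybrid_reads: VariantSet
    inbred_reads: VariantSet
    reference_reads: VariantSet
    exclusion: RegionSet | None = None
    # Blocking set for the inbred genome when cleaning other haplotypes'
    # markers. Marker *inclusion* demands dual evidence (the intersection in
    # `inbred_reads`), but marker *exclusion* is conservative: any reported
    # SNP blocks. Defaults to `inbred_reads` when not supplied.
    inbred_block: VariantSet | None = None

    def __post_init__(self) -> None:
        haps = {self.reference_id, self.inbred_id, *self.hybrid_hap_ids}
        if len(haps) != 4:
            raise ValidationError("four distinct haplotype ids are required")
        for h in self.hybrid_hap_ids:
            if h not in self.assembly_snps:
                raise ValidationError(f"missing assembly SNP set for haplotype {h!r}")


def derive_four_way_markers(inputs: FourWayInputs) -> MarkerSet:
    """Unique markers for each of the four haplotypes of a double-cross design.

    (i)  Hybrid-parent haplotype: its assembly SNPs restricted to positions
         called heterozygous in the hybrid's reads, minus every position of
         the reference and inbred genomes' SNPs and of the sister
         haplotype's assembly SNPs.
    (ii) Non-reference inbred: its homozygous dual-evidence SNPs minus every
         other genome's SNP positions.
    (iii) Reference haplotype: positions homozygous-alt in BOTH the inbred
         and the hybrid reads (i.e. every non-reference haplotype carries
         the alternate allele); the diagnostic allele is the reference base.

    The exclusion regions, if any, are applied last to all four lists.
    """
    ref_id = inputs.reference_id
    c_id, d_id = inputs.hybrid_hap_ids
    layout = inputs.hybrid_reads.layout or inputs.inbred_reads.layout

    het_hybrid = inputs.hybrid_reads.het()
    hom_hybrid = inputs.hybrid_reads.hom_alt()
    hom_inbred = inputs.inbred_reads.hom_alt()
    inbred_block = inputs.inbred_block if inputs.inbred_block is not None \
        else inputs.inbred_reads

    tables: dict[str, pd.DataFrame] = {}

    # (i) the two hybrid haplotypes
    for hap, sister in ((c_id, d_id), (d_id, c_id)):
        matched = _match_alleles(inputs.assembly_snps[hap], het_hybrid)
        matched_vs = VariantSet(matched.reset_index(drop=True), layout=layout)
        clean = subtract_overlaps(matched_vs, [inputs.reference_reads,
                                               inbred_block,
                                               inputs.assembly_snps[sister]])
        tables[hap] = clean.df[["chrom", "pos"]].assign(diagnostic_allele="alt")

    # (ii) the non-reference inbred
    clean = subtract_overlaps(hom_inbred, [inputs.reference_reads,
                                           inputs.hybrid_reads,
                                           inputs.assembly_snps[c_id],
                                           inputs.assembly_snps[d_id]])
    tables[inputs.inbred_id] = clean.df[["chrom", "pos"]].assign(diagnostic_allele="alt")

    # (iii) the reference haplotype: hom-alt everywhere else, diagnosed by ref reads
    ref_pos = hom_inbred.df[["chrom", "pos"]].merge(
        hom_hybrid.df[["chrom", "pos"]], on=["chrom", "pos"], how="inner")
    tables[ref_id] = ref_pos.assign(diagnostic_allele="ref")

    markers = MarkerSet(tables, reference_id=ref_id, layout=layout)
    if inputs.exclusion is not None and len(inputs.exclusion):
        markers = apply_exclusion(markers, inputs.exclusion)
    return markers


# ---------------------------------------------------------------------------
# Exclusion regions & the uniqueness oracle
# ---------------------------------------------------------------------------

def apply_exclusion(markers: MarkerSet, regions: RegionSet,
                    haplotypes: tuple[str, ...] | None = None) -> MarkerSet:
    """Drop markers falling inside any exclusion region.

    By default the mask applies to every haplotype list; pass ``haplotypes``
    to restrict it. Removal counts are logged per haplotype.
    """
    tables = {}
    for hap, df in markers.tables.items():
        if haplotypes is not None and hap not in haplotypes:
            tables[hap] = df
            continue
        if len(df) == 0 or len(regions) == 0:
            tables[hap] = df
            continue
        inside = regions.contains(df["chrom"].to_numpy(), df["pos"].to_numpy())
        n_removed = int(inside.sum())
        if n_removed:
            logger.info("apply_exclusion: removed %d markers from haplotype %s",
                        n_removed, hap)
        tables[hap] = df[~inside].reset_index(drop=True)
    return MarkerSet(tables, reference_id=markers.reference_id, layout=markers.layout)


@dataclasses.dataclass
class UniquenessReport:
    n_checked: int
    violations: pd.DataFrame  # haplotype, chrom, pos, n_carriers

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    def ok(self) -> bool:
        return self.n_violations == 0


def verify_marker_uniqueness(markers: MarkerSet, panel) -> UniquenessReport:
    """Brute-force oracle against simulator truth.

    For an alt-diagnostic marker of haplotype h, exactly one founder must
    carry the alternate allele at that position and it must be h. For a
    ref-diagnostic marker (reference haplotype), every founder except the
    reference must carry the alternate allele.
    """
    rows = []
    n_checked = 0
    site = panel.site_table
    founders = list(panel.founder_ids)
    for hap, df in markers.tables.items():
        if len(df) == 0:
            continue
        merged = df.merge(site, on=["chrom", "pos"], how="left")
        carrier_mat = merged[founders].fillna(False).astype(bool)
        n_carriers = carrier_mat.sum(axis=1)
        n_checked += len(merged)
        if (merged["diagnostic_allele"] == "alt").any():
            alt_rows = merged["diagnostic_allele"] == "alt"
            own = carrier_mat[hap] if hap in carrier_mat else pd.Series(False, index=merged.index)
            bad = alt_rows & ~((n_carriers == 1) & own)
            for _, r in merged[bad].iterrows():
                rows.append((hap, r["chrom"], r["pos"], int(n_carriers[r.name])))
        if (merged["diagnostic_allele"] == "ref").any():
            ref_rows = merged["diagnostic_allele"] == "ref"
            want = len(founders) - 1
            ref_carries = carrier_mat[hap] if hap in carrier_mat else pd.Series(False, index=merged.index)
            bad = ref_rows & ~((n_carriers == want) & ~ref_carries)
            for _, r in merged[bad].iterrows():
                rows.append((hap, r["chrom"], r["pos"], int(n_carriers[r.name])))
    violations = pd.DataFrame(rows, columns=["haplotype", "chrom", "pos", "n_carriers"])
    return UniquenessReport(n_checked=n_checked, violations=violations)
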