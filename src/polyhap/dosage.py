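"""Haplotype presence validation and gene dosage genotyping.

Presence: the fraction of a haplotype's unique markers whose diagnostic
allele is seen in a sample's reads. A true four-haplotype plant recovers
essentially all markers of all four grandparental haplotypes, while a
control hybrid recovers only sequencing-error hits on the haplotypes it
does not carry — the filled-versus-empty circle pattern.

Dosage: under clonal gamete transmission every grandparental haplotype
contributes exactly one copy, so the expected dosage of a gene haplotype is
the number of carrier grandparents; the observed dosage is the pooled
diagnostic-allele read fraction over the locus markers times the ploidy,
rounded to the nearest integer (ties round down, conservative against
overcalling resistance copies).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import AlleleCountTable, GenomeLayout, MarkerSet, ValidationError


# ---------------------------------------------------------------------------
# Marker presence
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PresenceReport:
    """Per-haplotype marker recovery for one sample.

    ``table`` columns: haplotype, n_total, n_covered, n_uncovered,
    n_observed, percent_found. ``percent_found`` is 100 * observed/covered
    (uncovered markers are excluded from the denominator and reported);
    haplotypes with an empty marker list get NaN.
    """

    sample_id: str
    min_supporting_reads: int
    table: pd.DataFrame

    def percent(self, haplotype: str) -> float:
        row = self.table[self.table["haplotype"] == haplotype]
        if row.empty:
            raise KeyError(f"no haplotype {haplotype!r} in report")
        return float(row["percent_found"].iloc[0])

    def percents(self) -> dict[str, float]:
        return dict(zip(self.table["haplotype"], self.table["percent_found"]))

    def summary(self) -> str:
        lines = [f"Marker presence - sample {self.sample_id} "
                 f"(min {self.min_supporting_reads} supporting read(s))",
                 f"{'haplotype':<12}{'markers':>9}{'covered':>9}{'observed':>10}{'% found':>9}"]
        for _, r in self.table.iterrows():
            pct = "NA" if np.isnan(r["percent_found"]) else f"{r['percent_found']:.2f}"
            lines.append(f"{r['haplotype']:<12}{r['n_total']:>9}{r['n_covered']:>9}"
                         f"{r['n_observed']:>10}{pct:>9}")
        return "\n".join(lines)


def marker_presence(counts: AlleleCountTable, markers: MarkerSet,
                    min_supporting_reads: int = 1,
                    sample_id: str | None = None,
                    strict: bool = False) -> PresenceReport:
    """Score marker recovery for one sample.

    A marker is observed when at least ``min_supporting_reads`` reads carry
    its diagnostic allele (alt reads for alt-diagnostic markers, ref reads
    for the reference haplotype's ref-diagnostic markers). With
    ``strict=True`` uncovered markers count as absent instead of being
    excluded from the denominator.
    """
    if sample_id is None:
        if len(counts.samples) != 1:
            raise ValidationError("counts holds several samples; pass sample_id")
        sample_id = counts.samples[0]
    sub = counts.for_sample(sample_id).df
    rows = []
    for hap, mdf in markers.tables.items():
        n_total = len(mdf)
        if n_total == 0:
            rows.append((hap, 0, 0, 0, 0, np.nan))
            continue
        merged = mdf.merge(sub, on=["chrom", "pos"], how="left")
        depth = (merged["ref_count"].fillna(0) + merged["alt_count"].fillna(0)).to_numpy()
        covered = depth > 0
        diag = np.where(merged["diagnostic_allele"] == "alt",
                        merged["alt_count"].fillna(0), merged["ref_count"].fillna(0))
        observed = covered & (diag >= min_supporting_reads)
        denom = n_total if strict else int(covered.sum())
        pct = 100.0 * observed.sum() / denom if denom else np.nan
        rows.append((hap, n_total, int(covered.sum()),
                     int(n_total - covered.sum()), int(observed.sum()), pct))
    table = pd.DataFrame(rows, columns=["haplotype", "n_total", "n_covered",
                                        "n_uncovered", "n_observed", "percent_found"])
    return PresenceReport(sample_id=sample_id,
                          min_supporting_reads=min_supporting_reads, table=table)


@dataclasses.dataclass(frozen=True)
class FourHapDecision:
    accepted: bool
    failing_haplotypes: tuple[str, ...]
    rationale: str


def validate_four_hap(report: PresenceReport, presence_floor: float = 90.0) -> FourHapDecision:
    """Accept a sample as a true 4-haplotype plant iff all four haplotype
    marker lists are recovered at or above the presence floor (percent)."""
    if len(report.table) != 4:
        raise ValidationError("four-haplotype validation needs exactly four haplotypes")
    failing = tuple(
        str(r["haplotype"]) for _, r in report.table.iterrows()
        if np.isnan(r["percent_found"]) or r["percent_found"] < presence_floor)
    if failing:
        rationale = (f"haplotype(s) {', '.join(failing)} below presence floor "
                     f"{presence_floor:.0f}%")
    else:
        rationale = f"all four haplotypes at or above {presence_floor:.0f}% marker recovery"
    return FourHapDecision(accepted=not failing, failing_haplotypes=failing,
                           rationale=rationale)


# ---------------------------------------------------------------------------
# Gene dosage
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LocusSpec:
    """A gene/region of agronomic interest for dosage genotyping.

    ``carriers`` records, per founder haplotype, whether that haplotype
    carries the gene haplotype of interest (0/1 copies). ``markers`` are the
    diagnostic SNPs used to read the dosage out of pooled allele counts:
    (pos, diagnostic_allele) pairs on ``chrom`` within [start, end).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    carriers: dict[str, int]
    markers: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("locus interval must be non-empty")
        for hap, c in self.carriers.items():
            if c not in (0, 1):
                raise ValidationError(f"carrier status for {hap!r} must be 0 or 1")
        for pos, allele in self.markers:
            if not (self.start < pos <= self.end):
                raise ValidationError(
                    f"diagnostic marker {pos} outside locus interval")
            if allele not in ("ref", "alt"):
                raise ValidationError("diagnostic allele must be 'ref' or 'alt'")

    @classmethod
    def from_marker_set(cls, locus_id: str, chrom: str, start: int, end: int,
                        carriers: dict[str, int], markers: MarkerSet,
                        carrier_haplotype: str) -> "LocusSpec":
        """Take the diagnostic markers of a carrier haplotype inside the interval."""
        df = markers[carrier_haplotype]
        sel = df[(df["chrom"] == chrom) & (df["pos"] > start) & (df["pos"] <= end)]
        return cls(locus_id=locus_id, chrom=chrom, start=start, end=end,
                   carriers=carriers,
                   markers=tuple(zip(sel["pos"].astype(int), sel["diagnostic_allele"])))


@dataclasses.dataclass(frozen=True)
class DosageCall:
    locus_id: str
    sample_id: str
    expected_copies: int | None
    observed_af: float
    estimated_copies: int
    n_markers: int
    pooled_depth: int


def expected_dosage(locus: LocusSpec, design: tuple[str, str, str, str]) -> int:
    """Expected copies in a 4-haplotype tetraploid: each grandparental
    haplotype contributes exactly one copy under clonal transmission."""
    total = 0
    for hap in design:
        if hap not in locus.carriers:
            raise ValidationError(f"haplotype {hap!r} missing from locus carrier table")
        total += locus.carriers[hap]
    return total


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def estimate_dosage(counts: AlleleCountTable, locus: LocusSpec, ploidy: int,
                    sample_id: str | None = None,
                    design: tuple[str, str, str, str] | None = None) -> DosageCall | None:
    """Dosage from pooled diagnostic-allele reads over the locus markers.

    observed_af = pooled diagnostic reads / pooled depth; estimated copies =
    nearest integer to observed_af * ploidy (ties down, clipped to
    [0, ploidy]). Returns None when no locus marker is covered.
    """
    if sample_id is None:
        if len(counts.samples) != 1:
            raise ValidationError("counts holds several samples; pass sample_id")
        sample_id = counts.samples[0]
    if not locus.markers:
        raise ValidationError(f"locus {locus.locus_id!r} has no diagnostic markers")
    sub = counts.for_sample(sample_id).df
    sub = sub[sub["chrom"] == locus.chrom]
    mdf = pd.DataFrame(locus.markers, columns=["pos", "diagnostic_allele"])
    merged = mdf.merge(sub, on="pos", how="inner")
    depth = (merged["ref_count"] + merged["alt_count"]).to_numpy()
    covered = depth > 0
    if not covered.any():
        return None
    diag = np.where(merged["diagnostic_allele"] == "alt",
                    merged["alt_count"], merged["ref_count"])
    pooled_diag = int(diag[covered].sum())
    pooled_depth = int(depth[covered].sum())
    af = pooled_diag / pooled_depth
    est = min(max(_round_half_down(af * ploidy), 0), ploidy)
    expected = expected_dosage(locus, design) if design is not None else None
    return DosageCall(locus_id=locus.locus_id, sample_id=sample_id,
                      expected_copies=expected, observed_af=float(af),
                      estimated_copies=est, n_markers=int(covered.sum()),
                      pooled_depth=pooled_depth)
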