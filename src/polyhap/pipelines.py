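"""End-to-end helpers wiring the simulator to marker derivation, profiling
and inference — the study designs exercised by the tests, the acceptance
script and the CLI `simulate` subcommand."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import AlleleCountTable, MarkerSet, RegionSet, ValidationError, VariantSet
from .markers import (
    FourWayInputs,
    derive_four_way_markers,
    derive_two_way_markers,
    intersect_evidence,
)
from .sim import (
    CLONAL,
    MEIOTIC,
    FounderPanel,
    OffspringGenome,
    SimulationConfig,
    TruncationSpec,
    f1_offspring,
    make_hybrid,
    rng_from,
    simulate_founders,
    simulate_gamete,
    simulate_offspring,
    simulate_reads,
)


def default_exclusion(panel: FounderPanel) -> RegionSet:
    """The reference founder's wild-introgression blocks (the chr9-style
    false-marker region excluded during marker derivation)."""
    return panel.introgression_regions(panel.reference_id)


# ---------------------------------------------------------------------------
# Marker pipelines over a simulated panel
# ---------------------------------------------------------------------------

def dual_evidence(panel: FounderPanel, founder: str) -> VariantSet:
    """Sites supported by both evidence replicates of a founder."""
    rep1, rep2 = panel.evidence[founder]
    return intersect_evidence(rep1, rep2)


def reference_noise(panel: FounderPanel) -> VariantSet:
    """SNPs reported when the reference genome's own data are aligned to
    itself: the union of the reference's (false-positive-only) replicates."""
    rep1, rep2 = panel.evidence[panel.reference_id]
    merged = pd.concat([rep1.df, rep2.df], ignore_index=True)
    merged = merged.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    return VariantSet(merged, layout=panel.layout)


def two_way_marker_pipeline(panel: FounderPanel, target: str | None = None,
                            exclusion: RegionSet | None | str = "auto") -> MarkerSet:
    """Two-haplotype design: dual-evidence homozygous SNPs of the target
    founder, cleaned against the reference genome's own SNPs and the
    introgression exclusion region."""
    target = target or next(f for f in panel.founder_ids if f != panel.reference_id)
    if exclusion == "auto":
        exclusion = default_exclusion(panel)
    dual = dual_evidence(panel, target)
    return derive_two_way_markers(dual, reference_noise(panel), haplotype_id=target,
                                  exclusion=exclusion, layout=panel.layout)


def hybrid_read_snps(panel: FounderPanel, hap_a: str, hap_b: str) -> VariantSet:
    """Read-based SNP calls for a hybrid of two founders, from truth:
    heterozygous where exactly one haplotype carries the alternate allele,
    homozygous-alt where both do."""
    st = panel.site_table
    a = st[hap_a].to_numpy(dtype=int)
    b = st[hap_b].to_numpy(dtype=int)
    total = a + b
    sub = st.loc[total > 0, ["chrom", "pos", "ref", "alt"]].copy()
    sub["genotype_class"] = np.where(total[total > 0] == 2, "hom_alt", "het")
    sub["evidence"] = ""
    return VariantSet(sub.reset_index(drop=True), layout=panel.layout)


def four_way_inputs_from_panel(panel: FounderPanel,
                               design: tuple[str, str, str, str] | None = None,
                               exclusion: RegionSet | None | str = "auto") -> FourWayInputs:
    """Assemble four-way derivation inputs from a simulated panel.

    ``design`` = (reference, inbred, hybrid_hap1, hybrid_hap2); defaults to
    the panel's founder order. Assembly SNP sets are the hybrid haplotypes'
    truth variants; the inbred contributes its dual-evidence intersection;
    the reference contributes its noise set.
    """
    if design is None:
        if len(panel.founder_ids) != 4:
            raise ValidationError("four-way derivation needs a four-founder panel")
        design = tuple(panel.founder_ids)
    ref, inbred, hap_c, hap_d = design
    if ref != panel.reference_id:
        raise ValidationError("design reference must be the panel reference")
    if exclusion == "auto":
        exclusion = default_exclusion(panel)
    rep1, rep2 = panel.evidence[inbred]
    union = pd.concat([rep1.df, rep2.df], ignore_index=True)
    union = union.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    return FourWayInputs(
        reference_id=ref,
        inbred_id=inbred,
        hybrid_hap_ids=(hap_c, hap_d),
        assembly_snps={hap_c: panel.variants[hap_c], hap_d: panel.variants[hap_d]},
        hybrid_reads=hybrid_read_snps(panel, hap_c, hap_d),
        inbred_reads=dual_evidence(panel, inbred),
        reference_reads=reference_noise(panel),
        exclusion=exclusion,
        inbred_block=VariantSet(union, layout=panel.layout),
    )


def four_way_marker_pipeline(panel: FounderPanel,
                             design: tuple[str, str, str, str] | None = None,
                             exclusion: RegionSet | None | str = "auto") -> MarkerSet:
    return derive_four_way_markers(four_way_inputs_from_panel(panel, design, exclusion))


# ---------------------------------------------------------------------------
# Sample simulators
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulatedSample:
    sample_id: str
    kind: str
    offspring: OffspringGenome
    counts: AlleleCountTable


SAMPLE_KINDS = ("f1", "f2", "clonal_tetraploid", "four_hap")


def simulate_sample(panel: FounderPanel, kind: str, cross,
                    sample_id: str, config: SimulationConfig,
                    rng: np.random.Generator,
                    sites: pd.DataFrame | None = None,
                    truncation: TruncationSpec | None = None) -> SimulatedSample:
    """Simulate one offspring of the given kind and its read counts.

    kinds
    -----
    f1                 the diploid hybrid plant itself; cross = (a, b)
    f2                 union of two meiotic gametes of the hybrid; cross = (a, b)
    clonal_tetraploid  union of two clonal gametes from hybrids of the same
                       two founders (the MiMe selfing design); cross = (a, b)
    four_hap           union of clonal gametes from two different hybrids;
                       cross = ((a, b), (c, d))

    ``sites`` defaults to every panel SNP site.
    """
    if kind not in SAMPLE_KINDS:
        raise ValidationError(f"unknown sample kind {kind!r}")
    if sites is None:
        sites = panel.site_table[["chrom", "pos"]]
    if kind == "four_hap":
        (a, b), (c, d) = cross
        hyb1, hyb2 = make_hybrid(panel, a, b), make_hybrid(panel, c, d)
        g1 = simulate_gamete(hyb1, CLONAL, config, rng=rng)
        g2 = simulate_gamete(hyb2, CLONAL, config, rng=rng)
        off = simulate_offspring(g1, g2, truncation=truncation, rng=rng,
                                 sample_id=sample_id)
    else:
        a, b = cross
        hyb = make_hybrid(panel, a, b)
        if kind == "f1":
            off = f1_offspring(hyb, sample_id=sample_id)
        elif kind == "f2":
            g1 = simulate_gamete(hyb, MEIOTIC, config, rng=rng)
            g2 = simulate_gamete(hyb, MEIOTIC, config, rng=rng)
            off = simulate_offspring(g1, g2, truncation=truncation, rng=rng,
                                     sample_id=sample_id)
        else:  # clonal_tetraploid
            g1 = simulate_gamete(hyb, CLONAL, config, rng=rng)
            g2 = simulate_gamete(hyb, CLONAL, config, rng=rng)
            off = simulate_offspring(g1, g2, truncation=truncation, rng=rng,
                                     sample_id=sample_id)
    counts = simulate_reads(off, sites, config.mean_depth, config.error_rate,
                            rng=rng, sample_id=sample_id)
    return SimulatedSample(sample_id=sample_id, kind=kind, offspring=off,
                           counts=counts)


def simulate_study(config: SimulationConfig,
                   samples: list[dict]) -> tuple[FounderPanel, list[SimulatedSample]]:
    """Simulate a panel plus a list of sample specs.

    Each spec is a dict with keys ``id``, ``kind``, ``cross`` and optional
    ``truncation`` (TruncationSpec). All randomness derives from
    ``config.seed``.
    """
    panel = simulate_founders(config, rng=rng_from(config.seed, 0))
    out = []
    for i, spec in enumerate(samples):
        rng = rng_from(config.seed, 10, i)
        out.append(simulate_sample(panel, spec["kind"], spec["cross"],
                                   sample_id=spec["id"], config=config, rng=rng,
                                   sites=spec.get("sites"),
                                   truncation=spec.get("truncation")))
    return panel, out
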