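"""Forward simulation of the polyploid genome design crossing scheme.

The scheme mirrors a double-cross design built on clonal (MiMe) gametes:
inbred founders -> F1 hybrids -> clonal or meiotic gametes -> diploid or
tetraploid offspring -> binomially sampled read counts at SNP sites. Every
stage records complete ground truth so downstream marker derivation,
transmission inference and dosage genotyping can be tested without any
external data.

Two classes of SNP site are simulated relative to the designated reference
founder:

* *founder-private* sites - the alternate allele is carried by exactly one
  non-reference founder (homogeneous point process at the configured
  density, multiplied inside that founder's introgression blocks);
* *reference-divergence* sites - the reference founder carries the
  divergent allele, so every non-reference founder is homozygous-alt there
  in reference coordinates. The reference founder's wild-introgression
  block (chromosome 9 by default) multiplies the density of this class,
  reproducing the dense, ambiguous marker band that motivates the chr9
  exclusion region.

Coordinates: chromatid segments and intervals are 0-based half-open; SNP
positions are 1-based.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import (
    BASES,
    AlleleCountTable,
    GenomeLayout,
    RegionSet,
    ValidationError,
    VariantSet,
    default_tomato_layout,
)

CLONAL = "clonal"
MEIOTIC = "meiotic"

# Evidence tags carried on the two simulated replicate call sets per genome.
EVIDENCE_TAGS = ("hifi", "short")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class IntrogressionBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    multiplier: float = 10.0


def default_introgressions(layout: GenomeLayout) -> dict[str, tuple[IntrogressionBlock, ...]]:
    """One wild-introgression block on chromosome 9 (5-58 Mb) in the reference."""
    chrom = layout.names[8] if len(layout.names) >= 9 else layout.names[-1]
    end = min(58_000_000, layout.length(chrom))
    if end <= 5_000_000:
        return {}
    return {"__reference__": (IntrogressionBlock(chrom, 5_000_000, end, 10.0),)}


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic cross.

    Densities are SNPs/Mb. ``snp_density`` governs founder-private sites;
    ``reference_private_density`` governs reference-divergence sites (the
    alternate allele shared by all non-reference founders). ``crossover_rate``
    is the expected crossover count per chromosome per meiotic chromatid;
    with ``obligate_co`` the count is max(1, Poisson(rate)), matching the
    obligate crossover of tomato bivalents. ``error_rate`` is the per-read
    probability that the observed allele is flipped.
    """

    layout: GenomeLayout = dataclasses.field(default_factory=default_tomato_layout)
    founder_ids: tuple[str, ...] = ("A", "B", "C", "D")
    snp_density: float = 100.0
    reference_private_density: float = 100.0
    introgressions: dict[str, tuple[IntrogressionBlock, ...]] | None = None
    sharing_fraction: float = 0.0
    evidence_dropout: float = 0.05
    evidence_fp_per_mb: float = 1.0
    crossover_rate: float = 1.0
    obligate_co: bool = True
    truncation_prob: float = 0.0
    truncation_min_bp: int = 3_000_000
    truncation_max_frac: float = 0.5
    mean_depth: float = 30.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.founder_ids) not in (2, 4):
            raise ValidationError("founder_ids must name 2 or 4 founders")
        if len(set(self.founder_ids)) != len(self.founder_ids):
            raise ValidationError("founder ids must be unique")
        for name, val in (("snp_density", self.snp_density),
                          ("reference_private_density", self.reference_private_density),
                          ("evidence_fp_per_mb", self.evidence_fp_per_mb),
                          ("crossover_rate", self.crossover_rate),
                          ("mean_depth", self.mean_depth)):
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValidationError("error_rate must lie in [0, 0.5)")
        for name, val in (("sharing_fraction", self.sharing_fraction),
                          ("evidence_dropout", self.evidence_dropout),
                          ("truncation_prob", self.truncation_prob),
                          ("truncation_max_frac", self.truncation_max_frac)):
            if not 0 <= val <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.introgressions is None:
            blocks = default_introgressions(self.layout)
            self.introgressions = {
                (self.reference_id if key == "__reference__" else key): blks
                for key, blks in blocks.items()
            }
        for fid, blocks in self.introgressions.items():
            if fid not in self.founder_ids:
                raise ValidationError(f"introgression founder {fid!r} not in founder_ids")
            for b in blocks:
                if b.chrom not in self.layout:
                    raise ValidationError(f"introgression chromosome {b.chrom!r} not in layout")
                if not 0 <= b.start < b.end <= self.layout.length(b.chrom):
                    raise ValidationError("introgression block outside chromosome bounds")
                if b.multiplier <= 0:
                    raise ValidationError("introgression multiplier must be > 0")

    @property
    def reference_id(self) -> str:
        return self.founder_ids[0]


def rng_from(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator: master seed plus a stage key."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FounderPanel:
    """Inbred founder genomes with truth variants and noisy evidence replicates.

    ``site_table`` is the union of all SNP sites with one boolean carrier
    column per founder (True where that founder carries the alternate
    allele) plus an ``origin`` column (``private:<fid>`` or ``refdiv``).
    """

    layout: GenomeLayout
    founder_ids: tuple[str, ...]
    reference_id: str
    variants: dict[str, VariantSet]
    evidence: dict[str, tuple[VariantSet, VariantSet]]
    introgressions: dict[str, tuple[IntrogressionBlock, ...]]
    site_table: pd.DataFrame

    def carriers(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Carrier columns aligned to an arbitrary (chrom, pos) site frame.

        Sites absent from the panel are treated as monomorphic reference
        (no founder carries the alternate allele).
        """
        merged = sites[["chrom", "pos"]].merge(self.site_table, on=["chrom", "pos"], how="left")
        for fid in self.founder_ids:
            merged[fid] = merged[fid].fillna(False).astype(bool)
        return merged

    def introgression_regions(self, founder: str | None = None) -> RegionSet:
        founder = founder if founder is not None else self.reference_id
        blocks = self.introgressions.get(founder, ())
        if not blocks:
            return RegionSet.empty()
        return RegionSet.from_intervals([(b.chrom, b.start, b.end) for b in blocks],
                                        layout=self.layout)


def _sample_positions(rng: np.random.Generator, n: int, chrom_len: int,
                      segments: list[tuple[int, int, float]],
                      taken: set[int]) -> np.ndarray:
    """Draw n distinct 1-based positions from weighted segments, avoiding `taken`.

    Rejection sampling; raises if the requested count cannot fit in the
    available positions.
    """
    if n == 0:
        return np.array([], dtype=np.int64)
    weights = np.array([w * (e - s) for s, e, w in segments], dtype=float)
    total_free = chrom_len - len(taken)
    if n > total_free:
        raise ValidationError(
            f"requested {n} SNP sites but only {total_free} free positions on a "
            f"{chrom_len} bp chromosome"
        )
    weights = weights / weights.sum()
    chosen: list[int] = []
    seen = set(taken)
    for _ in range(200):
        need = n - len(chosen)
        if need <= 0:
            break
        seg_idx = rng.choice(len(segments), size=need, p=weights)
        for i in range(len(segments)):
            k = int((seg_idx == i).sum())
            if k == 0:
                continue
            s, e, _ = segments[i]
            pos = rng.integers(s, e, size=k) + 1  # 1-based
            for p in pos.tolist():
                if p not in seen:
                    seen.add(p)
                    chosen.append(p)
                    if len(chosen) == n:
                        break
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValidationError("could not place all SNP sites without collisions")
    return np.array(sorted(chosen), dtype=np.int64)


def _density_segments(chrom: str, length: int, base: float,
                      blocks: Sequence[IntrogressionBlock]) -> list[tuple[int, int, float]]:
    """Piecewise-constant density (SNPs/Mb) over one chromosome."""
    cuts = {0, length}
    for b in blocks:
        if b.chrom == chrom:
            cuts.update((b.start, b.end))
    bounds = sorted(cuts)
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        mult = 1.0
        for b in blocks:
            if b.chrom == chrom and b.start <= s and e <= b.end:
                mult = b.multiplier
        segments.append((s, e, base * mult))
    return segments


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    bases = np.array(BASES)
    return bases[ref_idx], bases[alt_idx]


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> FounderPanel:
    """Draw the founder panel: truth SNP sites, carriers and evidence replicates."""
    rng = rng if rng is not None else rng_from(config.seed, 0)
    layout = config.layout
    ref = config.reference_id
    non_ref = [f for f in config.founder_ids if f != ref]

    taken: dict[str, set[int]] = {c: set() for c in layout.names}
    site_rows: list[pd.DataFrame] = []

    # Founder-private sites.
    private_pos: dict[str, dict[str, np.ndarray]] = {f: {} for f in non_ref}
    for fid in non_ref:
        own_blocks = [b for b in config.introgressions.get(fid, ())]
        for chrom, length in layout.chromosomes:
            segs = _density_segments(chrom, length, config.snp_density, own_blocks)
            lam = sum(w * (e - s) / 1e6 for s, e, w in segs)
            n = int(rng.poisson(lam))
            pos = _sample_positions(rng, n, length, segs, taken[chrom])
            taken[chrom].update(pos.tolist())
            private_pos[fid][chrom] = pos

    # Reference-divergence sites (alt shared by every non-reference founder).
    refdiv_pos: dict[str, np.ndarray] = {}
    ref_blocks = [b for b in config.introgressions.get(ref, ())]
    for chrom, length in layout.chromosomes:
        segs = _density_segments(chrom, length, config.reference_private_density, ref_blocks)
        lam = sum(w * (e - s) / 1e6 for s, e, w in segs)
        n = int(rng.poisson(lam))
        pos = _sample_positions(rng, n, length, segs, taken[chrom])
        taken[chrom].update(pos.tolist())
        refdiv_pos[chrom] = pos

    # Assemble the site table.
    for fid in non_ref:
        for chrom in layout.names:
            pos = private_pos[fid][chrom]
            if len(pos) == 0:
                continue
            refb, altb = _random_alleles(rng, len(pos))
            df = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": refb, "alt": altb,
                               "origin": f"private:{fid}"})
            for g in config.founder_ids:
                df[g] = g == fid
            site_rows.append(df)
    for chrom in layout.names:
        pos = refdiv_pos[chrom]
        if len(pos) == 0:
            continue
        refb, altb = _random_alleles(rng, len(pos))
        df = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": refb, "alt": altb,
                           "origin": "refdiv"})
        for g in config.founder_ids:
            df[g] = g != ref
        site_rows.append(df)

    cols = ["chrom", "pos", "ref", "alt", "origin", *config.founder_ids]
    if site_rows:
        site_table = pd.concat(site_rows, ignore_index=True)[cols]
    else:
        site_table = pd.DataFrame(columns=cols)
    site_table = layout.sort_frame(site_table)

    # Optional sharing: copy a fraction of each founder's private sites into
    # one other non-reference founder, to stress marker-uniqueness filters.
    if config.sharing_fraction > 0 and len(non_ref) > 1:
        for fid in non_ref:
            mask = site_table["origin"] == f"private:{fid}"
            idx = site_table.index[mask]
            k = int(np.floor(config.sharing_fraction * len(idx)))
            if k == 0:
                continue
            pick = rng.choice(idx.to_numpy(), size=k, replace=False)
            others = [g for g in non_ref if g != fid]
            tgt = rng.choice(len(others), size=k)
            for j, row in enumerate(pick):
                site_table.loc[row, others[int(tgt[j])]] = True
                site_table.loc[row, "origin"] = "shared"

    def founder_variants(fid: str) -> VariantSet:
        mask = site_table[fid].to_numpy(dtype=bool)
        sub = site_table.loc[mask, ["chrom", "pos", "ref", "alt"]].copy()
        sub["genotype_class"] = "hom_alt"
        sub["evidence"] = ""
        return VariantSet(sub, layout=layout)

    variants = {fid: founder_variants(fid) for fid in config.founder_ids}

    # Evidence replicates: independent thinnings of the truth set plus
    # false-positive sites, one replicate per evidence tag.
    evidence: dict[str, tuple[VariantSet, VariantSet]] = {}
    genome_mb = layout.total_bp / 1e6
    for fid in config.founder_ids:
        reps = []
        truth_df = variants[fid].df
        truth_keys = {c: set(truth_df.loc[truth_df["chrom"] == c, "pos"].tolist())
                      for c in layout.names}
        for tag in EVIDENCE_TAGS:
            keep = rng.random(len(truth_df)) >= config.evidence_dropout
            kept = truth_df.loc[keep, ["chrom", "pos", "ref", "alt", "genotype_class"]].copy()
            n_fp = int(rng.poisson(config.evidence_fp_per_mb * genome_mb))
            fp_rows = []
            if n_fp:
                lengths = np.array([l for _, l in layout.chromosomes], dtype=float)
                chrom_idx = rng.choice(len(lengths), size=n_fp, p=lengths / lengths.sum())
                for ci in chrom_idx.tolist():
                    chrom, length = layout.chromosomes[ci]
                    for _ in range(50):
                        p = int(rng.integers(0, length)) + 1
                        if p not in truth_keys[chrom]:
                            break
                    refb, altb = _random_alleles(rng, 1)
                    fp_rows.append((chrom, p, refb[0], altb[0], "hom_alt"))
            rep = pd.concat([kept, pd.DataFrame(fp_rows, columns=kept.columns)],
                            ignore_index=True) if fp_rows else kept
            rep = rep.drop_duplicates(["chrom", "pos"])
            rep["evidence"] = tag
            reps.append(VariantSet(rep, layout=layout))
        evidence[fid] = (reps[0], reps[1])

    return FounderPanel(layout=layout, founder_ids=config.founder_ids,
                        reference_id=ref, variants=variants, evidence=evidence,
                        introgressions=dict(config.introgressions),
                        site_table=site_table)


# ---------------------------------------------------------------------------
# Hybrids, gametes, offspring
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class HybridGenome:
    """F1 hybrid: one haplotype from each of two distinct founders."""

    panel: FounderPanel
    hap_a: str
    hap_b: str

    def __post_init__(self) -> None:
        for h in (self.hap_a, self.hap_b):
            if h not in self.panel.founder_ids:
                raise ValidationError(f"unknown founder id {h!r}")
        if self.hap_a == self.hap_b:
            raise ValidationError("a hybrid requires two distinct founders")

    @property
    def parent_id(self) -> str:
        return f"{self.hap_a}x{self.hap_b}"

    def genotypes(self) -> pd.DataFrame:
        """Truth genotype class at every panel site: hom_ref, het or hom_alt."""
        st = self.panel.site_table
        a = st[self.hap_a].to_numpy(dtype=int)
        b = st[self.hap_b].to_numpy(dtype=int)
        cls = np.where(a + b == 2, "hom_alt", np.where(a + b == 1, "het", "hom_ref"))
        return st[["chrom", "pos"]].assign(genotype_class=cls)


def make_hybrid(panel: FounderPanel, founder_a: str, founder_b: str) -> HybridGenome:
    return HybridGenome(panel, founder_a, founder_b)


# A chromatid is a mosaic of half-open intervals tiling the chromosome.
Chromatid = tuple[tuple[int, int, str], ...]


@dataclasses.dataclass
class Gamete:
    """One gamete: clonal (two parental chromatids) or meiotic (one recombinant)."""

    parent_id: str
    mode: str
    layout: GenomeLayout
    panel: FounderPanel
    chromatids: dict[str, tuple[Chromatid, ...]]
    breakpoints: dict[str, tuple[int, ...]]

    def n_chromatids(self) -> int:
        return sum(len(c) for c in self.chromatids.values())


def simulate_gamete(hybrid: HybridGenome, mode: str,
                    config: SimulationConfig | None = None,
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> Gamete:
    """Draw one gamete from a hybrid.

    Clonal gametes carry both parental haplotypes unrecombined (the gamete
    genotype equals the parent's full diploid genotype). Meiotic gametes
    carry one recombinant chromatid per chromosome with a crossover count
    from the configured model (``max(1, Poisson(rate))`` when the obligate
    crossover flag is set) and uniform breakpoint positions.
    """
    if mode not in (CLONAL, MEIOTIC):
        raise ValidationError(f"unknown gamete mode {mode!r}")
    layout = hybrid.panel.layout
    chromatids: dict[str, tuple[Chromatid, ...]] = {}
    breakpoints: dict[str, tuple[int, ...]] = {}
    if mode == CLONAL:
        for chrom, length in layout.chromosomes:
            chromatids[chrom] = (((0, length, hybrid.hap_a),),
                                 ((0, length, hybrid.hap_b),))
            breakpoints[chrom] = ()
    else:
        if rng is None:
            if seed is not None:
                rng = rng_from(seed, 1)
            else:
                cfg_seed = config.seed if config is not None else 0
                rng = rng_from(cfg_seed, 1)
        rate = config.crossover_rate if config is not None else 1.0
        obligate = config.obligate_co if config is not None else True
        for chrom, length in layout.chromosomes:
            k = int(rng.poisson(rate))
            if obligate:
                k = max(1, k)
            bps = np.unique(rng.integers(1, length, size=k)) if k else np.array([], dtype=np.int64)
            start_hap, other = ((hybrid.hap_a, hybrid.hap_b)
                                if rng.random() < 0.5 else (hybrid.hap_b, hybrid.hap_a))
            bounds = [0, *bps.tolist(), length]
            segs = []
            for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
                segs.append((s, e, start_hap if i % 2 == 0 else other))
            chromatids[chrom] = (tuple(segs),)
            breakpoints[chrom] = tuple(int(b) for b in bps.tolist())
    return Gamete(parent_id=hybrid.parent_id, mode=mode, layout=layout,
                  panel=hybrid.panel, chromatids=chromatids, breakpoints=breakpoints)


@dataclasses.dataclass(frozen=True)
class TruncationEvent:
    """A terminal chromosome-copy loss: `interval` [start, end) was removed
    from one chromatid whose terminal source haplotype is recorded."""

    chrom: str
    haplotype: str
    side: str  # 'left' or 'right'
    start: int
    end: int


@dataclasses.dataclass
class TruncationSpec:
    """Optional terminal copy-loss model.

    With probability ``prob`` one offspring loses a terminal segment of one
    chromatid; segment size is uniform between ``min_bp`` and ``max_frac``
    of the chromosome. ``forced`` bypasses the random draw with explicit
    (chrom, haplotype, side, size_bp) events (used by fault-injection tests).
    """

    prob: float = 0.0
    min_bp: int = 3_000_000
    max_frac: float = 0.5
    forced: tuple[tuple[str, str, str, int], ...] = ()

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "TruncationSpec":
        return cls(prob=config.truncation_prob, min_bp=config.truncation_min_bp,
                   max_frac=config.truncation_max_frac)


@dataclasses.dataclass
class TruthRecord:
    """Simulator ground truth for one offspring (oracle for tests)."""

    sample_id: str
    gamete_modes: tuple[str, str]
    breakpoints: dict[str, dict[str, tuple[int, ...]]]  # parent -> chrom -> positions
    truncations: tuple[TruncationEvent, ...]
    seed: int | None = None

    def all_breakpoints(self, chrom: str | None = None) -> list[tuple[str, int]]:
        out = []
        for parent, per_chrom in self.breakpoints.items():
            for c, bps in per_chrom.items():
                if chrom is not None and c != chrom:
                    continue
                out.extend((c, b) for b in bps)
        return sorted(out)

    def to_json(self) -> str:
        payload = {
            "sample_id": self.sample_id,
            "gamete_modes": list(self.gamete_modes),
            "breakpoints": {p: {c: list(b) for c, b in d.items()}
                            for p, d in self.breakpoints.items()},
            "truncations": [dataclasses.asdict(t) for t in self.truncations],
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclasses.dataclass
class OffspringGenome:
    """An offspring as a stack of chromatids over the shared layout."""

    sample_id: str
    panel: FounderPanel
    layout: GenomeLayout
    ploidy: int
    chromatids: dict[str, tuple[Chromatid, ...]]
    truth: TruthRecord

    def n_chromosome_copies(self) -> int:
        """Total chromosome copies across the genome (a truncated copy still
        counts as one chromosome)."""
        return sum(len(stack) for stack in self.chromatids.values())

    def local_state(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Per-site total copy number and per-founder alt-copy counts.

        `sites` needs chrom/pos columns; returns the same rows plus ``cn``
        and ``alt_copies`` (total across founders) and one integer column
        per founder.
        """
        carriers = self.panel.carriers(sites)
        out = sites[["chrom", "pos"]].copy()
        cn = np.zeros(len(out), dtype=np.int64)
        per_founder = {fid: np.zeros(len(out), dtype=np.int64)
                       for fid in self.panel.founder_ids}
        pos0 = out["pos"].to_numpy() - 1
        chrom_arr = out["chrom"].to_numpy()
        for chrom, stack in self.chromatids.items():
            cmask = chrom_arr == chrom
            if not cmask.any():
                continue
            cpos = pos0[cmask]
            for chromatid in stack:
                for s, e, hap in chromatid:
                    seg = (cpos >= s) & (cpos < e)
                    if not seg.any():
                        continue
                    idx = np.flatnonzero(cmask)[seg]
                    cn[idx] += 1
                    carry = carriers[hap].to_numpy(dtype=bool)[idx]
                    per_founder[hap][idx] += carry
        out["cn"] = cn
        for fid, arr in per_founder.items():
            out[fid] = arr
        out["alt_copies"] = sum(per_founder.values())
        return out

    def cn_segments(self) -> pd.DataFrame:
        """Copy-number segments (chrom, start, end, copy_number) after truncation."""
        rows = []
        for chrom, stack in self.chromatids.items():
            cuts = {0, self.layout.length(chrom)}
            for chromatid in stack:
                for s, e, _ in chromatid:
                    cuts.update((s, e))
            bounds = sorted(cuts)
            for s, e in zip(bounds[:-1], bounds[1:]):
                n = sum(1 for chromatid in stack for cs, ce, _ in chromatid
                        if cs <= s and e <= ce)
                rows.append((chrom, s, e, n))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number"])
        # merge adjacent equal-copy segments
        merged = []
        for chrom, grp in df.groupby("chrom", sort=False):
            cur = None
            for _, r in grp.iterrows():
                if cur is not None and cur[3] == r["copy_number"] and cur[2] == r["start"]:
                    cur = (chrom, cur[1], r["end"], cur[3])
                else:
                    if cur is not None:
                        merged.append(cur)
                    cur = (chrom, r["start"], r["end"], r["copy_number"])
            if cur is not None:
                merged.append(cur)
        return pd.DataFrame(merged, columns=["chrom", "start", "end", "copy_number"])


def _truncate_chromatid(chromatid: Chromatid, side: str, size: int,
                        length: int) -> tuple[Chromatid, tuple[int, int, str]]:
    """Remove a terminal interval; returns the new chromatid and the lost
    (start, end, terminal haplotype)."""
    if side == "right":
        lo, hi = length - size, length
        term_hap = chromatid[-1][2]
    elif side == "left":
        lo, hi = 0, size
        term_hap = chromatid[0][2]
    else:
        raise ValidationError(f"truncation side must be 'left' or 'right', not {side!r}")
    kept = []
    for s, e, hap in chromatid:
        if side == "left":
            ns, ne = max(s, hi), e
        else:
            ns, ne = s, min(e, lo)
        if ns < ne:
            kept.append((ns, ne, hap))
    return tuple(kept), (lo, hi, term_hap)


def simulate_offspring(gamete_m: Gamete, gamete_p: Gamete,
                       truncation: TruncationSpec | None = None,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None,
                       sample_id: str = "offspring") -> OffspringGenome:
    """Union of two gametes, with optional terminal chromosome-copy loss.

    Two clonal gametes yield the tetraploid 2+2 design; two meiotic gametes
    yield a diploid F2-style genome.
    """
    if gamete_m.layout.chromosomes != gamete_p.layout.chromosomes:
        raise ValidationError("gametes were simulated over different layouts")
    if gamete_m.panel is not gamete_p.panel and not gamete_m.panel.site_table.equals(
            gamete_p.panel.site_table):
        raise ValidationError("gametes come from different founder panels")
    layout = gamete_m.layout
    if rng is None:
        rng = rng_from(seed if seed is not None else 0, 2)
    chromatids = {c: gamete_m.chromatids[c] + gamete_p.chromatids[c]
                  for c in layout.names}
    ploidies = {len(stack) for stack in chromatids.values()}
    if len(ploidies) != 1:
        raise ValidationError("inconsistent chromatid counts across chromosomes")
    ploidy = ploidies.pop()

    truncation = truncation or TruncationSpec()
    events: list[TruncationEvent] = []

    def apply_loss(chrom: str, idx: int, side: str, size: int) -> None:
        stack = list(chromatids[chrom])
        new, (lo, hi, hap) = _truncate_chromatid(stack[idx], side, size,
                                                 layout.length(chrom))
        stack[idx] = new
        chromatids[chrom] = tuple(stack)
        events.append(TruncationEvent(chrom=chrom, haplotype=hap, side=side,
                                      start=lo, end=hi))

    if truncation.forced:
        for chrom, hap, side, size in truncation.forced:
            stack = chromatids[chrom]
            # pick the chromatid whose terminal segment matches the haplotype
            pick = None
            for i, chromatid in enumerate(stack):
                term = chromatid[-1][2] if side == "right" else chromatid[0][2]
                if term == hap:
                    pick = i
                    break
            if pick is None:
                raise ValidationError(
                    f"no chromatid of {chrom} has terminal haplotype {hap!r}")
            apply_loss(chrom, pick, side, int(size))
    elif truncation.prob > 0 and rng.random() < truncation.prob:
        chrom = layout.names[int(rng.integers(0, len(layout.names)))]
        length = layout.length(chrom)
        idx = int(rng.integers(0, len(chromatids[chrom])))
        side = "right" if rng.random() < 0.5 else "left"
        hi = max(truncation.min_bp + 1, int(truncation.max_frac * length))
        size = int(rng.integers(truncation.min_bp, hi))
        apply_loss(chrom, idx, side, size)

    truth = TruthRecord(
        sample_id=sample_id,
        gamete_modes=(gamete_m.mode, gamete_p.mode),
        breakpoints={"maternal": dict(gamete_m.breakpoints),
                     "paternal": dict(gamete_p.breakpoints)},
        truncations=tuple(events),
        seed=seed,
    )
    return OffspringGenome(sample_id=sample_id, panel=gamete_m.panel, layout=layout,
                           ploidy=ploidy, chromatids=chromatids, truth=truth)


def f1_offspring(hybrid: HybridGenome, sample_id: str = "F1") -> OffspringGenome:
    """The F1 hybrid plant itself, as a diploid offspring genome."""
    layout = hybrid.panel.layout
    chromatids = {c: (((0, l, hybrid.hap_a),), ((0, l, hybrid.hap_b),))
                  for c, l in layout.chromosomes}
    truth = TruthRecord(sample_id=sample_id, gamete_modes=(CLONAL, CLONAL),
                        breakpoints={"maternal": {}, "paternal": {}},
                        truncations=())
    return OffspringGenome(sample_id=sample_id, panel=hybrid.panel, layout=layout,
                           ploidy=2, chromatids=chromatids, truth=truth)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def simulate_reads(offspring: OffspringGenome, sites: pd.DataFrame,
                   mean_depth: float, error_rate: float,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None,
                   sample_id: str | None = None) -> AlleleCountTable:
    """Binomial read sampling at the given (chrom, pos) sites.

    Depth ~ Poisson(mean_depth * local_cn / ploidy); the alternate-allele
    read count is Binomial(depth, p') with p the local alt-copy fraction and
    p' = p(1-e) + (1-p)e. Zero-copy regions yield zero depth.
    """
    if error_rate >= 0.5 or error_rate < 0:
        raise ValidationError("error_rate must lie in [0, 0.5)")
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    for chrom in sites["chrom"].unique():
        if chrom not in offspring.layout:
            raise ValidationError(f"site chromosome {chrom!r} not in layout")
    rng = rng if rng is not None else rng_from(seed if seed is not None else 0, 3)
    sample_id = sample_id or offspring.sample_id
    state = offspring.local_state(sites)
    cn = state["cn"].to_numpy(dtype=float)
    alt = state["alt_copies"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cn > 0, alt / np.maximum(cn, 1), 0.0)
    p_err = p * (1 - error_rate) + (1 - p) * error_rate
    depth = rng.poisson(mean_depth * cn / offspring.ploidy)
    alt_count = rng.binomial(depth, p_err)
    df = pd.DataFrame({
        "sample": sample_id,
        "chrom": state["chrom"],
        "pos": state["pos"],
        "ref_count": depth - alt_count,
        "alt_count": alt_count,
    })
    return AlleleCountTable(df)
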