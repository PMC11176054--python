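"""Core containers shared by every pipeline stage.

The pipeline operates in reference coordinates throughout: variant and
marker positions are 1-based (VCF convention) at the I/O boundary and in the
tables below, while all interval arithmetic (regions, windows, chromatid
segments) is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
GENOTYPE_CLASSES = ("hom_alt", "het")
DIAGNOSTIC_ALLELES = ("ref", "alt")


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp).

    The chromosome order given at construction is the canonical sort order
    for every table in the pipeline. Names are matched exactly; no "chr"
    normalisation is attempted.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        if not chroms:
            raise ValidationError("layout needs at least one chromosome")
        for name, length in chroms:
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def chrom_index(self, chrom) -> pd.Series | int:
        """Integer rank of chromosome(s) in layout order (vectorised)."""
        order = {n: i for i, n in enumerate(self.names)}
        if isinstance(chrom, str):
            return order[chrom]
        return pd.Series(chrom).map(order)

    def sort_frame(self, df: pd.DataFrame, extra: list[str] | None = None) -> pd.DataFrame:
        """Sort a table with chrom/pos columns into layout order."""
        key = df["chrom"].map({n: i for i, n in enumerate(self.names)})
        if key.isna().any():
            bad = df.loc[key.isna(), "chrom"].iloc[0]
            raise ValidationError(f"chromosome {bad!r} not in layout")
        cols = ["_ord"] + (["pos"] if "pos" in df.columns else ["start"]) + (extra or [])
        out = df.assign(_ord=key).sort_values(cols, kind="mergesort")
        return out.drop(columns="_ord").reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chromosomes, columns=["chrom", "length"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        return cls(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))))


def default_tomato_layout() -> GenomeLayout:
    """Twelve-chromosome layout with tomato-scale lengths (~774 Mb total).

    Chromosome 9 is long enough (68.6 Mb) to hold the 5-58 Mb wild
    introgression exclusion region used throughout.
    """
    mb = 1_000_000
    sizes = [90.3, 53.9, 65.8, 64.9, 65.5, 47.4, 68.0, 63.9, 68.6, 64.8, 54.4, 66.7]
    return GenomeLayout(tuple((f"chr{i + 1:02d}", int(s * mb)) for i, s in enumerate(sizes)))


# ---------------------------------------------------------------------------
# Variant sets
# ---------------------------------------------------------------------------

_VS_COLS = ["chrom", "pos", "ref", "alt", "genotype_class", "evidence"]


class VariantSet:
    """Biallelic SNP records for one genome, in reference coordinates.

    Backed by a DataFrame with columns ``chrom, pos, ref, alt,
    genotype_class, evidence``. ``pos`` is 1-based. ``genotype_class`` is
    ``hom_alt`` or ``het``. ``evidence`` is a comma-joined tag string (may
    be empty). ``(chrom, pos)`` is unique within a set and rows are kept
    sorted (layout order when a layout is attached, else lexicographic).
    """

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None):
        df = df.reindex(columns=_VS_COLS).copy()
        if df["chrom"].isna().any() or df["pos"].isna().any():
            raise ValidationError("chrom/pos must be present for every record")
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["evidence"] = df["evidence"].fillna("").astype(str)
        if (df["pos"] < 1).any():
            raise ValidationError("positions are 1-based and must be >= 1")
        for col in ("ref", "alt"):
            vals = df[col].astype(str)
            if not vals.isin(BASES).all():
                bad = vals[~vals.isin(BASES)].iloc[0]
                raise ValidationError(f"{col} allele {bad!r} is not a single base SNP allele")
            df[col] = vals
        if (df["ref"] == df["alt"]).any():
            raise ValidationError("ref and alt alleles must differ")
        if not df["genotype_class"].isin(GENOTYPE_CLASSES).all():
            bad = df.loc[~df["genotype_class"].isin(GENOTYPE_CLASSES), "genotype_class"].iloc[0]
            raise ValidationError(f"invalid genotype_class {bad!r}")
        dup = df.duplicated(["chrom", "pos"])
        if dup.any():
            key = df.loc[dup, ["chrom", "pos"]].iloc[0]
            raise ValidationError(f"duplicate record at {key['chrom']}:{key['pos']}")
        if layout is not None:
            df = layout.sort_frame(df)
        else:
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.layout = layout
        self.n_skipped = 0  # populated by readers that drop records

    # -- constructors -------------------------------------------------------

    @classmethod
    def empty(cls, layout: GenomeLayout | None = None) -> "VariantSet":
        return cls(pd.DataFrame(columns=_VS_COLS), layout=layout)

    @classmethod
    def from_records(cls, records: Iterable[tuple], layout: GenomeLayout | None = None) -> "VariantSet":
        """Build from (chrom, pos, ref, alt, genotype_class[, evidence]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 5:
                rec = rec + ("",)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=_VS_COLS), layout=layout)

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.df[["chrom", "pos"]])

    def hom_alt(self) -> "VariantSet":
        return self._wrap(self.df[self.df["genotype_class"] == "hom_alt"])

    def het(self) -> "VariantSet":
        return self._wrap(self.df[self.df["genotype_class"] == "het"])

    def _wrap(self, df: pd.DataFrame) -> "VariantSet":
        vs = VariantSet(df.reset_index(drop=True), layout=self.layout)
        return vs

    def equals(self, other: "VariantSet") -> bool:
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    def __repr__(self) -> str:
        return f"VariantSet({len(self)} records)"


# ---------------------------------------------------------------------------
# Region sets (BED-like)
# ---------------------------------------------------------------------------

class RegionSet:
    """Genomic intervals, 0-based half-open."""

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None):
        df = df.reindex(columns=["chrom", "start", "end"]).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValidationError("region start must be >= 0")
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"empty or inverted region {row['chrom']}:{row['start']}-{row['end']}"
            )
        if layout is not None:
            for _, row in df.iterrows():
                if row["chrom"] not in layout:
                    raise ValidationError(f"region chromosome {row['chrom']!r} not in layout")
                if row["end"] > layout.length(row["chrom"]):
                    raise ValidationError(
                        f"region {row['chrom']}:{row['start']}-{row['end']} exceeds chromosome length"
                    )
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.layout = layout

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(pd.DataFrame(columns=["chrom", "start", "end"]))

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]],
                       layout: GenomeLayout | None = None) -> "RegionSet":
        return cls(pd.DataFrame(list(intervals), columns=["chrom", "start", "end"]), layout=layout)

    def __len__(self) -> int:
        return len(self.df)

    def contains(self, chrom, pos) -> np.ndarray:
        """Membership of 1-based positions, vectorised.

        A position p (1-based) falls in [start, end) iff start < p <= end,
        i.e. 0-based p-1 in [start, end).
        """
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos, dtype=np.int64) - 1
        out = np.zeros(len(pos0), dtype=bool)
        for _, row in self.df.iterrows():
            out |= (chrom == row["chrom"]) & (pos0 >= row["start"]) & (pos0 < row["end"])
        return out

    def equals(self, other: "RegionSet") -> bool:
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals)"


# ---------------------------------------------------------------------------
# Allele count tables
# ---------------------------------------------------------------------------

_ACT_COLS = ["sample", "chrom", "pos", "ref_count", "alt_count"]


class AlleleCountTable:
    """Per-sample per-site read allele observations.

    Columns ``sample, chrom, pos, ref_count, alt_count``; depth is the sum
    of the two counts. ``(sample, chrom, pos)`` is unique. Zero-depth rows
    are retained (their allele frequency is treated as missing downstream).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reindex(columns=_ACT_COLS).copy()
        df["sample"] = df["sample"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for col in ("ref_count", "alt_count"):
            vals = df[col].astype(np.int64)
            if (vals < 0).any():
                raise ValidationError(f"negative {col} is not a read count")
            df[col] = vals
        dup = df.duplicated(["sample", "chrom", "pos"])
        if dup.any():
            row = df.loc[dup, ["sample", "chrom", "pos"]].iloc[0]
            raise ValidationError(
                f"duplicate count row for ({row['sample']}, {row['chrom']}, {row['pos']})"
            )
        self.df = df.sort_values(["sample", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    @classmethod
    def empty(cls) -> "AlleleCountTable":
        return cls(pd.DataFrame(columns=_ACT_COLS))

    @classmethod
    def concat(cls, tables: Iterable["AlleleCountTable"]) -> "AlleleCountTable":
        frames = [t.df for t in tables]
        if not frames:
            return cls.empty()
        return cls(pd.concat(frames, ignore_index=True))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.df["sample"].unique())

    def for_sample(self, sample_id: str) -> "AlleleCountTable":
        sub = self.df[self.df["sample"] == sample_id]
        if sub.empty:
            raise KeyError(f"no rows for sample {sample_id!r}")
        return AlleleCountTable(sub.reset_index(drop=True))

    def depth(self) -> pd.Series:
        return self.df["ref_count"] + self.df["alt_count"]

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "AlleleCountTable") -> bool:
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"AlleleCountTable({len(self)} rows, {len(self.samples)} samples)"


# ---------------------------------------------------------------------------
# Marker sets
# ---------------------------------------------------------------------------

class MarkerSet:
    """Haplotype-unique diagnostic SNP markers.

    Maps haplotype id -> DataFrame(chrom, pos, diagnostic_allele). Each
    (chrom, pos) belongs to at most one haplotype (markers are unique by
    construction and the container enforces it). ``diagnostic_allele`` is
    ``alt`` except for markers of the designated reference haplotype, which
    are diagnosed by reference-supporting reads.
    """

    def __init__(self, tables: Mapping[str, pd.DataFrame],
                 reference_id: str | None = None,
                 layout: GenomeLayout | None = None):
        clean: dict[str, pd.DataFrame] = {}
        for hap, df in tables.items():
            df = df.reindex(columns=["chrom", "pos", "diagnostic_allele"]).copy()
            df["chrom"] = df["chrom"].astype(str)
            df["pos"] = df["pos"].astype(np.int64)
            if not df["diagnostic_allele"].isin(DIAGNOSTIC_ALLELES).all():
                raise ValidationError("diagnostic_allele must be 'ref' or 'alt'")
            if reference_id is not None and hap != reference_id:
                if (df["diagnostic_allele"] == "ref").any():
                    raise ValidationError(
                        f"ref-diagnostic marker under non-reference haplotype {hap!r}"
                    )
            if df.duplicated(["chrom", "pos"]).any():
                raise ValidationError(f"duplicate marker position within haplotype {hap!r}")
            if layout is not None:
                df = layout.sort_frame(df)
            else:
                df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            clean[str(hap)] = df
        combined = pd.concat(
            [df[["chrom", "pos"]] for df in clean.values()],
            ignore_index=True) if clean else pd.DataFrame(columns=["chrom", "pos"])
        if combined.duplicated().any():
            row = combined[combined.duplicated()].iloc[0]
            raise ValidationError(
                f"marker position {row['chrom']}:{row['pos']} assigned to more than one haplotype"
            )
        self.tables = clean
        self.reference_id = reference_id
        self.layout = layout

    @property
    def haplotypes(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def __getitem__(self, hap: str) -> pd.DataFrame:
        return self.tables[hap]

    def counts(self) -> dict[str, int]:
        return {h: len(df) for h, df in self.tables.items()}

    def total(self) -> int:
        return sum(len(df) for df in self.tables.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: haplotype, chrom, pos, diagnostic_allele."""
        frames = [df.assign(haplotype=h)[["haplotype", "chrom", "pos", "diagnostic_allele"]]
                  for h, df in self.tables.items()]
        if not frames:
            return pd.DataFrame(columns=["haplotype", "chrom", "pos", "diagnostic_allele"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_id: str | None = None,
                   layout: GenomeLayout | None = None) -> "MarkerSet":
        tables = {str(h): g.drop(columns="haplotype").reset_index(drop=True)
                  for h, g in df.groupby("haplotype", sort=False)}
        return cls(tables, reference_id=reference_id, layout=layout)

    def positions_frame(self) -> pd.DataFrame:
        """All marker positions across haplotypes (chrom, pos), sorted."""
        f = self.to_frame()[["chrom", "pos"]]
        return f.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def density_per_mb(self, layout: GenomeLayout) -> pd.DataFrame:
        """Genome-wide marker density per haplotype (markers / Mb)."""
        total_mb = layout.total_bp / 1e6
        rows = [(h, len(df), len(df) / total_mb) for h, df in self.tables.items()]
        return pd.DataFrame(rows, columns=["haplotype", "n_markers", "per_mb"])

    def __repr__(self) -> str:
        inner = ", ".join(f"{h}:{n}" for h, n in self.counts().items())
        return f"MarkerSet({inner})"
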