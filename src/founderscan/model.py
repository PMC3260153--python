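"""Shared domain types for the autozygosity-mapping pipeline.

Coordinates are 1-based, fully-closed intervals throughout the package:
a block reported as [start, stop] includes both bounding positions, the
convention used when intervals are delimited by their flanking SNPs.
BED files are converted at the I/O boundary (see :mod:`founderscan.io`).

Genotype encodings
------------------
Array genotypes (biallelic markers with abstract alleles A/B) are stored
in a compact ``int8`` matrix::

    0 = AA    1 = AB    2 = BB    -1 = missing

Exome variant genotypes use the same shape with alt-allele dosage::

    0 = ref-hom    1 = het    2 = alt-hom    -1 = unknown/missing
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))

__all__ = [
    "AA", "AB", "BB", "MISSING",
    "REF_HOM", "HET", "ALT_HOM", "UNKNOWN",
    "CONSEQUENCE_CLASSES", "DEFAULT_PATHOGENIC_CLASSES",
    "FounderScanError", "ConfigError", "FormatError",
    "GenotypePanel", "SampleManifest", "VariantRecord", "VariantTable",
    "AlleleFrequencyTable", "HomozygousRun", "SharedBlock", "LinkageRegion",
    "TruthSet", "Interval",
]

# array-genotype codes
AA, AB, BB, MISSING = 0, 1, 2, -1
# variant-genotype codes (alt dosage)
REF_HOM, HET, ALT_HOM, UNKNOWN = 0, 1, 2, -1

#: The thirteen functional categories a variant may carry, exactly one each.
CONSEQUENCE_CLASSES = (
    "5'-flanking",
    "5'-UTR",
    "3'-UTR",
    "intron",
    "missense",
    "nonsense",
    "read-through",
    "splice site",
    "synonymous",
    "miRNA",
    "IGR",
    "other",
    "indel",
)

#: Classes treated as potentially pathogenic by default (configurable).
DEFAULT_PATHOGENIC_CLASSES = frozenset(
    {"missense", "nonsense", "read-through", "splice site", "indel"}
)


class FounderScanError(Exception):
    """Base class for package errors."""


class ConfigError(FounderScanError):
    """Invalid configuration or contract violation."""


class FormatError(FounderScanError):
    """Malformed input file."""


@dataclass(frozen=True)
class Interval:
    """1-based closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def size_mb(self) -> float:
        return self.size_bp / 1e6

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class GenotypePanel:
    """Marker map plus a sample x marker matrix of biallelic calls.

    Parameters
    ----------
    markers
        DataFrame with columns ``marker_id, chrom, pos, allele_a, allele_b``;
        re-sorted by (chrom, pos) on construction if needed.
    samples
        Ordered sample identifiers.
    calls
        ``int8`` array of shape (n_samples, n_markers) with codes
        {AA, AB, BB, MISSING}.
    """

    REQUIRED_MARKER_COLUMNS = ("marker_id", "chrom", "pos")

    def __init__(
        self,
        markers: pd.DataFrame,
        samples: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        markers = markers.copy()
        for col in self.REQUIRED_MARKER_COLUMNS:
            if col not in markers.columns:
                raise FormatError(f"marker table missing column {col!r}")
        if "allele_a" not in markers.columns:
            markers["allele_a"] = "A"
        if "allele_b" not in markers.columns:
            markers["allele_b"] = "B"
        samples = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers)):
            raise FormatError(
                f"call matrix shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        if markers["marker_id"].duplicated().any():
            dup = markers.loc[markers["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FormatError(f"duplicate marker id {dup!r}")
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample ids")
        bad = ~np.isin(calls, (AA, AB, BB, MISSING))
        if bad.any():
            raise FormatError(f"invalid genotype code(s): {np.unique(calls[bad])}")
        order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(markers))):
            markers = markers.iloc[order].reset_index(drop=True)
            calls = calls[:, order]
        else:
            markers = markers.reset_index(drop=True)
        self.markers = markers
        self.samples = samples
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def sample_rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.stack([self.sample_row(s) for s in sample_ids])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def marker_mask(self, chrom: str) -> np.ndarray:
        return (self.markers["chrom"] == chrom).to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers.equals(other.markers)
            and np.array_equal(self.calls, other.calls)
        )


class SampleManifest:
    """Pedigree, affection status, role, and deme label per sample.

    Wraps a DataFrame with columns ``sample_id, family_id, father_id,
    mother_id, status, role, deme``; absent parents are empty strings.
    """

    STATUSES = ("affected", "unaffected")
    ROLES = ("case", "parent", "sibling", "population_control")

    def __init__(self, table: pd.DataFrame) -> None:
        table = table.copy()
        required = ("sample_id", "family_id", "status", "role")
        for col in required:
            if col not in table.columns:
                raise FormatError(f"manifest missing column {col!r}")
        for col in ("father_id", "mother_id", "deme"):
            if col not in table.columns:
                table[col] = ""
        table = table.fillna({"father_id": "", "mother_id": "", "deme": ""})
        if table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in manifest")
        bad_status = set(table["status"]) - set(self.STATUSES)
        if bad_status:
            raise FormatError(f"unknown status value(s): {sorted(bad_status)}")
        bad_role = set(table["role"]) - set(self.ROLES)
        if bad_role:
            raise FormatError(f"unknown role value(s): {sorted(bad_role)}")
        ids = set(table["sample_id"])
        for col in ("father_id", "mother_id"):
            refs = set(table[col]) - {""}
            unresolved = refs - ids
            if unresolved:
                raise FormatError(
                    f"{col} references unknown sample(s): {sorted(unresolved)}"
                )
        self.table = table.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            row.sample_id: {p for p in (row.father_id, row.mother_id) if p}
            for row in self.table.itertuples()
        }
        WHITE, GRAY, BLACK = 0, 1, 2
        color = dict.fromkeys(parents, WHITE)

        def visit(s: str) -> None:
            color[s] = GRAY
            for p in parents[s]:
                if color[p] == GRAY:
                    raise FormatError(f"pedigree cycle involving {s!r}")
                if color[p] == WHITE:
                    visit(p)
            color[s] = BLACK

        for s in parents:
            if color[s] == WHITE:
                visit(s)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def ids_where(self, **conditions: str) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    @property
    def affected_ids(self) -> list[str]:
        return self.ids_where(status="affected")

    @property
    def unaffected_ids(self) -> list[str]:
        return self.ids_where(status="unaffected")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_where(role="population_control")

    def parents_of(self, sample_id: str) -> tuple[str, str]:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in manifest")
        r = row.iloc[0]
        return r["father_id"], r["mother_id"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleManifest):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class VariantRecord:
    """One exome variant (one ALT allele) with per-sample genotypes.

    ``genotypes`` maps sample id to alt-allele dosage; indels called with
    unknown zygosity use :data:`UNKNOWN` plus ``zygosity_known=False``.
    ``catalogs`` lists the reference catalogs the variant appears in —
    novelty is simple absence from all queried catalogs.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    genotypes: dict[str, int]
    catalogs: frozenset[str] = frozenset()
    gene: str | None = None
    zygosity_known: bool = True
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise FormatError(
                f"unknown consequence class {self.consequence!r} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.consequence != "indel" and not self.zygosity_known:
            raise FormatError(
                f"SNV record at {self.chrom}:{self.pos} may not carry "
                "unknown zygosity"
            )
        self.catalogs = frozenset(self.catalogs)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.consequence == "indel"

    def genotype(self, sample_id: str) -> int:
        return self.genotypes.get(sample_id, UNKNOWN)

    def with_genotypes(self, genotypes: Mapping[str, int]) -> "VariantRecord":
        return replace(self, genotypes=dict(genotypes))


class VariantTable:
    """Column-oriented table of exome variants.

    ``variants`` holds one row per (chrom, pos, ref, alt) with columns
    ``chrom, pos, ref, alt, consequence, gene, zygosity_known, catalogs``
    (``catalogs`` stores frozensets of catalog names). ``genotypes`` is an
    ``int8`` dosage matrix of shape (n_variants, n_samples) with codes
    {REF_HOM, HET, ALT_HOM, UNKNOWN}. Rows are kept sorted by coordinate
    so that identical inputs always serialize identically.
    """

    COLUMNS = ("chrom", "pos", "ref", "alt", "consequence", "gene",
               "zygosity_known", "catalogs")

    def __init__(
        self,
        variants: pd.DataFrame,
        genotypes: np.ndarray,
        samples: Sequence[str],
    ) -> None:
        variants = variants.copy()
        for col in self.COLUMNS:
            if col not in variants.columns:
                raise FormatError(f"variant table missing column {col!r}")
        samples = list(samples)
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(variants), len(samples)):
            raise FormatError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        bad = ~variants["consequence"].isin(CONSEQUENCE_CLASSES)
        if bad.any():
            raise FormatError(
                "unknown consequence class(es): "
                f"{sorted(variants.loc[bad, 'consequence'].unique())}"
            )
        snv_unknown_zyg = (~variants["zygosity_known"]) & (
            variants["consequence"] != "indel"
        )
        if snv_unknown_zyg.any():
            row = variants.loc[snv_unknown_zyg].iloc[0]
            raise FormatError(
                f"SNV record at {row['chrom']}:{row['pos']} may not carry "
                "unknown zygosity"
            )
        order = variants.sort_values(
            ["chrom", "pos", "ref", "alt"], kind="mergesort"
        ).index.to_numpy()
        self.variants = variants.loc[order].reset_index(drop=True)
        self.genotypes = genotypes[order]
        self.samples = samples
        self._sample_index = {s: i for i, s in enumerate(samples)}

    @classmethod
    def from_records(cls, records: Iterable[VariantRecord]) -> "VariantTable":
        records = list(records)
        samples: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                samples.setdefault(s)
        samples = list(samples)
        idx = {s: i for i, s in enumerate(samples)}
        geno = np.full((len(records), len(samples)), UNKNOWN, dtype=np.int8)
        rows = []
        for i, r in enumerate(records):
            rows.append(
                (r.chrom, r.pos, r.ref, r.alt, r.consequence, r.gene,
                 r.zygosity_known, frozenset(r.catalogs))
            )
            for s, g in r.genotypes.items():
                geno[i, idx[s]] = g
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, geno, samples)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return self.records()

    def records(self):
        """Yield one :class:`VariantRecord` per row (materialized lazily)."""
        for i in range(len(self)):
            yield self.record(i)

    def record(self, i: int) -> VariantRecord:
        row = self.variants.iloc[i]
        return VariantRecord(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            consequence=row["consequence"],
            genotypes={
                s: int(self.genotypes[i, j]) for j, s in enumerate(self.samples)
            },
            catalogs=row["catalogs"],
            gene=row["gene"] if pd.notna(row["gene"]) else None,
            zygosity_known=bool(row["zygosity_known"]),
        )

    def sample_column(self, sample_id: str) -> np.ndarray:
        try:
            return self.genotypes[:, self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in variant table") from None

    def sample_columns(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Dosage sub-matrix (n_variants x len(sample_ids))."""
        return np.stack([self.sample_column(s) for s in sample_ids], axis=1)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.variants.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            self.samples,
        )

    def class_counts(self) -> pd.Series:
        counts = self.variants["consequence"].value_counts()
        return counts.reindex(list(CONSEQUENCE_CLASSES), fill_value=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants.equals(other.variants)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class AlleleFrequencyTable:
    """Per-marker frequency of allele A estimated from control samples.

    ``freq_a`` is NaN for markers with every control call missing; those
    markers are excluded from LOD scoring.
    """

    freq_a: np.ndarray
    n_chromosomes: np.ndarray
    pseudocount: float

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.freq_a)


@dataclass(frozen=True)
class HomozygousRun:
    """Maximal run of homozygous calls in one sample."""

    sample_id: str
    chrom: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    n_markers: int
    n_missing: int = 0
    n_het: int = 0


@dataclass
class SharedBlock:
    """Interval of identical homozygosity across all affected samples."""

    chrom: str
    start_bp: int
    end_bp: int
    start_marker: str
    end_marker: str
    start_index: int
    end_index: int
    n_markers: int
    n_affected: int
    location_score: float | None = None
    n_skipped_markers: int = 0

    @property
    def size_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start_bp, self.end_bp)


@dataclass(frozen=True)
class LinkageRegion:
    """Region consistent with recessive linkage in one nuclear family."""

    chrom: str
    start_bp: int
    end_bp: int
    family_id: str

    @property
    def size_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start_bp, self.end_bp)


@dataclass
class TruthSet:
    """Simulator ground truth: realized autozygous segments per sample and
    the planted pathogenic variant with its carrier list."""

    ibd_segments: list[tuple[str, str, int, int]] = field(default_factory=list)
    pathogenic_variant: tuple[str, int, str, str] | None = None
    carriers: list[str] = field(default_factory=list)
    planted_dosage: dict[str, int] = field(default_factory=dict)

    def segments_for(self, sample_id: str) -> list[tuple[str, int, int]]:
        return [
            (chrom, start, end)
            for s, chrom, start, end in self.ibd_segments
            if s == sample_id
        ]
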