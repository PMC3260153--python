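"""Founder-population study simulator with known ground truth.

The generator emulates the study design used for mapping recessive
disorders in endogamous founder demes: a disease allele enters through one
founder couple, descends through consanguineous lineages to two or more
sibships, and renders affected children autozygous for a shared haplotype
block around the causal variant.  It produces

* a SNP-array-like :class:`~founderscan.model.GenotypePanel` (evenly
  spaced biallelic markers at a 10K- or 50K-like density, with genotype
  error and missing-call noise),
* an exome :class:`~founderscan.model.VariantTable` calibrated to the
  per-sample variant counts typical of early exome studies (~16,500
  autosomal variants of which ~4% are absent from reference catalogs),
* a :class:`~founderscan.model.TruthSet` recording realized autozygous
  segments and the planted pathogenic variant, so recovery can be scored.

Ancestry is tracked explicitly: each haplotype is a piecewise-constant map
from genomic position to a founder haplotype index, and meioses recombine
these maps with a Poisson crossover process (no interference).  Genotypes
are read off the founder haplotypes, which makes identity by descent an
exact, recorded quantity rather than an inference.

The planted autozygous segment has sharp, known boundaries: the affected
children's haplotypes switch to independent founder haplotypes exactly at
the segment edges (obligate crossovers), so that boundary-recovery tests
compare against a well-defined truth rather than against the fuzzy tail of
a naturally continuing haplotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    AA, AB, BB, MISSING,
    CONSEQUENCE_CLASSES,
    ConfigError,
    GenotypePanel,
    SampleManifest,
    TruthSet,
    VariantTable,
)

__all__ = [
    "MARKER_DENSITY_PER_MB",
    "TABLE_CLASS_WEIGHTS",
    "SimulationConfig",
    "Individual",
    "Pedigree",
    "FounderPool",
    "build_study_pedigree",
    "simulate_founders",
    "gene_drop",
    "simulate_exomes",
    "simulate_genes",
    "simulate_study",
    "StudyData",
]

#: Marker densities emulating the 10,000- and 50,000-SNP array generations
#: (autosomal genome ~2,880 Mb).
MARKER_DENSITY_PER_MB = {"10K": 3.5, "50K": 17.4}

#: Default consequence-class weights: average per-sample autosomal variant
#: counts by class in an early-exome cohort (see docs/methods.md).
TABLE_CLASS_WEIGHTS: dict[str, float] = {
    "5'-flanking": 12,
    "5'-UTR": 25,
    "3'-UTR": 29,
    "intron": 207,
    "missense": 6936,
    "nonsense": 46,
    "read-through": 10,
    "splice site": 16,
    "synonymous": 8931,
    "miRNA": 5,
    "IGR": 56,
    "other": 62,
    "indel": 203,
}

# rng stream indices fanned out from the top-level seed
_STAGE_FOUNDERS, _STAGE_GENEDROP, _STAGE_NOISE, _STAGE_EXOME, _STAGE_GENES = range(5)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(5)
    return np.random.Generator(np.random.PCG64(children[stage]))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic founder-population generator.

    Defaults describe the emulated study: two consanguineous sibships
    (four affected children and eleven genotyped relatives), a 50K-like
    marker panel, a 4 Mb planted autozygous block, array noise at realistic
    call-error/no-call rates, and exomes calibrated to ~16,540 variants per
    sample with ~4% novel.
    """

    n_founder_haplotypes: int = 40
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 80_000_000}
    )
    target_inbreeding_F: float = 0.03
    marker_density_per_mb: float = MARKER_DENSITY_PER_MB["50K"]
    marker_freq_range: tuple[float, float] = (0.3, 0.7)
    genotype_error_rate: float = 0.005
    missing_call_rate: float = 0.005
    recombination_rate_per_bp: float = 1e-8  # 1 crossover / 100 Mb expected

    # pedigree structure: affecteds drawn from separate sibships, the
    # configuration that maps cleanly in practice (siblings share flanking
    # haplotypes, which blurs shared-block boundaries)
    n_sibships: int = 4
    n_affected_per_sibship: int = 1
    n_unaffected_per_sibship: tuple[int, ...] = (1, 1, 1, 0)
    n_population_controls: int = 100
    deme: str = "deme1"

    # planted disease locus (None disables planting and conditioning)
    pathogenic_block: tuple[str, int, int] | None = ("chr1", 48_000_000, 52_000_000)
    pathogenic_position: int | None = None  # default: block midpoint
    pathogenic_ref: str = "C"
    pathogenic_alt: str = "T"
    pathogenic_consequence: str = "missense"

    # exome model
    exome_variant_rate: float = 16540.0
    novel_fraction: float = 667.0 / 16540.0
    consequence_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(TABLE_CLASS_WEIGHTS)
    )
    known_site_freq_range: tuple[float, float] = (0.05, 0.5)
    catalog_names: tuple[str, ...] = ("dbSNP129", "1KG")
    n_benign_shared: int = 1

    # synthetic gene annotation
    genes_per_mb: float = 18.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_founder_haplotypes < 4:
            raise ConfigError("n_founder_haplotypes must be >= 4")
        if not self.chromosome_lengths:
            raise ConfigError("chromosome_lengths must not be empty")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {chrom!r} has non-positive length")
        for name in (
            "genotype_error_rate", "missing_call_rate", "novel_fraction",
            "target_inbreeding_F",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.marker_density_per_mb <= 0:
            raise ConfigError("marker_density_per_mb must be positive")
        if self.pathogenic_block is not None:
            chrom, start, end = self.pathogenic_block
            if chrom not in self.chromosome_lengths:
                raise ConfigError(f"pathogenic block chromosome {chrom!r} unknown")
            if not 1 <= start < end <= self.chromosome_lengths[chrom]:
                raise ConfigError("pathogenic block must lie inside its chromosome")
            pos = self.pathogenic_position
            if pos is not None and not start <= pos <= end:
                raise ConfigError("pathogenic position outside the planted block")
        unknown = set(self.consequence_class_weights) - set(CONSEQUENCE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown consequence class(es): {sorted(unknown)}")
        if sum(self.consequence_class_weights.values()) <= 0:
            raise ConfigError("consequence_class_weights must sum to > 0")
        if self.pathogenic_consequence not in CONSEQUENCE_CLASSES:
            raise ConfigError(
                f"unknown pathogenic consequence {self.pathogenic_consequence!r}"
            )
        lo, hi = self.marker_freq_range
        if not 0 < lo < hi < 1:
            raise ConfigError("marker_freq_range must satisfy 0 < lo < hi < 1")

    @property
    def planted_variant_position(self) -> int | None:
        if self.pathogenic_block is None:
            return None
        if self.pathogenic_position is not None:
            return self.pathogenic_position
        _, start, end = self.pathogenic_block
        return (start + end) // 2

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("pathogenic_block", "n_unaffected_per_sibship",
                    "marker_freq_range", "known_site_freq_range",
                    "catalog_names"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_file(self, path) -> None:
        raw = dataclasses.asdict(self)
        for key, value in raw.items():
            if isinstance(value, tuple):
                raw[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class Individual:
    """One pedigree member; ``genotyped`` marks panel membership."""

    id: str
    father: str | None = None
    mother: str | None = None
    status: str = "unaffected"
    role: str = "sibling"
    family_id: str = "FAM"
    genotyped: bool = True
    # conditioning: parent ids whose gamete must carry the disease haplotype
    # across the planted span
    must_carry_from: tuple[str, ...] = ()


class Pedigree:
    """Ordered pedigree (parents precede children)."""

    def __init__(self, deme: str = "deme1") -> None:
        self.members: dict[str, Individual] = {}
        self.deme = deme
        self.disease_founder: str | None = None

    def add(self, ind: Individual) -> Individual:
        if ind.id in self.members:
            raise ConfigError(f"duplicate pedigree id {ind.id!r}")
        for parent in (ind.father, ind.mother):
            if parent is not None and parent not in self.members:
                raise ConfigError(
                    f"parent {parent!r} of {ind.id!r} not defined before child"
                )
        self.members[ind.id] = ind
        return ind

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def founders(self) -> list[Individual]:
        return [m for m in self if m.father is None and m.mother is None]

    def genotyped_ids(self) -> list[str]:
        return [m.id for m in self if m.genotyped]

    def affected_ids(self) -> list[str]:
        return [m.id for m in self if m.status == "affected" and m.genotyped]

    def ancestors(self, sample_id: str) -> set[str]:
        out: set[str] = set()
        stack = [sample_id]
        while stack:
            ind = self.members[stack.pop()]
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def has_consanguinity_loop(self) -> bool:
        for m in self:
            if m.father is not None and m.mother is not None:
                if self.ancestors(m.father) & self.ancestors(m.mother):
                    return True
        return False

    def to_manifest(self) -> SampleManifest:
        genotyped = set(self.genotyped_ids())
        rows = []
        for m in self:
            if not m.genotyped:
                continue
            rows.append({
                "sample_id": m.id,
                "family_id": m.family_id,
                "father_id": m.father if m.father in genotyped else "",
                "mother_id": m.mother if m.mother in genotyped else "",
                "status": m.status,
                "role": m.role,
                "deme": self.deme,
            })
        return SampleManifest(pd.DataFrame(rows))


def _lineage_depths(target_F: float) -> tuple[int, int]:
    """Depths of the two lineages from the founder couple to the parents.

    With a single shared founder couple the offspring inbreeding
    coefficient is F = 2^-(d1+d2); depths are chosen so F is as close as
    possible to the target (first cousins 1/16, once removed 1/32, second
    cousins 1/64).
    """
    if target_F <= 0:
        raise ConfigError("target_inbreeding_F must be > 0 for a study pedigree")
    total = int(round(-np.log2(target_F)))
    total = max(4, min(6, total))
    d1 = total // 2
    return d1, total - d1


def build_study_pedigree(config: SimulationConfig) -> Pedigree:
    """Pedigree for the mapping study defined by ``config``.

    One founder couple carries the disease haplotype; for each sibship two
    lineages descend from the couple to a consanguineous parent pair whose
    children include affected individuals.  Lineage ancestors are not
    genotyped (as in retrospective studies); affected children, their
    parents, unaffected siblings and population controls are.
    """
    ped = Pedigree(deme=config.deme)
    fc1 = ped.add(Individual("FC1", role="parent", genotyped=False))
    ped.add(Individual("FC2", role="parent", genotyped=False))
    ped.disease_founder = fc1.id

    d1, d2 = _lineage_depths(config.target_inbreeding_F)
    n_unaff = config.n_unaffected_per_sibship
    if isinstance(n_unaff, int):
        n_unaff = (n_unaff,) * config.n_sibships
    if len(n_unaff) < config.n_sibships:
        n_unaff = tuple(n_unaff) + (n_unaff[-1],) * (config.n_sibships - len(n_unaff))

    for s in range(1, config.n_sibships + 1):
        fam = f"FAM{s:02d}"
        parents = []
        for lineage, depth in (("a", d1), ("b", d2)):
            carrier = "FC1"
            other = "FC2"
            for g in range(1, depth + 1):
                child_id = f"L{s}{lineage}{g}"
                ped.add(Individual(
                    child_id, father=carrier, mother=other, family_id=fam,
                    genotyped=(g == depth),
                    role="parent" if g == depth else "sibling",
                    must_carry_from=(carrier,),
                ))
                if g < depth:
                    spouse_id = f"S{s}{lineage}{g}"
                    ped.add(Individual(spouse_id, family_id=fam, genotyped=False,
                                       role="parent"))
                    carrier, other = child_id, spouse_id
                else:
                    carrier = child_id
            parents.append(carrier)
        father, mother = parents
        for i in range(1, config.n_affected_per_sibship + 1):
            ped.add(Individual(
                f"AFF{s}_{i}", father=father, mother=mother, family_id=fam,
                status="affected", role="case",
                must_carry_from=(father, mother),
            ))
        for i in range(1, n_unaff[s - 1] + 1):
            ped.add(Individual(
                f"SIB{s}_{i}", father=father, mother=mother, family_id=fam,
                role="sibling",
            ))

    for i in range(1, config.n_population_controls + 1):
        ped.add(Individual(f"CTRL{i:03d}", family_id=f"CTRL{i:03d}",
                           role="population_control"))
    return ped


def build_cousin_mating_pedigree(
    n_couples: int, n_children: int, degree_F: float = 1 / 16
) -> Pedigree:
    """Plain consanguineous matings (no disease) for inbreeding checks."""
    cfg = SimulationConfig(
        target_inbreeding_F=degree_F,
        n_sibships=n_couples,
        n_affected_per_sibship=0,
        n_unaffected_per_sibship=(n_children,) * n_couples,
        n_population_controls=0,
        pathogenic_block=None,
    )
    return build_study_pedigree(cfg)


@dataclass
class FounderPool:
    """Founder haplotype alleles plus the generating frequency spectrum."""

    markers: pd.DataFrame
    haplotypes: np.ndarray  # (n_haplotypes, n_markers) 0 = allele A, 1 = B
    spectrum_freq_a: np.ndarray
    realized_freq_a: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def _marker_map(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[chrom]
        n = max(1, int(round(config.marker_density_per_mb * length / 1e6)))
        spacing = length / n
        for i in range(n):
            pos = int(round((i + 0.5) * spacing))
            rows.append((f"{chrom}_snp{i + 1:06d}", chrom, max(1, pos)))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    df["allele_a"] = "A"
    df["allele_b"] = "B"
    return df


def simulate_founders(config: SimulationConfig) -> FounderPool:
    """Draw the founder haplotype pool.

    Marker positions are evenly spaced at the configured density; allele-A
    frequencies are drawn uniformly from ``marker_freq_range`` (emulating
    array SNPs ascertained to be polymorphic) and haplotype alleles are
    independent Bernoulli draws per marker.
    """
    if config.n_founder_haplotypes < 4:
        raise ConfigError("n_founder_haplotypes must be >= 4")
    rng = _stage_rng(config.rng_seed, _STAGE_FOUNDERS)
    markers = _marker_map(config)
    n_markers = len(markers)
    lo, hi = config.marker_freq_range
    freq_a = rng.uniform(lo, hi, size=n_markers)
    haps = (rng.random((config.n_founder_haplotypes, n_markers))
            >= freq_a).astype(np.int8)
    return FounderPool(
        markers=markers,
        haplotypes=haps,
        spectrum_freq_a=freq_a,
        realized_freq_a=1.0 - haps.mean(axis=0),
    )


# --------------------------------------------------------------------------
# ancestry tracks: piecewise-constant founder-haplotype index along a
# chromosome, encoded as (starts, hap_ids) with starts[0] == 1

Track = tuple[np.ndarray, np.ndarray]


def _constant_track(hap_id: int) -> Track:
    return np.array([1], dtype=np.int64), np.array([hap_id], dtype=np.int32)


def _track_at(track: Track, pos: np.ndarray | int):
    starts, haps = track
    idx = np.searchsorted(starts, pos, side="right") - 1
    return haps[idx]


def _simplify(starts: np.ndarray, haps: np.ndarray) -> Track:
    keep = np.ones(len(starts), dtype=bool)
    keep[1:] = haps[1:] != haps[:-1]
    return starts[keep], haps[keep]


def _meiosis(rng: np.random.Generator, t1: Track, t2: Track,
             length: int, rate: float) -> Track:
    """One gamete: alternate between the parent's two tracks at Poisson
    crossover points (no interference)."""
    n_x = rng.poisson(length * rate)
    cuts = np.sort(rng.integers(2, length + 1, size=n_x)) if n_x else \
        np.empty(0, dtype=np.int64)
    phase = int(rng.integers(0, 2))
    tracks = (t1, t2)
    seg_starts: list[np.ndarray] = []
    seg_haps: list[np.ndarray] = []
    bounds = np.concatenate(([1], cuts, [length + 1]))
    for i in range(len(bounds) - 1):
        a, b = int(bounds[i]), int(bounds[i + 1]) - 1
        if a > b:
            continue
        starts, haps = tracks[(phase + i) % 2]
        j0 = np.searchsorted(starts, a, side="right") - 1
        j1 = np.searchsorted(starts, b, side="right") - 1
        piece_starts = starts[j0:j1 + 1].copy()
        piece_starts[0] = a
        seg_starts.append(piece_starts)
        seg_haps.append(haps[j0:j1 + 1])
    return _simplify(np.concatenate(seg_starts), np.concatenate(seg_haps))


def _carries_throughout(track: Track, hap_id: int, span: tuple[int, int]) -> bool:
    starts, haps = track
    a, b = span
    j0 = np.searchsorted(starts, a, side="right") - 1
    j1 = np.searchsorted(starts, b, side="right") - 1
    return bool(np.all(haps[j0:j1 + 1] == hap_id))


def _force_span(track: Track, hap_id: int, span: tuple[int, int],
                length: int) -> Track:
    """Rewrite a track to carry ``hap_id`` exactly on ``span`` with obligate
    crossovers at the span edges (flanks keep the original ancestry)."""
    a, b = span
    starts, haps = track
    pieces_s = [starts[starts < a]]
    pieces_h = [haps[: len(pieces_s[0])]]
    pieces_s.append(np.array([a], dtype=np.int64))
    pieces_h.append(np.array([hap_id], dtype=np.int32))
    if b < length:
        after_val = _track_at(track, b + 1)
        tail_mask = starts > b
        pieces_s.append(np.array([b + 1], dtype=np.int64))
        pieces_h.append(np.array([after_val], dtype=np.int32))
        pieces_s.append(starts[tail_mask])
        pieces_h.append(haps[tail_mask])
    return _simplify(np.concatenate(pieces_s),
                     np.concatenate(pieces_h).astype(np.int32))


def _autozygous_segments(t1: Track, t2: Track, length: int) -> list[tuple[int, int]]:
    s1, h1 = t1
    s2, h2 = t2
    starts = np.union1d(s1, s2)
    v1 = _track_at(t1, starts)
    v2 = _track_at(t2, starts)
    ends = np.concatenate((starts[1:] - 1, [length]))
    segs: list[tuple[int, int]] = []
    for a, b, x, y in zip(starts, ends, v1, v2):
        if x == y:
            if segs and segs[-1][1] == a - 1:
                segs[-1] = (segs[-1][0], int(b))
            else:
                segs.append((int(a), int(b)))
    return segs


def gene_drop(
    founders: FounderPool,
    pedigree: Pedigree,
    config: SimulationConfig,
) -> tuple[GenotypePanel, TruthSet]:
    """Drop founder haplotypes through the pedigree and emit the panel.

    Affected individuals are conditioned (by resampling gametes) to inherit
    the disease founder haplotype from both parents across the whole
    planted block; unaffected relatives are resampled only if homozygous
    for the disease haplotype at the causal position.  Genotype errors and
    missing calls are injected at the configured rates afterwards.
    """
    if config.target_inbreeding_F > 0 and len(pedigree) > len(pedigree.founders()):
        if not pedigree.has_consanguinity_loop():
            raise ConfigError(
                "target_inbreeding_F > 0 requires a consanguinity loop "
                "in the pedigree"
            )
    rng = _stage_rng(config.rng_seed, _STAGE_GENEDROP)
    chroms = sorted(config.chromosome_lengths)
    lengths = config.chromosome_lengths
    rate = config.recombination_rate_per_bp

    planted = config.pathogenic_block
    p_pos = config.planted_variant_position
    disease_hap = 0  # first haplotype of the disease founder

    # assign founder haplotypes
    ped_founders = [m for m in pedigree.founders()
                    if m.role != "population_control"]
    controls = [m for m in pedigree.founders()
                if m.role == "population_control"]
    needed = 2 * len(ped_founders)
    if needed > founders.n_haplotypes:
        raise ConfigError(
            f"pedigree needs {needed} founder haplotypes, pool has "
            f"{founders.n_haplotypes}"
        )

    ancestry: dict[str, dict[str, tuple[Track, Track]]] = {}

    def set_founder(ind_id: str, hap_pair: tuple[int, int]) -> None:
        ancestry[ind_id] = {
            c: (_constant_track(hap_pair[0]), _constant_track(hap_pair[1]))
            for c in chroms
        }

    next_hap = 0
    for m in ped_founders:
        set_founder(m.id, (next_hap, next_hap + 1))
        next_hap += 2
    for m in controls:
        pair = rng.choice(founders.n_haplotypes, size=2, replace=False)
        set_founder(m.id, (int(pair[0]), int(pair[1])))

    def draw_gamete(parent_id: str, condition_carry: bool,
                    avoid_flanks: bool = False) -> dict[str, Track]:
        for _ in range(10_000):
            gamete = {
                c: _meiosis(rng, *ancestry[parent_id][c], lengths[c], rate)
                for c in chroms
            }
            if planted is None:
                return gamete
            chrom, a, b = planted
            if condition_carry and not _carries_throughout(
                    gamete[chrom], disease_hap, (a, b)):
                continue
            if avoid_flanks:
                # the planted segment must end exactly at the span edges:
                # the flanking ancestry of an affected child may not carry
                # the disease haplotype right outside the span, otherwise
                # the truth boundary would blur into its continuation
                if a > 1 and _track_at(gamete[chrom], a - 1) == disease_hap:
                    continue
                if (b < lengths[chrom]
                        and _track_at(gamete[chrom], b + 1) == disease_hap):
                    continue
            return gamete
        raise RuntimeError(f"conditioned gamete from {parent_id!r} not achieved")

    for m in pedigree:
        if m.father is None:
            continue
        affected = m.status == "affected" and planted is not None
        for _ in range(10_000):
            if affected:
                # transmission of the disease haplotype is forced below;
                # the drawn gametes only provide the flanking ancestry
                pat = draw_gamete(m.father, False, avoid_flanks=True)
                mat = draw_gamete(m.mother, False, avoid_flanks=True)
                break
            pat = draw_gamete(m.father, m.father in m.must_carry_from)
            mat = draw_gamete(m.mother, m.mother in m.must_carry_from)
            if planted is None:
                break
            chrom = planted[0]
            if not (_track_at(pat[chrom], p_pos) == disease_hap
                    and _track_at(mat[chrom], p_pos) == disease_hap):
                break  # unaffected must not be homozygous at the causal site
        else:
            raise RuntimeError(f"could not realize genotype for {m.id!r}")
        if affected:
            chrom, a, b = planted
            pat[chrom] = _force_span(pat[chrom], disease_hap, (a, b),
                                     lengths[chrom])
            mat[chrom] = _force_span(mat[chrom], disease_hap, (a, b),
                                     lengths[chrom])
        ancestry[m.id] = {c: (pat[c], mat[c]) for c in chroms}

    # genotypes at marker positions
    samples = pedigree.genotyped_ids()
    markers = founders.markers
    calls = np.empty((len(samples), len(markers)), dtype=np.int8)
    chrom_cols = markers["chrom"].to_numpy()
    pos_col = markers["pos"].to_numpy()
    for si, sid in enumerate(samples):
        for chrom in chroms:
            mask = chrom_cols == chrom
            pos = pos_col[mask]
            t1, t2 = ancestry[sid][chrom]
            a1 = founders.haplotypes[_track_at(t1, pos), np.flatnonzero(mask)]
            a2 = founders.haplotypes[_track_at(t2, pos), np.flatnonzero(mask)]
            calls[si, mask] = (a1 + a2).astype(np.int8)  # 0=AA 1=AB 2=BB

    # noise injection
    noise_rng = _stage_rng(config.rng_seed, _STAGE_NOISE)
    if config.genotype_error_rate > 0:
        err = noise_rng.random(calls.shape) < config.genotype_error_rate
        shift = noise_rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_call_rate > 0:
        miss = noise_rng.random(calls.shape) < config.missing_call_rate
        calls = np.where(miss, np.int8(MISSING), calls)

    panel = GenotypePanel(markers, samples, calls)

    # truth
    segments: list[tuple[str, str, int, int]] = []
    for sid in samples:
        for chrom in chroms:
            for a, b in _autozygous_segments(*ancestry[sid][chrom],
                                             lengths[chrom]):
                segments.append((sid, chrom, a, b))
    truth = TruthSet(ibd_segments=segments)
    if planted is not None:
        chrom = planted[0]
        dosage = {
            sid: (
                int(_track_at(ancestry[sid][chrom][0], p_pos) == disease_hap)
                + int(_track_at(ancestry[sid][chrom][1], p_pos) == disease_hap)
            )
            for sid in samples
        }
        truth.pathogenic_variant = (
            chrom, p_pos, config.pathogenic_ref, config.pathogenic_alt
        )
        truth.carriers = [s for s in samples if dosage[s] >= 1]
        truth.planted_dosage = dosage  # extra field, used by simulate_exomes
    truth._ancestry = ancestry  # internal: inspected by diagnostics/tests
    return panel, truth


def _random_bases(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def _draw_positions(rng: np.random.Generator, config: SimulationConfig,
                    n: int) -> tuple[np.ndarray, np.ndarray]:
    chroms = sorted(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[which]).astype(np.int64) + 1
    return np.array(chroms, dtype=object)[which], pos


def simulate_exomes(
    panel: GenotypePanel,
    truth: TruthSet,
    config: SimulationConfig,
    manifest: SampleManifest | None = None,
) -> VariantTable:
    """Emit the cohort exome variant table.

    Catalogued (non-novel) sites are shared across samples with
    Hardy-Weinberg genotypes at ascertainment frequencies; novel variants
    are private Poisson draws per sample, homozygous when they land inside
    one of the sample's realized autozygous segments (which reproduces the
    observed handful of novel homozygous variants per inbred exome).  The
    planted pathogenic variant receives exactly the genotypes implied by
    the gene-drop; optional "benign shared" confounders are novel variants
    homozygous in all affecteds and in one unaffected relative, emulating
    shared non-pathogenic founder variation.
    """
    rng = _stage_rng(config.rng_seed, _STAGE_EXOME)
    if manifest is not None:
        samples = [s for s in panel.samples
                   if s in set(manifest.sample_ids)
                   and s not in set(manifest.control_ids)]
        affected = [s for s in manifest.affected_ids if s in samples]
        unaffected = [s for s in samples if s not in set(affected)]
    else:
        samples = list(panel.samples)
        affected, unaffected = [], list(samples)
    n_samples = len(samples)

    frames: list[pd.DataFrame] = []
    genos: list[np.ndarray] = []

    classes = np.array(list(config.consequence_class_weights), dtype=object)
    weights = np.array(list(config.consequence_class_weights.values()), float)
    weights = weights / weights.sum()

    # --- catalogued background sites -------------------------------------
    lo, hi = config.known_site_freq_range
    # E[1-(1-q)^2] for q ~ U(lo, hi)
    e_nonref = 1.0 - ((1 - lo) ** 3 - (1 - hi) ** 3) / (3 * (hi - lo))
    known_per_sample = config.exome_variant_rate * (1.0 - config.novel_fraction)
    n_known = int(round(known_per_sample / e_nonref))
    if n_known > 0:
        chrom, pos = _draw_positions(rng, config, n_known)
        ref, alt = _random_bases(rng, n_known)
        csq = rng.choice(classes, size=n_known, p=weights)
        q = rng.uniform(lo, hi, size=n_known)
        g = (
            (rng.random((n_known, n_samples)) < q[:, None]).astype(np.int8)
            + (rng.random((n_known, n_samples)) < q[:, None]).astype(np.int8)
        )
        cat_choice = rng.choice(3, size=n_known, p=[0.8, 0.15, 0.05])
        cat_sets = np.array([
            frozenset(config.catalog_names),
            frozenset(config.catalog_names[:1]),
            frozenset(config.catalog_names[1:]) or
            frozenset(config.catalog_names[:1]),
        ], dtype=object)
        is_indel = csq == "indel"
        g[is_indel] = (g[is_indel] > 0).astype(np.int8)
        df = pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "consequence": csq, "gene": None,
            "zygosity_known": ~is_indel, "catalogs": cat_sets[cat_choice],
        })
        frames.append(df)
        genos.append(g)

    # --- private novel variants ------------------------------------------
    novel_rate = config.exome_variant_rate * config.novel_fraction
    auto_segs = {
        s: {} for s in samples
    }
    for s in samples:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, a, b in truth.segments_for(s):
            by_chrom.setdefault(chrom, []).append((a, b))
        auto_segs[s] = {
            c: (np.array([x[0] for x in v]), np.array([x[1] for x in v]))
            for c, v in by_chrom.items()
        }
    for si, s in enumerate(samples):
        n_s = rng.poisson(novel_rate)
        if n_s == 0:
            continue
        chrom, pos = _draw_positions(rng, config, n_s)
        ref, alt = _random_bases(rng, n_s)
        csq = rng.choice(classes, size=n_s, p=weights)
        hom = np.zeros(n_s, dtype=bool)
        for c in np.unique(chrom):
            if c not in auto_segs[s]:
                continue
            starts, ends = auto_segs[s][c]
            mask = chrom == c
            p = pos[mask]
            idx = np.searchsorted(starts, p, side="right") - 1
            inside = (idx >= 0) & (p <= ends[np.clip(idx, 0, None)])
            hom[mask] = inside
        g = np.zeros((n_s, n_samples), dtype=np.int8)
        g[:, si] = np.where(hom, 2, 1).astype(np.int8)
        is_indel = csq == "indel"
        g[is_indel, si] = np.minimum(g[is_indel, si], 1)
        df = pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "consequence": csq, "gene": None,
            "zygosity_known": ~is_indel,
            "catalogs": [frozenset()] * n_s,
        })
        frames.append(df)
        genos.append(g)

    # --- planted pathogenic variant and benign shared confounders ---------
    if truth.pathogenic_variant is not None:
        chrom, p_pos, ref, alt = truth.pathogenic_variant
        block = config.pathogenic_block
        if block is not None and not block[1] <= p_pos <= block[2]:
            raise ConfigError("planted variant position outside planted block")
        dosage = getattr(truth, "planted_dosage", {})
        g = np.array([[dosage.get(s, 0) for s in samples]], dtype=np.int8)
        frames.append(pd.DataFrame({
            "chrom": [chrom], "pos": [p_pos], "ref": [ref], "alt": [alt],
            "consequence": [config.pathogenic_consequence],
            "gene": ["DISEASE1"], "zygosity_known": [True],
            "catalogs": [frozenset()],
        }))
        genos.append(g)

        for k in range(config.n_benign_shared):
            if not unaffected:
                break
            while True:
                c_arr, p_arr = _draw_positions(rng, config, 1)
                c0, p0 = c_arr[0], int(p_arr[0])
                if block is None or not (c0 == block[0]
                                         and block[1] <= p0 <= block[2]):
                    break
            lucky = int(rng.integers(0, len(unaffected)))
            g = np.zeros((1, n_samples), dtype=np.int8)
            for s in affected:
                g[0, samples.index(s)] = 2
            g[0, samples.index(unaffected[lucky])] = 2
            others = [s for s in unaffected if s != unaffected[lucky]]
            for s in others:
                g[0, samples.index(s)] = int(rng.integers(0, 2))
            ref0, alt0 = _random_bases(rng, 1)
            frames.append(pd.DataFrame({
                "chrom": [c0], "pos": [p0], "ref": [ref0[0]], "alt": [alt0[0]],
                "consequence": ["missense"], "gene": [f"BENIGN{k + 1}"],
                "zygosity_known": [True], "catalogs": [frozenset()],
            }))
            genos.append(g)

    if not frames:
        empty = pd.DataFrame({c: [] for c in VariantTable.COLUMNS})
        return VariantTable(empty, np.empty((0, n_samples), np.int8), samples)
    variants = pd.concat(frames, ignore_index=True)
    genotypes = np.concatenate(genos, axis=0)
    return VariantTable(variants, genotypes, samples)


def simulate_genes(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic gene annotation track (intervals only, 1-based closed)."""
    rng = _stage_rng(config.rng_seed, _STAGE_GENES)
    rows = []
    i = 0
    for chrom in sorted(config.chromosome_lengths):
        length = config.chromosome_lengths[chrom]
        n = int(round(config.genes_per_mb * length / 1e6))
        starts = np.sort(rng.integers(1, max(2, length - 100_000), size=n))
        sizes = rng.integers(10_000, 100_000, size=n)
        for a, w in zip(starts, sizes):
            i += 1
            rows.append((chrom, int(a), int(min(a + w, length)), f"GENE{i:05d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    config: SimulationConfig
    founders: FounderPool
    pedigree: Pedigree
    panel: GenotypePanel
    manifest: SampleManifest
    truth: TruthSet
    variants: VariantTable
    genes: pd.DataFrame


def simulate_study(config: SimulationConfig) -> StudyData:
    """Run the full generator: founders, gene drop, exomes, annotation."""
    founders = simulate_founders(config)
    pedigree = build_study_pedigree(config)
    panel, truth = gene_drop(founders, pedigree, config)
    manifest = pedigree.to_manifest()
    variants = simulate_exomes(panel, truth, config, manifest)
    genes = simulate_genes(config)
    return StudyData(config, founders, pedigree, panel, manifest, truth,
                     variants, genes)
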