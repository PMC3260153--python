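"""Recessive candidate-variant filtering under mutation homogeneity.

The cascade narrows a cohort exome table to candidates for a recessive
founder mutation: restrict to mapped intervals, keep variants absent from
reference catalogs (novel), require homozygosity in every affected
individual, exclude anything homozygous in an unaffected individual, and
optionally keep only consequence classes with pathogenic potential.
Each stage's input/kept/dropped counts are recorded; kept + dropped equals
the input count at every stage by construction.

With two or more affected individuals the same candidate emerges without
any mapping at all (:func:`homogeneity_scan`): a variant novel and
homozygous in all affecteds but homozygous in no other studied individual
is already essentially unique genome-wide, which is what makes the
mutation-homogeneity assumption so powerful in founder demes.

Indels whose zygosity the caller did not determine are retained through
the homozygosity stages (flagged) rather than silently dropped; a strict
mode drops them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ALT_HOM, HET, REF_HOM, UNKNOWN,
    CONSEQUENCE_CLASSES,
    DEFAULT_PATHOGENIC_CLASSES,
    ConfigError,
    Interval,
    SampleManifest,
    VariantRecord,
    VariantTable,
)

__all__ = [
    "DEFAULT_CATALOGS",
    "FilterConfig",
    "FilterReport",
    "CandidateVariant",
    "SegregationResult",
    "annotate_novelty",
    "classify_pathogenic_potential",
    "filter_candidates",
    "homogeneity_scan",
    "check_segregation",
]

DEFAULT_CATALOGS = ("dbSNP129", "1KG")


@dataclass
class FilterConfig:
    """Cascade options.

    ``catalog_names`` defines novelty (absence from all of them);
    ``valid_catalogs`` is the universe of known catalog names, used to
    reject typos.  ``consequence_filter`` gates the final class filter;
    ``retain_classes`` lets UTR/intronic classes through it when desired.
    ``strict_indels`` drops unknown-zygosity indels at the homozygosity
    stage instead of retaining them flagged.
    """

    catalog_names: tuple[str, ...] = DEFAULT_CATALOGS
    valid_catalogs: tuple[str, ...] = DEFAULT_CATALOGS
    pathogenic_classes: frozenset[str] = DEFAULT_PATHOGENIC_CLASSES
    consequence_filter: bool = True
    retain_classes: frozenset[str] = frozenset()
    strict_indels: bool = False
    genome_wide: bool = False


@dataclass
class FilterReport:
    """Stage-by-stage accounting plus per-variant flags.

    ``stages`` rows are (stage, n_input, n_kept, n_dropped); ``flags`` is
    aligned with the *input* variant table.
    """

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)
    flags: pd.DataFrame | None = None
    n_missing_affected_genotypes: int = 0
    n_indels_unknown_zygosity_retained: int = 0

    def add_stage(self, name: str, mask_in: np.ndarray,
                  mask_out: np.ndarray) -> None:
        n_in = int(mask_in.sum())
        n_kept = int(mask_out.sum())
        self.stages.append((name, n_in, n_kept, n_in - n_kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_input", "n_kept", "n_dropped"]
        )


@dataclass
class CandidateVariant:
    """A variant surviving the cascade, with its filter flags."""

    record: VariantRecord
    in_interval: bool = True
    novel: bool = True
    homozygous_in_all_affected: bool = True
    homozygous_in_any_unaffected: bool = False
    potentially_pathogenic: bool = True
    zygosity_warning: bool = False

    @property
    def key(self):
        return self.record.key


def annotate_novelty(
    variants: VariantTable,
    catalog_names=DEFAULT_CATALOGS,
    valid_catalogs=DEFAULT_CATALOGS,
) -> np.ndarray:
    """Boolean novelty per variant: present in none of the named catalogs."""
    requested = set(catalog_names)
    unknown = requested - set(valid_catalogs)
    if unknown:
        raise ConfigError(f"unknown catalog name(s): {sorted(unknown)}")
    return np.array(
        [not (c & requested) for c in variants.variants["catalogs"]],
        dtype=bool,
    )


def classify_pathogenic_potential(
    consequence_class: str,
    pathogenic_classes: frozenset[str] = DEFAULT_PATHOGENIC_CLASSES,
) -> bool:
    """Whether a consequence class has pathogenic potential.

    Defaults treat protein-altering classes — missense, nonsense,
    read-through, splice site, indel — as potentially pathogenic and
    synonymous/UTR/intronic/intergenic classes as not; the set is
    configurable.
    """
    if consequence_class not in CONSEQUENCE_CLASSES:
        raise ConfigError(f"unknown consequence class {consequence_class!r}")
    return consequence_class in pathogenic_classes


def _in_intervals(variants: VariantTable, intervals: list[Interval]) -> np.ndarray:
    chrom = variants.variants["chrom"].to_numpy()
    pos = variants.variants["pos"].to_numpy()
    mask = np.zeros(len(variants), dtype=bool)
    for iv in intervals:
        mask |= (chrom == iv.chrom) & (pos >= iv.start) & (pos <= iv.end)
    return mask


def _hom_in_all(variants: VariantTable, sample_ids: list[str],
                config: FilterConfig, report: FilterReport) -> np.ndarray:
    """Homozygous-alternate in every listed sample.

    Missing genotypes count as not homozygous (and are tallied);
    unknown-zygosity indels pass when the variant is present in every
    sample, unless strict mode is on.
    """
    geno = variants.sample_columns(sample_ids)
    zyg_known = variants.variants["zygosity_known"].to_numpy()
    hom = np.all(geno == ALT_HOM, axis=1)
    report.n_missing_affected_genotypes += int(
        ((geno == UNKNOWN) & zyg_known[:, None]).sum()
    )
    if not config.strict_indels:
        present = np.all(geno >= HET, axis=1)
        indel_pass = ~zyg_known & present
        report.n_indels_unknown_zygosity_retained += int(
            (indel_pass & ~hom).sum()
        )
        hom = hom | indel_pass
    else:
        hom = hom & zyg_known
    return hom


def _hom_in_any(variants: VariantTable, sample_ids: list[str]) -> np.ndarray:
    if not sample_ids:
        return np.zeros(len(variants), dtype=bool)
    geno = variants.sample_columns(sample_ids)
    zyg_known = variants.variants["zygosity_known"].to_numpy()
    return np.any(geno == ALT_HOM, axis=1) & zyg_known


def _candidates_from_mask(variants, mask, flags) -> list[CandidateVariant]:
    out = []
    for i in np.flatnonzero(mask):
        out.append(CandidateVariant(
            record=variants.record(int(i)),
            in_interval=bool(flags["in_interval"][i]),
            novel=bool(flags["novel"][i]),
            homozygous_in_all_affected=bool(flags["hom_all_affected"][i]),
            homozygous_in_any_unaffected=bool(flags["hom_any_unaffected"][i]),
            potentially_pathogenic=bool(flags["potentially_pathogenic"][i]),
            zygosity_warning=not bool(
                variants.variants["zygosity_known"].iloc[int(i)]
            ),
        ))
    return out


def filter_candidates(
    variants: VariantTable,
    mapped_intervals: list[Interval] | None,
    affected_ids: list[str],
    unaffected_ids: list[str],
    config: FilterConfig | None = None,
) -> tuple[list[CandidateVariant], FilterReport]:
    """Run the full cascade and return candidates plus the stage report.

    Stage order: mapped interval -> novelty -> homozygous in all
    affecteds -> not homozygous in any unaffected -> consequence class
    (optional).  The interval and novelty stages commute; the order here
    follows the workflow in which mapping precedes sequencing.
    """
    if not affected_ids:
        raise ConfigError("at least one affected sample is required")
    config = config or FilterConfig()
    report = FilterReport()
    n = len(variants)
    mask = np.ones(n, dtype=bool)

    if mapped_intervals:
        in_interval = _in_intervals(variants, mapped_intervals)
    elif config.genome_wide:
        in_interval = np.ones(n, dtype=bool)
    else:
        raise ConfigError(
            "no mapped intervals supplied and genome-wide scanning disabled"
        )
    novel = annotate_novelty(variants, config.catalog_names,
                             config.valid_catalogs)
    hom_all = _hom_in_all(variants, affected_ids, config, report)
    hom_any_unaff = _hom_in_any(variants, unaffected_ids)
    pathogenic = np.array([
        classify_pathogenic_potential(c, config.pathogenic_classes)
        or c in config.retain_classes
        for c in variants.variants["consequence"]
    ])

    flags = {
        "in_interval": in_interval,
        "novel": novel,
        "hom_all_affected": hom_all,
        "hom_any_unaffected": hom_any_unaff,
        "potentially_pathogenic": pathogenic,
    }
    stage_masks = [
        ("mapped_interval", in_interval),
        ("novel", novel),
        ("homozygous_in_all_affected", hom_all),
        ("not_homozygous_in_any_unaffected", ~hom_any_unaff),
    ]
    if config.consequence_filter:
        stage_masks.append(("potentially_pathogenic", pathogenic))
    for name, stage_mask in stage_masks:
        new_mask = mask & stage_mask
        report.add_stage(name, mask, new_mask)
        mask = new_mask
    report.flags = pd.DataFrame(flags)
    return _candidates_from_mask(variants, mask, flags), report


def homogeneity_scan(
    variants: VariantTable,
    affected_ids: list[str],
    all_other_ids: list[str],
    config: FilterConfig | None = None,
) -> list[CandidateVariant]:
    """Mapping-free scan: novel, homozygous in all affecteds, homozygous
    in no other studied individual.  No interval restriction and no
    consequence filter — the pure mutation-homogeneity argument."""
    if not affected_ids:
        raise ConfigError("at least one affected sample is required")
    config = config or FilterConfig()
    report = FilterReport()
    novel = annotate_novelty(variants, config.catalog_names,
                             config.valid_catalogs)
    hom_all = _hom_in_all(variants, affected_ids, config, report)
    hom_other = _hom_in_any(variants, all_other_ids)
    mask = novel & hom_all & ~hom_other
    flags = {
        "in_interval": np.ones(len(variants), dtype=bool),
        "novel": novel,
        "hom_all_affected": hom_all,
        "hom_any_unaffected": hom_other,
        "potentially_pathogenic": np.ones(len(variants), dtype=bool),
    }
    return _candidates_from_mask(variants, mask, flags)


@dataclass
class SegregationResult:
    """Outcome of the family segregation check for one variant."""

    passed: bool
    table: pd.DataFrame
    n_missing: int


_EXPECTATIONS = {
    "parent": ("het", lambda g: g == HET),
    "affected": ("alt-hom", lambda g: g == ALT_HOM),
    "unaffected": ("het or ref-hom", lambda g: g in (HET, REF_HOM)),
}

_GT_NAMES = {REF_HOM: "ref-hom", HET: "het", ALT_HOM: "alt-hom",
             UNKNOWN: "missing"}


def check_segregation(
    variant: VariantRecord,
    manifest: SampleManifest,
) -> SegregationResult:
    """Recessive segregation: genotyped parents of affecteds heterozygous,
    affecteds homozygous-alternate, no unaffected homozygous-alternate.
    Missing genotypes are reported but do not fail the check."""
    affected = set(manifest.affected_ids)
    parents: set[str] = set()
    for a in affected:
        for p in manifest.parents_of(a):
            if p:
                parents.add(p)
    rows = []
    passed = True
    n_missing = 0
    for sample in manifest.sample_ids:
        if manifest.table.set_index("sample_id").loc[sample, "role"] \
                == "population_control":
            continue
        if sample in parents:
            relation = "parent"
        elif sample in affected:
            relation = "affected"
        else:
            relation = "unaffected"
        expected, rule = _EXPECTATIONS[relation]
        g = variant.genotype(sample)
        if g == UNKNOWN:
            ok = None
            n_missing += 1
        else:
            ok = bool(rule(g))
            passed = passed and ok
        rows.append({
            "sample_id": sample,
            "relation": relation,
            "expected": expected,
            "observed": _GT_NAMES[g],
            "ok": ok,
        })
    return SegregationResult(
        passed=passed,
        table=pd.DataFrame(rows),
        n_missing=n_missing,
    )
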