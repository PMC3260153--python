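"""Control-screen arithmetic, report assembly, and the pipeline driver.

Carrier screening reports two related but distinct quantities: the
*allele frequency* (variant alleles per control chromosome, printed to
two decimals) and the *carrier rate* (carrier individuals per control
individual, printed to one decimal) — for rare variants these differ by
roughly a factor of two.  Rounding is half-up, as in printed tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from . import mapping as fmap
from .filtering import (
    DEFAULT_CATALOGS,
    FilterConfig,
    check_segregation,
    filter_candidates,
    homogeneity_scan,
)
from .model import ConfigError, round_half_up
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "ControlScreenResult",
    "allele_frequency_from_controls",
    "assemble_report",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("founderscan")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ControlScreenResult:
    """Carrier screen of one variant in population controls."""

    variant_id: str
    n_controls: int
    n_heterozygous: int
    n_homozygous_alt: int
    allele_frequency_pct: float  # per chromosome, 2 decimals
    carrier_rate_pct: float      # per individual, 1 decimal
    has_homozygous_controls: bool


def allele_frequency_from_controls(
    n_controls: int,
    n_het: int,
    n_hom_alt: int,
    variant_id: str = "",
) -> ControlScreenResult:
    """Allele frequency and carrier rate from control genotyping counts.

    allele frequency = (n_het + 2 n_hom_alt) / (2 n_controls) x 100,
    carrier rate = (n_het + n_hom_alt) / n_controls x 100.  Homozygous
    controls are flagged — finding one argues against pathogenicity of a
    fully penetrant recessive allele.
    """
    if n_controls <= 0:
        raise ConfigError("n_controls must be positive")
    if n_het < 0 or n_hom_alt < 0:
        raise ConfigError("genotype counts must be non-negative")
    if n_het + n_hom_alt > n_controls:
        raise ConfigError("carrier counts exceed the number of controls")
    allele_freq = (n_het + 2 * n_hom_alt) / (2 * n_controls) * 100.0
    carrier_rate = (n_het + n_hom_alt) / n_controls * 100.0
    return ControlScreenResult(
        variant_id=variant_id,
        n_controls=n_controls,
        n_heterozygous=n_het,
        n_homozygous_alt=n_hom_alt,
        allele_frequency_pct=round_half_up(allele_freq, 2),
        carrier_rate_pct=round_half_up(carrier_rate, 1),
        has_homozygous_controls=n_hom_alt > 0,
    )


def assemble_report(
    blocks,
    candidates,
    screens,
    manifest,
    filter_report=None,
    block_summary=None,
    segregation=None,
) -> dict:
    """One machine-readable report covering mapping, cascade and candidates.

    ``screens`` maps a candidate key (chrom, pos, ref, alt) to a
    :class:`ControlScreenResult`; ``segregation`` maps the same keys to
    :class:`~founderscan.filtering.SegregationResult`.
    """
    screens = screens or {}
    segregation = segregation or {}
    block_rows = []
    for b in blocks:
        block_rows.append({
            "chrom": b.chrom,
            "snp_start": b.start_marker,
            "snp_stop": b.end_marker,
            "start_bp": b.start_bp,
            "end_bp": b.end_bp,
            "size_mb": round_half_up(b.size_mb, 1),
            "n_markers": b.n_markers,
            "n_affected": b.n_affected,
            "location_score": (None if b.location_score is None
                               else round(b.location_score, 4)),
        })
    candidate_rows = []
    for c in candidates:
        r = c.record
        key = list(r.key)
        screen = screens.get(r.key)
        seg = segregation.get(r.key)
        candidate_rows.append({
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "consequence": r.consequence,
            "zygosity_warning": c.zygosity_warning,
            "segregation_pass": None if seg is None else seg.passed,
            "control_screen": None if screen is None else {
                "n_controls": screen.n_controls,
                "n_heterozygous": screen.n_heterozygous,
                "n_homozygous_alt": screen.n_homozygous_alt,
                "allele_frequency_pct": screen.allele_frequency_pct,
                "carrier_rate_pct": screen.carrier_rate_pct,
            },
            "key": key,
        })
    report = {
        "schema_version": SCHEMA_VERSION,
        "n_samples": len(manifest.sample_ids),
        "n_affected": len(manifest.affected_ids),
        "mapping": {
            "blocks": block_rows,
            "summary": (block_summary or {}).get("summary"),
        },
        "cascade": (
            [] if filter_report is None else [
                {"stage": s, "n_input": a, "n_kept": k, "n_dropped": d}
                for s, a, k, d in filter_report.stages
            ]
        ),
        "candidates": candidate_rows,
    }
    return report


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration.

    Either ``simulate`` is given (a full synthetic study) or the three
    input paths ``genotypes``, ``vcf`` and ``manifest`` are.
    """

    simulate: SimulationConfig | None = None
    genotypes: str | None = None
    vcf: str | None = None
    manifest: str | None = None
    genes_bed: str | None = None

    min_markers: int | None = None  # None: derived from marker density
    pseudocount: float = 0.5
    lod_error_rate: float = 0.01
    mode: str = "mapped"  # or "homogeneity"
    catalogs: tuple[str, ...] = DEFAULT_CATALOGS

    def __post_init__(self) -> None:
        if self.mode not in ("mapped", "homogeneity"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.simulate is None:
            for name in ("genotypes", "vcf", "manifest"):
                if getattr(self, name) is None:
                    raise ConfigError(f"config missing field {name!r}")

    @classmethod
    def from_file(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            if seed is not None:
                sim = {**sim, "rng_seed": seed}
            sim = SimulationConfig.from_dict(sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "catalogs" in raw and isinstance(raw["catalogs"], list):
            raw["catalogs"] = tuple(raw["catalogs"])
        return cls(simulate=sim, **raw)


def _default_min_markers(density_per_mb: float) -> int:
    # 25 markers suits 10K-like panels, 50 suits 50K-like ones
    return 25 if density_per_mb <= 8 else 50


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """simulate (optional) -> map -> filter -> screen -> report.

    Writes the panel, VCF, truth files (when simulated), block tables, the
    cascade TSV, candidate VCF and ``report.json`` under ``outdir`` and
    returns the report dict.  Identical config and seed produce
    byte-identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = None
    genes = None

    if config.simulate is not None:
        logger.info("simulating study (seed=%d)", config.simulate.rng_seed)
        study = simulate_study(config.simulate)
        panel, manifest, variants = study.panel, study.manifest, study.variants
        truth, genes = study.truth, study.genes
        fio.write_genotypes(panel, outdir / "genotypes.tsv")
        fio.write_manifest(manifest, outdir / "manifest.tsv")
        fio.write_variants(variants, outdir / "exome.vcf")
        fio.write_truth(truth, outdir / "truth_segments.bed",
                        outdir / "truth_variant.json")
        min_markers = config.min_markers or _default_min_markers(
            config.simulate.marker_density_per_mb
        )
    else:
        panel = fio.read_genotypes(config.genotypes)
        manifest = fio.read_manifest(config.manifest)
        variants = fio.read_variants(config.vcf)
        if config.genes_bed:
            genes = pd.DataFrame(
                [(iv.chrom, iv.start, iv.end, f"gene{i + 1}")
                 for i, iv in enumerate(fio.read_intervals(config.genes_bed))],
                columns=["chrom", "start", "end", "name"],
            )
        min_markers = config.min_markers or 50

    affected = manifest.affected_ids
    controls = manifest.control_ids
    if not affected:
        raise ConfigError("manifest contains no affected samples")

    logger.info("mapping: %d affected, %d controls, min_markers=%d",
                len(affected), len(controls), min_markers)
    freqs = fmap.estimate_allele_freqs(panel, controls or panel.samples,
                                       config.pseudocount)
    blocks = fmap.shared_blocks(panel, affected, min_markers=min_markers)
    fmap.score_blocks(blocks, panel, affected, freqs, config.lod_error_rate)
    fio.write_blocks(blocks, outdir / "blocks")
    lod = _lod_track(panel, affected, freqs, config.lod_error_rate)
    lod.to_csv(outdir / "lod_track.tsv", sep="\t", index=False)
    logger.info("mapping: %d shared block(s)", len(blocks))

    exome_samples = set(variants.samples)
    unaffected = [s for s in manifest.unaffected_ids
                  if s in exome_samples and s not in set(controls)]
    fconfig = FilterConfig(catalog_names=config.catalogs,
                           valid_catalogs=tuple(
                               set(config.catalogs) | set(DEFAULT_CATALOGS)))
    if config.mode == "homogeneity":
        candidates = homogeneity_scan(
            variants, [a for a in affected if a in exome_samples],
            unaffected, fconfig,
        )
        filter_report = None
    else:
        intervals = [b.interval for b in blocks]
        candidates, filter_report = filter_candidates(
            variants, intervals, [a for a in affected if a in exome_samples],
            unaffected, fconfig,
        )
        filter_report.to_frame().to_csv(outdir / "cascade.tsv", sep="\t",
                                        index=False)
    logger.info("filtering (%s): %d candidate(s)", config.mode,
                len(candidates))

    segregation = {
        c.record.key: check_segregation(c.record, manifest)
        for c in candidates
    }
    for key, seg in segregation.items():
        seg.table.to_csv(
            outdir / f"segregation_{key[0]}_{key[1]}.tsv",
            sep="\t", index=False,
        )

    # control screen: genotype counts at the planted variant come from the
    # simulated control cohort when available
    screens = {}
    if truth is not None and truth.pathogenic_variant is not None and controls:
        n_het = sum(1 for s in controls
                    if truth.planted_dosage.get(s, 0) == 1)
        n_hom = sum(1 for s in controls
                    if truth.planted_dosage.get(s, 0) == 2)
        key = tuple(truth.pathogenic_variant)
        screens[key] = allele_frequency_from_controls(
            len(controls), n_het, n_hom,
            variant_id=f"{key[0]}:{key[1]}",
        )

    block_summary = fmap.summarize_blocks(blocks, genes)
    report = assemble_report(
        blocks, candidates, screens, manifest,
        filter_report=filter_report,
        block_summary=block_summary,
        segregation=segregation,
    )
    if truth is not None and truth.pathogenic_variant is not None:
        report["truth"] = {
            "pathogenic_variant": list(truth.pathogenic_variant),
            "recovered": any(
                tuple(c["key"]) == tuple(truth.pathogenic_variant)
                for c in report["candidates"]
            ),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if candidates:
        sub = variants.subset(
            pd.Series(
                [r.key in {c.record.key for c in candidates}
                 for r in variants.records()]
            ).to_numpy()
        )
        fio.write_variants(sub, outdir / "candidates.vcf")
    return report


def _lod_track(panel, affected_ids, freqs, error_rate) -> pd.DataFrame:
    """Per-marker summed LOD contributions (0 for het/missing calls),
    suitable for plotting mapping profiles."""
    import numpy as np
    from .model import AA, BB

    calls = panel.sample_rows(affected_ids)
    f_a = freqs.freq_a
    lod = pd.Series(0.0, index=range(panel.n_markers))
    valid = ~pd.isna(f_a) & (f_a > 0) & (f_a < 1)
    for row in calls:
        is_aa = (row == AA) & valid
        is_bb = (row == BB) & valid
        with pd.option_context("mode.chained_assignment", None):
            lod[is_aa] += np.log10(
                ((1 - error_rate) * f_a[is_aa] + error_rate * f_a[is_aa] ** 2)
                / f_a[is_aa] ** 2
            )
            lod[is_bb] += np.log10(
                ((1 - error_rate) * (1 - f_a[is_bb])
                 + error_rate * (1 - f_a[is_bb]) ** 2)
                / (1 - f_a[is_bb]) ** 2
            )
    return pd.DataFrame({
        "marker_id": panel.markers["marker_id"],
        "chrom": panel.markers["chrom"],
        "pos": panel.markers["pos"],
        "lod": lod.round(6),
    })
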