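"""Readers and writers for the formats the pipeline touches.

Internally every interval is 1-based and fully closed (blocks are
delimited by their flanking SNPs); BED files are 0-based half-open on
disk and converted at this boundary, in both directions, nowhere else.

Genotype panels round-trip through either a wide TSV (one row per marker,
one column per sample) or a PED/MAP pair; exome variants through VCF 4.2
with genotype (GT) fields and consequence/catalog annotations in INFO.
Readers validate and reject rather than coerce.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AA, AB, BB, MISSING,
    FormatError,
    GenotypePanel,
    Interval,
    SampleManifest,
    TruthSet,
    VariantTable,
)

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_variants", "write_variants",
    "read_intervals", "write_intervals",
    "write_blocks",
    "read_manifest", "write_manifest",
    "read_truth", "write_truth",
]

_CALL_TO_TEXT = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
_TEXT_TO_CALL = {
    "AA": AA, "AB": AB, "BA": AB, "BB": BB,
    "NA": MISSING, "00": MISSING, "--": MISSING, "./.": MISSING, ".": MISSING,
}

_META_COLUMNS = ("marker_id", "chrom", "pos", "allele_a", "allele_b")


def read_genotypes(path, format: str = "auto") -> GenotypePanel:
    """Read a genotype panel from a wide TSV or a PED/MAP pair.

    For PED/MAP, ``path`` is the shared prefix (``prefix.ped`` /
    ``prefix.map``).  Markers are re-sorted by (chrom, position) with a
    warning if the input map is unsorted.
    """
    path = Path(path)
    if format == "auto":
        format = "pedmap" if (path.with_suffix(".ped").exists()
                              and not path.exists()) else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "pedmap":
        return _read_genotypes_pedmap(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _warn_if_unsorted(markers: pd.DataFrame, source: str) -> None:
    order = np.lexsort((markers["pos"].to_numpy(),
                        markers["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(markers))):
        warnings.warn(f"{source}: markers not sorted by (chrom, pos); "
                      "re-sorting", stacklevel=3)


def _read_genotypes_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ("marker_id", "chrom", "pos") if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing column(s) {missing_cols}")
    sample_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    markers = df[[c for c in _META_COLUMNS if c in df.columns]].copy()
    try:
        markers["pos"] = markers["pos"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position ({exc})") from None
    calls = np.empty((len(sample_cols), len(df)), dtype=np.int8)
    for j, col in enumerate(sample_cols):
        for i, text in enumerate(df[col]):
            code = _TEXT_TO_CALL.get(str(text).strip())
            if code is None:
                raise FormatError(
                    f"{path}: line {i + 2}: invalid genotype {text!r} "
                    f"for sample {col!r}"
                )
            calls[j, i] = code
    _warn_if_unsorted(markers, str(path))
    return GenotypePanel(markers, sample_cols, calls)


def write_genotypes(panel: GenotypePanel, path, format: str = "tsv",
                    manifest: SampleManifest | None = None) -> None:
    path = Path(path)
    if format == "tsv":
        call_cols = {
            sample: [_CALL_TO_TEXT[int(c)] for c in panel.calls[j]]
            for j, sample in enumerate(panel.samples)
        }
        df = pd.concat([panel.markers, pd.DataFrame(call_cols)], axis=1)
        df.to_csv(path, sep="\t", index=False)
    elif format == "pedmap":
        _write_genotypes_pedmap(panel, path, manifest)
    else:
        raise FormatError(f"unknown genotype format {format!r}")


_PED_PAIR = {AA: "A A", AB: "A B", BB: "B B", MISSING: "0 0"}
_PAIR_TO_CALL = {
    frozenset(("A",)): AA, frozenset(("A", "B")): AB,
    frozenset(("B",)): BB, frozenset(("0",)): MISSING,
}


def _write_genotypes_pedmap(panel, prefix: Path, manifest) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in panel.markers.itertuples():
            fh.write(f"{row.chrom}\t{row.marker_id}\t0\t{row.pos}\n")
    meta = {}
    if manifest is not None:
        meta = {r.sample_id: r for r in manifest.table.itertuples()}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for j, sample in enumerate(panel.samples):
            m = meta.get(sample)
            fam = m.family_id if m else sample
            father = (m.father_id or "0") if m else "0"
            mother = (m.mother_id or "0") if m else "0"
            pheno = "2" if (m and m.status == "affected") else "1"
            fields = [fam, sample, father, mother, "0", pheno]
            fields += [_PED_PAIR[int(c)] for c in panel.calls[j]]
            fh.write("\t".join(fields) + "\n")


def _read_genotypes_pedmap(prefix: Path) -> GenotypePanel:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    markers = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos"], dtype=str,
    )
    try:
        markers["pos"] = markers["pos"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{map_path}: non-integer position ({exc})") from None
    markers = markers[["marker_id", "chrom", "pos"]]
    _warn_if_unsorted(markers, str(map_path))
    n_markers = len(markers)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * n_markers} fields, found {len(fields)}"
                )
            samples.append(fields[1])
            calls = np.empty(n_markers, dtype=np.int8)
            for i in range(n_markers):
                a, b = fields[6 + 2 * i], fields[7 + 2 * i]
                code = _PAIR_TO_CALL.get(frozenset((a, b)))
                if code is None or ("0" in (a, b) and a != b):
                    raise FormatError(
                        f"{ped_path}: line {lineno}: invalid allele pair "
                        f"{a!r}/{b!r} at marker {i + 1}"
                    )
                calls[i] = code
            rows.append(calls)
    return GenotypePanel(markers, samples, np.vstack(rows))


# --------------------------------------------------------------------------
# VCF

_INFO_CONSEQUENCE = "VCLASS"
_INFO_CATALOGS = "CATALOGS"
_INFO_GENE = "GENE"
_INFO_ZYGUNK = "ZYGUNK"

_GT_TEXT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_variants(table: VariantTable, path) -> None:
    """Write a biallelic VCF 4.2 with GT fields and INFO annotations."""
    chroms = list(dict.fromkeys(table.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=%s,Number=1,Type=String,'
                 'Description="Consequence class">\n' % _INFO_CONSEQUENCE)
        fh.write('##INFO=<ID=%s,Number=.,Type=String,'
                 'Description="Catalogs containing this variant">\n'
                 % _INFO_CATALOGS)
        fh.write('##INFO=<ID=%s,Number=1,Type=String,Description="Gene">\n'
                 % _INFO_GENE)
        fh.write('##INFO=<ID=%s,Number=0,Type=Flag,'
                 'Description="Zygosity not determined by caller">\n'
                 % _INFO_ZYGUNK)
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(len(table)):
            row = table.variants.iloc[i]
            info = [f"{_INFO_CONSEQUENCE}={row['consequence'].replace(' ', '_')}"]
            if row["catalogs"]:
                info.append(f"{_INFO_CATALOGS}={','.join(sorted(row['catalogs']))}")
            if row["gene"]:
                info.append(f"{_INFO_GENE}={row['gene']}")
            if not row["zygosity_known"]:
                info.append(_INFO_ZYGUNK)
            gts = "\t".join(_GT_TEXT[int(g)] for g in table.genotypes[i])
            fh.write(f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t{';'.join(info)}\tGT\t{gts}\n")


def read_variants(path) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Multiallelic sites are decomposed into one record per ALT allele (the
    genotype dosage counts that allele only).  Record-level problems —
    absent GT, unknown consequence strings — are collected and reported
    together in one :class:`FormatError`.
    """
    from cyvcf2 import VCF
    from .model import CONSEQUENCE_CLASSES

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    errors: list[str] = []
    rows = []
    genos = []
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            errors.append(f"{v.CHROM}:{v.POS}: missing GT field")
            continue
        csq_raw = v.INFO.get(_INFO_CONSEQUENCE) or ""
        csqs = [c.replace("_", " ") for c in str(csq_raw).split(",")]
        cats_raw = v.INFO.get(_INFO_CATALOGS)
        catalogs = frozenset(str(cats_raw).split(",")) if cats_raw else frozenset()
        gene = v.INFO.get(_INFO_GENE)
        zygunk = bool(v.INFO.get(_INFO_ZYGUNK))
        gt = np.asarray([g[:2] for g in v.genotypes], dtype=np.int64)
        for k, alt in enumerate(v.ALT):
            csq = csqs[k] if len(csqs) == len(v.ALT) else csqs[0]
            if csq not in CONSEQUENCE_CLASSES:
                errors.append(
                    f"{v.CHROM}:{v.POS} alt {alt}: unknown consequence "
                    f"{csq!r}"
                )
                continue
            dosage = (gt == k + 1).sum(axis=1).astype(np.int8)
            dosage[np.any(gt < 0, axis=1)] = MISSING
            rows.append((v.CHROM, int(v.POS), v.REF, alt, csq, gene,
                         not zygunk, catalogs))
            genos.append(dosage)
    if errors:
        raise FormatError("invalid VCF records:\n  " + "\n  ".join(errors))
    df = pd.DataFrame(rows, columns=list(VariantTable.COLUMNS))
    geno = (np.vstack(genos) if genos
            else np.empty((0, len(samples)), dtype=np.int8))
    return VariantTable(df, geno, samples)


# --------------------------------------------------------------------------
# BED intervals and block tables

def read_intervals(path) -> list[Interval]:
    """Read a BED file into internal 1-based closed intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            out.append(Interval(chrom, start + 1, end))
    return out


def write_intervals(intervals, path, names=None) -> None:
    """Write internal 1-based closed intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def write_blocks(blocks, prefix) -> None:
    """Write shared blocks as a BED plus a mapping-summary-shaped TSV
    (chromosome, flanking SNP ids, size in Mb, marker count, score)."""
    from .model import round_half_up

    prefix = Path(prefix)
    write_intervals(
        [b.interval for b in blocks],
        prefix.with_suffix(".bed"),
        names=[f"block{i + 1}" for i in range(len(blocks))],
    )
    rows = []
    for b in blocks:
        rows.append({
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
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)


# --------------------------------------------------------------------------
# manifests and truth sets

def read_manifest(path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthSet, bed_path, json_path) -> None:
    """IBD segments as BED (name = sample id); variant and carriers as JSON."""
    with open(bed_path, "w") as fh:
        for sample, chrom, start, end in truth.ibd_segments:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{sample}\n")
    payload = {
        "pathogenic_variant": (list(truth.pathogenic_variant)
                               if truth.pathogenic_variant else None),
        "carriers": truth.carriers,
        "planted_dosage": truth.planted_dosage,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(bed_path, json_path) -> TruthSet:
    segments = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, sample = line.split("\t")[:4]
            segments.append((sample.strip(), chrom, int(start) + 1, int(end)))
    with open(json_path) as fh:
        payload = json.load(fh)
    variant = payload.get("pathogenic_variant")
    return TruthSet(
        ibd_segments=segments,
        pathogenic_variant=tuple(variant) if variant else None,
        carriers=payload.get("carriers", []),
        planted_dosage=payload.get("planted_dosage", {}),
    )
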