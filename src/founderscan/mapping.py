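"""Autozygosity mapping: runs of homozygosity, shared blocks, LOD scores.

The mapping statistic follows the classic founder-population recipe: per
individual, find runs of homozygous marker calls; across affected
individuals, find maximal intervals of *identical* homozygosity; score each
interval by summing per-marker two-point LOD contributions

    lod(f, e) = log10( [(1 - e) * f + e * f^2] / f^2 )

where ``f`` is the control-population frequency of the observed homozygous
allele and ``e`` a per-call genotyping error rate.  With ``e = 0`` this is
-log10(f): the improbability of drawing the same allele twice from the
population.  The cumulative score over a block (summed over affecteds) is
the block's *location score*, a relative ranking of candidate intervals.

Run/block detection is a maximal-window enumeration with explicit noise
tolerances.  Each marker is classified as

* GOOD  — consistent with shared identical homozygosity,
* SOFT  — exactly one sample deviates from a consensus supported by at
  least two others (the signature of a single miscalled genotype),
* BAD   — a genuine conflict (two or more deviating samples, or a
  heterozygous call in single-sample mode),
* MISS  — no usable calls.

A qualifying window starts and ends on GOOD markers, may not have a BAD
marker adjacent to either terminal marker, and holds at most the
configured budget of SOFT / BAD / MISS markers; reported runs are the
windows not contained in any other qualifying window.  The terminal rules
keep single edge-adjacent miscalls from clipping a block and keep the
tolerance budget from dragging block ends across chance homozygosity
beyond the true segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    AA, AB, BB, MISSING,
    AlleleFrequencyTable,
    ConfigError,
    GenotypePanel,
    HomozygousRun,
    Interval,
    LinkageRegion,
    SampleManifest,
    SharedBlock,
    round_half_up,
)

__all__ = [
    "GOOD", "SOFT", "BAD", "MISS",
    "BlockTolerances",
    "estimate_allele_freqs",
    "detect_runs",
    "shared_blocks",
    "snp_lod",
    "location_score",
    "score_blocks",
    "exclusion_linkage_regions",
    "summarize_blocks",
    "maximal_windows",
    "classify_shared_status",
]

GOOD, SOFT, BAD, MISS = 0, 1, 2, 3


@dataclass(frozen=True)
class BlockTolerances:
    """Noise budgets for shared-block detection.

    ``max_single_deviations`` bounds SOFT markers (single-sample
    deviations, the typical footprint of array call errors over a block of
    tens of markers); ``max_conflicts`` bounds BAD markers;
    ``max_missing`` bounds markers with no usable call in any sample.
    """

    max_single_deviations: int = 6
    max_conflicts: int = 1
    max_missing: int = 2


def estimate_allele_freqs(
    panel: GenotypePanel,
    control_sample_ids: list[str],
    pseudocount: float = 0.5,
) -> AlleleFrequencyTable:
    """Per-marker allele-A frequency from control genotypes.

    f = (n_A + pseudocount) / (2 * n_called + 2 * pseudocount); missing
    calls drop out of the denominator.  A positive pseudocount keeps f
    strictly inside (0, 1) so LOD scores stay finite.  Markers where every
    control call is missing get f = NaN and are excluded from scoring.
    """
    if not control_sample_ids:
        raise ConfigError("at least one control sample is required")
    calls = panel.sample_rows(control_sample_ids)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_a = (2 * (calls == AA) + (calls == AB)).sum(axis=0, where=called)
    with np.errstate(invalid="ignore"):
        freq = (n_a + pseudocount) / (2.0 * n_called + 2.0 * pseudocount)
    freq = np.where(n_called == 0, np.nan, freq)
    return AlleleFrequencyTable(
        freq_a=freq,
        n_chromosomes=2 * n_called,
        pseudocount=pseudocount,
    )


def maximal_windows(
    status: np.ndarray,
    min_markers: int,
    max_soft: int,
    max_bad: int,
    max_miss: int,
    edge_span: int = 5,
    max_edge_deviations: int = 1,
) -> list[tuple[int, int]]:
    """All maximal qualifying windows over one chromosome's status codes.

    A window qualifies when it starts and ends on GOOD markers, its
    SOFT/BAD/MISS counts are within budget, its outermost
    ``min(edge_span, length)`` markers on each side contain no BAD marker
    and at most ``max_edge_deviations`` SOFT/MISS markers, and it spans
    at least ``min_markers``.  Returns the windows not contained in any
    other qualifying window, as inclusive (start, end) pairs sorted by
    start.

    The edge rules are what make reported boundaries trustworthy: a
    single miscall just inside a true block (a SOFT marker) does not clip
    it, while the tolerance budgets cannot drag an endpoint outward
    across chance matches beyond the block.
    """
    n = len(status)
    if n == 0:
        return []
    good = status == GOOD
    is_soft = status == SOFT
    is_bad = status == BAD
    is_miss = status == MISS
    cum_soft = np.concatenate(([0], np.cumsum((is_soft | is_miss)
                                              .astype(np.int64))))
    cum_hard = np.concatenate(([0], np.cumsum(is_bad.astype(np.int64))))

    def zone_ok_span(a: int, b: int) -> bool:
        return (cum_hard[b + 1] - cum_hard[a] == 0
                and cum_soft[b + 1] - cum_soft[a] <= max_edge_deviations)

    w = edge_span
    # validity of full-size (length >= edge_span) window terminals
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    end_ok = good & (idx >= w - 1) \
        & (cum_hard[idx + 1] - cum_hard[lo] == 0) \
        & (cum_soft[idx + 1] - cum_soft[lo] <= max_edge_deviations)
    hi = np.minimum(idx + w, n)
    start_ok = good & (idx <= n - w) \
        & (cum_hard[hi] - cum_hard[idx] == 0) \
        & (cum_soft[hi] - cum_soft[idx] <= max_edge_deviations)
    last_end_ok = np.where(end_ok, idx, -1)
    np.maximum.accumulate(last_end_ok, out=last_end_ok)

    windows: list[tuple[int, int]] = []
    last_r = -1
    r = -1  # inclusive budget pointer
    soft = bad = miss = 0

    for l in range(n):
        if r < l - 1:
            r = l - 1
            soft = bad = miss = 0
        while r + 1 < n:
            s = status[r + 1]
            if ((s == SOFT and soft + 1 > max_soft)
                    or (s == BAD and bad + 1 > max_bad)
                    or (s == MISS and miss + 1 > max_miss)):
                break
            r += 1
            soft += is_soft[r]
            bad += is_bad[r]
            miss += is_miss[r]
        if good[l]:
            rl = -1
            if start_ok[l] and r >= l + w - 1:
                cand = last_end_ok[r]
                if cand >= l + w - 1:
                    rl = int(cand)
            if rl < 0:
                # short windows (length < edge_span): both zones are the
                # whole window
                for cand in range(min(r, l + w - 2), l - 1, -1):
                    if good[cand] and zone_ok_span(l, cand):
                        rl = cand
                        break
            if rl >= l and rl - l + 1 >= min_markers and rl > last_r:
                windows.append((l, rl))
                last_r = rl
        # slide budgets past l
        if r >= l:
            soft -= is_soft[l]
            bad -= is_bad[l]
            miss -= is_miss[l]
    return windows


def _single_sample_status(calls: np.ndarray) -> np.ndarray:
    status = np.full(calls.shape, BAD, dtype=np.int8)
    status[(calls == AA) | (calls == BB)] = GOOD
    status[calls == MISSING] = MISS
    return status


def classify_shared_status(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify each marker across affected samples.

    ``calls`` has shape (n_samples, n_markers).  Returns (status,
    consensus) where consensus holds the shared genotype code at GOOD/SOFT
    markers and -9 elsewhere.  Missing calls are ignored: a marker is GOOD
    when every non-missing call is the same homozygous genotype, SOFT when
    exactly one call deviates from an identical-homozygous consensus
    carried by at least two samples, BAD otherwise, MISS when nothing was
    called.
    """
    n_samples, n_markers = calls.shape
    status = np.full(n_markers, BAD, dtype=np.int8)
    consensus = np.full(n_markers, -9, dtype=np.int8)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_aa = (calls == AA).sum(axis=0)
    n_bb = (calls == BB).sum(axis=0)

    status[n_called == 0] = MISS
    for hom, n_hom in ((AA, n_aa), (BB, n_bb)):
        all_hom = (n_called > 0) & (n_hom == n_called)
        status[all_hom] = GOOD
        consensus[all_hom] = hom
        soft = (n_hom == n_called - 1) & (n_hom >= 2)
        soft &= status == BAD
        status[soft] = SOFT
        consensus[soft] = hom
    return status, consensus


def _per_chrom(panel: GenotypePanel):
    chrom_col = panel.markers["chrom"].to_numpy()
    for chrom in panel.chromosomes():
        idx = np.flatnonzero(chrom_col == chrom)
        yield chrom, int(idx[0]), idx


def detect_runs(
    panel: GenotypePanel,
    sample_id: str,
    min_markers: int = 25,
    max_missing_per_run: int = 2,
    max_het_per_run: int = 0,
) -> list[HomozygousRun]:
    """Maximal runs of homozygosity for one sample.

    Heterozygous calls consume ``max_het_per_run`` and missing calls
    ``max_missing_per_run``; runs start and end on homozygous calls and
    never with a heterozygous call adjacent to a terminal marker.
    """
    calls = panel.sample_row(sample_id)
    status_all = _single_sample_status(calls)
    runs: list[HomozygousRun] = []
    pos = panel.markers["pos"].to_numpy()
    for chrom, offset, idx in _per_chrom(panel):
        status = status_all[idx]
        for l, r in maximal_windows(status, min_markers,
                                    max_soft=0,
                                    max_bad=max_het_per_run,
                                    max_miss=max_missing_per_run):
            gl, gr = offset + l, offset + r
            seg = calls[gl:gr + 1]
            runs.append(HomozygousRun(
                sample_id=sample_id,
                chrom=chrom,
                start_index=gl,
                end_index=gr,
                start_bp=int(pos[gl]),
                end_bp=int(pos[gr]),
                n_markers=gr - gl + 1,
                n_missing=int((seg == MISSING).sum()),
                n_het=int((seg == AB).sum()),
            ))
    return runs


def shared_blocks(
    panel: GenotypePanel,
    affected_ids: list[str],
    min_markers: int = 50,
    tolerances: BlockTolerances | None = None,
) -> list[SharedBlock]:
    """Maximal intervals of identical homozygosity across all affecteds.

    Location scores are left unfilled; see :func:`score_blocks`.  With a
    single affected sample this reduces to run detection (with
    ``max_conflicts`` acting as the heterozygote budget).
    """
    if not affected_ids:
        raise ConfigError("at least one affected sample is required")
    tol = tolerances or BlockTolerances()
    calls = panel.sample_rows(affected_ids)
    status_all, _ = classify_shared_status(calls)
    pos = panel.markers["pos"].to_numpy()
    ids = panel.markers["marker_id"].to_numpy()
    blocks: list[SharedBlock] = []
    for chrom, offset, idx in _per_chrom(panel):
        status = status_all[idx]
        for l, r in maximal_windows(status, min_markers,
                                    max_soft=tol.max_single_deviations,
                                    max_bad=tol.max_conflicts,
                                    max_miss=tol.max_missing):
            gl, gr = offset + l, offset + r
            blocks.append(SharedBlock(
                chrom=chrom,
                start_bp=int(pos[gl]),
                end_bp=int(pos[gr]),
                start_marker=str(ids[gl]),
                end_marker=str(ids[gr]),
                start_index=gl,
                end_index=gr,
                n_markers=gr - gl + 1,
                n_affected=len(affected_ids),
            ))
    blocks.sort(key=lambda b: (b.chrom, b.start_bp))
    return blocks


def snp_lod(genotype_call: int, f_of_homozygous_allele: float,
            error_rate: float = 0.01) -> float:
    """Two-point LOD contribution of one homozygous marker genotype.

    log10 of P(observed homozygote | autozygous, error rate e) over
    P(observed homozygote | Hardy-Weinberg), i.e.
    log10(((1-e)f + e f^2) / f^2).  Missing calls contribute 0.
    Heterozygous calls are a contract violation: callers must route
    heterozygotes through the block tolerance machinery instead.
    """
    if genotype_call == MISSING:
        return 0.0
    if genotype_call == AB:
        raise ConfigError("snp_lod is defined for homozygous calls only")
    if genotype_call not in (AA, BB):
        raise ConfigError(f"invalid genotype code {genotype_call!r}")
    f = f_of_homozygous_allele
    if not 0.0 < f < 1.0:
        raise ConfigError(f"allele frequency must be in (0, 1), got {f}")
    if not 0.0 <= error_rate < 1.0:
        raise ConfigError(f"error rate must be in [0, 1), got {error_rate}")
    return float(np.log10(((1.0 - error_rate) * f + error_rate * f * f)
                          / (f * f)))


def _block_score(block, panel, affected_ids, freqs, error_rate):
    score = 0.0
    skipped = 0
    if not affected_ids:
        return score, skipped
    calls = panel.sample_rows(affected_ids)
    for m in range(block.start_index, block.end_index + 1):
        f_a = freqs.freq_a[m]
        col = calls[:, m]
        has_hom = bool(np.any((col == AA) | (col == BB)))
        if has_hom and (np.isnan(f_a) or not 0.0 < f_a < 1.0):
            skipped += 1
            continue
        for call in col:
            if call == AA:
                score += snp_lod(AA, f_a, error_rate)
            elif call == BB:
                score += snp_lod(BB, 1.0 - f_a, error_rate)
    return score, skipped


def location_score(
    block: SharedBlock,
    panel: GenotypePanel,
    affected_ids: list[str],
    freqs: AlleleFrequencyTable,
    error_rate: float = 0.01,
) -> float:
    """Cumulative two-point LOD over a block, summed over affecteds.

    Heterozygous and missing calls contribute 0; markers with undefined
    allele frequency are skipped (use :func:`score_blocks` to record skip
    counts on the blocks).  The score is additive over any split of the
    block into sub-intervals.
    """
    score, _ = _block_score(block, panel, affected_ids, freqs, error_rate)
    return score


def score_blocks(
    blocks: list[SharedBlock],
    panel: GenotypePanel,
    affected_ids: list[str],
    freqs: AlleleFrequencyTable,
    error_rate: float = 0.01,
) -> list[SharedBlock]:
    """Fill ``location_score`` and ``n_skipped_markers`` on each block."""
    for block in blocks:
        score, skipped = _block_score(block, panel, affected_ids, freqs,
                                      error_rate)
        block.location_score = score
        block.n_skipped_markers = skipped
    blocks.sort(key=lambda b: (-(b.location_score or 0.0), b.chrom, b.start_bp))
    return blocks


def _matching_runs(match: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ok in enumerate(match):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(match) - 1))
    return runs


def exclusion_linkage_regions(
    panel: GenotypePanel,
    manifest: SampleManifest,
    min_size_mb: float = 5.0,
    tolerances: BlockTolerances | None = None,
    sib_match_min_mb: float = 3.0,
    sib_match_trim: int = 2,
) -> list[LinkageRegion]:
    """Regions consistent with recessive linkage in nuclear families.

    Within each family, candidate regions are maximal intervals where all
    affected children carry identical genotypes (heterozygous or
    homozygous) at every informative marker.  Each unaffected sibling then
    *excludes* the stretches over which its genotypes match the affected
    consensus contiguously for at least ``sib_match_min_mb`` — the
    footprint of sharing both parental haplotypes, which an unaffected
    sibling cannot do at the disease locus.  Short chance matches are not
    treated as sharing, and subtracted stretches are trimmed by
    ``sib_match_trim`` markers at each end so that chance continuation of
    a match into a true linkage region does not erode it.  Remaining
    intervals of at least ``min_size_mb`` are reported.
    """
    tol = tolerances or BlockTolerances(max_single_deviations=6,
                                        max_conflicts=1, max_missing=2)
    pos = panel.markers["pos"].to_numpy()
    regions: list[LinkageRegion] = []
    families = sorted({
        f for f in manifest.table["family_id"]
        if manifest.ids_where(family_id=f, status="affected")
    })
    for family in families:
        affected = manifest.ids_where(family_id=family, status="affected")
        sibs = [
            s for s in manifest.ids_where(family_id=family, status="unaffected")
            if manifest.table.set_index("sample_id").loc[s, "role"] == "sibling"
        ]
        if not sibs:
            warnings.warn(
                f"family {family!r} has no unaffected siblings; regions are "
                "affected-sharing only",
                stacklevel=2,
            )
        aff_calls = panel.sample_rows(affected)
        status_all, consensus_all = _identity_status(aff_calls)
        sib_calls = panel.sample_rows(sibs) if sibs else None
        for chrom, offset, idx in _per_chrom(panel):
            status = status_all[idx]
            consensus = consensus_all[idx]
            cpos = pos[idx]
            windows = maximal_windows(
                status, min_markers=2,
                max_soft=tol.max_single_deviations,
                max_bad=tol.max_conflicts,
                max_miss=tol.max_missing,
            )
            for l, r in windows:
                keep = np.ones(r - l + 1, dtype=bool)
                if sibs:
                    for k in range(len(sibs)):
                        calls = sib_calls[k, idx[l:r + 1]]
                        cons = consensus[l:r + 1]
                        match = (calls == cons) | (calls == MISSING) | (cons == -9)
                        for a, b in _matching_runs(match):
                            span = cpos[l + b] - cpos[l + a] + 1
                            if span >= sib_match_min_mb * 1e6:
                                a2 = a + sib_match_trim
                                b2 = b - sib_match_trim
                                if a2 <= b2:
                                    keep[a2:b2 + 1] = False
                for a, b in _matching_runs(keep):
                    start_bp = int(cpos[l + a])
                    end_bp = int(cpos[l + b])
                    if (end_bp - start_bp + 1) / 1e6 >= min_size_mb:
                        regions.append(LinkageRegion(
                            chrom=chrom, start_bp=start_bp, end_bp=end_bp,
                            family_id=family,
                        ))
    regions.sort(key=lambda x: (x.family_id, x.chrom, x.start_bp))
    return regions


def _identity_status(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`classify_shared_status` but for genotype identity
    (heterozygous consensus allowed), the linkage-screen criterion."""
    n_samples, n_markers = calls.shape
    status = np.full(n_markers, BAD, dtype=np.int8)
    consensus = np.full(n_markers, -9, dtype=np.int8)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    status[n_called == 0] = MISS
    for code in (AA, AB, BB):
        n_code = (calls == code).sum(axis=0)
        all_same = (n_called > 0) & (n_code == n_called)
        status[all_same] = GOOD
        consensus[all_same] = code
        soft = (n_code == n_called - 1) & (n_code >= 2) & (status == BAD)
        status[soft] = SOFT
        consensus[soft] = code
    return status, consensus


def summarize_blocks(blocks, gene_annotation: pd.DataFrame | None) -> dict:
    """Per-block gene counts plus size/count summaries.

    ``gene_annotation`` is a DataFrame with 1-based closed ``chrom, start,
    end`` columns (``name`` optional); a gene counts for a block if they
    overlap by at least 1 bp.  Sizes are reported in Mb to 1 decimal and
    mean gene counts as half-up integers, matching how mapping summaries
    are printed.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    if gene_annotation is not None and len(gene_annotation):
        for row in gene_annotation.itertuples():
            # half-open tree coordinates; +1 makes the closed end inclusive
            trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end + 1, getattr(row, "name", None)
            )
    per_block = []
    for b in blocks:
        iv = b.interval if hasattr(b, "interval") else b
        tree = trees.get(iv.chrom)
        n_genes = len(tree.overlap(iv.start, iv.end + 1)) if tree else 0
        per_block.append({
            "chrom": iv.chrom,
            "start_bp": iv.start,
            "end_bp": iv.end,
            "size_mb": round_half_up(iv.size_mb, 1),
            "n_genes": n_genes,
        })
    sizes = [b["size_mb"] for b in per_block]
    genes = [b["n_genes"] for b in per_block]
    summary = {
        "n_blocks": len(per_block),
        "mean_size_mb": round_half_up(float(np.mean(sizes)), 1) if sizes else None,
        "size_range_mb": (min(sizes), max(sizes)) if sizes else None,
        "mean_genes": int(round_half_up(float(np.mean(genes)))) if genes else None,
        "gene_range": (min(genes), max(genes)) if genes else None,
    }
    return {"per_block": per_block, "summary": summary}
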