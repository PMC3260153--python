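import numpy as np
import pytest

from founderscan.filtering import (
    FilterConfig,
    annotate_novelty,
    check_segregation,
    classify_pathogenic_potential,
    filter_candidates,
    homogeneity_scan,
)
from founderscan.model import (
    ALT_HOM, HET, REF_HOM, UNKNOWN,
    ConfigError, Interval, VariantRecord, VariantTable,
)
from conftest import make_manifest


def make_table(rows):
    """rows: (chrom, pos, consequence, catalogs, genotypes dict)."""
    records = [
        VariantRecord(chrom, pos, "A", "T", csq, dict(geno),
                      catalogs=frozenset(cats),
                      zygosity_known=(csq != "indel"))
        for chrom, pos, csq, cats, geno in rows
    ]
    return VariantTable.from_records(records)


class TestNovelty:
    def test_catalog_membership_examples(self):
        table = make_table([
            ("chr1", 10, "missense", {"dbSNP129"}, {"S1": 1}),
            ("chr1", 20, "missense", set(), {"S1": 1}),
        ])
        novel = annotate_novelty(table, ("dbSNP129", "1KG"))
        assert novel.tolist() == [False, True]

    def test_unknown_catalog_rejected(self):
        table = make_table([("chr1", 10, "missense", set(), {"S1": 1})])
        with pytest.raises(ConfigError, match="dbSNP999"):
            annotate_novelty(table, ("dbSNP999",))

    def test_matches_set_membership_oracle(self):
        rng = np.random.default_rng(17)
        pool = ["dbSNP129", "1KG"]
        rows = []
        for i in range(300):
            cats = {c for c in pool if rng.random() < 0.5}
            rows.append(("chr1", 10 + i, "missense", cats, {"S1": 1}))
        table = make_table(rows)
        for requested in (("dbSNP129",), ("1KG",), ("dbSNP129", "1KG")):
            novel = annotate_novelty(table, requested)
            expected = [
                not (set(requested) & c)
                for c in table.variants["catalogs"]
            ]
            assert novel.tolist() == expected


class TestPathogenicPotential:
    @pytest.mark.parametrize("csq,expected", [
        ("missense", True), ("nonsense", True), ("splice site", True),
        ("read-through", True), ("indel", True),
        ("synonymous", False), ("intron", False), ("5'-UTR", False),
        ("3'-UTR", False), ("5'-flanking", False), ("miRNA", False),
        ("IGR", False), ("other", False),
    ])
    def test_default_class_assignment(self, csq, expected):
        assert classify_pathogenic_potential(csq) is expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigError):
            classify_pathogenic_potential("gargoyle")

    def test_set_is_configurable(self):
        assert classify_pathogenic_potential(
            "synonymous", frozenset({"synonymous"}))


class TestCascade:
    def _toy(self):
        """20 hand-built variants; expected survivors worked out by hand."""
        interval = Interval("chr1", 1000, 2000)
        aff = {"A1": ALT_HOM, "A2": ALT_HOM}
        rows = []
        # 8 outside the interval
        for i in range(8):
            rows.append(("chr2", 100 + i, "missense", set(), dict(aff, U1=HET)))
        # 4 inside but catalogued
        for i in range(4):
            rows.append(("chr1", 1100 + i, "missense", {"dbSNP129"},
                         dict(aff, U1=HET)))
        # 3 inside, novel, not hom in all affecteds
        for i in range(3):
            rows.append(("chr1", 1200 + i, "missense", set(),
                         {"A1": ALT_HOM, "A2": HET, "U1": REF_HOM}))
        # 2 inside, novel, hom in affecteds AND one unaffected
        for i in range(2):
            rows.append(("chr1", 1300 + i, "missense", set(),
                         dict(aff, U1=ALT_HOM)))
        # 2 survivors of hom stages: one synonymous, one missense
        rows.append(("chr1", 1400, "synonymous", set(), dict(aff, U1=HET)))
        rows.append(("chr1", 1500, "missense", set(), dict(aff, U1=REF_HOM)))
        # total: 8+4+3+2+2 = 19; add an indel with unknown zygosity,
        # present in all affecteds, inside interval, novel
        rows.append(("chr1", 1600, "indel", set(),
                     {"A1": HET, "A2": HET, "U1": REF_HOM}))
        return make_table(rows), [interval]

    def test_hand_enumerated_counts(self):
        table, intervals = self._toy()
        candidates, report = filter_candidates(
            table, intervals, ["A1", "A2"], ["U1"])
        stages = {s: (a, k, d) for s, a, k, d in report.stages}
        assert stages["mapped_interval"] == (20, 12, 8)
        assert stages["novel"] == (12, 8, 4)
        # hom-in-all drops the 3 het-in-A2; the indel is retained flagged
        assert stages["homozygous_in_all_affected"] == (8, 5, 3)
        assert stages["not_homozygous_in_any_unaffected"] == (5, 3, 2)
        assert stages["potentially_pathogenic"] == (3, 2, 1)
        keys = {c.record.pos for c in candidates}
        assert keys == {1500, 1600}
        indel = next(c for c in candidates if c.record.pos == 1600)
        assert indel.zygosity_warning

    def test_strict_indel_mode_drops_unknown_zygosity(self):
        table, intervals = self._toy()
        candidates, _ = filter_candidates(
            table, intervals, ["A1", "A2"], ["U1"],
            FilterConfig(strict_indels=True))
        assert {c.record.pos for c in candidates} == {1500}

    def test_counts_partition_at_every_stage(self):
        """kept + dropped == input, and stage inputs chain, on random
        tables (the conservation property of the cascade report)."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            rows = []
            for i in range(int(rng.integers(1, 80))):
                geno = {
                    s: int(rng.choice([REF_HOM, HET, ALT_HOM, UNKNOWN]))
                    for s in ("A1", "A2", "U1", "U2")
                }
                cats = {c for c in ("dbSNP129", "1KG") if rng.random() < 0.4}
                csq = str(rng.choice(["missense", "synonymous", "intron"]))
                rows.append((f"chr{rng.integers(1, 3)}",
                             int(rng.integers(1, 10_000)), csq, cats, geno))
            table = make_table(rows)
            _, report = filter_candidates(
                table, [Interval("chr1", 1, 5000)], ["A1", "A2"],
                ["U1", "U2"])
            prev_kept = len(table)
            for stage, n_in, n_kept, n_dropped in report.stages:
                assert n_in == prev_kept
                assert n_kept + n_dropped == n_in
                prev_kept = n_kept

    def test_interval_and_novelty_filters_commute(self):
        table, intervals = self._toy()
        base = FilterConfig()
        a, _ = filter_candidates(table, intervals, ["A1", "A2"], ["U1"], base)
        # novelty applied "first" by pre-subsetting the table
        novel_mask = annotate_novelty(table, base.catalog_names)
        b, _ = filter_candidates(table.subset(novel_mask), intervals,
                                 ["A1", "A2"], ["U1"], base)
        assert {c.record.key for c in a} == {c.record.key for c in b}

    def test_no_intervals_without_genome_wide_rejected(self):
        table, _ = self._toy()
        with pytest.raises(ConfigError, match="genome-wide"):
            filter_candidates(table, None, ["A1"], ["U1"])

    def test_missing_affected_genotype_counts_as_not_homozygous(self):
        table = make_table([
            ("chr1", 1500, "missense", set(),
             {"A1": ALT_HOM, "A2": UNKNOWN, "U1": REF_HOM}),
        ])
        candidates, report = filter_candidates(
            table, [Interval("chr1", 1, 5000)], ["A1", "A2"], ["U1"])
        assert candidates == []
        assert report.n_missing_affected_genotypes == 1


class TestHomogeneityScan:
    def test_planted_variant_unique_in_synthetic_study(self, small_study):
        aff = [s for s in small_study.manifest.affected_ids]
        others = [s for s in small_study.variants.samples
                  if s not in set(aff)]
        found = homogeneity_scan(small_study.variants, aff, others)
        chrom, pos, ref, alt = small_study.truth.pathogenic_variant
        assert [c.record.key for c in found] == [(chrom, pos, ref, alt)]

    def test_variant_homozygous_in_unaffected_excluded(self):
        table = make_table([
            ("chr1", 10, "missense", set(),
             {"A1": ALT_HOM, "A2": ALT_HOM, "U1": ALT_HOM}),
        ])
        assert homogeneity_scan(table, ["A1", "A2"], ["U1"]) == []

    def test_single_affected_degenerates_to_novel_hom_list(self):
        rows = []
        rng = np.random.default_rng(11)
        for i in range(50):
            cats = {"dbSNP129"} if rng.random() < 0.5 else set()
            g = int(rng.choice([REF_HOM, HET, ALT_HOM]))
            rows.append(("chr1", 100 + i, "missense", cats, {"A1": g}))
        table = make_table(rows)
        found = homogeneity_scan(table, ["A1"], [])
        expected = {
            (r.chrom, r.pos, r.ref, r.alt)
            for r in table.records()
            if not r.catalogs and r.genotypes["A1"] == ALT_HOM
        }
        assert {c.record.key for c in found} == expected


class TestSegregation:
    def _manifest(self):
        return make_manifest([
            {"sample_id": "FA", "family_id": "F", "status": "unaffected",
             "role": "parent"},
            {"sample_id": "MO", "family_id": "F", "status": "unaffected",
             "role": "parent"},
            {"sample_id": "A1", "family_id": "F", "father_id": "FA",
             "mother_id": "MO", "status": "affected", "role": "case"},
            {"sample_id": "A2", "family_id": "F", "father_id": "FA",
             "mother_id": "MO", "status": "affected", "role": "case"},
            *[{"sample_id": f"U{i}", "family_id": "F", "father_id": "FA",
               "mother_id": "MO", "status": "unaffected", "role": "sibling"}
              for i in range(1, 7)],
        ])

    def _variant(self, genotypes):
        return VariantRecord("chr5", 100, "G", "T", "splice site", genotypes)

    def test_classic_recessive_family_passes(self):
        """Parents het, affecteds homozygous, six sibs het or wild-type."""
        geno = {"FA": HET, "MO": HET, "A1": ALT_HOM, "A2": ALT_HOM,
                "U1": HET, "U2": REF_HOM, "U3": HET, "U4": REF_HOM,
                "U5": HET, "U6": REF_HOM}
        result = check_segregation(self._variant(geno), self._manifest())
        assert result.passed
        assert result.n_missing == 0

    def test_homozygous_unaffected_sibling_fails(self):
        geno = {"FA": HET, "MO": HET, "A1": ALT_HOM, "A2": ALT_HOM,
                "U1": ALT_HOM, "U2": REF_HOM, "U3": HET, "U4": REF_HOM,
                "U5": HET, "U6": REF_HOM}
        assert not check_segregation(self._variant(geno),
                                     self._manifest()).passed

    def test_missing_genotypes_reported_not_failing(self):
        geno = {"FA": HET, "MO": UNKNOWN, "A1": ALT_HOM, "A2": ALT_HOM,
                "U1": HET, "U2": REF_HOM, "U3": HET, "U4": REF_HOM,
                "U5": HET, "U6": REF_HOM}
        result = check_segregation(self._variant(geno), self._manifest())
        assert result.passed
        assert result.n_missing == 1

    def test_matches_rule_oracle_on_random_trios(self):
        rng = np.random.default_rng(42)
        manifest = make_manifest([
            {"sample_id": "FA", "family_id": "F", "status": "unaffected",
             "role": "parent"},
            {"sample_id": "MO", "family_id": "F", "status": "unaffected",
             "role": "parent"},
            {"sample_id": "A1", "family_id": "F", "father_id": "FA",
             "mother_id": "MO", "status": "affected", "role": "case"},
        ])
        for _ in range(200):
            geno = {s: int(rng.choice([REF_HOM, HET, ALT_HOM, UNKNOWN]))
                    for s in ("FA", "MO", "A1")}
            result = check_segregation(self._variant(geno), manifest)
            expected = True
            for s in ("FA", "MO"):
                if geno[s] != UNKNOWN:
                    expected &= geno[s] == HET
            if geno["A1"] != UNKNOWN:
                expected &= geno["A1"] == ALT_HOM
            assert result.passed == expected, geno
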