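"""COG subcategory percentages, SBG/WBG ratios, AVDT and pathway fractions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandbias.errors import ParseError, UndefinedStatisticError
from strandbias.functional_categories import (
    COG_SUBCATEGORIES,
    DiffRecord,
    avdt,
    diff_ratios,
    genome_group_proportions,
    pathway_proportions,
    pcog,
    select_scog_wcog,
    split_cohort,
)


class TestPCOG:
    def test_rsx_filter_and_fractions(self):
        assignments = (
            [(f"j{i}", "J") for i in range(10)]
            + [(f"c{i}", "C") for i in range(10)]
            + [(f"r{i}", "R") for i in range(5)]
        )
        p = pcog(assignments)
        assert p["J"] == pytest.approx(0.5)
        assert p["C"] == pytest.approx(0.5)
        assert "R" not in p
        assert sum(p.values()) == pytest.approx(1.0)

    def test_multi_letter_assignment_counts_per_letter(self):
        p = pcog([("g1", "KL")])
        assert p["K"] == pytest.approx(0.5)
        assert p["L"] == pytest.approx(0.5)

    def test_only_excluded_letters_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pcog([("g1", "R"), ("g2", "SX")])

    @settings(derandomize=True, max_examples=40)
    @given(st.data())
    def test_normalization_and_counting_oracle(self, data):
        letters = data.draw(
            st.lists(
                st.sampled_from(list(COG_SUBCATEGORIES) + ["R", "S", "X"]),
                min_size=1, max_size=60,
            )
        )
        if all(ch in "RSX" for ch in letters):
            return
        p = pcog([(f"g{i}", ch) for i, ch in enumerate(letters)])
        kept = [ch for ch in letters if ch not in "RSX"]
        assert sum(p.values()) == pytest.approx(1.0)
        for ch in COG_SUBCATEGORIES:
            assert p[ch] == pytest.approx(kept.count(ch) / len(kept))


class TestSplitCohort:
    def test_1111_genomes_split_555_556(self):
        scores = [(f"g{i:04d}", i / 10000) for i in range(1111)]
        sbg, wbg = split_cohort(scores)
        assert (len(sbg), len(wbg)) == (555, 556)
        assert min(float(g[1:]) for g in sbg) == 556  # top 555 by score

    def test_top_half_by_score(self):
        sbg, wbg = split_cohort([("a", 1.0), ("b", 2.0), ("c", 3.0), ("d", 4.0)])
        assert set(sbg) == {"c", "d"}

    def test_ties_broken_by_id(self):
        scores = [(g, 0.5) for g in "fedcba"]
        sbg, wbg = split_cohort(scores)
        assert sbg == ["a", "b", "c"]
        assert split_cohort(scores) == (sbg, wbg)  # deterministic

    def test_too_few_genomes(self):
        with pytest.raises(UndefinedStatisticError):
            split_cohort([("a", 1.0)])


class TestDiffRatios:
    def test_basic_ratio(self):
        (rec,) = diff_ratios({"g1": 10}, {"g1": 5})
        assert rec.ratio == pytest.approx(2.0)

    def test_zero_sbg_count(self):
        (rec,) = diff_ratios({"g1": 0}, {"g1": 7})
        assert rec.ratio == 0.0

    def test_absent_from_wbg_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            out = diff_ratios({"g1": 10}, {})
        assert out == []
        assert "g1" in caplog.text

    def test_pseudocount_alternative(self):
        (rec,) = diff_ratios({"g1": 9}, {}, pseudocount=1)
        assert rec.ratio == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        counts=st.dictionaries(
            st.sampled_from([f"G{i}" for i in range(8)]),
            st.tuples(st.integers(0, 50), st.integers(1, 50)),
            min_size=1,
        ),
        scale=st.integers(2, 7),
    )
    def test_homogeneity_under_count_scaling(self, counts, scale):
        """Scaling all counts in both groups leaves every ratio unchanged."""
        sbg = {g: c[0] for g, c in counts.items()}
        wbg = {g: c[1] for g, c in counts.items()}
        base = diff_ratios(sbg, wbg)
        scaled = diff_ratios(
            {g: scale * v for g, v in sbg.items()},
            {g: scale * v for g, v in wbg.items()},
        )
        assert [r.ratio for r in base] == pytest.approx([r.ratio for r in scaled])


class TestAVDT:
    def test_single_group(self):
        out = avdt([DiffRecord("g1", 3, 1, 3.0)], {"g1": "J"})
        assert out[0].subcategory == "J"
        assert out[0].avdt == pytest.approx(3.0)

    def test_mean_of_two_groups(self):
        recs = [DiffRecord("g1", 2, 1, 2.0), DiffRecord("g2", 4, 1, 4.0)]
        out = avdt(recs, {"g1": "J", "g2": "J"})
        assert out[0].avdt == pytest.approx(3.0)
        assert out[0].n_groups == 2

    def test_multi_letter_group_contributes_to_each(self):
        out = avdt([DiffRecord("g1", 2, 1, 2.0)], {"g1": "KL"})
        assert {r.subcategory for r in out} == {"K", "L"}
        assert all(r.avdt == pytest.approx(2.0) for r in out)

    def test_uniform_ratio_is_fixed_point(self, rng):
        """A subcategory whose groups all have ratio r has AVDT exactly r."""
        r = 1.7
        recs = [DiffRecord(f"g{i}", 17, 10, r) for i in range(6)]
        out = avdt(recs, {f"g{i}": "C" for i in range(6)})
        assert out[0].avdt == r

    def test_random_tables_match_groupby_mean_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 30))
            recs = [
                DiffRecord(f"g{i}", 0, 1, float(rng.uniform(0, 8)))
                for i in range(n)
            ]
            mapping = {
                f"g{i}": str(rng.choice(list("JCDEK"))) for i in range(n)
            }
            expected = {}
            for rec in recs:
                expected.setdefault(mapping[rec.cog_group_id], []).append(rec.ratio)
            out = {a.subcategory: a.avdt for a in avdt(recs, mapping)}
            for letter, vals in expected.items():
                assert out[letter] == pytest.approx(sum(vals) / len(vals))


class TestSelection:
    def test_threshold_application(self):
        recs = [
            DiffRecord("g1", 6, 1, 6.0),
            DiffRecord("g2", 1, 1, 1.0),
            DiffRecord("g3", 1, 10, 0.1),
        ]
        sets = select_scog_wcog(recs)
        assert sets.scog_ids == {"g1"}
        assert sets.wcog_ids == {"g3"}

    def test_empty_input(self):
        sets = select_scog_wcog([])
        assert sets.scog_ids == frozenset()
        assert sets.wcog_ids == frozenset()

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            select_scog_wcog([], hi=0.1, lo=0.5)


class TestGenomeGroupProportions:
    SETS = select_scog_wcog(
        [DiffRecord("s1", 6, 1, 6.0), DiffRecord("w1", 1, 10, 0.1)]
    )

    def test_fraction_of_annotated_genes(self):
        assignments = [(f"g{i}", "s1") for i in range(4)] + [
            (f"h{i}", "x1") for i in range(6)
        ]
        s, w = genome_group_proportions(assignments, self.SETS)
        assert s == pytest.approx(0.4)
        assert w == 0.0

    def test_no_genes_in_either_set(self):
        s, w = genome_group_proportions([("g1", "x1")], self.SETS)
        assert (s, w) == (0.0, 0.0)

    def test_unannotated_genome_propagates_na(self):
        s, w = genome_group_proportions([], self.SETS)
        assert math.isnan(s) and math.isnan(w)


class TestPathwayProportions:
    def test_basic_fraction(self):
        pairs = [(f"g{i}", "ko03430") for i in range(5)]
        out = pathway_proportions(pairs, n_genes_annotated=100)
        assert out["ko03430"] == pytest.approx(0.05)

    def test_no_repair_genes(self):
        out = pathway_proportions([], n_genes_annotated=50)
        assert all(v == 0.0 for v in out.values())
        assert len(out) == 10

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ParseError, match="ko99999"):
            pathway_proportions([("g1", "ko99999")])

    def test_matches_bruteforce_tally(self, rng):
        from strandbias.functional_categories import REPAIR_PATHWAYS

        for _ in range(10):
            n = int(rng.integers(1, 60))
            pairs = [
                (f"g{i}", str(rng.choice(REPAIR_PATHWAYS))) for i in range(n)
            ]
            out = pathway_proportions(pairs, n_genes_annotated=n)
            for pid in REPAIR_PATHWAYS:
                want = len({g for g, p in pairs if p == pid}) / n
                assert out[pid] == pytest.approx(want)
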