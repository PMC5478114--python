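import itertools

import numpy as np
import pandas as pd
import pytest

from sigcore.combos import (
    enumerate_combinations,
    evaluate_all,
    extract_cores,
    intersect_cores,
    leave_one_pathway_out,
    pairwise_cooccurrence,
    partner_threshold,
    pathway_coverage,
    select_core1,
    select_core2,
    select_top,
)
from sigcore.io import median_center
from sigcore.resources import load_core, load_core1, load_core2, load_htics
from sigcore.ssm import ssm_scores
from sigcore.survival import oe_hr, logrank_p

from conftest import make_clinical, make_expr, make_signature


def records_from_masks(masks, genes):
    df = pd.DataFrame({"mask": masks})
    df.attrs["genes"] = list(genes)
    return df


class TestEnumeration:
    @pytest.mark.parametrize("k,count", [(1, 1), (3, 7), (10, 1023)])
    def test_counts(self, k, count):
        masks = list(enumerate_combinations(k))
        assert len(masks) == count
        assert len(set(masks)) == count

    def test_distinct_and_complete_for_signature(self):
        sig = make_signature([(f"G{i}", 1) for i in range(5)])
        assert sorted(enumerate_combinations(sig)) == list(range(1, 32))

    def test_refuses_blowup(self):
        with pytest.raises(ValueError, match="pre-select"):
            enumerate_combinations(25)


class TestEvaluateAll:
    def _toy_cohort(self, seed, n=60):
        rng = np.random.default_rng(seed)
        expr = make_expr({"A": list(rng.normal(size=n)), "B": list(rng.normal(size=n))})
        clin = make_clinical(
            expr.sample_ids, rng.exponential(10, size=n), rng.integers(0, 2, size=n)
        )
        return expr, clin

    def test_k2_records_match_direct_survival_calls(self):
        sig = make_signature([("A", 1), ("B", -1)])
        em, cm = self._toy_cohort(1)
        eo, co = self._toy_cohort(2)
        rec = evaluate_all(em, cm, eo, co, sig).set_index("mask")
        for mask in (1, 2, 3):
            sub = sig.subset_mask(mask)
            g = ssm_scores(median_center(em), sub).match.to_numpy()
            t = cm.df["time_months"].to_numpy()
            e = cm.df["event"].to_numpy()
            assert rec.loc[mask, "hr_mfs"] == pytest.approx(oe_hr(t, e, g), rel=1e-12)
            assert rec.loc[mask, "p_mfs"] == pytest.approx(logrank_p(t, e, g), rel=1e-9)

    def test_sweep_is_deterministic(self):
        sig = make_signature([("A", 1), ("B", -1)])
        em, cm = self._toy_cohort(3)
        eo, co = self._toy_cohort(4)
        r1 = evaluate_all(em, cm, eo, co, sig)
        r2 = evaluate_all(em, cm, eo, co, sig)
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_subsets_flagged_not_fatal(self):
        # gene C is constant: its singleton subset puts everyone in "match"
        rng = np.random.default_rng(5)
        n = 40
        em = make_expr(
            {"A": list(rng.normal(size=n)), "C": [1.0] * n}
        )
        cm = make_clinical(em.sample_ids, rng.exponential(10, n), rng.integers(0, 2, n))
        sig = make_signature([("A", 1), ("C", 1)])
        rec = evaluate_all(em, cm, em, cm, sig).set_index("mask")
        assert np.isnan(rec.loc[2, "hr_mfs"])  # C alone: no split
        assert not rec.loc[2, "significant"]


class TestPairwiseCooccurrence:
    def test_three_record_fixture(self):
        # records {AB, AC, ABC} over genes A, B, C
        rec = records_from_masks([0b011, 0b101, 0b111], ["A", "B", "C"])
        stats = pairwise_cooccurrence(rec)
        assert stats.cooccurrence.loc["A", "B"] == pytest.approx(200 / 3)
        assert stats.cooccurrence.loc["B", "C"] == pytest.approx(100 / 3)
        assert stats.gene_frequency["A"] == pytest.approx(100.0)

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_all_subsets_closed_form(self, k):
        rec = records_from_masks(list(enumerate_combinations(k)), [f"G{i}" for i in range(k)])
        stats = pairwise_cooccurrence(rec)
        expected = 100.0 * 2 ** (k - 2) / (2**k - 1)
        off = stats.cooccurrence.to_numpy()[np.triu_indices(k, 1)]
        np.testing.assert_allclose(off, expected)

    def test_matches_brute_force_double_loop(self, rng):
        genes = [f"G{i}" for i in range(7)]
        masks = rng.integers(1, 2**7, size=150)
        rec = records_from_masks(masks, genes)
        stats = pairwise_cooccurrence(rec)
        for i, j in itertools.combinations(range(7), 2):
            both = sum(1 for m in masks if (m >> i) & 1 and (m >> j) & 1)
            assert stats.cooccurrence.iloc[i, j] == pytest.approx(100 * both / len(masks))

    def test_cooccurrence_bounded_by_marginal_frequencies(self, rng):
        genes = [f"G{i}" for i in range(6)]
        rec = records_from_masks(rng.integers(1, 2**6, size=80), genes)
        stats = pairwise_cooccurrence(rec)
        c = stats.cooccurrence.to_numpy()
        f = stats.gene_frequency.to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            assert c[i, j] <= min(f[i], f[j]) + 1e-9

    def test_threshold_is_mean_plus_one_sd(self, rng):
        rec = records_from_masks(rng.integers(1, 2**5, size=50), [f"G{i}" for i in range(5)])
        stats = pairwise_cooccurrence(rec)
        assert stats.threshold == stats.mean_overlap + stats.sd_overlap
        assert partner_threshold(stats.mean_overlap, stats.sd_overlap) == stats.threshold


class TestCoreSelection:
    def test_core1_empty_when_nothing_partners(self):
        # all pairs at identical overlap: nothing exceeds mean + sd
        rec = records_from_masks(
            list(enumerate_combinations(4)), ["A", "B", "C", "D"]
        )
        stats = pairwise_cooccurrence(rec)
        assert select_core1(stats) == []

    def test_core1_partner_counting_by_hand(self):
        # A pairs with B and C in most records; D rarely appears
        masks = [0b0111] * 6 + [0b0011] * 2 + [0b1000] * 2
        stats = pairwise_cooccurrence(records_from_masks(masks, ["A", "B", "C", "D"]))
        # overlaps: AB=80%, AC=BC=60%, *D=0 -> mean 33.3, sd ~34 -> threshold ~67
        assert select_core1(stats, min_partners=1) == ["A", "B"]
        assert select_core1(stats, min_partners=2) == []

    def test_select_top_membership_by_direct_comparison(self):
        rec = pd.DataFrame(
            {
                "mask": [1, 2, 3, 4],
                "hr_mfs": [5.0, 4.0, 6.0, 7.0],
                "hr_os": [5.0, 6.0, 4.5, 5.5],
                "significant": [True, True, True, False],
            }
        )
        rec.attrs["genes"] = ["A", "B", "C"]
        top = select_top(rec, (5.0, 5.0))
        assert top["mask"].tolist() == [1]  # 4 fails significance, 2 and 3 fail one HR
        # margin 0.9: thresholds (4.5, 4.5) -> record 2 fails hr_mfs 4.0
        top_margin = select_top(rec, (5.0, 5.0), margin=0.9)
        assert top_margin["mask"].tolist() == [1, 3]

    def test_core2_empty_under_uniform_frequencies(self):
        rec = records_from_masks(list(enumerate_combinations(4)), list("ABCD"))
        assert select_core2(rec) == []  # strict > median removes everything

    def test_intersect_cores_printed_fixture(self):
        core = intersect_cores(load_core1().genes, load_core2().genes)
        assert core == sorted(["Ccr2", "Nrp1", "Scrn1", "CD74", "Chaf1b", "Npy"])
        signed = intersect_cores(load_core1().genes, load_core2().genes, load_htics())
        assert set(signed.genes) == set(load_core().genes)
        ups = {g for g, d in zip(signed.genes, signed.directions) if d == 1}
        assert ups == {"Chaf1b", "Scrn1", "Npy"}

    def test_intersect_disjoint_and_identical(self):
        assert intersect_cores(["A"], ["B"]) == []
        assert intersect_cores(["A", "B"], ["B", "A"]) == ["A", "B"]


class TestPathwayTools:
    def test_full_signature_covers_all_five_pathways(self):
        htics = load_htics()
        rec = records_from_masks([(1 << 17) - 1], htics.genes)
        per_record, summary = pathway_coverage(rec, htics)
        assert per_record[0] == {
            "Cell Cycle",
            "Immune Response",
            "Cell Migration",
            "Homeostasis",
            "Glycan Metabolism",
        }

    def test_single_gene_record_maps_to_its_pathway(self):
        htics = load_htics()
        atp7b_mask = 1 << htics.genes.index("Atp7b")
        per_record, _ = pathway_coverage(records_from_masks([atp7b_mask], htics.genes), htics)
        assert per_record[0] == {"Homeostasis"}

    def test_core_record_covers_exactly_three_pathways(self):
        htics = load_htics()
        mask = 0
        for g in load_core().genes:
            mask |= 1 << htics.genes.index(g)
        per_record, _ = pathway_coverage(records_from_masks([mask], htics.genes), htics)
        assert per_record[0] == {"Cell Cycle", "Immune Response", "Cell Migration"}

    @pytest.mark.parametrize(
        "pathway,remaining", [("Cell Cycle", 13), ("Glycan Metabolism", 16)]
    )
    def test_leave_one_pathway_out_sizes(self, pathway, remaining):
        reduced = leave_one_pathway_out(load_htics(), pathway)
        assert len(reduced) == remaining
        assert pathway not in set(reduced.pathways)

    def test_leave_out_missing_pathway_errors(self):
        with pytest.raises(KeyError):
            leave_one_pathway_out(load_htics(), "Metabolism of Tears")
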