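import numpy as np
import pandas as pd
import pytest

from sigcore.io import median_center
from sigcore.resources import htics_m, load_htics, load_substitutes
from sigcore.ssm import ssm_scores
from sigcore.substitution import (
    apply_substitution,
    find_substitutes,
    score_agreement,
    substitution_map_from_table,
)
from sigcore.synthetic import SyntheticConfig, generate_cohort

from conftest import make_expr, make_signature


def toy_matrix(rng, n=20):
    sig_vals = rng.normal(size=n)
    return make_expr(
        {
            "SIG": list(sig_vals),
            "COPY": list(sig_vals),
            "ANTI": list(-sig_vals),
            "NOISE": list(rng.normal(size=n)),
        }
    )


class TestFindSubstitutes:
    def test_identical_candidate_wins_with_r_one(self, rng):
        expr = toy_matrix(rng)
        sig = make_signature([("SIG", 1)])
        smap = find_substitutes(expr, sig, ["COPY", "NOISE"])
        assert smap.substitute_for("SIG") == "COPY"
        assert smap.table["r"].iloc[0] == pytest.approx(1.0)

    def test_signed_r_prefers_uncorrelated_over_anticorrelated(self, rng):
        expr = toy_matrix(rng)
        sig = make_signature([("SIG", 1)])
        smap = find_substitutes(expr, sig, ["ANTI", "NOISE"])
        assert smap.substitute_for("SIG") == "NOISE"
        # absolute-r mode flips the choice and flags the anticorrelation
        smap_abs = find_substitutes(expr, sig, ["ANTI", "NOISE"], absolute=True)
        assert smap_abs.substitute_for("SIG") == "ANTI"
        assert bool(smap_abs.table["anticorrelated"].iloc[0])

    def test_argmax_matches_brute_force_pearson(self, rng):
        n = 15
        expr = make_expr({g: list(rng.normal(size=n)) for g in ["S", "C1", "C2", "C3"]})
        sig = make_signature([("S", 1)])
        smap = find_substitutes(expr, sig, ["C1", "C2", "C3"])
        rs = {
            c: np.corrcoef(expr.values.loc["S"], expr.values.loc[c])[0, 1]
            for c in ["C1", "C2", "C3"]
        }
        assert smap.substitute_for("S") == max(rs, key=rs.get)
        assert smap.table["r"].iloc[0] == pytest.approx(max(rs.values()))

    def test_invariant_to_sample_order_and_positive_affine(self, rng):
        expr = toy_matrix(rng)
        sig = make_signature([("SIG", 1)])
        base = find_substitutes(expr, sig, ["COPY", "NOISE", "ANTI"])
        perm = rng.permutation(expr.sample_ids)
        shuffled = expr.subset_samples(list(perm))
        transformed = make_expr(
            {g: list(3.0 * shuffled.values.loc[g] + 5.0) for g in shuffled.gene_ids},
            samples=list(perm),
        )
        again = find_substitutes(transformed, sig, ["COPY", "NOISE", "ANTI"])
        pd.testing.assert_frame_equal(base.table, again.table)

    def test_empty_candidates_error(self, rng):
        with pytest.raises(ValueError):
            find_substitutes(toy_matrix(rng), make_signature([("SIG", 1)]), [])

    def test_same_pathway_recovery_on_blocked_cohorts(self):
        """With tight pathway blocks, substitutes come from the same block."""
        fractions = []
        for seed in range(11):
            cfg = SyntheticConfig(
                n_samples=200, n_genes=300, block_rho=0.7, beta=0.0, frac_her2=0.0,
                seed=900 + seed,
            )
            expr, _, truth = generate_cohort(cfg)
            block_of = truth["block_of"]
            sig = cfg.signature
            candidates = [g for g in block_of if g not in set(sig.genes)]
            smap = find_substitutes(expr, sig, candidates, block_of)
            fractions.append(smap.table["same_pathway"].mean())
        assert np.median(fractions) > 0.9


class TestApplySubstitution:
    def test_replace_none_is_identity(self):
        htics = load_htics()
        smap = substitution_map_from_table(load_substitutes()[lambda d: d.role == "ffpe_backup"])
        out = apply_substitution(htics, smap, genes_to_replace=[])
        assert out.genes == htics.genes

    def test_ffpe_backup_substitution_builds_modified_signature(self):
        m = htics_m()
        htics = load_htics()
        assert len(m) == 17
        for original, substitute in [
            ("Npy", "Spink5"),
            ("Ccr2", "Ctss"),
            ("CD180", "Aim2"),
            ("CD72", "CD48"),
        ]:
            assert substitute in m.genes and original not in m.genes
            # substitutes inherit the replaced gene's direction
            assert m.direction_of(substitute) == htics.direction_of(original)
        assert set(htics.genes) - set(m.genes) == {"Npy", "Ccr2", "CD180", "CD72"}

    def test_missing_map_entry_errors(self):
        htics = load_htics()
        smap = substitution_map_from_table(
            pd.DataFrame({"gene": ["Npy"], "substitute": ["Spink5"]})
        )
        with pytest.raises(KeyError):
            apply_substitution(htics, smap, genes_to_replace=["Ccr2"])


class TestScoreAgreement:
    def test_self_agreement_is_perfect(self, rng):
        genes = [f"G{i}" for i in range(5)]
        centered = median_center(make_expr({g: list(rng.normal(size=21)) for g in genes}))
        sig = make_signature([(g, 1) for g in genes])
        r, auc = score_agreement(centered, sig, sig)
        assert (r, auc) == (1.0, 1.0)

    def test_direction_flip_anticorrelates(self, rng):
        genes = [f"G{i}" for i in range(5)]
        centered = median_center(make_expr({g: list(rng.normal(size=20)) for g in genes}))
        centered.values = centered.values.replace(0.0, 0.3)  # no exact-median ties
        sig = make_signature([(g, 1) for g in genes])
        r, _ = score_agreement(centered, sig, sig.flipped())
        assert r == pytest.approx(-1.0)

    def test_exact_copy_substitution_leaves_scores_unchanged(self, rng):
        genes = ["A", "B"]
        vals = {g: list(rng.normal(size=15)) for g in genes}
        vals["A2"] = vals["A"]
        centered = median_center(make_expr(vals))
        sig = make_signature([("A", 1), ("B", -1)])
        smap = substitution_map_from_table(
            pd.DataFrame({"gene": ["A"], "substitute": ["A2"]})
        )
        alt = apply_substitution(sig, smap, genes_to_replace=["A"])
        a = ssm_scores(centered, sig)
        b = ssm_scores(centered, alt)
        np.testing.assert_allclose(a.ssm.to_numpy(), b.ssm.to_numpy())

    def test_correlated_substitutes_track_original_scores(self):
        """Block-mates at rho = 0.7 yield strongly agreeing signatures."""
        rs = []
        for seed in range(9):
            cfg = SyntheticConfig(
                n_samples=200, n_genes=300, block_rho=0.7, beta=0.0, frac_her2=0.0,
                seed=300 + seed,
            )
            expr, _, truth = generate_cohort(cfg)
            sig = cfg.signature
            candidates = [g for g in truth["block_of"] if g not in set(sig.genes)]
            smap = find_substitutes(expr, sig, candidates, truth["block_of"])
            alt = apply_substitution(sig, smap, "all")
            r, _ = score_agreement(median_center(expr), sig, alt)
            rs.append(r)
        assert np.median(rs) > 0.5
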