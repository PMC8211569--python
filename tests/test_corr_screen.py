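import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glucoscreen import (
    ExpressionMatrix,
    ScreenConfig,
    classify_change,
    correlation_matrix,
    fisher_z_difference,
    generate_cohorts,
    pair_change_table,
    render_corr_dotplot,
    screen_consistent_pairs,
)
from glucoscreen.corr_screen import classify_change_array
from glucoscreen.synthetic_data import PlantedPair, SyntheticSpec


def pearson_oracle(x, y):
    """Textbook sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    return (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))


def classify_oracle(rn, rc, sign_tau, delta_min):
    """Straight-line restatement of the six-category definition."""
    start = "pos" if rn > sign_tau else ("neg" if rn < -sign_tau else "none")
    if start == "none":
        return "undefined"
    if abs(rn - rc) < delta_min:
        return "null_change"
    if start == "pos":
        if rc > rn:
            return "pos_more_pos"
        return "pos_to_neg" if rc < -sign_tau else "pos_less_pos"
    if rc < rn:
        return "neg_more_neg"
    return "neg_to_pos" if rc > sign_tau else "neg_less_neg"


class TestCorrelationMatrix:
    def test_duplicated_gene_correlates_perfectly(self, rng):
        x = rng.gamma(2.0, 10.0, size=12)
        m = ExpressionMatrix(["A", "Acopy"], [f"s{i}" for i in range(12)],
                             np.vstack([x, x]))
        cm = correlation_matrix(m, transform="none")
        assert cm.r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_gene_correlates_at_minus_one(self, rng):
        x = rng.gamma(2.0, 10.0, size=12)
        m = ExpressionMatrix(["A", "B"], [f"s{i}" for i in range(12)],
                             np.vstack([x, 2 * x.max() - x]))
        cm = correlation_matrix(m, transform="none")
        assert cm.r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula_entrywise(self, rng):
        values = rng.gamma(2.0, 10.0, size=(5, 30))
        m = ExpressionMatrix([f"g{i}" for i in range(5)],
                             [f"s{j}" for j in range(30)], values)
        cm = correlation_matrix(m, transform="none")
        for i in range(5):
            for j in range(5):
                assert cm.r[i, j] == pytest.approx(
                    pearson_oracle(values[i], values[j]), abs=1e-10
                )

    def test_symmetric_and_unit_diagonal(self, rng):
        values = rng.gamma(2.0, 10.0, size=(8, 15))
        cm = correlation_matrix(
            ExpressionMatrix([f"g{i}" for i in range(8)],
                             [f"s{j}" for j in range(15)], values)
        )
        np.testing.assert_allclose(cm.r, cm.r.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(cm.r), 1.0)

    def test_zero_variance_gene_is_undefined_everywhere(self, rng):
        values = rng.gamma(2.0, 10.0, size=(3, 10))
        values[1] = 7.0
        cm = correlation_matrix(
            ExpressionMatrix(["A", "flat", "C"], [f"s{j}" for j in range(10)], values)
        )
        assert not cm.defined_mask[1].any()
        assert np.isnan(cm.r[1]).all()
        assert cm.defined_mask[0, 2]

    def test_fewer_than_three_samples_rejected(self):
        m = ExpressionMatrix(["A"], ["s1", "s2"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match=">= 3 samples"):
            correlation_matrix(m)


class TestChangeClassifier:
    @pytest.mark.parametrize(
        "rn, rc, expected",
        [
            (-0.60, -0.20, "neg_less_neg"),   # the ADH6-GYC1 pattern
            (0.70, 0.70, "null_change"),
            (0.70, 0.20, "pos_less_pos"),
            (0.50, 0.80, "pos_more_pos"),
            (0.50, -0.30, "pos_to_neg"),
            (-0.50, -0.80, "neg_more_neg"),
            (-0.50, 0.30, "neg_to_pos"),
            (0.05, 0.90, "undefined"),
        ],
    )
    def test_canonical_patterns(self, rn, rc, expected):
        assert classify_change(rn, rc, ScreenConfig(0.1, 0.1)) == expected

    def test_boundary_landing_on_dead_zone_edge_is_less_not_crossing(self):
        cfg = ScreenConfig(0.1, 0.1)
        assert classify_change(0.8, -0.1, cfg) == "pos_less_pos"
        assert classify_change(-0.8, 0.1, cfg) == "neg_less_neg"

    def test_undefined_input_rejected(self):
        with pytest.raises(ValueError, match="r_normal"):
            classify_change(float("nan"), 0.5, ScreenConfig())
        with pytest.raises(ValueError, match="r_cancer"):
            classify_change(0.5, 1.5, ScreenConfig())

    @pytest.mark.parametrize("sign_tau", [0.0, 0.05, 0.1, 0.25])
    @pytest.mark.parametrize("delta_min", [0.05, 0.1, 0.3])
    def test_exhaustive_grid_matches_oracle(self, sign_tau, delta_min):
        cfg = ScreenConfig(sign_tau, delta_min)
        grid = np.linspace(-1.0, 1.0, 41)
        for rn in grid:
            for rc in grid:
                assert classify_change(rn, rc, cfg) == classify_oracle(
                    rn, rc, sign_tau, delta_min
                )

    def test_vectorized_classifier_agrees_with_scalar(self):
        cfg = ScreenConfig(0.1, 0.1)
        grid = np.linspace(-1.0, 1.0, 41)
        rn, rc = map(np.ravel, np.meshgrid(grid, grid))
        vec = classify_change_array(rn, rc, cfg)
        assert all(
            v == classify_change(a, b, cfg) for v, a, b in zip(vec, rn, rc)
        )

    MIRROR = {
        "pos_more_pos": "neg_more_neg",
        "pos_less_pos": "neg_less_neg",
        "pos_to_neg": "neg_to_pos",
        "neg_more_neg": "pos_more_pos",
        "neg_less_neg": "pos_less_pos",
        "neg_to_pos": "pos_to_neg",
        "null_change": "null_change",
        "undefined": "undefined",
    }

    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
        st.floats(0, 0.5), st.floats(0, 0.5),
    )
    def test_negating_both_correlations_mirrors_the_category(self, rn, rc, tau, dm):
        cfg = ScreenConfig(tau, dm)
        assert classify_change(-rn, -rc, cfg) == self.MIRROR[classify_change(rn, rc, cfg)]


def _pair_records(per_cohort):
    """per_cohort: {cancer_type: [(gene_a, gene_b, category), ...]}"""
    rows = []
    for ct, entries in per_cohort.items():
        for a, b, cat in entries:
            rows.append({"gene_a": a, "gene_b": b, "cancer_type": ct,
                         "r_normal": 0.8, "r_cancer": 0.2, "category": cat})
    return pd.DataFrame(rows)


class TestConsistencyScreen:
    def test_identical_category_across_cohorts_is_a_hit(self):
        records = _pair_records(
            {ct: [("A", "B", "pos_less_pos")] for ct in ("C1", "C2", "C3")}
        )
        hits = screen_consistent_pairs(records)
        assert hits[["gene_a", "gene_b", "category"]].values.tolist() == [
            ["A", "B", "pos_less_pos"]
        ]

    def test_one_null_change_cohort_disqualifies(self):
        records = _pair_records(
            {"C1": [("A", "B", "pos_less_pos")],
             "C2": [("A", "B", "pos_less_pos")],
             "C3": [("A", "B", "null_change")]}
        )
        assert screen_consistent_pairs(records).empty

    def test_require_all_drops_pairs_missing_from_a_cohort(self):
        records = _pair_records(
            {"C1": [("A", "B", "pos_less_pos")], "C2": [("A", "B", "pos_less_pos")]}
        )
        assert screen_consistent_pairs(records, cohorts=["C1", "C2", "C3"]).empty
        kept = screen_consistent_pairs(records, require_all=False,
                                       cohorts=["C1", "C2", "C3"])
        assert len(kept) == 1

    def test_hits_sorted_by_gene_pair(self):
        records = _pair_records(
            {"C1": [("Z", "W", "pos_less_pos"), ("A", "B", "neg_less_neg")]}
        )
        records.loc[records["gene_a"] == "Z", ["gene_a", "gene_b"]] = ["W", "Z"]
        hits = screen_consistent_pairs(records)
        assert hits["gene_a"].tolist() == ["A", "W"]

    def test_hit_set_shrinks_as_delta_min_grows_and_cohorts_are_added(self, rng):
        gene_names = [f"g{i}" for i in range(12)]
        frames = {}
        for ct in ("C1", "C2", "C3"):
            rows = []
            for i in range(0, 12, 2):
                rn, rc = rng.uniform(-1, 1, size=2)
                rows.append({"gene_a": gene_names[i], "gene_b": gene_names[i + 1],
                             "cancer_type": ct, "r_normal": rn, "r_cancer": rc})
            frames[ct] = pd.DataFrame(rows)

        def hits_for(delta_min, cohorts):
            recs = pd.concat([frames[c] for c in cohorts], ignore_index=True)
            recs["category"] = classify_change_array(
                recs["r_normal"], recs["r_cancer"], ScreenConfig(0.1, delta_min)
            )
            out = screen_consistent_pairs(recs, cohorts=list(cohorts))
            return set(map(tuple, out[["gene_a", "gene_b"]].values))

        for cohorts in (("C1", "C2"), ("C1", "C2", "C3")):
            assert hits_for(0.3, cohorts) <= hits_for(0.1, cohorts)
        assert hits_for(0.1, ("C1", "C2", "C3")) <= hits_for(0.1, ("C1", "C2"))

    def test_planted_decoupling_pairs_recovered_across_seeds(self):
        # 5 planted weakening pairs (3 positive, 2 negative) among 60
        # background genes, 12 cohorts, n = 40 normal / 200 cancer per arm
        n_recovered_all, n_fp_total = 0, 0
        for seed in range(10):
            spec = SyntheticSpec(
                n_genes=60, k_cohorts=12, n_normal=40, n_cancer=200,
                planted_pairs=[
                    PlantedPair(0, 1, 0.9, 0.2, "pos_less_pos"),
                    PlantedPair(2, 3, 0.9, 0.2, "pos_less_pos"),
                    PlantedPair(4, 5, 0.9, 0.2, "pos_less_pos"),
                    PlantedPair(6, 7, -0.9, -0.2, "neg_less_neg"),
                    PlantedPair(8, 9, -0.9, -0.2, "neg_less_neg"),
                ],
                seed=seed,
            )
            cohort_pairs, truth = generate_cohorts(spec)
            records = pd.concat(
                [
                    pair_change_table(
                        correlation_matrix(p.normal),
                        correlation_matrix(p.cancer),
                        ScreenConfig(),
                        p.cancer_type,
                    )
                    for p in cohort_pairs
                ],
                ignore_index=True,
            )
            hits = screen_consistent_pairs(records)
            got = set(map(tuple, hits[["gene_a", "gene_b", "category"]].values))
            planted = set(map(tuple,
                              truth.pairs[["gene_a", "gene_b", "category"]].values))
            n_recovered_all += planted <= got
            n_fp_total += len(got - planted)
        assert n_recovered_all >= 9
        assert n_fp_total <= 10  # <= 1 false positive per seed on average

    def test_planted_pairs_are_weaker_in_cancer_arms(self):
        spec = SyntheticSpec(
            n_genes=20, k_cohorts=2, n_normal=80, n_cancer=80,
            planted_pairs=[PlantedPair(0, 1, 0.9, 0.2, "pos_less_pos"),
                           PlantedPair(2, 3, -0.9, -0.2, "neg_less_neg")],
            seed=3,
        )
        cohort_pairs, truth = generate_cohorts(spec)
        for p in cohort_pairs:
            cm_n = correlation_matrix(p.normal)
            cm_c = correlation_matrix(p.cancer)
            for _, row in truth.pairs.iterrows():
                i = p.gene_ids.index(row["gene_a"])
                j = p.gene_ids.index(row["gene_b"])
                assert abs(cm_n.r[i, j]) > abs(cm_c.r[i, j])


class TestFisherZ:
    def test_equal_correlations_are_null(self):
        assert fisher_z_difference(0.5, 10, 0.5, 1000) == (0.0, 1.0)

    def test_matches_closed_form(self):
        z, p = fisher_z_difference(0.8, 50, 0.1, 50)
        expected = (math.atanh(0.8) - math.atanh(0.1)) / math.sqrt(1 / 47 + 1 / 47)
        assert z == pytest.approx(expected, abs=1e-12)
        assert 0 < p < 1e-3

    def test_small_samples_and_degenerate_r_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fisher_z_difference(0.5, 3, 0.5, 10)
        with pytest.raises(ValueError, match="r1"):
            fisher_z_difference(1.0, 10, 0.5, 10)

    def test_null_rejection_rate_is_calibrated(self, rng):
        # bivariate normal, true r = 0.4 in both arms, n = 50, 2000 replicates
        n, reps, r = 50, 2000, 0.4
        rejections = 0
        cov = np.array([[1.0, r], [r, 1.0]])
        for _ in range(reps):
            a = rng.multivariate_normal([0, 0], cov, size=n)
            b = rng.multivariate_normal([0, 0], cov, size=n)
            r1 = np.corrcoef(a.T)[0, 1]
            r2 = np.corrcoef(b.T)[0, 1]
            _, p = fisher_z_difference(r1, n, r2, n)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestDotPlot:
    def test_identity_and_all_negative_toys_render(self, tmp_path):
        from glucoscreen.corr_screen import CorrelationMatrix

        n = 4
        genes = [f"g{i}" for i in range(n)]
        eye = CorrelationMatrix(genes, np.eye(n), 10, np.ones((n, n), bool))
        allneg = CorrelationMatrix(
            genes, 2 * np.eye(n) - 1, 10, np.ones((n, n), bool)
        )
        out = tmp_path / "dots.png"
        render_corr_dotplot(eye, allneg, out)
        assert out.stat().st_size > 0

    def test_ten_gene_fixture_smoke(self, tmp_path, rng):
        values = rng.gamma(2.0, 10.0, size=(10, 20))
        genes = [f"g{i}" for i in range(10)]
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(20)], values)
        cm = correlation_matrix(m)
        out = tmp_path / "ten.png"
        render_corr_dotplot(cm, cm, out)
        assert out.stat().st_size > 0

    def test_gene_set_mismatch_rejected(self, rng):
        from glucoscreen.corr_screen import CorrelationMatrix

        a = CorrelationMatrix(["A"], np.eye(1), 5, np.ones((1, 1), bool))
        b = CorrelationMatrix(["B"], np.eye(1), 5, np.ones((1, 1), bool))
        with pytest.raises(ValueError, match="share genes"):
            render_corr_dotplot(a, b, "unused.png")
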