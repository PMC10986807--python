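"""Regression screen machinery: BH, model fits, screen structure, replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import small_config
from proteoscreen.association import (CONFOUNDERS, bh_adjust, final_hits,
                                      fit_linear, fit_logistic, replicate,
                                      run_screen, technical_correlation)
from proteoscreen.diffexpr import prioritize
from proteoscreen.preprocess import preprocess
from proteoscreen.simulate import generate_cohort


def bh_stepup_oracle(p):
    """Literal step-up definition: q_i = p_(i) * m / i, monotone from top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=100))
    def test_matches_stepup_oracle_and_dominates_input(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_stepup_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestFitLinear:
    def test_perfect_fit_recovers_slope(self):
        x = np.arange(10.0)
        res = fit_linear(x, 2.0 * x)
        assert res.effect == pytest.approx(2.0)
        assert res.p_raw < 1e-12

    def test_matches_normal_equations_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        y = 1.0 + 0.7 * x - 0.3 * z + rng.normal(0, 0.5, 30)
        cov = pd.DataFrame({"z": z})
        res = fit_linear(x, y, covariates=cov)
        design = np.column_stack([np.ones(30), x, z])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert res.effect == pytest.approx(beta[1], rel=1e-10)

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(12.0)
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="dup"):
            fit_linear(x, 2 * x, covariates=cov)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            fit_linear([1.0, 2.0], [1.0, 2.0])


class TestFitLogistic:
    def test_null_association_or_near_one(self):
        rng = np.random.default_rng(7)
        ors = []
        for _ in range(20):
            x = rng.normal(0, 1, 150)
            y = rng.random(150) < 0.4
            ors.append(np.log(fit_logistic(x, y.astype(float)).effect))
        assert abs(np.mean(ors)) < 0.1

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(np.arange(10.0), np.ones(10))

    def test_complete_separation_flagged_not_reported(self):
        x = np.concatenate([np.linspace(-3, -1, 15), np.linspace(1, 3, 15)])
        y = (x > 0).astype(float)
        res = fit_logistic(x, y)
        assert not res.ok
        assert "separation" in res.note or "converge" in res.note

    def test_ci_contains_effect(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(-0.5 + 0.8 * x))))
        res = fit_logistic(x, y.astype(float))
        assert res.ci_low <= res.effect <= res.ci_high
        assert res.effect > 0


class TestTechnicalCorrelation:
    def test_exact_log_relation_gives_r_one(self):
        elisa = np.array([1.0, 2.0, 4.0, 8.0, 32.0])
        r, ci, p = technical_correlation(np.log2(elisa), elisa)
        assert r == pytest.approx(1.0)

    def test_negated_relation_gives_r_minus_one(self):
        elisa = np.array([1.0, 2.0, 4.0, 8.0, 32.0])
        r, _, _ = technical_correlation(-np.log2(elisa), elisa)
        assert r == pytest.approx(-1.0)

    def test_fisher_band_covers_simulated_truth(self):
        rho, n = 0.85, 180
        rng = np.random.default_rng(13)
        cover = 0
        reps = 40
        for _ in range(reps):
            z = rng.normal(0, 1, n)
            x = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
            r, (lo, hi), _ = technical_correlation(x, np.exp2(z * 2 + 4))
            cover += lo <= rho <= hi
        assert cover / reps >= 0.85

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            technical_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])

    def test_non_positive_elisa_rejected(self):
        with pytest.raises(ValueError):
            technical_correlation([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])


class TestScreenStructure:
    @pytest.fixture(scope="class")
    def screened(self, small_study, small_processed):
        dmat, _ = small_processed
        retained, *_ = prioritize(dmat)
        results = run_screen(dmat, small_study.discovery_clinical, retained)
        return retained, results

    def test_empty_retained_list_exits_cleanly(self, small_study,
                                               small_processed):
        dmat, _ = small_processed
        assert run_screen(dmat, small_study.discovery_clinical, []) == []

    def test_lag_validity(self, screened):
        _, results = screened
        valid = {("baseline", "month3"), ("baseline", "month6"),
                 ("month3", "month6")}
        assert {(r.protein_timepoint, r.outcome_timepoint)
                for r in results} <= valid

    def test_adjusted_p_dominates_raw(self, screened):
        _, results = screened
        for r in results:
            if r.ok and np.isfinite(r.p_adj):
                assert r.p_adj >= r.p_raw - 1e-12
                assert 0.0 <= r.p_adj <= 1.0

    def test_stage2_is_subset_of_stage1_survivors(self, screened):
        _, results = screened
        s1 = {(r.protein_id, r.family) for r in results
              if r.stage == "univariate" and r.ok
              and np.isfinite(r.p_adj) and r.p_adj < 0.05}
        s2 = {(r.protein_id, r.family) for r in results
              if r.stage == "multivariable"}
        assert s2 <= s1

    def test_or_reported_positive_with_ci_around_effect(self, screened):
        _, results = screened
        for r in results:
            if r.model == "logistic" and r.ok and np.isfinite(r.effect):
                assert r.effect > 0
                assert r.ci_low <= r.effect <= r.ci_high

    def test_invariant_to_column_and_row_order(self, small_study,
                                               small_processed):
        dmat, _ = small_processed
        retained, *_ = prioritize(dmat)
        retained = retained[:8]
        base = run_screen(dmat, small_study.discovery_clinical, retained)

        rng = np.random.default_rng(3)
        shuffled = dmat.copy()
        cols = list(rng.permutation(shuffled.values.columns))
        rows = list(rng.permutation(shuffled.values.index))
        shuffled.values = shuffled.values.loc[rows, cols]
        shuffled.sample_meta = shuffled.sample_meta.loc[rows]
        other = run_screen(shuffled, small_study.discovery_clinical, retained)

        def key(rs):
            return sorted((r.protein_id, r.outcome, r.protein_timepoint,
                           r.outcome_timepoint, r.stage, round(r.effect, 9),
                           round(r.p_raw, 12))
                          for r in rs if r.ok and np.isfinite(r.effect))

        assert key(base) == key(other)

    def test_unknown_retained_protein_rejected(self, small_study,
                                               small_processed):
        dmat, _ = small_processed
        with pytest.raises(ValueError, match="absent"):
            run_screen(dmat, small_study.discovery_clinical, ["NOPE"])


class TestReplication:
    def test_empty_hits_give_empty_output(self, small_study, small_processed):
        _, vmat = small_processed
        assert replicate([], vmat, small_study.validation_clinical) == []

    def test_absent_protein_flagged_untestable(self, small_study,
                                               small_processed):
        dmat, vmat = small_processed
        retained, *_ = prioritize(dmat)
        results = run_screen(dmat, small_study.discovery_clinical,
                             retained[:10])
        hits = final_hits(results) or [r for r in results
                                       if r.stage == "univariate"][:1]
        vshrunk = vmat.copy()
        vshrunk.values = vshrunk.values.drop(columns=[hits[0].protein_id])
        rows = replicate(hits[:1], vshrunk, small_study.validation_clinical)
        assert not rows[0].ok
        assert "untestable" in rows[0].note

    def test_null_validation_rarely_replicates(self):
        # same discovery truth, but a validation cohort with no planted
        # effects: replication should behave like the false-positive rate
        cfg = small_config(seed=31, n_cases_discovery=120)
        matrix, clinical, truth = generate_cohort(cfg)
        dmat, _ = preprocess(matrix)
        retained, *_ = prioritize(dmat)
        results = run_screen(dmat, clinical, retained)
        hits = final_hits(results)
        null_cfg = small_config(seed=77, n_cases_discovery=120,
                                n_effect_proteins=0)
        nmat, nclin, _ = generate_cohort(null_cfg)
        nmat, _ = preprocess(nmat)
        rows = replicate(hits, nmat, nclin)
        n_rep = sum(1 for r in rows if r.ok and r.note == "replicated")
        assert n_rep <= max(1, int(0.2 * max(len(hits), 1)))
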