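"""Tests of matching variables, model fitters, and the four DIF detectors."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

from ersdif import (
    DetectorConfig,
    ItemParams,
    Persons,
    ResponseDataset,
    compute_matching_variables,
    detect_dif_all,
    detect_dif_item,
    fit_binary_logit,
    fit_cumulative_logit,
    simulate_responses,
)

STUDY_TAU = (-0.6, 0.0, 0.6)


class TestMatchingVariables:
    def test_hand_computations(self):
        data = ResponseDataset(np.array([[2, 2, 2, 2], [0, 3, 0, 3]]), np.array([0, 1]))
        mv = compute_matching_variables(data)
        assert mv.total.tolist() == [8, 6]
        assert mv.score_var[0] == pytest.approx(0.0)
        assert mv.score_var[1] == pytest.approx(3.0)  # mean 1.5, SS 9, 9/3

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        resp = rng.integers(0, 4, size=(50, 10))
        data = ResponseDataset(resp, rng.integers(0, 2, size=50))
        mv = compute_matching_variables(data)
        for n in range(50):
            row = resp[n].astype(float)
            assert mv.total[n] == row.sum()
            mean = row.mean()
            assert mv.score_var[n] == pytest.approx(
                ((row - mean) ** 2).sum() / 9, abs=1e-12
            )

    def test_single_item_rejected(self):
        data = ResponseDataset(np.array([[1], [2]]), np.array([0, 1]))
        with pytest.raises(ValueError):
            compute_matching_variables(data)


def _po_nll(params, y, X, M):
    """Independent proportional-odds negative log-likelihood for the oracle."""
    cuts, gamma = params[: M - 1], params[M - 1 :]
    eta = X @ gamma
    ll = 0.0
    for i in range(len(y)):
        upper = expit(cuts[y[i]] + eta[i]) if y[i] < M - 1 else 1.0
        lower = expit(cuts[y[i] - 1] + eta[i]) if y[i] > 0 else 0.0
        p = upper - lower
        if p <= 0:
            return np.inf
        ll += np.log(p)
    return -ll


class TestCumulativeLogit:
    def test_loglik_matches_bruteforce_optimizer(self):
        rng = np.random.default_rng(5)
        n = 30
        x = rng.normal(size=n)
        y = np.clip(np.round(1 + 0.8 * x + rng.normal(scale=0.8, size=n)), 0, 2).astype(int)
        fit = fit_cumulative_logit(y, {"x": x})
        res = minimize(
            _po_nll,
            x0=np.array([-0.5, 0.5, 0.0]),
            args=(y, x[:, None], 3),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000},
        )
        assert fit.converged
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-4)

    def test_agrees_with_statsmodels(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        g = rng.integers(0, 2, size=n).astype(float)
        cuts = np.array([-1.0, 0.2, 1.1])
        ple = expit(cuts[None, :] + (0.7 * x - 0.3 * g)[:, None])
        y = (rng.random((n, 1)) > ple).sum(axis=1)
        fit = fit_cumulative_logit(y, {"x": x, "g": g})
        sm_fit = OrderedModel(y, np.column_stack([x, g]), distr="logit").fit(
            method="bfgs", disp=0
        )
        assert fit.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-6)
        # shared slopes agree up to the opposite linear-predictor sign
        # convention; statsmodels' BFGS stops at a looser gradient tolerance
        assert fit.coefficients["x"] == pytest.approx(-sm_fit.params[0], abs=1e-4)
        z_mine, _ = fit.wald_p("g")
        z_sm = sm_fit.params[1] / sm_fit.bse[1]
        assert abs(z_mine) == pytest.approx(abs(z_sm), abs=1e-3)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(size=n)
        cuts = np.array([-1.0, 0.0, 1.0])
        ple = expit(cuts[None, :] - (1.0 * x)[:, None])
        y = (rng.random((n, 1)) > ple).sum(axis=1)
        fit = fit_cumulative_logit(y, {"x": x})
        i = fit.names.index("x")
        se = np.sqrt(fit.covariance[i, i])
        assert abs(fit.params[i] - (-1.0)) < 3 * se  # own convention: -slope

    def test_degenerate_design_rejected(self):
        y = np.array([0, 1, 2, 1, 0, 2] * 5)
        with pytest.raises(ValueError):
            fit_cumulative_logit(y, {"z": np.zeros(30)})
        x = np.arange(30.0)
        with pytest.raises(ValueError):
            fit_cumulative_logit(y, {"a": x, "b": 2 * x})

    def test_single_level_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_cumulative_logit(np.ones(20, dtype=int), {"x": np.arange(20.0)})

    def test_unobserved_category_handled(self):
        rng = np.random.default_rng(8)
        y = rng.choice([0, 3], size=60)  # middle categories never observed
        x = rng.normal(size=60)
        fit = fit_cumulative_logit(y, {"x": x})
        assert fit.converged


class TestBinaryLogit:
    def test_log_odds_ratio_closed_form(self):
        # 2x2 table: exposure x group with counts 30/10 and 15/25
        y = np.repeat([1, 1, 0, 0], [30, 10, 15, 25])
        x = np.repeat([1, 0, 1, 0], [30, 10, 15, 25]).astype(float)
        fit = fit_binary_logit(y, {"x": x})
        lor = np.log((30 * 25) / (10 * 15))
        assert fit.coefficients["x"] == pytest.approx(lor, abs=1e-6)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_binary_logit(np.ones(10), {"x": np.arange(10.0)})

    def test_perfect_separation_flagged_not_silent(self):
        y = np.repeat([0, 1], 10)
        x = np.arange(20.0)  # perfectly separates y
        fit = fit_binary_logit(y, {"x": x})
        assert fit.converged is False


def _simulate_two_group(delta_shift=0.0, n=500, seed=0, n_items=5):
    rng = np.random.default_rng(seed)
    from ersdif import sample_item_params, sample_persons, PopulationSpec

    items_ref = sample_item_params(n_items, rng)
    items_foc = [
        ItemParams(it.beta, it.delta + (delta_shift if i == 0 else 0.0), it.tau)
        for i, it in enumerate(items_ref)
    ]
    spec = PopulationSpec(n=n, log_omega_mean=0.0, log_omega_var=0.6)
    persons = Persons.concat(
        sample_persons(spec, rng, group=0), sample_persons(spec, rng, group=1)
    )
    return simulate_responses(
        persons, items_ref, rng, items_by_group={0: items_ref, 1: items_foc}
    )


class TestDetectors:
    @pytest.mark.parametrize("method", ["olr", "ldfa", "olr_m", "ldfa_m"])
    def test_strong_dif_detected_by_every_method(self, method):
        hits = 0
        for rep in range(5):
            data = _simulate_two_group(delta_shift=-1.0, seed=100 + rep)
            r = detect_dif_item(data, 0, DetectorConfig(method=method))
            hits += r.flagged and r.p_value < 1e-3 and r.direction == "favors_focal"
        assert hits == 5

    def test_constant_group_rejected(self, null_dataset):
        data = ResponseDataset(null_dataset.responses, np.zeros(null_dataset.n_persons))
        with pytest.raises(ValueError):
            detect_dif_item(data, 0, DetectorConfig())

    def test_all_items_shapes_and_modified_terms(self, null_dataset):
        res_olr = detect_dif_all(null_dataset, DetectorConfig(method="olr"))
        res_olrm = detect_dif_all(null_dataset, DetectorConfig(method="olr_m"))
        assert len(res_olr) == len(res_olrm) == null_dataset.n_items
        assert [r.item_index for r in res_olr] == list(range(10))
        # modified design genuinely differs: estimates move
        assert any(
            a.estimate != pytest.approx(b.estimate, abs=1e-12)
            for a, b in zip(res_olr, res_olrm)
        )

    def test_item_permutation_equivariance(self, null_dataset):
        perm = np.array([3, 1, 4, 0, 2, 9, 8, 7, 6, 5])
        permuted = ResponseDataset(null_dataset.responses[:, perm], null_dataset.group)
        base = detect_dif_all(null_dataset, DetectorConfig(method="ldfa"))
        shuffled = detect_dif_all(permuted, DetectorConfig(method="ldfa"))
        for new_pos, old_pos in enumerate(perm):
            assert shuffled[new_pos].p_value == pytest.approx(
                base[old_pos].p_value, abs=1e-9
            )

    def test_constant_score_variance_collapses_modified_to_standard(self):
        # every person answers with the same spread: S is constant, so the
        # modified design must coincide with the standard one
        rng = np.random.default_rng(3)
        # rows are permutations of two shift-equivalent patterns: identical
        # per-row variance, but totals (and item responses) still vary
        patterns = [np.array([0, 0, 1, 1, 2]), np.array([1, 1, 2, 2, 3])]
        rows = np.array(
            [rng.permutation(patterns[rng.integers(2)]) for _ in range(200)]
        )
        data = ResponseDataset(rows, rng.integers(0, 2, size=200))
        r_std = detect_dif_item(data, 0, DetectorConfig(method="olr"))
        r_mod = detect_dif_item(data, 0, DetectorConfig(method="olr_m"))
        assert r_mod.p_value == pytest.approx(r_std.p_value, abs=1e-10)

    def test_affine_shift_of_total_leaves_p_unchanged(self, null_dataset):
        from ersdif.dif_detection import _design, _fit, compute_matching_variables

        mv = compute_matching_variables(null_dataset)
        cfg = DetectorConfig(method="olr")
        y, pred, name = _design(null_dataset, 2, cfg, mv)
        fit1 = _fit(y, pred, "olr")
        pred_shifted = dict(pred, X=pred["X"] + 7.0)
        fit2 = _fit(y, pred_shifted, "olr")
        assert fit1.wald_p(name)[1] == pytest.approx(fit2.wald_p(name)[1], abs=1e-6)

    def test_wald_lrt_asymptotic_agreement(self):
        """Wald and LRT p-values for the group term correlate > 0.99 on null data."""
        p_wald, p_lrt = [], []
        for rep in range(120):
            data = _simulate_two_group(delta_shift=0.0, n=150, seed=500 + rep, n_items=4)
            rw = detect_dif_item(data, 0, DetectorConfig(method="olr", test="wald"))
            rl = detect_dif_item(data, 0, DetectorConfig(method="olr", test="lrt"))
            if rw.converged and rl.converged:
                p_wald.append(rw.p_value)
                p_lrt.append(rl.p_value)
        r, _ = stats.pearsonr(p_wald, p_lrt)
        assert r > 0.99

    def test_ldfa_without_matching_reduces_to_log_odds_ratio(self):
        rng = np.random.default_rng(9)
        y_item = rng.integers(0, 2, size=400)  # binary item
        group = (rng.random(400) < expit(0.8 * y_item - 0.4)).astype(int)
        fit = fit_binary_logit(group, {"Y": y_item.astype(float)})
        a, b = np.sum((y_item == 1) & (group == 1)), np.sum((y_item == 1) & (group == 0))
        c, d = np.sum((y_item == 0) & (group == 1)), np.sum((y_item == 0) & (group == 0))
        assert fit.coefficients["Y"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
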