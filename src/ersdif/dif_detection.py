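"""Logistic-regression detectors of uniform DIF in polytomous items.

Four detectors are provided, all flagging an item when its group term is
significant at a nominal level:

``olr``
    Ordinal (cumulative-logit / proportional-odds) regression of the studied
    item's response on the total score X and group G; the group coefficient
    gamma2 carries the uniform-DIF test.
``ldfa``
    Logistic discriminant function analysis: binary logistic regression of
    group membership on X and the studied item response Y; the item-response
    coefficient alpha2 carries the test.
``olr_m`` / ``ldfa_m``
    The modified detectors.  Each adds the per-person variance of item
    scores S and its interaction XS as matching covariates.  S tracks a
    respondent's extreme-response tendency (endpoint-heavy response vectors
    have large score variance), so conditioning on it partials a group
    difference in response style out of the DIF test.

The cumulative-logit fitter is an in-house Newton-Raphson implementation
with analytic gradient and Hessian, written because each Monte-Carlo study
requires tens of thousands of fits; it is cross-checked against
statsmodels' OrderedModel in the test suite.  The binary logit is delegated
to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .ers_gpcm import ResponseDataset

__all__ = [
    "MatchingVariables",
    "DetectorConfig",
    "FittedModel",
    "DIFResult",
    "METHODS",
    "compute_matching_variables",
    "fit_cumulative_logit",
    "fit_binary_logit",
    "detect_dif_item",
    "detect_dif_all",
]

METHODS = ("olr", "ldfa", "olr_m", "ldfa_m")


@dataclass
class MatchingVariables:
    """Per-person matching statistics: total score X and item-score variance S."""

    total: np.ndarray
    score_var: np.ndarray


@dataclass(frozen=True)
class DetectorConfig:
    """Which detector to run and how to call significance."""

    method: str = "olr"
    alpha: float = 0.05
    test: str = "wald"  # or "lrt"
    uniform_only: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("wald", "lrt"):
            raise ValueError("test must be 'wald' or 'lrt'")


@dataclass
class FittedModel:
    """Maximum-likelihood fit of a cumulative or binary logit model."""

    names: list[str]
    params: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.names, self.params))

    def wald_p(self, name: str) -> tuple[float, float]:
        """(z statistic, two-sided p) for H0: coefficient = 0."""
        i = self.names.index(name)
        se = np.sqrt(self.covariance[i, i])
        z = self.params[i] / se
        return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class DIFResult:
    """Outcome of one detector on one item."""

    item_index: int
    method: str
    estimate: float
    statistic: float
    p_value: float
    flagged: bool
    direction: str  # favors_reference | favors_focal | none
    converged: bool


def compute_matching_variables(data: ResponseDataset) -> MatchingVariables:
    """Total score and per-person item-score variance (ddof=1), all items included.

    The studied item is not removed from either statistic: the total score of
    the instrument is the matching variable, and S is the variance of the
    individual's scores across the whole instrument.
    """
    if data.n_items < 2:
        raise ValueError("need at least 2 items to compute a score variance")
    resp = data.responses
    return MatchingVariables(
        total=resp.sum(axis=1),
        score_var=resp.var(axis=1, ddof=1),
    )


# ---------------------------------------------------------------------------
# cumulative-logit (proportional-odds) fitter


def _po_loglik_parts(cuts: np.ndarray, gamma: np.ndarray, X: np.ndarray, y: np.ndarray, M: int):
    """Log-likelihood plus per-observation logistic quantities for Newton steps."""
    xb = X @ gamma
    eta_u = np.where(y < M - 1, cuts[np.minimum(y, M - 2)] + xb, np.inf)
    eta_l = np.where(y > 0, cuts[np.maximum(y - 1, 0)] + xb, -np.inf)
    Fu = expit(eta_u)
    Fl = expit(eta_l)
    p = Fu - Fl
    return xb, Fu, Fl, p


def fit_cumulative_logit(
    outcome: np.ndarray,
    predictors: dict[str, np.ndarray] | None,
    *,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> FittedModel:
    """Fit logit P(Y <= j) = c_j + x'gamma by Newton-Raphson.

    Shared slopes across the M-1 cumulative splits (proportional odds), one
    free cutpoint per split.  Returns cutpoints named ``cut_0..`` followed by
    the named slopes.  Non-convergence is reported via ``converged``; a
    rank-deficient design raises ``ValueError``.
    """
    y = np.asarray(outcome, dtype=int)
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    # relabel to dense 0..M-1 so unobserved categories do not create dead cutpoints
    y = np.searchsorted(levels, y)
    M = levels.size
    names = list(predictors) if predictors else []
    X = (
        np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
        if names
        else np.empty((y.size, 0))
    )
    if X.shape[1]:
        if np.any(X.std(axis=0) == 0):
            raise ValueError("degenerate design: zero-variance predictor")
        if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), X])) < X.shape[1] + 1:
            raise ValueError("degenerate design: collinear predictors")

    n, k = y.size, X.shape[1]
    # start at the empirical marginal cumulative logits, zero slopes
    cum = np.cumsum(np.bincount(y, minlength=M)[:-1]) / n
    cum = np.clip(cum, 1 / (2 * n), 1 - 1 / (2 * n))
    w = np.concatenate([np.log(cum / (1 - cum)), np.zeros(k)])

    iu = np.minimum(y, M - 2)  # cutpoint index of the upper split (invalid for y=M-1)
    il = np.maximum(y - 1, 0)
    has_u = y < M - 1
    has_l = y > 0

    def loglik(w: np.ndarray) -> float:
        _, Fu, Fl, p = _po_loglik_parts(w[: M - 1], w[M - 1 :], X, y, M)
        if np.any(p <= 0):
            return -np.inf
        return float(np.log(p).sum())

    ll = loglik(w)
    converged = False
    for _ in range(max_iter):
        cuts, gamma = w[: M - 1], w[M - 1 :]
        _, Fu, Fl, p = _po_loglik_parts(cuts, gamma, X, y, M)
        fu = np.where(has_u, Fu * (1 - Fu), 0.0)
        fl = np.where(has_l, Fl * (1 - Fl), 0.0)
        gu = fu / p
        gl = -fl / p
        # curvature terms of log p wrt the two linear predictors involved
        dfu = fu * (1 - 2 * np.where(has_u, Fu, 0.0))
        dfl = fl * (1 - 2 * Fl)
        huu = np.where(has_u, dfu / p - gu**2, 0.0)
        hll = np.where(has_l, -dfl / p - gl**2, 0.0)
        hul = np.where(has_u & has_l, fu * fl / p**2, 0.0)

        grad = np.zeros(M - 1 + k)
        np.add.at(grad, iu[has_u], gu[has_u])
        np.add.at(grad, il[has_l], gl[has_l])
        if k:
            grad[M - 1 :] = (gu + gl) @ X

        H = np.zeros((M - 1 + k, M - 1 + k))
        np.add.at(H, (iu[has_u], iu[has_u]), huu[has_u])
        np.add.at(H, (il[has_l], il[has_l]), hll[has_l])
        both = has_u & has_l
        np.add.at(H, (iu[both], il[both]), hul[both])
        np.add.at(H, (il[both], iu[both]), hul[both])
        if k:
            wu = huu + hul
            wl = hll + hul
            cg = np.zeros((M - 1, k))
            np.add.at(cg, iu[has_u], (wu[has_u, None] * X[has_u]))
            np.add.at(cg, il[has_l], (wl[has_l, None] * X[has_l]))
            H[: M - 1, M - 1 :] = cg
            H[M - 1 :, : M - 1] = cg.T
            H[M - 1 :, M - 1 :] = X.T @ ((huu + 2 * hul + hll)[:, None] * X)

        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # damped Newton: halve until the likelihood improves
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            ll_new = loglik(w_new)
            if ll_new > ll - 1e-12:
                break
            t /= 2
        else:
            break
        if abs(ll_new - ll) < 1e-12 and np.max(np.abs(grad)) < 1e-5:
            w, ll = w_new, ll_new
            converged = True
            break
        w, ll = w_new, ll_new

    cuts, gamma = w[: M - 1], w[M - 1 :]
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.full((M - 1 + k, M - 1 + k), np.nan)
        converged = False
    all_names = [f"cut_{j}" for j in range(M - 1)] + names
    return FittedModel(all_names, w.copy(), cov, ll, converged)


def fit_binary_logit(
    outcome: np.ndarray,
    predictors: dict[str, np.ndarray],
    *,
    add_constant: bool = True,
) -> FittedModel:
    """Binary logistic regression via statsmodels; separation reported, not raised."""
    y = np.asarray(outcome, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("degenerate outcome: only one level observed")
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate design: zero-variance predictor")
    if add_constant:
        X = np.column_stack([np.ones(y.size), X])
        names = ["const"] + names
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            ll = float(res.llf)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError, ValueError):
            return FittedModel(names, np.full(len(names), np.nan), np.full((len(names),) * 2, np.nan), np.nan, False)
    if not np.all(np.isfinite(cov)):
        converged = False
    return FittedModel(names, params, cov, ll, converged)


# ---------------------------------------------------------------------------
# detectors


def _design(data: ResponseDataset, item_index: int, config: DetectorConfig, mv: MatchingVariables):
    """Outcome and predictor dict for the requested detector on one item."""
    y_item = data.responses[:, item_index]
    G = data.group.astype(float)
    X = mv.total.astype(float)
    S = mv.score_var
    # A constant S (e.g. every response vector equally dispersed) carries no
    # style information and would make S, XS collinear with the intercept and
    # X; the modified design then collapses to the standard one.
    modified = config.method.endswith("_m") and not np.allclose(S, S[0])
    if config.method.startswith("olr"):
        pred = {"X": X, "G": G}
        if not config.uniform_only:
            pred["XG"] = X * G
        if modified:
            pred["S"] = S
            pred["XS"] = X * S
        return y_item, pred, "G"
    # LDFA family: group membership is the outcome
    pred = {"X": X, "Y": y_item.astype(float)}
    if not config.uniform_only:
        pred["XY"] = X * y_item
    if modified:
        pred["S"] = S
        pred["XS"] = X * S
    return G.astype(int), pred, "Y"


def _fit(outcome, predictors, family: str) -> FittedModel:
    if family == "olr":
        return fit_cumulative_logit(outcome, predictors)
    return fit_binary_logit(outcome, predictors)


def detect_dif_item(
    data: ResponseDataset,
    item_index: int,
    config: DetectorConfig,
    matching: MatchingVariables | None = None,
) -> DIFResult:
    """Test one item for uniform DIF; fit failures yield an unflagged result."""
    if np.unique(data.group).size < 2:
        raise ValueError("both groups must be present")
    if np.unique(data.responses[:, item_index]).size < 2:
        raise ValueError("studied item has fewer than 2 observed categories")
    mv = matching if matching is not None else compute_matching_variables(data)
    outcome, predictors, test_name = _design(data, item_index, config, mv)
    family = "olr" if config.method.startswith("olr") else "ldfa"
    try:
        fit = _fit(outcome, predictors, family)
    except (ValueError, np.linalg.LinAlgError):
        return DIFResult(item_index, config.method, np.nan, np.nan, np.nan, False, "none", False)

    if not fit.converged:
        return DIFResult(item_index, config.method, np.nan, np.nan, np.nan, False, "none", False)

    estimate = fit.coefficients[test_name]
    if config.test == "wald":
        statistic, p = fit.wald_p(test_name)
    else:
        reduced = {k: v for k, v in predictors.items() if k != test_name}
        try:
            fit0 = _fit(outcome, reduced, family)
        except (ValueError, np.linalg.LinAlgError):
            return DIFResult(item_index, config.method, estimate, np.nan, np.nan, False, "none", False)
        if not fit0.converged:
            return DIFResult(item_index, config.method, estimate, np.nan, np.nan, False, "none", False)
        statistic = 2 * (fit.log_likelihood - fit0.log_likelihood)
        statistic = max(statistic, 0.0)
        p = float(stats.chi2.sf(statistic, df=1))

    flagged = bool(p < config.alpha)
    if not flagged:
        direction = "none"
    elif family == "olr":
        # logit P(Y<=j) = c_j + gamma2*G: positive gamma2 pushes the focal
        # group toward low categories, i.e. the item favors the reference group
        direction = "favors_reference" if estimate > 0 else "favors_focal"
    else:
        # positive alpha2: higher item response predicts focal membership at
        # fixed X, i.e. the item favors the focal group
        direction = "favors_focal" if estimate > 0 else "favors_reference"
    return DIFResult(item_index, config.method, float(estimate), float(statistic), p, flagged, direction, True)


def detect_dif_all(data: ResponseDataset, config: DetectorConfig) -> list[DIFResult]:
    """Run one detector over every item, sharing the full-test matching variables."""
    mv = compute_matching_variables(data)
    results = []
    for i in range(data.n_items):
        try:
            results.append(detect_dif_item(data, i, config, matching=mv))
        except ValueError:
            results.append(DIFResult(i, config.method, np.nan, np.nan, np.nan, False, "none", False))
    return results
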