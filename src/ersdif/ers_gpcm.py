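"""Generative model for ordinal responses under the ERS-GPCM.

The ERS-GPCM extends the generalized partial credit model (GPCM) with a
person-specific response-style multiplier ``omega`` acting on the item step
thresholds.  Adjacent-category log-odds are linear in the latent trait::

    log[P(Y = j) / P(Y = j - 1)] = beta * (theta - (delta + omega * tau_j))

A person with small ``omega`` has compressed thresholds and gravitates to the
endpoint categories (extreme response style, ERS); large ``omega`` disperses
the thresholds and favours the middle categories (mild response style, MRS).
With ``omega = 1`` for everyone the model is exactly the GPCM.

This module provides the category-probability kernel, samplers for item and
person populations, the response simulator, and theoretical expected-score
curves (item and test characteristic curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ItemParams",
    "PersonSample",
    "Persons",
    "PopulationSpec",
    "ResponseDataset",
    "gpcm_category_probs",
    "category_prob_matrix",
    "sample_item_params",
    "sample_persons",
    "simulate_responses",
    "expected_item_score",
    "expected_total_score",
]

REFERENCE = 0
FOCAL = 1


@dataclass(frozen=True)
class ItemParams:
    """Parameters of one polytomous item.

    beta
        Positive slope (discrimination) on the logit scale.
    delta
        Mean location of the item (logit scale).
    tau
        Step thresholds, length ``M - 1`` for an ``M``-category item.
        GPCM thresholds need not be ordered; the fixed study value
        ``(-0.6, 0, 0.6)`` happens to be.
    """

    beta: float
    delta: float
    tau: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"slope beta must be positive, got {self.beta}")
        tau = tuple(float(t) for t in self.tau)
        if len(tau) < 1 or not all(np.isfinite(tau)):
            raise ValueError(f"malformed threshold vector {self.tau}")
        object.__setattr__(self, "tau", tau)

    @property
    def n_categories(self) -> int:
        return len(self.tau) + 1


@dataclass(frozen=True)
class PersonSample:
    """Latent parameters of one simulee: trait, ERS multiplier, group label."""

    theta: float
    omega: float
    group: int  # REFERENCE (0) or FOCAL (1)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling distribution of a group of simulees.

    ``theta ~ Normal(theta_mean, theta_var)``;
    ``omega = exp(z)`` with ``z ~ Normal(log_omega_mean, log_omega_var)`` —
    the mean/variance of omega are specified on the log scale, the only scale
    on which a zero mean is coherent for a positive variable.
    """

    n: int
    theta_mean: float = 0.0
    theta_var: float = 1.0
    log_omega_mean: float = 0.0
    log_omega_var: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.theta_var <= 0:
            raise ValueError("theta_var must be > 0")
        if self.log_omega_var < 0:
            raise ValueError("log_omega_var must be >= 0")


@dataclass
class Persons:
    """Vectorized collection of simulees (columnar PersonSample storage)."""

    theta: np.ndarray
    omega: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.group = np.asarray(self.group, dtype=int)
        if not (self.theta.shape == self.omega.shape == self.group.shape):
            raise ValueError("theta, omega, group must have equal length")
        if np.any(self.omega <= 0):
            raise ValueError("all omega must be positive")

    def __len__(self) -> int:
        return self.theta.size

    def __iter__(self) -> Iterator[PersonSample]:
        for t, w, g in zip(self.theta, self.omega, self.group):
            yield PersonSample(float(t), float(w), int(g))

    @classmethod
    def concat(cls, *parts: "Persons") -> "Persons":
        return cls(
            np.concatenate([p.theta for p in parts]),
            np.concatenate([p.omega for p in parts]),
            np.concatenate([p.group for p in parts]),
        )


@dataclass
class ResponseDataset:
    """An N x I integer response matrix plus the binary group vector.

    The unit every DIF detector consumes.  Entries are category codes
    ``0 .. M-1``; ``group`` codes the reference group 0 and focal group 1.
    """

    responses: np.ndarray
    group: np.ndarray
    item_params: Sequence[ItemParams] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if self.group.shape != (self.responses.shape[0],):
            raise ValueError("group length must match number of rows")
        if self.responses.min(initial=0) < 0:
            raise ValueError("negative category codes")
        if not np.isin(self.group, (0, 1)).all():
            raise ValueError("group must be coded 0/1")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_categories(self) -> int:
        if self.item_params:
            return self.item_params[0].n_categories
        return int(self.responses.max()) + 1


def _cumulative_logits(theta: np.ndarray, omega: np.ndarray, item: ItemParams) -> np.ndarray:
    """Unnormalized log-masses sum_{k<=j} beta*(theta - delta - omega*tau_k), j=0..M-1."""
    tau = np.asarray(item.tau)
    # steps[n, j] for j = 1..M-1; the j = 0 cumulative sum is 0 by convention
    steps = item.beta * (theta[:, None] - (item.delta + omega[:, None] * tau[None, :]))
    z = np.concatenate([np.zeros((steps.shape[0], 1)), np.cumsum(steps, axis=1)], axis=1)
    return z


def category_prob_matrix(theta, omega, item: ItemParams) -> np.ndarray:
    """Category probabilities for arrays of persons on one item; shape (N, M)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    z = _cumulative_logits(theta, omega, item)
    z -= z.max(axis=1, keepdims=True)  # guard against overflow
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def gpcm_category_probs(theta: float, omega: float, item: ItemParams) -> np.ndarray:
    """Probability vector of the M response categories for one person-item pair."""
    return category_prob_matrix([theta], [omega], item)[0]


def sample_item_params(
    n_items: int,
    seed: int | np.random.Generator,
    *,
    delta_range: tuple[float, float] = (-2.0, 2.0),
    log_beta_mean: float = 0.0,
    log_beta_sd: float = 0.3,
    tau: tuple[float, ...] = (-0.6, 0.0, 0.6),
) -> list[ItemParams]:
    """Draw item parameters from the study's generating distributions.

    Locations are uniform on (-2, 2), slopes lognormal(0, 0.3^2), and the
    three step thresholds are fixed at (-0.6, 0, 0.6) for every item.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    deltas = rng.uniform(*delta_range, size=n_items)
    betas = np.exp(rng.normal(log_beta_mean, log_beta_sd, size=n_items))
    return [ItemParams(beta=b, delta=d, tau=tau) for b, d in zip(betas, deltas)]


def sample_persons(spec: PopulationSpec, seed: int | np.random.Generator, group: int = REFERENCE) -> Persons:
    """Draw a group of simulees from a population specification."""
    rng = np.random.default_rng(seed)
    theta = rng.normal(spec.theta_mean, np.sqrt(spec.theta_var), size=spec.n)
    if spec.log_omega_var == 0:
        omega = np.full(spec.n, np.exp(spec.log_omega_mean))
    else:
        omega = np.exp(rng.normal(spec.log_omega_mean, np.sqrt(spec.log_omega_var), size=spec.n))
    return Persons(theta, omega, np.full(spec.n, group))


def simulate_responses(
    persons: Persons,
    items: Sequence[ItemParams],
    seed: int | np.random.Generator,
    *,
    items_by_group: dict[int, Sequence[ItemParams]] | None = None,
) -> ResponseDataset:
    """Simulate a response matrix; one categorical draw per person-item cell.

    ``items_by_group`` optionally supplies group-specific parameter lists
    (used to inject DIF); ``items`` then serves as the reference record.
    """
    if len(persons) == 0 or len(items) == 0:
        raise ValueError("persons and items must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(persons)
    resp = np.empty((n, len(items)), dtype=int)
    u = rng.random(size=(n, len(items)))
    for i, item in enumerate(items):
        if items_by_group is None:
            probs = category_prob_matrix(persons.theta, persons.omega, item)
        else:
            probs = np.empty((n, item.n_categories))
            for g, g_items in items_by_group.items():
                mask = persons.group == g
                if mask.any():
                    probs[mask] = category_prob_matrix(
                        persons.theta[mask], persons.omega[mask], g_items[i]
                    )
        cum = np.cumsum(probs, axis=1)
        resp[:, i] = (u[:, [i]] > cum[:, :-1]).sum(axis=1)
    return ResponseDataset(resp, persons.group, item_params=list(items))


def expected_item_score(theta, omega, item: ItemParams) -> float | np.ndarray:
    """Model-expected score E[Y] = sum_j j P(Y=j) on one item; in [0, M-1]."""
    probs = category_prob_matrix(theta, omega, item)
    scores = np.arange(item.n_categories)
    out = probs @ scores
    return float(out[0]) if np.isscalar(theta) or np.ndim(theta) == 0 else out


def expected_total_score(theta, omega, items: Sequence[ItemParams]) -> float | np.ndarray:
    """Test characteristic curve: sum of expected item scores across items."""
    total = sum(expected_item_score(theta, omega, item) for item in items)
    return total
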