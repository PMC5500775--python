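"""Monte-Carlo harness: false/true-positive rates of the DIF detectors.

A study condition fixes the instrument (item parameters), the two group
populations (latent trait standard normal; log response-style multiplier
normal with group-specific mean and common variance 0.6), an optional DIF
injection, and a replication count.  Item parameters are held fixed across
replications; persons are redrawn every replication.  The per-item flag rate
across replications is the false-positive rate for DIF-free items and the
true-positive rate for injected DIF items.

Also here: the average-score-difference (ASD) diagnostic that explains why a
group gap in extreme responding contaminates the total-score matching
variable, and the correlation between a person's item-score dispersion and
their true response-style parameter omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .dif_detection import DetectorConfig, DIFResult, detect_dif_all
from .ers_gpcm import (
    FOCAL,
    REFERENCE,
    ItemParams,
    Persons,
    PopulationSpec,
    sample_item_params,
    sample_persons,
    simulate_responses,
    expected_item_score,
)
from .fixtures import benchmark_items

__all__ = [
    "ERS_CONDITIONS",
    "StudyCondition",
    "DIFSpec",
    "RateTable",
    "inject_dif",
    "run_replication",
    "run_study",
    "ers_indicator_correlation",
    "compute_asd",
]

# group means of log(omega): (reference, focal). The gap of 0, 0.4, 0.6 encodes
# no, moderate and large group differences in extreme response style.
ERS_CONDITIONS = {
    "I": (0.0, 0.0),
    "II": (0.2, -0.2),
    "III": (0.3, -0.3),
}

LOG_OMEGA_VAR = 0.6


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the simulation design."""

    n_items: int = 10
    ers_condition: str = "I"
    n_per_group: int = 500
    n_categories: int = 4
    dif_fraction: float = 0.0
    dif_pattern: str = "none"  # none | balanced | unbalanced
    dif_size: float = 0.2
    n_replications: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ers_condition not in ERS_CONDITIONS:
            raise ValueError(f"unknown ERS condition {self.ers_condition!r}")
        n_dif = self.dif_fraction * self.n_items
        if abs(n_dif - round(n_dif)) > 1e-9:
            raise ValueError("dif_fraction * n_items must be an integer")
        if self.dif_pattern == "balanced" and round(n_dif) % 2:
            raise ValueError("balanced DIF needs an even number of DIF items")
        if self.dif_pattern == "none" and self.dif_fraction:
            raise ValueError("dif_fraction > 0 requires a DIF pattern")

    @property
    def n_dif_items(self) -> int:
        return int(round(self.dif_fraction * self.n_items))

    def population(self, group: int) -> PopulationSpec:
        mu_ref, mu_focal = ERS_CONDITIONS[self.ers_condition]
        return PopulationSpec(
            n=self.n_per_group,
            log_omega_mean=mu_ref if group == REFERENCE else mu_focal,
            log_omega_var=LOG_OMEGA_VAR,
        )


@dataclass(frozen=True)
class DIFSpec:
    """Record of one injected DIF item: where the focal location moved."""

    item_index: int
    delta_shift_focal: float
    favored_group: str  # "focal" | "reference"


@dataclass
class RateTable:
    """Per-item flag rates over replications for one detector in one condition."""

    method: str
    condition: StudyCondition
    per_item_rates: np.ndarray
    dif_items: list[DIFSpec] = field(default_factory=list)
    n_failed_fits: int = 0

    @property
    def _dif_mask(self) -> np.ndarray:
        mask = np.zeros(self.condition.n_items, dtype=bool)
        mask[[d.item_index for d in self.dif_items]] = True
        return mask

    @property
    def average_fp(self) -> float:
        """Mean flag rate over DIF-free items."""
        return float(self.per_item_rates[~self._dif_mask].mean())

    @property
    def average_tp(self) -> float | None:
        """Mean flag rate over injected DIF items (None in null conditions)."""
        if not self.dif_items:
            return None
        return float(self.per_item_rates[self._dif_mask].mean())

    @property
    def per_mille(self) -> np.ndarray:
        return self.per_item_rates * 1000


def inject_dif(
    items: Sequence[ItemParams],
    pattern: str,
    fraction: float,
    size: float,
    item_indices: Sequence[int] | None = None,
) -> tuple[list[ItemParams], list[ItemParams], list[DIFSpec]]:
    """Create group-specific item lists with uniform DIF on a subset of items.

    An item "favors" a group when that group's location delta is lowered by
    ``size`` logits, raising its expected score at fixed theta.  Balanced:
    half the DIF items favor each group; unbalanced: all favor the focal
    group.  By default the first ``fraction * len(items)`` items carry DIF.
    """
    if pattern not in ("balanced", "unbalanced"):
        raise ValueError(f"unknown DIF pattern {pattern!r}")
    n_dif = fraction * len(items)
    if abs(n_dif - round(n_dif)) > 1e-9 or round(n_dif) < 1:
        raise ValueError("fraction * n_items must be a positive integer")
    n_dif = int(round(n_dif))
    if pattern == "balanced" and n_dif % 2:
        raise ValueError("balanced DIF needs an even number of DIF items")
    idx = list(item_indices) if item_indices is not None else list(range(n_dif))
    if len(idx) != n_dif:
        raise ValueError("item_indices length must equal the DIF item count")

    items_ref = list(items)
    items_focal = list(items)
    specs = []
    for k, i in enumerate(idx):
        favors_focal = pattern == "unbalanced" or k < n_dif // 2
        shift = -size if favors_focal else size
        items_focal[i] = replace(items[i], delta=items[i].delta + shift)
        specs.append(DIFSpec(i, shift, "focal" if favors_focal else "reference"))
    return items_ref, items_focal, specs


def _draw_groups(condition: StudyCondition, rng: np.random.Generator) -> Persons:
    ref = sample_persons(condition.population(REFERENCE), rng, group=REFERENCE)
    foc = sample_persons(condition.population(FOCAL), rng, group=FOCAL)
    return Persons.concat(ref, foc)


def run_replication(
    condition: StudyCondition,
    items_ref: Sequence[ItemParams],
    items_focal: Sequence[ItemParams],
    rep_seed: int | np.random.SeedSequence,
    methods: Sequence[DetectorConfig],
) -> dict[str, list[DIFResult]]:
    """One replication: fresh persons, fresh responses, all detectors, all items."""
    rng = np.random.default_rng(rep_seed)
    persons = _draw_groups(condition, rng)
    data = simulate_responses(
        persons,
        items_ref,
        rng,
        items_by_group={REFERENCE: list(items_ref), FOCAL: list(items_focal)},
    )
    return {cfg.method: detect_dif_all(data, cfg) for cfg in methods}


def run_study(
    condition: StudyCondition,
    methods: Sequence[DetectorConfig],
    items: Sequence[ItemParams] | None = None,
) -> dict[str, RateTable]:
    """Replicate a condition and tabulate per-item flag rates for each detector.

    Items default to the frozen 10/20-item benchmark set.  Replication seeds
    are spawned from the condition's master seed, so the full table is
    deterministic.
    """
    if items is None:
        items = benchmark_items(condition.n_items)
    if len(items) != condition.n_items:
        raise ValueError("item list length must match condition.n_items")

    if condition.dif_pattern == "none":
        items_ref, items_focal, specs = list(items), list(items), []
    else:
        items_ref, items_focal, specs = inject_dif(
            items, condition.dif_pattern, condition.dif_fraction, condition.dif_size
        )

    flags = {cfg.method: np.zeros(condition.n_items) for cfg in methods}
    failures = {cfg.method: 0 for cfg in methods}
    seeds = np.random.SeedSequence(condition.seed).spawn(condition.n_replications)
    for rep_seed in seeds:
        results = run_replication(condition, items_ref, items_focal, rep_seed, methods)
        for method, res_list in results.items():
            for r in res_list:
                flags[method][r.item_index] += r.flagged
                failures[method] += not r.converged

    return {
        m: RateTable(
            method=m,
            condition=condition,
            per_item_rates=flags[m] / condition.n_replications,
            dif_items=specs,
            n_failed_fits=failures[m],
        )
        for m in flags
    }


def ers_indicator_correlation(
    indicator: str = "variance",
    n: int = 100_000,
    seed: int = 0,
    items: Sequence[ItemParams] | None = None,
    ers_condition: str = "III",
    log_omega_var: float = LOG_OMEGA_VAR,
) -> float:
    """Pearson correlation between a person's item-score dispersion and omega.

    Simulates a pooled two-group population (default: large ERS difference,
    20-item benchmark) and correlates the per-person variance (or SD) of item
    scores with the true response-style multiplier.  Mild responders (large
    omega) cluster in the middle categories, so the correlation is negative;
    its magnitude gauges how well the dispersion statistic proxies omega.
    """
    if indicator not in ("variance", "sd"):
        raise ValueError("indicator must be 'variance' or 'sd'")
    if n < 2:
        raise ValueError("need n >= 2")
    if items is None:
        items = benchmark_items(20)
    mu_ref, mu_focal = ERS_CONDITIONS[ers_condition]
    rng = np.random.default_rng(seed)
    half = n // 2
    ref = sample_persons(PopulationSpec(n=half, log_omega_mean=mu_ref, log_omega_var=log_omega_var), rng, REFERENCE)
    foc = sample_persons(PopulationSpec(n=n - half, log_omega_mean=mu_focal, log_omega_var=log_omega_var), rng, FOCAL)
    persons = Persons.concat(ref, foc)
    data = simulate_responses(persons, items, rng)
    disp = data.responses.var(axis=1, ddof=1)
    if indicator == "sd":
        disp = np.sqrt(disp)
    if np.std(disp) == 0 or np.std(persons.omega) == 0:
        raise ValueError("correlation undefined: zero-variance input")
    r, _ = stats.pearsonr(disp, persons.omega)
    return float(r)


def compute_asd(
    items_reference: Sequence[ItemParams],
    items_focal: Sequence[ItemParams],
    pop_reference: PopulationSpec,
    pop_focal: PopulationSpec,
    n_sim: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-item |mean expected score (focal) - mean expected score (reference)|.

    Monte-Carlo over ``n_sim`` simulees per group: each simulee's
    model-expected item score is computed from their (theta, omega) and the
    group means are differenced.  A non-zero ASD on a DIF-free item signals
    that the total score is contaminated as a matching variable.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    ref = sample_persons(replace(pop_reference, n=n_sim), rng, REFERENCE)
    foc = sample_persons(replace(pop_focal, n=n_sim), rng, FOCAL)
    out = np.empty(len(items_reference))
    for i, (it_r, it_f) in enumerate(zip(items_reference, items_focal)):
        m_ref = expected_item_score(ref.theta, ref.omega, it_r).mean()
        m_foc = expected_item_score(foc.theta, foc.omega, it_f).mean()
        out[i] = abs(m_foc - m_ref)
    return out
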