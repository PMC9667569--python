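"""Next-state prediction from a fitted factor model.

The probability that a subject with sparse history ``x`` shows state ``s``
at a future bin marginalizes the latent profile over the empirical
distribution of fitted training profiles: each training row ``n``
contributes the kernel likelihood of the target state at the target bin
times the kernel likelihood of every prior observation in ``x`` under that
row's (shift-adjusted) latent profile.  The sums are accumulated in the
log domain — with thousands of rows and long histories the literal product
of kernel terms underflows.

Classification applies a threshold cascade: cancer, high-risk and low-risk
are tested in order of severity against per-state probability thresholds
(counteracting the extreme class imbalance of screening data), with normal
as the fallback.  Thresholds are fitted by differential evolution to
minimize the area between per-state Kaplan-Meier curves of true and
predicted labels.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import differential_evolution
from scipy.special import logsumexp

from .data import STATES, StateMatrix, TimeGrid
from .evaluation import _km_on_grid
from .factorization import FactorModel


@dataclass(frozen=True)
class StateProbabilities:
    """Normalized four-state distribution at a target time bin."""

    subject: object
    target_bin: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("probs must be a 4-vector over states 1-4")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be a normalized distribution")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-state probability thresholds τ₂, τ₃, τ₄, each in the open (0, 1)."""

    tau2: float
    tau3: float
    tau4: float

    def __post_init__(self) -> None:
        for name, tau in (("tau2", self.tau2), ("tau3", self.tau3), ("tau4", self.tau4)):
            if not 0.0 < tau < 1.0:
                raise ValueError(f"{name}={tau} must lie strictly inside (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.tau2, self.tau3, self.tau4])


@dataclass(frozen=True)
class EvalCase:
    """One prediction target: prior history, target bin, and true state.

    The history contains only observations at least one forecast horizon
    before the target (the moving exclusion window); at least two priors
    are required for a case to exist.
    """

    subject: object
    history: tuple
    target_bin: int
    true_state: int
    horizon_bins: int


def state_log_kernel(latent, theta: float) -> np.ndarray:
    """Log of the normalized four-state kernel ``log p(s | m)``.

    The normalizer is the four-state sum ``C_m = 1/Σ_s' exp(-θ(s'-m)²)``.
    Output shape is ``latent.shape + (4,)``.
    """
    latent = np.asarray(latent, dtype=float)
    logits = -theta * (np.arange(1, 5, dtype=float) - latent[..., None]) ** 2
    return logits - logsumexp(logits, axis=-1, keepdims=True)


def predict_probabilities(
    model: FactorModel, history, target_bin: int, subject=None
) -> StateProbabilities:
    """Next-state distribution at ``target_bin`` given prior observations.

    ``history`` is a sequence of ``(bin, state)`` pairs.  Accumulation over
    training rows runs in the log domain with a max-subtracting logsumexp.
    """
    latent = model.latent()
    n, t = latent.shape
    if latent.size == 0:
        raise ValueError("model has no training rows")
    if not 0 <= target_bin < t:
        raise ValueError(f"target_bin {target_bin} outside [0, {t})")
    history = list(history)
    if history:
        bins = np.array([int(b) for b, _ in history])
        states = np.array([int(s) for _, s in history])
        if bins.min() < 0 or bins.max() >= t:
            raise ValueError("history bin outside the model grid")
        if np.any((states < 1) | (states > 4)):
            raise ValueError("history states must lie in {1, 2, 3, 4}")
    return _predict_from_latent(latent, model.theta, history, target_bin, subject)


def predict_case_probabilities(
    model: FactorModel, cases: list["EvalCase"]
) -> list[StateProbabilities]:
    """Eq-style next-state probabilities for a batch of evaluation cases.

    Shares one latent-matrix evaluation across cases; equivalent to calling
    :func:`predict_probabilities` per case.
    """
    latent = model.latent()
    theta = model.theta
    out = []
    for case in cases:
        out.append(
            _predict_from_latent(
                latent, theta, case.history, case.target_bin, case.subject
            )
        )
    return out


def _predict_from_latent(latent, theta, history, target_bin, subject):
    n, t = latent.shape
    history = list(history)
    log_weight = np.zeros(n)
    if history:
        bins = np.array([int(b) for b, _ in history])
        states = np.array([int(s) for _, s in history])
        logk = state_log_kernel(latent[:, bins], theta)
        log_weight = logk[:, np.arange(bins.size), states - 1].sum(axis=1)
    log_target = state_log_kernel(latent[:, target_bin], theta)
    log_p = logsumexp(log_weight[:, None] + log_target, axis=0)
    log_p -= logsumexp(log_p)
    return StateProbabilities(subject, target_bin, np.exp(log_p))


def classify(p: StateProbabilities, tau: ThresholdSet) -> int:
    """Threshold cascade: first of states 4, 3, 2 whose probability clears
    its threshold; otherwise normal (state 1)."""
    probs = p.probs
    for s, t in ((4, tau.tau4), (3, tau.tau3), (2, tau.tau2)):
        if probs[s - 1] >= t:
            return s
    return 1


def _classify_matrix(probs: np.ndarray, tau_arr: np.ndarray) -> np.ndarray:
    """Vectorized cascade on an (n, 4) probability matrix."""
    return np.where(
        probs[:, 3] >= tau_arr[2],
        4,
        np.where(probs[:, 2] >= tau_arr[1], 3, np.where(probs[:, 1] >= tau_arr[0], 2, 1)),
    )


def build_eval_cases(test: StateMatrix, horizon_bins: int) -> list[EvalCase]:
    """Emit prediction cases with a moving exclusion window.

    For every observed bin ``t`` of every subject, a case is emitted iff at
    least two observations strictly precede ``t − horizon``; observations
    inside the window ``(t − horizon, t)`` are withheld from the history.
    """
    if horizon_bins < 1:
        raise ValueError("horizon must be at least one bin")
    cases = []
    for row, subject in enumerate(test.subjects):
        bins = np.flatnonzero(test.mask[row])
        states = test.values[row, bins]
        for j, t in enumerate(bins):
            cutoff = t - horizon_bins
            prior = bins[:j]
            if np.count_nonzero(prior < cutoff) < 2:
                continue
            keep = prior <= cutoff
            history = tuple(
                (int(b), int(s)) for b, s in zip(prior[keep], states[:j][keep])
            )
            cases.append(
                EvalCase(
                    subject=subject,
                    history=history,
                    target_bin=int(t),
                    true_state=int(states[j]),
                    horizon_bins=horizon_bins,
                )
            )
    return cases


def _first_event_arrays(group_ids, n_groups, bins, labels, state, last_bin):
    """Per-group first-event (time, event) arrays for one state."""
    ev = np.full(n_groups, np.inf)
    np.minimum.at(ev, group_ids, np.where(labels == state, bins, np.inf))
    event = np.isfinite(ev)
    time = np.where(event, ev, last_bin)
    return time, event.astype(float)


def threshold_objective(
    probs: np.ndarray,
    group_ids: np.ndarray,
    n_groups: int,
    bins: np.ndarray,
    true_labels: np.ndarray,
    grid_times: np.ndarray,
    states=STATES,
):
    """Factory for the Eq-style curve-matching objective over τ.

    Returns a callable mapping τ=(τ₂,τ₃,τ₄) to Σ_s ∫ |S_s(t) − Ŝ_s(t)| dt
    where the survival curves are per-state first-encounter Kaplan-Meier
    estimates of true versus cascade-classified labels.
    """
    last_bin = np.full(n_groups, -np.inf)
    np.maximum.at(last_bin, group_ids, bins)
    truth_curves = {}
    present = []
    for s in states:
        time, event = _first_event_arrays(
            group_ids, n_groups, bins, true_labels, s, last_bin
        )
        if event.sum() == 0:
            continue
        present.append(s)
        truth_curves[s] = _km_on_grid(time, event, grid_times)
    if not present:
        raise ValueError("no events of any state in the evaluation cases")
    missing = [s for s in states if s not in truth_curves]
    if missing:
        warnings.warn(f"states {missing} have no cases and are skipped")

    def objective(tau_arr: np.ndarray) -> float:
        pred = _classify_matrix(probs, np.asarray(tau_arr, dtype=float))
        total = 0.0
        for s in present:
            time, event = _first_event_arrays(
                group_ids, n_groups, bins, pred, s, last_bin
            )
            s_pred = _km_on_grid(time, event, grid_times)
            total += np.trapezoid(np.abs(truth_curves[s] - s_pred), grid_times)
        return total

    return objective


def fit_thresholds(
    cases: list[EvalCase],
    probabilities,
    grid: TimeGrid,
    seed: int = 0,
    maxiter: int = 200,
    popsize: int = 15,
) -> ThresholdSet:
    """Fit the threshold cascade by differential evolution over (0, 1)³.

    ``probabilities`` matches ``cases`` elementwise (StateProbabilities or
    raw 4-vectors).  The objective integrates, per state, the absolute gap
    between Kaplan-Meier curves from true and predicted labels (trapezoid
    on the bin grid); the search is seeded and uses population 15 with up
    to 200 generations.
    """
    if len(cases) == 0:
        raise ValueError("no evaluation cases")
    if len(probabilities) != len(cases):
        raise ValueError("need one probability vector per case")
    probs = np.vstack(
        [p.probs if isinstance(p, StateProbabilities) else np.asarray(p, float)
         for p in probabilities]
    )
    seen: dict = {}
    group_ids = np.array(
        [seen.setdefault(c.subject, len(seen)) for c in cases], dtype=np.int64
    )
    n_groups = len(seen)
    bins = np.array([c.target_bin for c in cases], dtype=float)
    true_labels = np.array([c.true_state for c in cases])
    grid_times = np.arange(grid.n_bins, dtype=float)
    objective = threshold_objective(
        probs, group_ids, n_groups, bins, true_labels, grid_times
    )
    eps = 1e-6
    result = differential_evolution(
        objective,
        bounds=[(eps, 1.0 - eps)] * 3,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        polish=False,  # objective is piecewise constant in tau
        init="sobol",
        tol=1e-8,
    )
    tau = np.clip(result.x, eps, 1.0 - eps)
    return ThresholdSet(tau2=float(tau[0]), tau3=float(tau[1]), tau4=float(tau[2]))
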