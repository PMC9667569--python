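"""Kaplan-Meier estimation and probability-of-agreement evaluation.

Model performance is judged at the cohort level: for each state ``s`` we
compare the Kaplan-Meier curve of time to *first* encounter of ``s`` in
the true labels against the same curve built from predicted labels.  The
probability of agreement (PoA)

    φ_s(t) = P(|S_s(t) − Ŝ_s(t)| ≤ δ_s(t))

uses an equivalence margin δ_s(t) = 2·σ̂(S_s(t)) estimated from bootstrap
resamples of the reference curve; Φ_s is the normalized area under φ_s
over the study window, with 1 indicating perfect agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def first_event_times(sequences, state: int) -> np.ndarray:
    """Per-subject (time, event) pairs for first encounter of ``state``.

    ``sequences`` is an iterable of per-subject label sequences, each a
    sequence of ``(time_bin, state)`` pairs on the common grid.  Subjects
    never showing the state are censored at their last labelled bin;
    repeat encounters after the first are ignored.
    """
    pairs = []
    for seq in sequences:
        if len(seq) == 0:
            continue
        seq = sorted(seq)
        hit = [t for t, s in seq if s == state]
        if hit:
            pairs.append((hit[0], 1.0))
        else:
            pairs.append((seq[-1][0], 0.0))
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated on a common grid.

    ``survival`` is the right-continuous step function carried forward
    between event times; ``at_risk`` and ``events`` give the risk-set size
    and event count at each distinct event/censoring time (``step_times``).
    """

    times: np.ndarray
    survival: np.ndarray
    step_times: np.ndarray
    step_survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t) -> np.ndarray:
        """Evaluate the step function at arbitrary times (S=1 before data)."""
        return _step_eval(self.step_times, self.step_survival, np.asarray(t, float))


def _step_eval(step_times, step_survival, t):
    idx = np.searchsorted(step_times, t, side="right") - 1
    out = np.where(idx >= 0, step_survival[np.clip(idx, 0, None)], 1.0)
    return out if out.ndim else float(out)


def _km_steps(times, events):
    """Unique times with at-risk counts, event counts, and survival values.

    Subjects censored at an event time stay at risk through that time
    (events precede censorings at ties, the standard convention).
    """
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, start)
    n_at_risk = times.size - start
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    return uniq, n_at_risk.astype(float), d, surv


def km_estimate(pairs, grid_times=None) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator from (time, event) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("cannot estimate a survival curve from no subjects")
    times = pairs[:, 0]
    events = pairs[:, 1]
    uniq, n_at_risk, d, surv = _km_steps(times, events)
    if grid_times is None:
        grid_times = uniq
    grid_times = np.asarray(grid_times, dtype=float)
    return SurvivalCurve(
        times=grid_times,
        survival=_step_eval(uniq, surv, grid_times),
        step_times=uniq,
        step_survival=surv,
        at_risk=n_at_risk,
        events=d,
    )


def _km_on_grid(times, events, grid_times):
    uniq, _, _, surv = _km_steps(times, events)
    return _step_eval(uniq, surv, grid_times)


def margin(
    pairs,
    grid_times,
    B: int = 1000,
    width_factor: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Equivalence margin δ(t): ``width_factor`` x bootstrap sd of the KM curve.

    Subjects are resampled with replacement ``B`` times (default 1000) and
    the product-limit curve recomputed on the grid each time.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    pairs = np.asarray(pairs, dtype=float)
    grid_times = np.asarray(grid_times, dtype=float)
    rng = np.random.default_rng(seed)
    n = pairs.shape[0]
    curves = np.empty((B, grid_times.size))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        curves[b] = _km_on_grid(pairs[idx, 0], pairs[idx, 1], grid_times)
    return width_factor * curves.std(axis=0, ddof=1)


def poa_curve(
    truth_pairs,
    prediction_pairs,
    delta,
    grid_times,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Pointwise probability of agreement between two survival curves.

    The probability law is a paired bootstrap over subjects: truth and
    prediction label the *same* cohort, so one resample of subject indices
    is applied to both label sets per replicate, and φ(t) is the fraction
    of replicates with ``|S*(t) − Ŝ*(t)| ≤ δ(t)``.
    """
    truth_pairs = np.asarray(truth_pairs, dtype=float)
    prediction_pairs = np.asarray(prediction_pairs, dtype=float)
    if truth_pairs.shape != prediction_pairs.shape:
        raise ValueError(
            "paired agreement requires one prediction pair per truth pair"
        )
    grid_times = np.asarray(grid_times, dtype=float)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), grid_times.shape)
    rng = np.random.default_rng(seed)
    n = truth_pairs.shape[0]
    agree = np.empty((B, grid_times.size), dtype=bool)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        s_true = _km_on_grid(truth_pairs[idx, 0], truth_pairs[idx, 1], grid_times)
        s_pred = _km_on_grid(
            prediction_pairs[idx, 0], prediction_pairs[idx, 1], grid_times
        )
        agree[b] = np.abs(s_true - s_pred) <= delta
    return agree.mean(axis=0)


def poa_score(phi, times) -> float:
    """Normalized area under the PoA curve: trapezoid of φ over [t₀, T]."""
    phi = np.asarray(phi, dtype=float)
    times = np.asarray(times, dtype=float)
    span = times[-1] - times[0]
    if span <= 0:
        raise ValueError("study window must have positive length")
    return float(np.trapezoid(phi, times) / span)


@dataclass
class AgreementResult:
    """PoA curve, margin, scalar score and its percentile-bootstrap CI."""

    phi: np.ndarray
    delta: np.ndarray
    score: float
    times: np.ndarray
    B: int
    ci_low: float = np.nan
    ci_high: float = np.nan


def probability_of_agreement(
    truth_pairs,
    prediction_pairs,
    grid_times,
    B: int = 1000,
    width_factor: float = 2.0,
    seed: int = 0,
    ci_level: float = 0.95,
    ci_reps: int = 200,
) -> AgreementResult:
    """Full agreement pipeline: margin, PoA curve, normalized area, and CI.

    The CI on Φ is a percentile bootstrap over the B paired replicates'
    agreement indicators (resampling replicate curves, ``ci_reps`` times).
    """
    grid_times = np.asarray(grid_times, dtype=float)
    rng = np.random.default_rng(seed)
    delta = margin(
        truth_pairs,
        grid_times,
        B=B,
        width_factor=width_factor,
        seed=int(rng.integers(2**31)),
    )
    truth_pairs = np.asarray(truth_pairs, dtype=float)
    prediction_pairs = np.asarray(prediction_pairs, dtype=float)
    if truth_pairs.shape != prediction_pairs.shape:
        raise ValueError(
            "paired agreement requires one prediction pair per truth pair"
        )
    n = truth_pairs.shape[0]
    agree = np.empty((B, grid_times.size), dtype=bool)
    poa_seed = int(rng.integers(2**31))
    poa_rng = np.random.default_rng(poa_seed)
    for b in range(B):
        idx = poa_rng.integers(0, n, size=n)
        s_true = _km_on_grid(truth_pairs[idx, 0], truth_pairs[idx, 1], grid_times)
        s_pred = _km_on_grid(
            prediction_pairs[idx, 0], prediction_pairs[idx, 1], grid_times
        )
        agree[b] = np.abs(s_true - s_pred) <= delta
    phi = agree.mean(axis=0)
    score = poa_score(phi, grid_times)
    scores = np.empty(ci_reps)
    for i in range(ci_reps):
        idx = rng.integers(0, B, size=B)
        scores[i] = poa_score(agree[idx].mean(axis=0), grid_times)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(scores, [alpha, 1.0 - alpha])
    return AgreementResult(
        phi=phi,
        delta=delta,
        score=score,
        times=grid_times,
        B=B,
        ci_low=float(lo),
        ci_high=float(hi),
    )
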