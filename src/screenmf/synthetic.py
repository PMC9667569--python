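"""Synthetic screening-history generator.

Emulates the three statistical signatures of registry screening data:

* **scarcity** — only a small fraction (~8%) of the state matrix is observed;
* **irregularity** — observation timing depends on the last observed state
  (long routine intervals after a normal result, rapid follow-up after an
  abnormal one);
* **imbalance** — the overwhelming majority of observed results are normal.

Ground-truth latent profiles are linear combinations of ``K`` smooth basic
profiles ``V[t, k] = exp(-1e-3 (t - mu_k)^2)`` with non-negative subject
coefficients ``U[n, k] ~ Exp(1)``.  Latent values are mapped to discrete
states 1-4 by sampling the Gaussian-kernel observation model with
reliability ``theta``, and entries are then thinned by a state-dependent
observation process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data import StateMatrix, TimeGrid

#: key used in observation tables before any state has been observed
BEFORE_FIRST = "none"

#: per-bin observation probabilities conditioned on the most recent observed
#: state; calibrated to a realized density near 0.08 with triennial-like gaps
#: after a normal result and rapid follow-up after abnormal ones.
DEFAULT_OBSERVATION_TABLE = {
    BEFORE_FIRST: 0.05,
    1: 0.05,
    2: 0.20,
    3: 0.30,
    4: 0.05,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    ``theta`` is the reliability of the discrete observation kernel
    (default 2.5); ``profile_centers`` default to even spacing across the
    grid.  With ``rescale_latent`` the latent matrix is affinely mapped
    onto [1, 4] so that it lives on the state scale before discretization.
    ``discretize`` is ``"sample"`` (draw from the kernel distribution) or
    ``"argmax"`` (most probable state).
    """

    n_subjects: int = 2000
    n_bins: int = 176
    n_profiles: int = 5
    profile_centers: tuple | None = None
    theta: float = 2.5
    rescale_latent: bool = True
    observation_table: dict = field(
        default_factory=lambda: dict(DEFAULT_OBSERVATION_TABLE)
    )
    target_density: float | None = None
    discretize: str = "sample"
    seed: int = 0
    origin_age: float = 25.0

    def __post_init__(self) -> None:
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        for key, p in self.observation_table.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"observation probability for {key!r} not in [0, 1]")
        if self.discretize not in ("sample", "argmax"):
            raise ValueError("discretize must be 'sample' or 'argmax'")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.n_bins, origin_age=self.origin_age)

    def centers(self) -> np.ndarray:
        if self.profile_centers is not None:
            mu = np.asarray(self.profile_centers, dtype=float)
        else:
            # evenly spaced, away from the grid edges
            mu = (np.arange(self.n_profiles) + 0.5) * self.n_bins / self.n_profiles
        if mu.size != self.n_profiles:
            raise ValueError("profile_centers length must equal n_profiles")
        if np.any(mu < 0) or np.any(mu >= self.n_bins):
            raise ValueError("profile centers must lie within [0, n_bins)")
        return mu


@dataclass
class SyntheticDataset:
    """Ground truth plus the observed, thinned state matrix."""

    latent: np.ndarray
    full_states: np.ndarray
    observed: StateMatrix
    config: SyntheticConfig


def make_basic_profiles(grid: TimeGrid, centers) -> np.ndarray:
    """Smooth Gaussian-bump profiles ``V[t, k] = exp(-1e-3 (t - mu_k)^2)``."""
    mu = np.asarray(centers, dtype=float)
    if np.any(mu < 0) or np.any(mu >= grid.n_bins):
        raise ValueError("profile centers must lie within [0, n_bins)")
    t = np.arange(grid.n_bins, dtype=float)[:, None]
    return np.exp(-1e-3 * (t - mu[None, :]) ** 2)


def sample_coefficients(n_subjects: int, n_profiles: int, seed) -> np.ndarray:
    """Unit-rate exponential subject coefficients ``U[n, k] ~ Exp(1)``."""
    if n_subjects < 1 or n_profiles < 1:
        raise ValueError("n_subjects and n_profiles must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0, size=(n_subjects, n_profiles))


def state_probabilities(latent: np.ndarray, theta: float) -> np.ndarray:
    """Four-state kernel probabilities ``p(s | m) ∝ exp(-theta (s - m)^2)``.

    Returns an array of shape ``latent.shape + (4,)`` normalized over the
    four states.
    """
    latent = np.asarray(latent, dtype=float)
    logits = -theta * (np.arange(1, 5, dtype=float) - latent[..., None]) ** 2
    logits -= logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=-1, keepdims=True)


def discretize_states(
    latent: np.ndarray, theta: float, seed, mode: str = "sample"
) -> np.ndarray:
    """Map latent values to discrete states 1-4 through the observation kernel."""
    p = state_probabilities(latent, theta)
    if mode == "argmax":
        return np.argmax(p, axis=-1).astype(np.int64) + 1
    if mode != "sample":
        raise ValueError("mode must be 'sample' or 'argmax'")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(size=latent.shape)
    return (u[..., None] > cdf).sum(axis=-1).astype(np.int64) + 1


def _table_vector(observation_table: dict) -> np.ndarray:
    """Probabilities indexed by last-kept state: slot 0 = 'none', 1-4 = states."""
    q = np.empty(5)
    try:
        q[0] = observation_table[BEFORE_FIRST]
        for s in range(1, 5):
            q[s] = observation_table[s]
    except KeyError as exc:
        raise ValueError(f"observation_table missing entry for {exc.args[0]!r}")
    return q


def expected_density(full_states: np.ndarray, observation_table: dict) -> float:
    """Exact expected observed fraction of the masking process.

    Forward pass over the distribution of the "most recent kept state"
    (a 5-valued chain per row: none, 1-4), exact in O(N·T).
    """
    q = _table_vector(observation_table)
    full = np.asarray(full_states)
    n, t_max = full.shape
    pi = np.zeros((n, 5))
    pi[:, 0] = 1.0
    expected = 0.0
    rows = np.arange(n)
    for t in range(t_max):
        p_keep = pi @ q
        expected += p_keep.sum()
        pi *= 1.0 - q[None, :]
        np.add.at(pi, (rows, full[:, t]), p_keep)
    return expected / (n * t_max)


def _scaled_table(observation_table: dict, scale: float) -> dict:
    return {k: min(1.0, scale * p) for k, p in observation_table.items()}


def mask_states(
    full_states: np.ndarray,
    observation_table: dict,
    target_density: float | None,
    seed,
    grid: TimeGrid | None = None,
) -> StateMatrix:
    """Thin a fully observed state matrix with a state-dependent process.

    Each row is scanned left to right; the entry at a bin is kept with the
    probability the table assigns to the most recent *kept* state
    (``"none"`` before the first kept entry).  With ``target_density`` the
    table is globally rescaled so the exact expected density matches it.
    """
    full = np.asarray(full_states)
    if grid is None:
        grid = TimeGrid(full.shape[1])
    table = dict(observation_table)
    if target_density is not None:
        if not 0.0 <= target_density <= 1.0:
            raise ValueError(f"target_density {target_density} not in [0, 1]")
        base = expected_density(full, table)
        if target_density > 0 and base == 0.0:
            raise ValueError("all observation probabilities are zero")
        if target_density > 0:
            # expected density is monotone in a global scaling of the table
            hi = 1.0
            while (
                expected_density(full, _scaled_table(table, hi)) < target_density
                and hi < 1e6
            ):
                hi *= 2.0
            if expected_density(full, _scaled_table(table, hi)) < target_density:
                raise ValueError(f"target_density {target_density} unreachable")
            scale = brentq(
                lambda c: expected_density(full, _scaled_table(table, c))
                - target_density,
                0.0,
                hi,
                xtol=1e-10,
            )
            table = _scaled_table(table, scale)
        else:
            table = _scaled_table(table, 0.0)
    q = _table_vector(table)
    rng = np.random.default_rng(seed)
    n, t_max = full.shape
    u = rng.random(size=(n, t_max))
    mask = np.zeros((n, t_max), dtype=bool)
    last = np.zeros(n, dtype=np.int64)  # 0 = none
    for t in range(t_max):
        keep = u[:, t] < q[last]
        mask[:, t] = keep
        last = np.where(keep, full[:, t], last)
    values = np.where(mask, full, 0)
    return StateMatrix(values, mask, grid)


def rescale_to_states(latent: np.ndarray) -> np.ndarray:
    """Affinely map a latent matrix onto [1, 4] (min -> 1, max -> 4)."""
    lo, hi = float(np.min(latent)), float(np.max(latent))
    if hi == lo:
        raise ValueError("latent matrix is constant; cannot rescale to [1, 4]")
    return 1.0 + 3.0 * (latent - lo) / (hi - lo)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; a pure function of ``config``."""
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    grid = config.grid
    profiles = make_basic_profiles(grid, config.centers())
    coeffs = sample_coefficients(config.n_subjects, config.n_profiles, seeds[0])
    latent = coeffs @ profiles.T
    if config.rescale_latent:
        latent = rescale_to_states(latent)
    full = discretize_states(latent, config.theta, seeds[1], mode=config.discretize)
    observed = mask_states(
        full, config.observation_table, config.target_density, seeds[2], grid=grid
    )
    return SyntheticDataset(latent, full, observed, config)


def config_from_dict(payload: dict) -> SyntheticConfig:
    """Build a config from a parsed YAML/TOML mapping (string state keys ok)."""
    payload = dict(payload)
    table = payload.get("observation_table")
    if table is not None:
        payload["observation_table"] = {
            (k if k == BEFORE_FIRST else int(k)): float(v) for k, v in table.items()
        }
    if payload.get("profile_centers") is not None:
        payload["profile_centers"] = tuple(payload["profile_centers"])
    allowed = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return SyntheticConfig(**payload)
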