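"""Synthetic grid ECoG: a linear Gaussian VAR with a planted ictal source.

The generator emulates the two regimes the localization pipeline consumes: a
patient-specific *rest-state* coupling structure present in every block, and
an *ictal* regime in which one planted source node's outgoing coupling is
transiently multiplied by ``source_gain`` inside each annotated seizure
interval.  A linear Gaussian VAR was chosen because both causal-influence
measures used downstream (Granger causality and directed information) have
closed-form population values for it, so the generator doubles as an oracle.

Model, per channel j at sample t:

    x_t[j] = sum_l c_l * x_{t-l}[j]  +  sum_i C[i, j] * x_{t-1}[i]  +  w_t[j]

with self coefficients ``c_l`` (default AR(2): 0.5, -0.2), cross-coupling
matrix ``C`` (zero diagonal; ``C[i, j]`` is the lag-1 influence of channel i
on channel j), and i.i.d. Gaussian innovations of standard deviation
``noise_sd``.  During a seizure the row ``C[source_node, :]`` is multiplied
by ``source_gain``.  Both regimes must be stable (companion spectral
radius < 1) or the configuration is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .recordings import GridLayout, RecordingSession

__all__ = [
    "SimConfig",
    "grid_rest_coupling",
    "simulate_session",
    "stationary_covariance",
    "companion_matrix",
]


def grid_rest_coupling(n_rows: int, n_cols: int, strength: float = 0.05) -> np.ndarray:
    """Nearest-neighbour (4-adjacency) directed coupling of uniform magnitude."""
    n = n_rows * n_cols
    c = np.zeros((n, n))
    for r in range(n_rows):
        for col in range(n_cols):
            i = r * n_cols + col
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, col + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    c[i, rr * n_cols + cc] = strength
    return c


@dataclass
class SimConfig:
    """Configuration of the synthetic session generator.

    ``rest_coupling`` is the zero-diagonal cross-channel matrix applied at
    lag 1 (entry ``[i, j]`` couples channel i into channel j); per-channel
    self dynamics are the AR coefficients ``self_coefs``, one per lag.
    """

    n_rows: int = 6
    n_cols: int = 6
    fs: float = 500.0
    duration: float = 600.0
    ar_order: int = 2
    rest_coupling: np.ndarray | None = None  # defaults to grid_rest_coupling(...)
    self_coefs: tuple[float, ...] = (0.5, -0.2)
    source_node: int = 0
    source_gain: float = 1.0
    noise_sd: float = 1.0
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0
    coupling_strength: float = 0.05  # used when rest_coupling is None
    burn_in: float = 2.0  # seconds discarded before t = 0

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def resolved_coupling(self) -> np.ndarray:
        c = (
            grid_rest_coupling(self.n_rows, self.n_cols, self.coupling_strength)
            if self.rest_coupling is None
            else np.asarray(self.rest_coupling, dtype=float).copy()
        )
        if c.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("rest_coupling must be N x N with N = n_rows * n_cols")
        if np.any(np.diag(c) != 0):
            raise ValueError("rest_coupling diagonal must be zero (self terms live in self_coefs)")
        if np.any(c < 0):
            raise ValueError("rest_coupling must be nonnegative")
        return c

    def ictal_coupling(self) -> np.ndarray:
        c = self.resolved_coupling()
        c[self.source_node, :] *= self.source_gain
        return c

    def validate(self) -> None:
        if len(self.self_coefs) != self.ar_order:
            raise ValueError("self_coefs must supply one coefficient per lag")
        if not (0 <= self.source_node < self.n_nodes):
            raise ValueError(f"source_node {self.source_node} outside 0..{self.n_nodes - 1}")
        ivs = sorted((float(s), float(e)) for s, e in self.seizure_intervals)
        for s, e in ivs:
            if not (0.0 <= s < e <= self.duration):
                raise ValueError(f"seizure interval ({s}, {e}) outside [0, {self.duration}]")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping seizure intervals ({s1},{e1}) and ({s2},{e2})")
        for name, c in (("rest", self.resolved_coupling()), ("ictal", self.ictal_coupling())):
            rho = spectral_radius(self._var_coefs(c))
            if rho >= 1.0:
                raise ValueError(
                    f"unstable VAR in the {name} regime (companion spectral radius {rho:.3f} >= 1)"
                )

    def _var_coefs(self, coupling: np.ndarray) -> list[np.ndarray]:
        """Per-lag matrices B_l with x_t = sum_l B_l x_{t-l} + w_t."""
        n = self.n_nodes
        mats = [np.diag(np.full(n, c)) for c in self.self_coefs]
        mats[0] = mats[0] + coupling.T  # C[i, j]: i drives j  =>  B_1[j, i] = C[i, j]
        return mats


def companion_matrix(coefs: list[np.ndarray]) -> np.ndarray:
    n = coefs[0].shape[0]
    m = len(coefs)
    comp = np.zeros((n * m, n * m))
    comp[:n, :] = np.hstack(coefs)
    if m > 1:
        comp[n:, : n * (m - 1)] = np.eye(n * (m - 1))
    return comp


def spectral_radius(coefs: list[np.ndarray]) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coefs)))))


def stationary_covariance(config: SimConfig) -> np.ndarray:
    """Closed-form stationary covariance of the rest regime (Lyapunov solve)."""
    coefs = config._var_coefs(config.resolved_coupling())
    comp = companion_matrix(coefs)
    n, m = config.n_nodes, config.ar_order
    q = np.zeros((n * m, n * m))
    q[:n, :n] = np.eye(n) * config.noise_sd**2
    sigma = scipy.linalg.solve_discrete_lyapunov(comp, q)
    return sigma[:n, :n]


def simulate_session(config: SimConfig) -> RecordingSession:
    """Draw one session; deterministic (bit-identical) under a fixed seed.

    The innovation stream is drawn once up front, so two configurations that
    differ only in regime bookkeeping but share the same effective VAR (e.g.
    ``source_gain = 1`` with and without seizure annotations) produce
    identical signals under the same seed.
    """
    config.validate()
    n = config.n_nodes
    m = config.ar_order
    fs = config.fs
    t_total = int(round(config.duration * fs))
    burn = int(round(config.burn_in * fs))
    rng = np.random.default_rng(config.seed)
    innov = rng.normal(0.0, config.noise_sd, size=(burn + t_total, n))

    b_rest = config._var_coefs(config.resolved_coupling())
    b_ictal = config._var_coefs(config.ictal_coupling())

    ictal_mask = np.zeros(burn + t_total, dtype=bool)
    for s, e in config.seizure_intervals:
        i0 = burn + int(round(s * fs))
        i1 = burn + int(round(e * fs))
        ictal_mask[i0:i1] = True

    x = np.zeros((burn + t_total, n))
    hist = np.zeros((m, n))
    for t in range(burn + t_total):
        coefs = b_ictal if ictal_mask[t] else b_rest
        acc = innov[t].copy()
        for lag in range(m):
            acc += coefs[lag] @ hist[lag]
        x[t] = acc
        if m > 1:
            hist[1:] = hist[:-1]
        hist[0] = acc

    grid = GridLayout(config.n_rows, config.n_cols)
    return RecordingSession(
        signal=x[burn:],
        fs=fs,
        channel_labels=list(grid.labels),
        grid=grid,
        seizure_intervals=[(float(s), float(e)) for s, e in config.seizure_intervals],
        exclusion_intervals=[],
        eoi={grid.labels[config.source_node]},
    )
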