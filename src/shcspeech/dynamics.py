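"""Generative core: sequential and spectral dynamics.

Two coupled nonlinear dynamical systems generate reduced cochleagram
trajectories:

* **Second level** — a Lotka-Volterra-type winnerless-competition network
  whose saddle equilibria form a stable heteroclinic channel (SHC).  Each
  of the ``N`` neuronal ensembles dominates for a brief contiguous window
  before handing over to its successor, so one cycle of the network acts
  as a timing chain for the word being generated.  A second set of hidden
  states relaxes toward an exponential (softmax-like) normalization of
  the membrane potentials, confining the causal output ``v2`` to [0, 1]
  and keeping it near one-hot away from handovers.

* **First level** — a Hopfield network with asymmetric coupling ``W`` and
  self-decay ``a``.  For a fixed drive the network has a unique global
  attractor; the drive is a linear combination ``I @ v2`` of learned
  feedback columns, one per second-level ensemble, so the attractor (and
  hence the predicted 6-channel firing-rate pattern) follows the
  second-level sequence.

All integration is explicit Euler(-Maruyama); trajectories are recorded
once per model time unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "SHCParams",
    "SHCState",
    "HopfieldParams",
    "FeedbackWeights",
    "GenerativeModel",
    "SimulationConfig",
    "build_rho",
    "default_w",
    "shc_initial_state",
    "shc_step",
    "simulate_level2",
    "attractor_input",
    "hopfield_equilibrium",
    "hopfield_step",
    "simulate_hierarchy",
    "default_model",
]

# Global time-scale factor on the second-level vector field, fixed once so
# that a noise-free N = 8 cycle spans ~100 model time units (dwell ~ T/N).
# For other N the factor scales proportionally, keeping one full cycle at
# ~100 units regardless of sequence length.
BASE_TIME_SCALE_N8 = 0.60

# Saddle-chain rest levels used to start trajectories inside the basin of
# ensemble 1 (active potential / suppressed potential).
_X_ACTIVE = 1.7
_X_SUPPRESSED = -2.2


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _softmax(x: np.ndarray, temperature: float) -> np.ndarray:
    z = x / temperature
    z = z - np.max(z)
    e = np.exp(z)
    return e / e.sum()


def build_rho(N: int) -> np.ndarray:
    """Cyclic inhibition matrix for a stable heteroclinic channel.

    ``rho[i, j]`` is the strength of the inhibition exerted *on* ensemble
    ``i`` *by* ensemble ``j``.  For the intended order 1 -> 2 -> ... -> N
    -> 1, the currently active ensemble inhibits its successor weakly
    (0.5) so the successor can grow, while every other ordered pair —
    including the successor's back-inhibition of the current ensemble —
    is strong (2.0).  Self terms are moderate (1.0).  The wrap N -> 1
    closes the cycle.
    """
    if N < 2:
        raise ValueError(f"need at least 2 ensembles, got N={N}")
    rho = np.full((N, N), 2.0)
    np.fill_diagonal(rho, 1.0)
    for i in range(N):
        succ = (i + 1) % N
        rho[succ, i] = 0.5  # weak current -> next
    return rho


@dataclass
class SHCParams:
    """Second-level (sequencer) parameters.

    kappa1 is the rate constant of the normalizing (y) dynamics and
    kappa2 that of the competition (x) dynamics; lam is the self-decay
    rate of the potentials.  ``rho`` is the inhibition matrix (see
    :func:`build_rho`).  ``sharpness`` is the temperature of the
    exponential normalization: low values force the causal output near
    one-hot.  ``time_scale`` multiplies the competition vector field and
    thereby sets dwell and cycle duration; ``None`` selects the
    calibrated default (dwell ~12.5 units, sped up for N > 8 so a full
    cycle always fits ~100 units).
    """

    N: int = 8
    kappa1: float = 2.0
    kappa2: float = 1.0
    lam: float = 1.0 / 8.0
    rho: Optional[np.ndarray] = None
    sigmoid_gain: float = 2.0
    sharpness: float = 0.1
    noise_sd_x: float = 0.02
    noise_sd_y: float = 0.002
    time_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.rho is None:
            self.rho = build_rho(self.N)
        else:
            self.rho = np.asarray(self.rho, dtype=float)
            if self.rho.shape != (self.N, self.N):
                raise ValueError("rho shape does not match N")
            if np.any(self.rho < 0):
                raise ValueError("rho must be nonnegative")

    @property
    def effective_time_scale(self) -> float:
        # Default: constant dwell (~12.5 units) up to N = 8, so an N = 8
        # cycle spans ~100 units; for longer chains the field is sped up
        # proportionally so a full cycle still fits 100 units.
        if self.time_scale is not None:
            return self.time_scale
        return BASE_TIME_SCALE_N8 * max(self.N, 8) / 8.0


@dataclass
class SHCState:
    """Second-level state: potentials x2, normalizers y2, output v2."""

    x2: np.ndarray
    y2: np.ndarray
    v2: np.ndarray


def shc_initial_state(p: SHCParams) -> SHCState:
    """Start inside the basin of ensemble 1."""
    x2 = np.full(p.N, _X_SUPPRESSED)
    x2[0] = _X_ACTIVE
    y2 = _softmax(x2, p.sharpness)
    return SHCState(x2=x2, y2=y2.copy(), v2=y2.copy())


def _shc_field(x2: np.ndarray, y2: np.ndarray, p: SHCParams):
    # The calibrated time scale acts on the competition (x) dynamics only:
    # it sets the dwell/cycle duration, while the normalizing (y) dynamics
    # keep their own rate so that handovers stay sharp relative to dwells.
    ts = p.effective_time_scale
    s = _sigmoid(p.sigmoid_gain * x2)
    fx = ts * p.kappa2 * (1.0 - p.lam * x2 - p.rho @ s)
    fy = p.kappa1 * (_softmax(x2, p.sharpness) - y2)
    return fx, fy


def shc_step(
    s: SHCState,
    p: SHCParams,
    dt: float,
    noise: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> SHCState:
    """One Euler(-Maruyama) step of the second-level dynamics."""
    if not (np.all(np.isfinite(s.x2)) and np.all(np.isfinite(s.y2))):
        raise FloatingPointError("non-finite second-level state")
    fx, fy = _shc_field(s.x2, s.y2, p)
    x2 = s.x2 + dt * fx
    y2 = s.y2 + dt * fy
    if noise is not None:
        wx, wy = noise
        x2 = x2 + np.sqrt(dt) * p.noise_sd_x * wx
        y2 = y2 + np.sqrt(dt) * p.noise_sd_y * wy
    v2 = y2.copy()
    return SHCState(x2=x2, y2=y2, v2=v2)


@dataclass
class SimulationConfig:
    """Forward-simulation settings (T model time units, Euler step dt)."""

    T: int = 100
    dt: float = 0.05
    seed: int = 0
    noisy: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = self.T / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("T/dt must be integral")


def simulate_level2(p: SHCParams, cfg: SimulationConfig) -> np.ndarray:
    """Simulate the sequencer; return the v2 trajectory (N x T).

    Samples are recorded once per model time unit at t = 0, 1, ..., T-1.
    """
    rng = np.random.default_rng(cfg.seed)
    per_unit = round(1.0 / cfg.dt)
    state = shc_initial_state(p)
    out = np.empty((p.N, cfg.T))
    for t in range(cfg.T):
        out[:, t] = state.v2
        for _ in range(per_unit):
            noise = None
            if cfg.noisy:
                noise = (rng.standard_normal(p.N), rng.standard_normal(p.N))
            state = shc_step(state, p, cfg.dt, noise)
    return out


@dataclass
class HopfieldParams:
    """First-level (spectral) parameters.

    ``a`` is the diagonal self-decay, ``W`` the asymmetric coupling,
    ``kappa`` an overall rate constant, and ``input_gain`` scales the
    second-level drive.  ``W`` must satisfy the contraction condition
    (max absolute row sum < a) so that any fixed drive has a unique
    global attractor.
    """

    n: int = 6
    a: float = 0.2
    W: Optional[np.ndarray] = None
    kappa: float = 2.0
    input_gain: float = 1.0
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.W is None:
            self.W = default_w(self.n)
        else:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape != (self.n, self.n):
                raise ValueError("W shape does not match n")


def default_w(n: int, seed: int = 42, row_sum: float = 0.15) -> np.ndarray:
    """Asymmetric coupling with max absolute row sum ``row_sum`` < a.

    Drawn once from U(-1, 1) with a fixed seed and rescaled; the same W
    is shared by every module so that modules differ only in their
    feedback weights.
    """
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n, n))
    W *= row_sum / np.abs(W).sum(axis=1).max()
    return W


@dataclass
class FeedbackWeights:
    """Backward connections: column j is delivered while ensemble j is active."""

    I: np.ndarray

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        if self.I.ndim != 2:
            raise ValueError("I must be a matrix")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("I must be finite")


def attractor_input(target: np.ndarray, hop: HopfieldParams) -> np.ndarray:
    """Constant drive making ``target`` the global equilibrium.

    From the equilibrium condition 0 = -A x* + W tanh(x*) + I_j with
    x* = target:  I_j = A target - W tanh(target).
    """
    target = np.asarray(target, dtype=float)
    if np.any(target < 0) or np.any(target > 1):
        raise ValueError("target firing rates must lie in [0, 1]")
    return hop.a * target - hop.W @ np.tanh(target)


def hopfield_equilibrium(hop: HopfieldParams, drive: np.ndarray) -> np.ndarray:
    """Unique fixed point of the first level under constant drive.

    Solved by fixed-point iteration x <- (W tanh x + drive)/a, a
    contraction when max abs row sum of W < a.
    """
    x = drive / hop.a
    for _ in range(200):
        x_new = (hop.W @ np.tanh(x) + drive) / hop.a
        if np.max(np.abs(x_new - x)) < 1e-12:
            return x_new
        x = x_new
    return x


def hopfield_step(
    x1: np.ndarray,
    v2: np.ndarray,
    hop: HopfieldParams,
    fb: FeedbackWeights,
    dt: float,
    noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One Euler(-Maruyama) step of the first-level dynamics."""
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(v2))):
        raise FloatingPointError("non-finite first-level input")
    drive = hop.input_gain * (fb.I @ v2)
    f = hop.kappa * (-hop.a * x1 + hop.W @ np.tanh(x1) + drive)
    x1 = x1 + dt * f
    if noise is not None:
        x1 = x1 + np.sqrt(dt) * hop.noise_sd * noise
    return x1


@dataclass
class GenerativeModel:
    """Complete two-level generative model (shared rho and W, trained I)."""

    shc: SHCParams
    hop: HopfieldParams
    fb: FeedbackWeights

    def __post_init__(self) -> None:
        if self.fb.I.shape != (self.hop.n, self.shc.N):
            raise ValueError(
                f"feedback weights must be {self.hop.n} x {self.shc.N}, "
                f"got {self.fb.I.shape}"
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "shc": asdict(self.shc),
            "hop": asdict(self.hop),
            "fb": {"I": self.fb.I.tolist()},
        }
        d["shc"]["rho"] = self.shc.rho.tolist()
        d["hop"]["W"] = self.hop.W.tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        shc = SHCParams(**{**d["shc"], "rho": np.asarray(d["shc"]["rho"])})
        hop = HopfieldParams(**{**d["hop"], "W": np.asarray(d["hop"]["W"])})
        fb = FeedbackWeights(I=np.asarray(d["fb"]["I"]))
        return cls(shc=shc, hop=hop, fb=fb)

    @classmethod
    def from_json(cls, path) -> "GenerativeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_model(N: int = 8, n: int = 6, I: Optional[np.ndarray] = None) -> GenerativeModel:
    shc = SHCParams(N=N)
    hop = HopfieldParams(n=n)
    if I is None:
        I = np.zeros((n, N))
    return GenerativeModel(shc=shc, hop=hop, fb=FeedbackWeights(I=I))


def simulate_hierarchy(m: GenerativeModel, cfg: SimulationConfig):
    """Run both levels; return (output, latents).

    ``output`` is the generated n x T reduced cochleagram prediction
    (first-level causal states, clipped to [0, 1]); ``latents`` is a dict
    with the full x2/y2/v2/x1 records at 1 sample per time unit.  This is
    the read-out used to compare a learned module's internal model with
    the stimulus it was trained on.
    """
    rng = np.random.default_rng(cfg.seed)
    per_unit = round(1.0 / cfg.dt)
    state = shc_initial_state(m.shc)
    drive0 = m.hop.input_gain * (m.fb.I @ state.v2)
    x1 = hopfield_equilibrium(m.hop, drive0)
    N, n, T = m.shc.N, m.hop.n, cfg.T
    rec = {
        "x2": np.empty((N, T)),
        "y2": np.empty((N, T)),
        "v2": np.empty((N, T)),
        "x1": np.empty((n, T)),
    }
    for t in range(T):
        rec["x2"][:, t] = state.x2
        rec["y2"][:, t] = state.y2
        rec["v2"][:, t] = state.v2
        rec["x1"][:, t] = x1
        for _ in range(per_unit):
            noise2 = noise1 = None
            if cfg.noisy:
                noise2 = (rng.standard_normal(N), rng.standard_normal(N))
                noise1 = rng.standard_normal(n)
            x1 = hopfield_step(x1, state.v2, m.hop, m.fb, cfg.dt, noise1)
            state = shc_step(state, m.shc, cfg.dt, noise2)
    output = np.clip(rec["x1"], 0.0, 1.0)
    return output, rec
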