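"""Online Bayesian inversion of the hierarchical generative model.

A module inverts its two-level dynamical generative model against an
incoming reduced cochleagram ``z(t)`` by gradient flow on the
instantaneous variational free energy under the Laplace (Gaussian,
modes-only) assumption.  States are represented in generalized
coordinates of motion (value plus temporal derivatives up to a
configured embedding order); prediction errors at each level —

* sensory:          ``z - mu_x1``              (the level-1 causal states
  are observed directly),
* level-1 hidden:   ``mu_x1' - f1(mu_x1, mu_v2)``,
* level-2 causal:   ``mu_v2 - mu_y2``,
* level-2 hidden:   ``mu_{x2,y2}' - f2(mu_x2, mu_y2)``,

are weighted by fixed prior precisions (inverse variances) and jointly
minimized.  The filter is causal: the estimate at sample t uses only
samples <= t.  The stiff gradient flow (precisions span many orders of
magnitude) is integrated with an implicit Euler step linearized with the
Gauss-Newton curvature of the free energy.

Feedback-weight learning operates on the slower time scale of whole
stimulus presentations: hidden-state prediction errors and their
sensitivities to the weights are accumulated over a presentation and a
single natural (curvature-scaled) update with prior shrinkage is applied
after it, repeated until the accumulated error stops decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import GenerativeModel, _sigmoid, _softmax, shc_initial_state

__all__ = [
    "PrecisionConfig",
    "InferenceSettings",
    "PosteriorTrajectory",
    "LearningRecord",
    "InferenceDivergence",
    "precision_to_sd",
    "infer_states",
    "learn_feedback",
    "error_summary",
    "recognition_accuracy",
]


def precision_to_sd(logpi: float) -> float:
    """Standard deviation implied by a log-precision: sd = exp(-logpi/2)."""
    if not np.all(np.isfinite(logpi)):
        raise ValueError("log-precision must be finite")
    return float(np.exp(-0.5 * logpi))


@dataclass(frozen=True)
class PrecisionConfig:
    """Fixed prior log-precisions per (level, causal/hidden) state group.

    The sensory/internal ratio at the first level (``logpi_v1 -
    logpi_x1``) selects the operating mode: a high ratio forces the
    module to take the input literally and adapt (learning), a low ratio
    lets it explain deviations as sensory noise (recognition under
    noise).  ``logpi_param`` is the prior log-precision shrinking the
    feedback-weight update.
    """

    logpi_v1: float
    logpi_x1: float
    logpi_v2: float
    logpi_x2: float
    logpi_param: float = 0.0

    @classmethod
    def learning(cls) -> "PrecisionConfig":
        """High sensory/internal ratio; precise sequencer."""
        return cls(logpi_v1=8.0, logpi_x1=2.0, logpi_v2=7.0, logpi_x2=7.0)

    @classmethod
    def clean_recognition(cls) -> "PrecisionConfig":
        """Moderate sensory precision; parameters fixed."""
        return cls(logpi_v1=4.0, logpi_x1=4.0, logpi_v2=8.0, logpi_x2=8.0)

    @classmethod
    def noisy_recognition(cls) -> "PrecisionConfig":
        """Low sensory precision relative to internal dynamics."""
        return cls(logpi_v1=2.0, logpi_x1=6.0, logpi_v2=8.0, logpi_x2=8.0)

    def sds(self) -> dict:
        return {
            k: precision_to_sd(getattr(self, k))
            for k in ("logpi_v1", "logpi_x1", "logpi_v2", "logpi_x2")
        }


@dataclass(frozen=True)
class InferenceSettings:
    """Numerical settings of the generalized-coordinate filter.

    ``embed_order`` is the number of temporal derivatives carried per
    state; ``smoothness`` the assumed Gaussian autocorrelation width of
    the fluctuations (model time units); ``n_inner`` the number of
    implicit gradient-flow steps per stimulus sample.
    """

    embed_order: int = 2
    smoothness: float = 0.5
    n_inner: int = 4
    divergence_bound: float = 1e4
    score: str = "v1"


DEFAULT_SETTINGS = InferenceSettings()


class InferenceDivergence(RuntimeError):
    """State norm exceeded the divergence bound; carries the partial result."""

    def __init__(self, message: str, trajectory: "PosteriorTrajectory"):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class PosteriorTrajectory:
    """Posterior modes and precision-weighted error series per level."""

    mu_x1: np.ndarray  # n x T
    mu_v1: np.ndarray  # n x T (identity observation model: equals mu_x1)
    mu_x2: np.ndarray  # N x T
    mu_y2: np.ndarray  # N x T
    mu_v2: np.ndarray  # N x T
    err_v1: np.ndarray  # T
    err_x1: np.ndarray  # T
    err_v2: np.ndarray  # T
    err_x2: np.ndarray  # T
    free_action: float
    cov_diag: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.mu_x1.shape[1]


@dataclass
class LearningRecord:
    """Feedback-weight learning across repetitions of one stimulus."""

    I_history: list
    error_curve: list
    converged_at: Optional[int]


def generalized_precision(order: int, smoothness: float) -> np.ndarray:
    """Precision among temporal derivatives of smooth Gaussian noise.

    For fluctuations with Gaussian autocorrelation rho(h) =
    exp(-h^2/(2 s^2)), the covariance between the i-th and j-th
    derivative at lag 0 is (-1)^i rho^(i+j)(0), zero for odd i+j, with
    rho^(2k)(0) = (-1)^k (2k-1)!! / s^(2k).  Returns the inverse of that
    (order+1) x (order+1) covariance.
    """
    b = order + 1
    s2 = smoothness**2

    def rho_deriv(m: int) -> float:
        if m % 2 == 1:
            return 0.0
        k = m // 2
        dfact = 1.0
        for j in range(2 * k - 1, 0, -2):
            dfact *= j
        return (-1.0) ** k * dfact / s2**k

    C = np.zeros((b, b))
    for i in range(b):
        for j in range(b):
            C[i, j] = (-1.0) ** i * rho_deriv(i + j)
    return np.linalg.inv(C)


def _generalized_data(z: np.ndarray, t: int, order: int) -> np.ndarray:
    """Causal backward-difference embedding of the data at sample t."""
    n = z.shape[0]
    out = np.zeros((order + 1, n))
    out[0] = z[:, t]
    for k in range(1, order + 1):
        acc = np.zeros(n)
        for j in range(k + 1):
            sign = -1.0 if j % 2 else 1.0
            acc += sign * _binom(k, j) * z[:, max(t - j, 0)]
        out[k] = acc
    return out


def _binom(k: int, j: int) -> float:
    from math import comb

    return float(comb(k, j))


def _as_values(z) -> np.ndarray:
    v = getattr(z, "values", z)
    return np.asarray(v, dtype=float)


class _Filter:
    """Workspace for one inversion run (dimensions, layout, constants)."""

    def __init__(self, m: GenerativeModel, pc: PrecisionConfig, st: InferenceSettings):
        self.m, self.pc, self.st = m, pc, st
        self.n, self.N = m.hop.n, m.shc.N
        self.b = st.embed_order + 1
        n, N, b = self.n, self.N, self.b
        self.R = generalized_precision(st.embed_order, st.smoothness)
        self.pi = {
            "v1": np.exp(pc.logpi_v1),
            "x1": np.exp(pc.logpi_x1),
            "v2": np.exp(pc.logpi_v2),
            "x2": np.exp(pc.logpi_x2),
        }
        # state layout: x1 | v2 | x2 | y2, each var contiguous by block
        sizes = [n, N, N, N]
        self.var_dim = dict(zip(("x1", "v2", "x2", "y2"), sizes))
        off, self.off = 0, {}
        for name, s in self.var_dim.items():
            self.off[name] = off
            off += s * b
        self.M = off
        # error layout: o | h1 | c2 | h2x | h2y, by block
        esizes = {"o": n, "h1": n, "c2": N, "h2x": N, "h2y": N}
        self.err_dim = esizes
        eoff, self.eoff = 0, {}
        for name, s in esizes.items():
            self.eoff[name] = eoff
            eoff += s * b
        self.E = eoff
        self.Dmat = self._build_shift()
        self.Ejac = np.zeros((self.E, self.M))
        self._fill_constant_jacobian()
        # generative constants
        hop, shc = m.hop, m.shc
        self.kg = hop.kappa * hop.input_gain
        self.J1v = self.kg * m.fb.I  # constant within a run unless I changes
        self.ts = shc.effective_time_scale

    # ---- layout helpers -------------------------------------------------
    def sl(self, var: str, k: int) -> slice:
        d = self.var_dim[var]
        start = self.off[var] + k * d
        return slice(start, start + d)

    def esl(self, err: str, k: int) -> slice:
        d = self.err_dim[err]
        start = self.eoff[err] + k * d
        return slice(start, start + d)

    def _build_shift(self) -> np.ndarray:
        D = np.zeros((self.M, self.M))
        for var in self.var_dim:
            for k in range(self.b - 1):
                rows = self.sl(var, k)
                cols = self.sl(var, k + 1)
                D[rows, cols] = np.eye(self.var_dim[var])
        return D

    def _fill_constant_jacobian(self) -> None:
        n, N, b = self.n, self.N, self.b
        E = self.Ejac
        In, IN = np.eye(n), np.eye(N)
        for k in range(b):
            E[self.esl("o", k), self.sl("x1", k)] = -In
            E[self.esl("c2", k), self.sl("v2", k)] = IN
            E[self.esl("c2", k), self.sl("y2", k)] = -IN
            if k < b - 1:
                E[self.esl("h1", k), self.sl("x1", k + 1)] = In
                E[self.esl("h2x", k), self.sl("x2", k + 1)] = IN
                E[self.esl("h2y", k), self.sl("y2", k + 1)] = IN
            # -J2yy = kappa1 * I (constant)
            E[self.esl("h2y", k), self.sl("y2", k)] = self.m.shc.kappa1 * IN

    # ---- model fields and Jacobians ------------------------------------
    def f1(self, x1: np.ndarray, v2: np.ndarray) -> np.ndarray:
        hop = self.m.hop
        return hop.kappa * (
            -hop.a * x1 + hop.W @ np.tanh(x1) + hop.input_gain * (self.m.fb.I @ v2)
        )

    def J1x(self, x1: np.ndarray) -> np.ndarray:
        hop = self.m.hop
        sech2 = 1.0 - np.tanh(x1) ** 2
        return hop.kappa * (-hop.a * np.eye(self.n) + hop.W * sech2[None, :])

    def f2x(self, x2: np.ndarray) -> np.ndarray:
        shc = self.m.shc
        s = _sigmoid(shc.sigmoid_gain * x2)
        return self.ts * shc.kappa2 * (1.0 - shc.lam * x2 - shc.rho @ s)

    def J2xx(self, x2: np.ndarray) -> np.ndarray:
        shc = self.m.shc
        s = _sigmoid(shc.sigmoid_gain * x2)
        ds = shc.sigmoid_gain * s * (1.0 - s)
        return self.ts * shc.kappa2 * (-shc.lam * np.eye(self.N) - shc.rho * ds[None, :])

    def f2y(self, x2: np.ndarray, y2: np.ndarray) -> np.ndarray:
        shc = self.m.shc
        return shc.kappa1 * (_softmax(x2, shc.sharpness) - y2)

    def J2yx(self, x2: np.ndarray) -> np.ndarray:
        shc = self.m.shc
        p = _softmax(x2, shc.sharpness)
        return shc.kappa1 / shc.sharpness * (np.diag(p) - np.outer(p, p))

    # ---- error vector ---------------------------------------------------
    def errors(self, mu: np.ndarray, zg: np.ndarray) -> np.ndarray:
        """Stacked generalized prediction errors at the current modes."""
        b = self.b
        e = np.zeros(self.E)
        x1_0 = mu[self.sl("x1", 0)]
        v2_0 = mu[self.sl("v2", 0)]
        x2_0 = mu[self.sl("x2", 0)]
        y2_0 = mu[self.sl("y2", 0)]
        J1x = self.J1x(x1_0)
        J2xx = self.J2xx(x2_0)
        J2yx = self.J2yx(x2_0)
        kappa1 = self.m.shc.kappa1
        for k in range(b):
            x1_k = mu[self.sl("x1", k)]
            v2_k = mu[self.sl("v2", k)]
            x2_k = mu[self.sl("x2", k)]
            y2_k = mu[self.sl("y2", k)]
            x1_k1 = mu[self.sl("x1", k + 1)] if k < b - 1 else 0.0
            x2_k1 = mu[self.sl("x2", k + 1)] if k < b - 1 else 0.0
            y2_k1 = mu[self.sl("y2", k + 1)] if k < b - 1 else 0.0
            e[self.esl("o", k)] = zg[k] - x1_k
            if k == 0:
                f1 = self.f1(x1_k, v2_k)
                f2x = self.f2x(x2_k)
                f2y = self.f2y(x2_k, y2_k)
            else:
                f1 = J1x @ x1_k + self.J1v @ v2_k
                f2x = J2xx @ x2_k
                f2y = J2yx @ x2_k - kappa1 * y2_k
            e[self.esl("h1", k)] = x1_k1 - f1
            e[self.esl("c2", k)] = v2_k - y2_k
            e[self.esl("h2x", k)] = x2_k1 - f2x
            e[self.esl("h2y", k)] = y2_k1 - f2y
        self._J1x, self._J2xx, self._J2yx = J1x, J2xx, J2yx
        return e

    def update_jacobian(self) -> None:
        """Refresh the state-dependent blocks of the error Jacobian."""
        E = self.Ejac
        for k in range(self.b):
            E[self.esl("h1", k), self.sl("x1", k)] = -self._J1x
            E[self.esl("h1", k), self.sl("v2", k)] = -self.J1v
            E[self.esl("h2x", k), self.sl("x2", k)] = -self._J2xx
            E[self.esl("h2y", k), self.sl("x2", k)] = -self._J2yx

    def weighted(self, e: np.ndarray) -> np.ndarray:
        """Apply the generalized precisions (pi * R along the block axis)."""
        out = np.empty_like(e)
        for err, pi_key in (
            ("o", "v1"),
            ("h1", "x1"),
            ("c2", "v2"),
            ("h2x", "x2"),
            ("h2y", "x2"),
        ):
            d = self.err_dim[err]
            start = self.eoff[err]
            blockview = e[start : start + d * self.b].reshape(self.b, d)
            out[start : start + d * self.b] = (
                self.pi[pi_key] * (self.R @ blockview)
            ).ravel()
        return out


def infer_states(
    m: GenerativeModel,
    pc: PrecisionConfig,
    z,
    settings: Optional[InferenceSettings] = None,
    collect_param_stats: bool = False,
):
    """Filter a reduced stimulus through the model's posterior modes.

    Parameters are held fixed; only states are inferred, online.  Returns
    a :class:`PosteriorTrajectory`; with ``collect_param_stats=True``
    returns ``(trajectory, (grad, curvature))`` — the accumulated
    free-action gradient with respect to the feedback weights and the
    accumulated Gauss-Newton curvature in second-level output space, as
    consumed by :func:`learn_feedback`.

    Raises :class:`InferenceDivergence` if the state norm exceeds the
    configured bound; the partial trajectory rides on the exception.
    """
    st = settings or DEFAULT_SETTINGS
    z = _as_values(z)
    if z.ndim != 2 or z.shape[0] != m.hop.n:
        raise ValueError(f"stimulus must be {m.hop.n} x T, got {z.shape}")
    T = z.shape[1]
    fw = _Filter(m, pc, st)
    n, N, b, M = fw.n, fw.N, fw.b, fw.M

    mu = np.zeros(M)
    init = shc_initial_state(m.shc)
    mu[fw.sl("x1", 0)] = z[:, 0]
    mu[fw.sl("x2", 0)] = init.x2
    mu[fw.sl("y2", 0)] = init.y2
    mu[fw.sl("v2", 0)] = init.v2
    if fw.b > 1:
        # consistent generalized start: first derivative = model flow
        mu[fw.sl("x1", 1)] = fw.f1(z[:, 0], init.v2)
        mu[fw.sl("x2", 1)] = fw.f2x(init.x2)
        mu[fw.sl("y2", 1)] = fw.f2y(init.x2, init.y2)
        mu[fw.sl("v2", 1)] = mu[fw.sl("y2", 1)]

    rec = {
        "mu_x1": np.empty((n, T)),
        "mu_x2": np.empty((N, T)),
        "mu_y2": np.empty((N, T)),
        "mu_v2": np.empty((N, T)),
    }
    errs = {k: np.empty(T) for k in ("err_v1", "err_x1", "err_v2", "err_x2")}
    free_action = 0.0
    dt = 1.0 / st.n_inner
    Idt = np.eye(M) / dt
    G_acc = np.zeros((n, N))
    H_acc = np.zeros((N, N))

    def snapshot(upto: int) -> PosteriorTrajectory:
        return PosteriorTrajectory(
            mu_x1=rec["mu_x1"][:, :upto].copy(),
            mu_v1=rec["mu_x1"][:, :upto].copy(),
            mu_x2=rec["mu_x2"][:, :upto].copy(),
            mu_y2=rec["mu_y2"][:, :upto].copy(),
            mu_v2=rec["mu_v2"][:, :upto].copy(),
            err_v1=errs["err_v1"][:upto].copy(),
            err_x1=errs["err_x1"][:upto].copy(),
            err_v2=errs["err_v2"][:upto].copy(),
            err_x2=errs["err_x2"][:upto].copy(),
            free_action=free_action,
        )

    H = None
    zg_prev = _generalized_data(z, 0, st.embed_order)
    for t in range(T):
        zg_new = _generalized_data(z, t, st.embed_order)
        for j in range(st.n_inner):
            # data ramps linearly across the inter-sample window (causal:
            # the window ending at sample t uses samples <= t only)
            frac = (j + 1) / st.n_inner
            zg = (1.0 - frac) * zg_prev + frac * zg_new
            e = fw.errors(mu, zg)
            free_action += dt * 0.5 * float(e @ fw.weighted(e))
            fw.update_jacobian()
            we = fw.weighted(e)
            grad = fw.Ejac.T @ we
            PiE = np.empty_like(fw.Ejac)
            for err, pi_key in (
                ("o", "v1"),
                ("h1", "x1"),
                ("c2", "v2"),
                ("h2x", "x2"),
                ("h2y", "x2"),
            ):
                d = fw.err_dim[err]
                start = fw.eoff[err]
                block = fw.Ejac[start : start + d * b].reshape(b, d, M)
                PiE[start : start + d * b] = (
                    fw.pi[pi_key] * np.tensordot(fw.R, block, axes=(1, 0))
                ).reshape(b * d, M)
            H = fw.Ejac.T @ PiE
            rhs = fw.Dmat @ mu - grad
            A = Idt - fw.Dmat + H
            mu = mu + np.linalg.solve(A, rhs)
        if not np.all(np.isfinite(mu)) or np.max(np.abs(mu)) > st.divergence_bound:
            raise InferenceDivergence(
                f"state norm exceeded {st.divergence_bound} at sample {t}",
                snapshot(t),
            )
        # record order-0 modes and precision-weighted squared errors at the
        # end of the sample window
        e = fw.errors(mu, zg_new)
        rec["mu_x1"][:, t] = mu[fw.sl("x1", 0)]
        rec["mu_x2"][:, t] = mu[fw.sl("x2", 0)]
        rec["mu_y2"][:, t] = mu[fw.sl("y2", 0)]
        rec["mu_v2"][:, t] = mu[fw.sl("v2", 0)]
        errs["err_v1"][t] = fw.pi["v1"] * np.sum(e[fw.esl("o", 0)] ** 2)
        errs["err_x1"][t] = fw.pi["x1"] * np.sum(e[fw.esl("h1", 0)] ** 2)
        errs["err_v2"][t] = fw.pi["v2"] * np.sum(e[fw.esl("c2", 0)] ** 2)
        errs["err_x2"][t] = fw.pi["x2"] * (
            np.sum(e[fw.esl("h2x", 0)] ** 2) + np.sum(e[fw.esl("h2y", 0)] ** 2)
        )
        zg_prev = zg_new
        if collect_param_stats:
            d = fw.err_dim["h1"]
            start = fw.eoff["h1"]
            eh1 = e[start : start + d * b].reshape(b, d)
            we_h1 = fw.pi["x1"] * (fw.R @ eh1)
            Vb = np.stack([mu[fw.sl("v2", k)] for k in range(b)])
            G_acc += fw.kg * (we_h1.T @ Vb)
            H_acc += fw.kg**2 * fw.pi["x1"] * (Vb.T @ fw.R @ Vb)

    traj = snapshot(T)
    traj.free_action = free_action
    if H is not None:
        # crude conditional-covariance diagnostic: inverse curvature of the
        # final step, order-0 diagonal per level
        Sigma = np.linalg.inv(H + Idt)
        dg = np.diag(Sigma)
        traj.cov_diag = {
            "x1": dg[fw.sl("x1", 0)].copy(),
            "v2": dg[fw.sl("v2", 0)].copy(),
            "x2": dg[fw.sl("x2", 0)].copy(),
            "y2": dg[fw.sl("y2", 0)].copy(),
        }
    if collect_param_stats:
        return traj, (G_acc, H_acc)
    return traj


def error_summary(pt: PosteriorTrajectory, score: str = "v1") -> dict:
    """Time-summed precision-weighted squared errors per level + a score.

    ``score`` selects the scalar used for classification: "x2"
    (second-level hidden, the default), "v1", "x1", "v2", or "all".
    """
    totals = {
        "v1": float(np.sum(pt.err_v1)),
        "x1": float(np.sum(pt.err_x1)),
        "v2": float(np.sum(pt.err_v2)),
        "x2": float(np.sum(pt.err_x2)),
    }
    totals["all"] = sum(totals.values())
    if score not in totals:
        raise ValueError(f"unknown score '{score}'")
    totals["score"] = totals[score]
    return totals


def recognition_accuracy(baseline_err: float, test_err: float) -> float:
    """Percent error reduction relative to a baseline condition.

    100 * (baseline - test) / baseline; the convention used to map
    prediction errors onto a recognition-accuracy scale.
    """
    if baseline_err <= 0:
        raise ValueError("baseline error must be positive")
    return 100.0 * (baseline_err - test_err) / baseline_err


def learn_feedback(
    m: GenerativeModel,
    pc: PrecisionConfig,
    z,
    max_reps: int = 16,
    tol: float = 0.02,
    settings: Optional[InferenceSettings] = None,
) -> LearningRecord:
    """Learn the feedback weights I across repetitions of one stimulus.

    Each repetition filters the whole presentation with parameters fixed,
    accumulating the free-action gradient and Gauss-Newton curvature with
    respect to I; after the presentation, I receives one natural update
    shrunk by the parameter prior precision.  Stops when the accumulated
    precision-weighted error drops by less than ``tol`` (relative)
    between repetitions, or at ``max_reps``.  ``m.fb.I`` is updated in
    place; the record holds a copy after every repetition.
    """
    if pc.logpi_v1 - pc.logpi_x1 < 2.0:
        warnings.warn(
            "precision configuration has a low sensory/internal ratio; "
            "feedback learning may stall",
            stacklevel=2,
        )
    record = LearningRecord(I_history=[], error_curve=[], converged_at=None)
    prev_err = None
    for rep in range(1, max_reps + 1):
        traj, (G, Hv) = infer_states(
            m, pc, z, settings=settings, collect_param_stats=True
        )
        # accumulated level-1 dynamics prediction error: the component of
        # free action the feedback-weight gradient acts on (the sensory
        # series carries an I-independent tracking floor)
        err = error_summary(traj)["x1"]
        ridge = np.exp(pc.logpi_param) * np.eye(m.shc.N)
        dI = np.linalg.solve(Hv + ridge, G.T).T
        m.fb.I = m.fb.I + dI
        record.I_history.append(m.fb.I.copy())
        record.error_curve.append(err)
        if prev_err is not None and prev_err > 0:
            if (prev_err - err) / prev_err < tol:
                record.converged_at = rep
                break
        prev_err = err
    return record
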