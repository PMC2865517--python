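"""Unscented Kalman filter with joint state-and-parameter augmentation.

The filter follows the plain-average formulation: 2D equally weighted sigma
points at x_bar +/- rows of sqrt(D*P) (no central point, no scaling
parameters), prediction by propagating every point through the model
dynamics over one observation interval (10 RK4 substeps by default), and a
measurement update that by default redraws sigma points from the prior
before computing the innovation and cross covariances.  Tracked parameters
are appended to the state with trivial dynamics; positivity-constrained
parameters are carried in log space.

The generic components (:func:`sigma_points`, :func:`predict`,
:func:`measurement_update`) accept arbitrary Python transition/observation
callables and are checked against the closed-form Kalman recursion on
linear-Gaussian benchmarks; :func:`run_filter` binds them to the compiled
neuron-model propagators for production runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import _kernels as K
from .biophysics import (CellParams, MicroenvParams, SynapseParams, pack_params)
from .errors import ConfigError, FilterDivergenceError, NeuroassimError
from .simulate import CELL_COLUMNS, PAIR_COLUMNS, StimulusProtocol, TraceRecord

__all__ = [
    "GaussianBelief", "SigmaSet", "NoiseSpec", "AugmentedStateSpec",
    "FilterResult", "sigma_points", "predict", "measurement_update",
    "condition_covariance", "run_filter", "augment", "default_process_noise",
]


@dataclass
class GaussianBelief:
    """Mean and covariance of the filter's Gaussian state approximation."""
    mean: np.ndarray
    cov: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ConfigError("covariance shape does not match mean length")

    @property
    def dim(self) -> int:
        return self.mean.size

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


@dataclass
class SigmaSet:
    """2D equally weighted sigma points (rows), weights implicitly 1/(2D)."""
    points: np.ndarray

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def mean(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def cov(self) -> np.ndarray:
        d = self.points - self.mean()
        return d.T @ d / self.n


@dataclass
class NoiseSpec:
    """Process covariance Q (D x D or diagonal vector) and measurement variance R."""
    Q: np.ndarray
    R: float

    def q_matrix(self, dim: int) -> np.ndarray:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim == 1:
            if Q.size != dim:
                raise ConfigError(f"diagonal Q has size {Q.size}, expected {dim}")
            return np.diag(Q)
        if Q.shape != (dim, dim):
            raise ConfigError(f"Q shape {Q.shape} does not match dimension {dim}")
        return Q


def condition_covariance(P: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Symmetrize and floor the spectrum at ``jitter * trace(P)/D``."""
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise FilterDivergenceError("covariance contains non-finite entries")
    P = 0.5 * (P + P.T)
    floor = jitter * max(np.trace(P), 0.0) / P.shape[0]
    w, V = np.linalg.eigh(P)
    if w[0] >= floor:
        return P
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _sqrt_dp(P: np.ndarray, dim: int) -> np.ndarray:
    """Matrix square root of D*P: Cholesky, eigendecomposition fallback."""
    A = dim * P
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(0.5 * (A + A.T))
        if w[-1] <= 0 or not np.all(np.isfinite(w)):
            raise FilterDivergenceError("matrix square root failed: covariance "
                                        "not positive definite after conditioning")
        return V @ np.diag(np.sqrt(np.maximum(w, 0.0)))


def sigma_points(belief: GaussianBelief) -> SigmaSet:
    """The 2D points x_bar +/- columns of sqrt(D*P); moments match exactly."""
    D = belief.dim
    S = _sqrt_dp(belief.cov, D)
    pts = np.empty((2 * D, D))
    pts[:D] = belief.mean + S.T
    pts[D:] = belief.mean - S.T
    return SigmaSet(pts)


def predict(belief: GaussianBelief, transition: Callable[[np.ndarray], np.ndarray],
            Q: np.ndarray) -> tuple[GaussianBelief, SigmaSet]:
    """Propagate the belief through one step of the dynamics.

    ``transition`` maps a sigma-point matrix (rows = points) to its
    propagated matrix.  Prior mean is the plain average of the propagated
    points; prior covariance their scatter plus Q.
    """
    sig = sigma_points(belief)
    pts = transition(np.array(sig.points))
    if not np.all(np.isfinite(pts)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(pts), axis=1))[0])
        raise FilterDivergenceError(f"sigma point {bad} diverged during prediction")
    prop = SigmaSet(pts)
    mean = prop.mean()
    cov = prop.cov() + np.asarray(Q, dtype=float)
    return GaussianBelief(mean, cov, belief.labels), prop


def measurement_update(prior: GaussianBelief, propagated: SigmaSet,
                       observe: Callable[[np.ndarray], np.ndarray], R: float,
                       y: float, redraw: bool = True,
                       jitter: float = 1e-10) -> tuple[GaussianBelief, np.ndarray, float]:
    """Scalar-observation update; returns (posterior, gain, predicted y).

    With ``redraw`` (default, matching the reference formulation) fresh sigma
    points are drawn from the conditioned prior before transforming through
    the observation function; switching it off reuses the propagated points.
    """
    if not np.isfinite(y):
        raise ConfigError("observation must be finite")
    prior_cov = condition_covariance(prior.cov, jitter)
    prior = replace(prior, cov=prior_cov)
    sig = sigma_points(prior) if redraw else propagated
    ys = np.asarray(observe(sig.points), dtype=float).ravel()
    y_pred = ys.mean()
    dy = ys - y_pred
    dx = sig.points - (prior.mean if redraw else sig.mean())
    P_yy = float(dy @ dy) / sig.n + R
    if P_yy <= 0 or not np.isfinite(P_yy):
        raise FilterDivergenceError(f"singular innovation covariance P_yy={P_yy}")
    P_xy = dx.T @ dy / sig.n
    gain = P_xy / P_yy
    mean = prior.mean + gain * (y - y_pred)
    cov = prior_cov - np.outer(gain, gain) * P_yy
    return GaussianBelief(mean, cov, prior.labels), gain, y_pred


# ---------------------------------------------------------------------------
# model binding

_LOG_DEFAULT = {  # parameters carried in log space unless configured otherwise
    "rho", "G_glia", "epsilon", "K_bath", "alpha_m", "g_Na", "g_K", "g_AHP",
    "g_KL", "g_NaL", "g_ClL", "g_Ca", "g_exc", "g_inh", "delta",
}

# name -> (home, slot); home 0 = cell/PC vector, 1 = IN vector, 2 = synapse
_PARAM_SLOTS = {
    "g_Na": (0, K.P_GNA), "g_K": (0, K.P_GK), "g_AHP": (0, K.P_GAHP),
    "g_KL": (0, K.P_GKL), "g_NaL": (0, K.P_GNAL), "g_ClL": (0, K.P_GCLL),
    "g_Ca": (0, K.P_GCA), "rho": (0, K.P_RHO), "G_glia": (0, K.P_GGLIA),
    "epsilon": (0, K.P_EPS), "K_bath": (0, K.P_KBATH), "delta": (0, K.P_DELTA),
    "alpha_m": (0, K.P_ALPHA_M),
    "g_exc": (2, K.S_GEXC), "g_inh": (2, K.S_GINH),
}


@dataclass
class AugmentedStateSpec:
    """Maps between the belief vector and the model structures.

    The belief vector is [dynamic variables..., transformed parameters...].
    ``model`` is one of ``pc_full``, ``pc_fixed_ions``, ``pc_crippled`` or
    ``pair``; tracked parameters must name a slot in the cell, interneuron or
    synapse parameter vectors.
    """
    model: str
    dynamic_labels: tuple[str, ...]
    tracked_parameters: tuple[str, ...]
    transforms: tuple[str, ...]               # 'identity' | 'log', per parameter
    p_cell: np.ndarray                        # packed PC (or single-cell) params
    p_in: np.ndarray | None = None
    p_syn: np.ndarray | None = None
    base_state: np.ndarray = None             # values for non-belief components
    observed_label: str = "V"
    dt: float = 0.01
    n_substeps: int = 10

    def __post_init__(self):
        labels = self.dynamic_labels + self.tracked_parameters
        if len(set(labels)) != len(labels):
            raise ConfigError("belief component labels must be unique")
        all_cols = PAIR_COLUMNS if self.model == "pair" else CELL_COLUMNS
        for lab in self.dynamic_labels:
            if lab not in all_cols:
                raise ConfigError(f"unknown dynamic variable {lab!r}")
        for name in self.tracked_parameters:
            if name not in _PARAM_SLOTS:
                raise ConfigError(f"unknown tracked parameter {name!r}; "
                                  f"known: {sorted(_PARAM_SLOTS)}")
        if self.base_state is None:
            self.base_state = np.zeros(len(all_cols))
        self._columns = all_cols
        self._dyn_idx = np.array([all_cols.index(l) for l in self.dynamic_labels],
                                 dtype=np.int64)
        self._par_home = np.array([_PARAM_SLOTS[n][0] for n in self.tracked_parameters],
                                  dtype=np.int64)
        self._par_idx = np.array([_PARAM_SLOTS[n][1] for n in self.tracked_parameters],
                                 dtype=np.int64)
        self._par_tf = np.array([1 if t == "log" else 0 for t in self.transforms],
                                dtype=np.int64)
        self._obs_idx = list(self.dynamic_labels).index(self.observed_label)
        # valid-region box for the dynamic part of the belief mean
        if self.model == "pair":
            full_lo = np.concatenate([K.CELL_LO, K.CELL_LO, K.SYN_LO])
            full_hi = np.concatenate([K.CELL_HI, K.CELL_HI, K.SYN_HI])
        else:
            full_lo, full_hi = K.CELL_LO, K.CELL_HI
        self._lo = full_lo[self._dyn_idx]
        self._hi = full_hi[self._dyn_idx]

    def clamp_mean(self, mean: np.ndarray) -> np.ndarray:
        """Project the dynamic components of a belief mean onto the valid box."""
        nd = len(self.dynamic_labels)
        mean[:nd] = np.clip(mean[:nd], self._lo, self._hi)
        return mean

    @property
    def dim(self) -> int:
        return len(self.dynamic_labels) + len(self.tracked_parameters)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.dynamic_labels + self.tracked_parameters

    # -- assemble/disassemble -------------------------------------------------
    def assemble(self, state_values: dict[str, float],
                 param_values: dict[str, float]) -> np.ndarray:
        """Build a belief vector from physical values (applies transforms)."""
        x = np.empty(self.dim)
        for i, lab in enumerate(self.dynamic_labels):
            x[i] = state_values[lab]
        nd = len(self.dynamic_labels)
        for j, name in enumerate(self.tracked_parameters):
            v = param_values[name]
            if self._par_tf[j] == 1:
                if v <= 0:
                    raise ConfigError(f"log-transformed parameter {name} must be > 0")
                v = np.log(v)
            x[nd + j] = v
        return x

    def disassemble(self, x: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
        """Invert :meth:`assemble`: belief vector -> physical values."""
        nd = len(self.dynamic_labels)
        states = {lab: float(x[i]) for i, lab in enumerate(self.dynamic_labels)}
        params = {}
        for j, name in enumerate(self.tracked_parameters):
            v = float(x[nd + j])
            params[name] = float(np.exp(v)) if self._par_tf[j] == 1 else v
        return states, params

    def parameter_values(self, x: np.ndarray) -> dict[str, float]:
        return self.disassemble(x)[1]

    # -- compiled transition over one observation interval --------------------
    def make_transition(self, t0: float) -> Callable[[np.ndarray], np.ndarray]:
        mode = {"pc_full": K.MODE_FULL, "pc_fixed_ions": K.MODE_FIXED_IONS,
                "pc_crippled": K.MODE_CRIPPLED}.get(self.model)

        def transition(points: np.ndarray) -> np.ndarray:
            if self.model == "pair":
                bad = K.propagate_sigma_pair(
                    points, self.base_state, self._dyn_idx, self._par_idx,
                    self._par_tf, self._par_home, self.p_cell, self.p_in,
                    self.p_syn, t0, self.dt, self.n_substeps)
            else:
                bad = K.propagate_sigma_cell(
                    points, self.base_state, self._dyn_idx, self._par_idx,
                    self._par_tf, self.p_cell, t0, self.dt, self.n_substeps, mode)
            if bad >= 0:
                points[bad] = np.nan
            return points

        return transition

    def observe(self, points: np.ndarray) -> np.ndarray:
        return points[..., self._obs_idx]


def augment(model: str, tracked_parameters: Sequence[str] = (),
            transforms: dict[str, str] | None = None,
            cell: CellParams | None = None, env: MicroenvParams | None = None,
            in_cell: CellParams | None = None, in_env: MicroenvParams | None = None,
            syn: SynapseParams | None = None,
            protocol: StimulusProtocol | None = None,
            pinned_ions: tuple[float, float] = (4.0, 18.0),
            dt: float = 0.01, n_substeps: int = 10,
            observed: str = "pc") -> AugmentedStateSpec:
    """Build the augmented-state specification for a filter run.

    For the fixed-ion variant the concentrations are pinned at
    ``pinned_ions`` = ([K]_o, [Na]_i) (physiologically normal 4 and 18 mM)
    and leave the belief vector.  Transforms default to log for
    positivity-constrained parameters, identity otherwise.
    """
    tracked = tuple(tracked_parameters)
    tf_map = transforms or {}
    tfs = tuple(tf_map.get(n, "log" if n in _LOG_DEFAULT else "identity")
                for n in tracked)
    cell = cell or CellParams()
    env = env or MicroenvParams()
    if protocol is None:
        p_cell = pack_params(cell, env)
    else:
        p_cell = pack_params(cell, env, stim_amp=protocol.amplitude,
                             stim_onset=protocol.onset_ms,
                             stim_duration=protocol.duration_ms)

    if model == "pair":
        in_cell = in_cell or CellParams.interneuron()
        in_env = in_env or env
        p_in = pack_params(in_cell, in_env)
        p_syn = (syn or SynapseParams()).to_array()
        dyn = PAIR_COLUMNS
        obs_label = "pc_V" if observed == "pc" else "in_V"
        return AugmentedStateSpec(model, dyn, tracked, tfs, p_cell, p_in, p_syn,
                                  observed_label=obs_label, dt=dt,
                                  n_substeps=n_substeps)
    if model == "pc_fixed_ions":
        dyn = ("V", "m", "h", "n", "Ca_i")
        base = np.zeros(len(CELL_COLUMNS))
        base[CELL_COLUMNS.index("K_o")] = pinned_ions[0]
        base[CELL_COLUMNS.index("Na_i")] = pinned_ions[1]
        return AugmentedStateSpec(model, dyn, tracked, tfs, p_cell,
                                  base_state=base, dt=dt, n_substeps=n_substeps)
    if model in ("pc_full", "pc_crippled"):
        dyn = CELL_COLUMNS
        return AugmentedStateSpec(model, dyn, tracked, tfs, p_cell,
                                  dt=dt, n_substeps=n_substeps)
    raise ConfigError(f"unknown model variant {model!r}")


def default_process_noise(spec: AugmentedStateSpec,
                          param_q: float = 1e-3,
                          fast_param_q: dict[str, float] | None = None) -> np.ndarray:
    """Diagonal process noise tuned to the component type (per 0.1 ms step).

    Voltage gets the largest floor (it moves tens of mV per step during a
    spike), gates and concentrations small floors, tracked parameters a
    random-walk variance ``param_q`` (in transformed space) that can be
    raised per-parameter for genuinely time-varying targets.
    """
    q = np.empty(spec.dim)
    for i, lab in enumerate(spec.dynamic_labels):
        if lab.endswith("V"):
            q[i] = 1e-2
        elif lab.endswith(("m", "h", "n")) or lab.startswith(("s_", "eta")) \
                or lab.endswith(("s_p", "s_i", "eta_p", "eta_i")):
            q[i] = 1e-6
        elif "Ca" in lab:
            q[i] = 1e-8
        else:  # concentrations
            q[i] = 1e-7
    nd = len(spec.dynamic_labels)
    fast = fast_param_q or {}
    for j, name in enumerate(spec.tracked_parameters):
        q[nd + j] = fast.get(name, param_q)
    return q


@dataclass
class FilterResult:
    """Posterior trajectory of one assimilation run."""
    time: np.ndarray
    means: np.ndarray               # (n_obs, D) posterior means (belief space)
    marginal_sd: np.ndarray         # (n_obs, D)
    innovations: np.ndarray         # y - y_pred
    predicted_obs: np.ndarray       # a-priori predicted measurement
    gain_norms: np.ndarray
    spec: AugmentedStateSpec
    observations: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, label: str) -> np.ndarray:
        """Posterior mean of one component, back-transformed to physical units."""
        idx = self.spec.labels.index(label)
        nd = len(self.spec.dynamic_labels)
        col = self.means[:, idx]
        if idx >= nd and self.spec._par_tf[idx - nd] == 1:
            return np.exp(col)
        return col

    def to_frame(self):
        import pandas as pd
        data = {lab: self[lab] for lab in self.spec.labels}
        df = pd.DataFrame(data, index=pd.Index(self.time, name="time_ms"))
        df["innovation"] = self.innovations
        df["predicted_obs"] = self.predicted_obs
        return df


def run_filter(spec: AugmentedStateSpec, trace: TraceRecord, noise: NoiseSpec,
               init: GaussianBelief, redraw: bool = True, jitter: float = 1e-10,
               raise_on_divergence: bool = True) -> FilterResult:
    """Iterate predict + measurement update over every observation.

    The transition integrates the model across one observation interval
    (``spec.n_substeps`` RK4 substeps of ``spec.dt``).  On mid-run divergence
    a partial result is attached to the raised error.
    """
    if init.dim != spec.dim:
        raise ConfigError(f"initial belief has dimension {init.dim}, "
                          f"spec requires {spec.dim}")
    n_obs = len(trace)
    interval = trace.interval
    n_sub = int(round(interval / spec.dt))
    if abs(n_sub * spec.dt - interval) > 1e-9 or n_sub < 1:
        raise ConfigError("observation interval must be an integer multiple of dt")
    spec = replace(spec, n_substeps=n_sub)

    D = spec.dim
    Q = noise.q_matrix(D)
    belief = GaussianBelief(init.mean.copy(),
                            condition_covariance(init.cov, jitter), spec.labels)
    means = np.empty((n_obs, D))
    sds = np.empty((n_obs, D))
    innov = np.empty(n_obs)
    ypred = np.empty(n_obs)
    gains = np.empty(n_obs)

    k = 0
    try:
        for k in range(n_obs):
            t0 = trace.time[k] - interval  # propagate from previous obs time
            transition = spec.make_transition(t0)
            prior, propagated = predict(belief, transition, Q)
            prior = replace(prior, cov=condition_covariance(prior.cov, jitter))
            belief, gain, yp = measurement_update(
                prior, propagated, spec.observe, noise.R, float(trace.v[k]),
                redraw=redraw, jitter=jitter)
            spec.clamp_mean(belief.mean)
            means[k] = belief.mean
            sds[k] = belief.marginal_sd()
            ypred[k] = yp
            innov[k] = trace.v[k] - yp
            gains[k] = float(np.linalg.norm(gain))
    except NeuroassimError as exc:
        partial = FilterResult(trace.time[:k], means[:k], sds[:k], innov[:k],
                               ypred[:k], gains[:k], spec, trace.v[:k],
                               meta={"diverged_at_ms": float(trace.time[k])})
        if raise_on_divergence:
            raise FilterDivergenceError(
                f"filter diverged at t={trace.time[k]:.2f} ms: {exc}",
                partial=partial) from exc
        return partial

    return FilterResult(trace.time.copy(), means, sds, innov, ypred, gains,
                        spec, trace.v.copy(),
                        meta={"redraw": redraw, "R": noise.R})
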