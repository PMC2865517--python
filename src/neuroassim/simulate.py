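"""Fixed-step integration, stimulus protocols and synthetic-recording fixtures.

The fixtures replace whole-cell recordings in twin experiments: the model
generates a ground-truth trajectory, the membrane potential is subsampled at
the observation interval and corrupted with i.i.d. Gaussian noise, and every
hidden variable plus the full generating parameter set ride along so that
reconstruction quality can be scored.

Shipped presets:

* ``spiking_pc`` — a single pyramidal cell in a physiological
  microenvironment, driven by a 100 pA current pulse lasting 1 s, producing
  repetitive spiking (the conversion from pA to current density goes through
  the same 7 um spherical-cell geometry that sets gamma).
* ``seizure`` — a single PC with weakened glial buffering and slowed bath
  exchange, producing spontaneous seizure-like episodes during which [K]_o
  climbs from its ~3 mM baseline to ~7 mM and back.
* ``pair`` — a synaptically and diffusively coupled PC-IN pair in which the
  interneuron enters depolarization block (chi(eta_i) -> 0), releasing the
  PC into intense firing.

All randomness is seeded; identical (preset, seed, dt) gives bit-identical
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import _kernels as K
from .biophysics import (CellParams, CellState, MicroenvParams, NetworkState,
                         SynapseParams, pack_params, resting_state,
                         stim_density_from_pA)
from .errors import ConfigError, DivergenceError, NoSeizureRegimeError

__all__ = [
    "StimulusProtocol", "Trajectory", "TraceRecord", "integrate",
    "integrate_cell_model", "integrate_pair_model", "make_observations",
    "spiking_pc_fixture", "seizure_fixture", "coupled_pair_fixture",
    "spike_times", "firing_rate", "detect_episodes",
    "SEIZURE_PRESET", "PAIR_PRESET", "CELL_COLUMNS", "PAIR_COLUMNS",
]

CELL_COLUMNS = ("V", "m", "h", "n", "Ca_i", "K_o", "Na_i")
PAIR_COLUMNS = tuple(f"pc_{c}" for c in CELL_COLUMNS) + \
    tuple(f"in_{c}" for c in CELL_COLUMNS) + ("s_p", "eta_p", "s_i", "eta_i")

DEFAULT_DT_MS = 0.01
DEFAULT_OBS_INTERVAL_MS = 0.1
DEFAULT_NOISE_SD_MV = 0.5


@dataclass
class StimulusProtocol:
    """A rectangular current injection.

    ``amplitude`` is a current density in uA/cm^2; use :meth:`from_pA` to
    convert a pipette current through the documented cell geometry
    (100 pA over a 7 um sphere ~ 16.2 uA/cm^2).
    """
    amplitude: float = 0.0
    onset_ms: float = 0.0
    duration_ms: float = 0.0

    def __post_init__(self):
        if self.duration_ms < 0:
            raise ConfigError("stimulus duration must be non-negative")

    @classmethod
    def from_pA(cls, current_pA: float, onset_ms: float, duration_ms: float,
                radius_um: float = 20.0) -> "StimulusProtocol":
        """Pipette current to density over the cell's whole membrane.

        The default 20 um effective radius represents the total somatodendritic
        membrane a patch current spreads over; it is deliberately larger than
        the 7 um somatic micro-domain radius that sets gamma (100 pA -> ~2
        uA/cm^2, which drives regular repetitive spiking without potassium
        runaway).
        """
        return cls(stim_density_from_pA(current_pA, radius_um), onset_ms, duration_ms)


@dataclass
class Trajectory:
    """A uniformly sampled state history with labelled columns."""
    time: np.ndarray            # [ms]
    states: np.ndarray          # (n_times, n_vars)
    columns: tuple[str, ...]
    dt: float                   # sampling step of `time` [ms]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.time) != len(self.states):
            raise ConfigError("time and state lengths differ")
        if not np.all(np.isfinite(self.states)):
            raise DivergenceError("trajectory contains non-finite entries")

    def __getitem__(self, column: str) -> np.ndarray:
        return self.states[:, self.columns.index(column)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.states, index=pd.Index(self.time, name="time_ms"),
                            columns=list(self.columns))


@dataclass
class TraceRecord:
    """An observed (noisy, subsampled) voltage trace, plus optional truth."""
    time: np.ndarray            # [ms]
    v: np.ndarray               # observed V [mV]
    noise_sd: float
    seed: int | None = None
    truth: Trajectory | None = None     # aligned hidden-truth trajectory
    observed: str = "pc"                # which cell the electrode is in
    meta: dict = field(default_factory=dict)

    @property
    def interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# integrators

def integrate(rhs: Callable, y0, duration_ms: float, dt: float,
              protocol: StimulusProtocol | None = None) -> Trajectory:
    """Generic fixed-step RK4 for an arbitrary ``rhs(t, y)`` callable.

    Used for small benchmark systems and convergence checks; the neuron
    models go through the compiled integrators below.  A stimulus protocol,
    if given, is passed to the rhs as a third argument (the current).
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    y = np.atleast_1d(np.asarray(y0, dtype=float)).copy()
    n = int(round(duration_ms / dt))
    out = np.empty((n + 1, y.size))
    out[0] = y
    tgrid = np.arange(n + 1) * dt

    def f(t, y):
        if protocol is not None:
            amp = protocol.amplitude if (protocol.onset_ms <= t <
                                         protocol.onset_ms + protocol.duration_ms) else 0.0
            return np.asarray(rhs(t, y, amp), dtype=float)
        return np.asarray(rhs(t, y), dtype=float)

    for i in range(n):
        t = i * dt
        k1 = f(t, y)
        if not np.all(np.isfinite(k1)):
            raise DivergenceError("rhs non-finite", last_valid_time_ms=t)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise DivergenceError("state non-finite", last_valid_time_ms=t)
        out[i + 1] = y
    cols = tuple(f"y{i}" for i in range(y.size))
    return Trajectory(tgrid, out, cols, dt)


def integrate_cell_model(state0: CellState, cell: CellParams, env: MicroenvParams,
                         duration_ms: float, dt: float = DEFAULT_DT_MS,
                         protocol: StimulusProtocol | None = None,
                         stride: int = 10, variant: str = "full",
                         alpha_m_const: float = 0.0, t0: float = 0.0) -> Trajectory:
    """Compiled RK4 trajectory of a single cell, sampled every ``stride`` steps."""
    from .biophysics import VALID_VARIANTS, _MODE
    if variant not in VALID_VARIANTS:
        raise ConfigError(f"unknown model variant {variant!r}")
    if protocol is None:
        p = pack_params(cell, env, alpha_m_const=alpha_m_const)
    else:
        p = pack_params(cell, env, stim_amp=protocol.amplitude,
                        stim_onset=protocol.onset_ms,
                        stim_duration=protocol.duration_ms,
                        alpha_m_const=alpha_m_const)
    n = int(round(duration_ms / dt))
    n = (n // stride) * stride
    out, n_ok = K.integrate_cell(state0.to_array(), p, t0, dt, n, stride, _MODE[variant])
    if n_ok != n:
        raise DivergenceError(
            f"single-cell integration diverged (|V|>150 mV or non-finite)",
            last_valid_time_ms=t0 + n_ok * dt)
    tgrid = t0 + np.arange(out.shape[0]) * dt * stride
    return Trajectory(tgrid, out, CELL_COLUMNS, dt * stride,
                      meta={"dt_model": dt, "variant": variant})


def integrate_pair_model(net0: NetworkState, pc_cell: CellParams, pc_env: MicroenvParams,
                         in_cell: CellParams, in_env: MicroenvParams,
                         syn: SynapseParams, duration_ms: float,
                         dt: float = DEFAULT_DT_MS, stride: int = 10,
                         t0: float = 0.0) -> Trajectory:
    p_pc = pack_params(pc_cell, pc_env)
    p_in = pack_params(in_cell, in_env)
    n = int(round(duration_ms / dt))
    n = (n // stride) * stride
    out, n_ok = K.integrate_pair(net0.to_array(), p_pc, p_in, syn.to_array(),
                                 t0, dt, n, stride)
    if n_ok != n:
        raise DivergenceError("pair integration diverged",
                              last_valid_time_ms=t0 + n_ok * dt)
    tgrid = t0 + np.arange(out.shape[0]) * dt * stride
    return Trajectory(tgrid, out, PAIR_COLUMNS, dt * stride, meta={"dt_model": dt})


# ---------------------------------------------------------------------------
# observations

def make_observations(trajectory: Trajectory, obs_interval_ms: float = DEFAULT_OBS_INTERVAL_MS,
                      noise_sd: float = DEFAULT_NOISE_SD_MV, seed: int | None = 0,
                      column: str = "V") -> TraceRecord:
    """Subsample the voltage column and add i.i.d. Gaussian measurement noise."""
    ratio = obs_interval_ms / trajectory.dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9:
        raise ConfigError(
            f"observation interval {obs_interval_ms} ms is not an integer "
            f"multiple of the trajectory step {trajectory.dt} ms")
    idx = np.arange(0, len(trajectory.time), stride)
    t = trajectory.time[idx]
    v_true = trajectory[column][idx]
    rng = np.random.default_rng(seed)
    v = v_true + rng.normal(0.0, noise_sd, size=v_true.shape) if noise_sd > 0 \
        else v_true.copy()
    truth = Trajectory(t, trajectory.states[idx], trajectory.columns,
                       obs_interval_ms, dict(trajectory.meta))
    observed = "in" if column.startswith("in_") else "pc"
    return TraceRecord(time=t, v=v, noise_sd=noise_sd, seed=seed, truth=truth,
                       observed=observed, meta=dict(trajectory.meta))


# ---------------------------------------------------------------------------
# event detection

def spike_times(time: np.ndarray, v: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Times of upward threshold crossings (default 0 mV)."""
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return time[idx]

def firing_rate(time: np.ndarray, v: np.ndarray, window_ms: float = 500.0,
                threshold: float = 0.0) -> np.ndarray:
    """Sliding-window firing rate (Hz) on the trace's own time grid."""
    st = spike_times(time, v, threshold)
    counts = np.searchsorted(st, time + window_ms / 2) - \
        np.searchsorted(st, time - window_ms / 2)
    return counts / (window_ms / 1000.0)


def detect_episodes(time: np.ndarray, v: np.ndarray, rate_on_hz: float = 15.0,
                    rate_off_hz: float = 5.0, window_ms: float = 500.0,
                    min_duration_ms: float = 500.0) -> list[tuple[float, float]]:
    """Seizure-like episode intervals from the firing rate, with hysteresis.

    An episode starts when the sliding-window rate exceeds ``rate_on_hz`` and
    ends when it falls below ``rate_off_hz``.
    """
    rate = firing_rate(time, v, window_ms)
    episodes = []
    start = None
    for i, r in enumerate(rate):
        if start is None and r >= rate_on_hz:
            start = time[i]
        elif start is not None and r <= rate_off_hz:
            if time[i] - start >= min_duration_ms:
                episodes.append((start, time[i]))
            start = None
    if start is not None and time[-1] - start >= min_duration_ms:
        episodes.append((start, time[-1]))
    return episodes


# ---------------------------------------------------------------------------
# fixtures

def spiking_pc_fixture(seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD_MV,
                       dt: float = DEFAULT_DT_MS,
                       obs_interval_ms: float = DEFAULT_OBS_INTERVAL_MS,
                       pre_ms: float = 200.0, stim_ms: float = 1000.0,
                       post_ms: float = 300.0,
                       current_pA: float = 100.0) -> tuple[Trajectory, TraceRecord]:
    """Current-injected spiking pyramidal cell in a physiological bath.

    A 100 pA pulse lasting 1 s (after ``pre_ms`` of rest) produces
    repetitive spiking; observations are V every 0.1 ms with Gaussian noise.
    """
    cell = CellParams()
    env = MicroenvParams()
    proto = StimulusProtocol.from_pA(current_pA, onset_ms=pre_ms, duration_ms=stim_ms)
    state0 = resting_state(cell, env, polish=False)
    stride = int(round(obs_interval_ms / dt))
    traj = integrate_cell_model(state0, cell, env, pre_ms + stim_ms + post_ms,
                                dt, proto, stride=stride)
    traj.meta.update(preset="spiking_pc", seed=seed, noise_sd=noise_sd,
                     stim_amplitude=proto.amplitude, stim_onset=proto.onset_ms,
                     stim_duration=proto.duration_ms, current_pA=current_pA,
                     cell=vars(cell).copy(), env=vars(env).copy())
    rec = make_observations(traj, obs_interval_ms, noise_sd, seed)
    return traj, rec


#: Spontaneous recurrent seizure regime for a single PC, from a coarse scan
#: over (G_glia, epsilon, I_dc) documented in docs/methods.md: physiological
#: glial strength but limited bath exchange, plus a just-suprarheobase
#: depolarizing bias standing in for the raised excitability of the seizing
#: preparation.  Stronger spike-frequency adaptation (g_AHP) lets the
#: Na_i/pump feedback terminate each episode before depolarization block.
#: ``time_scale`` compresses the slow concentration subsystem for desk-scale
#: runs; the (K_o, Na_i) orbit — interictal baseline ~3.2 mM, episode peak
#: ~6.7 mM — is preserved under this scaling (see docs/methods.md).  Episode
#: period ~12.4 s, episode duration ~5.6 s.
SEIZURE_PRESET: dict = {
    "cell": {"I_stim": 2.3, "g_AHP": 0.05},
    "env": {"rho": 1.25, "G_glia": 60.0, "epsilon": 1.3, "K_bath": 3.0,
            "time_scale": 12.0},
}

#: Physiological override that switches the seizure preset back to a quiet cell.
PHYSIOLOGICAL_OVERRIDE: dict = {
    "cell": {"I_stim": 0.0, "g_AHP": 0.01},
    "env": {"rho": 1.25, "G_glia": 66.0, "epsilon": 1.25, "K_bath": 3.0,
            "time_scale": 1.0},
}


def seizure_fixture(params_override: dict | None = None, duration_ms: float = 12000.0,
                    seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD_MV,
                    dt: float = DEFAULT_DT_MS,
                    obs_interval_ms: float = DEFAULT_OBS_INTERVAL_MS,
                    burn_in_ms: float = 20000.0,
                    require_episode: bool = True) -> tuple[Trajectory, TraceRecord]:
    """Spontaneous recurrent seizure-like episodes in a single PC.

    The shipped preset puts the cell in a spontaneous-bursting regime; a
    burn-in of one inter-event period is discarded so the recording starts
    in the periodic regime.  ``params_override`` may carry ``cell`` and
    ``env`` sub-dicts; overriding back to physiological values yields a
    quiet cell and (if ``require_episode``) an explicit no-seizure error.
    """
    override = params_override or {}
    cell_kwargs = {**SEIZURE_PRESET["cell"], **override.get("cell", {})}
    env_kwargs = {**SEIZURE_PRESET["env"], **override.get("env", {})}
    cell = CellParams(**cell_kwargs)
    env = MicroenvParams(**env_kwargs)
    state0 = resting_state(CellParams(), MicroenvParams(), polish=False)
    stride = int(round(obs_interval_ms / dt))
    if burn_in_ms > 0:
        burn = integrate_cell_model(state0, cell, env, burn_in_ms, dt,
                                    stride=int(round(burn_in_ms / dt)))
        state0 = CellState.from_array(burn.states[-1])
    traj = integrate_cell_model(state0, cell, env, duration_ms, dt, stride=stride)
    traj.meta.update(preset="seizure", seed=seed, noise_sd=noise_sd,
                     burn_in_ms=burn_in_ms, cell=vars(cell).copy(),
                     env=vars(env).copy())
    episodes = detect_episodes(traj.time, traj["V"])
    if require_episode and not episodes:
        raise NoSeizureRegimeError(
            "no seizure-like episode detected; the supplied parameters put the "
            "cell in a stable resting regime")
    traj.meta["episodes"] = episodes
    rec = make_observations(traj, obs_interval_ms, noise_sd, seed)
    return traj, rec


#: Coupled PC-IN regime with interneuron depolarization block: the OLM layer's
#: buffering is much weaker than the pyramidal layer's, and the IN is driven
#: harder, so after a brief intense-firing phase it locks into a sustained
#: depolarized state (eta_i -> 1, chi(eta_i) -> 0).  The silenced inhibition
#: releases the PC, whose firing rate roughly quadruples (~16 -> ~65 Hz).
PAIR_PRESET: dict = {
    "pc_cell": {"I_stim": 2.3, "g_AHP": 0.05},
    "in_cell": {"I_stim": 3.1},
    "pc_env": {"rho": 1.25, "G_glia": 10.0, "epsilon": 1.45, "K_bath": 3.0,
               "time_scale": 12.0, "delta": 0.05},
    "in_env": {"rho": 1.25, "G_glia": 2.0, "epsilon": 0.2, "K_bath": 3.0,
               "time_scale": 12.0, "delta": 0.05},
}

def coupled_pair_fixture(params_override: dict | None = None,
                         duration_ms: float = 8000.0, seed: int = 0,
                         noise_sd: float = DEFAULT_NOISE_SD_MV,
                         dt: float = DEFAULT_DT_MS,
                         obs_interval_ms: float = DEFAULT_OBS_INTERVAL_MS,
                         require_block: bool = True,
                         ) -> tuple[Trajectory, TraceRecord, TraceRecord]:
    """PC-IN pair with firing interplay; returns (truth, PC trace, IN trace)."""
    override = params_override or {}
    pc_env = MicroenvParams(**{**PAIR_PRESET["pc_env"], **override.get("pc_env", {})})
    in_env = MicroenvParams(**{**PAIR_PRESET["in_env"], **override.get("in_env", {})})
    syn = SynapseParams(**override.get("syn", {}))
    pc_cell = CellParams(**{**PAIR_PRESET["pc_cell"], **override.get("pc_cell", {})})
    in_cell = CellParams.interneuron(**{**PAIR_PRESET["in_cell"],
                                        **override.get("in_cell", {})})
    rest_pc = resting_state(pc_cell, MicroenvParams(), polish=False)
    rest_in = resting_state(in_cell, MicroenvParams(), polish=False)
    net0 = NetworkState(pc=rest_pc, in_=rest_in)
    stride = int(round(obs_interval_ms / dt))
    traj = integrate_pair_model(net0, pc_cell, pc_env, in_cell, in_env, syn,
                                duration_ms, dt, stride=stride)
    traj.meta.update(preset="pair", seed=seed, noise_sd=noise_sd,
                     pc_env=vars(pc_env).copy(), in_env=vars(in_env).copy(),
                     syn=vars(syn).copy())
    chi = 1.0 / (1.0 + np.exp((traj["eta_i"] - syn.chi_half) / syn.chi_slope))
    traj.meta["block_fraction"] = float(np.mean(chi < 0.05))
    if require_block and traj.meta["block_fraction"] <= 0.0:
        raise NoSeizureRegimeError(
            "no interneuron depolarization block (chi(eta_i) never < 0.05) "
            "with the supplied parameters")
    rec_pc = make_observations(traj, obs_interval_ms, noise_sd, seed, column="pc_V")
    rec_in = make_observations(traj, obs_interval_ms, noise_sd,
                               None if seed is None else seed + 1, column="in_V")
    return traj, rec_pc, rec_in
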