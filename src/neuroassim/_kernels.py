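"""Compiled inner loops: model right-hand sides, RK4 stepping, sigma-point propagation.

Everything here works on flat float64 arrays so numba can compile it once and
the filter can push tens of millions of derivative evaluations through the
model.  The readable, validated API lives in :mod:`neuroassim.biophysics`;
unit tests assert that both agree to machine precision on random states.

State layout (single cell, length 7)::

    0 V      membrane potential          [mV]
    1 m      Na+ activation gate         [-]
    2 h      Na+ inactivation gate       [-]
    3 n      K+ activation gate          [-]
    4 Ca     intracellular Ca2+          [a.u.]
    5 Ko     extracellular K+            [mM]
    6 Nai    intracellular Na+           [mM]

Pair layout (length 18): PC cell (0-6), IN cell (7-13), then the four
synaptic variables s_p, eta_p, s_i, eta_i (14-17).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- parameter-vector slots (one vector per cell) ------------------------------
P_CM = 0        # membrane capacitance          [uF/cm^2]
P_GNA = 1       # transient Na+ conductance     [mS/cm^2]
P_GK = 2        # delayed-rectifier K+          [mS/cm^2]
P_GAHP = 3      # afterhyperpolarization K+     [mS/cm^2]
P_GKL = 4       # K+ leak                       [mS/cm^2]
P_GNAL = 5      # Na+ leak                      [mS/cm^2]
P_GCLL = 6      # Cl- leak                      [mS/cm^2]
P_GCA = 7       # Ca2+ conductance              [mS/cm^2]
P_PHI = 8       # gating time-constant factor   [1/ms]
P_ECA = 9       # fixed Ca2+ reversal           [mV]
P_CLI = 10      # intracellular Cl-             [mM]
P_CLO = 11      # extracellular Cl-             [mM]
P_RHO = 12      # max Na/K pump rate            [mM/s]
P_GGLIA = 13    # max glial buffering rate      [mM/s]
P_EPS = 14      # bath diffusion coefficient    [1/s]
P_KBATH = 15    # reservoir K+                  [mM]
P_BETA = 16     # intra/extracellular volume ratio [-]
P_GAMMA = 17    # current->concentration factor [mM cm^2 / uC]
P_DELTA = 18    # lateral K+ diffusion          [1/s]
P_THERM = 19    # thermal factor in Nernst eq   [mV]
P_STIM_AMP = 20  # stimulus amplitude           [uA/cm^2]
P_STIM_ON = 21   # stimulus onset               [ms]
P_STIM_DUR = 22  # stimulus duration            [ms]
P_ALPHA_M = 23   # crippled-mode alpha_m constant [1/ms]
P_ION_SCALE = 24  # slow-subsystem time-scale factor [-]
NPARAM = 25

# synapse parameter slots
S_GEXC = 0      # AMPA strength (PC->IN)        [mS/cm^2]
S_GINH = 1      # GABA strength (IN->PC)        [mS/cm^2]
S_TAUE = 2      # excitatory s time constant    [ms]
S_TAUI = 3      # inhibitory s time constant    [ms]
S_EEXC = 4      # excitatory reversal           [mV]
S_EINH = 5      # inhibitory reversal           [mV]
S_STHETA = 6    # s_inf half-activation voltage [mV]
S_SSLOPE = 7    # s_inf slope                   [mV]
S_ETHETA = 8    # depol.-block indicator threshold [mV]
S_ESLOPE = 9    # indicator slope               [mV]
S_TAUETA = 10   # eta low-pass time constant    [ms]
S_CHIHALF = 11  # chi gate half point (in eta)  [-]
S_CHISLOPE = 12  # chi gate slope               [-]
NSYN = 13

# model variants
MODE_FULL = 0
MODE_FIXED_IONS = 1
MODE_CRIPPLED = 2

NSTATE_CELL = 7
NSTATE_PAIR = 18

# resting reference concentrations anchoring the electroneutrality identities [mM]
KI_REST = 140.0
NAI_REST = 18.0
NAO_REST = 144.0


@njit(cache=True)
def _xexprel(x):
    """x / (1 - exp(-x)) with its removable singularity filled in at x = 0."""
    if abs(x) < 1e-7:
        return 1.0 + 0.5 * x + x * x / 12.0
    return x / (1.0 - np.exp(-x))


@njit(cache=True)
def gating_rates(V):
    """The six voltage-dependent HH rate constants (alpha_m ... beta_n), 1/ms."""
    am = _xexprel(0.1 * (V + 30.0))
    bm = 4.0 * np.exp(-(V + 55.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 44.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-0.1 * (V + 14.0)))
    an = 0.1 * _xexprel(0.1 * (V + 34.0))
    bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _pump(Nai, Ko, rho):
    return rho / ((1.0 + np.exp((25.0 - Nai) / 3.0)) * (1.0 + np.exp(5.5 - Ko)))


@njit(cache=True)
def _glia(Ko, gglia):
    return gglia / (1.0 + np.exp((18.0 - Ko) / 2.5))


@njit(cache=True)
def cell_rhs(y, p, t, mode, lateral, i_syn, dy):
    """Single-cell derivative (ms time base) written into ``dy``.

    ``lateral`` is the extracellular-K+ exchange term from a neighbour (mM/s,
    already signed); ``i_syn`` a synaptic current (uA/cm^2, positive outward).
    Returns 0 on success, 1 if the state is non-finite / out of range.
    """
    V = y[0]
    m = y[1]
    h = y[2]
    n = y[3]
    Ca = y[4]
    Ko = y[5]
    Nai = y[6]
    if not np.isfinite(V) or abs(V) > 150.0 or Ko <= 0.0 or Nai <= 0.0:
        return 1

    Ki = KI_REST + (NAI_REST - Nai)
    Nao = NAO_REST - p[P_BETA] * (Nai - NAI_REST)
    if Ki <= 0.0 or Nao <= 0.0:
        return 1
    therm = p[P_THERM]
    EK = therm * np.log(Ko / Ki)
    ENa = therm * np.log(Nao / Nai)
    ECl = therm * np.log(p[P_CLI] / p[P_CLO])

    ina_g = p[P_GNA] * m * m * m * h * (V - ENa)
    ina_l = p[P_GNAL] * (V - ENa)
    ik_g = p[P_GK] * n * n * n * n * (V - EK)
    ik_l = p[P_GKL] * (V - EK)
    i_ahp = p[P_GAHP] * (Ca / (1.0 + Ca)) * (V - EK)
    icl_l = p[P_GCLL] * (V - ECl)

    i_stim = 0.0
    if p[P_STIM_ON] <= t < p[P_STIM_ON] + p[P_STIM_DUR]:
        i_stim = p[P_STIM_AMP]

    dy[0] = (-(ina_g + ina_l + ik_g + ik_l + i_ahp + icl_l) + i_stim - i_syn) / p[P_CM]

    am, bm, ah, bh, an, bn = gating_rates(V)
    if mode == MODE_CRIPPLED:
        am = p[P_ALPHA_M]
    phi = p[P_PHI]
    dy[1] = phi * (am * (1.0 - m) - bm * m)
    dy[2] = phi * (ah * (1.0 - h) - bh * h)
    dy[3] = phi * (an * (1.0 - n) - bn * n)

    dy[4] = (-0.002 * p[P_GCA] * (V - p[P_ECA]) / (1.0 + np.exp(-(V + 25.0) / 2.5))
             - Ca / 80.0)

    if mode == MODE_FIXED_IONS:
        dy[5] = 0.0
        dy[6] = 0.0
    else:
        ik_flux = ik_g + ik_l + i_ahp
        ina_flux = ina_g + ina_l
        pump = _pump(Nai, Ko, p[P_RHO])
        glia = _glia(Ko, p[P_GGLIA])
        diff = p[P_EPS] * (Ko - p[P_KBATH])
        beta = p[P_BETA]
        gamma = p[P_GAMMA]
        scale = p[P_ION_SCALE] * 1e-3  # per-second dynamics on the ms time base
        dy[5] = (gamma * beta * ik_flux - 2.0 * beta * pump - glia - diff + lateral) * scale
        dy[6] = (-gamma * ina_flux - 3.0 * pump) * scale
    return 0


@njit(cache=True)
def _chi(eta, half, slope):
    return 1.0 / (1.0 + np.exp((eta - half) / slope))


@njit(cache=True)
def _sigmoid(V, theta, slope):
    return 1.0 / (1.0 + np.exp(-(V - theta) / slope))


@njit(cache=True)
def pair_rhs(y, p_pc, p_in, p_syn, t, dy):
    """Coupled PC-IN derivative (length 18) written into ``dy``."""
    Vp = y[0]
    Vi = y[7]
    sp = y[14]
    etap = y[15]
    si = y[16]
    etai = y[17]

    chi_p = _chi(etap, p_syn[S_CHIHALF], p_syn[S_CHISLOPE])
    chi_i = _chi(etai, p_syn[S_CHIHALF], p_syn[S_CHISLOPE])
    # positive-outward synaptic currents entering each cell's V equation
    i_syn_pc = p_syn[S_GINH] * si * chi_i * (Vp - p_syn[S_EINH])
    i_syn_in = p_syn[S_GEXC] * sp * chi_p * (Vi - p_syn[S_EEXC])

    # lateral extracellular K+ exchange, pairwise conservative (mM/s)
    lat_pc = p_pc[P_DELTA] * (y[12] - y[5])
    lat_in = p_in[P_DELTA] * (y[5] - y[12])

    err = cell_rhs(y[0:7], p_pc, t, MODE_FULL, lat_pc, i_syn_pc, dy[0:7])
    err += cell_rhs(y[7:14], p_in, t, MODE_FULL, lat_in, i_syn_in, dy[7:14])
    if err != 0:
        return 1

    sinf_p = _sigmoid(Vp, p_syn[S_STHETA], p_syn[S_SSLOPE])
    sinf_i = _sigmoid(Vi, p_syn[S_STHETA], p_syn[S_SSLOPE])
    blk_p = _sigmoid(Vp, p_syn[S_ETHETA], p_syn[S_ESLOPE])
    blk_i = _sigmoid(Vi, p_syn[S_ETHETA], p_syn[S_ESLOPE])
    dy[14] = (sinf_p - sp) / p_syn[S_TAUE]
    dy[15] = (blk_p - etap) / p_syn[S_TAUETA]
    dy[16] = (sinf_i - si) / p_syn[S_TAUI]
    dy[17] = (blk_i - etai) / p_syn[S_TAUETA]
    return 0


@njit(cache=True)
def _rk4_cell_step(y, p, t, dt, mode, k1, k2, k3, k4, tmp):
    err = cell_rhs(y, p, t, mode, 0.0, 0.0, k1)
    for i in range(NSTATE_CELL):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    err += cell_rhs(tmp, p, t + 0.5 * dt, mode, 0.0, 0.0, k2)
    for i in range(NSTATE_CELL):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    err += cell_rhs(tmp, p, t + 0.5 * dt, mode, 0.0, 0.0, k3)
    for i in range(NSTATE_CELL):
        tmp[i] = y[i] + dt * k3[i]
    err += cell_rhs(tmp, p, t + dt, mode, 0.0, 0.0, k4)
    if err != 0:
        return 1
    for i in range(NSTATE_CELL):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return 0


@njit(cache=True)
def _rk4_pair_step(y, p_pc, p_in, p_syn, t, dt, k1, k2, k3, k4, tmp):
    err = pair_rhs(y, p_pc, p_in, p_syn, t, k1)
    for i in range(NSTATE_PAIR):
        tmp[i] = y[i] + 0.5 * dt * k1[i]
    err += pair_rhs(tmp, p_pc, p_in, p_syn, t + 0.5 * dt, k2)
    for i in range(NSTATE_PAIR):
        tmp[i] = y[i] + 0.5 * dt * k2[i]
    err += pair_rhs(tmp, p_pc, p_in, p_syn, t + 0.5 * dt, k3)
    for i in range(NSTATE_PAIR):
        tmp[i] = y[i] + dt * k3[i]
    err += pair_rhs(tmp, p_pc, p_in, p_syn, t + dt, k4)
    if err != 0:
        return 1
    for i in range(NSTATE_PAIR):
        y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return 0


@njit(cache=True)
def integrate_cell(y0, p, t0, dt, n_steps, stride, mode):
    """Fixed-step RK4 trajectory of one cell, sampled every ``stride`` steps.

    Returns (out, n_ok) where out[k] is the state after k*stride steps and
    n_ok the number of completed integration steps (== n_steps unless the
    trajectory diverged).
    """
    n_out = n_steps // stride + 1
    out = np.empty((n_out, NSTATE_CELL))
    y = y0.copy()
    k1 = np.empty(NSTATE_CELL)
    k2 = np.empty(NSTATE_CELL)
    k3 = np.empty(NSTATE_CELL)
    k4 = np.empty(NSTATE_CELL)
    tmp = np.empty(NSTATE_CELL)
    out[0] = y
    for step in range(n_steps):
        if _rk4_cell_step(y, p, t0 + step * dt, dt, mode, k1, k2, k3, k4, tmp) != 0:
            return out, step
        if (step + 1) % stride == 0:
            out[(step + 1) // stride] = y
    return out, n_steps


@njit(cache=True)
def integrate_pair(y0, p_pc, p_in, p_syn, t0, dt, n_steps, stride):
    n_out = n_steps // stride + 1
    out = np.empty((n_out, NSTATE_PAIR))
    y = y0.copy()
    k1 = np.empty(NSTATE_PAIR)
    k2 = np.empty(NSTATE_PAIR)
    k3 = np.empty(NSTATE_PAIR)
    k4 = np.empty(NSTATE_PAIR)
    tmp = np.empty(NSTATE_PAIR)
    out[0] = y
    for step in range(n_steps):
        if _rk4_pair_step(y, p_pc, p_in, p_syn, t0 + step * dt, dt,
                          k1, k2, k3, k4, tmp) != 0:
            return out, step
        if (step + 1) % stride == 0:
            out[(step + 1) // stride] = y
    return out, n_steps


@njit(cache=True)
def _clamp_cell(y, lo, hi):
    """Project one cell state onto the model's valid operating box."""
    for i in range(NSTATE_CELL):
        if y[i] < lo[i]:
            y[i] = lo[i]
        elif y[i] > hi[i]:
            y[i] = hi[i]


# valid-region box used to project sigma points / posterior means
CELL_LO = np.array([-140.0, 0.0, 0.0, 0.0, 0.0, 0.3, 3.0])
CELL_HI = np.array([80.0, 1.0, 1.0, 1.0, 100.0, 80.0, 60.0])
SYN_LO = np.array([0.0, 0.0, 0.0, 0.0])
SYN_HI = np.array([1.0, 1.5, 1.0, 1.5])


@njit(cache=True)
def propagate_sigma_cell(points, base_state, dyn_idx, par_idx, par_tf,
                         p, t0, dt, n_sub, mode):
    """Propagate sigma points of an augmented single-cell belief one interval.

    Each row of ``points`` holds [dynamic components..., tracked parameters...].
    Dynamic components are scattered into a copy of ``base_state`` via
    ``dyn_idx``; tracked parameters overwrite slots ``par_idx`` of a copy of
    ``p`` (``par_tf`` = 1 means the belief carries log(parameter)).  Parameter
    components have trivial dynamics and are returned bit-identical.

    Returns the index of the first diverging point, or -1.
    """
    n_pts = points.shape[0]
    n_dyn = dyn_idx.shape[0]
    n_par = par_idx.shape[0]
    k1 = np.empty(NSTATE_CELL)
    k2 = np.empty(NSTATE_CELL)
    k3 = np.empty(NSTATE_CELL)
    k4 = np.empty(NSTATE_CELL)
    tmp = np.empty(NSTATE_CELL)
    y = np.empty(NSTATE_CELL)
    for ipt in range(n_pts):
        for i in range(NSTATE_CELL):
            y[i] = base_state[i]
        for j in range(n_dyn):
            y[dyn_idx[j]] = points[ipt, j]
        _clamp_cell(y, CELL_LO, CELL_HI)
        ploc = p.copy()
        for j in range(n_par):
            v = points[ipt, n_dyn + j]
            if par_tf[j] == 1:
                v = np.exp(min(max(v, -14.0), 14.0))
            ploc[par_idx[j]] = v
        ok = True
        for s in range(n_sub):
            if _rk4_cell_step(y, ploc, t0 + s * dt, dt, mode, k1, k2, k3, k4, tmp) != 0:
                ok = False
                break
            # per-substep projection: far outside the data-constrained region
            # the gate kinetics are stiff for RK4, so keep points in the box
            _clamp_cell(y, CELL_LO, CELL_HI)
        if not ok:
            return ipt
        for j in range(n_dyn):
            points[ipt, j] = y[dyn_idx[j]]
    return -1


@njit(cache=True)
def propagate_sigma_pair(points, base_state, dyn_idx, par_idx, par_tf, par_home,
                         p_pc, p_in, p_syn, t0, dt, n_sub):
    """Pair analogue of :func:`propagate_sigma_cell`.

    ``par_home`` selects the vector a tracked parameter lives in
    (0 = PC cell, 1 = IN cell, 2 = synapse).
    """
    n_pts = points.shape[0]
    n_dyn = dyn_idx.shape[0]
    n_par = par_idx.shape[0]
    k1 = np.empty(NSTATE_PAIR)
    k2 = np.empty(NSTATE_PAIR)
    k3 = np.empty(NSTATE_PAIR)
    k4 = np.empty(NSTATE_PAIR)
    tmp = np.empty(NSTATE_PAIR)
    y = np.empty(NSTATE_PAIR)
    for ipt in range(n_pts):
        for i in range(NSTATE_PAIR):
            y[i] = base_state[i]
        for j in range(n_dyn):
            y[dyn_idx[j]] = points[ipt, j]
        _clamp_cell(y[0:7], CELL_LO, CELL_HI)
        _clamp_cell(y[7:14], CELL_LO, CELL_HI)
        for i in range(4):
            if y[14 + i] < SYN_LO[i]:
                y[14 + i] = SYN_LO[i]
            elif y[14 + i] > SYN_HI[i]:
                y[14 + i] = SYN_HI[i]
        ppc = p_pc.copy()
        pin = p_in.copy()
        psy = p_syn.copy()
        for j in range(n_par):
            v = points[ipt, n_dyn + j]
            if par_tf[j] == 1:
                v = np.exp(min(max(v, -14.0), 14.0))
            if par_home[j] == 0:
                ppc[par_idx[j]] = v
            elif par_home[j] == 1:
                pin[par_idx[j]] = v
            else:
                psy[par_idx[j]] = v
        ok = True
        for s in range(n_sub):
            if _rk4_pair_step(y, ppc, pin, psy, t0 + s * dt, dt,
                              k1, k2, k3, k4, tmp) != 0:
                ok = False
                break
            _clamp_cell(y[0:7], CELL_LO, CELL_HI)
            _clamp_cell(y[7:14], CELL_LO, CELL_HI)
            for i in range(4):
                if y[14 + i] < SYN_LO[i]:
                    y[14 + i] = SYN_LO[i]
                elif y[14 + i] > SYN_HI[i]:
                    y[14 + i] = SYN_HI[i]
        if not ok:
            return ipt
        for j in range(n_dyn):
            points[ipt, j] = y[dyn_idx[j]]
    return -1
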