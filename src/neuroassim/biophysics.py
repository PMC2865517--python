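"""Conductance-based PC/OLM-IN model with a dynamic ion microenvironment.

A single cell is a modified Hodgkin-Huxley membrane (transient Na+, delayed
rectifier K+, Ca2+-gated afterhyperpolarization K+, and a three-component
leak) coupled to the slow dynamics of its extracellular potassium [K]_o and
intracellular sodium [Na]_i.  Those concentrations are moved by the neuron's
own ionic currents, an electrogenic 3 Na+ : 2 K+ pump, saturating glial
uptake, and Fickian diffusion toward a distant reservoir (bath/vasculature)
held at ``K_bath``.  Intracellular K+ and extracellular Na+ are slaved to
[Na]_i through bulk-electroneutrality identities, and the Nernst equation
feeds the concentrations back into the membrane reversal potentials — the
loop that lets rising [K]_o depolarize the cell into seizure-like firing.

Two cells (a pyramidal cell and an OLM interneuron) can be coupled
synaptically (AMPA PC->IN, GABA_A IN->PC, each multiplied by a
depolarization-block gate chi(eta) that silences a presynaptic cell stuck in
a depolarized non-spiking state) and by lateral extracellular K+ diffusion.

Membrane/gating/synaptic equations run on a millisecond time base; the ion
concentration equations are written per second and rescaled inside the RHS,
so a single ms-based integrator handles the fast/slow split.

This module is the validated, structure-aware surface.  The number-crunching
twin lives in :mod:`neuroassim._kernels`; the two are cross-checked in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .errors import ConfigError, DomainError

__all__ = [
    "GatingState", "IonState", "CellState", "CellParams", "MicroenvParams",
    "SynapseParams", "SynapseState", "NetworkState",
    "gating_rate_functions", "gating_derivatives", "nernst_reversals",
    "membrane_currents", "pump_flux", "glial_flux", "bath_flux",
    "dependent_concentrations", "ion_derivatives", "synaptic_gate_chi",
    "synaptic_dynamics", "lateral_K_diffusion",
    "rhs_single_cell", "rhs_coupled_pair", "resting_state",
    "gamma_from_radius", "epsilon_from_geometry", "stim_density_from_pA",
    "FARADAY_uC_PER_uMOL", "THERMAL_FACTOR_mV",
]

FARADAY_uC_PER_uMOL = 96485.0e-6 * 1e6  # = 96485 uC per umol
THERMAL_FACTOR_mV = 26.64  # RT/F at ~37 C, standard for this model family

# resting reference concentrations [mM] anchoring the electroneutrality identities
KI_REST, NAI_REST, NAO_REST = K.KI_REST, K.NAI_REST, K.NAO_REST

VALID_VARIANTS = ("full", "fixed_ions", "crippled_alpha_m")
_MODE = {"full": K.MODE_FULL, "fixed_ions": K.MODE_FIXED_IONS,
         "crippled_alpha_m": K.MODE_CRIPPLED}


# ---------------------------------------------------------------------------
# geometry helpers (documented derivations of gamma / epsilon defaults)

def gamma_from_radius(radius_um: float = 7.0) -> float:
    """Current-to-concentration factor gamma = A/(F*Vol) for a spherical cell.

    With current density in uA/cm^2 and concentrations in mM, gamma =
    3/(r*F) in mM cm^2/uC.  At the 7 um radius of this model family this is
    0.0445; multiplied by the volume ratio beta = 7 it gives the ~0.3 factor
    that scales the K+ current in the extracellular-potassium equation.
    """
    r_cm = radius_um * 1e-4
    return 3.0 / (r_cm * FARADAY_uC_PER_uMOL)


def epsilon_from_geometry(D_cm2_per_s: float = 2.5e-6, spacing_um: float = 20.0) -> float:
    """Bath diffusion coefficient from Fick's law, eps = 2*D/dx^2 (1/s).

    ``D`` is the K+ diffusion constant in neocortex and ``dx`` the average
    distance to the nearest capillary (or bath); the defaults give 1.25/s.
    """
    dx_cm = spacing_um * 1e-4
    return 2.0 * D_cm2_per_s / dx_cm ** 2


def stim_density_from_pA(current_pA: float, radius_um: float = 7.0) -> float:
    """Convert an injected current in pA to a density in uA/cm^2."""
    area_cm2 = 4.0 * math.pi * (radius_um * 1e-4) ** 2
    return current_pA * 1e-6 / area_cm2


# ---------------------------------------------------------------------------
# domain types

@dataclass
class GatingState:
    """Hodgkin-Huxley channel gates, each dimensionless in [0, 1]."""
    m: float
    h: float
    n: float

    def validate(self) -> None:
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise DomainError(f"gating variable {name}={x} outside [0, 1]")


@dataclass
class IonState:
    """The three dynamic concentrations: [K]_o, [Na]_i (mM), [Ca]_i (a.u.)."""
    K_o: float
    Na_i: float
    Ca_i: float = 0.0

    def validate(self) -> None:
        if self.K_o <= 0 or self.Na_i <= 0:
            raise DomainError(
                f"non-positive concentration: K_o={self.K_o}, Na_i={self.Na_i}")
        if self.Ca_i < 0:
            raise DomainError(f"negative Ca_i={self.Ca_i}")


@dataclass
class CellState:
    """Full state of one neuron; V is the (only) observable component."""
    V: float
    gating: GatingState
    ions: IonState

    def validate(self) -> None:
        if not np.isfinite(self.V) or not (-150.0 <= self.V <= 80.0):
            raise DomainError(f"membrane potential V={self.V} outside [-150, 80] mV")
        self.gating.validate()
        self.ions.validate()

    def to_array(self) -> np.ndarray:
        g, i = self.gating, self.ions
        return np.array([self.V, g.m, g.h, g.n, i.Ca_i, i.K_o, i.Na_i])

    @classmethod
    def from_array(cls, y) -> "CellState":
        return cls(V=float(y[0]),
                   gating=GatingState(float(y[1]), float(y[2]), float(y[3])),
                   ions=IonState(K_o=float(y[5]), Na_i=float(y[6]), Ca_i=float(y[4])))


@dataclass
class CellParams:
    """Membrane parameters of one cell (conductances in mS/cm^2).

    ``g_AHP`` models the pyramidal cell's spike-frequency adaptation and must
    be zero for interneurons.
    """
    C_m: float = 1.0
    g_Na: float = 100.0
    g_K: float = 40.0
    g_AHP: float = 0.01
    g_KL: float = 0.05
    g_NaL: float = 0.0175
    g_ClL: float = 0.05
    g_Ca: float = 0.1
    phi: float = 3.0
    E_Ca: float = 120.0
    Cl_i: float = 6.0
    Cl_o: float = 130.0
    cell_type: str = "PC"
    I_stim: float = 0.0

    def __post_init__(self):
        if self.cell_type not in ("PC", "IN"):
            raise ConfigError(f"cell_type must be PC or IN, got {self.cell_type!r}")
        if self.C_m <= 0:
            raise ConfigError("C_m must be positive")
        for name in ("g_Na", "g_K", "g_AHP", "g_KL", "g_NaL", "g_ClL", "g_Ca"):
            if getattr(self, name) < 0:
                raise ConfigError(f"negative conductance {name}")
        if self.cell_type == "IN" and self.g_AHP != 0.0:
            raise ConfigError("interneurons carry no afterhyperpolarization current"
                              " (g_AHP must be 0 for cell_type='IN')")

    @classmethod
    def interneuron(cls, **kw) -> "CellParams":
        kw.setdefault("g_AHP", 0.0)
        kw["cell_type"] = "IN"
        return cls(**kw)


@dataclass
class MicroenvParams:
    """Ion-microenvironment parameters of one cell's extracellular space.

    Per-cell so that layer differences (e.g. weaker glial buffering around
    OLM interneurons) are expressible.  ``time_scale`` uniformly speeds up
    the slow concentration subsystem; 1.0 is the physical model.
    """
    rho: float = 1.25           # max Na/K pump rate [mM/s]
    G_glia: float = 66.0        # max glial uptake [mM/s]
    epsilon: float = 1.25       # bath diffusion coefficient [1/s]
    K_bath: float = 3.0         # reservoir K+ [mM]; 3 mM physiological
    beta_vol: float = 7.0       # intracellular / extracellular volume ratio
    gamma: float = 0.0445       # current->concentration factor [mM cm^2/uC]
    delta: float = 0.0          # lateral K+ diffusion to a neighbour [1/s]
    time_scale: float = 1.0

    def __post_init__(self):
        for name in ("rho", "G_glia", "epsilon", "K_bath", "beta_vol",
                     "gamma", "delta", "time_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class SynapseParams:
    """PC<->IN synaptic coupling and the depolarization-block gate chi.

    The gate variable eta is a slow low-pass filter (time constant
    ``tau_eta``) of a sigmoidal sustained-depolarization indicator of the
    presynaptic voltage; chi(eta) is a descending sigmoid that multiplies the
    synaptic conductance, so a presynaptic cell locked above ``eta_theta`` mV
    stops transmitting while brief spikes barely move eta.
    """
    g_exc: float = 0.17         # AMPA strength PC->IN [mS/cm^2]
    g_inh: float = 0.84         # GABA_A strength IN->PC [mS/cm^2]
    tau_e: float = 4.0          # excitatory synaptic time constant [ms]
    tau_i: float = 8.0          # inhibitory synaptic time constant [ms]
    E_exc: float = 0.0          # AMPA reversal [mV]
    E_inh: float = -80.0        # GABA_A reversal [mV]
    s_theta: float = -20.0      # s_inf half-activation [mV]
    s_slope: float = 3.0
    eta_theta: float = -40.0    # sustained-depolarization threshold [mV]
    eta_slope: float = 2.0
    tau_eta: float = 800.0      # depolarization-block integration [ms]
    chi_half: float = 0.6       # chi = 1/2 at this eta
    chi_slope: float = 0.06

    def __post_init__(self):
        if self.g_exc < 0 or self.g_inh < 0:
            raise ConfigError("synaptic strengths must be non-negative")
        if self.tau_e <= 0 or self.tau_i <= 0 or self.tau_eta <= 0:
            raise ConfigError("synaptic time constants must be positive")

    def to_array(self) -> np.ndarray:
        p = np.empty(K.NSYN)
        p[K.S_GEXC] = self.g_exc
        p[K.S_GINH] = self.g_inh
        p[K.S_TAUE] = self.tau_e
        p[K.S_TAUI] = self.tau_i
        p[K.S_EEXC] = self.E_exc
        p[K.S_EINH] = self.E_inh
        p[K.S_STHETA] = self.s_theta
        p[K.S_SSLOPE] = self.s_slope
        p[K.S_ETHETA] = self.eta_theta
        p[K.S_ESLOPE] = self.eta_slope
        p[K.S_TAUETA] = self.tau_eta
        p[K.S_CHIHALF] = self.chi_half
        p[K.S_CHISLOPE] = self.chi_slope
        return p


@dataclass
class SynapseState:
    s_p: float = 0.0
    eta_p: float = 0.0
    s_i: float = 0.0
    eta_i: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.s_p <= 1.0 and 0.0 <= self.s_i <= 1.0):
            raise DomainError("synaptic gating s outside [0, 1]")
        if self.eta_p < 0 or self.eta_i < 0:
            raise DomainError("depolarization-block integrator eta negative")


@dataclass
class NetworkState:
    pc: CellState
    in_: CellState
    syn: SynapseState = field(default_factory=SynapseState)

    def validate(self) -> None:
        self.pc.validate()
        self.in_.validate()
        self.syn.validate()

    def to_array(self) -> np.ndarray:
        s = self.syn
        return np.concatenate([self.pc.to_array(), self.in_.to_array(),
                               [s.s_p, s.eta_p, s.s_i, s.eta_i]])

    @classmethod
    def from_array(cls, y) -> "NetworkState":
        return cls(pc=CellState.from_array(y[0:7]),
                   in_=CellState.from_array(y[7:14]),
                   syn=SynapseState(*map(float, y[14:18])))


def pack_params(cell: CellParams, env: MicroenvParams,
                stim_amp: float | None = None, stim_onset: float = 0.0,
                stim_duration: float = np.inf, alpha_m_const: float = 0.0) -> np.ndarray:
    """Flatten a (cell, microenvironment, stimulus) bundle for the kernels.

    With no explicit stimulus, ``cell.I_stim`` is applied as a constant bias.
    """
    p = np.zeros(K.NPARAM)
    p[K.P_CM] = cell.C_m
    p[K.P_GNA] = cell.g_Na
    p[K.P_GK] = cell.g_K
    p[K.P_GAHP] = cell.g_AHP
    p[K.P_GKL] = cell.g_KL
    p[K.P_GNAL] = cell.g_NaL
    p[K.P_GCLL] = cell.g_ClL
    p[K.P_GCA] = cell.g_Ca
    p[K.P_PHI] = cell.phi
    p[K.P_ECA] = cell.E_Ca
    p[K.P_CLI] = cell.Cl_i
    p[K.P_CLO] = cell.Cl_o
    p[K.P_RHO] = env.rho
    p[K.P_GGLIA] = env.G_glia
    p[K.P_EPS] = env.epsilon
    p[K.P_KBATH] = env.K_bath
    p[K.P_BETA] = env.beta_vol
    p[K.P_GAMMA] = env.gamma
    p[K.P_DELTA] = env.delta
    p[K.P_THERM] = THERMAL_FACTOR_mV
    if stim_amp is None:
        # always-on bias: finite onset so onset + duration stays well-defined
        p[K.P_STIM_AMP] = cell.I_stim
        p[K.P_STIM_ON] = -1e300
        p[K.P_STIM_DUR] = np.inf
    else:
        p[K.P_STIM_AMP] = stim_amp
        p[K.P_STIM_ON] = stim_onset
        p[K.P_STIM_DUR] = stim_duration
    p[K.P_ALPHA_M] = alpha_m_const
    p[K.P_ION_SCALE] = env.time_scale
    return p


# ---------------------------------------------------------------------------
# elementary operations

def gating_rate_functions(V: float) -> dict[str, float]:
    """The six HH rate constants at voltage ``V`` (1/ms), singularities filled."""
    if not np.isfinite(V):
        raise DomainError(f"non-finite membrane potential V={V}")
    am, bm, ah, bh, an, bn = K.gating_rates(float(V))
    return {"alpha_m": am, "beta_m": bm, "alpha_h": ah,
            "beta_h": bh, "alpha_n": an, "beta_n": bn}


def gating_derivatives(V: float, gating: GatingState, phi: float = 3.0) -> dict[str, float]:
    """dx/dt = phi * (alpha_x (1 - x) - beta_x x) for x in {m, h, n}."""
    gating.validate()
    r = gating_rate_functions(V)
    return {
        "dm_dt": phi * (r["alpha_m"] * (1 - gating.m) - r["beta_m"] * gating.m),
        "dh_dt": phi * (r["alpha_h"] * (1 - gating.h) - r["beta_h"] * gating.h),
        "dn_dt": phi * (r["alpha_n"] * (1 - gating.n) - r["beta_n"] * gating.n),
    }


def dependent_concentrations(Na_i: float, beta_vol: float = 7.0) -> dict[str, float]:
    """[K]_i and [Na]_o slaved to [Na]_i by bulk electroneutrality.

    K_i = 140 + (18 - Na_i); Na_o = 144 - beta_vol * (Na_i - 18), with 140,
    18 and 144 mM the normal resting intracellular K+, intracellular Na+ and
    extracellular Na+ concentrations.
    """
    if Na_i <= 0:
        raise DomainError(f"Na_i={Na_i} must be positive")
    K_i = KI_REST + (NAI_REST - Na_i)
    Na_o = NAO_REST - beta_vol * (Na_i - NAI_REST)
    return {"K_i": K_i, "Na_o": Na_o}


def nernst_reversals(ions: IonState, params: CellParams,
                     microenv: MicroenvParams) -> dict[str, float]:
    """E_X = (RT/F) ln([X]_out/[X]_in) for Na+, K+ and Cl- (anion inverted)."""
    ions.validate()
    dep = dependent_concentrations(ions.Na_i, microenv.beta_vol)
    if dep["K_i"] <= 0 or dep["Na_o"] <= 0:
        raise DomainError("derived K_i/Na_o non-positive: state outside validity")
    t = THERMAL_FACTOR_mV
    return {
        "E_K": t * math.log(ions.K_o / dep["K_i"]),
        "E_Na": t * math.log(dep["Na_o"] / ions.Na_i),
        "E_Cl": t * math.log(params.Cl_i / params.Cl_o),
    }


def membrane_currents(V: float, gating: GatingState, reversals: dict,
                      Ca_i: float, params: CellParams) -> dict[str, float]:
    """All membrane currents (uA/cm^2, positive outward), per conductance.

    The leak has three components (K+, Na+, Cl-); I_AHP is identically zero
    for interneurons by the g_AHP = 0 constraint.
    """
    g = gating
    m3h = g.m ** 3 * g.h
    n4 = g.n ** 4
    I_Na = params.g_Na * m3h * (V - reversals["E_Na"])
    I_K = params.g_K * n4 * (V - reversals["E_K"])
    I_AHP = params.g_AHP * (Ca_i / (1.0 + Ca_i)) * (V - reversals["E_K"])
    I_KL = params.g_KL * (V - reversals["E_K"])
    I_NaL = params.g_NaL * (V - reversals["E_Na"])
    I_ClL = params.g_ClL * (V - reversals["E_Cl"])
    return {"I_Na": I_Na, "I_K": I_K, "I_AHP": I_AHP,
            "I_KL": I_KL, "I_NaL": I_NaL, "I_ClL": I_ClL,
            "I_L": I_KL + I_NaL + I_ClL}


def pump_flux(Na_i: float, K_o: float, rho: float) -> float:
    """Na/K pump rate: product of sigmoids saturating in Na_i and K_o (mM/s)."""
    if rho < 0:
        raise ConfigError("pump strength rho must be non-negative")
    if Na_i <= 0 or K_o <= 0:
        raise DomainError("pump_flux requires positive concentrations")
    return float(K._pump(Na_i, K_o, rho))


def glial_flux(K_o: float, G_glia: float) -> float:
    """Glial K+ uptake: single sigmoid of K_o saturating at G_glia (mM/s)."""
    if K_o <= 0:
        raise DomainError("glial_flux requires positive K_o")
    return float(K._glia(K_o, G_glia))


def bath_flux(K_o: float, K_bath: float, epsilon: float) -> float:
    """Fickian loss to the reservoir, eps*(K_o - K_bath) (mM/s)."""
    if epsilon < 0:
        raise ConfigError("epsilon must be non-negative")
    return epsilon * (K_o - K_bath)


def lateral_K_diffusion(K_o_pc: float, K_o_in: float, delta: float) -> tuple[float, float]:
    """Pairwise-conservative lateral exchange: (term for PC, term for IN)."""
    term_pc = delta * (K_o_in - K_o_pc)
    return term_pc, -term_pc


def ion_derivatives(state: CellState, cell: CellParams, env: MicroenvParams,
                    coupling_term: float = 0.0) -> dict[str, float]:
    """d[K]_o/dt, d[Na]_i/dt (mM/s) and d[Ca]_i/dt (a.u./ms).

    The pump enters with its electrogenic stoichiometry: -3*pump in the Na_i
    equation and -2*beta_vol*pump in the K_o equation (2:3 K:Na per cycle;
    beta_vol converts intracellular-equivalents to the smaller extracellular
    volume).  ``coupling_term`` is the lateral-diffusion contribution (mM/s).
    """
    state.validate()
    rev = nernst_reversals(state.ions, cell, env)
    cur = membrane_currents(state.V, state.gating, rev, state.ions.Ca_i, cell)
    I_Kflux = cur["I_K"] + cur["I_KL"] + cur["I_AHP"]
    I_Naflux = cur["I_Na"] + cur["I_NaL"]
    pump = pump_flux(state.ions.Na_i, state.ions.K_o, env.rho)
    glia = glial_flux(state.ions.K_o, env.G_glia)
    diff = bath_flux(state.ions.K_o, env.K_bath, env.epsilon)
    b, g = env.beta_vol, env.gamma
    dKo = g * b * I_Kflux - 2.0 * b * pump - glia - diff + coupling_term
    dNai = -g * I_Naflux - 3.0 * pump
    dCa = (-0.002 * cell.g_Ca * (state.V - cell.E_Ca)
           / (1.0 + math.exp(-(state.V + 25.0) / 2.5)) - state.ions.Ca_i / 80.0)
    return {"dK_o_dt": dKo, "dNa_i_dt": dNai, "dCa_i_dt": dCa}


def synaptic_gate_chi(eta: float, params: SynapseParams | None = None) -> float:
    """Depolarization-block gate in (0, 1]: ~1 at eta = 0, -> 0 for large eta."""
    if eta < 0:
        raise DomainError("eta must be non-negative")
    p = params or SynapseParams()
    return float(K._chi(eta, p.chi_half, p.chi_slope))


def synaptic_dynamics(net: NetworkState, params: SynapseParams) -> dict[str, float]:
    """Synaptic currents into each cell and the kinetics of s_p, s_i, eta_p, eta_i.

    Currents are positive-outward: I_syn_pc = g_inh * s_i * chi(eta_i) *
    (V_pc - E_inh) enters the PC equation, and symmetrically for the IN.
    Each s relaxes toward a sigmoid of its presynaptic voltage with its tau.
    """
    net.syn.validate()
    p = params
    chi_p = synaptic_gate_chi(net.syn.eta_p, p)
    chi_i = synaptic_gate_chi(net.syn.eta_i, p)
    Vp, Vi = net.pc.V, net.in_.V
    sinf = lambda V: 1.0 / (1.0 + math.exp(-(V - p.s_theta) / p.s_slope))
    blk = lambda V: 1.0 / (1.0 + math.exp(-(V - p.eta_theta) / p.eta_slope))
    return {
        "I_syn_pc": p.g_inh * net.syn.s_i * chi_i * (Vp - p.E_inh),
        "I_syn_in": p.g_exc * net.syn.s_p * chi_p * (Vi - p.E_exc),
        "ds_p_dt": (sinf(Vp) - net.syn.s_p) / p.tau_e,
        "ds_i_dt": (sinf(Vi) - net.syn.s_i) / p.tau_i,
        "deta_p_dt": (blk(Vp) - net.syn.eta_p) / p.tau_eta,
        "deta_i_dt": (blk(Vi) - net.syn.eta_i) / p.tau_eta,
    }


# ---------------------------------------------------------------------------
# full right-hand sides (ms time base throughout)

def rhs_single_cell(state: CellState, cell: CellParams, env: MicroenvParams,
                    t: float = 0.0, variant: str = "full",
                    alpha_m_const: float = 0.0) -> np.ndarray:
    """Complete derivative of one cell in kernel layout (per ms).

    ``variant`` selects the full model, the fixed-ion reduction (ion
    derivatives identically zero, concentrations pinned at their current
    values), or the crippled model in which alpha_m(V) is replaced by the
    supplied constant.
    """
    if variant not in VALID_VARIANTS:
        raise ConfigError(f"unknown model variant {variant!r}; "
                          f"expected one of {VALID_VARIANTS}")
    state.validate()
    p = pack_params(cell, env, alpha_m_const=alpha_m_const)
    dy = np.empty(K.NSTATE_CELL)
    err = K.cell_rhs(state.to_array(), p, t, _MODE[variant], 0.0, 0.0, dy)
    if err:
        raise DomainError("state outside the model's valid operating range")
    return dy


def rhs_coupled_pair(net: NetworkState, pc_cell: CellParams, pc_env: MicroenvParams,
                     in_cell: CellParams, in_env: MicroenvParams,
                     syn: SynapseParams, t: float = 0.0) -> np.ndarray:
    """Derivative of the coupled PC-IN pair (length 18, kernel layout)."""
    net.validate()
    p_pc = pack_params(pc_cell, pc_env)
    p_in = pack_params(in_cell, in_env)
    dy = np.empty(K.NSTATE_PAIR)
    err = K.pair_rhs(net.to_array(), p_pc, p_in, syn.to_array(), t, dy)
    if err:
        raise DomainError("network state outside the model's valid operating range")
    return dy


def resting_state(cell: CellParams | None = None, env: MicroenvParams | None = None,
                  settle_ms: float = 20000.0, dt: float = 0.05,
                  polish: bool = True) -> CellState:
    """Numerically locate the unstimulated cell's stable rest state.

    Settles by forward integration, then polishes the fixed point with a
    root solve of the full RHS so residual derivatives are at solver
    precision.
    """
    cell = cell or CellParams()
    env = env or MicroenvParams()
    y0 = np.array([-65.0, 0.05, 0.95, 0.08, 0.0, env.K_bath, NAI_REST])
    p = pack_params(replace(cell, I_stim=0.0), env)
    n = int(round(settle_ms / dt))
    out, n_ok = K.integrate_cell(y0, p, 0.0, dt, n, n, K.MODE_FULL)
    if n_ok != n:
        raise DomainError("resting-state settle diverged")
    y = out[-1]
    if polish:
        from scipy import optimize

        def f(yv):
            dy = np.empty(K.NSTATE_CELL)
            if K.cell_rhs(yv, p, 0.0, K.MODE_FULL, 0.0, 0.0, dy):
                return np.full(K.NSTATE_CELL, 1e6)
            return dy

        sol = optimize.root(f, y, method="hybr", tol=1e-14)
        # accept only a nearby physical fixed point (slow Na_i drift can leave
        # the settle a few mM short of the true equilibrium)
        if sol.success and abs(sol.x[0] - y[0]) < 5.0 and sol.x[5] > 0 \
                and sol.x[6] > 0:
            y = sol.x
    return CellState.from_array(y)
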