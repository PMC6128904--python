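"""Simplified CA1 pyramidal-cell compartmental model with extracellular
point-source potentials.

The cell is a soma plus a 150-µm apical dendritic cable (10 segments).
Conductances are Hodgkin–Huxley-style: Na and delayed-rectifier K in soma
and dendrites, A-type K and the muscarinic M-current in the soma, and the
hyperpolarization-activated cation current Ih in the soma and the distal
dendritic segment (0.01 µS total in each, entered as absolute
conductances).  Rate functions use smooth Boltzmann steady states with
voltage-dependent or fixed time constants; all kinetic parameters live in
one editable dictionary (:data:`DEFAULT_CHANNELS`) because the questions
this model answers — post-inhibitory rebound and the laminar position of
the theta current source — are qualitative, not kinetically exact.

Synapses are alpha-function conductances
``g(t) = g_max (t/τ) e^{1−t/τ}``: fast excitation (τ = 0.1 ms, 0 mV) on the
distal dendrite for the temporoammonic/Schaffer pathways and GABAergic
inhibition (τ = 0.3 ms, −75 mV) from OLM cells on the distal dendrite and
basket cells on the soma.

Extracellular potentials treat each compartment as a point source in an
infinite homogeneous medium: ``φ_e = (1/4πσ) Σ_k I_k / r_k``.  Because the
total membrane current sums to ~0 at every instant (Kirchhoff), the summed
source is dipolar at a distance, as for a real neuron.

Rhythmic OLM inhibition of the HCN-rich distal dendrite produces
theta-locked rebound depolarizations whose associated return currents make
the perisomatic region the dominant theta current source — the laminar
pattern characteristic of type 2 theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csd import CSDMap, compute_csd

__all__ = [
    "CellModel",
    "SynapseSpec",
    "LFPProbe",
    "SimResult",
    "DEFAULT_CHANNELS",
    "simulate",
    "extracellular_potential",
    "csd_of_simulation",
    "olm_train",
    "poisson_train",
]

# Channel kinetics: steady state x_inf = 1/(1+exp((v_half - V)/k)) (k < 0 for
# inactivation/hyperpolarization-activated gates), first-order relaxation
# with time constant tau (ms).  Densities in mS/cm2 unless given as
# absolute µS totals (Ih).
DEFAULT_CHANNELS: dict = {
    "e_na": 50.0,
    "e_k": -90.0,
    "e_h": -30.0,
    "e_pas": -70.0,
    "g_pas": 0.1,  # mS/cm2
    "na": {"g_soma": 50.0, "g_dend": 5.0,
           "m_half": -38.0, "m_k": 5.0, "m_tau": 0.15,
           "h_half": -45.0, "h_k": -4.0, "h_tau": 10.0},
    "kdr": {"g_soma": 12.0, "g_dend": 5.0,
            "n_half": -35.0, "n_k": 10.0, "n_tau": 3.0},
    "ka": {"g_soma": 5.0,
           "a_half": -45.0, "a_k": 12.0, "a_tau": 1.0,
           "b_half": -70.0, "b_k": -8.0, "b_tau": 20.0},
    "im": {"g_soma": 1.0, "p_half": -40.0, "p_k": 6.0, "p_tau": 60.0},
    "ih": {"g_soma_uS": 0.01, "g_distal_uS": 0.01,
           "r_half": -78.0, "r_k": -8.0, "r_tau": 40.0},
}


@dataclass
class CellModel:
    """Geometry, passive properties and channel parameters of the cell."""

    n_dend: int = 10
    dend_length: float = 150.0  # µm total
    dend_diam: float = 2.0  # µm
    soma_length: float = 20.0  # µm
    soma_diam: float = 20.0  # µm
    ra: float = 150.0  # Ω·cm axial resistivity
    cm: float = 1.0  # µF/cm2
    channels: dict = field(default_factory=lambda: {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CHANNELS.items()})

    @property
    def n_comp(self) -> int:
        return self.n_dend + 1

    @property
    def distal_index(self) -> int:
        return self.n_dend  # last dendritic segment

    def geometry(self):
        """Per-compartment (length µm, diameter µm, area cm2, z-position µm).

        The soma sits at z = 0 with the dendrite extending toward +z.
        """
        seg_l = self.dend_length / self.n_dend
        lengths = np.array([self.soma_length] + [seg_l] * self.n_dend)
        diams = np.array([self.soma_diam] + [self.dend_diam] * self.n_dend)
        areas = np.pi * diams * lengths * 1e-8  # µm2 -> cm2
        z = np.empty(self.n_comp)
        z[0] = 0.0
        z[1:] = self.soma_length / 2 + (np.arange(self.n_dend) + 0.5) * seg_l
        return lengths, diams, areas, z

    def axial_conductances(self) -> np.ndarray:
        """µS between consecutive compartments (half-length series rule)."""
        lengths, diams, _, _ = self.geometry()
        # resistance of a half compartment: Ra * (l/2) / cross-section
        half_r = self.ra * (lengths / 2 * 1e-4) / (np.pi * (diams * 1e-4) ** 2 / 4)  # Ω
        g = 1.0 / (half_r[:-1] + half_r[1:])  # S
        return g * 1e6  # µS


@dataclass(frozen=True)
class SynapseSpec:
    kind: str  # excitatory | inhibitory_OLM | inhibitory_basket
    tau: float  # ms
    g_max: float  # µS
    e_rev: float  # mV
    target: int  # compartment index

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.g_max < 0:
            raise ValueError("tau must be positive and g_max non-negative")

    @classmethod
    def excitatory(cls, target: int) -> "SynapseSpec":
        return cls("excitatory", 0.1, 0.05, 0.0, target)

    @classmethod
    def olm(cls, target: int) -> "SynapseSpec":
        return cls("inhibitory_OLM", 0.3, 0.05, -75.0, target)

    @classmethod
    def basket(cls, target: int = 0) -> "SynapseSpec":
        return cls("inhibitory_basket", 0.3, 0.05, -75.0, target)


@dataclass(frozen=True)
class LFPProbe:
    """Electrode positions (µm, relative to the soma at the origin) and the
    extracellular conductivity (S/m)."""

    positions: tuple[tuple[float, float, float], ...]
    sigma: float = 0.3


@dataclass
class SimResult:
    t: np.ndarray  # ms
    v: np.ndarray  # n_comp x nt, mV
    i_membrane: np.ndarray  # n_comp x nt, nA (outward positive)
    model: CellModel


def olm_train(
    freq: float,
    duration: float,
    events_per_cycle: int = 5,
    intra_interval_ms: float = 3.0,
    start: float = 0.0,
) -> np.ndarray:
    """Periodic inhibitory burst times (s): ``events_per_cycle`` events
    ``intra_interval_ms`` apart at the start of every theta cycle."""
    cycle_starts = np.arange(start, duration, 1.0 / freq)
    offsets = np.arange(events_per_cycle) * intra_interval_ms * 1e-3
    return np.sort((cycle_starts[:, None] + offsets[None, :]).ravel())


def poisson_train(rate: float, duration: float, seed=0) -> np.ndarray:
    """Homogeneous Poisson event times (s)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


def _alpha_conductance(events_s, g_max, tau_ms, nt, dt_ms):
    """Summed alpha-function conductance (µS) sampled on the time grid."""
    g = np.zeros(nt)
    kernel_len = int(round(12 * tau_ms / dt_ms)) + 1
    tk = np.arange(kernel_len) * dt_ms
    kernel = g_max * (tk / tau_ms) * np.exp(1.0 - tk / tau_ms)
    for ev in np.atleast_1d(np.asarray(events_s, dtype=float)):
        i0 = int(round(ev * 1e3 / dt_ms))
        if i0 >= nt:
            continue
        j1 = min(i0 + kernel_len, nt)
        g[i0:j1] += kernel[: j1 - i0]
    return g


def _boltz(v, half, k):
    return 1.0 / (1.0 + np.exp((half - v) / k))


def simulate(
    model: CellModel,
    inputs: list[tuple[SynapseSpec, np.ndarray]],
    duration: float,
    dt: float = 0.025,
    v_init: float = -68.0,
    record_stride: int = 4,
    i_inj: np.ndarray | None = None,
) -> SimResult:
    """Integrate the cable equation with HH-type kinetics.

    ``inputs`` pairs each synapse with its event-time list (s).  The voltage
    equation is stepped implicitly (backward Euler on the tridiagonal cable
    system, channel conductances frozen within the step); gates relax
    exponentially toward their steady state.  Membrane current (outward,
    nA) per compartment is ``C dV/dt + I_ionic + I_syn`` — its spatial sum
    vanishes by current conservation.  State is recorded every
    ``record_stride`` steps.

    Raises on numerical divergence (|Vm| > 100 mV) and on events beyond
    ``duration``.
    """
    if dt > 0.025 + 1e-12:
        raise ValueError("dt must be <= 0.025 ms for stable kinetics")
    ch = model.channels
    nc = model.n_comp
    _, _, areas, _ = model.geometry()
    nt = int(round(duration * 1e3 / dt))

    for spec, events in inputs:
        events = np.atleast_1d(np.asarray(events, dtype=float))
        if events.size and events.max() > duration:
            raise ValueError("synaptic event beyond simulation duration")
        if not (0 <= spec.target < nc):
            raise ValueError(f"synapse target {spec.target} out of range")

    # per-compartment maximal conductances in µS
    def dens(d_soma, d_dend):
        g = np.empty(nc)
        g[0] = d_soma * areas[0] * 1e3
        g[1:] = d_dend * areas[1:] * 1e3
        return g

    g_na = dens(ch["na"]["g_soma"], ch["na"]["g_dend"])
    g_kdr = dens(ch["kdr"]["g_soma"], ch["kdr"]["g_dend"])
    g_ka = dens(ch["ka"]["g_soma"], 0.0)
    g_im = dens(ch["im"]["g_soma"], 0.0)
    g_pas = ch["g_pas"] * areas * 1e3
    g_ih = np.zeros(nc)
    g_ih[0] = ch["ih"]["g_soma_uS"]
    g_ih[model.distal_index] = ch["ih"]["g_distal_uS"]

    cap = model.cm * areas * 1e3  # nF; nF*mV/ms = nA
    g_ax = model.axial_conductances()

    # synaptic conductance time courses, grouped per compartment
    g_syn = np.zeros((nc, nt))
    ge_syn = np.zeros((nc, nt))
    for spec, events in inputs:
        g = _alpha_conductance(events, spec.g_max, spec.tau, nt, dt)
        g_syn[spec.target] += g
        ge_syn[spec.target] += g * spec.e_rev

    # optional constant injected current (nA, inward positive), e.g. to hold
    # the resting potential comparable across channel-conductance sweeps
    if i_inj is None:
        inj = np.zeros(nc)
    else:
        inj = np.asarray(i_inj, dtype=float)
        if inj.shape != (nc,):
            raise ValueError(f"i_inj must have shape ({nc},)")

    v = np.full(nc, float(v_init))
    m = _boltz(v, ch["na"]["m_half"], ch["na"]["m_k"])
    h = _boltz(v, ch["na"]["h_half"], ch["na"]["h_k"])
    n_g = _boltz(v, ch["kdr"]["n_half"], ch["kdr"]["n_k"])
    a = _boltz(v, ch["ka"]["a_half"], ch["ka"]["a_k"])
    b = _boltz(v, ch["ka"]["b_half"], ch["ka"]["b_k"])
    p = _boltz(v, ch["im"]["p_half"], ch["im"]["p_k"])
    r = _boltz(v, ch["ih"]["r_half"], ch["ih"]["r_k"])

    relax = {
        "m": 1.0 - np.exp(-dt / ch["na"]["m_tau"]),
        "h": 1.0 - np.exp(-dt / ch["na"]["h_tau"]),
        "n": 1.0 - np.exp(-dt / ch["kdr"]["n_tau"]),
        "a": 1.0 - np.exp(-dt / ch["ka"]["a_tau"]),
        "b": 1.0 - np.exp(-dt / ch["ka"]["b_tau"]),
        "p": 1.0 - np.exp(-dt / ch["im"]["p_tau"]),
        "r": 1.0 - np.exp(-dt / ch["ih"]["r_tau"]),
    }

    n_rec = nt // record_stride
    v_rec = np.empty((nc, n_rec))
    im_rec = np.empty((nc, n_rec))
    t_rec = (np.arange(n_rec) * record_stride + record_stride) * dt

    lower = np.zeros(nc)
    upper = np.zeros(nc)
    lower[1:] = -g_ax
    upper[:-1] = -g_ax
    ax_diag = np.zeros(nc)
    ax_diag[:-1] += g_ax
    ax_diag[1:] += g_ax

    e_na, e_k, e_h, e_pas = ch["e_na"], ch["e_k"], ch["e_h"], ch["e_pas"]
    rec_i = 0
    for it in range(nt):
        m += (_boltz(v, ch["na"]["m_half"], ch["na"]["m_k"]) - m) * relax["m"]
        h += (_boltz(v, ch["na"]["h_half"], ch["na"]["h_k"]) - h) * relax["h"]
        n_g += (_boltz(v, ch["kdr"]["n_half"], ch["kdr"]["n_k"]) - n_g) * relax["n"]
        a += (_boltz(v, ch["ka"]["a_half"], ch["ka"]["a_k"]) - a) * relax["a"]
        b += (_boltz(v, ch["ka"]["b_half"], ch["ka"]["b_k"]) - b) * relax["b"]
        p += (_boltz(v, ch["im"]["p_half"], ch["im"]["p_k"]) - p) * relax["p"]
        r += (_boltz(v, ch["ih"]["r_half"], ch["ih"]["r_k"]) - r) * relax["r"]

        gna = g_na * m**3 * h
        gk = g_kdr * n_g**4
        gka = g_ka * a * b
        gim = g_im * p
        gih = g_ih * r
        g_tot = gna + gk + gka + gim + gih + g_pas + g_syn[:, it]
        ge_tot = (
            gna * e_na
            + (gk + gka + gim) * e_k
            + gih * e_h
            + g_pas * e_pas
            + ge_syn[:, it]
        )

        # backward Euler tridiagonal solve (Thomas algorithm)
        diag = cap / dt + g_tot + ax_diag
        rhs = cap / dt * v + ge_tot + inj
        c_p = np.empty(nc)
        d_p = np.empty(nc)
        c_p[0] = upper[0] / diag[0]
        d_p[0] = rhs[0] / diag[0]
        for k in range(1, nc):
            denom = diag[k] - lower[k] * c_p[k - 1]
            c_p[k] = upper[k] / denom if k < nc - 1 else 0.0
            d_p[k] = (rhs[k] - lower[k] * d_p[k - 1]) / denom
        v_new = np.empty(nc)
        v_new[-1] = d_p[-1]
        for k in range(nc - 2, -1, -1):
            v_new[k] = d_p[k] - c_p[k] * v_new[k + 1]

        i_mem = cap * (v_new - v) / dt + g_tot * v_new - ge_tot  # nA, outward
        v = v_new
        if np.max(np.abs(v)) > 100.0:
            raise RuntimeError(
                f"numerical divergence at t={it * dt:.3f} ms: |Vm| exceeded 100 mV"
            )
        if (it + 1) % record_stride == 0 and rec_i < n_rec:
            v_rec[:, rec_i] = v
            im_rec[:, rec_i] = i_mem
            rec_i += 1

    return SimResult(t=t_rec, v=v_rec, i_membrane=im_rec, model=model)


def extracellular_potential(result: SimResult, probe: LFPProbe) -> np.ndarray:
    """Point-source extracellular potential at each electrode (µV).

    ``φ_e(t) = (1/4πσ) Σ_k I_k(t)/r_k`` with compartments at their midpoint
    positions along the somato-dendritic (z) axis.  Raises if an electrode
    coincides with a compartment midpoint.
    """
    _, _, _, z = result.model.geometry()
    comp_pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    out = np.empty((len(probe.positions), result.i_membrane.shape[1]))
    for e, pos in enumerate(probe.positions):
        rvec = comp_pos - np.asarray(pos, dtype=float)
        rr = np.linalg.norm(rvec, axis=1)  # µm
        if np.any(rr < 1e-9):
            raise ValueError(f"electrode {e} coincides with a compartment midpoint")
        # nA / (S/m * µm): 1e3 factor converts to µV
        out[e] = 1e3 * (result.i_membrane / (4 * np.pi * probe.sigma * rr[:, None])).sum(axis=0)
    return out


def csd_of_simulation(
    result: SimResult,
    n_electrodes: int = 9,
    spacing: float = 25.0,
    lateral_offset: float = 30.0,
    sigma: float = 0.3,
    z_start: float = -25.0,
) -> tuple[CSDMap, np.ndarray]:
    """CSD along a virtual laminar probe parallel to the cell axis.

    Electrodes sit at ``(lateral_offset, 0, z_start + i*spacing)``.  Returns
    the CSD map plus the z-positions of all electrodes.
    """
    if n_electrodes < 3:
        raise ValueError("need at least 3 colinear electrodes for CSD")
    zs = z_start + np.arange(n_electrodes) * spacing
    probe = LFPProbe(
        positions=tuple((lateral_offset, 0.0, float(z)) for z in zs), sigma=sigma
    )
    pots = extracellular_potential(result, probe)
    return compute_csd(pots, spacing), zs
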