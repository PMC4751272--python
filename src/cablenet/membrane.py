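"""Membrane transport mechanisms: HH channels, calibrated leak, calcium.

All mechanisms follow the same explicit contract: internal states (gates,
pump occupancy) are advanced *before* a time step using only the previous
step's solution, and the densities they report enter the voltage/species
equations as known quantities.  The solver never couples to a mechanism
implicitly.

Sign convention: every current density and pump flux returned here is
*outward-positive*; the solver negates the total once when it assembles
the inward membrane term of the charge balance.

Units: potentials in volts, current densities in A m⁻², conductances in
S m⁻², concentrations in mM (≡ mol m⁻³), fluxes in mol m⁻² s⁻¹.  The one
exception is :func:`hh_rates`, which speaks the classical language of the
squid-axon formalism: membrane potential in mV and rates in ms⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "BODY_TEMPERATURE",
    "HHRegionParams",
    "MechanismSpec",
    "TABLE_NETWORK_SPEC",
    "HHState",
    "hh_rates",
    "hh_steady_state",
    "hh_gate_step",
    "hh_current_density",
    "leak_current_density",
    "calibrate_leak_reversal",
    "MembraneModel",
    "VDCCParams",
    "PumpParams",
    "CalciumParams",
    "CalciumState",
    "vdcc_gate_steady_state",
    "vdcc_current_density",
    "ghk_current_density",
    "pump_flux",
    "CalciumModel",
]

FARADAY = 96485.332  # C mol⁻¹
GAS_CONSTANT = 8.31446  # J mol⁻¹ K⁻¹
BODY_TEMPERATURE = 310.15  # K (37 °C)


# ---------------------------------------------------------------------------
# Hodgkin–Huxley channels


@dataclass(frozen=True)
class HHRegionParams:
    """Region-specific channel densities (S m⁻²)."""

    g_K: float
    g_Na: float
    g_l: float


@dataclass(frozen=True)
class MechanismSpec:
    """Full parameterisation of the HH + leak membrane.

    ``regions`` maps the three electrical region classes (axon, soma,
    dendrite) to their conductance densities.  ``E_l`` entries may be given
    explicitly; when absent they are obtained from
    :func:`calibrate_leak_reversal` so that the membrane carries zero net
    current at the resting potential.
    """

    regions: dict[str, HHRegionParams]
    E_K: float = -0.09    # V
    E_Na: float = 0.06    # V
    V_rest: float = -0.065  # V
    c_T: float = 3.21     # temperature factor on channel kinetics and flux
    E_l: dict[str, float] = field(default_factory=dict)

    def leak_reversal(self, region: str) -> float:
        if region in self.E_l:
            return self.E_l[region]
        return calibrate_leak_reversal(self, region)


#: The cortical-network parameter set (conductances per membrane class).
TABLE_NETWORK_SPEC = MechanismSpec(
    regions={
        "axon": HHRegionParams(g_K=400.0, g_Na=30000.0, g_l=200.0),
        "soma": HHRegionParams(g_K=200.0, g_Na=1500.0, g_l=1.0),
        "dendrite": HHRegionParams(g_K=30.0, g_Na=40.0, g_l=1.0),
    },
)


@dataclass
class HHState:
    """Per-vertex gating variables, each confined to [0, 1]."""

    n: np.ndarray
    m: np.ndarray
    h: np.ndarray


def hh_rates(V_mV, V_rest_mV: float = -65.0):
    """Classical squid-axon rate functions, shifted so rest sits at V_rest.

    Parameters are absolute membrane potential in mV; returns
    ``(α_n, β_n, α_m, β_m, α_h, β_h)`` in ms⁻¹.  The removable
    singularities of α_n (at v = 10 mV above rest) and α_m (v = 25 mV) are
    filled with their analytic limits.
    """
    v = np.asarray(V_mV, dtype=float) - V_rest_mV

    def _vtrap(x, y):
        # x / (exp(x / y) - 1) with the limit y at x -> 0
        x = np.asarray(x, dtype=float)
        small = np.abs(x / y) < 1e-7
        x_safe = np.where(small, y, x)  # keep the denominator non-zero
        return np.where(small, y - x / 2.0,
                        x_safe / np.expm1(np.clip(x_safe / y, -500, 500)))

    a_n = 0.01 * _vtrap(10.0 - v, 10.0)
    b_n = 0.125 * np.exp(-v / 80.0)
    a_m = 0.1 * _vtrap(25.0 - v, 10.0)
    b_m = 4.0 * np.exp(np.clip(-v / 18.0, -500, 500))
    a_h = 0.07 * np.exp(np.clip(-v / 20.0, -500, 500))
    b_h = 1.0 / (np.exp(np.clip((30.0 - v) / 10.0, -500, 500)) + 1.0)
    return a_n, b_n, a_m, b_m, a_h, b_h


def hh_steady_state(V_mV, V_rest_mV: float = -65.0):
    """Equilibrium gate values ``(n∞, m∞, h∞)`` at a held potential."""
    a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(V_mV, V_rest_mV)
    return a_n / (a_n + b_n), a_m / (a_m + b_m), a_h / (a_h + b_h)


def hh_gate_step(state: HHState, V_prev_mV, dt_ms: float,
                 c_T: float = 3.21, V_rest_mV: float = -65.0) -> HHState:
    """Explicit (forward-Euler) gate update from the previous potential.

    ``dg = c(T) · (α(V)(1−g) − β(V)g) · dt``, clamped to [0, 1].
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(V_prev_mV, V_rest_mV)

    def _upd(g, a, b):
        g = g + c_T * (a * (1.0 - g) - b * g) * dt_ms
        return np.clip(g, 0.0, 1.0)

    return HHState(_upd(state.n, a_n, b_n), _upd(state.m, a_m, b_m),
                   _upd(state.h, a_h, b_h))


def hh_current_density(state: HHState, V, spec: MechanismSpec,
                       region: str):
    """Outward HH current density ``c(T)(g_K n⁴(V−E_K) + g_Na m³h(V−E_Na))``.

    ``V`` in volts, result in A m⁻².
    """
    p = spec.regions[region]
    return spec.c_T * (
        p.g_K * state.n ** 4 * (V - spec.E_K)
        + p.g_Na * state.m ** 3 * state.h * (V - spec.E_Na)
    )


def leak_current_density(V, spec: MechanismSpec, region: str):
    """Outward leak density ``c(T) · g_l (V − E_l)`` in A m⁻²."""
    p = spec.regions[region]
    return spec.c_T * p.g_l * (V - spec.leak_reversal(region))


def calibrate_leak_reversal(spec: MechanismSpec, region: str) -> float:
    """Leak reversal potential giving zero net membrane current at rest.

    Solves ``g_l (V_r − E_l) + g_K n∞⁴(V_r−E_K) + g_Na m∞³h∞(V_r−E_Na) = 0``
    with the gates at their resting steady state.  The temperature factor
    multiplies channel and leak currents identically and cancels, so the
    calibration is temperature-independent.
    """
    p = spec.regions[region]
    if p.g_l <= 0:
        raise ValueError("leak calibration requires g_l > 0")
    n_inf, m_inf, h_inf = hh_steady_state(spec.V_rest * 1e3,
                                          spec.V_rest * 1e3)
    i_hh = (p.g_K * n_inf ** 4 * (spec.V_rest - spec.E_K)
            + p.g_Na * m_inf ** 3 * h_inf * (spec.V_rest - spec.E_Na))
    return spec.V_rest + i_hh / p.g_l


def _electrical_region(label: str) -> str:
    """Map a morphology region label to its membrane class."""
    if label.startswith("dendrite"):
        return "dendrite"
    if label in ("axon", "soma"):
        return label
    raise ValueError(f"unknown region label {label!r}")


class MembraneModel:
    """Vectorised HH + calibrated leak over all vertices of a mesh.

    Builds per-vertex conductance arrays from a :class:`MechanismSpec` and
    the morphology's region labels, keeps the gate state, and exposes the
    explicit-update interface the solver consumes.  State arrays broadcast
    over a trailing batch axis when the solver runs an ensemble.
    """

    def __init__(self, spec: MechanismSpec, region_labels, n_batch: int = 1):
        self.spec = spec
        regions = [_electrical_region(str(r)) for r in region_labels]
        self.g_K = np.array([spec.regions[r].g_K for r in regions])
        self.g_Na = np.array([spec.regions[r].g_Na for r in regions])
        self.g_l = np.array([spec.regions[r].g_l for r in regions])
        self.E_l = np.array([spec.leak_reversal(r) for r in regions])
        n = len(regions)
        shape = (n, n_batch) if n_batch > 1 else (n,)
        if n_batch > 1:
            self.g_K = self.g_K[:, None]
            self.g_Na = self.g_Na[:, None]
            self.g_l = self.g_l[:, None]
            self.E_l = self.E_l[:, None]
        n_inf, m_inf, h_inf = hh_steady_state(spec.V_rest * 1e3,
                                              spec.V_rest * 1e3)
        self.state = HHState(np.full(shape, n_inf), np.full(shape, m_inf),
                             np.full(shape, h_inf))

    def prepare(self, V_prev, dt_s: float) -> None:
        """Advance gates explicitly from the previous potential (V, s)."""
        st = self.state
        with np.errstate(over="ignore"):
            a_n, b_n, a_m, b_m, a_h, b_h = hh_rates(
                np.asarray(V_prev) * 1e3, self.spec.V_rest * 1e3)
        f = self.spec.c_T * dt_s * 1e3  # rates are ms⁻¹
        for g, a, b in ((st.n, a_n, b_n), (st.m, a_m, b_m), (st.h, a_h, b_h)):
            g += f * (a - (a + b) * g)
            np.clip(g, 0.0, 1.0, out=g)

    def current_density(self, V_prev):
        """Total outward density (A m⁻²) at the previous potential."""
        return self.densities(V_prev)[0]

    def conductance_density(self):
        """Instantaneous slope conductance (S m⁻²) for the CFL estimate."""
        st = self.state
        return self.spec.c_T * (
            self.g_K * st.n ** 4 + self.g_Na * st.m ** 3 * st.h + self.g_l
        )

    def densities(self, V_prev):
        """Outward current density and slope conductance density, fused.

        Shares the gate powers between the two quantities; this is the
        solver's per-step entry point.
        """
        s, st = self.spec, self.state
        gK_open = self.g_K * (st.n * st.n) ** 2
        gNa_open = self.g_Na * st.m * st.m * st.m * st.h
        cur = s.c_T * (gK_open * (V_prev - s.E_K)
                       + gNa_open * (V_prev - s.E_Na)
                       + self.g_l * (V_prev - self.E_l))
        cond = s.c_T * (gK_open + gNa_open + self.g_l)
        return cur, cond


# ---------------------------------------------------------------------------
# Calcium machinery: VDCC (Borg-Graham formalism), NCX/PMCA pumps, leak


@dataclass(frozen=True)
class VDCCParams:
    """N-type voltage-dependent calcium channel in the Borg-Graham form.

    Gate rates are exponential in voltage,
    ``α = K·exp(zγ(V−V½)F/RT)``, ``β = K·exp(−z(1−γ)(V−V½)F/RT)``,
    with a lower bound ``tau_min`` on the gate time constant.  The channel
    opens with ``m²h``.  The numeric values are configuration defaults in
    the spirit of the published N-type set; they are not literature-exact
    reproductions.
    """

    permeability: float = 3.8e-8   # m s⁻¹
    # activation gate m (exponent 2)
    m_vhalf: float = -0.021  # V
    m_z: float = 3.4
    m_gamma: float = 0.8
    m_K: float = 500.0       # s⁻¹ base rate
    m_tau_min: float = 7e-4  # s
    # inactivation gate h (exponent 1), slow
    h_vhalf: float = -0.040  # V
    h_z: float = -2.0
    h_gamma: float = 0.0
    h_K: float = 12.5        # s⁻¹
    h_tau_min: float = 0.075  # s
    ca_external: float = 2.0  # mM
    ghk: bool = True          # GHK flux (default) vs ohmic


@dataclass(frozen=True)
class PumpParams:
    """NCX (first-order) and PMCA (second-order Hill) extrusion pumps."""

    ncx_vmax: float = 3.0e-9    # mol m⁻² s⁻¹
    ncx_K: float = 1.8e-3       # mM
    pmca_vmax: float = 8.5e-9   # mol m⁻² s⁻¹
    pmca_K: float = 6.0e-5      # mM


@dataclass(frozen=True)
class CalciumParams:
    """Everything the calcium species equation needs."""

    vdcc: VDCCParams = VDCCParams()
    pumps: PumpParams = PumpParams()
    ca_rest: float = 5.0e-5     # mM resting cytosolic concentration
    diffusion: float = 2.2e-10  # m² s⁻¹ axial diffusion coefficient
    ampa_ca_fraction: float = 0.001  # share of AMPA current carried by Ca²⁺


@dataclass
class CalciumState:
    """Per-vertex cytosolic [Ca²⁺] (mM) and VDCC gate states."""

    c: np.ndarray
    m: np.ndarray
    h: np.ndarray


def _bg_rates(V, vhalf, z, gamma, K):
    x = z * (np.asarray(V, dtype=float) - vhalf) * FARADAY / (
        GAS_CONSTANT * BODY_TEMPERATURE)
    alpha = K * np.exp(np.clip(gamma * x, -500, 500))
    beta = K * np.exp(np.clip(-(1.0 - gamma) * x, -500, 500))
    return alpha, beta


def _bg_gate(V, vhalf, z, gamma, K, tau_min):
    """Steady state and effective time constant of one Borg-Graham gate."""
    alpha, beta = _bg_rates(V, vhalf, z, gamma, K)
    x_inf = alpha / (alpha + beta)
    tau = np.maximum(1.0 / (alpha + beta), tau_min)
    return x_inf, tau


def vdcc_gate_steady_state(V, params: VDCCParams = VDCCParams()):
    """Equilibrium ``(m∞, h∞)`` of the VDCC gates at a held potential (V)."""
    m_inf, _ = _bg_gate(V, params.m_vhalf, params.m_z, params.m_gamma,
                        params.m_K, params.m_tau_min)
    h_inf, _ = _bg_gate(V, params.h_vhalf, params.h_z, params.h_gamma,
                        params.h_K, params.h_tau_min)
    return m_inf, h_inf


def ghk_current_density(V, c_in, c_out, permeability, z: int = 2):
    """Goldman–Hodgkin–Katz flux as a current density (A m⁻², outward +).

    Concentrations in mM (= mol m⁻³); the removable singularity at V = 0
    is filled with its limit ``P z F (c_in − c_out)``.
    """
    V = np.asarray(V, dtype=float)
    xi = z * FARADAY * V / (GAS_CONSTANT * BODY_TEMPERATURE)
    small = np.abs(xi) < 1e-9
    xi_safe = np.where(small, 1.0, xi)
    frac = np.where(
        small,
        c_in - c_out,
        (c_in - c_out * np.exp(-xi_safe)) / -np.expm1(-xi_safe) * xi_safe,
    )
    out = permeability * z * FARADAY * frac
    return out if out.shape else float(out)


def vdcc_current_density(state: CalciumState, V, ca,
                         params: VDCCParams = VDCCParams()):
    """Outward-positive VDCC calcium current density (A m⁻²).

    Depolarisation opens the ``m²h`` gate and, with the steep inward
    calcium gradient, produces a negative (inward) current.
    """
    p_open = state.m ** 2 * state.h
    if params.ghk:
        i = ghk_current_density(V, ca, params.ca_external,
                                params.permeability)
    else:  # ohmic alternative against a fixed calcium reversal of +0.14 V
        i = params.permeability * FARADAY * 2.0 * (np.asarray(V) - 0.14)
    return p_open * i


def pump_flux(kind: str, ca, params: PumpParams = PumpParams()):
    """Outward pump flux (mol m⁻² s⁻¹) of NCX or PMCA at [Ca²⁺] = ``ca`` mM.

    NCX is first-order Michaelis–Menten, PMCA a second-order Hill model.
    """
    ca = np.asarray(ca, dtype=float)
    if kind == "NCX":
        out = params.ncx_vmax * ca / (params.ncx_K + ca)
    elif kind == "PMCA":
        out = params.pmca_vmax * ca ** 2 / (params.pmca_K ** 2 + ca ** 2)
    else:
        raise ValueError(f"unknown pump kind {kind!r}")
    return out if out.shape else float(out)


class CalciumModel:
    """VDCC + NCX + PMCA + balancing leak on selected vertices.

    The constant leak influx is calibrated once so that the total membrane
    calcium flux vanishes at the resting state (resting potential, resting
    concentration), mirroring the electrical leak calibration.
    """

    def __init__(self, params: CalciumParams, region_labels,
                 V_rest: float = -0.065, n_batch: int = 1,
                 active_regions: frozenset[str] = frozenset({"soma", "dendrite"})):
        self.params = params
        regions = [_electrical_region(str(r)) for r in region_labels]
        mask = np.array([r in active_regions for r in regions])
        self.mask_idx = np.flatnonzero(mask)
        n = len(regions)
        self.k = n_batch
        shape = (n, n_batch) if n_batch > 1 else (n,)
        sub_shape = ((len(self.mask_idx), n_batch) if n_batch > 1
                     else (len(self.mask_idx),))
        m_inf, h_inf = vdcc_gate_steady_state(V_rest, params.vdcc)
        # gate state lives only on the membrane patches that carry the
        # calcium machinery; concentration is defined everywhere
        self.state = CalciumState(
            c=np.full(shape, params.ca_rest),
            m=np.full(sub_shape, float(m_inf)),
            h=np.full(sub_shape, float(h_inf)),
        )
        # leak calibration: cancel pumps + VDCC at rest (flux, outward +)
        i_vdcc_rest = (float(m_inf) ** 2 * float(h_inf)
                       * ghk_current_density(V_rest, params.ca_rest,
                                             params.vdcc.ca_external,
                                             params.vdcc.permeability))
        rest_flux = (pump_flux("NCX", params.ca_rest, params.pumps)
                     + pump_flux("PMCA", params.ca_rest, params.pumps)
                     + i_vdcc_rest / (2.0 * FARADAY))
        self.leak_flux = -rest_flux  # constant, inward at rest

    def _v_sub(self, V_prev):
        V_prev = np.asarray(V_prev)
        return V_prev[self.mask_idx]

    def prepare(self, V_prev, dt_s: float) -> None:
        """Explicit gate relaxation toward the voltage-dependent target."""
        p = self.params.vdcc
        v = self._v_sub(V_prev)
        with np.errstate(over="ignore"):
            m_inf, m_tau = _bg_gate(v, p.m_vhalf, p.m_z, p.m_gamma,
                                    p.m_K, p.m_tau_min)
            h_inf, h_tau = _bg_gate(v, p.h_vhalf, p.h_z, p.h_gamma,
                                    p.h_K, p.h_tau_min)
        st = self.state
        st.m += dt_s * (m_inf - st.m) / m_tau
        np.clip(st.m, 0.0, 1.0, out=st.m)
        st.h += dt_s * (h_inf - st.h) / h_tau
        np.clip(st.h, 0.0, 1.0, out=st.h)

    def fluxes(self, V_prev):
        """Outward calcium flux and VDCC charge current, full-size arrays.

        Returns ``(flux, i_vdcc)`` in mol m⁻² s⁻¹ and A m⁻²; both are zero
        off the calcium-carrying membrane patches.
        """
        p = self.params
        st = self.state
        c_sub = st.c[self.mask_idx]
        p_open = st.m * st.m * st.h
        i_vdcc_sub = p_open * ghk_current_density(
            self._v_sub(V_prev), c_sub, p.vdcc.ca_external,
            p.vdcc.permeability)
        flux_sub = (pump_flux("NCX", c_sub, p.pumps)
                    + pump_flux("PMCA", c_sub, p.pumps)
                    + i_vdcc_sub / (2.0 * FARADAY) + self.leak_flux)
        flux = np.zeros_like(st.c)
        i_vdcc = np.zeros_like(st.c)
        flux[self.mask_idx] = flux_sub
        i_vdcc[self.mask_idx] = i_vdcc_sub
        return flux, i_vdcc

    def membrane_flux(self, V_prev):
        """Total outward calcium flux density (mol m⁻² s⁻¹)."""
        return self.fluxes(V_prev)[0]

    def vdcc_charge_current(self, V_prev):
        """Outward electric current density of the VDCC (A m⁻²)."""
        return self.fluxes(V_prev)[1]

    def rate_bound(self):
        """Crude linearised membrane rate (m s⁻¹) for the species CFL."""
        p = self.params.pumps
        return p.ncx_vmax / p.ncx_K + p.pmca_vmax / p.pmca_K
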