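"""Study drivers: synapse loss vs. synchrony, and connectivity-driven
network activity — plus the spike/calcium trace analysis they rely on.

The loss study distributes excitatory synapses on a single cell in many
random sample configurations, activates them with a synchrony level
(σ_onset of the normally distributed onset times), removes growing
fractions of them, and asks whether the cell still fires.  The network
study drives a layered network through thalamic inputs on L4/L5B and
measures, per layer, the fraction of "active" somata (V ≥ −45 mV) over
time as a function of the synaptogenesis distance threshold.

All trace analysis here speaks SI units (seconds, volts, mM), matching
the solver's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .membrane import CalciumParams, TABLE_NETWORK_SPEC
from .morphology import NetworkGeometry, NeuronGraph, make_fixture, read_swc
from .netgen import (L23, L4, L5A, L5B, DEFAULT_CONNECTIVITY, LayerSpec,
                     NetgenConfig, create_interconnecting_synapses,
                     generate_network, place_thalamic_inputs)
from .solver import CableSimulation, SimulationConfig
from .synapses import (ActivationPattern, SynapseSet, distribute_primary,
                       remove_uniform, sample_pattern)

__all__ = [
    "detect_spikes",
    "calcium_metrics",
    "CalciumMetrics",
    "LossStudyConfig",
    "run_loss_study",
    "summarize_loss_study",
    "breakdown_loss",
    "NetworkStudyConfig",
    "run_network_study",
    "run_synaptogenesis_scaling",
]


# ---------------------------------------------------------------------------
# Trace analysis


def detect_spikes(times, V, threshold: float = 0.0,
                  refractory: float = 3e-3) -> np.ndarray:
    """Spike times from upward threshold crossings with a refractory gap.

    ``threshold`` in volts (default 0 V), ``refractory`` in seconds
    (default 3 ms); crossings closer than the refractory interval to the
    previous accepted spike are discarded.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    above = V >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    spikes = []
    for i in crossings:
        if not spikes or times[i] - spikes[-1] >= refractory:
            spikes.append(float(times[i]))
    return np.array(spikes)


@dataclass
class CalciumMetrics:
    """Per-spike calcium step sizes and the tail decay time constant."""

    step_sizes: np.ndarray          # mM, one per supplied spike
    decay_tau: float | None         # s; None when the tail is too short
    n_steps: int                    # steps with meaningful height
    flags: list[str] = field(default_factory=list)


def calcium_metrics(times, ca, spike_times,
                    pre_window: float = 1e-3,
                    post_window: float = 8e-3,
                    tail_offset: float = 2e-2,
                    min_step: float | None = None) -> CalciumMetrics:
    """Quantify spike-locked calcium steps and the relaxation tail.

    The step at each spike is the concentration increase from just before
    the spike to ``post_window`` after it (capped at the next spike).  The
    decay constant comes from a log-linear fit of ``c − c_eq`` on the tail
    after the last spike, with the initial concentration as equilibrium
    reference.  ``min_step`` (mM) separates real steps from numerical
    ripple; by default 5% of the largest observed step.
    """
    times = np.asarray(times, dtype=float)
    ca = np.asarray(ca, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    flags: list[str] = []
    if len(spike_times) == 0:
        return CalciumMetrics(np.array([]), None, 0, ["no spikes"])

    steps = []
    for si, ts in enumerate(spike_times):
        t_hi = ts + post_window
        if si + 1 < len(spike_times):
            t_hi = min(t_hi, spike_times[si + 1])
        before = ca[times <= ts - pre_window]
        c0 = before[-1] if len(before) else ca[0]
        window = ca[(times > ts) & (times <= t_hi)]
        c1 = window.max() if len(window) else c0
        steps.append(c1 - c0)
    steps = np.asarray(steps)
    if min_step is None:
        min_step = 0.05 * steps.max() if steps.size and steps.max() > 0 else 0.0
    n_steps = int(np.sum(steps > max(min_step, 0.0))) if steps.size else 0

    c_eq = ca[0]
    tail = times >= spike_times[-1] + tail_offset
    decay_tau = None
    if np.sum(tail) >= 2:
        y = ca[tail] - c_eq
        t = times[tail]
        pos = y > 0
        if np.sum(pos) >= 2:
            slope, _ = np.polyfit(t[pos], np.log(y[pos]), 1)
            if slope < 0:
                decay_tau = -1.0 / slope
            else:
                flags.append("tail not decaying")
        else:
            flags.append("tail at equilibrium")
    else:
        flags.append("tail too short for decay estimate")
    return CalciumMetrics(steps, decay_tau, n_steps, flags)


# ---------------------------------------------------------------------------
# Synapse loss vs. synchrony


def _default_loss_morphology() -> NeuronGraph:
    """Stick-and-soma cell with an axon: the scaled-down study geometry."""
    return make_fixture(
        "ball_and_stick", n_seg=40, length_um=350.0, radius_um=0.7,
        soma_radius_um=8.0, axon_n_seg=25, axon_length_um=150.0,
        axon_radius_um=0.4, cell_type="stick cell")


@dataclass
class LossStudyConfig:
    """Protocol parameters for the synapse-loss study.

    Defaults are the scaled-down geometry (stick cell, 200 synapses, 20
    sample configurations).  ``full_protocol`` builds the original-scale
    variant for a reconstructed pyramidal-cell SWC file (1000 synapses,
    100 samples).
    """

    morphology: NeuronGraph | None = None
    n_syn: int = 200
    n_samples: int = 20
    loss_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.75, 0.9, 0.95, 0.977)
    sigma_onsets_ms: tuple[float, ...] = (0.0, 5.0, 10.0)  # µ_onset = 3σ
    g_max: float = 1.2      # nS
    tau_ms: float = 0.4
    seed: int = 0
    with_calcium: bool = True
    calcium: CalciumParams = field(default_factory=CalciumParams)
    dt_max: float = 2e-5
    settle_ms: float = 25.0  # simulated tail after the last mean onset
    spike_threshold: float = 0.0  # V
    engine: str = "fused"  # "fused" (compiled ensemble) or "reference"

    def __post_init__(self):
        if self.morphology is None:
            self.morphology = _default_loss_morphology()
        if not all(0.0 <= x <= 1.0 for x in self.loss_grid):
            raise ValueError("loss grid must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("need at least one sample configuration")

    @classmethod
    def full_protocol(cls, swc_path, **overrides) -> "LossStudyConfig":
        defaults = dict(
            morphology=read_swc(swc_path, cell_type="L3 pyramidal"),
            n_syn=1000, n_samples=100,
            loss_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
                       0.95, 0.977),
        )
        defaults.update(overrides)
        return cls(**defaults)


def run_loss_study(config: LossStudyConfig) -> pd.DataFrame:
    """Run the loss × synchrony sweep; one row per (sample, loss, σ_onset).

    Per sample the synapse distribution and its activation times are drawn
    once; loss levels then remove nested subsets of that fixed set, so
    each sample's survivors are consistent across the loss grid.  All
    samples of one (loss, σ) cell run as a single batched simulation.
    """
    morph = config.morphology
    rng = np.random.default_rng(config.seed)
    sample_seeds = rng.integers(0, 2 ** 31 - 1, size=(config.n_samples, 3))
    soma_probe = 0
    rows = []
    for sigma in config.sigma_onsets_ms:
        mu = 3.0 * sigma
        pattern = ActivationPattern(mu_onset=mu, sigma_onset=sigma,
                                    mu_tau=config.tau_ms, sigma_tau=0.0)
        # base distributions with sampled activation times, per sample
        bases = []
        for i in range(config.n_samples):
            sset = distribute_primary(morph, config.n_syn,
                                      seed=int(sample_seeds[i, 0]),
                                      g_max=config.g_max)
            bases.append(sample_pattern(sset, pattern,
                                        seed=int(sample_seeds[i, 1])))
        duration = (mu + 2.5 * sigma + config.settle_ms) * 1e-3
        for loss in config.loss_grid:
            sets = [remove_uniform(bases[i], loss,
                                   seed=int(sample_seeds[i, 2]))
                    for i in range(config.n_samples)]
            sim_cfg = SimulationConfig(
                geometry=morph, spec=TABLE_NETWORK_SPEC,
                synapses=sets,
                calcium=config.calcium if config.with_calcium else None,
                duration=duration, dt_max=config.dt_max,
                probes=[soma_probe, morph.n_vertices - 1],
            )
            if config.engine == "fused":
                from .fastpath import run_alpha_ensemble
                times, V, ca_tr = run_alpha_ensemble(sim_cfg)
            elif config.engine == "reference":
                res = CableSimulation(sim_cfg).run(duration)
                times = res.times
                V = (res.V if config.n_samples > 1
                     else res.V[:, :, None])
                ca_tr = (None if not config.with_calcium
                         else (res.ca if config.n_samples > 1
                               else res.ca[:, :, None]))
            else:
                raise ValueError(f"unknown engine {config.engine!r}")
            for i in range(config.n_samples):
                spikes = detect_spikes(times, V[:, 0, i],
                                       threshold=config.spike_threshold)
                row = dict(sample=i, loss=loss, sigma_onset_ms=sigma,
                           n_synapses=len(sets[i]),
                           n_spikes=len(spikes))
                if config.with_calcium:
                    ca = ca_tr[:, 0, i]
                    row["ca_peak"] = float(ca.max())
                    cm = calcium_metrics(times, ca, spikes)
                    row["ca_steps"] = cm.n_steps
                    row["ca_decay_tau"] = (cm.decay_tau
                                           if cm.decay_tau is not None
                                           else np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_loss_study(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD spike count and responder fraction per (loss, σ_onset)."""
    g = table.groupby(["sigma_onset_ms", "loss"])
    out = g["n_spikes"].agg(["mean", "std"]).rename(
        columns={"mean": "spikes_mean", "std": "spikes_sd"})
    out["responding"] = g["n_spikes"].apply(lambda s: float((s >= 1).mean()))
    return out.reset_index()


def breakdown_loss(summary: pd.DataFrame, sigma: float,
                   responder_threshold: float = 0.9) -> float:
    """Largest loss fraction at which ≥ 90% of samples still fire.

    Returns −inf when the cell never responds at that synchrony level.
    """
    sel = summary[summary["sigma_onset_ms"] == sigma]
    ok = sel[sel["responding"] >= responder_threshold]
    return float(ok["loss"].max()) if len(ok) else float("-inf")


# ---------------------------------------------------------------------------
# Network study


def _default_network_layers(scale: int = 1) -> list[LayerSpec]:
    return [
        LayerSpec(L23, 7 * scale, (150.0, 400.0)),
        LayerSpec(L4, 7 * scale, (400.0, 600.0)),
        LayerSpec(L5A, 3 * scale, (600.0, 800.0)),
        LayerSpec(L5B, 3 * scale, (800.0, 1000.0)),
    ]


@dataclass
class NetworkStudyConfig:
    """Thalamic activation of a layered network, per synapse distance."""

    netgen: NetgenConfig | None = None
    network: NetworkGeometry | None = None  # overrides netgen when given
    dist_synapse: float = 3.0    # µm
    duration: float = 0.02       # s
    active_threshold: float = -0.045  # V
    pattern: ActivationPattern = field(default_factory=lambda: ActivationPattern(
        mu_onset=5.0, sigma_onset=2.5, mu_tau=2.5, sigma_tau=0.1))
    thalamic_g_max: float = 1.2  # nS
    seed: int = 0
    dt_max: float = 2e-5
    record_interval: float = 2e-4
    active_synapse_window: float = 8.5e-3  # s (≈ 5 τ₂)

    def __post_init__(self):
        if self.netgen is None and self.network is None:
            self.netgen = NetgenConfig(layers=_default_network_layers(),
                                       seed=self.seed)


def run_network_study(config: NetworkStudyConfig) -> dict:
    """Simulate one network and measure layered activity.

    Returns a dict with
    ``activity`` — tidy frame (t, cell_type, fraction of active somata);
    ``projections`` — active interconnecting synapse counts per
    pre→post type pair over time;
    ``peaks`` — per layer the peak active fraction and its time;
    ``n_synapses`` — interconnecting synapse count;
    ``result`` — the raw :class:`SimulationResult`.
    """
    net = (config.network if config.network is not None
           else generate_network(config.netgen))
    rng = np.random.default_rng(config.seed)
    thalamic = place_thalamic_inputs(net, seed=int(rng.integers(2 ** 31 - 1)),
                                     g_max=config.thalamic_g_max)
    thalamic = sample_pattern(thalamic, config.pattern,
                              seed=int(rng.integers(2 ** 31 - 1)))
    inter = create_interconnecting_synapses(net, config.dist_synapse)
    allsyn = SynapseSet(list(thalamic) + list(inter))

    sim_cfg = SimulationConfig(
        geometry=net, spec=TABLE_NETWORK_SPEC, synapses=allsyn,
        duration=config.duration, dt_max=config.dt_max,
        record_interval=config.record_interval,
        probes=None,  # default: every soma
    )
    res = CableSimulation(sim_cfg).run(config.duration)

    types = np.array([c.cell_type for c in net.cells])
    act_rows = []
    for ti, t in enumerate(res.times):
        v = res.V[ti]
        for ct in sorted(set(types)):
            mask = types == ct
            frac = float(np.mean(v[mask] >= config.active_threshold))
            act_rows.append(dict(t=t, cell_type=ct, fraction=frac))
    activity = pd.DataFrame(act_rows)

    proj_rows = []
    win = config.active_synapse_window
    inter_recs = [r for r in allsyn if r.kind == "interconnecting"]
    for t in res.times:
        counts: dict[tuple[str, str], int] = {}
        for r in inter_recs:
            if any(0.0 <= t - ta * 1e-3 <= win for ta in r.activation_times):
                key = (types[r.pre_cell], types[r.cell])
                counts[key] = counts.get(key, 0) + 1
        for (pre, post), c in counts.items():
            proj_rows.append(dict(t=t, pre=pre, post=post, active=c))
    projections = pd.DataFrame(proj_rows,
                               columns=["t", "pre", "post", "active"])

    peak_rows = []
    for ct in sorted(set(types)):
        sel = activity[activity["cell_type"] == ct]
        idx = sel["fraction"].to_numpy().argmax()
        peak_rows.append(dict(cell_type=ct,
                              peak_fraction=float(sel["fraction"].iloc[idx]),
                              peak_time=float(sel["t"].iloc[idx])))
    peaks = pd.DataFrame(peak_rows)

    return dict(activity=activity, projections=projections, peaks=peaks,
                n_synapses=len(inter), result=res)


# ---------------------------------------------------------------------------
# Synaptogenesis scaling


def _dense_neuropil_config(seed: int = 0) -> NetgenConfig:
    """A meandering-neurite box used to probe the distance rule's scaling.

    Many overlapping arbors at roughly uniform length density, so that
    the number of eligible axon–dendrite section pairs within a distance
    d grows like the volume of the search sphere.
    """
    from .netgen import CellTypeParams
    params = CellTypeParams(
        soma_radius=5.0, dend_radius=0.5, axon_radius=0.4,
        edge_length=4.0, n_basal=4, basal_length=300.0,
        apical_length=0.0, axon_length=600.0, axon_target_depth=None,
        tortuosity=0.5)
    return NetgenConfig(
        layers=[LayerSpec(L23, 15, (10.0, 190.0)),
                LayerSpec(L4, 15, (10.0, 190.0))],
        box_xy=(200.0, 200.0), min_separation=12.0,
        cell_params={L23: params, L4: params},
        seed=seed)


def run_synaptogenesis_scaling(seed: int = 0,
                               distances=(1.0, 2.0, 3.0, 4.0, 5.0),
                               netgen_config: NetgenConfig | None = None,
                               section_length: float = 0.25):
    """Synapse count vs. distance threshold on a fixed random network.

    Returns ``(table, slope)`` where ``slope`` is the log-log regression
    slope of synapse count against dist_synapse; the distance rule in
    homogeneous neuropil predicts a value near 3 (search-sphere volume).
    The geometry is regridded to short sections before the distance rule
    is evaluated: section-pair counting carries a finite-section-length
    correction of relative size O(section length / distance), so the
    asymptotic cubic law only emerges when sections are much shorter than
    the probed distances.
    """
    from .morphology import resample_edges
    cfg = netgen_config if netgen_config is not None else _dense_neuropil_config(seed)
    net = generate_network(cfg)
    if section_length is not None:
        net = NetworkGeometry(
            cells=[resample_edges(c, section_length) for c in net.cells],
            bounding_box=net.bounding_box)
    from .netgen import count_distance_rule_pairs
    counts = count_distance_rule_pairs(net, distances)
    table = pd.DataFrame({"dist_synapse": list(distances), "count": counts})
    valid = table["count"] > 0
    if valid.sum() < 2:
        raise ValueError("not enough non-empty distance levels for a fit")
    slope, _ = np.polyfit(np.log(table.loc[valid, "dist_synapse"]),
                          np.log(table.loc[valid, "count"]), 1)
    return table, float(slope)
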