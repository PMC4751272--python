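"""Synapse placement, activation patterns and conductance kinetics.

Two synapse categories are modelled:

* *primary* synapses — external inputs with an alpha-function conductance
  time course ``g(t) = g_max · (t−t_onset)/τ · exp(−(t−t_onset−τ)/τ)``,
  active on ``[t_onset, t_onset + 6τ]``.  They stand in for presynaptic
  partners outside the simulated network (e.g. thalamic afferents).
* *interconnecting* synapses — axon→dendrite contacts inside a network,
  triggered when the presynaptic membrane potential crosses a threshold
  and following a bi-exponential conductance normalised to peak at
  ``g_max``.

Units at this level are the ones experimentalists use: conductance in nS,
time in ms, potential in mV, current in nA.  The solver converts to SI.

Placement of primary synapses is length-weighted: edge ``j`` is drawn with
probability ``‖e_j‖ / Σ_k ‖e_k‖`` over the dendritic edges, and the
position on the edge uniformly in (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .morphology import DENDRITE_REGIONS, NeuronGraph

__all__ = [
    "PRIMARY",
    "INTERCONNECTING",
    "SynapseRecord",
    "SynapseSet",
    "ActivationPattern",
    "EdgeSampleSpace",
    "build_edge_sample_space",
    "distribute_primary",
    "remove_uniform",
    "sample_pattern",
    "alpha_conductance",
    "alpha_current",
    "biexp_peak_time",
    "biexp_normalizer",
    "biexp_conductance",
    "biexp_current",
    "update_activation",
]

logger = logging.getLogger(__name__)

PRIMARY = "primary"
INTERCONNECTING = "interconnecting"


@dataclass
class SynapseRecord:
    """One placed synapse.

    ``edge`` is identified by the child vertex of the (parent → child)
    morphology edge it sits on; ``offset`` ∈ (0, 1) is the position along
    that edge (0 = parent end).  ``cell`` indexes the postsynaptic cell in
    a network (0 for single-cell work).
    """

    kind: str
    cell: int
    edge: int
    offset: float
    g_max: float = 1.2          # nS
    # primary kinetics
    t_onset: float = float("nan")  # ms
    tau: float = float("nan")      # ms
    # interconnecting kinetics
    tau1: float = 0.2           # ms
    tau2: float = 1.7           # ms
    E_rev: float = 0.0          # mV
    V_th: float = -10.0         # mV
    pre_cell: int = -1
    pre_vertex: int = -1
    activation_times: list[float] = field(default_factory=list)
    _above: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in (PRIMARY, INTERCONNECTING):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if not 0.0 < self.offset < 1.0:
            raise ValueError("offset must lie in (0, 1)")
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")
        if self.kind == INTERCONNECTING and not 0 < self.tau1 < self.tau2:
            raise ValueError("need tau2 > tau1 > 0")


class SynapseSet:
    """An ordered collection of :class:`SynapseRecord`."""

    def __init__(self, records: list[SynapseRecord] | None = None):
        self.records: list[SynapseRecord] = list(records or [])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i) -> SynapseRecord:
        return self.records[i]

    def of_kind(self, kind: str) -> "SynapseSet":
        return SynapseSet([r for r in self.records if r.kind == kind])

    def extend(self, other: "SynapseSet") -> None:
        self.records.extend(other.records)

    def to_dicts(self) -> list[dict]:
        out = []
        for r in self.records:
            d = {
                "kind": r.kind, "cell": r.cell, "edge": r.edge,
                "offset": r.offset, "g_max": r.g_max,
            }
            if r.kind == PRIMARY:
                d.update(t_onset=r.t_onset, tau=r.tau)
            else:
                d.update(tau1=r.tau1, tau2=r.tau2, E_rev=r.E_rev,
                         V_th=r.V_th, pre_cell=r.pre_cell,
                         pre_vertex=r.pre_vertex,
                         activation_times=list(r.activation_times))
            out.append(d)
        return out

    @classmethod
    def from_dicts(cls, dicts: list[dict]) -> "SynapseSet":
        recs = []
        for d in dicts:
            d = dict(d)
            times = d.pop("activation_times", [])
            rec = SynapseRecord(**{k: v for k, v in d.items()})
            rec.activation_times = list(times)
            recs.append(rec)
        return cls(recs)


@dataclass(frozen=True)
class ActivationPattern:
    """Normal-distribution parameters for onset time and rise/decay τ (ms)."""

    mu_onset: float
    sigma_onset: float
    mu_tau: float
    sigma_tau: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_onset < 0 or self.sigma_tau < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class EdgeSampleSpace:
    """Dendritic edges with lengths and length-proportional probabilities."""

    edge_ids: np.ndarray     # child-vertex ids
    lengths: np.ndarray      # µm
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = self.probabilities
        if len(p) == 0:
            raise ValueError("empty edge sample space")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")


def build_edge_sample_space(
    graph: NeuronGraph, regions: frozenset[str] | set[str] = DENDRITE_REGIONS
) -> EdgeSampleSpace:
    """Length-weighted sample space over the edges in the given regions.

    An edge belongs to the region of its child vertex (the convention used
    throughout: an edge carries the label of its distal end).
    """
    edges = graph.edges
    lengths = graph.edge_lengths()
    mask = np.array([str(graph.regions[c]) in regions for _, c in edges])
    if not mask.any():
        raise ValueError(f"no edges in regions {sorted(regions)}")
    ids = edges[mask, 1]
    lens = lengths[mask]
    return EdgeSampleSpace(ids, lens, lens / lens.sum())


def distribute_primary(
    graph: NeuronGraph,
    n_syn: int,
    regions: frozenset[str] | set[str] = DENDRITE_REGIONS,
    seed: int | np.random.Generator = 0,
    g_max: float = 1.2,
    cell: int = 0,
) -> SynapseSet:
    """Place ``n_syn`` primary synapses with length-weighted edge choice.

    Kinetic parameters (``t_onset``, ``tau``) remain unset until a pattern
    is sampled with :func:`sample_pattern`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    space = build_edge_sample_space(graph, regions)
    idx = rng.choice(len(space.edge_ids), size=n_syn, p=space.probabilities)
    offsets = rng.uniform(0.0, 1.0, size=n_syn)
    # uniform(0,1) excludes 1; nudge exact zeros into the open interval
    offsets[offsets == 0.0] = 0.5
    return SynapseSet([
        SynapseRecord(PRIMARY, cell=cell, edge=int(space.edge_ids[i]),
                      offset=float(o), g_max=g_max)
        for i, o in zip(idx, offsets)
    ])


def remove_uniform(
    synapse_set: SynapseSet, loss_fraction: float, seed: int = 0
) -> SynapseSet:
    """Remove a uniformly chosen fraction of the synapses.

    ``round((1 − loss_fraction)·n)`` synapses survive (round-half-even),
    drawn without replacement.  For a fixed seed the survivor sets are
    nested: a higher loss fraction keeps a subset of a lower one's
    survivors, because both are prefixes of the same random permutation.
    """
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss_fraction must lie in [0, 1]")
    n = len(synapse_set)
    n_keep = int(round((1.0 - loss_fraction) * n))
    order = np.random.default_rng(seed).permutation(n)
    keep = np.sort(order[:n_keep])
    return SynapseSet([synapse_set[i] for i in keep])


def sample_pattern(
    synapse_set: SynapseSet, pattern: ActivationPattern, seed: int = 0
) -> SynapseSet:
    """Draw ``t_onset ~ N(μ_onset, σ_onset²)`` and ``τ ~ N(μ_τ, σ_τ²)``.

    With ``σ = 0`` every synapse receives exactly the mean (the fully
    synchronous case).  Non-positive τ draws are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    records = []
    n_rejected = 0
    for rec in synapse_set:
        if rec.kind != PRIMARY:
            raise ValueError("activation patterns apply to primary synapses")
        t_on = (pattern.mu_onset if pattern.sigma_onset == 0.0
                else float(rng.normal(pattern.mu_onset, pattern.sigma_onset)))
        if pattern.sigma_tau == 0.0:
            tau = pattern.mu_tau
        else:
            tau = float(rng.normal(pattern.mu_tau, pattern.sigma_tau))
            while tau <= 0.0:
                n_rejected += 1
                tau = float(rng.normal(pattern.mu_tau, pattern.sigma_tau))
        records.append(replace(rec, t_onset=t_on, tau=tau,
                               activation_times=list(rec.activation_times)))
    if n_rejected:
        logger.info("rejected %d non-positive tau draws", n_rejected)
    return SynapseSet(records)


# ---------------------------------------------------------------------------
# Conductance kinetics


def alpha_conductance(t, t_onset, tau, g_max):
    """Alpha-function conductance (nS); zero outside [t_onset, t_onset+6τ].

    Peaks at exactly ``g_max`` at ``t = t_onset + τ``.  Vectorised over any
    broadcastable combination of arguments.
    """
    t = np.asarray(t, dtype=float)
    dt = t - t_onset
    with np.errstate(invalid="ignore"):
        g = g_max * (dt / tau) * np.exp(-(dt - tau) / tau)
    g = np.where((dt >= 0.0) & (dt <= 6.0 * tau), g, 0.0)
    return g if g.shape else float(g)


def alpha_current(rec: SynapseRecord, V: float, t: float,
                  E_rev: float = 0.0) -> float:
    """Outward-positive synaptic current in nA: ``g(t)·(V − E_rev)``.

    The assembly negates this once when adding it to the membrane balance,
    so a synapse with E_rev = 0 mV depolarises a resting cell.
    """
    g = alpha_conductance(t, rec.t_onset, rec.tau, rec.g_max)
    return g * (V - E_rev) * 1e-3  # nS·mV = pA → nA


def biexp_peak_time(tau1: float, tau2: float) -> float:
    """Time of peak conductance after activation (ms)."""
    if tau1 == tau2:
        raise ValueError("bi-exponential requires tau1 != tau2")
    return tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)


def biexp_normalizer(tau1: float, tau2: float) -> float:
    """Factor that makes the conductance equal g_max at the peak time."""
    t_max = biexp_peak_time(tau1, tau2)
    return 1.0 / (np.exp(-t_max / tau2) - np.exp(-t_max / tau1))


def biexp_conductance(t_since, tau1, tau2, g_max):
    """Bi-exponential conductance (nS) ``t_since`` ms after activation."""
    n = biexp_normalizer(tau1, tau2)
    t = np.asarray(t_since, dtype=float)
    g = g_max * n * (np.exp(-t / tau2) - np.exp(-t / tau1))
    g = np.where(t >= 0.0, g, 0.0)
    return g if g.shape else float(g)


def biexp_current(rec: SynapseRecord, V: float,
                  t_since_activation: float) -> float:
    """Outward-positive current (nA) of an activated interconnecting synapse."""
    g = biexp_conductance(t_since_activation, rec.tau1, rec.tau2, rec.g_max)
    return g * (V - rec.E_rev) * 1e-3


def update_activation(rec: SynapseRecord, V_pre: float, t: float) -> SynapseRecord:
    """Register threshold crossings of the presynaptic potential.

    An upward crossing of ``V_th`` appends an activation time; the synapse
    can only re-activate after the presynaptic potential has fallen below
    threshold again.  ``V_pre`` must be the *previous* time step's solution
    (the one-step synaptic lag that decouples cells within a step).
    """
    above = V_pre >= rec.V_th
    if above and not rec._above:
        rec.activation_times.append(float(t))
    rec._above = above
    return rec
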