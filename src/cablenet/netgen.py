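"""Synthetic layered cortical networks and distance-rule synaptogenesis.

Cells are stylized parametric morphologies (tortuous dendrites and axons
grown from per-type templates), placed with their somata uniformly inside
per-layer depth slabs.  Interconnecting synapses are created by the
distance rule: wherever the minimum Euclidean distance between an axon
section of one cell and a dendrite section of another falls below the
global threshold ``dist_synapse`` — and the type pair is permitted by the
connectivity matrix — one synapse is placed at the closest points.

The postsynaptic peak conductance scales with the synapse's path distance
to the soma, ``g_max = (1 + 0.001·d_soma[µm]) · g_base(T1, T2)``, with the
type-pair base conductances of the cortical connectivity table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .morphology import (APICAL, AXON, BASAL, NetworkGeometry, NeuronGraph,
                         SOMA)
from .synapses import INTERCONNECTING, SynapseRecord, SynapseSet, \
    distribute_primary

__all__ = [
    "ForbiddenPairError",
    "ConnectivityMatrix",
    "DEFAULT_CONNECTIVITY",
    "CellTypeParams",
    "DEFAULT_CELL_PARAMS",
    "LayerSpec",
    "NetgenConfig",
    "generate_network",
    "create_interconnecting_synapses",
    "synaptic_conductance",
    "place_thalamic_inputs",
    "segment_segment_distance",
]

L23 = "L2/3 pyramidal"
L4 = "L4 stellate"
L5A = "L5A pyramidal"
L5B = "L5B pyramidal"


class ForbiddenPairError(KeyError):
    """The connectivity matrix forbids this pre→post type pair."""


class ConnectivityMatrix:
    """Allowed pre→post cell-type pairs with base conductances (nS).

    A forbidden pair raises :class:`ForbiddenPairError` on lookup — it is
    never reported as 0 nS, since a zero-conductance synapse and "no
    synapse" are different biological statements.
    """

    def __init__(self, table: dict[str, dict[str, float]]):
        for pre, row in table.items():
            for post, g in row.items():
                if g <= 0:
                    raise ValueError(
                        f"base conductance for {pre}→{post} must be > 0")
        self._table = {pre: dict(row) for pre, row in table.items()}

    def allowed(self, pre: str, post: str) -> bool:
        return post in self._table.get(pre, {})

    def base_conductance(self, pre: str, post: str) -> float:
        try:
            return self._table[pre][post]
        except KeyError:
            raise ForbiddenPairError(f"no synapse allowed for {pre}→{post}")

    def pairs(self):
        for pre, row in self._table.items():
            for post, g in row.items():
                yield pre, post, g


#: Cortical base conductance table (nS); missing entries are forbidden.
DEFAULT_CONNECTIVITY = ConnectivityMatrix({
    L23: {L23: 1.0, L5A: 0.8, L5B: 0.3},
    L4: {L23: 0.7, L4: 1.6, L5A: 0.6},
    L5A: {L23: 0.5, L5A: 2.0},
    L5B: {L5B: 1.3},
})


def synaptic_conductance(base: float, dsd: float) -> float:
    """Distance-scaled peak conductance ``(1 + 0.001·dsd) · base`` (nS).

    ``dsd`` is the postsynaptic site's path distance to the soma in µm.
    """
    if base <= 0:
        raise ValueError("base conductance must be > 0")
    if dsd < 0:
        raise ValueError("distance to soma must be >= 0")
    return (1.0 + 0.001 * dsd) * base


# ---------------------------------------------------------------------------
# Stylized morphologies


@dataclass(frozen=True)
class CellTypeParams:
    """Template for a stylized cell: branch counts, lengths, calibers (µm).

    ``tortuosity`` is the standard deviation of the random direction
    perturbation applied per growth step; neurites meander like real
    neuropil instead of running straight.
    """

    soma_radius: float = 8.0
    dend_radius: float = 0.6
    axon_radius: float = 0.4
    edge_length: float = 4.0
    n_basal: int = 4
    basal_length: float = 150.0
    apical_length: float = 0.0       # 0 = no apical trunk (stellate)
    apical_target_depth: float = 100.0
    axon_length: float = 400.0
    axon_target_depth: float | None = None  # None = local (random walk)
    tortuosity: float = 0.45


DEFAULT_CELL_PARAMS: dict[str, CellTypeParams] = {
    L23: CellTypeParams(apical_length=200.0, apical_target_depth=60.0,
                        axon_length=500.0, axon_target_depth=800.0),
    L4: CellTypeParams(n_basal=5, basal_length=160.0, apical_length=0.0,
                       axon_length=450.0, axon_target_depth=280.0),
    L5A: CellTypeParams(apical_length=450.0, apical_target_depth=250.0,
                        basal_length=180.0, axon_length=450.0,
                        axon_target_depth=300.0),
    L5B: CellTypeParams(apical_length=500.0, apical_target_depth=300.0,
                        basal_length=200.0, axon_length=400.0,
                        axon_target_depth=None),
}


def _tortuous_path(rng, start, bias_dir, length, step, tortuosity):
    """Random-walk polyline of total length ``length`` biased along a direction.

    The direction noise scales with √step and the homing bias with step,
    so the walk's persistence length is independent of the sectioning:
    refining ``step`` changes the resolution, not the shape statistics.
    """
    n_steps = max(1, int(round(length / step)))
    pts = np.empty((n_steps, 3))
    d = np.asarray(bias_dir, dtype=float)
    d = d / np.linalg.norm(d)
    pos = np.asarray(start, dtype=float).copy()
    heading = d.copy()
    noise_scale = tortuosity * np.sqrt(step / 4.0)  # per 4 µm reference step
    bias_gain = 0.075 * step
    for i in range(n_steps):
        heading = heading + rng.normal(scale=noise_scale, size=3) + bias_gain * d
        heading /= np.linalg.norm(heading)
        pos = pos + heading * step
        pts[i] = pos
    return pts


def _stylized_cell(cell_type: str, soma_pos, rng,
                   params: CellTypeParams) -> NeuronGraph:
    soma_pos = np.asarray(soma_pos, dtype=float)
    pos = [soma_pos]
    rad = [params.soma_radius]
    reg = [SOMA]
    par = [-1]

    def _append_path(pts, radius, region, parent):
        for p in pts:
            pos.append(p)
            rad.append(radius)
            reg.append(region)
            par.append(parent)
            parent = len(pos) - 1
        return parent

    # basal dendrites: radiate in random directions
    for _ in range(params.n_basal):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = _tortuous_path(rng, soma_pos, d, params.basal_length,
                             params.edge_length, params.tortuosity)
        _append_path(pts, params.dend_radius, BASAL, 0)
    # apical trunk: climbs toward the target depth (z is depth, µm)
    if params.apical_length > 0:
        target = np.array([soma_pos[0], soma_pos[1],
                           params.apical_target_depth])
        d = target - soma_pos
        if np.linalg.norm(d) < 1e-9:
            d = np.array([0.0, 0.0, -1.0])
        pts = _tortuous_path(rng, soma_pos, d, params.apical_length,
                             params.edge_length, params.tortuosity)
        _append_path(pts, params.dend_radius, APICAL, 0)
    # axon: steered toward its laminar target, or meandering locally
    if params.axon_target_depth is None:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
    else:
        target = np.array([soma_pos[0] + rng.normal(scale=30.0),
                           soma_pos[1] + rng.normal(scale=30.0),
                           params.axon_target_depth])
        d = target - soma_pos
        d /= np.linalg.norm(d)
    pts = _tortuous_path(rng, soma_pos, d, params.axon_length,
                         params.edge_length, params.tortuosity)
    _append_path(pts, params.axon_radius, AXON, 0)
    return NeuronGraph(np.array(pos), np.array(rad),
                       np.array(reg, dtype=object), np.array(par),
                       cell_type=cell_type)


# ---------------------------------------------------------------------------
# Network generation


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer: cell type, count and depth slab (µm)."""

    cell_type: str
    count: int
    depth_range: tuple[float, float]

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("cell count must be >= 0")


@dataclass
class NetgenConfig:
    """Parameters of the layered network generator."""

    layers: list[LayerSpec]
    box_xy: tuple[float, float] = (250.0, 250.0)  # lateral extents, µm
    dist_synapse: float = 3.0                     # µm
    min_separation: float = 15.0                  # µm between somata
    thalamic_means: dict[str, float] = field(
        default_factory=lambda: {L4: 30.0, L5B: 25.0})
    cell_params: dict[str, CellTypeParams] = field(
        default_factory=lambda: dict(DEFAULT_CELL_PARAMS))
    seed: int = 0

    def __post_init__(self):
        if self.dist_synapse <= 0:
            raise ValueError("dist_synapse must be > 0")


def _place_somata(rng, count, box_xy, depth_range, min_sep,
                  existing: list[np.ndarray]) -> list[np.ndarray]:
    placed = []
    lo, hi = depth_range
    tries = 0
    while len(placed) < count:
        p = np.array([rng.uniform(0, box_xy[0]), rng.uniform(0, box_xy[1]),
                      rng.uniform(lo, hi)])
        ok = all(np.linalg.norm(p - q) >= min_sep for q in existing + placed)
        if ok:
            placed.append(p)
        tries += 1
        if tries > 200 * max(count, 1):
            raise ValueError(
                f"cannot place {count} somata with separation {min_sep} µm "
                f"in {box_xy[0]}×{box_xy[1]}×{hi - lo} µm; box too small")
    return placed


def generate_network(config: NetgenConfig) -> NetworkGeometry:
    """Generate a layered network, deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    cells: list[NeuronGraph] = []
    all_somata: list[np.ndarray] = []
    depth_min, depth_max = np.inf, -np.inf
    for layer in config.layers:
        depth_min = min(depth_min, layer.depth_range[0])
        depth_max = max(depth_max, layer.depth_range[1])
        somata = _place_somata(rng, layer.count, config.box_xy,
                               layer.depth_range, config.min_separation,
                               all_somata)
        all_somata.extend(somata)
        params = config.cell_params.get(layer.cell_type, CellTypeParams())
        for p in somata:
            cells.append(_stylized_cell(layer.cell_type, p, rng, params))
    if not cells:
        return NetworkGeometry(cells=[], bounding_box=np.zeros((2, 3)))
    bbox = np.array([[0.0, 0.0, depth_min],
                     [config.box_xy[0], config.box_xy[1], depth_max]])
    return NetworkGeometry(cells=cells, bounding_box=bbox)


# ---------------------------------------------------------------------------
# Distance-rule synaptogenesis


def segment_segment_distance(P0, P1, Q0, Q1):
    """Minimum distance between segment batches [P0,P1] and [Q0,Q1].

    Returns ``(dist, s, u)`` with the closest-point parameters on the
    first and second segment.  Clamped-quadratic closest-point algorithm,
    vectorised over leading axes.
    """
    P0, P1 = np.atleast_2d(P0), np.atleast_2d(P1)
    Q0, Q1 = np.atleast_2d(Q0), np.atleast_2d(Q1)
    d1 = P1 - P0
    d2 = Q1 - Q0
    r = P0 - Q0
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-14, np.clip((b * f - c * e) / np.where(
        denom > 1e-14, denom, 1.0), 0.0, 1.0), 0.0)
    u = (b * s + f) / np.where(e > 1e-14, e, 1.0)
    u_cl = np.clip(u, 0.0, 1.0)
    # if u was clamped, recompute s for the clamped u
    s = np.where(u != u_cl,
                 np.clip((u_cl * b - c) / np.where(a > 1e-14, a, 1.0),
                         0.0, 1.0),
                 s)
    u = u_cl
    closest_p = P0 + s[:, None] * d1
    closest_q = Q0 + u[:, None] * d2
    dist = np.linalg.norm(closest_p - closest_q, axis=1)
    return dist, s, u


def _edge_segments(net: NetworkGeometry, region_test):
    """Collect (p0, p1, cell, child_vertex, length) for matching edges."""
    p0s, p1s, cells_, childs = [], [], [], []
    for ci, cell in enumerate(net.cells):
        edges = cell.edges
        for p, c in edges:
            if region_test(str(cell.regions[c])):
                p0s.append(cell.positions[p])
                p1s.append(cell.positions[c])
                cells_.append(ci)
                childs.append(int(c))
    if not p0s:
        return (np.empty((0, 3)), np.empty((0, 3)),
                np.empty(0, int), np.empty(0, int))
    return (np.asarray(p0s), np.asarray(p1s),
            np.asarray(cells_, int), np.asarray(childs, int))


def _qualifying_pairs(net: NetworkGeometry, dist_synapse: float,
                      conn: ConnectivityMatrix):
    """All allowed axon/dendrite edge pairs with min distance < threshold.

    Returns a dict of parallel arrays (edge indices into the axon and
    dendrite segment lists, closest-point parameters, distances) plus the
    segment lists themselves.  One KD-tree pass over segment midpoints
    prunes the candidate pairs before the exact segment distances.
    """
    a0, a1, a_cell, a_child = _edge_segments(net, lambda r: r == AXON)
    d0, d1, d_cell, d_child = _edge_segments(
        net, lambda r: r in (BASAL, APICAL))
    empty = dict(ai=np.empty(0, int), di=np.empty(0, int),
                 s=np.empty(0), u=np.empty(0), dist=np.empty(0),
                 a_cell=a_cell, a_child=a_child,
                 d_cell=d_cell, d_child=d_child)
    if len(a0) == 0 or len(d0) == 0:
        return empty

    type_names = sorted({c.cell_type for c in net.cells})
    t_code = {t: i for i, t in enumerate(type_names)}
    cell_code = np.array([t_code[c.cell_type] for c in net.cells])
    allowed = np.zeros((len(type_names), len(type_names)), dtype=bool)
    for i, pre in enumerate(type_names):
        for j, post in enumerate(type_names):
            allowed[i, j] = conn.allowed(pre, post)

    a_half = 0.5 * np.linalg.norm(a1 - a0, axis=1).max()
    d_half = 0.5 * np.linalg.norm(d1 - d0, axis=1).max()
    tree_a = cKDTree(0.5 * (a0 + a1))
    tree_d = cKDTree(0.5 * (d0 + d1))
    radius = dist_synapse + a_half + d_half
    pairs = tree_a.query_ball_tree(tree_d, r=radius)

    counts = np.fromiter((len(p) for p in pairs), dtype=int, count=len(pairs))
    ai_arr = np.repeat(np.arange(len(pairs)), counts)
    di_arr = np.fromiter((di for p in pairs for di in p), dtype=int,
                         count=int(counts.sum()))
    if len(ai_arr) == 0:
        return empty
    keep = (a_cell[ai_arr] != d_cell[di_arr]) & allowed[
        cell_code[a_cell[ai_arr]], cell_code[d_cell[di_arr]]]
    ai_arr, di_arr = ai_arr[keep], di_arr[keep]
    if len(ai_arr) == 0:
        return empty
    dist, s, u = segment_segment_distance(a0[ai_arr], a1[ai_arr],
                                          d0[di_arr], d1[di_arr])
    hit = dist < dist_synapse
    return dict(ai=ai_arr[hit], di=di_arr[hit], s=s[hit], u=u[hit],
                dist=dist[hit], a_cell=a_cell, a_child=a_child,
                d_cell=d_cell, d_child=d_child)


def count_distance_rule_pairs(net: NetworkGeometry, distances,
                              conn: ConnectivityMatrix = DEFAULT_CONNECTIVITY):
    """Synapse counts for several thresholds from a single geometric pass."""
    distances = np.asarray(distances, dtype=float)
    q = _qualifying_pairs(net, float(distances.max()), conn)
    return np.array([(q["dist"] < d).sum() for d in distances], dtype=int)


def create_interconnecting_synapses(
    net: NetworkGeometry,
    dist_synapse: float,
    conn: ConnectivityMatrix = DEFAULT_CONNECTIVITY,
    seed: int = 0,
    g_base_override: float | None = None,
) -> SynapseSet:
    """Apply the distance rule to every allowed axon/dendrite edge pair.

    For every pair of an axonal edge (presynaptic cell) and a dendritic
    edge (different, postsynaptic cell) of an allowed type pair whose
    minimum distance is below ``dist_synapse``, one interconnecting
    synapse is created at the closest point of the dendritic edge.  The
    result is deterministic; ``seed`` is accepted for interface symmetry
    but no randomness is involved.
    """
    q = _qualifying_pairs(net, dist_synapse, conn)
    types = [c.cell_type for c in net.cells]
    path_dist = [c.path_distances() for c in net.cells]
    a_cell, a_child = q["a_cell"], q["a_child"]
    d_cell, d_child = q["d_cell"], q["d_child"]
    records = []
    for ai, di, sv, uv in zip(q["ai"], q["di"], q["s"], q["u"]):
        pre_c, post_c = int(a_cell[ai]), int(d_cell[di])
        base = (g_base_override if g_base_override is not None
                else conn.base_conductance(types[pre_c], types[post_c]))
        child = int(d_child[di])
        parent = int(net.cells[post_c].parents[child])
        elen = float(np.linalg.norm(net.cells[post_c].positions[child]
                                    - net.cells[post_c].positions[parent]))
        dsd = float(path_dist[post_c][parent]) + float(uv) * elen
        offset = float(np.clip(uv, 1e-6, 1.0 - 1e-6))
        a_parent = int(net.cells[pre_c].parents[a_child[ai]])
        pre_vertex = a_parent if sv < 0.5 else int(a_child[ai])
        records.append(SynapseRecord(
            INTERCONNECTING, cell=post_c, edge=child, offset=offset,
            g_max=synaptic_conductance(base, dsd),
            pre_cell=pre_c, pre_vertex=pre_vertex))
    return SynapseSet(records)


def place_thalamic_inputs(
    net: NetworkGeometry,
    seed: int = 0,
    means: dict[str, float] | None = None,
    g_max: float = 1.2,
) -> SynapseSet:
    """Distribute primary (thalamic) synapses on the input layers.

    Per-cell synapse counts are Poisson around the per-type mean (the
    protocol states averages, not exact counts); placement on each cell is
    length-weighted over its dendrites.
    """
    rng = np.random.default_rng(seed)
    means = means if means is not None else {L4: 30.0, L5B: 25.0}
    out = SynapseSet()
    for ci, cell in enumerate(net.cells):
        mean = means.get(cell.cell_type)
        if mean is None:
            continue
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        out.extend(distribute_primary(cell, n, seed=rng, g_max=g_max,
                                      cell=ci))
    return out
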