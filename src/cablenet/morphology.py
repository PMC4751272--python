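"""Neuron morphologies as rooted trees in 3-D space.

A neuron is represented as a graph of vertices (position in µm, radius in
µm, region label) connected by edges, rooted at the soma.  This is the SWC
view of a cell: the solver later wraps a piecewise-tubular compartment
around every vertex.  Coordinates and radii stay in µm throughout this
module (the NeuroMorpho convention); conversion to SI metres happens only
when a compartment mesh is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOMA",
    "AXON",
    "BASAL",
    "APICAL",
    "DENDRITE_REGIONS",
    "MorphologyError",
    "NeuronGraph",
    "NetworkGeometry",
    "read_swc",
    "write_swc",
    "path_distance_to_soma",
    "make_fixture",
    "resample_edges",
]

SOMA = "soma"
AXON = "axon"
BASAL = "dendrite-basal"
APICAL = "dendrite-apical"
DENDRITE_REGIONS = frozenset({BASAL, APICAL})

#: SWC type code -> region label (NeuroMorpho dialect)
_SWC_TYPE_TO_REGION = {1: SOMA, 2: AXON, 3: BASAL, 4: APICAL}
_REGION_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_REGION.items()}


class MorphologyError(ValueError):
    """Structural or validation error in a morphology."""


@dataclass
class NeuronGraph:
    """Rooted tree of 3-D vertices with radii and region labels.

    Parameters
    ----------
    positions : (n, 3) float array, µm
    radii : (n,) float array, µm; all > 0
    regions : (n,) array of region labels (see module constants)
    parents : (n,) int array; ``parents[root] == -1``, every other vertex
        has exactly one parent
    cell_type : free-form cell type label, e.g. ``"L2/3 pyramidal"``
    original_ids : optional map from the contiguous internal index to the
        vertex id used in the source file
    """

    positions: np.ndarray
    radii: np.ndarray
    regions: np.ndarray
    parents: np.ndarray
    cell_type: str = "generic"
    original_ids: dict[int, int] | None = None
    _children: list[list[int]] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.regions = np.asarray(self.regions, dtype=object).ravel()
        self.parents = np.asarray(self.parents, dtype=int).ravel()
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.parents)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parents < 0)[0])

    @property
    def edges(self) -> np.ndarray:
        """(n-1, 2) array of (parent, child) index pairs, child-ordered."""
        child = np.flatnonzero(self.parents >= 0)
        return np.column_stack([self.parents[child], child])

    def children(self, vertex: int) -> list[int]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for c, p in enumerate(self.parents):
                if p >= 0:
                    ch[p].append(c)
            self._children = ch
        return self._children[vertex]

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every (parent, child) edge in µm."""
        e = self.edges
        d = self.positions[e[:, 0]] - self.positions[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def validate(self) -> None:
        n = self.n_vertices
        if n == 0:
            raise MorphologyError("empty morphology")
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.parents >= n):
            raise MorphologyError("parent index out of range")
        if np.any(self.radii <= 0):
            raise MorphologyError("all radii must be > 0")
        # acyclicity + connectedness: walking up from every vertex must
        # terminate at the root within n steps
        for v in range(n):
            seen = 0
            u = v
            while self.parents[u] >= 0:
                u = int(self.parents[u])
                seen += 1
                if seen > n:
                    raise MorphologyError("cycle detected in parent pointers")
        if self.regions[self.root] != SOMA:
            warnings.warn("root vertex is not labelled soma", stacklevel=3)

    # -- metrics -----------------------------------------------------------

    def path_distances(self) -> np.ndarray:
        """Path length (µm) from every vertex to the root along the tree."""
        n = self.n_vertices
        dist = np.full(n, -1.0)
        dist[self.root] = 0.0
        order = _topological_order(self.parents, self.root)
        for v in order[1:]:
            p = self.parents[v]
            dist[v] = dist[p] + float(
                np.linalg.norm(self.positions[v] - self.positions[p])
            )
        return dist


def path_distance_to_soma(graph: NeuronGraph, vertex: int) -> float:
    """Sum of Euclidean edge lengths along the unique path to the root (µm)."""
    if not 0 <= vertex < graph.n_vertices:
        raise MorphologyError(f"vertex {vertex} does not exist")
    dist = 0.0
    v = vertex
    while graph.parents[v] >= 0:
        p = int(graph.parents[v])
        dist += float(np.linalg.norm(graph.positions[v] - graph.positions[p]))
        v = p
    return dist


def _topological_order(parents: np.ndarray, root: int) -> list[int]:
    """Vertices ordered root-first so parents precede children (BFS)."""
    children: list[list[int]] = [[] for _ in range(len(parents))]
    for c, p in enumerate(parents):
        if p >= 0:
            children[p].append(c)
    order = [root]
    head = 0
    while head < len(order):
        order.extend(children[order[head]])
        head += 1
    if len(order) != len(parents):
        raise MorphologyError("graph is not connected")
    return order


@dataclass
class NetworkGeometry:
    """A collection of cells with a bounding box and subset labels.

    Subset labels follow the ``<cell type>/<region>`` convention so that
    every edge and vertex of the network belongs to exactly one subset.
    """

    cells: list[NeuronGraph]
    bounding_box: np.ndarray | None = None  # (2, 3) µm, [lo; hi]

    def __post_init__(self) -> None:
        if self.bounding_box is None and self.cells:
            pts = np.vstack([c.positions for c in self.cells])
            self.bounding_box = np.array([pts.min(axis=0), pts.max(axis=0)])
        elif self.bounding_box is not None:
            self.bounding_box = np.asarray(self.bounding_box, dtype=float).reshape(2, 3)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return sum(c.n_vertices for c in self.cells)

    def cell_offsets(self) -> np.ndarray:
        """Global vertex index of the first vertex of each cell."""
        return np.concatenate([[0], np.cumsum([c.n_vertices for c in self.cells])])

    def subset_labels(self) -> dict[str, list[tuple[int, int]]]:
        """Map ``cell_type/region`` -> list of (cell index, vertex index)."""
        out: dict[str, list[tuple[int, int]]] = {}
        for ci, cell in enumerate(self.cells):
            for vi in range(cell.n_vertices):
                key = f"{cell.cell_type}/{cell.regions[vi]}"
                out.setdefault(key, []).append((ci, vi))
        return out

    def cells_of_type(self, cell_type: str) -> list[int]:
        return [i for i, c in enumerate(self.cells) if c.cell_type == cell_type]


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path, cell_type: str = "generic") -> NeuronGraph:
    """Read a 7-column SWC file into a :class:`NeuronGraph`.

    Multi-point somata (several type-1 points) are collapsed to a single
    root vertex at the soma centroid with an area-equivalent radius, since
    the compartment model is vertex-centered and needs a unique root.
    Unknown type codes are mapped to basal dendrite with a warning.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns")
            ids.append(int(cols[0]))
            types.append(int(cols[1]))
            xyz.append([float(cols[2]), float(cols[3]), float(cols[4])])
            radii.append(float(cols[5]))
            parents.append(int(cols[6]))
    if not ids:
        raise MorphologyError(f"{path}: no data lines")
    id_to_row = {i: r for r, i in enumerate(ids)}
    if len(id_to_row) != len(ids):
        raise MorphologyError("duplicate vertex ids in SWC file")
    for r, p in enumerate(parents):
        if p != -1 and p not in id_to_row:
            raise MorphologyError(f"parent id {p} referenced but not defined")
    n_roots = sum(1 for p in parents if p == -1)
    if n_roots != 1:
        raise MorphologyError(f"expected exactly one root, found {n_roots}")
    if min(radii) <= 0:
        raise MorphologyError("non-positive radius in SWC file")

    xyz = np.asarray(xyz)
    radii = np.asarray(radii)
    parent_rows = np.array(
        [id_to_row[p] if p != -1 else -1 for p in parents], dtype=int
    )

    regions = []
    for t in types:
        if t in _SWC_TYPE_TO_REGION:
            regions.append(_SWC_TYPE_TO_REGION[t])
        else:
            warnings.warn(f"unknown SWC type code {t}; labelling dendrite-basal",
                          stacklevel=2)
            regions.append(BASAL)

    soma_rows = [r for r in range(len(ids)) if regions[r] == SOMA]
    root_row = int(np.flatnonzero(parent_rows == -1)[0])
    if len(soma_rows) > 1 and root_row in soma_rows:
        return _collapse_soma(
            xyz, radii, regions, parent_rows, soma_rows, ids, cell_type
        )

    original = {r: ids[r] for r in range(len(ids))}
    graph = NeuronGraph(xyz, radii, regions, parent_rows,
                        cell_type=cell_type, original_ids=original)
    # cycle detection happens in validate(); connectedness too
    _topological_order(graph.parents, graph.root)
    return graph


def _collapse_soma(xyz, radii, regions, parent_rows, soma_rows, ids, cell_type):
    """Collapse a multi-point soma into one root vertex.

    The collapsed radius is area-equivalent: the side areas 2πaℓ of the
    soma polyline are summed and matched to a sphere surface 4πr².
    """
    soma_set = set(soma_rows)
    centroid = xyz[soma_rows].mean(axis=0)
    area = 0.0
    for r in soma_rows:
        p = parent_rows[r]
        if p >= 0 and p in soma_set:
            ell = float(np.linalg.norm(xyz[r] - xyz[p]))
            area += 2.0 * np.pi * 0.5 * (radii[r] + radii[p]) * ell
    if area > 0:
        r_eq = float(np.sqrt(area / (4.0 * np.pi)))
    else:  # degenerate multi-point soma with zero extent
        r_eq = float(radii[soma_rows].max())

    keep = [r for r in range(len(radii)) if r not in soma_set]
    new_index = {old: i + 1 for i, old in enumerate(keep)}  # 0 = new root
    n = len(keep) + 1
    pos = np.empty((n, 3))
    rad = np.empty(n)
    reg = np.empty(n, dtype=object)
    par = np.empty(n, dtype=int)
    pos[0], rad[0], reg[0], par[0] = centroid, r_eq, SOMA, -1
    original = {0: ids[soma_rows[0]]}
    for old in keep:
        i = new_index[old]
        pos[i], rad[i], reg[i] = xyz[old], radii[old], regions[old]
        p = parent_rows[old]
        par[i] = 0 if (p < 0 or p in soma_set) else new_index[p]
        original[i] = ids[old]
    return NeuronGraph(pos, rad, reg, par, cell_type=cell_type,
                       original_ids=original)


def write_swc(graph: NeuronGraph, path) -> None:
    """Write a :class:`NeuronGraph` as 7-column SWC (deterministic order)."""
    order = _topological_order(graph.parents, graph.root)
    new_id = {v: i + 1 for i, v in enumerate(order)}
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for v in order:
            t = _REGION_TO_SWC_TYPE.get(str(graph.regions[v]), 3)
            p = graph.parents[v]
            pid = -1 if p < 0 else new_id[int(p)]
            x, y, z = graph.positions[v]
            fh.write(
                f"{new_id[v]} {t} {x:.6f} {y:.6f} {z:.6f} "
                f"{graph.radii[v]:.6f} {pid}\n"
            )


# ---------------------------------------------------------------------------
# Fixture generators


def make_fixture(kind: str, **params):
    """Build small deterministic test geometries.

    Kinds
    -----
    ``ball_and_stick``
        Soma + unbranched dendrite of ``n_seg`` segments, total length
        ``length_um``, radius ``radius_um``; optionally an axon chain
        (``axon_n_seg``, ``axon_length_um``, ``axon_radius_um``).
    ``binary_tree``
        Soma + full binary dendritic tree of ``depth`` levels
        (2**(depth+1) − 1 dendritic segments).
    ``two_cell``
        A :class:`NetworkGeometry` of two ball-and-stick cells arranged so
        the closest axon(cell 0)–dendrite(cell 1) vertex distance equals
        ``gap_um``.
    """
    if kind == "ball_and_stick":
        return _ball_and_stick(**params)
    if kind == "binary_tree":
        return _binary_tree(**params)
    if kind == "two_cell":
        return _two_cell(**params)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _check_positive(**kwargs) -> None:
    for name, val in kwargs.items():
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")


def _ball_and_stick(
    n_seg: int = 100,
    length_um: float = 1000.0,
    radius_um: float = 1.0,
    soma_radius_um: float = 5.0,
    axon_n_seg: int = 0,
    axon_length_um: float = 0.0,
    axon_radius_um: float = 0.5,
    dendrite_region: str = BASAL,
    cell_type: str = "generic",
    origin=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
) -> NeuronGraph:
    _check_positive(n_seg=n_seg, length_um=length_um, radius_um=radius_um,
                    soma_radius_um=soma_radius_um)
    origin = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    n = 1 + n_seg + axon_n_seg
    pos = np.empty((n, 3))
    rad = np.empty(n)
    reg = np.empty(n, dtype=object)
    par = np.empty(n, dtype=int)
    pos[0], rad[0], reg[0], par[0] = origin, soma_radius_um, SOMA, -1
    h = length_um / n_seg
    for i in range(1, n_seg + 1):
        pos[i] = origin + u * i * h
        rad[i], reg[i], par[i] = radius_um, dendrite_region, i - 1
    if axon_n_seg:
        _check_positive(axon_length_um=axon_length_um,
                        axon_radius_um=axon_radius_um)
        ha = axon_length_um / axon_n_seg
        for k in range(axon_n_seg):
            i = 1 + n_seg + k
            pos[i] = origin - u * (k + 1) * ha
            rad[i], reg[i] = axon_radius_um, AXON
            par[i] = 0 if k == 0 else i - 1
    return NeuronGraph(pos, rad, reg, par, cell_type=cell_type)


def _binary_tree(
    depth: int = 4,
    segment_length_um: float = 50.0,
    radius_um: float = 1.0,
    soma_radius_um: float = 5.0,
    cell_type: str = "generic",
) -> NeuronGraph:
    _check_positive(depth=depth, segment_length_um=segment_length_um,
                    radius_um=radius_um)
    pos = [np.zeros(3)]
    rad = [soma_radius_um]
    reg = [SOMA]
    par = [-1]
    # level-order construction; branches fan out in the xy plane
    frontier = [(0, np.zeros(3), 0.0, np.pi)]  # (parent, pos, angle lo, hi)
    for level in range(depth + 1):
        nxt = []
        for parent, p0, lo, hi in frontier:
            mids = [(lo + hi) / 2] if level == 0 else [
                lo + (hi - lo) / 4, lo + 3 * (hi - lo) / 4
            ]
            for k, ang in enumerate(mids):
                u = np.array([np.cos(ang), np.sin(ang), 0.0])
                p1 = p0 + u * segment_length_um
                pos.append(p1)
                rad.append(radius_um)
                reg.append(BASAL)
                par.append(parent)
                idx = len(pos) - 1
                if level == 0:
                    nxt.append((idx, p1, lo, hi))
                else:
                    span = (hi - lo) / 2
                    nxt.append((idx, p1, lo + k * span, lo + (k + 1) * span))
        frontier = nxt
    return NeuronGraph(np.array(pos), np.array(rad),
                       np.array(reg, dtype=object), np.array(par),
                       cell_type=cell_type)


def _two_cell(
    gap_um: float = 2.0,
    n_seg: int = 20,
    length_um: float = 100.0,
    radius_um: float = 1.0,
    axon_n_seg: int = 20,
    axon_length_um: float = 100.0,
    cell_pre_type: str = "generic",
    cell_post_type: str = "generic",
) -> NetworkGeometry:
    """Two cells whose closest axon–dendrite vertex distance is ``gap_um``.

    Cell 0's axon runs along +x ending at x = axon tip; cell 1's dendrite
    starts ``gap_um`` beyond that tip on the same axis.
    """
    _check_positive(gap_um=gap_um)
    pre = _ball_and_stick(n_seg=n_seg, length_um=length_um,
                          radius_um=radius_um, axon_n_seg=axon_n_seg,
                          axon_length_um=axon_length_um,
                          cell_type=cell_pre_type,
                          origin=(0, 0, 0), direction=(-1, 0, 0))
    # pre's axon points along +x (opposite of dendrite direction), tip at
    # x = axon_length_um
    post_origin = (axon_length_um + gap_um + length_um, 0.0, 0.0)
    post = _ball_and_stick(n_seg=n_seg, length_um=length_um,
                           radius_um=radius_um, cell_type=cell_post_type,
                           origin=post_origin, direction=(-1, 0, 0))
    return NetworkGeometry(cells=[pre, post])


def resample_edges(graph: NeuronGraph, target_length_um: float) -> NeuronGraph:
    """Subdivide edges longer than ``target_length_um``.

    Total cable length per branch is preserved exactly (new vertices are
    placed on the original straight segments); edges are never merged, so
    branch points and radii stay untouched.
    """
    _check_positive(target_length_um=target_length_um)
    pos = [graph.positions[i].copy() for i in range(graph.n_vertices)]
    rad = list(graph.radii)
    reg = list(graph.regions)
    par = list(graph.parents)
    for p, c in graph.edges:
        p, c = int(p), int(c)
        vec = graph.positions[c] - graph.positions[p]
        length = float(np.linalg.norm(vec))
        n_sub = int(np.ceil(length / target_length_um))
        if n_sub <= 1:
            continue
        prev = p
        for k in range(1, n_sub):
            pos.append(graph.positions[p] + vec * (k / n_sub))
            rad.append(graph.radii[c])
            reg.append(graph.regions[c])
            par.append(prev)
            prev = len(pos) - 1
        par[c] = prev
    return NeuronGraph(np.array(pos), np.array(rad),
                       np.array(reg, dtype=object), np.array(par),
                       cell_type=graph.cell_type)
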