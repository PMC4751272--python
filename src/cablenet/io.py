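"""Network exchange format: one JSON document per network.

The document carries cells (vertices, radii, region labels, tree
topology), the bounding box, subset labels implied by cell type + region,
and optionally the placed synapses with their kinetic parameters.  Field
order is fixed so that re-exporting the same network is byte-identical.

Schema (version 1)::

    {
      "format": "cablenet-network",
      "version": 1,
      "bounding_box": [[x0,y0,z0],[x1,y1,z1]] | null,
      "cells": [
        {"cell_type": str,
         "vertices": [[x,y,z,radius], ...],   # µm
         "regions": [str, ...],
         "parents": [int, ...]},              # -1 marks the root
        ...],
      "synapses": [ {...}, ... ]              # see synapses.SynapseSet
    }
"""

from __future__ import annotations

import json

import numpy as np

from .morphology import NetworkGeometry, NeuronGraph
from .synapses import SynapseSet

__all__ = ["save_network", "load_network", "network_to_dict",
           "network_from_dict"]

FORMAT_NAME = "cablenet-network"
FORMAT_VERSION = 1


def network_to_dict(net: NetworkGeometry,
                    synapses: SynapseSet | None = None) -> dict:
    cells = []
    for cell in net.cells:
        verts = [
            [float(x), float(y), float(z), float(r)]
            for (x, y, z), r in zip(cell.positions, cell.radii)
        ]
        cells.append({
            "cell_type": cell.cell_type,
            "vertices": verts,
            "regions": [str(r) for r in cell.regions],
            "parents": [int(p) for p in cell.parents],
        })
    bbox = (None if net.bounding_box is None
            else [[float(v) for v in row] for row in net.bounding_box])
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "bounding_box": bbox,
        "cells": cells,
        "synapses": synapses.to_dicts() if synapses is not None else [],
    }


def network_from_dict(doc: dict) -> tuple[NetworkGeometry, SynapseSet]:
    if doc.get("format") != FORMAT_NAME:
        raise ValueError("not a cablenet network document")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('version')}")
    cells = []
    for c in doc["cells"]:
        verts = np.asarray(c["vertices"], dtype=float)
        cells.append(NeuronGraph(
            positions=verts[:, :3], radii=verts[:, 3],
            regions=np.asarray(c["regions"], dtype=object),
            parents=np.asarray(c["parents"], dtype=int),
            cell_type=c["cell_type"],
        ))
    bbox = doc.get("bounding_box")
    net = NetworkGeometry(cells=cells,
                          bounding_box=None if bbox is None else np.asarray(bbox))
    return net, SynapseSet.from_dicts(doc.get("synapses", []))


def save_network(path, net: NetworkGeometry,
                 synapses: SynapseSet | None = None) -> None:
    doc = network_to_dict(net, synapses)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_network(path) -> tuple[NetworkGeometry, SynapseSet]:
    with open(path) as fh:
        return network_from_dict(json.load(fh))
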