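"""Coarse bilayer-slab surrogate for membrane-embedded network analysis.

The lipid bilayer is represented by two square lattices of elastic-network
nodes at +/- z_leaflet (default 15 A, lateral size 80 x 80 A, spacing 5 A).
Embedding a pre-oriented protein (membrane normal along z) removes lipid
nodes that clash with protein heavy atoms and returns a combined node set;
downstream network building treats lipid nodes as ordinary nodes, so the
membrane's qualitative effect — extra connectivity damping the contact
surface — arises naturally.  Lipid chemistry, minimization and curvature
are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .elastic_network import NodeLabel, NodeSet
from .structure_io import Structure

logger = logging.getLogger(__name__)

DEFAULT_DIM = 80.0
DEFAULT_SPACING = 5.0
DEFAULT_LEAFLET_Z = 15.0
DEFAULT_CLASH_RADIUS = 3.0


@dataclass
class BilayerSlab:
    positions: np.ndarray  # (M, 3)
    dim_x: float
    dim_y: float
    spacing: float
    leaflet_z: float

    def __len__(self) -> int:
        return len(self.positions)


def build_bilayer_slab(
    dim_x: float = DEFAULT_DIM,
    dim_y: float = DEFAULT_DIM,
    spacing: float = DEFAULT_SPACING,
    leaflet_z: float = DEFAULT_LEAFLET_Z,
    center=(0.0, 0.0, 0.0),
    pucker: float = 0.0,
) -> BilayerSlab:
    """Two-leaflet square lattice of lipid surrogate nodes.

    Node count is 2 * (floor(dim_x/spacing)+1) * (floor(dim_y/spacing)+1).

    ``pucker`` displaces alternate lattice sites by +/- pucker/2 along z
    (checkerboard).  A strictly planar lattice of central-force springs is a
    mechanism — every node can move out of plane at zero energy cost — so a
    small pucker (e.g. 0.5 A) is needed whenever the slab itself must be
    rigid; the default 0 keeps nodes exactly on the leaflet planes.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if dim_x < spacing or dim_y < spacing:
        raise ValueError("slab dimensions must be at least one lattice spacing")
    nx = int(np.floor(dim_x / spacing)) + 1
    ny = int(np.floor(dim_y / spacing)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing + center[0]
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing + center[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    checker = ((np.indices((nx, ny)).sum(axis=0) % 2) - 0.5).ravel()
    dz = pucker * checker
    leaf = np.column_stack([gx.ravel(), gy.ravel(), dz])
    top = leaf + np.array([0.0, 0.0, center[2] + leaflet_z])
    bottom = leaf + np.array([0.0, 0.0, center[2] - leaflet_z])
    return BilayerSlab(
        positions=np.vstack([top, bottom]),
        dim_x=dim_x, dim_y=dim_y, spacing=spacing, leaflet_z=leaflet_z,
    )


@dataclass
class EmbeddedSystem:
    """Protein + lipid node union after clash removal."""

    nodes: NodeSet
    clash_radius: float
    n_removed: int

    @property
    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(self.nodes.component == "protein")

    @property
    def lipid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.nodes.component == "lipid")


def embed_protein(
    protein_nodes: NodeSet,
    slab: BilayerSlab,
    clash_radius: float = DEFAULT_CLASH_RADIUS,
    structure: Optional[Structure] = None,
) -> EmbeddedSystem:
    """Merge a pre-oriented protein with the slab, removing clashing lipids.

    A lipid node is removed when any protein heavy atom (from ``structure``
    if given, else the protein nodes themselves) lies within
    ``clash_radius``.  Warns when the protein misses the slab entirely.
    """
    heavy = (structure.coordinates if structure is not None
             else protein_nodes.positions)
    tree = cKDTree(heavy)
    d, _ = tree.query(slab.positions)
    keep = d > clash_radius
    n_removed = int(np.sum(~keep))
    if n_removed == 0:
        logger.warning("no lipid node clashes with the protein; is the "
                       "protein oriented into the slab?")
    lipid_pos = slab.positions[keep]
    n_prot = len(protein_nodes)
    labels = list(protein_nodes.labels) + [
        NodeLabel("M", i + 1, "", "MEM", "C", True)
        for i in range(len(lipid_pos))
    ]
    bexp = None
    if protein_nodes.b_experimental is not None:
        bexp = np.concatenate(
            [protein_nodes.b_experimental, np.zeros(len(lipid_pos))]
        )
    combined = NodeSet(
        positions=np.vstack([protein_nodes.positions, lipid_pos]),
        masses=np.concatenate([protein_nodes.masses, np.ones(len(lipid_pos))]),
        labels=labels,
        b_experimental=bexp,
        component=np.array(
            ["protein"] * n_prot + ["lipid"] * len(lipid_pos), dtype=object
        ),
    )
    return EmbeddedSystem(nodes=combined, clash_radius=clash_radius,
                          n_removed=n_removed)


def contact_residue_indices(
    system: EmbeddedSystem, contact_radius: float = 5.0
) -> np.ndarray:
    """Protein node indices within ``contact_radius`` of any lipid node."""
    lipids = system.nodes.positions[system.lipid_indices]
    if len(lipids) == 0:
        return np.array([], dtype=int)
    tree = cKDTree(lipids)
    prot = system.protein_indices
    d, _ = tree.query(system.nodes.positions[prot])
    return prot[d <= contact_radius]
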