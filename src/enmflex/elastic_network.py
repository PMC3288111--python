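"""Tirion single-parameter elastic network and its Hessian.

The network treats a molecule as point nodes joined by identical Hookean
springs: every node pair closer than a connectivity cutoff ``R_c`` gets a
spring with force constant ``k`` at its native distance, so the input
conformation is the energy minimum by construction.  All quantities are in
reduced units by default (k = 1, k_B*T = 1, unit masses); positions are in
Angstroms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: node count above which the Hessian is assembled in sparse storage
SPARSE_THRESHOLD = 1000

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class NodeLabel(NamedTuple):
    """Back-reference from a network node to its source atom."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    is_hetero: bool


@dataclass
class NodeSet:
    """Point nodes of an elastic network.

    Attributes
    ----------
    positions : (N, 3) float array, Angstroms.
    masses : (N,) float array, reduced units (all 1 by default).
    labels : per-node back-references to (chain, residue, atom).
    block_id : optional per-node block index (set by RTB partitioning).
    b_experimental : optional per-node experimental B-factor (A^2).
    component : optional per-node component tag ("protein", "lipid", ...).
    """

    positions: np.ndarray
    masses: np.ndarray = None
    labels: list = field(default_factory=list)
    block_id: np.ndarray = None
    b_experimental: np.ndarray = None
    component: np.ndarray = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = len(self.positions)
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if not self.labels:
            self.labels = [
                NodeLabel("A", i + 1, "", "GLY", "CA", False) for i in range(n)
            ]
        if self.b_experimental is not None:
            self.b_experimental = np.asarray(self.b_experimental, dtype=float)
        if self.component is None:
            self.component = np.array(["protein"] * n, dtype=object)

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, indices: Sequence[int]) -> "NodeSet":
        idx = np.asarray(indices, dtype=int)
        return NodeSet(
            positions=self.positions[idx],
            masses=self.masses[idx],
            labels=[self.labels[i] for i in idx],
            b_experimental=None
            if self.b_experimental is None
            else self.b_experimental[idx],
            component=self.component[idx],
        )

    @property
    def residue_keys(self) -> list:
        """(chain, residue_number, insertion_code) per node."""
        return [(l.chain_id, l.residue_number, l.insertion_code) for l in self.labels]


class DegenerateNetworkError(ValueError):
    """Raised when a network has no springs or coincident nodes."""


@dataclass
class ElasticNetwork:
    """Hookean spring network under a distance cutoff.

    ``springs`` is an (M, 2) int array of node pairs (i < j) and
    ``rest_lengths`` the matching native distances d0_ij.
    """

    nodes: NodeSet
    springs: np.ndarray
    rest_lengths: np.ndarray
    cutoff: float
    force_constant: float = 1.0
    n_components: int = 1

    @property
    def n_springs(self) -> int:
        return len(self.springs)


def build_network(nodes: NodeSet, cutoff: float, k: float = 1.0) -> ElasticNetwork:
    """Connect every node pair within ``cutoff`` by a spring of constant ``k``.

    Raises :class:`DegenerateNetworkError` if no pair is within the cutoff.
    Logs a warning if the network splits into more than one connected
    component (the rigid-mode count then exceeds 6).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to build a network")
    tree = cKDTree(nodes.positions)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
    if pairs.size == 0:
        raise DegenerateNetworkError(
            f"no node pair within cutoff {cutoff} A; network is degenerate"
        )
    d0 = np.linalg.norm(
        nodes.positions[pairs[:, 0]] - nodes.positions[pairs[:, 1]], axis=1
    )
    n = len(nodes)
    adj = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        logger.warning(
            "network has %d connected components; expect %d rigid modes",
            n_comp,
            6 * n_comp,
        )
    return ElasticNetwork(
        nodes=nodes,
        springs=pairs,
        rest_lengths=d0,
        cutoff=cutoff,
        force_constant=k,
        n_components=n_comp,
    )


def hessian(network: ElasticNetwork):
    """Assemble the 3N x 3N second-derivative matrix of the Tirion energy.

    For spring (i, j) with native separation vector d = r_i - r_j, the
    off-diagonal 3x3 super-element is -(k/d0^2) d d^T and each diagonal
    super-element is minus the sum of its row's off-diagonal blocks, which
    makes every row-block sum vanish (translation invariance).

    Returns a dense ndarray for small systems and a CSR matrix above
    :data:`SPARSE_THRESHOLD` nodes.
    """
    n = len(network.nodes)
    if np.any(network.rest_lengths == 0):
        raise DegenerateNetworkError("coincident nodes (zero rest length)")
    pos = network.nodes.positions
    k = network.force_constant
    i_idx, j_idx = network.springs[:, 0], network.springs[:, 1]
    d = pos[i_idx] - pos[j_idx]  # (M, 3)
    coef = k / network.rest_lengths**2  # (M,)
    blocks = -coef[:, None, None] * d[:, :, None] * d[:, None, :]  # (M, 3, 3)

    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            v = blocks[:, a, b]
            rows.extend([3 * i_idx + a, 3 * j_idx + a, 3 * i_idx + a, 3 * j_idx + a])
            cols.extend([3 * j_idx + b, 3 * i_idx + b, 3 * i_idx + b, 3 * j_idx + b])
            vals.extend([v, v, -v, -v])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    h = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    if n <= SPARSE_THRESHOLD:
        return h.toarray()
    return h


def tirion_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Tirion potential energy of a conformation (reduced units).

    E = (k/2) * sum over springs of (|r_i - r_j| - d0_ij)^2.  Zero at the
    input conformation by construction.
    """
    coords = np.asarray(coords, dtype=float).reshape(len(network.nodes), 3)
    d = np.linalg.norm(
        coords[network.springs[:, 0]] - coords[network.springs[:, 1]], axis=1
    )
    return 0.5 * network.force_constant * float(np.sum((d - network.rest_lengths) ** 2))


def write_edge_list(network: ElasticNetwork, path) -> None:
    """Dump springs as a tab-separated (i, j, rest_length) edge list."""
    with open(path, "w") as fh:
        fh.write("i\tj\trest_length\n")
        for (i, j), d0 in zip(network.springs, network.rest_lengths):
            fh.write(f"{i}\t{j}\t{d0:.6f}\n")
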