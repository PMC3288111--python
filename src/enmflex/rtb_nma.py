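"""Normal-mode solving with the rotation-translation-block (RTB) projection.

The RTB approximation groups runs of consecutive residues into rigid blocks
with 6 degrees of freedom each (3 translations + 3 rotations about the block
centroid), projects the Hessian into that subspace, solves the reduced
eigenproblem and back-projects eigenvectors into atomic space.  With one
residue per block in a C-alpha network the projection is exact; coarser
blocks give Rayleigh-Ritz upper bounds to the true eigenvalues.

Mode numbering follows the crystallographic-NMA convention: the rigid-body
modes of a free connected molecule are modes 1-6 and the first internal mode
is mode 7.  Relative frequencies are quoted as omega_j / omega_7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh

from .elastic_network import NodeSet

logger = logging.getLogger(__name__)

#: eigenvalues below ZERO_TOL * lambda_max count as rigid-body (zero) modes
ZERO_TOL = 1e-8

#: above this projected dimension, use a sparse Lanczos solve
DENSE_LIMIT = 3000


@dataclass
class BlockPartition:
    """Node -> block mapping for the RTB projection.

    Blocks are runs of ``residues_per_block`` consecutive residues that never
    span a chain boundary; each hetero residue forms its own block.
    """

    block_of: np.ndarray
    n_blocks: int
    residues_per_block: int = 1

    def members(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.block_of == b)


def make_blocks(nodes: NodeSet, residues_per_block: int = 1) -> BlockPartition:
    """Deterministically partition nodes into RTB blocks.

    A trailing short block is allowed at the end of each chain.
    """
    if residues_per_block < 1:
        raise ValueError("residues_per_block must be >= 1")
    block_of = np.empty(len(nodes), dtype=int)
    n_blocks = 0
    prev_chain = None
    prev_reskey = None
    prev_was_hetero = False
    residues_in_block = 0
    current_block = -1
    for i, lab in enumerate(nodes.labels):
        reskey = (lab.chain_id, lab.residue_number, lab.insertion_code)
        new_residue = reskey != prev_reskey
        if lab.is_hetero:
            # one block per hetero residue
            if new_residue:
                current_block = n_blocks
                n_blocks += 1
                residues_in_block = 0
            prev_chain = lab.chain_id
        elif (
            new_residue
            and (
                lab.chain_id != prev_chain
                or residues_in_block >= residues_per_block
                or current_block < 0
                or prev_was_hetero
            )
        ):
            current_block = n_blocks
            n_blocks += 1
            residues_in_block = 1
            prev_chain = lab.chain_id
        elif new_residue:
            residues_in_block += 1
        block_of[i] = current_block
        prev_reskey = reskey
        prev_was_hetero = lab.is_hetero
    return BlockPartition(block_of, n_blocks, residues_per_block)


def default_block_size(n_residues: int) -> int:
    """One residue per block up to 2000 residues, then ceil(N/2000)."""
    if n_residues <= 2000:
        return 1
    return int(np.ceil(n_residues / 2000))


def rtb_project(hessian, partition: BlockPartition, nodes: NodeSet):
    """Build the RTB projection operator and the projected Hessian.

    Each block contributes up to 6 orthonormal columns: 3 rigid translations
    and 3 rotations about the block centroid.  Blocks with fewer than 3
    non-collinear nodes contribute only their well-defined rigid degrees
    (single node -> 3 columns, collinear pair -> 5).  Returns
    ``(projected_matrix, P)`` with ``projected = P.T @ H @ P``.
    """
    n = len(nodes)
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError("hessian dimension does not match the node set")
    cols = []
    rows_all, cols_all, vals_all = [], [], []
    col_count = 0
    for b in range(partition.n_blocks):
        idx = partition.members(b)
        if idx.size == 0:
            raise ValueError(f"block {b} is empty")
        pos = nodes.positions[idx]
        centroid = pos.mean(axis=0)
        rel = pos - centroid
        m = idx.size
        basis = np.zeros((3 * m, 6))
        for a in range(3):  # translations
            basis[a::3, a] = 1.0
        for a in range(3):  # rotations: u_i = e_a x (r_i - c)
            e = np.zeros(3)
            e[a] = 1.0
            basis[:, 3 + a] = np.cross(e, rel).ravel()
        q, r = np.linalg.qr(basis)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        q = q[:, keep]
        dof = np.repeat(3 * idx, 3) + np.tile([0, 1, 2], m)
        for c in range(q.shape[1]):
            rows_all.append(dof)
            cols_all.append(np.full(3 * m, col_count))
            vals_all.append(q[:, c])
            col_count += 1
    P = sp.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(3 * n, col_count),
    ).tocsc()
    if sp.issparse(hessian):
        projected = (P.T @ (hessian @ P)).toarray()
    else:
        Pd = P.toarray()
        projected = Pd.T @ hessian @ Pd
    projected = 0.5 * (projected + projected.T)
    return projected, P


@dataclass
class ModeSet:
    """Eigen-decomposition of an elastic-network Hessian.

    ``eigenvalues`` ascend; ``eigenvectors`` (3N x n_v) have orthonormal
    columns in atomic space.  ``n_zero`` counts numerically zero eigenvalues
    (6 for a connected free molecule).  Paper-convention numbering: mode j is
    1-based over the whole spectrum, so the first internal mode is
    ``n_zero + 1`` (7 when n_zero = 6).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    nodes: Optional[NodeSet] = None

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def first_internal(self) -> int:
        """1-based label of the first internal mode (7 for a free molecule)."""
        return self.n_zero + 1

    def internal_indices(self) -> np.ndarray:
        return np.arange(self.n_zero, self.n_modes)

    def mode_vector(self, mode_number: int) -> np.ndarray:
        """Eigenvector by 1-based paper-convention mode number, (N, 3)."""
        u = self.eigenvectors[:, mode_number - 1]
        return u.reshape(-1, 3)

    def relative_frequency(self, mode_number: int) -> float:
        """omega_j / omega of the first internal mode."""
        w = self.frequencies
        ref = w[self.n_zero]
        if ref == 0:
            raise ZeroDivisionError("first internal frequency is zero")
        return float(w[mode_number - 1] / ref)

    def physical_frequencies(self, anchor_cm1: float = 2.5) -> np.ndarray:
        """Frequencies in cm^-1, anchoring the slowest internal mode."""
        w = self.frequencies
        return w / w[self.n_zero] * anchor_cm1

    def summary_table(self) -> pd.DataFrame:
        w = self.frequencies
        ref = w[self.n_zero] if w[self.n_zero] > 0 else np.nan
        return pd.DataFrame(
            {
                "mode": np.arange(1, self.n_modes + 1),
                "eigenvalue": self.eigenvalues,
                "frequency": w,
                "relative_frequency": w / ref,
                "is_rigid": np.arange(self.n_modes) < self.n_zero,
            }
        )


class EigensolverError(RuntimeError):
    """Eigensolver failed to converge; carries solver diagnostics."""


def solve_modes(
    matrix,
    n_modes: Optional[int] = None,
    back_projection=None,
    nodes: Optional[NodeSet] = None,
) -> ModeSet:
    """Solve for the smallest-eigenvalue normal modes.

    ``matrix`` is the (possibly RTB-projected) Hessian.  With
    ``back_projection`` (the RTB operator P), eigenvectors are returned in
    the full 3N atomic space; P has orthonormal columns so they stay
    orthonormal.  Zero modes are detected with a relative tolerance of
    ``ZERO_TOL`` against the largest computed eigenvalue.
    """
    dim = matrix.shape[0]
    if n_modes is None:
        n_modes = dim
    if n_modes > dim:
        raise ValueError(f"n_modes={n_modes} exceeds matrix dimension {dim}")
    try:
        if dim <= DENSE_LIMIT or n_modes > dim // 2:
            dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix)
            dense = 0.5 * (dense + dense.T)
            vals, vecs = scipy.linalg.eigh(dense)
            vals, vecs = vals[:n_modes], vecs[:, :n_modes]
        else:
            # shift keeps the operator invertible despite the 6 zero modes
            vals, vecs = eigsh(matrix, k=n_modes, sigma=-1e-4, which="LM")
            order = np.argsort(vals)
            vals, vecs = vals[order], vecs[:, order]
    except (np.linalg.LinAlgError, scipy.sparse.linalg.ArpackNoConvergence) as exc:
        raise EigensolverError(f"eigensolve failed (dim={dim}): {exc}") from exc
    scale = max(abs(vals[-1]), 1e-30)
    n_zero = int(np.sum(np.abs(vals) < ZERO_TOL * scale))
    vals = np.where(np.abs(vals) < ZERO_TOL * scale, 0.0, vals)
    if back_projection is not None:
        vecs = back_projection @ vecs
        # columns of P are orthonormal, so this stays orthonormal; re-project
        # defensively against accumulated round-off
        q, _ = np.linalg.qr(vecs)
        # keep eigenvector signs/spans: QR of an orthonormal matrix only
        # flips signs, which are physically irrelevant
        vecs = q * np.sign(np.sum(q * vecs, axis=0))
    return ModeSet(eigenvalues=vals, eigenvectors=np.asarray(vecs), n_zero=n_zero,
                   nodes=nodes)


def normal_modes(
    hessian,
    nodes: NodeSet,
    residues_per_block: Optional[int] = None,
    n_modes: Optional[int] = None,
) -> ModeSet:
    """Convenience pipeline: block partition -> RTB projection -> solve."""
    n_res = len(set(nodes.residue_keys))
    if residues_per_block is None:
        residues_per_block = default_block_size(n_res)
    partition = make_blocks(nodes, residues_per_block)
    projected, P = rtb_project(hessian, partition, nodes)
    if n_modes is not None:
        n_modes = min(n_modes, projected.shape[0])
    return solve_modes(projected, n_modes=n_modes, back_projection=P, nodes=nodes)


# ---------------------------------------------------------------------------
# mode matching between systems
# ---------------------------------------------------------------------------

def _rigid_space(positions: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid translations+rotations over a node set."""
    m = len(positions)
    rel = positions - positions.mean(axis=0)
    basis = np.zeros((3 * m, 6))
    for a in range(3):
        basis[a::3, a] = 1.0
        e = np.zeros(3)
        e[a] = 1.0
        basis[:, 3 + a] = np.cross(e, rel).ravel()
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def match_modes(
    modeset_a: ModeSet,
    modeset_b: ModeSet,
    shared_a: Sequence[int],
    shared_b: Sequence[int],
    n_modes: Optional[int] = None,
) -> list:
    """Pair internal modes of two systems by eigenvector overlap.

    Eigenvectors are restricted to the shared nodes, net rigid-body motion
    over the shared set is projected out, and the overlap is the absolute
    cosine of the two restricted vectors.  Greedy best-match pairing: the
    highest remaining overlap is taken first.  Returns a list of
    ``(mode_a, mode_b, overlap)`` with 1-based paper-convention numbers.
    """
    shared_a = np.asarray(shared_a, dtype=int)
    shared_b = np.asarray(shared_b, dtype=int)
    if shared_a.size == 0 or shared_a.size != shared_b.size:
        raise ValueError("shared node sets must be non-empty and same length")

    def restricted(ms: ModeSet, shared: np.ndarray, rigid: np.ndarray):
        sel = (np.repeat(3 * shared, 3) + np.tile([0, 1, 2], shared.size))
        idx = ms.internal_indices()
        if n_modes is not None:
            idx = idx[:n_modes]
        u = ms.eigenvectors[sel][:, idx]
        u = u - rigid @ (rigid.T @ u)
        norms = np.linalg.norm(u, axis=0)
        norms[norms == 0] = 1.0
        return u / norms, idx

    rigid_a = _rigid_space(modeset_a.nodes.positions[shared_a])
    rigid_b = _rigid_space(modeset_b.nodes.positions[shared_b])
    ua, ia = restricted(modeset_a, shared_a, rigid_a)
    ub, ib = restricted(modeset_b, shared_b, rigid_b)
    overlap = np.abs(ua.T @ ub)
    pairs = []
    ov = overlap.copy()
    for _ in range(min(ov.shape)):
        i, j = np.unravel_index(np.argmax(ov), ov.shape)
        pairs.append((int(ia[i]) + 1, int(ib[j]) + 1, float(overlap[i, j])))
        ov[i, :] = -1.0
        ov[:, j] = -1.0
    pairs.sort(key=lambda t: t[0])
    return pairs


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_modes(modeset: ModeSet, path) -> None:
    """Plain-text mode file: one block per mode (eigenvalue, then 3N vector)."""
    with open(path, "w") as fh:
        fh.write(f"# modes {modeset.n_modes} dof {modeset.eigenvectors.shape[0]} "
                 f"n_zero {modeset.n_zero}\n")
        for j in range(modeset.n_modes):
            fh.write(f"MODE {j + 1} {modeset.eigenvalues[j]:.12e}\n")
            np.savetxt(fh, modeset.eigenvectors[:, j][None].reshape(-1, 3),
                       fmt="%.9e")


def read_modes(path, nodes: Optional[NodeSet] = None) -> ModeSet:
    with open(path) as fh:
        header = fh.readline().split()
        n_modes, dof, n_zero = int(header[2]), int(header[4]), int(header[6])
        vals = np.empty(n_modes)
        vecs = np.empty((dof, n_modes))
        for j in range(n_modes):
            tag = fh.readline().split()
            vals[j] = float(tag[2])
            rows = [fh.readline().split() for _ in range(dof // 3)]
            vecs[:, j] = np.array(rows, dtype=float).ravel()
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero, nodes=nodes)
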