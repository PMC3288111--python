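"""Mode-perturbed conformers and eigenvector arrow fields.

A trajectory along mode j displaces every node linearly,
``x(a) = x0 + a * U_j``, over an amplitude grid (default -100..100 in steps
of 20, i.e. 11 frames); arrows are the eigenvector components scaled for
visualization (default factor 200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elastic_network import NodeSet
from .rtb_nma import ModeSet
from . import structure_io

logger = logging.getLogger(__name__)

DEFAULT_AMPLITUDES = tuple(range(-100, 101, 20))
DEFAULT_ARROW_SCALE = 200.0


@dataclass
class ModeTrajectory:
    mode_number: int
    amplitudes: np.ndarray
    frames: np.ndarray  # (n_frames, N, 3)
    nodes: Optional[NodeSet] = None

    mode_vector: np.ndarray = None  # (N, 3) unscaled eigenvector

    @property
    def n_frames(self) -> int:
        return len(self.amplitudes)

    def _index(self, amplitude: float) -> int:
        i = np.flatnonzero(np.isclose(self.amplitudes, amplitude))
        if i.size == 0:
            raise KeyError(f"amplitude {amplitude} not on the grid")
        return int(i[0])

    def frame(self, amplitude: float) -> np.ndarray:
        return self.frames[self._index(amplitude)]

    def displacement(self, amplitude: float) -> np.ndarray:
        """a * U_j for a grid amplitude; equal-and-opposite at +/-a by
        IEEE sign symmetry of multiplication."""
        return self.amplitudes[self._index(amplitude)] * self.mode_vector


def perturb_along_mode(
    modeset: ModeSet,
    mode_number: int,
    amplitudes: Sequence[float] = DEFAULT_AMPLITUDES,
    nodes: Optional[NodeSet] = None,
) -> ModeTrajectory:
    """Displace the structure along one normal mode over an amplitude grid.

    ``mode_number`` is 1-based in the paper convention (first internal mode
    = n_zero + 1).  Perturbing a rigid mode is allowed but logged, since it
    only translates/rotates the molecule.
    """
    nodes = nodes if nodes is not None else modeset.nodes
    if nodes is None:
        raise ValueError("no node set available for the trajectory")
    if mode_number <= modeset.n_zero:
        logger.warning("mode %d is a rigid-body mode; trajectory is a rigid "
                       "displacement", mode_number)
    u = modeset.mode_vector(mode_number)  # (N, 3)
    amps = np.asarray(list(amplitudes), dtype=float)
    frames = nodes.positions[None, :, :] + amps[:, None, None] * u[None, :, :]
    return ModeTrajectory(mode_number=mode_number, amplitudes=amps,
                          frames=frames, nodes=nodes, mode_vector=u)


@dataclass
class ArrowSet:
    mode_number: int
    scale: float
    base: np.ndarray  # (N, 3)
    vectors: np.ndarray  # (N, 3), scaled
    nodes: Optional[NodeSet] = None


def eigenvector_arrows(
    modeset: ModeSet,
    mode_number: int,
    scale: float = DEFAULT_ARROW_SCALE,
    nodes: Optional[NodeSet] = None,
) -> ArrowSet:
    """Per-node displacement arrows of one mode, scaled for visualization."""
    nodes = nodes if nodes is not None else modeset.nodes
    if nodes is None:
        raise ValueError("no node set available for arrows")
    u = modeset.mode_vector(mode_number)
    return ArrowSet(mode_number=mode_number, scale=scale,
                    base=nodes.positions.copy(), vectors=scale * u, nodes=nodes)


def nodes_as_structure(nodes: NodeSet, coordinates=None) -> structure_io.Structure:
    """Represent a node set as a Structure (one pseudo-atom per node)."""
    coords = nodes.positions if coordinates is None else np.asarray(coordinates)
    atoms = []
    for i, (lab, xyz) in enumerate(zip(nodes.labels, coords)):
        atoms.append(
            structure_io.AtomRecord(
                serial=i + 1,
                name=lab.atom_name or "CA",
                element="C",
                residue_name=lab.residue_name,
                chain_id=lab.chain_id,
                residue_number=lab.residue_number,
                insertion_code=lab.insertion_code,
                position=np.asarray(xyz, dtype=float),
                b_experimental=0.0 if nodes.b_experimental is None
                else float(nodes.b_experimental[i]),
                occupancy=1.0,
                is_hetero=bool(lab.is_hetero),
            )
        )
    return structure_io.Structure(atoms=atoms, provenance="nodes")


def write_trajectory_pdb(trajectory: ModeTrajectory, path) -> None:
    """Write the trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    st = nodes_as_structure(trajectory.nodes)
    structure_io.write_structure(st, path, coordinates=trajectory.frames)


def write_arrows_tsv(arrows: ArrowSet, path) -> None:
    """Arrow field as TSV: chain, residue, x, y, z, dx, dy, dz."""
    nodes = arrows.nodes
    with open(path, "w") as fh:
        fh.write("chain\tresidue\tx\ty\tz\tdx\tdy\tdz\n")
        for lab, b, v in zip(nodes.labels, arrows.base, arrows.vectors):
            fh.write(
                f"{lab.chain_id}\t{lab.residue_number}\t"
                f"{b[0]:.3f}\t{b[1]:.3f}\t{b[2]:.3f}\t"
                f"{v[0]:.6f}\t{v[1]:.6f}\t{v[2]:.6f}\n"
            )
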