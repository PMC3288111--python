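"""Synthetic test structures with known elastic-network spectra.

Every generator emits legal PDB-style atom records (through the same
Structure type the reader produces), so synthetic systems exercise the real
I/O path.  All randomness is seeded: the same spec + seed gives identical
output.

Generators
----------
``make_zigzag_chain``
    Near-linear C-alpha chain whose nearest-neighbor-only network has a
    spectrum checkable by dense eigensolve.
``make_helix``
    Ideal alpha-helix-like C-alpha spiral; a compact connected "protein".
``make_two_domain_dumbbell``
    Two dense clusters joined by a thin linker; its slowest internal mode is
    a hinge that moves the clusters in anti-phase.
``make_ring_oligomer``
    C_n-symmetric ring of monomer copies for oligomer and symmetry tests.
``make_pseudo_bfactors``
    Affine transform of a computed MSF profile plus Gaussian noise, standing
    in for experimental B-factors with a known planted (scale, shift).
"""

from __future__ import annotations

import logging

import numpy as np

from .flexibility import BFACTOR_CONSTANT
from .structure_io import AtomRecord, Structure

logger = logging.getLogger(__name__)


def _calpha_structure(
    positions: np.ndarray,
    chain_ids=None,
    provenance: str = "synthetic",
    b_factors=None,
    residue_name: str = "ALA",
) -> Structure:
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    chain_ids = chain_ids if chain_ids is not None else ["A"] * n
    b_factors = b_factors if b_factors is not None else np.zeros(n)
    atoms = []
    resnum = 0
    prev_chain = None
    for i in range(n):
        if chain_ids[i] != prev_chain:
            resnum = 0
            prev_chain = chain_ids[i]
        resnum += 1
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                element="C",
                residue_name=residue_name,
                chain_id=chain_ids[i],
                residue_number=resnum,
                insertion_code="",
                position=positions[i],
                b_experimental=float(b_factors[i]),
                occupancy=1.0,
                is_hetero=False,
            )
        )
    return Structure(atoms=atoms, provenance=provenance)


def make_zigzag_chain(
    n: int, spacing: float = 3.8, zigzag_amplitude: float = 1.0
) -> Structure:
    """Planar zigzag C-alpha chain with exact consecutive spacing.

    With a cutoff just above ``spacing`` the network is nearest-neighbor
    only (n-1 springs).  A zero amplitude makes the chain collinear (5 rigid
    modes instead of 6) and is warned about.
    """
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if zigzag_amplitude >= spacing:
        raise ValueError("zigzag_amplitude must be smaller than spacing")
    if zigzag_amplitude == 0:
        logger.warning("collinear chain: expect 5 rigid modes, not 6")
    dx = np.sqrt(spacing**2 - zigzag_amplitude**2)
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * dx
    pos[:, 1] = zigzag_amplitude * (np.arange(n) % 2)
    return _calpha_structure(pos, provenance=f"synthetic:zigzag(n={n})")


def make_helix(
    n: int, radius: float = 2.3, rise: float = 1.5, twist_deg: float = 100.0
) -> Structure:
    """Ideal helical C-alpha trace (alpha-helix geometry by default)."""
    if n < 4:
        raise ValueError("need at least 4 residues")
    t = np.deg2rad(twist_deg) * np.arange(n)
    pos = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)]
    )
    return _calpha_structure(pos, provenance=f"synthetic:helix(n={n})")


def _lattice_cluster(
    n: int, rng: np.random.Generator, spacing: float = 3.5, jitter: float = 0.5
) -> np.ndarray:
    """Compact jittered-lattice cluster, rigid at an 8 A cutoff for any seed."""
    g = np.arange(-3, 4)
    pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T * spacing
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order[:n]].astype(float)
    pts += rng.uniform(-jitter, jitter, pts.shape)
    return pts - pts.mean(axis=0)


def make_two_domain_dumbbell(
    n_per_domain: int = 12,
    linker_length: float = 16.0,
    seed: int = 0,
    hinge_offset: float = 4.0,
) -> Structure:
    """Two mirror-image dense clusters bridged by a double-stranded linker.

    Geometry choices, all forced by central-force spring mechanics:

    * clusters are compact jittered lattices, so they are internally rigid
      at the standard cutoffs for every seed;
    * domain B is the exact mirror image of domain A through the yz-plane,
      so the MSF profile is symmetric under domain swap to round-off;
    * the linker is two intertwined strands offset from the cluster-cluster
      axis (``hinge_offset``): a single thin strand would leave zero-energy
      bending/torsion mechanisms, and an on-axis linker makes torsion the
      slowest motion.  Off-axis double strands price stretch and torsion
      above bending, so the slowest internal mode is the anti-phase hinge
      bend: the two cluster-mean displacement vectors are anti-parallel and
      the linker sits at the node of the motion.
    """
    if n_per_domain < 4:
        raise ValueError("n_per_domain must be >= 4")
    rng = np.random.default_rng(seed)
    a = _lattice_cluster(n_per_domain, rng)
    extent = np.abs(a[:, 0]).max()
    half = linker_length / 2.0
    a = a - np.array([half + extent, 0, 0])
    b = a * np.array([-1.0, 1.0, 1.0])
    n_link = max(int(np.floor(linker_length / 2.0)) - 1, 2)
    xs = np.linspace(-half, half, n_link + 2)[1:-1]
    # phase even in x keeps the strands mirror-symmetric too
    phase = 1.1 * np.abs(xs)
    strand1 = np.column_stack(
        [xs, hinge_offset + np.cos(phase), np.sin(phase)]
    )
    strand2 = np.column_stack(
        [xs, hinge_offset - np.cos(phase), -np.sin(phase)]
    )
    pos = np.vstack([a, strand1, strand2, b])
    return _calpha_structure(
        pos, provenance=f"synthetic:dumbbell(n={n_per_domain},seed={seed})"
    )


def dumbbell_partition(n_per_domain: int, n_total: int):
    """(domain_a, linker, domain_b) node index arrays for a dumbbell."""
    a = np.arange(n_per_domain)
    b = np.arange(n_total - n_per_domain, n_total)
    link = np.arange(n_per_domain, n_total - n_per_domain)
    return a, link, b


def make_ring_oligomer(
    monomer: Structure, n_copies: int, radius: float, min_clearance: float = 1.0
) -> Structure:
    """C_n-symmetric ring: copies rotated by 2 pi / n about z on a circle.

    Raises if two copies come closer than ``min_clearance`` A, reporting the
    minimum inter-copy distance found.
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    coords = monomer.coordinates
    centered = coords - coords.mean(axis=0)
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    all_pos, chains = [], []
    for k in range(n_copies):
        theta = 2 * np.pi * k / n_copies
        c, s = np.cos(theta), np.sin(theta)
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        shifted = centered + np.array([radius, 0.0, 0.0])
        pos = shifted @ rz.T
        all_pos.append(pos)
        chains.extend([alphabet[k % 26]] * len(pos))
    from scipy.spatial import cKDTree

    for k in range(n_copies):
        tree = cKDTree(all_pos[k])
        d = tree.query(all_pos[(k + 1) % n_copies])[0].min()
        if d < min_clearance:
            raise ValueError(
                f"ring copies overlap: minimum inter-copy distance {d:.3f} A "
                f"< clearance {min_clearance} A"
            )
    return _calpha_structure(
        np.vstack(all_pos),
        chain_ids=chains,
        provenance=f"{monomer.provenance}|ring(n={n_copies},r={radius})",
    )


def make_pseudo_bfactors(
    msf: np.ndarray,
    scale: float = 2.0,
    shift: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Planted pseudo-experimental B-factors.

    B = scale * (8 pi^2 / 3) * MSF + shift + N(0, noise_sd).  With zero
    noise the affine transform is exact, so a least-squares fit must recover
    (scale, shift) to machine precision.
    """
    msf = np.asarray(msf, dtype=float)
    if np.any(msf < 0):
        raise ValueError("MSF must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=msf.shape) if noise_sd > 0 else 0.0
    return scale * BFACTOR_CONSTANT * msf + shift + noise
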