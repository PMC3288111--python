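"""PDB structure I/O, crystallographic symmetry expansion and region logic.

Parsing, writing and space-group math are delegated to gemmi; this module
exposes a flat atom-record view suited to elastic-network building, plus the
residue-set bookkeeping used for region and layer flexibility averages
(catalytic cleft, access channel, heme-proximal cavity, and radial layers
about the bound substrate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import yaml

from .elastic_network import NodeLabel, NodeSet

logger = logging.getLogger(__name__)

ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"LYS", "ARG"})
HEME_NAMES = frozenset({"HEM", "HEC", "HEA", "HEB"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: chain relabeling pool for symmetry copies
_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


class EmptyStructureError(ValueError):
    """No atoms survived parsing/filtering."""


class ConfigurationError(ValueError):
    """Missing or inconsistent structural metadata (unit cell, regions...)."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    b_experimental: float
    occupancy: float
    is_hetero: bool
    altloc: str = ""

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """Ordered atom records with optional crystal metadata."""

    atoms: list
    unit_cell: Optional[tuple] = None  # (a, b, c, alpha, beta, gamma)
    space_group: Optional[str] = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list:
        seen = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def iter_residues(self):
        """Yield (residue_key, residue_name, [atoms]) in file order."""
        current, buf = None, []
        for a in self.atoms:
            key = a.residue_key
            if key != current:
                if buf:
                    yield current, buf[0].residue_name, buf
                current, buf = key, []
            buf.append(a)
        if buf:
            yield current, buf[0].residue_name, buf


@dataclass
class SymmetryOperator:
    """Fractional-basis rotation + translation (x' = R x + t)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "SymmetryOperator":
        rinv = np.linalg.inv(self.rotation)
        return SymmetryOperator(rinv, -rinv @ self.translation)

    def shifted(self, lattice_shift) -> "SymmetryOperator":
        """Same operator composed with an integer lattice translation."""
        return SymmetryOperator(
            self.rotation, self.translation + np.asarray(lattice_shift, float)
        )


def space_group_operators(hermann_mauguin: str) -> list:
    """All symmetry operators of a space group, from gemmi's tables."""
    sg = gemmi.SpaceGroup(hermann_mauguin)
    ops = []
    for op in sg.operations().sym_ops:
        ops.append(
            SymmetryOperator(
                np.array(op.rot, dtype=float) / op.DEN,
                np.array(op.tran, dtype=float) / op.DEN,
            )
        )
    return ops


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _resolve_altlocs(atoms: list, policy: str) -> list:
    """Keep one atom per (residue, name) group of alternate locations."""
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy: {policy!r}")
    out, groups = [], {}
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        groups.setdefault(key, []).append(a)
    seen = set()
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
        if key in seen:
            continue
        seen.add(key)
        grp = groups[key]
        if len(grp) == 1 or policy == "first":
            out.append(grp[0])
        else:
            # max() is stable: ties go to the first listed
            out.append(max(grp, key=lambda x: x.occupancy))
    return out


def read_structure(
    path,
    altloc_policy: str = "highest_occupancy",
    keep_waters: bool = False,
) -> Structure:
    """Read a PDB file into a flat :class:`Structure`.

    Hydrogens are dropped; hetero groups (heme, steroid ligands) are kept
    and flagged; waters are dropped unless ``keep_waters``.  Alternate
    locations are resolved per ``altloc_policy`` (highest occupancy wins by
    default, ties to the first listed).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                if het and res.name in WATER_NAMES and not keep_waters:
                    continue
                for atom in res:
                    if atom.element.is_hydrogen:
                        continue
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            name=atom.name,
                            element=atom.element.name,
                            residue_name=res.name,
                            chain_id=chain.name,
                            residue_number=res.seqid.num,
                            insertion_code=(res.seqid.icode or " ").strip(),
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            b_experimental=float(atom.b_iso),
                            occupancy=float(atom.occ),
                            is_hetero=het,
                            altloc=(atom.altloc or "").strip(),
                        )
                    )
        break  # first model only; trajectories are re-read frame-wise
    atoms = _resolve_altlocs(atoms, altloc_policy)
    if not atoms:
        raise EmptyStructureError(f"no atoms left after filtering in {path}")
    cell = None
    if st.cell and st.cell.a > 0:
        cell = (st.cell.a, st.cell.b, st.cell.c,
                st.cell.alpha, st.cell.beta, st.cell.gamma)
    return Structure(
        atoms=atoms,
        unit_cell=cell,
        space_group=st.spacegroup_hm or None,
        provenance=str(path),
    )


def _to_gemmi(structure: Structure, coordinates=None) -> gemmi.Structure:
    st = gemmi.Structure()
    if structure.unit_cell:
        st.cell = gemmi.UnitCell(*structure.unit_cell)
    if structure.space_group:
        st.spacegroup_hm = structure.space_group
    coords = structure.coordinates if coordinates is None else np.asarray(coordinates)
    frames = coords.reshape(-1, len(structure.atoms), 3)
    for imodel, frame in enumerate(frames, start=1):
        model = gemmi.Model(str(imodel))
        chain = None
        res = None
        res_key = None
        for a, xyz in zip(structure.atoms, frame):
            if chain is None or chain.name != a.chain_id:
                chain = gemmi.Chain(a.chain_id)
                model.add_chain(chain)
                chain = model[-1]
                res_key = None
            key = (a.residue_number, a.insertion_code, a.residue_name)
            if key != res_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                chain.add_residue(res)
                res = chain[-1]
                res_key = key
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = a.occupancy
            atom.b_iso = a.b_experimental
            res.add_atom(atom)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path, coordinates=None) -> None:
    """Write fixed-column PDB; ``coordinates`` with extra leading dims yields
    a multi-model file (MODEL/ENDMDL)."""
    st = _to_gemmi(structure, coordinates)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# crystallographic symmetry expansion
# ---------------------------------------------------------------------------

def apply_symmetry(
    structure: Structure,
    operators: Sequence[SymmetryOperator] = None,
    copies: Sequence[int] = None,
) -> Structure:
    """Expand a structure by crystallographic symmetry operators.

    Operators act in fractional coordinates; conversion uses the standard
    crystallographic orthogonalization matrix of the unit cell.  Each copy's
    chains are relabeled to keep atom identities unique.  ``copies`` selects
    operator indices (default: all).
    """
    if structure.unit_cell is None:
        raise ConfigurationError("symmetry expansion requires a unit cell")
    if operators is None:
        if not structure.space_group:
            raise ConfigurationError("no operators given and no space group set")
        operators = space_group_operators(structure.space_group)
    if copies is not None:
        operators = [operators[i] for i in copies]
    cell = gemmi.UnitCell(*structure.unit_cell)
    orth = np.array(cell.orth.mat.tolist())
    frac = np.array(cell.frac.mat.tolist())
    coords = structure.coordinates
    fcoords = coords @ frac.T

    out_atoms = []
    used_chains = 0
    serial = 0
    identity = np.eye(3)
    for op in operators:
        if (np.array_equal(op.rotation, identity)
                and not np.any(op.translation)):
            new_xyz = coords.copy()  # exact: skip the fractional round trip
        else:
            new_f = fcoords @ op.rotation.T + op.translation
            new_xyz = new_f @ orth.T
        chain_map = {}
        for a, xyz in zip(structure.atoms, new_xyz):
            if a.chain_id not in chain_map:
                chain_map[a.chain_id] = _CHAIN_ALPHABET[
                    used_chains % len(_CHAIN_ALPHABET)
                ]
                used_chains += 1
            serial += 1
            out_atoms.append(
                AtomRecord(
                    serial=serial,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    chain_id=chain_map[a.chain_id],
                    residue_number=a.residue_number,
                    insertion_code=a.insertion_code,
                    position=np.asarray(xyz, dtype=float),
                    b_experimental=a.b_experimental,
                    occupancy=a.occupancy,
                    is_hetero=a.is_hetero,
                )
            )
    return Structure(
        atoms=out_atoms,
        unit_cell=structure.unit_cell,
        space_group=structure.space_group,
        provenance=f"{structure.provenance}|sym_x{len(operators)}",
    )


# ---------------------------------------------------------------------------
# node selection
# ---------------------------------------------------------------------------

def select_nodes(structure: Structure, scheme: str = "calpha_plus_hetero") -> NodeSet:
    """Pick network nodes from a structure.

    ``calpha_plus_hetero``: one node per residue at its C-alpha plus one node
    per hetero heavy atom, so heme and substrate enter the network with all
    their heavy atoms.  ``all_heavy``: one node per heavy atom.  Residues
    lacking a C-alpha under the C-alpha scheme are skipped with a warning.
    """
    if len(structure) == 0:
        raise EmptyStructureError("cannot select nodes from an empty structure")
    if scheme not in ("calpha_plus_hetero", "all_heavy"):
        raise ValueError(f"unknown node scheme: {scheme!r}")
    positions, labels, bexp = [], [], []
    if scheme == "all_heavy":
        chosen = structure.atoms
    else:
        chosen = []
        for key, resname, atoms in structure.iter_residues():
            if atoms[0].is_hetero:
                chosen.extend(atoms)
                continue
            ca = [a for a in atoms if a.name == "CA"]
            if not ca:
                logger.warning("residue %s %s lacks a CA; skipped", resname, key)
                continue
            chosen.append(ca[0])
    for a in chosen:
        positions.append(a.position)
        bexp.append(a.b_experimental)
        labels.append(
            NodeLabel(
                a.chain_id, a.residue_number, a.insertion_code,
                a.residue_name, a.name, a.is_hetero,
            )
        )
    return NodeSet(
        positions=np.array(positions),
        labels=labels,
        b_experimental=np.array(bexp),
    )


# ---------------------------------------------------------------------------
# regions and layers
# ---------------------------------------------------------------------------

LAYER_NAMES = ("inner_core", "middle_layer", "outer_layer")

REGION_KEYS = (
    "heme", "substrate", "catalytic_cleft", "access_channel",
    "proximal_cavity", "e_site", "p_site",
)


@dataclass
class RegionSpec:
    """Named residue sets plus radial-layer thresholds.

    Selectors per region: residue names ("HEM"), residue numbers (192), or
    "chain:number" strings ("A:192").  ``layer_radii`` are strictly
    increasing distances (A) from the reference point (default: centroid of
    substrate heavy atoms) bounding the inner core and middle layer.
    """

    regions: dict = field(default_factory=dict)
    layer_radii: Sequence[float] = (15.0, 20.0)
    reference_rule: str = "centroid of substrate heavy atoms"

    def __post_init__(self):
        radii = list(self.layer_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigurationError("layer_radii must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "RegionSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        radii = data.pop("layer_radii", (15.0, 20.0))
        regions = {k: v for k, v in data.items() if v}
        return cls(regions=regions, layer_radii=radii)

    def to_yaml(self, path) -> None:
        data = dict(self.regions)
        data["layer_radii"] = list(self.layer_radii)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _selector_match(label: NodeLabel, selector) -> bool:
    if isinstance(selector, int):
        return label.residue_number == selector and not label.is_hetero
    s = str(selector)
    if ":" in s:
        chain, num = s.split(":", 1)
        return label.chain_id == chain and label.residue_number == int(num)
    if s.isdigit():
        return label.residue_number == int(s) and not label.is_hetero
    return label.residue_name == s.upper()


def resolve_selectors(nodes: NodeSet, selectors: Iterable) -> np.ndarray:
    """Node indices matched by any selector in the list."""
    sel = list(selectors)
    mask = np.zeros(len(nodes), dtype=bool)
    for i, lab in enumerate(nodes.labels):
        mask[i] = any(_selector_match(lab, s) for s in sel)
    return np.flatnonzero(mask)


@dataclass
class RegionAssignment:
    """Per-node region labels and layer index over a NodeSet."""

    region_members: dict  # region name -> node index array
    layer_index: np.ndarray  # per node: 0 inner, 1 middle, 2 outer; -1 if no layers
    reference_point: Optional[np.ndarray] = None

    def layer_members(self, layer: int) -> np.ndarray:
        return np.flatnonzero(self.layer_index == layer)


def assign_regions(
    structure: Structure,
    nodes: NodeSet,
    spec: RegionSpec,
    layers: bool = True,
) -> RegionAssignment:
    """Resolve region membership and radial-layer index for every node.

    Layer membership uses each residue node's position (C-alpha in C-alpha
    mode) relative to the substrate centroid, with the boundary convention
    r <= r1 inner, r1 < r <= r2 middle, r > r2 outer.  If the spec leaves
    ``catalytic_cleft`` empty, the fallback rule selects residues having any
    heavy atom within 4.5 A of the substrate.
    """
    members = {}
    for name, selectors in spec.regions.items():
        idx = resolve_selectors(nodes, selectors)
        if idx.size:
            members[name] = idx
    if "catalytic_cleft" not in members and "substrate" in spec.regions:
        idx = cleft_by_proximity(structure, nodes, spec.regions["substrate"])
        if idx.size:
            members["catalytic_cleft"] = idx
            logger.info("catalytic_cleft set by 4.5 A substrate proximity "
                        "(%d nodes)", idx.size)

    layer_index = np.full(len(nodes), -1, dtype=int)
    ref = None
    if layers:
        sub_sel = spec.regions.get("substrate", [])
        sub_idx = resolve_selectors(nodes, sub_sel)
        if sub_idx.size == 0:
            raise ConfigurationError(
                "layers requested but the substrate selection is empty"
            )
        ref = nodes.positions[sub_idx].mean(axis=0)
        dist = np.linalg.norm(nodes.positions - ref, axis=1)
        radii = list(spec.layer_radii)
        layer_index = np.searchsorted(radii, dist, side="left")
        # searchsorted puts r == threshold into the inner side (r <= r1 inner)
    return RegionAssignment(
        region_members=members, layer_index=layer_index, reference_point=ref
    )


def cleft_by_proximity(
    structure: Structure,
    nodes: NodeSet,
    substrate_selectors: Iterable,
    radius: float = 4.5,
) -> np.ndarray:
    """Residue nodes with any heavy atom within ``radius`` of the substrate."""
    sub_names = {str(s).upper() for s in substrate_selectors}
    sub_xyz = np.array(
        [a.position for a in structure.atoms if a.residue_name in sub_names]
    )
    if sub_xyz.size == 0:
        return np.array([], dtype=int)
    from scipy.spatial import cKDTree

    tree = cKDTree(sub_xyz)
    close_res = set()
    for a in structure.atoms:
        if a.is_hetero:
            continue
        if tree.query_ball_point(a.position, radius):
            close_res.add(a.residue_key)
    idx = [
        i
        for i, lab in enumerate(nodes.labels)
        if not lab.is_hetero
        and (lab.chain_id, lab.residue_number, lab.insertion_code) in close_res
    ]
    return np.array(idx, dtype=int)


class ChargeCensus(tuple):
    """(n_acidic, n_basic, include_heme) for a site's residue set."""

    def __new__(cls, n_acidic, n_basic, include_heme):
        return super().__new__(cls, (n_acidic, n_basic, include_heme))

    n_acidic = property(lambda self: self[0])
    n_basic = property(lambda self: self[1])
    include_heme = property(lambda self: self[2])


def charge_census(
    structure: Structure,
    site: Iterable,
    count_histidine: bool = False,
) -> ChargeCensus:
    """Count charged residues in a site's residue set.

    Acidic: Asp/Glu.  Basic: Lys/Arg (His optional, excluded by default).
    The heme prosthetic group counts as one positive moiety when its residue
    is inside the site set.
    """
    basic = BASIC_RESIDUES | ({"HIS"} if count_histidine else set())
    sel = list(site)
    seen = set()
    n_acid = n_base = 0
    include_heme = False
    for key, resname, atoms in structure.iter_residues():
        lab = NodeLabel(key[0], key[1], key[2], resname, "", atoms[0].is_hetero)
        if not any(_selector_match(lab, s) for s in sel):
            continue
        if key in seen:
            continue
        seen.add(key)
        if resname in ACIDIC_RESIDUES:
            n_acid += 1
        elif resname in basic:
            n_base += 1
        elif resname in HEME_NAMES:
            include_heme = True
    return ChargeCensus(n_acid, n_base, include_heme)
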