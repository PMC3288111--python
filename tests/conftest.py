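import numpy as np
import pytest

import enmflex as ef
from enmflex import synthetic_data as sd
from enmflex.structure_io import AtomRecord, Structure


def _atom(serial, name, resname, chain, resnum, xyz, b=10.0, occ=1.0,
          het=False, element="C"):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=resname,
        chain_id=chain, residue_number=resnum, insertion_code="",
        position=np.asarray(xyz, dtype=float), b_experimental=b,
        occupancy=occ, is_hetero=het,
    )


@pytest.fixture(scope="session")
def helix_structure():
    return sd.make_helix(30)


@pytest.fixture(scope="session")
def helix_modes(helix_structure):
    nodes = ef.select_nodes(helix_structure)
    net = ef.build_network(nodes, cutoff=10.0)
    return ef.solve_modes(ef.hessian(net), nodes=nodes)


@pytest.fixture(scope="session")
def dumbbell_structure():
    return sd.make_two_domain_dumbbell(12, 16.0, seed=1)


@pytest.fixture(scope="session")
def dumbbell_modes(dumbbell_structure):
    nodes = ef.select_nodes(dumbbell_structure)
    net = ef.build_network(nodes, cutoff=8.0)
    return ef.solve_modes(ef.hessian(net), nodes=nodes)


@pytest.fixture
def liganded_structure():
    """Toy protein with a hetero 'substrate' (LIG) and a heme-like group.

    C-alphas sit at controlled distances from the substrate centroid at the
    origin, so layer boundaries are exercised exactly.
    """
    atoms = []
    serial = 0
    dists = [2.0, 5.0, 14.9, 15.0, 15.1, 18.0, 20.0, 20.1, 30.0]
    for i, d in enumerate(dists, start=1):
        serial += 1
        atoms.append(_atom(serial, "CA", "ALA", "A", i, (d, 0.0, 0.0)))
    # substrate: two heavy atoms straddling the origin
    for j, x in enumerate((-1.0, 1.0)):
        serial += 1
        atoms.append(_atom(serial, f"C{j+1}", "LIG", "A", 501, (x, 0.0, 0.0),
                           het=True))
    serial += 1
    atoms.append(_atom(serial, "FE", "HEM", "A", 502, (0.0, 3.0, 0.0),
                       het=True, element="FE"))
    return Structure(atoms=atoms, provenance="fixture:liganded")


@pytest.fixture
def charged_structure():
    """Chain carrying the charged residue types plus a heme."""
    names = ["ASP", "GLU", "LYS", "ARG", "HIS", "ALA", "GLU", "ASP"]
    atoms = []
    for i, rn in enumerate(names, start=1):
        atoms.append(_atom(i, "CA", rn, "A", i, (4.0 * i, 0.0, 0.0)))
    atoms.append(_atom(len(names) + 1, "FE", "HEM", "A", 100,
                       (0.0, 5.0, 0.0), het=True, element="FE"))
    return Structure(atoms=atoms, provenance="fixture:charged")
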