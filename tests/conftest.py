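import numpy as np
import pytest

from shellmap.contacts import Contact, ContactNetwork
from shellmap.structure import Atom, Residue, ResidueID, Structure


def make_atom(name: str, coord, serial: int = 1, element: str | None = None,
              occupancy: float = 1.0, altloc: str = "") -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element or name[0],
        altloc=altloc,
        occupancy=occupancy,
        coord=tuple(float(x) for x in coord),
    )


def make_residue(chain: str, number: int, atom_specs, name: str = "ALA",
                 is_polymer: bool = True) -> Residue:
    """atom_specs: iterable of (atom_name, coord)."""
    atoms = [make_atom(n, c, serial=i + 1) for i, (n, c) in enumerate(atom_specs)]
    return Residue(id=ResidueID(chain, number), name=name, atoms=atoms,
                   is_polymer=is_polymer)


def graph_as_network(graph) -> ContactNetwork:
    """Wrap an abstract networkx graph (integer nodes) as a contact network."""
    ids = {n: ResidueID("A", int(n)) for n in graph.nodes}
    edges = {}
    for u, v in graph.edges:
        a, b = sorted((ids[u], ids[v]))
        edges[(a, b)] = Contact(res_a=a, res_b=b, min_distance=1.0, n_atom_pairs=1)
    return ContactNetwork(cutoff=5.0, scope="intra_chain",
                          nodes=set(ids.values()), edges=edges)


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  occ=1.0, b=20.0, altloc=" ", icode=" ", element=None,
                  record="ATOM") -> str:
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_residue_pdb() -> str:
    lines = [
        pdb_atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_atom_line(2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0),
        pdb_atom_line(3, "N", "ALA", "A", 2, 3.0, 0.0, 0.0, element="N"),
        pdb_atom_line(4, "CA", "ALA", "A", 2, 4.5, 0.0, 0.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def wt_cellobiose_params():
    """Wild-type cellobiose kinetics used throughout: Km 2.36 mM, kcat 2.61 1/s."""
    return 2.36, 2.61
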