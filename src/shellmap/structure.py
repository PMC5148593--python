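"""Typed structural model: chains, residues, heavy atoms.

The model is a thin, explicit layer over PDB-format coordinates.  Parsing and
serialisation are delegated to :mod:`gemmi`; this module owns the policies
that downstream contact analysis depends on:

* hydrogens are dropped by default (X-ray structures of this resolution carry
  none, and contact counts must not depend on protonation modelling);
* alternate conformations are collapsed to the highest-occupancy conformer
  (ties broken by file order), so every atom name is unique within a residue;
* author residue numbering is kept verbatim — functional-residue labels such
  as E187 or E399 must match the literature;
* waters and other hetero groups (Tris, NAG glycans) are retained in the
  model but flagged, so network construction can exclude them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueID",
    "Residue",
    "Structure",
    "PDBParseError",
    "PDBWriteError",
    "read_pdb",
    "write_pdb",
    "select_residues",
    "atom_class",
    "MAIN_CHAIN_ATOMS",
]

#: Backbone heavy-atom names; everything else on a standard residue is side chain.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names treated as solvent and never part of residue networks.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    """Raised when a PDB stream cannot be turned into a Structure."""


class PDBWriteError(ValueError):
    """Raised when a Structure cannot be serialised to PDB format."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    altloc: str  # '' when single conformer
    occupancy: float
    coord: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True, order=True)
class ResidueID:
    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.number}{self.icode}"


@dataclass
class Residue:
    id: ResidueID
    name: str
    atoms: list[Atom]
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.id} has no atoms")

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.id} ({self.name})")

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if atom_class(self, a) == "side_chain"]


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def polymer_chain_ids(self) -> list[str]:
        """Chains containing at least one standard (ATOM-record) residue."""
        return [c for c, rs in self.chains.items() if any(r.is_polymer for r in rs)]

    def residue(self, rid: ResidueID) -> Residue:
        for r in self.chains.get(rid.chain_id, []):
            if r.id == rid:
                return r
        raise KeyError(f"residue {rid} not in structure {self.id}")

    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())


def atom_class(residue: Residue, atom: Atom) -> str:
    """Partition a heavy atom into ``main_chain`` or ``side_chain``.

    Backbone atoms N, CA, C, O (and terminal OXT) are main chain; everything
    else is side chain.  Glycine therefore has no side-chain atoms.  Hetero
    residues have no backbone in the peptide sense, so all their atoms are
    classed ``side_chain``.
    """
    if residue.is_polymer and atom.name in MAIN_CHAIN_ATOMS:
        return "main_chain"
    return "side_chain"


# ---------------------------------------------------------------------------
# reading


def _as_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        # heuristically a path if it exists on disk and has no newline
        if "\n" not in source and Path(source).exists():
            return Path(source).read_text()
        return source
    if hasattr(source, "read"):
        return source.read()
    raise TypeError(f"cannot read PDB from {type(source)!r}")


def _pick_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Collapse alternate conformations: keep highest occupancy per atom name,
    ties resolved by file order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [replace(best[n], altloc="") for n in order]


def read_pdb(source, *, keep_hydrogens: bool = False, structure_id: str | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    ``source`` may be a path, raw PDB text, or an open text stream.  Only the
    first model of a multi-model file is read.  Hydrogen (and deuterium)
    atoms are dropped unless ``keep_hydrogens`` is set.
    """
    text = _as_text(source)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise PDBParseError(f"malformed PDB input: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no coordinate records (ATOM/HETATM) in input")

    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            raw_atoms: list[Atom] = []
            for at in res:
                if not keep_hydrogens and at.element.is_hydrogen:
                    continue
                altloc = at.altloc if at.altloc not in ("\0", "\x00") else ""
                raw_atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        altloc=altloc,
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        is_hetero=(res.het_flag == "H"),
                    )
                )
            if not raw_atoms:
                continue
            residues.append(
                Residue(
                    id=ResidueID(chain.name, res.seqid.num, (res.seqid.icode or "").strip()),
                    name=res.name.strip(),
                    atoms=_pick_altlocs(raw_atoms),
                    is_polymer=(res.het_flag != "H"),
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.id.number, r.id.icode))
            chains[chain.name] = residues
    if not chains:
        raise PDBParseError("structure contains no residues after filtering")
    return Structure(id=structure_id or (st.name or "structure"), chains=chains)


# ---------------------------------------------------------------------------
# writing


def write_pdb(structure: Structure) -> str:
    """Serialise a Structure back to PDB-format text.

    Coordinates survive a round trip to 3 decimals (the format's precision).
    """
    if not structure.chains:
        raise PDBWriteError("structure has no chains")
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain_id, residues in structure.chains.items():
        if not residues:
            raise PDBWriteError(f"chain {chain_id!r} is empty")
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.id.number, res.id.icode or " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise PDBWriteError(
                        f"atom name {atom.name!r} exceeds the 4-character PDB field"
                    )
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*atom.coord)
                gat.occ = atom.occupancy
                gat.serial = atom.serial
                if atom.altloc:
                    gat.altloc = atom.altloc
                gres.add_atom(gat)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# selection


def select_residues(
    structure: Structure, chain_id: str, *, polymer_only: bool = True
) -> list[Residue]:
    """Residues of one chain, optionally restricted to standard amino acids.

    ``polymer_only=True`` drops waters and hetero groups (Tris, NAG, ...).
    """
    if chain_id not in structure.chains:
        raise KeyError(
            f"chain {chain_id!r} not in structure {structure.id}; "
            f"available: {', '.join(structure.chain_ids)}"
        )
    residues = structure.chains[chain_id]
    if polymer_only:
        residues = [r for r in residues if r.is_polymer and not r.is_water]
    return list(residues)
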