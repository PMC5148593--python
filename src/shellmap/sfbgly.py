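"""Convenience analyses specific to the Sfβgly structure (PDB entry 5CG0).

These helpers run the generic pipeline with the Sfβgly functional-region
definitions and expose the structure-level observables the mutational
analysis rests on: the catalytic-glutamate carboxylate geometry, the NAG
glycan census, and the chain-A contact-shell table.  They need a local copy
of the deposited structure; nothing here downloads anything.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .contacts import build_contact_network
from .data import load_sfbgly_regions
from .layers import FunctionalRegion, LayerTable, steps_to_regions
from .structure import ResidueID, Structure, read_pdb, select_residues

__all__ = [
    "find_local_structure",
    "sfbgly_regions",
    "chain_layer_table",
    "nag_residue_count",
    "catalytic_carboxylate_distances",
]

#: Environment variable pointing at a local copy of the 5CG0 PDB file.
STRUCTURE_ENV = "SHELLMAP_5CG0_PDB"


def find_local_structure() -> Path | None:
    """Locate a local 5CG0 coordinate file, if the user has one.

    Checks ``$SHELLMAP_5CG0_PDB`` and then ``5CG0.pdb`` in the working
    directory.  Returns None when absent — callers decide whether that is an
    error or a reason to skip.
    """
    env = os.environ.get(STRUCTURE_ENV)
    if env and Path(env).exists():
        return Path(env)
    local = Path("5CG0.pdb")
    return local if local.exists() else None


def sfbgly_regions(chain: str = "A") -> list[FunctionalRegion]:
    """CR / GBS / ABS region definitions on one chain."""
    raw = load_sfbgly_regions()
    order = ["GBS", "ABS", "CR"]
    return [
        FunctionalRegion(
            name=name, members=frozenset(ResidueID(chain, n) for n in raw[name])
        )
        for name in order
    ]


def chain_layer_table(
    structure: Structure, chain: str = "A", cutoff: float = 5.0
) -> LayerTable:
    """Contact-shell table of one chain under the standard 5 Å criterion."""
    residues = select_residues(structure, chain, polymer_only=True)
    network = build_contact_network(residues, cutoff=cutoff, scope="intra_chain")
    return steps_to_regions(network, sfbgly_regions(chain))


def nag_residue_count(structure: Structure) -> int:
    """Number of NAG (N-acetylglucosamine) residues across all chains."""
    return sum(1 for r in structure if r.name == "NAG")


def catalytic_carboxylate_distances(
    structure: Structure, chain: str, donor: int = 187, nucleophile: int = 399
) -> np.ndarray:
    """Pairwise distances between the carboxylate oxygens of the catalytic pair.

    For a retaining glycosidase the proton donor and nucleophile carboxylates
    sit roughly 4.5–5.5 Å apart; returns the four OE1/OE2 cross distances.
    """
    res_d = structure.residue(ResidueID(chain, donor))
    res_n = structure.residue(ResidueID(chain, nucleophile))
    oxy_d = [a.xyz for a in res_d.atoms if a.name in ("OE1", "OE2")]
    oxy_n = [a.xyz for a in res_n.atoms if a.name in ("OE1", "OE2")]
    if not oxy_d or not oxy_n:
        raise ValueError(
            f"missing carboxylate oxygens on {chain}:{donor} or {chain}:{nucleophile}"
        )
    return np.array([[np.linalg.norm(a - b) for b in oxy_n] for a in oxy_d])
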