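"""Inter-chain contacts and dimer-interface reciprocity.

The oligomeric arrangement in a crystal places chains in contact; for a
pseudo-twofold dimer the interface should read the same from either side:
if residue i of chain X touches residue j of chain Y, then residue i of
chain Y should touch residue j of chain X.  ``check_reciprocity`` measures
how completely an interface honours that symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .contacts import DEFAULT_CUTOFF, build_contact_network
from .structure import Residue, ResidueID, Structure, select_residues

__all__ = [
    "InterfaceContact",
    "ReciprocityReport",
    "interchain_contacts",
    "check_reciprocity",
    "interface_residue_sets",
]


@dataclass(frozen=True)
class InterfaceContact:
    res_a: ResidueID  # in chain X
    res_b: ResidueID  # in chain Y
    min_distance: float

    def __post_init__(self) -> None:
        if self.res_a.chain_id == self.res_b.chain_id:
            raise ValueError("interface contact must span two chains")


@dataclass
class ReciprocityReport:
    total: int
    reciprocal: int
    non_reciprocal_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return self.reciprocal / self.total if self.total else 1.0


def interchain_contacts(
    structure: Structure,
    chain_x: str,
    chain_y: str,
    cutoff: float = DEFAULT_CUTOFF,
    *,
    include_hetero: bool = False,
) -> list[InterfaceContact]:
    """All residue pairs across two chains with min atomic distance < cutoff.

    Contacts are reported with the chain-X residue first, sorted by residue
    number.
    """
    if chain_x == chain_y:
        raise ValueError(f"need two distinct chains, got {chain_x!r} twice")
    res_x = select_residues(structure, chain_x, polymer_only=not include_hetero)
    res_y = select_residues(structure, chain_y, polymer_only=not include_hetero)
    network = build_contact_network(
        list(res_x) + list(res_y),
        cutoff=cutoff,
        scope="inter_chain",
        include_hetero=include_hetero,
    )
    out = []
    for contact in network.edges.values():
        a, b = contact.res_a, contact.res_b
        if a.chain_id == chain_y:
            a, b = b, a
        out.append(InterfaceContact(res_a=a, res_b=b, min_distance=contact.min_distance))
    out.sort(key=lambda c: (c.res_a, c.res_b))
    return out


def check_reciprocity(
    contacts_xy: Sequence[InterfaceContact],
    contacts_yx: Sequence[InterfaceContact],
) -> ReciprocityReport:
    """Check the pseudo-symmetry of a dimer interface.

    A contact (residue i of X, residue j of Y) is reciprocal when the
    mirrored contact (residue i of Y, residue j of X) exists — i.e. the pair
    of author numbers (i, j) appears in ``contacts_yx`` as well.  Both lists
    must come from the same structure, computed in the two chain orders.
    """
    mirrored = {(c.res_a.number, c.res_b.number) for c in contacts_yx}
    non_reciprocal = []
    reciprocal = 0
    for c in contacts_xy:
        if (c.res_a.number, c.res_b.number) in mirrored:
            reciprocal += 1
        else:
            non_reciprocal.append((c.res_a.number, c.res_b.number))
    return ReciprocityReport(
        total=len(contacts_xy),
        reciprocal=reciprocal,
        non_reciprocal_pairs=non_reciprocal,
    )


def interface_residue_sets(
    contacts: Sequence[InterfaceContact],
) -> dict[str, list[int]]:
    """Endpoints of any cross-chain contact, per chain, as sorted numbers."""
    out: dict[str, set[int]] = {}
    for c in contacts:
        out.setdefault(c.res_a.chain_id, set()).add(c.res_a.number)
        out.setdefault(c.res_b.chain_id, set()).add(c.res_b.number)
    return {chain: sorted(nums) for chain, nums in sorted(out.items())}
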