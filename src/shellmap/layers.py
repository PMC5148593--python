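"""Contact shells and shortest-path region association around an active site.

Functional residues are grouped into named regions — for a GH1 β-glycosidase
the catalysis-related residues (CR), the glycone-binding site (GBS) and the
aglycone-binding site (ABS).  Every other residue is characterised by its
graph distance, in contact steps, to each region: residues one step away
form the first shell (L1, direct contacts of functional residues), residues
two steps away form the second shell (L2), and so on.  A residue's
*association* is the set of regions it reaches at its minimal step count;
ties produce multi-region (Venn-intersection) categories.

The side-chain-constrained variant asks a sharper question: which regions
can a substitution at this position perturb *through its side chain*?  The
first contact step out of the query residue is then restricted to edges in
which that residue's side chain participates.  This resolves cases where a
residue's backbone touches one region's neighbourhood while its side chain
points at another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .contacts import ContactNetwork
from .structure import ResidueID

__all__ = [
    "FunctionalRegion",
    "LayerAssignment",
    "LayerTable",
    "steps_to_regions",
    "assign_layers",
    "region_association",
    "sidechain_constrained_association",
    "REGION_ORDER",
]

#: Fixed rendering order for region names in reports.
REGION_ORDER = ("GBS", "ABS", "CR")


@dataclass(frozen=True)
class FunctionalRegion:
    name: str
    members: frozenset[ResidueID]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"region {self.name!r} has no members")


@dataclass(frozen=True)
class LayerAssignment:
    residue: ResidueID
    #: region name -> graph distance in contact steps; unreachable regions absent
    steps_to_region: Mapping[str, int]
    layer: int
    association: frozenset[str]


@dataclass
class LayerTable:
    assignments: dict[ResidueID, LayerAssignment]
    #: region name -> members that were not nodes of the network
    missing_members: dict[str, list[ResidueID]] = field(default_factory=dict)
    region_names: tuple[str, ...] = REGION_ORDER

    def __getitem__(self, rid: ResidueID) -> LayerAssignment:
        return self.assignments[rid]

    def __iter__(self):
        return iter(self.assignments.values())

    def __len__(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in sorted(self.assignments.values(), key=lambda a: a.residue):
            row = {
                "chain": a.residue.chain_id,
                "number": a.residue.number,
                "icode": a.residue.icode,
                "layer": a.layer,
            }
            for name in self.region_names:
                row[f"steps_to_{name}"] = a.steps_to_region.get(name, pd.NA)
            row["association"] = format_association(a.association, self.region_names)
            rows.append(row)
        return pd.DataFrame(rows)


def format_association(assoc: Iterable[str], order: Sequence[str] = REGION_ORDER) -> str:
    names = set(assoc)
    ordered = [n for n in order if n in names] + sorted(names - set(order))
    return "+".join(ordered)


def _check_regions(regions: Sequence[FunctionalRegion]) -> None:
    seen: dict[ResidueID, str] = {}
    for reg in regions:
        for m in reg.members:
            if m in seen and seen[m] != reg.name:
                raise ValueError(
                    f"regions must be pairwise disjoint; {m} is in both "
                    f"{seen[m]} and {reg.name}"
                )
            seen[m] = reg.name


def steps_to_regions(
    network: ContactNetwork, regions: Sequence[FunctionalRegion]
) -> LayerTable:
    """Multi-source BFS distance from each region's member set to every node.

    Region members missing from the network are reported (warning + listed in
    the returned table), never silently dropped.  A residue's ``layer`` is
    the minimum step count over regions; its ``association`` is the set of
    regions achieving that minimum.
    """
    if not network.nodes:
        raise ValueError("empty contact network")
    _check_regions(regions)
    graph = network.to_graph()

    per_region: dict[str, dict[ResidueID, int]] = {}
    missing: dict[str, list[ResidueID]] = {}
    for reg in regions:
        present = [m for m in reg.members if m in network.nodes]
        absent = sorted(set(reg.members) - set(present))
        if absent:
            missing[reg.name] = absent
            warnings.warn(
                f"region {reg.name}: members not in network: "
                + ", ".join(map(str, absent)),
                stacklevel=2,
            )
        if not present:
            per_region[reg.name] = {}
            continue
        lengths = nx.multi_source_dijkstra_path_length(graph, present, weight=None)
        per_region[reg.name] = {rid: int(d) for rid, d in lengths.items()}

    assignments: dict[ResidueID, LayerAssignment] = {}
    region_names = tuple(r.name for r in regions)
    for rid in network.nodes:
        steps = {
            name: dist[rid] for name, dist in per_region.items() if rid in dist
        }
        if steps:
            layer = min(steps.values())
            assoc = frozenset(n for n, s in steps.items() if s == layer)
        else:
            layer = -1  # disconnected from every region
            assoc = frozenset()
        assignments[rid] = LayerAssignment(
            residue=rid, steps_to_region=steps, layer=layer, association=assoc
        )
    return LayerTable(assignments=assignments, missing_members=missing,
                      region_names=region_names)


def assign_layers(
    table: LayerTable, *, max_layer: int = 2
) -> dict[str, list[ResidueID]]:
    """Partition nodes into shells: L0 (functional), L1 .. L{max_layer}, beyond.

    Residues disconnected from every region land in ``unreachable``.
    """
    parts: dict[str, list[ResidueID]] = {f"L{k}": [] for k in range(max_layer + 1)}
    parts["beyond"] = []
    parts["unreachable"] = []
    for a in table:
        if a.layer < 0:
            parts["unreachable"].append(a.residue)
        elif a.layer <= max_layer:
            parts[f"L{a.layer}"].append(a.residue)
        else:
            parts["beyond"].append(a.residue)
    for v in parts.values():
        v.sort()
    return parts


def region_association(assignment: LayerAssignment) -> frozenset[str]:
    """The Venn category: regions reached at the minimal step count."""
    if not assignment.steps_to_region:
        raise ValueError(
            f"residue {assignment.residue} reaches no functional region"
        )
    best = min(assignment.steps_to_region.values())
    return frozenset(
        n for n, s in assignment.steps_to_region.items() if s == best
    )


def sidechain_constrained_association(
    network: ContactNetwork,
    regions: Sequence[FunctionalRegion],
    residue: ResidueID,
    *,
    table: LayerTable | None = None,
) -> frozenset[str]:
    """Association when the first contact step must involve the query's side chain.

    Models which regions a side-chain substitution can perturb: the path
    leaves the residue through a contact in which its side chain
    participates; subsequent steps are unrestricted.  Returns the set of
    regions at the minimal constrained path length; empty (with a warning)
    when the residue has no side-chain-mediated contacts, e.g. glycine.
    """
    if residue not in network.nodes:
        raise KeyError(f"residue {residue} not in network")
    member_of = frozenset(r.name for r in regions if residue in r.members)
    if member_of:
        return member_of  # a functional residue perturbs its own region directly

    if table is None:
        table = steps_to_regions(network, regions)

    allowed: list[ResidueID] = []
    for (a, b), c in network.edges.items():
        if a == residue and c.a_side_chain_involved:
            allowed.append(b)
        elif b == residue and c.b_side_chain_involved:
            allowed.append(a)
    if not allowed:
        warnings.warn(
            f"residue {residue} has no side-chain-mediated contacts; "
            "constrained association is empty",
            stacklevel=2,
        )
        return frozenset()

    best_steps: dict[str, int] = {}
    for nbr in allowed:
        for name, s in table[nbr].steps_to_region.items():
            cand = 1 + s
            if name not in best_steps or cand < best_steps[name]:
                best_steps[name] = cand
    if not best_steps:
        return frozenset()
    best = min(best_steps.values())
    return frozenset(n for n, s in best_steps.items() if s == best)
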