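"""Synthetic structures and rate data with known ground truth.

Every stage of the pipeline is testable without downloading a real
structure: bead polymers force a known contact topology by arithmetic,
shell clusters force a known layer decomposition by a radial construction,
symmetric dimers force interface reciprocity, and forward-simulated
Michaelis–Menten series carry their generating parameters.

All randomness sits behind explicit integer seeds; no global random state
is touched.  Each generator asserts the self-consistency of the truth it
returns before handing it out.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contacts import Contact, ContactNetwork, DEFAULT_CUTOFF
from .kinetics import RateSeries, michaelis_menten
from .layers import FunctionalRegion
from .structure import Atom, Residue, ResidueID, Structure

__all__ = [
    "make_bead_polymer",
    "make_random_cloud",
    "make_shell_cluster",
    "make_symmetric_dimer",
    "simulate_rate_series",
    "ShellTruth",
]


def _residue(chain: str, number: int, coords: Sequence[Sequence[float]],
             names: Sequence[str] | None = None, resname: str = "ALA") -> Residue:
    names = names or ["CA", "CB", "CG", "CD", "CE", "CZ", "NZ", "OG"][: len(coords)]
    atoms = [
        Atom(
            serial=number * 10 + i,
            name=names[i],
            element=names[i][0],
            altloc="",
            occupancy=1.0,
            coord=tuple(float(x) for x in c),
        )
        for i, c in enumerate(coords)
    ]
    return Residue(id=ResidueID(chain, number), name=resname, atoms=atoms)


# ---------------------------------------------------------------------------
# bead polymer


def make_bead_polymer(
    n: int,
    spacing: float,
    seed: int = 0,
    *,
    cutoff: float = DEFAULT_CUTOFF,
    atoms_per_residue: int = 1,
    jitter: float = 0.3,
) -> tuple[Structure, ContactNetwork]:
    """Collinear single-atom residues with arithmetic contact truth.

    With one atom per residue the truth is forced by geometry: residues i, j
    are in contact iff |i - j| * spacing < cutoff (strict).  With extra
    atoms (a small jittered cloud around each bead, radius ``jitter``) the
    truth edge set is recomputed exhaustively from the actual coordinates.
    """
    if n < 2:
        raise ValueError("a polymer needs at least 2 residues")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n):
        center = np.array([i * spacing, 0.0, 0.0])
        coords = [center]
        for _ in range(atoms_per_residue - 1):
            offset = rng.normal(size=3)
            offset *= jitter * rng.uniform(0.2, 1.0) / np.linalg.norm(offset)
            coords.append(center + offset)
        residues.append(_residue("A", i + 1, coords))
    structure = Structure(id=f"bead_polymer_n{n}", chains={"A": residues})
    truth = _exhaustive_truth(residues, cutoff)
    if atoms_per_residue == 1:
        expected = {
            (residues[i].id, residues[j].id)
            for i, j in itertools.combinations(range(n), 2)
            if (j - i) * spacing < cutoff
        }
        assert set(truth.edges) == expected, "bead-polymer truth violated its predicate"
    return structure, truth


def _exhaustive_truth(residues: Sequence[Residue], cutoff: float) -> ContactNetwork:
    """Plain double-loop truth network (independent of the k-d tree path)."""
    edges: dict[tuple[ResidueID, ResidueID], Contact] = {}
    for ra, rb in itertools.combinations(residues, 2):
        best = math.inf
        n_pairs = 0
        for a in ra.atoms:
            for b in rb.atoms:
                d = math.dist(a.coord, b.coord)
                if d < cutoff:
                    n_pairs += 1
                    best = min(best, d)
        if n_pairs:
            ida, idb = sorted((ra.id, rb.id))
            edges[(ida, idb)] = Contact(
                res_a=ida, res_b=idb, min_distance=best, n_atom_pairs=n_pairs
            )
    return ContactNetwork(
        cutoff=cutoff,
        scope="intra_chain",
        nodes={r.id for r in residues},
        edges=edges,
    )


# ---------------------------------------------------------------------------
# random clouds (oracle-equality fodder)


def make_random_cloud(
    n_residues: int,
    seed: int,
    *,
    atoms_per_residue: tuple[int, int] = (1, 8),
    box: float = 30.0,
    chain: str = "A",
) -> Structure:
    """Residues scattered in a cubic box with 1–8 atoms each.

    Dense enough (default box 30 Å) that contact edges are plentiful; no
    truth attached — pair it with the brute-force oracle.
    """
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_residues):
        center = rng.uniform(0, box, size=3)
        k = int(rng.integers(atoms_per_residue[0], atoms_per_residue[1] + 1))
        coords = [center + rng.normal(scale=0.8, size=3) for _ in range(k)]
        coords[0] = center
        residues.append(_residue(chain, i + 1, coords))
    return Structure(id=f"cloud_{seed}", chains={chain: residues})


# ---------------------------------------------------------------------------
# shell clusters


@dataclass
class ShellTruth:
    """Ground truth attached to a generated shell cluster."""

    regions: list[FunctionalRegion]
    layer: dict[ResidueID, int]
    association: dict[ResidueID, frozenset[str]]
    steps: dict[ResidueID, dict[str, int]]


def _tilt(direction: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate a unit vector by ``angle`` about a random perpendicular axis."""
    perp = np.cross(direction, rng.normal(size=3))
    norm = np.linalg.norm(perp)
    if norm < 1e-9:  # pathological draw parallel to direction; retry
        return _tilt(direction, angle, rng)
    perp /= norm
    return direction * math.cos(angle) + perp * math.sin(angle)


def make_shell_cluster(
    region_sizes: Sequence[int],
    layer_sizes: Sequence[int],
    seed: int = 0,
    *,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[Structure, ShellTruth]:
    """Concentric shells with guaranteed layer structure.

    Region members sit in small balls near the origin; each non-region
    residue lives on a radial spoke anchored at one region member, at radius
    4.4 + 4.5·(k−1) from its anchor for layer k.  The radii force the layer
    decomposition: every layer-k residue touches its spoke's layer-(k−1)
    residue (4.5 Å < cutoff) and is at least 5 Å from anything two or more
    layers in; contact-step layers therefore equal the construction layers.

    Association and step-count truth are recomputed at generation time by an
    exhaustive pairwise distance census plus a plain queue-based traversal —
    a code path shared with nothing in the analysis pipeline — and the
    layer truth is asserted against the radial argument before returning.
    """
    if any(s < 1 for s in region_sizes) or any(s < 0 for s in layer_sizes):
        raise ValueError("region sizes must be >= 1 and layer sizes >= 0")
    n_layers = len(layer_sizes)
    rng = np.random.default_rng(seed)

    region_names = [f"R{i+1}" for i in range(len(region_sizes))]
    if len(region_sizes) <= 3:
        region_names = ["GBS", "ABS", "CR"][: len(region_sizes)]

    # region centers on a small circle; members jittered within 0.4 Å
    centers = []
    for i in range(len(region_sizes)):
        angle = 2 * math.pi * i / max(len(region_sizes), 1)
        centers.append(np.array([math.cos(angle), math.sin(angle), 0.0]))
    residues: list[Residue] = []
    member_positions: list[tuple[np.ndarray, str]] = []
    number = itertools.count(1)
    regions: list[FunctionalRegion] = []
    for name, center, size in zip(region_names, centers, region_sizes):
        members = []
        for _ in range(size):
            pos = center + rng.normal(scale=0.15, size=3)
            res = _residue("A", next(number), [pos])
            residues.append(res)
            members.append(res.id)
            member_positions.append((pos, name))
        regions.append(FunctionalRegion(name=name, members=frozenset(members)))

    # parent-based radial placement: a layer-k residue sits at radius
    # 4.4 + 4.5*(k-1) from its parent's anchor member, its direction tilted
    # from the parent's by at most the angle that keeps the parent within
    # the cutoff; the radii alone keep it >= cutoff from layers <= k-2.
    layer_truth: dict[ResidueID, int] = {r.id: 0 for r in residues}
    placed: list[list[dict]] = [[]]  # placed[k] = residues of layer k
    for pos, _name in member_positions:
        placed[0].append({"anchor": pos, "dir": None, "radius": 0.0})
    for k, size in enumerate(layer_sizes, start=1):
        if size > 0 and not placed[k - 1]:
            raise ValueError(
                f"cannot place a layer-{k} residue: layer {k-1} is empty"
            )
        placed.append([])
        for _ in range(size):
            parent = placed[k - 1][int(rng.integers(len(placed[k - 1])))]
            if parent["dir"] is None:  # parent is a region member
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                radius = 4.4
            else:
                r_prev = parent["radius"]
                radius = r_prev + 4.5
                # largest tilt keeping |child - parent| < cutoff
                cos_max = (radius**2 + r_prev**2 - cutoff**2) / (2 * radius * r_prev)
                alpha = 0.9 * math.acos(min(1.0, max(-1.0, cos_max)))
                direction = _tilt(parent["dir"], rng.uniform(0.0, alpha), rng)
            pos = parent["anchor"] + direction * radius
            res = _residue("A", next(number), [pos])
            residues.append(res)
            placed[k].append(
                {"anchor": parent["anchor"], "dir": direction, "radius": radius}
            )
            layer_truth[res.id] = k

    structure = Structure(id=f"shell_cluster_{seed}", chains={"A": residues})

    # independent truth: exhaustive distances + queue BFS per region
    adj = {r.id: set() for r in residues}
    pos_of = {r.id: r.atoms[0].xyz for r in residues}
    for ra, rb in itertools.combinations(residues, 2):
        if math.dist(ra.atoms[0].coord, rb.atoms[0].coord) < cutoff:
            adj[ra.id].add(rb.id)
            adj[rb.id].add(ra.id)
    steps: dict[ResidueID, dict[str, int]] = {r.id: {} for r in residues}
    for reg in regions:
        dist = {m: 0 for m in reg.members}
        queue = deque(reg.members)
        while queue:
            cur = queue.popleft()
            for nbr in adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + 1
                    queue.append(nbr)
        for rid, d in dist.items():
            steps[rid][reg.name] = d
    association = {}
    for rid, s in steps.items():
        best = min(s.values())
        association[rid] = frozenset(n for n, d in s.items() if d == best)
        assert best == layer_truth[rid], (
            f"shell construction violated its radial layer argument at {rid}: "
            f"BFS {best} vs construction {layer_truth[rid]}"
        )

    truth = ShellTruth(
        regions=regions, layer=layer_truth, association=association, steps=steps
    )
    return structure, truth


# ---------------------------------------------------------------------------
# symmetric dimers


def make_symmetric_dimer(
    n_residues: int = 12,
    seed: int = 0,
    *,
    extra_one_sided: bool = False,
) -> Structure:
    """Two chains related by an exact twofold rotation about the z axis.

    Chain B is chain A rotated by 180° about z, so every cross-chain contact
    is reciprocal by construction.  ``extra_one_sided`` appends one residue
    to chain B only, next to a chain-A residue, breaking the symmetry with a
    single non-reciprocal contact.
    """
    if n_residues < 2:
        raise ValueError("a dimer chain needs at least 2 residues")
    rng = np.random.default_rng(seed)
    coords_a = []
    for i in range(n_residues):
        # keep a few residues near the symmetry axis so the chains touch
        radial = 1.6 + 4.0 * (i / n_residues)
        angle = rng.uniform(0, 2 * math.pi)
        z = rng.uniform(-4, 4)
        coords_a.append(np.array([radial * math.cos(angle), radial * math.sin(angle), z]))
    rot = np.diag([-1.0, -1.0, 1.0])
    chain_a = [_residue("A", i + 1, [c]) for i, c in enumerate(coords_a)]
    chain_b = [_residue("B", i + 1, [rot @ c]) for i, c in enumerate(coords_a)]
    if extra_one_sided:
        target = coords_a[0]
        chain_b.append(_residue("B", n_residues + 1, [target + np.array([0.0, 0.0, 2.0])]))
    return Structure(
        id=f"dimer_{seed}", chains={"A": chain_a, "B": chain_b}
    )


# ---------------------------------------------------------------------------
# kinetics


def simulate_rate_series(
    Km: float,
    kcat: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    enzyme_label: str = "synthetic",
    substrate: str = "synthetic",
) -> RateSeries:
    """Forward-simulate initial rates from the Michaelis–Menten law.

    Gaussian noise with standard deviation ``noise_sd · Vmax`` (Vmax = kcat
    in per-enzyme units) is added to each rate; negative draws are truncated
    at zero, as a rate assay cannot report a negative initial rate.
    """
    if Km <= 0 or kcat <= 0:
        raise ValueError("Km and kcat must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd cannot be negative")
    s = np.asarray(concentrations, dtype=float)
    v = michaelis_menten(s, kcat, Km)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(scale=noise_sd * kcat, size=v.shape)
        v = np.clip(v, 0.0, None)
    return RateSeries(
        enzyme_label=enzyme_label,
        substrate=substrate,
        concentrations=tuple(s),
        rates=tuple(float(x) for x in v),
    )
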