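"""End-to-end pipeline: structure -> contacts -> shells -> joined effects.

``run_pipeline`` sequences the library stages over one configuration and
writes a reproducible report bundle: contact edge list, per-residue layer
table, joined mutational effects, group summaries, hotspot ranking, and a
manifest (inputs, parameters, output hashes, versions) sufficient to verify
byte-identical reruns.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contacts import DEFAULT_CUTOFF, build_contact_network
from .effects import join_effects, rank_hotspots, summarize_groups
from .layers import (
    FunctionalRegion,
    format_association,
    assign_layers,
    sidechain_constrained_association,
    steps_to_regions,
)
from .structure import ResidueID, read_pdb, select_residues

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    structure: str | Path
    chain: str = "A"
    cutoff: float = DEFAULT_CUTOFF
    #: region name -> residue numbers in `chain`
    regions: dict[str, list[int]] = field(default_factory=dict)
    mutations: str | Path | None = None
    fold_threshold: float = 4.0
    neutral_band: tuple[float, float] = (0.4, 1.0)
    max_layer: int = 2
    outdir: str | Path = "shellmap_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.fold_threshold <= 0:
            raise ValueError("cutoff and fold_threshold must be positive")
        if not self.regions:
            raise ValueError("at least one functional region must be defined")
        for name, members in self.regions.items():
            if not members:
                raise ValueError(f"region {name!r} has an empty residue list")


@dataclass
class PipelineResult:
    outdir: Path
    files: dict[str, Path]
    manifest: dict

    @property
    def manifest_hash(self) -> str:
        return self.manifest["bundle_sha256"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    structure = read_pdb(Path(config.structure))
    residues = select_residues(structure, config.chain, polymer_only=True)

    network = build_contact_network(residues, cutoff=config.cutoff, scope="intra_chain")
    files["contacts"] = outdir / "contacts.tsv"
    _write_tsv(network.edge_table(), files["contacts"])

    regions = [
        FunctionalRegion(
            name=name,
            members=frozenset(ResidueID(config.chain, n) for n in members),
        )
        for name, members in config.regions.items()
    ]
    table = steps_to_regions(network, regions)
    shells = assign_layers(table, max_layer=config.max_layer)

    name_of = {r.id: r.name for r in residues}
    rows = []
    for a in sorted(table, key=lambda a: a.residue):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            constrained = sidechain_constrained_association(
                network, regions, a.residue, table=table
            )
        row = {
            "chain": a.residue.chain_id,
            "number": a.residue.number,
            "name": name_of.get(a.residue, ""),
            "layer": a.layer,
        }
        for reg in regions:
            row[f"steps_to_{reg.name}"] = a.steps_to_region.get(reg.name, "")
        row["association"] = format_association(a.association)
        row["constrained_association"] = format_association(constrained)
        rows.append(row)
    layer_df = pd.DataFrame(rows)
    files["layers"] = outdir / "layers.tsv"
    _write_tsv(layer_df, files["layers"])

    summary = {
        "layer_sizes": {k: len(v) for k, v in shells.items()},
        "missing_region_members": {
            name: [str(m) for m in members]
            for name, members in table.missing_members.items()
        },
        "venn_categories": _venn_census(layer_df),
    }
    files["layer_summary"] = outdir / "layer_summary.json"
    files["layer_summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    if config.mutations is not None:
        mutations = pd.read_csv(config.mutations)
        if "inactive" not in mutations.columns:
            mutations["inactive"] = mutations["relative_efficiency"].astype(str).str.strip() == "inactive"
            mutations["relative_efficiency"] = pd.to_numeric(
                mutations["relative_efficiency"], errors="coerce"
            )
        pos_table = layer_df.rename(columns={"number": "position"})[
            ["position", "layer", "association", "constrained_association"]
        ]
        joined, exceptions = join_effects(
            mutations,
            pos_table,
            fold_threshold=config.fold_threshold,
            neutral_band=config.neutral_band,
        )
        files["joined"] = outdir / "joined_effects.tsv"
        _write_tsv(joined, files["joined"])
        if not exceptions.empty:
            files["exceptions"] = outdir / "unresolved_mutations.tsv"
            _write_tsv(exceptions, files["exceptions"])
        if not joined.empty:
            files["groups"] = outdir / "group_summary.json"
            files["groups"].write_text(
                summarize_groups(joined).to_json(orient="records", indent=2) + "\n"
            )
            files["hotspots"] = outdir / "hotspots.tsv"
            _write_tsv(rank_hotspots(joined), files["hotspots"])

    manifest = {
        "shellmap_version": __version__,
        "python": platform.python_version(),
        "config": {
            "structure": str(config.structure),
            "structure_sha256": _sha256(Path(config.structure)),
            "chain": config.chain,
            "cutoff": config.cutoff,
            "regions": {k: sorted(v) for k, v in config.regions.items()},
            "mutations": str(config.mutations) if config.mutations else None,
            "fold_threshold": config.fold_threshold,
            "neutral_band": list(config.neutral_band),
            "max_layer": config.max_layer,
            "seed": config.seed,
        },
        "outputs": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    manifest["bundle_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path
    return PipelineResult(outdir=outdir, files=files, manifest=manifest)


def _venn_census(layer_df: pd.DataFrame) -> dict[str, list[int]]:
    """Positions per association category, for residues in L1/L2."""
    out: dict[str, list[int]] = {}
    shell = layer_df[(layer_df["layer"] >= 1) & (layer_df["layer"] <= 2)]
    for assoc, grp in shell.groupby("association"):
        if assoc:
            out[str(assoc)] = sorted(int(n) for n in grp["number"])
    return out
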