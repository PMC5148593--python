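"""Packaged reference data for the Sfβgly mutational-effect analysis.

The CSVs transcribe the published kinetic tables for the *Spodoptera
frugiperda* GH1 β-glycosidase: relative catalytic efficiencies of 51 single
mutants on p-nitrophenyl β-D-glucoside (NPβglc), the cellobiose
Michaelis–Menten parameters of the newly characterised mutants, and the
per-position contact-shell assignments (layer and region association) those
studies report.  Each mutation row carries a source tag naming the study it
was first characterised in.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "data_path",
    "load_npbglc_mutations",
    "load_cellobiose_kinetics",
    "load_position_layers",
    "load_sfbgly_regions",
]


def data_path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def load_npbglc_mutations() -> pd.DataFrame:
    """51 single mutations at 37 positions, relative kcat/Km on NPβglc.

    ``relative_efficiency`` is a float, NaN for inactive mutants; the
    ``inactive`` column carries that marker explicitly.
    """
    df = pd.read_csv(data_path("npbglc_mutations.csv"), dtype={"relative_efficiency": str})
    df["inactive"] = df["relative_efficiency"].str.strip() == "inactive"
    df["relative_efficiency"] = pd.to_numeric(df["relative_efficiency"], errors="coerce")
    return df


def load_cellobiose_kinetics() -> pd.DataFrame:
    """Cellobiose Km/kcat table; printed numbers kept as strings.

    Printed efficiency and relative columns stay strings so their printed
    precision is available to the audit; Km/kcat parse to floats (NaN for
    slope-only rows).
    """
    return pd.read_csv(
        data_path("cellobiose_kinetics.csv"),
        dtype={"efficiency_printed": str, "relative_printed": str},
    )


def load_position_layers() -> pd.DataFrame:
    """Per-position layer and region association of the 37 mutated positions."""
    df = pd.read_csv(data_path("sfbgly_positions.csv"), dtype={"constrained_association": str})
    df["constrained_association"] = df["constrained_association"].fillna("")
    return df


def load_sfbgly_regions() -> dict[str, list[int]]:
    """Functional-region residue numbers: CR, GBS, ABS."""
    with open(data_path("sfbgly_regions.yaml")) as fh:
        return yaml.safe_load(fh)
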