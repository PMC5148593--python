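"""Joining mutational effects to the contact-shell map; group summaries; hotspots.

A mutation is characterised by its relative catalytic efficiency on some
substrate; a position is characterised by its contact shell (layer) and the
set of functional regions its shortest contact paths reach.  Joining the two
lets the effects be read region by region: perturbations transmitted to the
glycone-binding site or the catalytic pair are deleterious, perturbations
reaching only the aglycone-binding site are mild or beneficial.  The hotspot
ranking operationalises that observation: positions whose (side-chain
constrained, when known) association includes ABS but not GBS, and whose
best observed substitution is at worst mildly negative, are candidate sites
for activity engineering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinetics import EffectClass, EffectLabel, classify_effect
from .layers import REGION_ORDER, format_association

__all__ = [
    "parse_association",
    "join_effects",
    "summarize_groups",
    "rank_hotspots",
]


def parse_association(text: str) -> frozenset[str]:
    """'GBS+ABS' -> frozenset({'GBS', 'ABS'}); empty string -> empty set."""
    if not text or (isinstance(text, float) and math.isnan(text)):
        return frozenset()
    return frozenset(p.strip() for p in str(text).split("+") if p.strip())


def _assoc_sort_key(assoc: str) -> tuple:
    parts = parse_association(assoc)
    return (len(parts), tuple(n not in parts for n in REGION_ORDER))


def join_effects(
    mutations: pd.DataFrame,
    positions: pd.DataFrame,
    *,
    fold_threshold: float = 4.0,
    neutral_band: tuple[float, float] = (0.4, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join mutation records to per-position layer/association data.

    ``mutations`` needs columns ``mutation, position, relative_efficiency,
    inactive`` (``substrate`` and ``source`` pass through when present);
    ``positions`` needs ``position, layer, association`` and optionally
    ``constrained_association``.

    Returns ``(joined, exceptions)``: one joined row per mutation whose
    position resolves, with effect class and log10 relative efficiency
    (NaN for inactive mutants); mutations at unresolvable positions go to
    the exceptions frame rather than being silently dropped.
    """
    pos_cols = ["position", "layer", "association"]
    if "constrained_association" in positions.columns:
        pos_cols.append("constrained_association")
    pos = positions[pos_cols].drop_duplicates("position")

    known = set(pos["position"])
    resolvable = mutations["position"].isin(known)
    exceptions = mutations.loc[~resolvable].copy()
    joined = mutations.loc[resolvable].merge(pos, on="position", how="left")

    classes: list[EffectClass] = []
    logs: list[float] = []
    for _, row in joined.iterrows():
        if row.get("inactive", False) or pd.isna(row["relative_efficiency"]):
            classes.append(EffectClass(EffectLabel.INACTIVE))
            logs.append(np.nan)
        else:
            ratio = float(row["relative_efficiency"])
            classes.append(
                classify_effect(
                    ratio, fold_threshold=fold_threshold, neutral_band=neutral_band
                )
            )
            logs.append(math.log10(ratio))
    joined["effect_class"] = [c.value.value for c in classes]
    joined["neutral"] = [c.neutral for c in classes]
    joined["log10_relative"] = logs
    if "constrained_association" not in joined.columns:
        joined["constrained_association"] = ""
    joined["constrained_association"] = joined["constrained_association"].fillna("")
    return joined, exceptions


def summarize_groups(joined: pd.DataFrame) -> pd.DataFrame:
    """Per (association × layer) effect-class counts and member lists.

    Output ordering is deterministic: single-region groups first in the
    fixed GBS, ABS, CR rendering order, then intersections, then by layer —
    and is invariant to the input row order.
    """
    if joined.empty:
        raise ValueError("no joined effect records to summarise")
    rows = []
    for (assoc, layer), grp in joined.groupby(["association", "layer"]):
        counts = grp["effect_class"].value_counts()
        members = sorted(
            (
                f"{m}:{'inactive' if pd.isna(l) else format(l, '+.2f')}"
                for m, l in zip(grp["mutation"], grp["log10_relative"])
            )
        )
        rows.append(
            {
                "association": assoc,
                "layer": int(layer),
                "n": len(grp),
                "n_positive": int(counts.get("positive", 0)),
                "n_mild_negative": int(counts.get("mild_negative", 0)),
                "n_strong_negative": int(counts.get("strong_negative", 0)),
                "n_inactive": int(counts.get("inactive", 0)),
                "members": ";".join(members),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["association", "layer"],
        key=lambda col: col.map(_assoc_sort_key) if col.name == "association" else col,
        kind="stable",
    ).reset_index(drop=True)
    return out


def rank_hotspots(
    joined: pd.DataFrame,
    *,
    require_region: str = "ABS",
    exclude_region: str = "GBS",
    allowed_classes: Iterable[str] = ("positive", "mild_negative"),
    min_best_ratio: float | None = None,
) -> pd.DataFrame:
    """Rank candidate positions for activity-enhancing mutagenesis.

    Default predicate: the position's effective association (side-chain
    constrained when available, otherwise the plain shortest-path
    association) includes ``require_region`` and excludes ``exclude_region``,
    and the best observed substitution at the position is at worst mildly
    negative.  Ranking is by best observed relative efficiency descending,
    ties broken by layer ascending (closer to the active site first).

    Positions with several characterised substitutions are judged by their
    best one — opposing effects at the same position are an observed
    reality, and the best substitution is what an engineering campaign would
    build on.
    """
    allowed = set(allowed_classes)
    if joined.empty:
        return pd.DataFrame(
            columns=[
                "position", "wt_aa", "layer", "association",
                "effective_association", "best_mutation", "best_ratio",
                "n_substitutions", "effect_class",
            ]
        )
    rows = []
    for position, grp in joined.groupby("position"):
        assoc = parse_association(grp["association"].iloc[0])
        constrained = parse_association(grp["constrained_association"].iloc[0])
        effective = constrained if constrained else assoc
        if require_region not in effective or exclude_region in effective:
            continue
        active = grp.dropna(subset=["relative_efficiency"])
        if active.empty:
            continue
        best = active.loc[active["relative_efficiency"].idxmax()]
        if best["effect_class"] not in allowed:
            continue
        ratio = float(best["relative_efficiency"])
        if min_best_ratio is not None and ratio < min_best_ratio:
            continue
        rows.append(
            {
                "position": int(position),
                "wt_aa": grp["wt_aa"].iloc[0] if "wt_aa" in grp else "",
                "layer": int(grp["layer"].iloc[0]),
                "association": format_association(assoc),
                "effective_association": format_association(effective),
                "best_mutation": best["mutation"],
                "best_ratio": ratio,
                "n_substitutions": len(grp),
                "effect_class": best["effect_class"],
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(
        by=["best_ratio", "layer"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
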