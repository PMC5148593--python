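"""Michaelis–Menten fitting, catalytic efficiency, and effect classification.

Initial rates v0 (per-enzyme, s^-1) measured over a range of substrate
concentrations are fit to

    v0 = kcat * [S] / (Km + [S])

by nonlinear least squares; standard errors come from the covariance of the
fit.  For near-inactive enzymes that never approach saturation the
pseudo-first-order route applies instead: at [S] << Km the curve is linear
through the origin with slope kcat/Km, so the catalytic efficiency is
estimated directly from that slope and Km and kcat are individually
undetermined.

Relative efficiency of a mutant is (kcat/Km)_mut / (kcat/Km)_WT: ratios in
(0, 1) are losses, ratios above 1 are gains.  Effects are classified with a
fold threshold (default 4): ratio > 1 positive, within 4-fold of wild type
mild_negative (with a configurable neutral sub-band), below 1/4
strong_negative; enzymes with no measurable activity are "inactive".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RateSeries",
    "KineticParams",
    "EffectClass",
    "EffectLabel",
    "FitError",
    "michaelis_menten",
    "fit_michaelis_menten",
    "fit_pseudo_first_order",
    "relative_efficiency",
    "classify_effect",
    "efficiency_from_params",
    "audit_printed_kinetics",
    "INACTIVE",
]

#: Marker accepted wherever a relative-efficiency ratio is expected.
INACTIVE = "inactive"


class FitError(RuntimeError):
    """Raised when a kinetic fit cannot produce usable parameters."""


@dataclass(frozen=True)
class RateSeries:
    """Initial-rate measurements for one enzyme and substrate.

    concentrations in mM; rates in s^-1 per enzyme.
    """

    enzyme_label: str
    substrate: str
    concentrations: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.rates):
            raise ValueError("concentrations and rates differ in length")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("substrate concentrations must be positive")
        if any(v < 0 for v in self.rates):
            raise ValueError("initial rates cannot be negative")

    @property
    def s(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


class EffectLabel(str, enum.Enum):
    POSITIVE = "positive"
    MILD_NEGATIVE = "mild_negative"
    STRONG_NEGATIVE = "strong_negative"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class EffectClass:
    value: EffectLabel
    neutral: bool = False  # sub-band of mild_negative

    def __str__(self) -> str:
        return self.value.value + (" (neutral)" if self.neutral else "")


@dataclass(frozen=True)
class KineticParams:
    """Fitted kinetic parameters.

    For the pseudo-first-order route only ``efficiency`` is defined; Km and
    kcat are None.
    """

    method: str  # "michaelis_menten" | "pseudo_first_order"
    efficiency: float  # kcat/Km, s^-1 mM^-1
    Km: float | None = None
    kcat: float | None = None
    se_Km: float | None = None
    se_kcat: float | None = None
    se_efficiency: float | None = None
    converged: bool = True
    inactive: bool = False
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.method == "michaelis_menten":
            if self.Km is None or self.kcat is None:
                raise ValueError("Michaelis-Menten params require Km and kcat")
            if self.Km <= 0 or self.kcat < 0:
                raise ValueError("Km must be positive and kcat non-negative")


def michaelis_menten(s, kcat: float, Km: float):
    """The rate law v0 = kcat [S] / (Km + [S])."""
    s = np.asarray(s, dtype=float)
    return kcat * s / (Km + s)


def efficiency_from_params(
    Km: float, kcat: float, se_Km: float | None = None, se_kcat: float | None = None
) -> tuple[float, float | None]:
    """kcat/Km with its standard error propagated in quadrature."""
    eff = kcat / Km
    if se_Km is None or se_kcat is None or kcat == 0:
        return eff, None
    se = abs(eff) * math.sqrt((se_kcat / kcat) ** 2 + (se_Km / Km) ** 2)
    return eff, se


def fit_michaelis_menten(
    series: RateSeries, *, maxfev: int = 10000
) -> KineticParams:
    """Nonlinear least-squares fit of the Michaelis–Menten equation.

    Initialised at Km0 = median concentration, Vmax0 = max rate — robust for
    both saturating and non-saturating designs.
    """
    s, v = series.s, series.v
    if len(np.unique(s)) < 4:
        raise FitError("need at least 4 distinct substrate concentrations")
    p0 = (max(v.max(), 1e-12), float(np.median(s)))
    try:
        popt, pcov = curve_fit(michaelis_menten, s, v, p0=p0, maxfev=maxfev)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    kcat, Km = float(popt[0]), float(popt[1])
    if Km <= 0 or kcat < 0:
        raise FitError(
            f"fit converged to non-physical parameters (kcat={kcat:.4g}, Km={Km:.4g}); "
            "check the concentration range"
        )
    perr = np.sqrt(np.diag(pcov))
    se_kcat = float(perr[0]) if np.isfinite(perr[0]) else None
    se_Km = float(perr[1]) if np.isfinite(perr[1]) else None
    eff, se_eff = efficiency_from_params(Km, kcat, se_Km, se_kcat)
    return KineticParams(
        method="michaelis_menten",
        efficiency=eff,
        Km=Km,
        kcat=kcat,
        se_Km=se_Km,
        se_kcat=se_kcat,
        se_efficiency=se_eff,
        converged=True,
        n_points=len(s),
    )


def fit_pseudo_first_order(
    series: RateSeries, *, r2_threshold: float = 0.98
) -> KineticParams:
    """Catalytic efficiency from the linear low-substrate regime.

    Fits v0 = (kcat/Km)·[S] through the origin; valid when every
    concentration is far below Km, where the full rate law degenerates to
    first order in substrate.  A clear departure from linearity (R² below
    threshold, computed against the through-origin line) means the enzyme is
    approaching saturation and the full fit should be used instead.
    """
    s, v = series.s, series.v
    if len(s) < 3:
        raise FitError("need at least 3 points for a slope estimate")
    if np.allclose(v, 0.0):
        return KineticParams(
            method="pseudo_first_order",
            efficiency=0.0,
            inactive=True,
            n_points=len(s),
        )
    slope = float(np.dot(s, v) / np.dot(s, s))
    resid = v - slope * s
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(v, v))  # through-origin convention
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < r2_threshold:
        raise FitError(
            f"v0 vs [S] deviates from the through-origin line (R²={r2:.4f} < "
            f"{r2_threshold}); the series is curving towards saturation — use "
            "the full Michaelis-Menten fit"
        )
    n = len(s)
    se_slope = (
        math.sqrt(ss_res / (n - 1) / float(np.dot(s, s))) if n > 1 else None
    )
    return KineticParams(
        method="pseudo_first_order",
        efficiency=slope,
        se_efficiency=se_slope,
        n_points=n,
    )


def relative_efficiency(mutant: KineticParams, wild_type: KineticParams) -> float:
    """(kcat/Km)_mut / (kcat/Km)_WT."""
    if wild_type.efficiency <= 0:
        raise ValueError("wild-type efficiency must be positive")
    if mutant.efficiency < 0:
        raise ValueError("mutant efficiency cannot be negative")
    return mutant.efficiency / wild_type.efficiency


def classify_effect(
    ratio,
    *,
    fold_threshold: float = 4.0,
    neutral_band: tuple[float, float] = (0.4, 1.0),
) -> EffectClass:
    """Map a relative efficiency (or the inactive marker) to an effect class.

    ratio > 1                      -> positive
    1/fold_threshold <= ratio <= 1 -> mild_negative (neutral flag inside band)
    ratio < 1/fold_threshold       -> strong_negative

    Boundary conventions: exactly 1 and exactly 1/fold_threshold both count
    as mild_negative — only genuine increments are "positive" and only
    decrements beyond the threshold are "strong".
    """
    if isinstance(ratio, str):
        if ratio.strip().lower() == INACTIVE:
            return EffectClass(EffectLabel.INACTIVE)
        raise ValueError(f"unrecognised effect marker {ratio!r}")
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return EffectClass(EffectLabel.INACTIVE)
    ratio = float(ratio)
    if not math.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"relative efficiency must be positive and finite, got {ratio}")
    if ratio > 1.0:
        return EffectClass(EffectLabel.POSITIVE)
    if ratio >= 1.0 / fold_threshold:
        neutral = neutral_band[0] <= ratio < neutral_band[1]
        return EffectClass(EffectLabel.MILD_NEGATIVE, neutral=neutral)
    return EffectClass(EffectLabel.STRONG_NEGATIVE)


# ---------------------------------------------------------------------------
# auditing printed parameter tables


def _printed_decimals(text: str) -> int:
    text = text.strip()
    if "." in text:
        return len(text.split(".", 1)[1])
    return 0


def audit_printed_kinetics(table: pd.DataFrame, *, pct_flag: float = 2.0) -> pd.DataFrame:
    """Recompute kcat/Km and relative efficiency from printed Km/kcat values.

    ``table`` needs columns ``mutation, Km_mM, kcat_s, efficiency_printed,
    relative_printed, method`` with the printed numbers kept as strings so
    their precision is known.  The wild-type row is labelled ``WT``.

    Rows fitted by the pseudo-first-order route carry no Km/kcat and are
    passed through with their printed efficiency.

    A row is flagged ``discrepant`` when the recomputed efficiency, rounded
    to the precision the table prints, differs from the printed value; the
    percent difference is reported and differences above ``pct_flag`` percent
    are additionally marked ``severe``.
    """
    recs = []
    wt = table.loc[table["mutation"] == "WT"]
    if wt.empty:
        raise ValueError("table has no WT row to normalise against")
    wt = wt.iloc[0]
    wt_eff = float(wt["kcat_s"]) / float(wt["Km_mM"])

    for _, row in table.iterrows():
        printed_eff_str = str(row["efficiency_printed"])
        printed_eff = float(printed_eff_str)
        if row.get("method") == "pseudo_first_order" or pd.isna(row.get("Km_mM")):
            recomputed = printed_eff  # slope-derived; nothing to recompute from
            discrepant = False
            pct = 0.0
        else:
            recomputed = float(row["kcat_s"]) / float(row["Km_mM"])
            nd = _printed_decimals(printed_eff_str)
            discrepant = round(recomputed, nd) != printed_eff
            pct = 100.0 * abs(recomputed - printed_eff) / printed_eff
        rel_recomputed = (
            None if row["mutation"] == "WT" else recomputed / wt_eff
        )
        rel_printed = (
            None
            if row["mutation"] == "WT" or pd.isna(row.get("relative_printed"))
            else float(row["relative_printed"])
        )
        recs.append(
            {
                "mutation": row["mutation"],
                "method": row.get("method", "michaelis_menten"),
                "efficiency_printed": printed_eff,
                "efficiency_recomputed": recomputed,
                "relative_printed": rel_printed,
                "relative_recomputed": rel_recomputed,
                "pct_difference": pct,
                "discrepant": discrepant,
                "severe": discrepant and pct > pct_flag,
            }
        )
    return pd.DataFrame(recs)
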