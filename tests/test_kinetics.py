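"""Kinetics: fit recovery, pseudo-first-order regime, classification rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shellmap.data import load_cellobiose_kinetics
from shellmap.kinetics import (
    EffectLabel,
    FitError,
    KineticParams,
    RateSeries,
    audit_printed_kinetics,
    classify_effect,
    fit_michaelis_menten,
    fit_pseudo_first_order,
    michaelis_menten,
    relative_efficiency,
)
from shellmap.synth import simulate_rate_series

CONCS = (0.5, 1, 2, 4, 6, 8, 10, 15, 20, 30)


def mm_params(Km, kcat):
    eff = kcat / Km
    return KineticParams(method="michaelis_menten", efficiency=eff, Km=Km, kcat=kcat)


class TestMichaelisMentenFit:
    def test_noiseless_recovery_of_wildtype_parameters(self, wt_cellobiose_params):
        Km, kcat = wt_cellobiose_params
        series = simulate_rate_series(Km, kcat, CONCS, noise_sd=0.0)
        fit = fit_michaelis_menten(series)
        assert fit.Km == pytest.approx(Km, abs=1e-6)
        assert fit.kcat == pytest.approx(kcat, abs=1e-6)

    def test_half_saturation_identity(self, wt_cellobiose_params):
        Km, kcat = wt_cellobiose_params
        series = simulate_rate_series(Km, kcat, CONCS, noise_sd=0.0)
        fit = fit_michaelis_menten(series)
        assert michaelis_menten(fit.Km, fit.kcat, fit.Km) == pytest.approx(
            fit.kcat / 2
        )

    @pytest.mark.parametrize("Km", [0.1, 2.36, 100.0])
    @pytest.mark.parametrize("kcat", [0.01, 2.61, 100.0])
    def test_recovery_across_parameter_grid(self, Km, kcat):
        concs = tuple(Km * f for f in (0.1, 0.25, 0.5, 1, 2, 4, 8, 16))
        series = simulate_rate_series(Km, kcat, concs, noise_sd=0.0)
        fit = fit_michaelis_menten(series)
        assert fit.Km == pytest.approx(Km, rel=1e-6)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)

    def test_scale_equivariance(self, wt_cellobiose_params):
        Km, kcat = wt_cellobiose_params
        series = simulate_rate_series(Km, kcat, CONCS, noise_sd=0.02, seed=9)
        scaled = RateSeries(
            enzyme_label=series.enzyme_label,
            substrate=series.substrate,
            concentrations=series.concentrations,
            rates=tuple(3.0 * v for v in series.rates),
        )
        f1 = fit_michaelis_menten(series)
        f2 = fit_michaelis_menten(scaled)
        assert f2.kcat == pytest.approx(3.0 * f1.kcat, rel=1e-6)
        assert f2.efficiency == pytest.approx(3.0 * f1.efficiency, rel=1e-6)
        assert f2.Km == pytest.approx(f1.Km, rel=1e-6)

    def test_too_few_distinct_concentrations(self):
        series = RateSeries("e", "s", (1.0, 1.0, 2.0, 2.0), (0.2, 0.2, 0.3, 0.3))
        with pytest.raises(FitError):
            fit_michaelis_menten(series)

    def test_noisy_km_recovery_is_unbiased(self, wt_cellobiose_params):
        """Median relative Km error stays small at 2% rate noise (20 replicates).

        Uses the standard log-spaced design spanning 0.2-10x Km.
        """
        Km, kcat = wt_cellobiose_params
        concs = tuple(Km * np.geomspace(0.2, 10, 10))
        errors = []
        for rep in range(20):
            series = simulate_rate_series(Km, kcat, concs, noise_sd=0.02, seed=rep)
            fit = fit_michaelis_menten(series)
            errors.append(abs(fit.Km - Km) / Km)
        assert float(np.median(errors)) < 0.05


class TestPseudoFirstOrder:
    def test_exact_line_recovers_slope(self):
        concs = (10.0, 20.0, 40.0, 80.0)
        series = RateSeries("R97A", "cellobiose", concs,
                            tuple(0.0014 * c for c in concs))
        fit = fit_pseudo_first_order(series)
        assert fit.efficiency == pytest.approx(0.0014)
        assert fit.Km is None and fit.kcat is None

    def test_zero_rates_flagged_inactive(self):
        series = RateSeries("dead", "cellobiose", (1.0, 2.0, 4.0), (0.0, 0.0, 0.0))
        fit = fit_pseudo_first_order(series)
        assert fit.efficiency == 0.0
        assert fit.inactive

    def test_slope_matches_efficiency_in_low_substrate_limit(self):
        Km, kcat = 100.0, 2.0
        concs = tuple(Km / 100 * f for f in (0.1, 0.2, 0.4, 0.6, 0.8, 1.0))
        series = simulate_rate_series(Km, kcat, concs, noise_sd=0.0)
        fit = fit_pseudo_first_order(series)
        assert fit.efficiency == pytest.approx(kcat / Km, rel=0.01)

    def test_saturating_data_rejected_with_advice(self):
        series = simulate_rate_series(1.0, 5.0, (0.5, 1, 2, 5, 10, 20), noise_sd=0.0)
        with pytest.raises(FitError, match="Michaelis-Menten"):
            fit_pseudo_first_order(series)


class TestRelativeEfficiency:
    def test_wild_type_against_itself(self, wt_cellobiose_params):
        wt = mm_params(*wt_cellobiose_params)
        assert relative_efficiency(wt, wt) == 1.0

    def test_gain_of_function_mutant(self, wt_cellobiose_params):
        # N249A on cellobiose: Km 1.3 mM, kcat 7.52 1/s
        ratio = relative_efficiency(mm_params(1.3, 7.52),
                                    mm_params(*wt_cellobiose_params))
        assert round(ratio, 2) == 5.23

    def test_loss_of_function_mutant(self, wt_cellobiose_params):
        # Y420A on cellobiose: Km 3.1 mM, kcat 0.99 1/s
        ratio = relative_efficiency(mm_params(3.1, 0.99),
                                    mm_params(*wt_cellobiose_params))
        assert round(ratio, 2) == 0.29

    def test_zero_wildtype_rejected(self):
        dead = KineticParams(method="pseudo_first_order", efficiency=0.0)
        live = KineticParams(method="pseudo_first_order", efficiency=1.0)
        with pytest.raises(ValueError):
            relative_efficiency(live, dead)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "ratio,label,neutral",
        [
            (3.3, EffectLabel.POSITIVE, False),
            (1.6, EffectLabel.POSITIVE, False),
            (1.0, EffectLabel.MILD_NEGATIVE, False),   # exactly WT-like: not a gain
            (0.765, EffectLabel.MILD_NEGATIVE, True),
            (0.538, EffectLabel.MILD_NEGATIVE, True),
            (0.48, EffectLabel.MILD_NEGATIVE, True),
            (0.3, EffectLabel.MILD_NEGATIVE, False),
            (0.25, EffectLabel.MILD_NEGATIVE, False),  # boundary: exactly 4-fold
            (0.208, EffectLabel.STRONG_NEGATIVE, False),
            (0.0000008, EffectLabel.STRONG_NEGATIVE, False),
        ],
    )
    def test_class_boundaries(self, ratio, label, neutral):
        effect = classify_effect(ratio)
        assert effect.value == label
        assert effect.neutral == neutral

    def test_inactive_marker(self):
        assert classify_effect("inactive").value == EffectLabel.INACTIVE
        assert classify_effect(float("nan")).value == EffectLabel.INACTIVE

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            classify_effect(0.0)
        with pytest.raises(ValueError):
            classify_effect(-1.2)
        with pytest.raises(ValueError):
            classify_effect("broken")

    @settings(max_examples=200, derandomize=True)
    @given(ratio=st.floats(min_value=1e-9, max_value=1e4,
                           allow_nan=False, allow_infinity=False))
    def test_total_deterministic_step_function(self, ratio):
        effect = classify_effect(ratio)
        if ratio > 1:
            assert effect.value == EffectLabel.POSITIVE
        elif ratio >= 0.25:
            assert effect.value == EffectLabel.MILD_NEGATIVE
        else:
            assert effect.value == EffectLabel.STRONG_NEGATIVE
        assert classify_effect(ratio) == effect


class TestPrintedTableAudit:
    def test_self_consistent_rows_match_at_printed_precision(self):
        audit = audit_printed_kinetics(load_cellobiose_kinetics())
        clean = audit.set_index("mutation").loc[
            ["WT", "N249A", "S247A", "F251A", "L350A", "Y420A"]
        ]
        assert not clean["discrepant"].any()
        for _, row in clean.iterrows():
            assert round(row["efficiency_recomputed"], 2) == pytest.approx(
                round(row["efficiency_printed"], 2)
            )

    def test_known_rounding_discrepancies_flagged(self):
        audit = audit_printed_kinetics(load_cellobiose_kinetics())
        flagged = set(audit.loc[audit["discrepant"], "mutation"])
        assert flagged == {"K366A", "F334A", "S358A"}

    def test_slope_only_rows_pass_through(self):
        audit = audit_printed_kinetics(load_cellobiose_kinetics())
        r97a = audit.set_index("mutation").loc["R97A"]
        assert r97a["method"] == "pseudo_first_order"
        assert not r97a["discrepant"]
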