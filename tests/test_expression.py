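"""Gene on/off calling, reaction activity, transcriptomic flux fitting,
and flux/expression consistency reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import commfba as cf
from commfba.expression import (
    accuracies_from_categories,
    call_gene_activity,
    consistency_report,
    reaction_activity,
    transcriptomic_fba,
)
from commfba.fba import FluxSolution
from conftest import tiny_chain_model


class TestGeneCalling:
    def test_threshold_equals_universal_percentile(self):
        # universal-role genes at 1..80: the 10th percentile with linear
        # interpolation between order statistics is 1 + 0.1*79 = 8.9
        values = {f"u{i:02d}": float(i) for i in range(1, 81)}
        values.update({"low": 8.0, "high": 9.0})
        profile = call_gene_activity(values, [f"u{i:02d}" for i in range(1, 81)])
        assert profile.threshold == pytest.approx(8.9)
        assert profile.call("low") == "off"
        assert profile.call("high") == "on"

    def test_tie_at_threshold_called_on(self):
        values = {f"u{i}": 100.0 for i in range(5)}
        values.update({"below": 5.0, "above": 200.0})
        profile = call_gene_activity(values, [f"u{i}" for i in range(5)])
        assert profile.threshold == 100.0
        assert profile.call("u0") == "on"       # exactly at threshold
        assert profile.call("below") == "off"
        assert profile.call("above") == "on"

    def test_absent_gene_is_unknown(self):
        values = {"u1": 1.0, "u2": 2.0}
        profile = call_gene_activity(values, ["u1", "u2"])
        assert profile.call("ghost") == "unknown"

    def test_requires_two_universal_genes(self):
        with pytest.raises(ValueError, match="universal"):
            call_gene_activity({"u1": 1.0, "x": 3.0}, ["u1"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=40))
    def test_threshold_is_numpy_linear_percentile(self, uni_values):
        values = {f"u{i}": v for i, v in enumerate(uni_values)}
        profile = call_gene_activity(values, list(values), percentile=10)
        assert profile.threshold == pytest.approx(
            float(np.percentile(uni_values, 10)), rel=1e-12
        )


class TestReactionActivity:
    def test_gpr_semantics_lift_to_reactions(self, phototroph):
        profile = call_gene_activity(
            {"u1": 10.0, "u2": 10.0, "pho_light": 50.0, "pho_cfix": 1.0},
            ["u1", "u2"],
        )
        activity = reaction_activity(phototroph, profile)
        assert activity["LIGHT"] == "active"
        assert activity["CFIX"] == "inactive"
        assert activity["NRED"] == "unknown"          # gene not measured
        assert activity["BIOMASS_pho"] == "unknown"   # no gene rule
        assert activity["EX_co2_e0"] == "unknown"


class TestTranscriptomicFBA:
    def test_flux_consistent_calls_reach_full_agreement(self, phototroph, autotrophic):
        expr = cf.make_expression_profile(phototroph, cf.FixtureSpec(noise=0.0),
                                          autotrophic)
        profile = call_gene_activity(expr.values, expr.universal_role_genes)
        activity = reaction_activity(phototroph, profile)
        sol, agreement = transcriptomic_fba(phototroph, autotrophic, activity)
        assert all(agreement.values())
        assert sol.objective_value >= 0.01 - 1e-9

    def test_sole_biomass_route_overrides_inactive_call(self, chain_model):
        # R1 is the only path to biomass but its gene is called off: the
        # optimizer must sacrifice exactly that one agreement
        activity = {"R1": "inactive"}
        sol, agreement = transcriptomic_fba(chain_model, None, activity,
                                            epsilon=1.0)
        assert agreement == {"R1": False}
        assert sol.fluxes["R1"] >= 1.0 - 1e-9

    def test_zero_epsilon_silences_all_inactive(self, chain_model):
        activity = {"R1": "inactive"}
        sol, agreement = transcriptomic_fba(chain_model, None, activity,
                                            epsilon=1e-12)
        assert agreement["R1"]
        assert abs(sol.fluxes["R1"]) < 1e-9

    def test_biomass_floor_always_respected(self, phototroph, autotrophic):
        # even with everything called off, biomass stays above epsilon
        activity = {rid: "inactive" for rid, r in phototroph.reactions.items()
                    if not r.gene_association.is_empty()}
        sol, _ = transcriptomic_fba(phototroph, autotrophic, activity, epsilon=0.01)
        assert sol.objective_value >= 0.01 - 1e-9

    def test_agreement_at_least_plain_pfba(self, phototroph, autotrophic):
        expr = cf.make_expression_profile(phototroph, cf.FixtureSpec(noise=1.0, seed=5),
                                          autotrophic)
        profile = call_gene_activity(expr.values, expr.universal_role_genes)
        activity = reaction_activity(phototroph, profile)
        delta = 1e-3
        pfba = cf.run_fba(phototroph, autotrophic, parsimonious=True)
        pfba_agree = sum(
            1 for rid, a in activity.items()
            if a in ("active", "inactive")
            and (abs(pfba.fluxes[rid]) >= delta) == (a == "active")
        )
        _, agreement = transcriptomic_fba(phototroph, autotrophic, activity)
        assert sum(agreement.values()) >= pfba_agree


class TestConsistencyReport:
    @pytest.mark.parametrize(
        "categories, expected",
        [
            # published consistency rows: four category percentages and the
            # accuracies they imply
            ((16.1, 37.0, 17.5, 29.5), (35.3, 67.9, 53.1)),
            ((54.5, 14.9, 9.4, 21.2), (72.0, 61.2, 69.4)),
            ((25.5, 15.9, 5.6, 53.0), (32.5, 74.0, 41.4)),
            ((20.5, 35.2, 20.4, 23.9), (46.2, 63.3, 55.7)),
        ],
    )
    def test_accuracy_arithmetic_reproduces_published_rows(self, categories, expected):
        # the category inputs are printed rounded to 0.1, so a ratio of two
        # of them can shift by up to ~0.2 relative to the published value
        fe, nn, fn, ne = categories
        acc_active, acc_inactive, overall = accuracies_from_categories(fe, nn, fn, ne)
        assert acc_active == pytest.approx(expected[0], abs=0.2)
        assert acc_inactive == pytest.approx(expected[1], abs=0.2)
        assert overall == pytest.approx(expected[2], abs=0.1)

    def test_overall_equals_sum_of_agreeing_categories(self):
        for fe, nn, fn, ne in [(16.1, 37.0, 17.5, 29.5), (25.5, 15.9, 5.6, 53.0),
                               (54.5, 14.9, 9.4, 21.2), (20.5, 35.2, 20.4, 23.9)]:
            _, _, overall = accuracies_from_categories(fe, nn, fn, ne)
            assert overall == pytest.approx(100 * (fe + nn) / (fe + nn + fn + ne),
                                            abs=1e-9)

    def test_percentages_sum_to_100(self, phototroph, autotrophic):
        expr = cf.make_expression_profile(phototroph, cf.FixtureSpec(noise=1.0, seed=3),
                                          autotrophic)
        profile = call_gene_activity(expr.values, expr.universal_role_genes)
        activity = reaction_activity(phototroph, profile)
        sol, _ = transcriptomic_fba(phototroph, autotrophic, activity)
        report = consistency_report(sol, activity, phototroph)
        total = (report.pct_flux_exp + report.pct_noflux_noexp
                 + report.pct_flux_noexp + report.pct_noflux_exp)
        assert total == pytest.approx(100.0, abs=0.2)
        assert report.accuracy_overall == pytest.approx(
            report.pct_flux_exp + report.pct_noflux_noexp, abs=1e-9
        )

    def test_degenerate_inactive_denominator_is_na(self):
        model = tiny_chain_model()
        sol = FluxSolution("optimal", 10.0,
                           {"EX_A_e0": -10.0, "T_A": 10.0, "R1": 10.0, "BIO": 10.0},
                           "BIO")
        report = consistency_report(sol, {"R1": "active"}, model)
        assert report.pct_flux_exp == 100.0
        assert report.accuracy_inactive is None
        assert report.accuracy_overall == 100.0

    def test_gapfilled_active_counted_per_pathway(self, heterotroph, database,
                                                  glucose_minimal):
        result = cf.gapfill(heterotroph, database, glucose_minimal)
        model = cf.integrate_gapfill(heterotroph, result)
        sol = cf.run_fba(model, glucose_minimal, parsimonious=True)
        report = consistency_report(sol, {}, model)
        gapfilled_active = sum(
            counts["gapfilled_active"] for counts in report.per_pathway.values()
        )
        # the vitamin pathway was gapfilled and must carry flux
        assert gapfilled_active == 3


class TestRecoveryFromSyntheticProfiles:
    def test_noise_free_recovery_is_exact(self, phototroph, autotrophic):
        expr = cf.make_expression_profile(phototroph, cf.FixtureSpec(noise=0.0),
                                          autotrophic)
        profile = call_gene_activity(expr.values, expr.universal_role_genes)
        called_on = {g for g, c in profile.calls.items()
                     if c == "on" and not g.startswith("uni_")}
        assert called_on == expr.active_genes

    def test_mean_recovery_above_90pct_with_noise(self, phototroph, autotrophic):
        rates = []
        for seed in range(20):
            expr = cf.make_expression_profile(
                phototroph, cf.FixtureSpec(seed=seed, noise=1.0), autotrophic
            )
            profile = call_gene_activity(expr.values, expr.universal_role_genes)
            genes = expr.active_genes | expr.inactive_genes
            hits = sum(
                1 for g in genes
                if (profile.calls[g] == "on") == (g in expr.active_genes)
            )
            rates.append(hits / len(genes))
        assert np.mean(rates) >= 0.90
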