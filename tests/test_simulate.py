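"""Synthetic-study generator: determinism, dropout, planted-effect calibration."""

import numpy as np
import pytest
from scipy import stats

from shockmetab import (ContrastSpec, PlantedEffect, SimulationConfig,
                        prepare_contrast, simulate_study,
                        simulate_survival_counts)
from shockmetab.dataset import TIMEPOINTS
from shockmetab.simulate import SimulationError


def _no_dropout(**kw):
    kw.setdefault("dropout", {"CPF": 0.0, "FS": 0.0})
    return SimulationConfig(**kw)


class TestStudyShape:
    def test_no_dropout_full_followup_all_compartments(self):
        cfg = _no_dropout(n_per_group=2, seed=0)
        datasets, truth = simulate_study(cfg)
        assert set(datasets) == {"liver", "muscle", "serum", "urine"}
        for comp, ds in datasets.items():
            assert ds.n_samples == 2 * 2 * len(TIMEPOINTS)
            per_animal = ds.sample_meta.groupby("animal_id")["timepoint"].count()
            assert (per_animal == 6).all()
        assert len(truth.survivors["CPF"]) == 2

    def test_default_panel_sizes(self):
        datasets, _ = simulate_study(_no_dropout(n_per_group=2, seed=0))
        sizes = {c: ds.n_metabolites for c, ds in datasets.items()}
        assert sizes == {"liver": 51, "muscle": 39, "serum": 53, "urine": 60}

    def test_dead_animals_truncated(self):
        cfg = SimulationConfig(n_per_group=16, panel_sizes={"serum": 4},
                               dropout={"CPF": 0.6, "FS": 0.6}, seed=2)
        datasets, truth = simulate_study(cfg)
        meta = datasets["serum"].sample_meta
        for animal, phase in truth.death_phase.items():
            observed = set(meta.loc[meta["animal_id"] == animal, "timepoint"])
            if phase is None:
                assert observed == set(TIMEPOINTS)
            elif phase == "shock":
                assert observed == {"B", "S45"}
            else:
                assert observed == {"B", "S45", "FR2", "FR8"}

    def test_zero_survivors_raises(self):
        cfg = SimulationConfig(n_per_group=2, panel_sizes={"serum": 4},
                               dropout={"CPF": 1.0, "FS": 0.0}, seed=0)
        with pytest.raises(SimulationError, match="surviv"):
            simulate_study(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_per_group=3, seed=7)
        a, _ = simulate_study(cfg)
        b, _ = simulate_study(cfg)
        for comp in a:
            np.testing.assert_array_equal(a[comp].values, b[comp].values)

    def test_different_seeds_differ(self):
        a, _ = simulate_study(SimulationConfig(n_per_group=3, seed=7))
        b, _ = simulate_study(SimulationConfig(n_per_group=3, seed=8))
        assert not np.array_equal(a["serum"].values, b["serum"].values)

    def test_compartment_streams_independent(self):
        """Dropping one compartment leaves another compartment's draws untouched."""
        full, _ = simulate_study(_no_dropout(n_per_group=3, seed=5))
        only, _ = simulate_study(_no_dropout(
            n_per_group=3, panel_sizes={"serum": 53}, seed=5))
        np.testing.assert_array_equal(full["serum"].values, only["serum"].values)


class TestNullCalibration:
    def test_no_effects_group_means_close(self):
        """With no planted effects the group-mean log difference is ~0."""
        cfg = _no_dropout(n_per_group=40, panel_sizes={"serum": 10}, seed=13)
        datasets, _ = simulate_study(cfg)
        ds = datasets["serum"]
        at_b = ds.subset((ds.sample_meta["timepoint"] == "B").to_numpy())
        logv = np.log10(at_b.values)
        grp = at_b.sample_meta["group"].to_numpy()
        diff = logv[grp == "CPF"].mean(axis=0) - logv[grp == "FS"].mean(axis=0)
        # per-metabolite sampling se ~ sqrt(2/40)*s_single ~ 0.065
        assert np.abs(diff).max() < 4 * 0.065

    def test_unplanted_metabolite_distribution_matches_across_groups(self):
        cfg = _no_dropout(
            n_per_group=30, panel_sizes={"serum": 6}, seed=21,
            planted_effects=[PlantedEffect("serum", "B", 0, 3.0)])
        datasets, _ = simulate_study(cfg)
        ds = datasets["serum"]
        at_b = ds.subset((ds.sample_meta["timepoint"] == "B").to_numpy())
        grp = at_b.sample_meta["group"].to_numpy()
        ks = stats.ks_2samp(at_b.values[grp == "CPF", 3],
                            at_b.values[grp == "FS", 3])
        assert ks.pvalue > 0.001


class TestPlantedEffects:
    def test_urine_interval_effect_power(self):
        """d=3 planted on a urine interval: t > 3 in >= 90% of seeds.

        On the log-analysis scale the planted standardized effect is exact,
        so the two-sample t statistic is noncentral-t with
        delta = d*sqrt(n/2) = 8.5 and P(t > 3) is essentially 1; the
        empirical frequency over 60 seeds must clear 0.9 comfortably.
        """
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = _no_dropout(
                n_per_group=16, panel_sizes={"urine": 6}, zero_rate_urine=0.0,
                planted_effects=[PlantedEffect("urine", "S45-B", 2, 3.0)],
                seed=seed)
            datasets, _ = simulate_study(cfg)
            ads = prepare_contrast(datasets, ContrastSpec.from_label("S45-B", "urine"))
            grp = ads.sample_meta["group"].to_numpy()
            t = stats.ttest_ind(ads.values[grp == "CPF", 2],
                                ads.values[grp == "FS", 2], equal_var=False).statistic
            hits += t > 3
        assert hits / n_seeds >= 0.9

    def test_serum_interval_effect_power(self):
        """d=3 on a serum interval shows up in the raw-scale differences."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = _no_dropout(
                n_per_group=16, panel_sizes={"serum": 6},
                planted_effects=[PlantedEffect("serum", "S45-B", 1, 3.0)],
                seed=seed)
            datasets, _ = simulate_study(cfg)
            ads = prepare_contrast(datasets, ContrastSpec.from_label("S45-B", "serum"))
            grp = ads.sample_meta["group"].to_numpy()
            t = stats.ttest_ind(ads.values[grp == "CPF", 1],
                                ads.values[grp == "FS", 1], equal_var=False).statistic
            hits += t > 3
        assert hits / n_seeds >= 0.9

    def test_effect_confined_to_planted_contrast(self):
        cfg = _no_dropout(
            n_per_group=50, panel_sizes={"serum": 4}, seed=3,
            planted_effects=[PlantedEffect("serum", "S45", 0, 4.0)])
        datasets, _ = simulate_study(cfg)
        ds = datasets["serum"]
        for tp, expect_shift in [("S45", True), ("B", False)]:
            sub = ds.subset((ds.sample_meta["timepoint"] == tp).to_numpy())
            grp = sub.sample_meta["group"].to_numpy()
            t = stats.ttest_ind(sub.values[grp == "CPF", 0],
                                sub.values[grp == "FS", 0], equal_var=False).statistic
            assert (abs(t) > 5) == expect_shift


class TestUrineRealism:
    def test_span_and_zero_rate(self):
        cfg = _no_dropout(n_per_group=16, panel_sizes={"urine": 60}, seed=17)
        datasets, _ = simulate_study(cfg)
        from shockmetab.preprocess import normalize_urine_dataset
        norm = normalize_urine_dataset(datasets["urine"])
        vals = norm.values
        pos = vals[vals > 0]
        assert np.log10(pos.max() / pos.min()) >= 4.0
        n_cells = vals.size
        rate = (vals == 0).mean()
        se = np.sqrt(0.05 * 0.95 / n_cells)
        assert abs(rate - 0.05) <= 2 * se + 1e-12

    def test_urine_output_dips_at_shock(self):
        cfg = _no_dropout(n_per_group=20, panel_sizes={"urine": 4}, seed=23)
        datasets, _ = simulate_study(cfg)
        meta = datasets["urine"].sample_meta
        flow = meta.groupby("timepoint")["urine_output"].mean()
        assert flow["S45"] < flow["B"]
        assert flow["S45"] < flow["FR8"]


class TestSurvivalCounts:
    def test_zero_and_total_dropout(self):
        cfg = SimulationConfig(dropout={"CPF": 0.0, "FS": 0.0})
        assert simulate_survival_counts(cfg) == {"CPF": 0.0, "FS": 0.0}
        cfg = SimulationConfig(dropout={"CPF": 1.0, "FS": 1.0})
        assert simulate_survival_counts(cfg, n_per_group=10) == {"CPF": 1.0, "FS": 1.0}

    def test_death_rates_match_configured_totals(self):
        """Scalar dropout is the total death probability (47/28% defaults)."""
        cfg = SimulationConfig(dropout={"CPF": 0.47, "FS": 0.28}, seed=1)
        rates = simulate_survival_counts(cfg, n_per_group=100_000)
        assert abs(rates["CPF"] - 0.47) < 0.01
        assert abs(rates["FS"] - 0.28) < 0.01
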