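"""Macroscopic-constant fitting, bootstrap uncertainty and cooperativity verdicts."""

import numpy as np
import pandas as pd
import pytest

from bindpoly.binding_model import (
    MacroscopicConstants,
    MicroscopicConstants,
    cooperativity_ratios,
    macro_from_micro,
)
from bindpoly.multisite import (
    IdentifiabilityError,
    MultisiteBindingModel,
    TitrationDataset,
    assess_cooperativity,
    bootstrap_uncertainty,
    fit_macroscopic,
)
from bindpoly.synthetic import simulate_titration

GRID = np.linspace(0.05, 5.0, 12)


def noiseless(K, grid=GRID, reps=1, **kw):
    return simulate_titration(K, grid_uM=grid, noise_alpha=0.0, reps=reps,
                              seed=0, **kw)


class TestTitrationDataset:
    def test_rows_renormalized_within_slack(self):
        df = pd.DataFrame({
            "replicate": ["a"] * 4, "protein_uM": [0.1, 0.5, 1.0, 2.0],
            "dna_uM": 0.02,
            "f0": [0.99, 0.5, 0.3, 0.1], "f1": [0.02, 0.3, 0.3, 0.2],
            "f2": [0.0, 0.1, 0.2, 0.3], "f3": [0.0, 0.11, 0.21, 0.41],
        })
        data = TitrationDataset(df)
        sums = data.table[["f0", "f1", "f2", "f3"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_sum_outside_slack_rejected(self):
        df = pd.DataFrame({
            "replicate": ["a"] * 4, "protein_uM": [0.1, 0.5, 1.0, 2.0],
            "dna_uM": 0.02,
            "f0": [0.9, 0.5, 0.3, 0.1], "f1": [0.2, 0.3, 0.3, 0.2],
            "f2": [0.0, 0.1, 0.2, 0.3], "f3": [0.0, 0.1, 0.2, 0.4],
        })
        with pytest.raises(ValueError, match="sum"):
            TitrationDataset(df)

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame({
            "replicate": ["a"] * 3, "protein_uM": [0.1, 0.5, 1.0], "dna_uM": 0.02,
            "f0": [0.9, 0.5, 0.3], "f1": [0.1, 0.3, 0.3],
            "f2": [0.0, 0.1, 0.2], "f3": [0.0, 0.1, 0.2],
        })
        with pytest.raises(ValueError, match="4 distinct"):
            TitrationDataset(df)


class TestFitMacroscopic:
    @pytest.mark.parametrize("K_true", [
        MacroscopicConstants(3, 3, 3),
        MacroscopicConstants(4, 5, 6),
        MacroscopicConstants(0.03, 0.02, 0.01),
        MacroscopicConstants(30, 400, 900),
    ])
    def test_noiseless_recovery(self, K_true):
        fit = fit_macroscopic(noiseless(K_true))
        for got, want in zip(fit.K, K_true):
            assert got == pytest.approx(want, rel=1e-6)
        assert fit.converged

    def test_no_binding_signal_raises(self):
        df = pd.DataFrame({
            "replicate": ["a"] * 5, "protein_uM": [0.1, 0.3, 0.5, 1.0, 2.0],
            "dna_uM": 0.02, "f0": 1.0, "f1": 0.0, "f2": 0.0, "f3": 0.0,
        })
        with pytest.raises(IdentifiabilityError):
            fit_macroscopic(TitrationDataset(df))

    def test_multi_replicate_dataset_rejected(self):
        data = noiseless(MacroscopicConstants(3, 3, 3), reps=2)
        with pytest.raises(ValueError, match="one replicate"):
            fit_macroscopic(data)

    def test_exact_ligand_conservation_round_trip(self):
        K = MacroscopicConstants.from_site_ka(1.2)
        data = noiseless(K, grid=np.linspace(0.1, 1.3, 12), ligand="exact")
        fit = fit_macroscopic(data, ligand="exact")
        for got, want in zip(fit.K, K):
            assert got == pytest.approx(want, rel=1e-5)

    def test_total_ligand_approximation_is_biased_when_depletion_matters(self):
        # with DNA at 1 uM against a 0.1-1.3 uM protein grid depletion is
        # gross, so the two ligand conventions must disagree
        K = MacroscopicConstants.from_site_ka(1.2)
        data = simulate_titration(K, grid_uM=np.linspace(0.3, 1.3, 8),
                                  dna_uM=1.0, noise_alpha=0.0, seed=0,
                                  ligand="exact")
        fit = fit_macroscopic(data, ligand="total")
        assert abs(fit.K.K1 - K.K1) / K.K1 > 0.05

    def test_sklearn_api_round_trip(self):
        est = MultisiteBindingModel()
        assert est.get_params()["ligand"] == "total"
        data = noiseless(MacroscopicConstants(3, 3, 3)).table
        est.fit(data["protein_uM"], data[["f1", "f2", "f3"]])
        pred = est.predict([1.0])
        assert pred[0] == pytest.approx([0.1, 0.3, 0.3, 0.3], abs=1e-6)


class TestBootstrap:
    def test_seeded_determinism(self):
        data = simulate_titration(MacroscopicConstants(3, 3, 3), grid_uM=GRID,
                                  noise_alpha=300, seed=5)
        a = bootstrap_uncertainty(data, n_boot=100, seed=11)
        b = bootstrap_uncertainty(data, n_boot=100, seed=11)
        for key in ("K1", "K2", "K3", "r2", "r3", "Ka"):
            assert np.array_equal(a[key], b[key])

    def test_noiseless_data_gives_degenerate_distributions(self):
        data = noiseless(MacroscopicConstants(3, 3, 3))
        boot = bootstrap_uncertainty(data, n_boot=100, seed=3)
        for key in ("K1", "K2", "K3"):
            assert np.std(boot[key]) < 1e-6

    def test_seed_is_mandatory(self):
        data = noiseless(MacroscopicConstants(3, 3, 3))
        with pytest.raises(ValueError, match="seed"):
            bootstrap_uncertainty(data, n_boot=100)

    def test_interval_coverage_of_true_constants(self):
        # central 95% bootstrap interval should cover each true Ki in at
        # least 90% of seeded trials
        K = MacroscopicConstants(3, 3, 3)
        n_trials, hits = 20, {"K1": 0, "K2": 0, "K3": 0}
        for trial in range(n_trials):
            data = simulate_titration(K, grid_uM=GRID, noise_alpha=300,
                                      seed=100 + trial)
            boot = bootstrap_uncertainty(data, n_boot=500, seed=trial)
            for key, truth in zip(("K1", "K2", "K3"), K):
                lo, hi = np.quantile(boot[key], [0.025, 0.975])
                hits[key] += lo <= truth <= hi
        for key in hits:
            assert hits[key] >= 0.9 * n_trials, f"{key} coverage {hits[key]}/20"


class TestAssessCooperativity:
    def test_noiseless_independent_data_is_not_cooperative(self):
        K = MacroscopicConstants.from_site_ka(2.5)
        fit = fit_macroscopic(noiseless(K))
        boot = bootstrap_uncertainty(noiseless(K), n_boot=100, seed=1)
        report = assess_cooperativity([fit], boot)
        assert report.r2_mean == pytest.approx(1.0, abs=1e-6)
        assert report.r3_mean == pytest.approx(1.0, abs=1e-6)
        assert report.verdict2 == report.verdict3 == "not-inferred"
        assert report.Ka_mean == pytest.approx(2.5, rel=1e-6)
        assert report.Kd == pytest.approx(0.4, rel=1e-6)
        assert report.r2_sd == report.r3_sd == 0.0

    def test_pairwise_coupling_triggers_cooperative_verdict(self):
        # micro k = 1 with all couplings 10 gives K = (3, 30, 30), r2 = 10
        m = MicroscopicConstants(1, 1, 1, 10, 10, 10)
        K = macro_from_micro(m)
        assert tuple(K) == (3.0, 30.0, 30.0)
        assert cooperativity_ratios(K).r2 == pytest.approx(10.0)
        data = simulate_titration(K, grid_uM=GRID, noise_alpha=300, seed=2)
        fit = fit_macroscopic(data)
        boot = bootstrap_uncertainty(data, n_boot=100, seed=2)
        report = assess_cooperativity([fit], boot)
        assert report.verdict2 == "cooperative"
        assert report.Ka_mean is None  # reduction refused under cooperativity

    def test_full_pipeline_kd_within_two_percent_noiseless(self):
        for ka in (0.3, 1.2, 5.0):
            data = noiseless(MacroscopicConstants.from_site_ka(ka))
            report = assess_cooperativity([fit_macroscopic(data)])
            assert report.Kd == pytest.approx(1.0 / ka, rel=0.02)

    def test_verdict_false_positive_rate_under_independence(self):
        # per-assay calibration: noisy independent titrations should be
        # called cooperative in at most 10% of seeded datasets per event
        K = MacroscopicConstants.from_site_ka(1.2)
        n, coop2, coop3 = 50, 0, 0
        for s in range(n):
            data = simulate_titration(K, grid_uM=np.linspace(0.1, 1.3, 12),
                                      noise_alpha=300, seed=s)
            fit = fit_macroscopic(data)
            boot = bootstrap_uncertainty(data, n_boot=200, seed=1000 + s)
            report = assess_cooperativity([fit], boot)
            coop2 += report.verdict2 == "cooperative"
            coop3 += report.verdict3 == "cooperative"
        assert coop2 <= 0.1 * n
        assert coop3 <= 0.1 * n
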