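"""Normalization, 4PL summaries, global parameter recovery, Gaussian optimum."""

import math

import numpy as np
import pandas as pd
import pytest

from icbind import (
    LigandSpec,
    SignalingDataset,
    fit_4pl,
    fit_gaussian_optimum,
    fit_global_model,
    normalize_response,
)
from icbind.model_fit import DegenerateCurveError, four_pl, global_model_rss
from icbind.synthetic_data import GeneratorConfig, gen_signaling_dataset


class TestNormalizeResponse:
    def test_forced_arithmetic(self):
        out = normalize_response([100.0, 600.0, 1100.0], 100.0)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_constant_curve_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            normalize_response([100.0, 100.0, 100.0], 100.0)

    def test_idempotent(self):
        once = normalize_response([100.0, 250.0, 900.0], 50.0)
        twice = normalize_response(once, 0.0)
        assert np.allclose(once, twice)


class TestFourPL:
    conc = np.logspace(-13, -7, 12)

    def exact(self, ec50=1e-10, hill=1.0, baseline=0.0, emax=1.0):
        return four_pl(self.conc, math.log10(ec50), emax, hill, baseline)

    def test_exact_self_consistency(self):
        fit = fit_4pl(self.conc, self.exact())
        assert fit.ok
        assert fit.ec50 == pytest.approx(1e-10, rel=1e-6)
        assert fit.emax == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert abs(fit.baseline) < 1e-6

    def test_midpoint_definition(self):
        fit = fit_4pl(self.conc, self.exact(ec50=3e-11, hill=1.4, baseline=0.1, emax=0.9))
        mid = four_pl(np.array([fit.ec50]), math.log10(fit.ec50), fit.emax,
                      fit.hill, fit.baseline)[0]
        assert mid == pytest.approx((fit.baseline + fit.emax) / 2.0, rel=1e-9)

    def test_rescaling_leaves_ec50(self):
        y = self.exact(ec50=2e-10, hill=1.2, baseline=0.05, emax=0.8)
        e1 = fit_4pl(self.conc, y).ec50
        e2 = fit_4pl(self.conc, 137.0 * y).ec50
        assert e2 == pytest.approx(e1, rel=1e-8)

    def test_flat_data_flagged(self):
        fit = fit_4pl(self.conc, np.ones_like(self.conc))
        assert not fit.ok and "flat" in fit.reason

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_4pl([1e-9, 2e-9, 3e-9], [0, 0.5, 1.0])  # too few points
        with pytest.raises(ValueError):
            fit_4pl([1e-9, 2e-9, 3e-9, 4e-9], [0, 0.3, 0.6, 1.0])  # < 2 decades

    def test_noisy_recovery_rate(self):
        """EC50 within 15% of truth in >= 95% of 100 simulated assays.

        Each assay is 12 concentrations measured in triplicate (the design of
        the signaling experiments) under 5% signal-proportional noise.
        """
        rng = np.random.default_rng(2024)
        conc = np.repeat(self.conc, 3)
        truth = four_pl(conc, -10.0, 1.0, 1.0, 0.0)
        hits = 0
        for _ in range(100):
            y = truth + rng.normal(0.0, 0.05 * truth)
            fit = fit_4pl(conc, y)
            hits += fit.ok and abs(fit.ec50 / 1e-10 - 1) <= 0.15
        assert hits >= 95


class TestGlobalFit:
    def _noiseless(self, two_ligand_setup, seed=3):
        ligs, panel = two_ligand_setup
        cfg = GeneratorConfig(seed=seed, cv=0.0, n_experiments=1,
                              ligands=ligs, panel=panel)
        return gen_signaling_dataset(cfg), ligs, panel

    def test_noiseless_recovery(self, two_ligand_setup):
        (data, truth), ligs, panel = self._noiseless(two_ligand_setup)
        res = fit_global_model(data, ligs, ["biased_ic"], panel, seed=1)
        assert abs(math.log10(res.kd_betagamma["biased_ic"] / 3e-5)) < 0.01
        assert abs(math.log10(res.kx_star / truth["kx_star"])) < 0.05
        assert res.rss < 1e-12

    def test_seed_determinism(self, two_ligand_setup):
        (data, _), ligs, panel = self._noiseless(two_ligand_setup)
        r1 = fit_global_model(data, ligs, ["biased_ic"], panel, seed=7)
        r2 = fit_global_model(data, ligs, ["biased_ic"], panel, seed=7)
        assert r1.kx_star == r2.kx_star
        assert r1.kd_betagamma == r2.kd_betagamma
        assert r1.best_start == r2.best_start

    def test_accepted_trace_monotone(self, two_ligand_setup):
        (data, _), ligs, panel = self._noiseless(two_ligand_setup)
        res = fit_global_model(data, ligs, ["biased_ic"], panel, seed=1)
        trace = np.asarray(res.accepted_trace)
        assert np.all(np.diff(trace) <= 0)

    def test_profile_likelihood_sanity(self, two_ligand_setup):
        """Perturbing the recovered parameters by ±0.5 log10 increases RSS."""
        (data, _), ligs, panel = self._noiseless(two_ligand_setup)
        res = fit_global_model(data, ligs, ["biased_ic"], panel, seed=1)
        kd_hat = res.kd_betagamma["biased_ic"]
        at_hat = global_model_rss(
            data, {**ligs, "biased_ic": ligs["biased_ic"].with_kd_betagamma(kd_hat)},
            panel, res.kx_star,
        )
        for shift in (+0.5, -0.5):
            perturbed = global_model_rss(
                data,
                {**ligs, "biased_ic": ligs["biased_ic"].with_kd_betagamma(
                    kd_hat * 10.0**shift)},
                panel, res.kx_star,
            )
            assert perturbed > at_hat + 1e-6

    def test_all_zero_dataset_degenerate(self, two_ligand_setup):
        ligs, panel = two_ligand_setup
        rows = []
        for cell in panel:
            for lig in ligs:
                for c in np.logspace(-12, -8, 5):
                    rows.append({"experiment_id": "e1", "cell_type": cell,
                                 "ligand": lig, "conc_M": c, "mfi": 50.0,
                                 "unstim_mfi": 50.0})
        data = SignalingDataset(pd.DataFrame(rows))
        res = fit_global_model(data, ligs, ["biased_ic"], panel, seed=0)
        assert res.degenerate
        assert not res.kd_betagamma

    def test_requires_fixed_anchor(self, two_ligand_setup):
        (data, _), ligs, panel = self._noiseless(two_ligand_setup)
        with pytest.raises(ValueError, match="anchor"):
            fit_global_model(data, ligs, ["biased_ic", "control_ic"], panel, seed=0)


class TestSignalingDataset:
    def test_rejects_nonpositive_concentration(self):
        df = pd.DataFrame({
            "experiment_id": ["e"] * 4, "cell_type": ["c"] * 4,
            "ligand": ["l"] * 4, "conc_M": [0.0, 1e-9, 1e-8, 1e-7],
            "mfi": [1, 2, 3, 4], "unstim_mfi": [1] * 4,
        })
        with pytest.raises(ValueError, match="concentration"):
            SignalingDataset(df)

    def test_rejects_short_curves(self):
        df = pd.DataFrame({
            "experiment_id": ["e"] * 3, "cell_type": ["c"] * 3,
            "ligand": ["l"] * 3, "conc_M": [1e-9, 1e-8, 1e-7],
            "mfi": [1, 2, 3], "unstim_mfi": [1] * 3,
        })
        with pytest.raises(ValueError, match="4 distinct"):
            SignalingDataset(df)

    def test_roundtrip(self, tmp_path, two_ligand_setup):
        ligs, panel = two_ligand_setup
        cfg = GeneratorConfig(seed=5, cv=0.0, n_experiments=1, ligands=ligs, panel=panel)
        data, _ = gen_signaling_dataset(cfg)
        path = tmp_path / "sig.tsv"
        data.to_csv(path)
        back = SignalingDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.df, data.df)


class TestGaussianOptimum:
    x = np.linspace(-12, -8, 9)

    def test_exact_recovery(self):
        y = 2.5 * np.exp(-((self.x + 10.2) ** 2) / (2 * 0.6**2))
        fit = fit_gaussian_optimum(self.x, y)
        assert fit.mu == pytest.approx(-10.2, rel=1e-6)
        assert fit.sigma == pytest.approx(0.6, rel=1e-6)
        assert fit.amplitude == pytest.approx(2.5, rel=1e-6)
        assert not fit.warning

    def test_symmetric_data_centered(self):
        x0 = -10.0
        y = np.exp(-((self.x - x0) ** 2))  # symmetric about x0
        fit = fit_gaussian_optimum(self.x, y)
        assert fit.mu == pytest.approx(x0, abs=1e-8)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        y = 2.0 * np.exp(-((self.x + 10.0) ** 2) / (2 * 0.5**2))
        y = y + rng.normal(0, 0.1, y.size)
        fit = fit_gaussian_optimum(self.x, y)
        assert abs(fit.mu - (-10.0)) < 0.2

    def test_monotone_data_warns(self):
        y = np.linspace(0.1, 2.0, self.x.size)  # no interior peak
        fit = fit_gaussian_optimum(self.x, y)
        assert fit.warning
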