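import math

import numpy as np
import pytest

from mgcscan.kinetics import (
    AbsorbanceTrace,
    KineticDataset,
    SubstrateInhibitionModel,
    fit_substrate_inhibition,
    fold_change_slower,
    initial_rate,
    isosbestic_drift,
    michaelis_menten_rate,
    optimal_substrate,
    substrate_inhibition_rate,
)
from mgcscan.synthetic import generate_kinetic_dataset

# apparent constants of the ClMlp2 methylcobalamin:selenide assay
KCAT, KM, KI = 0.778, 79.8, 3830.0

DESIGN_S = [20, 40, 80, 160, 320, 640, 1000, 1600, 2200, 2800, 3200, 3500]


class TestModelFunction:
    def test_zero_substrate_gives_zero_rate(self):
        assert substrate_inhibition_rate(0.0, KCAT, KM, KI) == 0.0

    def test_half_saturation_in_the_michaelis_limit(self):
        v = substrate_inhibition_rate(KM, KCAT, KM, KI=1e15)
        assert v == pytest.approx(KCAT / 2, rel=1e-9)

    def test_rate_maximum_sits_at_sqrt_km_ki(self):
        S = np.linspace(1.0, 3500.0, 200001)  # fine-grid numeric maximiser
        v = substrate_inhibition_rate(S, KCAT, KM, KI)
        argmax = S[np.argmax(v)]
        assert argmax == pytest.approx(math.sqrt(KM * KI), abs=0.05)
        assert optimal_substrate(KM, KI) == pytest.approx(math.sqrt(KM * KI))

    def test_uniform_convergence_to_michaelis_menten(self):
        S = np.linspace(0, 5000, 2000)
        mm = michaelis_menten_rate(S, KCAT, KM)
        for KI_big, tol in [(1e6, 6e-3), (1e8, 6e-5)]:
            si = substrate_inhibition_rate(S, KCAT, KM, KI_big)
            assert np.max(np.abs(si - mm)) < tol

    def test_nonpositive_parameters_rejected(self):
        for bad in [(0, KM, KI), (KCAT, -1, KI), (KCAT, KM, 0)]:
            with pytest.raises(ValueError):
                substrate_inhibition_rate(100.0, *bad)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            substrate_inhibition_rate(-5.0, KCAT, KM, KI)


class TestFit:
    def test_noise_free_data_recovered_to_machine_precision(self):
        ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=1,
                                      noise_cv=0.0)
        res = fit_substrate_inhibition(ds)
        assert res.kcat == pytest.approx(KCAT, rel=1e-6)
        assert res.KM == pytest.approx(KM, rel=1e-6)
        assert res.KI == pytest.approx(KI, rel=1e-6)
        assert res.rss < 1e-12

    def test_noisy_replicated_design_recovers_within_15_percent(self):
        ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=3,
                                      noise_cv=0.03, seed=42)
        res = fit_substrate_inhibition(ds, seed=1)
        assert res.kcat == pytest.approx(KCAT, rel=0.15)
        assert res.KM == pytest.approx(KM, rel=0.15)
        assert res.KI == pytest.approx(KI, rel=0.15)
        for name in ("kcat", "KM", "KI"):
            assert res.bse[name] > 0

    def test_pure_michaelis_menten_sets_no_inhibition_flag(self):
        S = np.repeat(DESIGN_S, 2)
        v = michaelis_menten_rate(S, KCAT, KM)
        res = fit_substrate_inhibition(
            KineticDataset(substrate_uM=S, rate_per_min=v)
        )
        assert "no_inhibition_detected" in res.flags

    def test_scale_equivariance(self):
        ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=2,
                                      noise_cv=0.02, seed=3)
        res1 = fit_substrate_inhibition(ds, seed=0)
        scaled = KineticDataset(
            substrate_uM=ds.substrate_uM, rate_per_min=10.0 * ds.rate_per_min
        )
        res2 = fit_substrate_inhibition(scaled, seed=0)
        assert res2.kcat == pytest.approx(10.0 * res1.kcat, rel=1e-4)
        assert res2.KM == pytest.approx(res1.KM, rel=1e-4)
        assert res2.KI == pytest.approx(res1.KI, rel=1e-4)

    def test_median_relative_error_below_10_percent_across_simulations(self):
        errs = {"kcat": [], "KM": [], "KI": []}
        truth = dict(zip(("kcat", "KM", "KI"), (KCAT, KM, KI)))
        for sim in range(200):
            ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=3,
                                          noise_cv=0.03, seed=1000 + sim)
            res = SubstrateInhibitionModel(ds).fit(restarts=0)
            for name in errs:
                errs[name].append(abs(res.params[name] - truth[name]) / truth[name])
        for name, es in errs.items():
            assert float(np.median(es)) < 0.10, name

    def test_too_few_substrate_levels_rejected(self):
        ds = KineticDataset(substrate_uM=[1, 2, 3, 4] * 3,
                            rate_per_min=[0.1] * 12)
        with pytest.raises(ValueError, match="distinct substrate levels"):
            SubstrateInhibitionModel(ds)

    def test_summary_reports_estimates_and_units(self):
        ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=1,
                                      noise_cv=0.0)
        text = fit_substrate_inhibition(ds).summary()
        assert "kcat" in text and "1/min" in text and "sqrt(KM*KI)" in text

    def test_proportional_weighting_accepted(self):
        ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=3,
                                      noise_cv=0.03, seed=11)
        res = SubstrateInhibitionModel(ds, weighting="proportional").fit()
        assert res.kcat == pytest.approx(KCAT, rel=0.15)

    def test_dataframe_constructor(self):
        import pandas as pd

        ds = generate_kinetic_dataset(KCAT, KM, KI, DESIGN_S, replicates=1,
                                      noise_cv=0.0)
        df = pd.DataFrame({"substrate_uM": ds.substrate_uM,
                           "rate": ds.rate_per_min})
        res = SubstrateInhibitionModel.from_dataframe(df).fit()
        assert res.KM == pytest.approx(KM, rel=1e-5)


class TestTraces:
    def _trace(self, slope=-0.01, noise=0.0, seed=0, a485=None):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 30, 61)
        a525 = 1.0 + slope * t + (rng.normal(0, noise, len(t)) if noise else 0.0)
        return AbsorbanceTrace(time_min=t, a525=a525, a485=a485)

    def test_exact_line_recovers_slope(self):
        slope, _ = initial_rate(self._trace(), (0, 10))
        assert slope == pytest.approx(-0.01)

    def test_flat_trace_has_zero_slope(self):
        slope, _ = initial_rate(self._trace(slope=0.0), (0, 10))
        assert slope == pytest.approx(0.0, abs=1e-15)

    def test_noisy_line_within_three_standard_errors(self):
        slope, se = initial_rate(self._trace(noise=0.001, seed=7), (0, 30))
        assert abs(slope - (-0.01)) < 3 * se

    def test_window_outside_trace_is_an_error(self):
        with pytest.raises(ValueError, match="window"):
            initial_rate(self._trace(), (100, 120))

    def test_fold_change_semantics(self):
        assert fold_change_slower(-0.0137, -0.001) == pytest.approx(13.7)
        assert fold_change_slower(-0.005, -0.005) == 1.0
        assert fold_change_slower(-0.01, 0.0) == math.inf

    def test_isosbestic_drift_constant_and_ramp(self):
        t = np.linspace(0, 30, 61)
        flat = AbsorbanceTrace(t, 1 - 0.01 * t, a485=np.full(61, 0.5))
        assert isosbestic_drift(flat) == 0.0
        ramp = AbsorbanceTrace(t, 1 - 0.01 * t, a485=0.5 + 0.02 * t / 30)
        assert isosbestic_drift(ramp) == pytest.approx(0.02)

    def test_noisy_isosbestic_stays_below_qc_threshold(self):
        rng = np.random.default_rng(99)
        t = np.linspace(0, 30, 61)
        trace = AbsorbanceTrace(t, 1 - 0.01 * t,
                                a485=0.5 + rng.normal(0, 0.002, 61))
        assert isosbestic_drift(trace) <= 0.01

    def test_missing_isosbestic_channel_is_an_error(self):
        with pytest.raises(ValueError, match="485"):
            isosbestic_drift(self._trace())

    def test_nonmonotonic_time_rejected(self):
        with pytest.raises(ValueError):
            AbsorbanceTrace(np.array([0, 1, 1]), np.array([1.0, 0.9, 0.8]))
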