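"""Synthetic-dataset generator and the benchmark driver."""

import numpy as np
import pytest

import circastat as cs
from circastat import SimulationSpec, generate_series, run_benchmark, table1_specs


class TestGenerator:
    def test_same_seed_is_bit_identical(self):
        spec = SimulationSpec(waveform="cosine", n_groups=5, seed=3)
        a = generate_series(spec)
        b = generate_series(spec)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)
            assert np.array_equal(x.times, y.times)

    def test_noiseless_cosine_round_trips_through_cosinor(self):
        spec = SimulationSpec(waveform="cosine", n_groups=6, seed=1,
                              noise_pct_range=(0.0, 0.0))
        series, truth = generate_series(spec, return_params=True)
        for ts, params in zip(series, truth):
            fit = cs.fit_cosinor(ts, 24.0)
            assert fit.amplitude == pytest.approx(params["amplitude"], rel=1e-9)
            assert fit.acrophase == pytest.approx(params["phase"], abs=1e-6)
            assert fit.p_raw < 1e-12

    def test_pseudo_random_class_has_no_daily_autocorrelation(self):
        spec = SimulationSpec(waveform="pseudo-random", n_groups=50, seed=2,
                              noise_pct_range=(0.0, 0.0))
        rs = []
        for ts in generate_series(spec):
            v = ts.values - ts.values.mean()
            rs.append(float(v[:-24] @ v[24:]) / float(v @ v))
        assert abs(np.mean(rs)) < 2 / np.sqrt(50 * 48)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(waveform="square", n_groups=5)
        with pytest.raises(ValueError):
            SimulationSpec(waveform="cosine", n_groups=5, noise_pct_range=(0.5, 0.2))
        with pytest.raises(ValueError):
            SimulationSpec(waveform="cosine", n_groups=5, duration=10.0, dt=1.0)
        with pytest.raises(ValueError):
            SimulationSpec(waveform="cosine", n_groups=5, amplitude_range=(0, 1))

    def test_table1_specs_match_study_design(self):
        specs = table1_specs(seed=0)
        assert specs["pseudo-random"].n_groups == 50
        assert specs["cosine"].n_groups == 80
        assert specs["cosine"].amplitude_range == (0.001, 10000.0)
        assert specs["cosine"].noise_pct_range == (0.20, 0.40)
        assert specs["triangle"].n_groups == 40
        assert specs["triangle"].asymmetric
        assert specs["triangle"].noise_pct_range == (0.30, 0.40)
        assert specs["bimodal"].n_groups == 32
        assert specs["bimodal"].noise_pct_range == (0.20, 0.20)
        for s in specs.values():
            assert s.duration == 48.0 and s.dt == 1.0
            assert 0 <= s.seed < 2**31
        assert table1_specs(seed=0) == specs  # deterministic derivation

    def test_csv_round_trip(self, tmp_path):
        spec = SimulationSpec(waveform="triangle", n_groups=3, seed=5, asymmetric=True)
        series = generate_series(spec)
        path = tmp_path / "tri.csv"
        cs.write_dataset_csv(series, path)
        back = cs.load_csv(path)
        assert [s.label for s in back] == [s.label for s in series]
        for x, y in zip(series, back):
            assert np.allclose(x.values, y.values)


class TestBenchmark:
    def test_single_group_smoke(self):
        spec = SimulationSpec(waveform="cosine", n_groups=1, seed=0)
        rep = run_benchmark([spec], methods=["cosinor"])
        cell = rep.cell("cosinor", "cosine")
        assert cell.n_groups == 1 and cell.detected in (0, 1)

    def test_unknown_method_rejected(self):
        spec = SimulationSpec(waveform="cosine", n_groups=1, seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            run_benchmark([spec], methods=["periodogram"])

    def test_noiseless_high_amplitude_classes_fully_detected(self):
        base = dict(n_groups=4, seed=7, noise_pct_range=(0.0, 0.0),
                    amplitude_range=(1.0, 10.0))
        pairs = [
            ("cosine", "cosinor"), ("cosine", "cosine-kendall"),
            ("triangle", "jtk"), ("bimodal", "harmonic"),
        ]
        for waveform, method in pairs:
            spec = SimulationSpec(waveform=waveform, asymmetric=waveform != "cosine",
                                  **base)
            rep = run_benchmark([spec], methods=[method])
            assert rep.cell(method, waveform).detected == 4, (waveform, method)

    def test_power_monotone_in_noise_level(self):
        # fixed clean signals, increasing noise-to-amplitude ratio
        spec = SimulationSpec(waveform="cosine", n_groups=25, seed=11,
                              noise_pct_range=(0.0, 0.0),
                              amplitude_range=(1.0, 1.0))
        clean, truth = cs.generate_series(spec, return_params=True)
        counts = []
        for noise in (0.25, 1.5, 6.0):
            rng = np.random.default_rng(99)
            detected = 0
            for ts, params in zip(clean, truth):
                amp = params["amplitude"]
                noisy = ts.values + rng.uniform(-noise * amp, noise * amp, ts.n)
                res = cs.scan_cosinor(ts.with_values(noisy))
                detected += res.adj_p < 0.05
            counts.append(detected)
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] == 25  # low noise: full power

    def test_report_serializes(self, tmp_path):
        spec = SimulationSpec(waveform="cosine", n_groups=2, seed=0)
        noise = SimulationSpec(waveform="pseudo-random", n_groups=2, seed=1,
                               noise_pct_range=(0.0, 0.0))
        rep = run_benchmark([spec, noise], methods=["cosinor"])
        text = rep.to_text()
        assert "cosinor" in text and "/2" in text
        out = tmp_path / "rep.csv"
        rep.to_csv(out)
        assert out.exists() and out.stat().st_size > 0
        assert 0.0 <= rep.fpr("cosinor") <= 1.0
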