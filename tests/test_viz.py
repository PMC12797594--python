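"""Figure outputs: previews, actograms, best-fit overlays."""

import numpy as np
import pytest

import circastat as cs
from circastat import TimeSeries, align_groups, plot_actogram, plot_fit, plot_preview
from circastat.viz import actogram_rows


@pytest.fixture
def study(make_cosine):
    s1 = [make_cosine(label="WT", seed=1, noise_sd=0.2),
          make_cosine(label="WT", seed=2, noise_sd=0.2),
          make_cosine(label="KO", seed=3, noise_sd=0.2),
          make_cosine(label="CTRL", seed=4, noise_sd=0.2)]
    return align_groups(s1)


class TestPreview:
    def test_writes_nonempty_file_with_spans(self, study, tmp_path):
        out = plot_preview(study, spans=[(12, 24, "grey")], path=tmp_path / "p.png")
        assert (tmp_path / "p.png").stat().st_size > 0

    def test_plain_curves_without_spans(self, study, tmp_path):
        plot_preview(study, spans=[], path=tmp_path / "p2.png")
        assert (tmp_path / "p2.png").exists()

    def test_legend_lists_each_group_once(self, study, tmp_path, monkeypatch):
        captured = {}
        import matplotlib.pyplot as plt

        orig = plt.Axes.legend

        def spy(self, *a, **k):
            leg = orig(self, *a, **k)
            captured["labels"] = [t.get_text() for t in leg.get_texts()]
            return leg

        monkeypatch.setattr(plt.Axes, "legend", spy)
        plot_preview(study, path=tmp_path / "p3.png")
        assert captured["labels"] == ["WT", "KO", "CTRL"]

    def test_out_of_range_span_warns(self, study, tmp_path):
        with pytest.warns(UserWarning, match="outside"):
            plot_preview(study, spans=[(100, 120, "grey")], path=tmp_path / "p4.png")

    def test_does_not_mutate_input(self, study, tmp_path):
        before = {lab: [m.values.copy() for m in study.members(lab)]
                  for lab in study.labels}
        plot_preview(study, path=tmp_path / "p5.png")
        for lab in study.labels:
            for got, want in zip(study.members(lab), before[lab]):
                assert np.array_equal(got.values, want)


class TestActogram:
    def test_double_plot_right_half_equals_next_row_left_half(self, tmp_path, monkeypatch):
        import matplotlib.pyplot as plt

        import circastat.viz as viz

        captured = {}
        monkeypatch.setattr(
            viz, "_save", lambda fig, path: captured.setdefault("fig", fig) and str(path)
        )
        t = np.arange(96.0)
        rng = np.random.default_rng(0)
        ts = TimeSeries(t, rng.uniform(0, 1, 96), label="fly")
        plot_actogram(ts, path=tmp_path / "a.png")
        fig = captured["fig"]
        axes = fig.axes
        assert len(axes) == 4
        bars = [np.array([p.get_height() for p in ax.patches]) for ax in axes]
        for r in range(3):
            assert len(bars[r]) == 48  # day r plus day r+1
            assert np.allclose(bars[r][24:], bars[r + 1][:24])
        assert len(bars[3]) == 24  # last row has no following day
        plt.close(fig)

    def test_96h_series_gives_four_rows(self, tmp_path):
        t = np.arange(96.0)
        ts = TimeSeries(t, np.cos(2 * np.pi * t / 24), label="x")
        plot_actogram(ts, path=tmp_path / "a.png")
        assert len(actogram_rows(ts, 24.0)) == 4
        assert (tmp_path / "a.png").stat().st_size > 0

    def test_short_day_length_makes_more_rows(self):
        t = np.arange(48.0)
        ts = TimeSeries(t, np.cos(2 * np.pi * t / 24), label="x")
        assert len(actogram_rows(ts, 12.0)) == 4

    def test_constant_series_renders(self, tmp_path):
        t = np.arange(48.0)
        plot_actogram(TimeSeries(t, np.ones(48), label="c"), path=tmp_path / "c.png")
        assert (tmp_path / "c.png").exists()

    def test_sub_day_series_warns_single_row(self, tmp_path):
        t = np.arange(0, 12, 1.0)
        ts = TimeSeries(t, np.cos(t), label="s")
        with pytest.warns(UserWarning, match="single-row"):
            plot_actogram(ts, path=tmp_path / "s.png")
        assert len(actogram_rows(ts, 24.0)) == 1


class TestFitOverlay:
    def test_cosinor_curve_passes_through_fitted_values(self, make_cosine, tmp_path):
        ts = make_cosine(noise_sd=0.4, seed=1)
        res = cs.scan_cosinor(ts)
        assert np.allclose(res.fit_curve(ts.times), res.best_fit.fitted, atol=1e-10)
        plot_fit(ts, res, res.fit_curve, path=tmp_path / "f.png")
        assert (tmp_path / "f.png").stat().st_size > 0

    def test_jtk_overlay_uses_least_squares_scaling(self, make_cosine):
        ts = make_cosine(noise_sd=0.4, seed=2, amplitude=1.0, mesor=5.0)
        res = cs.scan_jtk(ts)
        template = res.template_values(ts.times)
        X = np.column_stack([template, np.ones(ts.n)])
        k, b = np.linalg.pinv(X) @ ts.values
        assert res.scale == pytest.approx((k, b), abs=1e-9)
        assert np.allclose(res.fit_curve(ts.times), k * template + b, atol=1e-9)

    def test_ar_corrected_overlay_uses_filtered_series(self, tmp_path):
        rng = np.random.default_rng(7)
        t = np.arange(48.0)
        wander = np.zeros(48)
        for i in range(1, 48):
            wander[i] = 0.85 * wander[i - 1] + rng.normal()
        ts = TimeSeries(t, np.cos(2 * np.pi * t / 24) + wander, label="ar")
        res = cs.ar_jtk(ts)
        if res.ar.detected:
            assert res.analyzed_ts.n == ts.n - 1
            plot_fit(ts, res, res.fit_curve, path=tmp_path / "arfit.png")
            assert (tmp_path / "arfit.png").exists()

    def test_svg_output_is_deterministic(self, make_cosine, tmp_path):
        ts = make_cosine()
        res = cs.scan_cosinor(ts)
        p1, p2 = tmp_path / "one.svg", tmp_path / "two.svg"
        plot_fit(ts, res, res.fit_curve, path=p1)
        plot_fit(ts, res, res.fit_curve, path=p2)
        assert p1.read_bytes() == p2.read_bytes()
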