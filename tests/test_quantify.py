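"""XIC construction, isomer peak detection and area integration."""

import math
from dataclasses import replace

import numpy as np
import pytest

from guindex.calibrate import fit
from guindex.compositions import GlycanComposition, glycan_formula
from guindex.config import Config
from guindex.isotopes import envelope, envelope_mz
from guindex.ladder import assign_ladder, extract_ladder_candidates
from guindex.msio import build_index
from guindex.quantify import (
    XICTrace,
    build_xic,
    detect_peaks,
    integrate,
    quantify_run,
)
from guindex.annotate import annotate_run
from guindex.synth import PlantedGlycan, SynthSpec, default_spec, generate_run

COMP = GlycanComposition(2, 3, 0, 0)


def trace(rts, intensities):
    return XICTrace(COMP, 1, "proton", np.asarray(rts, float), np.asarray(intensities, float))


class TestDetectPeaks:
    def test_five_point_peak_spans_all_points(self):
        peaks = detect_peaks(trace([0, 1, 2, 3, 4], [10, 50, 100, 50, 10]), 0.5)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.apex_rt == 2 and p.apex_intensity == 100
        # 50 >= 50 passes the boundary rule; local-minimum walk reaches the ends
        assert (p.left_rt, p.right_rt) == (0, 4)

    def test_two_gaussians_with_deep_valley(self):
        x = np.arange(0, 10, 0.05)
        y = 100 * np.exp(-0.5 * ((x - 3) / 0.3) ** 2) + 80 * np.exp(
            -0.5 * ((x - 7) / 0.3) ** 2
        )
        peaks = detect_peaks(trace(x, y), 0.5)
        assert len(peaks) == 2
        assert peaks[0].apex_rt == pytest.approx(3.0, abs=0.05)
        assert peaks[1].apex_rt == pytest.approx(7.0, abs=0.05)

    def test_monotone_ramp_single_peak_at_end(self):
        peaks = detect_peaks(trace([0, 1, 2, 3], [1, 2, 3, 4]), 0.5)
        assert len(peaks) == 1
        assert peaks[0].apex_rt == 3

    def test_all_zero_trace_is_empty(self):
        assert detect_peaks(trace([0, 1, 2], [0, 0, 0]), 0.5) == []

    def test_min_apex_floor_suppresses_small_peaks(self):
        x = np.arange(0, 10, 0.1)
        y = 100 * np.exp(-0.5 * ((x - 3) / 0.3) ** 2) + 5 * np.exp(
            -0.5 * ((x - 7) / 0.3) ** 2
        )
        assert len(detect_peaks(trace(x, y), 0.5, min_apex=10.0)) == 1

    def test_shift_invariance(self):
        x = np.arange(0, 10, 0.05)
        y = 100 * np.exp(-0.5 * ((x - 4) / 0.4) ** 2)
        p0 = detect_peaks(trace(x, y), 0.5)
        p1 = detect_peaks(trace(x + 11.5, y), 0.5)
        assert len(p0) == len(p1) == 1
        assert p1[0].apex_rt - p0[0].apex_rt == pytest.approx(11.5, abs=1e-9)
        assert p1[0].area == pytest.approx(p0[0].area, rel=1e-12)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            detect_peaks(trace([0, 1], [1, 2]), 1.5)

    def test_two_isomer_resolution_rate(self):
        """Valley below cutoff·min(apex) ⇒ two peaks, over random traces."""
        rng = np.random.default_rng(77)
        n_pairs = detected = 0
        x = np.arange(0, 20, 0.05)
        for _ in range(100):
            c1 = rng.uniform(4, 7)
            c2 = c1 + rng.uniform(3, 6)
            h1, h2 = rng.uniform(50, 150, 2)
            s1, s2 = rng.uniform(0.2, 0.5, 2)
            y = h1 * np.exp(-0.5 * ((x - c1) / s1) ** 2) + h2 * np.exp(
                -0.5 * ((x - c2) / s2) ** 2
            )
            valley = float(y[(x > c1) & (x < c2)].min())
            if valley >= 0.5 * min(h1, h2):
                continue  # not a resolvable pair under the 50% rule
            n_pairs += 1
            if len(detect_peaks(trace(x, y), 0.5)) == 2:
                detected += 1
        assert n_pairs > 50
        assert detected >= 0.95 * n_pairs


class TestIntegrate:
    def test_rectangle(self):
        t = trace(np.arange(0, 2.25, 0.25), np.full(9, 100.0))
        assert integrate(t, 0.0, 2.0) == pytest.approx(200.0)

    def test_triangle(self):
        assert integrate(trace([0, 1, 2], [0, 100, 0]), 0, 2) == pytest.approx(100.0)

    def test_gaussian_analytic_area(self):
        h, sigma = 250.0, 0.4
        x = np.arange(-3 * sigma, 3 * sigma + 1e-9, 0.05)
        y = h * np.exp(-0.5 * (x / sigma) ** 2)
        got = integrate(trace(x, y), float(x[0]), float(x[-1]))
        assert got == pytest.approx(h * sigma * math.sqrt(2 * math.pi), rel=0.02)

    def test_linearity(self):
        x = np.arange(0, 5, 0.1)
        y = np.exp(-0.5 * ((x - 2) / 0.5) ** 2)
        a1 = integrate(trace(x, y), 0, 5)
        a2 = integrate(trace(x, 3.0 * y), 0, 5)
        assert a2 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_sum_mode_and_inverted_bounds(self):
        t = trace([0, 1, 2], [5, 10, 15])
        assert integrate(t, 0, 2, mode="sum") == 30.0
        with pytest.raises(ValueError):
            integrate(t, 2, 0)


class TestBuildXic:
    def test_planted_gaussian_apex_recovered(self, small_run, small_index, cfg):
        t = build_xic(small_run, small_index, COMP, 1, "proton", cfg)
        apex_rt = t.rts[np.argmax(t.intensities)]
        assert apex_rt == pytest.approx(20.0, abs=0.05)
        env = envelope(glycan_formula(COMP))
        p = np.sort(env.probabilities)[::-1]
        expected_apex = 5e5 * float(p[:3].sum() / p[0])
        assert float(t.intensities.max()) == pytest.approx(expected_apex, rel=1e-6)

    def test_absent_glycan_gives_zero_trace(self, small_run, small_index, cfg):
        t = build_xic(small_run, small_index, GlycanComposition(6, 6, 2, 2), 1, "proton", cfg)
        assert np.all(t.intensities == 0.0)
        assert len(t.rts) == len(small_run.ms1_spectra())

    def test_monoisotopic_only_fixture(self, spectrum_factory, cfg):
        from guindex.msio import Run

        env = envelope(glycan_formula(COMP))
        mzs = envelope_mz(env, 1)
        top = env.most_abundant_index
        spectra = [
            spectrum_factory([mzs[top]], [321.0], rt=float(r), scan_id=f"s{r}")
            for r in (1, 2, 3)
        ]
        run = Run(spectra=spectra)
        idx = build_index(run, cfg.tol_da(2000.0))
        t = build_xic(run, idx, COMP, 1, "proton", cfg)
        assert t.intensities.tolist() == [321.0, 321.0, 321.0]


@pytest.fixture(scope="module")
def multi_charge_pipeline():
    spec = SynthSpec(
        gu_range=(2, 6),
        rt_range=(8.0, 36.0),
        glycans=(
            PlantedGlycan(GlycanComposition(4, 5, 0, 0), (1, 2), "proton", apex_rt=22.0, height=4e5),
        ),
        noise_density=0.0,
        seed=8,
    )
    run = generate_run(spec)
    cfg = Config()
    idx = build_index(run, cfg.tol_da(2500.0))
    model = fit(assign_ladder(extract_ladder_candidates(run, idx, cfg)).fit_points())
    anns = annotate_run(run, idx, model, cfg)
    return spec, run, cfg, idx, model, anns


class TestQuantifyRun:
    def test_total_area_sums_charge_states(self, multi_charge_pipeline):
        spec, run, cfg, idx, model, anns = multi_charge_pipeline
        quants = quantify_run(anns, run, idx, model, cfg)
        q = next(x for x in quants if x.composition == GlycanComposition(4, 5, 0, 0))
        g = spec.glycans[0]
        env = envelope(glycan_formula(g.composition))
        p = np.sort(env.probabilities)[::-1]
        analytic = 2 * g.height * g.sigma * math.sqrt(2 * math.pi) * float(p[:3].sum() / p[0])
        assert len(q.isomers) == 1
        assert q.total_area == pytest.approx(analytic, rel=0.02)

    def test_doubled_intensities_double_areas(self, multi_charge_pipeline):
        spec, run, cfg, idx, model, anns = multi_charge_pipeline
        q1 = quantify_run(anns, run, idx, model, cfg)
        from guindex.msio import Run, Spectrum

        doubled = Run(
            spectra=[
                Spectrum(s.scan_id, s.rt, s.ms_level, s.mz.copy(), 2.0 * s.intensity)
                for s in run.spectra
            ]
        )
        idx2 = build_index(doubled, cfg.tol_da(2500.0))
        q2 = quantify_run(anns, doubled, idx2, model, cfg)
        for a, b in zip(q1, q2):
            assert b.total_area == pytest.approx(2.0 * a.total_area, rel=1e-9)

    def test_isomer_guis_hit_planted_targets(self):
        spec = replace(default_spec(seed=4), noise_density=0.0)
        run = generate_run(spec)
        cfg = Config()
        idx = build_index(run, cfg.tol_da(2500.0))
        model = fit(assign_ladder(extract_ladder_candidates(run, idx, cfg)).fit_points())
        anns = annotate_run(run, idx, model, cfg)
        quants = quantify_run(anns, run, idx, model, cfg)
        targets = {
            str(g.composition): g.target_gui
            for g in spec.glycans
            if g.target_gui is not None
        }
        seen = {}
        for q in quants:
            if str(q.composition) in targets:
                assert len(q.isomers) == 1
                seen[str(q.composition)] = q.isomers[0].gui
        assert set(seen) == set(targets)
        for comp, gui in seen.items():
            assert gui == pytest.approx(targets[comp], abs=0.1)

    def test_summed_isomer_areas_bounded_by_total_trace_area(self, multi_charge_pipeline):
        spec, run, cfg, idx, model, anns = multi_charge_pipeline
        quants = quantify_run(anns, run, idx, model, cfg)
        for q in quants:
            total = 0.0
            for z, adduct in {(a.charge, a.adduct) for a in anns if a.composition == q.composition}:
                t = build_xic(run, idx, q.composition, z, adduct, cfg)
                total += integrate(t, float(t.rts[0]), float(t.rts[-1]))
            assert sum(p.area for p in q.isomers) <= total * (1 + 1e-9)

    def test_empty_annotations_rejected(self, multi_charge_pipeline):
        spec, run, cfg, idx, model, _ = multi_charge_pipeline
        with pytest.raises(ValueError):
            quantify_run([], run, idx, model, cfg)
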