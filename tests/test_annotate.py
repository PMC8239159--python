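"""Envelope matching, Pearson scoring and run-level annotation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import pearsonr

from guindex.annotate import (
    EnvelopeMatch,
    annotate_run,
    match_envelope,
    score_match,
)
from guindex.calibrate import fit
from guindex.compositions import GlycanComposition, glycan_formula
from guindex.config import Config
from guindex.isotopes import envelope, envelope_mz
from guindex.ladder import assign_ladder, extract_ladder_candidates
from guindex.msio import Run, build_index
from guindex.synth import PlantedGlycan, SynthSpec, default_spec, generate_run


def planted_spectrum(factory, comp, charge, scale=1000.0, rt=10.0):
    env = envelope(glycan_formula(comp))
    mzs = envelope_mz(env, charge)
    keep = env.probabilities > 1e-6
    return factory(mzs[keep], scale * env.probabilities[keep], rt=rt)


class TestMatchEnvelope:
    def test_planted_identity_matches_proportionally(self, spectrum_factory):
        comp = GlycanComposition(5, 2, 0, 0)
        s = planted_spectrum(spectrum_factory, comp, 1)
        m = match_envelope(s, comp, 1)
        assert m is not None
        ratio = m.observed[m.theoretical > 0] / m.theoretical[m.theoretical > 0]
        assert ratio == pytest.approx(np.full(ratio.shape, 1000.0), rel=1e-9)

    def test_missing_anchor_rejects_match(self, spectrum_factory):
        comp = GlycanComposition(2, 5, 0, 0)
        env = envelope(glycan_formula(comp))
        mzs = envelope_mz(env, 1)
        anchor = env.most_abundant_index
        keep = (env.probabilities > 1e-6) & (np.arange(len(env)) != anchor)
        s = spectrum_factory(mzs[keep], 1000 * env.probabilities[keep])
        assert match_envelope(s, comp, 1) is None

    def test_wrong_charge_has_no_anchor(self, spectrum_factory):
        comp = GlycanComposition(2, 3, 0, 0)
        s = planted_spectrum(spectrum_factory, comp, 2)
        assert match_envelope(s, comp, 1) is None

    def test_unmatched_positions_recorded_as_zero(self, spectrum_factory):
        comp = GlycanComposition(2, 3, 0, 0)
        env = envelope(glycan_formula(comp))
        mzs = envelope_mz(env, 1)
        s = spectrum_factory([mzs[0]], [500.0])  # anchor only (monoisotopic)
        m = match_envelope(s, comp, 1)
        assert m is not None
        assert m.observed[0] == 500.0
        assert np.all(m.observed[1:] == 0.0)
        assert m.matched_peaks == 1


class TestScoreMatch:
    def test_identity_scores_one(self):
        t = np.array([5.0, 3.0, 1.0])
        m = EnvelopeMatch(t, t.copy(), 0.0, 3)
        assert score_match(m) == pytest.approx(1.0)

    def test_linear_transformation_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = rng.uniform(0.1, 1.0, size=rng.integers(3, 8))
            if np.ptp(t) == 0:
                continue
            o = 5.0 * t + 100.0
            assert score_match(EnvelopeMatch(t, o, 0.0, len(t))) == pytest.approx(1.0)

    def test_reversed_envelope_matches_hand_formula(self):
        t = np.array([6.0, 3.0, 1.0])
        o = t[::-1].copy()
        got = score_match(EnvelopeMatch(t, o, 0.0, 3))
        assert got == pytest.approx(pearsonr(t, o).statistic, abs=1e-12)

    def test_scipy_pearson_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = rng.uniform(0, 1, 5)
            o = rng.uniform(0, 1, 5)
            got = score_match(EnvelopeMatch(t, o, 0.0, 5))
            assert got == pytest.approx(pearsonr(t, o).statistic, abs=1e-12)

    def test_zero_variance_is_rejected(self):
        assert score_match(EnvelopeMatch(np.ones(3), np.arange(3.0), 0.0, 3)) is None
        assert score_match(EnvelopeMatch(np.arange(3.0), np.zeros(3), 0.0, 0)) is None


def _pipeline(run, cfg):
    idx = build_index(run, cfg.tol_da(2500.0))
    model = fit(assign_ladder(extract_ladder_candidates(run, idx, cfg)).fit_points())
    return idx, model


class TestAnnotateRun:
    def test_zero_noise_soundness_and_completeness(self):
        spec = replace(default_spec(seed=2), noise_density=0.0)
        run = generate_run(spec)
        cfg = Config()
        idx, model = _pipeline(run, cfg)
        anns = annotate_run(run, idx, model, cfg)
        planted = {str(g.composition) for g in spec.glycans}
        assert {str(a.composition) for a in anns} == planted
        # every annotation's scan lies within the planted elution window
        apex = {str(g.composition): g.resolved_apex(spec.gu_curve) for g in spec.glycans}
        for a in anns:
            assert abs(a.rt - apex[str(a.composition)]) < 0.5
        assert all(a.score >= cfg.score_cutoff for a in anns)

    def test_perturbed_envelopes_still_recovered(self):
        """±5% multiplicative envelope noise keeps r >= 0.9 recovery."""
        cfg = Config()
        recovered = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = replace(default_spec(seed=seed), noise_density=0.0)
            run = generate_run(spec)
            rng = np.random.default_rng(1000 + seed)
            for s in run.spectra:
                s.intensity = s.intensity * rng.uniform(0.95, 1.05, size=len(s))
            idx, model = _pipeline(run, cfg)
            anns = annotate_run(run, idx, model, cfg)
            planted = {str(g.composition) for g in spec.glycans}
            recovered += len(planted & {str(a.composition) for a in anns})
        assert recovered >= 0.95 * n_seeds * 5

    def test_cutoff_monotonicity(self, small_run, small_index, small_model):
        counts = []
        for cutoff in (0.5, 0.9, 0.999999999):
            cfg = Config(score_cutoff=cutoff, bounds=(2, 3, 0, 0))
            counts.append(
                len(annotate_run(small_run, small_index, small_model, cfg))
            )
        assert counts == sorted(counts, reverse=True)

    def test_tolerance_monotonicity(self, small_run, small_index, small_model):
        counts = []
        for tol in (20.0, 10.0, 0.001):
            cfg = Config(tol_ppm=tol, bounds=(2, 3, 0, 0))
            counts.append(len(annotate_run(small_run, small_index, small_model, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_output_order_is_deterministic(self, small_run, small_index, small_model, cfg):
        a1 = annotate_run(small_run, small_index, small_model, cfg)
        a2 = annotate_run(small_run, small_index, small_model, cfg)
        assert a1 == a2
        keys = [(str(a.composition), a.rt, a.charge) for a in a1]
        assert keys == sorted(keys)
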