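"""Spectrum preprocessing, fitting, aggregation and comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from eelvision import msp
from eelvision.msp import (
    FitConfig,
    Spectrum,
    StageSummary,
    TemplateFit,
    chromophore_ratio,
    compare_from_stats,
    compare_stages,
    fit_spectrum,
    grid_search_fit,
    histogram,
    preprocess,
    summarize_stage,
)
from eelvision.synthetic import SpectrumSimConfig, simulate_spectra
from eelvision.templates import evaluate_template

from conftest import WL


def make_spectrum(absorbance, cell_id="c1", stage="glass", cell_type="rod"):
    return Spectrum(cell_id, "s1", stage, cell_type, WL, absorbance)


def make_fit(cell_id, lam, accepted=True, chromophore="A1", sd=1.0):
    return TemplateFit(cell_id, lam, chromophore, sd, accepted, 30)


class TestPreprocess:
    def test_baseline_and_scale_removed(self):
        template = evaluate_template(493.0, "A1", WL).relative_absorbance
        raw = make_spectrum(0.8 * template + 0.05)
        out = preprocess(raw)
        assert out.absorbance.max() == pytest.approx(1.0, abs=1e-9)
        tail = out.absorbance[WL >= 730]
        assert np.all(np.abs(tail) < 0.01)

    def test_all_zero_trace_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            preprocess(make_spectrum(np.zeros_like(WL)))

    def test_idempotent(self):
        template = evaluate_template(493.0, "A1", WL).relative_absorbance
        once = preprocess(make_spectrum(0.8 * template + 0.05))
        twice = preprocess(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-6)

    def test_short_span_raises(self):
        wl = np.arange(450.0, 530.0, 1.0)
        s = Spectrum("c", "s", "glass", "rod", wl, np.ones_like(wl))
        with pytest.raises(ValueError, match="span"):
            preprocess(s)


class TestFitSpectrum:
    def test_noiseless_a1_recovery(self, noiseless_a1_493):
        fit = fit_spectrum(noiseless_a1_493)
        assert fit.lambda_max_hat == pytest.approx(493.0, abs=0.2)
        assert fit.chromophore == "A1"
        assert fit.quality_sd < 0.1
        assert fit.accepted

    def test_noiseless_a2_recovery(self, noiseless_a2_520):
        fit = fit_spectrum(noiseless_a2_520)
        assert fit.lambda_max_hat == pytest.approx(520.0, abs=0.2)
        assert fit.chromophore == "A2"

    def test_quality_sd_grows_with_noise(self):
        # dispersion of the limb estimates is monotone in the noise
        # level, checked over 50 replicate pairs with a common seed
        sds = {}
        for noise in (0.02, 0.10):
            cfg = SpectrumSimConfig(true_lambda_max=493.0, n_cells=50,
                                    noise_sd=noise, seed=7)
            fits = [fit_spectrum(s) for s in simulate_spectra(cfg)]
            sds[noise] = np.mean([f.quality_sd for f in fits])
        assert sds[0.10] > sds[0.02]

    def test_too_few_limb_points_rejects_without_raising(self, noiseless_a1_493):
        cfg = FitConfig(min_limb_points=1000)
        fit = fit_spectrum(noiseless_a1_493, cfg)
        assert not fit.accepted
        assert fit.reason == "too_few_limb_points"
        assert math.isinf(fit.quality_sd)

    def test_qc_threshold_monotonicity(self):
        cfg = SpectrumSimConfig(true_lambda_max=493.0, n_cells=20,
                                noise_sd=0.05, seed=3)
        spectra = simulate_spectra(cfg)
        counts = []
        for thr in (7.5, 2.0, 0.5, 0.1):
            fits = [fit_spectrum(s, FitConfig(qc_threshold=thr)) for s in spectra]
            counts.append(sum(f.accepted for f in fits))
        assert counts == sorted(counts, reverse=True)

    def test_matches_grid_search_oracle(self, noiseless_a1_493, noiseless_a2_520):
        for spectrum in (noiseless_a1_493, noiseless_a2_520):
            fit = fit_spectrum(spectrum)
            lm, chromophore = grid_search_fit(spectrum)
            assert chromophore == fit.chromophore
            assert abs(lm - fit.lambda_max_hat) <= 0.5

    def test_parameter_recovery_population(self):
        cfg = SpectrumSimConfig(true_lambda_max=493.0, n_cells=100,
                                noise_sd=0.02, seed=21)
        fits = [fit_spectrum(s) for s in simulate_spectra(cfg)]
        accepted = [f for f in fits if f.accepted]
        assert len(accepted) >= 90
        assert abs(np.mean([f.lambda_max_hat for f in accepted]) - 493.0) <= 1.0

    def test_chromophore_classification_noiseless(self):
        # family-only separation: same λ_max, different chromophore
        correct = 0
        cases = [(lm, ch) for lm in (460.0, 500.0, 540.0) for ch in ("A1", "A2")]
        for lm, ch in cases:
            cfg = SpectrumSimConfig(true_lambda_max=lm, chromophore=ch,
                                    n_cells=2, noise_sd=0.0, seed=5)
            for s in simulate_spectra(cfg):
                correct += fit_spectrum(s).chromophore == ch
        assert correct / (2 * len(cases)) >= 0.95


class TestSummarize:
    def test_exact_values(self):
        fits = [make_fit(f"c{i}", 493.0) for i in range(60)]
        spectra_meta = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(60)],
                "specimen_id": [f"s{i % 3}" for i in range(60)],
                "stage": "glass",
                "cell_type": "rod",
            }
        )
        (summary,) = summarize_stage(fits, spectra_meta)
        assert summary.mean_lambda_max == 493.0
        assert summary.sd_lambda_max == 0.0
        assert summary.n_cells == 60
        assert summary.n_specimens == 3

    def test_rejected_fits_excluded(self):
        fits = [make_fit("a", 490.0), make_fit("b", 530.0, accepted=False)]
        meta = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "specimen_id": ["s1", "s1"],
                "stage": "glass",
                "cell_type": "rod",
            }
        )
        (summary,) = summarize_stage(fits, meta)
        assert summary.mean_lambda_max == 490.0
        assert summary.n_cells == 1

    def test_zero_accepted_stage_flagged(self):
        fits = [make_fit("a", 490.0, accepted=False)]
        meta = pd.DataFrame(
            {"cell_id": ["a"], "specimen_id": ["s1"], "stage": "glass",
             "cell_type": "cone"}
        )
        (summary,) = summarize_stage(fits, meta)
        assert not summary.detectable
        assert summary.n_cells == 0

    def test_missing_metadata_raises(self):
        fits = [make_fit("a", 490.0)]
        meta = pd.DataFrame(
            {"cell_id": ["b"], "specimen_id": ["s1"], "stage": "glass",
             "cell_type": "rod"}
        )
        with pytest.raises(KeyError):
            summarize_stage(fits, meta)


class TestCompareStages:
    GLASS = StageSummary("glass", "rod", 493.0, 4.7, 60, 3)
    CULTURED = StageSummary("cultured_yellow", "rod", 489.0, 6.1, 40, 4)

    def test_rod_shift_significant(self):
        cmp = compare_stages(self.GLASS, self.CULTURED)
        assert cmp.significant
        assert cmp.p_value < 0.05

    def test_student_t_value_matches_hand_computation(self):
        # pooled SD √[(59·4.7² + 39·6.1²)/98] = 5.303 →
        # t = 4 / (5.303·√(1/60+1/40)) = 3.696
        cmp = compare_stages(self.GLASS, self.CULTURED)
        assert cmp.t_statistic == pytest.approx(3.696, abs=0.01)
        assert cmp.dof == 98

    def test_welch_t_value(self):
        t, dof, p = compare_from_stats(493.0, 4.7, 60, 489.0, 6.1, 40, welch=True)
        # 4/√(4.7²/60 + 6.1²/40) = 3.511
        assert t == pytest.approx(3.511, abs=0.01)
        assert p < 0.05

    def test_identical_summaries_not_significant(self):
        cmp = compare_stages(self.GLASS, self.GLASS)
        assert cmp.t_statistic == 0.0
        assert not cmp.significant

    def test_symmetry(self):
        ab = compare_stages(self.GLASS, self.CULTURED)
        ba = compare_stages(self.CULTURED, self.GLASS)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)
        assert ab.t_statistic == pytest.approx(-ba.t_statistic, rel=1e-12)

    def test_zero_sd_equal_means_p_one(self):
        t, _, p = compare_from_stats(493.0, 0.0, 10, 493.0, 0.0, 10)
        assert (t, p) == (0.0, 1.0)

    def test_cone_comparison_not_significant(self):
        # cultured (508±8.0, n=9) vs wild (517±14.2, n=7) green cones:
        # the two-sample test from the summary statistics does not reach
        # significance at α = 0.05
        cultured = StageSummary("cultured_yellow", "cone", 508.0, 8.0, 9, 4)
        wild = StageSummary("wild_yellow", "cone", 517.0, 14.2, 7, 2)
        cmp = compare_stages(cultured, wild)
        assert not cmp.significant

    def test_mismatched_cell_types_raise(self):
        cone = StageSummary("glass", "cone", 508.0, 8.0, 9, 3)
        with pytest.raises(ValueError):
            compare_stages(self.GLASS, cone)


class TestRatioAndHistogram:
    def test_ratio_three_to_one(self):
        fits = [make_fit(f"a{i}", 493.0) for i in range(30)] + [
            make_fit(f"b{i}", 505.0, chromophore="A2") for i in range(10)
        ]
        ratio = chromophore_ratio(fits)
        assert (ratio.n_a1, ratio.n_a2) == (30, 10)
        assert ratio.ratio_a1_a2 == pytest.approx(3.0)

    def test_no_a2_flags_infinite(self):
        ratio = chromophore_ratio([make_fit("a", 493.0)])
        assert ratio.infinite
        assert math.isinf(ratio.ratio_a1_a2)

    def test_no_accepted_fits_raises(self):
        with pytest.raises(ValueError):
            chromophore_ratio([make_fit("a", 493.0, accepted=False)])

    def test_single_fit_bin(self):
        h = histogram([make_fit("a", 493.0)], bin_width=5.0, anchor=400.0)
        assert len(h) == 1
        assert (h.bin_left[0], h.bin_right[0], h["count"][0]) == (490.0, 495.0, 1)

    def test_counts_conserved(self):
        rng = np.random.default_rng(4)
        fits = [make_fit(f"c{i}", lam) for i, lam in
                enumerate(rng.uniform(450, 550, 37))]
        h = histogram(fits, bin_width=5.0)
        assert h["count"].sum() == 37

    def test_empty_histogram(self):
        assert len(histogram([], 5.0)) == 0

    def test_bad_bin_width_raises(self):
        with pytest.raises(ValueError):
            histogram([make_fit("a", 493.0)], bin_width=0.0)
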