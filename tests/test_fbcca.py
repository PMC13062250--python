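"""FBCCA core: references, CCA against a brute-force oracle, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvepauth.fbcca import (DegenerateInputError, FBCCAParams, FBCCAScores,
                             build_reference, canonical_correlation,
                             fbcca_scores, select_target, subband_weight)
from ssvepauth.filters import high_set_bank, low_set_bank
from ssvepauth.session import frequency_set
from ssvepauth.simulate import (ChannelMontage, EEGSegment, SimConfig,
                                generate_ssvep_segment)

FS = 600.0


def brute_force_cca(X: np.ndarray, Y: np.ndarray) -> float:
    """Textbook first canonical correlation: largest eigenvalue of
    Sxx^-1 Sxy Syy^-1 Syx, formed explicitly."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = Xc @ Xc.T
    syy = Yc @ Yc.T
    sxy = Xc @ Yc.T
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    eig = np.linalg.eigvals(m).real
    return float(np.sqrt(np.clip(eig.max(), 0.0, 1.0)))


class TestReference:
    def test_first_column_is_sin0_cos0(self):
        y = build_reference(40.0, 1, FS, 600)
        assert y.shape == (2, 600)
        np.testing.assert_allclose(y[:, 0], [0.0, 1.0], atol=1e-15)

    def test_harmonic_rows_oscillate_at_h_times_f(self):
        y = build_reference(7.5, 4, FS, 600)
        assert y.shape == (8, 600)
        # rows for h=4 are 30 Hz: 30 full cycles over 600 samples
        zero_crossings = np.sum(np.diff(np.sign(y[6])) != 0)
        assert zero_crossings == 60
        assert np.all(np.abs(y) <= 1.0)

    def test_sin_cos_orthogonal_over_integer_periods(self):
        y = build_reference(6.0, 2, FS, 600)  # exactly 6 cycles
        t = np.arange(600)
        for h in (1, 2):
            direct_sin = np.sin(2 * np.pi * h * 6.0 * t / FS)
            np.testing.assert_allclose(y[2 * (h - 1)], direct_sin,
                                       atol=1e-12)
            inner = y[2 * (h - 1)] @ y[2 * (h - 1) + 1]
            assert abs(inner) < 1e-9

    def test_nyquist_guard(self):
        # 2nd harmonic of the high set starts at 72 Hz; at fs=600 that is
        # fine, but H high enough to cross fs/2 must be rejected
        with pytest.raises(ValueError, match="Nyquist"):
            build_reference(45.0, 7, FS, 600)  # 315 Hz > 300
        with pytest.raises(ValueError):
            build_reference(100.0, 3, FS, 600)


class TestCanonicalCorrelation:
    def test_signal_in_reference_span_gives_one(self, rng):
        y = build_reference(8.57, 2, FS, 450)
        x = (1.3 * y[0] - 0.4 * y[3] + 5.0)[None, :]
        assert canonical_correlation(x, y) == pytest.approx(1.0, abs=1e-10)

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(100):
            X = rng.standard_normal((3, 300))
            Y = rng.standard_normal((4, 300))
            assert canonical_correlation(X, Y) == pytest.approx(
                brute_force_cca(X, Y), abs=1e-8)

    def test_disjoint_exact_sinusoids_are_uncorrelated(self):
        t = np.arange(600)
        x = np.vstack([np.sin(2 * np.pi * 6 * t / FS),
                       np.cos(2 * np.pi * 6 * t / FS)])
        y = build_reference(30.0, 1, FS, 600)  # integer periods, disjoint
        assert canonical_correlation(x, y) == pytest.approx(0.0, abs=1e-8)

    def test_invariance_under_channel_mixing_and_row_scaling(self, rng):
        X = rng.standard_normal((3, 400))
        Y = rng.standard_normal((4, 400))
        base = canonical_correlation(X, Y)
        mix = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        scaled_y = Y * rng.uniform(0.5, 2.0, size=(4, 1))
        assert canonical_correlation(mix @ X, Y) == pytest.approx(base,
                                                                  abs=1e-8)
        assert canonical_correlation(X, scaled_y) == pytest.approx(base,
                                                                   abs=1e-8)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rho_always_in_unit_interval(self, seed):
        g = np.random.default_rng(seed)
        rho = canonical_correlation(g.standard_normal((2, 120)),
                                    g.standard_normal((3, 120)))
        assert 0.0 <= rho <= 1.0

    def test_single_harmonic_rho_squared_is_sinusoid_fit_r2(self, rng):
        """With a 2-row sin/cos reference, rho^2 equals the R^2 of the
        best phase-free single-frequency sinusoidal least-squares fit."""
        x = rng.standard_normal(500)[None, :]
        y = build_reference(12.0, 1, FS, 500)
        rho = canonical_correlation(x, y)
        xc = x[0] - x[0].mean()
        design = np.vstack([y[0] - y[0].mean(), y[1] - y[1].mean()]).T
        coef, *_ = np.linalg.lstsq(design, xc, rcond=None)
        resid = xc - design @ coef
        r2 = 1 - resid @ resid / (xc @ xc)
        assert rho**2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_row_rejected(self):
        x = np.vstack([np.ones(300), np.random.default_rng(0).standard_normal(300)])
        y = build_reference(10.0, 1, FS, 300)
        with pytest.raises(DegenerateInputError):
            canonical_correlation(x, y)

    def test_too_few_samples_rejected(self):
        g = np.random.default_rng(0)
        with pytest.raises(ValueError):
            canonical_correlation(g.standard_normal((3, 3)),
                                  g.standard_normal((2, 3)))


class TestWeights:
    def test_table_values(self):
        assert subband_weight(1) == pytest.approx(1.25)
        assert subband_weight(2) == pytest.approx(2 ** -1.25 + 0.25)
        assert subband_weight(2) == pytest.approx(0.6705, abs=5e-4)

    def test_strictly_decreasing(self):
        w = [subband_weight(n) for n in range(1, 6)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_invalid_subband_number(self):
        with pytest.raises(ValueError):
            subband_weight(0)


class TestScoring:
    def _clean_segment(self, freq, fset, n=600, channels=1):
        mont = (ChannelMontage() if channels == 3
                else ChannelMontage(("Oz",), (1.0,), (1.0,)))
        cfg = SimConfig(noise_scale=0, alpha_amp=0, line_amp=0,
                        harmonic_count=fset.fbcca_params.harmonics_H)
        return generate_ssvep_segment(freq, n, mont, cfg, rng=1)

    @pytest.mark.parametrize("set_name", ["low", "high"])
    @pytest.mark.parametrize("channels", [1, 3])
    def test_noise_free_winner_for_every_frequency(self, set_name, channels):
        fset = frequency_set(set_name)
        for k, freq in enumerate(fset.frequencies):
            seg = self._clean_segment(freq, fset, channels=channels)
            scores = fbcca_scores(seg, fset.fbcca_params)
            assert scores.winner == k
            assert np.all(scores.rho >= 0) and np.all(scores.rho <= 1)

    def test_single_subband_combined_equals_raw_rho(self):
        fset = frequency_set("high")
        seg = self._clean_segment(40.0, fset)
        scores = fbcca_scores(seg, fset.fbcca_params)
        np.testing.assert_allclose(scores.combined, scores.rho[:, 0])

    def test_frequency_order_permutation_permutes_scores(self):
        fset = frequency_set("low")
        seg = self._clean_segment(7.5, fset)
        base = fbcca_scores(seg, fset.fbcca_params)
        permuted_params = FBCCAParams(
            frequencies=(8.57, 6.67, 7.50), harmonics_H=4,
            subbands=low_set_bank(FS))
        perm = fbcca_scores(seg, permuted_params)
        np.testing.assert_allclose(perm.combined,
                                   base.combined[[2, 0, 1]], atol=1e-12)

    def test_buffer_start_shift_is_immaterial(self):
        """The reference clock restarts at every snapshot; a shifted
        copy of the same stationary signal scores identically."""
        fset = frequency_set("low")
        long = self._clean_segment(8.57, fset, n=1200)
        a = EEGSegment(long.samples[:, :600], FS)
        b = EEGSegment(long.samples[:, 450:1050], FS)
        sa = fbcca_scores(a, fset.fbcca_params)
        sb = fbcca_scores(b, fset.fbcca_params)
        # phase-invariance is exact only over integer periods; finite
        # 600-sample windows leak slightly, so allow a small tolerance
        assert sa.winner == sb.winner
        np.testing.assert_allclose(sa.combined, sb.combined, atol=0.05)
        assert sa.margin == pytest.approx(sb.margin, abs=0.05)

    def test_squared_fusion_mode(self):
        fset = frequency_set("low")
        seg = self._clean_segment(6.67, fset)
        raw = fbcca_scores(seg, fset.fbcca_params)
        sq_params = FBCCAParams(combine_squared=True)
        sq = fbcca_scores(seg, sq_params)
        w = fset.fbcca_params.weights()
        np.testing.assert_allclose(sq.combined, (raw.rho**2) @ w, atol=1e-12)


class TestSelectTarget:
    def _scores(self, combined):
        combined = np.asarray(combined, float)
        return FBCCAScores.from_combined(np.zeros((len(combined), 1)),
                                         combined)

    def test_clear_margin_fires(self):
        sel = select_target(self._scores([0.80, 0.40, 0.30]), 0.30)
        assert sel == (0, pytest.approx(0.40))

    def test_insufficient_margin_defers(self):
        assert select_target(self._scores([0.50, 0.45, 0.10]), 0.30) is None

    def test_exact_tie_breaks_to_lower_index_at_zero_threshold(self):
        sel = select_target(self._scores([0.6, 0.6, 0.1]), 0.0)
        assert sel == (0, 0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_target(self._scores([0.5, 0.1]), -0.1)
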