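"""Signal-space-projection contracts: smoothing, basis, projector, pipeline."""

import numpy as np
import pytest

import hisbeat as hb


class TestOversmooth:
    def test_cubic_polynomial_passes_through(self):
        t = np.linspace(0, 1, 400)
        x = 2 - t + 0.5 * t**2 - 3 * t**3
        out = hb.oversmooth(x, order=3, frame_ms=23.0, fs=1000.0)
        np.testing.assert_allclose(out[30:-30], x[30:-30], atol=1e-6)

    def test_100hz_sine_strongly_attenuated(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 100 * t)
        out = hb.oversmooth(x, order=3, frame_ms=23.0, fs=1000.0)
        assert np.abs(out[100:-100]).max() < 0.5

    def test_constant_unchanged(self):
        out = hb.oversmooth(np.full(200, 3.7), fs=1000.0)
        np.testing.assert_allclose(out, 3.7)

    def test_frame_not_exceeding_order_rejected(self):
        with pytest.raises(ValueError):
            hb.oversmooth(np.zeros(100), order=3, frame_ms=3.0, fs=1000.0)

    def test_frame_rounded_odd_at_other_rates(self):
        # 23 ms at 512 Hz -> 11.776 samples -> nearest odd frame, no error
        out = hb.oversmooth(np.zeros(256), order=3, frame_ms=23.0, fs=512.0)
        assert out.shape == (256,)


class TestAtrialBasis:
    def test_identical_epochs_rank_one(self):
        row = np.sin(np.arange(350) / 20.0)
        stack = hb.EpochStack(np.tile(row, (6, 1)), 1000.0, 349)
        basis = hb.build_atrial_basis(stack)
        assert basis.n == 1
        unit = row / np.linalg.norm(row)
        assert abs(abs(np.dot(basis.U_n[:, 0], unit)) - 1.0) < 1e-10

    def test_two_independent_shapes_rank_two(self):
        a = np.sin(np.arange(350) / 20.0)
        b = np.cos(np.arange(350) / 15.0)
        stack = hb.EpochStack(np.vstack([a, a, b, b]), 1000.0, 349)
        basis = hb.build_atrial_basis(stack)
        assert basis.n == 2

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(3)
        stack = hb.EpochStack(rng.standard_normal((12, 200)), 1000.0, 200)
        basis = hb.build_atrial_basis(stack, energy_rule=0.9)
        gram = basis.U_n.T @ basis.U_n
        np.testing.assert_allclose(gram, np.eye(basis.n), atol=1e-8)

    def test_rank_strictly_below_m(self):
        rng = np.random.default_rng(4)
        stack = hb.EpochStack(rng.standard_normal((5, 64)), 1000.0, 64)
        basis = hb.build_atrial_basis(stack, energy_rule=1.0)
        assert basis.n <= 4

    def test_all_zero_input_rejected(self):
        stack = hb.EpochStack(np.zeros((4, 64)), 1000.0, 64)
        with pytest.raises(ValueError, match="atrial subspace undefined"):
            hb.build_atrial_basis(stack)


def _random_basis(T=64, n=3, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((T, n)))
    s = np.linalg.svd(rng.standard_normal((T, n)), compute_uv=False)
    return hb.AtrialBasis(U_n=q, n=n, singular_values=s, energy_rule=0.99)


class TestProjector:
    def test_axis_projector_2d(self):
        basis = hb.AtrialBasis(
            U_n=np.array([[1.0], [0.0]]), n=1,
            singular_values=np.array([1.0]), energy_rule=0.99,
        )
        P = hb.projection_operator(basis)
        np.testing.assert_allclose(P, [[0.0, 0.0], [0.0, 1.0]], atol=1e-15)
        np.testing.assert_allclose(P @ np.array([3.0, 4.0]), [0.0, 4.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_projector_laws(self, seed):
        basis = _random_basis(seed=seed)
        P = hb.projection_operator(basis)
        assert np.abs(P @ basis.U_n).max() < 1e-10
        assert np.abs(P @ P - P).max() < 1e-10
        assert np.abs(P - P.T).max() < 1e-12

    def test_materialized_and_implicit_forms_agree(self):
        basis = _random_basis(T=128, n=4, seed=7)
        rng = np.random.default_rng(11)
        X = rng.standard_normal((6, 128))
        P = hb.projection_operator(basis)
        implicit = X - (X @ basis.U_n) @ basis.U_n.T
        np.testing.assert_allclose(X @ P, implicit, atol=1e-10)


class TestExtractHbs:
    def test_annihilates_epochs_in_span(self):
        basis = _random_basis(T=100, n=2, seed=1)
        coefs = np.array([[2.0, -1.0], [0.5, 3.0]])
        stack = hb.EpochStack(coefs @ basis.U_n.T, 1000.0, 100)
        out = hb.extract_hbs(stack, basis)
        assert np.abs(out.epochs).max() < 1e-8 * np.abs(stack.epochs).max()

    def test_projection_idempotent(self):
        basis = _random_basis(T=80, n=3, seed=2)
        rng = np.random.default_rng(5)
        stack = hb.EpochStack(rng.standard_normal((4, 80)), 1000.0, 80)
        once = hb.extract_hbs(stack, basis)
        twice = hb.extract_hbs(once, basis)
        np.testing.assert_allclose(twice.epochs, once.epochs, atol=1e-10)

    def test_linearity(self):
        basis = _random_basis(T=80, n=3, seed=3)
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 80))
        y = rng.standard_normal((1, 80))
        mix = hb.EpochStack(2.0 * x - 0.5 * y, 1000.0, 80)
        fx = hb.extract_hbs(hb.EpochStack(x, 1000.0, 80), basis).epochs
        fy = hb.extract_hbs(hb.EpochStack(y, 1000.0, 80), basis).epochs
        fmix = hb.extract_hbs(mix, basis).epochs
        np.testing.assert_allclose(fmix, 2.0 * fx - 0.5 * fy, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        basis = _random_basis(T=80, n=2)
        stack = hb.EpochStack(np.zeros((3, 90)), 1000.0, 90)
        with pytest.raises(ValueError, match="does not match"):
            hb.extract_hbs(stack, basis)

    def test_high_snr_extraction_correlates_with_reference(self, pipeline_28db):
        """Type 1 at 28 dB: mean correlation with the clean HBS >= 0.70."""
        cfg, stack, gt, template, spec, hbs = pipeline_28db
        lo = int(round(template.t1_ms / 1000.0 * cfg.fs))
        hi = int(round(template.t2_ms / 1000.0 * cfg.fs))
        rs = [
            hb.pearson_corr(row, gt.clean_hbs, window=(lo, hi))
            for row in hbs.epochs
        ]
        assert np.mean(rs) >= 0.70


class TestRunPipeline:
    def test_atrial_only_input_suppressed(self):
        cfg = hb.SimConfig(snr_db=np.inf, hbs_amp=0.0, n_epochs=10)
        stack, gt = hb.simulate_pr_epoch(cfg)
        tpl = hb.template_from_truth(stack, gt)
        out = hb.run_pipeline(stack, hb.build_threshold_spec(tpl))
        assert np.abs(out.epochs).max() < 0.05 * cfg.p_amp

    def test_noiseless_hbs_retained(self, noiseless_stack):
        cfg, stack, gt = noiseless_stack
        tpl = hb.template_from_truth(stack, gt)
        out = hb.run_pipeline(stack, hb.build_threshold_spec(tpl))
        lo = int(round(tpl.t1_ms / 1000.0 * cfg.fs))
        hi = int(round(tpl.t2_ms / 1000.0 * cfg.fs))
        peak = np.abs(out.epochs[0][lo:hi]).max()
        assert peak >= 0.5 * np.abs(gt.clean_hbs).max()

    def test_deterministic(self, noisy_stack_28db):
        cfg, stack, gt = noisy_stack_28db
        tpl = hb.template_from_truth(stack, gt)
        spec = hb.build_threshold_spec(tpl)
        a = hb.run_pipeline(stack, spec)
        b = hb.run_pipeline(stack, spec)
        np.testing.assert_array_equal(a.epochs, b.epochs)

    def test_stage_errors_carry_stage_name(self):
        cfg = hb.SimConfig(snr_db=10.0, n_epochs=2, seed=0)
        stack, gt = hb.simulate_pr_epoch(cfg)
        tpl = hb.template_from_truth(stack, gt)
        spec = hb.build_threshold_spec(tpl)
        short = hb.EpochStack(stack.epochs[:, :300], cfg.fs, 299)
        with pytest.raises(ValueError, match="IDWT stage"):
            hb.run_pipeline(short, spec)

    def test_atrial_suppression_ser_pattern(self, pipeline_28db):
        """Projection lowers P-band SER and raises His-band SER vs averaging."""
        cfg, stack, gt, template, spec, hbs = pipeline_28db
        avg = hb.signal_average(stack).samples
        raw = stack.epochs[0]
        ext = hbs.epochs[0]
        assert hb.ser(raw, ext, hb.P_WAVE_BAND, cfg.fs) < hb.ser(
            raw, avg, hb.P_WAVE_BAND, cfg.fs
        )
        assert hb.ser(raw, ext, hb.HBS_BAND, cfg.fs) > hb.ser(
            raw, avg, hb.HBS_BAND, cfg.fs
        )
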