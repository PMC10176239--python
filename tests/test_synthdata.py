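"""Generator correctness: signal closed forms, noise model, cohort structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label

from dtialps.synthdata import (
    CohortSpec,
    PhantomSpec,
    add_rician_noise,
    analytic_alps,
    generate_cohort,
    generate_phantom,
    generate_structural,
    gradient_table,
    ground_truth_tensors,
    phantom_layout,
    signal_from_tensors,
)


class TestDiffusionPhantom:
    def test_isotropic_phantom_signals_follow_closed_form(self):
        # fully isotropic medium: every b>0 signal is S0 * exp(-b * lambda)
        lam = 0.9e-3
        spec = PhantomSpec(
            grid_shape=(32, 32, 16),
            n_dirs_per_shell=12,
            n_b0=2,
            lambda_parallel=lam,
            lambda_perp=lam,
            d_background=lam,
            d_csf=lam,
            noise_sigma=0.0,
        )
        dwi, _, _ = generate_phantom(spec)
        expected = spec.S0 * np.exp(-dwi.bvals * lam)
        assert np.allclose(dwi.signal, expected[None, None, None, :], rtol=1e-12)

    def test_on_axis_signal_closed_form(self):
        # fiber along z probed along z: S = S0 * exp(-b * lambda_parallel)
        spec = PhantomSpec(
            grid_shape=(32, 32, 16), lambda_parallel=1.5e-3, lambda_perp=0.3e-3
        )
        D, layout = ground_truth_tensors(spec)
        g = np.array([[0.0, 0.0, 1.0]])
        b = np.array([1500.0])
        sig = signal_from_tensors(D, b, g, spec.S0)
        proj = layout.blocks["proj_left"]
        assert np.allclose(sig[proj], spec.S0 * np.exp(-1.5e-3 * 1500.0), rtol=1e-12)

    def test_perivascular_boost_read_back_from_ground_truth(self, fast_phantom):
        spec, _, truth, layout = fast_phantom
        for name, block in layout.blocks.items():
            np.testing.assert_allclose(
                truth.dxx[block], spec.lambda_perp + 0.3e-3, rtol=1e-12
            )

    def test_noise_free_signals_match_tensor_closed_form_everywhere(self, fast_phantom):
        spec, dwi, truth, _ = fast_phantom
        adc = np.einsum("...ij,vi,vj->...v", truth.tensors, dwi.bvecs, dwi.bvecs)
        np.testing.assert_allclose(dwi.signal, spec.S0 * np.exp(-dwi.bvals * adc), rtol=1e-9)

    def test_gradient_vectors_unit_norm_and_counted(self, fast_spec):
        bvals, bvecs = gradient_table(fast_spec)
        assert bvals.size == fast_spec.n_b0 + 2 * fast_spec.n_dirs_per_shell
        dw = bvals > 0
        np.testing.assert_allclose(np.linalg.norm(bvecs[dw], axis=1), 1.0, atol=1e-12)

    def test_phantom_determinism(self, fast_spec):
        spec = dataclasses.replace(fast_spec, noise_sigma=0.05, seed=9)
        a, _, _ = generate_phantom(spec)
        b, _, _ = generate_phantom(spec)
        assert np.array_equal(a.signal, b.signal)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(lambda_perp=0.0),
            dict(lambda_parallel=0.2e-3, lambda_perp=0.4e-3),
            dict(d_perivascular=-1e-4),
            dict(noise_sigma=-0.1),
            dict(n_b0=0),
            dict(grid_shape=(8, 8, 6)),  # too small for the ROI blocks
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad).validate()

    def test_layout_mirror_symmetric(self):
        layout = phantom_layout((40, 40, 20))
        flip = lambda m: m[::-1]
        assert np.array_equal(layout.blocks["proj_left"], flip(layout.blocks["proj_right"]))
        assert np.array_equal(layout.blocks["assoc_left"], flip(layout.blocks["assoc_right"]))
        assert np.array_equal(layout.ventricle, flip(layout.ventricle))


class TestRicianNoise:
    def test_converges_to_clean_signal_as_sigma_vanishes(self, rng):
        clean = np.full(2000, 100.0)
        for sigma, tol in [(1.0, 0.1), (0.01, 1e-3)]:
            noisy = add_rician_noise(clean, sigma, np.random.default_rng(0))
            assert np.abs(noisy - clean).max() < 6 * sigma + tol

    def test_rician_bias_raises_mean_at_high_sigma(self):
        # magnitude noise has positive bias: E[M] > S, pronounced at low SNR
        clean = np.full(20000, 10.0)
        noisy = add_rician_noise(clean, 30.0, np.random.default_rng(1))
        assert noisy.mean() > clean.mean() + 10


class TestStructuralPhantom:
    def test_zero_tubules_empty_truth_mask(self, fast_spec):
        pair = generate_structural(fast_spec, 0, seed=1)
        assert not pair.pvs_truth_mask.any()

    def test_tubule_count_matches_connected_components(self, fast_spec):
        pair = generate_structural(fast_spec, 12, seed=5, noise_sigma=0.0)
        _, n = label(pair.pvs_truth_mask, connectivity=3, return_num=True)
        assert n == 12

    def test_determinism_bit_identical(self, fast_spec):
        a = generate_structural(fast_spec, 8, seed=3)
        b = generate_structural(fast_spec, 8, seed=3)
        assert np.array_equal(a.t1w, b.t1w)
        assert np.array_equal(a.t2w, b.t2w)
        assert np.array_equal(a.pvs_truth_mask, b.pvs_truth_mask)

    def test_tubules_inside_wm_and_csf_contrast(self, fast_spec):
        pair = generate_structural(fast_spec, 10, seed=2, noise_sigma=0.0)
        tm = pair.pvs_truth_mask
        assert not (tm & ~pair.wm_mask).any()
        wm_bg = pair.wm_mask & ~tm
        assert pair.t1w[tm].mean() < pair.t1w[wm_bg].mean()  # dark on T1w
        assert pair.t2w[tm].mean() > pair.t2w[wm_bg].mean()  # bright on T2w


class TestCohort:
    def test_nfl_is_linear_in_parameters_without_noise(self):
        spec = CohortSpec(nfl_sd=0.0, nfl_b_alps=-100.0, nfl_b_age=0.0, seed=4)
        table, _ = generate_cohort(spec)
        pred = spec.nfl_intercept - 100.0 * table["alps_true"]
        clip = pred > 0.1  # generator floors NfL at a small positive value
        np.testing.assert_allclose(table.loc[clip, "nfl"], pred[clip], rtol=1e-12)
        # two subjects differing by +0.1 in the ALPS parameter differ by -10 in NfL
        t = table[clip]
        d_nfl = np.diff(t["nfl"]) / np.diff(t["alps_true"])
        np.testing.assert_allclose(d_nfl[np.isfinite(d_nfl)], -100.0, rtol=1e-9)

    def test_no_effect_spec_gives_zero_expected_group_difference(self):
        spec = CohortSpec(
            n_tbi=400,
            n_control=400,
            group_alps_means={"TBI": 1.35, "control": 1.35},
            age_slope_alps=0.0,
            age_range_control=(19.0, 85.0),
            seed=11,
        )
        table, _ = generate_cohort(spec)
        tbi = table[table.group == "TBI"]["alps_true"]
        ctl = table[table.group == "control"]["alps_true"]
        se = np.sqrt(tbi.var() / len(tbi) + ctl.var() / len(ctl))
        assert abs(tbi.mean() - ctl.mean()) < 4 * se

    def test_study_scale_sample_sizes(self):
        table, specs = generate_cohort(CohortSpec(n_tbi=37, n_control=13, seed=0))
        assert len(table) == 50
        assert (table.group == "TBI").sum() == 37
        assert (table.group == "control").sum() == 13
        assert len(specs) == 50

    def test_pure_function_of_spec_and_seed(self):
        a, _ = generate_cohort(CohortSpec(seed=7))
        b, _ = generate_cohort(CohortSpec(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_group_fields_respect_missingness_contract(self):
        table, _ = generate_cohort(CohortSpec(seed=1))
        ctl = table[table.group == "control"]
        assert ctl["days_since_injury"].isna().all()
        assert ctl["gcs"].isna().all()

    def test_phantom_specs_encode_glymphatic_parameter(self):
        table, specs = generate_cohort(CohortSpec(seed=2))
        base = PhantomSpec()
        for (_, row), ps in zip(table.iterrows(), specs):
            expected = max(row["alps_true"] - 1.0, 0.0) * base.lambda_perp
            assert ps.d_perivascular == pytest.approx(expected, rel=1e-12)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_tbi=1).validate()
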