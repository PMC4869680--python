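"""Design construction, GLM inversion, model-based and model-free scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpr.basis import BasisSet, make_basis_set
from hpr.exceptions import MissingConditionError
from hpr.glm import (
    build_design,
    condition_mean_epoch,
    convolve_impulses,
    estimate,
    reconstruct_response,
    score_model_based,
    score_model_free,
)
from hpr.hp_series import FilterSpec, TrialEpoch, apply_filter


def trials_df(onsets, types, reinforced=None, soa=3.5):
    n = len(onsets)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": 4.0,
            "trial_type": types,
            "reinforced": reinforced if reinforced is not None else [0] * n,
            "soa": soa,
        }
    )


def make_epoch(values, condition="cs_plus", reinforced=False, fs=10.0):
    return TrialEpoch(values=np.asarray(values, dtype=float), fs=fs,
                      condition=condition, reinforced=reinforced, soa=3.5, onset=0.0)


class TestBuildDesign:
    def test_single_onset_column_equals_basis(self):
        bset = make_basis_set("G1")
        trials = trials_df([0.0], ["cs_plus"])
        d = build_design(trials, bset, n_samples=110, fs=10.0)
        assert d.column_meta == (("cs_plus", "canonical"),)
        assert np.allclose(d.X[:, 0], bset.functions[0].samples)

    def test_non_overlapping_onsets_sum_linearly(self):
        bset = make_basis_set("G1")
        d = build_design(trials_df([0.0, 18.0], ["cs_plus", "cs_plus"]), bset,
                         n_samples=400, fs=10.0)
        col = d.X[:, 0]
        assert np.allclose(col[:110], bset.functions[0].samples)
        assert np.allclose(col[180:290], bset.functions[0].samples)
        assert np.allclose(col[110:180], 0.0)

    def test_randomized_schedule_matches_direct_summation(self, rng):
        """Engine linearity/time-invariance: column == sum_i h(t - t_i)."""
        bset = make_basis_set("G2")
        n, fs = 3000, 10.0
        onsets = np.sort(rng.uniform(0, 250, 40))
        onsets = np.round(onsets * fs) / fs
        trials = trials_df(onsets, ["cs_plus"] * 40)
        d = build_design(trials, bset, n_samples=n, fs=fs)
        for j, f in enumerate(bset.functions):
            direct = np.zeros(n)
            for t in onsets:
                i = int(round(t * fs))
                seg = f.samples[: n - i]
                direct[i : i + seg.size] += seg
            assert np.max(np.abs(d.X[:, j] - direct)) < 1e-10

    def test_reinforced_trials_become_nuisance_columns(self):
        bset = make_basis_set("G1")
        trials = trials_df([0.0, 20.0, 40.0], ["cs_plus", "cs_plus", "cs_minus"],
                           reinforced=[0, 1, 0])
        d = build_design(trials, bset, n_samples=600, fs=10.0)
        conds = [c for c, _ in d.column_meta]
        assert conds == ["cs_plus", "cs_minus", "nuisance_reinforced", "nuisance_us"]
        d2 = build_design(trials, bset, n_samples=600, fs=10.0, nuisance_reinforced=False)
        assert [c for c, _ in d2.column_meta] == ["cs_plus", "cs_minus"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_impulse_convolution_linearity(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(size=30)
        a = rng.integers(0, 150, size=5)
        b = rng.integers(0, 150, size=7)
        both = convolve_impulses(np.r_[a, b], h, 200)
        separate = convolve_impulses(a, h, 200) + convolve_impulses(b, h, 200)
        assert np.allclose(both, separate, atol=1e-12)


class TestEstimate:
    def test_orthonormal_design_gives_projection(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(60, 3)))
        from hpr.glm import DesignMatrix

        d = DesignMatrix(X=q, column_meta=(("cs_plus", "canonical"),) * 3, fs=10.0)
        y = rng.normal(size=60)
        est = estimate(d, y)
        assert np.allclose(est.beta, q.T @ y, atol=1e-12)

    def test_noiseless_recovery(self, rng):
        bset = make_basis_set("G2")
        trials = trials_df([5.0, 30.0, 55.0], ["cs_plus", "cs_minus", "cs_plus"])
        d = build_design(trials, bset, n_samples=800, fs=10.0)
        beta_true = np.array([3.0, -1.0, 1.5, 0.5])
        est = estimate(d, d.X @ beta_true)
        assert np.allclose(est.beta, beta_true, atol=1e-8)

    def test_normal_equations_oracle(self, rng):
        from hpr.glm import DesignMatrix

        X = rng.normal(size=(80, 4))
        y = rng.normal(size=80)
        d = DesignMatrix(X=X, column_meta=(("cs_plus", "canonical"),) * 4, fs=10.0)
        beta = estimate(d, y).beta
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(beta - oracle)) / np.max(np.abs(oracle)) < 1e-8

    def test_filter_commutes_with_noiseless_model(self):
        """Filtering design columns like the data keeps recovery exact."""
        bset = make_basis_set("G2")
        spec = FilterSpec(0.015, 0.5)
        fs, n = 10.0, 1200
        trials = trials_df([10.0, 40.0, 70.0, 95.0],
                           ["cs_plus", "cs_minus", "cs_plus", "cs_minus"])
        raw = build_design(trials, bset, n_samples=n, fs=fs)
        beta_true = np.array([2.0, 0.7, 0.5, -0.2])
        y = apply_filter(raw.X @ beta_true, spec, fs)
        filt = build_design(trials, bset, n_samples=n, fs=fs, filter_spec=spec)
        est = estimate(filt, y)
        assert np.allclose(est.beta, beta_true, atol=1e-6)


class TestScoreModelBased:
    def test_single_component_scales_with_beta(self, canonical):
        bset = make_basis_set("G1")
        trials = trials_df([0.0], ["cs_plus"])
        d = build_design(trials, bset, n_samples=110, fs=10.0)
        est = estimate(d, 4.0 * d.X[:, 0])
        score = score_model_based(est, bset)["cs_plus"]
        assert score == pytest.approx(4.0 * np.max(canonical.samples[20:110]), abs=1e-8)

    def test_negative_response_scores_negative(self):
        bset = make_basis_set("G1")
        d = build_design(trials_df([0.0], ["cs_plus"]), bset, n_samples=110, fs=10.0)
        est = estimate(d, -2.5 * d.X[:, 0])
        assert score_model_based(est, bset)["cs_plus"] == pytest.approx(
            -2.5 * np.max(bset.functions[0].samples[20:110]), abs=1e-8
        )

    def test_matches_exhaustive_scan(self, rng):
        bset = make_basis_set("G2")
        d = build_design(trials_df([0.0], ["cs_plus"]), bset, n_samples=110, fs=10.0)
        y = d.X @ np.array([2.0, 5.0]) + rng.normal(0, 0.1, 110)
        est = estimate(d, y)
        score = score_model_based(est, bset)["cs_plus"]
        recon = reconstruct_response(est, bset, "cs_plus")
        window = recon[20:110]
        best = max(range(window.size), key=lambda i: (abs(window[i]), -i))
        assert score == pytest.approx(window[best], abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_basis_recombination_invariance(self, seed):
        """Invertible recombination of basis functions leaves reconstructed
        responses, hence scores, unchanged."""
        rng = np.random.default_rng(seed)
        bset = make_basis_set("G2")
        M = rng.normal(size=(2, 2))
        if abs(np.linalg.det(M)) < 0.1:
            M += np.eye(2)
        from dataclasses import replace as dc_replace

        mixed_funcs = tuple(
            dc_replace(f, samples=sum(M[i, j] * g.samples for j, g in enumerate(bset.functions)))
            for i, f in enumerate(bset.functions)
        )
        mixed = BasisSet(functions=mixed_funcs, model_id="G2")
        trials = trials_df([3.0, 25.0], ["cs_plus", "cs_minus"])
        n, fs = 500, 10.0
        y = rng.normal(0, 1, n)
        d1 = build_design(trials, bset, n, fs)
        d2 = build_design(trials, mixed, n, fs)
        s1 = score_model_based(estimate(d1, y), bset)
        s2 = score_model_based(estimate(d2, y), mixed)
        for cond in s1:
            assert s1[cond] == pytest.approx(s2[cond], abs=1e-8)


class TestScoreModelFree:
    def test_constant_epoch_all_methods_agree(self):
        epochs = [make_epoch(np.full(110, 5.0), c) for c in ("cs_plus", "cs_minus")]
        for m in ("P1", "P2", "P3"):
            assert score_model_free(epochs, m)["cs_plus"] == pytest.approx(5.0)

    def test_signed_versus_positive_peak(self):
        v = np.zeros(110)
        v[30] = -8.0  # 3 s
        v[60] = 4.0  # 6 s
        epochs = [make_epoch(v, "cs_plus"), make_epoch(np.zeros(110), "cs_minus")]
        assert score_model_free(epochs, "P1")["cs_plus"] == -8.0
        assert score_model_free(epochs, "P2")["cs_plus"] == 4.0

    def test_p3_is_mean_of_two_to_eight(self):
        v = np.arange(110, dtype=float)
        epochs = [make_epoch(v, "cs_plus"), make_epoch(v, "cs_minus")]
        assert score_model_free(epochs, "P3")["cs_plus"] == pytest.approx(v[20:80].mean())

    def test_reinforced_trials_excluded(self):
        epochs = [
            make_epoch(np.full(110, 2.0), "cs_plus"),
            make_epoch(np.full(110, 100.0), "cs_plus", reinforced=True),
            make_epoch(np.zeros(110), "cs_minus"),
        ]
        assert score_model_free(epochs, "P3")["cs_plus"] == pytest.approx(2.0)

    def test_missing_condition_raises(self):
        with pytest.raises(MissingConditionError):
            score_model_free([make_epoch(np.zeros(110), "cs_plus")], "P1")

    def test_condition_mean_is_plain_average(self):
        epochs = [make_epoch(np.full(110, v), "cs_minus") for v in (1.0, 3.0)]
        assert np.allclose(condition_mean_epoch(epochs, "cs_minus"), 2.0)
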