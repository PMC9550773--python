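"""PARAFAC/ALS, core consistency, fixed-mode fitting, BIC and comparison."""

import numpy as np
import pytest

from hierpc.decomp import (
    bic,
    compare_models,
    congruence,
    corcondia,
    fit_fixed_contrast,
    grid_search,
    parafac,
)
from hierpc.pcmodel import MODEL_2LEVEL, ScalingFactors, within_contrast_profile
from hierpc.synthetic import model_contrast_tensor, random_rank_tensor


def match_congruences(est, true):
    """Best-permutation congruence of estimated vs generating loadings."""
    k = true.shape[1]
    out = []
    used = set()
    for r in range(k):
        cands = [(congruence(est[:, s], true[:, r]), s) for s in range(k) if s not in used]
        c, s = max(cands)
        used.add(s)
        out.append(c)
    return out


class TestParafac:
    def test_rank1_exact_recovery(self):
        x, loadings = random_rank_tensor((12, 40, 8), k=1, seed=0)
        fm = parafac(x, k=1, seed=0)
        for est, true in zip((fm.a, fm.b, fm.c), loadings):
            assert congruence(est[:, 0], true[:, 0]) > 0.999
        assert fm.rss < 1e-8 * np.sum(x**2)

    def test_rank2_recovery_up_to_permutation(self):
        x, loadings = random_rank_tensor((15, 60, 10), k=2, seed=1)
        fm = parafac(x, k=2, seed=0)
        for est, true in zip((fm.a, fm.b, fm.c), loadings):
            assert min(match_congruences(est, true)) > 0.99

    @pytest.mark.parametrize("init", ["svd", "dtld", "random"])
    def test_inits_reach_exact_fit(self, init):
        x, _ = random_rank_tensor((10, 30, 6), k=2, seed=3)
        fm = parafac(x, k=2, init=init, seed=4)
        assert fm.rss < 1e-6 * np.sum(x**2)

    def test_rss_nesting_in_k(self):
        x, _ = random_rank_tensor((10, 30, 6), k=2, noise=0.1, seed=5)
        r1 = parafac(x, k=1, seed=0).rss
        r2 = parafac(x, k=2, seed=0).rss
        assert r2 <= r1 + 1e-9

    def test_als_rss_monotone(self):
        x, _ = random_rank_tensor((10, 30, 6), k=2, noise=0.3, seed=6)
        fm = parafac(x, k=2, init="random", seed=7)
        hist = np.array(fm.rss_history)
        assert (np.diff(hist) <= 1e-9 * hist[0]).all()

    def test_deterministic_given_seed(self):
        x, _ = random_rank_tensor((10, 30, 6), k=2, noise=0.2, seed=8)
        a = parafac(x, k=2, init="random", seed=9)
        b = parafac(x, k=2, init="random", seed=9)
        assert np.array_equal(a.a, b.a) and np.array_equal(a.b, b.b) and np.array_equal(a.c, b.c)

    def test_sign_convention(self):
        x, _ = random_rank_tensor((10, 30, 6), k=2, seed=10)
        fm = parafac(x, k=2, seed=0)
        for col in fm.a.T:
            assert col[np.argmax(np.abs(col))] > 0
        assert np.allclose(np.linalg.norm(fm.a, axis=0), 1.0)


class TestCorcondia:
    def test_exact_rank2_is_100(self):
        x, _ = random_rank_tensor((12, 50, 8), k=2, seed=11)
        fm = parafac(x, k=2, seed=0)
        assert corcondia(x, fm) == pytest.approx(100.0, abs=0.5)

    def test_single_component_is_100_by_construction(self):
        x, _ = random_rank_tensor((12, 50, 8), k=2, noise=0.3, seed=12)
        fm = parafac(x, k=1, seed=0)
        assert corcondia(x, fm) == pytest.approx(100.0, abs=1e-6)

    def test_overfactoring_drops_consistency(self):
        x, _ = random_rank_tensor((12, 50, 8), k=2, noise=0.05, seed=13)
        fm2 = parafac(x, k=2, seed=0)
        fm3 = parafac(x, k=3, seed=0)
        assert corcondia(x, fm2) > 95.0
        assert corcondia(x, fm3) < 80.0


@pytest.fixture(scope="module")
def profile_and_tensor(designs8):
    prof = within_contrast_profile(designs8, ScalingFactors(s0=0.3, s1=1.2, s2=1.0))
    x, a, b = model_contrast_tensor(prof.values, n_channels=12, n_tf=200, noise=0.05, seed=14)
    return prof, x


class TestFixedContrast:
    def test_true_profile_matches_free_fit(self, profile_and_tensor):
        prof, x = profile_and_tensor
        fixed = fit_fixed_contrast(x, prof.values.T)
        free = parafac(x, k=2, seed=0)
        assert fixed.rss <= 1.05 * free.rss
        assert np.array_equal(fixed.c, prof.values.T)  # bit-identical fixed mode

    def test_shuffled_profile_fits_worse(self, profile_and_tensor, rng):
        prof, x = profile_and_tensor
        true_rss = fit_fixed_contrast(x, prof.values.T).rss
        shuffled = prof.values.T[rng.permutation(prof.values.shape[1])]
        assert fit_fixed_contrast(x, shuffled).rss > 1.5 * true_rss

    def test_fixed_never_beats_free(self, profile_and_tensor, designs8):
        prof, x = profile_and_tensor
        free = parafac(x, k=2, seed=0).rss
        other = within_contrast_profile(designs8, ScalingFactors(s0=0.8, s1=0.4, s2=1.8))
        assert fit_fixed_contrast(x, other.values.T).rss >= free - 1e-9

    def test_collinear_profiles_rejected(self):
        c = np.ones((16, 2))
        x = np.zeros((4, 10, 16))
        with pytest.raises(ValueError, match="collinear"):
            fit_fixed_contrast(x, c)


class TestGridSearch:
    def test_grid_restricted_to_generating_point(self, designs8):
        f = ScalingFactors(s0=0.3, s1=1.2, s2=1.0)
        prof = within_contrast_profile(designs8, f)
        x, _, _ = model_contrast_tensor(prof.values, n_channels=10, n_tf=150, noise=0.05, seed=15)
        fit = grid_search(
            x, designs8, model_id=MODEL_2LEVEL, scope="within",
            grids={"s0": [0.3], "s1": [1.2], "s2": [1.0]},
        )
        assert fit.feasible
        assert fit.best_params == {"s0": 0.3, "s1": 1.2, "s2": 1.0}

    def test_generating_point_beats_neighbors(self, designs8):
        f = ScalingFactors(s0=0.3, s1=1.2, s2=1.0)
        prof = within_contrast_profile(designs8, f)
        x, _, _ = model_contrast_tensor(prof.values, n_channels=10, n_tf=150, noise=0.05, seed=16)
        fit = grid_search(
            x, designs8, model_id=MODEL_2LEVEL, scope="within",
            grids={"s0": [0.1, 0.3, 0.5], "s1": [0.8, 1.2, 1.6], "s2": [0.6, 1.0, 1.4]},
        )
        assert fit.best_params == {"s0": 0.3, "s1": 1.2, "s2": 1.0}
        assert fit.best_consistency > 80.0


class TestBic:
    # printed comparison-table cells: (u, w, RSS) -> BIC, natural log
    @pytest.mark.parametrize(
        "u, w, rss, expected",
        [
            (60 * 37500 * 16, (60 + 37500 + 16) * 2, 2.2013e5, -1.8219e8),
            (60 * 37500 * 16, (60 + 37500) * 2, 2.2068e5, -1.8210e8),
            (60 * 37500 * 24, (60 + 37500) * 3, 1.2911e6, -1.9960e8),
            (60 * 37500 * 24, (60 + 37500) * 1, 1.3433e6, -1.9880e8),
        ],
    )
    def test_reference_cells_to_four_significant_figures(self, u, w, rss, expected):
        assert bic(u, w, rss) == pytest.approx(expected, rel=5e-4)

    def test_no_parameter_limit(self):
        assert bic(100, 0, 50.0) == pytest.approx(100 * np.log(0.5))

    def test_penalty_monotone_in_w(self):
        assert bic(1000, 20, 5.0) > bic(1000, 10, 5.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bic(0, 1, 1.0)
        with pytest.raises(ValueError):
            bic(10, 1, 0.0)


def test_comparison_table_counts_match_printed_expressions(designs8):
    # model-free row: u = 60 x 37500 x 16 and w = (60 + 37500 + 16) * 2 —
    # checked on a reduced tensor with the same bookkeeping
    x, _ = random_rank_tensor((10, 200, 16), k=2, noise=0.2, seed=17)
    table = compare_models(
        x, designs8, "within", model_ids=("Model-free",),
    )
    row = table.iloc[0]
    assert row.u == 10 * 200 * 16
    assert row.w == (10 + 200 + 16) * 2
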