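import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from latentord import (
    HPDSummary,
    PosteriorChains,
    anchor,
    diagnostics,
    hpd_interval,
    hpd_region_2d,
    mean_hpd_width,
)
from latentord.posterior import align_rotation


def brute_force_hpd(samples, level):
    x = np.sort(samples)
    m = len(x)
    k = int(np.ceil(level * m))
    best = None
    for i in range(m - k + 1):
        w = x[i + k - 1] - x[i]
        if best is None or w < best[0] - 1e-15:
            best = (w, x[i], x[i + k - 1])
    return best[1], best[2]


def make_chains(Z, **extra):
    m, n, q = Z.shape
    draws = {
        "alpha": np.zeros((m, n)),
        "beta": np.zeros((m, n)),
        "Z": Z,
        "Theta": np.zeros((m, n, q)),
    }
    draws.update(extra)
    return PosteriorChains(draws=draws, family="binary", dims={"n": n, "p": n, "q": q, "K": 0})


class TestHPDInterval:
    def test_integer_grid_tie_break(self):
        lo, hi = hpd_interval(np.arange(100), level=0.95)
        assert (lo, hi) == (0.0, 94.0)

    def test_standard_normal_width(self):
        x = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(2 * 1.959964, abs=0.02)

    def test_exponential_interval_starts_at_zero(self):
        x = np.random.default_rng(1).exponential(size=1_000_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(0.0, abs=0.01)
        assert hi == pytest.approx(-np.log(0.05), abs=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(50), 0.95)

    @given(st.integers(0, 2**32 - 1))
    @hsettings(max_examples=30, deadline=None)
    def test_matches_window_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(100, 400))
        dist = rng.integers(3)
        x = [rng.standard_normal(m), rng.exponential(size=m), rng.integers(0, 10, m).astype(float)][dist]
        level = float(rng.uniform(0.5, 0.99))
        assert hpd_interval(x, level) == pytest.approx(brute_force_hpd(x, level))


class TestMeanHPDWidth:
    def test_degenerate_chain_zero_width(self):
        Z = np.tile(np.arange(6.0).reshape(3, 2), (120, 1, 1))
        s = mean_hpd_width(make_chains(Z))
        assert np.all(s.widths == 0)
        assert s.mean_width == 0

    def test_iid_normal_width(self):
        Z = np.random.default_rng(2).standard_normal((100_000, 3, 2))
        s = mean_hpd_width(make_chains(Z))
        assert s.mean_width == pytest.approx(3.92, abs=0.03)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((500, 4, 2))
        base = mean_hpd_width(make_chains(Z))
        Z2 = Z.copy()
        Z2[:, 1, 0] += 7.5  # constant shift of one coordinate across all draws
        shifted = mean_hpd_width(make_chains(Z2))
        np.testing.assert_allclose(base.widths, shifted.widths, atol=1e-12)

    def test_summary_frame_shape(self):
        Z = np.random.default_rng(4).standard_normal((200, 5, 2))
        df = mean_hpd_width(make_chains(Z)).to_frame()
        assert len(df) == 10
        assert set(df.columns) == {"site", "dimension", "lower", "upper", "width"}


class TestAnchor:
    def test_anchor_site_exactly_zero(self):
        Z = np.random.default_rng(5).standard_normal((300, 6, 2))
        a = anchor(make_chains(Z), 3)
        assert np.all(a.draws["Z"][:, 3, :] == 0.0)

    def test_common_shift_removed(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((300, 6, 2))
        shift = rng.standard_normal((300, 1, 2))
        a1 = anchor(make_chains(Z), 0)
        a2 = anchor(make_chains(Z + shift), 0)
        np.testing.assert_allclose(a1.draws["Z"], a2.draws["Z"], atol=1e-12)

    def test_constant_two_site_chain(self):
        Z = np.tile(np.array([[1.0, 1.0], [3.0, 2.0]]), (150, 1, 1))
        a = anchor(make_chains(Z), 0)
        np.testing.assert_allclose(a.draws["Z"][:, 1], [[2.0, 1.0]] * 150)

    def test_idempotent(self):
        Z = np.random.default_rng(7).standard_normal((200, 4, 2))
        once = anchor(make_chains(Z), 2)
        twice = anchor(once, 2)
        np.testing.assert_array_equal(once.draws["Z"], twice.draws["Z"])

    def test_widths_change_under_anchoring(self):
        # anchored widths measure relative uncertainty and differ from raw
        rng = np.random.default_rng(8)
        Z = rng.standard_normal((2000, 5, 2)) + rng.standard_normal((2000, 1, 2))
        raw = mean_hpd_width(make_chains(Z)).mean_width
        anchored = mean_hpd_width(anchor(make_chains(Z), 0)).mean_width
        assert abs(raw - anchored) > 0.1

    def test_bad_index(self):
        Z = np.random.default_rng(9).standard_normal((150, 3, 2))
        with pytest.raises(IndexError):
            anchor(make_chains(Z), 5)


class TestHPDRegion2D:
    def test_normal_ellipse_area(self):
        pts = np.random.default_rng(10).standard_normal((100_000, 2))
        reg = hpd_region_2d(pts, 0.95, method="normal_ellipse")
        assert reg["area"] == pytest.approx(np.pi * 5.991, rel=0.03)
        assert reg["fraction"] == pytest.approx(0.95, abs=0.02)
        evals = np.linalg.eigvalsh(reg["cov"])
        assert np.sqrt(evals[1] / evals[0]) == pytest.approx(1.0, abs=0.05)

    def test_kde_encloses_nominal_fraction(self):
        pts = np.random.default_rng(11).standard_normal((20_000, 2))
        reg = hpd_region_2d(pts, 0.95, method="kde")
        assert reg["fraction"] == pytest.approx(0.95, abs=0.02)
        assert len(reg["polygons"]) >= 1

    def test_methods_agree_on_gaussian_draws(self):
        pts = np.random.default_rng(12).multivariate_normal(
            [1.0, -2.0], [[2.0, 0.6], [0.6, 1.0]], size=100_000
        )
        a_kde = hpd_region_2d(pts, 0.95, "kde")["area"]
        a_ell = hpd_region_2d(pts, 0.95, "normal_ellipse")["area"]
        assert a_kde == pytest.approx(a_ell, rel=0.10)

    def test_degenerate_draws_fall_back(self):
        pts = np.zeros((500, 2))
        pts[:, 0] = np.random.default_rng(13).standard_normal(500)
        with pytest.warns(RuntimeWarning):
            reg = hpd_region_2d(pts, 0.95)
        assert reg["method"] == "box"


class TestDiagnostics:
    def test_iid_chain_is_clean(self):
        Z = np.random.default_rng(14).standard_normal((10_000, 2, 2))
        d = diagnostics(make_chains(Z))
        assert np.max(d["Z"]["rhat"]) < 1.01
        np.testing.assert_allclose(d["Z"]["ess"], 10_000, rtol=0.15)

    def test_split_halves_with_distinct_means_flagged(self):
        Z = np.random.default_rng(15).standard_normal((1000, 2, 2)) * 0.01
        Z[500:] += 5.0
        with pytest.warns(RuntimeWarning, match="Rhat"):
            d = diagnostics(make_chains(Z))
        assert np.max(d["Z"]["rhat"]) > 1.1


class TestAlignRotation:
    def test_alignment_preserves_configuration_product(self, binary_fit):
        _, _, chains = binary_fit
        al = align_rotation(chains)
        np.testing.assert_allclose(
            al.draws["Z"] @ np.transpose(al.draws["Theta"], (0, 2, 1)),
            chains.draws["Z"] @ np.transpose(chains.draws["Theta"], (0, 2, 1)),
            atol=1e-8,
        )

    def test_alignment_never_widens_mean_width(self, binary_fit):
        _, _, chains = binary_fit
        raw = mean_hpd_width(chains).mean_width
        aligned = mean_hpd_width(align_rotation(chains)).mean_width
        assert aligned <= raw + 1e-9


class TestSerialization:
    def test_round_trip_exact(self, binary_fit, tmp_path):
        _, _, chains = binary_fit
        path = tmp_path / "chains.npz"
        chains.save(path)
        back = PosteriorChains.load(path)
        assert back.family == chains.family
        assert back.dims == chains.dims
        for k in chains.draws:
            np.testing.assert_array_equal(back.draws[k], chains.draws[k])
        assert back.settings == chains.settings
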