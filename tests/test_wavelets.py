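"""Wavelet catalogue, packet decomposition and energy descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wavederm as wd
from wavederm.wavelets import FEATURE_LENGTH, N_BASES, QUADRANTS, feature_names


# --- independent reference: dense periodized convolve-then-decimate ---------

def analysis_1d(x, filt):
    """y[k] = sum_j filt[j] * x[(2k + L/2 - j) mod n]: circular convolution
    followed by decimation by two (filters in the catalogue have even length)."""
    n, L = len(x), len(filt)
    off = L // 2
    return np.array(
        [sum(filt[j] * x[(2 * k + off - j) % n] for j in range(L)) for k in range(n // 2)]
    )


def reference_dwt2(img, base):
    lo, hi = np.array(base.dec_lo), np.array(base.dec_hi)

    def separable(frow, fcol):
        tmp = np.array([analysis_1d(row, frow) for row in img])
        return np.array([analysis_1d(col, fcol) for col in tmp.T]).T

    return (
        separable(lo, lo),  # LL
        separable(lo, hi),  # LH
        separable(hi, lo),  # HL
        separable(hi, hi),  # HH
    )


# --- catalogue ---------------------------------------------------------------

class TestCatalogue:
    def test_exactly_53_bases(self):
        assert N_BASES == 53
        assert sorted(wd.WAVELET_CATALOGUE) == list(range(1, 54))

    @pytest.mark.parametrize(
        "wavelet_id, name, family",
        [
            (1, "haar", "Haar"),
            (2, "db1", "Daubechies"),
            (11, "db10", "Daubechies"),
            (12, "sym2", "Symlet"),
            (18, "sym8", "Symlet"),
            (19, "coif1", "Coiflet"),
            (23, "coif5", "Coiflet"),
            (24, "bior1.1", "Biorthogonal"),
            (26, "bior1.5", "Biorthogonal"),
            (38, "bior6.8", "Biorthogonal"),
            (39, "rbio1.1", "ReverseBiorthogonal"),
            (46, "rbio3.1", "ReverseBiorthogonal"),
            (53, "rbio6.8", "ReverseBiorthogonal"),
        ],
    )
    def test_id_name_map(self, wavelet_id, name, family):
        base = wd.get_wavelet_base(wavelet_id)
        assert base.name == name and base.family == family

    def test_haar_filter_coefficients(self):
        base = wd.get_wavelet_base(1)
        np.testing.assert_allclose(base.dec_lo, [1 / np.sqrt(2)] * 2, atol=1e-15)
        assert np.linalg.norm(base.dec_lo) == pytest.approx(1.0)

    @pytest.mark.parametrize("wavelet_id", [1, 4, 13, 21])
    def test_orthogonal_unit_norm_and_qmf(self, wavelet_id):
        base = wd.get_wavelet_base(wavelet_id)
        lo, hi = np.array(base.dec_lo), np.array(base.dec_hi)
        # published coefficient tables carry ~1e-11 rounding
        assert np.linalg.norm(lo) == pytest.approx(1.0, abs=1e-9)
        # quadrature mirror: hi[k] = (-1)^k lo[L-1-k] up to overall sign
        mirror = np.array([(-1) ** k * lo[len(lo) - 1 - k] for k in range(len(lo))])
        assert min(np.abs(hi - mirror).max(), np.abs(hi + mirror).max()) < 1e-12

    def test_rbio_swaps_analysis_and_synthesis(self):
        bior = wd.get_wavelet_base(31)  # bior3.1
        rbio = wd.get_wavelet_base(46)  # rbio3.1
        np.testing.assert_allclose(np.abs(bior.rec_lo), np.abs(rbio.dec_lo), atol=1e-12)

    @pytest.mark.parametrize("bad", [0, 54, -3])
    def test_out_of_range_id(self, bad):
        with pytest.raises(ValueError):
            wd.get_wavelet_base(bad)


# --- single decomposition step ----------------------------------------------

class TestDwt2Step:
    def test_constant_image_haar(self):
        ll, lh, hl, hh = wd.dwt2_step(np.full((4, 4), 3.0), wd.get_wavelet_base(1))
        np.testing.assert_allclose(ll, np.full((2, 2), 6.0), atol=1e-12)
        for band in (lh, hl, hh):
            np.testing.assert_allclose(band, 0.0, atol=1e-12)

    def test_checkerboard_energy_in_hh(self):
        img = wd.make_fixture_image("checkerboard", 4, 4, period=1)
        ll, lh, hl, hh = wd.dwt2_step(img, wd.get_wavelet_base(1))
        # mean goes to LL, the per-pixel alternation is pure diagonal detail
        np.testing.assert_allclose(ll, 255.0, atol=1e-10)
        np.testing.assert_allclose(lh, 0.0, atol=1e-10)
        np.testing.assert_allclose(hl, 0.0, atol=1e-10)
        assert np.abs(hh).max() > 100.0

    @pytest.mark.parametrize("wavelet_id", [1, 5, 26, 46])
    def test_matches_convolution_reference(self, wavelet_id):
        rng = np.random.default_rng(wavelet_id)
        img = rng.standard_normal((16, 16))
        base = wd.get_wavelet_base(wavelet_id)
        got = wd.dwt2_step(img, base)
        want = reference_dwt2(img, base)
        for g, w in zip(got, want):
            assert np.abs(g - w).max() < 1e-10

    @pytest.mark.parametrize("wavelet_id", [1, 7, 15, 20])
    def test_parseval_orthogonal(self, wavelet_id):
        rng = np.random.default_rng(wavelet_id + 100)
        img = rng.standard_normal((16, 16))
        bands = wd.dwt2_step(img, wd.get_wavelet_base(wavelet_id))
        total = sum(np.sum(b**2) for b in bands)
        assert total == pytest.approx(np.sum(img**2), rel=1e-8)

    @pytest.mark.parametrize("wavelet_id", range(1, 54))
    def test_perfect_reconstruction_all_bases(self, wavelet_id):
        rng = np.random.default_rng(wavelet_id + 200)
        img = rng.standard_normal((16, 16))
        base = wd.get_wavelet_base(wavelet_id)
        rec = wd.idwt2_step(wd.dwt2_step(img, base), base)
        assert np.abs(rec - img).max() < 1e-8


# --- full packet tree ---------------------------------------------------------

class TestWptDecompose:
    def test_depth3_node_counts(self):
        img = wd.make_fixture_image("ramp", 32, 32)
        nodes = wd.wpt_decompose(img, wd.get_wavelet_base(1), depth=3)
        assert len(nodes) == 85
        assert len(wd.internal_nodes(nodes, depth=3)) == 21
        assert sum(n.depth == 3 for n in nodes) == 64

    def test_depth1(self):
        nodes = wd.wpt_decompose(np.ones((8, 8)), wd.get_wavelet_base(1), depth=1)
        assert len(nodes) == 5

    def test_subimage_dimensions_halve(self):
        nodes = wd.wpt_decompose(np.ones((16, 16)), wd.get_wavelet_base(5), depth=3)
        for n in nodes:
            assert n.subimage.shape == (16 >> n.depth, 16 >> n.depth)

    def test_impulse_haar_one_nonzero_per_leaf(self):
        img = wd.make_fixture_image("impulse", 8, 8)
        nodes = wd.wpt_decompose(img, wd.get_wavelet_base(1), depth=2)
        for n in nodes:
            if n.depth == 2:
                assert np.count_nonzero(np.abs(n.subimage) > 1e-12) == 1

    def test_depth3_parseval_over_leaves(self):
        rng = np.random.default_rng(5)
        img = rng.standard_normal((16, 16))
        nodes = wd.wpt_decompose(img, wd.get_wavelet_base(9), depth=3)
        leaf_energy = sum(np.sum(n.subimage**2) for n in nodes if n.depth == 3)
        assert leaf_energy == pytest.approx(np.sum(img**2), rel=1e-6)


# --- branch features and the 252-vector ---------------------------------------

class TestBranchFeatures:
    @staticmethod
    def from_energies(energies):
        """Build four 1x1 children with the requested absolute-value sums."""
        return tuple(np.array([[e]]) for e in energies)

    def test_single_nonzero_energy(self):
        f = wd.branch_features(self.from_energies([8.0, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(f[:4], [8, 0, 0, 0])
        np.testing.assert_allclose(f[4:8], [1, 0, 0, 0])
        assert f[8] == pytest.approx(8.0 / 1e-12)
        np.testing.assert_allclose(f[9:], 0.0)

    def test_equal_energies(self):
        f = wd.branch_features(self.from_energies([2.0, 2.0, 2.0, 2.0]))
        np.testing.assert_allclose(f[4:8], 1.0)
        np.testing.assert_allclose(f[8:], 1.0 / 3.0)

    def test_all_zero_convention(self):
        np.testing.assert_array_equal(
            wd.branch_features(self.from_energies([0.0] * 4)), np.zeros(12)
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e6), min_size=4, max_size=4))
    def test_feature_invariants(self, energies):
        f = wd.branch_features(self.from_energies(energies))
        assert np.isfinite(f).all()
        assert len(f) == 12
        if max(energies) > 0:
            assert f[4:8].max() == pytest.approx(1.0)


class TestFeatureVector:
    def test_length_252(self):
        img = wd.make_fixture_image("ramp", 32, 32)
        assert len(wd.feature_vector(img, wd.get_wavelet_base(46))) == FEATURE_LENGTH == 252

    def test_constant_image_only_ll_lineage(self):
        """Zero detail energy everywhere: only the pure-LL branch survives."""
        fv = wd.feature_vector(np.full((32, 32), 7.0), wd.get_wavelet_base(1))
        fv = fv.reshape(21, 12)
        # branch 0 (root) and its LL-descendant branches carry energy only in child LL
        assert fv[0, 0] > 0 and np.allclose(fv[0, 1:4], 0.0)
        # branches whose parent path contains any detail quadrant are all-zero
        assert np.allclose(fv[2:5], 0.0)  # depth-1 LH, HL, HH branches

    def test_determinism(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32)) * 255
        base = wd.get_wavelet_base(26)
        np.testing.assert_array_equal(wd.feature_vector(img, base), wd.feature_vector(img, base))

    def test_branch_ordering_breadth_first(self):
        names = feature_names()
        assert names[0] == "branch0_e1" and names[11] == "branch0_fracr4"
        assert len(names) == 252

    def test_feature_matrix_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        imgs = [rng.random((16, 16)) for _ in range(3)]
        base = wd.get_wavelet_base(12)
        X = np.array([wd.feature_vector(i, base) for i in imgs])
        y = np.array([1, 0, 1])
        path = tmp_path / "features.csv"
        wd.write_feature_matrix(path, X, y)
        X2, y2 = wd.read_feature_matrix(path)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(y, y2)
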