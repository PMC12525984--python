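import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyspec.errors import PreprocessError
from canopyspec.grids import WavelengthGrid
from canopyspec.preprocess import (
    Preprocessor,
    PreprocessSpec,
    SpectraTable,
    msc,
    normalize,
    pca,
    savgol,
    snv,
)

RNG = np.random.default_rng(0)


class TestSNV:
    def test_small_example(self):
        out = snv(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 0.0, 1.0]])

    def test_rows_standardized(self):
        X = RNG.uniform(size=(20, 50))
        out = snv(X)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0)

    def test_idempotent(self):
        X = RNG.uniform(size=(5, 30))
        assert np.allclose(snv(snv(X)), snv(X))

    def test_zero_variance_row_named(self):
        X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(PreprocessError, match=r"\[1\]"):
            snv(X)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(-0.5, 0.5), b=st.floats(0.1, 3.0))
    def test_affine_invariance(self, a, b):
        """SNV output is exactly invariant to x -> a + b*x (b > 0)."""
        X = RNG.uniform(size=(3, 40))
        assert np.allclose(snv(a + b * X), snv(X), atol=1e-9)


class TestMSC:
    def test_exact_inversion_of_affine_scatter(self):
        r = RNG.uniform(0.1, 0.9, size=60)
        a = RNG.uniform(-0.1, 0.1, size=(8, 1))
        b = RNG.uniform(0.5, 1.5, size=(8, 1))
        X = a + b * r[None, :]
        assert np.allclose(msc(X, r), np.tile(r, (8, 1)))

    def test_reference_row_unchanged(self):
        r = RNG.uniform(size=40)
        assert np.allclose(msc(r[None, :], r), r)

    def test_fit_matches_normal_equations_oracle(self):
        r = RNG.uniform(size=30)
        X = RNG.uniform(size=(6, 30))
        out = msc(X, r)
        A = np.column_stack([np.ones(30), r])
        for i in range(6):
            (a_i, b_i), *_ = np.linalg.lstsq(A, X[i], rcond=None)
            assert np.allclose(out[i], (X[i] - a_i) / b_i)

    def test_zero_slope_rejected(self):
        r = np.linspace(0, 1, 20)
        X = np.sin(40 * np.pi * r)[None, :] * 0 + 0.5 + 0 * r
        # constant row: slope vs any reference is ~0
        with pytest.raises(PreprocessError):
            msc(X, r)


class TestSavgol:
    def test_second_derivative_of_quadratic_is_constant(self):
        k = np.arange(40.0)
        row = 1.5 + 0.3 * k + 0.25 * k ** 2
        out = savgol(row[None, :], window=11, polyorder=3, deriv=2)
        assert np.allclose(out, 2 * 0.25)

    def test_smoothing_leaves_constant_untouched(self):
        row = np.full((1, 30), 0.7)
        assert np.allclose(savgol(row, 11, 2, 0), 0.7)

    def test_smoothing_reduces_noise_variance(self):
        noise = np.random.default_rng(1).normal(size=(1000, 80))
        out = savgol(noise, 11, 2, 0)
        assert out.var() < noise.var()

    def test_parameter_validation(self):
        X = np.zeros((1, 30))
        with pytest.raises(PreprocessError):
            savgol(X, window=10, polyorder=2)
        with pytest.raises(PreprocessError):
            savgol(X, window=5, polyorder=7)


class TestNormalize:
    def test_examples(self):
        assert np.allclose(normalize(np.array([[2.0, 4.0, 6.0]]), "range"),
                           [[0.0, 0.5, 1.0]])
        X = RNG.uniform(0.1, 1.0, size=(10, 20))
        assert np.allclose(normalize(X, "max").max(axis=1), 1.0)
        assert np.allclose(normalize(X, "mean").mean(axis=1), 1.0)
        rn = normalize(X, "range")
        assert rn.min() >= 0.0 and rn.max() <= 1.0

    def test_degenerate_rows_rejected(self):
        with pytest.raises(PreprocessError, match="range"):
            normalize(np.full((1, 5), 3.0), "range")
        with pytest.raises(PreprocessError, match="max"):
            normalize(np.zeros((1, 5)), "max")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(-0.5, 0.5), b=st.floats(0.1, 3.0))
    def test_range_norm_affine_invariance(self, a, b):
        X = RNG.uniform(size=(3, 25))
        assert np.allclose(normalize(a + b * X, "range"),
                           normalize(X, "range"), atol=1e-9)


class TestPCA:
    def test_rank_one_data(self):
        direction = RNG.uniform(size=12)
        X = 0.3 + np.outer(RNG.normal(size=15), direction)
        _, _, frac = pca(X, 3)
        assert frac[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        X = RNG.uniform(size=(10, 6))
        scores, loadings, _ = pca(X, 6)
        assert np.allclose(scores @ loadings.T, X - X.mean(axis=0))
        assert np.allclose(loadings.T @ loadings, np.eye(6), atol=1e-10)

    def test_fractions_match_eigendecomposition_oracle(self):
        X = RNG.uniform(size=(10, 6))
        _, _, frac = pca(X, 5)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(frac, (eig / eig.sum())[:5])
        assert np.all(np.diff(frac) <= 1e-12)

    def test_component_bound(self):
        with pytest.raises(ValueError):
            pca(RNG.uniform(size=(5, 6)), 5)     # > N-1


class TestOperatorsAreRowIndependent:
    @pytest.mark.parametrize("op", [
        snv,
        lambda X: normalize(X, "range"),
        lambda X: savgol(X, 7, 2, 0),
    ])
    def test_row_permutation_commutes(self, op):
        X = RNG.uniform(size=(8, 30)) + 0.1
        perm = np.random.default_rng(2).permutation(8)
        assert np.allclose(op(X)[perm], op(X[perm]))


class TestPreprocessorChain:
    def test_msc_reference_frozen_on_calibration(self):
        Xcal = RNG.uniform(size=(10, 25)) + 0.2
        pre = Preprocessor(["msc"]).fit(Xcal)
        ref = pre.specs[0].reference
        assert np.allclose(ref, Xcal.mean(axis=0))
        # applying to new data uses the frozen reference, not its own mean
        Xnew = RNG.uniform(size=(4, 25)) + 0.5
        assert np.allclose(pre.transform(Xnew), msc(Xnew, ref))

    def test_chain_serialization_roundtrip(self):
        Xcal = RNG.uniform(size=(10, 25)) + 0.2
        pre = Preprocessor([PreprocessSpec("sg_smooth", window=7),
                            PreprocessSpec("msc")]).fit(Xcal)
        clone = Preprocessor.from_dict(pre.to_dict())
        Xnew = RNG.uniform(size=(3, 25)) + 0.3
        assert np.allclose(pre.transform(Xnew), clone.transform(Xnew))

    def test_unfitted_chain_rejected(self):
        with pytest.raises(PreprocessError):
            Preprocessor(["snv"]).transform(np.zeros((2, 5)))

    def test_sg_window_validation(self):
        with pytest.raises(PreprocessError):
            PreprocessSpec("sg_2nd", window=3)   # window <= polyorder


class TestSpectraTable:
    def _table(self):
        grid = WavelengthGrid(np.linspace(500, 900, 20))
        X = RNG.uniform(size=(6, 20))
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        split = np.array(["cal", "val", "test", "cal", "val", "test"])
        return SpectraTable(X, labels, split, grid)

    def test_csv_roundtrip(self, tmp_path):
        t = self._table()
        t.to_csv(tmp_path / "t.csv")
        back = SpectraTable.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.X, t.X)
        assert np.array_equal(back.labels, t.labels)
        assert np.array_equal(back.split, t.split)
        # the CSV header stores wavelengths at 0.1 nm print precision
        assert np.allclose(back.grid.wavelengths_nm,
                           np.round(t.grid.wavelengths_nm, 1))

    def test_invariants(self):
        t = self._table()
        with pytest.raises(ValueError):
            SpectraTable(t.X * np.nan, t.labels, t.split, t.grid)
        with pytest.raises(ValueError):
            SpectraTable(t.X, t.labels[:3], t.split, t.grid)


def test_cube_table_consistency(grid, calibrated_scene, banded_scene):
    """Preprocess-then-extract equals extract-then-preprocess, because
    every operator acts per spectrum."""
    from canopyspec.imaging import PlantMask, apply_mask, extract_roi_spectra

    truth = banded_scene["truth_mask"]
    cube = apply_mask(calibrated_scene, PlantMask(truth))
    table = extract_roi_spectra(cube, n_rois=4, roi_size=1, seed=3)
    direct = snv(table.X)
    # pixel-wise preprocessing of the cube, then the same 1-px extraction
    flat = cube.data[truth]
    pre_cube = cube.data.copy()
    pre_cube[truth] = snv(flat)
    from canopyspec.imaging import ReflectanceCube
    cube2 = ReflectanceCube(pre_cube, grid, mask=PlantMask(truth))
    table2 = extract_roi_spectra(cube2, n_rois=4, roi_size=1, seed=3)
    assert np.allclose(table2.X, direct)
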