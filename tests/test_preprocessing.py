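import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beanspec.preprocessing import (
    PreprocessingChain,
    baseline,
    detrend,
    msc,
    normalize,
    parse_chain,
    savgol_derivative,
    snv,
)

rows_strategy = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=8, max_size=8
).filter(lambda r: np.std(r) > 1e-3)


class TestSNV:
    def test_worked_example(self):
        np.testing.assert_allclose(snv(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])

    @given(row=rows_strategy)
    @settings(deadline=None, max_examples=50)
    def test_output_standardized(self, row):
        out = snv(np.array([row]))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=1) - 1) < 1e-9

    @given(row=rows_strategy, a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_affine_invariance(self, row, a, b):
        x = np.array([row])
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-6)

    def test_constant_row_error_names_row(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        with pytest.raises(ValueError, match="row 1"):
            snv(X)


class TestMSC:
    def test_reference_row_unchanged(self):
        ref = np.array([0.1, 0.5, 0.9, 0.3])
        np.testing.assert_allclose(msc(ref[None, :], ref), ref[None, :])

    def test_exact_scatter_recovery(self):
        ref = np.array([0.1, 0.5, 0.9, 0.3])
        row = 2.0 * ref + 0.5
        np.testing.assert_allclose(msc(row[None, :], ref), ref[None, :], atol=1e-12)

    def test_reduces_scatter_variance(self, lib256):
        """On scatter-perturbed copies of one spectrum MSC shrinks the
        between-row spread."""
        rng = np.random.default_rng(3)
        base = lib256.mixture({"water": 0.1, "lipid": 0.15, "matrix": 0.75})
        X = rng.normal(1, 0.1, (30, 1)) * base + rng.normal(0, 0.05, (30, 1))
        corrected = msc(X, X.mean(axis=0))
        assert corrected.std(axis=0).mean() < X.std(axis=0).mean() / 5

    def test_orthogonal_spectrum_error(self):
        ref = np.array([1.0, -1.0, 1.0, -1.0])
        flatish = np.array([[1.0, 1.0, 1.0, 1.0 + 1e-15]])
        with pytest.raises(ValueError, match="orthogonal"):
            msc(flatish, ref)


class TestSavgol:
    def test_linear_ramp_gives_constant_slope(self):
        x = (0.37 * np.arange(32))[None, :]
        out = savgol_derivative(x, order=1, window=9, polyorder=2)
        np.testing.assert_allclose(out, 0.37, atol=1e-10)

    def test_quadratic_second_derivative_constant(self):
        t = np.arange(32, dtype=float)
        x = (1.5 * t ** 2 + 2 * t + 3)[None, :]
        out = savgol_derivative(x, order=2, window=11, polyorder=2)
        np.testing.assert_allclose(out, 3.0, atol=1e-8)

    def test_constant_row_first_derivative_zero(self):
        out = savgol_derivative(np.full((1, 20), 7.0), order=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(window=4), dict(window=9, polyorder=9), dict(order=3),
        dict(order=2, polyorder=1),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            savgol_derivative(np.zeros((1, 20)), **kwargs)


class TestSimpleSteps:
    def test_detrend_kills_quadratic(self):
        t = np.arange(16, dtype=float)
        x = (0.2 * t ** 2 - t + 4)[None, :]
        np.testing.assert_allclose(detrend(x, degree=2), 0.0, atol=1e-9)

    def test_normalize_worked_example(self):
        np.testing.assert_allclose(normalize(np.array([[3.0, 4.0]])), [[0.6, 0.8]])

    def test_normalize_zero_row_error(self):
        with pytest.raises(ValueError):
            normalize(np.zeros((1, 4)))

    def test_baseline_subtracts_minimum(self):
        out = baseline(np.array([[2.0, 5.0, 3.0]]))
        np.testing.assert_allclose(out, [[0.0, 3.0, 1.0]])


class TestChain:
    def test_mean_center_state_reused_at_transform(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6))
        chain = parse_chain("mean_center").fit(X)
        np.testing.assert_allclose(chain.transform(X).mean(axis=0), 0.0, atol=1e-12)
        # a new batch is centered by the *fitted* means, not its own
        Xnew = rng.normal(loc=3.0, size=(4, 6))
        out = chain.transform(Xnew)
        np.testing.assert_allclose(out, Xnew - X.mean(axis=0))

    def test_single_row_equals_batch_row(self, lib256):
        rng = np.random.default_rng(1)
        X = rng.normal(1, 0.1, (12, 1)) * lib256.mixture(
            {"water": 0.1, "matrix": 0.9}
        ) + rng.normal(0, 0.01, (12, lib256.band_grid.size))
        for spec in ("snv", "msc", "savgol:1", "snv,savgol:1,mean_center"):
            chain = parse_chain(spec).fit(X)
            batch = chain.transform(X)
            single = chain.transform(X[3])
            np.testing.assert_allclose(single, batch[3], atol=1e-10, err_msg=spec)

    def test_transform_requires_fit(self):
        with pytest.raises(RuntimeError):
            parse_chain("snv").transform(np.ones((2, 5)))

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError):
            PreprocessingChain([("wavelet", {})])

    def test_parse_chain_specs(self):
        chain = parse_chain("snv,savgol:2")
        assert chain.names == ["snv", "savgol_derivative"]
        assert chain.steps[1][1]["order"] == 2
        assert chain.steps[1][1]["window"] == 11
        assert parse_chain("log1r").names == ["none"]
        assert parse_chain(None).spec_string() == "none"

    def test_scatter_removal_brings_spectra_closer_to_truth(self, lib256):
        """SNV-treated scatter-on spectra deviate less from the treated
        noiseless mixture than raw spectra do from the raw mixture."""
        rng = np.random.default_rng(5)
        clean = lib256.mixture({"water": 0.11, "lipid": 0.14, "matrix": 0.75})
        X = rng.normal(1, 0.07, (40, 1)) * clean + rng.normal(0, 0.03, (40, 1))
        rms_raw = np.sqrt(((X - clean) ** 2).mean())
        chain = parse_chain("snv").fit(X)
        rms_snv = np.sqrt(((chain.transform(X) - snv(clean[None, :])[0]) ** 2).mean())
        # compare on comparable scales: normalize by the spread of the target
        assert rms_snv / np.std(snv(clean[None, :])) < rms_raw / np.std(clean)
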