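"""Distribution classification, normalization and binarization of
expression data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logiprofile.expression import (
    DistributionStats,
    ExpressionConfig,
    ExpressionMatrix,
    GeneDistributionFit,
    admissibility_filter,
    bimodality_index,
    binarize_gene,
    classify_gene,
    dip_statistic,
    dip_test,
    excess_kurtosis,
    normalize_bimodal,
    normalize_unimodal,
    normalize_zero_inflated,
    process_matrix,
)
from logiprofile.fixtures import CohortSpec, UnimodalSpec, generate_expression_cohort


def _oracle_samples():
    """Regenerate the samples whose dip statistics were frozen against an
    independent reference implementation (draw order matters)."""
    rng = np.random.default_rng(777)
    return {
        "normal_n200": rng.normal(size=200),
        "uniform_n151": rng.random(151),
        "bimodal_n300": np.concatenate(
            [rng.normal(0, 1, 150), rng.normal(6, 1, 150)]
        ),
        "exp_ties_n97": np.round(rng.exponential(size=97), 2),
    }


class TestDipStatistic:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("normal_n200", 0.020230877076419393),
            ("uniform_n151", 0.038717022257188934),
            ("bimodal_n300", 0.09874612588179768),
            ("exp_ties_n97", 0.028718703976435934),
        ],
    )
    def test_frozen_reference_values(self, name, expected):
        x = _oracle_samples()[name]
        assert dip_statistic(x) == pytest.approx(expected, abs=1e-12)

    def test_small_sample_conventions(self):
        assert dip_statistic([3.0]) == 0.0
        assert dip_statistic([5.0, 5.0, 5.0, 5.0]) == 0.0
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25)
        assert dip_statistic([0.0, 0.5, 1.0]) == pytest.approx(1.0 / 6.0)

    def test_location_scale_invariance(self):
        x = _oracle_samples()["bimodal_n300"]
        d = dip_statistic(x)
        assert dip_statistic(3.0 * x - 7.0) == pytest.approx(d, abs=1e-12)

    def test_pvalue_separates_unimodal_from_bimodal(self):
        samples = _oracle_samples()
        _, p_uni = dip_test(samples["normal_n200"])
        _, p_bim = dip_test(samples["bimodal_n300"])
        assert p_uni > 0.2
        assert p_bim < 0.001

    def test_pvalue_deterministic(self):
        x = _oracle_samples()["normal_n200"]
        assert dip_test(x) == dip_test(x)


class TestMomentStatistics:
    def test_uniform_excess_kurtosis(self):
        # evenly spaced grid has the population uniform kurtosis in the limit
        x = np.linspace(0, 1, 20001)
        assert excess_kurtosis(x) == pytest.approx(-1.2, abs=1e-3)

    def test_two_point_excess_kurtosis_exact(self):
        assert excess_kurtosis([0, 0, 1, 1]) == pytest.approx(-2.0, abs=1e-12)

    def test_normal_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(8).normal(size=20000)
        assert excess_kurtosis(x) == pytest.approx(0.0, abs=0.1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            excess_kurtosis([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            excess_kurtosis([2.0, 2.0, 2.0, 2.0])

    def test_bimodality_index_recovers_balanced_separated_mixture(self):
        """π = 0.5 and separation δ = |μ2−μ1|/σ = 4 give BI = 0.5·4 = 2."""
        rng = np.random.default_rng(123)
        x = np.concatenate([rng.normal(0, 1, 1500), rng.normal(4, 1, 1500)])
        bi, mu1, mu2, sigma, pi = bimodality_index(x)
        assert bi == pytest.approx(2.0, abs=0.15)
        assert mu1 == pytest.approx(0.0, abs=0.15)
        assert mu2 == pytest.approx(4.0, abs=0.15)
        assert pi == pytest.approx(0.5, abs=0.05)
        assert np.sqrt(pi * (1 - pi)) * (mu2 - mu1) / sigma == pytest.approx(bi)

    def test_bimodality_index_low_for_single_gaussian(self):
        x = np.random.default_rng(5).normal(10, 2, 2000)
        bi, *_ = bimodality_index(x)
        assert bi < 1.0

    def test_constant_sample_degenerates_to_zero(self):
        bi, mu1, mu2, sigma, pi = bimodality_index(np.full(50, 3.0))
        assert (bi, sigma) == (0.0, 0.0)


class TestAdmissibility:
    def test_flat_and_mostly_zero_genes_fail(self):
        rng = np.random.default_rng(0)
        n = 100
        df = pd.DataFrame(
            {
                "LIVE": rng.normal(10, 2, n),
                "FLAT": np.full(n, 5.0),
                "NEARFLAT": 5.0 + rng.normal(0, 1e-4, n),
                "SPARSE": np.concatenate([np.zeros(97), [8.0, 9.0, 10.0]]),
            }
        ).T
        out = admissibility_filter(df)
        assert bool(out.loc["LIVE", "admissible"])
        assert not out.loc["FLAT", "admissible"]
        assert not out.loc["NEARFLAT", "admissible"]
        assert not out.loc["SPARSE", "admissible"]  # 3% nonzero < 5%

    def test_amplitude_threshold_is_relative_to_cohort_median(self):
        rng = np.random.default_rng(1)
        rows = {f"G{i}": rng.normal(10, 2, 60) for i in range(9)}
        rows["SMALL"] = 5.0 + 0.01 * rng.random(60)  # amplitude ~0.01 << median
        out = admissibility_filter(pd.DataFrame(rows).T)
        assert not out.loc["SMALL", "admissible"]
        assert out.loc[[f"G{i}" for i in range(9)], "admissible"].all()


class TestClassification:
    def test_separated_mixture_called_bimodal(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(2, 1, 300), rng.normal(8, 1, 300)])
        fit = classify_gene(x, "g")
        assert fit.category == "bimodal"
        assert fit.mu1 == pytest.approx(2.0, abs=0.3)
        assert fit.mu2 == pytest.approx(8.0, abs=0.3)
        assert fit.stats.dip_pvalue < 0.05
        assert fit.stats.bimodality_index > 1.5
        assert fit.stats.excess_kurtosis < 1.0

    def test_gaussian_called_unimodal_with_sigmoid_parameters(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10, 2, 500)
        fit = classify_gene(x, "g")
        assert fit.category == "unimodal"
        assert fit.median == pytest.approx(float(np.median(x)))
        assert fit.mad == pytest.approx(
            float(np.median(np.abs(x - np.median(x))))
        )
        assert fit.lam == pytest.approx(np.log(3.0) / fit.mad)

    def test_zero_inflated_called_by_low_density_peak(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(2.0, 400)
        x[rng.random(400) < 0.7] = 0.0
        fit = classify_gene(x, "g")
        assert fit.category == "zero_inflated"
        assert fit.q1 == pytest.approx(float(np.quantile(x, 0.01)))
        assert fit.q99 == pytest.approx(float(np.quantile(x, 0.99)))

    def test_mad_zero_falls_back_to_scaled_iqr(self):
        """More than half the values tie at the median, so MAD = 0 and the
        slope falls back to IQR/1.349."""
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [np.full(52, 10.0), np.full(5, 9.0), 10.0 + rng.uniform(0.2, 2.0, 43)]
        )
        fit = classify_gene(x, "g")
        assert fit.category == "unimodal"
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        assert fit.mad == pytest.approx(iqr / 1.349)

    def test_tiny_or_flat_samples_discarded(self):
        assert classify_gene(np.arange(5.0), "g").category == "discarded"
        assert classify_gene(np.full(50, 2.0), "g").category == "discarded"


def _unimodal_fit(median=0.0, mad=1.0):
    return GeneDistributionFit(
        gene="g",
        category="unimodal",
        stats=DistributionStats(amplitude=1.0, fraction_nonzero=1.0),
        median=median,
        mad=mad,
        lam=float(np.log(3.0) / mad),
    )


class TestNormalization:
    def test_sigmoid_anchors_at_median_plus_minus_mad(self):
        fit = _unimodal_fit(median=7.0, mad=2.5)
        norm = normalize_unimodal([7.0 + 2.5, 7.0, 7.0 - 2.5], fit)
        assert norm[0] == pytest.approx(0.75, abs=1e-12)
        assert norm[1] == pytest.approx(0.5, abs=1e-12)
        assert norm[2] == pytest.approx(0.25, abs=1e-12)

    def test_sigmoid_strictly_increasing_and_bounded(self):
        fit = _unimodal_fit()
        x = np.linspace(-20, 20, 1001)
        norm = normalize_unimodal(x, fit)
        assert np.all(np.diff(norm) > 0)
        assert np.all((norm > 0) & (norm < 1))
        # far in the tails the sigmoid saturates but stays within [0, 1]
        extreme = normalize_unimodal([-1e6, 1e6], fit)
        assert extreme[0] >= 0.0 and extreme[1] <= 1.0

    def test_bimodal_posteriors_sum_to_one(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(2, 1, 300), rng.normal(8, 1, 300)])
        fit = classify_gene(x, "g")
        upper = normalize_bimodal(x, fit)
        # independent posterior computation from the mixture densities
        from scipy.stats import norm as gaussian

        d1 = fit.pi * gaussian.pdf(x, fit.mu1, fit.sigma)
        d2 = (1 - fit.pi) * gaussian.pdf(x, fit.mu2, fit.sigma)
        assert upper == pytest.approx(d2 / (d1 + d2), abs=1e-9)
        assert np.all((upper >= 0) & (upper <= 1))

    def test_balanced_mixture_posterior_half_at_midpoint(self):
        fit = GeneDistributionFit(
            gene="g",
            category="bimodal",
            stats=DistributionStats(amplitude=1.0, fraction_nonzero=1.0),
            mu1=2.0,
            mu2=8.0,
            sigma=1.0,
            pi=0.5,
        )
        assert normalize_bimodal([5.0], fit)[0] == pytest.approx(0.5, abs=1e-12)
        assert np.all(np.diff(normalize_bimodal(np.linspace(0, 10, 101), fit)) > 0)

    def test_zero_inflated_rescaling_and_clipping(self):
        fit = GeneDistributionFit(
            gene="g",
            category="zero_inflated",
            stats=DistributionStats(amplitude=1.0, fraction_nonzero=0.5),
            q1=1.0,
            q99=9.0,
        )
        norm = normalize_zero_inflated([0.0, 1.0, 5.0, 9.0, 20.0], fit)
        assert norm == pytest.approx([0.0, 0.0, 0.5, 1.0, 1.0])

    def test_category_mismatch_rejected(self):
        fit = _unimodal_fit()
        with pytest.raises(ValueError):
            normalize_bimodal([0.0], fit)


@settings(derandomize=True, max_examples=50)
@given(
    shift=st.floats(-100, 100),
    scale=st.floats(0.01, 100),
    x=st.floats(-20, 20),
)
def test_sigmoid_normalization_affine_equivariance(shift, scale, x):
    """Applying x → a·x + b to both the data point and the fitted location/
    spread leaves the normalized value unchanged."""
    base = _unimodal_fit(median=1.0, mad=2.0)
    moved = _unimodal_fit(median=1.0 * scale + shift, mad=2.0 * scale)
    a = normalize_unimodal([x], base)[0]
    b = normalize_unimodal([x * scale + shift], moved)[0]
    assert a == pytest.approx(b, abs=1e-9)


class TestBinarization:
    def test_tail_thresholds_and_missing_middle(self):
        fit = _unimodal_fit(median=0.0, mad=1.0)
        # median ± MAD normalize to exactly 0.75/0.25 — on the thresholds
        out = binarize_gene([1.0, 0.0, -1.0, 5.0, -5.0], fit, tau=0.25)
        assert out[0] == 1.0 and out[2] == 0.0
        assert np.isnan(out[1])
        assert out[3] == 1.0 and out[4] == 0.0

    def test_bimodal_binarization_has_no_missing(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(2, 1, 300), rng.normal(8, 1, 300)])
        fit = classify_gene(x, "g")
        out = binarize_gene(x, fit)
        assert set(np.unique(out)) <= {0.0, 1.0}
        # posterior > 0.5 exactly when above the equal-density boundary
        assert out.mean() == pytest.approx(0.5, abs=0.06)

    def test_invalid_tau_rejected(self):
        fit = _unimodal_fit()
        with pytest.raises(ValueError):
            binarize_gene([0.0], fit, tau=0.6)


class TestMatrixPipeline:
    def test_synthetic_cohort_classes_recovered(self):
        from logiprofile.fixtures import default_cohort_spec

        matrix, truth = generate_expression_cohort(
            default_cohort_spec(n_samples=400, n_per_class=5, seed=9)
        )
        norm, binr, fits = process_matrix(matrix)
        agree = sum(fits[g].category == truth[g] for g in truth)
        assert agree / len(truth) >= 0.8
        assert norm.shape[1] == 400
        assert ((norm.to_numpy() >= 0) & (norm.to_numpy() <= 1)).all()
        vals = binr.to_numpy()
        assert np.isin(vals[~np.isnan(vals)], [0.0, 1.0]).all()

    def test_discarded_genes_absent_from_outputs(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"LIVE": rng.normal(10, 2, 100), "FLAT": np.full(100, 4.0)}
        ).T
        with pytest.warns(UserWarning, match="discarded"):
            norm, binr, fits = process_matrix(df)
        assert list(norm.index) == ["LIVE"]
        assert fits["FLAT"].category == "discarded"

    def test_reference_mode_fits_on_healthy_applies_to_tumor(self):
        rng = np.random.default_rng(15)
        ref_cols = [f"N{i}" for i in range(100)]
        tum_cols = [f"T{i}" for i in range(80)]
        # healthy centered at 10; tumors shifted up, so reference-anchored
        # normalization should call most tumor samples high
        vals = np.concatenate([rng.normal(10, 1, 100), rng.normal(14, 1, 80)])
        df = pd.DataFrame({"G": vals}, index=ref_cols + tum_cols).T
        matrix = ExpressionMatrix(values=df, reference_samples=ref_cols)
        norm, binr, fits = process_matrix(matrix, mode="reference")
        assert list(norm.columns) == tum_cols
        ref_median = float(np.median(vals[:100]))
        assert fits["G"].median == pytest.approx(ref_median)
        assert (norm.loc["G"] > 0.5).mean() > 0.95

    def test_reference_mode_requires_reference_samples(self):
        df = pd.DataFrame(
            {"G": np.random.default_rng(0).normal(10, 1, 50)}
        ).T
        with pytest.raises(ValueError, match="reference"):
            process_matrix(ExpressionMatrix(values=df), mode="reference")

    def test_negative_expression_rejected(self):
        df = pd.DataFrame({"G": [-1.0, 2.0, 3.0]}).T
        with pytest.raises(ValueError, match="nonnegative"):
            ExpressionMatrix(values=df)
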