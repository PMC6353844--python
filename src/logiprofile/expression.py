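"""Expression-distribution classification, normalization and binarization.

Each gene's cross-cohort expression distribution is classified as bimodal,
unimodal or zero-inflated (after an admissibility filter dropping flat or
almost-all-zero genes), and then mapped to [0, 1]:

* bimodal genes — posterior probability of the upper component of an
  equal-variance two-Gaussian mixture fit;
* unimodal genes — logistic (sigmoid) transform centered on the median with
  slope λ = ln(3)/MAD, which maps median ± MAD to 0.75 / 0.25;
* zero-inflated genes — linear min–max rescaling over the [q1, q99]
  quantile range, clipped outside it.

Bimodality is called only when three criteria agree: Hartigan's dip test
(p < 0.05), the Bimodality Index of the mixture fit (BI > 1.5) and excess
kurtosis (K < 1).  Classification and fit parameters can be estimated
either on the whole cohort or on a flagged reference (healthy) subset and
then applied to the remaining samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from ._dip import dip_statistic, dip_test

__all__ = [
    "ExpressionMatrix",
    "ExpressionConfig",
    "DistributionStats",
    "GeneDistributionFit",
    "admissibility_filter",
    "dip_test",
    "dip_statistic",
    "bimodality_index",
    "excess_kurtosis",
    "classify_gene",
    "normalize_bimodal",
    "normalize_unimodal",
    "normalize_zero_inflated",
    "binarize_gene",
    "process_matrix",
]

Category = Literal["discarded", "bimodal", "unimodal", "zero_inflated"]


@dataclass
class ExpressionMatrix:
    """Genes × samples table of continuous nonnegative expression values,
    with an optional list of reference (healthy) sample labels."""

    values: pd.DataFrame
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.reference_samples) - set(self.values.columns)
        if missing:
            raise ValueError(f"reference samples not in matrix: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionConfig:
    """Tunable thresholds of the classification/normalization pipeline."""

    dip_alpha: float = 0.05
    bi_threshold: float = 1.5
    kurtosis_threshold: float = 1.0
    tau: float = 0.25  # binarization tail threshold for non-bimodal genes
    zero_peak_fraction: float = 0.1  # density mode within this low fraction of range
    amplitude_fraction: float = 0.1  # of median amplitude, admissibility
    min_nonzero_fraction: float = 0.05
    dip_n_boot: int = 2000
    dip_seed: int = 20230
    gmm_random_state: int = 0
    log2: bool = False  # apply log2(1+x) before processing


@dataclass
class DistributionStats:
    amplitude: float
    fraction_nonzero: float
    dip_stat: float | None = None
    dip_pvalue: float | None = None
    bimodality_index: float | None = None
    excess_kurtosis: float | None = None
    density_peak_location: float | None = None


@dataclass
class GeneDistributionFit:
    """Per-gene classification with the parameters of the fitted transform."""

    gene: str
    category: Category
    stats: DistributionStats
    # bimodal (equal-variance two-Gaussian) parameters, mu1 <= mu2
    mu1: float | None = None
    mu2: float | None = None
    sigma: float | None = None
    pi: float | None = None  # weight of the lower-mean component
    delta: float | None = None
    # unimodal parameters
    median: float | None = None
    mad: float | None = None
    lam: float | None = None
    # zero-inflated parameters
    q1: float | None = None
    q99: float | None = None
    vmin: float | None = None
    vmax: float | None = None


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def excess_kurtosis(values) -> float:
    """Fisher excess kurtosis (normal → 0; uniform → −1.2; symmetric
    two-point mass → −2)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("kurtosis requires at least 4 finite values")
    if np.var(x) == 0:
        raise ValueError("kurtosis undefined for zero-variance sample")
    return float(sps.kurtosis(x, fisher=True, bias=True))


def bimodality_index(values, random_state: int = 0):
    """Equal-variance two-Gaussian fit and Bimodality Index.

    Returns ``(BI, mu1, mu2, sigma, pi)`` with ``mu1 <= mu2`` and ``pi`` the
    weight of the lower-mean component; BI = sqrt(pi (1 − pi)) · |mu1 − mu2| / sigma.
    Degenerate data (fit failure or zero common variance) yields BI = 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("bimodality index requires at least 10 finite values")
    if np.ptp(x) == 0:
        return 0.0, float(x[0]), float(x[0]), 0.0, 1.0
    try:
        gm = GaussianMixture(
            n_components=2,
            covariance_type="tied",
            n_init=3,
            random_state=random_state,
        ).fit(x.reshape(-1, 1))
    except Exception:  # pragma: no cover - sklearn failure on pathological data
        return 0.0, float(np.mean(x)), float(np.mean(x)), float(np.std(x)), 1.0
    means = gm.means_.ravel()
    sigma = float(np.sqrt(gm.covariances_.ravel()[0]))
    order = np.argsort(means)
    mu1, mu2 = float(means[order[0]]), float(means[order[1]])
    pi = float(gm.weights_[order[0]])
    if sigma <= 0:
        return 0.0, mu1, mu2, sigma, pi
    delta = abs(mu2 - mu1) / sigma
    bi = float(np.sqrt(max(pi * (1.0 - pi), 0.0)) * delta)
    return bi, mu1, mu2, sigma, pi


def _density_peak(values) -> float:
    """Location of the global mode of a Gaussian-kernel density estimate."""
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        return float(x[0])
    kde = sps.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


# ---------------------------------------------------------------------------
# Admissibility and classification
# ---------------------------------------------------------------------------


def admissibility_filter(
    matrix: ExpressionMatrix | pd.DataFrame,
    config: ExpressionConfig | None = None,
) -> pd.DataFrame:
    """Per-gene admissibility: a gene passes when its amplitude (max − min
    across the cohort) is at least one tenth of the median amplitude over
    all genes AND at least 5% of its values are non-zero.

    Returns a DataFrame indexed by gene with columns ``amplitude``,
    ``fraction_nonzero`` and boolean ``admissible``.
    """
    config = config or ExpressionConfig()
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("admissibility requires at least 2 samples")
    if df.shape[0] == 0:
        raise ValueError("empty expression matrix")
    arr = df.to_numpy(dtype=float)
    amplitude = np.nanmax(arr, axis=1) - np.nanmin(arr, axis=1)
    frac_nonzero = np.mean(arr != 0, axis=1)
    med_amp = float(np.median(amplitude))
    admissible = (amplitude >= config.amplitude_fraction * med_amp) & (
        frac_nonzero >= config.min_nonzero_fraction
    )
    return pd.DataFrame(
        {
            "amplitude": amplitude,
            "fraction_nonzero": frac_nonzero,
            "admissible": admissible,
        },
        index=df.index,
    )


def classify_gene(
    values,
    gene: str = "",
    config: ExpressionConfig | None = None,
    precomputed: DistributionStats | None = None,
) -> GeneDistributionFit:
    """Classify one admissible gene and populate its transform parameters.

    The gene is bimodal iff dip p < 0.05 AND BI > 1.5 AND K < 1; otherwise
    zero-inflated when the kernel-density mode lies within the lowest 10%
    of the observed value range, else unimodal.
    """
    config = config or ExpressionConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]

    amplitude = float(np.ptp(x)) if x.size else 0.0
    frac_nonzero = float(np.mean(x != 0)) if x.size else 0.0
    stats = precomputed or DistributionStats(
        amplitude=amplitude, fraction_nonzero=frac_nonzero
    )

    if x.size < 10 or amplitude == 0.0:
        return GeneDistributionFit(gene=gene, category="discarded", stats=stats)

    stats.dip_stat, stats.dip_pvalue = dip_test(
        x, n_boot=config.dip_n_boot, seed=config.dip_seed
    )
    bi, mu1, mu2, sigma, pi = bimodality_index(x, random_state=config.gmm_random_state)
    stats.bimodality_index = bi
    stats.excess_kurtosis = excess_kurtosis(x)

    fit = GeneDistributionFit(gene=gene, category="unimodal", stats=stats)
    if (
        stats.dip_pvalue < config.dip_alpha
        and bi > config.bi_threshold
        and stats.excess_kurtosis < config.kurtosis_threshold
    ):
        fit.category = "bimodal"
        fit.mu1, fit.mu2, fit.sigma, fit.pi = mu1, mu2, sigma, pi
        fit.delta = abs(mu2 - mu1) / sigma if sigma > 0 else 0.0
        return fit

    peak = _density_peak(x)
    stats.density_peak_location = peak
    if peak - x.min() <= config.zero_peak_fraction * amplitude:
        fit.category = "zero_inflated"
        fit.q1 = float(np.quantile(x, 0.01))
        fit.q99 = float(np.quantile(x, 0.99))
        fit.vmin = float(x.min())
        fit.vmax = float(x.max())
        if fit.q99 <= fit.q1:
            fit.category = "discarded"
        return fit

    fit.median = float(np.median(x))
    mad = float(np.median(np.abs(x - fit.median)))
    if mad == 0.0:
        # robust fallback when more than half the values tie at the median
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        mad = iqr / 1.349
    if mad == 0.0:
        fit.category = "discarded"
        return fit
    fit.mad = mad
    fit.lam = float(np.log(3.0) / mad)
    return fit


# ---------------------------------------------------------------------------
# Normalization transforms
# ---------------------------------------------------------------------------


def normalize_bimodal(values, fit: GeneDistributionFit) -> np.ndarray:
    """Posterior probability of membership in the upper-mean component of
    the equal-variance two-Gaussian fit (the two posteriors sum to 1)."""
    if fit.category != "bimodal":
        raise ValueError("fit is not bimodal")
    x = np.asarray(values, dtype=float)
    # Equal variances make the log posterior ratio linear in x:
    #   log P(M1|x)/P(M0|x) = log((1-pi)/pi) + (mu2-mu1)(x - (mu1+mu2)/2)/sigma^2
    slope = (fit.mu2 - fit.mu1) / fit.sigma**2
    with np.errstate(over="ignore"):
        logit = np.log((1.0 - fit.pi) / fit.pi) + slope * (x - 0.5 * (fit.mu1 + fit.mu2))
        return 1.0 / (1.0 + np.exp(-logit))


def normalize_unimodal(values, fit: GeneDistributionFit) -> np.ndarray:
    """Sigmoid transform 1/(1+exp(−λ(x − median))) with λ = ln(3)/MAD, so
    that median ± MAD map to 0.75 / 0.25."""
    if fit.category != "unimodal":
        raise ValueError("fit is not unimodal")
    x = np.asarray(values, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-fit.lam * (x - fit.median)))


def normalize_zero_inflated(values, fit: GeneDistributionFit) -> np.ndarray:
    """Linear rescaling over the [q1, q99] quantile range; values outside
    are clipped to 0 / 1, preserving the asymmetric original pattern."""
    if fit.category != "zero_inflated":
        raise ValueError("fit is not zero_inflated")
    x = np.asarray(values, dtype=float)
    return np.clip((x - fit.q1) / (fit.q99 - fit.q1), 0.0, 1.0)


def normalize_gene(values, fit: GeneDistributionFit) -> np.ndarray:
    if fit.category == "bimodal":
        return normalize_bimodal(values, fit)
    if fit.category == "unimodal":
        return normalize_unimodal(values, fit)
    if fit.category == "zero_inflated":
        return normalize_zero_inflated(values, fit)
    raise ValueError(f"cannot normalize a {fit.category} gene")


def binarize_gene(
    values, fit: GeneDistributionFit, tau: float = 0.25
) -> np.ndarray:
    """Binarize one gene: bimodal genes by upper-component posterior > 0.5;
    unimodal/zero-inflated genes by the tails of the normalized value
    (Norm ≥ 1 − τ → 1, Norm ≤ τ → 0, otherwise NaN for 'missing')."""
    if not 0.0 < tau <= 0.5:
        raise ValueError("tau must be in (0, 0.5]")
    norm = normalize_gene(values, fit)
    if fit.category == "bimodal":
        return (norm > 0.5).astype(float)
    out = np.full(norm.shape, np.nan)
    out[norm >= 1.0 - tau] = 1.0
    out[norm <= tau] = 0.0
    return out


# ---------------------------------------------------------------------------
# Whole-matrix pipeline
# ---------------------------------------------------------------------------


def process_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    mode: Literal["cohort", "reference"] = "cohort",
    config: ExpressionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, GeneDistributionFit]]:
    """Classify, normalize and binarize every gene of a cohort matrix.

    In ``cohort`` mode the classification and all fit parameters are
    estimated on all samples and applied to all samples.  In ``reference``
    mode they are estimated on the reference-flagged (healthy) samples only
    and applied to the non-reference (tumor) samples.

    Returns ``(normalized, binarized, fits)``; discarded genes are absent
    from the two matrices but present in ``fits`` with category
    ``"discarded"``.
    """
    config = config or ExpressionConfig()
    if isinstance(matrix, pd.DataFrame):
        matrix = ExpressionMatrix(values=matrix)
    df = matrix.values
    if config.log2:
        df = np.log2(1.0 + df)

    if mode == "reference":
        if not matrix.reference_samples:
            raise ValueError("reference mode requires at least one reference sample")
        fit_df = df[matrix.reference_samples]
        apply_df = df.drop(columns=matrix.reference_samples)
    elif mode == "cohort":
        fit_df = df
        apply_df = df
    else:
        raise ValueError(f"unknown mode {mode!r}")

    adm = admissibility_filter(fit_df, config)
    fits: dict[str, GeneDistributionFit] = {}
    norm_rows, bin_rows, kept = [], [], []
    for gene in df.index:
        row = adm.loc[gene]
        stats = DistributionStats(
            amplitude=float(row["amplitude"]),
            fraction_nonzero=float(row["fraction_nonzero"]),
        )
        if not row["admissible"]:
            fits[gene] = GeneDistributionFit(
                gene=gene, category="discarded", stats=stats
            )
            continue
        fit = classify_gene(
            fit_df.loc[gene].to_numpy(), gene=gene, config=config, precomputed=stats
        )
        fits[gene] = fit
        if fit.category == "discarded":
            continue
        x = apply_df.loc[gene].to_numpy(dtype=float)
        norm_rows.append(normalize_gene(x, fit))
        bin_rows.append(binarize_gene(x, fit, tau=config.tau))
        kept.append(gene)

    cols = apply_df.columns
    normalized = pd.DataFrame(norm_rows, index=kept, columns=cols)
    binarized = pd.DataFrame(bin_rows, index=kept, columns=cols)
    n_disc = sum(1 for f in fits.values() if f.category == "discarded")
    if n_disc:
        warnings.warn(
            f"{n_disc} of {len(fits)} genes discarded by admissibility/degeneracy",
            stacklevel=2,
        )
    return normalized, binarized, fits
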