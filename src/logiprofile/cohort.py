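"""Cohort-level analysis of personalized model simulations.

Simulates every patient's personalized settings on the shared model,
collects asymptotic phenotype probabilities (with the unpersonalized
wild-type model as reference), correlates them with external scores
(Spearman rank with bootstrap confidence intervals), and builds prognostic
groups by median split — per phenotype, and as the four-way combination of
two phenotypes (e.g., high/low Proliferation × high/low Apoptosis).  The
grouped survival table it exports is ready for any standard Kaplan–Meier /
log-rank / Cox routine; the survival tests themselves are delegated.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import LogicalModel, SimulationSettings
from .simulate import asymptotic_probabilities, simulate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "StratificationResult",
    "patient_seed",
    "simulate_cohort",
    "median_split",
    "correlate_with_score",
    "export_survival_groups",
    "plot_phenotype_densities",
]


@dataclass
class PhenotypeTable:
    """Patients × phenotypes matrix of asymptotic probabilities plus the
    wild-type (unpersonalized) reference probabilities."""

    values: pd.DataFrame
    wildtype: dict[str, float]
    strategy: str = ""
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)


@dataclass
class StratificationResult:
    """Median-split group labels: per-phenotype thresholds, per-patient
    high/low labels, and (for two phenotypes) the four-way combined label."""

    thresholds: dict[str, float]
    labels: pd.DataFrame
    group_sizes: dict[str, int]


def patient_seed(master_seed: int, patient: str) -> int:
    """Stable per-patient seed: a patient's simulation never depends on
    which other patients are in the cohort."""
    return (int(master_seed) ^ zlib.crc32(patient.encode("utf-8"))) % (2**31)


def simulate_cohort(
    model: LogicalModel,
    settings_map: dict[str, SimulationSettings],
    base_settings: SimulationSettings,
    phenotypes: list[str] | None = None,
    master_seed: int = 0,
    n_trajectories: int | None = None,
    strategy: str = "",
) -> PhenotypeTable:
    """Simulate all personalized settings and collect asymptotic phenotype
    probabilities.

    ``phenotypes`` defaults to the model's declared outputs.  A wild-type
    run of ``base_settings`` (seeded with the master seed) provides the
    reference row.  A failing patient simulation is recorded and skipped.
    """
    if phenotypes is None:
        phenotypes = list(model.declared_outputs)
    if not phenotypes:
        raise ValueError("no phenotype nodes specified or declared on the model")
    for ph in phenotypes:
        if ph not in model.nodes:
            raise ValueError(f"phenotype {ph!r} is not a model node")

    wt = base_settings.copy()
    wt.seed = int(master_seed) % (2**31)
    wt_result = asymptotic_probabilities(
        simulate_ensemble(model, wt, n_trajectories=n_trajectories)
    )
    wildtype = {ph: wt_result.nodes[ph] for ph in phenotypes}

    rows, failures = {}, {}
    for patient in sorted(settings_map):
        settings = settings_map[patient].copy()
        settings.seed = patient_seed(master_seed, patient)
        try:
            res = asymptotic_probabilities(
                simulate_ensemble(model, settings, n_trajectories=n_trajectories)
            )
            rows[patient] = [res.nodes[ph] for ph in phenotypes]
        except Exception as exc:  # pragma: no cover - defensive
            failures[patient] = str(exc)
            logger.warning("simulation failed for %s: %s", patient, exc)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=phenotypes)
    return PhenotypeTable(
        values=values, wildtype=wildtype, strategy=strategy, failures=failures
    )


def median_split(
    table: PhenotypeTable | pd.DataFrame,
    phenotypes: str | list[str],
) -> StratificationResult:
    """Group patients by the cohort median of each phenotype probability.

    Values strictly above the median are 'high', values at or below it are
    'low' (ties go to low).  With two phenotypes a combined label of the
    form ``high_P/low_A`` is added.
    """
    df = table.values if isinstance(table, PhenotypeTable) else table
    if df.shape[0] < 2:
        raise ValueError("median split requires at least 2 patients")
    if isinstance(phenotypes, str):
        phenotypes = [phenotypes]

    thresholds: dict[str, float] = {}
    labels = pd.DataFrame(index=df.index)
    for ph in phenotypes:
        col = df[ph]
        med = float(col.median())
        thresholds[ph] = med
        labels[ph] = np.where(col > med, "high", "low")
        if col.nunique() == 1:
            logger.warning("phenotype %s is constant; all patients in one group", ph)
    if len(phenotypes) == 2:
        p0, p1 = phenotypes
        labels["combined"] = (
            labels[p0] + "_" + p0 + "/" + labels[p1] + "_" + p1
        )
    sizes_col = labels["combined"] if "combined" in labels else labels[phenotypes[0]]
    group_sizes = sizes_col.value_counts().to_dict()
    return StratificationResult(
        thresholds=thresholds, labels=labels, group_sizes=group_sizes
    )


def correlate_with_score(
    table: PhenotypeTable | pd.DataFrame,
    phenotype: str,
    score,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation between a phenotype probability and an
    external per-patient score, with a percentile bootstrap 95% CI
    (``n_boot`` resamples, seeded)."""
    df = table.values if isinstance(table, PhenotypeTable) else table
    x = df[phenotype].to_numpy(dtype=float)
    y = np.asarray(score, dtype=float)
    if len(y) != len(x):
        raise ValueError(f"score length {len(y)} != number of patients {len(x)}")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 patients")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(x)
    with warnings.catch_warnings():
        # constant resamples yield NaN correlations; they are filtered below
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = sps.spearmanr(x[idx], y[idx]).statistic
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return rho, (float(lo), float(hi))


def export_survival_groups(
    stratification: StratificationResult,
    survival: pd.DataFrame,
    patient_col: str = "patient",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Join group labels onto a survival table.

    Returns a table (patient, time, event, one column per label) suitable
    for any log-rank/Cox routine.  Patients without survival rows are
    dropped with a logged count.
    """
    for col in (patient_col, time_col, event_col):
        if col not in survival.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    labels = stratification.labels.reset_index().rename(columns={"index": patient_col})
    merged = labels.merge(survival, on=patient_col, how="inner")
    n_missing = len(labels) - len(merged)
    if n_missing:
        logger.info("%d stratified patients had no survival data", n_missing)
    cols = [patient_col, time_col, event_col] + [
        c for c in stratification.labels.columns
    ]
    return merged[cols]


def plot_phenotype_densities(table: PhenotypeTable, path: str) -> None:
    """Kernel-density plot of each phenotype's probability distribution
    across the cohort, with the wild-type reference as a dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phenotypes = table.phenotypes
    fig, axes = plt.subplots(1, len(phenotypes), figsize=(5 * len(phenotypes), 4))
    if len(phenotypes) == 1:
        axes = [axes]
    for ax, ph in zip(axes, phenotypes):
        vals = table.values[ph].dropna()
        if vals.nunique() > 1:
            kde = sps.gaussian_kde(vals)
            grid = np.linspace(0, 1, 200)
            ax.plot(grid, kde(grid))
        ax.hist(vals, bins=20, range=(0, 1), density=True, alpha=0.3)
        ax.axvline(table.wildtype[ph], ls="--", color="k", label="wild type")
        ax.set_xlabel(f"P({ph})")
        ax.set_ylabel("density")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
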