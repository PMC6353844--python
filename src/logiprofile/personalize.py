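"""Per-patient tailoring of a generic logical model.

Two mechanisms specialize the generic model's simulation settings without
ever touching its rules:

* **Strict node variants** — a node with a confident discrete effect
  (e.g., from a mutation) is frozen: its initial value is set to the effect
  and the opposing transition rate is zeroed, permanently overriding the
  node's logical rule.
* **Soft node variants** — a node with a continuous normalized value
  ``norm`` keeps its rule but is biased toward it: the initial probability
  becomes ``norm`` and the transition rates become
  ``k_up = AF ** (2 (norm − 0.5))`` and ``k_down = 1 / k_up`` for an
  amplification factor AF (default 100), so norm = 1 gives k_up = 100 and
  k_down = 0.01.

Strategies name which data types feed each channel (the six standard
recipes combine mutations/CNA as strict variants with CNA/RNA/protein as
soft variants).  When a node receives candidates from several sources,
mutation-derived strict assignments beat CNA-derived ones beat binarized
expression; among soft values protein beats RNA beats CNA; a strict
assignment silences any soft candidate for that node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import pandas as pd

from .genomics import FunctionalEffect
from .model import LogicalModel, SimulationSettings

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNodeMapping",
    "PatientProfile",
    "PersonalizationStrategy",
    "STRATEGIES",
    "CohortData",
    "map_genes_to_nodes",
    "apply_strict_nv",
    "apply_soft_nv",
    "resolve_precedence",
    "build_patient_profile",
    "personalize_cohort",
]

_STRICT_PRECEDENCE = {"mutation": 0, "cna": 1, "rna_binarized": 2}
_SOFT_PRECEDENCE = {"protein": 0, "rna": 1, "cna": 2}


@dataclass
class GeneNodeMapping:
    """Correspondence table node → gene symbols (gene families allowed,
    e.g., AKT → AKT1, AKT2, AKT3)."""

    node_to_genes: dict[str, list[str]]

    def __post_init__(self):
        for node, genes in self.node_to_genes.items():
            if not genes:
                raise ValueError(f"node {node!r} maps to an empty gene list")

    def validate_against(self, model: LogicalModel) -> None:
        unknown = set(self.node_to_genes) - set(model.nodes)
        if unknown:
            raise ValueError(f"mapped nodes absent from model: {sorted(unknown)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneNodeMapping":
        """Build from a two-column (node, gene) table."""
        mapping: dict[str, list[str]] = {}
        for _, row in df.iterrows():
            mapping.setdefault(str(row.iloc[0]), []).append(str(row.iloc[1]))
        return cls(mapping)


@dataclass
class PatientProfile:
    """Resolved per-node assignments for one patient: ``strict`` holds
    frozen 0/1 values with their data-type tag, ``soft`` holds normalized
    values in [0, 1].  A node never appears in both."""

    patient: str
    strict: dict[str, tuple[int, str]] = field(default_factory=dict)
    soft: dict[str, tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.strict) & set(self.soft)
        if overlap:
            raise ValueError(f"nodes assigned both strictly and softly: {sorted(overlap)}")


@dataclass(frozen=True)
class PersonalizationStrategy:
    """Which data types feed the strict and soft channels."""

    name: str
    strict_sources: tuple[str, ...]
    soft_sources: tuple[str, ...]
    amplification_factor: float = 100.0

    def __post_init__(self):
        if self.amplification_factor <= 1:
            raise ValueError("amplification_factor must be > 1")
        for src in self.strict_sources:
            if src not in _STRICT_PRECEDENCE:
                raise ValueError(f"unknown strict data type {src!r}")
        for src in self.soft_sources:
            if src not in _SOFT_PRECEDENCE:
                raise ValueError(f"unknown soft data type {src!r}")

    @property
    def required_data_types(self) -> set[str]:
        req = set(self.strict_sources) | set(self.soft_sources)
        return {"rna" if t == "rna_binarized" else t for t in req}


STRATEGIES: dict[str, PersonalizationStrategy] = {
    s.name: s
    for s in [
        PersonalizationStrategy("case1", ("mutation",), ()),
        PersonalizationStrategy("case2", ("mutation", "cna"), ()),
        PersonalizationStrategy("case3", ("mutation",), ("cna",)),
        PersonalizationStrategy("case4", (), ("rna",)),
        PersonalizationStrategy("case5", ("mutation",), ("rna",)),
        PersonalizationStrategy("case6", ("mutation", "cna"), ("rna",)),
    ]
}


@dataclass
class CohortData:
    """Per-cohort omics bundles keyed by shared sample identifiers.

    ``mutations``/``cna`` come from genomic inference (sample → gene →
    effect); ``rna``/``protein`` are normalized genes × samples matrices;
    ``rna_binarized`` an optional binarized matrix (NaN = missing).  The
    ``*_samples`` lists declare which samples were measured for the
    discrete data types (a measured sample may carry zero alterations);
    they default to the dict keys.
    """

    mutations: dict[str, dict[str, FunctionalEffect]] | None = None
    cna: dict[str, dict[str, FunctionalEffect]] | None = None
    rna: pd.DataFrame | None = None
    protein: pd.DataFrame | None = None
    rna_binarized: pd.DataFrame | None = None
    mutation_samples: list[str] | None = None
    cna_samples: list[str] | None = None

    def samples_with(self, data_type: str) -> set[str]:
        if data_type == "mutation":
            if self.mutations is None:
                return set()
            return set(self.mutation_samples or self.mutations.keys())
        if data_type == "cna":
            if self.cna is None:
                return set()
            return set(self.cna_samples or self.cna.keys())
        if data_type == "rna":
            return set() if self.rna is None else set(self.rna.columns)
        if data_type == "protein":
            return set() if self.protein is None else set(self.protein.columns)
        raise ValueError(f"unknown data type {data_type!r}")


# ---------------------------------------------------------------------------
# Gene → node aggregation
# ---------------------------------------------------------------------------


def map_genes_to_nodes(
    gene_values: dict[str, float],
    mapping: GeneNodeMapping,
    kind: Literal["discrete", "continuous"] = "continuous",
) -> dict[str, float]:
    """Aggregate per-gene values onto model nodes.

    Discrete values propagate any definitive effect; conflicting effects
    among a node's genes drop the node with a warning.  Continuous values
    are averaged over the genes with data.
    """
    out: dict[str, float] = {}
    for node, genes in mapping.node_to_genes.items():
        present = [gene_values[g] for g in genes if g in gene_values
                   and gene_values[g] == gene_values[g]]  # NaN-safe
        if not present:
            continue
        if kind == "discrete":
            values = set(int(v) for v in present)
            if len(values) > 1:
                logger.warning(
                    "node %s dropped: conflicting discrete effects %s", node, values
                )
                continue
            out[node] = float(values.pop())
        else:
            out[node] = float(sum(present) / len(present))
    return out


# ---------------------------------------------------------------------------
# Settings modification
# ---------------------------------------------------------------------------


def apply_strict_nv(
    settings: SimulationSettings, node: str, value: int
) -> SimulationSettings:
    """Freeze ``node`` at ``value`` in a copy of ``settings``: the initial
    probability becomes the value and the opposing rate is zeroed, so the
    node can never leave its assigned state."""
    if value not in (0, 1):
        raise ValueError("strict value must be 0 or 1")
    if node not in settings.node_settings:
        raise KeyError(f"unknown node {node!r}")
    new = settings.copy()
    ns = new.node_settings[node]
    ns.initial_prob = float(value)
    if value == 0:
        ns.k_up = 0.0
    else:
        ns.k_down = 0.0
    return new


def apply_soft_nv(
    settings: SimulationSettings,
    node: str,
    norm_value: float,
    amplification_factor: float = 100.0,
) -> SimulationSettings:
    """Bias ``node`` toward ``norm_value`` in a copy of ``settings``:
    initial probability = norm, k_up = AF^(2(norm − 0.5)), k_down = 1/k_up."""
    if not 0.0 <= norm_value <= 1.0:
        raise ValueError(f"normalized value must be in [0,1], got {norm_value}")
    if amplification_factor <= 1:
        raise ValueError("amplification_factor must be > 1")
    if node not in settings.node_settings:
        raise KeyError(f"unknown node {node!r}")
    new = settings.copy()
    ns = new.node_settings[node]
    ns.initial_prob = float(norm_value)
    ns.k_up = float(amplification_factor ** (2.0 * (norm_value - 0.5)))
    ns.k_down = 1.0 / ns.k_up
    return new


# ---------------------------------------------------------------------------
# Precedence resolution and cohort personalization
# ---------------------------------------------------------------------------


def resolve_precedence(
    patient: str,
    strict_candidates: dict[str, list[tuple[int, str]]],
    soft_candidates: dict[str, list[tuple[float, str]]],
    strategy: PersonalizationStrategy,
) -> PatientProfile:
    """Collapse per-node candidate lists into one profile.

    Per node: the highest-precedence strict candidate wins (mutation > CNA >
    binarized expression); a node with a strict assignment receives no soft
    assignment; among soft candidates protein beats RNA beats CNA.
    """
    profile = PatientProfile(patient=patient)
    for node, cands in strict_candidates.items():
        best = min(cands, key=lambda vc: _STRICT_PRECEDENCE[vc[1]])
        profile.strict[node] = (int(best[0]), best[1])
    for node, cands in soft_candidates.items():
        if node in profile.strict:
            continue
        best = min(cands, key=lambda vc: _SOFT_PRECEDENCE[vc[1]])
        profile.soft[node] = (float(best[0]), best[1])
    return profile


def _discrete_node_values(
    effects: dict[str, FunctionalEffect] | None, mapping: GeneNodeMapping
) -> dict[str, float]:
    if not effects:
        return {}
    gene_values = {g: float(e.value) for g, e in effects.items()}
    return map_genes_to_nodes(gene_values, mapping, kind="discrete")


def _continuous_node_values(
    matrix: pd.DataFrame | None, sample: str, mapping: GeneNodeMapping
) -> dict[str, float]:
    if matrix is None or sample not in matrix.columns:
        return {}
    col = matrix[sample].dropna()
    return map_genes_to_nodes(col.to_dict(), mapping, kind="continuous")


def build_patient_profile(
    patient: str,
    data: CohortData,
    mapping: GeneNodeMapping,
    strategy: PersonalizationStrategy,
) -> PatientProfile:
    """Gather, aggregate and resolve all of one patient's data into a
    :class:`PatientProfile` according to the strategy."""
    strict_candidates: dict[str, list[tuple[int, str]]] = {}
    for source in strategy.strict_sources:
        if source == "mutation":
            node_vals = _discrete_node_values(
                (data.mutations or {}).get(patient), mapping
            )
        elif source == "cna":
            node_vals = _discrete_node_values((data.cna or {}).get(patient), mapping)
        else:  # rna_binarized
            vals = _continuous_node_values(data.rna_binarized, patient, mapping)
            node_vals = {n: v for n, v in vals.items() if v in (0.0, 1.0)}
        for node, v in node_vals.items():
            strict_candidates.setdefault(node, []).append((int(v), source))

    soft_candidates: dict[str, list[tuple[float, str]]] = {}
    for source in strategy.soft_sources:
        if source == "cna":
            node_vals = _discrete_node_values((data.cna or {}).get(patient), mapping)
        elif source == "rna":
            node_vals = _continuous_node_values(data.rna, patient, mapping)
        else:  # protein
            node_vals = _continuous_node_values(data.protein, patient, mapping)
        for node, v in node_vals.items():
            soft_candidates.setdefault(node, []).append((float(v), source))

    return resolve_precedence(patient, strict_candidates, soft_candidates, strategy)


def apply_profile(
    base_settings: SimulationSettings,
    profile: PatientProfile,
    amplification_factor: float = 100.0,
) -> SimulationSettings:
    """Produce one personalized settings object from a resolved profile;
    nodes with no patient data keep the generic base settings."""
    settings = base_settings.copy()
    for node, (value, _src) in profile.strict.items():
        settings = apply_strict_nv(settings, node, value)
    for node, (norm, _src) in profile.soft.items():
        settings = apply_soft_nv(settings, node, norm, amplification_factor)
    return settings


def personalize_cohort(
    model: LogicalModel,
    base_settings: SimulationSettings,
    data: CohortData,
    strategy: PersonalizationStrategy | str,
    mapping: GeneNodeMapping,
) -> dict[str, SimulationSettings]:
    """One personalized :class:`SimulationSettings` per retained patient.

    Patients lacking any data type the strategy requires are excluded (the
    count is logged).  The model itself is never modified; results are
    independent of patient iteration order.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    mapping.validate_against(model)

    required = strategy.required_data_types
    if not required:
        raise ValueError("strategy uses no data types")
    sample_sets = [data.samples_with(t) for t in sorted(required)]
    retained = set.intersection(*sample_sets)
    all_samples = set.union(*sample_sets)
    excluded = all_samples - retained
    if excluded:
        logger.info(
            "%d patients excluded for missing required data types %s",
            len(excluded), sorted(required),
        )
    if not retained:
        raise ValueError("no patient has all required data types")

    out: dict[str, SimulationSettings] = {}
    for patient in sorted(retained):
        profile = build_patient_profile(patient, data, mapping, strategy)
        out[patient] = apply_profile(
            base_settings, profile, strategy.amplification_factor
        )
    return out
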