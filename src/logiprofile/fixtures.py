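"""Seeded synthetic inputs for every stage of the pipeline.

Everything the pipeline consumes can be generated here deterministically:
small Boolean models with phenotype read-outs, expression cohorts whose
genes have known distribution classes, mutation/CNA tables with known
functional effects and a fictional knowledge base covering every inference
route, and survival tables with known group hazards.  All generators are
pure functions of their parameters and seed.

The knowledge base and all gene/variant effects here are fictional test
constructs (synthetic stand-ins for curated databases), chosen only to
exercise each decision branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genomics import CnaRecord, KnowledgeBase, MutationRecord
from .model import LogicalModel, SimulationSettings, parse_rule, write_bnd, write_cfg
from .personalize import GeneNodeMapping

__all__ = [
    "toy_model",
    "mini_cancer_model",
    "mini_model_mapping",
    "fixture_knowledge_base",
    "BimodalSpec",
    "UnimodalSpec",
    "ZeroInflatedSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_expression_cohort",
    "generate_genomic_profiles",
    "SurvivalSpec",
    "generate_survival",
    "make_fixture_files",
]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


def toy_model() -> tuple[LogicalModel, SimulationSettings]:
    """Three-node model: input A (self-rule), B activated by A, C inhibited
    by A; all rates 1.  From (A=1, B=0, C=1) the unique absorbing state is
    (1, 1, 0)."""
    model = LogicalModel(
        nodes=["A", "B", "C"],
        rules={"A": parse_rule("A"), "B": parse_rule("A"), "C": parse_rule("!A")},
        declared_outputs=["B", "C"],
    )
    return model, SimulationSettings.defaults_for(model)


def mini_cancer_model() -> tuple[LogicalModel, SimulationSettings]:
    """Ten-node cancer-signaling caricature with Proliferation/Apoptosis
    read-outs, small enough for the exact master-equation oracle.

    Growth-factor input drives an RTK→PI3K→AKT survival cascade and cyclin
    activation; DNA damage activates a p53-like tumor suppressor that
    blocks the cyclin and, unless survival signaling intervenes, triggers a
    caspase that commits the cell to apoptosis.
    """
    rules = {
        "Growth_Factor": "Growth_Factor",
        "DNA_Damage": "DNA_Damage",
        "RTK": "Growth_Factor",
        "PI3K": "RTK",
        "AKT": "PI3K",
        "p53": "DNA_Damage",
        "CyclinD": "(RTK | AKT) & !p53",
        "Caspase": "p53 & !AKT",
        "Proliferation": "CyclinD",
        "Apoptosis": "Caspase",
    }
    model = LogicalModel(
        nodes=list(rules),
        rules={n: parse_rule(r) for n, r in rules.items()},
        declared_outputs=["Proliferation", "Apoptosis"],
    )
    return model, SimulationSettings.defaults_for(model)


def mini_model_mapping() -> GeneNodeMapping:
    """Gene → node correspondence for the mini model (AKT is a two-gene
    family to exercise family aggregation)."""
    return GeneNodeMapping(
        {
            "RTK": ["EGFR"],
            "PI3K": ["PIK3CA"],
            "AKT": ["AKT1", "AKT2"],
            "p53": ["TP53"],
            "CyclinD": ["CCND1"],
            "Caspase": ["CASP3"],
        }
    )


def fixture_knowledge_base() -> KnowledgeBase:
    """Fictional knowledge tables covering every cascade branch: known GOF
    and LOF variants, an oncogene, a tumor suppressor and an unannotated
    gene."""
    return KnowledgeBase(
        known_variants={
            ("PIK3CA", "p.H1047R"): "GOF",
            ("TP53", "p.R175H"): "LOF",
            ("EGFR", "p.L858R"): "GOF",
        },
        gene_roles={
            "TP53": "tumor_suppressor",
            "PIK3CA": "oncogene",
            "EGFR": "oncogene",
            "CASP3": "tumor_suppressor",
            "GENE_X": "unknown",
        },
    )


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BimodalSpec:
    pi: float = 0.5  # weight of the lower mode
    mu1: float = 2.0
    mu2: float = 6.0
    sigma: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lower = rng.random(n) < self.pi
        mu = np.where(lower, self.mu1, self.mu2)
        return np.clip(rng.normal(mu, self.sigma), 0.0, None)


@dataclass(frozen=True)
class UnimodalSpec:
    median: float = 8.0
    scale: float = 1.0  # MAD-equivalent spread

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.clip(rng.normal(self.median, self.scale / 0.6745, n), 0.0, None)


@dataclass(frozen=True)
class ZeroInflatedSpec:
    zero_fraction: float = 0.7
    tail_scale: float = 2.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.exponential(self.tail_scale, n)
        x[rng.random(n) < self.zero_fraction] = 0.0
        return x


@dataclass
class CohortSpec:
    """Generative specification of a synthetic expression cohort."""

    n_samples: int
    genes: dict[str, BimodalSpec | UnimodalSpec | ZeroInflatedSpec]
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")


_CLASS_NAMES = {
    BimodalSpec: "bimodal",
    UnimodalSpec: "unimodal",
    ZeroInflatedSpec: "zero_inflated",
}


def default_cohort_spec(
    n_samples: int = 1000, n_per_class: int = 10, seed: int = 0
) -> CohortSpec:
    """A three-class cohort with ``n_per_class`` genes of each distribution
    class at the canonical parameters (balanced bimodal mixture with
    standardized separation δ = 4; symmetric unimodal; 70%-zero-inflated)."""
    genes: dict[str, BimodalSpec | UnimodalSpec | ZeroInflatedSpec] = {}
    for i in range(n_per_class):
        genes[f"BIM{i}"] = BimodalSpec()
        genes[f"UNI{i}"] = UnimodalSpec()
        genes[f"ZIF{i}"] = ZeroInflatedSpec()
    return CohortSpec(n_samples=n_samples, genes=genes, seed=seed)


def generate_expression_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Sample a genes × samples matrix per the spec; returns the matrix and
    the ground-truth class of every gene."""
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{j:04d}" for j in range(spec.n_samples)]
    rows, truth = {}, {}
    for gene, gspec in spec.genes.items():
        rows[gene] = gspec.sample(spec.n_samples, rng)
        truth[gene] = _CLASS_NAMES[type(gspec)]
    df = pd.DataFrame(
        np.vstack(list(rows.values())), index=list(rows), columns=samples
    )
    return ExpressionMatrix(values=df), truth


# ---------------------------------------------------------------------------
# Genomic profiles
# ---------------------------------------------------------------------------

# (description, record factory, expected effect value or None)
_MUTATION_ROUTES = [
    ("truncating_nonsense",
     lambda s, g: MutationRecord(s, g, "nonsense"), 0),
    ("truncating_frameshift",
     lambda s, g: MutationRecord(s, g, "frameshift_del"), 0),
    ("known_gof",
     lambda s, g: MutationRecord(s, "PIK3CA", "missense", "p.H1047R",
                                 sift_label="deleterious"), 1),
    ("known_lof",
     lambda s, g: MutationRecord(s, "TP53", "missense", "p.R175H",
                                 polyphen_label="probably_damaging"), 0),
    ("oncogene_role",
     lambda s, g: MutationRecord(s, "EGFR", "missense", "p.A1B",
                                 sift_label="deleterious"), 1),
    ("tsg_role",
     lambda s, g: MutationRecord(s, "CASP3", "missense", "p.C2D",
                                 polyphen_label="possibly_damaging"), 0),
    ("missense_unlabelled",
     lambda s, g: MutationRecord(s, "EGFR", "missense", "p.E3F"), None),
    ("unknown_role",
     lambda s, g: MutationRecord(s, "GENE_X", "missense", "p.G4H",
                                 sift_label="deleterious"), None),
    ("silent",
     lambda s, g: MutationRecord(s, g, "silent"), None),
]

_CNA_ROUTES = [
    ("amplification", 2, 1),
    ("homdel", -2, 0),
    ("low_gain", 1, None),
    ("low_loss", -1, None),
    ("neutral", 0, None),
]


def generate_genomic_profiles(
    n_samples: int = 20,
    mutation_frequency: float = 0.3,
    cna_frequency: float = 0.3,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[
    list[MutationRecord],
    list[CnaRecord],
    KnowledgeBase,
    dict[tuple[str, str], int | None],
]:
    """MAF-like and GISTIC-like records with known generating effects.

    The first samples deterministically traverse every cascade route once;
    the remainder draw routes at random.  At most one alteration is placed
    per (sample, gene) so the ground truth is unambiguous.  Returns
    ``(mutations, cnas, knowledge_base, truth)`` with ``truth`` mapping
    (sample, gene) to the expected profile value (None when the route must
    yield no call).
    """
    rng = np.random.default_rng(seed)
    kb = fixture_knowledge_base()
    gene_pool = genes or ["TP53", "PIK3CA", "EGFR", "CCND1", "CASP3", "GENE_X"]
    mutations: list[MutationRecord] = []
    cnas: list[CnaRecord] = []
    truth: dict[tuple[str, str], int | None] = {}

    def place_mut(sample: str, route_idx: int, gene: str):
        _, factory, expected = _MUTATION_ROUTES[route_idx]
        rec = factory(sample, gene)
        if (sample, rec.gene) in truth:
            return
        mutations.append(rec)
        truth[(sample, rec.gene)] = expected

    def place_cna(sample: str, route_idx: int, gene: str):
        _, call, expected = _CNA_ROUTES[route_idx]
        if (sample, gene) in truth:
            return
        cnas.append(CnaRecord(sample, gene, call))
        truth[(sample, gene)] = expected

    # Deterministic branch coverage.
    for i, _ in enumerate(_MUTATION_ROUTES):
        place_mut(f"COV_M{i}", i, "CCND1")
    for i, _ in enumerate(_CNA_ROUTES):
        place_cna(f"COV_C{i}", i, "CCND1")

    # Random sparse profiles.
    for j in range(n_samples):
        sample = f"P{j:03d}"
        for gene in gene_pool:
            u = rng.random()
            if u < mutation_frequency:
                place_mut(sample, int(rng.integers(len(_MUTATION_ROUTES))), gene)
            elif u < mutation_frequency + cna_frequency:
                place_cna(sample, int(rng.integers(len(_CNA_ROUTES))), gene)
    return mutations, cnas, kb, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalSpec:
    """Exponential survival with group-specific hazard multipliers and
    independent uniform censoring."""

    baseline_hazard: float = 0.05
    hazard_multipliers: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if any(m <= 0 for m in self.hazard_multipliers.values()):
            raise ValueError("hazard multipliers must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must be in [0, 1)")


def generate_survival(groups: pd.Series | dict[str, str], spec: SurvivalSpec) -> pd.DataFrame:
    """Event times drawn exponential with the group's hazard; a fraction of
    patients is censored uniformly before their event.  Returns columns
    (patient, time, event)."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for patient, group in groups.items():
        hazard = spec.baseline_hazard * spec.hazard_multipliers.get(str(group), 1.0)
        t = rng.exponential(1.0 / hazard)
        if rng.random() < spec.censoring_rate:
            rows.append((patient, t * rng.random(), 0))
        else:
            rows.append((patient, t, 1))
    return pd.DataFrame(rows, columns=["patient", "time", "event"])


# ---------------------------------------------------------------------------
# File emission (all plain text)
# ---------------------------------------------------------------------------


def make_fixture_files(out_dir: str | Path, seed: int = 42,
                       n_samples: int = 50, n_expr_samples: int = 200) -> dict[str, Path]:
    """Write every input format the pipeline consumes into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    model, settings = mini_cancer_model()
    paths["bnd"] = out / "mini_model.bnd"
    paths["bnd"].write_text(write_bnd(model))
    paths["cfg"] = out / "mini_model.cfg"
    paths["cfg"].write_text(write_cfg(settings, model))

    genes = {
        g: UnimodalSpec(median=8.0 + i * 0.3, scale=1.0)
        for i, g in enumerate(["EGFR", "PIK3CA", "AKT1", "AKT2", "TP53", "CCND1", "CASP3"])
    }
    matrix, _ = generate_expression_cohort(
        CohortSpec(n_samples=n_expr_samples, genes=genes, seed=seed)
    )
    paths["expression"] = out / "expression.tsv"
    matrix.values.to_csv(paths["expression"], sep="\t")

    mutations, cnas, kb, _ = generate_genomic_profiles(
        n_samples=n_samples, seed=seed
    )
    # emit MAF-style classification names so the file round-trips through
    # the MAF adapter
    maf_names = {
        "nonsense": "Nonsense_Mutation",
        "frameshift_ins": "Frame_Shift_Ins",
        "frameshift_del": "Frame_Shift_Del",
        "splice_site": "Splice_Site",
        "translation_start_site": "Translation_Start_Site",
        "missense": "Missense_Mutation",
        "silent": "Silent",
    }
    maf = pd.DataFrame(
        [
            {
                "Tumor_Sample_Barcode": m.sample,
                "Hugo_Symbol": m.gene,
                "Variant_Classification": maf_names[m.variant_classification],
                "HGVSp_Short": m.protein_change,
                "SIFT": m.sift_label,
                "PolyPhen": m.polyphen_label,
            }
            for m in mutations
        ]
    )
    paths["maf"] = out / "mutations.maf.tsv"
    maf.to_csv(paths["maf"], sep="\t", index=False)

    cna_df = (
        pd.DataFrame([(c.gene, c.sample, c.gistic_call) for c in cnas],
                     columns=["gene", "sample", "call"])
        .pivot_table(index="gene", columns="sample", values="call", fill_value=0)
        .astype(int)
    )
    paths["cna"] = out / "cna_gistic.tsv"
    cna_df.to_csv(paths["cna"], sep="\t")

    paths["kb_variants"] = out / "kb_variants.tsv"
    pd.DataFrame(
        [(g, p, e) for (g, p), e in kb.known_variants.items()],
        columns=["gene", "protein_change", "effect"],
    ).to_csv(paths["kb_variants"], sep="\t", index=False)
    paths["kb_roles"] = out / "kb_roles.tsv"
    pd.DataFrame(
        list(kb.gene_roles.items()), columns=["gene", "role"]
    ).to_csv(paths["kb_roles"], sep="\t", index=False)

    mapping = mini_model_mapping()
    paths["mapping"] = out / "gene_node_mapping.csv"
    pd.DataFrame(
        [(n, g) for n, gs in mapping.node_to_genes.items() for g in gs],
        columns=["node", "gene"],
    ).to_csv(paths["mapping"], index=False)

    groups = pd.Series(
        {f"P{j:03d}": ("high" if j % 2 else "low") for j in range(n_samples)}
    )
    surv = generate_survival(
        groups, SurvivalSpec(hazard_multipliers={"high": 2.0, "low": 1.0}, seed=seed)
    )
    paths["survival"] = out / "survival.tsv"
    surv.to_csv(paths["survival"], sep="\t", index=False)
    return paths
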