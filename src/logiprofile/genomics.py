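"""Functional inference from mutation and copy-number records.

Converts discrete genomic observations into per-gene Boolean functional
effects (0 = loss of function / absent, 1 = gain of function / present):

* truncating mutations (nonsense, frameshift insertions/deletions, splice
  and translation-start-site variants) → loss of function;
* missense mutations matched in a user-supplied known-variant table
  (OncoKB-like) → the table's GOF/LOF call;
* otherwise, missense mutations in genes annotated as oncogenes → gain of
  function, in tumor suppressors → loss of function;
* copy-number GISTIC calls: +2 (amplification) → 1, −2 (homozygous
  deletion) → 0; ±1 and 0 are discarded as low-confidence.

Missense routes additionally require a deleteriousness label (SIFT
deleterious or PolyPhen damaging) to rule passenger mutations out.  When a
gene has effects from both mutation and CNA, mutation wins; among mutation
routes, truncating > known variant > gene role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "CnaRecord",
    "KnowledgeBase",
    "FunctionalEffect",
    "TRUNCATING_CLASSES",
    "infer_mutation_effect",
    "infer_cna_effect",
    "build_discrete_profile",
    "read_maf",
    "read_cna_matrix",
    "read_knowledge_base",
    "profile_to_frame",
]

TRUNCATING_CLASSES = frozenset(
    {
        "nonsense",
        "frameshift_ins",
        "frameshift_del",
        "splice_site",
        "translation_start_site",
    }
)

_VALID_CLASSES = TRUNCATING_CLASSES | {"missense", "silent", "other"}

_SOURCE_PRECEDENCE = {"truncating": 0, "known_variant": 1, "gene_role": 2}


@dataclass(frozen=True)
class MutationRecord:
    sample: str
    gene: str
    variant_classification: str
    protein_change: str = ""
    sift_label: str = ""  # deleterious / tolerated / ""
    polyphen_label: str = ""  # probably_damaging / possibly_damaging / benign / ""

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.variant_classification not in _VALID_CLASSES:
            raise ValueError(
                f"unknown variant classification "
                f"{self.variant_classification!r} for {self.gene}"
            )

    @property
    def is_deleterious_labelled(self) -> bool:
        return self.sift_label == "deleterious" or self.polyphen_label in (
            "probably_damaging",
            "possibly_damaging",
        )


@dataclass(frozen=True)
class CnaRecord:
    sample: str
    gene: str
    gistic_call: int

    def __post_init__(self):
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.gistic_call not in (-2, -1, 0, 1, 2):
            raise ValueError(f"GISTIC call out of range: {self.gistic_call}")


@dataclass
class KnowledgeBase:
    """User-supplied knowledge tables: known variant effects keyed by
    (gene, protein change) and oncogene/tumor-suppressor role per gene."""

    known_variants: dict[tuple[str, str], Literal["GOF", "LOF"]]
    gene_roles: dict[str, Literal["oncogene", "tumor_suppressor", "unknown"]]

    def __post_init__(self):
        for key, effect in self.known_variants.items():
            if effect not in ("GOF", "LOF"):
                raise ValueError(f"variant effect must be GOF/LOF, got {effect!r} for {key}")
        for gene, role in self.gene_roles.items():
            if role not in ("oncogene", "tumor_suppressor", "unknown"):
                raise ValueError(f"unknown gene role {role!r} for {gene}")


@dataclass(frozen=True)
class FunctionalEffect:
    sample: str
    gene: str
    value: int  # 0 or 1
    source: Literal["truncating", "known_variant", "gene_role", "cna"]
    data_type: Literal["mutation", "cna"]


# ---------------------------------------------------------------------------
# Single-record cascades
# ---------------------------------------------------------------------------


def infer_mutation_effect(
    rec: MutationRecord, kb: KnowledgeBase
) -> FunctionalEffect | None:
    """Decision cascade for one mutation record; returns None when no
    confident functional call can be made (silent/other/unmatched missense,
    or missense without a deleteriousness label)."""
    vc = rec.variant_classification
    if vc in TRUNCATING_CLASSES:
        return FunctionalEffect(rec.sample, rec.gene, 0, "truncating", "mutation")
    if vc != "missense":
        return None
    if not rec.is_deleterious_labelled:
        return None
    known = kb.known_variants.get((rec.gene, rec.protein_change))
    if known is not None:
        return FunctionalEffect(
            rec.sample, rec.gene, 1 if known == "GOF" else 0, "known_variant", "mutation"
        )
    role = kb.gene_roles.get(rec.gene, "unknown")
    if role == "oncogene":
        return FunctionalEffect(rec.sample, rec.gene, 1, "gene_role", "mutation")
    if role == "tumor_suppressor":
        return FunctionalEffect(rec.sample, rec.gene, 0, "gene_role", "mutation")
    return None


def infer_cna_effect(rec: CnaRecord) -> FunctionalEffect | None:
    """Only high-confidence calls are used: +2 → 1, −2 → 0, else None."""
    if rec.gistic_call == 2:
        return FunctionalEffect(rec.sample, rec.gene, 1, "cna", "cna")
    if rec.gistic_call == -2:
        return FunctionalEffect(rec.sample, rec.gene, 0, "cna", "cna")
    return None


# ---------------------------------------------------------------------------
# Per-sample profiles with precedence resolution
# ---------------------------------------------------------------------------


def build_discrete_profile(
    mutations: Iterable[MutationRecord],
    cnas: Iterable[CnaRecord],
    kb: KnowledgeBase,
) -> dict[str, dict[str, FunctionalEffect]]:
    """Resolve all records into per-sample gene → effect maps.

    Mutation-derived effects always override CNA-derived effects for the
    same gene.  Within mutations, precedence is truncating > known variant >
    gene role.  Conflicting effects at equal precedence drop the gene for
    that sample with a logged warning (a wrong forced state is worse than
    no constraint).  The result is independent of input record order.
    """
    mut_effects: dict[tuple[str, str], list[FunctionalEffect]] = {}
    for rec in mutations:
        eff = infer_mutation_effect(rec, kb)
        if eff is not None:
            mut_effects.setdefault((eff.sample, eff.gene), []).append(eff)

    cna_effects: dict[tuple[str, str], list[FunctionalEffect]] = {}
    for rec in cnas:
        eff = infer_cna_effect(rec)
        if eff is not None:
            cna_effects.setdefault((eff.sample, eff.gene), []).append(eff)

    profiles: dict[str, dict[str, FunctionalEffect]] = {}
    dropped: list[tuple[str, str]] = []
    for key in sorted(set(mut_effects) | set(cna_effects)):
        sample, gene = key
        if key in mut_effects:
            effs = mut_effects[key]
            best_rank = min(_SOURCE_PRECEDENCE[e.source] for e in effs)
            top = [e for e in effs if _SOURCE_PRECEDENCE[e.source] == best_rank]
            values = {e.value for e in top}
            if len(values) > 1:
                dropped.append(key)
                continue
            chosen = top[0]
        else:
            values = {e.value for e in cna_effects[key]}
            if len(values) > 1:
                dropped.append(key)
                continue
            chosen = cna_effects[key][0]
        profiles.setdefault(sample, {})[gene] = chosen
    if dropped:
        logger.warning(
            "dropped %d gene/sample pairs with conflicting same-precedence "
            "effects: %s", len(dropped), dropped[:10],
        )
    return profiles


def profile_to_frame(
    profiles: dict[str, dict[str, FunctionalEffect]],
) -> pd.DataFrame:
    """Long-format profile table (sample, gene, value, source, data_type)."""
    rows = [
        (e.sample, e.gene, e.value, e.source, e.data_type)
        for sample in sorted(profiles)
        for e in (profiles[sample][g] for g in sorted(profiles[sample]))
    ]
    return pd.DataFrame(
        rows, columns=["sample", "gene", "value", "source", "data_type"]
    )


# ---------------------------------------------------------------------------
# File-format adapters
# ---------------------------------------------------------------------------

_MAF_CLASS_MAP = {
    "nonsense_mutation": "nonsense",
    "frame_shift_ins": "frameshift_ins",
    "frame_shift_del": "frameshift_del",
    "splice_site": "splice_site",
    "translation_start_site": "translation_start_site",
    "missense_mutation": "missense",
    "silent": "silent",
}


def _norm_sift(label: str) -> str:
    label = str(label).strip().lower()
    if label.startswith("deleterious"):
        return "deleterious"
    if label.startswith("tolerated"):
        return "tolerated"
    return ""


def _norm_polyphen(label: str) -> str:
    label = str(label).strip().lower()
    for key in ("probably_damaging", "possibly_damaging", "benign"):
        if label.startswith(key):
            return key
    return ""


def read_maf(path_or_buf) -> list[MutationRecord]:
    """Read a MAF-like TSV (columns Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification, HGVSp_Short, SIFT, PolyPhen) into records.
    Unrecognized variant classes are mapped to ``other``."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        vc = _MAF_CLASS_MAP.get(
            str(row["Variant_Classification"]).strip().lower(), "other"
        )
        records.append(
            MutationRecord(
                sample=row["Tumor_Sample_Barcode"],
                gene=row["Hugo_Symbol"],
                variant_classification=vc,
                protein_change=row.get("HGVSp_Short", ""),
                sift_label=_norm_sift(row.get("SIFT", "")),
                polyphen_label=_norm_polyphen(row.get("PolyPhen", "")),
            )
        )
    return records


def read_cna_matrix(path_or_buf) -> list[CnaRecord]:
    """Read a GISTIC gene × sample integer matrix TSV (first column the
    gene symbol) into records."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    records = []
    for gene, row in df.iterrows():
        for sample, call in row.items():
            records.append(CnaRecord(sample=str(sample), gene=str(gene),
                                     gistic_call=int(call)))
    return records


def read_knowledge_base(variants_path, roles_path) -> KnowledgeBase:
    """Read the known-variant table (columns gene, protein_change, effect)
    and the gene-role table (columns gene, role) from TSVs."""
    var_df = pd.read_csv(variants_path, sep="\t", dtype=str)
    kv = {}
    for _, row in var_df.iterrows():
        key = (row["gene"], row["protein_change"])
        if key in kv:
            raise ValueError(f"duplicate known-variant entry {key}")
        kv[key] = row["effect"]
    role_df = pd.read_csv(roles_path, sep="\t", dtype=str)
    roles = dict(zip(role_df["gene"], role_df["role"]))
    return KnowledgeBase(known_variants=kv, gene_roles=roles)
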