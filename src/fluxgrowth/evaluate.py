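"""Prediction combination, critical-reaction mapping, and model accuracy.

Critical genes from an experimental screen are mapped to reactions through
GPR rules: a gene's loss disables every reaction whose rule turns false when
that single gene is knocked out.  Model accuracy is the precision-style
statistic P(B/A) = |A ∩ B| / |A|, where A is the predicted beneficial set
restricted to reactions mediated by a single protein or complex (no
isozymes) and B is the critical-reaction set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .learn_en import PredictionSet
from .model_io import MetabolicModel, classify_single_protein_reactions, evaluate_gpr

__all__ = [
    "CriticalSet",
    "AccuracyReport",
    "consensus",
    "map_genes_to_reactions",
    "prediction_accuracy",
    "cross_condition_summary",
]


@dataclass
class CriticalSet:
    """Genes reported critical in a screen, with their GPR-mapped reactions."""

    source_label: str
    genes: set[str]
    reactions: set[str]

    @classmethod
    def from_genes(
        cls, model: MetabolicModel, genes: Iterable[str], source_label: str = ""
    ) -> "CriticalSet":
        genes = set(genes)
        return cls(
            source_label=source_label,
            genes=genes,
            reactions=map_genes_to_reactions(model, genes),
        )


@dataclass
class AccuracyReport:
    """P(B/A) accuracy for one prediction set against one critical set."""

    condition_id: str
    predicted_count: int
    overlap_count: int
    accuracy_percent: float  # rounded to one decimal; NaN when undefined
    accuracy_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_count <= max(self.predicted_count, 0):
            raise ValueError("overlap cannot exceed predicted count")


def consensus(en: PredictionSet, mlp: PredictionSet) -> PredictionSet:
    """Reactions called by both models; scores carried as (en, mlp) pairs."""
    if en.condition_id != mlp.condition_id:
        raise ValueError(
            f"condition mismatch: {en.condition_id!r} vs {mlp.condition_id!r}"
        )
    beneficial = {
        r: (en.beneficial[r], mlp.beneficial[r])
        for r in set(en.beneficial) & set(mlp.beneficial)
    }
    detrimental = {
        r: (en.detrimental[r], mlp.detrimental[r])
        for r in set(en.detrimental) & set(mlp.detrimental)
    }
    return PredictionSet(
        condition_id=en.condition_id,
        beneficial=beneficial,
        detrimental=detrimental,
        model_tag="consensus",
        excluded=en.excluded | mlp.excluded,
    )


def map_genes_to_reactions(model: MetabolicModel, genes: Iterable[str]) -> set[str]:
    """Reactions disabled by the loss of any single listed gene.

    For each gene g, a reaction is included when its (non-empty) GPR turns
    false under the singleton deletion {g}; an isozyme-backed reaction is not
    attributed to either isozyme alone.
    """
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    out: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        gpr_genes = rxn.gpr.genes
        for gene in genes & gpr_genes:
            if not evaluate_gpr(rxn.gpr, {gene}):
                out.add(rxn.rxn_id)
                break
    return out


def prediction_accuracy(
    predicted: PredictionSet,
    critical: CriticalSet,
    model: MetabolicModel,
) -> AccuracyReport:
    """P(B/A) with A = beneficial ∩ single-protein reactions, B = critical.

    The single-protein filter applies to the predicted set only.  When A is
    empty the accuracy is undefined (reported as NaN with a warning).
    """
    single = classify_single_protein_reactions(model)
    A = set(predicted.beneficial) & single
    B = critical.reactions
    overlap = len(A & B)
    if len(A) == 0:
        warnings.warn(
            f"no single-protein beneficial predictions for condition "
            f"{predicted.condition_id!r}; accuracy undefined",
            stacklevel=2,
        )
        return AccuracyReport(predicted.condition_id, 0, 0, float("nan"), float("nan"))
    fraction = overlap / len(A)
    return AccuracyReport(
        condition_id=predicted.condition_id,
        predicted_count=len(A),
        overlap_count=overlap,
        accuracy_percent=round(100.0 * fraction, 1),
        accuracy_fraction=fraction,
    )


def cross_condition_summary(predictions: Sequence[PredictionSet]) -> pd.DataFrame:
    """Set-algebra summary across conditions, per model tag.

    Per model: how many reactions are called under at least one condition
    (union), under every condition (intersection), and the mean per-condition
    count; plus, for each model pair sharing conditions, the mean fraction of
    one model's beneficial calls also made by the other.
    """
    by_model: dict[str, dict[str, PredictionSet]] = {}
    for ps in predictions:
        slot = by_model.setdefault(ps.model_tag, {})
        if ps.condition_id in slot:
            raise ValueError(
                f"duplicate condition {ps.condition_id!r} for model {ps.model_tag!r}"
            )
        slot[ps.condition_id] = ps
    rows = []
    for tag, per_cond in sorted(by_model.items()):
        sets_b = [set(ps.beneficial) for ps in per_cond.values()]
        sets_d = [set(ps.detrimental) for ps in per_cond.values()]
        union_b = set().union(*sets_b)
        inter_b = set.intersection(*sets_b) if sets_b else set()
        union_d = set().union(*sets_d)
        inter_d = set.intersection(*sets_d) if sets_d else set()
        row = {
            "model": tag,
            "n_conditions": len(per_cond),
            "beneficial_union": len(union_b),
            "beneficial_intersection": len(inter_b),
            "beneficial_mean_per_condition": sum(map(len, sets_b)) / len(sets_b),
            "detrimental_union": len(union_d),
            "detrimental_intersection": len(inter_d),
            "detrimental_mean_per_condition": sum(map(len, sets_d)) / len(sets_d),
        }
        for other_tag, other in sorted(by_model.items()):
            if other_tag == tag:
                continue
            shared = sorted(set(per_cond) & set(other))
            fracs = []
            for cond in shared:
                mine = set(per_cond[cond].beneficial)
                theirs = set(other[cond].beneficial)
                if mine:
                    fracs.append(len(mine & theirs) / len(mine))
            if fracs:
                row[f"beneficial_overlap_with_{other_tag}"] = sum(fracs) / len(fracs)
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
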