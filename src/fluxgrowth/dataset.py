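"""Assembly of the supervised-learning dataset.

The feature matrix X holds absolute simulated fluxes (mutants x reactions):
negative fluxes are folded to magnitudes so that reverse operation is not
mistaken for low activity.  Columns that are zero across every mutant are
removed (variance thresholding at exactly zero); constant non-zero columns —
the ATP-maintenance analog — are retained.  The output vector y is endpoint
biomass normalized per condition by the wild-type value, with mutants of
listed essential genes forced to zero regardless of measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import FluxDistribution

__all__ = [
    "TrainingDataset",
    "build_feature_matrix",
    "build_output_vector",
    "assemble_dataset",
    "mutant_key",
]

#: magnitudes below this are treated as numerically zero when testing for
#: all-zero feature columns
ZERO_TOL = 1e-9


def mutant_key(genes: Iterable[str]) -> str:
    """Canonical mutant identifier: sorted gene ids joined by "+".

    Single deletions reduce to the gene id; double deletions like an
    isozyme-pair knockout become e.g. "aceB+glcB".
    """
    genes = sorted(genes)
    if not genes:
        raise ValueError("a mutant must delete at least one gene")
    return "+".join(genes)


@dataclass
class TrainingDataset:
    """Paired feature matrix (|flux|) and normalized-growth output vector."""

    condition_id: str
    X: pd.DataFrame            # mutants x reactions, non-negative
    y: pd.Series | None = None  # normalized biomass, aligned to X rows
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.X.values < 0).any():
            raise ValueError("feature matrix contains negative entries")
        if self.y is not None and not self.X.index.equals(self.y.index):
            raise ValueError("X rows and y entries are not aligned by mutant id")
        overlap = set(self.dropped_features) & set(self.X.columns)
        if overlap:
            raise ValueError(f"dropped features still present as columns: {sorted(overlap)}")

    @property
    def mutant_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.X.columns)


def build_feature_matrix(
    panel: Sequence[FluxDistribution],
    condition_id: str,
) -> TrainingDataset:
    """Feature matrix from a deletion panel of one condition.

    X[i, j] = |v_j| for mutant i.  Columns numerically zero in every mutant
    are removed and recorded in ``dropped_features`` (sorted); constant
    non-zero columns are retained.
    """
    entries = [fd for fd in panel if fd.condition_id == condition_id]
    if not entries:
        raise ValueError(f"panel holds no entries for condition {condition_id!r}")
    reaction_sets = {frozenset(fd.fluxes) for fd in entries}
    if len(reaction_sets) != 1:
        raise ValueError("panel entries do not share a single reaction set")
    order = sorted(next(iter(reaction_sets)))
    rows = {fd.strain_id: [abs(fd.fluxes[r]) for r in order] for fd in entries}
    X = pd.DataFrame.from_dict(rows, orient="index", columns=order)
    all_zero = X.columns[(X.values <= ZERO_TOL).all(axis=0)]
    dropped = sorted(all_zero)
    X = X.drop(columns=dropped)
    return TrainingDataset(condition_id=condition_id, X=X, dropped_features=dropped)


def build_output_vector(
    growth: Mapping[str, float],
    essential_genes: Iterable[str],
    wildtype_biomass: float,
) -> pd.Series:
    """Normalized growth vector: biomass / wild-type, essential mutants zeroed.

    Mutants deleting a listed essential gene are set to zero whether or not a
    biomass was recorded (the list overrides measurement); every other mutant
    must have a recorded biomass.  Values are clipped at zero below.
    """
    if wildtype_biomass <= 0:
        raise ValueError("wild-type biomass must be positive")
    essential = set(essential_genes)
    y: dict[str, float] = {}
    mutants = set(growth) | essential
    for mutant in sorted(mutants):
        if mutant in essential:
            y[mutant] = 0.0
        elif mutant not in growth:
            raise KeyError(f"no biomass recorded for non-essential mutant {mutant!r}")
        else:
            y[mutant] = max(growth[mutant] / wildtype_biomass, 0.0)
    return pd.Series(y, name="normalized_growth")


def assemble_dataset(
    panel: Sequence[FluxDistribution],
    condition_id: str,
    growth: Mapping[str, float],
    essential_genes: Iterable[str],
    wildtype_biomass: float,
) -> TrainingDataset:
    """Feature matrix + aligned output vector for one condition."""
    ds = build_feature_matrix(panel, condition_id)
    y = build_output_vector(growth, essential_genes, wildtype_biomass)
    missing = [m for m in ds.mutant_ids if m not in y.index]
    if missing:
        raise KeyError(f"no growth entry for panel mutant(s) {missing}")
    return TrainingDataset(
        condition_id=condition_id,
        X=ds.X,
        y=y.loc[ds.mutant_ids],
        dropped_features=ds.dropped_features,
    )
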