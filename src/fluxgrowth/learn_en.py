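"""Elastic-net regression on flux features and the sign + one-tenth-SD rule.

Per condition, normalized growth y is regressed on standardized |flux|
features with an elastic-net penalty (L1:L2 mix fixed, overall strength
chosen by cross-validation minimizing squared error).  Coefficients are then
split by sign; within each sign group, reactions whose coefficient magnitude
exceeds one tenth of that group's standard deviation are selected as
beneficial (positive) or detrimental (negative).  Exchange and transport
reactions are excluded from the selected sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .dataset import TrainingDataset
from .model_io import MetabolicModel

__all__ = ["ENConfig", "PredictionSet", "fit_elastic_net", "select_by_sign_sd", "en_predictions"]


@dataclass(frozen=True)
class ENConfig:
    """Elastic-net hyperparameters.

    ``cv_folds`` is interpreted as K-fold with K capped at the number of
    samples (leave-one-out on desk-scale datasets).  Features are
    standardized to unit variance before fitting and coefficients reported on
    the standardized scale.
    """

    l1_ratio: float = 0.01
    cv_folds: int = 300
    max_iterations: int = 10_000
    tolerance: float = 1e-6
    selection_fraction: float = 0.1
    n_alphas: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_fraction <= 0:
            raise ValueError("selection_fraction must be positive")


@dataclass
class PredictionSet:
    """Per-condition beneficial/detrimental reaction calls with scores."""

    condition_id: str
    beneficial: dict[str, float]
    detrimental: dict[str, float]
    model_tag: str  # "en" | "mlp" | "consensus"
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        common = set(self.beneficial) & set(self.detrimental)
        if common:
            raise ValueError(f"reactions in both beneficial and detrimental: {sorted(common)}")
        touched = (set(self.beneficial) | set(self.detrimental)) & self.excluded
        if touched:
            raise ValueError(f"excluded reactions still selected: {sorted(touched)}")


def fit_elastic_net(dataset: TrainingDataset, config: ENConfig = ENConfig()) -> dict[str, float]:
    """Cross-validated elastic-net coefficients, keyed by reaction.

    The penalty is alpha * (l1_ratio * ||b||_1 + (1 - l1_ratio)/2 * ||b||_2^2)
    with alpha chosen on a CV grid by minimum mean squared error (the RMSE
    argmin).  Fold assignment is seeded for reproducibility.  Constant
    (zero-variance) columns carry no information and receive coefficient 0.
    """
    if dataset.y is None:
        raise ValueError("dataset has no output vector; assemble y first")
    if dataset.X.shape[1] == 0:
        raise ValueError(
            "feature matrix has no columns; run zero-variance filtering on a non-empty panel first"
        )
    X = dataset.X.values
    y = dataset.y.values
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)  # zero-variance columns scale to all-zero
    n = X.shape[0]
    if np.allclose(y, y[0]):
        return {r: 0.0 for r in dataset.reaction_ids}
    k = min(config.cv_folds, n)
    cv = KFold(n_splits=k, shuffle=True, random_state=config.seed)
    # l1_ratio=0 (pure ridge) is outside ElasticNetCV's coordinate-descent
    # comfort zone; the default 0.01 mix is fine.
    model = ElasticNetCV(
        l1_ratio=config.l1_ratio,
        alphas=config.n_alphas,  # size of the CV grid of penalty strengths
        cv=cv,
        max_iter=config.max_iterations,
        tol=config.tolerance,
        random_state=config.seed,
    )
    model.fit(Xs, y)
    return {r: float(c) for r, c in zip(dataset.reaction_ids, model.coef_)}


def select_by_sign_sd(
    coefs: Mapping[str, float],
    model: MetabolicModel,
    fraction: float = 0.1,
    condition_id: str = "",
    model_tag: str = "en",
) -> PredictionSet:
    """Sign + one-tenth-SD selection with exchange/transport exclusion.

    Scores are split into a positive and a negative group (exact zeros belong
    to neither).  A positive score is selected when it exceeds ``fraction``
    times the positive group's population SD; a negative score when its
    magnitude exceeds ``fraction`` times the negative group's SD.  Selected
    exchange/transport reactions are moved to ``excluded``.  The rule is
    scale-equivariant: rescaling all scores by c > 0 changes nothing.
    """
    if not coefs:
        raise ValueError("empty score map")
    pos = {r: s for r, s in coefs.items() if s > 0}
    neg = {r: s for r, s in coefs.items() if s < 0}
    sd_pos = float(np.std(list(pos.values()))) if pos else 0.0
    sd_neg = float(np.std(list(neg.values()))) if neg else 0.0
    beneficial = {r: s for r, s in pos.items() if s > fraction * sd_pos}
    detrimental = {r: s for r, s in neg.items() if abs(s) > fraction * sd_neg}
    excluded: set[str] = set()
    for selected in (beneficial, detrimental):
        for rxn_id in list(selected):
            if model.is_exchange(rxn_id) or model.is_transport(rxn_id):
                excluded.add(rxn_id)
                del selected[rxn_id]
    return PredictionSet(
        condition_id=condition_id,
        beneficial=beneficial,
        detrimental=detrimental,
        model_tag=model_tag,
        excluded=excluded,
    )


def en_predictions(
    dataset: TrainingDataset,
    model: MetabolicModel,
    config: ENConfig = ENConfig(),
) -> PredictionSet:
    """Fit the elastic net and convert coefficients into reaction calls."""
    coefs = fit_elastic_net(dataset, config)
    return select_by_sign_sd(
        coefs,
        model,
        fraction=config.selection_fraction,
        condition_id=dataset.condition_id,
        model_tag="en",
    )
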