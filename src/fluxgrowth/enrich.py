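"""Hypergeometric overrepresentation analysis of predicted reaction sets.

For a category holding K of the N annotated reactions, with n predicted
reactions of which k fall in the category, the enrichment P value is the
upper tail P[X >= k] of X ~ Hypergeometric(N, K, n) (inclusive of the
observed k), and the cumulative probability is P[X <= k].  A category is
significantly overrepresented when P <= alpha and the cumulative
probability >= gamma (both thresholds as commonly applied to pathway
overrepresentation: alpha 0.01, gamma 0.95).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import false_discovery_control, hypergeom

__all__ = ["EnrichmentResult", "hypergeometric_enrichment"]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    category: str
    population_size: int   # N: annotated reactions
    category_size: int     # K
    sample_size: int       # n: predicted reactions (annotated)
    overlap: int           # k
    p_value: float
    cumulative_probability: float
    significant: bool

    def __post_init__(self) -> None:
        if self.overlap > min(self.category_size, self.sample_size):
            raise ValueError("overlap exceeds category or sample size")
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p_value outside [0, 1]")


def hypergeometric_enrichment(
    predicted: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.01,
    gamma: float = 0.95,
    fdr_correct: bool = False,
) -> list[EnrichmentResult]:
    """Overrepresentation of each category within the predicted reactions.

    ``annotation`` maps reaction -> categories; the population is every
    annotated reaction.  Predicted reactions without annotation are dropped
    (with a logged count).  Results are sorted by ascending P value, ties
    broken by category identifier.  ``fdr_correct`` applies a
    Benjamini-Hochberg adjustment to the P values before thresholding
    (off by default: raw P values are the convention here).
    """
    universe = {r for r, cats in annotation.items() if cats}
    if not universe:
        raise ValueError("empty annotation universe")
    predicted = set(predicted)
    dropped = predicted - universe
    if dropped:
        logger.info("dropping %d unannotated predicted reaction(s)", len(dropped))
    sample = predicted & universe
    N, n = len(universe), len(sample)
    members: dict[str, set[str]] = {}
    for rxn, cats in annotation.items():
        for cat in cats:
            members.setdefault(cat, set()).add(rxn)
    results = []
    for cat, rxns in members.items():
        K = len(rxns)
        k = len(sample & rxns)
        p_value = float(hypergeom.sf(k - 1, N, K, n))       # P[X >= k]
        cumulative = float(hypergeom.cdf(k, N, K, n))       # P[X <= k]
        results.append(
            EnrichmentResult(
                category=cat,
                population_size=N,
                category_size=K,
                sample_size=n,
                overlap=k,
                p_value=min(p_value, 1.0),
                cumulative_probability=cumulative,
                significant=False,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.category))
    pvals = [r.p_value for r in results]
    if fdr_correct and pvals:
        pvals = list(false_discovery_control(pvals, method="bh"))
    for r, p in zip(results, pvals):
        r.significant = p <= alpha and r.cumulative_probability >= gamma
    return results
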