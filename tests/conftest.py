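"""Shared fixtures: tiny hand-built models and the default synthetic study."""

from __future__ import annotations

import pytest

from fluxgrowth import (
    MediumDefinition,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    simulate_deletion_panel,
)
from fluxgrowth.synthetic_data import (
    SyntheticSpec,
    generate_growth_screen,
    generate_toy_model,
    toy_media,
)


def make_model(model_id, metabolites, reactions, genes, objective):
    """Terse model constructor: reactions as (id, stoich, lb, ub, gpr)."""
    return MetabolicModel(
        model_id=model_id,
        metabolites=[Metabolite(m, c) for m, c in metabolites],
        reactions=[
            Reaction(
                rxn_id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(gpr),
            )
            for rid, stoich, lb, ub, gpr in reactions
        ],
        genes=genes,
        objective_reaction=objective,
    )


@pytest.fixture
def chain_model():
    """EX_a (uptake <= 10) -> A -> B -> biomass, unit stoichiometry."""
    return make_model(
        "chain",
        [("a", "c"), ("b", "c")],
        [
            ("EX_a", {"a": -1}, -10.0, 1000.0, ""),
            ("R1", {"a": -1, "b": 1}, 0.0, 1000.0, "g1"),
            ("BIOMASS", {"b": -1}, 0.0, 1000.0, ""),
        ],
        ["g1"],
        "BIOMASS",
    )


@pytest.fixture
def parallel_model():
    """Two equivalent routes A -> B plus a biomass sink; tie-broken by L2."""
    return make_model(
        "parallel",
        [("a", "c"), ("b", "c")],
        [
            ("EX_a", {"a": -1}, -10.0, 1000.0, ""),
            ("R1", {"a": -1, "b": 1}, 0.0, 1000.0, "g1"),
            ("R2", {"a": -1, "b": 1}, 0.0, 1000.0, "g2"),
            ("BIOMASS", {"b": -1}, 0.0, 1000.0, ""),
        ],
        ["g1", "g2"],
        "BIOMASS",
    )


@pytest.fixture(scope="session")
def toy_study():
    """Default synthetic study: model, ground truth, screen, media, panel."""
    spec = SyntheticSpec()
    model, truth = generate_toy_model(spec)
    screen = generate_growth_screen(model, truth, spec)
    media = toy_media(spec)
    panel = simulate_deletion_panel(model, sorted(model.genes), media, replicates=1)
    return dict(
        spec=spec, model=model, truth=truth, screen=screen, media=media, panel=panel
    )
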