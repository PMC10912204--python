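"""Toy metabolic models and growth screens with known ground truth.

The generator emulates, at desk scale, the study design of a genome-wide
deletion screen over multiple carbon sources paired with a genome-scale
model: each carbon source gets an exchange, a transporter and a catabolic
step feeding a shared precursor; a linear core chain builds a biosynthetic
building block; branches for amino-acid-like and nucleotide-like precursors
and an oxygen-consuming energy reaction feed a biomass sink that consumes
three precursors.  Structural features of real networks are planted
deliberately:

* a lower-yield *bypass* catabolic route per carbon makes the main catabolic
  step nonessential yet growth-promoting (the class of reaction the ML
  models are meant to find beyond essentiality);
* isozyme pairs (OR-GPRs) and protein complexes (AND-GPRs);
* a forced-flux wasteful *drain* reaction whose deletion raises growth —
  the planted detrimental reaction (the glyoxylate-shunt analog);
* a spontaneous forced maintenance reaction, giving a constant non-zero
  flux column (the ATP-maintenance analog).

Ground truth is derived from the model itself by exhaustive single-gene
deletion FBA per carbon: genes whose loss drops growth below 5% of wild
type are essential, reactions disabled by genes whose loss cuts growth by
more than 10% are beneficial, and reactions whose removal raises growth are
detrimental.  The growth screen is mutant FBA growth under multiplicative
lognormal noise, with planted-essential mutants forced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import map_genes_to_reactions
from .model_io import (
    INFINITY_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_gene_deletion,
    parse_gpr,
)
from .simulate import MediumDefinition, fba, set_medium

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_toy_model",
    "generate_growth_screen",
    "toy_media",
]

#: in-silico essentiality cutoff (fraction of wild-type growth)
ESSENTIAL_CUTOFF = 0.05
#: growth-reduction cutoff defining a beneficial gene (10% loss)
BENEFICIAL_CUTOFF = 0.90
#: relative growth gain defining a detrimental reaction
DETRIMENTAL_GAIN = 1.01


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generated study.

    ``n_linear_pathways`` is the length of the shared linear core chain;
    ``n_branches`` the number of carbons given a lower-yield alternative
    catabolic route; ``essential_fraction`` the fraction of genes force-zeroed
    in the screen on top of the structurally essential ones (the analog of
    externally curated essential-gene lists).  ``noise_sd`` is the sigma of
    multiplicative lognormal noise on endpoint biomass.
    """

    n_linear_pathways: int = 3
    n_branches: int = 3
    n_isozyme_pairs: int = 2
    n_complexes: int = 1
    n_carbons: int = 3
    noise_sd: float = 0.1
    essential_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_linear_pathways,
            self.n_branches,
            self.n_isozyme_pairs,
            self.n_complexes,
            self.n_carbons,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_carbons < 1 or self.n_linear_pathways < 1:
            raise ValueError("need at least one carbon and one core step")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, per carbon condition."""

    planted_essential_genes: set[str]
    planted_beneficial_reactions: dict[str, set[str]]
    planted_detrimental_reactions: dict[str, set[str]]
    wildtype_growth: dict[str, float] = field(default_factory=dict)
    deletion_growth: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond in self.planted_beneficial_reactions:
            both = self.planted_beneficial_reactions[cond] & self.planted_detrimental_reactions.get(cond, set())
            if both:
                raise ValueError(f"beneficial/detrimental overlap in {cond!r}: {sorted(both)}")


def _condition_id(i: int) -> str:
    return f"carbon{i + 1}"


def toy_media(spec: SyntheticSpec) -> list[MediumDefinition]:
    """One minimal medium per generated carbon source."""
    return [
        MediumDefinition(
            condition_id=_condition_id(i),
            carbon_exchange=f"EX_carbon{i + 1}_e",
            carbon_uptake_max=10.0,
            oxygen_uptake_max=20.0,
            oxygen_exchange="EX_o2_e",
            free_exchanges=frozenset({"EX_spent_e"}),
        )
        for i in range(spec.n_carbons)
    ]


def _build_network(spec: SyntheticSpec) -> MetabolicModel:
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    genes: list[str] = []

    def met(met_id, comp, name=""):
        mets.append(Metabolite(met_id, comp, name))

    def rxn(rxn_id, stoich, lb=0.0, ub=INFINITY_BOUND, gpr="", subsystem="", ko=None):
        rxns.append(
            Reaction(
                rxn_id=rxn_id,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(gpr),
                subsystem=subsystem,
                ko_category=ko,
            )
        )

    # which reactions receive isozyme OR-pairs, in priority order
    iso_targets = ["ENER", "AA"] + [f"CATB_C{i + 1}" for i in range(spec.n_branches)]
    iso_set = set(iso_targets[: spec.n_isozyme_pairs])

    def gpr_for(tag: str, base: str) -> str:
        if tag in iso_set:
            genes.extend([f"{base}a", f"{base}b"])
            return f"{base}a or {base}b"
        genes.append(base)
        return base

    met("o2_e", "e", "oxygen (extracellular)")
    met("o2_c", "c", "oxygen")
    met("spent_c", "c", "spent carbon/energy")
    met("spent_e", "e", "spent (extracellular)")
    met("prec1", "c", "shared catabolic precursor")
    for k in range(1, spec.n_linear_pathways):
        met(f"core{k}", "c", f"core intermediate {k}")
    met("bb", "c", "biosynthetic building block")
    met("aa", "c", "amino-acid-like precursor")
    met("nt_int", "c", "nucleotide intermediate")
    met("nt", "c", "nucleotide-like precursor")
    met("energy", "c", "energy carrier")

    rxn("EX_o2_e", {"o2_e": -1}, lb=-20.0, subsystem="exchange")
    rxn("T_O2", {"o2_e": -1, "o2_c": 1}, subsystem="transport")
    rxn("EX_spent_e", {"spent_e": -1}, subsystem="exchange")
    rxn("T_SPENT", {"spent_c": -1, "spent_e": 1}, subsystem="transport")

    for i in range(spec.n_carbons):
        c = i + 1
        met(f"carbon{c}_e", "e", f"carbon source {c} (extracellular)")
        met(f"carbon{c}_c", "c", f"carbon source {c}")
        rxn(f"EX_carbon{c}_e", {f"carbon{c}_e": -1}, subsystem="exchange")
        genes.append(f"gT{c}")
        rxn(
            f"TPT_C{c}",
            {f"carbon{c}_e": -1, f"carbon{c}_c": 1},
            gpr=f"gT{c}",
            subsystem="transport",
        )
        genes.append(f"gM{c}")
        rxn(
            f"CAT_C{c}",
            {f"carbon{c}_c": -1, "prec1": 2},
            gpr=f"gM{c}",
            subsystem=f"catabolism_carbon{c}",
            ko="carbohydrate_metabolism",
        )
        if i < spec.n_branches:
            tag = f"CATB_C{c}"
            rxn(
                tag,
                {f"carbon{c}_c": -1, "prec1": 1},
                gpr=gpr_for(tag, f"gB{c}"),
                subsystem=f"catabolism_carbon{c}",
                ko="carbohydrate_metabolism",
            )

    chain = ["prec1"] + [f"core{k}" for k in range(1, spec.n_linear_pathways)] + ["bb"]
    for k in range(spec.n_linear_pathways):
        if k < spec.n_complexes:
            genes.extend([f"gC{k + 1}a", f"gC{k + 1}b"])
            gpr = f"gC{k + 1}a and gC{k + 1}b"
        else:
            genes.append(f"gC{k + 1}")
            gpr = f"gC{k + 1}"
        rxn(
            f"CORE{k + 1}",
            {chain[k]: -1, chain[k + 1]: 1},
            gpr=gpr,
            subsystem="core_biosynthesis",
            ko="amino_acid_metabolism",
        )

    rxn("AA", {"bb": -1, "aa": 1}, gpr=gpr_for("AA", "gA"), subsystem="amino_acid_biosynthesis", ko="amino_acid_metabolism")
    genes.append("gN1")
    rxn("NT1", {"bb": -1, "nt_int": 1}, gpr="gN1", subsystem="nucleotide_biosynthesis", ko="nucleotide_metabolism")
    genes.append("gN2")
    rxn("NT2", {"nt_int": -1, "nt": 1}, gpr="gN2", subsystem="nucleotide_biosynthesis", ko="nucleotide_metabolism")
    rxn("ENER", {"prec1": -1, "o2_c": -1, "energy": 1}, gpr=gpr_for("ENER", "gE"), subsystem="energy_metabolism", ko="energy_metabolism")
    genes.append("gD")
    # forced wasteful drain: constitutive flux that burns precursor and energy
    rxn("DRAIN", {"aa": -1, "energy": -1, "spent_c": 2}, lb=1.0, gpr="gD", subsystem="overflow_metabolism", ko="energy_metabolism")
    rxn("MAINT", {"energy": -1, "spent_c": 1}, lb=0.2, subsystem="maintenance", ko="energy_metabolism")
    rxn("BIOMASS", {"aa": -1, "nt": -1, "energy": -2}, subsystem="biomass")

    return MetabolicModel(
        model_id=f"toy_synthetic_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction="BIOMASS",
    )


def generate_toy_model(spec: SyntheticSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy model and derive its ground truth by exhaustive FBA.

    Deterministic apart from the seeded choice of extra force-zeroed genes.
    Raises if any carbon yields zero wild-type growth (the construction is
    deterministic, so a retry cannot fix it).
    """
    model = _build_network(spec)
    rng = np.random.default_rng(spec.seed)
    media = toy_media(spec)
    excluded = {
        r for r in model.reaction_ids if model.is_exchange(r) or model.is_transport(r)
    }

    wildtype_growth: dict[str, float] = {}
    deletion_growth: dict[str, dict[str, float]] = {}
    essential_per_cond: dict[str, set[str]] = {}
    beneficial: dict[str, set[str]] = {}
    detrimental: dict[str, set[str]] = {}
    for medium in media:
        cond = medium.condition_id
        conditioned = set_medium(model, medium)
        wt = fba(conditioned, condition_id=cond)
        if wt.status != "optimal" or wt.objective_value <= 0:
            raise RuntimeError(
                f"generated model has zero wild-type growth on {cond!r}; "
                "the spec does not admit a growing network"
            )
        wildtype_growth[cond] = wt.objective_value
        growth_c: dict[str, float] = {}
        for gene in model.genes:
            mut = fba(apply_gene_deletion(conditioned, {gene}), strain_id=gene, condition_id=cond)
            growth_c[gene] = mut.objective_value
        deletion_growth[cond] = growth_c
        essential_per_cond[cond] = {
            g for g, mu in growth_c.items() if mu < ESSENTIAL_CUTOFF * wt.objective_value
        }
        beneficial_genes = {
            g for g, mu in growth_c.items() if mu < BENEFICIAL_CUTOFF * wt.objective_value
        }
        beneficial[cond] = (
            map_genes_to_reactions(model, beneficial_genes) - excluded
            if beneficial_genes
            else set()
        )
        detr: set[str] = set()
        for rxn_id in model.reaction_ids:
            # only gene-mediated reactions: a gene-deletion screen cannot
            # perturb spontaneous (empty-GPR) reactions, so they are outside
            # the identifiable universe
            if rxn_id in excluded or rxn_id == model.objective_reaction:
                continue
            if model.reaction(rxn_id).gpr is None:
                continue
            ko = conditioned.with_bounds({rxn_id: (0.0, 0.0)})
            mut = fba(ko, strain_id=f"d{rxn_id}", condition_id=cond)
            if mut.objective_value > DETRIMENTAL_GAIN * wt.objective_value:
                detr.add(rxn_id)
        detrimental[cond] = detr - beneficial[cond]

    core_essential = set.intersection(*essential_per_cond.values())
    n_extra = math.ceil(spec.essential_fraction * len(model.genes))
    pool = sorted(set(model.genes) - core_essential)
    extra = (
        {str(g) for g in rng.choice(pool, size=min(n_extra, len(pool)), replace=False)}
        if n_extra
        else set()
    )
    truth = GroundTruth(
        planted_essential_genes=core_essential | extra,
        planted_beneficial_reactions=beneficial,
        planted_detrimental_reactions=detrimental,
        wildtype_growth=wildtype_growth,
        deletion_growth=deletion_growth,
    )
    return model, truth


def generate_growth_screen(
    model: MetabolicModel,
    truth: GroundTruth,
    spec: SyntheticSpec,
) -> pd.DataFrame:
    """Endpoint-biomass matrix (mutants x carbons) with lognormal noise.

    Rows are single-gene deletion mutants keyed by gene plus a "WT" row;
    entries are FBA growth times multiplicative lognormal(0, noise_sd) noise.
    Mutants of planted essential genes are forced to zero on every carbon.
    """
    rng = np.random.default_rng(spec.seed + 1)
    conditions = sorted(truth.wildtype_growth)
    index = sorted(model.genes) + ["WT"]
    data = np.zeros((len(index), len(conditions)))
    for j, cond in enumerate(conditions):
        for i, strain in enumerate(index):
            if strain == "WT":
                mu = truth.wildtype_growth[cond]
            elif strain in truth.planted_essential_genes:
                data[i, j] = 0.0
                continue
            else:
                mu = truth.deletion_growth[cond][strain]
            noise = rng.lognormal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 1.0
            data[i, j] = mu * noise
    return pd.DataFrame(data, index=index, columns=conditions)
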