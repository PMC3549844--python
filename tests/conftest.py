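"""Shared fixtures: generated toy networks, problem specs, and an
independent cobra/GLPK model builder used as the LP oracle."""

from __future__ import annotations

import numpy as np
import pytest

from momaknock import generate_toy_network, solve_fba
from momaknock.network import MetabolicNetwork, ProblemSpec


@pytest.fixture(scope="session")
def toy_net() -> MetabolicNetwork:
    return generate_toy_network(7, seed=1)


@pytest.fixture(scope="session")
def spec() -> ProblemSpec:
    return ProblemSpec(v_glc_uptake=10.0, v_biom_target=1.0, K=1)


@pytest.fixture(scope="session")
def wild_type(toy_net, spec):
    return solve_fba(toy_net, spec)


def build_cobra_model(net: MetabolicNetwork, spec: ProblemSpec):
    """Independent route: the same constraint set expressed as a cobra model
    solved by GLPK (optlang), with the glucose rate pinned and the biomass
    floor applied.  Used to cross-check the HiGHS-based LP solutions."""
    import cobra

    model = cobra.Model("oracle")
    mets = {mid: cobra.Metabolite(mid) for mid in net.metabolite_ids}
    rxns = []
    for j, rid in enumerate(net.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound, r.upper_bound = float(net.lb[j]), float(net.ub[j])
        col = net.S.getcol(j).tocoo()
        r.add_metabolites(
            {mets[net.metabolite_ids[i]]: float(v) for i, v in zip(col.row, col.data)}
        )
        rxns.append(r)
    model.add_reactions(rxns)
    model.reactions.get_by_id(net.glucose_rxn).bounds = (
        spec.v_glc_uptake,
        spec.v_glc_uptake,
    )
    biom = model.reactions.get_by_id(net.biomass_rxn)
    biom.lower_bound = max(biom.lower_bound, spec.v_biom_target)
    return model


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random point on the probability simplex (valid beta vector)."""
    x = rng.dirichlet(np.ones(n))
    return x
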