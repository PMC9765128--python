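import numpy as np
import pytest

import aromflux as af


@pytest.fixture(scope="session")
def toy_model():
    return af.make_toy_model()


@pytest.fixture(scope="session")
def toy_presets():
    return af.toy_conditions()


@pytest.fixture(scope="session")
def toy_solutions(toy_model, toy_presets):
    """One optimal FBA solution per shipped condition preset."""
    out = {}
    for cond in toy_presets:
        bounded = af.apply_condition(toy_model, cond)
        sol = af.solve_fba(bounded, cond)
        assert sol.optimal
        out[cond.label] = (bounded, sol)
    return out


@pytest.fixture(scope="session")
def toy_ranges(toy_solutions):
    """Flux-variability ranges per condition."""
    return [
        af.flux_variability(bounded, condition_label=label)
        for label, (bounded, _) in toy_solutions.items()
    ]


def linear_chain_model(uptake_max=10.0, ngam=0.0, atp_per_biomass=2.0):
    """Uptake A ≤ uptake_max, A → ATP (1:1), biomass consumes ATP.

    With no maintenance the biomass optimum is uptake_max / atp_per_biomass.
    """
    mets = [
        af.Metabolite("a_e", compartment="external", formula={"C": 1}),
        af.Metabolite("a_c", compartment="cytoplasm", formula={"C": 1}),
        af.Metabolite("atp_c", compartment="cytoplasm", formula={}),
    ]
    rxns = [
        af.Reaction("EX_a", {"a_e": -1}, -uptake_max, 1000.0, category="boundary"),
        af.Reaction("T_a", {"a_e": -1, "a_c": 1}, 0.0, 1000.0, category="transport"),
        af.Reaction("CONV", {"a_c": -1, "atp_c": 1}, 0.0, 1000.0),
        af.Reaction("NGAM", {"atp_c": -1}, ngam, ngam if ngam else 1000.0,
                    category="maintenance"),
        af.Reaction("BIO", {"atp_c": -atp_per_biomass}, 0.0, 1000.0,
                    category="biomass"),
    ]
    return af.MetabolicModel(mets, rxns, "BIO")


@pytest.fixture
def chain_model():
    return linear_chain_model()
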