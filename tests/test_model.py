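"""Model data structures, I/O round-trips and balance checking."""

import json

import numpy as np
import pytest

import aromflux as af
from aromflux.model import (
    ModelParseError,
    ModelValidationError,
    parse_equation,
    stoichiometric_matrix,
)

TOY_JSON = {
    "objective_id": "BIO",
    "metadata": {"name": "three-reaction toy"},
    "metabolites": [
        {"id": "s_e", "compartment": "external", "formula": {"C": 2}},
        {"id": "s_c", "compartment": "cytoplasm", "formula": {"C": 2}},
    ],
    "reactions": [
        {"id": "EX_s", "stoichiometry": {"s_e": -1}, "lower_bound": -10,
         "upper_bound": 0, "category": "boundary"},
        {"id": "T_s", "stoichiometry": {"s_e": -1, "s_c": 1}, "lower_bound": 0,
         "upper_bound": 1000, "category": "transport"},
        {"id": "BIO", "stoichiometry": {"s_c": -1}, "lower_bound": 0,
         "upper_bound": 1000, "category": "biomass"},
    ],
}


def test_load_native_json_counts(tmp_path):
    path = tmp_path / "toy.json"
    path.write_text(json.dumps(TOY_JSON))
    model = af.load_model(path, "native-json")
    assert len(model.reactions) == 3
    assert len(model.metabolites) == 2
    assert model.objective_id == "BIO"


def test_undeclared_metabolite_is_an_error(tmp_path):
    doc = json.loads(json.dumps(TOY_JSON))
    doc["reactions"][1]["stoichiometry"]["ghost_c"] = 1.0
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelValidationError, match="ghost_c"):
        af.load_model(path, "native-json")


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda d: d["metabolites"].append({"id": "s_e", "compartment": "external"}),
         "duplicate metabolite"),
        (lambda d: d.update(objective_id="NOPE"), "not in model"),
        (lambda d: d["reactions"][0]["stoichiometry"].update(s_c=1.0),
         "exactly one metabolite"),
    ],
)
def test_validation_errors(tmp_path, mutate, message):
    doc = json.loads(json.dumps(TOY_JSON))
    mutate(doc)
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelValidationError, match=message):
        af.load_model(path, "native-json")


def test_malformed_json_names_line(tmp_path):
    path = tmp_path / "broken.json"
    path.write_text('{"metabolites": [,]}')
    with pytest.raises(ModelParseError, match="line"):
        af.load_model(path, "native-json")


def test_json_round_trip_is_lossless(tmp_path, toy_model):
    path = tmp_path / "toy_model.json"
    af.save_model(toy_model, path)
    back = af.load_model(path, "native-json")
    assert back.objective_id == toy_model.objective_id
    assert back.metadata == toy_model.metadata
    for a, b in zip(toy_model.metabolites, back.metabolites):
        assert (a.id, a.name, a.compartment, a.charge) == (b.id, b.name, b.compartment, b.charge)
        assert a.formula == b.formula
    for a, b in zip(toy_model.reactions, back.reactions):
        assert a.id == b.id
        assert a.stoichiometry == b.stoichiometry
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert a.gene_association == b.gene_association
        assert a.category == b.category


class TestSummary:
    def test_per_category_counts(self):
        model = af.MetabolicModel(
            [af.Metabolite("x_e", compartment="external"),
             af.Metabolite("x_c")],
            [af.Reaction("EX", {"x_e": -1}, category="boundary"),
             af.Reaction("T", {"x_e": -1, "x_c": 1}, category="transport",
                         gene_association=("g1",)),
             af.Reaction("E", {"x_c": -1}, category="enzymatic"),
             af.Reaction("BIO", {"x_c": -1}, category="biomass")],
            "BIO",
        )
        counts = af.model_summary(model)
        assert counts.per_category == {"boundary": 1, "transport": 1,
                                       "enzymatic": 1, "biomass": 1}
        assert counts.n_reactions_total == 4
        # enzymatic + gene-associated transport count as enzyme-catalyzed
        assert counts.n_enzyme_catalyzed == 2

    def test_totals_conserved_under_reordering(self, toy_model):
        counts = af.model_summary(toy_model)
        assert sum(counts.per_category.values()) == counts.n_reactions_total
        shuffled = toy_model.copy()
        shuffled.reactions = list(reversed(shuffled.reactions))
        again = af.model_summary(shuffled)
        assert again.per_category == counts.per_category
        assert again.n_enzyme_catalyzed == counts.n_enzyme_catalyzed

    def test_gene_free_transport_not_enzyme_catalyzed(self, toy_model):
        counts = af.model_summary(toy_model)
        by_hand = sum(
            1 for r in toy_model.reactions
            if r.category == "enzymatic"
            or (r.category == "transport" and r.gene_association)
        )
        assert counts.n_enzyme_catalyzed == by_hand
        # O2 enters by diffusion (no genes) and must not be counted
        assert not toy_model.reaction("T_o2").gene_association


class TestMassBalance:
    def _two_met_model(self, formula_a, formula_b):
        return af.MetabolicModel(
            [af.Metabolite("A", formula=formula_a), af.Metabolite("B", formula=formula_b),
             af.Metabolite("bio")],
            [af.Reaction("R", {"A": -1, "B": 1}),
             af.Reaction("BIO", {"bio": -1}, category="biomass")],
            "BIO",
        )

    def test_balanced_conversion(self):
        model = self._two_met_model({"C": 2, "H": 4, "O": 2}, {"C": 2, "H": 4, "O": 2})
        report = af.check_mass_balance(model, ["C", "H", "O"])
        assert report.balanced
        assert "R" not in report.unchecked
        # "bio" has no formula, so BIO would be unchecked — but biomass is exempt
        assert report.unchecked == []

    def test_carbon_deficit_reported(self):
        model = self._two_met_model({"C": 2}, {"C": 1})
        report = af.check_mass_balance(model, ["C"])
        assert report.imbalances == {"R": {"C": -1.0}}

    def test_missing_formula_marks_unchecked(self):
        model = self._two_met_model({"C": 1}, None)
        report = af.check_mass_balance(model, ["C"])
        assert report.unchecked == ["R"]
        assert report.balanced  # no *known* imbalance, but R is flagged

    def test_unknown_element_warns(self):
        model = self._two_met_model({"C": 1}, {"C": 1})
        with pytest.warns(UserWarning, match="not checked"):
            report = af.check_mass_balance(model, ["C", "Xx"])
        assert report.balanced

    def test_single_corruption_yields_single_entry(self, toy_model):
        assert af.check_mass_balance(toy_model, ["C"]).balanced
        corrupt = toy_model.copy()
        corrupt.reaction("TCA").stoichiometry["co2_c"] += 1.0
        report = af.check_mass_balance(corrupt, ["C"])
        assert list(report.imbalances) == ["TCA"]
        assert report.imbalances["TCA"]["C"] == pytest.approx(1.0)


class TestStoichiometricMatrix:
    def test_column_signs(self):
        model = af.MetabolicModel(
            [af.Metabolite("A"), af.Metabolite("B")],
            [af.Reaction("R", {"A": -1, "B": 1}),
             af.Reaction("BIO", {"B": -1}, category="biomass")],
            "BIO",
        )
        S = stoichiometric_matrix(model).toarray()
        assert S.shape == (2, 2)
        assert S[0, 0] == -1 and S[1, 0] == 1
        assert S[1, 1] == -1

    def test_round_trip_rebuild(self, toy_model):
        S = stoichiometric_matrix(toy_model)
        assert S.shape == (len(toy_model.metabolites), len(toy_model.reactions))
        mids = toy_model.metabolite_ids
        dense = S.toarray()
        for j, rxn in enumerate(toy_model.reactions):
            rebuilt = {mids[i]: dense[i, j] for i in np.nonzero(dense[:, j])[0]}
            assert rebuilt == rxn.stoichiometry


class TestEquationTSV:
    @pytest.mark.parametrize(
        "equation, expected, reversible",
        [
            ("2 A + B -> C", {"A": -2.0, "B": -1.0, "C": 1.0}, False),
            ("A <-> B", {"A": -1.0, "B": 1.0}, True),
            ("A ->", {"A": -1.0}, False),
            ("0.5 A -> B", {"A": -0.5, "B": 1.0}, False),
        ],
    )
    def test_parse_equation(self, equation, expected, reversible):
        stoich, rev = parse_equation(equation)
        assert stoich == expected
        assert rev is reversible

    def test_parse_error(self):
        with pytest.raises(ModelParseError, match="arrow"):
            parse_equation("A + B")

    def test_tsv_load_and_solve(self, tmp_path):
        rows = [
            "id\tequation\tlower_bound\tupper_bound\tgenes\tcategory",
            "EX_s\ts_e ->\t-10\t1000\t\tboundary",
            "T_s\ts_e -> s_c\t\t\t\ttransport",
            "CONV\ts_c -> 2 x_c\t\t\tgene1\t",
            "BIO\t2 x_c ->\t\t\t\tbiomass",
        ]
        path = tmp_path / "model.tsv"
        path.write_text("\n".join(rows) + "\n")
        model = af.load_model(path, "tsv")
        assert len(model.reactions) == 4
        assert model.reaction("CONV").gene_association == ("gene1",)
        sol = af.solve_fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0)


class TestSBML:
    def test_import_matches_cobra(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("mini")
        a_e = cobra.Metabolite("a_e", compartment="e")
        a_c = cobra.Metabolite("a_c", compartment="c")
        ex = cobra.Reaction("EX_a", lower_bound=-5.0, upper_bound=0.0)
        ex.add_metabolites({a_e: -1})
        t = cobra.Reaction("T_a", lower_bound=0.0, upper_bound=1000.0)
        t.add_metabolites({a_e: -1, a_c: 1})
        bio = cobra.Reaction("BIOMASS_mini", lower_bound=0.0, upper_bound=1000.0)
        bio.add_metabolites({a_c: -1})
        cm.add_reactions([ex, t, bio])
        cm.objective = "BIOMASS_mini"
        path = tmp_path / "mini.xml"
        cobra.io.write_sbml_model(cm, str(path))

        model = af.load_model(path, "sbml")
        assert len(model.reactions) == 3
        assert model.objective_id == "BIOMASS_mini"
        sol = af.solve_fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(cm.optimize().objective_value)


def test_unknown_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown format"):
        af.load_model(tmp_path / "x", "yaml")
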