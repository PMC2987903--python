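"""Model representation, medium overlay and FBA behaviour."""

import pytest
from hypothesis import given, strategies as st

from symbiomedia.core_model import (
    Medium,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    apply_medium,
    check_steady_state,
    formula_to_string,
    grows,
    parse_formula,
    solve_fba,
)


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("CH2O", {"C": 1, "H": 2, "O": 1}),
            ("H2S", {"H": 2, "S": 1}),
            ("NaCl", {"Na": 1, "Cl": 1}),
            ("CH3CH3", {"C": 2, "H": 6}),
            ("", {}),
            ("-", {}),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text) == expected

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_formula("c6h12")

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe", "Mg"]),
            st.integers(min_value=1, max_value=40),
            min_size=1,
            max_size=6,
        )
    )
    def test_roundtrip(self, formula):
        assert parse_formula(formula_to_string(formula)) == formula


class TestStructuralInvariants:
    def test_reaction_bounds_must_order(self):
        with pytest.raises(ModelError):
            Reaction("r", {"a": -1.0}, 5, -5)

    def test_exchange_touches_one_metabolite(self):
        with pytest.raises(ModelError):
            Reaction("ex", {"a": -1.0, "b": 1.0}, 0, 10, kind="exchange")

    def test_dangling_stoichiometry_rejected(self):
        with pytest.raises(ModelError):
            MetabolicModel(
                "m",
                [Metabolite("a", "CYT")],
                [Reaction("r", {"a": -1.0, "ghost": 1.0}, 0, 10)],
            )

    def test_medium_rates_positive(self):
        with pytest.raises(ModelError):
            Medium({"a": 0.0})


class TestApplyMedium:
    def test_bounds_overlay(self, toy_pair):
        m1, _, _ = toy_pair
        applied = apply_medium(m1, Medium({"X_e": 10, "Z_e": 10}))
        assert applied.reaction("EX_X").lower_bound == -10
        assert applied.reaction("EX_Z").lower_bound == -10
        assert applied.reaction("EX_Y").lower_bound == 0
        # secretion caps untouched
        assert applied.reaction("EX_Y").upper_bound == 1000
        # source model untouched
        assert m1.reaction("EX_X").lower_bound == -1000

    def test_empty_medium_closes_all_uptake(self, toy_pair):
        m1, _, _ = toy_pair
        applied = apply_medium(m1, Medium({}))
        assert all(r.lower_bound == 0 for r in applied.exchange_reactions())

    def test_unknown_metabolite_named_in_error(self, toy_pair):
        m1, _, _ = toy_pair
        with pytest.raises(ModelError, match="unknown medium metabolite Q"):
            apply_medium(m1, Medium({"Q": 5}))


class TestSolveFba:
    def test_growth_on_full_medium(self, toy_pair):
        m1, _, _ = toy_pair
        sol = solve_fba(m1, Medium({"X_e": 10, "Z_e": 10}))
        assert sol.ok and sol.objective_value > 0

    @pytest.mark.parametrize("availability", [{}, {"X_e": 10}])
    def test_insufficient_media_mean_zero_growth(self, toy_pair, availability):
        m1, _, _ = toy_pair
        sol = solve_fba(m1, Medium(availability))
        assert sol.ok and sol.objective_value == pytest.approx(0, abs=1e-9)

    def test_steady_state_and_bounds_of_optimum(self, toy_pair):
        m1, _, _ = toy_pair
        medium = Medium({"X_e": 10, "Z_e": 10})
        sol = solve_fba(m1, medium)
        assert check_steady_state(m1, sol) <= 1e-6
        applied = apply_medium(m1, medium)
        for rxn in applied.reactions:
            v = sol.fluxes[rxn.id]
            assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9

    def test_monotone_in_medium(self, toy_pair):
        """Enlarging the medium can never decrease the optimal biomass flux."""
        m1, _, _ = toy_pair
        small = solve_fba(m1, Medium({"X_e": 4, "Z_e": 2})).objective_value
        bigger = solve_fba(m1, Medium({"X_e": 8, "Z_e": 2})).objective_value
        superset = solve_fba(m1, Medium({"X_e": 8, "Z_e": 2, "Y_e": 5})).objective_value
        assert small <= bigger + 1e-9 <= superset + 2e-9

    def test_homogeneous_scaling(self, toy_pair):
        """Doubling all availabilities doubles the toy optimum (LP homogeneity)."""
        m1, _, _ = toy_pair
        base = solve_fba(m1, Medium({"X_e": 10, "Z_e": 10})).objective_value
        doubled = solve_fba(m1, Medium({"X_e": 20, "Z_e": 20})).objective_value
        assert doubled == pytest.approx(2 * base, rel=1e-9)


class TestGrows:
    def test_toy_truths(self, toy_pair):
        _, m2, _ = toy_pair
        assert grows(m2, Medium({"X_e": 10, "Y_e": 10}))
        assert not grows(m2, Medium({"X_e": 10, "Z_e": 10}))

    def test_eps_must_be_positive(self, toy_pair):
        m1, _, _ = toy_pair
        with pytest.raises(ValueError):
            grows(m1, Medium({"X_e": 10}), eps=0)


def test_fba_agrees_with_cobra_oracle(toy_pair):
    """Cross-check the LP layer against an independent implementation."""
    cobra = pytest.importorskip("cobra")
    m1, _, _ = toy_pair

    cm = cobra.Model("toy1")
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment) for m in m1.metabolites}
    for rxn in m1.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
    cm.objective = "BIO"
    medium = Medium({"X_e": 10, "Z_e": 10})
    for rxn in cm.exchanges:
        pass  # our exchange reactions are explicit columns; set bounds directly
    cm.reactions.EX_X.lower_bound = -10
    cm.reactions.EX_Z.lower_bound = -10
    cm.reactions.EX_Y.lower_bound = 0
    expected = cm.optimize().objective_value

    ours = solve_fba(m1, medium).objective_value
    assert ours == pytest.approx(expected, rel=1e-6)
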