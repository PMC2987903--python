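"""Media search: replacement recursion, assembly, classification pipeline."""

import itertools

import pytest

from symbiomedia.core_model import Medium
from symbiomedia.fixtures import make_random_pair
from symbiomedia.joint_builder import build_joint
from symbiomedia.milp_common import MilpConfig
from symbiomedia.sim_search import (
    INTERACTION_CLASSES,
    InfeasibleSeedError,
    assemble_media,
    classify_interaction,
    find_replacements,
    interaction_class_from_growth,
    joint_dual_growth,
    run_sim,
)

from oracles import sim_bruteforce_media


class TestTruthTable:
    def test_exhaustive_and_mutually_exclusive(self):
        for booleans in itertools.product([True, False], repeat=4):
            gj, ga = booleans[:2], booleans[2:]
            cls = interaction_class_from_growth(gj, ga)
            assert cls in INTERACTION_CLASSES

    @pytest.mark.parametrize(
        "gj,ga,expected",
        [
            ((True, True), (True, True), "neutralism"),
            ((True, True), (True, False), "commensal_1_provider"),
            ((True, True), (False, True), "commensal_2_provider"),
            ((True, True), (False, False), "mutualism"),
            ((True, False), (True, True), "no_growth"),
            ((False, False), (False, False), "no_growth"),
        ],
    )
    def test_assignments(self, gj, ga, expected):
        assert interaction_class_from_growth(gj, ga) == expected


class TestClassifyToy:
    @pytest.mark.parametrize(
        "availability,expected",
        [
            ({"X": 10}, "mutualism"),
            ({"X": 10, "Z": 10}, "commensal_1_provider"),
            ({"X": 10, "Y": 10}, "commensal_2_provider"),
            ({"X": 10, "Y": 10, "Z": 10}, "neutralism"),
            ({"Y": 10, "Z": 10}, "no_growth"),
        ],
    )
    def test_media(self, toy_joint, config, availability, expected):
        record = classify_interaction(toy_joint, Medium(availability), config)
        assert record.interaction_class == expected


class TestFindReplacements:
    def test_planted_carbon_sources_found_as_singletons(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="mutual", seed=3)
        joint = build_joint(m1, m2, mm)
        reps = find_replacements("C", joint, truth.designed_medium, config=config)
        assert reps == [frozenset({c}) for c in truth.viable_carbon_sources]

    def test_absent_element_recovers_growing_singletons(self, toy_joint, config):
        # no phosphorus source in the toy medium: stripping removes nothing,
        # so any pool metabolite keeping the (already growing) medium viable
        # comes back as a degenerate replacement
        reps = find_replacements("P", toy_joint, Medium({"X": 10}), config=config)
        assert reps == [frozenset({"Y"}), frozenset({"Z"})]

    def test_exhausted_pool_returns_empty(self, toy_joint, config):
        reps = find_replacements(
            "C", toy_joint, Medium({"X": 10}), pool=[], config=config
        )
        assert reps == []

    def test_sole_carbon_source_recovers_only_itself(self, toy_joint, config):
        """X is the only viable carbon source: the stripped source re-enters
        the pool and is found back, and nothing else restores growth."""
        reps = find_replacements("C", toy_joint, Medium({"X": 10}), config=config)
        assert reps == [frozenset({"X"})]

    def test_no_replacement_exists_returns_empty(self, toy_joint, config):
        """With X barred from the pool the carbon branch terminates empty."""
        reps = find_replacements(
            "C", toy_joint, Medium({"X": 10}), pool=["Y", "Z"], config=config
        )
        assert reps == []

    def test_multi_metabolite_replacement_bifurcates(self, config):
        """Stripping hydrogen removes every source; only pairs restore growth."""
        m1, m2, mm, truth = make_random_pair(dependency_plan="neutral", seed=2)
        joint = build_joint(m1, m2, mm)
        reps = find_replacements("H", joint, truth.designed_medium, config=config)
        assert reps and all(len(s) == 2 for s in reps)
        assert len(reps) >= 2  # bifurcation explored alternatives
        for s in reps:
            assert joint_dual_growth(
                joint, Medium({m: 10.0 for m in s}), config
            )


class TestAssembleMedia:
    def test_product_count(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="neutral", seed=0)
        joint = build_joint(m1, m2, mm)
        reps = {
            "C": [frozenset({"cs1"}), frozenset({"cs2"})],
            "N": [frozenset({"ns1"}), frozenset({"ns2"}), frozenset({"ns3"})],
        }
        media = assemble_media(reps, truth.designed_medium, joint, config)
        assert len(media) == 6

    def test_shared_metabolite_counted_once(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="neutral", seed=0)
        joint = build_joint(m1, m2, mm)
        reps = {
            "C": [frozenset({"dc1"})],
            "N": [frozenset({"dc1", "ns1"})],
        }
        media = assemble_media(reps, truth.designed_medium, joint, config)
        assert len(media) == 1
        assert media[0].metabolite_ids == {"dc1", "ns1"}

    def test_empty_replacement_list_kills_assembly(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="neutral", seed=0)
        joint = build_joint(m1, m2, mm)
        reps = {"C": [], "N": [frozenset({"ns1"})]}
        assert assemble_media(reps, truth.designed_medium, joint, config) == []


class TestRunSim:
    @pytest.mark.parametrize("plan", ["neutral", "commensal_1to2", "mutual"])
    def test_planted_classes_recovered_everywhere(self, plan, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan=plan, seed=11)
        joint = build_joint(m1, m2, mm)
        records = run_sim(joint, truth.designed_medium, ("C", "N"), config)
        growing = [r for r in records if r.interaction_class != "no_growth"]
        assert growing, "media search found nothing"
        assert {r.interaction_class for r in growing} == {truth.expected_class}

    def test_media_match_bruteforce_enumeration(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="mutual", seed=4)
        joint = build_joint(m1, m2, mm)
        records = run_sim(joint, truth.designed_medium, ("C", "N"), config)
        ours = {r.medium.metabolite_ids for r in records
                if r.interaction_class != "no_growth"}
        oracle = sim_bruteforce_media(joint, truth.designed_medium, ("C", "N"), config)
        assert ours == oracle

    def test_emitted_growing_media_reverify(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="commensal_2to1", seed=9)
        joint = build_joint(m1, m2, mm)
        for rec in run_sim(joint, truth.designed_medium, ("C", "N"), config):
            if rec.interaction_class != "no_growth":
                assert joint_dual_growth(joint, rec.medium, config)

    def test_class_counts_partition_growing_media(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="commensal_1to2", seed=6)
        joint = build_joint(m1, m2, mm)
        records = run_sim(joint, truth.designed_medium, ("C", "N"), config)
        growing = sum(
            1 for r in records
            if r.grows_joint[0] and r.grows_joint[1]
        )
        by_class = sum(
            1 for r in records
            if r.interaction_class in
            ("mutualism", "commensal_1_provider", "commensal_2_provider", "neutralism")
        )
        assert growing == by_class

    def test_pool_permutation_invariance(self, config):
        m1, m2, mm, truth = make_random_pair(dependency_plan="mutual", seed=8)
        joint = build_joint(m1, m2, mm)
        pool = sorted(joint.env_metabolites - truth.designed_medium.metabolite_ids)
        forward = run_sim(joint, truth.designed_medium, ("C", "N"), config, pool=pool)
        backward = run_sim(
            joint, truth.designed_medium, ("C", "N"), config, pool=pool[::-1]
        )
        as_sets = lambda recs: {r.medium.metabolite_ids for r in recs}
        assert as_sets(forward) == as_sets(backward)

    def test_no_elements_returns_seed_record(self, toy_joint, config):
        records = run_sim(toy_joint, Medium({"X": 10}), (), config)
        assert len(records) == 1
        assert records[0].interaction_class == "mutualism"

    def test_infeasible_seed_raises(self, toy_joint, config):
        with pytest.raises(InfeasibleSeedError):
            run_sim(toy_joint, Medium({"Y": 10}), ("C",), config)
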