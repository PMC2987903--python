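"""Usage matrix, Jaccard clustering, perturbations, transition matrices."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from symbiomedia.core_model import Medium
from symbiomedia.eco_analysis import (
    PerturbationSpec,
    build_usage_matrix,
    cluster_columns,
    clustering_class_accuracy,
    estimate_transitions,
    jaccard_condensed,
    perturb_medium,
    perturb_network,
)
from symbiomedia.fixtures import make_random_pair
from symbiomedia.joint_builder import build_joint
from symbiomedia.sim_search import InteractionRecord, classify_interaction
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def _record(mets, cls="neutralism"):
    return InteractionRecord(
        medium=Medium({m: 10.0 for m in mets}),
        grows_joint=(True, True),
        grows_alone=(True, True),
        interaction_class=cls,
    )


class TestUsageMatrix:
    def test_binary_rows(self):
        matrix = build_usage_matrix([_record(["A", "B"]), _record(["B", "C"])])
        assert matrix.metabolite_ids == ["A", "B", "C"]
        assert matrix.data.tolist() == [[1, 1, 0], [0, 1, 1]]

    def test_ubiquitous_metabolite_gives_all_ones_column(self):
        matrix = build_usage_matrix(
            [_record(["A", "B"]), _record(["B", "C"]), _record(["B"])]
        )
        j = matrix.metabolite_ids.index("B")
        assert matrix.data[:, j].tolist() == [1, 1, 1]

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            build_usage_matrix([])

    def test_roundtrip_to_media_sets(self):
        records = [_record(["A", "B"]), _record(["B", "C"]), _record(["A", "C"])]
        matrix = build_usage_matrix(records)
        assert matrix.media_sets() == [r.medium.metabolite_ids for r in records]


class TestJaccard:
    def test_identical_columns_distance_zero(self):
        X = np.array([[1, 1], [0, 0], [1, 1]])
        assert jaccard_condensed(X)[0] == 0.0

    def test_disjoint_columns_distance_one(self):
        X = np.array([[1, 0], [0, 1]])
        assert jaccard_condensed(X)[0] == 1.0

    def test_all_zero_columns_treated_as_identical(self):
        X = np.array([[0, 0], [0, 0]])
        assert jaccard_condensed(X)[0] == 0.0

    @given(
        hnp.arrays(
            dtype=np.int8,
            shape=st.tuples(
                st.integers(min_value=2, max_value=8),
                st.integers(min_value=2, max_value=6),
            ),
            elements=st.integers(min_value=0, max_value=1),
        )
    )
    def test_metric_properties(self, X):
        dist = squareform(jaccard_condensed(X))
        assert np.allclose(dist, dist.T)
        assert ((dist >= 0) & (dist <= 1)).all()
        for i in range(X.shape[1]):
            for j in range(X.shape[1]):
                equal_support = (X[:, i].astype(bool) == X[:, j].astype(bool)).all()
                assert (dist[i, j] == 0) == equal_support


class TestClusterColumns:
    def test_identical_columns_merge_first(self):
        matrix = build_usage_matrix(
            [_record(["A", "B"]), _record(["A", "B", "C"])]
        )
        order, linkage = cluster_columns(matrix)
        # A and B have identical usage -> first merge at height 0
        first = linkage[0]
        merged = {matrix.metabolite_ids[int(first[0])], matrix.metabolite_ids[int(first[1])]}
        assert merged == {"A", "B"} and first[2] == 0.0

    def test_planted_blocks_recovered(self):
        """Four groups of identically-used metabolites map to four clusters."""
        blocks = {
            "w": ["w1", "w2", "w3"],
            "x": ["x1", "x2"],
            "y": ["y1", "y2", "y3"],
            "z": ["z1", "z2"],
        }
        records = []
        for i, key in enumerate(["w", "x", "y", "z"] * 3):
            records.append(_record(blocks[key] + [f"noise{i % 2}"]))
        # noise metabolites appear in many media; block members co-occur exactly
        matrix = build_usage_matrix(records)
        order, linkage = cluster_columns(matrix)
        labels = hierarchy.fcluster(linkage, t=1e-9, criterion="distance")
        by_label = {}
        for mid, lab in zip(matrix.metabolite_ids, labels):
            by_label.setdefault(lab, set()).add(mid)
        recovered = [s for s in by_label.values() if len(s) > 1]
        assert sorted(map(sorted, recovered)) == sorted(
            sorted(v) for v in blocks.values()
        )

    def test_needs_two_columns(self):
        matrix = build_usage_matrix([_record(["A"])])
        with pytest.raises(ValueError):
            cluster_columns(matrix)


class TestClusteringAccuracy:
    @staticmethod
    def _separable_records(n_per_class=12):
        records = []
        for i in range(n_per_class):
            records.append(_record(["glu", "nh4", f"m{i % 3}"], cls="mutualism"))
            records.append(_record(["lys", "ade", f"n{i % 3}"], cls="neutralism"))
        return records

    def test_perfectly_separable_media(self):
        matrix = build_usage_matrix(self._separable_records())
        result = clustering_class_accuracy(matrix)
        assert result.accuracy == 1.0
        assert result.fp == result.fn == 0
        assert result.p_value < 1e-6

    def test_shuffled_labels_score_near_majority_fraction(self):
        rng = np.random.default_rng(42)
        matrix = build_usage_matrix(self._separable_records())
        labels = np.array(matrix.classes)
        majority = max(np.mean(labels == c) for c in set(labels))
        scores = []
        for _ in range(100):
            shuffled = rng.permutation(labels)
            if len(set(shuffled)) < 2:
                continue
            scores.append(
                clustering_class_accuracy(matrix, labels=list(shuffled)).accuracy
            )
        mean = float(np.mean(scores))
        # best-mapping accuracy can't fall below the majority fraction, and
        # under label shuffling it shouldn't exceed it by much
        assert majority <= mean <= majority + 0.1

    def test_single_class_rejected(self):
        matrix = build_usage_matrix([_record(["A"]), _record(["B"])])
        with pytest.raises(ValueError):
            clustering_class_accuracy(matrix, labels=["mutualism", "mutualism"])

    def test_identical_media_with_different_labels_share_fate(self):
        records = [
            _record(["A", "B"], cls="mutualism"),
            _record(["A", "B"], cls="neutralism"),
            _record(["C", "D"], cls="mutualism"),
            _record(["C", "D"], cls="neutralism"),
        ]
        matrix = build_usage_matrix(records)
        result = clustering_class_accuracy(matrix)
        # the twin rows cannot be split, so half the calls must be wrong
        assert result.accuracy == 0.5


@pytest.fixture(scope="module")
def mutual_pair():
    m1, m2, mm, truth = make_random_pair(dependency_plan="mutual", seed=13)
    return build_joint(m1, m2, mm), truth


class TestPerturbMedium:
    def test_unique_viable_swap_found(self, mutual_pair, config):
        joint, truth = mutual_pair
        medium = truth.designed_medium
        current_c = next(m for m in medium if m.startswith("cs"))
        pool = [current_c, "cs2" if current_c != "cs2" else "cs1"]
        rng = np.random.default_rng(0)
        result = perturb_medium(medium, pool, joint, rng, config)
        assert result.ok
        swapped = result.medium.metabolite_ids - medium.metabolite_ids
        assert swapped == {pool[1]}

    def test_pool_without_alternatives_fails_gracefully(self, mutual_pair, config):
        joint, truth = mutual_pair
        medium = truth.designed_medium
        pool = [m for m in medium if m.startswith("cs")]  # only the current one
        result = perturb_medium(medium, pool, joint, np.random.default_rng(0), config)
        assert not result.ok and result.medium is None

    def test_fixed_seed_reproduces_swap(self, mutual_pair, config):
        joint, truth = mutual_pair
        pool = truth.viable_carbon_sources
        a = perturb_medium(truth.designed_medium, pool, joint,
                           np.random.default_rng(7), config)
        b = perturb_medium(truth.designed_medium, pool, joint,
                           np.random.default_rng(7), config)
        assert a.ok and b.ok
        assert a.medium.availability == b.medium.availability


class TestPerturbNetwork:
    def test_deleting_sole_transporter_flips_class(self, toy_joint, config):
        """Deleting organism 1's Z transporter breaks its solo growth on {X,Z}."""
        medium = Medium({"X": 10, "Z": 10})
        before = classify_interaction(toy_joint, medium, config)
        assert before.interaction_class == "commensal_1_provider"
        modified = toy_joint.copy_with_model(toy_joint.model.copy())
        rxn = modified.model.reaction("S1:TZ")
        rxn.lower_bound = rxn.upper_bound = 0.0
        after = classify_interaction(modified, medium, config)
        assert after.interaction_class == "no_growth"

    def test_deleting_flux_zero_reaction_is_neutral(self, mutual_pair, config):
        joint, truth = mutual_pair
        before = classify_interaction(joint, truth.designed_medium, config)
        modified = joint.copy_with_model(joint.model.copy())
        rxn = modified.model.reaction("S1:T_dc1")  # decoy transporter, never used
        rxn.lower_bound = rxn.upper_bound = 0.0
        after = classify_interaction(modified, truth.designed_medium, config)
        assert after.interaction_class == before.interaction_class

    def test_k_insults_apply_exactly_k_deletions(self, toy_joint):
        spec = PerturbationSpec(kind="reaction_deletion", k=3)
        perturbed = perturb_network(toy_joint, spec, np.random.default_rng(1))
        zeroed = [
            r.id for r in perturbed.model.reactions
            if r.lower_bound == 0 and r.upper_bound == 0 and r.kind in
            ("internal", "transport")
        ]
        originally_zero = [
            r.id for r in toy_joint.model.reactions
            if r.lower_bound == 0 and r.upper_bound == 0
        ]
        assert len(set(zeroed) - set(originally_zero)) == 3

    def test_protected_reactions_survive(self, toy_joint):
        spec = PerturbationSpec(kind="reaction_deletion", k=5)
        perturbed = perturb_network(toy_joint, spec, np.random.default_rng(2))
        for rid in (*toy_joint.biomass_ids, *toy_joint.exchange_registry.values(),
                    *toy_joint.shuttle_registry.values()):
            rxn = perturbed.model.reaction(rid)
            assert (rxn.lower_bound, rxn.upper_bound) != (0.0, 0.0)

    def test_addition_without_pool_is_an_error(self, toy_joint):
        spec = PerturbationSpec(kind="reaction_addition", k=1)
        with pytest.raises(ValueError, match="pool"):
            perturb_network(toy_joint, spec, np.random.default_rng(0))


class TestEstimateTransitions:
    def test_rows_sum_to_one(self, toy_joint, config):
        spec = PerturbationSpec(kind="reaction_deletion", k=1)
        matrix = estimate_transitions(
            toy_joint, [Medium({"X": 10})], spec, reps=50, config=config,
            rng=np.random.default_rng(3),
        )
        probs = matrix.probabilities
        for i, row in enumerate(matrix.counts):
            if row.sum() > 0:
                assert abs(probs[i].sum() - 1.0) <= 1e-12

    def test_counts_equal_media_times_reps(self, toy_joint, config):
        spec = PerturbationSpec(kind="reaction_deletion", k=1)
        media = [Medium({"X": 10}), Medium({"X": 10, "Z": 10})]
        matrix = estimate_transitions(
            toy_joint, media, spec, reps=20, config=config,
            rng=np.random.default_rng(4),
        )
        assert matrix.counts.sum() == len(media) * 20

    def test_interchangeable_swap_is_identity(self, config):
        """Swapping among equivalent planted sources never changes the class."""
        m1, m2, mm, truth = make_random_pair(dependency_plan="mutual", seed=21)
        joint = build_joint(m1, m2, mm)
        spec = PerturbationSpec(
            kind="medium_swap", metabolite_pool=truth.viable_carbon_sources
        )
        matrix = estimate_transitions(
            joint, [truth.designed_medium], spec, reps=30, config=config,
            rng=np.random.default_rng(5),
        )
        i = matrix.classes.index(truth.expected_class)
        assert matrix.probabilities[i, i] == 1.0
        assert matrix.counts.sum() == matrix.counts[i, i]

    def test_monte_carlo_matches_exact_deletion_enumeration(self, toy_joint, config):
        """MC transition estimate vs exact enumeration over all deletions."""
        from symbiomedia.eco_analysis import _deletable_reactions

        medium = Medium({"X": 10})
        # exact: delete each eligible reaction once, reclassify
        outcomes = {}
        for rid in _deletable_reactions(toy_joint):
            modified = toy_joint.copy_with_model(toy_joint.model.copy())
            rxn = modified.model.reaction(rid)
            rxn.lower_bound = rxn.upper_bound = 0.0
            cls = classify_interaction(modified, medium, config).interaction_class
            outcomes[rid] = cls
        exact_p_stay = sum(
            1 for c in outcomes.values() if c == "mutualism"
        ) / len(outcomes)

        spec = PerturbationSpec(kind="reaction_deletion", k=1)
        reps = 200
        matrix = estimate_transitions(
            toy_joint, [medium], spec, reps=reps, config=config,
            rng=np.random.default_rng(6),
        )
        i = matrix.classes.index("mutualism")
        mc_p_stay = matrix.probabilities[i, i]
        se = np.sqrt(max(exact_p_stay * (1 - exact_p_stay), 1e-9) / reps)
        assert abs(mc_p_stay - exact_p_stay) <= max(3 * se, 0.02)
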