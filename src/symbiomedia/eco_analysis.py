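"""Analyses downstream of the media search.

* a binary media-by-metabolite usage matrix, with average-linkage
  hierarchical clustering of columns (metabolites) or rows (media) under the
  Jaccard distance;
* a two-class clustering accuracy (confusion counts, accuracy, and a
  hypergeometric enrichment p-value) measuring how well unsupervised media
  clustering separates interaction classes;
* environmental perturbations (random swap of a carbon-containing medium
  metabolite) and network perturbations (random reaction deletions and/or
  additions), with Monte-Carlo estimates of the class-to-class transition
  probability matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

from .core_model import Medium, Reaction
from .joint_builder import JointModel
from .milp_common import MilpConfig
from .sim_search import (
    INTERACTION_CLASSES,
    InteractionRecord,
    classify_interaction,
    joint_dual_growth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UsageMatrix",
    "TransitionMatrix",
    "PerturbationSpec",
    "SwapResult",
    "ClusterAccuracy",
    "build_usage_matrix",
    "jaccard_condensed",
    "cluster_columns",
    "clustering_class_accuracy",
    "perturb_medium",
    "perturb_network",
    "estimate_transitions",
]

PERTURBATION_KINDS = (
    "reaction_deletion",
    "reaction_addition",
    "add_and_delete",
    "medium_swap",
)


# ---------------------------------------------------------------------------
# usage matrix and clustering
# ---------------------------------------------------------------------------


@dataclass
class UsageMatrix:
    """Binary media-by-metabolite matrix with row class labels."""

    data: np.ndarray  # shape (n_media, n_metabolites), entries in {0, 1}
    media_ids: list[str]
    classes: list[str]
    metabolite_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, index=self.media_ids, columns=self.metabolite_ids)
        frame.insert(0, "interaction_class", self.classes)
        return frame

    def media_sets(self) -> list[frozenset[str]]:
        cols = np.asarray(self.metabolite_ids)
        return [frozenset(cols[row.astype(bool)]) for row in self.data]


def build_usage_matrix(records: Sequence[InteractionRecord]) -> UsageMatrix:
    """Compile the binary usage matrix from classified media records."""
    if not records:
        raise ValueError("cannot build a usage matrix from zero records")
    metabolites = sorted({m for rec in records for m in rec.medium.metabolite_ids})
    col = {m: j for j, m in enumerate(metabolites)}
    data = np.zeros((len(records), len(metabolites)), dtype=np.int8)
    for i, rec in enumerate(records):
        for mid in rec.medium.metabolite_ids:
            data[i, col[mid]] = 1
    return UsageMatrix(
        data=data,
        media_ids=[f"medium_{i}" for i in range(len(records))],
        classes=[rec.interaction_class for rec in records],
        metabolite_ids=metabolites,
    )


def jaccard_condensed(columns: np.ndarray) -> np.ndarray:
    """Condensed Jaccard distance over the columns of a binary matrix.

    ``d(u, v) = 1 - |u & v| / |u | v|``; a pair of all-zero columns has
    distance 0 (identical support) rather than the undefined 0/0, which is
    logged once.
    """
    X = np.asarray(columns, dtype=bool)
    n = X.shape[1]
    inter = (X.T.astype(np.int32) @ X.astype(np.int32)).astype(float)
    sizes = X.sum(axis=0).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    zero_pairs = union == 0
    if zero_pairs.sum() > n:  # off-diagonal all-zero pairs exist
        logger.warning("all-zero columns present; their mutual distance is 0")
    dist[zero_pairs] = 0.0
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def cluster_columns(matrix: UsageMatrix) -> tuple[list[int], np.ndarray]:
    """Average-linkage hierarchical clustering of the metabolite columns.

    Returns the leaf ordering (column indices) and the linkage matrix.
    Deterministic given the input column order.
    """
    if matrix.data.shape[1] < 2:
        raise ValueError("need at least two columns to cluster")
    dist = jaccard_condensed(matrix.data)
    linkage = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(linkage)
    return list(map(int, order)), linkage


@dataclass
class ClusterAccuracy:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    p_value: float
    positive_class: str
    cluster_of_positive: int

    def counts(self) -> dict[str, int]:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def clustering_class_accuracy(
    matrix: UsageMatrix,
    labels: Sequence[str] | None = None,
    positive_class: str | None = None,
) -> ClusterAccuracy:
    """How well does unsupervised media clustering recover two classes?

    Rows are clustered (Jaccard distance, average linkage), the tree is cut
    into two groups, and each group is assigned the class label that
    maximizes overall accuracy (an upper-bound mapping, since no labels are
    used during clustering).  Accuracy is (TP+TN)/(P+N); the p-value is the
    hypergeometric tail probability of the positive class being at least as
    enriched in its cluster by chance.
    """
    labels = list(labels if labels is not None else matrix.classes)
    uniques = sorted(set(labels))
    if len(uniques) != 2:
        raise ValueError(f"exactly two classes required, got {uniques}")
    if positive_class is None:
        positive_class = "mutualism" if "mutualism" in uniques else uniques[0]
    if positive_class not in uniques:
        raise ValueError(f"positive class {positive_class!r} not in labels")

    dist = jaccard_condensed(matrix.data.T)  # rows as observations
    linkage = hierarchy.linkage(dist, method="average")
    assignment = hierarchy.fcluster(linkage, t=2, criterion="maxclust")

    y = np.array([1 if lab == positive_class else 0 for lab in labels])
    best = None
    for positive_cluster in (1, 2):
        pred = (assignment == positive_cluster).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        acc = (tp + tn) / len(y)
        if best is None or acc > best[0]:
            best = (acc, tp, tn, fp, fn, positive_cluster)
    acc, tp, tn, fp, fn, positive_cluster = best
    # enrichment of the positive class in the positive cluster
    p_value = float(hypergeom.sf(tp - 1, len(y), int(y.sum()), tp + fp))
    return ClusterAccuracy(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=acc, p_value=p_value,
        positive_class=positive_class,
        cluster_of_positive=positive_cluster,
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


@dataclass
class PerturbationSpec:
    """What to perturb and how hard.

    ``k`` is the number of cumulative insults per application;
    ``reaction_pool`` supplies candidate reactions for addition kinds (they
    may reference only metabolites already in the joint model);
    ``metabolite_pool`` supplies swap candidates for ``medium_swap`` (default:
    all carbon-containing ENV metabolites).
    """

    kind: str
    k: int = 1
    reaction_pool: list[Reaction] = field(default_factory=list)
    metabolite_pool: list[str] | None = None
    swap_element: str = "C"
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SwapResult:
    medium: Medium | None
    ok: bool
    attempts: int = 0


def perturb_medium(
    medium: Medium,
    pool: Sequence[str],
    joint: JointModel,
    rng: np.random.Generator,
    config: MilpConfig | None = None,
    element: str = "C",
    max_retries: int = 100,
) -> SwapResult:
    """Swap one random element-containing medium metabolite for another.

    The replacement is drawn uniformly from ``pool`` (minus the current
    medium) and rejection-sampled until the joint model still grows; an
    exhausted retry budget yields ``ok=False`` rather than an exception.
    """
    config = config or MilpConfig()
    model = joint.model
    swappable = sorted(
        m for m in medium.metabolite_ids
        if model.has_metabolite(m) and model.metabolite(m).has_element(element)
    )
    if not swappable:
        raise ValueError(f"medium has no {element}-containing metabolite to swap")
    candidates = sorted(
        m for m in pool
        if m not in medium
        and model.has_metabolite(m)
        and model.metabolite(m).has_element(element)
    )
    if not candidates:
        return SwapResult(medium=None, ok=False, attempts=0)
    for attempt in range(1, max_retries + 1):
        out = swappable[int(rng.integers(len(swappable)))]
        repl = candidates[int(rng.integers(len(candidates)))]
        rate = medium.availability[out]
        trial = medium.without(out).adding(repl, rate)
        if joint_dual_growth(joint, trial, config):
            return SwapResult(medium=trial, ok=True, attempts=attempt)
    return SwapResult(medium=None, ok=False, attempts=max_retries)


def _deletable_reactions(joint: JointModel) -> list[str]:
    protected_kinds = {"biomass", "exchange", "shuttle"}
    return [
        r.id
        for r in joint.model.reactions
        if r.kind not in protected_kinds and r.id not in joint.biomass_ids
    ]


def perturb_network(
    joint: JointModel,
    spec: PerturbationSpec,
    rng: np.random.Generator,
) -> JointModel:
    """Apply ``spec.k`` random reaction insults to a copy of the joint model.

    Deletions zero both bounds of a random internal or transport reaction
    (never biomass, exchange or shuttle reactions); additions append a pool
    reaction with its own bounds.  Pool reactions must reference only
    metabolites already present.
    """
    if spec.kind == "medium_swap":
        raise ValueError("medium_swap perturbs media, not networks")
    needs_pool = spec.kind in ("reaction_addition", "add_and_delete")
    if needs_pool and not spec.reaction_pool:
        raise ValueError(f"perturbation kind {spec.kind} requires a reaction pool")
    model = joint.model.copy()
    added: set[str] = set()
    for _ in range(spec.k):
        if spec.kind in ("reaction_deletion", "add_and_delete"):
            candidates = [
                rid for rid in _deletable_reactions(joint)
                if not (model.reaction(rid).lower_bound == 0
                        and model.reaction(rid).upper_bound == 0)
            ]
            if candidates:
                rid = candidates[int(rng.integers(len(candidates)))]
                rxn = model.reaction(rid)
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
        if spec.kind in ("reaction_addition", "add_and_delete"):
            available = [r for r in spec.reaction_pool if r.id not in added]
            if not available:
                continue
            rxn = available[int(rng.integers(len(available)))].copy()
            unknown = [m for m in rxn.stoichiometry if not model.has_metabolite(m)]
            if unknown:
                raise ValueError(
                    f"pool reaction {rxn.id} references unknown metabolites {unknown}"
                )
            added.add(rxn.id)
            model = _with_reaction(model, rxn)
    return joint.copy_with_model(model)


def _with_reaction(model, rxn: Reaction):
    from .core_model import MetabolicModel

    return MetabolicModel(
        id=model.id,
        metabolites=model.metabolites,
        reactions=model.reactions + [rxn],
        biomass_reaction_id=model.biomass_reaction_id,
        objective=model.objective,
    )


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # square tallies, rows = origin class
    kind: str

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            probs = np.where(totals > 0, self.counts / np.where(totals > 0, totals, 1), 0.0)
        return probs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=self.classes, columns=self.classes)


def estimate_transitions(
    joint: JointModel,
    media_sample: Sequence[Medium],
    spec: PerturbationSpec,
    reps: int,
    config: MilpConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TransitionMatrix:
    """Monte-Carlo class-to-class transition probabilities under perturbation.

    Each medium is classified, then perturbed ``reps`` times independently
    (fresh copy each time) and reclassified; tallies are row-normalized into
    probabilities.  A medium swap that finds no viable replacement counts as
    an unchanged environment (a self-transition).
    """
    config = config or MilpConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    classes = INTERACTION_CLASSES
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=float)
    swap_pool = spec.metabolite_pool
    if spec.kind == "medium_swap" and swap_pool is None:
        swap_pool = [
            m for m in sorted(joint.env_metabolites)
            if joint.model.metabolite(m).has_element(spec.swap_element)
        ]
    for medium in media_sample:
        origin = classify_interaction(joint, medium, config).interaction_class
        for _ in range(reps):
            if spec.kind == "medium_swap":
                swap = perturb_medium(
                    medium, swap_pool, joint, rng, config,
                    element=spec.swap_element, max_retries=spec.max_retries,
                )
                if not swap.ok:
                    counts[index[origin], index[origin]] += 1
                    continue
                outcome = classify_interaction(joint, swap.medium, config)
            else:
                perturbed = perturb_network(joint, spec, rng)
                outcome = classify_interaction(perturbed, medium, config)
            counts[index[origin], index[outcome.interaction_class]] += 1
    return TransitionMatrix(classes=classes, counts=counts, kind=spec.kind)
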