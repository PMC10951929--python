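"""Population-level cell-cycle staging from latent representations.

A Gaussian mixture with more components than biological stages (eight by
default, versus six labels) is fitted to pooled latents; the surplus
components absorb sub-populations within a stage.  Stage labels enter only
*after* fitting: each component is named by the majority label of its
members, components sharing a stage are merged (in the reference data this
collapses three G1 components and the two early/mid-S components, 8 -> 5
predictive clusters), and held-out frames are classified by their
highest-responsibility component.

A temporal constraint sharpens the G1/G2 ambiguity, the one confusion a
purely morphological model cannot resolve: within a cycle, any growth-stage
call after the inferred late-S time must be G2 and any before it must be G1.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

from .data import STAGES

__all__ = ["StageClusterModel", "ConfusionMatrix", "fit_gmm",
           "majority_stage_mapping", "merge_components", "classify_frames",
           "confusion_and_accuracy", "apply_g1g2_constraint", "merge_labels",
           "StagingGMM", "EARLY_MID_S_MERGE"]

#: The reference merge: early-S and mid-S frames form one "S" cluster.
EARLY_MID_S_MERGE: dict[str, str] = {"earlyS": "S", "midS": "S"}


def _stage_rank(stage: str) -> int:
    order = list(STAGES) + sorted(set([stage]) - set(STAGES))
    return order.index(stage)


def fit_gmm(latents: np.ndarray, k: int = 8, seed: int = 0,
            covariance_type: str = "full") -> GaussianMixture:
    """Fit a k-component Gaussian mixture to pooled latent vectors."""
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2:
        raise ValueError("latents must be (n, d)")
    if len(latents) <= k * latents.shape[1]:
        raise ValueError(
            f"need more than {k * latents.shape[1]} points to fit "
            f"{k} components in {latents.shape[1]}-d")
    gmm = GaussianMixture(n_components=k, covariance_type=covariance_type,
                          random_state=seed, init_params="kmeans")
    gmm.fit(latents)
    return gmm


def majority_stage_mapping(assignments: np.ndarray, labels: np.ndarray,
                           n_components: int | None = None
                           ) -> dict[int, str]:
    """Name each mixture component by the modal stage label of its members.

    Ties break towards the stage with more frames overall, then by canonical
    stage order.  An empty component maps to the globally most frequent
    stage, with a warning.
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels must have equal length")
    if n_components is None:
        n_components = int(assignments.max()) + 1
    global_counts = Counter(labels.tolist())

    def keyfun(stage_count):
        stage, count = stage_count
        return (-count, -global_counts[stage], _stage_rank(stage))

    global_best = min(global_counts.items(), key=keyfun)[0]
    mapping = {}
    for comp in range(n_components):
        members = labels[assignments == comp]
        if len(members) == 0:
            warnings.warn(f"component {comp} has no assigned frames; "
                          f"mapping it to the most frequent stage")
            mapping[comp] = global_best
            continue
        mapping[comp] = min(Counter(members.tolist()).items(), key=keyfun)[0]
    return mapping


def merge_labels(labels: np.ndarray,
                 label_merges: dict[str, str] | None) -> np.ndarray:
    """Apply a stage-renaming map (e.g. earlyS/midS -> S) to label arrays."""
    if not label_merges:
        return np.asarray(labels)
    return np.array([label_merges.get(s, s) for s in np.asarray(labels)])


@dataclass
class StageClusterModel:
    """Fitted mixture plus the component -> stage naming after merging."""

    gmm: GaussianMixture
    component_to_stage: dict[int, str]
    stages: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if set(self.component_to_stage) != set(range(self.gmm.n_components)):
            raise ValueError("every component needs exactly one stage")
        self.stages = tuple(sorted(set(self.component_to_stage.values()),
                                   key=_stage_rank))


def merge_components(gmm: GaussianMixture, component_to_stage: dict[int, str],
                     label_merges: dict[str, str] | None = None
                     ) -> StageClusterModel:
    """Merge same-stage components into single predictive stages.

    ``label_merges`` optionally renames stages first (the reference pipeline
    merges early-S and mid-S into one "S" cluster before this step).
    """
    mapping = {c: (label_merges or {}).get(s, s)
               for c, s in component_to_stage.items()}
    return StageClusterModel(gmm=gmm, component_to_stage=mapping)


def classify_frames(model: StageClusterModel, latents: np.ndarray
                    ) -> np.ndarray:
    """Stage call per frame: the stage of the argmax-responsibility component."""
    comp = model.gmm.predict(np.asarray(latents, dtype=np.float64))
    lut = np.array([model.component_to_stage[c]
                    for c in range(model.gmm.n_components)])
    return lut[comp]


@dataclass
class ConfusionMatrix:
    """Counts of true stage (rows) versus predicted stage (columns)."""

    counts: np.ndarray
    stage_order: tuple[str, ...]

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * np.trace(self.counts) / self.counts.sum()


def confusion_and_accuracy(pred: np.ndarray, truth: np.ndarray,
                           stage_order: tuple[str, ...] | None = None
                           ) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix over the union of stages and accuracy in percent."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    if stage_order is None:
        stage_order = tuple(sorted(set(pred) | set(truth), key=_stage_rank))
    index = {s: i for i, s in enumerate(stage_order)}
    unknown = (set(pred) | set(truth)) - set(stage_order)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    counts = np.zeros((len(stage_order), len(stage_order)), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(counts=counts, stage_order=tuple(stage_order))
    return cm, cm.accuracy_percent


def apply_g1g2_constraint(stages: np.ndarray, lateS_frame: int,
                          start: int = 0, end: int | None = None
                          ) -> np.ndarray:
    """Temporal G1/G2 disambiguation around the inferred late-S time.

    Within ``[start, end)`` (default: the whole trajectory), a G1 call at or
    after ``lateS_frame`` becomes G2 and a G2 call before it becomes G1;
    every other call is untouched.  Idempotent.
    """
    stages = np.asarray(stages)
    end = len(stages) if end is None else end
    if not start <= lateS_frame < end:
        raise ValueError("lateS_frame outside the trajectory segment")
    out = stages.copy()
    idx = np.arange(len(stages))
    seg = (idx >= start) & (idx < end)
    out[seg & (idx >= lateS_frame) & (stages == "G1")] = "G2"
    out[seg & (idx < lateS_frame) & (stages == "G2")] = "G1"
    return out


class StagingGMM(BaseEstimator, ClassifierMixin):
    """Scikit-learn front end: GMM staging with post-hoc cluster naming.

    ``fit(X, y)`` clusters latents ``X`` without looking at ``y``, then uses
    ``y`` only to name and merge components; ``predict`` returns stage
    strings for new latents.
    """

    def __init__(self, n_components: int = 8, covariance_type: str = "full",
                 label_merges: dict[str, str] | None = None, seed: int = 0):
        self.n_components = n_components
        self.covariance_type = covariance_type
        self.label_merges = label_merges
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StagingGMM":
        gmm = fit_gmm(X, k=self.n_components, seed=self.seed,
                      covariance_type=self.covariance_type)
        mapping = majority_stage_mapping(
            gmm.predict(np.asarray(X, dtype=np.float64)),
            merge_labels(y, self.label_merges), gmm.n_components)
        self.cluster_model_ = merge_components(gmm, mapping,
                                               self.label_merges)
        self.classes_ = np.array(self.cluster_model_.stages)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return classify_frames(self.cluster_model_, X)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Frame-level accuracy (fraction, not percent) on merged labels."""
        _, acc = confusion_and_accuracy(
            self.predict(X), merge_labels(y, self.label_merges))
        return acc / 100.0
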