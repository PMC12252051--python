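"""K-means over 54-dim gait embeddings, regular-cluster identification and
label-based clustering evaluation.

The number of clusters ``k`` is user-supplied (the method assumes prior
knowledge of how many pathology classes exist); a silhouette-based ``k``
suggestion is offered as a diagnostic only.  Evaluation maps clusters to
classes with maximum-weight bipartite matching on the contingency table —
majority voting can assign two clusters the same class, matching cannot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .types import EmbeddingVector, stack_embeddings


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray            # (k, 54), in standardized space
    assignments: np.ndarray          # (n,) cluster ids
    inertia: float
    seed: int
    scale_mean: np.ndarray = field(default_factory=lambda: np.zeros(54))
    scale_std: np.ndarray = field(default_factory=lambda: np.ones(54))
    regular_cluster_id: Optional[int] = None

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Apply the model's standardization to raw 54-dim vectors."""
        return (vectors - self.scale_mean) / self.scale_std


@dataclass
class EvalResult:
    mapping: dict[int, str]          # cluster id -> class label (injective)
    accuracy: float
    macro_f1: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame          # rows: clusters, cols: classes
    note: str = ""


def fit_kmeans(embeddings: Sequence[EmbeddingVector] | np.ndarray, k: int,
               seed: int = 0, n_init: int = 10,
               standardize: bool = False) -> ClusterModel:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    By default embeddings are clustered on their native scale: first-component
    PCA scores already carry the data's variance structure, and per-dimension
    z-scoring inflates near-constant (dead or noise-only) dimensions until
    they drown the informative ones.  Set ``standardize=True`` to z-score
    each dimension first; centroids are stored in whichever space was used.
    """
    x = embeddings if isinstance(embeddings, np.ndarray) else stack_embeddings(list(embeddings))
    if len(x) < k:
        raise ValueError(f"k={k} exceeds number of instances {len(x)}")
    if standardize:
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std > 1e-12, std, 1.0)
    else:
        mean = np.zeros(x.shape[1])
        std = np.ones(x.shape[1])
    xs = (x - mean) / std
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(xs)
    return ClusterModel(k=k, centroids=km.cluster_centers_,
                        assignments=km.labels_.astype(int),
                        inertia=float(km.inertia_), seed=seed,
                        scale_mean=mean, scale_std=std)


def identify_regular_cluster(model: ClusterModel,
                             reference_index: Sequence[int]) -> int:
    """Designate the cluster holding the majority of known-regular instances.

    ``reference_index`` are positions (into the clustered vectors) of
    instances known to be regular gait — the single piece of supervision the
    explainability metrics require.  Ties break toward the smaller cluster
    id with a warning; low reference purity also warns.
    """
    ref = np.asarray(list(reference_index), dtype=int)
    if ref.size == 0:
        raise ValueError("reference set of known-regular instances is empty; "
                         "the method is semi-supervised and requires one")
    counts = np.bincount(model.assignments[ref], minlength=model.k)
    best = int(np.argmax(counts))  # argmax takes the smallest id on ties
    if (counts == counts[best]).sum() > 1:
        warnings.warn("regular-cluster majority tie; choosing the smaller "
                      "cluster id", stacklevel=2)
    purity = counts[best] / ref.size
    if purity < 0.8:
        warnings.warn(f"regular reference instances are only {purity:.0%} "
                      "concentrated in one cluster", stacklevel=2)
    model.regular_cluster_id = best
    return best


def evaluate_clustering(model: ClusterModel,
                        labels: Sequence[str]) -> EvalResult:
    """Matched clustering accuracy and macro-F1 against ground-truth labels.

    Clusters are paired one-to-one with classes by maximum-weight bipartite
    matching on the contingency table; when ``k`` differs from the number of
    classes only ``min(k, n_classes)`` pairs are formed (noted in the result).
    """
    labels = np.asarray(list(labels))
    if len(labels) != len(model.assignments):
        raise ValueError("labels must cover every clustered instance")
    classes = sorted(set(labels))
    table = np.zeros((model.k, len(classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for a, l in zip(model.assignments, labels):
        table[a, cls_index[l]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    mapping = {int(r): classes[c] for r, c in zip(rows, cols)}
    note = ""
    if model.k != len(classes):
        note = (f"k={model.k} differs from {len(classes)} classes; matched "
                f"{min(model.k, len(classes))} pairs")
    matched = sum(table[r, c] for r, c in zip(rows, cols))
    accuracy = matched / len(labels)

    # macro-F1 over the mapped classes
    f1s = []
    per_class = {}
    for r, c in zip(rows, cols):
        tp = table[r, c]
        fp = table[r].sum() - tp
        fn = table[:, c].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        per_class[classes[c]] = rec
    confusion = pd.DataFrame(table, columns=classes,
                             index=[f"cluster_{i}" for i in range(model.k)])
    return EvalResult(mapping=mapping, accuracy=float(accuracy),
                      macro_f1=float(np.mean(f1s)),
                      per_class_accuracy=per_class, confusion=confusion,
                      note=note)


def suggest_k(vectors: np.ndarray, k_range: Sequence[int] = range(2, 9),
              seed: int = 0) -> pd.DataFrame:
    """Silhouette scores over a range of k — a diagnostic, not a decision."""
    rows = []
    for k in k_range:
        if k >= len(vectors):
            continue
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(vectors)
        rows.append({"k": k, "silhouette": float(
            silhouette_score(vectors, km.labels_))})
    return pd.DataFrame(rows)
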