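"""Performance metrics and the Classification Difficulty Index (CDI).

The accuracy family treats 'unassigned' as a first-class label: the true
type of query cells not covered by the reference is 'unassigned', and
balanced accuracy averages per-type accuracies with 'unassigned' counted as
a type.  The CDI summarizes how hard a reference/query pairing is, from the
batch effect (measured by an F1 of average silhouette widths) and the
proportion of classifiable query cells:

    CDI = sqrt(((1 - F1_ASW)^2 + (1 - P)^2) / 2)
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricReport",
    "CDIReport",
    "accuracy",
    "balanced_accuracy",
    "labeled_metrics",
    "cluster_accuracy",
    "metric_report",
    "f1_asw",
    "cdi",
    "joint_embedding",
]

UNASSIGNED = "unassigned"


@dataclass
class MetricReport:
    accuracy: float
    balanced_accuracy: float
    labeled_accuracy: float | None
    labeled_balanced_accuracy: float | None
    cluster_accuracy: float | None
    confusion: pd.DataFrame  # rows = true types, cols = predicted, row-normalized

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "labeled_accuracy": self.labeled_accuracy,
            "labeled_balanced_accuracy": self.labeled_balanced_accuracy,
            "cluster_accuracy": self.cluster_accuracy,
        }


@dataclass
class CDIReport:
    asw_batch_norm: float
    asw_celltype_norm: float
    f1_asw: float
    p_classifiable: float
    cdi: float


def _as_arrays(pred, truth):
    pred = np.asarray(list(pred), dtype=object)
    truth = np.asarray(list(truth), dtype=object)
    if pred.size == 0:
        raise ValueError("empty prediction/truth vectors")
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    return pred, truth


def accuracy(pred, truth) -> float:
    """Proportion of query cells with exactly matching labels."""
    pred, truth = _as_arrays(pred, truth)
    return float(np.mean(pred == truth))


def balanced_accuracy(pred, truth) -> float:
    """Accuracy averaged over true query cell types ('unassigned' included)."""
    pred, truth = _as_arrays(pred, truth)
    types = sorted(set(truth))
    per_type = [np.mean(pred[truth == t] == t) for t in types]
    return float(np.mean(per_type))


def labeled_metrics(pred, truth) -> tuple[float | None, float | None]:
    """Accuracy and balanced accuracy after removing cells predicted 'unassigned'."""
    pred, truth = _as_arrays(pred, truth)
    keep = pred != UNASSIGNED
    if not keep.any():
        return None, None
    return accuracy(pred[keep], truth[keep]), balanced_accuracy(pred[keep], truth[keep])


def _plurality(labels) -> str:
    counts = Counter(labels)
    return min(counts, key=lambda l: (-counts[l], l))  # lexicographic tie-break


def cluster_accuracy(pred: dict, truth: dict, partition) -> float:
    """Proportion of clusters whose plurality predicted label matches the
    cluster's plurality true type."""
    members = partition.members() if hasattr(partition, "members") else partition
    correct = 0
    for cluster, barcodes in members.items():
        pred_label = _plurality([pred[b] for b in barcodes])
        true_label = _plurality([truth[b] for b in barcodes])
        correct += pred_label == true_label
    return correct / len(members)


def confusion_matrix(pred, truth) -> pd.DataFrame:
    """Row-normalized confusion matrix: rows true types, columns predictions."""
    pred, truth = _as_arrays(pred, truth)
    true_types = sorted(set(truth))
    pred_types = sorted(set(pred) | {UNASSIGNED})
    mat = pd.DataFrame(0.0, index=true_types, columns=pred_types)
    for t in true_types:
        sub = pred[truth == t]
        for p, c in Counter(sub).items():
            mat.loc[t, p] = c / sub.size
    return mat


def metric_report(pred, truth, partition=None) -> MetricReport:
    """Compute the full accuracy family from aligned label vectors.

    ``pred`` and ``truth`` may be dicts (barcode -> label) or aligned
    sequences; a cluster partition enables cluster accuracy.
    """
    if isinstance(pred, dict) and isinstance(truth, dict):
        barcodes = list(truth)
        pred_v = [pred[b] for b in barcodes]
        truth_v = [truth[b] for b in barcodes]
    else:
        pred_v, truth_v = list(pred), list(truth)
    lab_acc, lab_bacc = labeled_metrics(pred_v, truth_v)
    clus = None
    if partition is not None:
        clus = cluster_accuracy(dict(pred), dict(truth), partition)
    return MetricReport(
        accuracy=accuracy(pred_v, truth_v),
        balanced_accuracy=balanced_accuracy(pred_v, truth_v),
        labeled_accuracy=lab_acc,
        labeled_balanced_accuracy=lab_bacc,
        cluster_accuracy=clus,
        confusion=confusion_matrix(pred_v, truth_v),
    )


def _mean_silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton-label points contribute 0."""
    from sklearn.metrics import silhouette_samples

    labels = np.asarray(labels)
    counts = Counter(labels)
    multi = np.array([counts[l] > 1 for l in labels])
    if len(set(labels[multi])) < 2:
        raise ValueError("silhouette needs >= 2 labels with >= 2 members")
    vals = np.zeros(len(labels))
    vals[multi] = silhouette_samples(embedding[multi], labels[multi])
    return float(vals.mean())


def f1_asw(
    embedding: np.ndarray,
    batch_labels,
    celltype_labels,
) -> tuple[float, float, float]:
    """Batch-effect severity as an F1 of average silhouette widths.

    ASW_batch and ASW_celltype are mean silhouette widths (Euclidean) of
    the embedding under batch and cell-type labels, each rescaled to [0,1]
    via (ASW+1)/2.  Returns (asw_batch_norm, asw_celltype_norm, F1_ASW)
    with

        F1 = 2 (1 - ASW_batch_norm) ASW_celltype_norm
             / (1 - ASW_batch_norm + ASW_celltype_norm).
    """
    batch_labels = np.asarray(list(batch_labels))
    celltype_labels = np.asarray(list(celltype_labels))
    if len(set(batch_labels)) < 2 or len(set(celltype_labels)) < 2:
        raise ValueError("need >= 2 batches and >= 2 cell types")
    asw_batch = (_mean_silhouette(embedding, batch_labels) + 1.0) / 2.0
    asw_ct = (_mean_silhouette(embedding, celltype_labels) + 1.0) / 2.0
    return asw_batch, asw_ct, f1_asw_from_norms(asw_batch, asw_ct)


def f1_asw_from_norms(asw_batch_norm: float, asw_celltype_norm: float) -> float:
    """F1_ASW from already-normalized silhouette widths."""
    denom = 1.0 - asw_batch_norm + asw_celltype_norm
    if denom == 0:
        return 0.0
    return 2.0 * (1.0 - asw_batch_norm) * asw_celltype_norm / denom


def cdi(f1_asw_value: float, p_classifiable: float) -> float:
    """Classification Difficulty Index: RMS of (1 - F1_ASW) and (1 - P)."""
    for name, v in (("f1_asw", f1_asw_value), ("p_classifiable", p_classifiable)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return float(
        np.sqrt(((1.0 - f1_asw_value) ** 2 + (1.0 - p_classifiable) ** 2) / 2.0)
    )


def joint_embedding(ref_counts, query_counts, n_pcs: int = 50, seed: int = 0):
    """PCA embedding of the merged, log-normalized reference+query matrix.

    Returns (embedding, batch_labels) with batches 'reference'/'query';
    used as the input space for :func:`f1_asw`.
    """
    from sklearn.decomposition import PCA

    shared = sorted(set(ref_counts.genes) & set(query_counts.genes))
    if not shared:
        raise ValueError("reference and query share no genes")
    r = ref_counts.subset_genes(shared).dense().astype(float)
    q = query_counts.subset_genes(shared).dense().astype(float)
    x = np.concatenate([r.T, q.T], axis=0)  # cells x genes
    depth = x.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    x = np.log1p(x / depth * 1e4)
    n_comps = int(min(n_pcs, x.shape[0] - 1, x.shape[1]))
    emb = PCA(n_components=n_comps, random_state=seed).fit_transform(x)
    batches = np.array(["reference"] * r.shape[1] + ["query"] * q.shape[1])
    return emb, batches
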