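"""Confidence scoring and validation of candidate labels.

For every query cell, a one-sided Wilcoxon rank-sum test asks whether its
candidate type's marker genes are expressed above the cell's remaining
genes; the p-value becomes a confidence score via -log10.  Scores are then
pooled per candidate label and their density decomposed into Gaussian
components; only cells in the highest-mean component are validated.
Low-scoring unvalidated cells become the label's negative controls, and the
validated cells form the local reference used in round 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .io import CellAnnotation, CountMatrix, ValidationError

__all__ = [
    "ConfidenceRecord",
    "LocalReference",
    "MixtureFit",
    "confidence_score",
    "confidence_scores",
    "decompose_scores",
    "validate_round1",
    "build_local_reference",
    "validate_round2",
]


@dataclass
class ConfidenceRecord:
    """Scored candidate assignment for one query cell."""

    barcode: str
    candidate_label: str
    confidence: float
    component_id: int = -1
    validated: bool = False
    negative_control: bool = False
    flagged: bool = False

    def __post_init__(self):
        if self.confidence < 0:
            raise ValidationError("confidence must be >= 0")

    def check(self):
        assert not (self.validated and self.negative_control)


@dataclass
class LocalReference:
    """Validated query cells with their labels and negative-control matrices."""

    counts: CountMatrix
    annotation: CellAnnotation
    negcontrols: dict[str, CountMatrix] = field(default_factory=dict)


def confidence_score(
    cell_counts: np.ndarray,
    genes: list[str],
    marker_genes: list[str],
    log_base: float = 10.0,
) -> tuple[float, bool]:
    """Within-cell marker-vs-rest rank-sum confidence score.

    One-sided p-value that the marker genes outrank the cell's other genes,
    returned as -log_base(p).  Exact enumeration when there are <= 10
    markers among <= 30 genes and no ties; tie-corrected normal
    approximation otherwise.  Returns ``(score, flagged)``; a cell with no
    marker present scores 0 with the flag set.
    """
    cell_counts = np.asarray(cell_counts, dtype=float)
    marker_set = set(marker_genes)
    is_marker = np.array([g in marker_set for g in genes])
    n_marker = int(is_marker.sum())
    if n_marker == 0:
        return 0.0, True
    if (~is_marker).sum() < 2:
        return 0.0, True
    x = cell_counts[is_marker]
    y = cell_counts[~is_marker]
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied cell: the rank-sum statistic carries no information
        return -np.log(0.5) / np.log(log_base), False
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = n_marker <= 10 and pooled.size <= 30 and not has_ties
    method = "exact" if exact else "asymptotic"
    p = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return max(-np.log(p) / np.log(log_base), 0.0), False


def confidence_scores(
    counts: np.ndarray,
    genes: list[str],
    marker_genes: list[str],
    log_base: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`confidence_score` over the columns of a genes x
    cells matrix (tie-corrected normal approximation throughout).

    Returns (scores, flagged) arrays, one entry per cell.
    """
    counts = np.asarray(counts, dtype=float)
    marker_set = set(marker_genes)
    mask = np.array([g in marker_set for g in genes])
    n_cells = counts.shape[1]
    if mask.sum() == 0 or (~mask).sum() < 2:
        return np.zeros(n_cells), np.ones(n_cells, dtype=bool)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    n = n1 + n2
    ranks = stats.rankdata(counts, axis=0)
    r1 = ranks[mask, :].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_term = np.zeros(n_cells)
    for c in range(n_cells):
        _, cnt = np.unique(counts[:, c], return_counts=True)
        tie_term[c] = (cnt**3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-30))
    z = (u - mu - 0.5) / sigma
    p = np.clip(stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    p[sigma2 <= 0] = 0.5  # fully tied cell: no rank information
    scores = np.maximum(-np.log(p) / np.log(log_base), 0.0)
    return scores, np.zeros(n_cells, dtype=bool)


@dataclass
class MixtureFit:
    """1-D Gaussian mixture: weights, means, variances and hard assignments."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    assignments: np.ndarray  # component id per score
    converged: bool = True

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def top_component(self) -> int:
        return int(np.argmax(self.means))


def decompose_scores(
    scores: np.ndarray,
    max_components: int = 5,
    seed: int = 1,
    n_init: int = 5,
    max_iter: int = 500,
) -> MixtureFit:
    """Decompose a group's confidence-score distribution into Gaussians.

    Fits equal-variance and unequal-variance mixtures by EM for 1 to
    ``max_components`` components and keeps the BIC-best fit; cells are
    hard-assigned to their maximum-posterior component.  Groups smaller
    than 3 (or degenerate, all-equal score sets) get a single closed-form
    component.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValidationError("no scores to decompose")
    if scores.size < 3 or np.allclose(scores, scores[0]):
        return MixtureFit(
            weights=np.array([1.0]),
            means=np.array([scores.mean()]),
            variances=np.array([scores.var()]),
            assignments=np.zeros(scores.size, dtype=int),
        )
    x = scores.reshape(-1, 1)
    best = None
    best_bic = np.inf
    # require ~3 points per component on average: with fewer, BIC happily
    # fits near-singleton components of vanishing variance
    n_max = min(max_components, len(np.unique(scores)), max(1, scores.size // 3))
    for cov_type in ("full", "tied"):
        for k in range(1, n_max + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=cov_type,
                    random_state=seed,
                    n_init=n_init,
                    max_iter=max_iter,
                    reg_covar=1e-6,
                )
                try:
                    gm.fit(x)
                except ValueError:
                    continue
            bic = gm.bic(x)
            if bic < best_bic:
                best_bic = bic
                best = gm
    if best is None:
        return MixtureFit(
            weights=np.array([1.0]),
            means=np.array([scores.mean()]),
            variances=np.array([scores.var()]),
            assignments=np.zeros(scores.size, dtype=int),
            converged=False,
        )
    if best.covariance_type == "tied":
        variances = np.full(best.n_components, float(best.covariances_.ravel()[0]))
    else:
        variances = best.covariances_.ravel()
    return MixtureFit(
        weights=best.weights_.ravel(),
        means=best.means_.ravel(),
        variances=variances,
        assignments=best.predict(x),
        converged=bool(best.converged_),
    )


def validate_round1(
    records: list[ConfidenceRecord],
    fit: MixtureFit,
    threshold: float = 5.0,
) -> list[ConfidenceRecord]:
    """Mark cells of one candidate-label group as validated or negative control.

    A cell is validated iff it belongs to the mixture component with the
    greatest mean; an unvalidated cell with confidence below ``threshold``
    becomes a negative control.  For tiny groups (single closed-form
    component) validation additionally requires the group mean to reach the
    threshold.
    """
    top = fit.top_component
    tiny = len(records) < 3
    group_ok = fit.means[top] >= threshold if tiny else True
    for rec, comp in zip(records, fit.assignments):
        rec.component_id = int(comp)
        rec.validated = (comp == top) and group_ok
        rec.negative_control = (not rec.validated) and rec.confidence < threshold
        rec.check()
    return records


def build_local_reference(
    query: CountMatrix,
    records: list[ConfidenceRecord],
    atlas_mode: bool = False,
    min_cells_atlas_label: int = 10,
) -> LocalReference:
    """Assemble the local reference from confidently validated query cells.

    In atlas mode, labels backed by fewer than ``min_cells_atlas_label``
    validated cells are dropped (their cells revert to unvalidated) to
    reduce false-positive label seeding.  Per-label negative-control
    matrices are attached for the round-2 marker contrast.
    """
    validated = [r for r in records if r.validated]
    if not validated:
        raise ValidationError("no validated cells: local reference not constructible")
    by_label: dict[str, list[ConfidenceRecord]] = {}
    for r in validated:
        by_label.setdefault(r.candidate_label, []).append(r)
    if atlas_mode:
        for label in list(by_label):
            if len(by_label[label]) < min_cells_atlas_label:
                for r in by_label[label]:
                    r.validated = False
                del by_label[label]
    if not by_label:
        raise ValidationError(
            "no label survives the minimum-cell rule: local reference not constructible"
        )
    barcodes, labels = [], {}
    for label in sorted(by_label):
        for r in by_label[label]:
            barcodes.append(r.barcode)
            labels[r.barcode] = label
    counts = query.subset_cells(barcodes)
    negcontrols: dict[str, CountMatrix] = {}
    for label in sorted(by_label):
        nc_barcodes = [
            r.barcode
            for r in records
            if r.negative_control and r.candidate_label == label
        ]
        if nc_barcodes:
            negcontrols[label] = query.subset_cells(nc_barcodes)
    return LocalReference(counts, CellAnnotation(labels), negcontrols)


def validate_round2(
    records: list[ConfidenceRecord],
    fit: MixtureFit,
    threshold: float = 5.0,
) -> dict[str, str]:
    """Final round-2 decision for one candidate-label group.

    Every mixture component whose mean is strictly below ``threshold`` has
    its cells labeled 'unassigned'; cells of all other components keep the
    group's candidate label.  Returns barcode -> final label.
    """
    low = set(np.nonzero(fit.means < threshold)[0])
    out = {}
    for rec, comp in zip(records, fit.assignments):
        rec.component_id = int(comp)
        keep = int(comp) not in low
        rec.validated = keep
        rec.negative_control = False
        out[rec.barcode] = rec.candidate_label if keep else "unassigned"
    return out
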