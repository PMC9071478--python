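"""Candidate label assignment: similarity of query cells to reference types.

Round 1 correlates each query cell with each pseudo-bulk reference column
over the reference's variable genes using Kendall's tau-b — a rank-based
metric robust to the monotone distortions that batch effects and library
size impose.  Round 2, run against the batch-free local reference, scores
each cell by the multinomial log-probability of its counts given each
label's depth-normalized profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io import CountMatrix, ProfileMatrix, ValidationError
from .markers import cp10k

__all__ = [
    "VariableGeneSet",
    "CandidateAssignment",
    "find_variable_genes",
    "kendall_tau",
    "assign_candidates_round1",
    "multinomial_logprob",
    "assign_candidates_round2",
]


@dataclass
class VariableGeneSet:
    """Ordered variable genes with their dispersion statistic."""

    genes: list[str]
    dispersion: np.ndarray

    def __post_init__(self):
        self.dispersion = np.asarray(self.dispersion, dtype=float)


@dataclass
class CandidateAssignment:
    """Per-cell candidate label for one classification round."""

    barcode: str
    candidate_label: str
    similarity: float
    round: int
    low_evidence: bool = False


def find_variable_genes(profile: ProfileMatrix, n: int = 2000) -> VariableGeneSet:
    """Rank genes by variability of log CP10K expression across profile columns.

    With >= 10 columns the gene-wise variance is standardized against a
    mean-variance trend fitted by binned local averaging (20 bins on the
    mean); with fewer columns the trend fit degenerates and the plain
    log-CP10K variance is used.  Constant genes are excluded.
    """
    if len(profile.cell_types) < 2:
        raise ValidationError("variable genes need >= 2 profile columns")
    if n < 1:
        raise ValueError("n must be >= 1")
    logv = np.log2(cp10k(profile.values) + 1.0)
    mean = logv.mean(axis=1)
    var = logv.var(axis=1, ddof=1)
    nonconst = var > 0
    if not nonconst.any():
        raise ValidationError("no variable genes: profile is constant")
    if len(profile.cell_types) >= 10:
        stat = np.zeros_like(var)
        # binned mean-variance trend: expected variance given mean expression
        idx = np.nonzero(nonconst)[0]
        order = np.argsort(mean[idx], kind="stable")
        bins = np.array_split(idx[order], 20)
        for b in bins:
            if b.size == 0:
                continue
            trend = var[b].mean()
            stat[b] = var[b] / max(trend, 1e-12)
    else:
        stat = var.copy()
    stat[~nonconst] = -np.inf
    ranked = sorted(
        np.nonzero(nonconst)[0],
        key=lambda i: (-stat[i], profile.genes[i]),
    )
    take = ranked[: min(n, len(ranked))]
    return VariableGeneSet([profile.genes[i] for i in take], stat[take])


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Tie-corrected Kendall correlation (tau-b) of two equal-length vectors.

    Returns ``(tau, flagged)``; a constant vector makes the tau-b
    denominator vanish, in which case 0 is returned with the flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0, True
    tau = stats.kendalltau(x, y).statistic
    if np.isnan(tau):
        return 0.0, True
    return float(tau), False


def assign_candidates_round1(
    query: CountMatrix,
    profile: ProfileMatrix,
    vgenes: VariableGeneSet,
) -> list[CandidateAssignment]:
    """Round-1 candidates: per cell, the reference type with maximal tau.

    Similarity is computed over the variable genes shared with the query;
    ties are broken by lexicographic cell-type name.  Cells with zero counts
    on the shared genes still receive the (lexicographic) argmax but are
    flagged low-evidence.
    """
    qi = query.gene_index()
    shared = [g for g in vgenes.genes if g in qi]
    if not shared:
        raise ValidationError("no shared variable gene between query and reference")
    pgi = profile.gene_index()
    prof = profile.values[[pgi[g] for g in shared], :]
    qsub = query.counts[[qi[g] for g in shared], :]
    qdense = np.asarray(qsub.todense()) if hasattr(qsub, "todense") else np.asarray(qsub)
    order = sorted(range(len(profile.cell_types)),
                   key=lambda j: profile.cell_types[j])
    out = []
    for c, barcode in enumerate(query.cells):
        cell = qdense[:, c].astype(float)
        low = not np.any(cell > 0)
        best_label, best_tau = None, -np.inf
        for j in order:
            tau, _ = kendall_tau(cell, prof[:, j])
            if tau > best_tau:  # strict: first (lexicographic) wins ties
                best_tau, best_label = tau, profile.cell_types[j]
        out.append(
            CandidateAssignment(barcode, best_label, float(best_tau), 1, low)
        )
    return out


def multinomial_logprob(x: np.ndarray, p: np.ndarray) -> float:
    """Exact multinomial log-probability of counts ``x`` under proportions ``p``.

    log n! - sum log x_i! + sum x_i log p_i, evaluated with log-gamma.
    """
    x = np.asarray(x)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError("count and probability vectors must have equal length")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must be positive and sum to 1")
    x = x.astype(float)
    n = x.sum()
    return float(gammaln(n + 1) - gammaln(x + 1).sum() + (x * np.log(p)).sum())


def assign_candidates_round2(
    query: CountMatrix,
    local_profile: ProfileMatrix,
    gene_set: list[str],
    pseudocount: float = 1.0,
) -> list[CandidateAssignment]:
    """Round-2 candidates: argmax multinomial log-probability per cell.

    Each label's probability vector is its depth-normalized profile column
    on ``gene_set`` with a pseudocount added per gene before normalization
    (keeps the support strictly positive).  Lexicographic tie-break.
    """
    if not gene_set:
        raise ValidationError("round-2 gene set is empty")
    qi = query.gene_index()
    shared = [g for g in gene_set if g in qi]
    if not shared:
        raise ValidationError("no round-2 gene shared with the query")
    pgi = local_profile.gene_index()
    prof = local_profile.values[[pgi[g] for g in shared], :].astype(float)
    probs = prof + pseudocount
    probs = probs / probs.sum(axis=0, keepdims=True)
    logp = np.log(probs)  # genes x labels
    qsub = query.counts[[qi[g] for g in shared], :]
    qdense = np.asarray(qsub.todense()) if hasattr(qsub, "todense") else np.asarray(qsub)
    qdense = qdense.astype(float)
    # per-cell constant term log n! - sum log x_i!
    const = gammaln(qdense.sum(axis=0) + 1) - gammaln(qdense + 1).sum(axis=0)
    scores = qdense.T @ logp + const[:, None]  # cells x labels
    labels = np.array(local_profile.cell_types)
    lex = np.argsort(labels, kind="stable")
    out = []
    for c, barcode in enumerate(query.cells):
        row = scores[c, lex]
        best = lex[int(np.argmax(row))]  # first lexicographic label on ties
        low = not np.any(qdense[:, c] > 0)
        out.append(
            CandidateAssignment(
                barcode, str(labels[best]), float(scores[c, best]), 2, low
            )
        )
    return out
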