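"""Reference cell-type marker-gene identification for both classification rounds.

Round 1 works on pseudo-bulk profiles: per cell type the highly expressed
genes are intersected with genes significantly up-regulated versus the other
reference cell types and versus the cell types of an organism-wide atlas
profile matrix (after a factor-analysis batch adjustment of the two profile
matrices).  Round 2 works at single-cell resolution on the local reference
built from validated query cells, contrasting each label against the other
local cells, against its negative-control cells, and against the atlas.

Depth normalization throughout is counts per 10,000 (CP10K) per column or
cell; contrasts are computed on log2(CP10K + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CellAnnotation, CountMatrix, ProfileMatrix, ValidationError

__all__ = [
    "DEResult",
    "MarkerGeneSet",
    "aggregate_profiles",
    "select_highly_expressed",
    "de_up_one_vs_rest",
    "ruv_adjust",
    "de_up_vs_atlas",
    "identify_markers_round1",
    "identify_markers_round2",
]

CP10K = 1e4


def cp10k(values: np.ndarray) -> np.ndarray:
    """Depth-normalize columns to counts per 10,000."""
    values = np.asarray(values, dtype=float)
    depth = values.sum(axis=0)
    depth = np.where(depth > 0, depth, 1.0)
    return values / depth * CP10K


def log_cp10k(values: np.ndarray) -> np.ndarray:
    return np.log2(cp10k(values) + 1.0)


@dataclass
class DEResult:
    """Differential-expression table for one contrast.

    One row per tested gene: log2 fold change, raw and BH-adjusted p-value.
    """

    table: pd.DataFrame  # columns: gene, lfc, pvalue, padj, contrast
    flagged: bool = False

    def up_genes(self, alpha: float) -> list[str]:
        t = self.table
        sel = t[(t["lfc"] > 0) & (t["padj"] < alpha)]
        return list(sel["gene"])


@dataclass
class MarkerGeneSet:
    """Per-cell-type validated marker genes, ordered by descending effect size."""

    markers: dict[str, list[str]]
    effects: dict[str, pd.DataFrame] = field(default_factory=dict)
    empty_types: list[str] = field(default_factory=list)

    def __post_init__(self):
        for ct, genes in self.markers.items():
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate marker genes for {ct!r}")


def aggregate_profiles(counts: CountMatrix, ann: CellAnnotation) -> ProfileMatrix:
    """Sum single-cell counts per label into a pseudo-bulk profile matrix."""
    ci = counts.cell_index()
    missing = [b for b in ann.barcodes if b not in ci]
    if missing:
        raise ValidationError(f"annotated barcodes absent from matrix: {missing[:5]}")
    labels = ann.label_set
    dense = None
    cols = []
    kept = []
    for label in labels:
        members = [ci[b] for b, l in ann.labels.items() if l == label]
        if not members:
            warnings.warn(f"label {label!r} has no member cells; dropped")
            continue
        sub = counts.counts[:, members]
        col = np.asarray(sub.sum(axis=1)).ravel().astype(float)
        cols.append(col)
        kept.append(label)
    dense = np.column_stack(cols)
    return ProfileMatrix(list(counts.genes), kept, dense)


def select_highly_expressed(
    profile: ProfileMatrix, cell_type: str, fraction: float = 0.20
) -> list[str]:
    """Top ``fraction`` most highly expressed genes of one profile column.

    The fraction is taken over genes with nonzero expression in the column
    (ceil of fraction x expressed count); ties broken by lexicographic gene
    symbol for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    col = cp10k(profile.values)[:, profile.cell_types.index(cell_type)]
    expressed = np.nonzero(col > 0)[0]
    if expressed.size == 0:
        warnings.warn(f"all-zero profile column for {cell_type!r}")
        return []
    n_take = math.ceil(fraction * expressed.size)
    order = sorted(expressed, key=lambda i: (-col[i], profile.genes[i]))
    return [profile.genes[i] for i in order[:n_take]]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _moderated_one_vs_rest(
    log_values: np.ndarray,
    target_col: int,
    rest_cols: np.ndarray,
    genes: list[str],
    contrast: str,
    prior_df: float = 4.0,
    covariates: np.ndarray | None = None,
) -> DEResult:
    """Moderated one-vs-rest contrast of pseudo-bulk columns.

    Per gene, an OLS fit of the log values of the target + rest columns on
    [intercept, target indicator] (+ optional unwanted-variation covariate
    scores, one row per column) yields the target effect; gene-wise
    residual variances are shrunk toward their median with ``prior_df``
    pseudo-observations (empirical-Bayes style) and the effect is tested
    one-sided for up-regulation.  Without covariates this reduces to a
    moderated two-sample t with the rest columns as replicates.
    """
    cols = np.concatenate([[target_col], rest_cols])
    y = log_values[:, cols]  # genes x n
    n = len(cols)
    if n < 3:
        # two-column fallback: rank by log fold change, no p-values
        lfc = log_values[:, target_col] - log_values[:, rest_cols[0]]
        table = pd.DataFrame(
            {"gene": genes, "lfc": lfc, "pvalue": np.nan, "padj": np.nan,
             "contrast": contrast}
        )
        return DEResult(table, flagged=True)
    t_ind = np.zeros(n)
    t_ind[0] = 1.0
    design = [np.ones(n), t_ind]
    if covariates is not None and covariates.size:
        w = np.atleast_2d(np.asarray(covariates, dtype=float))
        if w.shape[0] != n:
            w = w.T
        # drop covariates that cannot be separated from the design
        keep = [j for j in range(w.shape[1]) if np.ptp(w[1:, j]) > 1e-12]
        design.extend(w[:, j] for j in keep)
    d = np.column_stack(design)  # n x p
    p = d.shape[1]
    if n - p < 1:
        d = d[:, :2]
        p = 2
    dtd_inv = np.linalg.pinv(d.T @ d)
    hat = dtd_inv @ d.T  # p x n
    beta = y @ hat.T  # genes x p
    resid = y - beta @ d.T
    df_resid = n - p
    s2 = (resid**2).sum(axis=1) / df_resid
    s2_prior = np.median(s2[s2 > 0]) if (s2 > 0).any() else 1e-8
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    s2_mod = np.maximum(s2_mod, 1e-12)
    lfc = beta[:, 1]
    se = np.sqrt(s2_mod * dtd_inv[1, 1])
    tstat = lfc / se
    df_total = prior_df + df_resid
    pvals = stats.t.sf(tstat, df_total)  # one-sided: up-regulation
    table = pd.DataFrame(
        {"gene": genes, "lfc": lfc, "pvalue": pvals, "padj": _bh_adjust(pvals),
         "contrast": contrast}
    )
    return DEResult(table)


def de_up_one_vs_rest(
    profile: ProfileMatrix,
    cell_type: str,
    candidate_genes: list[str],
    alpha: float = 0.05,
) -> DEResult:
    """Genes up-regulated in one cell type versus all other reference types.

    Computed as a moderated one-vs-rest t on log2(CP10K+1) pseudo-bulk
    columns; returns the full DE table (use ``up_genes(alpha)`` to filter).
    """
    if len(profile.cell_types) < 2:
        raise ValidationError("one-vs-rest contrast needs at least 2 cell types")
    gi = profile.gene_index()
    missing = [g for g in candidate_genes if g not in gi]
    if missing:
        raise ValidationError(f"candidate genes absent from profile: {missing[:5]}")
    rows = [gi[g] for g in candidate_genes]
    logv = log_cp10k(profile.values)[rows, :]
    tcol = profile.cell_types.index(cell_type)
    rest = np.array([j for j in range(len(profile.cell_types)) if j != tcol])
    return _moderated_one_vs_rest(
        logv, tcol, rest, list(candidate_genes), f"{cell_type}_vs_rest"
    )


@dataclass
class AdjustedProfiles:
    """Reference and atlas profiles on a shared gene space after adjustment.

    ``log_values`` holds log2(CP10K+1) with ``k`` unwanted-variation
    factors removed globally; ``raw_log_values`` and ``factors`` (the
    per-column factor scores) allow contrast-specific leave-target-out
    re-adjustment in :func:`de_up_vs_atlas`.
    """

    genes: list[str]
    ref_types: list[str]
    atlas_types: list[str]
    log_values: np.ndarray  # genes x (ref + atlas) columns, log2 space
    raw_log_values: np.ndarray = None
    factors: np.ndarray = None  # (ref + atlas) columns x k scores

    def __post_init__(self):
        if self.raw_log_values is None:
            self.raw_log_values = self.log_values

    def ref_col(self, cell_type: str) -> int:
        return self.ref_types.index(cell_type)

    @property
    def atlas_cols(self) -> np.ndarray:
        n_ref = len(self.ref_types)
        return np.arange(n_ref, n_ref + len(self.atlas_types))

    def adjusted_excluding(self, col: int) -> np.ndarray:
        """Log values with factor contributions re-estimated without ``col``.

        Each gene's loading on the unwanted factors is fit from every other
        column, so a genuine elevation in ``col`` cannot leak into its own
        adjustment.  Without factors this is just the raw log values.
        """
        if self.factors is None:
            return self.raw_log_values
        w = self.factors
        keep = np.arange(w.shape[0]) != col
        centered = self.raw_log_values - self.raw_log_values.mean(
            axis=1, keepdims=True
        )
        wk = w[keep, :]
        alpha = centered[:, keep] @ wk @ np.linalg.pinv(wk.T @ wk)
        return np.maximum(self.raw_log_values - alpha @ w.T, 0.0)


def ruv_adjust(
    ref_profile: ProfileMatrix,
    atlas_profile: ProfileMatrix,
    k: int = 2,
    control_fraction: float = 0.10,
) -> AdjustedProfiles:
    """Remove unwanted variation between reference and atlas profiles.

    On the shared gene space, empirical control genes (the least-variable
    ``control_fraction`` of genes across all depth-normalized columns) drive
    a factor analysis of the centered log counts: the top ``k`` right
    singular vectors of the control-gene block estimate per-column unwanted
    factors, whose fitted contribution is subtracted from every gene.
    ``k = 0`` returns the depth-normalized log values unchanged.
    """
    shared = sorted(set(ref_profile.genes) & set(atlas_profile.genes))
    if not shared:
        raise ValidationError("reference and atlas share no genes")
    if len(shared) < 200:
        warnings.warn(f"only {len(shared)} shared genes between reference and atlas")
    n_cols = len(ref_profile.cell_types) + len(atlas_profile.cell_types)
    if k < 0 or (k > 0 and k >= n_cols - 1):
        raise ValueError(f"k={k} must satisfy 0 <= k < n_columns - 1 = {n_cols - 1}")
    ref_sub = ref_profile.subset_genes(shared)
    atlas_sub = atlas_profile.subset_genes(shared)
    raw = np.column_stack([log_cp10k(ref_sub.values), log_cp10k(atlas_sub.values)])
    logv, w = raw, None
    if k > 0:
        centered = raw - raw.mean(axis=1, keepdims=True)
        gene_var = centered.var(axis=1)
        n_ctrl = max(int(round(control_fraction * len(shared))), k + 1)
        ctrl = np.argsort(gene_var, kind="stable")[:n_ctrl]
        # factor analysis via SVD of the control-gene block
        _, _, vt = np.linalg.svd(centered[ctrl, :], full_matrices=False)
        w = vt[:k, :].T  # columns x k, orthonormal factor scores
        logv = np.maximum(raw - (centered @ w) @ w.T, 0.0)
    return AdjustedProfiles(
        shared,
        list(ref_profile.cell_types),
        list(atlas_profile.cell_types),
        logv,
        raw_log_values=raw,
        factors=w,
    )


def de_up_vs_atlas(
    adjusted: AdjustedProfiles,
    cell_type: str,
    candidate_genes: list[str],
    alpha_atlas: float = 0.001,
) -> tuple[DEResult, list[str]]:
    """Genes up in a reference cell type versus all atlas cell types.

    Same moderated statistic as :func:`de_up_one_vs_rest`, contrasting the
    target reference column against the atlas columns after
    leave-target-out factor re-adjustment (the tested column's own
    elevation never feeds its adjustment).  Genes absent from the shared
    gene space are skipped and reported.
    """
    if len(adjusted.atlas_types) < 2:
        raise ValidationError("atlas contrast needs at least 2 atlas cell types")
    gi = {g: i for i, g in enumerate(adjusted.genes)}
    tested = [g for g in candidate_genes if g in gi]
    skipped = [g for g in candidate_genes if g not in gi]
    if not tested:
        empty = pd.DataFrame(
            columns=["gene", "lfc", "pvalue", "padj", "contrast"]
        )
        return DEResult(empty, flagged=True), skipped
    tcol = adjusted.ref_col(cell_type)
    rows = [gi[g] for g in tested]
    logv = adjusted.adjusted_excluding(tcol)[rows, :]
    res = _moderated_one_vs_rest(
        logv, tcol, adjusted.atlas_cols, tested, f"{cell_type}_vs_atlas"
    )
    return res, skipped


def identify_markers_round1(
    ref_profile: ProfileMatrix,
    atlas_profile: ProfileMatrix | None,
    alpha_ref: float = 0.05,
    alpha_atlas: float = 0.001,
    he_fraction: float = 0.20,
    ruv_k: int = 2,
    control_fraction: float = 0.10,
) -> MarkerGeneSet:
    """First-round marker genes: highly expressed AND up vs other reference
    types AND (when an atlas is given) up vs atlas types after adjustment.

    Markers are ordered by descending one-vs-rest log fold change.
    """
    if len(ref_profile.cell_types) < 2:
        raise ValidationError("marker identification needs >= 2 reference cell types")
    adjusted = None
    if atlas_profile is not None:
        adjusted = ruv_adjust(ref_profile, atlas_profile, ruv_k, control_fraction)
    markers: dict[str, list[str]] = {}
    effects: dict[str, pd.DataFrame] = {}
    empty_types: list[str] = []
    for ct in ref_profile.cell_types:
        he = select_highly_expressed(ref_profile, ct, he_fraction)
        if not he:
            markers[ct] = []
            empty_types.append(ct)
            continue
        de_ref = de_up_one_vs_rest(ref_profile, ct, he, alpha_ref)
        up_ref = set(de_ref.up_genes(alpha_ref))
        selected = up_ref
        if adjusted is not None and selected:
            de_atlas, _ = de_up_vs_atlas(adjusted, ct, sorted(selected), alpha_atlas)
            selected = selected & set(de_atlas.up_genes(alpha_atlas))
        lfc = dict(zip(de_ref.table["gene"], de_ref.table["lfc"]))
        ordered = sorted(selected, key=lambda g: (-lfc.get(g, 0.0), g))
        markers[ct] = ordered
        effects[ct] = de_ref.table[de_ref.table["gene"].isin(selected)]
        if not ordered:
            empty_types.append(ct)
            warnings.warn(f"no round-1 markers for cell type {ct!r}")
    return MarkerGeneSet(markers, effects, empty_types)


def _ranksum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (x > y) Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    small = min(x.size, y.size) <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def identify_markers_round2(
    local_counts: CountMatrix,
    local_ann: CellAnnotation,
    negcontrols: dict[str, CountMatrix],
    atlas_profile: ProfileMatrix | None,
    lfc: float = 1.5,
    alpha: float = 0.05,
    alpha_atlas: float = 0.001,
    ruv_k: int = 2,
    control_fraction: float = 0.10,
) -> MarkerGeneSet:
    """Second-round marker genes from the local reference.

    Per label: (a) genes up in the label's cells versus all other local
    cells (one-sided rank-sum, Bonferroni-adjusted p < ``alpha``, fold
    change > ``lfc`` on CP10K means with pseudocount 1); (b) of those, genes
    up versus the label's negative-control cells by the same criteria;
    (c) of those, genes passing the atlas contrast as in round 1.
    """
    dense = local_counts.dense().astype(float)
    norm = cp10k(dense)
    labels_vec = local_ann.vector(local_counts.cells)
    genes = local_counts.genes
    markers: dict[str, list[str]] = {}
    effects: dict[str, pd.DataFrame] = {}
    empty_types: list[str] = []
    profile = aggregate_profiles(local_counts, local_ann)
    adjusted = None
    if atlas_profile is not None:
        adjusted = ruv_adjust(profile, atlas_profile, ruv_k, control_fraction)
    for label in profile.cell_types:
        in_lab = labels_vec == label
        if in_lab.sum() < 3:
            markers[label] = []
            empty_types.append(label)
            continue
        sel_genes, sel_stats = _ranksum_markers(
            norm, in_lab, genes, lfc, alpha
        )
        # (b) contrast against negative controls
        if sel_genes and label in negcontrols and len(negcontrols[label].cells) >= 3:
            nc = negcontrols[label]
            nc_norm = cp10k(nc.dense().astype(float))
            nc_gi = nc.gene_index()
            survivors = []
            gi = local_counts.gene_index()
            n_tests = len(sel_genes)
            for g in sel_genes:
                if g not in nc_gi:
                    survivors.append(g)
                    continue
                xv = norm[gi[g], in_lab]
                yv = nc_norm[nc_gi[g], :]
                fc = (xv.mean() + 1.0) / (yv.mean() + 1.0)
                p = _ranksum_greater(xv, yv)
                if fc > lfc and min(p * n_tests, 1.0) < alpha:
                    survivors.append(g)
            sel_genes = survivors
        # (c) atlas contrast on the aggregated local profile
        if sel_genes and adjusted is not None:
            de_atlas, _ = de_up_vs_atlas(adjusted, label, sel_genes, alpha_atlas)
            keep = set(de_atlas.up_genes(alpha_atlas))
            sel_genes = [g for g in sel_genes if g in keep]
        markers[label] = sel_genes
        effects[label] = sel_stats[sel_stats["gene"].isin(sel_genes)]
        if not sel_genes:
            empty_types.append(label)
    return MarkerGeneSet(markers, effects, empty_types)


def _ranksum_markers(norm, in_lab, genes, lfc, alpha):
    """Stage (a) of round-2 markers: label cells vs all other local cells."""
    x = norm[:, in_lab]
    y = norm[:, ~in_lab]
    mx = x.mean(axis=1)
    my = y.mean(axis=1)
    fc = (mx + 1.0) / (my + 1.0)
    # screen on fold change first; rank-sum only on candidates (speed)
    cand = np.nonzero(fc > lfc)[0]
    n_tests = max(len(genes), 1)
    rows = []
    sel = []
    if cand.size:
        # vectorized tie-corrected normal approximation across genes
        pv = _batch_ranksum_greater(x[cand, :], y[cand, :])
        for idx, p in zip(cand, pv):
            padj = min(p * n_tests, 1.0)  # Bonferroni over all genes
            rows.append((genes[idx], float(np.log2(fc[idx])), p, padj))
            if padj < alpha:
                sel.append(genes[idx])
    table = pd.DataFrame(rows, columns=["gene", "lfc", "pvalue", "padj"])
    order = {g: i for i, g in enumerate(table.sort_values(
        ["lfc", "gene"], ascending=[False, True])["gene"])}
    sel.sort(key=lambda g: order[g])
    return sel, table


def _batch_ranksum_greater(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise one-sided rank-sum p-values, tie-corrected normal approx."""
    n1, n2 = x.shape[1], y.shape[1]
    pooled = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per row
    tie_term = np.zeros(x.shape[0])
    for i in range(x.shape[0]):
        _, counts = np.unique(pooled[i], return_counts=True)
        tie_term[i] = (counts**3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-30))
    z = (u - mu - 0.5) / sigma  # continuity correction
    return stats.norm.sf(z)
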