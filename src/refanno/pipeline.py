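"""End-to-end two-round annotation workflow.

Stage order: optional speed-up merging -> round-1 markers -> round-1
candidates (Kendall tau) -> round-1 confidence validation -> local
reference -> round-2 markers -> round-2 candidates (multinomial) ->
round-2 validation ('unassigned' rule) -> recapture by clustering ->
label transfer back to member cells.  All randomness funnels through the
seeds in :class:`AnnotateConfig`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import assignment, markers, postprocess, validation
from .io import (
    AnnotationResult,
    CellAnnotation,
    CountMatrix,
    OrthologMap,
    ProfileMatrix,
    ValidationError,
    map_orthologs,
)

__all__ = ["AnnotateConfig", "annotate"]

log = logging.getLogger("refanno")

UNASSIGNED = "unassigned"


@dataclass
class AnnotateConfig:
    """Tunable parameters of the annotation workflow (ledgered defaults)."""

    # round-1 markers
    alpha_ref: float = 0.05
    alpha_atlas: float = 0.001
    he_fraction: float = 0.20
    ruv_k: int = 2
    control_fraction: float = 0.10
    # round-2 markers
    round2_lfc: float = 1.5
    round2_alpha: float = 0.05
    # candidate assignment
    n_variable_genes: int = 2000
    pseudocount: float = 1.0
    # validation
    confidence_threshold: float = 5.0
    score_log_base: float = 10.0
    min_cells_atlas_label: int = 10
    max_components: int = 5
    em_seed: int = 1
    # clustering / speed-up
    n_pcs: int = 50
    cluster_resolution: float = 3.0
    cluster_seed: int = 1
    speedup_trigger: int = 5000
    speedup_divisor: int = 3000
    recapture_majority: float = 0.5
    recapture_max_unassigned: float = 0.20
    # diagnostic modes
    single_round: bool = False
    use_atlas: bool = True

    def reseed(self, seed: int) -> "AnnotateConfig":
        """Funnel one root seed into every stochastic stage."""
        return replace(self, em_seed=seed, cluster_seed=seed + 1)


@dataclass
class _RoundState:
    candidates: dict[str, str]
    similarities: dict[str, float]
    records: list[validation.ConfidenceRecord] = field(default_factory=list)


def _score_and_group(
    work: CountMatrix,
    candidates: list[assignment.CandidateAssignment],
    marker_sets: markers.MarkerGeneSet,
    cfg: AnnotateConfig,
) -> dict[str, list[validation.ConfidenceRecord]]:
    """Confidence-score cells grouped by candidate label."""
    dense = work.dense().astype(float)
    pos = {b: i for i, b in enumerate(work.cells)}
    groups: dict[str, list[assignment.CandidateAssignment]] = {}
    for c in candidates:
        groups.setdefault(c.candidate_label, []).append(c)
    out: dict[str, list[validation.ConfidenceRecord]] = {}
    for label, members in groups.items():
        cols = [pos[c.barcode] for c in members]
        mgenes = marker_sets.markers.get(label, [])
        if mgenes:
            scores, flags = validation.confidence_scores(
                dense[:, cols], work.genes, mgenes, cfg.score_log_base
            )
        else:
            scores = np.zeros(len(cols))
            flags = np.ones(len(cols), dtype=bool)
        out[label] = [
            validation.ConfidenceRecord(
                barcode=c.barcode,
                candidate_label=label,
                confidence=float(s),
                flagged=bool(f),
            )
            for c, s, f in zip(members, scores, flags)
        ]
    return out


def _stage(name: str, t0: float, **counts):
    log.info("stage %-22s %6.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def annotate(
    query: CountMatrix,
    reference: CountMatrix | None = None,
    ref_annotation: CellAnnotation | None = None,
    atlas: ProfileMatrix | None = None,
    ortholog_map: OrthologMap | None = None,
    config: AnnotateConfig | None = None,
) -> AnnotationResult:
    """Annotate query cells with reference cell types or 'unassigned'.

    Either a single-cell reference (``reference`` + ``ref_annotation``) or
    an atlas used as the reference (``atlas`` alone; each atlas column acts
    as a one-cell type, with the >= 10-validated-cells rule enforced) must
    be provided.  Returns a per-cell result with full stage provenance; if
    no cell survives round-1 validation every cell is 'unassigned' and the
    result's ``diagnostic`` attribute explains why.
    """
    cfg = config or AnnotateConfig()
    t0 = time.perf_counter()

    if reference is not None and ortholog_map is not None:
        reference, frac = map_orthologs(reference, ortholog_map)
        log.info("ortholog mapping retained %.1f%% of reference genes", 100 * frac)

    atlas_mode = reference is None
    if atlas_mode:
        if atlas is None:
            raise ValidationError("provide a reference or an atlas")
        ref_profile = atlas
        atlas_for_contrast = None
    else:
        if ref_annotation is None:
            raise ValidationError("a single-cell reference needs an annotation")
        ref_profile = markers.aggregate_profiles(reference, ref_annotation)
        atlas_for_contrast = atlas if cfg.use_atlas else None
    if not set(ref_profile.genes) & set(query.genes):
        raise ValidationError("reference and query share no genes")

    # ---- speed-up merging ------------------------------------------------
    merge_map = postprocess.merge_cells(
        query,
        trigger=cfg.speedup_trigger,
        divisor=cfg.speedup_divisor,
        n_pcs=cfg.n_pcs,
        resolution=cfg.cluster_resolution,
        seed=cfg.cluster_seed,
    )
    work = merge_map.merged
    _stage("speed-up", t0, merged=len(work.cells), identity=merge_map.identity)

    # ---- round 1 ---------------------------------------------------------
    t = time.perf_counter()
    mset1 = markers.identify_markers_round1(
        ref_profile,
        atlas_for_contrast,
        alpha_ref=cfg.alpha_ref,
        alpha_atlas=cfg.alpha_atlas,
        he_fraction=cfg.he_fraction,
        ruv_k=cfg.ruv_k,
        control_fraction=cfg.control_fraction,
    )
    _stage("round1-markers", t,
           types=len(mset1.markers), empty=len(mset1.empty_types))

    t = time.perf_counter()
    vgenes = assignment.find_variable_genes(ref_profile, cfg.n_variable_genes)
    cands1 = assignment.assign_candidates_round1(work, ref_profile, vgenes)
    _stage("round1-candidates", t, cells=len(cands1))

    t = time.perf_counter()
    grouped = _score_and_group(work, cands1, mset1, cfg)
    all_records: list[validation.ConfidenceRecord] = []
    for label, records in grouped.items():
        fit = validation.decompose_scores(
            np.array([r.confidence for r in records]),
            max_components=cfg.max_components,
            seed=cfg.em_seed,
        )
        validation.validate_round1(records, fit, cfg.confidence_threshold)
        all_records.extend(records)
    n_validated = sum(r.validated for r in all_records)
    _stage("round1-validation", t, validated=n_validated,
           negcontrols=sum(r.negative_control for r in all_records))

    r1_validated = {r.barcode for r in all_records if r.validated}
    rec_by_bc = {r.barcode: r for r in all_records}
    round1_candidate = {r.barcode: r.candidate_label for r in all_records}
    round1_conf = {r.barcode: r.confidence for r in all_records}

    if n_validated == 0:
        labels = {b: UNASSIGNED for b in work.cells}
        return _finalize(
            query, work, merge_map, labels, round1_candidate, round1_conf,
            rec_by_bc, set(), set(),
            diagnostic="no query cell validated in round 1",
        )

    if cfg.single_round:
        labels = {
            r.barcode: (r.candidate_label if r.validated else UNASSIGNED)
            for r in all_records
        }
        final_conf = round1_conf
    else:
        # ---- local reference & round 2 ----------------------------------
        t = time.perf_counter()
        try:
            local = validation.build_local_reference(
                work, all_records, atlas_mode=atlas_mode,
                min_cells_atlas_label=cfg.min_cells_atlas_label,
            )
        except ValidationError:
            labels = {b: UNASSIGNED for b in work.cells}
            return _finalize(
                query, work, merge_map, labels, round1_candidate, round1_conf,
                rec_by_bc, set(), r1_validated,
                diagnostic="no label survived local-reference construction",
            )
        _stage("local-reference", t, cells=len(local.counts.cells),
               labels=len(local.annotation.label_set))

        t = time.perf_counter()
        mset2 = markers.identify_markers_round2(
            local.counts,
            local.annotation,
            local.negcontrols,
            atlas_for_contrast,
            lfc=cfg.round2_lfc,
            alpha=cfg.round2_alpha,
            alpha_atlas=cfg.alpha_atlas,
            ruv_k=cfg.ruv_k,
            control_fraction=cfg.control_fraction,
        )
        _stage("round2-markers", t,
               types=len(mset2.markers), empty=len(mset2.empty_types))

        t = time.perf_counter()
        local_profile = markers.aggregate_profiles(local.counts, local.annotation)
        if len(local_profile.cell_types) >= 2:
            gene_set = assignment.find_variable_genes(
                local_profile, cfg.n_variable_genes
            ).genes
        else:  # single surviving label: fall back to its expressed genes
            expressed = np.asarray(local_profile.values[:, 0]) > 0
            gene_set = [g for g, e in zip(local_profile.genes, expressed) if e]
        cands2 = assignment.assign_candidates_round2(
            work, local_profile, gene_set, pseudocount=cfg.pseudocount
        )
        _stage("round2-candidates", t, cells=len(cands2))

        t = time.perf_counter()
        grouped2 = _score_and_group(work, cands2, mset2, cfg)
        labels = {}
        final_conf = {}
        for label, records in grouped2.items():
            fit = validation.decompose_scores(
                np.array([r.confidence for r in records]),
                max_components=cfg.max_components,
                seed=cfg.em_seed,
            )
            labels.update(
                validation.validate_round2(records, fit, cfg.confidence_threshold)
            )
            for r in records:
                final_conf[r.barcode] = r.confidence
                rec_by_bc[r.barcode].validated = r.validated
        _stage("round2-validation", t,
               assigned=sum(l != UNASSIGNED for l in labels.values()))

    # ---- recapture -------------------------------------------------------
    t = time.perf_counter()
    if len(work.cells) >= 3:
        partition = postprocess.cluster_cells(
            work, n_pcs=cfg.n_pcs, resolution=cfg.cluster_resolution,
            seed=cfg.cluster_seed,
        )
        labels, recaptured = postprocess.recapture_unassigned(
            labels, partition,
            majority=cfg.recapture_majority,
            max_unassigned=cfg.recapture_max_unassigned,
        )
    else:
        recaptured = set()
    _stage("recapture", t, recaptured=len(recaptured))

    return _finalize(
        query, work, merge_map, labels, round1_candidate, final_conf,
        rec_by_bc, recaptured, r1_validated,
    )


def _finalize(
    query: CountMatrix,
    work: CountMatrix,
    merge_map: postprocess.MergeMap,
    labels: dict[str, str],
    round1_candidate: dict[str, str],
    confidence: dict[str, float],
    rec_by_bc: dict,
    recaptured: set[str],
    r1_validated: set[str],
    diagnostic: str | None = None,
) -> AnnotationResult:
    merged_of = {
        b: mid for mid, members in merge_map.members.items() for b in members
    }
    per_cell = postprocess.transfer_labels(labels, merge_map)
    rows = []
    for b in query.cells:
        mid = merged_of[b]
        rows.append(
            {
                "barcode": b,
                "final_label": per_cell[b],
                "round1_candidate": round1_candidate.get(mid, UNASSIGNED),
                "confidence_score": confidence.get(mid, 0.0),
                "validated": bool(rec_by_bc[mid].validated) if mid in rec_by_bc else False,
                "round1_validated": mid in r1_validated,
                "recaptured": mid in recaptured,
                "merged_cell_id": "" if merge_map.identity else mid,
            }
        )
    result = AnnotationResult(pd.DataFrame(rows))
    result.diagnostic = diagnostic
    return result
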