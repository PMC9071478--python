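"""Synthetic reference / query / atlas generator with known ground truth.

Counts are negative binomial: per-gene base means are drawn log-normal and
each cell type multiplies its disjoint marker genes' means by a fold
change; dropout emerges from low means rather than an explicit
zero-inflation term.  The reference/query batch effect is modeled as a
per-gene multiplicative log-normal capture factor (one draw per gene,
shared by all query cells) plus a global library-size rescale — enough to
span the cross-platform and low-depth axes of real annotation tasks.
Query types absent from the reference ("unclassifiable") carry their own
marker sets and a ground-truth label of 'unassigned'.  Everything is
deterministic under the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellAnnotation, CountMatrix, ProfileMatrix, ValidationError

__all__ = [
    "ScenarioConfig",
    "generate_reference",
    "generate_query",
    "generate_atlas",
    "generate_scenario",
    "PRESETS",
    "preset",
]

UNASSIGNED = "unassigned"


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic annotation scenario."""

    seed: int
    n_genes: int = 2000
    ref_types: dict[str, int] = field(
        default_factory=lambda: {f"type{i}": 100 for i in range(5)}
    )
    markers_per_type: int = 20
    marker_fold_change: float = 8.0
    query_types: dict[str, int] = None  # defaults to ref_types
    unclassifiable_types: dict[str, int] = field(default_factory=dict)
    batch_sigma: float = 0.0  # per-gene log-normal capture sd
    library_scale: float = 1.0  # global query depth rescale
    # real organism-wide atlases hold hundreds of aggregated cell types;
    # 100 is the smallest scale that keeps the atlas contrast in its
    # intended many-column operating regime
    atlas_types: int = 100
    atlas_depth: float = 5e4  # expected counts per atlas column
    dispersion: float = 0.3  # NB dispersion (1/size)
    base_mean_log_sd: float = 1.0
    cell_size_log_sd: float = 0.25
    # broadly expressed program genes: every cell type (reference,
    # unclassifiable and atlas-only) expresses them at its own random
    # activity level, so one-vs-rest contrasts cannot fully remove them —
    # only the atlas contrast reveals they are not type-specific
    broad_genes: int = 150
    broad_log_mean: float = 2.0
    broad_log_sd: float = 0.75

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("scenario seed is mandatory")
        if self.query_types is None:
            self.query_types = dict(self.ref_types)
        all_types = list(self.ref_types) + list(self.unclassifiable_types)
        if len(set(all_types)) != len(all_types):
            raise ValidationError("reference and unclassifiable type names overlap")
        needed = len(all_types) * self.markers_per_type + self.broad_genes
        if needed > self.n_genes:
            raise ValidationError(
                f"{needed} marker/broad genes needed but only {self.n_genes} genes"
            )
        for name, cnt in {**self.ref_types, **self.query_types,
                          **self.unclassifiable_types}.items():
            if cnt < 1:
                raise ValidationError(f"cell count for {name!r} must be >= 1")
        unknown = set(self.query_types) - set(self.ref_types)
        if unknown:
            raise ValidationError(
                f"query types {sorted(unknown)} not in reference; "
                "use unclassifiable_types for novel types"
            )

    # -- derived, deterministic structure -------------------------------
    @property
    def gene_names(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def marker_indices(self) -> dict[str, np.ndarray]:
        """Disjoint marker-gene index blocks, reference types first."""
        out = {}
        pos = 0
        for t in list(self.ref_types) + list(self.unclassifiable_types):
            out[t] = np.arange(pos, pos + self.markers_per_type)
            pos += self.markers_per_type
        return out

    def broad_indices(self) -> np.ndarray:
        """Index block of the broadly expressed program genes."""
        n_marked = (
            len(self.ref_types) + len(self.unclassifiable_types)
        ) * self.markers_per_type
        return np.arange(n_marked, n_marked + self.broad_genes)


@dataclass
class GeneratorTruth:
    """Ground truth shared between the three generators of one scenario."""

    base_means: np.ndarray  # per-gene base expression means
    marker_indices: dict[str, np.ndarray]
    broad_indices: np.ndarray = None
    broad_factors: dict[str, np.ndarray] = None  # per-type activity levels

    def type_means(self, cell_type: str, fold_change: float) -> np.ndarray:
        means = self.base_means.copy()
        means[self.marker_indices[cell_type]] *= fold_change
        if self.broad_factors and cell_type in self.broad_factors:
            means[self.broad_indices] *= self.broad_factors[cell_type]
        return means


def _nb_sample(rng: np.random.Generator, means: np.ndarray, dispersion: float):
    """Negative binomial draws (gamma-Poisson) with fixed dispersion."""
    if dispersion <= 0:
        return rng.poisson(means)
    size = 1.0 / dispersion
    lam = rng.gamma(shape=size, scale=means / size)
    return rng.poisson(lam)


def _scenario_truth(config: ScenarioConfig) -> GeneratorTruth:
    rng = np.random.default_rng(config.seed)
    base = rng.lognormal(mean=0.0, sigma=config.base_mean_log_sd, size=config.n_genes)
    # marker genes sit in the upper half of the expression distribution:
    # curated cell-type markers are detectably expressed genes
    mk = config.marker_indices()
    for idx in mk.values():
        base[idx] = np.exp(
            np.abs(rng.normal(0.0, config.base_mean_log_sd, size=idx.size))
        )
    broad_idx = config.broad_indices()
    broad = {
        t: np.exp(
            rng.normal(config.broad_log_mean, config.broad_log_sd, broad_idx.size)
        )
        for t in list(config.ref_types) + list(config.unclassifiable_types)
    }
    return GeneratorTruth(base, mk, broad_idx, broad)


def generate_reference(
    config: ScenarioConfig,
) -> tuple[CountMatrix, CellAnnotation, GeneratorTruth]:
    """Simulate the annotated reference count matrix."""
    truth = _scenario_truth(config)
    rng = np.random.default_rng(config.seed + 1)
    cols, barcodes, labels = [], [], {}
    for t, n_cells in config.ref_types.items():
        means = truth.type_means(t, config.marker_fold_change)
        sizes = rng.lognormal(0.0, config.cell_size_log_sd, size=n_cells)
        for i in range(n_cells):
            cols.append(_nb_sample(rng, means * sizes[i], config.dispersion))
            bc = f"ref_{t}_{i}"
            barcodes.append(bc)
            labels[bc] = t
    counts = CountMatrix(config.gene_names, barcodes, np.column_stack(cols))
    return counts, CellAnnotation(labels), truth


def generate_query(
    config: ScenarioConfig, truth: GeneratorTruth
) -> tuple[CountMatrix, CellAnnotation]:
    """Simulate the query with batch distortion and unclassifiable types.

    Shared types reuse the reference type means; every query cell then sees
    the same per-gene log-normal capture factor (sd = ``batch_sigma``) and
    the global ``library_scale``.  Unclassifiable cells carry a ground-truth
    label of 'unassigned'.
    """
    rng = np.random.default_rng(config.seed + 2)
    capture = (
        rng.lognormal(0.0, config.batch_sigma, size=config.n_genes)
        if config.batch_sigma > 0
        else np.ones(config.n_genes)
    )
    cols, barcodes, labels = [], [], {}
    items = [(t, n, t) for t, n in config.query_types.items()] + [
        (t, n, UNASSIGNED) for t, n in config.unclassifiable_types.items()
    ]
    for t, n_cells, true_label in items:
        means = truth.type_means(t, config.marker_fold_change)
        means = means * capture * config.library_scale
        sizes = rng.lognormal(0.0, config.cell_size_log_sd, size=n_cells)
        for i in range(n_cells):
            cols.append(_nb_sample(rng, means * sizes[i], config.dispersion))
            bc = f"q_{t}_{i}"
            barcodes.append(bc)
            labels[bc] = true_label
    counts = CountMatrix(config.gene_names, barcodes, np.column_stack(cols))
    return counts, CellAnnotation(labels)


def generate_atlas(config: ScenarioConfig, truth: GeneratorTruth) -> ProfileMatrix:
    """Simulate a many-cell-type, low-depth aggregated atlas profile.

    Columns matching reference types are multinomial samples of the type's
    mean profile at ``atlas_depth``.  The remaining columns are unrelated
    cell types: they keep the scenario's shared per-gene base means (gene
    expression magnitude is largely conserved across cell types in real
    aggregated atlases) modulated by mild per-type log-normal noise, and
    boost their own independently drawn marker blocks.
    """
    if config.atlas_types < len(config.ref_types):
        raise ValidationError("atlas must have at least as many types as reference")
    rng = np.random.default_rng(config.seed + 3)
    names, cols = [], []
    for t in config.ref_types:
        means = truth.type_means(t, config.marker_fold_change)
        p = means / means.sum()
        cols.append(rng.multinomial(int(config.atlas_depth), p))
        names.append(f"atlas_{t}")
    n_extra = config.atlas_types - len(config.ref_types)
    # marker disjointness extends to atlas-only types: their blocks are drawn
    # outside the reserved reference/unclassifiable marker blocks
    reserved = np.concatenate(
        list(truth.marker_indices.values())
        + ([truth.broad_indices] if truth.broad_indices is not None else [])
    )
    free = np.setdiff1d(np.arange(config.n_genes), reserved)
    for j in range(n_extra):
        base = truth.base_means * rng.lognormal(0.0, 0.3, size=config.n_genes)
        mk = rng.choice(free, size=config.markers_per_type, replace=False)
        base[mk] *= config.marker_fold_change
        if truth.broad_indices is not None and truth.broad_indices.size:
            base[truth.broad_indices] *= np.exp(
                rng.normal(config.broad_log_mean, config.broad_log_sd,
                           truth.broad_indices.size)
            )
        p = base / base.sum()
        cols.append(rng.multinomial(int(config.atlas_depth), p))
        names.append(f"atlas_extra{j}")
    return ProfileMatrix(config.gene_names, names, np.column_stack(cols).astype(float))


def generate_scenario(config: ScenarioConfig):
    """Generate (reference, ref annotation, query, query truth, atlas)."""
    ref, ref_ann, truth = generate_reference(config)
    query, q_truth = generate_query(config, truth)
    atlas = generate_atlas(config, truth)
    return ref, ref_ann, query, q_truth, atlas


# ---------------------------------------------------------------------------
# Bundled presets (the study conditions exercised by the test suite)
# ---------------------------------------------------------------------------

def _preset_situation1_easy(seed: int) -> ScenarioConfig:
    return ScenarioConfig(seed=seed)


def _preset_situation2_unclassifiable(seed: int) -> ScenarioConfig:
    return ScenarioConfig(
        seed=seed,
        ref_types={f"type{i}": 100 for i in range(5)},
        query_types={f"type{i}": 250 for i in range(5)},
        unclassifiable_types={"novel0": 250},
        batch_sigma=0.5,
    )


def _preset_situation2_lowdepth(seed: int) -> ScenarioConfig:
    # the low-depth pairing is the severe-batch scenario: shallow libraries
    # and much stronger cross-platform per-gene capture distortion
    cfg = _preset_situation2_unclassifiable(seed)
    cfg.library_scale = 0.2
    cfg.batch_sigma = 1.0
    return cfg


def _preset_atlas_reference(seed: int) -> ScenarioConfig:
    return ScenarioConfig(seed=seed, atlas_depth=1e5)


PRESETS = {
    "situation1_easy": _preset_situation1_easy,
    "situation2_unclassifiable": _preset_situation2_unclassifiable,
    "situation2_lowdepth": _preset_situation2_lowdepth,
    "atlas_reference": _preset_atlas_reference,
}


def preset(name: str, seed: int = 7) -> ScenarioConfig:
    """Look up a bundled scenario preset by name."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](seed)
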