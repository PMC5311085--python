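"""Array-design pipeline: filter, coverage, top-F_ST selection, LD pruning.

The pipeline mirrors how a balanced multi-source SNP array is assembled:
candidates from several pools are filtered on missingness and
within-population polymorphism, thinned to an even physical coverage (at
least ``min_per_window`` markers per 100 kb window where candidates exist),
optionally ranked by between-population F_ST, pooled across sources with
first-source-wins deduplication, and finally LD-pruned so that no retained
pair within a 50-SNP window has r^2 above 0.1.

Each stage is a scikit-learn style estimator (``fit`` learns the selected
variant ids, ``transform`` subsets a :class:`GenotypeMatrix`), so stages
compose with :class:`sklearn.pipeline.Pipeline`. The module-level functions
are thin wrappers over the estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, SnpPanelError
from .matrix import MISSING, GenotypeMatrix, Source
from .stats import allele_frequencies, fst_weir_cockerham, ld_r2, sample_rates


@dataclass
class DesignConfig:
    """Thresholds of the design pipeline.

    Defaults follow the standard mid-density array recipe: drop variants
    missing in >= 5% of samples, require polymorphism (MAF >= 0.05) within
    each population, guarantee one marker per 100 kb window, and prune any
    pair with r^2 > 0.1 among the previous 50 retained markers.
    """

    missing_max: float = 0.05
    require_polymorphic_both: bool = True
    maf_min: float = 0.05
    coverage_window: int = 100_000
    min_per_window: int = 1
    fst_top_n: int | None = None
    ld_window_snps: int = 50
    ld_r2_max: float = 0.1

    def validate(self) -> None:
        for name in ("missing_max", "maf_min", "ld_r2_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_window <= 0 or self.min_per_window <= 0 or self.ld_window_snps <= 0:
            raise ConfigError("windows and counts must be positive")


@dataclass
class PanelDesign:
    """Result of panel assembly.

    ``selected`` is ordered by (chrom, pos); ``provenance`` records, per
    candidate id, its source pool and the stage at which it was kept or
    dropped; ``stage_counts`` is non-increasing along the filter stages.
    """

    selected: list[str]
    provenance: pd.DataFrame  # columns: id, source, stage
    stage_counts: dict[str, int]


# -- estimators ------------------------------------------------------------


def _check_matrix(X) -> GenotypeMatrix:
    if not isinstance(X, GenotypeMatrix):
        raise ConfigError(f"expected a GenotypeMatrix, got {type(X).__name__}")
    return X


class _SelectsVariants(TransformerMixin):
    """Mixin: ``transform`` subsets the matrix to the fitted variant ids."""

    def transform(self, X) -> GenotypeMatrix:
        if not hasattr(self, "selected_ids_"):
            raise SnpPanelError(f"{type(self).__name__} is not fitted")
        return _check_matrix(X).subset(variant_ids=self.selected_ids_)


class CandidateFilter(BaseEstimator, _SelectsVariants):
    """Keep variants with low missingness and (optionally) polymorphism
    at MAF >= ``maf_min`` within every population separately."""

    def __init__(self, missing_max: float = 0.05, maf_min: float = 0.05, require_polymorphic_both: bool = True):
        self.missing_max = missing_max
        self.maf_min = maf_min
        self.require_polymorphic_both = require_polymorphic_both

    def fit(self, X, y=None):
        m = _check_matrix(X)
        _, per_variant = sample_rates(m)
        keep = per_variant["missing_rate"].values < self.missing_max
        if self.require_polymorphic_both:
            groups = m.population_groups()
            if not groups:
                raise ConfigError("population labels required when require_polymorphic_both=True")
            freqs = allele_frequencies(m, groups)
            for name in groups:
                f = freqs[name].values
                maf = np.minimum(f, 1 - f)
                keep &= ~np.isnan(f) & (maf >= self.maf_min)
        self.support_ = keep
        self.selected_ids_ = [v.id for v, k in zip(m.variants, keep) if k]
        return self


class EvenCoverageSelector(BaseEstimator, _SelectsVariants):
    """Per disjoint ``coverage_window`` bin, keep the ``min_per_window``
    best-ranked candidates (ties by position, then id).

    Bins are half-open on 0-based coordinates, per chromosome. Bins with no
    candidate are reported in ``gaps_`` as (chrom, start, end); chromosome
    extents default to the largest observed position.
    """

    def __init__(self, coverage_window: int = 100_000, min_per_window: int = 1, chrom_lengths: dict | None = None):
        self.coverage_window = coverage_window
        self.min_per_window = min_per_window
        self.chrom_lengths = chrom_lengths

    def fit(self, X, y=None, ranking: dict[str, float] | None = None):
        """``ranking`` maps variant id -> score (higher is better); unranked
        candidates score 0."""
        m = _check_matrix(X)
        if self.coverage_window <= 0 or self.min_per_window <= 0:
            raise ConfigError("coverage_window and min_per_window must be positive")
        ranking = ranking or {}
        by_bin: dict[tuple[str, int], list[tuple[float, int, str]]] = {}
        for v in m.variants:
            b = (v.pos - 1) // self.coverage_window
            by_bin.setdefault((v.chrom, b), []).append((-ranking.get(v.id, 0.0), v.pos, v.id))
        selected: list[str] = []
        for key in sorted(by_bin):
            members = sorted(by_bin[key])
            selected.extend(vid for _, _, vid in members[: self.min_per_window])
        lengths = self.chrom_lengths or m.chrom_lengths()
        gaps: list[tuple[str, int, int]] = []
        for chrom, length in sorted(lengths.items()):
            n_bins = int(np.ceil(length / self.coverage_window))
            for b in range(n_bins):
                if (chrom, b) not in by_bin:
                    start = b * self.coverage_window
                    gaps.append((chrom, start, min(start + self.coverage_window, length)))
        self.gaps_ = gaps
        order = {vid: j for j, vid in enumerate(m.variant_ids)}
        self.selected_ids_ = sorted(selected, key=order.__getitem__)
        return self


class TopFstSelector(BaseEstimator, _SelectsVariants):
    """Keep the ``n`` candidates with the largest per-site Weir–Cockerham
    F_ST between the two populations (ties by chrom, pos, id).

    Variants with undefined F_ST are excluded with a warning.
    """

    def __init__(self, n: int = 1000):
        self.n = n

    def fit(self, X, y=None):
        m = _check_matrix(X)
        if self.n <= 0:
            raise ConfigError(f"n must be positive, got {self.n}")
        theta = fst_weir_cockerham(m)
        undefined = int(np.isnan(theta).sum())
        if undefined:
            warnings.warn(f"{undefined} variant(s) have undefined F_ST and were excluded")
        scored = [
            (-theta[j], v.chrom, v.pos, v.id)
            for j, v in enumerate(m.variants)
            if not np.isnan(theta[j])
        ]
        scored.sort()
        chosen = {vid for _, _, _, vid in scored[: self.n]}
        self.fst_ = theta
        self.selected_ids_ = [vid for vid in m.variant_ids if vid in chosen]
        return self


class LDPruner(BaseEstimator, _SelectsVariants):
    """Greedy left-to-right LD pruning.

    Scanning candidates in (chrom, pos) order, a candidate is dropped when
    its r^2 with any of the previous ``ld_window_snps`` retained candidates
    on the same chromosome exceeds ``ld_r2_max``; hence no retained pair
    within the window exceeds the threshold. Undefined r^2 (monomorphic
    sites) never triggers removal.
    """

    def __init__(self, ld_window_snps: int = 50, ld_r2_max: float = 0.1):
        self.ld_window_snps = ld_window_snps
        self.ld_r2_max = ld_r2_max

    def fit(self, X, y=None):
        m = _check_matrix(X)
        if self.ld_window_snps <= 0:
            raise ConfigError("ld_window_snps must be positive")
        kept: list[str] = []
        window: list[int] = []
        current_chrom: str | None = None
        for j, v in enumerate(m.variants):
            if v.chrom != current_chrom:
                current_chrom = v.chrom
                window = []
            col = m.calls[:, j]
            redundant = False
            for k in window[-self.ld_window_snps:]:
                r2 = ld_r2(m.calls[:, k], col)
                if not np.isnan(r2) and r2 > self.ld_r2_max:
                    redundant = True
                    break
            if not redundant:
                kept.append(v.id)
                window.append(j)
        self.selected_ids_ = kept
        return self


# -- functional wrappers ---------------------------------------------------


def filter_candidates(matrix: GenotypeMatrix, config: DesignConfig) -> list[str]:
    config.validate()
    est = CandidateFilter(config.missing_max, config.maf_min, config.require_polymorphic_both)
    return est.fit(matrix).selected_ids_


def even_coverage_select(
    matrix: GenotypeMatrix,
    candidates: list[str] | None,
    config: DesignConfig,
    ranking: dict[str, float] | None = None,
    chrom_lengths: dict | None = None,
) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Returns (selected ids, coverage gaps)."""
    config.validate()
    sub = matrix.subset(variant_ids=candidates) if candidates is not None else matrix
    est = EvenCoverageSelector(config.coverage_window, config.min_per_window, chrom_lengths)
    est.fit(sub, ranking=ranking)
    return est.selected_ids_, est.gaps_


def top_fst_select(matrix: GenotypeMatrix, candidates: list[str] | None, n: int) -> list[str]:
    sub = matrix.subset(variant_ids=candidates) if candidates is not None else matrix
    return TopFstSelector(n).fit(sub).selected_ids_


def ld_prune(matrix: GenotypeMatrix, candidates: list[str] | None, config: DesignConfig) -> list[str]:
    config.validate()
    sub = matrix.subset(variant_ids=candidates) if candidates is not None else matrix
    return LDPruner(config.ld_window_snps, config.ld_r2_max).fit(sub).selected_ids_


def assemble_panel(
    source_sets: list[tuple[Source | str, list[str]]],
    matrix: GenotypeMatrix,
    config: DesignConfig,
) -> PanelDesign:
    """Pool candidate id sets, deduplicate (first source wins), LD-prune.

    ``source_sets`` preserves the caller's priority order; every pooled id's
    source and surviving stage are recorded in the provenance table.
    """
    config.validate()
    source_of: dict[str, str] = {}
    for src, ids in source_sets:
        tag = src.value if isinstance(src, Source) else str(src)
        for vid in ids:
            source_of.setdefault(vid, tag)
    if not source_of:
        raise SnpPanelError("no candidate ids after pooling")
    pooled = list(source_of)
    matrix.variant_indices(pooled)  # validate ids exist
    kept = set(ld_prune(matrix, pooled, config))
    order = {vid: j for j, vid in enumerate(matrix.variant_ids)}
    selected = sorted(kept, key=order.__getitem__)
    provenance = pd.DataFrame(
        {
            "id": sorted(pooled, key=order.__getitem__),
            "source": [source_of[v] for v in sorted(pooled, key=order.__getitem__)],
            "stage": ["ld_pruned" if v in kept else "dropped_ld" for v in sorted(pooled, key=order.__getitem__)],
        }
    )
    stage_counts = {"pooled": len(pooled), "ld_pruned": len(selected)}
    return PanelDesign(selected=selected, provenance=provenance, stage_counts=stage_counts)
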