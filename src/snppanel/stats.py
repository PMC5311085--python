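"""Per-variant, per-sample and pairwise population-genetic statistics.

Covers the evaluation battery of a two-population SNP panel: per-group
allele frequencies, MAF, polymorphism information content (PIC), allele
frequency differentiation (AFD), per-site Weir–Cockerham (1984) F_ST,
the two-dimensional folded site frequency spectrum, per-sample/per-variant
missing and heterozygosity rates, identity-by-state distance, an
IBS-derived kinship, and LD decay from squared Pearson correlation of
dosages.

Missing-data policy: every statistic here is pairwise- or cell-complete —
missing calls are dropped from both numerator and denominator, never
imputed. Quantities with an empty denominator are NaN ("undefined").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SnpPanelError
from .matrix import MISSING, GenotypeMatrix


# -- containers ----------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample measure.

    ``kind`` is ``"ibs_distance"`` (diagonal 0; larger = more different) or
    ``"kinship"`` (diagonal reported; larger = more related, clones near the
    matrix maximum).
    """

    sample_ids: list[str]
    values: np.ndarray
    kind: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class LDDecayCurve:
    """Mean r^2 per physical-distance bin (contiguous half-open bins from 0)."""

    bin_edges: np.ndarray  # length n_bins + 1, starts at 0
    mean_r2: np.ndarray  # NaN where a bin holds no pairs
    n_pairs: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "low": self.bin_edges[:-1],
                "high": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


# -- allele frequencies ---------------------------------------------------


def _resolve_groups(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray] | None
) -> dict[str, np.ndarray]:
    if groups is None:
        groups = matrix.population_groups()
    if not groups:
        raise ConfigError("no population labels available and no explicit grouping given")
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ConfigError(f"group {name!r} is empty")
    return groups


def allele_frequencies(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Alt-allele frequency per variant, per group plus pooled ("overall").

    freq = (sum of dosages) / (2 x non-missing count); all-missing cells
    are NaN.
    """
    groups = _resolve_groups(matrix, groups)
    calls = matrix.calls
    out: dict[str, np.ndarray] = {}
    for name, idx in groups.items():
        sub = calls[idx]
        ok = sub != MISSING
        n = ok.sum(axis=0)
        s = np.where(ok, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(n > 0, s / (2.0 * n), np.nan)
    pooled_idx = np.unique(np.concatenate(list(groups.values())))
    sub = calls[pooled_idx]
    ok = sub != MISSING
    n = ok.sum(axis=0)
    s = np.where(ok, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["overall"] = np.where(n > 0, s / (2.0 * n), np.nan)
    return pd.DataFrame(out, index=matrix.variant_ids)


def minor_allele_frequency(freq: np.ndarray | pd.Series) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    return np.minimum(f, 1.0 - f)


# -- marker informativeness ----------------------------------------------


def pic(allele_freqs) -> float:
    """Polymorphism information content of one marker.

    PIC = 1 - sum_i P_i^2 - sum_{i<j} 2 P_i^2 P_j^2 for allele frequencies
    ``P``; for a biallelic marker the maximum is 0.375 at P = 0.5.
    """
    p = np.asarray(allele_freqs, dtype=float)
    if (p < 0).any():
        raise ConfigError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError(f"allele frequencies must sum to 1, got {p.sum()!r}")
    sq = p**2
    cross = np.outer(sq, sq)
    pairs = np.triu(cross, k=1).sum()
    return float(1.0 - sq.sum() - 2.0 * pairs)


def pic_biallelic(alt_freq: np.ndarray | float) -> np.ndarray | float:
    """Vectorized biallelic PIC; NaN propagates for undefined frequencies."""
    p = np.asarray(alt_freq, dtype=float)
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * (p**2) * (q**2)
    return out if out.ndim else float(out)


def afd(freq_temperate, freq_tropical) -> np.ndarray | float:
    """Allele frequency differentiation: |temperate - tropical| frequency."""
    a = np.asarray(freq_temperate, dtype=float)
    b = np.asarray(freq_tropical, dtype=float)
    with np.errstate(invalid="ignore"):
        if (np.nan_to_num(a, nan=0.5) < 0).any() or (np.nan_to_num(a, nan=0.5) > 1).any():
            raise ConfigError("frequencies must be in [0, 1]")
        if (np.nan_to_num(b, nan=0.5) < 0).any() or (np.nan_to_num(b, nan=0.5) > 1).any():
            raise ConfigError("frequencies must be in [0, 1]")
    out = np.abs(a - b)
    return out if out.ndim else float(out)


# -- Weir-Cockerham F_ST --------------------------------------------------


def _wc_components(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components (a, b, c, valid)."""
    groups = _resolve_groups(matrix, groups)
    if len(groups) != 2:
        raise ConfigError(f"exactly two groups required, got {len(groups)}")
    (idx1, idx2) = groups.values()
    stats = []
    for idx in (idx1, idx2):
        sub = matrix.calls[idx]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        s = np.where(ok, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, s / (2.0 * n), np.nan)
            h = np.where(n > 0, np.where(ok, sub == 1, False).sum(axis=0) / n, np.nan)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)  # r - 1 = 1
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    return a, b, c, valid


def fst_weir_cockerham(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    """Per-site Weir–Cockerham (1984) theta for two populations.

    Computed from the genotype-based variance components a, b, c with
    sample-size and observed-heterozygosity corrections; theta = a/(a+b+c).
    Sites monomorphic across both groups (or with fewer than two genotyped
    individuals in either group) are NaN. Negative estimates are preserved.
    """
    a, b, c, valid = _wc_components(matrix, groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    return np.where(valid, theta, np.nan)


def fst_weir_cockerham_global(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None
) -> float:
    """Multi-locus Weir–Cockerham theta: sum(a) / sum(a + b + c).

    This is the 1984 recommendation for combining loci — variance
    components are summed before taking the ratio, which avoids the
    downward bias of averaging per-site ratios. NaN components (sites with
    too few genotyped individuals) are excluded.
    """
    a, b, c, valid = _wc_components(matrix, groups)
    keep = valid & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[keep] + b[keep] + c[keep]).sum()
    if denom == 0:
        return float("nan")
    return float(a[keep].sum() / denom)


# -- folded 2-D SFS -------------------------------------------------------


def folded_sfs_2d(
    matrix: GenotypeMatrix,
    n_bins: int = 20,
    groups: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """2-D folded site frequency spectrum (first axis tropical, second temperate).

    Folding is joint: each variant is oriented once by the pooled minor
    allele (pooled frequency > 0.5 flips both axes), so the two populations'
    frequencies stay comparable. Variants with an undefined frequency in
    either group are excluded; counts sum to the retained variant count.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    freqs = allele_frequencies(matrix, groups)
    cols = [c for c in freqs.columns if c != "overall"]
    if set(cols) >= {"temperate", "tropical"}:
        f_tro, f_tem = freqs["tropical"].values, freqs["temperate"].values
    else:  # generic two-group input: first group on x, second on y
        if len(cols) != 2:
            raise ConfigError("folded 2-D SFS needs exactly two groups")
        f_tro, f_tem = freqs[cols[0]].values, freqs[cols[1]].values
    pooled = freqs["overall"].values
    keep = ~(np.isnan(f_tro) | np.isnan(f_tem) | np.isnan(pooled))
    f_tro, f_tem, pooled = f_tro[keep], f_tem[keep], pooled[keep]
    flip = pooled > 0.5
    f_tro = np.where(flip, 1.0 - f_tro, f_tro)
    f_tem = np.where(flip, 1.0 - f_tem, f_tem)
    bx = np.clip((f_tro * n_bins).astype(int), 0, n_bins - 1)
    by = np.clip((f_tem * n_bins).astype(int), 0, n_bins - 1)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(counts, (bx, by), 1)
    return counts


# -- per-sample / per-variant rates ---------------------------------------


def sample_rates(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-sample, per-variant) DataFrames of missing_rate and het_rate.

    het_rate is the fraction of dosage-1 calls among non-missing calls.
    """
    calls = matrix.calls
    ok = calls != MISSING
    het = calls == 1

    def _rates(axis: int) -> tuple[np.ndarray, np.ndarray]:
        total = calls.shape[axis]
        n_ok = ok.sum(axis=axis)
        with np.errstate(invalid="ignore", divide="ignore"):
            miss = 1.0 - n_ok / total
            hr = np.where(n_ok > 0, het.sum(axis=axis) / n_ok, np.nan)
        return miss, hr

    miss_s, het_s = _rates(axis=1)
    miss_v, het_v = _rates(axis=0)
    per_sample = pd.DataFrame({"missing_rate": miss_s, "het_rate": het_s}, index=matrix.sample_ids)
    per_variant = pd.DataFrame({"missing_rate": miss_v, "het_rate": het_v}, index=matrix.variant_ids)
    return per_sample, per_variant


# -- IBS distance ----------------------------------------------------------


def _pairwise_abs_diff_sums(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sum over shared sites of |d_i - d_j|, shared-site counts) for all pairs."""
    ok = (calls != MISSING).astype(np.float64)
    ind = [((calls == v) & (calls != MISSING)).astype(np.float64) for v in (0, 1, 2)]
    n_joint = ok @ ok.T
    diff = np.zeros_like(n_joint)
    for u in range(3):
        for v in range(3):
            if u != v:
                diff += abs(u - v) * (ind[u] @ ind[v].T)
    return diff, n_joint


def ibs_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean identity-by-state over jointly non-missing variants.

    Per variant, IBS credit is 1 for identical dosages, 0.5 when the pair
    shares exactly one allele (het vs hom), 0 for opposite homozygotes —
    i.e. 1 - |d_i - d_j| / 2. Pairs sharing no genotyped variant are NaN
    and flagged with a warning.
    """
    if matrix.n_samples < 2:
        raise ConfigError("need at least two samples")
    diff, n_joint = _pairwise_abs_diff_sums(matrix.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n_joint > 0, diff / (2.0 * n_joint), np.nan)
    np.fill_diagonal(dist, 0.0)
    undefined = np.isnan(dist).sum() // 2
    if undefined:
        warnings.warn(f"{undefined} sample pair(s) share no genotyped variant; distance undefined")
    return DistanceMatrix(matrix.sample_ids, dist.astype(float), kind="ibs_distance")


def nucleotide_diversity_within(matrix: GenotypeMatrix, group) -> float:
    """Mean pairwise IBS distance over unordered pairs within a group.

    ``group`` is a population label or an explicit list of sample ids.
    """
    ids = _group_sample_ids(matrix, group)
    if len(ids) < 2:
        raise ConfigError(f"group {group!r} has fewer than two samples")
    d = ibs_distance_matrix(matrix.subset(sample_ids=ids)).values
    iu = np.triu_indices(len(ids), k=1)
    return float(np.nanmean(d[iu]))


def nucleotide_diversity_between(matrix: GenotypeMatrix, group_a, group_b) -> float:
    """Mean IBS distance over cross-group sample pairs."""
    ids_a = _group_sample_ids(matrix, group_a)
    ids_b = _group_sample_ids(matrix, group_b)
    if not ids_a or not ids_b:
        raise ConfigError("both groups must be non-empty")
    dm = ibs_distance_matrix(matrix)
    ia = matrix.sample_indices(ids_a)
    ib = matrix.sample_indices(ids_b)
    return float(np.nanmean(dm.values[np.ix_(ia, ib)]))


def _group_sample_ids(matrix: GenotypeMatrix, group) -> list[str]:
    if isinstance(group, str):
        return [s.id for s in matrix.samples if s.population.value == group or s.group == group]
    return list(group)


# -- kinship ---------------------------------------------------------------


def kinship_matrix(
    matrix: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.2
) -> DistanceMatrix:
    """Centered-IBS kinship on filtered variants, scaled to [0, 1].

    Variants are first filtered to MAF > ``maf_min`` and per-variant missing
    rate < ``missing_max``. Dosages are centered by twice the pooled allele
    frequency (missing cells contribute zero after centering), the
    cross-product is normalised by sum(2 p q), negative raw values are
    truncated to 0 and the matrix is scaled by its maximal diagonal entry,
    so clones score ~1 and unrelated lines ~0.
    """
    calls = matrix.calls
    ok = calls != MISSING
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ok > 0, np.where(ok, calls, 0).sum(axis=0) / (2.0 * n_ok), np.nan)
    miss = 1.0 - n_ok / calls.shape[0]
    maf = np.minimum(p, 1 - p)
    keep = (~np.isnan(p)) & (maf > maf_min) & (miss < missing_max)
    if not keep.any():
        raise ConfigError("no variants survive the kinship filters")
    p = p[keep]
    sub = calls[:, keep].astype(float)
    okk = ok[:, keep]
    centered = np.where(okk, sub - 2.0 * p[None, :], 0.0)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0.0:
        raise ConfigError("all retained variants are monomorphic; kinship undefined")
    k = centered @ centered.T / denom
    k = np.clip(k, 0.0, None)
    top = k.diagonal().max()
    if top == 0.0:
        raise ConfigError("kinship matrix degenerate (zero variance)")
    return DistanceMatrix(matrix.sample_ids, k / top, kind="kinship")


# -- linkage disequilibrium ------------------------------------------------


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete).

    NaN when fewer than two complete pairs remain or either site is
    monomorphic among them.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError(f"length mismatch: {a.shape} vs {b.shape}")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay_curve(
    matrix: GenotypeMatrix,
    max_distance: int = 500_000,
    bin_width: int = 50_000,
    maf_min: float = 0.05,
) -> LDDecayCurve:
    """Mean r^2 of same-chromosome variant pairs binned by physical distance.

    Uses disjoint half-open distance bins of ``bin_width`` from 0 to
    ``max_distance``; variants are pre-filtered to pooled MAF > ``maf_min``.
    Pairs with undefined r^2 are skipped (not counted).
    """
    calls = matrix.calls.astype(np.float64)
    ok = matrix.calls != MISSING
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ok > 0, np.where(ok, matrix.calls, 0).sum(axis=0) / (2.0 * n_ok), np.nan)
    keep = (~np.isnan(p)) & (np.minimum(p, 1 - p) > maf_min)

    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    chroms = matrix.chroms
    positions = matrix.positions
    x_ok = ok.T.astype(np.float64)  # variants x samples indicator
    x_val = np.where(ok, calls, 0.0).T
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero((chroms == chrom) & keep)
        pos = positions[sel]
        order = np.argsort(pos, kind="stable")
        sel, pos = sel[order], pos[order]
        for a in range(len(sel)):
            hi = np.searchsorted(pos, pos[a] + max_distance, side="left")
            if hi <= a + 1:
                continue
            js = sel[a + 1 : hi]
            dist = pos[a + 1 : hi] - pos[a]
            m_a, v_a = x_ok[sel[a]], x_val[sel[a]]
            m_b, v_b = x_ok[js], x_val[js]
            mm = m_b * m_a[None, :]
            n = mm.sum(axis=1)
            sa = mm @ v_a
            sb = (v_b * m_a[None, :]).sum(axis=1)
            saa = mm @ (v_a * v_a)
            sbb = (v_b * v_b * m_a[None, :]).sum(axis=1)
            sab = (v_b * v_a[None, :] * mm).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sab - sa * sb / n
                var_a = saa - sa * sa / n
                var_b = sbb - sb * sb / n
                r2 = (cov * cov) / (var_a * var_b)
            good = (n >= 2) & (var_a > 0) & (var_b > 0) & np.isfinite(r2)
            if not good.any():
                continue
            bins = (dist[good] // bin_width).astype(int)
            np.add.at(sums, bins, r2[good])
            np.add.at(counts, bins, 1)
    if counts.sum() == 0:
        raise SnpPanelError("no eligible variant pairs for the LD decay curve")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / counts, np.nan)
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    return LDDecayCurve(bin_edges=edges, mean_r2=mean_r2, n_pairs=counts)


def decay_distance(curve: LDDecayCurve, threshold: float = 0.1) -> tuple[int, int] | None:
    """First distance bin whose mean r^2 falls below ``threshold``.

    Returns the bin's [low, high) range in base pairs, or None if mean r^2
    never crosses the threshold within the curve.
    """
    for k in range(len(curve.n_pairs)):
        if curve.n_pairs[k] > 0 and curve.mean_r2[k] < threshold:
            return int(curve.bin_edges[k]), int(curve.bin_edges[k + 1])
    return None


# -- assembled per-variant table -------------------------------------------


def variant_stats(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """One row per variant: frequencies, MAF, rates, PIC, AFD, F_ST."""
    groups = _resolve_groups(matrix, groups)
    freqs = allele_frequencies(matrix, groups)
    _, per_variant = sample_rates(matrix)
    names = [c for c in freqs.columns if c != "overall"]
    df = pd.DataFrame(index=matrix.variant_ids)
    for name in names:
        df[f"freq_{name}"] = freqs[name]
    df["freq_overall"] = freqs["overall"]
    df["maf"] = minor_allele_frequency(freqs["overall"].values)
    df["missing_rate"] = per_variant["missing_rate"]
    df["het_rate"] = per_variant["het_rate"]
    df["pic"] = pic_biallelic(freqs["overall"].values)
    if len(names) == 2:
        df["afd"] = afd(freqs[names[0]].values, freqs[names[1]].values)
        df["fst"] = fst_weir_cockerham(matrix, groups)
    return df
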