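"""Core SNP set construction.

A core set is a small marker subset retaining fingerprinting power and
genome coverage. Construction has three parts:

1. *Genotyping bins*: variants are clustered into K bins by the similarity
   of their genotype patterns across the sample panel (k-medoids under
   Hamming distance, missing calls excluded pairwise).
2. *Genetic bins*: the genome is partitioned into B fixed physical
   intervals, apportioned to chromosomes proportionally to length.
3. A seedable (1+1) hill-climbing genetic algorithm starts from one random
   representative per genotyping bin and mutates by swapping a bin's
   representative for another member of the same bin, accepting any
   proposal that does not decrease the number of distinct genetic bins
   covered. In complementary mode, later sets score only genetic bins not
   covered by earlier sets, so the union of sets spreads across the genome.

Evaluation: per-set and union bin coverage, and the differential locus
rate (fraction of markers at which two lines differ) over sample pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import ConfigError
from .matrix import MISSING, GenotypeMatrix


@dataclass
class BinAssignment:
    """Per-variant genotyping-bin and genetic-bin indices."""

    variant_ids: list[str]
    genotyping_bin: np.ndarray  # dense ints in [0, k)
    genetic_bin: np.ndarray  # ints in [0, b)
    k: int
    b: int


@dataclass
class CoreSetResult:
    """Selected core sets plus coverage and GA diagnostics.

    Coverages are fractions of all bins of each kind containing at least
    one selected id, per set and for the union of sets. Each fitness
    trajectory is non-decreasing (hill-climbing acceptance rule).
    """

    sets: list[list[str]]
    genotyping_coverage: list[float]
    genetic_coverage: list[float]
    genotyping_coverage_union: float
    genetic_coverage_union: float
    fitness_trajectories: list[np.ndarray]
    seed: int


# -- genotyping bins (pattern clustering) ----------------------------------


def _pattern_distance_matrix(patterns: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance between dosage patterns (rows).

    Distance = fraction of jointly non-missing samples at which the two
    patterns disagree; pairs with no jointly non-missing sample get the
    maximal distance 1.
    """
    ok = (patterns != MISSING).astype(np.float32)
    n_joint = ok @ ok.T
    equal = np.zeros_like(n_joint)
    for v in (0, 1, 2):
        ind = ((patterns == v) & (patterns != MISSING)).astype(np.float32)
        equal += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n_joint > 0, 1.0 - equal / n_joint, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_genotyping_bins(
    matrix: GenotypeMatrix, k: int, seed: int = 0, max_iter: int = 20
) -> np.ndarray:
    """k-medoids clustering of variants by genotype pattern.

    Identical patterns always co-cluster (clustering runs on distinct
    patterns, weighted by multiplicity). Initialisation is greedy
    distance-squared seeding from the given seed; assignment and medoid
    updates iterate to convergence or ``max_iter``. Deterministic under
    ``seed``.
    """
    patterns, inverse, counts = np.unique(
        matrix.calls.T, axis=0, return_inverse=True, return_counts=True
    )
    n_distinct = patterns.shape[0]
    if k > n_distinct:
        raise ConfigError(
            f"k={k} exceeds the {n_distinct} distinct genotype patterns; use k <= {n_distinct}"
        )
    if k <= 0:
        raise ConfigError("k must be positive")
    dist = _pattern_distance_matrix(patterns)
    w = counts.astype(np.float64)
    rng = np.random.default_rng(seed)

    # D^2 seeding over distinct patterns
    medoids = [int(rng.choice(n_distinct, p=w / w.sum()))]
    min_d = dist[medoids[0]].copy()
    for _ in range(1, k):
        probs = w * min_d**2
        if probs.sum() == 0:  # all remaining points coincide with a medoid
            remaining = np.setdiff1d(np.arange(n_distinct), medoids)
            medoids.append(int(remaining[0]))
        else:
            medoids.append(int(rng.choice(n_distinct, p=probs / probs.sum())))
        min_d = np.minimum(min_d, dist[medoids[-1]])

    medoid_arr = np.array(medoids)
    labels = np.argmin(dist[:, medoid_arr], axis=1)
    for _ in range(max_iter):
        new_medoids = medoid_arr.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            costs = (dist[np.ix_(members, members)] * w[members][None, :]).sum(axis=1)
            new_medoids[c] = members[int(np.argmin(costs))]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoid_arr) and np.array_equal(new_labels, labels):
            break
        medoid_arr, labels = new_medoids, new_labels

    # densify labels (some clusters may have emptied during reassignment)
    dense = {c: i for i, c in enumerate(dict.fromkeys(labels.tolist()))}
    labels = np.array([dense[c] for c in labels])
    return labels[inverse]


class GenotypingBinClusterer(BaseEstimator, ClusterMixin):
    """Estimator facade over :func:`cluster_genotyping_bins`.

    ``fit`` sets ``labels_`` (one genotyping-bin index per variant).
    """

    def __init__(self, n_bins: int = 1000, random_state: int = 0, max_iter: int = 20):
        self.n_bins = n_bins
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.labels_ = cluster_genotyping_bins(X, self.n_bins, self.random_state, self.max_iter)
        return self


# -- genetic bins ----------------------------------------------------------


def _apportion_bins(chrom_lengths: dict[str, int], b: int) -> dict[str, tuple[int, int]]:
    """(offset, n_bins) per chromosome, largest-remainder, every chrom >= 1."""
    names = sorted(chrom_lengths)
    if b < len(names):
        raise ConfigError(f"b={b} is smaller than the {len(names)} chromosomes")
    total = float(sum(chrom_lengths[c] for c in names))
    quotas = {c: b * chrom_lengths[c] / total for c in names}
    alloc = {c: int(np.floor(quotas[c])) for c in names}
    remainder = b - sum(alloc.values())
    for c in sorted(names, key=lambda c: (-(quotas[c] - alloc[c]), c))[:remainder]:
        alloc[c] += 1
    while any(v == 0 for v in alloc.values()):
        zero = next(c for c in names if alloc[c] == 0)
        donor = max(names, key=lambda c: alloc[c])
        alloc[zero] += 1
        alloc[donor] -= 1
    out: dict[str, tuple[int, int]] = {}
    offset = 0
    for c in names:
        out[c] = (offset, alloc[c])
        offset += alloc[c]
    return out


def assign_genetic_bins(
    chroms: np.ndarray,
    positions: np.ndarray,
    chrom_lengths: dict[str, int],
    b: int,
) -> np.ndarray:
    """Map each variant to a genome-wide genetic-bin index in [0, b).

    Bins are allocated to chromosomes proportionally to length
    (largest-remainder rounding; the total is exactly ``b``) and are
    equal-width half-open intervals within a chromosome.
    """
    layout = _apportion_bins(chrom_lengths, b)
    out = np.empty(len(positions), dtype=np.int64)
    for j, (chrom, pos) in enumerate(zip(chroms, positions)):
        if chrom not in layout:
            raise ConfigError(f"variant on unknown chromosome {chrom!r}")
        length = chrom_lengths[chrom]
        if not (1 <= pos <= length):
            raise ConfigError(f"position {pos} outside chromosome {chrom!r} (length {length})")
        offset, n_bins = layout[chrom]
        local = int((int(pos) - 1) * n_bins // length)
        out[j] = offset + min(local, n_bins - 1)
    return out


def make_bin_assignment(
    matrix: GenotypeMatrix,
    k: int,
    b: int,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> BinAssignment:
    chrom_lengths = chrom_lengths or matrix.chrom_lengths()
    return BinAssignment(
        variant_ids=matrix.variant_ids,
        genotyping_bin=cluster_genotyping_bins(matrix, k, seed),
        genetic_bin=assign_genetic_bins(matrix.chroms, matrix.positions, chrom_lengths, b),
        k=k,
        b=b,
    )


# -- genetic algorithm -----------------------------------------------------


def ga_core_set(
    bins: BinAssignment,
    candidates: list[str] | None = None,
    n_sets: int = 2,
    iterations: int = 1000,
    seed: int = 0,
    complementary: bool = False,
    count_accepted_only: bool = False,
) -> CoreSetResult:
    """(1+1) hill-climbing core-set selection over genotyping bins.

    Each set holds exactly one representative per non-empty genotyping bin
    (empty bins are skipped with a warning). A proposal swaps one bin's
    representative for another member of the same bin and is accepted iff
    the fitness — the number of distinct genetic bins covered, restricted
    in complementary mode to bins uncovered by earlier sets — does not
    decrease. ``iterations`` counts proposals, or accepted proposals when
    ``count_accepted_only`` is set. Sets differ by a seed offset; without
    complementary mode they are fully independent runs.
    """
    if iterations <= 0:
        raise ConfigError("iterations must be positive")
    if n_sets <= 0:
        raise ConfigError("n_sets must be positive")
    id_index = {vid: j for j, vid in enumerate(bins.variant_ids)}
    if candidates is None:
        cand_idx = np.arange(len(bins.variant_ids))
    else:
        cand_idx = np.array(sorted(id_index[v] for v in candidates), dtype=np.intp)
    members: dict[int, np.ndarray] = {}
    for g in range(bins.k):
        mem = cand_idx[bins.genotyping_bin[cand_idx] == g]
        if mem.size:
            members[g] = mem
    n_empty = bins.k - len(members)
    if n_empty:
        warnings.warn(f"{n_empty} genotyping bin(s) contain no candidate and were skipped")
    if not members:
        raise ConfigError("no genotyping bin contains any candidate")
    filled = sorted(members)
    multi = [g for g in filled if members[g].size > 1]

    sets: list[list[str]] = []
    trajectories: list[np.ndarray] = []
    covered_prev = np.zeros(bins.b, dtype=bool)
    for s in range(n_sets):
        rng = np.random.default_rng(seed + s)
        reps = {g: int(members[g][rng.integers(members[g].size)]) for g in filled}
        scoreable = ~covered_prev if complementary else np.ones(bins.b, dtype=bool)
        counts = np.zeros(bins.b, dtype=np.int64)
        for g in filled:
            counts[bins.genetic_bin[reps[g]]] += 1
        fitness = int(((counts > 0) & scoreable).sum())
        traj: list[int] = []
        budget = iterations
        max_proposals = iterations * 50 if count_accepted_only else iterations
        proposals = 0
        while budget > 0 and proposals < max_proposals and multi:
            proposals += 1
            g = multi[int(rng.integers(len(multi)))]
            mem = members[g]
            new = int(mem[rng.integers(mem.size)])
            old = reps[g]
            if new == old:
                alternatives = mem[mem != old]
                new = int(alternatives[rng.integers(alternatives.size)])
            gb_old = bins.genetic_bin[old]
            gb_new = bins.genetic_bin[new]
            delta = 0
            if gb_old != gb_new:
                if counts[gb_old] == 1 and scoreable[gb_old]:
                    delta -= 1
                if counts[gb_new] == 0 and scoreable[gb_new]:
                    delta += 1
            if delta >= 0:
                counts[gb_old] -= 1
                counts[gb_new] += 1
                reps[g] = new
                fitness += delta
                if count_accepted_only:
                    budget -= 1
            if not count_accepted_only:
                budget -= 1
            traj.append(fitness)
        chosen = sorted(reps.values())
        sets.append([bins.variant_ids[j] for j in chosen])
        trajectories.append(np.array(traj, dtype=np.int64))
        covered_prev |= counts > 0

    cov = coverage_metrics_from_sets(sets, bins)
    return CoreSetResult(
        sets=sets,
        genotyping_coverage=cov["genotyping_per_set"],
        genetic_coverage=cov["genetic_per_set"],
        genotyping_coverage_union=cov["genotyping_union"],
        genetic_coverage_union=cov["genetic_union"],
        fitness_trajectories=trajectories,
        seed=seed,
    )


def coverage_metrics_from_sets(sets: list[list[str]], bins: BinAssignment) -> dict:
    """Fraction of genotyping/genetic bins hit, per set and for the union."""
    id_index = {vid: j for j, vid in enumerate(bins.variant_ids)}

    def _cov(ids: list[str]) -> tuple[float, float]:
        idx = [id_index[v] for v in ids]
        g_hit = len(set(bins.genotyping_bin[idx].tolist()))
        b_hit = len(set(bins.genetic_bin[idx].tolist()))
        return g_hit / bins.k, b_hit / bins.b

    per = [_cov(s) for s in sets]
    union_ids = [vid for s in sets for vid in s]
    gu, bu = _cov(union_ids)
    return {
        "genotyping_per_set": [g for g, _ in per],
        "genetic_per_set": [b for _, b in per],
        "genotyping_union": gu,
        "genetic_union": bu,
    }


def coverage_metrics(result: CoreSetResult, bins: BinAssignment) -> dict:
    return coverage_metrics_from_sets(result.sets, bins)


class CoreSetSelector(BaseEstimator):
    """End-to-end core-set estimator: cluster, bin, run the GA.

    ``fit(X)`` on a :class:`GenotypeMatrix` sets ``bins_`` and ``result_``
    plus the flattened coverage attributes.
    """

    def __init__(
        self,
        k: int = 1000,
        b: int = 2000,
        n_sets: int = 2,
        iterations: int = 1000,
        complementary: bool = True,
        count_accepted_only: bool = False,
        chrom_lengths: dict | None = None,
        random_state: int = 0,
    ):
        self.k = k
        self.b = b
        self.n_sets = n_sets
        self.iterations = iterations
        self.complementary = complementary
        self.count_accepted_only = count_accepted_only
        self.chrom_lengths = chrom_lengths
        self.random_state = random_state

    def fit(self, X, y=None):
        self.bins_ = make_bin_assignment(X, self.k, self.b, self.chrom_lengths, self.random_state)
        self.result_ = ga_core_set(
            self.bins_,
            n_sets=self.n_sets,
            iterations=self.iterations,
            seed=self.random_state,
            complementary=self.complementary,
            count_accepted_only=self.count_accepted_only,
        )
        self.sets_ = self.result_.sets
        self.genotyping_coverage_union_ = self.result_.genotyping_coverage_union
        self.genetic_coverage_union_ = self.result_.genetic_coverage_union
        return self


# -- evaluation ------------------------------------------------------------


def differential_locus_rate(
    matrix: GenotypeMatrix, marker_ids: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Fraction of jointly genotyped markers at which two lines differ.

    Returns a per-pair table (sample_a, sample_b, rate) over unordered
    pairs and a summary dict with mean, median and the number of pairs
    excluded for sharing no genotyped marker.
    """
    sub = matrix.subset(variant_ids=marker_ids) if marker_ids is not None else matrix
    if sub.n_samples < 2:
        raise ConfigError("need at least two samples")
    calls = sub.calls
    ok = (calls != MISSING).astype(np.float64)
    n_joint = ok @ ok.T
    equal = np.zeros_like(n_joint)
    for v in (0, 1, 2):
        ind = ((calls == v) & (calls != MISSING)).astype(np.float64)
        equal += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 1.0 - equal / n_joint
    iu = np.triu_indices(sub.n_samples, k=1)
    rows = pd.DataFrame(
        {
            "sample_a": [sub.sample_ids[i] for i in iu[0]],
            "sample_b": [sub.sample_ids[j] for j in iu[1]],
            "rate": rate[iu],
            "n_markers": n_joint[iu].astype(int),
        }
    )
    excluded = int((rows["n_markers"] == 0).sum())
    valid = rows.loc[rows["n_markers"] > 0, "rate"]
    summary = {
        "mean": float(valid.mean()),
        "median": float(valid.median()),
        "n_pairs": int(len(valid)),
        "n_pairs_excluded": excluded,
    }
    return rows, summary
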