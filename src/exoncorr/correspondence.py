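"""Overlap tests and correspondence maps.

The core statistic of the pipeline: two biological samples are compared by an
*overlap test* on their associated-exon sets.  Within a species the population
is every cassette exon counted twice (once per inclusion status, HIGH and LOW);
between species the population is the two-row-per-pair array built from the
conserved exon-pair table (2M rows for M pairs).  The p-value is the upper tail
of the hypergeometric distribution, evaluated entirely in log space, and the
map cell value ("mapping score") is -log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import gammaln, logsumexp

from .errors import ConfigurationError, DomainError

__all__ = [
    "AssociatedExonSet",
    "OverlapTestResult",
    "PairedStatusRows",
    "CorrespondenceMap",
    "NegativeControlConfig",
    "ShuffleControlResult",
    "hypergeom_tail",
    "hypergeom_log_pmf",
    "within_test",
    "between_test",
    "paired_status_rows",
    "build_map",
    "order_samples",
    "shuffle_control",
    "calibration_pvalues",
]

_LN10 = np.log(10.0)

Status = Literal["HIGH", "LOW"]
STATUSES: tuple[Status, Status] = ("HIGH", "LOW")


@dataclass(frozen=True)
class AssociatedExonSet:
    """The (exon, status) members associated with one sample."""

    sample_id: str
    members: frozenset  # of (exon_id, "HIGH"|"LOW")

    def __post_init__(self):
        exons_high = {e for e, s in self.members if s == "HIGH"}
        exons_low = {e for e, s in self.members if s == "LOW"}
        if exons_high & exons_low:
            raise ConfigurationError(
                f"sample {self.sample_id}: exon(s) both HIGH and LOW: "
                f"{sorted(exons_high & exons_low)[:3]}"
            )


@dataclass(frozen=True)
class OverlapTestResult:
    statistic: int
    size_a: int
    size_b: int
    population: int
    log10_p: float

    @property
    def mapping_score(self) -> float:
        return -self.log10_p

    @property
    def p_value(self) -> float:
        return 10.0 ** self.log10_p


@dataclass(frozen=True)
class PairedStatusRows:
    """Two-column array of 2M rows: each conserved pair split into an h and an l row.

    Row r pairs ``fly_exon[r]`` with ``worm_exon[r]`` in status ``status[r]``;
    ``pair_index[r]`` identifies the underlying conserved pair.  One-to-many
    pairings are represented naturally: a reused exon occupies several rows.
    """

    pair_index: np.ndarray  # int, length 2M
    status: np.ndarray  # "HIGH"/"LOW", length 2M
    fly_exon: np.ndarray
    worm_exon: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.pair_index)

    @property
    def n_pairs(self) -> int:
        return self.n_rows // 2


def paired_status_rows(pairs: pd.DataFrame) -> PairedStatusRows:
    """Build the 2M-row status array from a pair table.

    ``pairs`` needs columns ``fly_exon_id`` and ``worm_exon_id``; each of the M
    pairs contributes one HIGH row and one LOW row (rows 0..M-1 are HIGH,
    M..2M-1 LOW, aligned by pair index).
    """
    if len(pairs) == 0:
        raise DomainError("empty pair table")
    fly = pairs["fly_exon_id"].to_numpy()
    worm = pairs["worm_exon_id"].to_numpy()
    m = len(fly)
    return PairedStatusRows(
        pair_index=np.concatenate([np.arange(m), np.arange(m)]),
        status=np.array(["HIGH"] * m + ["LOW"] * m),
        fly_exon=np.concatenate([fly, fly]),
        worm_exon=np.concatenate([worm, worm]),
    )


def _lchoose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """log C(n, k) with -inf outside the support; vectorized."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    n, k = np.broadcast_arrays(n, k)
    out = np.full(n.shape, -np.inf)
    ok = (k >= 0) & (k <= n)
    out[ok] = gammaln(n[ok] + 1) - gammaln(k[ok] + 1) - gammaln(n[ok] - k[ok] + 1)
    return out


def hypergeom_tail(k: int, size_a: int, size_b: int, population: int) -> float:
    """log10 of the upper-tail overlap probability P(X >= k).

    X is the overlap of two independent uniform draws of sizes ``size_a`` and
    ``size_b`` from a population of ``population`` items — equivalently a
    hypergeometric variable.  The sum

        p = sum_{i=k}^{min(a,b)} C(n,i) C(n-i,a-i) C(n-a,b-i) / (C(n,a) C(n,b))

    is evaluated with log-gamma binomials and log-sum-exp, so scores stay
    finite for arbitrarily extreme overlaps.  Returns log10(p) <= 0.
    """
    k, size_a, size_b, population = int(k), int(size_a), int(size_b), int(population)
    if not (0 <= size_a <= population and 0 <= size_b <= population):
        raise DomainError(
            f"set sizes ({size_a}, {size_b}) must lie in [0, population={population}]"
        )
    if not (0 <= k <= min(size_a, size_b)):
        raise DomainError(f"k={k} outside [0, min(|A|,|B|)={min(size_a, size_b)}]")
    if k == 0:
        return 0.0  # the sum runs over the entire support
    i = np.arange(k, min(size_a, size_b) + 1)
    log_num = (
        _lchoose(population, i)
        + _lchoose(population - i, size_a - i)
        + _lchoose(population - size_a, size_b - i)
    )
    log_den = _lchoose(population, size_a) + _lchoose(population, size_b)
    log_p = logsumexp(log_num) - float(log_den)
    return float(min(log_p, 0.0)) / _LN10


def hypergeom_log_pmf(k: int, size_a: int, size_b: int, population: int) -> float:
    """Natural-log pmf P(X = k) of the overlap, same parametrization as the tail."""
    k, a, b, n = int(k), int(size_a), int(size_b), int(population)
    if not (0 <= k <= min(a, b)):
        return -np.inf
    log_num = _lchoose(n, k) + _lchoose(n - k, a - k) + _lchoose(n - a, b - k)
    log_den = _lchoose(n, a) + _lchoose(n, b)
    return float(log_num - log_den)


def within_test(
    a: AssociatedExonSet, b: AssociatedExonSet, n_cassette: int
) -> OverlapTestResult:
    """Overlap test between two samples of the same species.

    The population is twice the number of cassette exons in the analysis
    universe (each exon in HIGH and LOW status); the statistic is the number
    of (exon, status) members shared by the two samples.
    """
    population = 2 * int(n_cassette)
    k = len(a.members & b.members)
    size_a, size_b = len(a.members), len(b.members)
    log10_p = hypergeom_tail(k, size_a, size_b, population)
    return OverlapTestResult(k, size_a, size_b, population, log10_p)


def _row_membership(rows: PairedStatusRows, assoc: AssociatedExonSet, side: str) -> np.ndarray:
    exon = rows.fly_exon if side == "fly" else rows.worm_exon
    return np.fromiter(
        ((e, s) in assoc.members for e, s in zip(exon, rows.status)),
        dtype=bool,
        count=rows.n_rows,
    )


def between_test(
    fly_assoc: AssociatedExonSet,
    worm_assoc: AssociatedExonSet,
    rows: PairedStatusRows,
) -> OverlapTestResult:
    """Overlap test between a fly sample and a worm sample through the pair rows.

    F' is the set of rows whose fly exon is associated (in the row's status)
    with the fly sample, W' the analogue for worm; the statistic T counts rows
    in both, and the population is the 2M rows.
    """
    f_mask = _row_membership(rows, fly_assoc, "fly")
    w_mask = _row_membership(rows, worm_assoc, "worm")
    t = int(np.sum(f_mask & w_mask))
    size_f, size_w = int(f_mask.sum()), int(w_mask.sum())
    log10_p = hypergeom_tail(t, size_f, size_w, rows.n_rows)
    return OverlapTestResult(t, size_f, size_w, rows.n_rows, log10_p)


@dataclass
class CorrespondenceMap:
    """Sample x sample matrix of mapping scores (-log10 p)."""

    row_labels: list[str]
    col_labels: list[str]
    scores: np.ndarray
    row_order: np.ndarray = field(default=None)
    col_order: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.row_labels), len(self.col_labels)):
            raise ConfigurationError("score matrix shape does not match labels")
        if self.row_order is None:
            self.row_order = np.arange(len(self.row_labels))
        if self.col_order is None:
            self.col_order = np.arange(len(self.col_labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.row_labels, columns=self.col_labels)


def _assoc_matrix(
    assoc_sets: Sequence[AssociatedExonSet], row_keys: list[tuple]
) -> np.ndarray:
    """Boolean membership matrix: rows = row_keys ((exon,status)), cols = samples."""
    index = {key: i for i, key in enumerate(row_keys)}
    mat = np.zeros((len(row_keys), len(assoc_sets)), dtype=bool)
    for j, aset in enumerate(assoc_sets):
        for key in aset.members:
            i = index.get(key)
            if i is not None:
                mat[i, j] = True
    return mat


def _score_matrix(
    t_mat: np.ndarray, sizes_a: np.ndarray, sizes_b: np.ndarray, population: int
) -> np.ndarray:
    scores = np.empty(t_mat.shape, dtype=float)
    for i in range(t_mat.shape[0]):
        for j in range(t_mat.shape[1]):
            scores[i, j] = -hypergeom_tail(
                int(t_mat[i, j]), int(sizes_a[i]), int(sizes_b[j]), population
            )
    return scores + 0.0  # normalize -0.0


def build_map(
    assoc_rows: Sequence[AssociatedExonSet],
    assoc_cols: Sequence[AssociatedExonSet],
    mode: Literal["within", "between"],
    *,
    n_cassette: int | None = None,
    rows: PairedStatusRows | None = None,
) -> CorrespondenceMap:
    """Assemble a correspondence map over all (row sample, column sample) pairs.

    ``mode='within'`` requires ``n_cassette`` (population = 2 * n_cassette, the
    exon x status universe); ``mode='between'`` requires the paired status
    ``rows`` built from the conserved-pair table in use.
    """
    if mode == "within":
        if n_cassette is None:
            raise ConfigurationError("within mode requires n_cassette")
        universe = sorted(
            {key for aset in list(assoc_rows) + list(assoc_cols) for key in aset.members}
        )
        ra = _assoc_matrix(assoc_rows, universe)
        rb = _assoc_matrix(assoc_cols, universe)
        population = 2 * n_cassette
        t_mat = ra.T.astype(np.int64) @ rb.astype(np.int64)
        sizes_a = np.array([len(a.members) for a in assoc_rows])
        sizes_b = np.array([len(b.members) for b in assoc_cols])
    elif mode == "between":
        if rows is None:
            raise ConfigurationError("between mode requires paired status rows")
        row_keys_f = list(zip(rows.fly_exon, rows.status))
        row_keys_w = list(zip(rows.worm_exon, rows.status))
        rf = np.column_stack([
            [key in a.members for key in row_keys_f] for a in assoc_rows
        ])
        rw = np.column_stack([
            [key in b.members for key in row_keys_w] for b in assoc_cols
        ])
        population = rows.n_rows
        t_mat = rf.T.astype(np.int64) @ rw.astype(np.int64)
        sizes_a = rf.sum(axis=0)
        sizes_b = rw.sum(axis=0)
    else:
        raise ConfigurationError(f"unknown mode '{mode}'")

    scores = _score_matrix(t_mat, sizes_a, sizes_b, population)
    return CorrespondenceMap(
        row_labels=[a.sample_id for a in assoc_rows],
        col_labels=[b.sample_id for b in assoc_cols],
        scores=scores,
    )


def order_samples(cmap: CorrespondenceMap, which: Literal["rows", "cols"]) -> np.ndarray:
    """Display permutation from hierarchical clustering of score vectors.

    Agglomerative average-linkage clustering on Euclidean distances between the
    score rows (or columns); returns the dendrogram leaf order.  Intended for
    tissue/cell axes only — developmental-stage axes keep chronological order
    and should not be passed through this function.
    """
    mat = cmap.scores if which == "rows" else cmap.scores.T
    n = mat.shape[0]
    if n < 2:
        return np.arange(n)
    z = linkage(mat, method="average", metric="euclidean")
    return np.asarray(leaves_list(z))


@dataclass(frozen=True)
class NegativeControlConfig:
    n_shuffles: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_shuffles < 1:
            raise ConfigurationError("n_shuffles must be >= 1")


@dataclass
class ShuffleControlResult:
    """Per-cell mean/sd of mapping scores across shuffles, plus raw per-shuffle data."""

    mean: np.ndarray
    sd: np.ndarray
    scores: np.ndarray  # (n_shuffles, n_fly_samples, n_worm_samples)
    statistics: np.ndarray  # T per shuffle/cell, same shape as scores
    sizes_f: np.ndarray
    sizes_w: np.ndarray
    population: int
    row_labels: list[str]
    col_labels: list[str]


def shuffle_control(
    rows: PairedStatusRows,
    fly_assoc: Sequence[AssociatedExonSet],
    worm_assoc: Sequence[AssociatedExonSet],
    config: NegativeControlConfig,
    *,
    permutations: Iterable[np.ndarray] | None = None,
) -> ShuffleControlResult:
    """Negative control: re-pair worm exons with fly exons at random.

    Each shuffle draws one uniform permutation of the M pairs and reassigns the
    worm exon column accordingly (the same permutation acts on the h and l rows
    of a pair), then recomputes the full between-species map.  ``permutations``
    is a test hook that overrides the random stream.
    """
    m = rows.n_pairs
    row_keys_f = list(zip(rows.fly_exon, rows.status))
    row_keys_w = list(zip(rows.worm_exon, rows.status))
    rf = np.column_stack([[key in a.members for key in row_keys_f] for a in fly_assoc])
    rw = np.column_stack([[key in b.members for key in row_keys_w] for b in worm_assoc])
    sizes_f = rf.sum(axis=0)
    sizes_w = rw.sum(axis=0)
    population = rows.n_rows

    if permutations is None:
        rng = np.random.default_rng(config.seed)
        permutations = (rng.permutation(m) for _ in range(config.n_shuffles))

    all_scores, all_t = [], []
    rf_t = rf.T.astype(np.int64)
    for b, perm in enumerate(permutations):
        if b >= config.n_shuffles:
            break
        perm = np.asarray(perm)
        row_perm = np.concatenate([perm, m + perm])
        t_mat = rf_t @ rw[row_perm].astype(np.int64)
        all_t.append(t_mat)
        all_scores.append(_score_matrix(t_mat, sizes_f, sizes_w, population))

    scores = np.stack(all_scores)
    stats = np.stack(all_t)
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1) if len(all_scores) > 1 else np.zeros_like(mean)
    return ShuffleControlResult(
        mean=mean,
        sd=sd,
        scores=scores,
        statistics=stats,
        sizes_f=sizes_f,
        sizes_w=sizes_w,
        population=population,
        row_labels=[a.sample_id for a in fly_assoc],
        col_labels=[b.sample_id for b in worm_assoc],
    )


def calibration_pvalues(result: ShuffleControlResult, rng: np.random.Generator) -> np.ndarray:
    """Randomized p-values for null-calibration diagnostics.

    The upper-tail p of a discrete statistic is super-uniform under the null
    (P(p <= a) <= a), so a direct uniformity test on raw tail p-values is
    biased for any correct implementation.  The standard randomization device
    p* = P(X > T) + U * P(X = T), U ~ Uniform(0,1), is exactly Uniform(0,1)
    under the null and is what this diagnostic checks.
    """
    b, nf, nw = result.statistics.shape
    out = np.empty((b, nf, nw))
    u = rng.random(size=(b, nf, nw))
    for i in range(nf):
        for j in range(nw):
            a_sz, b_sz = int(result.sizes_f[i]), int(result.sizes_w[j])
            for s in range(b):
                t = int(result.statistics[s, i, j])
                p_ge = 10.0 ** hypergeom_tail(t, a_sz, b_sz, result.population)
                pmf = float(np.exp(hypergeom_log_pmf(t, a_sz, b_sz, result.population)))
                out[s, i, j] = (p_ge - pmf) + u[s, i, j] * pmf
    return np.clip(out, 0.0, 1.0)
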