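"""Ensemble Outcome Agreement (EOA) index for multi-model ensembles.

The EOA quantifies, on [0, 1], the confidence that a multi-model ensemble
(MME) outcome fulfils a hypothesis H of the form ``aggregate > threshold``
(or ``< threshold``), given every possible sub-ensemble that can be formed
from the available members.  It combines three quantities:

* ``N`` — the number of available ensemble members,
* ``ES`` — the minimum ensemble size for which *every* subset of that size
  fulfils H (undefined when even the full ensemble fails),
* ``AF`` — an adjustment factor on [0, 1] separating ensembles with equal
  ``ES`` but different spread of sub-ensemble aggregates about the
  threshold.

The index itself is::

    EOA = (1 - (ES - AF) / (N + 1)) / (1 - 1 / (N + 1))

with EOA = 0 whenever ES is undefined.  AF is built from the per-size
agreement/disagreement distance ratios ``r_i = my_i / mn_i`` for sizes
``i < ES``::

    AF = max(1 - (ES - 1) / sum_i r_i, 0)

where ``my_i`` (``mn_i``) is the mean absolute distance to the threshold of
the fulfilling (non-fulfilling) subset aggregates at size ``i``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Hypothesis",
    "EnsembleSample",
    "SizeDistanceSummary",
    "EOAResult",
    "EOA_CLASSES",
    "aggregate_members",
    "count_subsets",
    "subset_aggregates",
    "find_min_fulfilling_size",
    "distance_summaries",
    "adjustment_factor",
    "eoa_from_components",
    "classify_eoa",
    "compute_eoa",
    "estimate_eoa_sampled",
]

logger = logging.getLogger(__name__)

Direction = Literal["greater", "less"]
AggregateMethod = Literal["median", "mean"]
AFGrouping = Literal["ratio_sum", "mean_ratio"]

#: Ordered EOA class labels, least to most confident.
EOA_CLASSES = ("Low", "Medium", "High", "Very high", "Maximum")

_CLASS_EDGES = (0.25, 0.5, 0.75, 1.0)
_EDGE_SNAP_TOL = 1e-12


@dataclass(frozen=True)
class Hypothesis:
    """A strict threshold condition on the aggregated ensemble outcome.

    Parameters
    ----------
    threshold
        Threshold in outcome units (e.g. % yield change).
    direction
        ``"greater"``: H is fulfilled when value > threshold (strictly).
        ``"less"``: fulfilled when value < threshold (strictly).
    """

    threshold: float
    direction: Direction = "greater"

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("hypothesis threshold must be finite")
        if self.direction not in ("greater", "less"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def fulfils(self, value):
        """Elementwise strict fulfilment test (scalar or array)."""
        if self.direction == "greater":
            return np.asarray(value) > self.threshold
        return np.asarray(value) < self.threshold

    def distance(self, value):
        """Absolute distance of a value (or array) to the threshold."""
        return np.abs(np.asarray(value, dtype=float) - self.threshold)


@dataclass(frozen=True)
class EnsembleSample:
    """Per-member scalar outcomes for one grid cell / option / context.

    Member order carries no meaning: every downstream quantity is invariant
    under permutation of the members.
    """

    member_ids: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("empty ensemble")
        if len(self.member_ids) != len(self.values):
            raise ValueError("member_ids and values must have equal length")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("member_ids must be unique")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("ensemble values must all be finite")

    @classmethod
    def from_values(cls, values: Iterable[float], member_ids=None) -> "EnsembleSample":
        vals = tuple(float(v) for v in values)
        if member_ids is None:
            member_ids = tuple(f"m{i + 1}" for i in range(len(vals)))
        return cls(member_ids=tuple(member_ids), values=vals)

    @property
    def n(self) -> int:
        return len(self.values)

    def sorted_values(self) -> np.ndarray:
        return np.sort(np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class SizeDistanceSummary:
    """Distance-to-threshold summary of all subset aggregates at one size.

    ``mn`` is ``None`` (absent, not zero) when every subset at this size
    fulfils the hypothesis; ``my`` is 0.0 when none does.
    """

    size: int
    my: float
    mn: float | None
    n_fulfilling: int
    n_total: int


@dataclass(frozen=True)
class EOAResult:
    """EOA index with its components for one ensemble.

    ``es`` is ``None`` exactly on the no-fulfilment path (EOA = 0).
    ``exhaustive`` is True when every subset size was fully enumerated,
    False for a sampled estimate.  ``n_aggregates`` records how many subset
    aggregates were evaluated when full enumeration across all sizes was
    requested (otherwise ``None``).
    """

    n_members: int
    es: int | None
    af: float
    eoa: float
    eoa_class: str
    aggregate_method: AggregateMethod
    exhaustive: bool
    n_aggregates: int | None = None
    summaries: tuple = field(default=(), compare=False, repr=False)


def aggregate_members(values: Sequence[float], method: AggregateMethod = "median") -> float:
    """Aggregate member outcomes to a single value.

    The median of an even-length sample is the arithmetic mean of the two
    central order statistics (the standard convention).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ensemble")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ensemble values must all be finite")
    if method == "median":
        return float(np.median(arr))
    if method == "mean":
        return float(np.mean(arr))
    raise ValueError(f"unknown aggregation method {method!r}")


def count_subsets(n: int) -> int:
    """Number of non-empty subsets of an ``n``-member ensemble: 2**n - 1.

    For the 17-member study ensemble this is 131071.
    """
    if n < 1:
        raise ValueError("ensemble must have at least one member")
    return 2**n - 1


def _combo_rows(sorted_values: np.ndarray, size: int) -> np.ndarray:
    """All C(n, size) subsets of a pre-sorted value array, one sorted row each.

    Combinations of indices of an ascending array are emitted in increasing
    index order, so every row is itself sorted: order statistics are direct
    column reads.
    """
    n = sorted_values.size
    n_rows = math.comb(n, size)
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), size)),
        dtype=np.intp,
        count=n_rows * size,
    )
    return sorted_values[idx].reshape(n_rows, size)


def _rows_aggregate(rows: np.ndarray, method: AggregateMethod) -> np.ndarray:
    """Aggregate each (sorted) row of a subset matrix."""
    k = rows.shape[1]
    if method == "median":
        if k % 2:
            return rows[:, k // 2].copy()
        return 0.5 * (rows[:, k // 2 - 1] + rows[:, k // 2])
    if method == "mean":
        return rows.mean(axis=1)
    raise ValueError(f"unknown aggregation method {method!r}")


def subset_aggregates(
    sample: EnsembleSample, size: int, method: AggregateMethod = "median"
) -> np.ndarray:
    """Aggregates of every subset of ``sample`` with exactly ``size`` members.

    Returns an array of length C(N, size).  Enumeration follows lexicographic
    order of the sorted member values, which is deterministic; as a multiset
    the result is invariant to member permutation.
    """
    if not 1 <= size <= sample.n:
        raise ValueError(f"subset size {size} out of range [1, {sample.n}]")
    rows = _combo_rows(sample.sorted_values(), size)
    return _rows_aggregate(rows, method)


def _worst_aggregate(sorted_values: np.ndarray, size: int, h: Hypothesis,
                     method: AggregateMethod) -> float:
    # For median and mean the size-s subset minimizing (maximizing) the
    # aggregate is the s smallest (largest) values: every order statistic of
    # an arbitrary s-subset dominates the corresponding one of the s smallest
    # values elementwise, and both aggregates are monotone in each order
    # statistic.
    if h.direction == "greater":
        return aggregate_members(sorted_values[:size], method)
    return aggregate_members(sorted_values[-size:], method)


def find_min_fulfilling_size(
    sample: EnsembleSample, h: Hypothesis, method: AggregateMethod = "median"
) -> int | None:
    """Smallest size ``s`` such that every size-``s`` subset fulfils H.

    Returns ``None`` when no size qualifies (equivalently, when the
    full-ensemble aggregate itself does not fulfil H).
    """
    svals = sample.sorted_values()
    for s in range(1, sample.n + 1):
        if h.fulfils(_worst_aggregate(svals, s, h, method)):
            return s
    return None


def distance_summaries(
    sample: EnsembleSample,
    h: Hypothesis,
    method: AggregateMethod,
    es: int,
) -> list[SizeDistanceSummary]:
    """Per-size distance summaries for all sizes below ``es`` (full enumeration)."""
    out: list[SizeDistanceSummary] = []
    for size in range(1, es):
        aggs = subset_aggregates(sample, size, method)
        ful = h.fulfils(aggs)
        dist = h.distance(aggs)
        n_ful = int(ful.sum())
        my = float(dist[ful].mean()) if n_ful else 0.0
        mn = float(dist[~ful].mean()) if n_ful < aggs.size else None
        out.append(
            SizeDistanceSummary(
                size=size, my=my, mn=mn, n_fulfilling=n_ful, n_total=int(aggs.size)
            )
        )
    return out


def _ratios(summaries: Sequence[SizeDistanceSummary]) -> list[float]:
    """my/mn ratios with the absent-mn fallback substitution applied.

    A size whose ``mn`` is absent (all subsets fulfil) — or exactly zero
    (dissenting aggregates sit on the threshold; zero disagreement
    magnitude) — borrows the maximum ratio defined at the other sizes.  If
    no size defines a ratio at all, every ratio is treated as unbounded and
    the caller maps that to AF = 1.
    """
    defined: list[float] = []
    for s in summaries:
        if s.mn is not None and s.mn > 0.0:
            defined.append(s.my / s.mn)
        elif s.mn == 0.0:
            logger.warning(
                "size %d: non-fulfilling aggregates all exactly at the "
                "threshold (mn = 0); using the fallback maximum-ratio rule",
                s.size,
            )
    if not defined:
        return []
    fallback = max(defined)
    return [
        (s.my / s.mn) if (s.mn is not None and s.mn > 0.0) else fallback
        for s in summaries
    ]


def adjustment_factor(
    summaries: Sequence[SizeDistanceSummary],
    es: int,
    grouping: AFGrouping = "ratio_sum",
) -> float:
    """Adjustment factor AF on [0, 1] from the per-size distance summaries.

    ``grouping`` selects the algebraic reading of the AF formula:
    ``ratio_sum`` (default) is ``max(1 - (ES - 1) / sum_i r_i, 0)``;
    ``mean_ratio`` is the alternate ``max(1 - mean_i r_i, 0)``, retained for
    auditability.  AF is 0 by definition at ES = 1 (empty sum; required so
    that ES = 1 yields EOA = 1).
    """
    if es < 1:
        raise ValueError("es must be >= 1")
    if es == 1:
        return 0.0
    sizes = [s.size for s in summaries]
    if sizes != list(range(1, es)):
        raise ValueError(f"summaries must cover sizes 1..{es - 1}, got {sizes}")
    ratios = _ratios(summaries)
    if not ratios:
        # No size below ES has non-fulfilling aggregates at nonzero distance:
        # disagreement magnitude is zero everywhere, the ratio is unbounded
        # and AF takes its limiting value 1.
        logger.warning("no defined my/mn ratio below ES=%d; AF set to 1", es)
        return 1.0
    if grouping == "ratio_sum":
        total = sum(ratios)
        if total == 0.0:
            return 0.0
        af = 1.0 - (es - 1) / total
    elif grouping == "mean_ratio":
        af = 1.0 - sum(ratios) / (es - 1)
    else:
        raise ValueError(f"unknown AF grouping {grouping!r}")
    return float(min(max(af, 0.0), 1.0))


def eoa_from_components(es: int | None, af: float, n: int) -> float:
    """EOA from its components; ``es=None`` encodes the no-fulfilment path (EOA = 0).

    With AF = 0 this reproduces the canonical anchor values: ES = 1 gives 1,
    ES = (N/4)+1 gives 0.75, ES = (N/2)+1 gives 0.5, ES = (3N/4)+1 gives 0.25.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"af must lie in [0, 1], got {af}")
    if es is None:
        return 0.0
    if not 1 <= es <= n:
        raise ValueError(f"es must lie in [1, {n}], got {es}")
    if es == 1:
        af = 0.0
    return (1.0 - (es - af) / (n + 1.0)) / (1.0 - 1.0 / (n + 1.0))


def classify_eoa(eoa: float) -> str:
    """Map an EOA value to its class label.

    Half-open intervals [0, 0.25) Low, [0.25, 0.5) Medium, [0.5, 0.75) High,
    [0.75, 1) Very high; exactly 1 is Maximum.  Values within 1e-12 of a
    boundary are snapped to it first so closed-form anchors land in the
    printed class despite floating-point rounding.
    """
    if not 0.0 <= eoa <= 1.0 + _EDGE_SNAP_TOL:
        raise ValueError(f"eoa must lie in [0, 1], got {eoa}")
    for edge in _CLASS_EDGES:
        if abs(eoa - edge) <= _EDGE_SNAP_TOL:
            eoa = edge
            break
    if eoa >= 1.0:
        return "Maximum"
    return EOA_CLASSES[int(eoa / 0.25)]


def _zero_result(sample: EnsembleSample, method: AggregateMethod,
                 exhaustive: bool, n_aggregates: int | None = None) -> EOAResult:
    return EOAResult(
        n_members=sample.n,
        es=None,
        af=0.0,
        eoa=0.0,
        eoa_class="Low",
        aggregate_method=method,
        exhaustive=exhaustive,
        n_aggregates=n_aggregates,
    )


def compute_eoa(
    sample: EnsembleSample,
    h: Hypothesis,
    method: AggregateMethod = "median",
    af_grouping: AFGrouping = "ratio_sum",
    enumerate_all: bool = False,
) -> EOAResult:
    """Exhaustive EOA computation for one ensemble.

    Short-circuits to EOA = 0 when the full-ensemble aggregate does not
    fulfil H (regardless of individual members).  Otherwise ES exists and is
    at most N; the distance summaries for sizes below ES are built by full
    enumeration of every subset at those sizes.

    With ``enumerate_all=True`` every subset of every size is enumerated and
    the total count (2**N - 1) is recorded in ``n_aggregates`` and logged —
    useful for audit, unnecessary for the result.
    """
    full = aggregate_members(sample.values, method)
    n_aggs: int | None = None
    if enumerate_all:
        n_aggs = sum(
            int(subset_aggregates(sample, size, method).size)
            for size in range(1, sample.n + 1)
        )
        logger.info(
            "enumerated %d subset aggregates for N=%d (expected %d)",
            n_aggs, sample.n, count_subsets(sample.n),
        )
    if not h.fulfils(full):
        return _zero_result(sample, method, exhaustive=True, n_aggregates=n_aggs)
    es = find_min_fulfilling_size(sample, h, method)
    assert es is not None and es <= sample.n  # full aggregate fulfils => size N qualifies
    summaries = distance_summaries(sample, h, method, es)
    af = adjustment_factor(summaries, es, grouping=af_grouping)
    eoa = eoa_from_components(es, af, sample.n)
    return EOAResult(
        n_members=sample.n,
        es=es,
        af=af,
        eoa=eoa,
        eoa_class=classify_eoa(eoa),
        aggregate_method=method,
        exhaustive=True,
        n_aggregates=n_aggs,
        summaries=tuple(summaries),
    )


def _sampled_rows(sorted_values: np.ndarray, size: int, n_samples: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Subset rows at one size: exact when C(N, size) is small, sampled otherwise.

    Returns ``(rows, exact)`` with each row sorted ascending.  Sampling is
    uniform without replacement over combinations when they can be cheaply
    enumerated, with replacement otherwise (collisions are then negligible).
    """
    n = sorted_values.size
    total = math.comb(n, size)
    if total <= n_samples:
        return _combo_rows(sorted_values, size), True
    if total <= 20 * n_samples and total <= 500_000:
        rows = _combo_rows(sorted_values, size)
        pick = rng.choice(total, size=n_samples, replace=False)
        return rows[pick], False
    # uniform random i-subsets via random-permutation prefixes
    keys = rng.random((n_samples, n))
    idx = np.argsort(keys, axis=1)[:, :size]
    idx.sort(axis=1)
    return sorted_values[idx], False


def estimate_eoa_sampled(
    sample: EnsembleSample,
    h: Hypothesis,
    method: AggregateMethod = "median",
    n_samples_per_size: int = 2000,
    seed: int | None = None,
    af_grouping: AFGrouping = "ratio_sum",
) -> EOAResult:
    """Monte-Carlo EOA estimate for ensembles too large to enumerate.

    For every size whose combination count is at most ``n_samples_per_size``
    the computation is exact; larger sizes are sampled.  ES is estimated as
    the smallest size with zero sampled violations, and the distance
    summaries are estimated from the sampled aggregates.  Deterministic for
    a fixed ``seed``.  When every size happens to enumerate fully the result
    degenerates to the exhaustive one (and is flagged as such).
    """
    if n_samples_per_size < 1:
        raise ValueError("n_samples_per_size must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for sampled estimation")
    full = aggregate_members(sample.values, method)
    if not h.fulfils(full):
        return _zero_result(sample, method, exhaustive=True)
    rng = np.random.default_rng(seed)
    svals = sample.sorted_values()
    per_size: list[tuple[np.ndarray, bool]] = []
    all_exact = True
    for size in range(1, sample.n + 1):
        rows, exact = _sampled_rows(svals, size, n_samples_per_size, rng)
        aggs = _rows_aggregate(rows, method)
        per_size.append((aggs, exact))
        all_exact = all_exact and exact

    es_hat: int | None = None
    for size, (aggs, _) in enumerate(per_size, start=1):
        if bool(h.fulfils(aggs).all()):
            es_hat = size
            break
    assert es_hat is not None  # size N is the full ensemble, exact and fulfilled

    summaries: list[SizeDistanceSummary] = []
    for size in range(1, es_hat):
        aggs, _ = per_size[size - 1]
        ful = h.fulfils(aggs)
        dist = h.distance(aggs)
        n_ful = int(ful.sum())
        my = float(dist[ful].mean()) if n_ful else 0.0
        mn = float(dist[~ful].mean()) if n_ful < aggs.size else None
        summaries.append(
            SizeDistanceSummary(size=size, my=my, mn=mn,
                                n_fulfilling=n_ful, n_total=int(aggs.size))
        )
    af = adjustment_factor(summaries, es_hat, grouping=af_grouping)
    eoa = eoa_from_components(es_hat, af, sample.n)
    return EOAResult(
        n_members=sample.n,
        es=es_hat,
        af=af,
        eoa=eoa,
        eoa_class=classify_eoa(eoa),
        aggregate_method=method,
        exhaustive=all_exact,
        summaries=tuple(summaries),
    )
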