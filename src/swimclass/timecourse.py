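"""Time-resolved drug-effect analysis ("sobering").

Predictions are binned into fixed windows (default 10 min) of the
recording; within each bin and true class the fractions of predicted
classes are compared with per-bin permutation baselines, non-significant
classes are masked, and the per-bin mean predicted concentration is
examined for monotone trends (Spearman) and abrupt changes (exact
piecewise-constant breakpoint search — recordings yield at most a handful
of bins, so exhaustive search is exact and cheap).
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifier import PredictionRecord
from .evaluate import permutation_threshold
from .trajectory import ValidationError

__all__ = [
    "TimeBin",
    "TimeBinProfile",
    "TrendResult",
    "BreakpointResult",
    "bin_predictions",
    "bin_permutation_nulls",
    "gate_significance",
    "mean_predicted_concentration",
    "sobering_trend",
    "detect_breakpoints",
]


@dataclass
class TimeBin:
    bin_index: int
    fractions: dict  # predicted class -> fraction (sums to 1 over classes)
    n_records: int
    significant: dict = field(default_factory=dict)  # predicted class -> bool


@dataclass
class TimeBinProfile:
    true_class: object
    bin_minutes: float
    classes: list  # predicted classes the fractions are over
    bins: list  # list[TimeBin], ordered by bin_index; empty bins have n_records=0


@dataclass
class TrendResult:
    rho: float
    p_value: float
    series: np.ndarray
    degenerate: bool = False  # constant series: rho reported as 0


@dataclass
class BreakpointResult:
    breakpoint_bins: list  # first index of each new piece, strictly inside
    segment_means: list
    cost: float


def _bin_of(start_time: float, bin_minutes: float) -> int:
    return int(start_time // (60.0 * bin_minutes))


def bin_predictions(records: list[PredictionRecord], true_class, classes,
                    bin_minutes: float = 10.0,
                    recording_minutes: float | None = None) -> TimeBinProfile:
    """Per-bin predicted-class fractions for one true class.

    A record belongs to the bin of its segment's start time.  ``classes``
    fixes the order of the fraction vector.  ``recording_minutes`` sets the
    number of bins (floor(recording/bin)); by default it is inferred from
    the latest record.
    """
    if bin_minutes <= 0:
        raise ValidationError("bin_minutes must be > 0")
    records = [r for r in records if r.true_label == true_class]
    if not records:
        raise ValidationError(f"no records with true class {true_class}")
    classes = list(classes)
    if recording_minutes is None:
        n_bins = max(_bin_of(r.start_time, bin_minutes) for r in records) + 1
    else:
        n_bins = int(recording_minutes // bin_minutes)
    by_bin: dict[int, list] = {i: [] for i in range(n_bins)}
    for r in records:
        b = _bin_of(r.start_time, bin_minutes)
        if b >= n_bins:
            raise ValidationError(
                f"record at {r.start_time}s beyond recording length")
        by_bin[b].append(r)
    bins = []
    for i in range(n_bins):
        recs = by_bin[i]
        if recs:
            counts = {c: 0 for c in classes}
            for r in recs:
                counts[r.predicted_label] += 1
            fractions = {c: counts[c] / len(recs) for c in classes}
        else:
            fractions = {c: float("nan") for c in classes}
        bins.append(TimeBin(bin_index=i, fractions=fractions, n_records=len(recs)))
    return TimeBinProfile(true_class=true_class, bin_minutes=bin_minutes,
                          classes=classes, bins=bins)


def bin_permutation_nulls(all_records: list[PredictionRecord], true_class, classes,
                          bin_minutes: float = 10.0, n_permutations: int = 1000,
                          alpha: float = 0.05, seed: int = 0) -> dict:
    """Per-bin, per-class permutation baselines for ``gate_significance``.

    For each time bin, the null shuffles true labels across *all* records in
    that bin (every true class) and recomputes the fraction of each
    predicted class among records relabeled as ``true_class``.
    """
    n_bins = max(_bin_of(r.start_time, bin_minutes) for r in all_records) + 1
    nulls: dict[int, dict] = {}
    for b in range(n_bins):
        recs = [r for r in all_records if _bin_of(r.start_time, bin_minutes) == b]
        if not any(r.true_label == true_class for r in recs):
            continue
        nulls[b] = {}
        for ci, c in enumerate(classes):
            nulls[b][c] = permutation_threshold(
                recs, statistic="class_fraction", n_permutations=n_permutations,
                alpha=alpha, seed=[seed, b, ci],
                predicted_class=c, true_class=true_class,
            )
    return nulls


def gate_significance(profile: TimeBinProfile, nulls: dict) -> TimeBinProfile:
    """Mark per-bin class fractions exceeding their permutation threshold.

    Fractions are kept (the mask is metadata) so displays can hatch
    non-significant sections rather than hide them.
    """
    for tb in profile.bins:
        if tb.n_records == 0:
            tb.significant = {c: False for c in profile.classes}
            continue
        if tb.bin_index not in nulls:
            raise ValidationError(f"no permutation null for bin {tb.bin_index}")
        bin_nulls = nulls[tb.bin_index]
        tb.significant = {}
        for c in profile.classes:
            if c not in bin_nulls:
                raise ValidationError(f"no permutation null for class {c} "
                                      f"in bin {tb.bin_index}")
            tb.significant[c] = bool(tb.fractions[c] > bin_nulls[c].threshold)
    return profile


def mean_predicted_concentration(records: list[PredictionRecord],
                                 concentration_map: dict | None = None) -> float:
    """Mean of predicted labels mapped to concentrations (control → 0)."""
    if not records:
        raise ValidationError("no records")
    values = []
    for r in records:
        label = r.predicted_label
        if concentration_map is not None:
            if label not in concentration_map:
                raise ValidationError(f"unmapped predicted label {label}")
            values.append(concentration_map[label])
        else:
            values.append(label.concentration)
    return float(np.mean(values))


def concentration_series(records: list[PredictionRecord], true_class,
                         bin_minutes: float = 10.0,
                         recording_minutes: float | None = None) -> np.ndarray:
    """Per-bin mean predicted concentration for one true class."""
    records = [r for r in records if r.true_label == true_class]
    if not records:
        raise ValidationError(f"no records with true class {true_class}")
    if recording_minutes is None:
        n_bins = max(_bin_of(r.start_time, bin_minutes) for r in records) + 1
    else:
        n_bins = int(recording_minutes // bin_minutes)
    series = np.full(n_bins, np.nan)
    for b in range(n_bins):
        recs = [r for r in records if _bin_of(r.start_time, bin_minutes) == b]
        if recs:
            series[b] = mean_predicted_concentration(recs)
    return series


@functools.lru_cache(maxsize=4)
def _perm_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _exact_spearman_p(values: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value of Spearman's rho vs. bin order."""
    n = len(values)
    ranks = stats.rankdata(values)
    time_ranks = np.arange(1, n + 1, dtype=np.float64)
    perms = ranks[_perm_indices(n)]
    # Spearman rho = Pearson correlation of ranks (ties handled by rankdata)
    tr = (time_ranks - time_ranks.mean()) / time_ranks.std()
    pr = perms - perms.mean(axis=1, keepdims=True)
    denom = pr.std(axis=1)
    denom[denom == 0] = np.inf
    rhos = (pr / denom[:, None]) @ tr / n
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def sobering_trend(series) -> TrendResult:
    """Spearman correlation between bin index and the per-bin series.

    A negative rho is the sobering signature: predicted concentration
    declining over the recording.  For nine or fewer bins the p-value is
    exact (full permutation enumeration); longer series fall back to the
    asymptotic approximation.  Constant series are flagged degenerate with
    rho 0.
    """
    series = np.asarray(series, dtype=np.float64)
    valid = ~np.isnan(series)
    values = series[valid]
    idx = np.flatnonzero(valid)
    if len(values) < 3:
        raise ValidationError("need at least 3 non-empty bins")
    if np.allclose(values, values[0]):
        return TrendResult(rho=0.0, p_value=1.0, series=series, degenerate=True)
    rho, p_approx = stats.spearmanr(idx, values)
    if len(values) <= 9:
        p = _exact_spearman_p(values, rho)
    else:
        p = float(p_approx)
    return TrendResult(rho=float(rho), p_value=p, series=series)


def detect_breakpoints(series, max_breakpoints: int = 2,
                       penalty: float = 0.0) -> BreakpointResult:
    """Exact piecewise-constant least-squares segmentation of a short series.

    All placements of up to ``max_breakpoints`` split points are enumerated
    (series have at most a handful of bins, so the exhaustive search is the
    exact optimum, not a heuristic).  Splits are added one at a time and an
    additional split is kept only if it lowers the residual sum of squares
    by more than ``penalty``.  A breakpoint index is the first bin of the
    new piece.
    """
    y = np.asarray(series, dtype=np.float64)
    if np.isnan(y).any():
        y = y[~np.isnan(y)]
    n = len(y)
    if n < 3:
        raise ValidationError("series must have at least 3 points")

    def cost(breaks: tuple) -> tuple[float, list]:
        bounds = [0, *breaks, n]
        sse = 0.0
        means = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            piece = y[a:b]
            mu = piece.mean()
            means.append(float(mu))
            sse += float(((piece - mu) ** 2).sum())
        return sse, means

    best_breaks: tuple = ()
    best_cost, best_means = cost(())
    for k in range(1, max_breakpoints + 1):
        candidates = [
            (cost(bp), bp) for bp in itertools.combinations(range(1, n), k)
        ]
        (c_k, means_k), bp_k = min(candidates, key=lambda t: (t[0][0], t[1]))
        if best_cost - c_k > penalty:
            best_breaks, best_cost, best_means = bp_k, c_k, means_k
        else:
            break
    return BreakpointResult(
        breakpoint_bins=list(best_breaks),
        segment_means=best_means,
        cost=best_cost,
    )
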