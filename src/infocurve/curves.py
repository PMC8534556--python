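"""Characteristic information curves: per-length mean surprisal profiles
aggregated into a fixed-length barycenter via dynamic time warping.

Sentences of different lengths cannot be averaged position-by-position, so the
per-position mean surprisal of each observed sentence length forms one
variable-length sequence, and DTW Barycenter Averaging (DBA) finds the short
template sequence (default 5 points) that these sequences are warped versions
of. DBA is an expectation-maximization loop: align every sequence to the
current barycenter (E-step), then move each barycenter coordinate to the mean
of all points aligned to it (M-step). The objective -- the sum of DTW
distances from the barycenter to the inputs -- never increases.

DTW conventions: local cost is the squared difference, steps are the symmetric
{(1,0), (0,1), (1,1)} pattern with no window constraint, and backtrace ties
prefer diagonal, then vertical, then horizontal moves, so alignments are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionalCurve",
    "Barycenter",
    "CenteredCurve",
    "mean_curve_by_length",
    "dtw_align",
    "dba_barycenter",
    "center_curve",
    "family_barycenter",
]


@dataclass(frozen=True)
class PositionalCurve:
    """Mean surprisal per word position over sentences of one length."""

    sentence_length: int
    values: tuple[float, ...]
    n_sentences: int

    def __post_init__(self) -> None:
        if len(self.values) != self.sentence_length:
            raise ValueError("values must have one entry per word position")
        if self.n_sentences < 1:
            raise ValueError("a curve needs support from at least one sentence")


@dataclass(frozen=True)
class Barycenter:
    """A K-point characteristic curve with its DBA objective.

    ``objective_trajectory`` holds the summed DTW distance evaluated at the
    start of each EM iteration, followed by the final objective; it is
    non-increasing on every run.
    """

    values: tuple[float, ...]
    objective: float
    n_iterations_used: int
    objective_trajectory: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CenteredCurve:
    """A mean-zero K-point curve (surprisal deviations in bits)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(float(np.mean(self.values))) > 1e-9:
            raise ValueError("centered curve must have zero mean")

    def __len__(self) -> int:
        return len(self.values)


def mean_curve_by_length(table: pd.DataFrame) -> dict[int, PositionalCurve]:
    """Average per-word surprisals position-wise within each sentence length.

    ``table`` is a surprisal table with columns ``sentence_index, position,
    surprisal, sentence_length``. Returns one :class:`PositionalCurve` per
    observed length, keyed by length.
    """
    if len(table) == 0:
        raise ValueError("surprisal table is empty")
    curves: dict[int, PositionalCurve] = {}
    for length, grp in table.groupby("sentence_length"):
        length = int(length)
        means = grp.groupby("position")["surprisal"].mean()
        if list(means.index) != list(range(1, length + 1)):
            raise ValueError(f"positions for length {length} are not contiguous 1..{length}")
        n = grp["sentence_index"].nunique()
        curves[length] = PositionalCurve(
            sentence_length=length,
            values=tuple(float(v) for v in means.to_numpy()),
            n_sentences=int(n),
        )
    return curves


def dtw_align(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, list[tuple[int, int]]]:
    """Dynamic time warping with squared-difference cost.

    Returns the minimal total squared difference over all monotone warping
    paths from (0, 0) to (len(a)-1, len(b)-1), together with one optimal path
    as a list of (i, j) index pairs. Ties in the backtrace prefer diagonal,
    then vertical, then horizontal predecessors.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cannot align an empty sequence")
    n, m = x.size, y.size
    cost = (x[:, None] - y[None, :]) ** 2
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(row_prev[j - 1], row_prev[j], row[j - 1])
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horiz = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:
                i, j = i - 1, j - 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return float(acc[n - 1, m - 1]), path


def _resample(values: np.ndarray, k: int) -> np.ndarray:
    """Linear-interpolation resampling of a sequence to length k."""
    if values.size == 1:
        return np.full(k, values[0], dtype=float)
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, k)
    return np.interp(dst, src, values)


def _medoid_index(seqs: list[np.ndarray]) -> int:
    """Index of the input minimizing the summed DTW distance to the others."""
    if len(seqs) == 1:
        return 0
    best_i, best_d = 0, np.inf
    for i, s in enumerate(seqs):
        d = 0.0
        for j, t in enumerate(seqs):
            if i != j:
                d += dtw_align(s, t)[0]
        if d < best_d:
            best_i, best_d = i, d
    return best_i


def dba_barycenter(
    curves: Iterable[Sequence[float]],
    k: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    weights: Sequence[float] | None = None,
) -> Barycenter:
    """DTW Barycenter Averaging: the length-``k`` template closest (in summed
    DTW distance) to a set of variable-length sequences.

    The barycenter is initialized from the medoid input resampled to length
    ``k`` by linear interpolation, then refined by EM until the relative
    objective improvement drops below ``tol`` or ``max_iter`` is reached.
    ``weights`` optionally weight each input sequence in both the M-step and
    the objective (default: unweighted). ``seed`` is accepted for interface
    stability; the procedure is deterministic.
    """
    seqs = [np.asarray(c, dtype=float) for c in curves]
    if not seqs:
        raise ValueError("need at least one input sequence")
    if any(s.size == 0 for s in seqs):
        raise ValueError("input sequences must be nonempty")
    if k < 1:
        raise ValueError("barycenter length k must be >= 1")
    if weights is None:
        w = np.ones(len(seqs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(seqs) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per input sequence")

    center = _resample(seqs[_medoid_index(seqs)], k)
    prev_obj = np.inf
    trajectory: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sums = np.zeros(k)
        counts = np.zeros(k)
        obj = 0.0
        for s, wt in zip(seqs, w):
            dist, path = dtw_align(center, s)
            obj += wt * dist
            for ci, sj in path:
                sums[ci] += wt * s[sj]
                counts[ci] += wt
        trajectory.append(obj)
        # every barycenter coordinate is on the path, so counts > 0
        center = sums / counts
        if np.isfinite(prev_obj):
            denom = prev_obj if prev_obj > 0 else 1.0
            if (prev_obj - obj) / denom < tol:
                break
        prev_obj = obj
    final_obj = sum(
        wt * dtw_align(center, s)[0] for s, wt in zip(seqs, w)
    )
    trajectory.append(float(final_obj))
    return Barycenter(
        values=tuple(float(v) for v in center),
        objective=float(final_obj),
        n_iterations_used=n_iter,
        objective_trajectory=tuple(trajectory),
    )


def center_curve(curve: Sequence[float] | Barycenter) -> CenteredCurve:
    """Subtract the arithmetic mean, giving a zero-mean deviation curve.

    Centering removes the corpus-size-driven overall surprisal level so that
    curve *shapes* can be compared across languages.
    """
    values = np.asarray(
        curve.values if isinstance(curve, Barycenter) else curve, dtype=float
    )
    centered = values - values.mean()
    return CenteredCurve(values=tuple(float(v) for v in centered))


def family_barycenter(
    centered_curves: Iterable[CenteredCurve | Sequence[float]],
    k: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Barycenter:
    """DBA over a set of already-centered per-language curves.

    Used for family-level characteristic curves: each member language's
    barycenter is centered first (so corpus size cancels), then averaged.
    """
    seqs = [
        c.values if isinstance(c, CenteredCurve) else tuple(c) for c in centered_curves
    ]
    return dba_barycenter(seqs, k=k, seed=seed, max_iter=max_iter, tol=tol)
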