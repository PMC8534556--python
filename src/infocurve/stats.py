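"""Cross-language statistics on characteristic curves.

Covers the comparisons made across languages once each language has a
centered characteristic curve: Pearson correlation between the curve-cosine
and shared-typological-feature similarity matrices (with a pair-level t-test
and a Mantel permutation alternative), per-position variance of the curves
with bootstrap confidence intervals, per-feature-category correlations with
Fisher-z intervals, and hierarchical clustering of languages with Newick
export.

The pair-level t-test treats language pairs as independent observations,
which entries of a pairwise similarity matrix are not; it is retained because
it is the conventional report, while the Mantel permutation test (permuting
language labels of one matrix) gives a dependence-robust p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .curves import CenteredCurve
from .typology import SimilarityMatrix, TypologyTable, pairwise_matrices

__all__ = [
    "CorrelationResult",
    "VarianceProfile",
    "ClusterTree",
    "correlate_similarities",
    "position_variance",
    "cluster_languages",
    "feature_type_correlations",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    p: float
    n_pairs: int
    method: str  # "pearson_t" | "mantel_permutation"
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class VarianceProfile:
    """Across-language variance of curve values at each barycenter position."""

    per_position: tuple[float, ...]
    mean_variance: float
    ci_low: float
    ci_high: float
    n_languages: int


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge tree over languages (scipy linkage encoding)."""

    languages: list[str]
    linkage: np.ndarray
    method: str

    def to_newick(self) -> str:
        """Serialize as a Newick string with merge heights as branch lengths."""
        n = len(self.languages)
        heights = {i: 0.0 for i in range(n)}

        def node_str(idx: int) -> str:
            if idx < n:
                return self.languages[idx]
            a, b, h, _ = self.linkage[idx - n]
            a, b = int(a), int(b)
            heights[idx] = h
            left = f"{node_str(a)}:{h - heights[a]:.10g}"
            right = f"{node_str(b)}:{h - heights[b]:.10g}"
            return f"({left},{right})"

        root = n + len(self.linkage) - 1
        return node_str(root) + ";"


def _joint_upper(a: SimilarityMatrix, b: SimilarityMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if a.languages != b.languages:
        raise ValueError("matrices must cover the same languages in the same order")
    n = len(a.languages)
    iu, ju = np.triu_indices(n, k=1)
    keep = a.defined[iu, ju] & b.defined[iu, ju]
    return a.values[iu[keep], ju[keep]], b.values[iu[keep], ju[keep]], iu[keep], ju[keep]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined: zero variance in one input")
    return float(xc @ yc / denom)


def correlate_similarities(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    method: str = "pearson_t",
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> CorrelationResult:
    """Pearson correlation between two similarity matrices over their jointly
    defined upper-triangle pairs.

    ``method="pearson_t"`` reports the conventional pair-level t-test,
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
    ``method="mantel_permutation"`` permutes the language labels of ``b``
    (``n_permutations`` times, seeded) and reports the permutation p-value;
    the t field then holds the observed r's z-score among permutations.
    """
    x, y, _, _ = _joint_upper(a, b)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 jointly defined pairs, got {n}")
    r = _pearson(x, y)
    if method == "pearson_t":
        if abs(r) >= 1.0:
            t = np.inf if r > 0 else -np.inf
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            sf = sps.t.sf(abs(t), df=n - 2)
            if alternative == "two-sided":
                p = 2.0 * sf
            elif alternative == "greater":
                p = sps.t.sf(t, df=n - 2)
            else:
                p = sps.t.cdf(t, df=n - 2)
        return CorrelationResult(r=r, t=float(t), p=float(min(p, 1.0)), n_pairs=n, method=method)
    if method != "mantel_permutation":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    nl = len(a.languages)
    iu, ju = np.triu_indices(nl, k=1)
    keep = a.defined[iu, ju] & b.defined[iu, ju]
    iu, ju = iu[keep], ju[keep]
    xa = a.values[iu, ju]
    perm_rs = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = rng.permutation(nl)
        perm_rs[k] = _pearson(xa, b.values[perm[iu], perm[ju]])
    if alternative == "two-sided":
        exceed = np.abs(perm_rs) >= abs(r) - 1e-12
    elif alternative == "greater":
        exceed = perm_rs >= r - 1e-12
    else:
        exceed = perm_rs <= r + 1e-12
    p = (1.0 + int(exceed.sum())) / (n_permutations + 1.0)
    spread = perm_rs.std(ddof=1)
    z = (r - perm_rs.mean()) / spread if spread > 0 else np.inf
    return CorrelationResult(r=r, t=float(z), p=float(p), n_pairs=n, method=method)


def position_variance(
    centered_curves: dict[str, CenteredCurve] | Sequence[CenteredCurve],
    n_boot: int = 1000,
    seed: int = 0,
) -> VarianceProfile:
    """Across-language sample variance at each barycenter position, with a
    percentile bootstrap CI (resampling languages) for the positional mean.
    """
    if isinstance(centered_curves, dict):
        curves = [centered_curves[k] for k in sorted(centered_curves)]
    else:
        curves = list(centered_curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 languages to compute variance")
    mat = np.array([c.values for c in curves], dtype=float)  # (n_lang, K)
    per_pos = mat.var(axis=0, ddof=1)
    mean_var = float(per_pos.mean())
    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = mat[idx].var(axis=0, ddof=1).mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return VarianceProfile(
        per_position=tuple(float(v) for v in per_pos),
        mean_variance=mean_var,
        ci_low=float(lo),
        ci_high=float(hi),
        n_languages=n,
    )


def cluster_languages(curve_sim: SimilarityMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of languages on distance = 1 - cosine similarity."""
    if not curve_sim.defined.all():
        raise ValueError("clustering requires a fully defined similarity matrix")
    dist = 1.0 - curve_sim.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices(len(curve_sim.languages), k=1)]
    z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(languages=list(curve_sim.languages), linkage=z, method=linkage)


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    half = sps.norm.ppf(0.5 + level / 2.0) * se
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def feature_type_correlations(
    curve_sim: SimilarityMatrix,
    table: TypologyTable,
    centered_curves: dict[str, CenteredCurve],
    method: str = "pearson_t",
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation between curve similarity and shared-feature similarity,
    recomputed per feature category.

    Returns a tidy frame with columns ``category, r, t, p, ci_low, ci_high,
    n_pairs``. Categories with no features, fewer than 3 defined pairs, or no
    variance in either similarity are omitted with a warning.
    """
    rows = []
    for cat in sorted({table.feature_category.get(f, "other") for f in table.features}):
        sub = table.restrict_to_category(cat)
        if not sub.features:
            continue
        usable = {l: c for l, c in centered_curves.items() if l in sub.values.index}
        if len(usable) < 3:
            warnings.warn(f"category {cat!r}: fewer than 3 languages with data; omitted")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm, sm = pairwise_matrices(usable, sub)
        try:
            res = correlate_similarities(cm, sm, method=method, seed=seed)
        except ValueError as err:
            warnings.warn(f"category {cat!r} omitted: {err}")
            continue
        lo, hi = _fisher_ci(res.r, res.n_pairs)
        rows.append(
            {
                "category": cat,
                "r": res.r,
                "t": res.t,
                "p": res.p,
                "ci_low": lo,
                "ci_high": hi,
                "n_pairs": res.n_pairs,
            }
        )
    return pd.DataFrame(rows, columns=["category", "r", "t", "p", "ci_low", "ci_high", "n_pairs"])
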