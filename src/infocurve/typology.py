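"""Pairwise curve similarity and categorical typological similarity.

Typological feature tables (languages x categorical features, with extensive
missingness, in the style of WALS exports) are compared by the proportion of
jointly observed features with exactly matching values. Curve similarity is
the cosine between centered characteristic curves. Missing feature values can
optionally be imputed with a regularized iterative multiple-correspondence
procedure: dummy-code the categories, initialize missing cells at observed
column means, and alternate a low-rank SVD reconstruction with re-imputation
of the missing cells until convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import CenteredCurve

FEATURE_CATEGORIES = (
    "phonology",
    "nominal categories",
    "verbal categories",
    "nominal syntax",
    "word order",
    "simple clauses",
    "other",
)

__all__ = [
    "FEATURE_CATEGORIES",
    "TypologyTable",
    "SimilarityMatrix",
    "curve_cosine",
    "shared_feature_proportion",
    "impute_features",
    "curve_similarity_matrix",
    "pairwise_matrices",
]


@dataclass
class TypologyTable:
    """Languages x categorical features with missing entries.

    ``values`` is a wide DataFrame (index = language ids, columns = feature
    ids) of category labels, with NaN for missing cells. ``feature_category``
    maps each feature id to one of :data:`FEATURE_CATEGORIES`.
    """

    values: pd.DataFrame
    feature_category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for feat, cat in self.feature_category.items():
            if cat not in FEATURE_CATEGORIES:
                raise ValueError(f"unknown feature category {cat!r} for feature {feat!r}")
        observed_per_lang = self.values.notna().sum(axis=1)
        if len(self.values) and (observed_per_lang == 0).any():
            empty = list(self.values.index[observed_per_lang == 0])
            raise ValueError(f"languages with no observed features: {empty}")

    @property
    def languages(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def features_in_category(self, category: str) -> list[str]:
        return [f for f in self.features if self.feature_category.get(f, "other") == category]

    def restrict_to_category(self, category: str) -> "TypologyTable":
        feats = self.features_in_category(category)
        sub = self.values[feats]
        keep = sub.notna().sum(axis=1) > 0
        return TypologyTable(
            values=sub.loc[keep],
            feature_category={f: category for f in feats},
        )

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "TypologyTable":
        """Read the long-format CSV (language_id, feature_id, feature_category,
        value); an empty value field means missing."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df["value"] = df["value"].replace("", np.nan)
        wide = df.pivot(index="language_id", columns="feature_id", values="value")
        cats = dict(
            df.drop_duplicates("feature_id")[["feature_id", "feature_category"]].to_numpy()
        )
        return cls(values=wide, feature_category=cats)

    def to_long_csv(self, path: str | Path) -> None:
        long = self.values.reset_index().melt(
            id_vars=self.values.index.name or "index",
            var_name="feature_id",
            value_name="value",
        )
        long.columns = ["language_id", "feature_id", "value"]
        long["feature_category"] = long["feature_id"].map(
            lambda f: self.feature_category.get(f, "other")
        )
        long = long[["language_id", "feature_id", "feature_category", "value"]]
        long["value"] = long["value"].fillna("")
        long.to_csv(path, index=False)


@dataclass
class SimilarityMatrix:
    """A symmetric languages x languages similarity matrix with a defined-pair mask."""

    languages: list[str]
    values: np.ndarray
    kind: str  # "curve_cosine" | "shared_features"
    defined: np.ndarray = None  # bool mask; True where the similarity exists

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.languages)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match language list")
        if self.defined is None:
            self.defined = ~np.isnan(self.values)
        if not np.allclose(
            np.where(self.defined, self.values, 0.0),
            np.where(self.defined, self.values, 0.0).T,
            equal_nan=True,
        ):
            raise ValueError("similarity matrix must be symmetric")

    def upper_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices (i, j), i < j, of defined off-diagonal pairs."""
        n = len(self.languages)
        iu, ju = np.triu_indices(n, k=1)
        keep = self.defined[iu, ju]
        return iu[keep], ju[keep]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.languages, columns=self.languages).to_csv(path)


def curve_cosine(a: CenteredCurve | Sequence[float], b: CenteredCurve | Sequence[float]) -> float:
    """Cosine similarity between two centered curves, in [-1, 1]."""
    x = np.asarray(a.values if isinstance(a, CenteredCurve) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, CenteredCurve) else b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("curves must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero curve")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def shared_feature_proportion(
    table: TypologyTable, lang_a: str, lang_b: str
) -> float | None:
    """Proportion of jointly observed features on which two languages match
    exactly; ``None`` when the languages share no observed features."""
    for lang in (lang_a, lang_b):
        if lang not in table.values.index:
            raise KeyError(f"unknown language id {lang!r}")
    ra = table.values.loc[lang_a]
    rb = table.values.loc[lang_b]
    joint = ra.notna() & rb.notna()
    n_joint = int(joint.sum())
    if n_joint == 0:
        return None
    matches = int((ra[joint] == rb[joint]).sum())
    return matches / n_joint


def _dummy_code(
    values: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, list[str]]]]:
    """One-hot encode observed categories; missing cells become NaN rows.

    Returns the (n_lang, n_dummy) matrix, a parallel bool matrix marking
    dummy columns that belong to a missing (language, feature) cell, and the
    per-feature (feature_id, category labels) layout.
    """
    blocks: list[np.ndarray] = []
    miss_blocks: list[np.ndarray] = []
    layout: list[tuple[str, list[str]]] = []
    for feat in values.columns:
        col = values[feat]
        cats = sorted(col.dropna().unique())
        block = np.zeros((len(col), len(cats)))
        for k, cat in enumerate(cats):
            block[:, k] = (col == cat).to_numpy(dtype=float)
        missing = col.isna().to_numpy()
        block[missing, :] = np.nan
        blocks.append(block)
        miss_blocks.append(np.repeat(missing[:, None], len(cats), axis=1))
        layout.append((feat, cats))
    return np.hstack(blocks), np.hstack(miss_blocks), layout


def impute_features(
    table: TypologyTable,
    n_components: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> TypologyTable:
    """Single imputation of missing categorical cells by iterative low-rank
    reconstruction of the dummy-coded table.

    The dummy-coded matrix is initialized with observed column means in the
    missing cells, then repeatedly centered, approximated by its rank-
    ``n_components`` SVD, and re-imputed in the missing cells only, until the
    largest change in an imputed cell falls below ``tol``. Each missing
    categorical cell is finally assigned the category with the highest
    reconstructed score. Observed cells are never altered. Features observed
    in fewer than two languages are dropped with a warning.

    ``seed`` is accepted for interface stability (and future multiple-
    imputation variants); the procedure itself is deterministic.
    """
    values = table.values.copy()
    observed_counts = values.notna().sum(axis=0)
    thin = [f for f in values.columns if observed_counts[f] < 2]
    if thin:
        warnings.warn(
            f"dropping features observed in fewer than 2 languages: {thin}",
            stacklevel=2,
        )
        values = values.drop(columns=thin)
    if values.isna().sum().sum() == 0:
        return TypologyTable(
            values=values,
            feature_category={f: table.feature_category.get(f, "other") for f in values.columns},
        )

    x, missing, layout = _dummy_code(values)
    col_means = np.nanmean(x, axis=0)
    x_filled = np.where(missing, col_means[None, :], x)

    rank = min(n_components, min(x_filled.shape) - 1)
    rank = max(rank, 1)
    for _ in range(max_iter):
        mu = x_filled.mean(axis=0)
        centered = x_filled - mu
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank] + mu
        new = np.where(missing, recon, x)
        delta = np.max(np.abs(new - x_filled)) if missing.any() else 0.0
        x_filled = new
        if delta < tol:
            break

    completed = values.copy()
    col = 0
    for feat, cats in layout:
        width = len(cats)
        scores = x_filled[:, col : col + width]
        col += width
        missing_rows = values[feat].isna().to_numpy()
        if missing_rows.any():
            best = np.argmax(scores[missing_rows], axis=1)
            completed.loc[missing_rows, feat] = [cats[k] for k in best]
    return TypologyTable(
        values=completed,
        feature_category={f: table.feature_category.get(f, "other") for f in completed.columns},
    )


def curve_similarity_matrix(centered_curves: dict[str, CenteredCurve]) -> SimilarityMatrix:
    """All-pairs curve-cosine matrix with no typology masking (all pairs defined)."""
    langs = sorted(centered_curves)
    n = len(langs)
    cos = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            cos[i, j] = cos[j, i] = curve_cosine(
                centered_curves[langs[i]], centered_curves[langs[j]]
            )
    return SimilarityMatrix(
        languages=langs, values=cos, kind="curve_cosine", defined=np.ones((n, n), dtype=bool)
    )


def pairwise_matrices(
    centered_curves: dict[str, CenteredCurve],
    table: TypologyTable,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """All-pairs curve-cosine and shared-feature similarity matrices.

    Languages present in ``centered_curves`` but absent from the typology
    table are kept in the matrices with their typology pairs masked (and a
    warning). Pairs with no jointly observed features are masked in *both*
    matrices so that downstream correlations use the same pair set.
    """
    langs = sorted(centered_curves)
    n = len(langs)
    missing_langs = [l for l in langs if l not in table.values.index]
    if missing_langs:
        warnings.warn(
            f"languages missing from typology table, pairs masked: {missing_langs}",
            stacklevel=2,
        )
    cos = np.eye(n)
    shared = np.full((n, n), np.nan)
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(defined, True)
    np.fill_diagonal(shared, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            cos[i, j] = cos[j, i] = curve_cosine(
                centered_curves[langs[i]], centered_curves[langs[j]]
            )
            if langs[i] in table.values.index and langs[j] in table.values.index:
                prop = shared_feature_proportion(table, langs[i], langs[j])
            else:
                prop = None
            if prop is not None:
                shared[i, j] = shared[j, i] = prop
                defined[i, j] = defined[j, i] = True
    curve_m = SimilarityMatrix(languages=langs, values=cos, kind="curve_cosine", defined=defined)
    shared_m = SimilarityMatrix(
        languages=langs, values=shared, kind="shared_features", defined=defined
    )
    return curve_m, shared_m
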