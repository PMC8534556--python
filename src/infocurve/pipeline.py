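"""End-to-end orchestration: per-language surprisal curves and the
cross-linguistic comparison stage, with reproducible file outputs.

The per-language stage (:func:`run_language`) reads a flattened corpus,
applies the register-appropriate length filter, computes cross-validated
surprisal under each configured n-gram order, averages per-length curves, and
fits the characteristic barycenter. The cross-linguistic stage
(:func:`run_crosslinguistic`) centers the per-language barycenters and runs
the similarity, variance, clustering, and per-feature-category analyses
against a typology table.

Outputs are plain CSV/JSON/Newick files in an append-only run directory; a
manifest records the configuration hash so identical re-runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import corpus as corpus_io
from . import curves as curve_mod
from . import ngrams, stats, typology

logger = logging.getLogger("infocurve")

__all__ = ["RunConfig", "run_language", "run_crosslinguistic", "characteristic_curve"]


def characteristic_curve(
    corpus: "corpus_io.TokenizedCorpus",
    order: int = 1,
    n_folds: int = 10,
    k: int = 5,
    seed: int = 0,
) -> "curve_mod.Barycenter":
    """In-memory convenience: cross-validated surprisal -> per-length mean
    curves -> K-point DBA barycenter for one corpus."""
    folds = corpus_io.split_folds(corpus, n_folds, seed=seed)
    table = ngrams.crossval_surprisals(corpus, order, folds)
    curves = curve_mod.mean_curve_by_length(table)
    return curve_mod.dba_barycenter(
        [c.values for _, c in sorted(curves.items())], k=k, seed=seed
    )

REGISTER_FILTERS = {
    "written": corpus_io.LengthFilter(5, 45),
    "spoken": corpus_io.LengthFilter(5, 15),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    corpus_paths: dict[str, str]
    output_dir: str
    register: str = "written"
    min_len: int | None = None  # override the register default
    max_len: int | None = None
    n_folds: int = 10
    orders: tuple[int, ...] = (1, 3)
    barycenter_k: int = 5
    seed: int = 0
    shuffle_folds: bool = False

    def length_filter(self) -> corpus_io.LengthFilter:
        base = REGISTER_FILTERS[self.register]
        return corpus_io.LengthFilter(
            self.min_len if self.min_len is not None else base.min_len,
            self.max_len if self.max_len is not None else base.max_len,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "corpus_paths": dict(sorted(self.corpus_paths.items())),
                "register": self.register,
                "min_len": self.min_len,
                "max_len": self.max_len,
                "n_folds": self.n_folds,
                "orders": list(self.orders),
                "barycenter_k": self.barycenter_k,
                "seed": self.seed,
                "shuffle_folds": self.shuffle_folds,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _curves_frame(curves: dict[int, curve_mod.PositionalCurve]) -> pd.DataFrame:
    rows = [
        {
            "sentence_length": length,
            "position": p + 1,
            "value": v,
            "n_support": c.n_sentences,
        }
        for length, c in sorted(curves.items())
        for p, v in enumerate(c.values)
    ]
    return pd.DataFrame(rows)


def run_language(config: RunConfig, language_id: str) -> dict:
    """Run the per-language stages, writing artifacts under the output directory.

    Returns the manifest dictionary (also written as
    ``manifest_<language>.json``), which records the config hash, corpus
    statistics, and the fitted barycenter for every configured order.
    """
    if language_id not in config.corpus_paths:
        raise KeyError(f"no corpus path registered for language {language_id!r}")
    t0 = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    raw = corpus_io.load_corpus(
        config.corpus_paths[language_id], language_id, register=config.register
    )
    filtered, retained = corpus_io.filter_by_length(raw, config.length_filter())
    if len(filtered) < config.n_folds:
        raise ValueError(
            f"language {language_id!r}: {len(filtered)} sentences after filtering, "
            f"fewer than {config.n_folds} folds"
        )
    folds = corpus_io.split_folds(
        filtered, config.n_folds, seed=config.seed, shuffle=config.shuffle_folds
    )

    manifest: dict = {
        "language_id": language_id,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sentences_raw": len(raw),
        "n_sentences": len(filtered),
        "retained_fraction": retained,
        "orders": {},
    }
    for order in config.orders:
        table = ngrams.crossval_surprisals(filtered, order, folds)
        table.to_csv(out / f"{language_id}_order{order}_surprisal.csv", index=False)
        curves = curve_mod.mean_curve_by_length(table)
        _curves_frame(curves).to_csv(
            out / f"{language_id}_order{order}_curves.csv", index=False
        )
        bary = curve_mod.dba_barycenter(
            [c.values for _, c in sorted(curves.items())],
            k=config.barycenter_k,
            seed=config.seed,
        )
        bary_payload = {
            "values": list(bary.values),
            "objective": bary.objective,
            "n_iterations_used": bary.n_iterations_used,
        }
        (out / f"{language_id}_order{order}_barycenter.json").write_text(
            json.dumps(bary_payload, indent=2)
        )
        manifest["orders"][str(order)] = bary_payload
    (out / f"manifest_{language_id}.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "run_language %s: %d sentences, orders %s, %.2fs",
        language_id,
        len(filtered),
        list(config.orders),
        time.perf_counter() - t0,
    )
    return manifest


def _load_barycenter(out: Path, language_id: str, order: int) -> curve_mod.Barycenter:
    payload = json.loads((out / f"{language_id}_order{order}_barycenter.json").read_text())
    return curve_mod.Barycenter(
        values=tuple(payload["values"]),
        objective=payload["objective"],
        n_iterations_used=payload["n_iterations_used"],
    )


def run_crosslinguistic(config: RunConfig, typology_path: str | Path) -> dict:
    """Run the cross-language analyses from completed per-language artifacts.

    Requires ``run_language`` outputs for at least two languages in the output
    directory. Emits, per order: similarity matrices (CSV), correlation
    results including the per-feature-category table (CSV), the variance
    profile (CSV), and the cluster tree (Newick).
    """
    out = Path(config.output_dir)
    langs = sorted(config.corpus_paths)
    done = [l for l in langs if (out / f"manifest_{l}.json").exists()]
    if len(done) < 2:
        raise ValueError(
            f"need completed run_language artifacts for >= 2 languages, found {len(done)}"
        )
    table = typology.TypologyTable.from_long_csv(typology_path)

    results: dict = {"orders": {}}
    for order in config.orders:
        centered = {
            l: curve_mod.center_curve(_load_barycenter(out, l, order)) for l in done
        }
        curve_m, shared_m = typology.pairwise_matrices(centered, table)
        curve_m.to_csv(out / f"similarity_curve_order{order}.csv")
        shared_m.to_csv(out / f"similarity_features_order{order}.csv")

        pearson = stats.correlate_similarities(curve_m, shared_m, method="pearson_t")
        mantel = stats.correlate_similarities(
            curve_m, shared_m, method="mantel_permutation", seed=config.seed
        )
        var_prof = stats.position_variance(centered, seed=config.seed)
        full_curve_m = typology.curve_similarity_matrix(centered)
        tree = stats.cluster_languages(full_curve_m)
        (out / f"dendrogram_order{order}.nwk").write_text(tree.to_newick() + "\n")
        per_cat = stats.feature_type_correlations(curve_m, table, centered, seed=config.seed)
        per_cat.to_csv(out / f"feature_type_correlations_order{order}.csv", index=False)

        corr_rows = [
            {
                "method": res.method,
                "r": res.r,
                "t": res.t,
                "p": res.p,
                "n_pairs": res.n_pairs,
            }
            for res in (pearson, mantel)
        ]
        pd.DataFrame(corr_rows).to_csv(out / f"correlations_order{order}.csv", index=False)
        var_frame = pd.DataFrame(
            {
                "position": list(range(1, len(var_prof.per_position) + 1)) + ["mean"],
                "variance": list(var_prof.per_position) + [var_prof.mean_variance],
                "ci_low": [np.nan] * len(var_prof.per_position) + [var_prof.ci_low],
                "ci_high": [np.nan] * len(var_prof.per_position) + [var_prof.ci_high],
            }
        )
        var_frame.to_csv(out / f"variance_order{order}.csv", index=False)

        results["orders"][order] = {
            "pearson": pearson,
            "mantel": mantel,
            "variance": var_prof,
            "tree": tree,
            "per_category": per_cat,
        }
    return results
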