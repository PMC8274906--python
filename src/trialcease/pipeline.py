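"""End-to-end experiment harness.

The experiment follows the leakage-safe protocol: the cohort is split into
stratified cross-validation folds, and *every* fitted object — the drug
feature spec, the TF-IDF keyword vocabulary, the paragraph-vector embedding
model and the ReliefF ranking — is fitted on the training portion of each
fold only, then applied to both portions.  On top of the per-fold feature
matrices, the grid (feature-subset size x undersampling ratio x classifier
family) is evaluated and the classifiers are compared across subset sizes
with the Friedman/Nemenyi machinery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensembles, evaluation, relieff, structured_features, text_features
from .ctgov_io import CESSATION, TrialRecord, filter_cohort, read_corpus
from .structured_features import (
    STAT_FEATURE_NAMES,
    DrugClassMap,
    default_drug_class_map,
    drug_matrix,
    fit_drug_feature_spec,
    statistics_matrix,
)
from .synthetic_corpus import GeneratorConfig, generate_corpus
from .text_features import (
    fit_keyword_spec,
    infer_embedding_matrix,
    keyword_tokens,
    tfidf_matrix,
    tokenize,
    train_doc_embedding,
)

logger = logging.getLogger(__name__)

FAMILY_TAGS = ("statistics", "top_drug", "drug_class", "keyword", "embedding")


@dataclass
class FeatureModel:
    """Per-fold fitted feature extractors and the resulting column layout."""

    drug_spec: structured_features.DrugFeatureSpec
    class_map: DrugClassMap
    keyword_spec: text_features.KeywordSpec
    embed_model: text_features.ParagraphVectorModel
    columns: list[str]
    families: dict[str, str]

    def spec_hash(self) -> str:
        payload = json.dumps(
            {
                "drugs": self.drug_spec.top_drugs,
                "classes": self.drug_spec.top_classes,
                "vocab": self.keyword_spec.vocabulary,
                "emb": self.embed_model.sidecar(),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def fit_feature_model(
    training: list[TrialRecord],
    class_map: DrugClassMap | None = None,
    top_k_keywords: int = 500,
    embed_dim: int = 100,
    embed_epochs: int = 20,
    seed: int = 0,
) -> FeatureModel:
    """Fit drug spec, keyword vocabulary and embedding on training records only."""
    class_map = class_map or default_drug_class_map()
    drug_spec = fit_drug_feature_spec(training, class_map)
    keyword_spec = fit_keyword_spec(
        [keyword_tokens(r) for r in training], top_k=top_k_keywords
    )
    embed_model = train_doc_embedding(
        [tokenize(r.detailed_description) for r in training],
        d=embed_dim,
        seed=seed,
        epochs=embed_epochs,
    )
    drug_names = drug_spec.feature_names()
    kw_names = [f"kw::{t}" for t in keyword_spec.vocabulary]
    emb_names = [f"emb::{i}" for i in range(embed_dim)]
    columns = list(STAT_FEATURE_NAMES) + drug_names + kw_names + emb_names
    families = {name: "statistics" for name in STAT_FEATURE_NAMES}
    families.update(
        {n: ("top_drug" if n.startswith("drug::") else "drug_class") for n in drug_names}
    )
    families.update({n: "keyword" for n in kw_names})
    families.update({n: "embedding" for n in emb_names})
    return FeatureModel(
        drug_spec=drug_spec,
        class_map=class_map,
        keyword_spec=keyword_spec,
        embed_model=embed_model,
        columns=columns,
        families=families,
    )


def transform_features(model: FeatureModel, records: list[TrialRecord]) -> pd.DataFrame:
    """Feature matrix for any records under an already-fitted model."""
    stats_block = statistics_matrix(records)
    drug_block = drug_matrix(records, model.drug_spec, model.class_map)
    kw_block = tfidf_matrix([keyword_tokens(r) for r in records], model.keyword_spec)
    emb_block = infer_embedding_matrix(
        model.embed_model, [tokenize(r.detailed_description) for r in records]
    )
    matrix = np.hstack([stats_block, drug_block, kw_block, emb_block])
    return pd.DataFrame(matrix, columns=model.columns, index=[r.trial_id for r in records])


def report_feature_family_mix(
    ranked: relieff.RankedFeatures,
    sizes,
    families: dict[str, str],
) -> pd.DataFrame:
    """Percentage of each feature family within every top-ranked prefix."""
    rows = {}
    for size in sizes:
        prefix = ranked.subsets[size]
        if not prefix:
            raise ValueError(f"empty feature prefix for size {size!r}")
        tags = pd.Series([families[name] for name in prefix])
        pct = tags.value_counts(normalize=True) * 100.0
        rows[size] = {tag: float(pct.get(tag, 0.0)) for tag in FAMILY_TAGS}
    table = pd.DataFrame(rows).T
    table.index.name = "subset_size"
    return table


@dataclass
class ExperimentConfig:
    """One experiment grid: input source, folds, subsets, ratios, families."""

    generator: GeneratorConfig | None = None
    xml_dir: str | Path | None = None
    class_map_path: str | Path | None = None
    families: tuple = ensembles.FAMILIES
    subset_sizes: tuple = relieff.SELECTION_SIZES
    ratios: tuple = ensembles.DEFAULT_RATIOS
    n_repeats: int = 10
    k_folds: int = 5
    seed: int = 0
    relieff_config: relieff.RelieffConfig | None = None
    top_k_keywords: int = 500
    embed_dim: int = 100
    embed_epochs: int = 20
    nemenyi_ratio: float = 1.0
    model_params: dict = dataclass_field(default_factory=dict)
    out_dir: str | Path | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.generator is None and self.xml_dir is None:
            raise ValueError("ExperimentConfig needs a generator or an xml_dir")
        if not self.families or not self.subset_sizes:
            raise ValueError("at least one family and one subset size required")


def _load_cohort(config: ExperimentConfig) -> tuple[list[TrialRecord], np.ndarray]:
    if config.xml_dir is not None:
        records = read_corpus(config.xml_dir)
        cohort, _ = filter_cohort(records)
        recs = [r for r, _ in cohort]
        y = np.array([int(label == CESSATION) for _, label in cohort])
    else:
        recs, labels = generate_corpus(config.generator)
        y = np.array([int(label == CESSATION) for label in labels])
    return recs, y


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame  # one row per (family, size, ratio, fold)
    summary: pd.DataFrame  # fold-averaged with SDs
    friedman: dict  # per metric: ranks, chi2, p, CD, bars
    family_mix: pd.DataFrame
    manifest: dict


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full grid; see the module docstring for the protocol."""
    records, y = _load_cohort(config)
    class_map = (
        structured_features.load_drug_class_map(config.class_map_path)
        if config.class_map_path
        else default_drug_class_map()
    )
    rl_config = config.relieff_config or relieff.RelieffConfig(seed=config.seed)
    split = evaluation.make_folds(y, k=config.k_folds, seed=config.seed)

    rows = []
    spec_hashes = []
    mix_tables = []
    for fold_no, (train_idx, test_idx) in enumerate(split.folds()):
        train_records = [records[i] for i in train_idx]
        model = fit_feature_model(
            train_records,
            class_map=class_map,
            top_k_keywords=config.top_k_keywords,
            embed_dim=config.embed_dim,
            embed_epochs=config.embed_epochs,
            seed=config.seed + fold_no,
        )
        spec_hashes.append(model.spec_hash())
        X_all = transform_features(model, records).to_numpy()
        X_train, y_train = X_all[train_idx], y[train_idx]
        X_test, y_test = X_all[test_idx], y[test_idx]

        # k_neighbors is capped by (smallest training-class size - 1) so the
        # default works on small folds; the core routine stays strict.
        smallest = int(min(np.bincount(y_train)))
        fold_rl = rl_config
        if rl_config.k_neighbors > smallest - 1:
            logger.warning(
                "capping ReliefF k_neighbors %d -> %d (smallest class has %d members)",
                rl_config.k_neighbors, smallest - 1, smallest,
            )
            fold_rl = relieff.RelieffConfig(
                k_neighbors=smallest - 1,
                iteration_policy=rl_config.iteration_policy,
                n_iterations=rl_config.n_iterations,
                normalizer_mode=rl_config.normalizer_mode,
                seed=rl_config.seed,
            )
        fw = relieff.relieff_weights(
            X_train, y_train, config=fold_rl, feature_names=model.columns
        )
        ranked = relieff.rank_and_select(fw, sizes=tuple(config.subset_sizes))
        mix_tables.append(
            report_feature_family_mix(ranked, config.subset_sizes, model.families)
        )
        col_index = {name: j for j, name in enumerate(model.columns)}

        for size in config.subset_sizes:
            cols = [col_index[name] for name in ranked.subsets[size]]
            for ratio in config.ratios:
                for family in config.families:
                    sampling = ensembles.SamplingConfig(
                        ratio=ratio,
                        n_repeats=config.n_repeats,
                        base_seed=config.seed * 1000 + fold_no,
                    )
                    model_e = ensembles.train_ensemble(
                        family,
                        X_train[:, cols],
                        y_train,
                        sampling,
                        params=config.model_params.get(family),
                    )
                    proba = ensembles.predict_proba(model_e, X_test[:, cols])
                    metrics = evaluation.compute_metrics(y_test, proba)
                    rows.append(
                        {
                            "family": family,
                            "size": str(size),
                            "ratio": ratio,
                            "fold": fold_no,
                            "single_model": model_e.single_model,
                            **metrics,
                        }
                    )
        logger.info("fold %d/%d done", fold_no + 1, config.k_folds)

    metrics_df = pd.DataFrame(rows)
    summary = (
        metrics_df.groupby(["family", "size", "ratio"])[list(evaluation.METRICS)]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c for c in col if c) if isinstance(col, tuple) else col
        for col in summary.columns
    ]

    friedman = {}
    if len(config.families) >= 2 and len(config.subset_sizes) >= 2:
        at_ratio = metrics_df[np.isclose(metrics_df["ratio"], config.nemenyi_ratio)]
        fold_avg = at_ratio.groupby(["family", "size"])[list(evaluation.METRICS)].mean()
        for metric in evaluation.METRICS:
            table = np.array(
                [
                    [fold_avg.loc[(fam, str(size)), metric] for size in config.subset_sizes]
                    for fam in config.families
                ]
            )
            test = evaluation.friedman_test(table)
            cd = evaluation.nemenyi_cd(k=test["k"], n=test["n"])
            grouping = evaluation.cd_grouping(
                test["average_ranks"], cd, names=list(config.families)
            )
            friedman[metric] = {
                "average_ranks": dict(
                    zip(config.families, map(float, test["average_ranks"]))
                ),
                "chi2": test["chi2"],
                "p": test["p"],
                "cd": cd,
                "bars": grouping.bars,
            }

    family_mix = sum(mix_tables) / len(mix_tables)
    manifest = {
        "seed": config.seed,
        "k_folds": config.k_folds,
        "n_records": len(records),
        "n_cessation": int(y.sum()),
        "families": list(config.families),
        "subset_sizes": [str(s) for s in config.subset_sizes],
        "ratios": list(map(float, config.ratios)),
        "n_repeats": config.n_repeats,
        "fold_spec_hashes": spec_hashes,
    }
    result = ExperimentResult(
        metrics=metrics_df,
        summary=summary,
        friedman=friedman,
        family_mix=family_mix,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_result(result, Path(config.out_dir), config.overwrite)
    return result


def _write_result(result: ExperimentResult, out: Path, overwrite: bool) -> None:
    out.mkdir(parents=True, exist_ok=True)
    targets = ["metrics.csv", "summary.csv", "friedman.json", "family_mix.csv",
               "manifest.json"]
    if not overwrite:
        existing = [t for t in targets if (out / t).exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite existing outputs in {out}: {existing}"
            )
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    with open(out / "friedman.json", "w") as fh:
        json.dump(result.friedman, fh, indent=2)
        fh.write("\n")
    result.family_mix.to_csv(out / "family_mix.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
        fh.write("\n")
    logger.info("experiment artifacts written to %s", out)
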