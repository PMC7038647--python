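"""End-to-end pipeline: preprocess -> split -> fit -> score -> analyse.

Importance scores are always computed on held-out test samples only; the
pipeline asserts that no training sample id appears in the importance
matrix. Every run writes a manifest (config, derived seeds, package version,
per-stage log) so a run can be repeated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, GeneSetCollection
from .model import ModelConfig, fit, predict, score_importance, save_model
from .preprocess import (
    aggregate_to_annotations,
    drop_zero_features,
    estimate_size_factors,
    filter_gene_sets,
    normalize_counts,
)
from . import analysis

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "split_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full run; YAML-loadable with full defaulting."""

    counts: str
    labels: str
    out_dir: str
    gmt: str | None = None
    clinical: str | None = None
    feature_space: str = "genes"  # "genes" | "annotations"
    min_set_size: int = 10
    aggregate_raw: bool = False  # sum raw counts before normalisation
    test_fraction: float | None = 1 / 3
    test_samples: list[str] | None = None
    train_samples: list[str] | None = None
    patient_column: str | None = None
    nmf_k: int = 2
    n_components: int = 3
    # correlation-mode PCA: importance columns span orders of magnitude once
    # attention concentrates, so within-class axes only surface after
    # per-column standardisation
    pca_scale: bool = True
    subset_class: str | int | None = 1
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.feature_space not in ("genes", "annotations"):
            raise ValueError(f"unknown feature_space {self.feature_space!r}")
        if self.feature_space == "annotations" and not self.gmt:
            raise ValueError("feature_space='annotations' requires a gene-set (GMT) file")
        if self.test_samples is not None and self.train_samples is not None:
            overlap = set(self.test_samples) & set(self.train_samples)
            if overlap:
                raise ValueError(f"train and test sample sets overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model_raw = raw.pop("model", {})
        cfg = cls(**raw, model=ModelConfig(**model_raw))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def split_cohort(
    sample_ids: list[str],
    labels: np.ndarray,
    test_fraction: float | None = None,
    test_samples: list[str] | None = None,
    train_samples: list[str] | None = None,
    seed: int = 0,
    patient_ids: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Deterministic train/test split, stratified by class when fraction-based.

    When ``patient_ids`` is given, every sample of any patient contributing
    more than one sample is removed before splitting (one sample per
    patient). Explicit id lists are honoured verbatim after disjointness
    validation. Both classes must be present in both resulting sets.
    """
    sample_ids = [str(s) for s in sample_ids]
    y = np.asarray(labels).ravel()
    if len(sample_ids) != len(y):
        raise ValueError("labels do not align with sample ids")

    keep = np.ones(len(sample_ids), dtype=bool)
    if patient_ids is not None:
        counts = pd.Series([str(p) for p in patient_ids]).value_counts()
        multi = set(counts[counts > 1].index)
        keep = np.array([str(p) not in multi for p in patient_ids])
        if multi:
            logger.info("removed %d samples from %d multi-sample patients", (~keep).sum(), len(multi))
    ids = [s for s, k in zip(sample_ids, keep) if k]
    y = y[keep]

    if test_samples is not None:
        test = [s for s in test_samples if s in set(ids)]
        if train_samples is not None:
            overlap = set(test_samples) & set(train_samples)
            if overlap:
                raise ValueError(f"train and test sets overlap: {sorted(overlap)[:5]}")
            train = [s for s in train_samples if s in set(ids)]
        else:
            train = [s for s in ids if s not in set(test)]
    else:
        if test_fraction is None or not (0.0 < test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1) when no explicit lists are given")
        rng = np.random.default_rng(seed)
        test_idx: list[int] = []
        for c in np.unique(y):
            idx_c = np.flatnonzero(y == c)
            rng.shuffle(idx_c)
            n_test = int(round(test_fraction * len(idx_c)))
            test_idx.extend(idx_c[:n_test])
        test_set = set(test_idx)
        test = [ids[i] for i in sorted(test_set)]
        train = [ids[i] for i in range(len(ids)) if i not in test_set]

    lab = dict(zip(ids, y))
    for name, part in (("train", train), ("test", test)):
        part_labels = {lab[s] for s in part}
        if len(part_labels) < 2:
            raise ValueError(f"{name} split does not contain both classes")
    return train, test


def _read_labels(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError("labels TSV needs sample_id and label columns")
    s = frame.set_index(frame.columns[0])[frame.columns[1]]
    s.index = s.index.astype(str)
    return s.astype(int)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stages: load -> drop zero features -> size-factor normalisation ->
    (optional) annotation aggregation -> split -> train -> importance scoring
    on the test set -> NMF / PCA / stage association / baselines.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg.to_dict(), "stages": []}

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("load")
        counts = ExpressionMatrix.read_tsv(cfg.counts)
        labels_s = _read_labels(cfg.labels)
        missing = [s for s in counts.sample_ids if s not in labels_s.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        y = labels_s.loc[counts.sample_ids].to_numpy()

        stage("preprocess")
        counts = drop_zero_features(counts)
        factors = estimate_size_factors(counts)
        norm = normalize_counts(counts, factors)
        if cfg.feature_space == "annotations":
            sets = GeneSetCollection.read_gmt(cfg.gmt)
            sets = filter_gene_sets(sets, counts.feature_ids, min_size=cfg.min_set_size)
            source = counts if cfg.aggregate_raw else norm
            features = aggregate_to_annotations(source, sets)
            if cfg.aggregate_raw:
                features = normalize_counts(features, estimate_size_factors(features))
        else:
            features = norm

        stage("split")
        patient_ids = None
        if cfg.patient_column and cfg.clinical:
            clin = pd.read_csv(cfg.clinical, sep="\t")
            patient_ids = clin.set_index("sample_id").loc[features.sample_ids, cfg.patient_column].tolist()
        ss = np.random.SeedSequence(cfg.seed)
        s_split, s_model = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
        train_ids, test_ids = split_cohort(
            features.sample_ids, y,
            test_fraction=cfg.test_fraction,
            test_samples=cfg.test_samples, train_samples=cfg.train_samples,
            seed=s_split, patient_ids=patient_ids,
        )
        manifest["seeds"] = {"split": s_split, "model": s_model, "root": cfg.seed}
        manifest["n_train"], manifest["n_test"] = len(train_ids), len(test_ids)
        pos = {s: i for i, s in enumerate(features.sample_ids)}
        train_m = features.subset_samples(train_ids)
        test_m = features.subset_samples(test_ids)
        y_train = y[[pos[s] for s in train_ids]]
        y_test = y[[pos[s] for s in test_ids]]

        stage("train")
        model_cfg = dataclasses.replace(cfg.model, seed=s_model)
        model = fit(train_m, y_train, model_cfg)
        save_model(model, out / "model.npz")

        stage("score")
        imp = score_importance(model, test_m)
        leaked = set(imp.sample_ids) & set(train_ids)
        assert not leaked, f"train samples leaked into the importance matrix: {sorted(leaked)[:5]}"
        imp.class_labels = y_test
        imp.to_tsv(out / "importance.tsv")
        prob = predict(model, test_m)
        from sklearn.metrics import f1_score

        pred_frame = pd.DataFrame(
            {"sample_id": test_ids, "probability": prob, "label": y_test.astype(int)}
        )
        pred_frame.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.10g")
        manifest["f1_deeptriage"] = float(f1_score(y_test, (prob >= 0.5).astype(int)))

        stage("analyze")
        fac = analysis.nmf_factorise(imp, k=cfg.nmf_k, seed=cfg.seed, class_labels=y_test)
        fac.contributions().rename("relative_contribution").to_csv(
            out / "factor_contributions.tsv", sep="\t"
        )
        r = min(cfg.n_components, len(test_ids) - 1, imp.B.shape[1])
        ordination = analysis.pca_ordinate(imp, r=r, scale=cfg.pca_scale)
        ordination.scores_frame().to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")
        ordination.loadings_frame().to_csv(out / "pca_loadings.tsv", sep="\t", float_format="%.10g")
        analysis.plot_factor_contributions(fac, out / "factor_contributions.png")
        analysis.plot_factor_boxplot(fac, y_test, out / "factor_boxplot.png")
        if r >= 2:
            analysis.plot_biplot(ordination, imp, out / "biplot.png", labels=y_test)

        if cfg.clinical:
            clin = pd.read_csv(cfg.clinical, sep="\t")
            subset = cfg.subset_class
            if subset is not None and "subtype" in clin.columns and str(subset) in ("0", "1"):
                subset = "A" if str(subset) == "1" else "B"
            assoc_rows = []
            for ax in range(r):
                try:
                    assoc = analysis.stage_association(
                        ordination, clin, axis=ax, subset_class=subset
                    )
                except (ValueError, KeyError) as exc:
                    logger.warning("stage association skipped for axis %d: %s", ax, exc)
                    continue
                frame = assoc.to_frame(bh=True)
                frame.insert(0, "axis", f"PC{ax + 1}")
                assoc_rows.append(frame)
            if assoc_rows:
                pd.concat(assoc_rows).to_csv(out / "stage_association.tsv", sep="\t", index=False)

        stage("baselines")
        baselines = analysis.run_baselines(
            train_m, y_train, test_m, y_test, feature_space=cfg.feature_space
        )
        baselines["deeptriage"] = manifest["f1_deeptriage"]
        baselines.to_csv(out / "baselines.tsv", sep="\t")
        manifest["baselines"] = baselines.iloc[0].to_dict()
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
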