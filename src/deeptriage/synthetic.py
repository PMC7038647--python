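"""Synthetic RNA-seq-like cohorts with planted structure.

The generator emulates the statistical regime the classifier targets: far
more features than samples, non-negative overdispersed counts, a binary
class structure carried by a small set of discriminative features, and
within-class heterogeneity tied to an ordinal clinical stage.

Counts for sample j, feature i are negative-binomial with mean

    mu_ji = lib_j * baseline_mean * exp(class_effect_i + gradient_effect_ji)

and variance mu + dispersion * mu^2. Planted discriminative features carry
``class_effect = effect_size`` (a natural-log fold change) in class B (y=0),
so they are up-regulated in the severe class. A random subgroup of class A
(fraction ``subgroup_fraction``) carries a severity gradient: the mean of
each gradient feature is shifted proportionally to the sample's stage,
placing those samples along a continuum toward class B. Library-size
multipliers lib_j are log-normal, which makes median-of-ratios size-factor
estimation non-trivial.

Stages 1-4 are assigned ordinally with class B skewed toward higher stages,
and exported as clinical T (T1-T4), N (N0-N2, noisy monotone in stage) and
M (M0/M1, rare and more likely at stage 4) categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort", "generate_gene_sets"]

# stage distributions: class A skewed low, class B skewed high
_STAGE_P_A = np.array([0.40, 0.30, 0.20, 0.10])
_STAGE_P_B = np.array([0.10, 0.20, 0.30, 0.40])


@dataclass
class SyntheticConfig:
    """Cohort generation parameters (defaults define the reference cohort)."""

    n_per_class: int = 150
    n_features: int = 500
    n_planted: int = 10
    effect_size: float = 2.0  # natural-log fold change of planted features in class B
    dispersion: float = 0.3  # NB overdispersion phi; var = mu + phi mu^2
    baseline_mean: float = 50.0
    subgroup_fraction: float = 0.5  # fraction of class A carrying the gradient
    gradient_features: int = 10
    gradient_scale: float = 1.0  # log-FC per unit of (stage-1)/3 on gradient features
    library_sigma: float = 0.3  # sd of log-normal library-size multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2 or self.n_features < 1:
            raise ValueError("need >=2 samples per class and >=1 feature")
        if self.n_planted + self.gradient_features > self.n_features:
            raise ValueError("planted + gradient features exceed the feature space")
        if not (0.0 <= self.subgroup_fraction <= 1.0):
            raise ValueError("subgroup_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")


@dataclass
class SyntheticCohort:
    counts: ExpressionMatrix
    labels: np.ndarray  # 1 = class A, 0 = class B
    stage: np.ndarray  # ordinal 1..4
    planted_features: np.ndarray  # indices carrying the class effect
    gradient_features: np.ndarray  # indices carrying the severity gradient
    subgroup_mask: np.ndarray  # class-A samples carrying the gradient
    library_factors: np.ndarray
    gene_sets: GeneSetCollection | None = None

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical-style table: sample_id, T, N, M, subtype."""
        return pd.DataFrame(
            {
                "sample_id": self.counts.sample_ids,
                "T": [f"T{s}" for s in self.stage],
                "N": self._n_stage,
                "M": self._m_stage,
                "subtype": np.where(self.labels == 1, "A", "B"),
            }
        )

    # N/M derived deterministically at generation time; stored post-init
    _n_stage: list[str] = None  # type: ignore[assignment]
    _m_stage: list[str] = None  # type: ignore[assignment]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_tsv(out / "counts.tsv", float_format="%.0f")
        pd.DataFrame(
            {"sample_id": self.counts.sample_ids, "label": self.labels.astype(int)}
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
        self.clinical_frame().to_csv(out / "clinical.tsv", sep="\t", index=False)
        if self.gene_sets is not None:
            self.gene_sets.write_gmt(out / "gene_sets.gmt")
        truth = {
            "planted_features": [self.counts.feature_ids[i] for i in self.planted_features],
            "gradient_features": [self.counts.feature_ids[i] for i in self.gradient_features],
            "subgroup_samples": [
                s for s, m in zip(self.counts.sample_ids, self.subgroup_mask) if m
            ],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi mu^2 via gamma-Poisson."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu * phi)
    return rng.poisson(lam).astype(float)


def generate_cohort(cfg: SyntheticConfig, with_gene_sets: bool = True) -> SyntheticCohort:
    """Draw a cohort; fully deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_class
    d = cfg.n_features

    # feature roles drawn first so generate_gene_sets can replay them
    feat_idx = rng.permutation(d)
    planted = np.sort(feat_idx[: cfg.n_planted])
    gradient = np.sort(feat_idx[cfg.n_planted : cfg.n_planted + cfg.gradient_features])

    labels = np.concatenate([np.ones(cfg.n_per_class), np.zeros(cfg.n_per_class)]).astype(int)
    labels = labels[rng.permutation(n)]

    stage_a = rng.choice([1, 2, 3, 4], size=n, p=_STAGE_P_A)
    stage_b = rng.choice([1, 2, 3, 4], size=n, p=_STAGE_P_B)
    stage = np.where(labels == 1, stage_a, stage_b)

    subgroup = np.zeros(n, dtype=bool)
    class_a = np.flatnonzero(labels == 1)
    n_sub = int(round(cfg.subgroup_fraction * len(class_a)))
    if n_sub:
        subgroup[rng.choice(class_a, size=n_sub, replace=False)] = True

    log_mu = np.full((n, d), np.log(cfg.baseline_mean))
    # class effect: planted features up-regulated in class B (y=0)
    log_mu[np.ix_(labels == 0, planted)] += cfg.effect_size
    # severity continuum: gradient features shift proportionally to stage for
    # the class-A subgroup and for every class-B sample (class B sits at the
    # severe end of the same continuum because its stages skew high)
    if len(gradient):
        on_continuum = subgroup | (labels == 0)
        grad_amount = cfg.gradient_scale * cfg.effect_size * (stage[on_continuum] - 1) / 3.0
        log_mu[np.ix_(on_continuum, gradient)] += grad_amount[:, None]

    lib = np.exp(rng.normal(0.0, cfg.library_sigma, size=n)) if cfg.library_sigma > 0 else np.ones(n)
    mu = lib[:, None] * np.exp(log_mu)
    counts = _nb_draw(rng, mu, cfg.dispersion)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    feature_ids = [f"G{i:04d}" for i in range(d)]
    matrix = ExpressionMatrix(sample_ids, feature_ids, counts)

    # clinical N and M: noisy monotone in stage
    n_stage = np.clip(stage - 1 + rng.integers(-1, 2, size=n), 0, 2)
    m_stage = (rng.random(n) < np.where(stage == 4, 0.3, 0.02)).astype(int)

    cohort = SyntheticCohort(
        counts=matrix,
        labels=labels,
        stage=stage,
        planted_features=planted,
        gradient_features=gradient,
        subgroup_mask=subgroup,
        library_factors=lib,
    )
    cohort._n_stage = [f"N{v}" for v in n_stage]
    cohort._m_stage = [f"M{v}" for v in m_stage]
    if with_gene_sets:
        cohort.gene_sets = generate_gene_sets(cfg, feature_ids=feature_ids, planted=planted)
    return cohort


def generate_gene_sets(
    cfg: SyntheticConfig,
    feature_ids: list[str] | None = None,
    planted: np.ndarray | None = None,
) -> GeneSetCollection:
    """Emulated annotation collection over the synthetic feature universe.

    Contains: two "signal" sets that split the planted features (padded with
    null features to size >= 10), a block of null sets, one overlapping pair
    sharing members, and one set smaller than 10 members (so the size filter
    has something to remove). Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    d = cfg.n_features
    if feature_ids is None:
        feature_ids = [f"G{i:04d}" for i in range(d)]
    if planted is None:
        # replay generate_cohort's first draw to recover the planted indices
        planted = np.sort(np.random.default_rng(cfg.seed).permutation(d)[: cfg.n_planted])

    planted = np.asarray(planted)
    null_pool = np.setdiff1d(np.arange(d), planted)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}

    half = max(1, len(planted) // 2)
    for tag, part in (("SIG01", planted[:half]), ("SIG02", planted[half:])):
        pad = rng.choice(null_pool, size=max(0, 12 - len(part)), replace=False)
        sets[tag] = [feature_ids[i] for i in np.concatenate([part, pad])]
        descriptions[tag] = "signal set containing planted discriminative features"

    max_null = max(11, min(40, len(null_pool)))
    for k in range(10):
        size = int(rng.integers(10, max_null)) if max_null > 10 else 10
        size = min(size, len(null_pool))
        members = rng.choice(null_pool, size=size, replace=False)
        sets[f"NULL{k:02d}"] = [feature_ids[i] for i in members]
        descriptions[f"NULL{k:02d}"] = "null set of non-discriminative features"

    # overlapping pair: share half their members (sizes shrink with the pool)
    part = max(2, min(8, len(null_pool) // 3))
    shared = rng.choice(null_pool, size=part, replace=False)
    rest = np.setdiff1d(null_pool, shared)
    extra_a = rng.choice(rest, size=part, replace=False)
    extra_b = rng.choice(np.setdiff1d(rest, extra_a), size=min(part, len(rest) - part), replace=False)
    sets["OVLP01"] = [feature_ids[i] for i in np.concatenate([shared, extra_a])]
    sets["OVLP02"] = [feature_ids[i] for i in np.concatenate([shared, extra_b])]
    descriptions["OVLP01"] = descriptions["OVLP02"] = "overlapping pair"

    small = rng.choice(null_pool, size=min(6, len(null_pool)), replace=False)
    sets["SMALL01"] = [feature_ids[i] for i in small]
    descriptions["SMALL01"] = "below the size-10 filter"

    return GeneSetCollection.from_mapping(sets, descriptions)
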