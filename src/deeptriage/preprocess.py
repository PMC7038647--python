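"""Count preprocessing: zero filtering, size-factor normalisation, gene-set
aggregation.

Size factors use the median-of-ratios estimator: each sample's counts are
divided by per-feature geometric means (computed over features with no zero
count) and the per-sample median ratio is taken. Factors are rescaled to
geometric mean 1 so that a normalised matrix re-estimates factors of exactly 1.

Annotation-level ("pathway-level") features are built by summing the
normalised expression of all member genes of each gene set, after removing
sets with fewer than ``min_size`` measured members (default 10).
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "drop_zero_features",
    "estimate_size_factors",
    "normalize_counts",
    "filter_gene_sets",
    "aggregate_to_annotations",
]


def drop_zero_features(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Remove features whose counts are zero across all samples.

    Column order of the surviving features is preserved. Raises if every
    feature is all-zero.
    """
    keep = counts.values.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("all features have zero counts across all samples: empty feature space")
    features = [f for f, k in zip(counts.feature_ids, keep) if k]
    return ExpressionMatrix(list(counts.sample_ids), features, counts.values[:, keep])


def estimate_size_factors(counts: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one positive scalar per sample.

    The reference pseudo-sample is the per-feature geometric mean, computed
    in log space over features with strictly positive counts in every sample.
    Each sample's factor is the median of its count/reference ratios over
    those features, rescaled so the factors have geometric mean 1.
    """
    x = counts.values
    usable = np.all(x > 0, axis=0)
    if not usable.any():
        raise ValueError(
            "no feature has all-positive counts across samples; "
            "the geometric-mean reference is not computable"
        )
    logx = np.log(x[:, usable])
    log_geomean = logx.mean(axis=0)
    log_ratios = logx - log_geomean
    log_factors = np.median(log_ratios, axis=1)
    log_factors -= log_factors.mean()  # geometric mean 1
    factors = np.exp(log_factors)
    return factors


def normalize_counts(counts: ExpressionMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Divide each sample's row by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValueError(
            f"got {factors.shape[0] if factors.ndim == 1 else factors.shape} factors "
            f"for {counts.n_samples} samples"
        )
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factors must be positive and finite")
    return ExpressionMatrix(
        list(counts.sample_ids), list(counts.feature_ids), counts.values / factors[:, None]
    )


def filter_gene_sets(
    sets: GeneSetCollection, universe: list[str] | set[str], min_size: int = 10
) -> GeneSetCollection:
    """Intersect each set with the measured feature universe and keep sets
    with at least ``min_size`` surviving members.

    Members outside the universe are dropped from retained sets; set order is
    preserved.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = set(universe)
    entries: dict[str, GeneSet] = {}
    for set_id, gs in sets.entries.items():
        measured = gs.members & universe
        if len(measured) >= min_size:
            entries[set_id] = GeneSet(gs.description, frozenset(measured))
    if not entries:
        raise ValueError(
            f"no gene set has >= {min_size} measured members; try a smaller min_size"
        )
    return GeneSetCollection(entries)


def aggregate_to_annotations(
    norm: ExpressionMatrix, sets: GeneSetCollection
) -> ExpressionMatrix:
    """Sum member-gene expression per set, producing an annotation-level matrix.

    Output features are the set ids in collection order; a gene in multiple
    sets contributes to each. Sets referencing no measured gene raise (they
    should have been removed by :func:`filter_gene_sets`).
    """
    pos = {f: i for i, f in enumerate(norm.feature_ids)}
    set_ids = list(sets.entries)
    out = np.empty((norm.n_samples, len(set_ids)))
    for k, set_id in enumerate(set_ids):
        idx = [pos[g] for g in sets.members(set_id) if g in pos]
        if not idx:
            raise ValueError(f"gene set {set_id!r} references no measured gene")
        out[:, k] = norm.values[:, idx].sum(axis=1)
    return ExpressionMatrix(list(norm.sample_ids), set_ids, out)
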