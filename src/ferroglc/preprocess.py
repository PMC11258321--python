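"""Normalization, filtering, half-minimum imputation and sample QC.

Pipeline order is fixed: normalize -> peptide filter -> impute. Imputed
values then inherit the normalized scale. Half-minimum imputation fills a
protein's fully-missing conditions with half the linear abundance of its
least abundant detected condition mean (log2(min) - 1), in every replicate
slot of that condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import AbundanceMatrix, condition_means


def normalize_central_tendency(matrix: AbundanceMatrix, center: str = "mean") -> AbundanceMatrix:
    """Scale each sample so its center over detected values equals the grand center.

    The grand center is the mean (or median) of the per-sample centers, so
    the operation is idempotent: a second pass changes nothing.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    agg = getattr(matrix.values, center)
    per_sample = agg(axis=0, skipna=True)
    if per_sample.isna().any():
        bad = per_sample.index[per_sample.isna()].tolist()
        raise ValueError(f"sample(s) with zero detected values: {bad}")
    grand = float(np.mean(per_sample) if center == "mean" else np.median(per_sample))
    scaled = matrix.values.mul(grand / per_sample, axis=1)
    return matrix.replace_values(scaled)


def filter_min_peptides(matrix: AbundanceMatrix, k: int) -> tuple[AbundanceMatrix, list[str]]:
    """Drop proteins with fewer than ``k`` unique peptides.

    Returns the filtered matrix and the removed protein ids.
    """
    keep = matrix.unique_peptides >= k
    removed = matrix.protein_ids[~keep].tolist()
    if not removed:
        return matrix, []
    return matrix.subset_proteins(matrix.protein_ids[keep]), removed


def drop_all_missing(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, list[str]]:
    """Drop proteins with no detected value in any sample (pre-imputation)."""
    detected = matrix.values.notna().any(axis=1)
    removed = matrix.protein_ids[~detected].tolist()
    if not removed:
        return matrix, []
    return matrix.subset_proteins(matrix.protein_ids[detected]), removed


def impute_missing_conditions(matrix: AbundanceMatrix, minimum: str = "condition") -> AbundanceMatrix:
    """Half-minimum imputation of fully-missing conditions.

    For each protein, every condition with no detected replicate receives
    log2(min over detected condition means) - 1 — i.e. half the minimum on
    the linear scale — in all of its replicate slots. With
    ``minimum="replicate"`` the minimum is taken over raw detected
    replicate values instead of condition means (a sensitivity-analysis
    switch). Detected cells are untouched and the imputed mask records the
    filled (protein, condition) pairs.
    """
    if minimum not in ("condition", "replicate"):
        raise ValueError("minimum must be 'condition' or 'replicate'")
    matrix = matrix.drop_excluded()
    lin_means, _ = condition_means(matrix)
    if lin_means.isna().all(axis=1).any():
        bad = lin_means.index[lin_means.isna().all(axis=1)].tolist()
        raise ValueError(f"protein(s) missing in all conditions: {bad[:5]}")

    if minimum == "condition":
        floor = lin_means.min(axis=1, skipna=True) / 2.0
    else:
        floor = matrix.values.min(axis=1, skipna=True) / 2.0

    values = matrix.values.copy()
    by_cond = matrix.samples_by_condition()
    mask = pd.DataFrame(False, index=matrix.protein_ids,
                        columns=[c.label for c in by_cond])
    for cond, ids in by_cond.items():
        missing = lin_means[cond.label].isna()
        if missing.any():
            values.loc[missing, ids] = np.tile(
                floor[missing].to_numpy()[:, None], (1, len(ids))
            )
            mask.loc[missing, cond.label] = True
    return matrix.replace_values(values, imputed_mask=mask)


def _complete_log2(matrix: AbundanceMatrix, min_peptides: int = 2) -> pd.DataFrame:
    keep = (matrix.values.notna().all(axis=1)) & (matrix.unique_peptides >= min_peptides)
    return np.log2(matrix.values.loc[keep])


def pca_summary(matrix: AbundanceMatrix, min_peptides: int = 2,
                n_components: int | None = None) -> pd.DataFrame:
    """Centered PCA of log2 abundances, samples as observations.

    Restricted to proteins detected in every sample with at least
    ``min_peptides`` unique peptides (no imputed values); no unit-variance
    scaling. Returns one row per component with the variance fraction in
    percent and per-sample coordinates.
    """
    log2 = _complete_log2(matrix, min_peptides)
    if len(log2) < 2:
        raise ValueError("need >=2 complete proteins for PCA")
    if len(log2.columns) < 2:
        raise ValueError("need >=2 samples for PCA")
    X = log2.to_numpy(float).T  # samples x proteins
    k = n_components or min(X.shape)
    pca = PCA(n_components=min(k, min(X.shape)))
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords.T, columns=log2.columns,
        index=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    out.insert(0, "variance_pct", pca.explained_variance_ratio_ * 100.0)
    out.index.name = "component"
    return out.reset_index()


def replicate_correlation(matrix: AbundanceMatrix, min_peptides: int = 2) -> pd.DataFrame:
    """Sample x sample Pearson correlation of complete-protein log2 values."""
    log2 = _complete_log2(matrix, min_peptides)
    if len(log2) < 2:
        raise ValueError("need >=2 complete proteins for correlations")
    corr = np.corrcoef(log2.to_numpy(float).T)
    return pd.DataFrame(corr, index=log2.columns, columns=log2.columns)
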