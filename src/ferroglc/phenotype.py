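"""Cross-compartment iron-response comparison and phenotype formulas.

The iron-sparing comparison contrasts per-subunit log2(-Fe/+Fe) abundance
ratios of the photosynthetic versus respiratory electron transport chains
within each (strain, Glc) stratum, tested by the Wilcoxon rank-sum test.
Also implemented here: volumetric biomass from cell diameter distributions
(sum of sphere volumes), the specific growth rate in log10 units per hour,
and the chlorophyll-fluorescence Fv/Fm noise-floor rule that assigns 0 when
the variable fluorescence does not rise above four standard deviations of
the baseline (Fo) noise.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceMatrix, AnnotationSet, Condition, condition_means

#: Group sizes up to which the tie-free exact Mann-Whitney null is enumerated.
_EXACT_N = 12


def fe_fold_changes(
    matrix: AbundanceMatrix,
    protein_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-protein log2(-Fe mean / +Fe mean) in every (strain, Glc) stratum.

    Ratios use linear-scale condition means (replicates averaged before the
    ratio); a row is emitted only where both condition means exist, and an
    ``imputed`` flag marks strata where either side was imputed.
    """
    matrix = matrix.drop_excluded()
    if protein_ids is not None:
        missing = [p for p in protein_ids if p not in matrix.protein_ids]
        if missing:
            import warnings

            warnings.warn(f"{len(missing)} protein(s) absent from matrix; skipped",
                          stacklevel=2)
        protein_ids = [p for p in protein_ids if p in matrix.protein_ids]
        matrix = matrix.subset_proteins(protein_ids)
    lin, _ = condition_means(matrix)
    mask = matrix.imputed_mask

    strata = sorted({(c.strain, c.glc) for c in matrix.conditions})
    rows = []
    for strain, glc in strata:
        minus = Condition(strain, -1, glc).label
        plus = Condition(strain, 1, glc).label
        if minus not in lin.columns or plus not in lin.columns:
            continue
        ratio = np.log2(lin[minus] / lin[plus])
        for pid in matrix.protein_ids:
            if not np.isfinite(ratio[pid]):
                continue
            imputed = bool(mask.loc[pid, [minus, plus]].any()) if mask is not None else False
            rows.append({"protein_id": pid, "strain": strain, "glc": glc,
                         "log2_fe_ratio": float(ratio[pid]), "imputed": imputed})
    return pd.DataFrame(rows)


def complex_mean_fold_change(
    fold_changes: pd.DataFrame,
    members: Iterable[str] | AnnotationSet,
    strain: str | None = None,
    glc: int | None = None,
) -> float:
    """Mean log2(-Fe/+Fe) over a complex's member subunits (optionally per stratum)."""
    if isinstance(members, AnnotationSet):
        members = members.members
    sel = fold_changes["protein_id"].isin(set(members))
    if strain is not None:
        sel &= fold_changes["strain"] == strain
    if glc is not None:
        sel &= fold_changes["glc"] == glc
    return float(fold_changes.loc[sel, "log2_fe_ratio"].mean())


def wilcoxon_rank_sum(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the Mann-Whitney U of the first group (rank sum of ``a`` under
    pooled mid-ranks minus |a|(|a|+1)/2). The null is enumerated exactly
    for tie-free pooled samples of size <= 12; otherwise the normal
    approximation with tie and continuity corrections is used. All values
    identical across both groups gives W = |a||b|/2 and p = 1.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return len(a) * len(b) / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(pooled) <= _EXACT_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def volumetric_biomass(
    diameters: Iterable[float],
    dilution: float = 1.0,
    counted_volume: float = 1.0,
) -> float:
    """Volumetric biomass: sum of per-cell sphere volumes, scaled to the culture.

    Each cell contributes 4*pi/3 * (d/2)^3 (um^3); the sum is multiplied by
    the dilution factor and divided by the counted volume (mL) to give
    um^3 per mL.
    """
    d = np.asarray(list(diameters), float)
    if d.size and (d <= 0).any():
        raise ValueError("diameters must be positive")
    volume = float(np.sum(4.0 * np.pi / 3.0 * (d / 2.0) ** 3))
    return volume * dilution / counted_volume


def specific_growth_rate(b0: float, b_end: float, hours: float) -> float:
    """Specific growth rate (log10(b_end) - log10(b0)) / hours, per hour."""
    if b0 <= 0 or b_end <= 0:
        raise ValueError("biomass values must be positive")
    if hours <= 0:
        raise ValueError("hours must be positive")
    return (np.log10(b_end) - np.log10(b0)) / hours


def fvfm_with_noise_floor(
    fo_trace: Sequence[float],
    fm: float,
) -> tuple[float, bool]:
    """Fv/Fm with the dark-fluorescence noise-floor detection rule.

    Fo is the mean of the baseline (measuring-light) fluorescence trace and
    its noise is four standard deviations of that trace (~95% of the noise
    range). If Fv = Fm - Fo does not exceed the noise — including any
    negative Fv — the sample is scored not-detected and assigned 0;
    otherwise Fv/Fm = (Fm - Fo)/Fm.
    """
    trace = np.asarray(list(fo_trace), float)
    if trace.size < 2:
        raise ValueError("fo_trace needs >=2 values to estimate noise")
    fo = float(trace.mean())
    noise = 4.0 * float(trace.std(ddof=1))
    fv = fm - fo
    if fv <= noise:
        return 0.0, False
    return fv / fm, True
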