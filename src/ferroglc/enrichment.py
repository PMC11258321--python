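"""Extreme-condition enrichment: lowest/highest-in-heterotrophy and TAG.

A protein is a candidate "lowest-in-heterotrophy" protein when its
abundance in the heterotrophic condition (WT-Fe+Glc) ranks strictly below
every other condition. The statistic per protein is then (i) the log2 gap
between the target extreme and the next-nearest non-target condition and
(ii) the maximum p-value over Welch two-tailed t-tests of the target
replicates against each other condition's replicates — the max ensures the
target separates from *every* other condition. Max p-values are BH-adjusted
across rank-passing proteins; the stringent tier requires FDR pass plus a
gap above the fold-change cutoff (0.5 log2), while the expanded tier adds
FDR-pass-only proteins and proteins whose simplified equations place the
-Fe+Glc corner at the extreme for both strains.

The TAG variant targets the two TAG-accumulating conditions (WT-Fe+Glc and
WT+Fe+Glc) as a single group: both must occupy the two most extreme ranks,
the gap is measured from the nearer target to the nearest non-target, and
t-tests pool the replicates of both targets.

Imputed conditions participate in ranking and testing exactly like real
data; their zero within-condition variance degrades the Welch test
gracefully (the statistic is then driven by the target's variance alone).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AbundanceMatrix, Condition, PipelineConfig, condition_means
from .factorial import SimplifiedEquation, TERMS, term_values

HETEROTROPHY_TARGET = (Condition("WT", -1, 1),)
TAG_TARGETS = (Condition("WT", -1, 1), Condition("WT", 1, 1))


def welch_t(a: Iterable[float], b: Iterable[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Degenerate rules (for noiseless and fully-imputed fixtures): when both
    groups have zero variance, p = 1 for equal means and p = 0 otherwise.
    When only one group has variance, the Welch-Satterthwaite df reduces to
    that group's n - 1 and the statistic uses its variance alone.
    """
    a = np.asarray([x for x in np.asarray(a, float).ravel() if np.isfinite(x)])
    b = np.asarray([x for x in np.asarray(b, float).ravel() if np.isfinite(x)])
    na, nb = len(a), len(b)
    if na < 1 or nb < 1 or (na < 2 and nb < 2):
        raise ValueError("welch_t needs both groups non-empty and one with >=2 values")
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    se2 = va / na + vb / nb
    if se2 <= 0.0:
        if np.isclose(ma, mb, rtol=0.0, atol=1e-12):
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(ma - mb) * np.inf), float(na + nb - 2), 0.0
    denom = 0.0
    if va > 0 and na > 1:
        denom += (va / na) ** 2 / (na - 1)
    if vb > 0 and nb > 1:
        denom += (vb / nb) ** 2 / (nb - 1)
    df = se2 ** 2 / denom
    t = (ma - mb) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def equation_predicted_extremes(
    equations: Sequence[SimplifiedEquation],
    direction: str,
    fe: int = -1,
    glc: int = 1,
) -> set[str]:
    """Proteins whose simplified equation puts the (fe, glc) corner at the extreme.

    The equation (retained signed betas only) is evaluated at all 8
    (strain, Fe, Glc) corners; the protein qualifies iff the target corner
    is the strict minimum (``direction="lowest"``) or maximum among the
    four (Fe, Glc) corners at *both* strain levels. Strain-only equations
    tie across (Fe, Glc) corners and never qualify.
    """
    if direction not in ("lowest", "highest"):
        raise ValueError("direction must be 'lowest' or 'highest'")
    out = set()
    for eq in equations:
        if not eq.retained:
            continue
        betas = dict(eq.retained)

        def value(s: int, f: int, g: int) -> float:
            x = term_values(strain=s, fe=f, glc=g)
            return sum(b * x[t] for t, b in betas.items())

        ok = True
        for s in (1, -1):
            target = value(s, fe, glc)
            others = [value(s, f, g) for f in (1, -1) for g in (1, -1)
                      if (f, g) != (fe, glc)]
            if direction == "lowest" and not all(target < v for v in others):
                ok = False
            if direction == "highest" and not all(target > v for v in others):
                ok = False
            if not ok:
                break
        if ok:
            out.add(eq.protein_id)
    return out


def extreme_condition_test(
    matrix: AbundanceMatrix,
    targets: Sequence[Condition],
    direction: str,
    config: PipelineConfig | None = None,
    equation_predicted: Iterable[str] = (),
    bh_family: str = "rank_passing",
) -> pd.DataFrame:
    """Rank / gap / max-p enrichment statistic for one (targets, direction).

    ``matrix`` should be imputed so all conditions have means. Returns one
    row per protein with the rank-filter outcome, gap, max pairwise Welch
    p, its BH adjustment, the assigned tier (stringent / expanded / none),
    the provenance of expanded membership, and volcano coordinates
    (x = -log10 max p, y = signed gap).
    """
    if direction not in ("lowest", "highest"):
        raise ValueError("direction must be 'lowest' or 'highest'")
    if not 1 <= len(targets) <= 2:
        raise ValueError("targets must contain 1 or 2 conditions")
    if bh_family not in ("rank_passing", "all"):
        raise ValueError("bh_family must be 'rank_passing' or 'all'")
    config = config or PipelineConfig()
    equation_predicted = set(equation_predicted)

    matrix = matrix.drop_excluded()
    by_cond = matrix.samples_by_condition()
    missing_targets = [t.label for t in targets if t not in by_cond]
    if missing_targets:
        raise ValueError(f"target condition(s) absent from matrix: {missing_targets}")
    target_labels = [t.label for t in targets]
    other_conds = [c for c in matrix.conditions if c not in set(targets)]

    _, log2m = condition_means(matrix)
    tmeans = log2m[target_labels]
    omeans = log2m[[c.label for c in other_conds]]

    # strict rank filter + gap, vectorized over proteins; exact ties (e.g.
    # from shared imputed values) fail the strict-extreme rule
    if direction == "lowest":
        rank_pass = tmeans.max(axis=1) < omeans.min(axis=1)
        gap = omeans.min(axis=1) - tmeans.max(axis=1)
    else:
        rank_pass = tmeans.min(axis=1) > omeans.max(axis=1)
        gap = tmeans.min(axis=1) - omeans.max(axis=1)
    rank_pass &= log2m.notna().all(axis=1)
    gap = gap.where(rank_pass)

    target_cols = [sid for t in targets for sid in by_cond[t]]
    log2v = matrix.log2_values

    max_p = pd.Series(np.nan, index=matrix.protein_ids)
    compute_for = matrix.protein_ids if bh_family == "all" else matrix.protein_ids[rank_pass]
    for pid in compute_for:
        tvals = log2v.loc[pid, target_cols].to_numpy(float)
        worst = 0.0
        for cond in other_conds:
            ovals = log2v.loc[pid, by_cond[cond]].to_numpy(float)
            if np.isfinite(tvals).sum() < 2 and np.isfinite(ovals).sum() < 2:
                # neither group offers a variance estimate: no evidence
                p = 1.0
            else:
                _, _, p = welch_t(tvals, ovals)
            worst = max(worst, p)
        max_p[pid] = worst

    adj = pd.Series(np.nan, index=matrix.protein_ids)
    family = max_p.dropna()
    if len(family):
        _, adj_vals, _, _ = multipletests(family.to_numpy(float),
                                          alpha=config.fdr_level, method="fdr_bh")
        adj[family.index] = adj_vals

    fdr_pass = rank_pass & (adj <= config.fdr_level)
    stringent = fdr_pass & (gap > config.fc_cutoff)
    eq_mask = matrix.protein_ids.isin(sorted(equation_predicted))
    expanded = stringent | fdr_pass | pd.Series(eq_mask, index=matrix.protein_ids)

    tier = pd.Series("none", index=matrix.protein_ids)
    tier[expanded] = "expanded"
    tier[stringent] = "stringent"

    sources = []
    for pid in matrix.protein_ids:
        tags = []
        if bool(stringent[pid]):
            tags.append("rank_fdr_fc")
        elif bool(fdr_pass[pid]):
            tags.append("rank_fdr")
        if pid in equation_predicted:
            tags.append("equation")
        sources.append("+".join(tags))

    analysis = "TAG" if len(targets) == 2 else "heterotrophy"
    sign = -1.0 if direction == "lowest" else 1.0
    with np.errstate(divide="ignore"):
        volcano_x = -np.log10(max_p)
    return pd.DataFrame({
        "protein_id": matrix.protein_ids,
        "analysis": analysis,
        "direction": direction,
        "rank_pass": rank_pass.to_numpy(),
        "gap": gap.to_numpy(float),
        "max_p": max_p.to_numpy(float),
        "adj_max_p": adj.to_numpy(float),
        "tier": tier.to_numpy(),
        "sources": sources,
        "volcano_x": volcano_x.to_numpy(float),
        "volcano_y": sign * gap.to_numpy(float),
    })
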