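"""Per-protein full-factorial modeling and equation simplification.

Each protein's log2 abundance is fit by ordinary least squares to

    log2(abundance) = alpha + b1*Fe + b2*Glc + b3*strain + b4*Fe:Glc
                      + b5*strain:Glc + b6*strain:Fe + b7*strain:Fe:Glc

with +Fe/+Glc/WT coded +1 and -Fe/-Glc/hxk1-2 coded -1 (hxk1-1 is excluded
from classification). Fitted equations are then simplified in three steps:
(1) terms failing a Benjamini-Hochberg FDR cut are dropped; (2) if every
surviving coefficient is below the effect floor (0.25 log2 by default) the
protein gets no terms; (3) coefficients are ordered by magnitude and all
terms after the first >=4x dominance break are truncated. Proteins sharing
a signed retained-term pattern form a subgroup; subgroups whose mean scaled
abundance profiles correlate at Pearson r > 0.9 are merged iteratively.

Note on scale: with +/-1 coding, a between-level condition difference
equals 2*beta; all thresholds here apply to beta as fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    AbundanceMatrix,
    Condition,
    MODEL_STRAINS,
    PipelineConfig,
    SampleRecord,
    condition_means,
)

#: The seven non-intercept model terms, in canonical order.
TERMS = ("Fe", "Glc", "strain", "Fe:Glc", "strain:Glc", "strain:Fe", "strain:Fe:Glc")

#: Reduced model used for the WT-train / hxk1-2-test cross-validation.
REDUCED_TERMS = ("Fe", "Glc", "Fe:Glc")

_ZERO_VAR_TOL = 1e-18
_ZERO_BETA_TOL = 1e-9


def term_values(strain: int, fe: int, glc: int) -> dict[str, float]:
    """Values of the seven +/-1-coded terms at one design point."""
    return {
        "Fe": fe,
        "Glc": glc,
        "strain": strain,
        "Fe:Glc": fe * glc,
        "strain:Glc": strain * glc,
        "strain:Fe": strain * fe,
        "strain:Fe:Glc": strain * fe * glc,
    }


def strain_code(strain: str) -> int:
    return 1 if strain == "WT" else -1


@dataclass
class FactorialFit:
    """OLS fit of the full factorial model for one protein."""

    protein_id: str
    alpha: float
    betas: dict[str, float]
    term_p: dict[str, float]
    residuals: pd.Series
    r_squared: float
    df_resid: int


@dataclass(frozen=True)
class SimplifiedEquation:
    """Pruned dominant-term description of one protein's response."""

    protein_id: str
    #: (term, signed beta) sorted by |beta| descending.
    retained: tuple[tuple[str, float], ...]
    #: canonical signed string, e.g. "+Fe+Glc+Fe:Glc"; "none" when empty.
    label: str
    #: unordered term set (the equation group).
    group_key: frozenset[str]
    #: term set with signs in canonical term order (the subgroup).
    subgroup_key: tuple[tuple[str, int], ...]

    @property
    def terms(self) -> frozenset[str]:
        return self.group_key

    def is_strain_independent(self) -> bool:
        return not any("strain" in t for t in self.group_key)


@dataclass
class EquationGroup:
    """A subgroup of proteins sharing a signed dominant-term pattern."""

    label: str
    subgroup_key: tuple[tuple[str, int], ...]
    members: list[str]
    #: per-condition mean of per-protein condition-centered log2 means.
    profile: pd.Series

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# design and OLS
# ---------------------------------------------------------------------------

def build_design(samples: Sequence[SampleRecord],
                 terms: Sequence[str] = TERMS) -> pd.DataFrame:
    """Design matrix (intercept + terms) for WT / hxk1-2 samples.

    Interaction columns are elementwise products of the main-effect columns,
    so a balanced 2x2x2 design has mutually orthogonal columns.
    """
    bad = sorted({s.strain for s in samples} - set(MODEL_STRAINS))
    if bad:
        raise ValueError(f"design restricted to {MODEL_STRAINS}; got strain(s) {bad}")
    if any(s.excluded for s in samples):
        raise ValueError("excluded samples must not enter the design")
    rows = []
    for s in samples:
        x = term_values(strain_code(s.strain), s.fe, s.glc)
        rows.append([1.0] + [x[t] for t in terms])
    design = pd.DataFrame(rows, index=[s.sample_id for s in samples],
                          columns=["intercept", *terms])
    if tuple(terms) == TERMS:
        cells = {(s.strain, s.fe, s.glc) for s in samples}
        missing = [
            Condition(st, fe, glc).label
            for st in MODEL_STRAINS for fe in (1, -1) for glc in (1, -1)
            if (st, fe, glc) not in cells
        ]
        if missing:
            raise ValueError(f"empty design cell(s): {missing}")
    return design


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int, float]:
    """Closed-form OLS: coefficients, p-values, sigma2, df, R^2.

    Degenerate rule: with zero residual variance, p = 0 for coefficients
    with |beta| > 1e-9 and 1 otherwise, which keeps noiseless fixtures
    well-defined.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more than {k} samples, got {n}")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular design matrix") from err
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    df = n - k
    sigma2 = ssr / df
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    if sigma2 < _ZERO_VAR_TOL:
        p = np.where(np.abs(beta) > _ZERO_BETA_TOL, 0.0, 1.0)
    else:
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, p, sigma2, df, r2


def fit_full_model(y: pd.Series, design: pd.DataFrame,
                   protein_id: str = "") -> FactorialFit:
    """OLS fit of one protein; NaN observations are dropped."""
    y = y.reindex(design.index)
    mask = y.notna().to_numpy()
    X = design.to_numpy(float)[mask]
    yv = y.to_numpy(float)[mask]
    beta, p, _, df, r2 = _ols(yv, X)
    terms = list(design.columns[1:])
    fitted = X @ beta
    residuals = pd.Series(yv - fitted, index=design.index[mask])
    return FactorialFit(
        protein_id=protein_id,
        alpha=float(beta[0]),
        betas={t: float(b) for t, b in zip(terms, beta[1:])},
        term_p={t: float(v) for t, v in zip(terms, p[1:])},
        residuals=residuals,
        r_squared=r2,
        df_resid=df,
    )


def fit_proteome(matrix: AbundanceMatrix,
                 strains: Sequence[str] = MODEL_STRAINS) -> list[FactorialFit]:
    """Fit the full model to every protein, on log2 abundances.

    Only samples from ``strains`` enter the design; proteins are fit on
    their detected (or imputed) samples, so per-protein designs may be
    mildly unbalanced when cells are missing.
    """
    matrix = matrix.drop_excluded()
    model_samples = [s for s in matrix.samples if s.strain in strains]
    design = build_design(model_samples)
    log2 = matrix.log2_values[[s.sample_id for s in model_samples]]
    return [
        fit_full_model(log2.loc[pid], design, protein_id=pid)
        for pid in matrix.protein_ids
    ]


# ---------------------------------------------------------------------------
# FDR and simplification
# ---------------------------------------------------------------------------

def adjust_fdr(
    pvalues: pd.DataFrame,
    level: float = 0.05,
    family: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benjamini-Hochberg step-up over model-term p-values.

    ``pvalues`` is proteins x terms. With ``family="pooled"`` (default) the
    BH family is all proteins x all terms at once — the most conservative
    single-family reading; ``"per_term"`` adjusts each term column
    separately. Returns (adjusted p, significance mask) with the input's
    shape.
    """
    if family == "pooled":
        flat = pvalues.to_numpy(float).ravel()
        reject, adj, _, _ = multipletests(flat, alpha=level, method="fdr_bh")
        shape = pvalues.shape
        return (
            pd.DataFrame(adj.reshape(shape), index=pvalues.index, columns=pvalues.columns),
            pd.DataFrame(reject.reshape(shape), index=pvalues.index, columns=pvalues.columns),
        )
    if family == "per_term":
        adj = {}
        rej = {}
        for col in pvalues.columns:
            r, a, _, _ = multipletests(pvalues[col].to_numpy(float),
                                       alpha=level, method="fdr_bh")
            adj[col], rej[col] = a, r
        return (pd.DataFrame(adj, index=pvalues.index),
                pd.DataFrame(rej, index=pvalues.index))
    raise ValueError("family must be 'pooled' or 'per_term'")


def _canonical_label(signed: Mapping[str, int]) -> str:
    if not signed:
        return "none"
    return "".join(
        f"{'+' if signed[t] > 0 else '-'}{t}" for t in TERMS if t in signed
    )


def simplify_equation(
    fit: FactorialFit,
    significant_terms: Sequence[str],
    config: PipelineConfig | None = None,
) -> SimplifiedEquation:
    """Prune a fit to its dominant terms.

    Applied in order: drop non-FDR-significant terms; if every survivor has
    |beta| below the effect floor, retain nothing; otherwise sort survivors
    by |beta| descending (canonical term order breaks exact ties) and
    truncate immediately after the first position whose coefficient is at
    least ``dominance_ratio`` times the next one.
    """
    config = config or PipelineConfig()
    survivors = [t for t in TERMS if t in set(significant_terms)]
    retained: list[str] = []
    if survivors and any(abs(fit.betas[t]) >= config.effect_floor for t in survivors):
        ordered = sorted(survivors, key=lambda t: (-abs(fit.betas[t]), TERMS.index(t)))
        retained = [ordered[0]]
        for nxt in ordered[1:]:
            if abs(fit.betas[retained[-1]]) >= config.dominance_ratio * abs(fit.betas[nxt]):
                break
            retained.append(nxt)
    signed = {t: (1 if fit.betas[t] > 0 else -1) for t in retained}
    return SimplifiedEquation(
        protein_id=fit.protein_id,
        retained=tuple((t, fit.betas[t]) for t in retained),
        label=_canonical_label(signed),
        group_key=frozenset(retained),
        subgroup_key=tuple((t, signed[t]) for t in TERMS if t in signed),
    )


def simplify_proteome(
    fits: Sequence[FactorialFit],
    config: PipelineConfig | None = None,
) -> tuple[list[SimplifiedEquation], pd.DataFrame]:
    """FDR-adjust all fits jointly, then simplify each equation.

    Returns the simplified equations plus the adjusted p-value table.
    """
    config = config or PipelineConfig()
    pvals = pd.DataFrame(
        [[f.term_p[t] for t in TERMS] for f in fits],
        index=[f.protein_id for f in fits],
        columns=list(TERMS),
    )
    adj, mask = adjust_fdr(pvals, level=config.fdr_level, family=config.bh_family)
    equations = [
        simplify_equation(f, [t for t in TERMS if mask.loc[f.protein_id, t]], config)
        for f in fits
    ]
    return equations, adj


# ---------------------------------------------------------------------------
# subgroups and merging
# ---------------------------------------------------------------------------

def scaled_profiles(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-protein condition-centered log2 condition means (proteins x conditions)."""
    _, log2m = condition_means(matrix)
    return log2m.sub(log2m.mean(axis=1), axis=0)


def assign_subgroups(
    equations: Sequence[SimplifiedEquation],
    matrix: AbundanceMatrix,
) -> list[EquationGroup]:
    """Partition proteins into signed-term subgroups with mean scaled profiles.

    Every protein lands in exactly one subgroup, including the "none"
    subgroup of proteins with no significant dominant term.
    """
    profiles = scaled_profiles(matrix)
    by_label: dict[str, list[SimplifiedEquation]] = {}
    for eq in equations:
        by_label.setdefault(eq.label, []).append(eq)
    groups = []
    for label in sorted(by_label):
        eqs = by_label[label]
        members = [e.protein_id for e in eqs]
        groups.append(
            EquationGroup(
                label=label,
                subgroup_key=eqs[0].subgroup_key,
                members=members,
                profile=profiles.loc[members].mean(axis=0),
            )
        )
    return groups


def merge_groups(
    groups: Sequence[EquationGroup],
    r_threshold: float = 0.9,
) -> list[EquationGroup]:
    """Iteratively merge subgroups whose mean profiles correlate above r_threshold.

    Greedy: the highest-correlated pair above the threshold merges first,
    the merged profile is recomputed as the member-weighted mean, and the
    merged subgroup takes the larger member's name (ties break to the
    lexicographically smaller label). Zero-variance profiles are excluded
    from merging with a warning. Terminates in at most n-1 merges and never
    increases the group count.
    """
    active = [EquationGroup(g.label, g.subgroup_key, list(g.members), g.profile.copy())
              for g in groups]
    frozen = [g for g in active if g.profile.std(ddof=0) < 1e-12]
    if frozen:
        warnings.warn(
            f"{len(frozen)} subgroup profile(s) with zero variance excluded "
            f"from merging: {[g.label for g in frozen]}",
            stacklevel=2,
        )
    active = [g for g in active if g.profile.std(ddof=0) >= 1e-12]

    while len(active) > 1:
        prof = np.vstack([g.profile.to_numpy(float) for g in active])
        corr = np.corrcoef(prof)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(int(np.argmax(corr)), corr.shape)
        if corr[i, j] <= r_threshold:
            break
        gi, gj = active[i], active[j]
        if gj.size > gi.size or (gj.size == gi.size and gj.label < gi.label):
            gi, gj = gj, gi
        merged = EquationGroup(
            label=gi.label,
            subgroup_key=gi.subgroup_key,
            members=gi.members + gj.members,
            profile=(gi.profile * gi.size + gj.profile * gj.size) / (gi.size + gj.size),
        )
        active = [g for k, g in enumerate(active) if k not in (i, j)] + [merged]

    out = active + frozen
    return sorted(out, key=lambda g: (-g.size, g.label))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate_reduced(
    matrix: AbundanceMatrix,
    full_equations: Sequence[SimplifiedEquation],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """WT-train / hxk1-2-test check of the simplification pipeline.

    A reduced ``Fe + Glc + Fe:Glc`` model is fit per protein on WT samples
    only and simplified with the same FDR / effect-floor / dominance steps.
    Residuals of the simplified prediction are evaluated on WT (train) and
    hxk1-2 (test) samples, and the fractions within 0.5 and 1.0 log2 are
    reported, stratified by whether the full model labeled the protein
    strain-independent.
    """
    config = config or PipelineConfig()
    matrix = matrix.drop_excluded()
    wt = [s for s in matrix.samples if s.strain == "WT"]
    test = [s for s in matrix.samples if s.strain == "hxk1-2"]
    if not wt or not test:
        raise ValueError("cross-validation needs both WT and hxk1-2 samples")
    design = build_design(wt, terms=REDUCED_TERMS)
    log2 = matrix.log2_values
    strain_indep = {e.protein_id: e.is_strain_independent() for e in full_equations}

    fits = [
        fit_full_model(log2.loc[pid, design.index], design, protein_id=pid)
        for pid in matrix.protein_ids
    ]
    pvals = pd.DataFrame(
        [[f.term_p[t] for t in REDUCED_TERMS] for f in fits],
        index=[f.protein_id for f in fits], columns=list(REDUCED_TERMS),
    )
    _, mask = adjust_fdr(pvals, level=config.fdr_level, family=config.bh_family)

    rows = []
    for fit in fits:
        pid = fit.protein_id
        sig = [t for t in REDUCED_TERMS if mask.loc[pid, t]]
        survivors = sig if any(abs(fit.betas[t]) >= config.effect_floor for t in sig) else []
        if survivors:
            ordered = sorted(survivors, key=lambda t: -abs(fit.betas[t]))
            kept = [ordered[0]]
            for nxt in ordered[1:]:
                if abs(fit.betas[kept[-1]]) >= config.dominance_ratio * abs(fit.betas[nxt]):
                    break
                kept.append(nxt)
        else:
            kept = []

        def predict(sample: SampleRecord) -> float:
            x = term_values(strain_code(sample.strain), sample.fe, sample.glc)
            return fit.alpha + sum(fit.betas[t] * x[t] for t in kept)

        row = {"protein_id": pid, "strain_independent": strain_indep.get(pid, True),
               "n_terms": len(kept)}
        for name, group in (("train", wt), ("test", test)):
            resid = np.array([
                log2.loc[pid, s.sample_id] - predict(s)
                for s in group
                if np.isfinite(log2.loc[pid, s.sample_id])
            ])
            row[f"{name}_frac_lt_0.5"] = float(np.mean(np.abs(resid) < 0.5)) if resid.size else np.nan
            row[f"{name}_frac_lt_1.0"] = float(np.mean(np.abs(resid) < 1.0)) if resid.size else np.nan
        rows.append(row)

    report = pd.DataFrame(rows)
    summary: dict = {}
    for indep, grp in report.groupby("strain_independent"):
        key = "strain_independent" if indep else "strain_dependent"
        summary[key] = {
            col: float(grp[col].mean())
            for col in ("train_frac_lt_0.5", "train_frac_lt_1.0",
                        "test_frac_lt_0.5", "test_frac_lt_1.0")
        }
    return report, summary


def equations_table(equations: Sequence[SimplifiedEquation]) -> pd.DataFrame:
    rows = []
    for eq in equations:
        rows.append({
            "protein_id": eq.protein_id,
            "label": eq.label,
            "n_terms": len(eq.retained),
            "terms": ",".join(t for t, _ in eq.retained),
            "betas": ",".join(f"{b:.6g}" for _, b in eq.retained),
        })
    return pd.DataFrame(rows)


def fits_table(fits: Sequence[FactorialFit], adjusted: pd.DataFrame | None = None) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {"protein_id": f.protein_id, "alpha": f.alpha, "r_squared": f.r_squared}
        for t in TERMS:
            row[f"beta_{t}"] = f.betas[t]
            row[f"p_{t}"] = f.term_p[t]
            if adjusted is not None:
                row[f"adj_p_{t}"] = adjusted.loc[f.protein_id, t]
        rows.append(row)
    return pd.DataFrame(rows)
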