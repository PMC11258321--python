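"""Synthetic factorial proteomes with known ground truth.

The generator mirrors the per-protein generative model the analysis fits:
log2 abundance = alpha + sum_t beta_t * x_t + N(0, noise_sd), where x_t are
the +/-1-coded main effects and their products (Fe, Glc, strain, Fe:Glc,
strain:Glc, strain:Fe, strain:Fe:Glc; hxk1 strains share the -1 strain
coding). Linear-scale values are exported. Non-detection is
intensity-dependent: each cell is independently missing with probability
logistic((detection_midpoint - log2 value) * detection_slope), which mimics
the drop-out of the least abundant treatments; a missing-completely-at-
random mode is available for null experiments.

Ground-truth classes (lowest/highest-in-heterotrophy, TAG up/down) are
assigned from the analytic extremum of the noiseless model over the 8
modeled design corners, so downstream recovery is well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    AbundanceMatrix,
    AnnotationSet,
    OrthologMap,
    SampleRecord,
    STRAINS,
    canonical_conditions,
)
from .factorial import TERMS, term_values

PLANTED_CLASSES = ("null", "lowest_in_het", "highest_in_het", "tag_high", "tag_low", "other")

#: Design corners of the modeled 2x2x2 design as (strain, fe, glc) codes.
_CORNERS = [(s, f, g) for s in (1, -1) for f in (1, -1) for g in (-1, 1)]
_HET_CORNER = (1, -1, 1)          # WT -Fe +Glc
_TAG_CORNERS = {(1, -1, 1), (1, 1, 1)}   # WT +Glc, either Fe


@dataclass(frozen=True)
class TruthRecord:
    """Generative truth for one synthetic protein."""

    protein_id: str
    alpha: float
    betas: Mapping[str, float]
    noise_sd: float
    planted_class: str

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(t for t, b in self.betas.items() if b != 0.0)


@dataclass
class SimulationParams:
    """Study conditions of the synthetic factorial proteome.

    Defaults emulate the published experiment's shape: 12 conditions
    (3 strains x 2 Fe x 2 Glc) x 4 replicates, Gaussian replicate noise of
    0.25 on the log2 scale, and effect magnitude 1 log2 unit per nonzero
    term for both generic non-null proteins and planted extreme-condition
    classes (putting a planted heterotrophy corner 2 log2 units beyond the
    rest of the landscape).
    """

    n_proteins: int = 1000
    n_replicates: int = 4
    strains: Sequence[str] = STRAINS
    noise_sd: float = 0.25
    effect_size: float = 1.0
    fraction_null: float = 0.6
    fraction_lowest_het: float = 0.0
    fraction_highest_het: float = 0.0
    fraction_tag_high: float = 0.0
    fraction_tag_low: float = 0.0
    #: per-term magnitude of planted-class coefficients (log2 units).
    het_effect: float = 1.0
    alpha_mean: float = 10.0
    alpha_sd: float = 1.5
    detection_midpoint: float | None = 6.0
    detection_slope: float = 1.0
    mcar_rate: float = 0.0
    peptide_lambda: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_null <= 1:
            raise ValueError("fraction_null must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        planted = (self.fraction_lowest_het + self.fraction_highest_het
                   + self.fraction_tag_high + self.fraction_tag_low)
        if planted > 1:
            raise ValueError("planted class fractions exceed 1")


def corner_values(betas: Mapping[str, float]) -> dict[tuple[int, int, int], float]:
    """Noiseless model value (minus alpha) at each of the 8 design corners."""
    out = {}
    for s, f, g in _CORNERS:
        x = term_values(strain=s, fe=f, glc=g)
        out[(s, f, g)] = sum(betas.get(t, 0.0) * x[t] for t in TERMS)
    return out


def classify_truth(betas: Mapping[str, float]) -> str:
    """Planted class from the analytic extremum over the 8 modeled corners."""
    if all(b == 0.0 for b in betas.values()):
        return "null"
    vals = corner_values(betas)
    het = vals[_HET_CORNER]
    others = [v for c, v in vals.items() if c != _HET_CORNER]
    if all(het < v for v in others):
        return "lowest_in_het"
    if all(het > v for v in others):
        return "highest_in_het"
    tag = [v for c, v in vals.items() if c in _TAG_CORNERS]
    rest = [v for c, v in vals.items() if c not in _TAG_CORNERS]
    if max(tag) < min(rest):
        return "tag_low"
    if min(tag) > max(rest):
        return "tag_high"
    return "other"


def _planted_betas(cls: str, m: float) -> dict[str, float]:
    """Three-term sign patterns placing the class's target corner(s) at the extreme.

    Heterotrophy classes use additive strain/Fe/Glc effects of magnitude
    ``m`` whose signs put the WT-Fe+Glc corner 2m log2 units beyond every
    other corner; TAG classes use strain/Glc/strain:Glc so both WT+Glc
    corners tie at the extreme, 4m beyond the rest. Every nonzero true
    coefficient has magnitude ``m``.
    """
    betas = dict.fromkeys(TERMS, 0.0)
    if cls in ("lowest_in_het", "highest_in_het"):
        sign = -1.0 if cls == "lowest_in_het" else 1.0
        betas["strain"] = sign * m      # extreme in WT (strain = +1)
        betas["Fe"] = -sign * m         # extreme at -Fe
        betas["Glc"] = sign * m         # extreme at +Glc
    else:
        sign = 1.0 if cls == "tag_high" else -1.0
        betas["strain"] = sign * m
        betas["Glc"] = sign * m
        betas["strain:Glc"] = sign * m  # WT+Glc face, Fe-independent
    return betas


def _draw_betas(rng: np.random.Generator, cls: str, params: SimulationParams) -> dict[str, float]:
    if cls == "null":
        return dict.fromkeys(TERMS, 0.0)
    if cls in ("lowest_in_het", "highest_in_het", "tag_high", "tag_low"):
        return _planted_betas(cls, params.het_effect)
    # generic effect protein: 1-3 terms of fixed magnitude, random sign
    k = int(rng.integers(1, 4))
    chosen = rng.choice(len(TERMS), size=k, replace=False)
    betas = dict.fromkeys(TERMS, 0.0)
    for i in chosen:
        betas[TERMS[i]] = params.effect_size * (1.0 if rng.random() < 0.5 else -1.0)
    return betas


def simulate_factorial_proteome(
    params: SimulationParams,
) -> tuple[AbundanceMatrix, list[TruthRecord]]:
    """Generate an abundance matrix plus per-protein ground truth."""
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_proteins

    counts = {
        "lowest_in_het": int(round(params.fraction_lowest_het * n)),
        "highest_in_het": int(round(params.fraction_highest_het * n)),
        "tag_high": int(round(params.fraction_tag_high * n)),
        "tag_low": int(round(params.fraction_tag_low * n)),
    }
    n_planted = sum(counts.values())
    n_null = int(round(params.fraction_null * (n - n_planted)))
    classes = (
        ["lowest_in_het"] * counts["lowest_in_het"]
        + ["highest_in_het"] * counts["highest_in_het"]
        + ["tag_high"] * counts["tag_high"]
        + ["tag_low"] * counts["tag_low"]
        + ["null"] * n_null
        + ["generic"] * (n - n_planted - n_null)
    )
    rng.shuffle(classes)

    samples = []
    for cond in canonical_conditions(tuple(params.strains)):
        for rep in range(1, params.n_replicates + 1):
            samples.append(
                SampleRecord(f"{cond.label}_r{rep}", cond.strain, cond.fe,
                             cond.glc, rep, batch="sim")
            )
    design = np.array(
        [
            [term_values(strain=1 if s.strain == "WT" else -1, fe=s.fe, glc=s.glc)[t]
             for t in TERMS]
            for s in samples
        ],
        dtype=float,
    )  # n_samples x 7

    alphas = rng.normal(params.alpha_mean, params.alpha_sd, size=n)
    beta_rows = np.empty((n, len(TERMS)))
    truths: list[TruthRecord] = []
    protein_ids = [f"P{i:05d}" for i in range(n)]
    for i, cls in enumerate(classes):
        betas = _draw_betas(rng, cls, params)
        beta_rows[i] = [betas[t] for t in TERMS]
        truths.append(
            TruthRecord(protein_ids[i], float(alphas[i]), betas,
                        params.noise_sd, classify_truth(betas))
        )

    log2 = alphas[:, None] + beta_rows @ design.T
    if params.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, params.noise_sd, size=log2.shape)
    values = np.power(2.0, log2)

    if params.detection_midpoint is not None and params.detection_slope > 0:
        p_miss = expit((params.detection_midpoint - log2) * params.detection_slope)
        values[rng.random(size=values.shape) < p_miss] = np.nan
    if params.mcar_rate > 0:
        values[rng.random(size=values.shape) < params.mcar_rate] = np.nan

    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} simulated protein(s) are missing in every "
            "sample; filter them before imputation",
            stacklevel=2,
        )

    peptides = rng.poisson(params.peptide_lambda, size=n) + 1
    matrix = AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                     columns=[s.sample_id for s in samples]),
        samples,
        pd.Series(peptides, index=pd.Index(protein_ids, name="protein_id")),
    )
    return matrix, truths


def truth_table(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Flatten TruthRecords into a TSV-friendly table."""
    rows = []
    for t in truths:
        row = {"protein_id": t.protein_id, "alpha": t.alpha,
               "noise_sd": t.noise_sd, "planted_class": t.planted_class}
        for term in TERMS:
            row[f"beta_{term}"] = t.betas[term]
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_annotation_universe(
    n_groups: int,
    planted: tuple[int, int, int],
    rng_seed: int = 0,
) -> tuple[OrthologMap, OrthologMap, AnnotationSet, AnnotationSet]:
    """Two species' gene lists with an exactly planted ortholog-group overlap.

    ``planted`` is (query set size, comparison set size, overlap size) in
    ortholog-group units. Every group has one gene in each species, so the
    shared-group universe equals all ``n_groups`` groups and the planted
    counts are recovered exactly by the overlap counter.
    """
    q_size, c_size, overlap = planted
    if overlap > min(q_size, c_size):
        raise ValueError("overlap cannot exceed either set size")
    if max(q_size, c_size) > n_groups or q_size + c_size - overlap > n_groups:
        raise ValueError("planted counts infeasible for universe size")
    rng = np.random.default_rng(rng_seed)
    groups = [f"OG{i:05d}" for i in range(n_groups)]
    order = rng.permutation(n_groups)
    shared = [groups[i] for i in order[:overlap]]
    q_only = [groups[i] for i in order[overlap: q_size]]
    c_only = [groups[i] for i in order[q_size: q_size + (c_size - overlap)]]

    map_a = OrthologMap("speciesA", {f"A_{g}": g for g in groups})
    map_b = OrthologMap("speciesB", {f"B_{g}": g for g in groups})
    query = AnnotationSet.from_members(
        "query", [f"A_{g}" for g in shared + q_only], "planted query genes")
    comparison = AnnotationSet.from_members(
        "comparison", [f"B_{g}" for g in shared + c_only], "planted comparison genes")
    return map_a, map_b, query, comparison


def simulate_cell_sizes(
    n_cells: int, diameter_mean: float, diameter_sd: float, rng_seed: int = 0
) -> np.ndarray:
    """Cell diameters (um) from a normal truncated at zero."""
    if diameter_mean <= 0:
        raise ValueError("diameter_mean must be > 0")
    rng = np.random.default_rng(rng_seed)
    if n_cells == 0:
        return np.empty(0)
    out = rng.normal(diameter_mean, diameter_sd, size=n_cells)
    while True:  # rejection sampling keeps the distribution truncated, not clipped
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(diameter_mean, diameter_sd, size=int(bad.sum()))
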