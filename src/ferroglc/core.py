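"""Core domain types for the factorial proteomics pipeline.

The experiment crossed three factors — iron supplementation (+Fe/-Fe),
exogenous glucose (+Glc/-Glc), and genotype (wild type vs. two hexokinase
knock-down strains) — giving 12 culture conditions with 3-4 biological
replicates each, quantified by isobaric-label proteomics. Everything
downstream operates on a protein x sample abundance table on the linear
scale with an explicit missing marker, plus per-sample factor levels.

Conventions fixed here and relied on throughout:

* Factor levels are coded as signed units: ``+Fe``/``+Glc``/``WT`` are +1,
  ``-Fe``/``-Glc``/``hxk1`` strains are -1.
* Missing abundances are NaN, never zero; all present values are strictly
  positive so log2 is defined.
* The canonical condition order is (strain: WT, hxk1-1, hxk1-2) x
  (Fe: +, -) x (Glc: -, +); rank-based statistics iterate conditions in
  this order so tie handling is reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

STRAINS = ("WT", "hxk1-1", "hxk1-2")
#: Strains entering the 2x2x2 linear-model design (hxk1-1 is excluded from
#: classification but kept for enrichment statistics).
MODEL_STRAINS = ("WT", "hxk1-2")

_SIGN = {1: "+", -1: "-"}


def _check_level(value: int, name: str) -> int:
    value = int(value)
    if value not in (1, -1):
        raise ValueError(f"{name} level must be +1 or -1, got {value!r}")
    return value


@dataclass(frozen=True)
class Condition:
    """One cell of the full design: a (strain, Fe, Glc) combination."""

    strain: str
    fe: int
    glc: int

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        object.__setattr__(self, "fe", _check_level(self.fe, "fe"))
        object.__setattr__(self, "glc", _check_level(self.glc, "glc"))

    @property
    def label(self) -> str:
        return f"{self.strain}{_SIGN[self.fe]}Fe{_SIGN[self.glc]}Glc"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def canonical_conditions(strains: Sequence[str] = STRAINS) -> list[Condition]:
    """All conditions for ``strains`` in the fixed canonical order."""
    return [
        Condition(strain, fe, glc)
        for strain in strains
        for fe in (1, -1)
        for glc in (-1, 1)
    ]


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: factor levels, replicate id and exclusion flag."""

    sample_id: str
    strain: str
    fe: int
    glc: int
    replicate: int
    batch: str = ""
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        object.__setattr__(self, "fe", _check_level(self.fe, "fe"))
        object.__setattr__(self, "glc", _check_level(self.glc, "glc"))
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def condition(self) -> Condition:
        return Condition(self.strain, self.fe, self.glc)


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene/protein set (GO term, ETC complex, lipid-droplet list...)."""

    set_id: str
    label: str
    members: frozenset[str]
    scores: Mapping[str, float] | None = None

    @classmethod
    def from_members(
        cls,
        set_id: str,
        members: Iterable[str],
        label: str | None = None,
        scores: Mapping[str, float] | None = None,
    ) -> "AnnotationSet":
        return cls(set_id, label if label is not None else set_id,
                   frozenset(members), scores)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OrthologMap:
    """A species' gene id -> ortholog group id mapping (one group per gene)."""

    species: str
    gene_to_group: Mapping[str, str]

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(self.gene_to_group.values())


@dataclass
class PipelineConfig:
    """Tunable thresholds of the categorization and enrichment pipeline.

    Defaults are the published analysis settings: 5% Benjamini-Hochberg FDR,
    a 0.25 log2 effect floor, a 4x dominance ratio for term truncation, a
    Pearson r > 0.9 subgroup-merge rule, a 0.5 log2 fold-change cutoff for
    the stringent enrichment tier, and a >=2 unique-peptide filter.
    """

    fdr_level: float = 0.05
    effect_floor: float = 0.25
    dominance_ratio: float = 4.0
    merge_correlation: float = 0.9
    fc_cutoff: float = 0.5
    min_unique_peptides: int = 2
    rng_seed: int = 0
    normalization_center: str = "mean"
    #: "pooled" = one BH family across all proteins x terms; "per_term"
    #: adjusts each model term across proteins separately.
    bh_family: str = "pooled"
    #: half-minimum imputation minimum taken over detected condition means
    #: ("condition") or raw replicate values ("replicate").
    impute_minimum: str = "condition"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.dominance_ratio <= 1:
            raise ValueError("dominance_ratio must be > 1")
        if not 0 < self.merge_correlation < 1:
            raise ValueError("merge_correlation must be in (0, 1)")
        if self.normalization_center not in ("mean", "median"):
            raise ValueError("normalization_center must be 'mean' or 'median'")
        if self.bh_family not in ("pooled", "per_term"):
            raise ValueError("bh_family must be 'pooled' or 'per_term'")
        if self.impute_minimum not in ("condition", "replicate"):
            raise ValueError("impute_minimum must be 'condition' or 'replicate'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance table, the pipeline's central container.

    ``values`` is a DataFrame indexed by protein id with one column per
    sample id, holding strictly positive linear-scale abundances and NaN for
    missing cells. ``samples`` lists the metadata records in column order.
    ``imputed_mask`` (protein x condition label, boolean) is set by the
    half-minimum imputation step and is None before it.
    """

    values: pd.DataFrame
    samples: list[SampleRecord]
    unique_peptides: pd.Series
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            raise ValueError("values columns must match sample metadata order")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        keys = {(s.strain, s.fe, s.glc, s.replicate) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("(strain, fe, glc, replicate) must be jointly unique")
        if not self.unique_peptides.index.equals(self.values.index):
            raise ValueError("unique_peptides index must match protein ids")
        bad = (self.values <= 0).any(axis=None)
        if bool(bad):
            prot, samp = np.argwhere(self.values.to_numpy() <= 0)[0]
            raise ValueError(
                "non-positive abundance at protein "
                f"{self.values.index[prot]!r}, sample {self.values.columns[samp]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.values.index)

    @property
    def log2_values(self) -> pd.DataFrame:
        return np.log2(self.values)

    @property
    def conditions(self) -> list[Condition]:
        """Conditions present among (non-excluded) samples, canonical order."""
        present = {s.condition for s in self.samples if not s.excluded}
        strains = [st for st in STRAINS if any(c.strain == st for c in present)]
        return [c for c in canonical_conditions(strains) if c in present]

    def samples_by_condition(self) -> dict[Condition, list[str]]:
        out: dict[Condition, list[str]] = {c: [] for c in self.conditions}
        for s in self.samples:
            if not s.excluded:
                out[s.condition].append(s.sample_id)
        return out

    # -- derived matrices ------------------------------------------------
    def drop_excluded(self) -> "AbundanceMatrix":
        keep = [s for s in self.samples if not s.excluded]
        if len(keep) == len(self.samples):
            return self
        ids = [s.sample_id for s in keep]
        return AbundanceMatrix(self.values[ids].copy(), keep,
                               self.unique_peptides.copy(), self.imputed_mask)

    def subset_proteins(self, protein_ids: Sequence[str]) -> "AbundanceMatrix":
        mask = self.imputed_mask.loc[protein_ids] if self.imputed_mask is not None else None
        return AbundanceMatrix(self.values.loc[protein_ids].copy(), list(self.samples),
                               self.unique_peptides.loc[protein_ids].copy(), mask)

    def replace_values(self, values: pd.DataFrame,
                       imputed_mask: pd.DataFrame | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values, list(self.samples),
                               self.unique_peptides.copy(),
                               imputed_mask if imputed_mask is not None else self.imputed_mask)


def condition_means(matrix: AbundanceMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition replicate means, on the linear scale, and their log2.

    Replicate averaging is done on linear abundances (log2 values are
    de-logged before averaging); log2 is then taken for reporting. A
    condition with no detected replicate is NaN in both outputs.
    """
    matrix = matrix.drop_excluded()
    linear = {}
    for cond, ids in matrix.samples_by_condition().items():
        linear[cond.label] = matrix.values[ids].mean(axis=1, skipna=True)
    lin = pd.DataFrame(linear, index=matrix.protein_ids)
    with np.errstate(invalid="ignore"):
        return lin, np.log2(lin)
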