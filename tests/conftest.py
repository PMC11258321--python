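"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest

from ferroglc.core import (
    AbundanceMatrix,
    PipelineConfig,
    SampleRecord,
    canonical_conditions,
)

_LABEL_RE = re.compile(r"^(WT|hxk1-1|hxk1-2)([+-])Fe([+-])Glc$")


def parse_label(label: str) -> tuple[str, int, int]:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"bad condition label {label!r}")
    strain, fe, glc = m.groups()
    return strain, (1 if fe == "+" else -1), (1 if glc == "+" else -1)


def matrix_from_log2(cond_reps: dict[str, dict[str, list[float]]],
                     peptides: dict[str, int] | None = None) -> AbundanceMatrix:
    """Build an AbundanceMatrix from per-condition log2 replicate values.

    ``cond_reps`` maps protein id -> condition label -> list of log2
    replicate values (None entries become missing cells). Proteins may use
    different replicate counts; shorter lists are NaN-padded.
    """
    labels: list[str] = []
    for per_cond in cond_reps.values():
        for lbl in per_cond:
            if lbl not in labels:
                labels.append(lbl)
    strains_present = {parse_label(lbl)[0] for lbl in labels}
    ordered = [c.label for c in canonical_conditions()
               if c.strain in strains_present and c.label in labels]
    n_rep = {lbl: max(len(per.get(lbl, [])) for per in cond_reps.values())
             for lbl in ordered}

    samples, columns = [], []
    for lbl in ordered:
        strain, fe, glc = parse_label(lbl)
        for r in range(1, n_rep[lbl] + 1):
            sid = f"{lbl}_r{r}"
            samples.append(SampleRecord(sid, strain, fe, glc, r))
            columns.append(sid)

    rows = {}
    for pid, per_cond in cond_reps.items():
        row = []
        for lbl in ordered:
            vals = list(per_cond.get(lbl, []))
            vals += [None] * (n_rep[lbl] - len(vals))
            row.extend(np.nan if v is None else 2.0 ** float(v) for v in vals)
        rows[pid] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    values.index.name = "protein_id"
    pep = pd.Series({pid: (peptides or {}).get(pid, 3) for pid in values.index},
                    index=values.index)
    return AbundanceMatrix(values, samples, pep)


def full_design_log2(fn, strains=("WT", "hxk1-2"), n_replicates=2,
                     noise=None) -> dict[str, list[float]]:
    """Condition-replicate dict for one protein from fn(strain_code, fe, glc)."""
    out = {}
    for c in canonical_conditions(strains):
        base = fn(1 if c.strain == "WT" else -1, c.fe, c.glc)
        reps = [base] * n_replicates
        if noise is not None:
            reps = [b + n for b, n in zip(reps, noise)]
        out[c.label] = reps
    return out


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240718)
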