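"""Fisher-exact overlap machinery: ortholog groups, GO terms, proteome lists.

Cross-species comparisons work in ortholog-group units: a query protein
list is mapped through a species' gene -> group map, deduplicated, and its
overlap with a comparison species' group set is tested against the
hypergeometric null on a shared universe. The default universe is the set
of groups with at least one member in *each* species' map; GO and
proteome-overlap tests reuse the same 2x2 machinery at the protein level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AnnotationSet, OrthologMap

log = logging.getLogger("ferroglc")


@dataclass(frozen=True)
class OverlapTable:
    """2x2 overlap contingency counts with the exact-test result."""

    a: int  # in both lists
    b: int  # query only
    c: int  # comparison only
    d: int  # universe remainder
    odds_ratio: float
    p: float
    alternative: str

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def map_to_groups(genes: Iterable[str], ortholog_map: OrthologMap) -> tuple[set[str], int]:
    """Map gene ids to their ortholog groups, deduplicated.

    Genes without a group are dropped; their count is returned alongside
    the group set.
    """
    groups = set()
    unmapped = 0
    for gene in genes:
        group = ortholog_map.gene_to_group.get(gene)
        if group is None:
            unmapped += 1
        else:
            groups.add(group)
    if unmapped:
        log.info("map_to_groups: %d gene(s) had no ortholog group", unmapped)
    return groups, unmapped


def shared_universe(map_a: OrthologMap, map_b: OrthologMap, mode: str = "shared") -> set[str]:
    """Ortholog-group universe for a two-species overlap test.

    ``"shared"`` (default) = groups with >=1 member in each species;
    ``"either"`` = groups present in either map.
    """
    if mode == "shared":
        return set(map_a.groups & map_b.groups)
    if mode == "either":
        return set(map_a.groups | map_b.groups)
    raise ValueError("mode must be 'shared' or 'either'")


def fisher_overlap(
    query: Iterable[str],
    comparison: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> OverlapTable:
    """Fisher's exact test of the overlap between two sets within a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    comparison = set(comparison)
    if not query <= universe or not comparison <= universe:
        raise ValueError("query and comparison must be subsets of the universe")
    a = len(query & comparison)
    b = len(query - comparison)
    c = len(comparison - query)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return OverlapTable(a, b, c, d, float(odds), float(p), alternative)


def go_enrichment(
    query: Iterable[str],
    go_sets: Mapping[str, AnnotationSet],
    background: Iterable[str],
    fdr: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Classic per-term Fisher GO enrichment over a background universe.

    One independent Fisher test per term with at least one query member
    (no GO-graph decorrelation); raw and BH-adjusted p-values are reported.
    Terms with no member in the background are skipped with a warning.
    """
    background = set(background)
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    rows = []
    for set_id in sorted(go_sets):
        term = go_sets[set_id]
        members = set(term.members) & background
        if not members:
            warnings.warn(f"term {set_id!r} absent from background; skipped",
                          stacklevel=2)
            continue
        if not members & query:
            continue
        table = fisher_overlap(query, members, background, alternative=alternative)
        rows.append({
            "set_id": set_id, "label": term.label,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "odds_ratio": table.odds_ratio, "p": table.p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        reject, adj, _, _ = multipletests(out["p"].to_numpy(float),
                                          alpha=fdr, method="fdr_bh")
        out["adj_p"] = adj
        out["significant"] = reject
    return out


def conservation_tally(
    per_species: Mapping[str, Iterable[str]],
    k: int,
) -> set[str]:
    """Groups qualifying (e.g. photosynthesis-associated) in at least k species."""
    if k > len(per_species):
        return set()
    counts: dict[str, int] = {}
    for groups in per_species.values():
        for g in set(groups):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= k}
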