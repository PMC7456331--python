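"""OTU-overlap (Venn logic) and shared-abundant-OTU screens."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import DesignError, OtuTable, SampleDesign


@dataclass
class OverlapResult:
    """Presence/absence overlap of taxa between factor levels.

    ``regions`` maps each non-empty subset of levels (frozenset) to the
    number of taxa present in exactly those levels, so the exclusive
    regions partition the union.  ``per_level`` gives, per level: total
    observed taxa, taxa unique to the level, and the unique percentage of
    the level's total.
    """

    factor: str
    levels: list[str]
    regions: dict[frozenset, int]
    per_level: pd.DataFrame

    def union_size(self) -> int:
        return sum(self.regions.values())


def otu_overlap(
    table: OtuTable,
    design: SampleDesign,
    factor: str,
    min_prevalence: int = 1,
) -> OverlapResult:
    """Count exclusive and shared taxa across the levels of a factor.

    A taxon is present in a level if it has a positive count in at least
    ``min_prevalence`` samples of that level.  Levels must number 2-4
    (Venn-tractable); beyond that request a presence matrix instead.
    """
    groups = design.groups(factor, sample_ids=table.sample_ids)
    levels = sorted(groups)
    if not 2 <= len(levels) <= 4:
        raise DesignError(
            f"otu_overlap supports 2-4 levels, factor {factor!r} has {len(levels)}"
        )
    col_of = {s: j for j, s in enumerate(table.sample_ids)}
    presence = {}
    for lvl in levels:
        cols = [col_of[s] for s in groups[lvl]]
        n_present = (table.counts[:, cols] > 0).sum(axis=1)
        presence[lvl] = n_present >= min_prevalence
        if not presence[lvl].any():
            warnings.warn(f"level {lvl!r} has no observed taxa")
    membership = np.column_stack([presence[lvl] for lvl in levels])
    regions: dict[frozenset, int] = {}
    for size in range(1, len(levels) + 1):
        for combo in combinations(range(len(levels)), size):
            mask = np.ones(table.n_taxa, dtype=bool)
            for i in range(len(levels)):
                mask &= membership[:, i] if i in combo else ~membership[:, i]
            regions[frozenset(levels[i] for i in combo)] = int(mask.sum())
    rows = []
    for i, lvl in enumerate(levels):
        total = int(membership[:, i].sum())
        unique = regions[frozenset([lvl])]
        rows.append(
            {
                "level": lvl,
                "n_observed": total,
                "n_unique": unique,
                "pct_unique": 100.0 * unique / total if total else 0.0,
            }
        )
    return OverlapResult(factor, levels, regions, pd.DataFrame(rows).set_index("level"))


def shared_abundant_otus(
    table: OtuTable,
    design: SampleDesign,
    type_a: str,
    type_b: str,
    threshold: float = 0.02,
    scope_factors: tuple[str, ...] = ("system", "day"),
    statistic: str = "mean",
) -> pd.DataFrame:
    """Taxa abundant (> ``threshold`` relative abundance) in both sample types.

    Within every scope (by default each system x day), the per-type summary
    relative abundance of each taxon is computed — ``statistic`` "mean"
    averages over samples, "max" takes the single highest sample — and taxa
    exceeding the threshold in *both* types in the *same* scope are listed
    with their qualifying scopes.
    """
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    rel = table.relative_abundances()
    col_of = {s: j for j, s in enumerate(table.sample_ids)}
    types = design.labels("sample_type", sample_ids=table.sample_ids)
    scopes = design.groups(list(scope_factors), sample_ids=table.sample_ids)
    agg = np.mean if statistic == "mean" else np.max
    records = []
    for scope, members in sorted(scopes.items()):
        sa = [col_of[s] for s in members if types[s] == type_a]
        sb = [col_of[s] for s in members if types[s] == type_b]
        if not sa or not sb:
            warnings.warn(f"scope {scope!r} lacks {type_a} or {type_b} samples; skipped")
            continue
        abund_a = agg(rel[:, sa], axis=1)
        abund_b = agg(rel[:, sb], axis=1)
        hits = np.where((abund_a > threshold) & (abund_b > threshold))[0]
        for i in hits:
            records.append(
                {
                    "taxon_id": table.taxon_ids[i],
                    "scope": scope,
                    f"abundance_{type_a}": float(abund_a[i]),
                    f"abundance_{type_b}": float(abund_b[i]),
                }
            )
    return pd.DataFrame(
        records,
        columns=["taxon_id", "scope", f"abundance_{type_a}", f"abundance_{type_b}"],
    )
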