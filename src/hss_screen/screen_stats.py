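"""Grid_n^mut/par enrichment, hit calling, and cross-context overlaps.

The enrichment statistic divides the fraction of a mutant's green-off
(nucleated) cells in a set of orange grids by the parent population's
fraction in the same grids. Hits must clear two thresholds: a significance
threshold (parent center + k*SD over parent isolates' own enrichments,
enabled only when at least two parent isolates exist) and a rank threshold
(the 85th percentile of all mutant enrichments — the top 15%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .events_io import ScreenConfig
from .normalize_gate import GridFractions


@dataclass(frozen=True)
class EnrichmentRecord:
    """One Grid_n^mut/par value for a (strain, context, phenotype).

    ``value`` is NaN and ``defined`` False when the parent fraction in the
    grid set is zero; such records are excluded from ranking rather than
    pseudocounted.
    """

    strain_id: str
    context: str
    phenotype: str
    grid_set: tuple[int, ...]
    value: float
    n_mut_gated: int
    parent_fraction_used: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class HitCall:
    """Hit decision for one strain, with both thresholds recorded.

    ``sig_threshold`` is None when the significance criterion is disabled
    (fewer than two parent isolates). Comparisons are inclusive (>=).
    """

    strain_id: str
    context: str
    phenotype: str
    value: float
    sig_threshold: float | None
    pct_threshold: float
    is_hit: bool


@dataclass(frozen=True)
class OverlapTable:
    """Exclusive set-intersection counts across contexts (upset-plot input)."""

    exclusive_counts: dict[frozenset[str], int]
    per_context_totals: dict[str, int]
    shared_by_multiplicity: dict[int, int]

    @property
    def union_size(self) -> int:
        return sum(self.exclusive_counts.values())


def grid_enrichment(
    mut: GridFractions,
    par: GridFractions,
    grid_set: Sequence[int],
    *,
    context: str = "",
    phenotype: str = "",
) -> EnrichmentRecord:
    """Grid_n^mut/par: summed mutant fraction over summed parent fraction."""
    grid_set = tuple(sorted(grid_set))
    if not grid_set or not set(grid_set) <= {1, 2, 3, 4}:
        raise ValueError(f"grid_set must be a non-empty subset of 1..4: {grid_set}")
    mut_sum = mut.grid_sum(grid_set)
    par_sum = par.grid_sum(grid_set)
    value = mut_sum / par_sum if par_sum > 0 else float("nan")
    return EnrichmentRecord(
        strain_id=mut.strain_id,
        context=context,
        phenotype=phenotype,
        grid_set=grid_set,
        value=value,
        n_mut_gated=mut.n,
        parent_fraction_used=par_sum,
    )


def pooled_parent(parents: Sequence[GridFractions]) -> GridFractions:
    """Cell-count-weighted average of parent fractions (= event pooling)."""
    if not parents:
        raise ValueError("at least one parent required")
    n_total = sum(p.n for p in parents)
    pooled = sum((p.fractions * p.n for p in parents), np.zeros(4)) / n_total
    return GridFractions(
        strain_id="pooled_parent",
        f1=float(pooled[0]),
        f2=float(pooled[1]),
        f3=float(pooled[2]),
        f4=float(pooled[3]),
        n=n_total,
    )


def parent_self_enrichments(
    parents: Sequence[GridFractions],
    grid_set: Sequence[int],
    *,
    context: str = "",
    phenotype: str = "",
) -> list[EnrichmentRecord]:
    """Each parent isolate's enrichment against the pool of the others.

    The leave-one-out denominator makes the parent band reflect
    isolate-to-isolate variation; pooling an isolate with itself would shrink
    it. With a single isolate the self-comparison (value 1) is returned.
    """
    records = []
    for i, par in enumerate(parents):
        others = [p for j, p in enumerate(parents) if j != i]
        denom = pooled_parent(others) if others else par
        records.append(
            grid_enrichment(
                par, denom, grid_set, context=context, phenotype=phenotype
            )
        )
    return records


def call_hits(
    records: Sequence[EnrichmentRecord],
    parent_records: Sequence[EnrichmentRecord],
    config: ScreenConfig,
    *,
    significance_enabled: bool = True,
) -> list[HitCall]:
    """Apply the significance and percentile thresholds to mutant enrichments.

    The percentile threshold is computed over the defined mutant values only
    (linear-interpolation quantile). The significance threshold is the parent
    center (median by default, mean selectable) plus ``k_parent`` times the
    parent SD, and is disabled when fewer than two parent isolates exist.
    """
    defined = [r for r in records if r.defined]
    if not defined:
        warnings.warn(
            "all enrichment values undefined; empty hit list", stacklevel=2
        )
        return []
    values = np.array([r.value for r in defined])
    pct_threshold = float(np.percentile(values, config.percentile))

    sig_threshold: float | None = None
    parent_values = np.array(
        [r.value for r in parent_records if r.defined]
    )
    if significance_enabled and len(parent_values) >= 2:
        center = (
            float(np.median(parent_values))
            if config.parent_center == "median"
            else float(np.mean(parent_values))
        )
        sig_threshold = center + config.k_parent * float(
            np.std(parent_values, ddof=1)
        )

    calls = []
    for rec in records:
        passes = (
            rec.defined
            and rec.value >= pct_threshold
            and (sig_threshold is None or rec.value >= sig_threshold)
        )
        calls.append(
            HitCall(
                strain_id=rec.strain_id,
                context=rec.context,
                phenotype=rec.phenotype,
                value=rec.value,
                sig_threshold=sig_threshold,
                pct_threshold=pct_threshold,
                is_hit=bool(passes),
            )
        )
    return calls


def overlap_counts(
    hit_sets: Mapping[str, set[str]]
) -> OverlapTable:
    """Exclusive-intersection tally over >= 2 context hit sets.

    For every non-empty context combination, counts the genes that are hits
    in exactly those contexts; exclusive counts partition the union.
    """
    if len(hit_sets) < 2:
        raise ValueError("need at least two contexts")
    contexts = sorted(hit_sets)
    all_genes = set().union(*hit_sets.values())
    exclusive: dict[frozenset[str], int] = {}
    multiplicity: dict[int, int] = {}
    for gene in all_genes:
        membership = frozenset(c for c in contexts if gene in hit_sets[c])
        exclusive[membership] = exclusive.get(membership, 0) + 1
        multiplicity[len(membership)] = multiplicity.get(len(membership), 0) + 1
    totals = {c: len(hit_sets[c]) for c in contexts}
    return OverlapTable(
        exclusive_counts=exclusive,
        per_context_totals=totals,
        shared_by_multiplicity=multiplicity,
    )


def all_combinations(contexts: Sequence[str]) -> list[frozenset[str]]:
    """Every non-empty combination of contexts, smallest first."""
    combos = []
    for k in range(1, len(contexts) + 1):
        combos.extend(frozenset(c) for c in combinations(sorted(contexts), k))
    return combos
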