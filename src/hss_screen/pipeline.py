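"""End-to-end screen analysis: tables in, enrichments and hit calls out."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._errors import EmptyGateWarning
from .events_io import EventTable, ScreenConfig, StrainManifest
from .normalize_gate import (
    GridFractions,
    GridSpec,
    adjust_unstained_off_reference,
    control_stats,
    gate_threshold,
    green_off_gate,
    grid_boundaries,
    grid_fractions,
    normalize_events,
    select_on_reference,
)
from .screen_stats import (
    EnrichmentRecord,
    HitCall,
    call_hits,
    grid_enrichment,
    parent_self_enrichments,
    pooled_parent,
)


@dataclass
class ScreenResult:
    """Everything one screen run produces, plus table exports."""

    context: str
    grid_spec: GridSpec
    fractions: dict[str, GridFractions]
    enrichments: dict[str, list[EnrichmentRecord]]
    parent_enrichments: dict[str, list[EnrichmentRecord]]
    hits: dict[str, list[HitCall]]
    skipped: list[str] = field(default_factory=list)

    def hit_genes(self, phenotype: str) -> set[str]:
        return {h.strain_id for h in self.hits.get(phenotype, []) if h.is_hit}

    def fractions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strain_id": f.strain_id,
                "n_gated": f.n,
                "f1": f.f1,
                "f2": f.f2,
                "f3": f.f3,
                "f4": f.f4,
            }
            for f in self.fractions.values()
        ]
        return pd.DataFrame(rows)

    def enrichments_frame(self) -> pd.DataFrame:
        rows = []
        for phenotype, records in self.enrichments.items():
            for r in records:
                rows.append(
                    {
                        "strain_id": r.strain_id,
                        "context": r.context,
                        "phenotype": phenotype,
                        "grid_set": "+".join(map(str, r.grid_set)),
                        "value": r.value,
                        "n_mut_gated": r.n_mut_gated,
                        "parent_fraction": r.parent_fraction_used,
                        "defined": r.defined,
                    }
                )
        return pd.DataFrame(rows)

    def hits_frame(self) -> pd.DataFrame:
        rows = []
        for phenotype, calls in self.hits.items():
            for h in calls:
                rows.append(
                    {
                        "strain_id": h.strain_id,
                        "context": h.context,
                        "phenotype": phenotype,
                        "value": h.value,
                        "sig_threshold": h.sig_threshold,
                        "pct_threshold": h.pct_threshold,
                        "is_hit": h.is_hit,
                    }
                )
        return pd.DataFrame(rows)

    def beeswarm_frame(self) -> pd.DataFrame:
        """Long-format table ready for a beeswarm/swarm plot of enrichments."""
        frames = [self.enrichments_frame()]
        for phenotype, records in self.parent_enrichments.items():
            rows = [
                {
                    "strain_id": r.strain_id,
                    "context": r.context,
                    "phenotype": phenotype,
                    "grid_set": "+".join(map(str, r.grid_set)),
                    "value": r.value,
                    "n_mut_gated": r.n_mut_gated,
                    "parent_fraction": r.parent_fraction_used,
                    "defined": r.defined,
                }
                for r in records
            ]
            frames.append(pd.DataFrame(rows).assign(phenotype=phenotype))
        out = pd.concat(frames, ignore_index=True)
        out["is_parent"] = out["strain_id"].str.startswith("parent")
        return out


def run_screen(
    manifest: StrainManifest,
    config: ScreenConfig,
    tables: dict[str, EventTable],
    *,
    seed: int | None = None,
) -> ScreenResult:
    """Run the full analysis for one context.

    Steps: normalize every strain against the ON control; derive the
    green-off gate from the OFF control; build grid boundaries from OFF/ON
    orange statistics; gate and grid every strain; compute loss (and, where
    defined, gain) enrichments of each mutant against the pooled parents;
    call hits with the significance and percentile thresholds.

    For the ectopic context the OFF reference is an unstained strain whose
    red values are first adjusted using the ON control (seeded by ``seed`` or
    ``config.seed``).
    """
    on_raw = tables[manifest.control_on]
    off_ids = manifest.strains_with_role("control_off")
    off_raw = tables[off_ids[0]]
    if manifest.context == "ECT":
        off_raw = adjust_unstained_off_reference(
            off_raw, on_raw, seed if seed is not None else config.seed
        )

    norm = {
        sid: normalize_events(tables[sid], on_raw)
        for sid in sorted(tables)
        if sid not in off_ids
    }
    off_norm = normalize_events(off_raw, on_raw)

    off_green = control_stats(off_norm, "green_norm")
    off_orange = control_stats(off_norm, "orange_norm")
    on_subset = select_on_reference(norm[manifest.control_on], "orange_norm")
    spec = grid_boundaries(
        off_orange,
        on_subset,
        config,
        gate_green_off=gate_threshold(off_green, config),
    )

    fractions: dict[str, GridFractions] = {}
    skipped: list[str] = []
    analysed = manifest.parents + manifest.mutants + manifest.strains_with_role(
        "clr4_like"
    )
    for sid in analysed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyGateWarning)
            gate = green_off_gate(norm[sid], off_green, config)
        if gate.n_retained == 0:
            skipped.append(sid)
            continue
        fractions[sid] = grid_fractions(gate.population, spec)

    parent_fracs = [fractions[p] for p in manifest.parents if p in fractions]
    pooled = pooled_parent(parent_fracs)

    phenotypes = {"loss": config.loss_grid_set}
    if config.gain_enabled and config.gain_grid_set:
        phenotypes["gain"] = config.gain_grid_set

    enrichments: dict[str, list[EnrichmentRecord]] = {}
    parent_enr: dict[str, list[EnrichmentRecord]] = {}
    hits: dict[str, list[HitCall]] = {}
    for phenotype, grid_set in phenotypes.items():
        records = [
            grid_enrichment(
                fractions[m],
                pooled,
                grid_set,
                context=manifest.context,
                phenotype=phenotype,
            )
            for m in manifest.mutants
            if m in fractions
        ]
        par_records = parent_self_enrichments(
            parent_fracs,
            grid_set,
            context=manifest.context,
            phenotype=phenotype,
        )
        enrichments[phenotype] = records
        parent_enr[phenotype] = par_records
        hits[phenotype] = call_hits(
            records,
            par_records,
            config,
            significance_enabled=manifest.significance_enabled,
        )
    return ScreenResult(
        context=manifest.context,
        grid_spec=spec,
        fractions=fractions,
        enrichments=enrichments,
        parent_enrichments=parent_enr,
        hits=hits,
        skipped=skipped,
    )


def recovery_metrics(
    result: ScreenResult, truth: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity/specificity of loss-hit calls against a planted truth table.

    Sensitivity is over planted loss_of_spreading strains; the false-positive
    rate is over strains with no planted effect. Nucleation-loss decoys are
    reported separately: they lose green silencing, not distal orange
    silencing, and must not surface as spreading hits.
    """
    loss_hits = result.hit_genes("loss")
    truth = truth.set_index("strain_id")
    planted_loss = set(truth.index[truth["effect"] == "loss_of_spreading"])
    nulls = set(truth.index[truth["effect"] == "none"])
    decoys = set(truth.index[truth["effect"] == "loss_of_nucleation"])
    sensitivity = (
        len(loss_hits & planted_loss) / len(planted_loss)
        if planted_loss
        else float("nan")
    )
    fpr = len(loss_hits & nulls) / len(nulls) if nulls else float("nan")
    return {
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "n_loss_hits": float(len(loss_hits)),
        "decoy_hits": float(len(loss_hits & decoys)),
    }
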