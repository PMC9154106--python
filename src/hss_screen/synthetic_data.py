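"""Synthetic three-channel flow-cytometry populations with planted effects.

Each simulated cell draws a red (normalizer) intensity from a lognormal
cell-size/expression noise model shared multiplicatively across channels,
a binary green nucleation state, and — conditional on green OFF — one of
three orange spreading states (off / intermediate / on). Raw intensities are
``state_mean * red_raw * lognormal(within-state CV)``, so dividing by red
removes the shared noise and, in the zero-CV limit, every normalized value
equals its state mean exactly.

Context presets emulate the screened populations: a bimodal, fully nucleated
near-complete-spreading context (MAT dcenH-like), stochastic-spreading
contexts with a vertical spread of orange states (MAT dREIII / ECT-like),
and a tightly silenced wild-type MAT. Planted mutant effects shift the state
weights or the nucleation probability and are recorded in a truth table for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .events_io import EventTable, ScreenConfig, StrainManifest

EFFECTS = (
    "none",
    "loss_of_spreading",
    "gain_of_spreading",
    "loss_of_nucleation",
    "loss_of_silencing",
)

#: State means on the normalized scale: silenced background, partial
#: spreading, fully expressed.
STATE_MEANS = {"off": 0.03, "intermediate": 0.5, "on": 1.0}


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one strain population.

    ``p_green_off`` is the probability a cell is nucleated (green reporter
    silenced). ``orange_state_weights`` are the off/intermediate/on state
    probabilities conditional on green OFF; green-ON cells have no
    heterochromatin and express orange fully. ``cv`` is the within-state
    lognormal coefficient of variation; ``red_cv`` the shared cell-size noise
    CV around ``red_scale`` (instrument arbitrary units).
    """

    n_cells: int = 30_000
    p_green_off: float = 0.9
    orange_state_weights: tuple[float, float, float] = (0.70, 0.255, 0.045)
    state_means: tuple[float, float, float] = (
        STATE_MEANS["off"],
        STATE_MEANS["intermediate"],
        STATE_MEANS["on"],
    )
    green_off_mean: float = STATE_MEANS["off"]
    green_on_mean: float = STATE_MEANS["on"]
    cv: float = 0.15
    red_cv: float = 0.35
    red_scale: float = 1000.0

    def __post_init__(self) -> None:
        w = np.asarray(self.orange_state_weights, dtype=float)
        if np.any(w < 0) or np.any(w > 1) or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                f"orange_state_weights must lie in [0,1] and sum to 1: {w}"
            )
        if not 0.0 <= self.p_green_off <= 1.0:
            raise ValueError("p_green_off must be a probability")
        if self.cv < 0 or self.red_cv < 0:
            raise ValueError("CVs must be >= 0")
        if any(m < 0 for m in self.state_means):
            raise ValueError("state means must be >= 0")


def preset_params(context: str, *, n_cells: int = 30_000) -> SimParams:
    """Study-condition presets per chromatin context.

    MAT dcenH: fully nucleated with near-complete local spreading (orange
    almost entirely off). WT MAT: similarly tight silencing. MAT dREIII and
    ECT: mostly nucleated but with a stochastic vertical distribution of
    orange spreading states.
    """
    presets = {
        "MAT_dcenH": SimParams(
            n_cells=n_cells,
            p_green_off=0.97,
            orange_state_weights=(0.95, 0.04, 0.01),
        ),
        "WT_MAT": SimParams(
            n_cells=n_cells,
            p_green_off=0.96,
            orange_state_weights=(0.92, 0.06, 0.02),
        ),
        "MAT_dREIII": SimParams(
            n_cells=n_cells,
            p_green_off=0.9,
            orange_state_weights=(0.70, 0.255, 0.045),
        ),
        "ECT": SimParams(
            n_cells=n_cells,
            p_green_off=0.85,
            orange_state_weights=(0.60, 0.33, 0.07),
        ),
    }
    if context not in presets:
        raise ValueError(f"unknown context {context!r}")
    return presets[context]


def _lognormal_unit_mean(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_population(
    params: SimParams,
    seed: int | np.random.Generator,
    strain_id: str = "sim",
) -> EventTable:
    """Draw one strain's raw event table from the generative model."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = params.n_cells
    red = params.red_scale * _lognormal_unit_mean(rng, params.red_cv, n)
    green_off = rng.random(n) < params.p_green_off
    green_mean = np.where(
        green_off, params.green_off_mean, params.green_on_mean
    )
    orange_state = rng.choice(3, size=n, p=params.orange_state_weights)
    orange_mean = np.asarray(params.state_means)[orange_state]
    # a cell that failed to nucleate silences nothing: orange fully ON
    orange_mean = np.where(green_off, orange_mean, params.state_means[2])
    green = green_mean * red * _lognormal_unit_mean(rng, params.cv, n)
    orange = orange_mean * red * _lognormal_unit_mean(rng, params.cv, n)
    return EventTable(
        strain_id=strain_id, green=green, orange=orange, red=red
    )


def simulate_controls(
    params: SimParams, seed: int | np.random.Generator
) -> tuple[EventTable, EventTable]:
    """Fully-OFF (red-only-like) and fully-ON (Delta-clr4-like) controls.

    The OFF control has green and orange at background (off state mean); the
    ON control expresses both reporters fully (mean 1 on the normalized
    scale). Both share the strain's noise parameters.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    off = replace(
        params,
        p_green_off=1.0,
        orange_state_weights=(1.0, 0.0, 0.0),
    )
    on = replace(
        params,
        p_green_off=0.0,
        orange_state_weights=(0.0, 0.0, 1.0),
    )
    control_off = simulate_population(off, rng, strain_id="control_off")
    control_on = simulate_population(on, rng, strain_id="control_on")
    return control_off, control_on


def apply_effect(
    params: SimParams, effect: str, magnitude: float
) -> SimParams:
    """Perturb base parameters per a planted effect.

    loss_of_spreading / loss_of_silencing move ``magnitude`` probability mass
    from the orange off state to the on state (loss_of_silencing also turns
    green on); gain_of_spreading moves mass from intermediate+on into off;
    loss_of_nucleation lowers ``p_green_off`` to ``magnitude``.
    """
    w = np.asarray(params.orange_state_weights, dtype=float)
    if effect == "none":
        return params
    if effect == "loss_of_spreading" or effect == "loss_of_silencing":
        shift = min(magnitude, w[0])
        w = w + np.array([-shift, 0.0, shift])
        out = replace(params, orange_state_weights=tuple(w))
        if effect == "loss_of_silencing":
            out = replace(out, p_green_off=max(0.0, params.p_green_off - 0.7))
        return out
    if effect == "gain_of_spreading":
        shift = min(magnitude, w[1] + w[2])
        take1 = min(shift, w[1])
        take2 = shift - take1
        w = w + np.array([shift, -take1, -take2])
        return replace(params, orange_state_weights=tuple(w))
    if effect == "loss_of_nucleation":
        return replace(params, p_green_off=magnitude)
    raise ValueError(f"unknown effect {effect!r}")


@dataclass
class SyntheticScreen:
    """A complete in-memory screen: tables, manifest, and ground truth."""

    manifest: StrainManifest
    config: ScreenConfig
    tables: dict[str, EventTable]
    truth: pd.DataFrame


def simulate_screen(
    n_mutants: int,
    planted: Mapping[str, tuple[str, float]] | None = None,
    params: SimParams | None = None,
    seed: int = 0,
    *,
    context: str = "MAT_dREIII",
    n_parents: int = 6,
    parent_jitter: float = 0.05,
    n_planted: Mapping[str, int] | None = None,
) -> SyntheticScreen:
    """Simulate a full deletion-library screen with planted effects.

    Either pass ``planted`` (strain id -> (effect, magnitude)) explicitly, or
    ``n_planted`` (effect -> count) to assign default-magnitude effects to
    the first mutants in order. Parent isolates receive a small (<=
    ``parent_jitter`` relative) perturbation of their orange state weights so
    the parent significance band is non-degenerate, mirroring biological
    isolate-to-isolate variation.
    """
    rng = np.random.default_rng(seed)
    base = params or preset_params(context)

    default_magnitude = {
        "loss_of_spreading": 0.4,
        "gain_of_spreading": 0.3,
        "loss_of_nucleation": 0.2,
        "loss_of_silencing": 0.4,
        "none": 0.0,
    }
    effects: dict[str, tuple[str, float]] = {}
    if planted is not None:
        effects.update(planted)
    mutant_ids = [f"mut_{i:04d}" for i in range(n_mutants)]
    if n_planted:
        cursor = 0
        for effect, count in n_planted.items():
            for _ in range(count):
                effects[mutant_ids[cursor]] = (
                    effect,
                    default_magnitude[effect],
                )
                cursor += 1

    tables: dict[str, EventTable] = {}
    roles: dict[str, str] = {}

    control_off, control_on = simulate_controls(base, rng)
    tables["control_off"] = control_off
    tables["control_on"] = control_on
    roles["control_off"] = "control_off"
    roles["control_on"] = "control_on"

    for i in range(n_parents):
        jit = 1.0 + parent_jitter * rng.uniform(-1, 1, size=3)
        w = np.asarray(base.orange_state_weights) * jit
        w = w / w.sum()
        par = replace(base, orange_state_weights=tuple(w))
        sid = f"parent_{i + 1}"
        tables[sid] = simulate_population(par, rng, strain_id=sid)
        roles[sid] = "parent_isolate"

    truth_rows = []
    for sid in mutant_ids:
        effect, magnitude = effects.get(sid, ("none", 0.0))
        mut_params = apply_effect(base, effect, magnitude)
        tables[sid] = simulate_population(mut_params, rng, strain_id=sid)
        roles[sid] = "mutant"
        truth_rows.append(
            {"strain_id": sid, "effect": effect, "magnitude": magnitude}
        )

    manifest = StrainManifest(context=context, roles=roles)
    config = ScreenConfig(context=context, seed=seed)
    truth = pd.DataFrame(truth_rows)
    return SyntheticScreen(
        manifest=manifest, config=config, tables=tables, truth=truth
    )


def write_screen(screen: SyntheticScreen, outdir: str | Path) -> Path:
    """Write a screen as ready-to-run manifest + event CSVs + truth TSV."""
    from .events_io import write_event_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strains = {}
    for sid, table in screen.tables.items():
        rel = f"{sid}.csv"
        write_event_table(table, outdir / rel)
        strains[sid] = {"role": screen.manifest.roles[sid], "path": rel}
    manifest_doc = {
        "context": screen.manifest.context,
        "strains": strains,
        "config": {
            "stat_mode": screen.config.stat_mode,
            "percentile": screen.config.percentile,
            "k_parent": screen.config.k_parent,
            "parent_center": screen.config.parent_center,
        },
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest_doc, sort_keys=True)
    )
    screen.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir / "manifest.yaml"
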