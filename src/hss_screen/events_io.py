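"""Read/write per-cell event tables and the strain manifest.

Event tables are delimited text (CSV or TSV, autodetected) with one row per
cell and named ``green``, ``orange``, ``red`` columns of raw fluorescence in
arbitrary units. The manifest (YAML or JSON) names each strain's role in the
screen — mutant, parent isolate, fully-OFF control (red-only/unstained) or
fully-ON control (Delta-clr4) — together with the chromatin context and the
run configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from ._errors import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
    LowEventCountWarning,
)

CONTEXTS = ("WT_MAT", "MAT_dcenH", "MAT_dREIII", "ECT")
ROLES = ("mutant", "parent_isolate", "control_off", "control_on", "clr4_like")

#: Loss-of-distal-silencing grid sets per context: tightly silenced contexts
#: (WT MAT, MAT dcenH) use grids 3+4; stochastic-spreading contexts
#: (MAT dREIII, ECT) use grid 4 only.
DEFAULT_LOSS_GRIDS: dict[str, tuple[int, ...]] = {
    "WT_MAT": (3, 4),
    "MAT_dcenH": (3, 4),
    "MAT_dREIII": (4,),
    "ECT": (4,),
}

#: Gain-of-distal-silencing uses grid 1; undefined for MAT dcenH, whose
#: population already sits almost entirely in grid 1.
DEFAULT_GAIN_GRIDS: dict[str, tuple[int, ...] | None] = {
    "WT_MAT": (1,),
    "MAT_dcenH": None,
    "MAT_dREIII": (1,),
    "ECT": (1,),
}

_CHANNELS = ("green", "orange", "red")


@dataclass(frozen=True)
class EventTable:
    """Raw per-cell three-channel fluorescence for one strain sample.

    All values are finite and strictly positive (red is a divisor during
    normalization); rows violating this are dropped at read time and counted
    in ``n_dropped``.
    """

    strain_id: str
    green: np.ndarray
    orange: np.ndarray
    red: np.ndarray
    replicate_id: str = "rep1"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for name in _CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.green)
        if not (len(self.orange) == len(self.red) == n):
            raise ValueError("channel arrays must have equal length")
        if n < 1:
            raise EmptyInputError(
                f"{self.strain_id}: event table has no events"
            )
        for name in _CHANNELS:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(
                    f"{self.strain_id}: {name} contains non-finite or "
                    "non-positive values; filter rows before construction"
                )

    @property
    def n(self) -> int:
        return len(self.green)

    def scaled(self, factor: float) -> "EventTable":
        """Return a copy with all three channels multiplied by ``factor``."""
        return replace(
            self,
            green=self.green * factor,
            orange=self.orange * factor,
            red=self.red * factor,
        )


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable analysis parameters with context-dependent grid-set defaults.

    ``k_off`` multiplies the off-control SD in the green-off gate threshold
    (screen mode); ``percentile`` is the rank cutoff applied to mutant
    enrichments (top 15% => 85); ``k_parent`` multiplies the parent-isolate SD
    in the significance threshold; ``stat_mode`` selects the screen (SD-based)
    or validation (MAD-based) boundary statistics.
    """

    context: str = "MAT_dREIII"
    stat_mode: str = "sd_screen"
    k_off: float = 2.0
    percentile: float = 85.0
    k_parent: float = 2.0
    parent_center: str = "median"
    min_events: int = 200
    seed: int = 0
    loss_grid_set: tuple[int, ...] | None = None
    gain_grid_set: tuple[int, ...] | None = None
    gain_enabled: bool | None = None

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ConfigurationError(
                f"unknown context {self.context!r}; expected one of {CONTEXTS}"
            )
        if self.stat_mode not in ("sd_screen", "mad_validation"):
            raise ConfigurationError(
                f"unknown stat_mode {self.stat_mode!r}"
            )
        if self.parent_center not in ("median", "mean"):
            raise ConfigurationError(
                f"parent_center must be 'median' or 'mean', "
                f"got {self.parent_center!r}"
            )
        if self.loss_grid_set is None:
            object.__setattr__(
                self, "loss_grid_set", DEFAULT_LOSS_GRIDS[self.context]
            )
        else:
            object.__setattr__(
                self, "loss_grid_set", tuple(sorted(self.loss_grid_set))
            )
        default_gain = DEFAULT_GAIN_GRIDS[self.context]
        if self.gain_enabled is None:
            object.__setattr__(self, "gain_enabled", default_gain is not None)
        if self.gain_enabled and default_gain is None:
            raise ConfigurationError(
                f"gain-of-distal-silencing analysis is not defined for "
                f"{self.context}: the population already occupies grid 1"
            )
        if self.gain_grid_set is None:
            object.__setattr__(self, "gain_grid_set", default_gain)
        else:
            object.__setattr__(
                self, "gain_grid_set", tuple(sorted(self.gain_grid_set))
            )
        for gs in (self.loss_grid_set, self.gain_grid_set):
            if gs is not None and not set(gs) <= {1, 2, 3, 4}:
                raise ConfigurationError(f"grid set {gs} outside 1..4")


@dataclass
class StrainManifest:
    """Roles, context and file paths for all strains of one screen run."""

    context: str
    roles: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ConfigurationError(f"unknown context {self.context!r}")
        bad = {r for r in self.roles.values() if r not in ROLES}
        if bad:
            raise ConfigurationError(f"unknown roles: {sorted(bad)}")
        # clr4_like strains are fully-ON by genotype but are screened strains,
        # not the normalization control; exactly one control_on is required.
        if len(self.strains_with_role("control_on")) != 1:
            raise ConfigurationError(
                "manifest must name exactly one control_on (Delta-clr4) strain"
            )
        if not self.strains_with_role("control_off"):
            raise ConfigurationError(
                "manifest must name at least one control_off "
                "(red-only or unstained) strain"
            )
        if not self.strains_with_role("parent_isolate"):
            raise ConfigurationError(
                "manifest must name at least one parent isolate"
            )

    def strains_with_role(self, role: str) -> list[str]:
        return sorted(s for s, r in self.roles.items() if r == role)

    @property
    def control_on(self) -> str:
        return self.strains_with_role("control_on")[0]

    @property
    def parents(self) -> list[str]:
        return self.strains_with_role("parent_isolate")

    @property
    def mutants(self) -> list[str]:
        return self.strains_with_role("mutant")

    @property
    def significance_enabled(self) -> bool:
        """The parent-SD significance criterion needs >= 2 parent isolates."""
        return len(self.parents) >= 2


def read_event_table(
    path: str | Path,
    strain_id: str | None = None,
    *,
    column_map: Mapping[str, str] | None = None,
    min_events: int = 200,
) -> EventTable:
    """Read a delimited-text event table, dropping invalid rows.

    Columns are matched case-insensitively against ``green``/``orange``/``red``
    (or the names given in ``column_map``). Rows with non-finite or
    non-positive values in any channel are dropped and counted.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    # round_trip parsing keeps written doubles bit-exact on re-read
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    wanted = {
        ch: (column_map or {}).get(ch, ch).strip().lower() for ch in _CHANNELS
    }
    missing = [col for col in wanted.values() if col not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    values = df[[wanted[ch] for ch in _CHANNELS]].apply(
        pd.to_numeric, errors="coerce"
    )
    arr = values.to_numpy(dtype=float)
    keep = np.all(np.isfinite(arr) & (arr > 0), axis=1)
    n_dropped = int((~keep).sum())
    arr = arr[keep]
    if arr.shape[0] == 0:
        raise EmptyInputError(f"{path}: all {n_dropped} rows were invalid")
    if arr.shape[0] < min_events:
        warnings.warn(
            f"{path}: only {arr.shape[0]} events (< {min_events})",
            LowEventCountWarning,
            stacklevel=2,
        )
    return EventTable(
        strain_id=strain_id or path.stem,
        green=arr[:, 0],
        orange=arr[:, 1],
        red=arr[:, 2],
        n_dropped=n_dropped,
    )


def write_event_table(table: EventTable, path: str | Path) -> Path:
    """Write an event table as CSV at full float precision (round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame(
        {"green": table.green, "orange": table.orange, "red": table.red}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_manifest(path: str | Path) -> tuple[StrainManifest, ScreenConfig]:
    """Load a YAML/JSON manifest into a validated manifest + configuration.

    Expected layout::

        context: MAT_dREIII
        strains:
          parent_1: {role: parent_isolate, path: parent_1.csv}
          red_only: {role: control_off, path: red_only.csv}
          clr4:     {role: control_on, path: clr4.csv}
          mutA:     {role: mutant, path: mutA.csv}
        config:            # optional overrides
          stat_mode: sd_screen
          percentile: 85

    Grid-set defaults for the context are applied unless overridden.
    """
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict) or "strains" not in data:
        raise ConfigurationError(f"{path}: manifest must map 'strains'")
    context = data.get("context")
    if context not in CONTEXTS:
        raise ConfigurationError(
            f"{path}: unknown or missing context {context!r}"
        )
    roles: dict[str, str] = {}
    paths: dict[str, Path] = {}
    for strain, entry in data["strains"].items():
        if isinstance(entry, str):
            entry = {"role": entry}
        roles[str(strain)] = entry["role"]
        if "path" in entry:
            p = Path(entry["path"])
            paths[str(strain)] = p if p.is_absolute() else path.parent / p
    manifest = StrainManifest(context=context, roles=roles, paths=paths)
    cfg_kwargs = dict(data.get("config", {}))
    for key in ("loss_grid_set", "gain_grid_set"):
        if key in cfg_kwargs and cfg_kwargs[key] is not None:
            cfg_kwargs[key] = tuple(int(g) for g in cfg_kwargs[key])
    config = ScreenConfig(context=context, **cfg_kwargs)
    return manifest, config


def load_event_tables(
    manifest: StrainManifest, *, min_events: int = 200
) -> dict[str, EventTable]:
    """Read every event table referenced by the manifest."""
    tables = {}
    for strain in sorted(manifest.roles):
        if strain not in manifest.paths:
            raise ConfigurationError(f"no path given for strain {strain!r}")
        tables[strain] = read_event_table(
            manifest.paths[strain], strain, min_events=min_events
        )
    return tables


def iter_strains(
    manifest: StrainManifest, roles: Iterable[str]
) -> list[str]:
    """Strains whose role is in ``roles``, in sorted order."""
    roleset = set(roles)
    return sorted(s for s, r in manifest.roles.items() if r in roleset)
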