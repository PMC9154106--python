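"""Red-normalization, green-off gating and orange grid construction.

Raw green/orange values are divided per cell by the red (noise-normalizer)
channel and then scaled by the ON-control median ratio, so that a fully
expressed reporter sits near 1 and a silenced one near 0. Nucleated cells are
selected with a green-off gate derived from the fully-OFF control; the
nucleation-distal orange axis is partitioned into four grids by boundaries
derived from the OFF and ON controls.

Screen mode statistics: gate threshold = median + 2*SD of the off control;
grid boundaries b_low = median + 2*SD of the orange-OFF control,
b_high = median - 2*SD of ON-control cells above 0.5, b_mid = their midpoint.
Validation mode replaces SD with the (unscaled) median absolute deviation:
off side median + 3*MAD, on side median - 2*MAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._errors import (
    DegenerateControlError,
    DegenerateGridError,
    EmptyGateWarning,
    NormalizationError,
)
from .events_io import EventTable, ScreenConfig

#: Normalized-fluorescence cutoff selecting fully-ON cells from the
#: Delta-clr4 control when deriving the orange ON boundary.
ON_SELECT_THRESHOLD = 0.5


@dataclass(frozen=True)
class NormalizedPopulation:
    """Per-cell red-normalized, ON-scaled green and orange values."""

    strain_id: str
    green_norm: np.ndarray
    orange_norm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "green_norm", np.asarray(self.green_norm, dtype=float)
        )
        object.__setattr__(
            self, "orange_norm", np.asarray(self.orange_norm, dtype=float)
        )
        if len(self.green_norm) != len(self.orange_norm):
            raise ValueError("channel arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.green_norm)

    def channel(self, name: str) -> np.ndarray:
        if name not in ("green_norm", "orange_norm"):
            raise ValueError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class ControlStats:
    """Summary statistics of one normalized channel of a control strain.

    ``sd`` is the sample standard deviation (n-1 denominator); ``mad`` is the
    raw median absolute deviation (no 1.4826 consistency scaling).
    """

    channel: str
    median: float
    sd: float
    mad: float
    n: int


@dataclass(frozen=True)
class GridSpec:
    """Green-off gate threshold and the three orange grid boundaries.

    Grids are half-open, lower-inclusive:
    grid1 = (-inf, b_low), grid2 = [b_low, b_mid), grid3 = [b_mid, b_high),
    grid4 = [b_high, +inf).
    """

    gate_green_off: float
    b_low: float
    b_mid: float
    b_high: float
    on_select_threshold: float = ON_SELECT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.b_low < self.b_mid < self.b_high:
            raise DegenerateGridError(
                f"grid boundaries must be ordered: "
                f"b_low={self.b_low:.4g}, b_mid={self.b_mid:.4g}, "
                f"b_high={self.b_high:.4g}"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.b_low, self.b_mid, self.b_high])


@dataclass(frozen=True)
class GateResult:
    """Green-off gate output: the retained subset plus gate diagnostics."""

    population: NormalizedPopulation
    threshold: float
    n_input: int

    @property
    def n_retained(self) -> int:
        return self.population.n

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0


@dataclass(frozen=True)
class GridFractions:
    """Fractions of a gated population in orange grids 1-4 (sum to 1)."""

    strain_id: str
    f1: float
    f2: float
    f3: float
    f4: float
    n: int

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4])

    def grid_sum(self, grid_set: tuple[int, ...]) -> float:
        return float(sum(self.fractions[g - 1] for g in grid_set))


def normalize_events(
    raw: EventTable, on_control_raw: EventTable
) -> NormalizedPopulation:
    """Normalize raw events against the fully-ON (Delta-clr4) control.

    For each cell, ``color_norm = (color_raw / red_raw) / M_color`` where
    ``M_color`` is the median color/red ratio over the ON-control cells. By
    construction the ON control's normalized medians equal 1 exactly, and all
    normalized values are invariant under uniform rescaling of the raw
    channels.
    """
    m_green = float(np.median(on_control_raw.green / on_control_raw.red))
    m_orange = float(np.median(on_control_raw.orange / on_control_raw.red))
    if m_green == 0 or m_orange == 0:
        raise NormalizationError(
            f"ON-control {on_control_raw.strain_id}: zero median ratio "
            f"(green {m_green:.3g}, orange {m_orange:.3g})"
        )
    return NormalizedPopulation(
        strain_id=raw.strain_id,
        green_norm=(raw.green / raw.red) / m_green,
        orange_norm=(raw.orange / raw.red) / m_orange,
    )


def control_stats(pop: NormalizedPopulation, channel: str) -> ControlStats:
    """Median, sample SD and raw MAD of one normalized channel."""
    x = pop.channel(channel)
    if len(x) == 0:
        raise ValueError(f"{pop.strain_id}: empty population")
    med = float(np.median(x))
    # a constant population has sd exactly 0; np.std would return a rounding
    # residual that breaks the degenerate gate/boundary closed forms
    if len(x) < 2 or np.ptp(x) == 0:
        sd = 0.0
    else:
        sd = float(np.std(x, ddof=1))
    mad = float(np.median(np.abs(x - med)))
    return ControlStats(channel=channel, median=med, sd=sd, mad=mad, n=len(x))


def gate_threshold(off_stats: ControlStats, config: ScreenConfig) -> float:
    """Green-off gate threshold from OFF-control green statistics."""
    if config.stat_mode == "mad_validation":
        return off_stats.median + 3.0 * off_stats.mad
    return off_stats.median + config.k_off * off_stats.sd


def green_off_gate(
    pop: NormalizedPopulation,
    off_stats: ControlStats,
    config: ScreenConfig,
) -> GateResult:
    """Retain nucleated cells: green_norm strictly below the gate threshold.

    A gate that retains zero cells emits :class:`EmptyGateWarning`; callers
    should skip the strain.
    """
    thr = gate_threshold(off_stats, config)
    keep = pop.green_norm < thr
    if not keep.any():
        warnings.warn(
            f"{pop.strain_id}: green-off gate at {thr:.4g} retained 0 of "
            f"{pop.n} cells; strain will be skipped",
            EmptyGateWarning,
            stacklevel=2,
        )
    subset = NormalizedPopulation(
        strain_id=pop.strain_id,
        green_norm=pop.green_norm[keep],
        orange_norm=pop.orange_norm[keep],
    )
    return GateResult(population=subset, threshold=thr, n_input=pop.n)


def select_on_reference(
    control_on: NormalizedPopulation, channel: str = "orange_norm"
) -> NormalizedPopulation:
    """ON-control cells with normalized fluorescence strictly above 0.5."""
    keep = control_on.channel(channel) > ON_SELECT_THRESHOLD
    if not keep.any():
        raise DegenerateControlError(
            f"{control_on.strain_id}: no {channel} values above "
            f"{ON_SELECT_THRESHOLD}; ON control is degenerate"
        )
    return NormalizedPopulation(
        strain_id=control_on.strain_id,
        green_norm=control_on.green_norm[keep],
        orange_norm=control_on.orange_norm[keep],
    )


def grid_boundaries(
    off_orange_stats: ControlStats,
    on_orange_subset: NormalizedPopulation,
    config: ScreenConfig,
    *,
    gate_green_off: float,
) -> GridSpec:
    """Construct the four-grid spec from OFF- and ON-control orange values."""
    on_stats = control_stats(on_orange_subset, "orange_norm")
    if config.stat_mode == "mad_validation":
        b_low = off_orange_stats.median + 3.0 * off_orange_stats.mad
        b_high = on_stats.median - 2.0 * on_stats.mad
    else:
        b_low = off_orange_stats.median + 2.0 * off_orange_stats.sd
        b_high = on_stats.median - 2.0 * on_stats.sd
    if b_low >= b_high:
        raise DegenerateGridError(
            f"orange controls overlap: off median {off_orange_stats.median:.4g}"
            f" sd {off_orange_stats.sd:.4g} mad {off_orange_stats.mad:.4g} vs "
            f"on median {on_stats.median:.4g} sd {on_stats.sd:.4g} "
            f"mad {on_stats.mad:.4g} give b_low {b_low:.4g} >= "
            f"b_high {b_high:.4g}"
        )
    return GridSpec(
        gate_green_off=gate_green_off,
        b_low=b_low,
        b_mid=(b_low + b_high) / 2.0,
        b_high=b_high,
    )


def grid_fractions(
    gated: NormalizedPopulation, spec: GridSpec
) -> GridFractions:
    """Fraction of gated cells per orange grid (half-open, lower-inclusive)."""
    if gated.n == 0:
        raise ValueError(f"{gated.strain_id}: empty gated population")
    # searchsorted side='right' puts a cell equal to a boundary into the
    # higher grid, matching the lower-inclusive convention.
    idx = np.searchsorted(spec.edges, gated.orange_norm, side="right")
    counts = np.bincount(idx, minlength=4)
    f = counts / gated.n
    return GridFractions(
        strain_id=gated.strain_id,
        f1=float(f[0]),
        f2=float(f[1]),
        f3=float(f[2]),
        f4=float(f[3]),
        n=gated.n,
    )


def adjust_unstained_off_reference(
    unstained: EventTable,
    on_control: EventTable,
    seed: int | np.random.Generator = 0,
) -> EventTable:
    """Build an ECT-style OFF reference from an unstained strain.

    The ectopic context lacks a red-only control strain; its background
    reference is a fluorescence-negative (unstained) strain whose values are
    adjusted by the red fluorescence of the Delta-clr4 control. Concretely,
    each unstained cell's red value is replaced by one resampled (with
    replacement, seeded) from the ON control's red channel, producing a
    red-normalized null background.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    red = rng.choice(on_control.red, size=unstained.n, replace=True)
    return replace(unstained, red=red)
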