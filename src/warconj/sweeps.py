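"""Parameter-space sweeps producing grid-shaped steady-state summaries.

Each sweep builds a grid of independent single-competition runs (one
:func:`~warconj.simulate.run_scenario` call per cell), so cells can be
evaluated in any order without changing results. Every cell carries its
exact inputs (variant, scenario, full parameter table, full initial state)
so any cell is reproducible in isolation; a cell whose integration fails is
recorded with the error message rather than raised, preserving the grid
shape for plotting.

Available sweeps:

* :func:`sweep_b_E` — conjugation rate x toxin potency.
* :func:`sweep_initial_frequencies` — initial target frequency at fixed
  total inoculum density.
* :func:`sweep_density_frequency` — total inoculum density x initial
  target frequency.
* :func:`sweep_niche_separation` — shifts a fixed total nutrient pool from
  fully shared (N1 = total) to fully private (N2 = N3 = total/2).
* :func:`sweep_one_at_a_time` — local sensitivity: one parameter varied,
  all others at defaults, run for both model variants side by side.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    STATE_FIELDS,
    ModelParams,
    ModelVariant,
    SystemState,
    default_initial_state,
)
from .simulate import Scenario, SteadyStateResult, run_scenario

__all__ = [
    "AxisSpec",
    "SweepCell",
    "SweepGrid",
    "sweep_b_E",
    "sweep_initial_frequencies",
    "sweep_density_frequency",
    "sweep_niche_separation",
    "sweep_one_at_a_time",
    "SWEEPABLE_NAMES",
]

#: Default total inoculum biomass for frequency presets (C1 + C2 at the
#: standard 0.01 + 0.01 initial condition).
DEFAULT_TOTAL_DENSITY = 0.02

#: Names accepted by :func:`sweep_one_at_a_time`: every rate/affinity
#: constant, every initial-state component, plus the two composite axes.
SWEEPABLE_NAMES = ModelParams.field_names() + STATE_FIELDS + ("density", "f_target")


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: a named parameter and its ordered values."""

    name: str
    values: tuple[float, ...]
    scale: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.scale not in ("linear", "log"):
            raise ValueError(f"axis scale must be 'linear' or 'log', got {self.scale!r}")
        for v in self.values:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"axis {self.name!r} values must be finite and >= 0, got {v!r}")
        if self.name == "f_target":
            for v in self.values:
                if v > 1:
                    raise ValueError(f"frequency-axis value must be in [0, 1], got {v!r}")

    @classmethod
    def linspace(cls, name: str, lo: float, hi: float, n: int) -> "AxisSpec":
        return cls(name, tuple(np.linspace(lo, hi, n)), "linear")

    @classmethod
    def logspace(cls, name: str, lo: float, hi: float, n: int) -> "AxisSpec":
        if lo <= 0 or hi <= 0:
            raise ValueError("log axis endpoints must be > 0")
        return cls(name, tuple(np.geomspace(lo, hi, n)), "log")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SweepCell:
    """One grid cell: exact inputs plus the endpoint summary (or the error)."""

    coords: dict[str, float]
    variant: ModelVariant
    scenario: Scenario
    params: ModelParams
    init: SystemState
    result: SteadyStateResult | None
    error: str | None = None

    @property
    def converged(self) -> bool:
        return self.result is not None and self.result.converged


@dataclass(frozen=True)
class SweepGrid:
    """Axes plus one :class:`SweepCell` per axis-value combination.

    Cells are stored in row-major order over the axes (last axis fastest);
    ``cell_count == product(len(axis) for axis in axes)``.
    """

    axes: tuple[AxisSpec, ...]
    variant: ModelVariant
    scenario: Scenario
    cells: tuple[SweepCell, ...]

    def __post_init__(self) -> None:
        expected = int(np.prod([len(a) for a in self.axes])) if self.axes else 0
        if len(self.cells) != expected:
            raise ValueError(f"expected {expected} cells for the axes, got {len(self.cells)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    def value_array(self, which: str = "f_transconjugant") -> np.ndarray:
        """Grid of one endpoint quantity, shaped like the axes (NaN if failed)."""
        vals = np.full(len(self.cells), np.nan)
        for i, cell in enumerate(self.cells):
            if cell.result is not None:
                vals[i] = getattr(cell.result, which)
        return vals.reshape(self.shape)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per cell with full provenance.

        Columns are the axis coordinates, every parameter, every
        initial-state component (prefixed ``init_``), the three final
        frequencies, ``converged``, ``t_final`` and ``error``; frequency
        and ``t_final`` fields are empty for failed cells.
        """
        reserved = {"variant", "scenario", "f_attacker", "f_target",
                    "f_transconjugant", "converged", "t_final", "error"}
        rows = []
        for cell in self.cells:
            row: dict = {"variant": cell.variant.value, "scenario": cell.scenario.value}
            # axis coordinates; renamed on collision with a result column
            # (e.g. an initial-frequency axis named f_target)
            row.update({
                (k if k not in reserved else f"axis_{k}"): v
                for k, v in cell.coords.items()
            })
            row.update(cell.params.to_dict())
            row.update({f"init_{k}": v for k, v in cell.init.to_dict().items()})
            if cell.result is not None:
                row.update(
                    f_attacker=cell.result.f_attacker,
                    f_target=cell.result.f_target,
                    f_transconjugant=cell.result.f_transconjugant,
                    converged=cell.result.converged,
                    t_final=cell.result.t_final,
                    error="",
                )
            else:
                row.update(
                    f_attacker=np.nan, f_target=np.nan, f_transconjugant=np.nan,
                    converged=False, t_final=np.nan, error=cell.error or "",
                )
            rows.append(row)
        if not rows:  # empty sweep: header-only output downstream
            base_cols = ["variant", "scenario", "f_attacker", "f_target",
                         "f_transconjugant", "converged", "t_final", "error"]
            return pd.DataFrame(columns=base_cols)
        frame = pd.DataFrame(rows)
        return frame.reindex(columns=sorted(frame.columns))


def _evaluate(
    axes: tuple[AxisSpec, ...],
    variant: ModelVariant,
    scenario: Scenario,
    make_inputs,
    **run_kwargs,
) -> SweepGrid:
    """Run one competition per axis-value combination.

    ``make_inputs(coords) -> (params, init)`` builds each cell's inputs
    from its axis coordinates; scenario overrides are applied afterwards
    inside :func:`run_scenario` (so e.g. a transfer-only sweep pins E = 0
    no matter what an E axis requests).
    """
    cells = []
    for combo in itertools.product(*(a.values for a in axes)):
        coords = {a.name: v for a, v in zip(axes, combo)}
        params, init = make_inputs(coords)
        try:
            result = run_scenario(
                scenario, variant, params=params, init=init, **run_kwargs
            )
            error = None
        except (RuntimeError, ValueError) as exc:
            result, error = None, str(exc)
        cells.append(
            SweepCell(
                coords=coords, variant=variant, scenario=scenario,
                params=params, init=init, result=result, error=error,
            )
        )
    return SweepGrid(axes=axes, variant=variant, scenario=scenario, cells=tuple(cells))


def _frequency_init(
    variant: ModelVariant, f_target: float, total_density: float
) -> SystemState:
    """Initial condition at a given target frequency, transconjugant-free."""
    base = default_initial_state(variant)
    return base.replace(
        C1=(1.0 - f_target) * total_density, C2=f_target * total_density, C3=0.0
    )


def sweep_b_E(
    variant: ModelVariant | str,
    scenario: Scenario | str,
    b_values,
    E_values,
    base_params: ModelParams | None = None,
    init: SystemState | None = None,
    **run_kwargs,
) -> SweepGrid:
    """Steady-state endpoints over a conjugation-rate x toxin-potency grid."""
    variant = ModelVariant(variant)
    scenario = Scenario(scenario)
    base = base_params or ModelParams()
    init = init or default_initial_state(variant)
    axes = (AxisSpec("b", tuple(b_values)), AxisSpec("E", tuple(E_values), "log"))

    def make_inputs(coords):
        return base.replace(b=coords["b"], E=coords["E"]), init

    return _evaluate(axes, variant, scenario, make_inputs, **run_kwargs)


def sweep_initial_frequencies(
    variant: ModelVariant | str,
    scenario: Scenario | str,
    freq_values,
    total_density: float = DEFAULT_TOTAL_DENSITY,
    base_params: ModelParams | None = None,
    **run_kwargs,
) -> SweepGrid:
    """Endpoints as a function of the initial target frequency.

    The axis is the target's share ``f_target`` of a fixed total inoculum
    (attacker share ``1 - f_target``; no initial transconjugants).
    """
    variant = ModelVariant(variant)
    scenario = Scenario(scenario)
    base = base_params or ModelParams()
    axes = (AxisSpec("f_target", tuple(freq_values)),)

    def make_inputs(coords):
        return base, _frequency_init(variant, coords["f_target"], total_density)

    return _evaluate(axes, variant, scenario, make_inputs, **run_kwargs)


def sweep_density_frequency(
    variant: ModelVariant | str,
    density_values,
    freq_values,
    base_params: ModelParams | None = None,
    scenario: Scenario | str = Scenario.KILLING_AND_TRANSFER,
    **run_kwargs,
) -> SweepGrid:
    """Endpoints over total inoculum density x initial target frequency."""
    variant = ModelVariant(variant)
    scenario = Scenario(scenario)
    base = base_params or ModelParams()
    axes = (
        AxisSpec("density", tuple(density_values), "log"),
        AxisSpec("f_target", tuple(freq_values)),
    )

    def make_inputs(coords):
        return base, _frequency_init(variant, coords["f_target"], coords["density"])

    return _evaluate(axes, variant, scenario, make_inputs, **run_kwargs)


def sweep_niche_separation(
    total_nutrients: float = 3.0,
    n_steps: int = 21,
    base_params: ModelParams | None = None,
    scenarios=tuple(Scenario),
    **run_kwargs,
) -> dict[Scenario, SweepGrid]:
    """Shift a fixed nutrient pool from fully shared to fully private.

    The separation axis ``s`` runs from 0 (``N1 = total``, ``N2 = N3 = 0``:
    complete niche overlap, identical to the default model) to 1
    (``N1 = 0``, ``N2 = N3 = total/2``: complete separation), holding
    ``N1 + N2 + N3 = total_nutrients`` and ``N2 = N3`` throughout. Returns
    one grid per requested scenario.
    """
    if total_nutrients <= 0:
        raise ValueError(f"total_nutrients must be > 0, got {total_nutrients!r}")
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps!r}")
    base = base_params or ModelParams()
    axes = (AxisSpec("niche_separation", tuple(np.linspace(0.0, 1.0, n_steps))),)

    def make_inputs(coords):
        s = coords["niche_separation"]
        init = SystemState(
            C1=0.01, C2=0.01, C3=0.0,
            N1=(1.0 - s) * total_nutrients,
            N2=s * total_nutrients / 2.0,
            N3=s * total_nutrients / 2.0,
            T=0.0,
        )
        return base, init

    return {
        Scenario(sc): _evaluate(
            axes, ModelVariant.METABOLIC_DIVERSITY, Scenario(sc), make_inputs, **run_kwargs
        )
        for sc in scenarios
    }


def _apply_axis_value(
    name: str,
    value: float,
    params: ModelParams,
    init: SystemState,
    variant: ModelVariant,
) -> tuple[ModelParams, SystemState]:
    if name in ModelParams.field_names():
        return params.replace(**{name: value}), init
    if name in STATE_FIELDS:
        return params, init.replace(**{name: value})
    if name == "density":
        total = init.total_biomass
        f_target = init.C2 / total if total > 0 else 0.5
        return params, init.replace(
            C1=(1.0 - f_target) * value, C2=f_target * value, C3=0.0
        )
    if name == "f_target":
        total = init.total_biomass or DEFAULT_TOTAL_DENSITY
        return params, init.replace(C1=(1.0 - value) * total, C2=value * total, C3=0.0)
    raise ValueError(
        f"unknown sweep parameter {name!r}; valid names: " + ", ".join(SWEEPABLE_NAMES)
    )


def sweep_axes(
    axes,
    variant: ModelVariant | str,
    scenario: Scenario | str,
    base_params: ModelParams | None = None,
    base_init: SystemState | None = None,
    **run_kwargs,
) -> SweepGrid:
    """General sweep over arbitrary named axes (any :data:`SWEEPABLE_NAMES`).

    Drives the config/CLI sweep path; the specialized ``sweep_*`` functions
    cover the standard study designs.
    """
    variant = ModelVariant(variant)
    scenario = Scenario(scenario)
    axes = tuple(axes)
    base = base_params or ModelParams()
    init0 = base_init or default_initial_state(variant)
    for axis in axes:
        if axis.name not in SWEEPABLE_NAMES:
            raise ValueError(
                f"unknown sweep parameter {axis.name!r}; valid names: "
                + ", ".join(SWEEPABLE_NAMES)
            )

    def make_inputs(coords):
        params, init = base, init0
        for name, value in coords.items():
            params, init = _apply_axis_value(name, value, params, init, variant)
        return params, init

    return _evaluate(axes, variant, scenario, make_inputs, **run_kwargs)


def sweep_one_at_a_time(
    parameter_name: str,
    values,
    base_params: ModelParams | None = None,
    scenario: Scenario | str = Scenario.KILLING_AND_TRANSFER,
    **run_kwargs,
) -> dict[ModelVariant, SweepGrid]:
    """Vary one parameter, defaults elsewhere, in both model variants.

    ``parameter_name`` may be any rate/affinity constant (e.g. ``gamma``,
    ``E``, ``b``, ``rC1``), any initial-state component (e.g. ``N1``,
    ``C1``), the total inoculum ``density`` (split 1:1 between attacker
    and target), or the initial target frequency ``f_target``.
    """
    if parameter_name not in SWEEPABLE_NAMES:
        raise ValueError(
            f"unknown parameter {parameter_name!r}; valid names: "
            + ", ".join(SWEEPABLE_NAMES)
        )
    scenario = Scenario(scenario)
    base = base_params or ModelParams()
    axes = (AxisSpec(parameter_name, tuple(values)),)
    out: dict[ModelVariant, SweepGrid] = {}
    for variant in (ModelVariant.DEFAULT, ModelVariant.METABOLIC_DIVERSITY):

        def make_inputs(coords, variant=variant):
            value = coords[parameter_name]
            if parameter_name in ModelParams.field_names():
                return base.replace(**{parameter_name: value}), default_initial_state(variant)
            if parameter_name == "density":
                return base, _frequency_init(variant, 0.5, value)
            if parameter_name == "f_target":
                return base, _frequency_init(variant, value, DEFAULT_TOTAL_DENSITY)
            return base, default_initial_state(variant).replace(**{parameter_name: value})

        out[variant] = _evaluate(axes, variant, scenario, make_inputs, **run_kwargs)
    return out
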