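"""Response surfaces: per-cell medians and EOA over the T x P perturbation grid.

An impact/adaptation response surface maps an outcome (here, the ensemble
median of a percent-change metric) over joint temperature (dT) and
precipitation (dP) perturbations.  The companion EOA surface attaches, to
each cell, the agreement index computed from the *same* per-cell ensemble,
so a recommendation can be qualified by how strongly the ensemble agrees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EOA_CLASSES,
    AggregateMethod,
    EnsembleSample,
    Hypothesis,
    aggregate_members,
    compute_eoa,
    estimate_eoa_sampled,
)

__all__ = [
    "PerturbationGrid",
    "SurfaceResult",
    "RecommendationReport",
    "DEFAULT_DT_SPEC",
    "DEFAULT_DP_SPEC",
    "build_grid",
    "default_study_grid",
    "median_response_surface",
    "eoa_surface",
    "recommendation_report",
    "write_surface",
    "read_surface",
]

logger = logging.getLogger(__name__)

#: Default study grid: -1..+7 degC in 1 degC steps, -40..+30 % in 10 % steps.
DEFAULT_DT_SPEC = (-1.0, 7.0, 1.0)
DEFAULT_DP_SPEC = (-40.0, 30.0, 10.0)

SURFACE_COLUMNS = ["dT", "dP", "n_members", "median_response", "ES", "AF", "EOA", "EOA_class"]

_LEVEL_DECIMALS = 9  # levels rounded to exact decimals so cell keys compare reliably


@dataclass(frozen=True)
class PerturbationGrid:
    """Ordered temperature and precipitation offset levels spanning the grid."""

    dT_levels: tuple
    dP_levels: tuple

    def __post_init__(self) -> None:
        for name, levels in (("dT", self.dT_levels), ("dP", self.dP_levels)):
            if len(levels) == 0:
                raise ValueError(f"{name}_levels must be non-empty")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"{name}_levels must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return len(self.dT_levels) * len(self.dP_levels)

    def cells(self):
        """All (dT, dP) cells, dT-major."""
        for dT in self.dT_levels:
            for dP in self.dP_levels:
                yield (dT, dP)


def _levels(spec: tuple[float, float, float], name: str) -> tuple:
    lo, hi, step = (float(x) for x in spec)
    if step <= 0:
        raise ValueError(f"{name} step must be positive")
    if lo > hi:
        raise ValueError(f"{name} min must not exceed max")
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{name} range ({lo}, {hi}) is not divisible by step {step}")
    return tuple(round(lo + k * step, _LEVEL_DECIMALS) for k in range(int(round(n)) + 1))


def build_grid(
    dT_spec: tuple[float, float, float] = DEFAULT_DT_SPEC,
    dP_spec: tuple[float, float, float] = DEFAULT_DP_SPEC,
) -> PerturbationGrid:
    """Inclusive arithmetic grids on both axes from (min, max, step) specs."""
    return PerturbationGrid(
        dT_levels=_levels(dT_spec, "dT"), dP_levels=_levels(dP_spec, "dP")
    )


def default_study_grid() -> PerturbationGrid:
    """The 9 x 8 = 72-cell study grid."""
    return build_grid(DEFAULT_DT_SPEC, DEFAULT_DP_SPEC)


@dataclass
class SurfaceResult:
    """Per-cell aggregate response and/or EOA over a perturbation grid.

    ``table`` is tidy, one row per grid cell (``dT, dP, n_members,
    median_response, ES, AF, EOA, EOA_class``) with NA for empty cells and
    for layers not computed.  ``metadata`` records the context (option,
    metric, threshold, soil, CO2, aggregation method).
    """

    grid: PerturbationGrid
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _grid_from_cells(cells: dict) -> PerturbationGrid:
    dTs = tuple(sorted({dT for dT, _ in cells}))
    dPs = tuple(sorted({dP for _, dP in cells}))
    return PerturbationGrid(dT_levels=dTs, dP_levels=dPs)


def _empty_row(dT: float, dP: float) -> dict:
    return {
        "dT": dT, "dP": dP, "n_members": pd.NA, "median_response": np.nan,
        "ES": pd.NA, "AF": np.nan, "EOA": np.nan, "EOA_class": pd.NA,
    }


def median_response_surface(
    cells: dict[tuple[float, float], EnsembleSample],
    method: AggregateMethod = "median",
    grid: PerturbationGrid | None = None,
    metadata: dict | None = None,
) -> SurfaceResult:
    """Full-ensemble aggregate per cell (the IRS/ARS layer); EOA columns left NA."""
    if grid is None:
        grid = _grid_from_cells(cells)
    rows = []
    for dT, dP in grid.cells():
        row = _empty_row(dT, dP)
        sample = cells.get((dT, dP))
        if sample is not None:
            row["n_members"] = sample.n
            row["median_response"] = aggregate_members(sample.values, method)
        rows.append(row)
    table = pd.DataFrame(rows, columns=SURFACE_COLUMNS)
    meta = dict(metadata or {})
    meta["aggregate_method"] = method
    return SurfaceResult(grid=grid, table=table, metadata=meta)


def eoa_surface(
    cells: dict[tuple[float, float], EnsembleSample],
    h: Hypothesis,
    method: AggregateMethod = "median",
    grid: PerturbationGrid | None = None,
    metadata: dict | None = None,
    mode: str = "exhaustive",
    n_samples_per_size: int = 2000,
    seed: int | None = None,
    af_grouping: str = "ratio_sum",
) -> SurfaceResult:
    """Median response and EOA per cell, both from the same per-cell ensemble.

    Cells with no sample stay NA (never 0 — an EOA of 0 is a meaningful
    result, absence of data is not).  ``mode="sampled"`` switches the
    per-cell index to the Monte-Carlo estimator (seed required).
    """
    if grid is None:
        grid = _grid_from_cells(cells)
    rows = []
    for dT, dP in grid.cells():
        row = _empty_row(dT, dP)
        sample = cells.get((dT, dP))
        if sample is not None:
            row["n_members"] = sample.n
            row["median_response"] = aggregate_members(sample.values, method)
            if mode == "sampled":
                res = estimate_eoa_sampled(
                    sample, h, method, n_samples_per_size=n_samples_per_size,
                    seed=seed, af_grouping=af_grouping,
                )
            else:
                res = compute_eoa(sample, h, method, af_grouping=af_grouping)
            row["ES"] = res.es if res.es is not None else pd.NA
            row["AF"] = res.af
            row["EOA"] = res.eoa
            row["EOA_class"] = res.eoa_class
        rows.append(row)
    table = pd.DataFrame(rows, columns=SURFACE_COLUMNS)
    meta = dict(metadata or {})
    meta.update(
        threshold=h.threshold, direction=h.direction,
        aggregate_method=method, mode=mode,
    )
    return SurfaceResult(grid=grid, table=table, metadata=meta)


@dataclass
class RecommendationReport:
    """Cells whose EOA class reaches a minimum level, with bounding ranges."""

    cells: pd.DataFrame
    min_class: str
    dT_range: tuple | None
    dP_range: tuple | None
    region: dict | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def recommendation_report(
    surface: SurfaceResult,
    min_class: str = "High",
    region: dict | None = None,
) -> RecommendationReport:
    """Cells of an EOA surface at or above ``min_class``, optionally within a region.

    ``region`` may bound either axis, e.g. ``{"dP_max": 0}`` to restrict to
    precipitation decreases.  Class order is Low < Medium < High <
    Very high < Maximum.  The report is a pure class filter; any expert
    judgement layered on top of the index is out of its scope.
    """
    if min_class not in EOA_CLASSES:
        raise ValueError(f"unknown EOA class {min_class!r}")
    rank = {c: i for i, c in enumerate(EOA_CLASSES)}
    tbl = surface.table
    mask = tbl["EOA_class"].map(lambda c: rank.get(c, -1)) >= rank[min_class]
    if region:
        if "dT_min" in region:
            mask &= tbl["dT"] >= region["dT_min"]
        if "dT_max" in region:
            mask &= tbl["dT"] <= region["dT_max"]
        if "dP_min" in region:
            mask &= tbl["dP"] >= region["dP_min"]
        if "dP_max" in region:
            mask &= tbl["dP"] <= region["dP_max"]
    sel = tbl[mask].reset_index(drop=True)
    dT_range = (float(sel["dT"].min()), float(sel["dT"].max())) if len(sel) else None
    dP_range = (float(sel["dP"].min()), float(sel["dP"].max())) if len(sel) else None
    return RecommendationReport(
        cells=sel, min_class=min_class, dT_range=dT_range,
        dP_range=dP_range, region=region,
    )


def write_surface(surface: SurfaceResult, path: str | Path) -> Path:
    """Write a surface as tidy CSV (6 significant digits) plus a JSON metadata sidecar."""
    path = Path(path)
    surface.table.to_csv(path, index=False, float_format="%.6g", na_rep="NA")
    sidecar = path.with_suffix(".json")
    meta = dict(surface.metadata)
    meta["dT_levels"] = list(surface.grid.dT_levels)
    meta["dP_levels"] = list(surface.grid.dP_levels)
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_surface(path: str | Path) -> SurfaceResult:
    """Read back a surface written by :func:`write_surface`."""
    path = Path(path)
    table = pd.read_csv(path, na_values=["NA"])
    table["n_members"] = table["n_members"].astype("Int64")
    table["ES"] = table["ES"].astype("Int64")
    sidecar = path.with_suffix(".json")
    metadata: dict = {}
    grid = None
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        if "dT_levels" in metadata and "dP_levels" in metadata:
            grid = PerturbationGrid(
                dT_levels=tuple(metadata.pop("dT_levels")),
                dP_levels=tuple(metadata.pop("dP_levels")),
            )
    if grid is None:
        grid = PerturbationGrid(
            dT_levels=tuple(sorted(table["dT"].unique())),
            dP_levels=tuple(sorted(table["dP"].unique())),
        )
    return SurfaceResult(grid=grid, table=table, metadata=metadata)
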