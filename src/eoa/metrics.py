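"""Adaptation and recovery response metrics from raw model-run tables.

Raw inputs are long-format tables of per-model 30-year-mean yields over a
temperature x precipitation perturbation grid (one row per member, option,
soil, CO2 level and grid cell).  Two percent-change metrics are derived:

* adaptation value — yield with an adaptation option relative to the
  unadapted run under the *same* climate perturbation;
* recovery value — yield with the option under perturbation relative to the
  member's own unperturbed, unadapted baseline (baseline CO2).

Each member's own runs provide its denominators; members lacking either
operand at a cell are dropped from that cell's ensemble (never imputed),
so the available ensemble size N can vary cell by cell.
"""

from __future__ import annotations

import logging
import math
from typing import Literal

import pandas as pd

from .core import EnsembleSample

__all__ = [
    "REQUIRED_COLUMNS",
    "UNADAPTED_CODE",
    "BASELINE_CO2",
    "adaptation_value",
    "recovery_value",
    "build_member_metric_table",
]

logger = logging.getLogger(__name__)

#: Long-format schema shared by all readers/writers.
REQUIRED_COLUMNS = ["member", "option", "soil", "co2_ppm", "dT", "dP", "yield"]

#: Option code of the no-adaptation reference runs.
UNADAPTED_CODE = "unadapted"

#: CO2 concentration (ppm) of the unperturbed baseline simulations.
BASELINE_CO2 = 360

Metric = Literal["adaptation", "recovery"]


def adaptation_value(y_adapted: float, y_unadapted: float) -> float:
    """Percent yield change of an adapted vs unadapted run, same perturbation.

    Returns NaN (member excluded downstream) when the unadapted yield is
    zero — a crop failure leaves no meaningful reference.
    """
    if y_unadapted < 0 or y_adapted < 0:
        raise ValueError("yields must be non-negative")
    if y_unadapted == 0:
        logger.warning("unadapted yield is 0; adaptation value undefined")
        return math.nan
    return 100.0 * (y_adapted - y_unadapted) / y_unadapted


def recovery_value(y_adapted_perturbed: float, y_baseline: float) -> float:
    """Percent yield change of an adapted, perturbed run vs the unperturbed baseline."""
    if y_baseline < 0 or y_adapted_perturbed < 0:
        raise ValueError("yields must be non-negative")
    if y_baseline == 0:
        logger.warning("baseline yield is 0; recovery value undefined")
        return math.nan
    return 100.0 * (y_adapted_perturbed - y_baseline) / y_baseline


def _check_columns(runs: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in runs.columns]
    if missing:
        raise ValueError(f"model-run table is missing columns: {missing}")


def build_member_metric_table(
    runs: pd.DataFrame,
    metric: Metric,
    option_code: str,
    soil: str,
    co2: float,
    unadapted_code: str = UNADAPTED_CODE,
    baseline_co2: float = BASELINE_CO2,
) -> dict[tuple[float, float], EnsembleSample]:
    """Per-cell ensembles of one response metric for one option/soil/CO2 context.

    Returns a mapping from grid cell ``(dT, dP)`` to the :class:`EnsembleSample`
    of per-member metric values at that cell.  Cells where no member has
    complete data are omitted (empty, to be rendered as NA downstream).
    Samples never mix options, soils or CO2 levels.
    """
    _check_columns(runs)
    if metric not in ("adaptation", "recovery"):
        raise ValueError(f"unknown metric {metric!r}")

    adapted = runs[
        (runs["option"] == option_code)
        & (runs["soil"] == soil)
        & (runs["co2_ppm"] == co2)
    ][["member", "dT", "dP", "yield"]]
    if adapted.empty:
        logger.warning(
            "no runs for option=%s soil=%s co2=%s", option_code, soil, co2
        )
        return {}

    if metric == "adaptation":
        ref = runs[
            (runs["option"] == unadapted_code)
            & (runs["soil"] == soil)
            & (runs["co2_ppm"] == co2)
        ][["member", "dT", "dP", "yield"]].rename(columns={"yield": "y_ref"})
        merged = adapted.merge(ref, on=["member", "dT", "dP"], how="inner")
    else:
        ref = runs[
            (runs["option"] == unadapted_code)
            & (runs["soil"] == soil)
            & (runs["co2_ppm"] == baseline_co2)
            & (runs["dT"] == 0)
            & (runs["dP"] == 0)
        ][["member", "yield"]].rename(columns={"yield": "y_ref"})
        merged = adapted.merge(ref, on="member", how="inner")

    dropped = merged["y_ref"] <= 0
    if dropped.any():
        bad = sorted(merged.loc[dropped, "member"].unique())
        logger.warning(
            "dropping %d member-cell records with zero reference yield "
            "(members: %s)", int(dropped.sum()), bad
        )
        merged = merged[~dropped]

    # Percent changes are rounded to 9 decimals: yields carry far less
    # precision, and a metric sitting a few ulps off a representable
    # threshold (e.g. 10.000000000000002 vs a strict "> 10") would make the
    # fulfilment test an artifact of multiplication order.
    merged = merged.assign(
        metric_value=(100.0 * (merged["yield"] - merged["y_ref"]) / merged["y_ref"]).round(9)
    )

    cells: dict[tuple[float, float], EnsembleSample] = {}
    for (dT, dP), grp in merged.groupby(["dT", "dP"], sort=True):
        grp = grp.sort_values("member")
        cells[(float(dT), float(dP))] = EnsembleSample(
            member_ids=tuple(grp["member"]),
            values=tuple(float(v) for v in grp["metric_value"]),
        )
    return cells
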