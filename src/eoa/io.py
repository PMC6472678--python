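"""Reading/writing model-run tables and the end-to-end surface pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import Hypothesis, count_subsets
from .metrics import (
    BASELINE_CO2,
    REQUIRED_COLUMNS,
    UNADAPTED_CODE,
    build_member_metric_table,
)
from .surfaces import SurfaceResult, eoa_surface, write_surface

__all__ = ["RunConfig", "read_model_runs", "write_model_runs", "run_pipeline"]

logger = logging.getLogger(__name__)

_KEY_COLUMNS = ["member", "option", "soil", "co2_ppm", "dT", "dP"]


def read_model_runs(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a long-format model-run table (CSV, or TSV for .tsv).

    Raises on a missing/malformed header, non-numeric values (reported with
    1-based file line numbers) and duplicate
    (member, option, soil, co2_ppm, dT, dP) keys (reported by key).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep, dtype={"member": str, "option": str, "soil": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: header is missing columns {missing}")
    for col in ("co2_ppm", "dT", "dP", "yield"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in table.index[bad][:5]]  # +2: header + 1-based
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        if coerced.isna().any():
            lines = [int(i) + 2 for i in table.index[coerced.isna()][:5]]
            raise ValueError(f"{path}: missing values in column {col!r} at line(s) {lines}")
        table[col] = coerced
    if (table["yield"] < 0).any():
        lines = [int(i) + 2 for i in table.index[table["yield"] < 0][:5]]
        raise ValueError(f"{path}: negative yield at line(s) {lines}")
    dup = table.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dup.any():
        key = tuple(table.loc[table.index[dup][0], _KEY_COLUMNS])
        raise ValueError(
            f"{path}: duplicate (member,option,soil,co2_ppm,dT,dP) key, e.g. {key}"
        )
    return table


def write_model_runs(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a model-run table as CSV (full double precision, round-trip safe)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Precedence when loading: CLI flags > config file > these defaults.
    ``options=None`` means every non-unadapted option present in the input.
    """

    input: str = ""
    output_dir: str = "eoa_output"
    metric: str = "adaptation"
    options: list | None = None
    thresholds: list = field(default_factory=lambda: [0.0])
    direction: str = "greater"
    aggregate_method: str = "median"
    af_grouping: str = "ratio_sum"
    soils: list | None = None
    co2_levels: list | None = None
    mode: str = "exhaustive"
    n_samples_per_size: int = 2000
    seed: int | None = None
    unadapted_code: str = UNADAPTED_CODE
    baseline_co2: float = BASELINE_CO2

    def __post_init__(self) -> None:
        if self.metric not in ("adaptation", "recovery"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mode not in ("exhaustive", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "sampled" and self.seed is None:
            raise ValueError("sampled mode requires a seed")
        if not self.thresholds:
            raise ValueError("at least one threshold is required")
        for t in self.thresholds:
            if not pd.notna(t) or abs(float(t)) == float("inf"):
                raise ValueError("thresholds must be finite")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _fmt_threshold(t: float) -> str:
    return f"{t:g}".replace("-", "m").replace(".", "p")


def output_name(option: str, metric: str, threshold: float, soil: str, co2) -> str:
    """Stable, shell-safe output file name for one surface."""
    return f"{option}__{metric}__thr{_fmt_threshold(threshold)}__{soil}__{co2:g}.csv"


def run_pipeline(config: RunConfig) -> list[Path]:
    """Metric table -> per-cell ensembles -> median + EOA surfaces -> CSV/JSON.

    One output file per (option, threshold, soil, CO2) combination.  A cell
    that cannot be computed degrades to NA with a warning; an empty
    selection (no matching runs at all) is an error.
    """
    runs = read_model_runs(config.input)
    options = config.options
    if not options:
        options = sorted(set(runs["option"]) - {config.unadapted_code})
    if not options:
        raise ValueError("no adaptation options selected or present in the input")
    soils = config.soils or sorted(runs["soil"].unique())
    co2_levels = config.co2_levels
    if co2_levels is None:
        co2_levels = sorted(set(runs["co2_ppm"]) - {config.baseline_co2})

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for option in options:
        for soil in soils:
            for co2 in co2_levels:
                t0 = time.perf_counter()
                cells = build_member_metric_table(
                    runs, config.metric, option, soil, co2,
                    unadapted_code=config.unadapted_code,
                    baseline_co2=config.baseline_co2,
                )
                if not cells:
                    logger.warning(
                        "no data for option=%s soil=%s co2=%s; skipped",
                        option, soil, co2,
                    )
                    continue
                ns = sorted({s.n for s in cells.values()})
                logger.info(
                    "option=%s soil=%s co2=%s: %d cells, N per cell %s, "
                    "subsets per cell up to %d",
                    option, soil, co2, len(cells), ns, count_subsets(max(ns)),
                )
                for threshold in config.thresholds:
                    h = Hypothesis(threshold=float(threshold), direction=config.direction)
                    surface = eoa_surface(
                        cells, h, config.aggregate_method,
                        metadata={
                            "option": option, "metric": config.metric,
                            "soil": soil, "co2_ppm": co2,
                            "input": str(config.input),
                        },
                        mode=config.mode,
                        n_samples_per_size=config.n_samples_per_size,
                        seed=config.seed,
                        af_grouping=config.af_grouping,
                    )
                    name = output_name(option, config.metric, float(threshold), soil, co2)
                    written.append(write_surface(surface, out_dir / name))
                logger.info(
                    "option=%s soil=%s co2=%s done in %.2f s",
                    option, soil, co2, time.perf_counter() - t0,
                )
    if not written:
        raise ValueError("selection matched no data; nothing was written")
    return written
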