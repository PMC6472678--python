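"""Synthetic ensembles and model-run tables with known agreement structure.

Two generators back the test strategy:

* :func:`make_known_es_ensemble` builds a two-level ensemble (``m``
  dissenters below the threshold, the rest above) whose minimum
  all-fulfilling size ES is known in closed form, and cross-checks that
  closed form against exhaustive subset enumeration at construction time.
* :func:`simulate_model_runs` emulates a multi-model crop ensemble over a
  temperature x precipitation perturbation grid: a linear climate response
  plus an injected adaptation effect, member-specific bias, residual noise
  and optional missing member-option pairs — every downstream stage can be
  exercised with a fully known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import EnsembleSample, Hypothesis, subset_aggregates
from .metrics import BASELINE_CO2, REQUIRED_COLUMNS, UNADAPTED_CODE
from .surfaces import PerturbationGrid, default_study_grid

__all__ = [
    "SyntheticEnsembleSpec",
    "SyntheticRunSpec",
    "closed_form_es",
    "make_known_es_ensemble",
    "simulate_model_runs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Two-level ensemble: ``n_dissenters`` members at ``dissent_value`` (below
    the threshold), the remainder at ``consent_value`` (above it)."""

    n_members: int
    n_dissenters: int
    dissent_value: float
    consent_value: float
    threshold: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_dissenters < self.n_members:
            raise ValueError("need 0 <= n_dissenters < n_members")
        if not self.dissent_value < self.threshold < self.consent_value:
            raise ValueError("need dissent_value < threshold < consent_value")

    @property
    def dissent_dominates(self) -> bool:
        """True when the dissenters sit further from the threshold than the consenters."""
        return (self.threshold - self.dissent_value) >= (
            self.consent_value - self.threshold
        )


def closed_form_es(spec: SyntheticEnsembleSpec) -> int:
    """Analytic ES of a two-level ensemble under median aggregation.

    The worst size-``s`` subset packs ``min(s, m)`` dissenters.  With the
    dissent magnitude at least the consent magnitude, an even split's median
    lands at or below the threshold (strict fulfilment fails), so every
    subset fulfils H iff ``2 m < s``: ES = 2m + 1.  With dissent strictly
    smaller in magnitude, the even split's median exceeds the threshold and
    ES = 2m (ES = 1 when there are no dissenters).
    """
    m = spec.n_dissenters
    if m == 0:
        return 1
    es = 2 * m + 1 if spec.dissent_dominates else 2 * m
    if es > spec.n_members:
        raise ValueError(
            f"no all-fulfilling size exists: implied ES {es} exceeds N {spec.n_members}"
        )
    return es


def make_known_es_ensemble(spec: SyntheticEnsembleSpec) -> tuple[EnsembleSample, int]:
    """Build the two-level ensemble and its analytically known ES.

    The closed form is verified against full subset enumeration before the
    sample is returned; a mismatch aborts construction (it would indicate a
    defect in the enumeration core, not in the fixture).  ``seed`` only
    shuffles member order, which no downstream result may depend on.
    """
    values = [spec.dissent_value] * spec.n_dissenters + [spec.consent_value] * (
        spec.n_members - spec.n_dissenters
    )
    if spec.seed is not None:
        rng = np.random.default_rng(spec.seed)
        rng.shuffle(values)
    sample = EnsembleSample.from_values(values)
    true_es = closed_form_es(spec)

    h = Hypothesis(threshold=spec.threshold, direction="greater")
    enumerated_es = None
    for size in range(1, spec.n_members + 1):
        if bool(h.fulfils(subset_aggregates(sample, size, "median")).all()):
            enumerated_es = size
            break
    if enumerated_es != true_es:
        raise AssertionError(
            f"closed-form ES {true_es} disagrees with enumeration {enumerated_es} "
            f"for spec {spec}"
        )
    return sample, true_es


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Parameters of the synthetic multi-model run table.

    Yields follow ``base_yield * soil_factor * co2_factor(co2) *
    (1 + slope_T*dT + slope_P*dP) * (1 + (effect(dT,dP) + bias_m)*[adapted]) *
    (1 + eps)``, clipped at zero.  The adaptation effect enters
    multiplicatively on the climate-adjusted yield, so in the noiseless case
    the injected effect is recovered *exactly* as the adaptation value (a
    ratio of yields) at every grid cell.  The member bias ``bias_m``
    perturbs each member's adaptation *response* — a pure level bias would
    cancel out of both response metrics (each member is its own
    denominator) and be unobservable.  Defaults mirror
    the study dimensions: 17 members, the
    72-cell grid, shallow/deep soils and CO2 at 447/522 ppm, with a
    360 ppm unperturbed baseline run per member and soil.

    ``adaptation_effects`` maps option codes to the injected adaptation
    effect, a fraction of yield (0.10 = +10 %) or a callable ``f(dT, dP)``.
    ``sigma_model`` is the s.d. of the per-member adaptation-response bias
    in yield-fraction units (default 0.03: members disagree about the
    benefit by a few percent of yield); ``sigma_resid`` the s.d. of per-run
    relative noise (default 0.02).  ``missing_fraction`` removes
    that share of adapted member-option pairs uniformly at random,
    mimicking members that never simulated an option; unadapted and
    baseline runs are always kept so denominators exist.
    """

    n_models: int = 17
    grid: PerturbationGrid = field(default_factory=default_study_grid)
    base_yield: float = 6000.0
    slope_T: float = -0.05
    slope_P: float = 0.005
    adaptation_effects: dict = field(
        default_factory=lambda: {"adapt1": 0.10}
    )
    soils: tuple = ("shallow", "deep")
    co2_levels: tuple = (447, 522)
    soil_factors: dict = field(
        default_factory=lambda: {"shallow": 0.85, "deep": 1.0}
    )
    co2_sensitivity: float = 0.0005  # fractional yield gain per ppm above baseline
    sigma_model: float = 0.03
    sigma_resid: float = 0.02
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.base_yield <= 0:
            raise ValueError("base_yield must be positive")
        if self.sigma_model < 0 or self.sigma_resid < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")


def _effect_at(effect, dT: float, dP: float) -> float:
    return float(effect(dT, dP)) if callable(effect) else float(effect)


def simulate_model_runs(spec: SyntheticRunSpec) -> pd.DataFrame:
    """Generate a long-format model-run table, deterministic under ``spec.seed``.

    Columns: ``member, option, soil, co2_ppm, dT, dP, yield``.  Includes the
    unadapted option at every grid cell / soil / CO2 level plus one
    unperturbed baseline row (dT=0, dP=0, 360 ppm, unadapted) per member and
    soil.
    """
    rng = np.random.default_rng(spec.seed)
    members = [f"model{i + 1:02d}" for i in range(spec.n_models)]
    bias = rng.normal(0.0, spec.sigma_model, size=spec.n_models)

    options = [UNADAPTED_CODE] + sorted(spec.adaptation_effects)
    cells = list(spec.grid.cells())

    rows: list[tuple] = []
    for mi, member in enumerate(members):
        for option in options:
            effect = spec.adaptation_effects.get(option, 0.0)
            for soil in spec.soils:
                sf = spec.soil_factors.get(soil, 1.0)
                for co2 in spec.co2_levels:
                    cf = 1.0 + spec.co2_sensitivity * (co2 - BASELINE_CO2)
                    eps = rng.normal(0.0, spec.sigma_resid, size=len(cells))
                    adapted = option != UNADAPTED_CODE
                    for (dT, dP), e in zip(cells, eps):
                        climate = 1.0 + spec.slope_T * dT + spec.slope_P * dP
                        boost = (
                            1.0 + _effect_at(effect, dT, dP) + bias[mi]
                            if adapted
                            else 1.0
                        )
                        rel = climate * boost * (1.0 + e)
                        rows.append(
                            (member, option, soil, co2,
                             dT, dP, max(spec.base_yield * sf * cf * rel, 0.0))
                        )
                if option == UNADAPTED_CODE:
                    e = float(rng.normal(0.0, spec.sigma_resid))
                    rows.append(
                        (member, option, soil, BASELINE_CO2, 0.0, 0.0,
                         max(spec.base_yield * sf * (1.0 + e), 0.0))
                    )

    table = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)

    if spec.missing_fraction > 0:
        pairs = [
            (m, o) for m in members for o in options if o != UNADAPTED_CODE
        ]
        n_drop = int(round(spec.missing_fraction * len(pairs)))
        if n_drop:
            drop_idx = rng.choice(len(pairs), size=n_drop, replace=False)
            dropped = {pairs[i] for i in drop_idx}
            keep = ~table.apply(
                lambda r: (r["member"], r["option"]) in dropped, axis=1
            )
            logger.info(
                "removed %d member-option pairs (%d rows) as missing",
                n_drop, int((~keep).sum()),
            )
            table = table[keep].reset_index(drop=True)

    return table
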