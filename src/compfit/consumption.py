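"""Food-consumption assays: plate GFP normalization and liquid OD clearing.

Plate assay: wells seeded with GFP-labelled bacteria are read at 0 h and
18 h.  Control wells (no animals) measure signal decay; their model is
F0 = beta * F18 with no intercept, so beta is estimated by least squares
through the origin over the control wells.  Consumption in a test well is
then F0 - beta * F18 — the signal loss beyond photobleaching/decay.
Negative values are reported as-is so group statistics stay unbiased.

Liquid assay: OD600 is read every 24 h for 5 days; clearing is the daily
first difference and the cumulative drop from day one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Well:
    well_id: str
    role: str  # "test" or "control"
    signal_t0: float = 0.0
    signal_t1: float = 0.0
    od_series: tuple = ()  # (day, od600) pairs, liquid assay only

    def __post_init__(self):
        if self.role not in ("test", "control"):
            raise ValueError(f"unknown well role {self.role!r}")
        if self.signal_t0 < 0 or self.signal_t1 < 0:
            raise ValueError("signals must be non-negative")


@dataclass(frozen=True)
class WellPlate:
    wells: tuple
    assay: str = "plate_gfp"  # or "liquid_od"

    def __post_init__(self):
        object.__setattr__(self, "wells", tuple(self.wells))
        if self.assay not in ("plate_gfp", "liquid_od"):
            raise ValueError(f"unknown assay {self.assay!r}")

    @property
    def test_wells(self):
        return [w for w in self.wells if w.role == "test"]

    @property
    def control_wells(self):
        return [w for w in self.wells if w.role == "control"]


@dataclass(frozen=True)
class ConsumptionResult:
    beta: float
    per_well_consumption: tuple
    well_ids: tuple
    n_controls: int

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")


def estimate_beta(plate: WellPlate, with_intercept: bool = False):
    """Estimate the control-well decay coefficient beta.

    Default regresses F0 on F18 through the origin (the decay model has no
    intercept): beta = sum(F0*F18) / sum(F18^2).  ``with_intercept=True``
    fits F0 = a + beta*F18 instead, returning (beta, a) for diagnostics.
    """
    controls = plate.control_wells
    if not controls:
        raise ValueError("no control wells; beta cannot be estimated")
    f0 = np.array([w.signal_t0 for w in controls])
    f1 = np.array([w.signal_t1 for w in controls])
    if np.all(f1 == 0):
        raise ValueError("all control wells have zero 18h signal")
    if with_intercept:
        X = np.column_stack([np.ones_like(f1), f1])
        (a, beta), *_ = np.linalg.lstsq(X, f0, rcond=None)
        return float(beta), float(a)
    return float(np.sum(f0 * f1) / np.sum(f1 * f1))


def consumption_per_well(plate: WellPlate, beta: float):
    """Per-test-well consumption F0 - beta*F18 (may be negative; not clipped)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return [w.signal_t0 - beta * w.signal_t1 for w in plate.test_wells]


def analyze_plate(plate: WellPlate, with_intercept: bool = False) -> ConsumptionResult:
    """Estimate beta from controls and consumption for every test well."""
    if with_intercept:
        beta, _ = estimate_beta(plate, with_intercept=True)
    else:
        beta = estimate_beta(plate)
    cons = consumption_per_well(plate, beta)
    return ConsumptionResult(
        beta=beta,
        per_well_consumption=tuple(cons),
        well_ids=tuple(w.well_id for w in plate.test_wells),
        n_controls=len(plate.control_wells),
    )


def liquid_clearing_summary(plate: WellPlate):
    """Daily and cumulative OD600 clearing per well of a liquid assay.

    Returns a dict well_id -> {"days", "daily_consumed", "cumulative"} where
    daily_consumed[k] = OD(day_k) - OD(day_{k+1}) and cumulative is the total
    drop from the first day.  Wells must have contiguous daily readings.
    """
    if plate.assay != "liquid_od":
        raise ValueError("liquid_clearing_summary requires a liquid_od plate")
    gaps = []
    out = {}
    for w in plate.wells:
        series = sorted(w.od_series)
        if len(series) < 2:
            gaps.append(w.well_id)
            continue
        days = [d for d, _ in series]
        if any(b - a != 1 for a, b in zip(days, days[1:])):
            gaps.append(w.well_id)
            continue
        od = np.array([v for _, v in series], dtype=float)
        daily = od[:-1] - od[1:]
        out[w.well_id] = {
            "days": tuple(days),
            "daily_consumed": tuple(float(x) for x in daily),
            "cumulative": float(od[0] - od[-1]),
        }
    if gaps:
        raise ValueError(
            "missing or non-contiguous daily OD readings in wells: "
            + ", ".join(gaps)
        )
    return out


def simulate_plate(true_consumption_mean=300.0, beta_true=0.9, noise_sd=0.0,
                   n_test=20, n_control=4, control_signal=4000.0,
                   test_signal=4000.0, rng=None) -> WellPlate:
    """Synthetic plate-GFP assay with known decay and consumption.

    Controls decay from F18 to F0 = beta_true*F18 (+ Gaussian noise on F0);
    test wells additionally lose ``true_consumption_mean`` fluorescence units
    to feeding.  At noise_sd = 0 the generated plate is exactly recoverable.
    """
    rng = np.random.default_rng(rng)
    wells = []
    for i in range(n_control):
        f18 = control_signal * (1.0 + 0.05 * i)  # spread for a stable fit
        f0 = beta_true * f18 + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        wells.append(Well(well_id=f"C{i + 1}", role="control",
                          signal_t0=max(f0, 0.0), signal_t1=f18))
    for i in range(n_test):
        f18 = test_signal
        f0 = (beta_true * f18 + true_consumption_mean
              + (rng.normal(0, noise_sd) if noise_sd else 0.0))
        wells.append(Well(well_id=f"T{i + 1}", role="test",
                          signal_t0=max(f0, 0.0), signal_t1=f18))
    return WellPlate(wells=tuple(wells), assay="plate_gfp")
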