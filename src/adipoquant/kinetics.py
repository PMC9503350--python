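"""Fractional glucose extraction and glucose uptake from dynamic PET TACs.

The quantification follows the fractional uptake rate (FUR) convention for an
irreversibly trapped tracer such as 18F-FDG: the steady-phase tissue activity
is normalized to the blood activity integrated from injection to the steady
phase,

    GE = mean tissue activity over the steady-phase window
         / integral of blood activity from t=0 to the integration endpoint

with units min^-1 (equivalently mL plasma cleared per min per mL tissue;
tissue density is taken as 1 g/mL so "per mL" and "per g" interchange).
Multiplying GE by plasma glucose (mmol/L == umol/mL) and by 100 gives glucose
uptake GU in umol/min per 100 g tissue. Scaling per-mass GU by the estimated
whole subcutaneous depot mass (1.5% of body weight in young mice, 2.0% in
adults) gives whole-depot uptake in umol/min.

Numerical conventions: TAC samples are taken at frame midpoints; the blood
integral uses the composite trapezoid after prepending a (t=0, activity=0)
origin (activity is zero at the moment of an intraperitoneal injection); the
default steady phase is the 40-60 min window with the integration endpoint at
its midpoint (50 min). All three are configurable through SteadyPhaseRule.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .imaging import Tac

#: Whole-depot SAT mass as a fraction of body weight, by age group.
SAT_MASS_FRACTION = {"1mo": 0.015, "6mo": 0.020}
_AGE_ALIASES = {
    "1mo": "1mo",
    "young": "1mo",
    "6mo": "6mo",
    "adult": "6mo",
}


@dataclasses.dataclass(frozen=True)
class SteadyPhaseRule:
    """Steady-phase window and blood-integration endpoint, in minutes."""

    window_start: float = 40.0
    window_end: float = 60.0
    integration_endpoint: str = "window_mid"

    def __post_init__(self) -> None:
        if not 0 <= self.window_start < self.window_end:
            raise ValueError("require 0 <= window_start < window_end")
        if self.integration_endpoint not in ("window_start", "window_mid", "window_end"):
            raise ValueError(
                "integration_endpoint must be one of "
                "'window_start', 'window_mid', 'window_end'"
            )

    @property
    def endpoint_time(self) -> float:
        if self.integration_endpoint == "window_start":
            return self.window_start
        if self.integration_endpoint == "window_end":
            return self.window_end
        return 0.5 * (self.window_start + self.window_end)


@dataclasses.dataclass(frozen=True)
class KineticResult:
    """Per-animal, per-ROI quantification output."""

    animal_id: str
    roi_label: str
    ge: float  # min^-1
    gu: float  # umol/min per 100 g
    hu: float | None = None
    sat_mass: float | None = None  # g (SAT only)
    whole_sat_gu: float | None = None  # umol/min (SAT only)


def fur_matrix(
    tissue: np.ndarray,
    blood: np.ndarray,
    times: np.ndarray,
    rule: SteadyPhaseRule = SteadyPhaseRule(),
    scan_end: float | None = None,
) -> np.ndarray:
    """Vectorized FUR over rows of (n, n_frames) tissue/blood activity matrices.

    `times` are the TAC sample times (frame midpoints). Returns GE per row.
    """
    tissue = np.atleast_2d(np.asarray(tissue, dtype=float))
    blood = np.atleast_2d(np.asarray(blood, dtype=float))
    times = np.asarray(times, dtype=float)
    if tissue.shape != blood.shape or tissue.shape[1] != times.size:
        raise ValueError("tissue, blood and times must agree in frame count")
    end = scan_end if scan_end is not None else float(times[-1])
    if rule.window_end > end + max(5.0, 0.1 * end):
        raise ValueError("steady-phase window extends far beyond the scan")

    in_window = (times >= rule.window_start - 1e-9) & (times <= rule.window_end + 1e-9)
    if not in_window.any():
        raise ValueError("steady-phase window contains no frames")
    numerator = tissue[:, in_window].mean(axis=1)

    t_int = rule.endpoint_time
    grid = times
    vals = blood
    if grid[0] > 0:  # IP injection: no activity in blood at t=0
        grid = np.concatenate([[0.0], grid])
        vals = np.concatenate([np.zeros((vals.shape[0], 1)), vals], axis=1)
    # value at the integration endpoint by linear interpolation (clamped at ends)
    before = grid < t_int - 1e-12
    idx = int(before.sum())
    v_end = np.array([np.interp(t_int, grid, row) for row in vals])
    sub_grid = np.concatenate([grid[:idx], [t_int]])
    sub_vals = np.concatenate([vals[:, :idx], v_end[:, None]], axis=1)
    integral = np.trapezoid(sub_vals, sub_grid, axis=1)
    if np.any(integral <= 0):
        raise ValueError("invalid input function: non-positive blood integral")
    return numerator / integral


def fractional_extraction(
    tissue: Tac, blood: Tac, rule: SteadyPhaseRule = SteadyPhaseRule()
) -> float:
    """Fractional glucose extraction (min^-1) of one tissue TAC.

    Steady-phase tissue activity divided by the blood activity integrated
    (trapezoid, origin prepended) from injection to the integration endpoint.
    """
    if tissue.schedule != blood.schedule:
        raise ValueError("tissue and blood TACs must share one frame schedule")
    ge = fur_matrix(
        tissue.activity[None, :],
        blood.activity[None, :],
        tissue.times,
        rule,
        scan_end=tissue.schedule.scan_end,
    )
    return float(ge[0])


def glucose_uptake(ge: float, scan_glycemia: float) -> float:
    """GU (umol/min per 100 g) = GE (min^-1) x glycemia (mmol/L) x 100."""
    if ge < 0:
        raise ValueError("fractional extraction must be >= 0")
    if scan_glycemia <= 0:
        raise ValueError("scan glycemia must be positive")
    return ge * scan_glycemia * 100.0


def sat_mass(body_weight: float, age_group: str) -> float:
    """Whole-depot SAT mass (g): 1.5% of body weight in young, 2.0% in adult mice."""
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    try:
        key = _AGE_ALIASES[str(age_group)]
    except KeyError:
        raise ValueError(
            f"unknown age group {age_group!r}; expected one of {sorted(_AGE_ALIASES)}"
        ) from None
    return SAT_MASS_FRACTION[key] * body_weight


def whole_depot_gu(gu: float, mass: float) -> float:
    """Whole-depot GU (umol/min) = per-100-g GU x depot mass (g) / 100."""
    if gu < 0 or mass < 0:
        raise ValueError("GU and mass must be >= 0")
    return gu * mass / 100.0


def bat_sat_ratio(gu_bat: float, gu_sat: float) -> float:
    """Per-animal BAT/SAT glucose uptake ratio; NaN when SAT GU is not positive.

    Group values are means of per-animal ratios (use `group_bat_sat_ratio`),
    not ratios of group means.
    """
    if not math.isfinite(gu_sat) or gu_sat <= 0:
        return float("nan")
    return gu_bat / gu_sat


def group_bat_sat_ratio(ratios) -> float:
    """Group BAT/SAT ratio: mean of per-animal ratios, NaNs excluded."""
    arr = np.asarray(list(ratios), dtype=float)
    if np.all(~np.isfinite(arr)):
        return float("nan")
    return float(np.nanmean(arr))
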