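"""Fitting thermostability readouts and summarizing variant panels.

Three standard readouts of enzyme thermostability are fitted here:

half-life (T½)
    The enzyme is held at a fixed stress temperature and residual activity
    is assayed over time.  Assuming first-order inactivation,
    ``ln(activity)`` is linear in time with slope ``k < 0`` and
    ``T½ = −ln(2)/k``.  The fit uses the linear part of the curve only
    (by default, points with at least 5% of initial activity — late points
    dominate log-space noise).

T50¹⁵
    Residual activity after 15 min at a ladder of temperatures, normalized
    to the lowest-temperature point (taken as 100%).  A sigmoidal
    Boltzmann curve ``y(T) = A2 + (A1 − A2)/(1 + exp((T − T50)/dT))`` is
    fitted; T50¹⁵ is its inflection temperature.

Tm (melting temperature)
    Intrinsic-fluorescence thermal denaturation (nanoDSF): the 350/330 nm
    tryptophan emission ratio is recorded over a temperature ramp, a
    polynomial (degree 9 by default) is fitted, and Tm is the temperature
    of the maximum of the fitted curve's first derivative within the ramp
    — the steepest point of the unfolding transition.

Variant panels are summarized as fold improvements (variant T½ ÷ parent
T½ at the same stress temperature) and a design success rate (percentage
of variants with fold > 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError, NoDecayError, ValidationError

#: Fraction of initial activity below which decay points leave the default
#: linear-fit window.
LINEAR_WINDOW_FLOOR = 0.05

#: Default polynomial degree for the melt-ratio fit.
TM_POLY_DEGREE = 9

#: Grid step (°C) for locating the derivative maximum.
TM_GRID_STEP = 0.01


@dataclass(frozen=True)
class AssayCurve:
    """One assay series: time- or temperature-indexed measurements.

    ``kind`` is ``"decay"`` (min → residual activity %), ``"t50"``
    (°C → residual activity %), or ``"melt"`` (°C → 350/330 ratio).
    """

    kind: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    variant: str = ""
    assay_temperature: float | None = None

    def __post_init__(self):
        if self.kind not in ("decay", "t50", "melt"):
            raise ValidationError(f"unknown assay kind '{self.kind}'")
        x = tuple(float(v) for v in self.x)
        y = tuple(float(v) for v in self.y)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) != len(y):
            raise ValidationError("x and y have different lengths")
        if len(x) < 4:
            raise ValidationError("a fit needs at least 4 points")
        if any(b <= a for a, b in zip(x, x[1:])):
            raise ValidationError("x values must be strictly increasing")
        if self.kind in ("decay", "t50") and (
            min(y) < 0 or max(y) > 120
        ):
            raise ValidationError("activity values must lie in [0, 120] %")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "variant": self.variant, "kind": self.kind}
        )


@dataclass(frozen=True)
class StabilityResult:
    """Fitted parameters for one variant; fields unused by an assay are None."""

    variant: str = ""
    k: float | None = None          # 1/min, negative
    t_half: float | None = None     # min
    t50_15: float | None = None     # °C
    dT: float | None = None         # Boltzmann width, °C
    tm: float | None = None         # °C
    fit_r2: float | None = None

    def __post_init__(self):
        if self.k is not None and self.t_half is not None:
            if not np.isclose(self.t_half, -np.log(2) / self.k, rtol=1e-9):
                raise ValidationError("t_half must equal −ln(2)/k")
        if self.t_half is not None and self.t_half <= 0:
            raise ValidationError("t_half must be positive")
        if self.fit_r2 is not None and not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValidationError("fit_r2 must lie in [0, 1]")


def fit_half_life(curve: AssayCurve, window: tuple[float, float] | None = None) -> StabilityResult:
    """First-order inactivation fit: OLS of ln(y/100) on time.

    ``window`` optionally restricts the fit to an explicit time interval;
    otherwise all points with activity ≥ 5% of the initial point are used.
    Points with non-positive activity are dropped with a warning.  Raises
    :class:`~phyloconsensus.errors.NoDecayError` if the slope is
    non-negative.
    """
    if curve.kind != "decay":
        raise ValidationError("fit_half_life expects a decay curve")
    x = np.array(curve.x)
    y = np.array(curve.y)
    keep = y > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} non-positive activity point(s)",
            stacklevel=2,
        )
    x, y = x[keep], y[keep]
    if window is not None:
        sel = (x >= window[0]) & (x <= window[1])
    else:
        sel = y >= LINEAR_WINDOW_FLOOR * y[0]
    x, y = x[sel], y[sel]
    if len(x) < 4:
        raise ValidationError("fewer than 4 usable points in the fit window")
    ln_y = np.log(y / 100.0)
    k, intercept = np.polyfit(x, ln_y, 1)
    if k >= 0:
        raise NoDecayError(f"slope {k:.3g} ≥ 0: no measurable inactivation")
    fitted = k * x + intercept
    ss_res = float(((ln_y - fitted) ** 2).sum())
    ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StabilityResult(
        variant=curve.variant, k=float(k), t_half=float(-np.log(2) / k), fit_r2=r2
    )


def _boltzmann(T, A1, A2, T50, dT):
    return A2 + (A1 - A2) / (1.0 + np.exp((T - T50) / dT))


def fit_t50(curve: AssayCurve) -> StabilityResult:
    """Boltzmann sigmoid fit of residual activity vs incubation temperature.

    Activity is renormalized so the lowest-temperature point reads 100%.
    The curve must span both plateaus (> 80% and < 20% after
    normalization) and must fall with temperature.
    """
    if curve.kind != "t50":
        raise ValidationError("fit_t50 expects a t50 curve")
    T = np.array(curve.x)
    y = np.array(curve.y) * (100.0 / curve.y[0])
    if y[0] < y[-1]:
        raise FitError(
            "activity rises with temperature; not an inactivation curve",
            residuals=y,
        )
    if y.max() <= 80 or y.min() >= 20:
        raise FitError(
            "curve does not span both plateaus (>80% and <20%)", residuals=y
        )
    # deterministic start: plateaus at extremes, T50 at the half-activity point
    mid = 0.5 * (y.max() + y.min())
    t50_guess = float(T[np.argmin(np.abs(y - mid))])
    p0 = [float(y.max()), float(y.min()), t50_guess, 2.0]
    try:
        popt, _ = curve_fit(_boltzmann, T, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}",
                       residuals=y) from exc
    A1, A2, T50, dT = (float(v) for v in popt)
    fitted = _boltzmann(T, *popt)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StabilityResult(
        variant=curve.variant, t50_15=T50, dT=abs(dT), fit_r2=min(r2, 1.0)
    )


def fit_tm(
    curve: AssayCurve,
    degree: int = TM_POLY_DEGREE,
    window_halfwidth: float = 12.0,
) -> StabilityResult:
    """Melting temperature from the derivative peak of the 350/330 ratio.

    A degree-``degree`` polynomial (default 9) is least-squares fitted to
    ratio vs temperature over a window of ``± window_halfwidth`` °C around
    the transition (coarsely located by the finite-difference slope
    maximum); Tm is the argmax of the fitted polynomial's first derivative
    on a dense (0.01 °C) grid.  The windowing matters: a single global
    polynomial over a 75 °C ramp cannot track a sharp unfolding transition
    and rings at the ramp ends.  A derivative maximum at the edge of the
    evaluated range triggers a boundary warning — the transition was not
    captured by the ramp.
    """
    if curve.kind != "melt":
        raise ValidationError("fit_tm expects a melt curve")
    T = np.array(curve.x)
    y = np.array(curve.y)
    if len(T) < 20:
        raise ValidationError("melt fit needs at least 20 ramp points")
    coarse_idx = int(np.argmax(np.gradient(y, T)))
    if coarse_idx == 0 or coarse_idx == len(T) - 1:
        warnings.warn(
            "derivative maximum at the edge of the ramp; "
            "unfolding transition not captured",
            stacklevel=2,
        )
    coarse = float(T[coarse_idx])
    sel = (T >= coarse - window_halfwidth) & (T <= coarse + window_halfwidth)
    Tw, yw = T[sel], y[sel]
    deg_eff = min(degree, len(Tw) - 2)
    poly = np.polynomial.Polynomial.fit(Tw, yw, deg=deg_eff)
    deriv = poly.deriv()
    grid = np.arange(Tw[0], Tw[-1] + TM_GRID_STEP / 2, TM_GRID_STEP)
    slopes = deriv(grid)
    idx = int(np.argmax(slopes))
    tm = float(grid[idx])
    if idx == 0 or idx == len(grid) - 1:
        warnings.warn(
            "derivative maximum at the edge of the ramp; "
            "unfolding transition not captured",
            stacklevel=2,
        )
    fitted = poly(Tw)
    ss_res = float(((yw - fitted) ** 2).sum())
    ss_tot = float(((yw - yw.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return StabilityResult(variant=curve.variant, tm=tm, fit_r2=r2)


def round_fold(ratio: float) -> float:
    """Reporting convention for fold improvements: two decimals below 10,
    one decimal at 10 and above."""
    return round(ratio, 2 if ratio < 10 else 1)


def fold_improvement(variant_t_half: float, reference_t_half: float) -> float:
    """Variant half-life ÷ reference half-life, rounded per convention."""
    if variant_t_half <= 0 or reference_t_half <= 0:
        raise ValidationError("half-lives must be positive")
    return round_fold(variant_t_half / reference_t_half)


@dataclass(frozen=True)
class VariantRecord:
    label: str
    t_half: float
    relative_activity: float | None = None


def summarize_variants(
    records: list[VariantRecord] | pd.DataFrame,
    reference_label: str,
) -> tuple[pd.DataFrame, float]:
    """Fold improvements vs a reference variant plus the design success rate.

    Returns ``(table, success_rate)``: the table holds one row per
    non-reference variant, sorted by fold improvement descending;
    ``success_rate`` is the integer-rounded percentage of variants whose
    fold improvement exceeds 1.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            VariantRecord(
                str(r["label"]),
                float(r["t_half"]),
                float(r["relative_activity"])
                if "relative_activity" in r and pd.notna(r["relative_activity"])
                else None,
            )
            for _, r in records.iterrows()
        ]
    by_label = {r.label: r for r in records}
    if reference_label not in by_label:
        raise ConfigError(f"reference '{reference_label}' not among records")
    ref = by_label[reference_label]
    variants = [r for r in records if r.label != reference_label]
    if not variants:
        raise ConfigError("no variants besides the reference")
    rows = []
    improved = 0
    for r in variants:
        raw = r.t_half / ref.t_half
        if raw > 1.0:
            improved += 1
        rows.append(
            {
                "label": r.label,
                "t_half_min": round(r.t_half, 1),
                "fold_improvement": round_fold(raw),
                "relative_activity_pct": r.relative_activity,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "fold_improvement", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    success_rate = round(100.0 * improved / len(variants))
    return table, float(success_rate)
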