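"""Fit the four kinetic parameters (C_e, A1, A2, A3) from micro-batch data.

The model couples a linear growth law with a classical-nucleation-theory
rate law:

* growth:      dL/dt = A1 · (C − C_e)                    [µm/h]
* nucleation:  I(C)  = A2 · C · exp(−A3 / ln(C/C_e)²)    [ml⁻¹ h⁻¹]

All four parameters come from straight-line regressions on transformed
observations:

1. Per container, crystal length vs time is linear once growth starts; the
   slope is the growth rate and the horizontal intercept the nucleation
   onset (:func:`fit_growth_onset`).
2. Growth rate vs initial concentration is linear at low supersaturation;
   the slope is A1 and the horizontal intercept C_e (:func:`fit_growth_law`).
3. Cumulative crystal count vs onset time is linear while the solution is
   undepleted; the slope over the container volume is the nucleation rate I
   (:func:`fit_nucleation_rate`).
4. ln(I/C) vs 1/ln(C/C_e)² is linear with slope −A3 and intercept ln A2
   (:func:`fit_nucleation_params`).

All regressions are ordinary least squares; standard errors of derived
ratios (C_e, onset time, A2) use the first-order delta method on the full
OLS covariance, which is what produces the characteristically large C_e
uncertainty when the regression line is shallow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFitError,
    EmptyRegionError,
    InsufficientEventsError,
    ValidationError,
)

__all__ = [
    "LinearFit",
    "GrowthSeries",
    "NucleationEvents",
    "GrowthOnsetFit",
    "GrowthLawFit",
    "NucleationRateFit",
    "NucleationParamsFit",
    "KineticParameters",
    "linear_fit",
    "fit_growth_onset",
    "fit_growth_law",
    "fit_nucleation_rate",
    "fit_nucleation_params",
]


# ---------------------------------------------------------------------------
# observation containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSeries:
    """Time course of one crystal's longest dimension in one container.

    ``times_h`` must be strictly increasing and ``lengths_um`` non-negative.
    """

    container_id: str
    conc0_mg_ml: float
    times_h: np.ndarray
    lengths_um: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        L = np.asarray(self.lengths_um, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "lengths_um", L)
        if t.shape != L.shape or t.ndim != 1:
            raise ValidationError("times_h and lengths_um must be 1-d and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"times must be strictly increasing (container {self.container_id})"
            )
        if np.any(L < 0):
            raise ValidationError(
                f"lengths must be non-negative (container {self.container_id})"
            )
        if not self.conc0_mg_ml > 0:
            raise ValidationError(f"conc0 must be > 0, got {self.conc0_mg_ml}")

    @property
    def n_points(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class NucleationEvents:
    """Nucleation onset times observed in one container.

    The k-th onset (sorted ascending) contributes the cumulative-count point
    (t_k, k).
    """

    conc0_mg_ml: float
    container_volume_ml: float
    onset_times_h: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.onset_times_h, dtype=float)
        object.__setattr__(self, "onset_times_h", t)
        if t.ndim != 1:
            raise ValidationError("onset_times_h must be 1-d")
        if t.size >= 2 and np.any(np.diff(t) < 0):
            raise ValidationError("onset times must be sorted ascending")
        if not self.container_volume_ml > 0:
            raise ValidationError(
                f"container_volume_ml must be > 0, got {self.container_volume_ml}"
            )
        if not self.conc0_mg_ml > 0:
            raise ValidationError(f"conc0 must be > 0, got {self.conc0_mg_ml}")


# ---------------------------------------------------------------------------
# shared straight-line machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearFit:
    """Result of an ordinary least-squares straight-line fit y = slope·x + intercept."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    cov_slope_intercept: float
    n_points: int


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS fit of y on x with full 2×2 parameter covariance.

    With exactly two points the fit is exact and all standard errors are
    zero (residual degrees of freedom are zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientEventsError(f"need >= 2 points for a line, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError("all abscissae identical: singular design")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    dof = n - 2
    sigma2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    var_slope = sigma2 / sxx
    var_intercept = sigma2 * (1.0 / n + x.mean() ** 2 / sxx)
    cov_si = -sigma2 * x.mean() / sxx
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_se=float(np.sqrt(var_slope)),
        intercept_se=float(np.sqrt(var_intercept)),
        cov_slope_intercept=float(cov_si),
        n_points=int(n),
    )


def _ratio_se(fit: LinearFit) -> float:
    """Delta-method SE of the horizontal intercept r = −intercept/slope."""
    m, b = fit.slope, fit.intercept
    dm = b / m**2
    db = -1.0 / m
    var = (
        dm**2 * fit.slope_se**2
        + db**2 * fit.intercept_se**2
        + 2.0 * dm * db * fit.cov_slope_intercept
    )
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# growth-side fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthOnsetFit:
    """Growth rate and nucleation onset extracted from one time course."""

    rate_um_h: float
    rate_se: float
    onset_h: float
    onset_se: float
    line: LinearFit
    negative_slope: bool = False


def fit_growth_onset(
    series: GrowthSeries, window: tuple[int, int] | None = None
) -> GrowthOnsetFit:
    """Fit L(t) = rate·(t − onset) to a growth time course.

    The slope of the OLS line of length on time is the initial growth rate;
    the horizontal intercept is the nucleation onset.  ``window`` restricts
    the fit to the index range [start, stop) so the early linear regime can
    be selected by eye, as is usual for these plots.
    """
    t = series.times_h
    L = series.lengths_um
    if window is not None:
        t = t[window[0] : window[1]]
        L = L[window[0] : window[1]]
    if t.size < 2:
        raise InsufficientEventsError(
            f"need >= 2 points in window, got {t.size} (container {series.container_id})"
        )
    line = linear_fit(t, L)
    negative = line.slope < 0
    onset = -line.intercept / line.slope if line.slope != 0 else np.nan
    return GrowthOnsetFit(
        rate_um_h=line.slope,
        rate_se=line.slope_se,
        onset_h=float(onset),
        onset_se=_ratio_se(line) if line.slope != 0 else np.nan,
        line=line,
        negative_slope=negative,
    )


@dataclass(frozen=True)
class GrowthLawFit:
    """A1 and C_e from growth rate vs initial concentration."""

    a1: float
    a1_se: float
    c_e: float
    c_e_se: float
    line: LinearFit
    n_used: int


def fit_growth_law(
    points: Sequence[tuple[float, float]], linear_max_conc: float = 15.0
) -> GrowthLawFit:
    """Fit rate = A1·(C − C_e) over the linear (low-supersaturation) region.

    ``points`` are (initial concentration mg/ml, growth rate µm/h) pairs;
    only points with concentration ≤ ``linear_max_conc`` enter the fit.  The
    growth mode changes at high supersaturation (for the lysozyme/PEG
    reference data, 18 mg/ml is visibly off the line), so the cutoff is a
    deliberate, visible parameter rather than something detected
    automatically.
    """
    pts = [(float(c), float(r)) for c, r in points]
    kept = [(c, r) for c, r in pts if c <= linear_max_conc]
    if not kept:
        raise EmptyRegionError(
            f"no points at or below linear_max_conc={linear_max_conc}"
        )
    if len(kept) < 2:
        raise InsufficientEventsError("need >= 2 points inside the linear region")
    c, r = zip(*kept)
    line = linear_fit(c, r)
    if line.slope == 0:
        raise DegenerateFitError("zero slope: C_e undefined")
    return GrowthLawFit(
        a1=line.slope,
        a1_se=line.slope_se,
        c_e=-line.intercept / line.slope,
        c_e_se=_ratio_se(line),
        line=line,
        n_used=len(kept),
    )


# ---------------------------------------------------------------------------
# nucleation-side fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleationRateFit:
    """Nucleation rate I from a cumulative-count regression.

    ``rate_per_ml_h`` is normalised by the container volume (the rate-law
    I is per unit volume); ``per_container_h`` gives the raw slope for
    comparison with per-container reports.
    """

    rate_per_ml_h: float
    rate_se: float
    container_volume_ml: float
    line: LinearFit

    @property
    def per_container_h(self) -> float:
        return self.rate_per_ml_h * self.container_volume_ml

    @property
    def per_container_se(self) -> float:
        return self.rate_se * self.container_volume_ml


def fit_nucleation_rate(events: NucleationEvents) -> NucleationRateFit:
    """Estimate I (ml⁻¹ h⁻¹) from onset times in one container.

    Plots cumulative count (1, 2, …) against onset time, fits a straight
    line, and divides the slope by the container volume.

    The reported standard error is NOT the textbook OLS slope SE: cumulative
    counts are a counting process whose deviations from the mean line are a
    (scaled) Brownian motion, so successive residuals are strongly
    correlated and the iid-error formula understates the sampling
    variability several-fold.  For a Poisson process the least-squares slope
    has asymptotic relative standard deviation (6/5 · 1/n)^{1/2} with n the
    number of events (the 6/5 comes from the covariance kernel
    min(s,t) of the counting process integrated against the regression
    weights), and that is what ``rate_se`` reports.
    """
    t = events.onset_times_h
    if t.size < 2:
        raise InsufficientEventsError(
            f"need >= 2 nucleation events, got {t.size}"
        )
    counts = np.arange(1, t.size + 1, dtype=float)
    line = linear_fit(t, counts)
    rate_per_ml = line.slope / events.container_volume_ml
    rel_sd = np.sqrt(1.2 / t.size)
    return NucleationRateFit(
        rate_per_ml_h=rate_per_ml,
        rate_se=abs(rate_per_ml) * rel_sd,
        container_volume_ml=events.container_volume_ml,
        line=line,
    )


@dataclass(frozen=True)
class NucleationParamsFit:
    """A2 and A3 from the linearised nucleation-theory plot."""

    a2: float
    a2_se: float
    a3: float
    a3_se: float
    y_sec: float
    line: LinearFit


def fit_nucleation_params(
    points: Sequence[tuple[float, float]],
    c_e: float,
    rate_ses: Sequence[float] | None = None,
) -> NucleationParamsFit:
    """Fit A2, A3 from (concentration, nucleation rate) pairs.

    Linearises I = A2·C·exp(−A3/ln(C/C_e)²) by plotting ln(I/C) against
    1/ln(C/C_e)²: the slope is −A3 and the vertical intercept Y_sec gives
    A2 = exp(Y_sec).  The A2 standard error follows from the intercept SE by
    the delta method.

    The point estimates are always the plain least-squares line.  When the
    per-point rate uncertainties are known (``rate_ses``, one SE per input
    rate, as returned by :func:`fit_nucleation_rate`), the reported standard
    errors use them directly: the transformed ordinates are heteroskedastic
    (sd of ln I equals the relative SE of I, which varies strongly between
    concentration levels), and the homoskedastic residual-based formula can
    badly understate the slope uncertainty in that case.
    """
    pts = [(float(c), float(i)) for c, i in points]
    if len(pts) < 2:
        raise InsufficientEventsError("need >= 2 (conc, rate) points")
    for c, i in pts:
        if c <= c_e:
            raise ValidationError(
                f"concentration {c} must exceed c_e={c_e} (log undefined)"
            )
        if i <= 0:
            raise ValidationError(f"nucleation rate must be > 0, got {i}")
    x = np.array([1.0 / np.log(c / c_e) ** 2 for c, _ in pts])
    y = np.array([np.log(i / c) for c, i in pts])
    line = linear_fit(x, y)
    if rate_ses is not None:
        if len(rate_ses) != len(pts):
            raise ValidationError("rate_ses must match points in length")
        # sd of y = ln(I/C) is the relative SE of I (delta method)
        sd_y = np.array([se / i for (_, i), se in zip(pts, rate_ses)])
        n = x.size
        sxx = float(np.sum((x - x.mean()) ** 2))
        w = (x - x.mean()) / sxx  # slope = Σ w_i y_i
        var_slope = float(np.sum(w**2 * sd_y**2))
        coef_int = 1.0 / n - x.mean() * w  # intercept = Σ coef_i y_i
        var_int = float(np.sum(coef_int**2 * sd_y**2))
        cov_si = float(np.sum(w * coef_int * sd_y**2))
        line = LinearFit(
            slope=line.slope,
            intercept=line.intercept,
            slope_se=float(np.sqrt(var_slope)),
            intercept_se=float(np.sqrt(var_int)),
            cov_slope_intercept=cov_si,
            n_points=line.n_points,
        )
    a2 = float(np.exp(line.intercept))
    return NucleationParamsFit(
        a2=a2,
        a2_se=a2 * line.intercept_se,
        a3=-line.slope,
        a3_se=line.slope_se,
        y_sec=line.intercept,
        line=line,
    )


# ---------------------------------------------------------------------------
# the fitted quadruple
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameters:
    """The four fitted constants of the crystallization model.

    Units: c_e in mg/ml; a1 in µm·ml·mg⁻¹·h⁻¹; a2 such that I is in
    ml⁻¹ h⁻¹ with C in mg/ml; a3 dimensionless.  Standard errors default to
    zero for parameter sets taken as exact inputs.
    """

    c_e: float
    a1: float
    a2: float
    a3: float
    c_e_se: float = 0.0
    a1_se: float = 0.0
    a2_se: float = 0.0
    a3_se: float = 0.0

    def __post_init__(self) -> None:
        if self.c_e < 0:
            raise ValidationError(f"c_e must be >= 0, got {self.c_e}")
        if not self.a1 > 0:
            raise ValidationError(f"a1 must be > 0, got {self.a1}")
        # a2 = 0 is allowed: it expresses the no-nucleation (seeded-growth) limit
        if self.a2 < 0:
            raise ValidationError(f"a2 must be >= 0, got {self.a2}")
        if self.a3 < 0:
            raise ValidationError(f"a3 must be >= 0, got {self.a3}")
        for name in ("c_e_se", "a1_se", "a2_se", "a3_se"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_fits(
        cls, growth: GrowthLawFit, nucleation: NucleationParamsFit
    ) -> "KineticParameters":
        return cls(
            c_e=growth.c_e,
            a1=growth.a1,
            a2=nucleation.a2,
            a3=nucleation.a3,
            c_e_se=growth.c_e_se,
            a1_se=growth.a1_se,
            a2_se=nucleation.a2_se,
            a3_se=nucleation.a3_se,
        )

    def to_dict(self) -> dict:
        return {
            "c_e_mg_ml": self.c_e,
            "c_e_se": self.c_e_se,
            "a1_um_ml_per_mg_h": self.a1,
            "a1_se": self.a1_se,
            "a2": self.a2,
            "a2_se": self.a2_se,
            "a3": self.a3,
            "a3_se": self.a3_se,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(
            c_e=d["c_e_mg_ml"],
            a1=d["a1_um_ml_per_mg_h"],
            a2=d["a2"],
            a3=d["a3"],
            c_e_se=d.get("c_e_se", 0.0),
            a1_se=d.get("a1_se", 0.0),
            a2_se=d.get("a2_se", 0.0),
            a3_se=d.get("a3_se", 0.0),
        )
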