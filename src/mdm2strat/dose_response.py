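"""Dose-response processing for a cell-proliferation inhibitor screen.

Raw replicate cell counts are transformed to percent of control (POC),
fitted with the four-parameter logistic (4PL) model

    y = A + (B - A) / (1 + (C / x) ** D)

where ``A`` is the response at vanishing dose (~100 POC for a healthy
culture), ``B`` the response at saturating dose, ``C`` the inflection
concentration and ``D`` the Hill slope.  The IC50 is reported as the
concentration at which the *fitted* curve crosses 50 POC; lines whose curve
never reaches 50 within the tested range are right-censored at the maximum
tested dose.  A normalized area under the POC-vs-log10(dose) curve is
provided as an alternative response metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import QCFailure, ValidationError

__all__ = [
    "DoseResponse",
    "FitResult",
    "IC50",
    "four_pl",
    "compute_poc",
    "qc_untreated",
    "fit_4pl",
    "derive_ic50",
    "compute_auc",
]

#: Default highest tested concentration (μM); censored IC50s carry this value.
DEFAULT_MAX_DOSE = 50.0


def four_pl(x, a, b, c, d):
    """Evaluate the 4PL model at concentration ``x`` (μM)."""
    x = np.asarray(x, dtype=float)
    return a + (b - a) / (1.0 + (c / x) ** d)


@dataclass(frozen=True)
class DoseResponse:
    """One cell line's dose series: strictly increasing doses (μM) and the
    matching POC values, plus the untreated replicate counts used for QC."""

    line_id: str
    doses: np.ndarray
    poc: np.ndarray
    untreated_counts: np.ndarray | None = None

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        poc = np.asarray(self.poc, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "poc", poc)
        if doses.shape != poc.shape:
            raise ValidationError(
                f"{self.line_id}: doses and poc differ in length "
                f"({doses.size} vs {poc.size})"
            )
        if np.any(doses <= 0):
            raise ValidationError(f"{self.line_id}: doses must be positive")
        if np.any(np.diff(doses) <= 0):
            raise ValidationError(f"{self.line_id}: doses must be strictly increasing")
        if np.any(poc < 0):
            raise ValidationError(f"{self.line_id}: POC values must be >= 0")


@dataclass(frozen=True)
class IC50:
    """A possibly right-censored IC50.  ``value`` is the crossing
    concentration, or the maximum tested dose when ``censored``."""

    value: float
    censored: bool

    def __str__(self) -> str:  # ">50" rendering used in TSV output
        return f">{self.value:g}" if self.censored else f"{self.value:g}"

    def ordering_value(self) -> float:
        """IC50 for ranking purposes: censored values sort above all numbers."""
        return math.inf if self.censored else self.value


@dataclass
class FitResult:
    """4PL least-squares estimates with convergence flag and derived metrics."""

    line_id: str
    a: float
    b: float
    c: float
    d: float
    converged: bool
    sse: float = math.nan
    ic50: IC50 | None = None
    auc: float = math.nan

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def compute_poc(compound_counts, vehicle_counts) -> np.ndarray:
    """Percent of control: 100 x compound-well count / mean vehicle count.

    Stimulation above control (POC > 100) is preserved, not clipped.
    Raises :class:`QCFailure` when the vehicle mean is not positive, which
    callers route to the poor-growth exclusion.
    """
    compound = np.asarray(compound_counts, dtype=float)
    vehicle_mean = float(np.mean(np.asarray(vehicle_counts, dtype=float)))
    if vehicle_mean <= 0:
        raise QCFailure(f"vehicle mean count {vehicle_mean} is not positive")
    return 100.0 * compound / vehicle_mean


def qc_untreated(
    untreated_counts, cv_threshold: float = 0.3, min_count: float = 200.0
) -> tuple[bool, str | None]:
    """QC on untreated replicates.

    Returns ``(passed, reason)`` where ``reason`` is ``poor_growth`` when the
    replicate mean is below ``min_count``, ``high_cv`` when sd/mean exceeds
    ``cv_threshold``, and ``insufficient_replicates`` for fewer than two
    replicates.
    """
    counts = np.asarray(untreated_counts, dtype=float)
    if counts.size < 2:
        return False, "insufficient_replicates"
    mean = counts.mean()
    if mean < min_count or mean <= 0:
        return False, "poor_growth"
    cv = counts.std(ddof=1) / mean
    if cv > cv_threshold:
        return False, "high_cv"
    return True, None


# Bounds from the data scale: POC lives on [0, ~200]; C is allowed two
# decades beyond the tested range so censoring, not the bound, is binding.
_SLOPE_STARTS = (0.5, 1.0, 2.0)


def fit_4pl(dr: DoseResponse, rel_tol: float = 1e-6) -> FitResult:
    """Multi-start nonlinear least-squares fit of the 4PL model.

    Starts from data-driven values (A = max POC, B = min POC, C = geometric
    mean dose) over three Hill-slope starts.  ``converged`` is False when no
    start succeeds or when the best fit improves on the flat (constant-mean)
    model by less than ``rel_tol`` of the flat-model SSE — degenerate
    (all-equal POC) input therefore yields a non-converged flat fit.
    """
    if np.unique(dr.doses).size < 4:
        raise ValidationError(f"{dr.line_id}: need >= 4 distinct doses to fit")
    x, y = dr.doses, dr.poc
    a0, b0 = float(y.max()), float(y.min())
    c0 = float(np.exp(np.mean(np.log(x))))
    lo = [0.0, 0.0, x.min() / 100.0, 1e-3]
    hi = [200.0, 200.0, x.max() * 100.0, 10.0]
    y_flat = float(y.mean())
    sse_flat = float(np.sum((y - y_flat) ** 2))

    best: tuple[float, np.ndarray] | None = None
    for d0 in _SLOPE_STARTS:
        p0 = [min(max(a0, lo[0]), hi[0]), min(max(b0, lo[1]), hi[1]), c0, d0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    four_pl, x, y, p0=p0, bounds=(lo, hi), maxfev=5000,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((four_pl(x, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)

    if best is None:
        return FitResult(dr.line_id, math.nan, math.nan, math.nan, math.nan,
                         converged=False, sse=sse_flat)
    sse, popt = best
    improved = (sse_flat - sse) > rel_tol * sse_flat + 1e-12
    return FitResult(dr.line_id, *map(float, popt), converged=improved, sse=sse)


def derive_ic50(
    fit: FitResult, max_dose: float = DEFAULT_MAX_DOSE, poc_level: float = 50.0
) -> IC50:
    """Concentration where the fitted curve crosses ``poc_level`` POC.

    Solved analytically from the 4PL: (C/x)^D = (B - L) / (L - A), so
    x = C * ((B - L)/(L - A)) ** (-1/D).  Censored (``>max_dose``) when the
    fit did not converge, when the fitted curve does not *descend* through
    ``poc_level`` (an inhibitory IC50 requires A > level > B; upward-sloping
    fits of flat data have no inhibitory crossing), or when the crossing
    does not fall in (0, max_dose].
    """
    if not fit.converged:
        return IC50(max_dose, censored=True)
    a, b, c, d = fit.params
    if not (a > poc_level > b):
        return IC50(max_dose, censored=True)
    t = (b - poc_level) / (poc_level - a)
    x = c * t ** (-1.0 / d)
    if not (0.0 < x <= max_dose) or not math.isfinite(x):
        return IC50(max_dose, censored=True)
    return IC50(float(x), censored=False)


def compute_auc(dr: DoseResponse) -> float:
    """Normalized area under POC vs log10(dose).

    Trapezoidal integral divided by (100 x log10 dose range), so a flat
    POC = 100 curve scores exactly 1.0 and complete inhibition scores 0.
    Monotone: pointwise-lower POC never yields a higher AUC.
    """
    if dr.doses.size < 2:
        raise ValidationError(f"{dr.line_id}: AUC needs >= 2 doses")
    logx = np.log10(dr.doses)
    area = float(np.trapezoid(dr.poc, logx))
    return area / (100.0 * (logx[-1] - logx[0]))
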