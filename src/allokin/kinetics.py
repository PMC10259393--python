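"""Coupled-assay enzyme kinetics: traces to rates to Michaelis-Menten constants.

ADP production by the kinase is coupled through pyruvate kinase / lactate
dehydrogenase to NADH oxidation, read as a decrease in absorbance at 340 nm.
Beer-Lambert converts the absorbance drop to product concentration, the
initial rate is the slope of the early linear portion (before 10% substrate
conversion), and v vs [S] points are fit to v = vmax·S/(KM + S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AssayTrace",
    "RateParameters",
    "trace_to_product",
    "initial_rate",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "fold_change",
    "round_sig",
    "FitError",
    "EPSILON_NADH_340",
]

#: molar extinction coefficient of NADH at 340 nm, M⁻¹cm⁻¹
EPSILON_NADH_340 = 6220.0


class FitError(RuntimeError):
    """Nonlinear fit failed or produced non-physical parameter estimates."""


@dataclass
class AssayTrace:
    """One spectrophotometric time course of the coupled assay.

    time in s, absorbance in AU; ``substrate_0`` µM, ``enzyme_conc`` nM.
    """

    time: np.ndarray
    absorbance: np.ndarray
    epsilon_nadh: float = EPSILON_NADH_340   # M⁻¹cm⁻¹
    path_length: float = 1.0                 # cm
    substrate_0: float = np.nan              # µM
    enzyme_conc: float = np.nan              # nM

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.epsilon_nadh <= 0 or self.path_length <= 0:
            raise ValueError("epsilon_nadh and path_length must be positive")


@dataclass
class RateParameters:
    """Michaelis-Menten constants for one enzyme construct."""

    kcat: float                 # s⁻¹
    km: float                   # µM
    vmax: float                 # µM/s at enzyme_conc
    efficiency: float           # kcat/KM, M⁻¹s⁻¹
    enzyme_conc: float = np.nan  # nM
    se_kcat: float = np.nan
    se_km: float = np.nan
    non_saturating: bool = False


def trace_to_product(trace: AssayTrace) -> Tuple[np.ndarray, np.ndarray]:
    """Convert an absorbance trace to a product concentration time course.

    P(t) = (A(0) − A(t)) / (ε·l) · 10⁶  µM.  Raw conversion: no smoothing.
    """
    el = trace.epsilon_nadh * trace.path_length
    if el <= 0:
        raise ValueError("epsilon * path length must be positive")
    product = (trace.absorbance[0] - trace.absorbance) / el * 1e6
    return trace.time.copy(), product


def initial_rate(
    time: np.ndarray,
    product: np.ndarray,
    substrate_0: float,
    enzyme_conc: float | None = None,
    max_conversion: float = 0.10,
    curvature_tol: float = 0.05,
    min_points: int = 5,
) -> Tuple[float, float]:
    """Initial velocity from the early linear portion of a progress curve.

    The window starts at t=0 and is the longest prefix satisfying both
    (a) P < ``max_conversion``·S₀ and (b) a linearity criterion: the
    quadratic term of a second-order fit contributes less than
    ``curvature_tol`` of the linear term over the window span.

    Returns (rate µM/s, specific rate s⁻¹); the specific rate is NaN when
    ``enzyme_conc`` (nM) is not given.
    """
    time = np.asarray(time, float)
    product = np.asarray(product, float)
    below = product < max_conversion * substrate_0
    n_cut = int(np.argmin(below)) if not below.all() else len(time)
    if n_cut < min_points:
        raise ValueError(
            f"only {n_cut} points before {max_conversion:.0%} conversion; "
            f"need at least {min_points}")
    n_best = min_points
    for n in range(min_points, n_cut + 1):
        t, p = time[:n], product[:n]
        span = t[-1] - t[0]
        if span == 0:
            continue
        c2, c1, _ = np.polyfit(t - t[0], p, 2)
        if abs(c1) < 1e-30:
            if abs(c2) * span < 1e-30:
                n_best = n
            continue
        if abs(c2) * span <= curvature_tol * abs(c1):
            n_best = n
        else:
            break
    slope = float(np.polyfit(time[:n_best], product[:n_best], 1)[0])
    specific = slope / (enzyme_conc * 1e-3) if enzyme_conc else float("nan")
    return slope, specific


def fit_michaelis_menten(
    substrate: np.ndarray,
    rate: np.ndarray,
    enzyme_conc: float,
) -> RateParameters:
    """Nonlinear least-squares fit of v = vmax·S/(KM + S).

    ``substrate`` in µM, ``rate`` in µM/s, ``enzyme_conc`` in nM.
    kcat = vmax/[E].  A ``non_saturating`` flag is raised when the largest
    assayed [S] is below the fitted KM (the design cannot pin down vmax, the
    situation reported as "ND" for weakly active constructs).
    """
    s = np.asarray(substrate, float)
    v = np.asarray(rate, float)
    if np.unique(s).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    vmax0 = 1.2 * float(v.max())
    half = vmax0 / 2.0
    order = np.argsort(s)
    km0 = float(np.interp(half, v[order], s[order]))
    km0 = km0 if np.isfinite(km0) and km0 > 0 else float(np.median(s))

    def mm(s_, vmax_, km_):
        return vmax_ * s_ / (km_ + s_)

    try:
        popt, pcov = curve_fit(mm, s, v, p0=[vmax0, km0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise FitError(
            f"non-physical estimates vmax={vmax:.3g}, KM={km:.3g} "
            f"(init vmax0={vmax0:.3g}, km0={km0:.3g})")
    se_vmax, se_km = np.sqrt(np.diag(pcov))
    e_um = enzyme_conc * 1e-3                    # nM -> µM
    kcat = vmax / e_um
    return RateParameters(
        kcat=kcat, km=km, vmax=vmax,
        efficiency=kcat / (km * 1e-6),
        enzyme_conc=enzyme_conc,
        se_kcat=se_vmax / e_um, se_km=se_km,
        non_saturating=bool(s.max() < km),
    )


def round_sig(x: float, sig: int = 1) -> float:
    """Round half away from zero to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - sig + 1)
    return math.copysign(math.floor(abs(x) / q + 0.5) * q, x)


def table_round(x: float) -> float:
    """Summary-table rounding of catalytic efficiencies.

    One significant figure, except two when the leading digit is 1 (a single
    figure would halve the resolution exactly where relative steps are
    largest): 67039 → 7×10⁴ but 18605 → 1.9×10⁴.
    """
    two = round_sig(x, 2)
    if two != 0 and f"{abs(two):e}"[0] == "1":
        return two
    return round_sig(x, 1)


def catalytic_efficiency(kcat: float, km: float) -> Tuple[float, float]:
    """kcat/KM in M⁻¹s⁻¹ with KM given in µM; returns (value, table rounding)."""
    if km <= 0:
        raise ValueError("km must be positive")
    eff = kcat / (km * 1e-6)
    return eff, table_round(eff)


def fold_change(
    a: RateParameters,
    b: RateParameters,
    metric: Literal["kcat", "km", "efficiency"],
) -> Tuple[float, float]:
    """Ratio a/b of a kinetic constant, with a rounded headline value.

    Returns (unrounded ratio, rounded).  Ratios ≥ 3 are rounded to the
    nearest integer; smaller ratios keep one decimal so that e.g. a 2.49-fold
    change reads 2.5-fold rather than 2-fold.
    """
    num = getattr(a, metric)
    den = getattr(b, metric)
    if den == 0:
        raise ValueError("zero denominator in fold change")
    if num <= 0 or den <= 0:
        raise ValueError("fold change requires positive values")
    r = num / den
    rounded = float(math.floor(r + 0.5)) if r >= 3 else round(r, 1)
    return r, rounded
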