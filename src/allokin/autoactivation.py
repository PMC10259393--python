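"""Four-state cis/trans autophosphorylation model of kinase autoactivation.

The enzyme complex carries two autophosphorylation sites: the activation-loop
threonine of the kinase and the TSS motif of its obligate partner. Each
molecule is therefore in one of four phospho-states::

    e00  neither site phosphorylated        (relative activity a00, ~1%)
    e10  loop only                          (a10, ~10%)
    e01  partner/IN-box only                (a01, ~5%)
    e11  both sites, fully active           (a11 = 1 by convention)

Loop phosphorylation proceeds intramolecularly (cis, first order, rate
``k_cis``) with an optional intermolecular channel (``k_loop_trans``);
phosphorylation of the partner's TSS motif is intermolecular (trans,
``k_inbox_trans``).  Trans steps are catalysed by the activity-weighted pool
``C = e_tot * sum(a_ij * e_ij)``: a partially active or fully active molecule
can phosphorylate another molecule, in proportion to its own specific
activity.  ATP is held saturating, so all steps are pseudo-first/second order
in enzyme only, and there is no phosphatase (activation never reverses).

Substrate turnover is reported alongside the state fractions through a
Michaelis-Menten term with reference constants ``kcat_ref``/``km_ref``
scaled by the instantaneous activity-weighted fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "AutoactivationParams",
    "StateTrajectory",
    "simulate_autoactivation",
    "preincubation_assay",
    "normalize_progress_curves",
    "cis_trans_statistic",
    "fit_autoactivation",
    "IntegrationError",
]

#: default relative specific activities (no-P, loop-P, IN-P, all-P)
DEFAULT_ACTIVITIES: Tuple[float, float, float, float] = (0.01, 0.10, 0.05, 1.00)

#: default simulation horizon, s (450 min of continuous monitoring)
DEFAULT_HORIZON_S = 450.0 * 60.0


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; carries the last valid state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class AutoactivationParams:
    """Rate constants and per-state relative activities.

    Parameters
    ----------
    k_cis : float
        Intramolecular loop-phosphorylation rate, s⁻¹.
    k_inbox_trans : float
        Intermolecular TSS/IN-box phosphorylation rate, M⁻¹s⁻¹.
    k_loop_trans : float
        Optional intermolecular loop-phosphorylation rate, M⁻¹s⁻¹ (default 0:
        the concentration-normalization test shows the loop step is
        concentration independent at assay concentrations).
    activities : tuple
        (a00, a10, a01, a11) dimensionless relative specific activities.
    kcat_ref : float
        Turnover number of the fully active enzyme, s⁻¹.
    km_ref : float
        Michaelis constant of the fully active enzyme, µM.
    """

    k_cis: float = 5.0e-4
    k_inbox_trans: float = 5.0e2
    k_loop_trans: float = 0.0
    activities: Tuple[float, float, float, float] = DEFAULT_ACTIVITIES
    kcat_ref: float = 12.0
    km_ref: float = 179.0

    def __post_init__(self):
        vals = (self.k_cis, self.k_inbox_trans, self.k_loop_trans,
                self.kcat_ref, self.km_ref, *self.activities)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("autoactivation parameters must be finite")
        if self.k_cis < 0 or self.k_inbox_trans < 0 or self.k_loop_trans < 0:
            raise ValueError("rate constants must be nonnegative")
        if not all(0.0 <= a <= 1.0 for a in self.activities):
            raise ValueError("relative activities must lie in [0, 1]")


@dataclass
class StateTrajectory:
    """Time course of phospho-state fractions and substrate turnover.

    ``fractions`` has shape (n_times, 4) ordered (e00, e10, e01, e11);
    ``product`` and ``substrate`` are µM and satisfy P + S = S₀.
    """

    time: np.ndarray            # s
    fractions: np.ndarray       # (T, 4)
    product: np.ndarray         # µM
    substrate: np.ndarray       # µM
    e_tot: float                # M
    params: AutoactivationParams = field(repr=False, default=None)

    @property
    def activity(self) -> np.ndarray:
        """Activity-weighted fraction sum(a_ij e_ij(t)), dimensionless."""
        a = np.asarray(self.params.activities)
        return self.fractions @ a


def _rhs(t, y, p: AutoactivationParams, e_tot: float):
    e00, e10, e01, e11, _prod, s = y
    a = p.activities
    act = a[0] * e00 + a[1] * e10 + a[2] * e01 + a[3] * e11
    c = e_tot * act                      # catalytic pool, M
    k_loop = p.k_cis + p.k_loop_trans * c
    k_in = p.k_inbox_trans * c
    d00 = -k_loop * e00 - k_in * e00
    d10 = +k_loop * e00 - k_in * e10
    d01 = +k_in * e00 - k_loop * e01
    d11 = +k_in * e10 + k_loop * e01
    dp = e_tot * 1e6 * p.kcat_ref * act * s / (p.km_ref + s) if s > 0 else 0.0
    return [d00, d10, d01, d11, dp, -dp]


def simulate_autoactivation(
    params: AutoactivationParams,
    e_tot: float,
    s0: float,
    t_grid: Sequence[float],
    initial_fractions: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StateTrajectory:
    """Integrate the four-state autoactivation scheme.

    Parameters
    ----------
    e_tot : float
        Total enzyme concentration, M.
    s0 : float
        Initial substrate concentration, µM.
    t_grid : array-like
        Output times, s (must start at the initial time).
    initial_fractions : sequence of 4 floats
        Initial distribution over (e00, e10, e01, e11); must sum to 1.
    """
    if e_tot <= 0 or s0 <= 0:
        raise ValueError("e_tot and s0 must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    f0 = np.asarray(initial_fractions, dtype=float)
    if f0.shape != (4,) or abs(f0.sum() - 1.0) > 1e-9 or (f0 < 0).any():
        raise ValueError("initial_fractions must be 4 nonnegative values summing to 1")
    y0 = [*f0, 0.0, s0]
    sol = solve_ivp(
        _rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        args=(params, e_tot), method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"autoactivation ODE failed: {sol.message}",
                               last_state=sol.y[:, -1] if sol.y.size else None)
    frac = sol.y[:4].T
    return StateTrajectory(time=t_grid, fractions=frac,
                           product=sol.y[4], substrate=sol.y[5],
                           e_tot=e_tot, params=params)


def preincubation_assay(
    params: AutoactivationParams,
    e_tot_preinc: float,
    preinc_times: Sequence[float],
    dilution_factor: float,
    s_assay: float,
    e_assay: float | None = None,
    initial_fractions: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
) -> np.ndarray:
    """Initial assay rate (µM/s) after each ATP preincubation time.

    The enzyme autophosphorylates at ``e_tot_preinc`` (M) with no substrate
    present; at each preincubation time the pool is diluted by
    ``dilution_factor`` into the assay and the state distribution is frozen
    (post-dilution autophosphorylation at low-nM enzyme over the first assay
    minutes is negligible).  The reported rate is the activity-weighted
    Michaelis-Menten initial rate at substrate ``s_assay`` (µM).
    """
    preinc_times = np.asarray(preinc_times, dtype=float)
    if preinc_times.size == 0:
        raise ValueError("preinc_times must be nonempty")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    e_assay = e_tot_preinc / dilution_factor if e_assay is None else e_assay

    t_end = float(preinc_times.max())
    grid = np.unique(np.concatenate([[0.0], preinc_times]))
    if t_end == 0.0:
        frac_at = {0.0: np.asarray(initial_fractions, float)}
    else:
        # no substrate during preincubation: track states only (s0 tiny dummy)
        traj = simulate_autoactivation(params, e_tot_preinc, 1e-12, grid,
                                       initial_fractions=initial_fractions)
        frac_at = {t: traj.fractions[i] for i, t in enumerate(grid)}
    a = np.asarray(params.activities)
    rates = []
    for t in preinc_times:
        act = float(frac_at[t] @ a)
        v = e_assay * 1e6 * params.kcat_ref * act * s_assay / (params.km_ref + s_assay)
        rates.append(v)
    return np.asarray(rates)


def normalize_progress_curves(
    curves: Mapping[float, Tuple[np.ndarray, np.ndarray]],
) -> Dict[float, Tuple[np.ndarray, np.ndarray]]:
    """Divide each product curve by its enzyme concentration.

    ``curves`` maps e_tot (any consistent unit) to (time, product) arrays.
    Curves are interpolated onto the shared overlapping time grid (that of
    the first curve, clipped to the common range).
    """
    if len(curves) < 2:
        raise ValueError("need at least two enzyme concentrations")
    items = sorted(curves.items())
    t_lo = max(t.min() for _, (t, _) in items)
    t_hi = min(t.max() for _, (t, _) in items)
    if t_lo >= t_hi:
        raise ValueError("time ranges of the curves do not overlap")
    t0 = items[0][1][0]
    grid = t0[(t0 >= t_lo) & (t0 <= t_hi)]
    out: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}
    for e_tot, (t, p) in items:
        out[e_tot] = (grid, np.interp(grid, t, p) / e_tot)
    return out


def cis_trans_statistic(
    normalized_curves: Mapping[float, Tuple[np.ndarray, np.ndarray]],
    lag_fraction: float = 0.2,
    spread_threshold: float = 0.05,
) -> Tuple[float, int, str]:
    """Concentration-normalization (Dodson) diagnostic over the lag phase.

    Overlapping concentration-normalized progress curves in the lag phase
    indicate a concentration-independent (cis, intramolecular) activation
    step; systematically ordered curves indicate a trans (intermolecular)
    step.

    Returns ``(spread, slope_sign, label)`` where spread is the maximum over
    lag-window times of (max - min)/mean across concentrations, slope_sign
    is the sign of the trend of late-lag normalized product vs enzyme
    concentration, and label is ``"cis"``, ``"trans"`` or ``"mixed"``.
    """
    if len(normalized_curves) < 2:
        raise ValueError("need at least two enzyme concentrations")
    items = sorted(normalized_curves.items())
    grid = items[0][1][0]
    mat = np.vstack([np.interp(grid, t, p) for _, (t, p) in items])
    # lag window: before the fastest curve reaches lag_fraction of its final value
    finals = mat[:, -1]
    rel = mat / np.where(finals[:, None] == 0, 1.0, finals[:, None])
    reached = (rel >= lag_fraction).any(axis=0)
    lag_end = int(np.argmax(reached)) if reached.any() else grid.size
    if lag_end < 3:
        raise ValueError("fewer than 3 time points in the lag window")
    win = mat[:, 1:lag_end]  # skip t=0 where all curves are 0
    mean = win.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spread_t = (win.max(axis=0) - win.min(axis=0)) / mean
    spread = float(np.nanmax(spread_t)) if win.size else 0.0
    e = np.array([k for k, _ in items], dtype=float)
    late = win[:, -1] if win.size else finals
    slope_sign = int(np.sign(np.polyfit(e, late, 1)[0])) if np.ptp(late) > 0 else 0
    monotone_up = bool(np.all(np.diff(late) > 0))
    if spread < spread_threshold:
        label = "cis"
    elif monotone_up and slope_sign > 0:
        label = "trans"
    else:
        label = "mixed"
    return spread, slope_sign, label


@dataclass
class AutoactivationFit:
    """Result of fitting rate constants to multi-concentration progress curves."""

    params: AutoactivationParams
    se: Dict[str, float]
    residual_rms: float
    ill_conditioned: bool
    condition_number: float


def fit_autoactivation(
    curves: Mapping[float, Tuple[np.ndarray, np.ndarray]],
    template: AutoactivationParams,
    s0: float,
    fit_loop_trans: bool = False,
    n_starts: int = 4,
    seed: int = 0,
    condition_threshold: float = 1e8,
) -> AutoactivationFit:
    """Least-squares estimation of (k_cis, k_inbox_trans[, k_loop_trans]).

    ``curves`` maps e_tot (M) to (time s, product µM) observations; activities
    and reference Michaelis constants are taken from ``template`` and held
    fixed.  Multi-start in log-rate space; returns estimates, standard errors
    from the Jacobian, and an ill-conditioning flag (never an exception for
    unidentifiable fits).
    """
    items = sorted(curves.items())
    if len(items) < 2:
        raise ValueError("need at least two enzyme concentrations")
    for _, (t, p) in items:
        if len(t) < 20:
            raise ValueError("need at least 20 points per curve")

    names = ["k_cis", "k_inbox_trans"] + (["k_loop_trans"] if fit_loop_trans else [])

    def model_resid(logk):
        k = 10.0 ** logk
        p_trial = replace(template, k_cis=k[0], k_inbox_trans=k[1],
                          k_loop_trans=k[2] if fit_loop_trans else template.k_loop_trans)
        res = []
        for e_tot, (t, pobs) in items:
            try:
                traj = simulate_autoactivation(p_trial, e_tot, s0, t)
            except IntegrationError:
                return np.full(sum(len(t) for _, (t, _) in items), 1e6)
            res.append(traj.product - pobs)
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    x0_base = np.log10([max(template.k_cis, 1e-8), max(template.k_inbox_trans, 1e-2)]
                       + ([max(template.k_loop_trans, 1e-2)] if fit_loop_trans else []))
    best = None
    for i in range(n_starts):
        x0 = x0_base + (rng.uniform(-1.5, 1.5, size=len(names)) if i else 0.0)
        sol = least_squares(model_resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    k = 10.0 ** best.x
    fitted = replace(template, k_cis=k[0], k_inbox_trans=k[1],
                     k_loop_trans=k[2] if fit_loop_trans else template.k_loop_trans)
    n_obs = best.fun.size
    dof = max(n_obs - len(names), 1)
    s2 = float(best.fun @ best.fun) / dof
    jtj = best.jac.T @ best.jac
    cond = float(np.linalg.cond(jtj))
    ill = cond > condition_threshold
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        # delta method: k = 10^x  =>  se_k = k ln10 se_x
        se_vals = np.sqrt(np.clip(np.diag(cov_log), 0, None)) * k * np.log(10)
    except np.linalg.LinAlgError:
        se_vals = np.full(len(names), np.inf)
        ill = True
    se = dict(zip(names, se_vals.tolist()))
    return AutoactivationFit(params=fitted, se=se,
                             residual_rms=float(np.sqrt(best.fun @ best.fun / n_obs)),
                             ill_conditioned=ill, condition_number=cond)
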