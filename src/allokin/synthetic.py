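"""Seeded synthetic-data generators for every analysis stage.

Each generator produces data with the statistical structure the matching
analysis stage assumes, with the noiseless ground truth retained so that
round-trip (generate → analyse → recover) tests are possible without any
instrument or simulation downloads:

* NADH-coupled assay traces — linear Beer-Lambert signal that flattens as
  substrate depletes, plus i.i.d. Gaussian observation noise;
* autoactivation progress curves from the four-phospho-state scheme at
  several enzyme concentrations;
* HDX uptake tables and isotope envelopes under EX2 (single envelope,
  exponential per-peptide exchange) or EX1 (two-envelope mixture whose
  high-mass weight grows as 1 − exp(−k_op·t)) regimes;
* toy two-lobe pseudo-protein trajectories with prescribed open-close,
  twist and loop modes plus optional random-walk (diffusive) drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np

from .autoactivation import AutoactivationParams, StateTrajectory, simulate_autoactivation
from .hdx import IsotopeEnvelope, PeptideUptake, max_uptake
from .kinetics import EPSILON_NADH_340, AssayTrace
from .trajectory import Trajectory

__all__ = [
    "SyntheticConfig",
    "PeptideSpec",
    "gen_assay_trace",
    "gen_autoactivation_curves",
    "gen_hdx_dataset",
    "gen_two_lobe_trajectory",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shared generator knobs: seed, observation noise, grids, replicates."""

    seed: int = 0
    noise_sd: float = 0.0
    time_grid: Tuple[float, ...] = ()
    replicate_count: int = 3

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be positive")
        tg = np.asarray(self.time_grid, float)
        if tg.size and np.any(np.diff(tg) <= 0):
            raise ValueError("time_grid must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_assay_trace(
    rate: float,
    s0: float,
    config: SyntheticConfig,
    a0: float = 1.0,
    epsilon_nadh: float = EPSILON_NADH_340,
    path_length: float = 1.0,
    enzyme_conc: float = np.nan,
) -> AssayTrace:
    """Coupled-assay absorbance trace for a constant turnover rate.

    Product accumulates as P(t) = min(rate·t, s0) µM and the 340 nm signal
    falls by Beer-Lambert: A(t) = A0 − ε·l·P(t)·10⁻⁶.  Gaussian noise of sd
    ``config.noise_sd`` (AU) is added to the absorbance.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    t = np.asarray(config.time_grid, float)
    if t.size == 0:
        t = np.arange(0.0, 301.0, 1.0)
    product = np.minimum(rate * t, s0)
    absorbance = a0 - epsilon_nadh * path_length * product * 1e-6
    if config.noise_sd > 0:
        absorbance = absorbance + config.rng().normal(0, config.noise_sd, t.shape)
    return AssayTrace(time=t, absorbance=absorbance,
                      epsilon_nadh=epsilon_nadh, path_length=path_length,
                      substrate_0=s0, enzyme_conc=enzyme_conc)


def gen_autoactivation_curves(
    params: AutoactivationParams,
    e_tots: Sequence[float],
    config: SyntheticConfig,
    s0: float = 600.0,
    initial_fractions: Sequence[float] = (1.0, 0.0, 0.0, 0.0),
) -> Tuple[Dict[float, Tuple[np.ndarray, np.ndarray]], Dict[float, StateTrajectory]]:
    """Noisy product progress curves at several enzyme concentrations (M).

    Returns ``(curves, truth)`` where curves maps e_tot to (time s, noisy
    product µM) and truth maps e_tot to the noiseless StateTrajectory, kept
    for parameter-recovery tests.
    """
    e_tots = list(e_tots)
    if any(e <= 0 for e in e_tots):
        raise ValueError("enzyme concentrations must be positive")
    t = np.asarray(config.time_grid, float)
    if t.size == 0:
        t = np.linspace(0.0, 450.0 * 60.0, 451)
    rng = config.rng()
    curves, truth = {}, {}
    for e_tot in e_tots:
        traj = simulate_autoactivation(params, e_tot, s0, t,
                                       initial_fractions=initial_fractions)
        p = traj.product.copy()
        if config.noise_sd > 0:
            p = p + rng.normal(0, config.noise_sd, p.shape)
        curves[e_tot] = (t, p)
        truth[e_tot] = traj
    return curves, truth


@dataclass(frozen=True)
class PeptideSpec:
    """Ground truth for one synthetic peptide.

    ``k_exchange`` is the per-peptide EX2 exchange rate (min⁻¹); ``k_open``
    the EX1 opening rate (min⁻¹, used only in the EX1 regime);
    ``protected_uptake`` the centroid uptake of the folded (low-mass)
    population, Da.
    """

    sequence: str
    start: int
    k_exchange: float = 0.5
    k_open: float = 0.0
    protected_uptake: float = 0.0
    mono_mass: float = 1000.0

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.start + len(self.sequence) - 1)


def _envelope(mass_grid, centers, weights, sigma):
    intensity = np.zeros_like(mass_grid)
    for c, w in zip(centers, weights):
        intensity += w * np.exp(-0.5 * ((mass_grid - c) / sigma) ** 2)
    s = intensity.sum()
    return intensity / s if s > 0 else intensity


def gen_hdx_dataset(
    peptides: Sequence[PeptideSpec],
    regime: Literal["EX2", "EX1"],
    config: SyntheticConfig,
    state: str = "synthetic",
    exposures: Sequence[float] = (3.0, 10.0, 30.0, 90.0),
    f_d2o: float = 0.95,
    envelope_sigma: float = 1.0,
    mass_step: float = 0.25,
) -> Tuple[List[PeptideUptake], Dict[Tuple[str, float], IsotopeEnvelope]]:
    """Uptake table plus isotope-envelope series for a protection profile.

    EX2: a single envelope whose centroid follows
    D(t) = MaxUptake·f_D2O·(1 − exp(−k·t)).  EX1: a two-component mixture —
    folded population at ``protected_uptake``, unfolded at MaxUptake·f_D2O —
    with high-mass weight 1 − exp(−k_open·t).  Replicate uptake values get
    Gaussian noise of sd ``config.noise_sd`` Da; envelopes are noiseless
    mixtures on a regular mass grid (centroided-spectrum abstraction).
    """
    if regime not in ("EX2", "EX1"):
        raise ValueError(f"unknown exchange regime {regime!r}")
    for pep in peptides:
        if regime == "EX2" and pep.k_exchange <= 0:
            raise ValueError("EX2 requires positive k_exchange")
        if regime == "EX1" and pep.k_open < 0:
            raise ValueError("EX1 requires nonnegative k_open")
    rng = config.rng()
    records: List[PeptideUptake] = []
    envelopes: Dict[Tuple[str, float], IsotopeEnvelope] = {}
    for pep in peptides:
        mu = max_uptake(pep.sequence)
        d_max = mu * f_d2o
        grid = np.arange(pep.mono_mass - 5.0,
                         pep.mono_mass + d_max + 5.0 + mass_step, mass_step)
        for t in exposures:
            if regime == "EX2":
                d_true = d_max * (1.0 - np.exp(-pep.k_exchange * t))
                centers, weights = [pep.mono_mass + d_true], [1.0]
            else:
                f_open = 1.0 - np.exp(-pep.k_open * t)
                d_true = (1 - f_open) * pep.protected_uptake + f_open * d_max
                centers = [pep.mono_mass + pep.protected_uptake,
                           pep.mono_mass + d_max]
                weights = [1.0 - f_open, f_open]
            reps = np.clip(
                d_true + rng.normal(0, config.noise_sd, config.replicate_count),
                0.0, None)
            records.append(PeptideUptake(
                sequence=pep.sequence, span=pep.span, state=state,
                exposure=float(t), replicates=reps.tolist(), fd_uptake=d_max))
            envelopes[(pep.sequence, float(t))] = IsotopeEnvelope(
                mass=grid,
                intensity=_envelope(grid, centers, weights, envelope_sigma),
                exposure=float(t), state=state)
    return records, envelopes


def gen_two_lobe_trajectory(
    mode_amplitudes: Dict[str, float],
    diffusion_sd: float,
    n_frames: int,
    config: SyntheticConfig,
    atoms_per_lobe: int = 8,
    loop_atoms: int = 4,
    lobe_separation: float = 4.0,
    open_close_period: float = 100.0,
    twist_period: float = 61.0,
    loop_period: float = 37.0,
) -> Trajectory:
    """Toy two-lobe pseudo-protein trajectory with prescribed modes.

    Two rigid clusters of pseudo-atoms sit on the x axis ``lobe_separation``
    apart.  The ``open_close`` mode moves the second lobe sinusoidally along
    the inter-centroid axis (inter-centroid distance amplitude = the given
    amplitude); ``twist`` rotates it about that axis; ``loop`` oscillates a
    small flexible group along y.  ``diffusion_sd`` adds an independent
    per-particle random walk (step sd per frame), emulating diffusive,
    unconverged dynamics.  Periods are incommensurate by default so the
    modes are mutually near-orthogonal over the trajectory.
    """
    amp = {"open_close": 0.0, "twist": 0.0, "loop": 0.0, **dict(mode_amplitudes)}
    if any(v < 0 for v in amp.values()) or diffusion_sd < 0:
        raise ValueError("amplitudes and diffusion_sd must be nonnegative")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if atoms_per_lobe < 3 or loop_atoms < 1:
        raise ValueError("groups must be nonempty (>=3 lobe atoms, >=1 loop atom)")
    rng = config.rng()

    # rigid lobe templates: fixed random blobs (seeded) so geometry is generic
    tmpl_rng = np.random.default_rng(12345)
    lobe_a = tmpl_rng.normal(0, 0.8, (atoms_per_lobe, 3))
    lobe_a -= lobe_a.mean(axis=0)
    lobe_b = tmpl_rng.normal(0, 0.8, (atoms_per_lobe, 3))
    lobe_b -= lobe_b.mean(axis=0)
    loop0 = tmpl_rng.normal(0, 0.3, (loop_atoms, 3)) + np.array([lobe_separation / 2, 1.5, 0.0])

    t = np.arange(n_frames, dtype=float)
    phase_oc = 2 * np.pi * t / open_close_period
    phase_tw = 2 * np.pi * t / twist_period
    phase_lp = 2 * np.pi * t / loop_period

    n_atoms = 2 * atoms_per_lobe + loop_atoms
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        a = lobe_a.copy()
        sep = lobe_separation + amp["open_close"] * np.sin(phase_oc[f])
        theta = np.deg2rad(amp["twist"]) * np.sin(phase_tw[f])
        c, s = np.cos(theta), np.sin(theta)
        rot_x = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        b = lobe_b @ rot_x.T + np.array([sep, 0.0, 0.0])
        lp = loop0 + np.array([0.0, amp["loop"] * np.sin(phase_lp[f]), 0.0])
        coords[f] = np.vstack([a, b, lp])
    if diffusion_sd > 0:
        steps = rng.normal(0, diffusion_sd, coords.shape)
        coords += np.cumsum(steps, axis=0)

    ia = np.arange(atoms_per_lobe)
    ib = np.arange(atoms_per_lobe, 2 * atoms_per_lobe)
    il = np.arange(2 * atoms_per_lobe, n_atoms)
    labels = ([f"NLB{i}" for i in ia] + [f"CLB{i - atoms_per_lobe}" for i in ib]
              + [f"LOP{i - 2 * atoms_per_lobe}" for i in il])
    return Trajectory(coords, labels=labels,
                      groups={"n_lobe": ia, "c_lobe": ib, "loop": il},
                      units="nm")
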