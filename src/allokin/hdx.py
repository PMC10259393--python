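"""Differential hydrogen-deuterium exchange (HDX-MS) analysis.

Peptide-level deuterium uptake from two protein states is normalized (by
theoretical maximum uptake or by a fully-deuterated control), filtered for
significance by a >5% difference threshold combined with a pooled-variance
95% confidence interval, and summed across exposure times for
butterfly-style comparison.  Centroided isotope envelopes are classified as
EX2 (single population, gradual centroid shift) or EX1-like (bimodal: a
locally unfolded state exchanges all amides before refolding) by BIC-selected
Gaussian-mixture deconvolution, and the EX1 unfolding rate is estimated from
the growth of the high-mass fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "PeptideUptake",
    "IsotopeEnvelope",
    "EnvelopeFit",
    "max_uptake",
    "percent_uptake_difference",
    "significance_filter",
    "cumulative_delta",
    "classify_envelope",
    "ex1_fraction_series",
    "ex1_unfolding_rate",
    "ex1_rate_ratio",
    "deuterium_fraction",
    "DEFAULT_EXPOSURES_MIN",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: default butterfly exposure set, min
DEFAULT_EXPOSURES_MIN = (3.0, 10.0, 30.0, 90.0)


@dataclass
class PeptideUptake:
    """Replicate deuterium uptake of one peptide in one state at one exposure.

    ``span`` is the 1-based inclusive residue interval in construct
    coordinates; ``replicates`` are uptake values in Da.
    """

    sequence: str
    span: Tuple[int, int]
    state: str
    exposure: float                       # min
    replicates: List[float]
    fd_uptake: float | None = None        # fully-deuterated control, Da

    def __post_init__(self):
        if self.span[1] - self.span[0] + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.span} inconsistent with sequence length "
                f"{len(self.sequence)} for {self.sequence!r}")
        if any(d < 0 for d in self.replicates):
            raise ValueError("uptake must be nonnegative")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0


@dataclass
class IsotopeEnvelope:
    """Centroided isotope envelope of one peptide at one exposure time."""

    mass: np.ndarray          # Da
    intensity: np.ndarray     # normalized to sum 1
    exposure: float = np.nan  # min
    state: str = ""

    def __post_init__(self):
        self.mass = np.asarray(self.mass, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.mass) <= 0):
            raise ValueError("mass axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        tot = self.intensity.sum()
        if tot <= 0:
            raise ValueError("envelope has no signal")
        self.intensity = self.intensity / tot


def max_uptake(sequence: str, convention: Literal["n-p-2", "n-p-1"] = "n-p-2") -> int:
    """Theoretical maximum exchangeable amides of a peptide.

    Default convention is N − P − 2 (N residues, P prolines, clamped at 0);
    ``convention="n-p-1"`` gives the more common N − P − 1 (only the
    N-terminal amide excluded).
    """
    if not sequence:
        raise ValueError("sequence must be nonempty")
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    if convention not in ("n-p-2", "n-p-1"):
        raise ValueError(f"unknown convention {convention!r}")
    n, p = len(seq), seq.count("P")
    sub = 2 if convention == "n-p-2" else 1
    return max(n - p - sub, 0)


def percent_uptake_difference(d_a: float, d_b: float, normalizer: float) -> float:
    """ΔD% = (D_a − D_b)/normalizer · 100 (first state minus second).

    ``normalizer`` is either the theoretical MaxUptake (in Da, times the
    D₂O fraction where appropriate) or the fully-deuterated control uptake.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    return (d_a - d_b) / normalizer * 100.0


@dataclass
class ComparisonResult:
    """Per-peptide, per-exposure differential uptake with significance call."""

    sequence: str
    span: Tuple[int, int]
    exposure: float
    delta_da: float
    delta_pct: float
    ci_halfwidth_da: float
    significant: bool
    warning: str = ""


def significance_filter(
    pairs: Sequence[Tuple[PeptideUptake, PeptideUptake]],
    alpha: float = 0.05,
    min_delta_pct: float = 5.0,
    normalizer: Literal["theoretical", "fd"] = "theoretical",
    f_d2o: float = 0.95,
    convention: Literal["n-p-2", "n-p-1"] = "n-p-2",
) -> List[ComparisonResult]:
    """Significance-filter state-A vs state-B uptake comparisons.

    A difference is significant iff |ΔD%| exceeds ``min_delta_pct`` AND the
    (1 − alpha) confidence interval for ΔD (Da) excludes zero.  The CI uses a
    global pooled replicate SD across all peptides and timepoints with
    Student-t on the summed degrees of freedom::

        CI = ± t(1 − α/2, Σ(nᵢ−1)) · s_pooled · √(1/n_a + 1/n_b)

    With fewer than 2 replicates in either state the threshold rule alone
    decides, flagged with a warning.
    """
    # global pooled SD over every replicate set with df >= 1
    sq, df = 0.0, 0
    for a, b in pairs:
        for p in (a, b):
            n = len(p.replicates)
            if n > 1:
                sq += (n - 1) * p.sd ** 2
                df += n - 1
    s_pooled = np.sqrt(sq / df) if df > 0 else 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, df) if df > 0 else np.inf

    out: List[ComparisonResult] = []
    for a, b in pairs:
        if a.sequence != b.sequence or a.exposure != b.exposure:
            raise ValueError("pair must compare the same peptide at the same exposure")
        delta = a.mean - b.mean
        if normalizer == "fd":
            norm = a.fd_uptake if a.fd_uptake is not None else b.fd_uptake
            if norm is None:
                raise ValueError(f"no fully-deuterated control for {a.sequence}")
        else:
            norm = max_uptake(a.sequence, convention=convention) * f_d2o
        pct = percent_uptake_difference(a.mean, b.mean, norm)
        n_a, n_b = len(a.replicates), len(b.replicates)
        warning = ""
        if min(n_a, n_b) < 2 or df == 0:
            half = np.nan
            ci_excludes_zero = True
            warning = "CI undefined (<2 replicates); threshold rule only"
        else:
            half = float(tcrit * s_pooled * np.sqrt(1 / n_a + 1 / n_b))
            ci_excludes_zero = abs(delta) > half
        sig = (abs(pct) > min_delta_pct) and ci_excludes_zero
        out.append(ComparisonResult(a.sequence, a.span, a.exposure, delta,
                                    pct, half, sig, warning))
    return out


def cumulative_delta(
    state_a: Sequence[PeptideUptake],
    state_b: Sequence[PeptideUptake],
    exposures: Sequence[float] = DEFAULT_EXPOSURES_MIN,
    units: Literal["da", "pct"] = "da",
    f_d2o: float = 0.95,
    convention: Literal["n-p-2", "n-p-1"] = "n-p-2",
) -> List[Tuple[Tuple[int, int], str, float]]:
    """Summed ΔHDX across exposure times per peptide (butterfly bar heights).

    Both state sequences must cover the same peptides at the same exposures.
    Returns (span, sequence, cumulative delta) ordered N- to C-terminus.
    """
    def index(records):
        d = {}
        for r in records:
            d[(r.span, r.sequence, r.exposure)] = r
        return d

    ia, ib = index(state_a), index(state_b)
    peptides = sorted({(r.span, r.sequence) for r in state_a})
    if peptides != sorted({(r.span, r.sequence) for r in state_b}):
        raise ValueError("states cover different peptide sets")
    out = []
    for span, seq in peptides:
        total = 0.0
        for t in exposures:
            ka, kb = (span, seq, t), (span, seq, t)
            if ka not in ia or kb not in ib:
                raise ValueError(f"exposure {t} min missing for peptide {seq!r}")
            delta = ia[ka].mean - ib[kb].mean
            if units == "pct":
                norm = max_uptake(seq, convention=convention) * f_d2o
                delta = delta / norm * 100.0
            total += delta
        out.append((span, seq, total))
    return out


# ---------------------------------------------------------------------------
# EX1/EX2 classification: Gaussian-mixture deconvolution of envelopes
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeFit:
    """Mixture deconvolution of one isotope envelope."""

    n_components: int                  # 1 or 2
    means: Tuple[float, ...]           # Da, ascending
    sigmas: Tuple[float, ...]
    fractions: Tuple[float, ...]       # sum to 1
    label: str                         # "EX2" or "EX1-like"
    bic_1: float = np.nan
    bic_2: float = np.nan
    converged: bool = True

    @property
    def high_mass_fraction(self) -> float:
        return self.fractions[-1] if self.n_components == 2 else 0.0


def _weighted_em(mass, w, mu0, sigma0, pi0, n_iter=300, tol=1e-10):
    """EM for a Gaussian mixture observed as an intensity-weighted histogram.

    Normalized intensities are treated as fractional counts; the effective
    sample size enters only through the BIC computed by the caller.
    """
    k = len(mu0)
    mu = np.array(mu0, float)
    sig = np.array(sigma0, float)
    pi = np.array(pi0, float)
    ll_old = -np.inf
    for _ in range(n_iter):
        comp = np.stack([
            pi[j] * stats.norm.pdf(mass, mu[j], max(sig[j], 1e-3))
            for j in range(k)
        ])
        tot = comp.sum(axis=0)
        tot = np.where(tot <= 0, 1e-300, tot)
        resp = comp / tot                      # (k, n)
        ll = float(np.sum(w * np.log(tot)))
        wk = resp * w                          # fractional counts per component
        nk = wk.sum(axis=1)
        if np.any(nk <= 1e-12):
            return mu, sig, pi, ll, False
        mu = (wk @ mass) / nk
        sig = np.sqrt(np.maximum((wk * (mass[None] - mu[:, None]) ** 2).sum(axis=1) / nk,
                                 1e-6))
        pi = nk / nk.sum()
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    order = np.argsort(mu)
    return mu[order], sig[order], pi[order], ll, True


def classify_envelope(
    envelope: IsotopeEnvelope,
    min_separation: float = 2.0,
    n_starts: int = 5,
    effective_ions: float = 1000.0,
    seed: int = 0,
) -> EnvelopeFit:
    """Classify an isotope envelope as single (EX2) or bimodal (EX1-like).

    One- and two-component Gaussian mixtures are fit by multi-start EM and
    compared by BIC with an effective ion count as the sample size; the
    two-component model is accepted only if it wins on BIC and its means are
    at least ``min_separation`` Da apart.
    """
    m, w = envelope.mass, envelope.intensity
    if np.count_nonzero(w) < 8:
        raise ValueError("need at least 8 mass channels with signal")
    rng = np.random.default_rng(seed)
    mbar = float(w @ m)
    msd = float(np.sqrt(w @ (m - mbar) ** 2))
    n_eff = effective_ions

    # 1-component fit is analytic
    ll1 = float(np.sum(w * stats.norm.logpdf(m, mbar, max(msd, 1e-3))))
    bic1 = -2 * n_eff * ll1 + 2 * np.log(n_eff)

    best2 = None
    any_converged = False
    lo, hi = m[w > 0][0], m[w > 0][-1]
    for i in range(n_starts):
        if i == 0:
            mu0 = [mbar - msd, mbar + msd]
        else:
            mu0 = sorted(rng.uniform(lo, hi, 2))
        res = _weighted_em(m, w, mu0, [max(msd / 2, 0.5)] * 2, [0.5, 0.5])
        mu, sig, pi, ll, ok = res
        any_converged = any_converged or ok
        if ok and (best2 is None or ll > best2[3]):
            best2 = res
    if best2 is None:
        return EnvelopeFit(1, (mbar,), (msd,), (1.0,), "EX2",
                           bic_1=bic1, converged=False)
    mu, sig, pi, ll2, _ = best2
    bic2 = -2 * n_eff * ll2 + 5 * np.log(n_eff)

    bimodal = (bic2 < bic1) and (mu[1] - mu[0] >= min_separation) and np.all(pi > 0.01)
    if bimodal:
        return EnvelopeFit(2, tuple(mu), tuple(sig), tuple(pi), "EX1-like",
                           bic_1=bic1, bic_2=bic2, converged=any_converged)
    return EnvelopeFit(1, (mbar,), (msd,), (1.0,), "EX2",
                       bic_1=bic1, bic_2=bic2, converged=any_converged)


def ex1_fraction_series(
    envelopes: Sequence[IsotopeEnvelope],
    folded_mass: float,
    unfolded_mass: float,
    **classify_kwargs,
) -> Tuple[np.ndarray, np.ndarray]:
    """High-mass (unfolded) population fraction at each exposure time.

    Each envelope is classified; bimodal fits report the mixture weight of
    the high-mass component directly.  Unimodal fits are assigned fraction 0
    or 1 by whichever reference centroid (``folded_mass`` / ``unfolded_mass``)
    is closer — at late exposures a fully unfolded peptide shows a single
    envelope at the unfolded mass, which is fraction 1, not 0.

    Returns (exposures min, fractions), sorted by exposure.
    """
    pairs = []
    for env in envelopes:
        fit = classify_envelope(env, **classify_kwargs)
        if fit.n_components == 2:
            frac = fit.high_mass_fraction
        else:
            frac = 1.0 if abs(fit.means[0] - unfolded_mass) < abs(fit.means[0] - folded_mass) else 0.0
        pairs.append((env.exposure, frac))
    pairs.sort()
    t = np.array([p[0] for p in pairs])
    f = np.array([p[1] for p in pairs])
    return t, f


def ex1_unfolding_rate(
    exposures: Sequence[float],
    high_mass_fractions: Sequence[float],
) -> Tuple[float, float]:
    """Opening (unfolding) rate from the growth of the high-mass population.

    Fits f(t) = 1 − exp(−k_op·t) by least squares.  Returns (k_op min⁻¹, SE).
    Raises a flagged ValueError when all fractions are 0 or 1 (rate
    unidentifiable: the transition lies outside the sampled exposures).
    """
    t = np.asarray(exposures, float)
    f = np.asarray(high_mass_fractions, float)
    if t.size < 3:
        raise ValueError("need at least 3 exposures with classified envelopes")
    if np.all(f <= 0) or np.all(f >= 1):
        raise ValueError("unidentifiable rate: all fractions saturated at 0 or 1")

    def model(t_, k):
        return 1.0 - np.exp(-k * t_)

    k0 = max(-np.log(max(1.0 - np.clip(f, 0, 0.999).mean(), 1e-6)) / max(t.mean(), 1e-9), 1e-6)
    popt, pcov = curve_fit(model, t, f, p0=[k0], bounds=(0, np.inf), maxfev=10000)
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def ex1_rate_ratio(
    k_fast: float, se_fast: float, k_slow: float, se_slow: float,
    alpha: float = 0.05,
) -> Tuple[float, Tuple[float, float]]:
    """Ratio of two unfolding rates with a delta-method confidence interval.

    The CI is computed on log(k_fast/k_slow) and exponentiated.
    """
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("rates must be positive")
    ratio = k_fast / k_slow
    se_log = np.sqrt((se_fast / k_fast) ** 2 + (se_slow / k_slow) ** 2)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(ratio) - z * se_log), np.exp(np.log(ratio) + z * se_log)
    return ratio, (float(lo), float(hi))


def deuterium_fraction(dilution_ratio: float) -> float:
    """Final D₂O fraction after diluting a protiated sample 1:ratio into D₂O.

    A 1:20 dilution gives 1 − 1/20 = 0.95.
    """
    if dilution_ratio < 1:
        raise ValueError("dilution ratio must be >= 1")
    return 1.0 - 1.0 / dilution_ratio
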