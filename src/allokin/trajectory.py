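"""Trajectory post-processing: superposition, RMSF, PCA, collective coordinates.

Operates on frames × particles × 3 coordinate arrays with named particle
groups (N-lobe, C-lobe, activation loop for a kinase).  Provides rigid-body
least-squares superposition, per-particle RMSF with block-resampled
probability densities, atom-pair distances, Cartesian principal component
analysis, the cosine-content diagnostic of diffusive versus concerted
motion, and open-close / twist collective coordinates between two lobes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

__all__ = [
    "Trajectory",
    "PCResult",
    "superpose",
    "rmsf",
    "pair_distance",
    "pca",
    "cosine_content",
    "open_close_twist",
]


@dataclass
class Trajectory:
    """Coordinate ensemble: frames × particles × 3, with named groups."""

    coordinates: np.ndarray                       # (F, N, 3)
    labels: Sequence[str] | None = None
    groups: Dict[str, np.ndarray] = field(default_factory=dict)
    units: str = "nm"
    dt_ps: float | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, particles, 3)")
        if self.coordinates.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        self.groups = {k: np.asarray(v, int) for k, v in self.groups.items()}
        n = self.n_particles
        for name, idx in self.groups.items():
            if idx.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if idx.min() < 0 or idx.max() >= n:
                raise ValueError(f"group {name!r} has out-of-range indices")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    def group(self, name: str) -> np.ndarray:
        return self.groups[name]


@dataclass
class PCResult:
    """Cartesian PCA of an aligned trajectory."""

    eigenvalues: np.ndarray       # descending, units²
    eigenvectors: np.ndarray      # (3N, n_modes), columns orthonormal
    projections: np.ndarray       # (F, n_modes), centered
    cosine_contents: np.ndarray   # per mode
    mean: np.ndarray              # (N, 3) mean structure


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal rotation (and translation) of mobile onto ref; both (N, 3)."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return rot, ref.mean(axis=0)


def superpose(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    fit_group: str | None = None,
    n_mean_iterations: int = 2,
) -> Trajectory:
    """Least-squares rigid-body superposition of every frame.

    Default reference is the iterated mean structure: frames are aligned to
    the plain mean, the mean is recomputed, and the alignment repeated
    (``n_mean_iterations`` passes).  No scaling; the per-frame residual is
    the optimal RMSD.  ``fit_group`` restricts the fit (all particles are
    still transformed).
    """
    x = traj.coordinates
    idx = traj.group(fit_group) if fit_group else np.arange(traj.n_particles)
    if idx.size < 3:
        raise ValueError("need at least 3 particles to superpose")
    # degenerate (collinear) geometry check on the reference frame
    ref0 = x[0, idx]
    if np.linalg.matrix_rank(ref0 - ref0.mean(axis=0), tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry: superposition undefined")

    def align_all(ref):
        out = np.empty_like(x)
        for f in range(x.shape[0]):
            rot, tref = _kabsch(x[f, idx], ref)
            out[f] = (x[f] - x[f, idx].mean(axis=0)) @ rot + tref
        return out

    if reference is not None:
        aligned = align_all(np.asarray(reference, float)[idx])
    else:
        ref = x.mean(axis=0)[idx]
        aligned = align_all(ref)
        for _ in range(n_mean_iterations - 1):
            ref = aligned.mean(axis=0)[idx]
            aligned = align_all(ref)
    return Trajectory(aligned, labels=traj.labels, groups=dict(traj.groups),
                      units=traj.units, dt_ps=traj.dt_ps)


def rmsf(
    traj: Trajectory,
    group: str | None = None,
    block_size: int = 50,
    density: str = "histogram",
    n_bins: int = 30,
) -> Tuple[np.ndarray, np.ndarray, Tuple[np.ndarray, np.ndarray]]:
    """Per-particle RMSF, per-block RMSF samples, and their density.

    RMSF_i = sqrt(<|r_i − <r_i>|²>) over the (already aligned) trajectory.
    The probability density is built from per-particle RMSF values computed
    in non-overlapping blocks of ``block_size`` frames, which is how a
    distribution (rather than a single number) is obtained for a region.

    Returns (rmsf_per_particle, block_rmsf_samples, (bin_centers, density)).
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    if block_size > traj.n_frames:
        raise ValueError("block_size exceeds the number of frames")
    idx = traj.group(group) if group else np.arange(traj.n_particles)
    x = traj.coordinates[:, idx]

    def _rmsf(chunk):
        dev = chunk - chunk.mean(axis=0)
        return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))

    overall = _rmsf(x)
    n_blocks = traj.n_frames // block_size
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks for a density")
    blocks = [_rmsf(x[b * block_size:(b + 1) * block_size]) for b in range(n_blocks)]
    samples = np.concatenate(blocks)
    if density == "kde" and np.ptp(samples) > 0:
        from scipy.stats import gaussian_kde
        grid = np.linspace(samples.min(), samples.max(), n_bins)
        dens = gaussian_kde(samples)(grid)
    else:
        hist, edges = np.histogram(samples, bins=n_bins, density=True)
        grid, dens = 0.5 * (edges[:-1] + edges[1:]), hist
    return overall, samples, (grid, dens)


def pair_distance(traj: Trajectory, i: int, j: int) -> np.ndarray:
    """Euclidean distance between particles i and j per frame."""
    if i == j:
        raise ValueError("particle indices must differ")
    d = traj.coordinates[:, i] - traj.coordinates[:, j]
    return np.linalg.norm(d, axis=1)


def detect_step(series: np.ndarray) -> int:
    """Change-point helper: frame index maximizing the two-segment mean split."""
    s = np.asarray(series, float)
    n = s.size
    best_f, best_gain = 1, -np.inf
    total_mean = s.mean()
    sse0 = ((s - total_mean) ** 2).sum()
    for f in range(1, n):
        sse = ((s[:f] - s[:f].mean()) ** 2).sum() + ((s[f:] - s[f:].mean()) ** 2).sum()
        gain = sse0 - sse
        if gain > best_gain:
            best_gain, best_f = gain, f
    return best_f


def pca(traj: Trajectory, group: str | None = None) -> PCResult:
    """Cartesian PCA: eigendecomposition of the 3N×3N positional covariance.

    The trajectory should be superposed first.  Warns when frames < 3N
    (covariance rank-deficient).  Cosine content is evaluated per mode.
    """
    import warnings

    idx = traj.group(group) if group else np.arange(traj.n_particles)
    x = traj.coordinates[:, idx].reshape(traj.n_frames, -1)
    n3 = x.shape[1]
    if traj.n_frames <= n3:
        warnings.warn(f"frames ({traj.n_frames}) <= 3N ({n3}): covariance rank-deficient",
                      stacklevel=2)
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        warnings.warn("zero-variance trajectory: rank-0 PCA result", stacklevel=2)
    cov = xc.T @ xc / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    proj = xc @ evecs
    cc = np.array([cosine_content(proj[:, m], 1) if evals[m] > 0 else 0.0
                   for m in range(len(evals))])
    return PCResult(eigenvalues=evals, eigenvectors=evecs, projections=proj,
                    cosine_contents=cc,
                    mean=x.mean(axis=0).reshape(len(idx), 3))


def cosine_content(projection: np.ndarray, mode_index: int = 1) -> float:
    """Cosine content of a principal-component projection.

    c_i = (2/T) (Σ_t cos(iπt/T) p(t))² / Σ_t p(t)², with p mean-centered and
    the result clamped to [0, 1].  Values near 1 indicate random-diffusion-
    like motion (the projection resembles a half-period cosine, the leading
    mode of a random walk); values near 0 indicate genuine concerted
    oscillation.
    """
    p = np.asarray(projection, float)
    t_n = p.size
    if t_n < 4:
        raise ValueError("need at least 4 frames")
    p = p - p.mean()
    denom = float(p @ p)
    if denom == 0:
        raise ValueError("zero-norm projection: cosine content undefined")
    t = np.arange(t_n)
    c = np.cos(mode_index * np.pi * t / t_n)
    num = (2.0 / t_n) * float(c @ p) ** 2
    return float(np.clip(num / denom, 0.0, 1.0))


def open_close_twist(
    traj: Trajectory,
    n_lobe: str = "n_lobe",
    c_lobe: str = "c_lobe",
    bins: int = 40,
    smooth_sigma: float = 1.0,
    prominence: float = 0.05,
) -> Dict[str, np.ndarray | int]:
    """Open-close and twist collective coordinates between two lobes.

    open-close: inter-group centroid distance, mean-centered.
    twist: rotation angle (degrees, mean-centered) of the C-lobe's leading
    principal axis about the inter-centroid axis, relative to frame 1 — a
    convention, since the shearing motion between kinase lobes has no unique
    quantitative definition.

    Returns per-frame series, a 2-D occupancy histogram over (open-close,
    twist), and a basin count from peak detection on the smoothed histogram.
    """
    ia, ib = traj.group(n_lobe), traj.group(c_lobe)
    if np.intersect1d(ia, ib).size:
        raise ValueError("lobe groups must be disjoint")
    xa = traj.coordinates[:, ia]
    xb = traj.coordinates[:, ib]
    ca, cb = xa.mean(axis=1), xb.mean(axis=1)
    axis = cb - ca
    dist = np.linalg.norm(axis, axis=1)
    if np.any(dist < 1e-12):
        raise ValueError("coincident lobe centroids")
    u = axis / dist[:, None]

    # leading principal axis of the C-lobe, per frame
    def principal_axis(pts):
        dev = pts - pts.mean(axis=0)
        cov = dev.T @ dev
        w, v = np.linalg.eigh(cov)
        return v[:, -1]

    twist = np.empty(traj.n_frames)
    v0 = principal_axis(xb[0])
    w_ref = v0 - (v0 @ u[0]) * u[0]
    nrm = np.linalg.norm(w_ref)
    if nrm < 1e-10:
        raise ValueError("degenerate geometry: C-lobe principal axis parallel "
                         "to the inter-centroid axis, twist undefined")
    w_ref /= nrm
    for f in range(traj.n_frames):
        v = principal_axis(xb[f])
        if v @ v0 < 0:          # eigenvector sign is arbitrary; keep continuity
            v = -v
        w = v - (v @ u[f]) * u[f]
        nw = np.linalg.norm(w)
        if nw < 1e-10:
            raise ValueError("degenerate geometry at frame %d" % f)
        w /= nw
        r = w_ref - (w_ref @ u[f]) * u[f]
        r /= np.linalg.norm(r)
        twist[f] = np.degrees(np.arctan2(u[f] @ np.cross(r, w), r @ w))

    oc = dist - dist.mean()
    tw = twist - twist.mean()
    hist, xe, ye = np.histogram2d(oc, tw, bins=bins)
    sm = gaussian_filter(hist, smooth_sigma)
    peak_mask = (maximum_filter(sm, size=3) == sm) & (sm > prominence * sm.max())
    n_basins = int(peak_mask.sum())
    return {
        "open_close": oc,
        "twist": tw,
        "occupancy": hist,
        "edges": (xe, ye),
        "n_basins": n_basins,
    }
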