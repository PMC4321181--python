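"""Nearest-neighbour spatial statistics under a mask-constrained CSR null.

The question: are detected beads clustered beyond what a homogeneous Poisson
process (complete spatial randomness, CSR) of the same intensity inside the
same compartment mask would show?  The observed mean nearest-neighbour (NN)
distance is compared against a Monte-Carlo envelope of CSR patterns with the
same point count simulated uniformly inside the mask.  No edge correction is
applied: the null is simulated in the identical domain, so edge effects
cancel by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError
from .stack_io import LabelVolume


@dataclass
class PointPattern:
    """Points (x, y, z) in nm inside a compartment mask."""

    points: np.ndarray
    domain: LabelVolume
    domain_labels: frozenset

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 3:
            raise ConfigError("points must be (n, 3) arrays of (x, y, z) nm")

    @property
    def n(self) -> int:
        return 0 if self.points.size == 0 else len(self.points)

    def mask(self) -> np.ndarray:
        return self.domain.mask(self.domain_labels)

    def domain_volume_um3(self) -> float:
        dz, dy, dx = self.domain.voxel_size
        return float(self.mask().sum()) * dz * dy * dx * 1e-9


@dataclass
class CSREnvelope:
    """Monte-Carlo envelope of one summary statistic under CSR."""

    statistic: str
    observed: float
    null_mean: float
    lo: float                 # 2.5th percentile of the null
    hi: float                 # 97.5th percentile of the null
    n_reps: int
    seed: int
    clustered: bool           # observed mean NN below the lower envelope

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ConfigError("envelope percentiles out of order")


def nn_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean nearest-other-point distance (nm) for every point."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ConfigError("nearest-neighbour distances need at least 2 points")
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=2)
    return dists[:, 1]


def fraction_separated(points: np.ndarray, r_nm: float = 200.0) -> float:
    """Fraction of points whose NN distance strictly exceeds ``r_nm``."""
    return float(np.mean(nn_distances(points) > r_nm))


def close_pair_count(points: np.ndarray, r_nm: float) -> int:
    """Number of unordered pairs at distance <= r (ties count as close)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0
    return len(cKDTree(points).query_pairs(r_nm))


def mean_nn_distance_csr(intensity_per_um3: float) -> float:
    """Closed-form mean NN distance (nm) of an unbounded 3D Poisson process:
    Gamma(4/3) * (4/3 * pi * lambda)^(-1/3) ~= 0.554 * lambda^(-1/3)."""
    from math import gamma, pi
    lam_nm3 = intensity_per_um3 * 1e-9
    return gamma(4.0 / 3.0) * (4.0 * pi * lam_nm3 / 3.0) ** (-1.0 / 3.0)


def void_probability_csr(intensity_per_um3: float, r_nm: float) -> float:
    """P(NN distance > r) = exp(-lambda * 4/3 pi r^3) for unbounded CSR."""
    lam_nm3 = intensity_per_um3 * 1e-9
    return float(np.exp(-lam_nm3 * 4.0 / 3.0 * np.pi * r_nm ** 3))


def csr_sample(domain: LabelVolume, domain_labels, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """``n`` points uniform in the voxelized mask (uniform within voxels),
    returned as (x, y, z) nm."""
    mask = domain.mask(domain_labels)
    voxels = np.flatnonzero(mask.ravel())
    if voxels.size == 0:
        raise ConfigError("empty domain mask")
    choice = rng.choice(voxels, size=n, replace=True)
    idx = np.column_stack(np.unravel_index(choice, domain.shape)).astype(float)
    idx += rng.uniform(-0.5, 0.5, size=idx.shape)
    zyx = idx * np.asarray(domain.voxel_size) + np.asarray(domain.origin)
    return zyx[:, ::-1]  # -> (x, y, z)


_STATISTICS = {
    "mean_nn": lambda pts: float(np.mean(nn_distances(pts))),
    "median_nn": lambda pts: float(np.median(nn_distances(pts))),
}


def csr_envelope(pattern: PointPattern, statistic: str = "mean_nn",
                 n_reps: int = 199, seed: int = 0) -> CSREnvelope:
    """Monte-Carlo CSR envelope for one NN summary statistic.

    ``n_reps`` CSR patterns of the observed count are simulated inside the
    observed mask; the pattern is flagged ``clustered`` when its statistic
    falls below the 2.5th percentile of the null (small NN distances =
    aggregation).
    """
    if statistic not in _STATISTICS:
        raise ConfigError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if n_reps < 99:
        raise ConfigError("need at least 99 replicates for a stable envelope")
    if pattern.n < 2:
        raise ConfigError("too few points for a NN statistic")
    stat = _STATISTICS[statistic]
    observed = stat(pattern.points)
    rng = np.random.default_rng(seed)
    null = np.array([
        stat(csr_sample(pattern.domain, pattern.domain_labels, pattern.n, rng))
        for _ in range(n_reps)
    ])
    lo, hi = np.percentile(null, [2.5, 97.5])
    return CSREnvelope(
        statistic=statistic,
        observed=observed,
        null_mean=float(null.mean()),
        lo=float(lo),
        hi=float(hi),
        n_reps=n_reps,
        seed=seed,
        clustered=bool(observed < lo),
    )


def analyze(particles, labels: LabelVolume, domain_labels,
            r_nm: float = 200.0, n_reps: int = 199, seed: int = 0) -> dict:
    """NN summary + CSR envelope for the particles inside one compartment."""
    sel = particles[particles["compartment"].isin(domain_labels)]
    points = sel[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    pattern = PointPattern(points, labels, frozenset(domain_labels))
    nn = nn_distances(points)
    env = csr_envelope(pattern, "mean_nn", n_reps=n_reps, seed=seed)
    return {
        "n": int(pattern.n),
        "domain_volume_um3": pattern.domain_volume_um3(),
        "mean_nn_nm": float(nn.mean()),
        "median_nn_nm": float(np.median(nn)),
        "fraction_separated": fraction_separated(points, r_nm),
        "separation_radius_nm": float(r_nm),
        "close_pairs": close_pair_count(points, r_nm),
        "csr_null_mean_nn_nm": env.null_mean,
        "csr_lo_nm": env.lo,
        "csr_hi_nm": env.hi,
        "csr_n_reps": env.n_reps,
        "csr_seed": env.seed,
        "clustered": env.clustered,
    }
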