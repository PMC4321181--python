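"""Slice-detectability model for spherical particles in serial sections.

A silver-amplified gold bead is an electron-dense sphere of diameter ``d``.
FIB milling exposes imaging planes every ``t`` nm, and the low-kV
back-scattered signal samples only a thin layer (penetration depth ``p``)
below each freshly milled surface.  With bead centres uniformly positioned
along the milling axis:

* the expected number of planes intersecting one bead is ``d / t``;
* a bead is never seen at all when it falls entirely between two consecutive
  planes, which happens with probability ``max(0, (t - d) / t)`` — the miss
  fraction used to correct observed counts.

Both closed forms take ``p = 0``: at 5 nm sections a 20 nm bead spans 4
consecutive sections on average, and 25 nm sections miss 20% of the beads,
which is exactly the ``p = 0`` arithmetic.  A penetration-inclusive variant
(effective diameter ``d + p``) is available behind the ``effective`` flag for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class DetectionGeometry:
    """Geometry driving detectability: particle diameter ``d``, slice
    thickness ``t``, BSE penetration depth ``p`` (all nm)."""

    d: float = 20.0
    t: float = 25.0
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.t <= 0 or self.p < 0:
            raise ConfigError(f"need d > 0, t > 0, p >= 0; got {self}")

    def effective_diameter(self, effective: bool = False) -> float:
        return self.d + self.p if effective else self.d


def miss_fraction(geom: DetectionGeometry, effective: bool = False) -> float:
    """Probability that a uniformly positioned bead intersects no imaged plane."""
    d = geom.effective_diameter(effective)
    return max(0.0, (geom.t - d) / geom.t)


def expected_sections(geom: DetectionGeometry, effective: bool = False) -> float:
    """Expected number of imaged planes intersecting one bead."""
    return geom.effective_diameter(effective) / geom.t


def corrected_count(n_observed: float, geom: DetectionGeometry,
                    effective: bool = False) -> float:
    """Scale an observed count up for beads lost between sections."""
    miss = miss_fraction(geom, effective)
    if miss >= 1.0 - 1e-9:
        raise ConfigError("miss fraction is ~1: no particle is ever detected")
    return n_observed / (1.0 - miss)


def intersecting_planes(z_nm: float, geom: DetectionGeometry, dz: float,
                        n_slices: int | None = None) -> np.ndarray:
    """Indices of imaged planes ``k*dz`` within the closed visibility window
    ``|k*dz - z| <= d/2 + p`` of a bead centred at ``z_nm``.

    The window is closed, so a plane exactly tangent to the bead counts as
    intersecting (its rendered contrast is zero, however — see synth).
    """
    half = geom.d / 2.0 + geom.p
    lo = int(np.ceil((z_nm - half) / dz - 1e-9))
    hi = int(np.floor((z_nm + half) / dz + 1e-9))
    ks = np.arange(max(lo, 0), hi + 1)
    if n_slices is not None:
        ks = ks[ks < n_slices]
    return ks


def monte_carlo_sections(geom: DetectionGeometry, n: int, rng) -> np.ndarray:
    """Plane-intersection counts for ``n`` bead centres uniform over one
    milling period; the independent check on both closed forms."""
    offsets = rng.uniform(0.0, geom.t, size=n)
    half = geom.d / 2.0 + geom.p
    # planes at multiples of t; count k with |k*t - u| <= half
    hi = np.floor((offsets + half) / geom.t)
    lo = np.ceil((offsets - half) / geom.t)
    return (hi - lo + 1).astype(np.int64)


def monte_carlo_miss_fraction(geom: DetectionGeometry, n: int, rng) -> float:
    counts = monte_carlo_sections(geom, n, rng)
    return float(np.mean(counts == 0))
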