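"""CryoET particle depth analysis: planes, percent deviation, histograms.

The depth of each picked particle inside the vitreous film is expressed
on a normalised scale anchored to the two air-water interfaces: 0% at
the mid-surface of the ice and 100% at either AWI.  The two interface
planes are fitted from user-picked points (three points define a plane
exactly; more are fitted by total least squares), the mid-surface is the
locus equidistant from both planes, and each particle's deviation is

``100 * |d_top - d_bot| / (d_top + d_bot)``

with ``d_top, d_bot`` the signed distances to the two planes along
their interior-pointing normals.  This local normalisation makes the
measure exact for tilted, non-parallel interfaces and invariant under
rigid motions of the tomogram.  Particles found beyond an interface
(deviation > 100%) are retained in an explicit overflow bin so counts
are conserved.  Binning follows the convention of five 20%-wide bins
plus overflow, reported as fractions of the total population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ParticleModel",
    "Plane",
    "DeviationProfile",
    "fit_plane",
    "deviation_percent",
    "deviation_profile",
    "deviation_histogram",
    "recover_adsorbed_fractions",
    "slab_select",
]

_A_PER_NM = 10.0


@dataclass(frozen=True)
class ParticleModel:
    """Picked particle coordinates from a tomogram.

    ``points``: (n, 3) array in voxels; ``pixel_size``: Å/voxel;
    optional per-particle string ``labels`` (e.g. ground-truth component
    for synthetic scenes).  ``points_nm`` gives metric coordinates.
    """

    points: np.ndarray
    pixel_size: float
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.labels is not None and len(self.labels) != len(pts):
            raise ValueError("labels length must match point count")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def points_nm(self) -> np.ndarray:
        """Coordinates in nm (voxels * Å/voxel / 10)."""
        return self.points * (self.pixel_size / _A_PER_NM)


@dataclass(frozen=True)
class Plane:
    """A plane ``normal . x = offset`` with a unit normal; nm units."""

    normal: np.ndarray
    offset: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not math.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a finite non-zero vector")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of each point from the plane along the normal."""
        return np.atleast_2d(points) @ self.normal - self.offset

    def oriented_toward(self, point: np.ndarray) -> "Plane":
        """The same plane with its normal pointing toward *point*."""
        if float(self.signed_distance(point)[0]) < 0:
            return Plane(-self.normal, -self.offset, self.residual_rms)
        return self


def fit_plane(points: np.ndarray) -> Plane:
    """Fit a plane to >= 3 points (nm).

    Three points give the exact plane through them; more give the total
    least-squares plane (smallest singular vector of the centred cloud),
    with the residual RMS recorded on the result.  Collinear or
    insufficient points raise a geometry error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("fit_plane requires at least 3 three-dimensional points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    scale = np.max(np.linalg.norm(centred, axis=1))
    if scale == 0 or s[1] <= 1e-12 * s[0]:
        raise ValueError("points are collinear or coincident; no unique plane")
    normal = vt[2]
    residuals = centred @ normal
    return Plane(
        normal=normal,
        offset=float(normal @ centroid),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
    )


def _interior_planes(top: Plane, bottom: Plane) -> tuple[Plane, Plane]:
    """Orient each plane's normal toward the other plane (film interior)."""
    anchor_bottom = bottom.offset * bottom.normal
    anchor_top = top.offset * top.normal
    parallel = abs(abs(float(top.normal @ bottom.normal)) - 1.0) < 1e-12
    if parallel and abs(float(top.signed_distance(anchor_bottom)[0])) < 1e-9:
        raise ValueError("top and bottom planes coincide")
    top_in = top.oriented_toward(anchor_bottom)
    bottom_in = bottom.oriented_toward(anchor_top)
    return top_in, bottom_in


def deviation_percent(
    points: np.ndarray, top: Plane, bottom: Plane
) -> tuple[np.ndarray, np.ndarray]:
    """Percent deviation from the ice mid-surface and nearer-side labels.

    For each point (nm), ``deviation = 100 |d_b - d_t| / (d_t + d_b)``
    with distances measured along the interior-pointing normals: 0 at
    the mid-surface, 100 on either interface, > 100 beyond it.  Returns
    ``(deviation, side)`` with side ``"top"`` or ``"bottom"`` for the
    nearer plane; exact ties go to ``"top"``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    top_in, bottom_in = _interior_planes(top, bottom)
    d_top = top_in.signed_distance(pts)
    d_bot = bottom_in.signed_distance(pts)
    thickness = d_top + d_bot  # local film thickness along the normals
    if np.any(thickness <= 0):
        raise ValueError("point lies outside the slab where the planes bound a film")
    dev = 100.0 * np.abs(d_bot - d_top) / thickness
    side = np.where(d_top <= d_bot, "top", "bottom")
    return dev, side


_BIN_LABEL_OVERFLOW = ">100"


@dataclass(frozen=True)
class DeviationProfile:
    """Per-particle deviations plus their binned distribution.

    ``bin_edges`` are in percent and cover [0, 100]; ``counts`` and
    ``fractions`` carry one extra trailing entry for the overflow bin
    (> 100%), so fractions always sum to 1.
    """

    deviation: np.ndarray
    side: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray

    def as_rows(self) -> list[dict]:
        rows = []
        for i in range(len(self.counts) - 1):
            rows.append(
                {
                    "bin_lo": float(self.bin_edges[i]),
                    "bin_hi": float(self.bin_edges[i + 1]),
                    "count": int(self.counts[i]),
                    "fraction": float(self.fractions[i]),
                }
            )
        rows.append(
            {
                "bin_lo": 100.0,
                "bin_hi": math.inf,
                "count": int(self.counts[-1]),
                "fraction": float(self.fractions[-1]),
            }
        )
        return rows


def deviation_histogram(
    model: ParticleModel, top: Plane, bottom: Plane, bin_width: float = 20.0
) -> DeviationProfile:
    """Bin particle deviations into ``100 / bin_width`` bins plus overflow.

    The default 20% width gives the five bins [0,20), [20,40), [40,60),
    [60,80), [80,100] plus an explicit overflow bin for particles found
    beyond an interface; fractions are of the total particle count and
    sum to 1.
    """
    if len(model) == 0:
        raise ValueError("empty particle model")
    n_bins = 100.0 / bin_width
    if bin_width <= 0 or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width must evenly divide 100, got {bin_width}")
    n_bins = int(round(n_bins))
    dev, side = deviation_percent(model.points_nm, top, bottom)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts = np.histogram(dev, bins=edges)[0]
    overflow = int(np.sum(dev > 100.0))
    # np.histogram's closed last edge already keeps dev == 100 in-range
    counts = np.append(counts, overflow)
    fractions = counts / len(model)
    return DeviationProfile(
        deviation=dev, side=side, bin_edges=edges, counts=counts, fractions=fractions
    )


def recover_adsorbed_fractions(
    profile: DeviationProfile, outer_bin_lo: float = 80.0
) -> dict[str, float]:
    """Estimate the adsorbed fractions behind a deviation profile.

    Treats every particle with deviation >= *outer_bin_lo* (including
    overflow) as interface-adsorbed and corrects for the share of a
    uniform bulk population expected in that outer band: with
    ``u = 1 - outer_bin_lo/100`` per film (split evenly between sides),

    ``f_bulk = P(dev < lo) / (1 - u)``,
    ``f_side = P(dev >= lo, side) - f_bulk * u / 2``.

    Valid when the adsorption jitter keeps adsorbed particles inside the
    outer band; returns the estimates clipped to [0, 1].
    """
    if not 0 < outer_bin_lo < 100:
        raise ValueError("outer_bin_lo must lie strictly inside (0, 100)")
    u = 1.0 - outer_bin_lo / 100.0
    n = len(profile.deviation)
    outer = profile.deviation >= outer_bin_lo
    p_in = float(np.sum(~outer)) / n
    f_bulk = min(p_in / (1.0 - u), 1.0)
    out = {"f_bulk": f_bulk}
    for side in ("top", "bottom"):
        p_side = float(np.sum(outer & (profile.side == side))) / n
        out[f"f_{side}"] = float(np.clip(p_side - f_bulk * u / 2.0, 0.0, 1.0))
    return out


def slab_select(model: ParticleModel, plane: Plane, thickness: float = 5.0) -> ParticleModel:
    """Particles within ``thickness/2`` of *plane* along its normal.

    Mirrors extracting a ~5-nm tomogram slice at an interface or at the
    film centre; returns a new model preserving order and labels.
    """
    if thickness < 0:
        raise ValueError("slab thickness must be non-negative")
    dist = np.abs(plane.signed_distance(model.points_nm))
    keep = dist <= thickness / 2.0
    labels = None
    if model.labels is not None:
        labels = tuple(lbl for lbl, k in zip(model.labels, keep) if k)
    return ParticleModel(points=model.points[keep], pixel_size=model.pixel_size, labels=labels)


def deviation_profile(
    model: ParticleModel, top: Plane, bottom: Plane, bin_width: float = 20.0
) -> DeviationProfile:
    """Alias for :func:`deviation_histogram` (full profile, not just bins)."""
    return deviation_histogram(model, top, bottom, bin_width)
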