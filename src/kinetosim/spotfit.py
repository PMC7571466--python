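"""Spot-based (kSHREC-style) delta measurement for human-sized kinetochores.

Kinetochores that appear as unresolved spots are segmented per channel,
their XY centroids obtained by 2D Gaussian fitting of maximum-intensity
projections (Z separately, from the XZ projection), chromatic aberration is
suppressed by translating one channel so the global centres of mass of the
two channels coincide, and delta is the 3D Euclidean distance between the
red and green centroids of the same kinetochore.

Unlike the pairwise line-scan delta, the per-kinetochore 3D distance is
invariant to kinetochore swivel, but it relies on the global-centroid
registration to remove chromatic shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

from ._fitting import fit_gaussian_2d, fit_gaussian_peaks
from .optics import FWHM_PER_SIGMA, ImageVolume

RESIDUAL_GATE = 0.10  # spots with larger relative residual are flagged not-fittable


@dataclass
class SpotRegion:
    """One segmented connected component of a channel volume."""

    label: int
    channel: str
    slices: tuple  # (z, y, x) slice objects into the full volume
    mask: np.ndarray  # bool array over the bounding box
    n_voxels: int


@dataclass(frozen=True)
class SpotFitResult:
    centroid: np.ndarray  # (x, y, z) nm
    fwhm_xy: float  # nm, longer axis in the XY plane
    residual: float  # RMS residual / fitted amplitude
    channel: str
    label: int
    fittable: bool = True  # residual within the 10% gate

    def shifted(self, translation) -> "SpotFitResult":
        return SpotFitResult(
            self.centroid + np.asarray(translation, float),
            self.fwhm_xy,
            self.residual,
            self.channel,
            self.label,
            self.fittable,
        )


@dataclass(frozen=True)
class RegistrationResult:
    """Global-centroid chromatic correction: translation applied to one channel."""

    translation: np.ndarray  # (x, y, z) nm added to the moved channel
    moved_channel: str
    pre_mismatch: float  # |mean(green) - mean(red)| before, nm
    post_mismatch: float  # after applying the translation, nm

    def apply(self, spots) -> list:
        return [
            s.shifted(self.translation) if s.channel == self.moved_channel else s
            for s in spots
        ]


def segment_spots(
    volume: ImageVolume,
    channel: str,
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
    min_size: int = 5,
) -> list:
    """Threshold + connected components segmentation of one channel.

    The volume is Gaussian-smoothed (``smooth_sigma`` voxels), thresholded
    (Otsu by default) and labelled; regions below ``min_size`` voxels are
    dropped.  Raises if nothing survives.
    """
    arr = volume.channel(channel)
    sm = gaussian_filter(arr, smooth_sigma) if smooth_sigma > 0 else arr
    thr = threshold_otsu(sm) if threshold is None else threshold
    mask = sm > thr
    labels, n = _label(mask, return_num=True)
    if n == 0:
        raise ValueError(f"no spots found in channel {channel!r} above threshold {thr:.3g}")
    counts = np.bincount(labels.ravel())
    regions = []
    for lab in range(1, n + 1):
        if counts[lab] < min_size:
            continue
        where = labels == lab
        zs, ys, xs = np.nonzero(where)
        sl = (
            slice(zs.min(), zs.max() + 1),
            slice(ys.min(), ys.max() + 1),
            slice(xs.min(), xs.max() + 1),
        )
        regions.append(
            SpotRegion(lab, channel, sl, where[sl], int(counts[lab]))
        )
    if not regions:
        raise ValueError(
            f"all spots in channel {channel!r} are below the {min_size}-voxel minimum"
        )
    return regions


def fit_spot(region: SpotRegion, volume: ImageVolume, pad: int = 2) -> SpotFitResult:
    """Sub-voxel spot localization: 2D Gaussian in XY projection, 1D Gaussian in Z.

    The XY centroid comes from an elliptical 2D Gaussian fitted to the
    maximum-intensity projection of the (padded) region bounding box;
    ``fwhm_xy`` reports the longer fitted axis.  The Z coordinate is fitted
    separately on the Z profile of the XZ projection, falling back to the
    intensity centroid when too few planes are available.  A relative
    residual above 10% marks the spot as not fittable.
    """
    arr = volume.channel(region.channel)
    nz, ny, nx = arr.shape
    zs, ys, xs = region.slices
    sl = (
        slice(max(zs.start - pad, 0), min(zs.stop + pad, nz)),
        slice(max(ys.start - pad, 0), min(ys.stop + pad, ny)),
        slice(max(xs.start - pad, 0), min(xs.stop + pad, nx)),
    )
    sub = arr[sl]
    grid = volume.grid
    xc = grid.axis_centers(0)[sl[2]]
    yc = grid.axis_centers(1)[sl[1]]
    zc = grid.axis_centers(2)[sl[0]]

    proj_xy = sub.max(axis=0)
    params, rel_err, converged = fit_gaussian_2d(xc, yc, proj_xy)
    _, x0, y0, sx, sy, _ = params
    fwhm_xy = max(sx, sy) * FWHM_PER_SIGMA

    proj_xz = sub.max(axis=1)  # (z, x)
    zprof = proj_xz.sum(axis=1)
    z0 = _fit_z(zc, zprof)

    return SpotFitResult(
        centroid=np.array([x0, y0, z0]),
        fwhm_xy=float(fwhm_xy),
        residual=rel_err,
        channel=region.channel,
        label=region.label,
        fittable=bool(converged and rel_err <= RESIDUAL_GATE),
    )


def _fit_z(zc: np.ndarray, zprof: np.ndarray) -> float:
    if len(zc) >= 4:
        try:
            peaks, _, _, converged = fit_gaussian_peaks(zc, zprof, 1)
            if converged:
                return float(peaks[0][1])
        except ValueError:
            pass
    w = np.clip(zprof - zprof.min(), 0, None)
    total = w.sum()
    return float((w * zc).sum() / total) if total > 0 else float(zc.mean())


def fit_all_spots(volume: ImageVolume, channel: str, **segment_kw) -> list:
    return [fit_spot(r, volume) for r in segment_spots(volume, channel, **segment_kw)]


def register_channels(
    green_spots, red_spots, move: str = "red"
) -> RegistrationResult:
    """Chromatic correction: align the global centres of mass of the two channels.

    Returns the translation applied to the ``move`` channel so that the mean
    centroids coincide.  At least two spots per channel are required for the
    global mean to be meaningful.
    """
    g = np.array([s.centroid for s in green_spots], float)
    r = np.array([s.centroid for s in red_spots], float)
    if len(g) < 2 or len(r) < 2:
        raise ValueError("registration needs at least 2 spots per channel")
    pre = g.mean(axis=0) - r.mean(axis=0)
    translation = pre if move == "red" else -pre
    moved = (r + translation) if move == "red" else r
    fixed = g if move == "red" else g + translation
    post = fixed.mean(axis=0) - moved.mean(axis=0)
    return RegistrationResult(
        translation=translation,
        moved_channel=move,
        pre_mismatch=float(np.linalg.norm(pre)),
        post_mismatch=float(np.linalg.norm(post)),
    )


@dataclass
class KshrecResult:
    deltas: np.ndarray  # per-kinetochore 3D distances, nm
    pairs: list  # (green index, red index)
    unpaired_green: list = field(default_factory=list)
    unpaired_red: list = field(default_factory=list)
    registration: RegistrationResult | None = None


def kshrec_delta(
    green_spots,
    red_spots,
    registration: RegistrationResult | None = None,
    max_pair_distance: float = 500.0,
) -> KshrecResult:
    """Per-kinetochore delta: 3D distance between matched red and green centroids.

    Spots are paired by mutual nearest neighbour within
    ``max_pair_distance`` nm; unmatched spots are reported and excluded.  If a
    registration is supplied it is applied first.
    """
    green_spots = list(green_spots)
    red_spots = list(red_spots)
    if registration is not None:
        green_spots = registration.apply(green_spots)
        red_spots = registration.apply(red_spots)
    g = np.array([s.centroid for s in green_spots], float)
    r = np.array([s.centroid for s in red_spots], float)
    if len(g) == 0 or len(r) == 0:
        raise ValueError("both channels need at least one spot")
    tree_r = cKDTree(r)
    tree_g = cKDTree(g)
    d_gr, nn_gr = tree_r.query(g)  # for each green, nearest red
    _, nn_rg = tree_g.query(r)  # for each red, nearest green
    pairs = []
    deltas = []
    used_r = set()
    for gi, (ri, dist) in enumerate(zip(nn_gr, d_gr)):
        if nn_rg[ri] == gi and dist <= max_pair_distance:
            pairs.append((gi, int(ri)))
            deltas.append(dist)
            used_r.add(int(ri))
    unpaired_g = [i for i in range(len(g)) if i not in {p[0] for p in pairs}]
    unpaired_r = [i for i in range(len(r)) if i not in used_r]
    return KshrecResult(
        np.asarray(deltas), pairs, unpaired_g, unpaired_r, registration
    )


def projected_delta(
    green_spot: SpotFitResult, red_spot: SpotFitResult, axis
) -> float:
    """1D delta: red-green centroid difference projected on a given axis.

    Provided for swivel-bias experiments: unlike the 3D Euclidean delta, the
    projected value shrinks by cos(swivel) when a kinetochore rotates away
    from the measurement axis.
    """
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    return float(abs((red_spot.centroid - green_spot.centroid) @ a))


def spots_table(spots, registration=None):
    """CSV-friendly per-spot table (ids, centroids, FWHM, residual)."""
    import pandas as pd

    rows = []
    for s in spots:
        rows.append(
            {
                "label": s.label,
                "channel": s.channel,
                "x_nm": s.centroid[0],
                "y_nm": s.centroid[1],
                "z_nm": s.centroid[2],
                "fwhm_xy_nm": s.fwhm_xy,
                "residual": s.residual,
                "fittable": s.fittable,
            }
        )
    df = pd.DataFrame(rows)
    if registration is not None:
        for ax, v in zip("xyz", registration.translation):
            df[f"registration_shift_{ax}_nm"] = v
    return df
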