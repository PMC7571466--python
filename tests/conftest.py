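import numpy as np
import pytest

from kinetosim import linescan, optics, scene


@pytest.fixture(scope="session")
def psf():
    """Bead-calibrated default PSF: 155 nm green / 172 nm red lateral FWHM."""
    return optics.psf_from_fwhm()


@pytest.fixture(scope="session")
def im_pair(psf):
    """One rendered antiparallel IM sister pair (1000 nm plates, 100 nm separation).

    Returns (cloud, volume, base_line) where base_line is the orthogonal scan
    through the pair centre.
    """
    spec = scene.im_sister_pair()
    cloud = scene.build_sister_pair(spec, seed=20_001)
    volume = optics.render(cloud, psf, seed=20_002)
    base_line = linescan.pair_scan_line(cloud.ground_truth, psf)
    return cloud, volume, base_line


def grid_search_circle(points, center0, radius0, span=30.0, levels=3, n=21):
    """Geometric least-squares circle via coarse-to-fine grid search over the centre.

    For each candidate centre the optimal radius is the mean distance to the
    points; used as an independent oracle for the Pratt algebraic fit.
    """
    pts = np.asarray(points, float)
    cx, cy = float(center0[0]), float(center0[1])
    best = None
    for level in range(levels):
        s = span / (n ** level)
        xs = cx + np.linspace(-s, s, n)
        ys = cy + np.linspace(-s, s, n)
        for x in xs:
            for y in ys:
                d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
                r = d.mean()
                sse = float(np.sum((d - r) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, x, y, r)
        _, cx, cy, _ = best
    return best[1], best[2], best[3]
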