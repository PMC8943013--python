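import numpy as np
import pytest

from mevae import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def uniform_cells():
    """Noise-free uniform-stain ellipses with polarized hotspots."""
    spec = PopulationSpec(n_cells=10, staining_pattern="uniform",
                          hotspot_fraction=0.3, noise_sd=0.0)
    return generate_population(spec, seed=42)


@pytest.fixture(scope="session")
def disc_image():
    """A centered disc (radius 14 on a 33x33 canvas) with a linear radial
    gradient I(r) = 0.1 + 0.01 r."""
    size = 33
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    dist = np.hypot(rows - c, cols - c)
    mask = dist <= 14
    img = np.where(mask, 0.1 + 0.01 * dist, 0.0)
    return img, mask


def polar_resample_oracle(image, mask, radius):
    """Independent polar resampler: samples the input along rays at 1-degree
    by 1-pixel resolution with plain bilinear interpolation; used as the
    oracle for circle registration ring means."""
    from scipy import ndimage

    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    thetas = np.deg2rad(np.arange(360))
    # boundary radius per ray: fine march at 0.05 px
    out = np.zeros((360, radius + 1))
    for ti, th in enumerate(thetas):
        rr = np.arange(0, max(mask.shape), 0.05)
        cc = cx + rr * np.cos(th)
        rw = cy - rr * np.sin(th)
        vals = ndimage.map_coordinates(mask.astype(float), [rw, cc], order=1, prefilter=False)
        inside = np.nonzero(vals >= 0.5)[0]
        r_b = rr[inside[-1]] if inside.size else 0.0
        r_out = np.arange(radius + 1)
        r_in = r_out * r_b / radius
        cc = cx + r_in * np.cos(th)
        rw = cy - r_in * np.sin(th)
        out[ti] = ndimage.map_coordinates(image, [rw, cc], order=1, prefilter=False)
    return out  # (angle, radius) intensity table
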