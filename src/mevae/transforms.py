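"""Nuisance canonicalization and randomization of single-cell images.

Three nuisance kinds are handled, each with a canonicalizer and a matching
randomizer (mutually inverse up to interpolation):

* ``rotation`` — the mask's major axis is rotated to horizontal (moment
  eigenvector), with the residual 180-degree ambiguity resolved toward the
  intensity center of mass when it is informative;
* ``polarity`` — the angle from the mask centroid to the intensity center
  of mass is rotated to the canonical 0 degrees (+x);
* ``size_shape`` — the cell is resampled onto a centered disc of fixed
  radius by per-angle ray remapping (circle registration), and randomized
  by the inverse warp onto a random ellipse.

Coordinate convention used throughout: images are row-major with origin at
the top-left; geometry is expressed in a y-up mathematical frame (+x right,
+y up, angles counter-clockwise from +x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, InvalidInputError
from .synthetic import CellRecord, NuisanceParams

TRANSFORM_KINDS = ("rotation", "polarity", "size_shape")


# ---------------------------------------------------------------------------
# basic geometry helpers
# ---------------------------------------------------------------------------

def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid of a binary mask as (col, row)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise InvalidInputError("empty mask")
    return float(cols.mean()), float(rows.mean())


def intensity_center_of_mass(image: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted center of mass (col, row) over masked pixels."""
    img = image[..., 0] if image.ndim == 3 else image
    w = np.where(mask, img, 0.0).astype(float)
    total = w.sum()
    if total <= 0:
        raise InvalidInputError("image has no intensity inside the mask")
    rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    return float((w * cols).sum() / total), float((w * rows).sum() / total)


def _angle_deg(dx: float, dy_down: float) -> float:
    """Angle CCW from +x (y-up frame) of an image-frame displacement."""
    return float(np.degrees(np.arctan2(-dy_down, dx)) % 360.0)


def rotate_about(arr: np.ndarray, angle_deg: float, center: tuple[float, float], order: int = 1) -> np.ndarray:
    """Rotate an image CCW (y-up frame) by angle_deg about center=(col, row).

    Background fill is 0.  order=0 for masks, order=1 (bilinear) otherwise.
    Multi-channel arrays are rotated per channel.
    """
    if arr.ndim == 3:
        return np.stack([rotate_about(arr[..., c], angle_deg, center, order) for c in range(arr.shape[2])], axis=-1)
    cx, cy = center
    th = np.deg2rad(angle_deg)
    rows, cols = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1]]
    x = cols - cx
    y = cy - rows  # y-up
    # active CCW rotation: output at p samples the input at R(-angle) p
    xs = x * np.cos(th) + y * np.sin(th)
    ys = -x * np.sin(th) + y * np.cos(th)
    in_cols = cx + xs
    in_rows = cy - ys
    out = ndimage.map_coordinates(arr.astype(float), [in_rows, in_cols], order=order, cval=0.0, prefilter=False)
    return out


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def stretch_normalize(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    p_low: float | None = None,
    p_high: float | None = None,
) -> np.ndarray:
    """Histogram stretching to the [low_pct, high_pct] percentiles.

    Percentiles are computed over masked pixels only (linear-interpolation
    quantile); pass p_low/p_high to apply precomputed dataset-level
    percentiles instead.  Output is clipped to [0, 1]; background stays 0.
    A constant image (degenerate range) maps to all zeros with a warning.
    """
    if low_pct >= high_pct:
        raise ConfigurationError("low_pct must be < high_pct")
    img = image.astype(float)
    m = np.ones(img.shape[:2], bool) if mask is None else mask.astype(bool)
    vals = img[m] if img.ndim == 2 else img[m].ravel()
    if p_low is None or p_high is None:
        p_low, p_high = np.percentile(vals, [low_pct, high_pct])
    if p_high - p_low <= 1e-12:
        warnings.warn("degenerate intensity range; returning all zeros", RuntimeWarning)
        return np.zeros_like(img)
    out = np.clip((img - p_low) / (p_high - p_low), 0.0, 1.0)
    bg = ~m
    out[bg] = 0.0
    return out


def dataset_percentiles(records: list[CellRecord], low_pct: float = 1.0, high_pct: float = 99.0):
    """Percentiles over all masked pixels of a dataset (scope=dataset)."""
    vals = np.concatenate([r.image[r.mask.astype(bool)].ravel() for r in records])
    lo, hi = np.percentile(vals, [low_pct, high_pct])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# canonicalizers
# ---------------------------------------------------------------------------

@dataclass
class RotationAlignment:
    image: np.ndarray
    mask: np.ndarray
    angle_applied: float  # in [0, 180): rotation applied, mod 180
    flipped: bool  # True if the 180-degree ambiguity was resolved by intensity
    unstable: bool  # near-circular mask, major axis ill-defined


def mask_orientation(mask: np.ndarray) -> tuple[float, float]:
    """Major-axis orientation (deg, in (-90, 90]) and eigenvalue ratio."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise InvalidInputError("empty mask")
    x = cols - cols.mean()
    y = -(rows - rows.mean())  # y-up
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    orientation = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    ratio = lam1 / max(lam2, 1e-12)
    return float(orientation), float(ratio)


def align_rotation(image: np.ndarray, mask: np.ndarray, resolve_flip: bool = True) -> RotationAlignment:
    """Rotate so the mask's major axis (moment eigenvector) is horizontal.

    The reported angle_applied lives in [0, 180) — the major axis only
    defines an orientation mod 180.  With resolve_flip, the remaining
    two-fold ambiguity is resolved by rotating a further 180 degrees when
    the intensity center of mass falls in the -x half, which makes
    randomize-then-canonicalize an identity for polarized cells.
    """
    orientation, ratio = mask_orientation(mask)
    unstable = ratio < 1.05
    center = mask_centroid(mask)
    out_img = rotate_about(image, -orientation, center, order=1)
    out_mask = rotate_about(mask.astype(float), -orientation, center, order=0) > 0.5
    flipped = False
    if resolve_flip:
        try:
            comx, comy = intensity_center_of_mass(out_img, out_mask)
        except InvalidInputError:
            comx = center[0]
        cx, _ = mask_centroid(out_mask)
        if comx < cx - 0.25:
            out_img = rotate_about(out_img, 180.0, center, order=1)
            out_mask = rotate_about(out_mask.astype(float), 180.0, center, order=0) > 0.5
            flipped = True
    out_img = np.where(out_mask[..., None] if out_img.ndim == 3 else out_mask, out_img, 0.0)
    angle = float((-orientation) % 180.0)
    return RotationAlignment(out_img, out_mask, angle, flipped, unstable)


@dataclass
class PolarityAlignment:
    image: np.ndarray
    mask: np.ndarray
    rotation_applied: float  # degrees CCW applied to the image
    degenerate: bool  # center of mass coincides with the centroid


def align_polarity(image: np.ndarray, mask: np.ndarray) -> PolarityAlignment:
    """Rotate so the centroid-to-center-of-mass angle becomes 0 (+x)."""
    cx, cy = mask_centroid(mask)
    comx, comy = intensity_center_of_mass(image, mask)
    if np.hypot(comx - cx, comy - cy) < 0.5:
        return PolarityAlignment(image.copy(), mask.copy(), 0.0, True)
    psi = _angle_deg(comx - cx, comy - cy)
    out_img = rotate_about(image, -psi, (cx, cy), order=1)
    out_mask = rotate_about(mask.astype(float), -psi, (cx, cy), order=0) > 0.5
    out_img = np.where(out_mask[..., None] if out_img.ndim == 3 else out_mask, out_img, 0.0)
    return PolarityAlignment(out_img, out_mask, float((-psi) % 360.0), False)


# ---------------------------------------------------------------------------
# circle registration (size/shape canonicalization)
# ---------------------------------------------------------------------------

def boundary_radius_profile(mask: np.ndarray, center: tuple[float, float], n_theta: int = 720, step: float = 0.25) -> np.ndarray:
    """R(theta): distance from center to the outermost mask boundary along
    each of n_theta evenly spaced angles (CCW from +x, y-up)."""
    cx, cy = center
    h, w = mask.shape
    r_max = float(np.hypot(h, w))
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rs = np.arange(0.0, r_max + step, step)
    cols = cx + np.outer(np.cos(thetas), rs)
    rows = cy - np.outer(np.sin(thetas), rs)
    m = mask.astype(float)
    vals = ndimage.map_coordinates(m, [rows.ravel(), cols.ravel()], order=1, cval=0.0, prefilter=False)
    vals = vals.reshape(len(thetas), len(rs))
    inside = vals >= 0.5
    # outermost crossing: last radius index still inside the mask
    any_inside = inside.any(axis=1)
    last_idx = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
    profile = np.where(any_inside, rs[last_idx], 0.0)
    # sub-pixel refinement: linear 0.5-crossing of the interpolated mask
    # between the last inside sample and the next one out
    nxt = np.minimum(last_idx + 1, len(rs) - 1)
    v_in = vals[np.arange(len(thetas)), last_idx]
    v_out = vals[np.arange(len(thetas)), nxt]
    drop = v_in - v_out
    frac = np.where(drop > 1e-9, np.clip((v_in - 0.5) / np.maximum(drop, 1e-9), 0.0, 1.0), 0.0)
    profile = np.where(any_inside, profile + frac * step, 0.0)
    return profile


def _interp_profile(profile: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Periodic linear interpolation of an angular profile at theta (rad)."""
    n = len(profile)
    pos = (theta % (2 * np.pi)) / (2 * np.pi) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    frac = pos - np.floor(pos)
    return profile[i0] * (1 - frac) + profile[i1] * frac


def _masked_bilinear(image: np.ndarray, mask: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sampling that renormalizes by in-mask support, so values near
    the mask boundary are not diluted toward the zero background."""
    m = mask.astype(float)
    den = ndimage.map_coordinates(m, [rows, cols], order=1, cval=0.0, prefilter=False)
    if image.ndim == 3:
        out = np.stack(
            [
                ndimage.map_coordinates(image[..., c] * m, [rows, cols], order=1, cval=0.0, prefilter=False)
                for c in range(image.shape[2])
            ],
            axis=-1,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den[..., None] > 1e-6, out / np.maximum(den, 1e-6)[..., None], 0.0)
        return out
    num = ndimage.map_coordinates(image * m, [rows, cols], order=1, cval=0.0, prefilter=False)
    return np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)


def register_to_circle(image: np.ndarray, mask: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Warp the cell onto a centered disc of the given radius.

    The output pixel at polar coordinate (theta, r_out) samples the input at
    (theta, r_out * R_mask(theta) / radius), where R_mask(theta) is the
    mask's outermost boundary radius along theta from its centroid.  The
    canvas keeps the input's spatial shape; rays with R_mask(theta)=0 fill 0.
    Returns (image, disc mask).
    """
    center = mask_centroid(mask)
    h, w = mask.shape
    profile = boundary_radius_profile(mask, center)
    out_cx, out_cy = (w - 1) / 2.0, (h - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dx = cols - out_cx
    dy = out_cy - rows
    r_out = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    r_mask = _interp_profile(profile, theta)
    disc = r_out <= radius
    with np.errstate(invalid="ignore"):
        r_in = np.where(disc, r_out * r_mask / radius, 0.0)
    in_cols = center[0] + r_in * np.cos(theta)
    in_rows = center[1] - r_in * np.sin(theta)
    sampled = _masked_bilinear(image, mask, in_rows.ravel(), in_cols.ravel())
    if image.ndim == 3:
        out = sampled.reshape(h, w, image.shape[2]) * disc[..., None]
    else:
        out = sampled.reshape(h, w) * disc
    return out, disc


def warp_disc_to_mask(image: np.ndarray, radius: int, target_mask: np.ndarray) -> np.ndarray:
    """Inverse circle registration: map a disc-supported image onto an
    arbitrary (star-convex) target mask by the inverse ray remapping."""
    h, w = target_mask.shape
    center = mask_centroid(target_mask)
    profile = boundary_radius_profile(target_mask, center)
    src_cx, src_cy = (image.shape[1] - 1) / 2.0, (image.shape[0] - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dx = cols - center[0]
    dy = center[1] - rows
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    r_mask = np.maximum(_interp_profile(profile, theta), 1e-6)
    r_src = r * radius / r_mask
    in_cols = src_cx + r_src * np.cos(theta)
    in_rows = src_cy - r_src * np.sin(theta)
    disc = (np.hypot(np.mgrid[0 : image.shape[0]][:, None] - src_cy, np.mgrid[0 : image.shape[1]][None, :] - src_cx) <= radius)
    sampled = _masked_bilinear(image, disc, in_rows.ravel(), in_cols.ravel())
    tm = target_mask.astype(bool)
    if image.ndim == 3:
        return sampled.reshape(h, w, image.shape[2]) * tm[..., None]
    return sampled.reshape(h, w) * tm


# ---------------------------------------------------------------------------
# randomizers and paired datasets
# ---------------------------------------------------------------------------

def default_radius(shape: tuple[int, ...]) -> int:
    return min(shape[0], shape[1]) // 2 - 2


def _random_ellipse_mask(shape: tuple[int, int], rng: np.random.Generator):
    h, w = shape
    cap = min(h, w) / 2 - 1.5
    a = rng.uniform(0.6, 1.0) * cap
    b = rng.uniform(0.55, 0.9) * a
    orient = rng.uniform(0.0, 180.0)
    c = (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - c
    y = (h - 1) / 2.0 - rows
    th = np.deg2rad(orient)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, (float(a), float(b), float(orient))


def random_transform(image: np.ndarray, mask: np.ndarray, kind: str, rng: np.random.Generator | int):
    """Re-apply one random instance of a nuisance to a canonical image.

    Returns (image, mask, param).  rotation: uniform angle on [0, 360);
    polarity: a random flip (none/h/v/both) plus a uniform rotation;
    size_shape: inverse circle registration onto a random ellipse (the input
    must be disc-registered).  Deterministic given an integer seed.
    """
    if kind not in TRANSFORM_KINDS:
        raise ConfigurationError(f"unknown transform kind {kind!r}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if kind == "rotation":
        angle = float(rng.uniform(0.0, 360.0))
        center = mask_centroid(mask)
        img = rotate_about(image, angle, center, order=1)
        m = rotate_about(mask.astype(float), angle, center, order=0) > 0.5
        img = img * (m[..., None] if img.ndim == 3 else m)
        return img, m, {"angle": angle}
    if kind == "polarity":
        flip = ["none", "h", "v", "hv"][int(rng.integers(4))]
        angle = float(rng.uniform(0.0, 360.0))
        img, m = image, mask.astype(bool)
        if "h" in flip and flip != "none":
            img, m = img[:, ::-1].copy(), m[:, ::-1].copy()
        if "v" in flip:
            img, m = img[::-1].copy(), m[::-1].copy()
        center = mask_centroid(m)
        out = rotate_about(img, angle, center, order=1)
        m2 = rotate_about(m.astype(float), angle, center, order=0) > 0.5
        out = out * (m2[..., None] if out.ndim == 3 else m2)
        return out, m2, {"flip": flip, "angle": angle}
    # size_shape
    radius = default_radius(mask.shape)
    new_mask, (a, b, orient) = _random_ellipse_mask(mask.shape, rng)
    img = warp_disc_to_mask(image, radius, new_mask)
    return img, new_mask, {"a": a, "b": b, "orientation": orient}


@dataclass
class PairedSample:
    """Self-supervision pair: per-encoder transformed inputs + canonical target."""

    cell_id: str
    label: str
    target: np.ndarray
    target_mask: np.ndarray
    inputs: list[np.ndarray]
    input_masks: list[np.ndarray]
    params: list[dict]
    corrections: tuple[str, ...]
    truth: NuisanceParams | None = None
    condition: np.ndarray | None = None
    target_is_canonical: bool = True


def canonicalize_record(record: CellRecord, corrections: tuple[str, ...], radius: int | None = None) -> CellRecord:
    """Apply the enabled canonicalizations in the fixed order
    rotation -> polarity -> circle registration."""
    for c in corrections:
        if c not in TRANSFORM_KINDS:
            raise ConfigurationError(f"unknown correction {c!r}")
    img, mask = record.image, record.mask.astype(bool)
    if "rotation" in corrections:
        res = align_rotation(img, mask)
        img, mask = res.image, res.mask
    if "polarity" in corrections:
        res = align_polarity(img, mask)
        img, mask = res.image, res.mask
    if "size_shape" in corrections:
        radius = radius or default_radius(mask.shape)
        img, mask = register_to_circle(img, mask, radius)
    return CellRecord(image=img, mask=mask, cell_id=record.cell_id, label=record.label, truth=record.truth)


def make_paired_dataset(
    records: list[CellRecord],
    corrections: tuple[str, ...],
    seed: int,
    radius: int | None = None,
) -> list[PairedSample]:
    """Build the self-supervised pairs driving the corrected architectures.

    Each sample's target is the canonicalized image (circle-registered when
    size_shape is enabled); inputs[i] re-applies a random instance of
    corrections[i] to the target.  One correction -> the output-corrected
    single-encoder pairing.
    """
    if not records:
        raise InvalidInputError("records must be nonempty")
    corrections = tuple(corrections)
    if not corrections:
        raise ConfigurationError("corrections set must be nonempty")
    rng = np.random.default_rng(seed)
    samples = []
    for rec in records:
        canon = canonicalize_record(rec, corrections, radius=radius)
        inputs, masks, params = [], [], []
        for kind in corrections:
            img, m, p = random_transform(canon.image, canon.mask, kind, rng)
            inputs.append(img)
            masks.append(m)
            params.append({"kind": kind, **p})
        samples.append(
            PairedSample(
                cell_id=rec.cell_id,
                label=rec.label,
                target=canon.image,
                target_mask=canon.mask,
                inputs=inputs,
                input_masks=masks,
                params=params,
                corrections=corrections,
                truth=rec.truth,
            )
        )
    return samples


def make_identity_dataset(records: list[CellRecord]) -> list[PairedSample]:
    """Matched raw-image pairs (input = target) for the baseline variants."""
    if not records:
        raise InvalidInputError("records must be nonempty")
    return [
        PairedSample(
            cell_id=r.cell_id,
            label=r.label,
            target=r.image,
            target_mask=r.mask.astype(bool),
            inputs=[r.image],
            input_masks=[r.mask.astype(bool)],
            params=[{"kind": "identity"}],
            corrections=(),
            truth=r.truth,
            target_is_canonical=False,
        )
        for r in records
    ]


def nuisance_condition_matrix(records: list[CellRecord]) -> np.ndarray:
    """Quantified nuisance vector c per cell for the invariant C-VAE:
    (sin, cos) of rotation and polarity plus z-scored area (5 columns)."""
    rot = np.array([r.truth.rotation_deg for r in records])
    pol = np.array([r.truth.polarity_deg for r in records])
    area = np.array([r.truth.area_px for r in records], float)
    area = (area - area.mean()) / max(area.std(), 1e-9)
    return np.column_stack(
        [np.sin(np.deg2rad(rot)), np.cos(np.deg2rad(rot)), np.sin(np.deg2rad(pol)), np.cos(np.deg2rad(pol)), area]
    )
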