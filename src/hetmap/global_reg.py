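"""Global motion model: masked affine registration followed by
diffeomorphic demons, plus the warping and field-composition primitives
used pipeline-wide.

Both stages operate on binary tissue masks treated as real-valued 0/1
images.  The affine stage minimizes mean squared error with a regular-step
gradient descent over a 3-level Gaussian pyramid; the demons stage iterates
the classical per-pixel attraction force, composes each exponentiated
update diffeomorphically into the accumulated displacement field, and
Gaussian-smooths the field after every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize

from .core import AffineMap, BinaryMask, DisplacementField


# ---------------------------------------------------------------------------
# warping primitives

def warp(image, field: DisplacementField, fill: float = 0.0):
    """Resample an image (2-D, RGB, or BinaryMask) through a backward field.

    Bilinear sampling at ``p + d(p)``; out-of-bounds positions take the
    fill value.  Masks are warped as 0/1 reals and re-thresholded at 0.5.
    """
    if isinstance(image, BinaryMask):
        out = warp(image.values.astype(float), field, fill=0.0)
        return BinaryMask(out > 0.5, image.pixel_size_um)
    arr = np.asarray(image, dtype=float)
    if arr.shape[:2] != field.shape:
        raise ValueError("field shape does not match image shape")
    rows, cols = field.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    sx = xx + field.u
    sy = yy + field.v
    coords = np.stack([sy.ravel(), sx.ravel()])
    if arr.ndim == 2:
        out = map_coordinates(arr, coords, order=1, mode="constant", cval=fill)
        return out.reshape(rows, cols)
    chans = [map_coordinates(arr[:, :, c], coords, order=1, mode="constant",
                             cval=fill).reshape(rows, cols)
             for c in range(arr.shape[2])]
    return np.stack(chans, axis=-1)


def warp_affine(image, affine: AffineMap, fill: float = 0.0, order: int = 1):
    """Resample through an affine backward map (sample input at A p + t)."""
    from scipy.ndimage import affine_transform

    if isinstance(image, BinaryMask):
        out = warp_affine(image.values.astype(float), affine, fill=0.0, order=order)
        return BinaryMask(out > 0.5, image.pixel_size_um)
    arr = np.asarray(image, dtype=float)
    m = affine.matrix[::-1, ::-1]  # (x, y) map expressed in (row, col)
    off = affine.offset[::-1]
    if arr.ndim == 2:
        return affine_transform(arr, m, offset=off, order=order,
                                mode="constant", cval=fill)
    chans = [affine_transform(arr[:, :, c], m, offset=off, order=order,
                              mode="constant", cval=fill)
             for c in range(arr.shape[2])]
    return np.stack(chans, axis=-1)


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Field of the composition p -> B_outer(B_inner(p)) of two backward
    maps B(p) = p + d(p): d(p) = d_in(p) + d_out(p + d_in(p))."""
    rows, cols = inner.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    qx = xx + inner.u
    qy = yy + inner.v
    coords = np.stack([qy.ravel(), qx.ravel()])
    du = map_coordinates(outer.u, coords, order=1, mode="nearest").reshape(rows, cols)
    dv = map_coordinates(outer.v, coords, order=1, mode="nearest").reshape(rows, cols)
    return DisplacementField(inner.u + du, inner.v + dv)


def exponentiate_field(update: DisplacementField) -> DisplacementField:
    """Scaling-and-squaring exponential of a stationary velocity field.

    Guarantees a diffeomorphic (positive-Jacobian) map for smooth updates
    even when the raw step is large.
    """
    mx = float(update.magnitude().max())
    if mx == 0.0:
        return DisplacementField(update.u.copy(), update.v.copy())
    n = max(0, int(np.ceil(np.log2(max(mx / 0.5, 1e-12)))) + 1)
    e = DisplacementField(update.u / (2 ** n), update.v / (2 ** n))
    for _ in range(n):
        e = compose_fields(e, e)
    return e


def save_field(path, field: DisplacementField) -> None:
    """Persist a displacement field as a 2-plane 32-bit TIFF (u, v)."""
    import tifffile

    tifffile.imwrite(path, np.stack([field.u, field.v]).astype(np.float32))


def load_field(path) -> DisplacementField:
    import tifffile

    planes = tifffile.imread(path)
    return DisplacementField(planes[0].astype(float), planes[1].astype(float))


def save_affine(path, affine: AffineMap) -> None:
    """Affine as JSON; the stored map is the backward sampling convention
    x_source = A x_fixed + t with (x, y) coordinates."""
    import json

    with open(path, "w") as fh:
        json.dump({"matrix": affine.matrix.tolist(),
                   "offset": affine.offset.tolist(),
                   "convention": "backward; x_source = A @ (x, y) + t"},
                  fh, indent=2)


def load_affine(path) -> AffineMap:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return AffineMap(np.array(d["matrix"]), np.array(d["offset"]))


# ---------------------------------------------------------------------------
# affine registration

@dataclass
class AffineOptConfig:
    """Regular-step gradient-descent settings for the affine stage."""

    gradient_magnitude_tolerance: float = 1e-4
    min_step: float = 1e-5
    max_step: float = 6.25e-2
    max_iterations: int = 100
    relaxation_factor: float = 0.8
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        if self.min_step >= self.max_step:
            raise ValueError("min_step must be below max_step")
        if self.pyramid_levels < 1:
            raise ValueError("need at least one pyramid level")


@dataclass
class AffineResult:
    transform: AffineMap
    final_mse: float
    initial_mse: float
    converged: bool


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, finest last."""
    pyr = [img]
    for _ in range(levels - 1):
        sm = gaussian_filter(pyr[0], 1.0)
        pyr.insert(0, sm[::2, ::2])
    return pyr


def _mse_and_gradient(fixed: np.ndarray, moving: np.ndarray, theta: np.ndarray,
                      diag: float, need_grad: bool = True):
    """MSE between fixed and affinely-warped moving plus its gradient in the
    scaled parameter space [a11, a12, a21, a22, tx/diag, ty/diag]."""
    rows, cols = fixed.shape
    a11, a12, a21, a22, txs, tys = theta
    aff = AffineMap(np.array([[a11, a12], [a21, a22]]),
                    np.array([txs * diag, tys * diag]))
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    qx = a11 * xx + a12 * yy + txs * diag
    qy = a21 * xx + a22 * yy + tys * diag
    coords = np.stack([qy.ravel(), qx.ravel()])
    w = map_coordinates(moving, coords, order=1, mode="constant", cval=0.0
                        ).reshape(rows, cols)
    diff = w - fixed
    mse = float(np.mean(diff ** 2))
    if not need_grad:
        return mse, None
    gy, gx = np.gradient(moving)
    mgx = map_coordinates(gx, coords, order=1, mode="constant", cval=0.0
                          ).reshape(rows, cols)
    mgy = map_coordinates(gy, coords, order=1, mode="constant", cval=0.0
                          ).reshape(rows, cols)
    n = diff.size
    s = 2.0 * diff / n
    g = np.array([
        np.sum(s * mgx * xx),
        np.sum(s * mgx * yy),
        np.sum(s * mgy * xx),
        np.sum(s * mgy * yy),
        np.sum(s * mgx) * diag,
        np.sum(s * mgy) * diag,
    ])
    return mse, g


def _regular_step_descent(fixed: np.ndarray, moving: np.ndarray,
                          theta0: np.ndarray, cfg: AffineOptConfig):
    """Regular-step gradient descent with monotone step acceptance.

    The step shrinks by the relaxation factor whenever the descent
    direction reverses or a trial step fails to decrease the MSE, so the
    accepted MSE sequence is nonincreasing.
    """
    diag = float(np.hypot(*fixed.shape))
    theta = theta0.copy()
    mse, grad = _mse_and_gradient(fixed, moving, theta, diag)
    best_theta, best_mse = theta.copy(), mse
    step = cfg.max_step
    prev_dir = None
    converged = False
    for _ in range(cfg.max_iterations):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < cfg.gradient_magnitude_tolerance or step < cfg.min_step:
            converged = True
            break
        direction = grad / gnorm
        if prev_dir is not None and float(direction @ prev_dir) < 0:
            step *= cfg.relaxation_factor
        trial = theta - step * direction
        trial_mse, trial_grad = _mse_and_gradient(fixed, moving, trial, diag)
        if trial_mse <= mse:
            theta, mse, grad = trial, trial_mse, trial_grad
            prev_dir = direction
            if mse < best_mse:
                best_theta, best_mse = theta.copy(), mse
        else:
            step *= cfg.relaxation_factor
    return best_theta, best_mse, converged, diag


def register_affine(fixed: BinaryMask, moving: BinaryMask,
                    cfg: AffineOptConfig | None = None) -> AffineResult:
    """Estimate the backward affine map aligning ``moving`` to ``fixed``.

    Masks are treated as 0/1 reals under an MSE metric, optimized coarse to
    fine over a Gaussian pyramid.  The returned transform samples the
    moving mask at ``A p + t`` for fixed-frame coordinates ``p``.
    """
    cfg = cfg or AffineOptConfig()
    if fixed.shape != moving.shape:
        raise ValueError("mask shapes differ")
    if fixed.area == 0 or moving.area == 0:
        raise ValueError("empty mask")
    f = fixed.values.astype(float)
    m = moving.values.astype(float)
    fpyr = _pyramid(f, cfg.pyramid_levels)
    mpyr = _pyramid(m, cfg.pyramid_levels)
    theta = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    converged = True
    for lvl, (fl, ml) in enumerate(zip(fpyr, mpyr)):
        diag = float(np.hypot(*fl.shape))
        theta, mse, conv, _ = _regular_step_descent(fl, ml, theta, cfg)
        converged = converged and conv
        if lvl < len(fpyr) - 1:
            # matrix entries carry over; scaled translations are
            # diagonal-relative and carry over unchanged as well
            pass
    diag = float(np.hypot(*f.shape))
    initial_mse, _ = _mse_and_gradient(f, m, np.array([1.0, 0, 0, 1.0, 0, 0]),
                                       diag, need_grad=False)
    final_mse, _ = _mse_and_gradient(f, m, theta, diag, need_grad=False)
    if final_mse > initial_mse:  # never return a worse-than-identity fit
        theta = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
        final_mse = initial_mse
        converged = False
    aff = AffineMap(np.array([[theta[0], theta[1]], [theta[2], theta[3]]]),
                    np.array([theta[4] * diag, theta[5] * diag]))
    return AffineResult(aff, final_mse, initial_mse, converged)


# ---------------------------------------------------------------------------
# diffeomorphic demons

@dataclass
class DemonsConfig:
    pyramid_levels: int = 3
    iterations_per_level: int = 100
    smoothing_sigma: float = 1.0  # field smoothing after every iteration
    update_sigma: float = 0.0  # fluid-like smoothing of the raw update (off)
    gradient_sigma: float = 0.5  # pre-smoothing that defines image gradients
    max_ssd_increases: int = 10

    def __post_init__(self) -> None:
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing sigma must be positive")


def demons_force(fixed: np.ndarray, moving_warped: np.ndarray) -> DisplacementField:
    """Per-pixel demons attraction v = (Im-If) grad(If) / (|grad If|^2 + (Im-If)^2).

    The gradient is the central difference of the *fixed* image; pixels
    where the denominator underflows get zero force.  |v| <= 0.5 everywhere
    by the AM-GM inequality.  Inside the demons iteration the force enters
    as a descent step on the SSD, i.e. with a negative sign.
    """
    f = np.asarray(fixed, dtype=float)
    m = np.asarray(moving_warped, dtype=float)
    if f.shape != m.shape:
        raise ValueError("shape mismatch")
    gy, gx = np.gradient(f)
    diff = m - f
    denom = gx ** 2 + gy ** 2 + diff ** 2
    safe = denom >= 1e-9
    u = np.where(safe, diff * gx / np.where(safe, denom, 1.0), 0.0)
    v = np.where(safe, diff * gy / np.where(safe, denom, 1.0), 0.0)
    return DisplacementField(u, v)


def _upsample_field(field: DisplacementField, shape: tuple[int, int]) -> DisplacementField:
    ry = shape[0] / field.shape[0]
    rx = shape[1] / field.shape[1]
    u = resize(field.u, shape, order=1, preserve_range=True) * rx
    v = resize(field.v, shape, order=1, preserve_range=True) * ry
    return DisplacementField(u, v)


def register_demons(fixed: BinaryMask, moving: BinaryMask,
                    cfg: DemonsConfig | None = None) -> DisplacementField:
    """Diffeomorphic demons between 0/1 mask images.

    Per pyramid level the loop is: warp the moving image through the
    accumulated backward field, evaluate the demons force, exponentiate the
    (negated) force by scaling and squaring, compose it into the field, and
    Gaussian-smooth the field.  SSD is monitored each iteration; the
    best-so-far field is kept and returned, with an early stop after too
    many consecutive SSD increases.
    """
    cfg = cfg or DemonsConfig()
    if fixed.shape != moving.shape:
        raise ValueError("mask shapes differ")
    f = fixed.values.astype(float)
    m = moving.values.astype(float)
    fpyr = _pyramid(f, cfg.pyramid_levels)
    mpyr = _pyramid(m, cfg.pyramid_levels)
    field = DisplacementField.zero(fpyr[0].shape)
    for lvl, (fl, ml) in enumerate(zip(fpyr, mpyr)):
        fs = gaussian_filter(fl, cfg.gradient_sigma)
        ms = gaussian_filter(ml, cfg.gradient_sigma)
        best = DisplacementField(field.u.copy(), field.v.copy())
        w = warp(ms, field)
        best_ssd = float(np.sum((w - fs) ** 2))
        increases = 0
        for _ in range(cfg.iterations_per_level):
            force = demons_force(fs, w)
            update = DisplacementField(-force.u, -force.v)
            if cfg.update_sigma > 0:
                update = DisplacementField(
                    gaussian_filter(update.u, cfg.update_sigma),
                    gaussian_filter(update.v, cfg.update_sigma))
            step = exponentiate_field(update)
            field = compose_fields(field, step)
            field = DisplacementField(gaussian_filter(field.u, cfg.smoothing_sigma),
                                      gaussian_filter(field.v, cfg.smoothing_sigma))
            w = warp(ms, field)
            ssd = float(np.sum((w - fs) ** 2))
            if ssd < best_ssd:
                best = DisplacementField(field.u.copy(), field.v.copy())
                best_ssd = ssd
                increases = 0
            else:
                increases += 1
                if increases >= cfg.max_ssd_increases:
                    break
        field = best
        if lvl < len(fpyr) - 1:
            field = _upsample_field(field, fpyr[lvl + 1].shape)
    return field
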