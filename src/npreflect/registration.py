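"""Cross-modality and serial-section alignment.

Provides point-pair least-squares estimation (rigid / affine),
preprocessed intensity-based registration (normalised cross-correlation
or mutual information), Coherent Point Drift (CPD) on point sets such as
nuclear centroids, pixel-size equalisation and min/max projections.

Conventions
-----------
All planar transforms act on physical coordinates in nm, ordered
``(y, x)`` to match array axes, and map **moving -> fixed** coordinates:
``p_fixed = matrix @ p_moving + translation``.  Images are resampled by
pulling from the inverse map with linear interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .image import as_array

log = logging.getLogger(__name__)

RIGID = "rigid"
AFFINE = "affine"


class RegistrationError(RuntimeError):
    """Raised on non-convergence; carries the best transform found so far."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


@dataclass
class PlanarTransform:
    """2-D affine map in physical (nm) coordinates: ``p' = M p + t``.

    ``model='rigid'`` requires the linear part to be a pure rotation
    (orthogonal, determinant +1); ``model='affine'`` only requires
    invertibility.
    """

    model: str
    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if self.model not in (RIGID, AFFINE):
            raise ValueError(f"unknown transform model {self.model!r}")
        det = float(np.linalg.det(self.matrix))
        if self.model == RIGID:
            if not np.allclose(self.matrix.T @ self.matrix, np.eye(2), atol=1e-6):
                raise ValueError("rigid transform must have an orthogonal linear part")
            if det < 0:
                raise ValueError("rigid transform must not contain a reflection")
        else:
            if abs(det) < 1e-12:
                raise ValueError("affine transform must be invertible")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, model: str = RIGID) -> "PlanarTransform":
        return cls(model, np.eye(2), np.zeros(2))

    @classmethod
    def rigid_about(
        cls, angle_rad: float, translation_nm=(0.0, 0.0), centre_nm=(0.0, 0.0)
    ) -> "PlanarTransform":
        """Rotation by ``angle_rad`` about ``centre_nm`` plus a translation.

        Angle is measured from +y towards +x in the (y, x) plane.
        """
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        r = np.array([[c, -s], [s, c]])
        centre = np.asarray(centre_nm, dtype=float)
        t = centre - r @ centre + np.asarray(translation_nm, dtype=float)
        return cls(RIGID, r, t)

    # -- algebra ------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def invert(self) -> "PlanarTransform":
        inv = np.linalg.inv(self.matrix)
        return PlanarTransform(self.model, inv, -inv @ self.translation)

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        model = RIGID if self.model == other.model == RIGID else AFFINE
        return PlanarTransform(
            model,
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    @property
    def rotation_angle(self) -> float:
        """Rotation angle in radians (rigid transforms only)."""
        if self.model != RIGID:
            raise ValueError("rotation angle is only defined for rigid transforms")
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "matrix": self.matrix.ravel().tolist(),
            "translation": self.translation.tolist(),
            "units": "nm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanarTransform":
        return cls(d["model"], np.reshape(d["matrix"], (2, 2)), d["translation"])


@dataclass
class PointSet:
    """Planar point set in nm, e.g. nuclear centroids used for CPD."""

    points: np.ndarray
    source: str = "manual"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array of (y, x) nm")

    def __len__(self) -> int:
        return len(self.points)


def _points(obj) -> np.ndarray:
    if isinstance(obj, PointSet):
        return obj.points
    return np.atleast_2d(np.asarray(obj, dtype=float))


# ---------------------------------------------------------------------
# point-pair estimation
# ---------------------------------------------------------------------

def estimate_from_points(fixed, moving, model: str = RIGID) -> PlanarTransform:
    """Least-squares transform mapping corresponding ``moving`` points
    onto ``fixed`` points.

    Rigid uses the orthogonal Procrustes (Kabsch) solution without
    scaling; affine solves the normal equations.  Point order defines
    correspondence.
    """
    x = _points(fixed)
    y = _points(moving)
    if x.shape != y.shape:
        raise ValueError("fixed and moving must contain the same number of points")
    n_min = 2 if model == RIGID else 3
    if len(x) < n_min:
        raise ValueError(f"{model} estimation needs at least {n_min} point pairs")
    mu_x = x.mean(axis=0)
    mu_y = y.mean(axis=0)
    xc = x - mu_x
    yc = y - mu_y
    if model == RIGID:
        h = yc.T @ xc
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, d]) @ u.T
        return PlanarTransform(RIGID, r, mu_x - r @ mu_y)
    if model == AFFINE:
        if np.linalg.matrix_rank(yc, tol=1e-9 * max(1.0, np.abs(yc).max())) < 2:
            raise ValueError("affine estimation needs >= 3 non-collinear points")
        g, *_ = np.linalg.lstsq(yc, xc, rcond=None)
        a = g.T
        return PlanarTransform(AFFINE, a, mu_x - a @ mu_y)
    raise ValueError(f"unknown model {model!r}")


def landmark_error(
    transform: PlanarTransform, fixed, moving
) -> float:
    """Mean Euclidean residual (nm) of ``transform`` on known pairs."""
    x = _points(fixed)
    y = _points(moving)
    return float(np.linalg.norm(transform.apply(y) - x, axis=1).mean())


# ---------------------------------------------------------------------
# intensity-based registration
# ---------------------------------------------------------------------

def _preprocess(img: np.ndarray, smooth_sigma: float, bg_sigma: float) -> np.ndarray:
    sm = ndimage.gaussian_filter(img, smooth_sigma)
    return np.clip(sm - ndimage.gaussian_filter(img, bg_sigma), 0.0, None)


def _warp(moving: np.ndarray, matrix: np.ndarray, translation_px: np.ndarray):
    """Resample ``moving`` into the fixed frame under p_f = M p_m + t (pixels)."""
    inv = np.linalg.inv(matrix)
    out = ndimage.affine_transform(
        moving,
        inv,
        offset=-inv @ translation_px,
        order=1,
        mode="constant",
        cval=np.nan,
    )
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 16:
        return -np.inf
    av = a[valid] - a[valid].mean()
    bv = b[valid] - b[valid].mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return -np.inf
    return float((av * bv).sum() / denom)


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 16:
        return -np.inf
    hist, _, _ = np.histogram2d(a[valid], b[valid], bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


@dataclass
class RegistrationResult:
    transform: PlanarTransform
    metric_value: float
    metric: str
    converged: bool = True
    extra: dict = field(default_factory=dict)


def register_intensity(
    fixed,
    moving,
    pixel_size_nm: float,
    model: str = RIGID,
    preprocess: bool = True,
    metric: str = "auto",
    cross_modality: bool = True,
    smooth_sigma: float = 2.0,
    bg_sigma: float = 12.0,
    max_angle_deg: float = 10.0,
    angle_step_deg: float = 2.0,
    max_iter: int = 400,
) -> RegistrationResult:
    """Automated intensity-based 2-D registration.

    Both images are optionally smoothed and background-subtracted (which
    removes the diffuse cellular reflectance that otherwise dominates the
    similarity metric).  A coarse search runs FFT phase correlation for
    the translation at each candidate rotation, then Powell refinement
    maximises the metric: NCC for same-modality pairs, mutual
    information (32-bin joint histogram) for cross-modality pairs.

    Returns the moving->fixed transform in nm and the final metric value.
    """
    fixed = as_array2d(fixed)
    moving = as_array2d(moving)
    if metric == "auto":
        metric = "mi" if cross_modality else "ncc"
    score = _mutual_information if metric == "mi" else _ncc

    if preprocess:
        fixed_p = _preprocess(fixed, smooth_sigma, bg_sigma)
        moving_p = _preprocess(moving, smooth_sigma, bg_sigma)
    else:
        fixed_p, moving_p = fixed, moving

    centre = (np.array(fixed_p.shape, dtype=float) - 1) / 2.0

    def build(angle_rad: float, shift_px) -> tuple[np.ndarray, np.ndarray]:
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        m = np.array([[c, -s], [s, c]])
        t = centre - m @ centre + np.asarray(shift_px, dtype=float)
        return m, t

    # coarse: rotation sweep + phase-correlation translation
    best = (-np.inf, 0.0, np.zeros(2))
    angles = np.deg2rad(
        np.arange(-max_angle_deg, max_angle_deg + 1e-9, angle_step_deg)
    )
    for ang in angles:
        m, t = build(ang, (0.0, 0.0))
        rotated = _warp(moving_p, m, t)
        rot_filled = np.nan_to_num(rotated)
        shift, _, _ = phase_cross_correlation(
            fixed_p, rot_filled, normalization=None
        )
        m2, t2 = build(ang, shift)
        val = score(fixed_p, _warp(moving_p, m2, t2))
        if val > best[0]:
            best = (val, ang, np.asarray(shift, dtype=float))

    # local refinement
    def cost_rigid(p):
        m, t = build(p[0], p[1:3])
        return -score(fixed_p, _warp(moving_p, m, t))

    x0 = np.array([best[1], best[2][0], best[2][1]])
    res = optimize.minimize(
        cost_rigid, x0, method="Powell", options={"maxiter": max_iter, "xtol": 1e-3}
    )
    m, t = build(res.x[0], res.x[1:3])
    converged = bool(res.success)

    if model == AFFINE:
        def cost_affine(p):
            mat = p[:4].reshape(2, 2)
            return -score(fixed_p, _warp(moving_p, mat, p[4:6]))

        p0 = np.concatenate([m.ravel(), t])
        res_a = optimize.minimize(
            cost_affine, p0, method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-3},
        )
        m = res_a.x[:4].reshape(2, 2)
        t = res_a.x[4:6]
        res = res_a
        converged = bool(res_a.success)

    transform = PlanarTransform(
        model if model == AFFINE else RIGID,
        m,
        np.asarray(t, dtype=float) * pixel_size_nm,
    )
    result = RegistrationResult(
        transform=transform,
        metric_value=float(-res.fun),
        metric=metric,
        converged=converged,
        extra={"n_evaluations": int(res.nfev)},
    )
    if not converged:
        raise RegistrationError(
            "intensity registration did not converge within the iteration cap",
            result=result,
        )
    return result


def as_array2d(image) -> np.ndarray:
    arr = as_array(image) if not isinstance(image, np.ndarray) else np.asarray(
        image, dtype=float
    )
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    return arr


# ---------------------------------------------------------------------
# Coherent Point Drift
# ---------------------------------------------------------------------

@dataclass
class CPDResult:
    transform: PlanarTransform
    probabilities: np.ndarray  # (N_fixed, M_moving) soft assignments
    sigma2: float
    n_iter: int
    converged: bool


def cpd_register(
    fixed,
    moving,
    model: str = RIGID,
    w: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CPDResult:
    """Coherent Point Drift registration of two unordered point sets.

    The moving set is treated as the centroids of an isotropic Gaussian
    mixture fitted to the fixed set by EM, with a uniform outlier
    component of weight ``w``.  The M-step solves the closed-form rigid
    (rotation + translation) or affine update and re-estimates the
    mixture variance; iteration stops when the variance changes by less
    than ``tol`` or after ``max_iter`` iterations.  Deterministic: the
    transform starts at identity and the variance at the mean pairwise
    squared distance.
    """
    x = _points(fixed)
    y = _points(moving)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both point sets must be nonempty")
    if not 0.0 <= w < 1.0:
        raise ValueError("outlier weight w must satisfy 0 <= w < 1")
    n, m, d = len(x), len(y), 2

    transform = PlanarTransform.identity(RIGID)
    diff0 = x[:, None, :] - y[None, :, :]
    sigma2 = float((diff0**2).sum() / (d * n * m))
    if model == AFFINE:
        # warm-start from the rigid solution: an affine M-step taken
        # from identity with a wide mixture variance can collapse the
        # linear part towards zero on structured (e.g. ring-like) sets
        rigid_stage = cpd_register(x, y, RIGID, w=w, tol=tol, max_iter=max_iter)
        transform = rigid_stage.transform
        ty0 = transform.apply(y)
        sigma2 = max(
            float(((x[:, None, :] - ty0[None, :, :]) ** 2).sum() / (d * n * m)),
            rigid_stage.sigma2,
        )
    p = np.zeros((n, m))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ty = transform.apply(y)
        d2 = ((x[:, None, :] - ty[None, :, :]) ** 2).sum(axis=2)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = (2.0 * np.pi * sigma2) ** (d / 2.0) * (w / (1.0 - w)) * (m / n)
        den = num.sum(axis=1, keepdims=True) + c
        den[den == 0] = np.finfo(float).tiny
        p = num / den

        n_p = p.sum()
        if n_p <= 0:
            break
        mu_x = (p.sum(axis=1) @ x) / n_p
        mu_y = (p.sum(axis=0) @ y) / n_p
        xc = x - mu_x
        yc = y - mu_y
        a = xc.T @ p @ yc
        if model == RIGID:
            u, _, vt = np.linalg.svd(a)
            corr = np.diag([1.0, np.sign(np.linalg.det(u @ vt))])
            r = u @ corr @ vt
            transform = PlanarTransform(RIGID, r, mu_x - r @ mu_y)
        else:
            yy = yc.T @ np.diag(p.sum(axis=0)) @ yc
            try:
                mat = a @ np.linalg.inv(yy)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "affine CPD needs at least 3 non-collinear moving points"
                ) from exc
            transform = PlanarTransform(AFFINE, mat, mu_x - mat @ mu_y)

        ty = transform.apply(y)
        d2 = ((x[:, None, :] - ty[None, :, :]) ** 2).sum(axis=2)
        sigma2_new = float((p * d2).sum() / (n_p * d))
        sigma2_new = max(sigma2_new, 1e-12)
        if abs(sigma2 - sigma2_new) < tol:
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new

    if not converged:
        warnings.warn(
            f"CPD reached max_iter={max_iter} without variance convergence",
            RuntimeWarning,
        )
    return CPDResult(
        transform=transform,
        probabilities=p,
        sigma2=sigma2,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------
# resampling and projections
# ---------------------------------------------------------------------

def equalize_pixel_size(
    a: np.ndarray,
    pixel_a_nm: float,
    b: np.ndarray,
    pixel_b_nm: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Resample the coarser 2-D image onto the finer pixel grid.

    Linear interpolation; physical extents are preserved (pixels are
    treated as cells, so n_coarse * pitch_coarse = n_fine * pitch_fine
    up to rounding).  Returns ``(a_out, b_out, pixel_nm)``.
    """
    if pixel_a_nm <= 0 or pixel_b_nm <= 0:
        raise ValueError("pixel sizes must be known and positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if pixel_a_nm == pixel_b_nm:
        return a, b, float(pixel_a_nm)
    fine = min(pixel_a_nm, pixel_b_nm)

    def resample(img, pitch):
        if pitch == fine:
            return img
        return ndimage.zoom(img, pitch / fine, order=1, grid_mode=True,
                            mode="nearest")

    return resample(a, pixel_a_nm), resample(b, pixel_b_nm), float(fine)


def min_projection(sections: list) -> np.ndarray:
    """Voxel-wise minimum across pre-aligned sections (dark NPs survive)."""
    if not sections:
        raise ValueError("min_projection needs at least one section")
    arrs = [np.asarray(s, dtype=float) for s in sections]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("sections must share a shape")
    return np.minimum.reduce(arrs)


def max_projection(stack) -> np.ndarray:
    """Maximum-intensity projection along z (bright NPs survive)."""
    arr = as_array(stack)
    if arr.ndim != 3:
        raise ValueError("max_projection expects a 3-D stack")
    return arr.max(axis=0)
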