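"""Director fields on regular grids: data model, image extraction, Q tensor,
distortion maps and π-periodic sampling.

Coordinate convention (used throughout the package): grids are row-major
arrays indexed ``[row, col]``; physical coordinates are ``x = col * pixel_size``
and ``y = row * pixel_size`` with *y* increasing downward (image convention).
All angles are measured counter-clockwise from the +x axis in this frame.
Director angles are line orientations, defined modulo π.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dc_field
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "DirectorField",
    "QTensorField",
    "StructureTensorField",
    "OutOfDomainError",
    "extract_director",
    "director_to_q",
    "splay_bend",
    "sample_director",
]


class OutOfDomainError(ValueError):
    """Raised when a continuous position falls outside the valid mask/domain."""


def _wrap_pi(angle):
    """Wrap line-field angles into [0, π)."""
    return np.mod(angle, np.pi)


def _wrap_half_pi(delta):
    """Map an angle difference into (−π/2, π/2], the nearest-line representative."""
    return -np.mod(-np.asarray(delta, dtype=float) + np.pi / 2, np.pi) + np.pi / 2


@dataclass
class DirectorField:
    """A 2D nematic director (line) field sampled on a regular grid.

    Parameters
    ----------
    angle
        Orientation φ in radians, wrapped to [0, π), shape (rows, cols).
    pixel_size
        Grid spacing in µm per pixel.
    mask
        Boolean validity grid; ``False`` nodes are never read by samplers.
    confinement_radius, confinement_center
        Optional disc-confinement geometry in µm (centre defaults to the grid
        centre). Used by the simulator's boundary handling.
    """

    angle: np.ndarray
    pixel_size: float
    mask: np.ndarray | None = None
    confinement_radius: float | None = None
    confinement_center: tuple[float, float] | None = None

    def __post_init__(self):
        self.angle = _wrap_pi(np.asarray(self.angle, dtype=float))
        if self.angle.ndim != 2:
            raise ValueError("angle grid must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.angle.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.angle.shape:
                raise ValueError("mask shape must match angle grid")
        if self.confinement_radius is not None and self.confinement_center is None:
            r, c = self.angle.shape
            self.confinement_center = (
                (c - 1) / 2 * self.pixel_size,
                (r - 1) / 2 * self.pixel_size,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.angle.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (width, height) in µm spanned by grid nodes."""
        r, c = self.angle.shape
        return ((c - 1) * self.pixel_size, (r - 1) * self.pixel_size)

    @property
    def n(self) -> np.ndarray:
        """Director components (nx, ny) stacked on the last axis."""
        return np.stack([np.cos(self.angle), np.sin(self.angle)], axis=-1)

    def sample(self, r) -> np.ndarray:
        """Sample director angle(s) at continuous µm position(s); see
        :func:`sample_director`."""
        return sample_director(self, r)

    def contains(self, r) -> np.ndarray:
        """Vectorized test whether µm positions fall on valid ground.

        A position is inside if its four surrounding grid nodes exist and at
        least one is valid (bilinear sampling renormalizes over valid nodes).
        """
        r = np.asarray(r, dtype=float)
        x = r[..., 0] / self.pixel_size
        y = r[..., 1] / self.pixel_size
        rows, cols = self.angle.shape
        inside = (x >= 0) & (x <= cols - 1) & (y >= 0) & (y <= rows - 1)
        if not self.mask.all():
            i0 = np.clip(np.floor(y).astype(int), 0, rows - 2) if rows > 1 else np.zeros_like(y, int)
            j0 = np.clip(np.floor(x).astype(int), 0, cols - 2) if cols > 1 else np.zeros_like(x, int)
            m = self.mask
            any_valid = m[i0, j0] | m[i0 + 1, j0] | m[i0, j0 + 1] | m[i0 + 1, j0 + 1]
            inside = inside & any_valid
        return inside


@dataclass
class QTensorField:
    """Symmetric-traceless nematic order tensor Q = S(n⊗n − I/2) on a grid.

    Only the independent components Qxx and Qxy are stored (Qyy = −Qxx).
    """

    qxx: np.ndarray
    qxy: np.ndarray
    pixel_size: float
    mask: np.ndarray = _dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.qxx = np.asarray(self.qxx, dtype=float)
        self.qxy = np.asarray(self.qxy, dtype=float)
        if self.qxx.shape != self.qxy.shape:
            raise ValueError("Qxx and Qxy must have identical shape")
        if self.mask is None:
            self.mask = np.ones(self.qxx.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.qxx.shape

    @property
    def order(self) -> np.ndarray:
        """Scalar order magnitude S = 2·sqrt(Qxx² + Qxy²)."""
        return 2.0 * np.hypot(self.qxx, self.qxy)

    def divergence(self) -> tuple[np.ndarray, np.ndarray]:
        """∇·Q in physical units (per µm): (∂x Qxx + ∂y Qxy, ∂x Qxy − ∂y Qxx)."""
        dqxx_dy, dqxx_dx = np.gradient(self.qxx, self.pixel_size)
        dqxy_dy, dqxy_dx = np.gradient(self.qxy, self.pixel_size)
        return dqxx_dx + dqxy_dy, dqxy_dx - dqxx_dy


@dataclass
class StructureTensorField:
    """Box-averaged structure tensor of normalized intensity tangents."""

    t11: np.ndarray
    t12: np.ndarray
    t22: np.ndarray
    box_length: float  # µm

    @property
    def coherence(self) -> np.ndarray:
        """Eigenvalue gap (λ1 − λ2) of T, in [0, 1] for normalized tangents."""
        half_diff = 0.5 * (self.t11 - self.t22)
        return 2.0 * np.hypot(half_diff, self.t12)


# ---------------------------------------------------------------------------
# Extraction from images (structure-tensor method)
# ---------------------------------------------------------------------------

def structure_tensor(
    image: np.ndarray,
    pixel_size: float,
    box: float = 1.3,
    smooth_sigma: float = 1.0,
    gradient_floor: float = 0.1,
) -> StructureTensorField:
    """Build the box-averaged structure tensor of intensity tangents.

    The intensity gradient of a fluorescence image of aligned filaments is
    perpendicular to the filaments, so the normalized tangent t = (I_y, −I_x)
    points along the local orientation. T = ⟨t⊗t⟩ over an L×L box (stride one
    pixel) then has the local director as its principal eigenvector.

    A σ=1 px Gaussian pre-smooth stabilizes tangent normalization; gradients
    are central differences. Because tangents are normalized, pixels whose
    gradient is pure background noise would otherwise vote with full weight;
    ``gradient_floor`` (fraction of the 95th-percentile gradient magnitude)
    screens them out.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    box_px = max(3, int(round(box / pixel_size)))
    if min(image.shape) < box_px:
        raise ValueError("image smaller than the averaging box")
    smoothed = ndimage.gaussian_filter(image, smooth_sigma)
    gy, gx = np.gradient(smoothed)
    tx, ty = gy, -gx  # tangent (I_y, −I_x)
    norm = np.hypot(tx, ty)
    scale = np.percentile(norm, 95)
    floor = gradient_floor * scale if scale > 0 else 0.0
    ok = norm > max(floor, 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        tx = np.where(ok, tx / norm, 0.0)
        ty = np.where(ok, ty / norm, 0.0)
    # box mean over valid tangents only
    weight = ndimage.uniform_filter(ok.astype(float), box_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        t11 = np.where(weight > 0, ndimage.uniform_filter(tx * tx, box_px) / weight, 0.0)
        t12 = np.where(weight > 0, ndimage.uniform_filter(tx * ty, box_px) / weight, 0.0)
        t22 = np.where(weight > 0, ndimage.uniform_filter(ty * ty, box_px) / weight, 0.0)
    return StructureTensorField(t11, t12, t22, box_length=box_px * pixel_size)


def extract_director(
    image: np.ndarray, pixel_size: float, box: float = 1.3, smooth_sigma: float = 1.0
) -> DirectorField:
    """Extract the nematic director field from a grayscale intensity image.

    Per node, the director is the principal eigenvector of the box-averaged
    structure tensor of normalized tangents. Nodes whose box contains no
    intensity gradient at all (or an isotropic tensor) are masked invalid.
    A uniform image yields a fully masked field with a warning.
    """
    st = structure_tensor(image, pixel_size, box=box, smooth_sigma=smooth_sigma)
    half_diff = 0.5 * (st.t11 - st.t22)
    aniso = np.hypot(half_diff, st.t12)
    trace = st.t11 + st.t22
    valid = (trace > 1e-9) & (aniso > 1e-9)
    # principal eigenvector angle of [[T11, T12], [T12, T22]]
    angle = 0.5 * np.arctan2(2.0 * st.t12, st.t11 - st.t22)
    fld = DirectorField(_wrap_pi(angle), pixel_size, mask=valid)
    if not valid.any():
        warnings.warn("no intensity gradients found; director field fully masked")
    return fld


# ---------------------------------------------------------------------------
# Q tensor
# ---------------------------------------------------------------------------

def director_to_q(
    fld: DirectorField,
    order_mode: Literal["unit", "coherence"] = "unit",
    coherence: np.ndarray | None = None,
) -> QTensorField:
    """Convert a director field to Q = S(n⊗n − I/2).

    Componentwise Qxx = (S/2)cos 2φ and Qxy = (S/2)sin 2φ. In ``unit`` mode
    S ≡ 1; in ``coherence`` mode S is the supplied local eigenvalue gap of the
    extraction structure tensor (defaults to 1 where not given).
    """
    if order_mode == "unit":
        s = np.ones(fld.shape)
    elif order_mode == "coherence":
        s = np.ones(fld.shape) if coherence is None else np.asarray(coherence, dtype=float)
    else:
        raise ValueError(f"unknown order_mode {order_mode!r}")
    qxx = 0.5 * s * np.cos(2.0 * fld.angle)
    qxy = 0.5 * s * np.sin(2.0 * fld.angle)
    qxx = np.where(fld.mask, qxx, 0.0)
    qxy = np.where(fld.mask, qxy, 0.0)
    return QTensorField(qxx, qxy, fld.pixel_size, mask=fld.mask.copy())


# ---------------------------------------------------------------------------
# Distortion maps
# ---------------------------------------------------------------------------

def _aligned_difference(nx, ny, axis, spacing):
    """Central difference of the director vector with local sign alignment.

    The director is a line field (n ≡ −n); before differencing, each
    neighbor is flipped to the hemisphere of the centre node so that the
    derivative is gauge invariant. Boundaries use one-sided differences.
    """
    def shifted(arr, offset):
        return np.roll(arr, -offset, axis=axis)

    out_x = np.empty_like(nx)
    out_y = np.empty_like(ny)
    # forward/backward neighbors, sign-aligned to the centre
    nx_f, ny_f = shifted(nx, 1), shifted(ny, 1)
    nx_b, ny_b = shifted(nx, -1), shifted(ny, -1)
    sgn_f = np.where(nx * nx_f + ny * ny_f < 0, -1.0, 1.0)
    sgn_b = np.where(nx * nx_b + ny * ny_b < 0, -1.0, 1.0)
    out_x = (sgn_f * nx_f - sgn_b * nx_b) / (2 * spacing)
    out_y = (sgn_f * ny_f - sgn_b * ny_b) / (2 * spacing)
    # one-sided at the two boundary slices
    first = [slice(None)] * nx.ndim
    last = [slice(None)] * nx.ndim
    second = [slice(None)] * nx.ndim
    penult = [slice(None)] * nx.ndim
    first[axis], last[axis], second[axis], penult[axis] = 0, -1, 1, -2
    first, last, second, penult = map(tuple, (first, last, second, penult))
    s0 = np.where(nx[first] * nx[second] + ny[first] * ny[second] < 0, -1.0, 1.0)
    out_x[first] = (s0 * nx[second] - nx[first]) / spacing
    out_y[first] = (s0 * ny[second] - ny[first]) / spacing
    s1 = np.where(nx[last] * nx[penult] + ny[last] * ny[penult] < 0, -1.0, 1.0)
    out_x[last] = (nx[last] - s1 * nx[penult]) / spacing
    out_y[last] = (ny[last] - s1 * ny[penult]) / spacing
    return out_x, out_y


def splay_bend(fld: DirectorField) -> tuple[np.ndarray, np.ndarray]:
    """Compute splay (∇·n)² and bend |n × ∇×n|² maps (units µm⁻²).

    Derivatives use locally sign-aligned central differences so the result is
    invariant under arbitrary n → −n gauge flips. For a unit director the
    bend magnitude equals the z-curl squared. Nodes without a full valid
    3-neighborhood are returned as NaN.
    """
    nx = np.cos(fld.angle)
    ny = np.sin(fld.angle)
    dnx_dx, dny_dx = _aligned_difference(nx, ny, axis=1, spacing=fld.pixel_size)
    dnx_dy, dny_dy = _aligned_difference(nx, ny, axis=0, spacing=fld.pixel_size)
    splay = (dnx_dx + dny_dy) ** 2
    curl_z = dny_dx - dnx_dy
    bend = curl_z**2
    good = ndimage.binary_erosion(fld.mask, structure=np.ones((3, 3)))
    # keep one-sided boundary estimates where the mask itself reaches the border
    border = np.zeros_like(fld.mask)
    border[[0, -1], :] = True
    border[:, [0, -1]] = True
    good = good | (fld.mask & border)
    splay = np.where(good, splay, np.nan)
    bend = np.where(good, bend, np.nan)
    return splay, bend


# ---------------------------------------------------------------------------
# π-periodic sampling
# ---------------------------------------------------------------------------

def sample_director(fld: DirectorField, r) -> np.ndarray:
    """Sample the director angle at continuous position(s) ``r`` (µm).

    Interpolates the double-angle vector (cos 2φ, sin 2φ) bilinearly and
    reconstructs the half angle, which is exact on grid nodes and never
    interpolates raw angles across the π wrap. Masked nodes carry zero weight;
    positions with no valid support raise :class:`OutOfDomainError`.

    Accepts shape (2,) or (..., 2); returns a scalar or matching-shape array
    of angles in [0, π).
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 1
    pts = np.atleast_2d(r)
    x = pts[..., 0] / fld.pixel_size
    y = pts[..., 1] / fld.pixel_size
    rows, cols = fld.angle.shape
    eps = 1e-9
    if np.any(x < -eps) or np.any(x > cols - 1 + eps) or np.any(y < -eps) or np.any(y > rows - 1 + eps):
        raise OutOfDomainError("position outside the field grid")
    x = np.clip(x, 0, cols - 1)
    y = np.clip(y, 0, rows - 1)
    j0 = np.clip(np.floor(x).astype(int), 0, max(cols - 2, 0))
    i0 = np.clip(np.floor(y).astype(int), 0, max(rows - 2, 0))
    fx = x - j0
    fy = y - i0
    # double-angle grids are cached: fields are treated as immutable
    cache = getattr(fld, "_double_angle_cache", None)
    if cache is None:
        cache = (np.cos(2 * fld.angle), np.sin(2 * fld.angle))
        fld._double_angle_cache = cache
    c2, s2 = cache
    m = fld.mask.astype(float)
    w00 = (1 - fx) * (1 - fy) * m[i0, j0]
    w01 = fx * (1 - fy) * m[i0, np.minimum(j0 + 1, cols - 1)]
    w10 = (1 - fx) * fy * m[np.minimum(i0 + 1, rows - 1), j0]
    w11 = fx * fy * m[np.minimum(i0 + 1, rows - 1), np.minimum(j0 + 1, cols - 1)]
    wsum = w00 + w01 + w10 + w11
    if np.any(wsum <= 0):
        raise OutOfDomainError("position has no valid (unmasked) support")
    j1 = np.minimum(j0 + 1, cols - 1)
    i1 = np.minimum(i0 + 1, rows - 1)
    cc = (w00 * c2[i0, j0] + w01 * c2[i0, j1] + w10 * c2[i1, j0] + w11 * c2[i1, j1]) / wsum
    ss = (w00 * s2[i0, j0] + w01 * s2[i0, j1] + w10 * s2[i1, j0] + w11 * s2[i1, j1]) / wsum
    ang = _wrap_pi(0.5 * np.arctan2(ss, cc))
    return float(ang[0]) if scalar else ang.reshape(r.shape[:-1])
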