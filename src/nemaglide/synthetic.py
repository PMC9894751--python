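"""Synthetic nematic textures and gliding-assay imagery.

Ground-truth director fields are built from the standard one-constant
multi-defect ansatz

    φ(r) = φ0 + Σ_i k_i · atan2(y − y_i, x − x_i),

whose winding number around any loop is exactly the sum of the enclosed
charges k_i. On top of the fields, the module renders fluorescence-style
images of short aligned filaments (the passive nematic, ~0.8 µm actin) and
movies of moving rods (~2 µm microtubules) so that the extraction, detection,
tracking and flow stages can all be exercised against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _dc_field, asdict

import numpy as np
from scipy import ndimage

from .fields import DirectorField, _wrap_pi

__all__ = [
    "DefectSpec",
    "FieldSpec",
    "make_field",
    "random_field_spec",
    "make_confined_field",
    "make_asymmetric_plus_half",
    "render_nematic_image",
    "render_mt_frames",
]

#: minimum pairwise defect separation enforced by generators, in pixels
MIN_SEPARATION_PX = 10.0


@dataclass
class DefectSpec:
    """A point disclination: position (µm), half-integer charge, phase offset."""

    position: tuple[float, float]
    charge: float
    phase_offset: float = 0.0

    def __post_init__(self):
        if abs(round(2 * self.charge) - 2 * self.charge) > 1e-9 or self.charge == 0:
            raise ValueError("charge must be a nonzero multiple of 1/2")
        self.position = (float(self.position[0]), float(self.position[1]))
        self.charge = float(self.charge)


@dataclass
class FieldSpec:
    """Recipe for a multi-defect director field on a grid.

    ``confinement_radius`` (µm), if set, restricts the field to a disc whose
    enclosed topological charge must then total +1 (Poincaré–Hopf for
    tangential anchoring on a disc).
    """

    shape: tuple[int, int]
    pixel_size: float
    background_angle: float = 0.0
    defects: list[DefectSpec] = _dc_field(default_factory=list)
    confinement_radius: float | None = None

    def __post_init__(self):
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.confinement_radius is not None:
            half_extent = min(self.shape[0] - 1, self.shape[1] - 1) / 2 * self.pixel_size
            if self.confinement_radius > half_extent + 1e-9:
                raise ValueError("confinement disc does not fit inside the grid")
            total = sum(d.charge for d in self.defects)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"confined disc requires total charge +1, got {total}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FieldSpec":
        d = json.loads(text)
        d["defects"] = [DefectSpec(**ds) for ds in d.get("defects", [])]
        d["shape"] = tuple(d["shape"])
        return cls(**d)


def _grid_xy(shape, pixel_size):
    rows, cols = shape
    x = np.arange(cols) * pixel_size
    y = np.arange(rows) * pixel_size
    return np.meshgrid(x, y)


def _validate_positions(spec: FieldSpec):
    w = (spec.shape[1] - 1) * spec.pixel_size
    h = (spec.shape[0] - 1) * spec.pixel_size
    pos = np.array([d.position for d in spec.defects], dtype=float).reshape(-1, 2)
    for p in pos:
        if not (0 <= p[0] <= w and 0 <= p[1] <= h):
            raise ValueError(f"defect at {tuple(p)} lies outside the grid")
        if spec.confinement_radius is not None:
            cx, cy = w / 2, h / 2
            if np.hypot(p[0] - cx, p[1] - cy) >= spec.confinement_radius:
                raise ValueError("defect outside the confinement disc")
    if len(pos) > 1:
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < (0.5 * spec.pixel_size) ** 2:
            raise ValueError("coincident defects")


def make_field(spec: FieldSpec) -> DirectorField:
    """Build the multi-defect ansatz director field for ``spec``.

    Defects sitting exactly on a grid node are nudged by half a pixel so the
    (singular) core never coincides with a sampled angle. The winding number
    of the result around any closed loop equals the sum of enclosed charges.
    """
    _validate_positions(spec)
    xx, yy = _grid_xy(spec.shape, spec.pixel_size)
    phi = np.full(spec.shape, float(spec.background_angle))
    half_px = 0.5 * spec.pixel_size
    for d in spec.defects:
        px, py = d.position
        # shift off-node if the core lands exactly on a grid point
        if (abs(px / spec.pixel_size - round(px / spec.pixel_size)) < 1e-9
                and abs(py / spec.pixel_size - round(py / spec.pixel_size)) < 1e-9):
            px += half_px
            py += half_px
        phi = phi + d.charge * np.arctan2(yy - py, xx - px) + d.phase_offset
    mask = None
    if spec.confinement_radius is not None:
        w = (spec.shape[1] - 1) * spec.pixel_size
        h = (spec.shape[0] - 1) * spec.pixel_size
        mask = np.hypot(xx - w / 2, yy - h / 2) <= spec.confinement_radius
    return DirectorField(
        _wrap_pi(phi),
        spec.pixel_size,
        mask=mask,
        confinement_radius=spec.confinement_radius,
    )


def random_field_spec(
    shape: tuple[int, int],
    pixel_size: float,
    n_defects: int,
    net_charge: float = 0.0,
    seed: int | np.random.Generator = 0,
    min_separation_px: float = MIN_SEPARATION_PX,
    margin_px: float = 12.0,
) -> FieldSpec:
    """Draw a random multi-defect configuration with a prescribed net charge.

    Positions are rejection-sampled with a minimum pairwise separation
    (default 10 px) inside a margin; charges are ±1/2 in shuffled order chosen
    to hit ``net_charge`` exactly. Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_net = int(round(2 * net_charge))
    if (n_defects - n_net) % 2 != 0 or abs(n_net) > n_defects:
        raise ValueError("net charge unreachable with ±1/2 charges")
    n_plus = (n_defects + n_net) // 2
    charges = [0.5] * n_plus + [-0.5] * (n_defects - n_plus)
    rng.shuffle(charges)
    w = (shape[1] - 1) * pixel_size
    h = (shape[0] - 1) * pixel_size
    margin = margin_px * pixel_size
    min_sep = min_separation_px * pixel_size
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n_defects:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place defects with requested separation")
        p = (
            float(rng.uniform(margin, w - margin)),
            float(rng.uniform(margin, h - margin)),
        )
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in positions):
            positions.append(p)
    defects = [DefectSpec(p, k) for p, k in zip(positions, charges)]
    phi0 = float(rng.uniform(0, np.pi))
    return FieldSpec(shape, pixel_size, background_angle=phi0, defects=defects)


def make_confined_field(
    radius: float,
    n_plus: int,
    n_minus: int = 0,
    seed: int | np.random.Generator = 0,
    pixel_size: float = 0.5,
    min_separation_px: float = MIN_SEPARATION_PX,
    placement: str = "random",
    max_radius_frac: float = 0.75,
) -> DirectorField:
    """Generate a disc-confined nematic with half-integer defects of total +1.

    A disc with tangential anchoring must enclose total charge +1
    (Poincaré–Hopf), so ``n_plus − n_minus == 2`` is required for charges
    ±1/2. The interior is the harmonic multi-defect ansatz completed by the
    method of images: each interior defect k at z₀ (complex coordinate from
    the disc centre) is paired with the term k·arg(R² − z·z̄₀), whose
    singularity sits outside the disc at R²/z̄₀. On the rim the pair sums to
    k·θ, so with total charge +1 and a π/2 phase the rim director is exactly
    tangential. ``placement`` is ``"random"`` (rejection-sampled within
    ``max_radius_frac``·R) or ``"symmetric"`` (defects evenly spaced on a
    ring of radius R/2). Defects near the rim make the edge distortions that
    select a single stable handedness of the edge current; deep placements
    leave a smooth tangential rim on which both directions can circulate.
    """
    if n_plus - n_minus != 2:
        raise ValueError(
            "half-integer charges in a tangential disc must satisfy n_plus - n_minus = 2"
        )
    if n_plus < 0 or n_minus < 0:
        raise ValueError("defect counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    npx = int(np.ceil(2 * radius / pixel_size)) + 9
    shape = (npx, npx)
    cx = (shape[1] - 1) / 2 * pixel_size
    cy = (shape[0] - 1) / 2 * pixel_size
    n_defects = n_plus + n_minus
    charges = [0.5] * n_plus + [-0.5] * n_minus
    rng.shuffle(charges)
    positions: list[tuple[float, float]] = []
    if placement == "symmetric":
        for i in range(n_defects):
            ang = 2 * np.pi * i / n_defects
            positions.append(
                (cx + 0.5 * radius * np.cos(ang), cy + 0.5 * radius * np.sin(ang))
            )
    else:
        min_sep = min_separation_px * pixel_size
        attempts = 0
        while len(positions) < n_defects:
            attempts += 1
            if attempts > 20000:
                raise RuntimeError("could not place defects inside the disc")
            rr = radius * max_radius_frac * np.sqrt(rng.uniform())
            aa = rng.uniform(0, 2 * np.pi)
            p = (cx + rr * np.cos(aa), cy + rr * np.sin(aa))
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in positions):
                positions.append((float(p[0]), float(p[1])))
    # nudge off grid nodes (half-pixel) before building the singular terms
    half_px = 0.5 * pixel_size
    nudged = []
    for (px_, py_) in positions:
        if (abs(px_ / pixel_size - round(px_ / pixel_size)) < 1e-9
                and abs(py_ / pixel_size - round(py_ / pixel_size)) < 1e-9):
            px_, py_ = px_ + half_px, py_ + half_px
        nudged.append((px_, py_))
    xx, yy = _grid_xy(shape, pixel_size)
    z = (xx - cx) + 1j * (yy - cy)
    phi = np.full(shape, np.pi / 2)
    for (px_, py_), k in zip(nudged, charges):
        z0 = (px_ - cx) + 1j * (py_ - cy)
        phi = phi + k * np.angle(z - z0) + k * np.angle(radius**2 - z * np.conj(z0))
    mask = np.abs(z) <= radius
    fld = DirectorField(
        _wrap_pi(phi), pixel_size, mask=mask, confinement_radius=radius
    )
    fld.defect_specs = [DefectSpec(p, k) for p, k in zip(nudged, charges)]
    return fld


def make_asymmetric_plus_half(
    skew_angle: float,
    shape: tuple[int, int] = (101, 101),
    pixel_size: float = 0.5,
    ramp_length: float = 1.0,
) -> DirectorField:
    """A +1/2 defect whose outgoing director is skewed relative to its axis.

    The canonical comet φ = θ/2 (axis along +x) is superposed with a smooth
    rotation skew·ramp(r)·cos²(θ/2) that vanishes at the core, saturates
    beyond ``ramp_length`` µm, and is windowed to the head side (it dies off
    toward θ = ±π), so the director sampled on the axis ray just past the
    core meets the axis at ``skew_angle`` while the tail side, and hence the
    axis itself, is left nearly untouched. A uniform rotation would instead
    co-rotate the comet and produce no asymmetry. This is the minimal
    texture reproducing the orientational symmetry breaking that makes +1/2
    defects eject gliding filaments preferentially to one side.
    """
    if not abs(skew_angle) < np.pi / 2:
        raise ValueError("|skew_angle| must be below π/2")
    xx, yy = _grid_xy(shape, pixel_size)
    cx = (shape[1] - 1) / 2 * pixel_size
    cy = (shape[0] - 1) / 2 * pixel_size
    # keep the core off grid nodes and off grid lines (quarter-pixel
    # diagonal shift); the exact core is exposed as ``core_position``
    core = (cx + 0.25 * pixel_size, cy + 0.25 * pixel_size)
    dx = xx - core[0]
    dy = yy - core[1]
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    ramp = np.minimum(r / ramp_length, 1.0)
    head_window = np.cos(theta / 2) ** 2  # 1 on the axis ray, 0 at the tail
    phi = 0.5 * theta + skew_angle * ramp * head_window
    fld = DirectorField(_wrap_pi(phi), pixel_size)
    fld.core_position = np.array(core)
    return fld


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _draw_segment(img, x0, y0, x1, y1, amplitude=1.0):
    """Accumulate an anti-aliased line segment onto ``img`` (row, col frame)."""
    from skimage.draw import line_aa

    r0, c0 = int(round(y0)), int(round(x0))
    r1, c1 = int(round(y1)), int(round(x1))
    rows, cols = img.shape
    rr, cc, val = line_aa(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
    img[rr[keep], cc[keep]] += amplitude * val[keep]


def render_nematic_image(
    fld: DirectorField,
    filament_length: float = 0.8,
    density: float = 2.0,
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    blur_sd: float = 0.8,
    dtype=np.uint16,
) -> np.ndarray:
    """Render a fluorescence-style image of short filaments aligned with ``fld``.

    ``density`` is filaments per µm²; filaments are ``filament_length`` µm
    segments centred at random valid positions and oriented along the local
    director, drawn with anti-aliasing and blurred by ``blur_sd`` px
    (the microscope point-spread function); Gaussian noise of ``noise_sd``
    (fraction of the segment amplitude) is added. Returned as 16-bit
    grayscale by default. Reproducible under a fixed seed.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = fld.shape
    w, h = fld.extent
    img = np.zeros((rows, cols), dtype=float)
    n_fil = rng.poisson(density * w * h) if density > 0 else 0
    half = filament_length / 2
    placed = 0
    guard = 0
    while placed < n_fil and guard < 50 * max(n_fil, 1):
        guard += 1
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        if not fld.contains(np.array([x, y])):
            continue
        ang = fld.sample(np.array([x, y]))
        ca, sa = np.cos(ang), np.sin(ang)
        _draw_segment(
            img,
            (x - half * ca) / fld.pixel_size,
            (y - half * sa) / fld.pixel_size,
            (x + half * ca) / fld.pixel_size,
            (y + half * sa) / fld.pixel_size,
        )
        placed += 1
    if blur_sd > 0:
        img = ndimage.gaussian_filter(img, blur_sd)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0, None)
    if dtype == np.uint16:
        peak = img.max() if img.max() > 0 else 1.0
        img = (img / peak * 60000).astype(np.uint16)
    return img


def render_mt_frames(
    trajectories,
    fld_shape: tuple[int, int],
    pixel_size: float,
    rod_length: float = 2.0,
    frame_interval: float = 5.0,
    sample_stride: int | None = None,
    blur_sd: float = 0.7,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render an image stack of gliding rods from simulated trajectories.

    One ``rod_length`` µm sprite per agent per frame, centred at the agent
    position and oriented along its heading θ; frames are blurred
    (``blur_sd`` px) and carry Gaussian noise. ``sample_stride`` picks every
    k-th trajectory sample as a frame; by default it is inferred from
    ``frame_interval`` and the trajectory timestamps. Returns an array of
    shape (n_frames, rows, cols), float in [0, ~1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample_stride is None:
        t = trajectories[0].t
        dt = t[1] - t[0] if len(t) > 1 else frame_interval
        sample_stride = max(1, int(round(frame_interval / dt)))
    n_frames = min(len(tr.t) for tr in trajectories)
    frame_idx = np.arange(0, n_frames, sample_stride)
    rows, cols = fld_shape
    half = rod_length / 2
    stack = np.zeros((len(frame_idx), rows, cols), dtype=float)
    for fi, k in enumerate(frame_idx):
        img = stack[fi]
        for tr in trajectories:
            x, y, th = tr.x[k], tr.y[k], tr.theta[k]
            ca, sa = np.cos(th), np.sin(th)
            _draw_segment(
                img,
                (x - half * ca) / pixel_size,
                (y - half * sa) / pixel_size,
                (x + half * ca) / pixel_size,
                (y + half * sa) / pixel_size,
            )
        if blur_sd > 0:
            stack[fi] = ndimage.gaussian_filter(img, blur_sd)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    return np.clip(stack, 0, None)
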