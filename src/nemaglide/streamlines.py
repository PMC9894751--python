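"""Q-tensor streamline heuristic: one oriented polar streamline per +1/2
defect.

The predictor needs only the director field. For each +1/2 defect with core
r⁺ and axis p⁺ it seeds a streamline at

    r_seed = r⁺ + d · p⁺        (d ≈ 2 µm, the single model parameter),

orients it along ±n(r_seed) picking the sign that minimizes the projection on
the local polarity field p = ∇·Q/|∇·Q| (i.e. direction = n · sign(−n·p)),
and integrates along the director with sign continuity until the streamline
reaches another +1/2 defect, exits the field, closes into a loop, or exhausts
its length budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

from .defects import Defect, detect_defects
from .fields import (
    DirectorField,
    OutOfDomainError,
    QTensorField,
    director_to_q,
    sample_director,
)

__all__ = [
    "StreamlineSeed",
    "Streamline",
    "PredictorParams",
    "polarity_field",
    "make_seed",
    "trace_streamline",
    "predict_all",
    "streamline_image",
]


@dataclass
class StreamlineSeed:
    """Seed point, offset distance and initial (unit) direction."""

    position: np.ndarray
    offset: float
    direction: np.ndarray
    defect: Defect | None = None
    ambiguous: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError("seed direction must be a unit vector")


@dataclass
class Streamline:
    """Oriented polyline (µm) with its terminating event.

    ``event`` is one of ``"defect"``, ``"edge"``, ``"loop"``, ``"max-length"``;
    point order is the direction of motion and consecutive spacing equals the
    integration step.
    """

    points: np.ndarray
    event: str
    seed: StreamlineSeed | None = None

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PredictorParams:
    """Tunables of the streamline predictor (all lengths in µm).

    ``seed_offset`` is the paper-level phenomenological distance d;
    ``step`` defaults to half a pixel at trace time when left as None.
    """

    seed_offset: float = 2.0
    step: float | None = None
    stop_radius: float = 1.0
    closure_tol: float = 0.5
    direction_agreement: float = float(np.cos(np.pi / 4))
    max_length: float | None = None  # default: 10 × field perimeter
    min_separation: float = 3.0
    divq_tolerance: float = 1e-8


def polarity_field(q: QTensorField, tolerance: float = 1e-8):
    """Unit polarity field p = ∇·Q/|∇·Q| with a validity mask.

    Nodes where |∇·Q| falls below ``tolerance`` (relative to the grid
    maximum) are masked: there the splay/bend distortions carry no direction.
    Returns (px_grid, py_grid, mask).
    """
    divx, divy = q.divergence()
    mag = np.hypot(divx, divy)
    scale = mag.max() if mag.max() > 0 else 1.0
    ok = mag > tolerance * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        px = np.where(ok, divx / np.maximum(mag, 1e-300), 0.0)
        py = np.where(ok, divy / np.maximum(mag, 1e-300), 0.0)
    return px, py, ok


def _sample_vector(grid_x, grid_y, pixel_size, r):
    coords = np.vstack([[r[1] / pixel_size], [r[0] / pixel_size]])
    vx = ndimage.map_coordinates(grid_x, coords, order=1, mode="nearest")[0]
    vy = ndimage.map_coordinates(grid_y, coords, order=1, mode="nearest")[0]
    return np.array([vx, vy])


def make_seed(
    defect: Defect,
    fld: DirectorField,
    q: QTensorField | None = None,
    d: float = 2.0,
) -> StreamlineSeed:
    """Place and orient the streamline seed of a +1/2 defect.

    r_seed = core + d·axis; the initial direction is the director at r_seed
    with the sign that minimizes its scalar product with the polarity field
    p = ∇·Q/|∇·Q| there (self-propelled particles leave the defect along the
    direction requiring the least reorientation). An exact tie n·p = 0 keeps
    +n and flags the seed ambiguous. Raises ``OutOfDomainError`` if the seed
    falls off valid ground (callers typically skip it with a record).
    """
    if defect.charge != 0.5 or defect.axis is None:
        raise ValueError("seeds are defined for +1/2 defects with a known axis")
    if q is None:
        q = director_to_q(fld)
    r_seed = defect.position + d * defect.axis
    phi = sample_director(fld, r_seed)  # raises OutOfDomainError when outside
    n = np.array([np.cos(phi), np.sin(phi)])
    divx, divy = q.divergence()
    p = _sample_vector(divx, divy, q.pixel_size, r_seed)
    nrm = np.linalg.norm(p)
    dot = float(n @ (p / nrm)) if nrm > 1e-12 else 0.0
    ambiguous = abs(dot) < 1e-9
    sign = 1.0 if ambiguous else float(np.sign(-dot))
    return StreamlineSeed(r_seed, d, sign * n, defect=defect, ambiguous=ambiguous)


class _SpatialHash:
    """Uniform-grid point index for O(1) loop-closure queries."""

    def __init__(self, cell: float):
        self.cell = cell
        self.bins: dict[tuple[int, int], list[int]] = {}

    def key(self, p):
        return (int(np.floor(p[0] / self.cell)), int(np.floor(p[1] / self.cell)))

    def add(self, idx: int, p):
        self.bins.setdefault(self.key(p), []).append(idx)

    def near(self, p):
        kx, ky = self.key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                yield from self.bins.get((kx + dx, ky + dy), ())


def trace_streamline(
    fld: DirectorField,
    seed: StreamlineSeed,
    defects: list[Defect] | None = None,
    step: float | None = None,
    stop_radius: float = 1.0,
    max_length: float | None = None,
    closure_tol: float = 0.5,
    direction_agreement: float = float(np.cos(np.pi / 4)),
) -> Streamline:
    """Integrate an oriented streamline along the director field.

    Midpoint (RK2) steps follow ±n with sign continuity: each evaluation
    flips the director so it maximizes the dot product with the previous
    direction. Termination events: entering ``stop_radius`` of a *different*
    +1/2 defect core ("defect"); leaving the valid domain ("edge"); coming
    back within ``closure_tol`` of an earlier point with direction agreement
    above ``direction_agreement`` ("loop"); or exceeding ``max_length``
    ("max-length", default 10× the field perimeter).
    """
    if step is None:
        step = 0.5 * fld.pixel_size
    if max_length is None:
        w, h = fld.extent
        max_length = 10.0 * 2 * (w + h)
    stops = []
    for d in defects or []:
        if d.charge != 0.5:
            continue
        if seed.defect is not None and (
            d is seed.defect
            or np.linalg.norm(d.position - seed.defect.position) < 1e-9
        ):
            continue
        stops.append(d)
    stop_pos = np.array([d.position for d in stops]).reshape(-1, 2)

    pos = seed.position.copy()
    direction = seed.direction.copy()
    if len(stop_pos) and np.min(np.linalg.norm(stop_pos - pos, axis=1)) <= stop_radius:
        return Streamline(pos[None, :], "defect", seed)
    pts = [pos.copy()]
    hash_ = _SpatialHash(max(closure_tol, 1e-6))
    dirs = [direction.copy()]
    hash_.add(0, pos)
    n_steps = int(np.ceil(max_length / step))
    # don't test closure against the immediate past of the path
    guard_back = max(4, int(np.ceil(4 * closure_tol / step)))

    def director_at(r, ref):
        phi = sample_director(fld, r)
        n = np.array([np.cos(phi), np.sin(phi)])
        return n if n @ ref >= 0 else -n

    event = "max-length"
    for k in range(n_steps):
        try:
            v1 = director_at(pos, direction)
            mid = pos + 0.5 * step * v1
            v2 = director_at(mid, v1)
            new = pos + step * v2
            if not fld.contains(new):
                event = "edge"
                break
        except OutOfDomainError:
            event = "edge"
            break
        direction = v2
        pos = new
        pts.append(pos.copy())
        dirs.append(direction.copy())
        idx = len(pts) - 1
        if len(stop_pos) and np.min(np.linalg.norm(stop_pos - pos, axis=1)) <= stop_radius:
            event = "defect"
            break
        closed = False
        for j in hash_.near(pos):
            if idx - j <= guard_back:
                continue
            if (np.linalg.norm(pts[j] - pos) <= closure_tol
                    and dirs[j] @ direction >= direction_agreement):
                closed = True
                break
        if closed:
            event = "loop"
            break
        hash_.add(idx, pos)
    return Streamline(np.array(pts), event, seed)


def predict_all(
    fld: DirectorField,
    params: PredictorParams | None = None,
    defects: list[Defect] | None = None,
    q: QTensorField | None = None,
) -> list[Streamline]:
    """Predict one oriented streamline per +1/2 defect of the field.

    Defects are detected if not given; defects without a defined axis or
    whose seed falls outside the domain are skipped (recorded as zero-length
    "edge" streamlines). Fully deterministic.
    """
    params = params or PredictorParams()
    if q is None:
        q = director_to_q(fld)
    if defects is None:
        defects = detect_defects(fld, min_separation=params.min_separation, q=q)
    out: list[Streamline] = []
    for d in defects:
        if d.charge != 0.5 or d.axis is None:
            continue
        try:
            seed = make_seed(d, fld, q, d=params.seed_offset)
        except OutOfDomainError:
            out.append(Streamline(np.empty((0, 2)), "edge", None))
            continue
        out.append(
            trace_streamline(
                fld,
                seed,
                defects,
                step=params.step,
                stop_radius=params.stop_radius,
                max_length=params.max_length,
                closure_tol=params.closure_tol,
                direction_agreement=params.direction_agreement,
            )
        )
    return out


def streamline_image(
    streamlines: list[Streamline], shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Rasterize streamlines to a count image (for visual/Pearson comparison
    with simulated occupancy)."""
    rows, cols = shape
    img = np.zeros((rows, cols), dtype=float)
    for s in streamlines:
        if len(s.points) == 0:
            continue
        j = np.clip(np.round(s.points[:, 0] / pixel_size).astype(int), 0, cols - 1)
        i = np.clip(np.round(s.points[:, 1] / pixel_size).astype(int), 0, rows - 1)
        img[i, j] += 1
    return img
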