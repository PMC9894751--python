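"""Quantitative read-outs of defect-steered gliding patterns.

Covers the velocity–director alignment order parameter S_v, the Pearson
agreement between occupancy images, the directional bias of filaments
leaving +1/2 defects, closed-loop detection with enclosed topological charge
and chirality, and edge-current statistics in disc-confined runs.

Chirality convention: the signed (shoelace) area of a closed polyline is
computed in the package's image frame (x right, y down); loops with positive
signed area are labelled "CCW", negative "CW". Mirroring any input flips
every label, as it must.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage, stats

from .defects import Defect, winding_number
from .fields import DirectorField
from .sim import Trajectory

__all__ = [
    "DirectionCounts",
    "DirectionFraction",
    "LoopRecord",
    "EdgeStats",
    "order_parameter",
    "pearson_images",
    "direction_fraction",
    "classify_exits",
    "detect_loops",
    "edge_stats",
]


# ---------------------------------------------------------------------------
# Order parameter
# ---------------------------------------------------------------------------

def order_parameter(n, v) -> float:
    """Alignment order parameter S_v = 2(n·v/|v|)² − 1.

    ``n`` is the local director, given as an angle (radians) or a 2-vector
    (normalized internally); ``v`` is the velocity vector. S_v is 1 when the
    velocity is parallel to the director, −1 when orthogonal, and invariant
    under n → −n and v → −v. Zero velocity is undefined and raises.
    """
    if np.isscalar(n):
        nvec = np.array([np.cos(n), np.sin(n)])
    else:
        nvec = np.asarray(n, dtype=float)
        nn = np.linalg.norm(nvec)
        if nn == 0:
            raise ValueError("director vector must be nonzero")
        nvec = nvec / nn
    v = np.asarray(v, dtype=float)
    speed = np.linalg.norm(v)
    if speed == 0:
        raise ValueError("S_v is undefined for zero velocity")
    c = float(nvec @ v) / speed
    return 2.0 * c * c - 1.0


# ---------------------------------------------------------------------------
# Pearson image agreement
# ---------------------------------------------------------------------------

def pearson_images(
    img1: np.ndarray,
    img2: np.ndarray,
    smooth_sd: float = 2.0,
    downsample_to: int = 256,
) -> float:
    """Pearson correlation between two occupancy/time-projection images.

    Both images are Gaussian-smoothed, block-averaged down to at most
    ``downsample_to`` per side to suppress pixel noise, and compared with
    r = Σ (I1 − Ī1)(I2 − Ī2) / (σ1 σ2 N). The images must cover the same
    physical extent (same shape). Zero-variance inputs are undefined.
    """
    a = np.asarray(img1, dtype=float)
    b = np.asarray(img2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shape (same physical extent)")

    def prep(x):
        if smooth_sd > 0:
            x = ndimage.gaussian_filter(x, smooth_sd)
        factor = max(1, int(np.ceil(max(x.shape) / downsample_to)))
        if factor > 1:
            r = (x.shape[0] // factor) * factor
            c = (x.shape[1] // factor) * factor
            x = x[:r, :c].reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))
        return x.ravel()

    fa, fb = prep(a), prep(b)
    if fa.std() == 0 or fb.std() == 0:
        raise ValueError("Pearson coefficient undefined for zero-variance image")
    return float(np.corrcoef(fa, fb)[0, 1])


# ---------------------------------------------------------------------------
# Defect-exit direction statistics
# ---------------------------------------------------------------------------

@dataclass
class DirectionCounts:
    """Exit counts on the two sides of a defect axis."""

    n1: int
    n2: int

    @property
    def total(self) -> int:
        return self.n1 + self.n2


@dataclass
class DirectionFraction:
    """max(n1,n2)/(n1+n2) with a two-sided binomial p-value against 0.5."""

    fraction: float
    p_value: float
    counts: DirectionCounts


def direction_fraction(counts: DirectionCounts) -> DirectionFraction:
    """Fraction of filaments taking the majority direction at a defect.

    Computed as max(n1, n2)/(n1 + n2); the attached p-value is the two-sided
    exact binomial test of the counts against an even split.
    """
    if counts.total < 1:
        raise ValueError("direction fraction undefined without any exits")
    frac = max(counts.n1, counts.n2) / counts.total
    p = stats.binomtest(counts.n1, counts.total, 0.5).pvalue
    return DirectionFraction(frac, float(p), counts)


def classify_exits(
    trajectories: list[Trajectory],
    defect: Defect,
    approach_radius: float = 2.0,
    gate_radius: float | None = None,
) -> DirectionCounts:
    """Count trajectories leaving a +1/2 defect on either side of its axis.

    A passage qualifies when the particle dwells within ``approach_radius``
    of the core (it actually visited the defect) and subsequently crosses the
    exit gate at ``gate_radius`` (default 2× the approach radius). The
    crossing is classified by the sign of the exit velocity's component
    transverse to the defect axis: n1 counts the positive side
    (cross(axis, v) > 0), n2 the other. Multiple independent passages of one
    trajectory each count once.
    """
    if defect.axis is None:
        raise ValueError("defect axis required to classify exits")
    if gate_radius is None:
        gate_radius = 2.0 * approach_radius
    ax, ay = defect.axis
    n1 = n2 = 0
    for tr in trajectories:
        d = np.hypot(tr.x - defect.position[0], tr.y - defect.position[1])
        k = 0
        n = len(d)
        while k < n:
            if d[k] > approach_radius:
                k += 1
                continue
            # dwell entered: find the gate crossing that follows
            j = k
            while j < n and d[j] <= gate_radius:
                j += 1
            if j < n:
                vx = tr.x[j] - tr.x[j - 1]
                vy = tr.y[j] - tr.y[j - 1]
                cross = ax * vy - ay * vx
                if cross > 0:
                    n1 += 1
                elif cross < 0:
                    n2 += 1
            # skip to when the particle has fully left the gate
            while j < n and d[j] <= gate_radius:
                j += 1
            k = j
    return DirectionCounts(n1, n2)


# ---------------------------------------------------------------------------
# Loop detection
# ---------------------------------------------------------------------------

@dataclass
class LoopRecord:
    """A closed path with chirality, enclosed charge and defect counts.

    For loops enclosing only ±1/2 defects the bookkeeping identity
    enclosed_charge = (n_plus − n_minus)/2 holds; polar loops in a nematic
    must enclose total charge +1, i.e. two more +1/2 than −1/2 defects.
    """

    points: np.ndarray
    chirality: str  # "CCW" (signed area > 0 in the image frame) or "CW"
    signed_area: float
    enclosed_charge: float | None = None
    n_plus: int = 0
    n_minus: int = 0


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _reversal_fraction(fld: DirectorField, loop_pts: np.ndarray) -> float | None:
    """Fraction of loop samples whose tangent sits on the minority alignment
    branch of the (continuously transported) director; None if sampling
    fails."""
    from .fields import _wrap_half_pi

    try:
        phi = fld.sample(loop_pts[:-1])
    except Exception:
        return None
    seg = np.diff(loop_pts, axis=0)
    tang = np.arctan2(seg[:, 1], seg[:, 0])
    # parallel-transport the director angle along the loop (lift mod π → R)
    psi = np.empty_like(phi)
    psi[0] = phi[0]
    for k in range(1, len(phi)):
        psi[k] = psi[k - 1] + _wrap_half_pi(phi[k] - psi[k - 1])
    sign = np.sign(np.cos(tang - psi))
    pos = np.mean(sign > 0)
    return float(min(pos, 1.0 - pos))


def _path_points(path) -> np.ndarray:
    if isinstance(path, Trajectory):
        return path.positions()
    if hasattr(path, "points"):
        return np.asarray(path.points, dtype=float)
    return np.asarray(path, dtype=float)


def detect_loops(
    paths,
    fld: DirectorField | None = None,
    defects: list[Defect] | None = None,
    closure_tol: float = 1.0,
    direction_agreement: float = float(np.cos(np.pi / 4)),
    min_circumference: float | None = None,
    require_polar: bool = True,
    max_reversal_fraction: float = 0.02,
) -> list[LoopRecord]:
    """Find closed circuits in trajectories or streamlines.

    A loop is the segment between a point and a later revisit within
    ``closure_tol`` whose travel directions agree above
    ``direction_agreement`` and whose circumference exceeds
    ``min_circumference`` (default 10× the closure tolerance). Per path, the
    smallest such circuit (one orbit rather than a multi-wound composite) is
    reported. Chirality is the sign of the shoelace area; if a director
    field is given, the enclosed topological charge is the winding number
    along the positively oriented loop, and given ground-truth/detected
    defects the enclosed ±1/2 counts come from point-in-polygon tests.

    Polar loops — circuits along which the motion stays on one nematic
    alignment branch (a full 2π turn of the heading) — are the loops that
    must enclose total charge +1. With ``require_polar`` and a field given,
    circuits whose tangent flips its alignment branch relative to the
    transported director for more than ``max_reversal_fraction`` of their
    samples (reversal artefacts from noise kicks near cores) are discarded.
    """
    if min_circumference is None:
        min_circumference = 10.0 * closure_tol
    records: list[LoopRecord] = []
    for path in paths:
        pts = _path_points(path)
        if len(pts) < 4:
            continue
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg_len)])
        with np.errstate(invalid="ignore", divide="ignore"):
            dirs = seg / np.maximum(seg_len[:, None], 1e-300)
        best = None
        cell = max(closure_tol, 1e-6)
        bins: dict[tuple[int, int], list[int]] = {}
        for idx in range(len(pts) - 1):  # use segment start points
            key = (int(pts[idx, 0] // cell), int(pts[idx, 1] // cell))
            p = pts[idx]
            for dxk in (-1, 0, 1):
                for dyk in (-1, 0, 1):
                    for j in bins.get((key[0] + dxk, key[1] + dyk), ()):
                        if arc[idx] - arc[j] < min_circumference:
                            continue
                        if np.linalg.norm(pts[j] - p) > closure_tol:
                            continue
                        if dirs[j] @ dirs[idx] < direction_agreement:
                            continue
                        if best is None or (arc[idx] - arc[j]) < best[2]:
                            best = (j, idx, arc[idx] - arc[j])
            bins.setdefault(key, []).append(idx)
        if best is None:
            continue
        j, i, _ = best
        loop_pts = np.vstack([pts[j : i + 1], pts[j : j + 1]])
        area = _signed_area(loop_pts[:-1])
        rec = LoopRecord(loop_pts, "CCW" if area > 0 else "CW", area)
        if fld is not None and require_polar:
            rev = _reversal_fraction(fld, loop_pts)
            if rev is None or rev > max_reversal_fraction:
                continue
        if fld is not None:
            oriented = loop_pts if area > 0 else loop_pts[::-1]
            try:
                rec.enclosed_charge = winding_number(fld, oriented)
            except Exception:
                rec.enclosed_charge = None
        if defects:
            poly = MplPath(loop_pts[:-1])
            inside = poly.contains_points(np.array([d.position for d in defects]))
            charges = np.array([d.charge for d in defects])
            rec.n_plus = int(np.sum(inside & (charges > 0)))
            rec.n_minus = int(np.sum(inside & (charges < 0)))
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Edge currents under confinement
# ---------------------------------------------------------------------------

@dataclass
class EdgeStats:
    """Per-frame chirality census of particles in the edge band.

    ``cw_minus_ccw`` counts clockwise-moving minus counterclockwise-moving
    particles within ``band`` of the confinement radius ("CW" means negative
    tangential sign, matching the loop chirality convention).
    ``mean_radius`` / ``std_radius`` are taken over all particles, per frame;
    the by-group arrays split particles by their *initial* handedness.
    """

    time: np.ndarray
    cw_minus_ccw: np.ndarray
    n_band: np.ndarray
    mean_radius: np.ndarray
    std_radius: np.ndarray
    group_mean_radius: dict
    empty: bool = False


def edge_stats(
    trajectories: list[Trajectory],
    radius: float,
    band: float | None = None,
    center: tuple[float, float] | None = None,
) -> EdgeStats:
    """Chirality and radial statistics of confined trajectories.

    For every frame, particles within ``band`` (default 0.15·R) of the rim
    are classified by the sign of their tangential velocity
    (cross(r̂, v): positive → CCW, negative → CW) and counted as CW − CCW.
    Mean distance from the centre is reported per frame, overall and split by
    each particle's initial handedness (the Fig.-style "started CW /
    started CCW" groups).
    """
    if band is None:
        band = 0.15 * radius
    if center is None:
        xs0 = np.mean([tr.x[0] for tr in trajectories])
        ys0 = np.mean([tr.y[0] for tr in trajectories])
        center = (float(xs0), float(ys0))
    n_frames = min(len(tr) for tr in trajectories)
    X = np.stack([tr.x[:n_frames] for tr in trajectories])
    Y = np.stack([tr.y[:n_frames] for tr in trajectories])
    t = trajectories[0].t[:n_frames]
    rx = X - center[0]
    ry = Y - center[1]
    rr = np.hypot(rx, ry)
    vx = np.gradient(X, axis=1)
    vy = np.gradient(Y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tang = (rx * vy - ry * vx) / np.maximum(rr, 1e-12)
    in_band = rr >= (radius - band)
    if not in_band.any():
        return EdgeStats(t, np.zeros(n_frames), np.zeros(n_frames, int),
                         rr.mean(axis=0), rr.std(axis=0), {}, empty=True)
    ccw = in_band & (tang > 0)
    cw = in_band & (tang < 0)
    cw_minus_ccw = cw.sum(axis=0) - ccw.sum(axis=0)
    init_sign = np.sign(tang[:, 0])
    groups = {}
    for label, sel in (("CCW", init_sign > 0), ("CW", init_sign < 0)):
        if sel.any():
            groups[label] = {
                "mean": rr[sel].mean(axis=0),
                "std": rr[sel].std(axis=0),
                "n": int(sel.sum()),
            }
    return EdgeStats(
        t,
        cw_minus_ccw.astype(int),
        in_band.sum(axis=0).astype(int),
        rr.mean(axis=0),
        rr.std(axis=0),
        groups,
    )
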