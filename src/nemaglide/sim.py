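"""Stochastic simulation of self-propelled gliding particles in a static
nematic field.

Each non-interacting point particle moves persistently at fixed speed v along
its heading u = (cos θ, sin θ) and receives an aligning torque from the local
director φ(r):

    dr/dt = v u
    dθ/dt = A sin[2(φ(r) − θ)] + sqrt(2 v / L_p) ξ(t)

with ξ Gaussian white noise of unit variance. The noise prefactor fixes the
path persistence length to L_p when the torque is off; the torque is
π-periodic in (φ − θ), respecting the nematic (head–tail) symmetry of the
field. Integration is Euler–Maruyama with the heading updated before the
position, so every step displaces the particle by exactly v·dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np

from .fields import DirectorField, sample_director, OutOfDomainError

__all__ = [
    "AgentState",
    "SimParams",
    "Trajectory",
    "PersistenceEstimate",
    "step",
    "simulate",
    "occupancy_image",
    "estimate_persistence",
]


@dataclass
class AgentState:
    """Position (µm) and full-circle heading θ ∈ [0, 2π) of one agent."""

    position: np.ndarray
    theta: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.theta = float(np.mod(self.theta, 2 * np.pi))

    @property
    def u(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])


@dataclass
class SimParams:
    """Simulation parameters.

    speed v in µm/s (default 0.1, the measured mean gliding speed);
    alignment_rate A in rad/s; persistence_length L_p in µm (default 100;
    ``np.inf`` disables noise); dt in s; boundary one of {"reflect", "slide"}.
    The stability guard A·dt < 0.2 keeps the explicit torque update well
    inside the alignment relaxation time.
    """

    speed: float = 0.1
    alignment_rate: float = 0.03
    persistence_length: float = 100.0
    dt: float = 0.1
    n_steps: int = 1000
    seed: int = 0
    boundary: str = "reflect"

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.alignment_rate < 0:
            raise ValueError("alignment_rate must be non-negative")
        if self.alignment_rate * self.dt >= 0.2:
            raise ValueError("stability guard: A*dt must be < 0.2")
        if self.boundary not in ("reflect", "slide"):
            raise ValueError("boundary must be 'reflect' or 'slide'")

    @property
    def noise_amplitude(self) -> float:
        """Std of the per-step angular kick, sqrt(2 v dt / L_p)."""
        if np.isinf(self.persistence_length):
            return 0.0
        return float(np.sqrt(2 * self.speed * self.dt / self.persistence_length))


@dataclass
class Trajectory:
    """Time-ordered samples (t, x, y, θ) of one agent."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    particle_id: int = 0

    def positions(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)

    @property
    def u(self) -> np.ndarray:
        return np.stack([np.cos(self.theta), np.sin(self.theta)], axis=1)

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _torque_kick(phi, theta, A, dt):
    return A * np.sin(2.0 * (phi - theta)) * dt


def _reflect_rect(x, y, theta, w, h):
    """Specular reflection of headings for agents leaving a rectangle."""
    out_x = (x < 0) | (x > w)
    out_y = (y < 0) | (y > h)
    theta = np.where(out_x, np.pi - theta, theta)
    theta = np.where(out_y, -theta, theta)
    return np.mod(theta, 2 * np.pi)


def _slide_rect(x, y, theta, w, h):
    out_x = (x < 0) | (x > w)
    out_y = (y < 0) | (y > h)
    # project heading on the wall tangent: vertical wall keeps sin, horizontal keeps cos
    theta = np.where(out_x, np.where(np.sin(theta) >= 0, np.pi / 2, -np.pi / 2), theta)
    theta = np.where(out_y, np.where(np.cos(theta) >= 0, 0.0, np.pi), theta)
    return np.mod(theta, 2 * np.pi)


def _disc_adjust(x, y, theta, cx, cy, R, mode):
    """Heading update for agents whose tentative move exits the disc."""
    rx, ry = x - cx, y - cy
    rr = np.hypot(rx, ry)
    out = rr > R
    if not np.any(out):
        return theta, out
    nx_, ny_ = rx / np.maximum(rr, 1e-12), ry / np.maximum(rr, 1e-12)
    ux, uy = np.cos(theta), np.sin(theta)
    dot = ux * nx_ + uy * ny_
    if mode == "reflect":
        vx = ux - 2 * dot * nx_
        vy = uy - 2 * dot * ny_
    else:  # slide: remove the outward normal component, renormalize
        vx = ux - dot * nx_
        vy = uy - dot * ny_
        nrm = np.hypot(vx, vy)
        tiny = nrm < 1e-9
        # heading exactly radial: fall back to reflection (turn around)
        vx = np.where(tiny, -ux, vx / np.maximum(nrm, 1e-9))
        vy = np.where(tiny, -uy, vy / np.maximum(nrm, 1e-9))
    theta_new = np.arctan2(vy, vx)
    return np.where(out, np.mod(theta_new, 2 * np.pi), theta), out


def _advance(x, y, theta, phi, noise, fld: DirectorField, p: SimParams):
    """One vectorized Euler–Maruyama step; returns updated (x, y, theta).

    The heading is updated first (torque + noise), then the position moves by
    exactly v·dt along the new heading; moves that would exit the domain are
    re-directed by the boundary handler (reflect/slide) before moving.
    """
    theta = theta + _torque_kick(phi, theta, p.alignment_rate, p.dt) + noise
    theta = np.mod(theta, 2 * np.pi)
    step_len = p.speed * p.dt
    for _attempt in range(3):
        nx = x + step_len * np.cos(theta)
        ny = y + step_len * np.sin(theta)
        if fld.confinement_radius is not None:
            cx, cy = fld.confinement_center
            theta_adj, out = _disc_adjust(nx, ny, theta, cx, cy, fld.confinement_radius, p.boundary)
        else:
            w, h = fld.extent
            out = (nx < 0) | (nx > w) | (ny < 0) | (ny > h)
            if p.boundary == "reflect":
                theta_adj = np.where(out, _reflect_rect(nx, ny, theta, w, h), theta)
            else:
                theta_adj = np.where(out, _slide_rect(nx, ny, theta, w, h), theta)
        if not np.any(out):
            break
        theta = theta_adj
    # final move; pathological leftovers (e.g. corner trap) turn around
    nx = x + step_len * np.cos(theta)
    ny = y + step_len * np.sin(theta)
    if fld.confinement_radius is not None:
        cx, cy = fld.confinement_center
        still_out = np.hypot(nx - cx, ny - cy) > fld.confinement_radius
    else:
        w, h = fld.extent
        still_out = (nx < 0) | (nx > w) | (ny < 0) | (ny > h)
    if np.any(still_out):
        theta = np.where(still_out, np.mod(theta + np.pi, 2 * np.pi), theta)
        nx = x + step_len * np.cos(theta)
        ny = y + step_len * np.sin(theta)
    return nx, ny, theta


def step(state: AgentState, fld: DirectorField, params: SimParams, rng) -> AgentState:
    """Advance a single agent by one timestep (Euler–Maruyama).

    θ' = θ + A sin(2(φ(r) − θ)) dt + sqrt(2 v dt / L_p) N(0,1), then
    r' = r + v (cos θ', sin θ') dt; the displacement norm is exactly v·dt.
    """
    phi = sample_director(fld, state.position)
    noise = params.noise_amplitude * rng.standard_normal()
    x, y, theta = _advance(
        np.atleast_1d(state.position[0]),
        np.atleast_1d(state.position[1]),
        np.atleast_1d(state.theta),
        np.atleast_1d(phi),
        np.atleast_1d(noise),
        fld,
        params,
    )
    return AgentState(np.array([x[0], y[0]]), theta[0])


# ---------------------------------------------------------------------------
# Full simulations
# ---------------------------------------------------------------------------

def _initial_states(fld: DirectorField, n_particles: int, init, seed):
    if isinstance(init, str):
        if init != "uniform-random":
            raise ValueError("init must be 'uniform-random' or an explicit list")
        w, h = fld.extent
        xs = np.empty(n_particles)
        ys = np.empty(n_particles)
        thetas = np.empty(n_particles)
        for i in range(n_particles):
            # a dedicated stream per particle: adding particles never shifts
            # the initial conditions (or noise) of existing ones
            rng = np.random.default_rng([seed, 0x1A17, i])
            guard = 0
            while True:
                guard += 1
                if guard > 100000:
                    raise ValueError("could not place particle on valid ground")
                x = rng.uniform(0, w)
                y = rng.uniform(0, h)
                if fld.confinement_radius is not None:
                    cx, cy = fld.confinement_center
                    if np.hypot(x - cx, y - cy) > fld.confinement_radius * 0.98:
                        continue
                if fld.contains(np.array([x, y])):
                    break
            xs[i], ys[i] = x, y
            thetas[i] = rng.uniform(0, 2 * np.pi)
        return xs, ys, thetas
    init = list(init)
    if len(init) != n_particles:
        raise ValueError("explicit init list length must equal n_particles")
    xs = np.array([s[0] for s in init], dtype=float)
    ys = np.array([s[1] for s in init], dtype=float)
    thetas = np.mod(np.array([s[2] for s in init], dtype=float), 2 * np.pi)
    return xs, ys, thetas


def simulate(
    fld: DirectorField,
    n_particles: int,
    params: SimParams,
    init="uniform-random",
) -> list[Trajectory]:
    """Simulate ``n_particles`` non-interacting agents on a static field.

    Each particle consumes its own counter-based RNG stream derived from the
    master seed (``default_rng([seed, particle_id])``), so trajectories are
    bit-reproducible and unchanged by the presence of other particles.
    ``init`` is ``"uniform-random"`` (positions drawn on valid ground with a
    dedicated stream) or an explicit list of (x, y, θ) tuples.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    if not fld.mask.any():
        raise ValueError("field is fully masked; nowhere to glide")
    xs, ys, thetas = _initial_states(fld, n_particles, init, params.seed)
    n_steps = params.n_steps
    amp = params.noise_amplitude
    noise = np.zeros((n_particles, n_steps))
    if amp > 0:
        for i in range(n_particles):
            noise[i] = amp * np.random.default_rng([params.seed, i]).standard_normal(n_steps)
    traj_x = np.empty((n_particles, n_steps + 1))
    traj_y = np.empty((n_particles, n_steps + 1))
    traj_th = np.empty((n_particles, n_steps + 1))
    traj_x[:, 0], traj_y[:, 0], traj_th[:, 0] = xs, ys, thetas
    pos = np.stack([xs, ys], axis=1)
    need_phi = params.alignment_rate > 0
    for k in range(n_steps):
        if need_phi:
            phi = sample_director(fld, pos)
        else:
            phi = thetas  # torque term vanishes when A = 0
        xs, ys, thetas = _advance(xs, ys, thetas, phi, noise[:, k], fld, params)
        pos[:, 0], pos[:, 1] = xs, ys
        traj_x[:, k + 1], traj_y[:, k + 1], traj_th[:, k + 1] = xs, ys, thetas
    t = np.arange(n_steps + 1) * params.dt
    return [
        Trajectory(t, traj_x[i].copy(), traj_y[i].copy(), traj_th[i].copy(), particle_id=i)
        for i in range(n_particles)
    ]


def occupancy_image(
    trajectories: list[Trajectory], shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Count how many trajectory samples fall on each pixel.

    The sum of the image equals the total number of in-frame samples; with
    all trajectories inside the grid the count is conserved exactly.
    """
    rows, cols = shape
    img = np.zeros((rows, cols), dtype=np.int64)
    for tr in trajectories:
        j = np.clip(np.round(tr.x / pixel_size).astype(int), 0, cols - 1)
        i = np.clip(np.round(tr.y / pixel_size).astype(int), 0, rows - 1)
        np.add.at(img, (i, j), 1)
    return img


# ---------------------------------------------------------------------------
# Persistence-length estimation
# ---------------------------------------------------------------------------

@dataclass
class PersistenceEstimate:
    """Point estimate of L_p (µm) with a bootstrap 95% interval."""

    value: float
    ci_low: float
    ci_high: float
    reliable: bool
    correlation: np.ndarray = _dc_field(default=None, repr=False)  # type: ignore[assignment]
    arc_length: np.ndarray = _dc_field(default=None, repr=False)  # type: ignore[assignment]


def _direction_autocorrelation(theta: np.ndarray, max_lag: int) -> np.ndarray:
    """⟨u(t+k)·u(t)⟩ for lags 0..max_lag via FFT of e^{iθ}."""
    z = np.exp(1j * theta)
    n = len(z)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.fft(z, nfft)
    acf = np.fft.ifft(f * np.conj(f))[: max_lag + 1].real
    counts = n - np.arange(max_lag + 1)
    return acf / counts


def estimate_persistence(
    trajectories: list[Trajectory],
    speed: float | None = None,
    dt: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> PersistenceEstimate:
    """Estimate the path persistence length from torque-free trajectories.

    Fits ⟨u(s)·u(0)⟩ = exp(−s/L_p) versus arc length s (particles move at
    constant speed, so s = v·Δt). The fit is a least-squares line through the
    origin on log C over the window C ∈ [0.2, 1); the 95% interval comes from
    bootstrap resampling of particles. Runs whose correlation never decays
    into the fit window (e.g. noise off, or paths much shorter than L_p) are
    flagged unreliable.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    tr0 = trajectories[0]
    if dt is None:
        dt = float(tr0.t[1] - tr0.t[0])
    if speed is None:
        speed = float(np.hypot(tr0.x[1] - tr0.x[0], tr0.y[1] - tr0.y[0]) / dt)
    n = len(tr0.theta)
    max_lag = n - 1
    acfs = np.stack([_direction_autocorrelation(tr.theta, max_lag) for tr in trajectories])
    s = np.arange(max_lag + 1) * speed * dt

    def fit_one(acf):
        window = (acf >= 0.2) & (s > 0)
        if window.sum() < 3 or acf[window].min() > 0.5:
            return np.nan
        slope = np.sum(s[window] * np.log(acf[window])) / np.sum(s[window] ** 2)
        if slope >= -1e-12:
            return np.nan
        return -1.0 / slope

    mean_acf = acfs.mean(axis=0)
    value = fit_one(mean_acf)
    rng = np.random.default_rng(seed)
    boots = []
    m = len(trajectories)
    for _ in range(n_boot):
        idx = rng.integers(0, m, m)
        boots.append(fit_one(acfs[idx].mean(axis=0)))
    boots = np.array([b for b in boots if np.isfinite(b)])
    reliable = np.isfinite(value) and len(boots) > n_boot // 2
    if not reliable:
        return PersistenceEstimate(np.inf, np.inf, np.inf, False, mean_acf, s)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PersistenceEstimate(float(value), float(lo), float(hi), True, mean_acf, s)
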