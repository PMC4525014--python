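"""Deterministic physics and scoring for the semi-virtual skittles throwing task.

The task: a ball tethered to a central post is thrown with a lever and
travels on an elliptic path around the post.  The player tries to pass the
ball within a threshold distance of a circular target placed up and to the
right of the post.  Ball flight is modelled as a two-dimensional isotropic
harmonic oscillator centred on the post, which yields exactly the centred
elliptic orbits of the classic skittles model: per axis

    u(t) = u0 * cos(w t) + (v0 / w) * sin(w t)

with angular frequency ``w`` (rad/s).  Release angle and angular velocity of
the lever fully determine the flight; the outcome of a throw is the minimal
distance between the ball path and the target centre, reached at the moment
of knowledge of results (KR).

Conventions: positions in metres in the screen plane with the post at the
origin; lever angle theta in degrees, counter-clockwise positive, 0 deg
along +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize

__all__ = [
    "TaskGeometry",
    "ReleaseState",
    "Trajectory",
    "TrialOutcome",
    "SolutionMap",
    "trajectory_to_tsv",
    "release_from_lever",
    "simulate_trajectory",
    "score_trial",
    "score_releases",
    "calibrate_omega",
    "map_solution_space",
    "hit_probability",
    "default_geometry",
    "find_aim_point",
    "MIN_VALID_ANGULAR_VELOCITY",
]

#: a throw only counts as a valid trial above this lever angular velocity (deg/s)
MIN_VALID_ANGULAR_VELOCITY = 50.0


@dataclass(frozen=True)
class TaskGeometry:
    """Spatial constants of the virtual work space plus the flight dynamics.

    Defaults reproduce the standard layout: a 25 cm post at the origin, a
    5 cm target centred 35 cm right / 100 cm above the post, a 40 cm lever
    pivoting below the post, and a 10 cm hit threshold (target radius plus
    ball radius).
    """

    post_center: tuple[float, float] = (0.0, 0.0)
    post_radius: float = 0.25
    target_center: tuple[float, float] = (0.35, 1.00)
    target_radius: float = 0.05
    ball_radius: float = 0.05
    lever_length: float = 0.40
    pivot: tuple[float, float] = (0.0, -0.90)
    omega: float = 4.0
    hit_threshold: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.hit_threshold is None:
            object.__setattr__(
                self, "hit_threshold", self.target_radius + self.ball_radius
            )
        for name in ("post_radius", "target_radius", "ball_radius",
                     "lever_length", "omega", "hit_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        sep = math.hypot(self.target_center[0] - self.post_center[0],
                         self.target_center[1] - self.post_center[1])
        if sep <= self.post_radius + self.target_radius:
            raise ValueError("target must lie outside the post disc")

    @property
    def period(self) -> float:
        """Orbital period 2*pi/omega of the ball dynamics (s)."""
        return 2.0 * math.pi / self.omega


@dataclass(frozen=True)
class ReleaseState:
    """Ball state at the moment of release (lever tip kinematics)."""

    position: tuple[float, float]
    velocity: tuple[float, float]
    release_angle: float  # deg
    release_angular_velocity: float  # deg/s


@dataclass
class Trajectory:
    """Sampled ball flight from release, possibly truncated at the post."""

    times: np.ndarray  # (n,) seconds from release, starting at 0
    positions: np.ndarray  # (n, 2) metres
    truncated_at_post: bool = False
    truncation_time: float | None = None
    release: "ReleaseState | None" = None  # enables analytic refinement
    omega: float | None = None


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one throw: minimal target distance, its time, and the label."""

    min_distance: float
    t_kr: float
    label: str  # 'hit' | 'error' | 'post_hit'


def trajectory_to_tsv(trajectory: Trajectory, path) -> None:
    """Export a sampled flight as a (t, x, y) TSV file."""
    import pandas as pd

    pd.DataFrame({"t": trajectory.times,
                  "x": trajectory.positions[:, 0],
                  "y": trajectory.positions[:, 1]}).to_csv(
        path, sep="\t", index=False)


def release_from_lever(theta: float, theta_dot: float,
                       geometry: TaskGeometry) -> ReleaseState:
    """Ball release state from lever angle (deg) and angular velocity (deg/s).

    The ball sits at the lever tip: position ``pivot + L (cos t, sin t)``,
    velocity tangential, ``L * tdot_rad * (-sin t, cos t)``.
    """
    th = math.radians(theta)
    thd = math.radians(theta_dot)
    L = geometry.lever_length
    px, py = geometry.pivot
    pos = (px + L * math.cos(th), py + L * math.sin(th))
    vel = (-L * thd * math.sin(th), L * thd * math.cos(th))
    return ReleaseState(pos, vel, theta, theta_dot)


def simulate_trajectory(release: ReleaseState, geometry: TaskGeometry,
                        duration: float | None = None,
                        dt: float = 1e-3) -> Trajectory:
    """Closed-form ball flight sampled at ``dt``, truncated at the post.

    ``duration`` defaults to one orbital period; it must cover at least one
    period so that the scoring step sees the full closest approach.  The ball
    is stopped at the first sample where its centre enters the post disc.
    """
    if duration is None:
        duration = geometry.period
    if duration < geometry.period - 1e-12:
        raise ValueError("duration must cover one orbital period 2*pi/omega")
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    r0 = np.asarray(release.position, float)
    v0 = np.asarray(release.velocity, float)
    if not (np.all(np.isfinite(r0)) and np.all(np.isfinite(v0))):
        raise ValueError("non-finite release state")
    c = np.asarray(geometry.post_center, float)
    w = geometry.omega
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    u0 = r0 - c
    pos = (u0[None, :] * np.cos(w * t)[:, None]
           + (v0[None, :] / w) * np.sin(w * t)[:, None]) + c
    d_post = np.hypot(pos[:, 0] - c[0], pos[:, 1] - c[1])
    inside = np.nonzero(d_post <= geometry.post_radius)[0]
    if inside.size:
        k = int(inside[0])
        return Trajectory(t[: k + 1], pos[: k + 1], True, float(t[k]),
                          release, w)
    return Trajectory(t, pos, False, None, release, w)


def _parabolic_refine(tm1, t0, tp1, ym1, y0, yp1):
    """Vertex of the parabola through three points; falls back to the centre."""
    denom = (ym1 - 2.0 * y0 + yp1)
    if denom <= 0:
        return t0, y0
    dt = 0.5 * (tm1 - tp1) * (ym1 - yp1) / (2.0 * denom)
    # guard: vertex must stay inside the bracket
    h = tp1 - t0
    dt = float(np.clip(dt, -h, h))
    tv = t0 + dt
    # parabola value at the vertex (in y = squared distance)
    a = denom / (2.0 * h * h)
    b = (yp1 - ym1) / (2.0 * h)
    yv = y0 + b * dt + a * dt * dt
    return tv, yv


def _golden_refine_analytic(u0, v0, w, tx, ty, lo, hi, iters: int = 48):
    """Vectorised golden-section minimisation of the analytic squared target
    distance over per-throw brackets [lo, hi] (times from release)."""
    u0 = np.atleast_2d(u0)
    v0 = np.atleast_2d(v0)
    lo = np.atleast_1d(np.asarray(lo, float)).copy()
    hi = np.atleast_1d(np.asarray(hi, float)).copy()

    def d2(t):
        ct, st = np.cos(w * t), np.sin(w * t)
        x = u0[:, 0] * ct + (v0[:, 0] / w) * st
        y = u0[:, 1] * ct + (v0[:, 1] / w) * st
        return (x - tx) ** 2 + (y - ty) ** 2

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = d2(c), d2(d)
    for _ in range(iters):
        take_c = fc < fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = d2(c), d2(d)
    t_star = 0.5 * (a + b)
    return t_star, d2(t_star)


def score_trial(trajectory: Trajectory, geometry: TaskGeometry) -> TrialOutcome:
    """Minimal target distance over the (first-period or truncated) flight.

    The discrete argmin of squared distance is refined within its one-sample
    bracket — analytically (golden-section on the closed-form flight) when
    the trajectory carries its release state, by local parabolic
    interpolation otherwise; ties break to the earliest time.  A throw
    stopped by the post is labelled ``post_hit`` and counts as an error
    downstream.
    """
    if trajectory.times.size == 0:
        raise ValueError("empty trajectory")
    tx, ty = geometry.target_center
    d2 = ((trajectory.positions[:, 0] - tx) ** 2
          + (trajectory.positions[:, 1] - ty) ** 2)
    i = int(np.argmin(d2))  # argmin returns the first minimum -> earliest time
    t = trajectory.times
    if trajectory.release is not None and 0 < i < len(t) - 1:
        c = np.asarray(geometry.post_center, float)
        u0 = np.asarray(trajectory.release.position, float) - c
        v0 = np.asarray(trajectory.release.velocity, float)
        ts, d2s = _golden_refine_analytic(
            u0, v0, trajectory.omega or geometry.omega,
            tx - c[0], ty - c[1], t[i - 1], t[i + 1])
        t_kr, d2min = float(ts[0]), float(d2s[0])
    elif 0 < i < len(t) - 1:
        t_kr, d2min = _parabolic_refine(t[i - 1], t[i], t[i + 1],
                                        d2[i - 1], d2[i], d2[i + 1])
    else:
        t_kr, d2min = float(t[i]), float(d2[i])
    min_distance = math.sqrt(max(d2min, 0.0))
    if trajectory.truncated_at_post:
        label = "post_hit"
    elif min_distance < geometry.hit_threshold:
        label = "hit"
    else:
        label = "error"
    return TrialOutcome(min_distance, float(t_kr), label)


def score_releases(thetas, theta_dots, geometry: TaskGeometry,
                   dt: float = 1e-3):
    """Vectorised simulate+score for arrays of lever release states.

    Returns ``(min_distance, t_kr, label_code)`` arrays where the label code
    is 0 = hit, 1 = error, 2 = post_hit.  Equivalent to calling
    :func:`simulate_trajectory` and :func:`score_trial` per throw; used by
    the cohort generator and the solution-space mapper where thousands of
    throws are scored at once.
    """
    thetas = np.atleast_1d(np.asarray(thetas, float))
    theta_dots = np.atleast_1d(np.asarray(theta_dots, float))
    # bound the working set: process large batches in chunks
    max_chunk = 4000
    if thetas.size > max_chunk:
        parts = [score_releases(thetas[k:k + max_chunk],
                                theta_dots[k:k + max_chunk], geometry, dt)
                 for k in range(0, thetas.size, max_chunk)]
        return tuple(np.concatenate([p[j] for p in parts]) for j in range(3))
    L = geometry.lever_length
    th = np.radians(thetas)
    thd = np.radians(theta_dots)
    px, py = geometry.pivot
    cx, cy = geometry.post_center
    x0 = px + L * np.cos(th) - cx
    y0 = py + L * np.sin(th) - cy
    vx0 = -L * thd * np.sin(th)
    vy0 = L * thd * np.cos(th)
    w = geometry.omega
    n = int(round(geometry.period / dt)) + 1
    t = np.arange(n) * dt
    ct, st = np.cos(w * t), np.sin(w * t)
    # (n_throws, n_times)
    x = x0[:, None] * ct[None, :] + (vx0 / w)[:, None] * st[None, :]
    y = y0[:, None] * ct[None, :] + (vy0 / w)[:, None] * st[None, :]
    inside = (x * x + y * y) <= geometry.post_radius ** 2
    truncated = inside.any(axis=1)
    # mask out all samples at/after first post contact (keep the contact sample)
    after = np.cumsum(inside, axis=1) - inside.astype(int) > 0
    tx = geometry.target_center[0] - cx
    ty = geometry.target_center[1] - cy
    d2 = (x - tx) ** 2 + (y - ty) ** 2
    d2m = np.where(after, np.inf, d2)
    i = np.argmin(d2m, axis=1)
    rows = np.arange(len(thetas))
    interior = (i > 0) & (i < n - 1) & ~after[rows, np.minimum(i + 1, n - 1)]
    d2c = d2m[rows, i]
    t_kr = t[i].astype(float)
    d2min = d2c.copy()
    if interior.any():
        r = rows[interior]
        ii = i[interior]
        u0 = np.stack([x0[r], y0[r]], axis=1)
        v0 = np.stack([vx0[r], vy0[r]], axis=1)
        ts, d2s = _golden_refine_analytic(u0, v0, w, tx, ty,
                                          t[ii - 1], t[ii + 1])
        t_kr[r] = ts
        d2min[r] = d2s
    min_distance = np.sqrt(np.maximum(d2min, 0.0))
    label = np.where(truncated, 2,
                     np.where(min_distance < geometry.hit_threshold, 0, 1))
    return min_distance, t_kr, label


def calibrate_omega(geometry: TaskGeometry, representative_releases,
                    target_t_kr: float,
                    bracket: tuple[float, float] = (1.0, 20.0)) -> float:
    """Angular frequency for which the median KR latency matches a target.

    Solves ``median t_kr(omega) = target_t_kr`` over the representative
    release set by a bracketed root search (the median latency decreases
    monotonically in ``omega`` over the search range).
    """
    releases = list(representative_releases)
    if not releases:
        raise ValueError("empty release set")
    if not target_t_kr > 0:
        raise ValueError("target_t_kr must be > 0")
    thetas = np.array([r.release_angle for r in releases])
    tdots = np.array([r.release_angular_velocity for r in releases])

    def median_tkr(w):
        g = replace(geometry, omega=w, hit_threshold=geometry.hit_threshold)
        _, t_kr, _ = score_releases(thetas, tdots, g)
        return float(np.median(t_kr))

    lo, hi = bracket
    f_lo = median_tkr(lo) - target_t_kr
    f_hi = median_tkr(hi) - target_t_kr
    if f_lo * f_hi > 0:
        raise RuntimeError("calibration failure: no bracketing interval for omega")
    return float(optimize.brentq(lambda w: median_tkr(w) - target_t_kr,
                                 lo, hi, xtol=1e-6))


@dataclass
class SolutionMap:
    """Exhaustive outcome map over a (theta, theta_dot) release grid."""

    theta_grid: np.ndarray  # (nt,) deg
    theta_dot_grid: np.ndarray  # (nd,) deg/s
    labels: np.ndarray  # (nt, nd) 0 = hit, 1 = error, 2 = post_hit
    min_distance: np.ndarray  # (nt, nd) m
    t_kr: np.ndarray  # (nt, nd) s
    valid: np.ndarray  # (nt, nd) bool, theta_dot above the validity floor

    LABELS = ("hit", "error", "post_hit")


def map_solution_space(geometry: TaskGeometry, theta_grid,
                       theta_dot_grid) -> SolutionMap:
    """Simulate every grid combination of release angle and velocity.

    Cells at or below the 50 deg/s lever-velocity floor are flagged invalid
    regardless of their simulated outcome (such throws would not count as
    trials).
    """
    theta_grid = np.asarray(theta_grid, float)
    theta_dot_grid = np.asarray(theta_dot_grid, float)
    if theta_grid.size == 0 or theta_dot_grid.size == 0:
        raise ValueError("grids must be non-empty")
    TH, TD = np.meshgrid(theta_grid, theta_dot_grid, indexing="ij")
    d, tk, lab = score_releases(TH.ravel(), TD.ravel(), geometry)
    shape = TH.shape
    valid = TD > MIN_VALID_ANGULAR_VELOCITY
    return SolutionMap(theta_grid, theta_dot_grid, lab.reshape(shape),
                       d.reshape(shape), tk.reshape(shape), valid)


def hit_probability(smap: SolutionMap, theta_mean: float, theta_sd: float,
                    theta_dot_mean: float, theta_dot_sd: float) -> float:
    """Probability that a normal release distribution lands in the hit region.

    Integrates the bivariate normal (independent axes) over the hit cells of
    the solution map by midpoint quadrature, conditioned on the throw being
    valid; used to predict a participant's expected hit rate from their
    release dispersion.
    """
    pt = np.exp(-0.5 * ((smap.theta_grid - theta_mean) / theta_sd) ** 2)
    pd = np.exp(-0.5 * ((smap.theta_dot_grid - theta_dot_mean) / theta_dot_sd) ** 2)
    wgt = np.outer(pt, pd)
    wgt = np.where(smap.valid, wgt, 0.0)
    total = wgt.sum()
    if total == 0:
        return 0.0
    return float(wgt[smap.labels == 0].sum() / total)


# representative "skilled throw" lever states used to calibrate the default
# dynamics: release angles around the upper-left of the swing with brisk
# angular velocities, the region where the hit manifold lives
def _representative_releases(geometry: TaskGeometry, omega_guess: float = 4.0,
                             max_n: int = 64):
    g = replace(geometry, omega=omega_guess, hit_threshold=geometry.hit_threshold)
    th = np.arange(150.0, 301.0, 3.0)
    td = np.arange(60.0, 601.0, 15.0)
    smap = map_solution_space(g, th, td)
    it, id_ = np.nonzero((smap.labels == 0) & smap.valid)
    if it.size == 0:
        raise RuntimeError("no hit region found at the calibration guess")
    step = max(1, it.size // max_n)
    return [release_from_lever(th[a], td[b], g)
            for a, b in zip(it[::step], id_[::step])]


@lru_cache(maxsize=4)
def _calibrated_omega(target_t_kr: float) -> float:
    base = TaskGeometry()
    rel = _representative_releases(base)
    w = calibrate_omega(base, rel, target_t_kr)
    # one refinement pass: re-pick representatives under the calibrated
    # dynamics so the hit set matches the final geometry
    rel = _representative_releases(base, omega_guess=w)
    return calibrate_omega(base, rel, target_t_kr)


def default_geometry(target_t_kr: float = 0.85) -> TaskGeometry:
    """Standard work-space geometry with omega calibrated so the typical KR
    latency of successful throws equals ``target_t_kr`` (default 0.85 s,
    the centre of the 817-910 ms range observed across real performers)."""
    return TaskGeometry(omega=_calibrated_omega(target_t_kr))


@lru_cache(maxsize=8)
def find_aim_point(geometry: TaskGeometry, t_kr_target: float = 0.85,
                   fine: bool = True) -> tuple[float, float]:
    """A central point of the hit region: the valid grid cell of minimal
    target distance among solutions whose KR latency is near ``t_kr_target``,
    refined on a locally finer grid.  Used as the default aiming point for
    simulated performers."""
    th = np.arange(150.0, 301.0, 2.0)
    td = np.arange(60.0, 601.0, 10.0)
    smap = map_solution_space(geometry, th, td)
    d = np.where(smap.valid, smap.min_distance, np.inf)
    d = np.where(np.abs(smap.t_kr - t_kr_target) < 0.10, d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    th0, td0 = th[i], td[j]
    if fine:
        th2 = np.linspace(th0 - 2, th0 + 2, 21)
        td2 = np.linspace(td0 - 10, td0 + 10, 21)
        smap2 = map_solution_space(geometry, th2, td2)
        d2 = np.where(smap2.valid, smap2.min_distance, np.inf)
        i2, j2 = np.unravel_index(np.argmin(d2), d2.shape)
        th0, td0 = th2[i2], td2[j2]
    return float(th0), float(td0)
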