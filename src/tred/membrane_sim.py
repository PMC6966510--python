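"""Synthetic-data generators for receptor-dynamics phenotyping.

The central model is hop diffusion in a compartmentalized ("corralled")
plasma membrane: a receptor performs Brownian motion with microscopic
diffusivity ``D_micro`` inside square compartments of side ``L_comp``
imposed by the cortical actin meshwork, and crosses a compartment
boundary only with probability ``p_hop`` per boundary encounter.  For a
square corral the long-lag MSD plateau equals ``L**2 / 3`` (two axes,
each contributing ``L**2 / 6`` for a uniform stationary distribution),
which is how confinement size is read off experimental MSD curves.

Also provided: a forward imaging model (integrated-Gaussian PSF spots on
a camera grid), a 3D membrane-then-inward internalization trajectory
generator, an actin z-stack phantom with a tunable cortical/basal
intensity ratio, and a wound-closure mask-series generator.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CorralParams",
    "Trajectory2D",
    "Trajectory3D",
    "OpticsParams",
    "ImageStack",
    "ZStackParams",
    "ZStack",
    "WoundSimParams",
    "MaskSeries",
    "simulate_corral_trajectory",
    "simulate_corral_ensemble",
    "render_movie",
    "simulate_internalization",
    "synth_actin_zstack",
    "apical_path_for_projection",
    "synth_wound_series",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CorralParams:
    """Parameters of the corral-confined / hop-diffusion simulator.

    Attributes
    ----------
    D_micro : float
        Microscopic (intra-compartment) diffusivity, µm²/s.
    L_comp : float
        Compartment side length in nm; ``np.inf`` means free diffusion.
    p_hop : float
        Probability of crossing a compartment boundary per boundary
        encounter (one encounter test per frame step), in [0, 1].
    dt : float
        Frame interval, s (default 0.05 s, i.e. 20 frames/s).
    n_steps : int
        Number of frames per trajectory (default 1200).
    sigma_loc : float
        Localization-noise SD per axis, nm (default 20).
    seed : int | None
        RNG seed; ``None`` draws entropy from the OS.
    """

    D_micro: float
    L_comp: float = np.inf
    p_hop: float = 0.0
    dt: float = 0.05
    n_steps: int = 1200
    sigma_loc: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.D_micro >= 0):
            raise ValueError("D_micro must be >= 0")
        if not (self.L_comp > 0):
            raise ValueError("L_comp must be > 0 (np.inf for free diffusion)")
        if not (0.0 <= self.p_hop <= 1.0):
            raise ValueError("p_hop must be in [0, 1]")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not (self.sigma_loc >= 0):
            raise ValueError("sigma_loc must be >= 0")


@dataclass
class Trajectory2D:
    """Time-ordered localizations of one receptor complex (2D)."""

    track_id: int
    frames: np.ndarray  # int, 0-based, strictly increasing
    t: np.ndarray  # s
    x: np.ndarray  # µm
    y: np.ndarray  # µm
    sigma_loc: float = np.nan  # localization SD used/estimated, nm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("trajectory must have length >= 2")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        for arr in (self.t, self.x, self.y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class Trajectory3D(Trajectory2D):
    """2D trajectory plus axial position; z increases into the cell."""

    z: np.ndarray = field(default_factory=lambda: np.empty(0))  # µm
    z_mem: float = np.nan  # membrane reference plane, µm

    def __post_init__(self) -> None:
        super().__post_init__()
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != self.x.shape:
            raise ValueError("z must match x/y in length")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite")


@dataclass(frozen=True)
class OpticsParams:
    """Camera / PSF parameters for the forward imaging model."""

    pixel_size: float = 107.0  # nm per pixel
    psf_sigma: float = 130.0  # nm
    photons_per_spot: float = 1000.0  # expected photons/frame
    background: float = 10.0  # photons per pixel
    frame_shape: tuple[int, int] = (64, 64)  # (H, W)
    noise_model: bool = True  # Poisson shot noise

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be > 0")
        if self.photons_per_spot < 0 or self.background < 0:
            raise ValueError("photon counts must be >= 0")


@dataclass
class ImageStack:
    """Multi-page image stack (frames, H, W), float photon counts."""

    data: np.ndarray
    pixel_size: float  # nm/px
    dt: float  # s

    def to_uint16(self) -> np.ndarray:
        return np.clip(np.round(self.data), 0, 65535).astype(np.uint16)


@dataclass(frozen=True)
class ZStackParams:
    """Phantom actin z-stack: ellipsoidal cell with an apical cortical
    shell and a bright basal layer (stress-fiber plane)."""

    shape: tuple[int, int, int] = (64, 160, 160)  # (nz, ny, nx)
    voxel_um: tuple[float, float, float] = (0.1, 0.25, 0.25)  # (dz, dy, dx)
    half_axes_um: tuple[float, float, float] = (18.0, 18.0, 5.0)  # (a_x, a_y, c_z)
    cortical_intensity: float = 500.0  # apical-shell mean, a.u.
    basal_intensity: float = 1000.0  # basal-layer mean, a.u.
    shell_thickness_um: float = 0.3
    basal_thickness_um: float = 0.2
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.shape) <= 0:
            raise ValueError("shape must be positive")
        if self.cortical_intensity < 0 or self.basal_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if min(self.voxel_um) <= 0 or min(self.half_axes_um) <= 0:
            raise ValueError("voxel sizes and half-axes must be > 0")


@dataclass
class ZStack:
    """3D fluorescence volume with voxel sizes and ground truth.

    ``data`` is indexed (z, y, x) with z = 0 at the coverslip.
    ``apical_z_um`` maps (y, x) to the ground-truth apical membrane
    height in µm (NaN outside the cell footprint).
    """

    data: np.ndarray  # (nz, ny, nx)
    voxel_um: tuple[float, float, float]  # (dz, dy, dx)
    apical_z_um: np.ndarray | None = None  # (ny, nx)


@dataclass(frozen=True)
class WoundSimParams:
    """Wound-healing mask-series generator parameters."""

    grid_shape: tuple[int, int] = (200, 300)  # (H, W)
    wound_half_width_px: int = 40
    closure_rate_per_h: float = 0.05
    outside_density: float = 0.7  # occupied fraction outside the wound
    times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 97, 12))
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.outside_density <= 1.0):
            raise ValueError("outside_density must be in [0, 1]")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if self.times_h[0] != 0:
            raise ValueError("times_h must start at 0 (baseline)")


@dataclass
class MaskSeries:
    """Binary cell masks over time plus the fixed wound region."""

    times_h: np.ndarray
    masks: np.ndarray  # (T, H, W) bool
    wound_region: np.ndarray  # (H, W) bool
    closure_fraction: np.ndarray | None = None  # analytic f(t), ground truth


# ---------------------------------------------------------------------------
# corral / hop diffusion


def _fold_into_box(pos: np.ndarray, lo: np.ndarray, L: float) -> np.ndarray:
    """Reflect (triangular-fold) positions into [lo, lo + L].

    Folding handles steps longer than the box; it is the method-of-images
    construction of reflected Brownian motion and preserves the uniform
    stationary distribution.
    """
    y = np.mod(pos - lo, 2.0 * L)
    return lo + np.where(y <= L, y, 2.0 * L - y)


def simulate_corral_ensemble(
    params: CorralParams, n_traj: int, seed: int | None = None
) -> list[Trajectory2D]:
    """Simulate ``n_traj`` independent corral-confined trajectories.

    Vectorized over trajectories; equivalent to repeated calls of
    :func:`simulate_corral_trajectory` in distribution.  The free
    (``L_comp = inf`` or ``p_hop = 1``) and hard-corral (``p_hop = 0``)
    limits use closed-form path constructions; intermediate ``p_hop``
    iterates frame by frame with one boundary test per step.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_steps
    L_um = params.L_comp / 1000.0
    step_sd = np.sqrt(2.0 * params.D_micro * params.dt)
    steps = rng.normal(0.0, step_sd, size=(n_traj, n - 1, 2))

    free = not np.isfinite(L_um) or params.p_hop == 1.0
    if free:
        x0 = np.zeros((n_traj, 1, 2))
    else:
        # start uniformly inside a compartment anchored at the origin
        x0 = rng.uniform(0.0, L_um, size=(n_traj, 1, 2))

    if free:
        pos = np.concatenate([x0, x0 + np.cumsum(steps, axis=1)], axis=1)
    elif params.p_hop == 0.0:
        raw = np.concatenate([x0, x0 + np.cumsum(steps, axis=1)], axis=1)
        pos = _fold_into_box(raw, 0.0, L_um)
    else:
        pos = np.empty((n_traj, n, 2))
        pos[:, 0] = x0[:, 0]
        hop_u = rng.uniform(size=(n_traj, n - 1, 2))
        cur = x0[:, 0].copy()
        comp = np.floor(cur / L_um)
        for i in range(n - 1):
            prop = cur + steps[:, i]
            comp_new = np.floor(prop / L_um)
            crossed = comp_new != comp
            hop = hop_u[:, i] < params.p_hop
            accept = ~crossed | hop
            lo = comp * L_um
            reflected = _fold_into_box(prop, lo, L_um)
            cur = np.where(accept, prop, reflected)
            comp = np.where(accept, comp_new, comp)
            pos[:, i + 1] = cur

    if params.sigma_loc > 0:
        pos = pos + rng.normal(0.0, params.sigma_loc / 1000.0, size=pos.shape)

    frames = np.arange(n)
    t = frames * params.dt
    return [
        Trajectory2D(
            track_id=k,
            frames=frames.copy(),
            t=t.copy(),
            x=pos[k, :, 0],
            y=pos[k, :, 1],
            sigma_loc=params.sigma_loc,
        )
        for k in range(n_traj)
    ]


def simulate_corral_trajectory(params: CorralParams) -> Trajectory2D:
    """Simulate one corral-confined / hop-diffusion trajectory.

    Brownian steps with per-axis variance ``2 * D_micro * dt``; a step
    that would cross a compartment boundary of the square lattice (side
    ``L_comp``) is accepted with probability ``p_hop`` and otherwise
    reflected back into the current compartment.  Gaussian localization
    noise (``sigma_loc``) is added independently per frame and axis.
    """
    return simulate_corral_ensemble(params, 1, seed=params.seed)[0]


# ---------------------------------------------------------------------------
# forward imaging model


def _integrated_gaussian(
    x0: float, y0: float, sigma_px: float, shape: tuple[int, int]
) -> np.ndarray:
    """Expected fraction of spot photons per pixel (integrated Gaussian)."""
    h, w = shape
    xs = np.arange(w)
    ys = np.arange(h)
    # pixel i spans [i - 0.5, i + 0.5] in pixel-center coordinates
    fx = ndtr((xs + 0.5 - x0) / sigma_px) - ndtr((xs - 0.5 - x0) / sigma_px)
    fy = ndtr((ys + 0.5 - y0) / sigma_px) - ndtr((ys - 0.5 - y0) / sigma_px)
    return np.outer(fy, fx)


def render_movie(
    trajs: list[Trajectory2D],
    optics: OpticsParams,
    seed: int | None = None,
) -> ImageStack:
    """Render trajectories into a camera movie.

    Each particle contributes an integrated 2D Gaussian PSF with expected
    ``photons_per_spot`` photons per frame on top of a uniform background;
    optional Poisson shot noise.  Particle positions are converted from µm
    to pixels with ``optics.pixel_size``; positions outside the field of
    view trigger a warning and are rendered clipped (their in-frame tail).
    """
    h, w = optics.frame_shape
    px_um = optics.pixel_size / 1000.0
    sigma_px = optics.psf_sigma / optics.pixel_size
    n_frames = 1 + max((int(tr.frames[-1]) for tr in trajs), default=0)
    dt = trajs[0].dt if trajs else np.nan
    stack = np.full((n_frames, h, w), float(optics.background))

    clipped = False
    for tr in trajs:
        xs_px = tr.x / px_um
        ys_px = tr.y / px_um
        if np.any((xs_px < -0.5) | (xs_px > w - 0.5) | (ys_px < -0.5) | (ys_px > h - 0.5)):
            clipped = True
        for f, x0, y0 in zip(tr.frames, xs_px, ys_px):
            stack[f] += optics.photons_per_spot * _integrated_gaussian(
                x0, y0, sigma_px, (h, w)
            )
    if clipped:
        warnings.warn("trajectory leaves the field of view; rendering clipped",
                      stacklevel=2)

    if optics.noise_model:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    return ImageStack(data=stack, pixel_size=optics.pixel_size, dt=dt)


# ---------------------------------------------------------------------------
# 3D internalization


def simulate_internalization(
    D_mem: float,
    v_in: float,
    t_switch: float,
    duration: float,
    dt: float = 0.05,
    sigma_loc: float = 20.0,
    z_mem: float = 0.0,
    axial_jitter_nm: float = 20.0,
    D_transport: float = 2e-4,
    seed: int | None = None,
    track_id: int = 0,
) -> Trajectory3D:
    """Simulate a membrane-then-inward receptor trajectory.

    For ``t < t_switch`` the particle diffuses laterally at the membrane
    plane ``z_mem`` (diffusivity ``D_mem``) with small independent axial
    jitter.  From ``t_switch`` on, directed inward transport
    ``dz/dt = v_in`` is superposed on 3D diffusion at ``D_transport``
    (default 2e-4 µm²/s: endocytosed cargo tethered to a molecular
    motor fluctuates far less than a free membrane receptor).
    Localization noise is additive Gaussian per frame on every axis.
    z increases from the coverslip into the cell interior.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    if v_in < 0:
        raise ValueError("v_in must be >= 0")
    if not (0.0 <= t_switch <= duration):
        raise ValueError("t_switch must lie in [0, duration]")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    inward = t >= t_switch
    lat_sd = np.where(inward[1:], np.sqrt(2.0 * D_transport * dt),
                      np.sqrt(2.0 * D_mem * dt))
    xy = np.zeros((n, 2))
    xy[1:] = np.cumsum(rng.normal(0.0, lat_sd[:, None], size=(n - 1, 2)), axis=0)

    z = np.full(n, z_mem)
    # membrane phase: independent axial jitter around the membrane plane
    z[~inward] += rng.normal(0.0, axial_jitter_nm / 1000.0, size=int((~inward).sum()))
    # transport phase: drift + axial diffusion accumulated from onset
    if inward.any():
        i0 = int(np.argmax(inward))
        sd_tr = np.sqrt(2.0 * D_transport * dt)
        dz = rng.normal(0.0, sd_tr, size=n - i0 - 1) if n - i0 > 1 else np.empty(0)
        z[i0:] = z_mem + v_in * (t[i0:] - t_switch)
        z[i0 + 1:] += np.cumsum(dz)

    if sigma_loc > 0:
        noise = rng.normal(0.0, sigma_loc / 1000.0, size=(n, 3))
        xy = xy + noise[:, :2]
        z = z + noise[:, 2]
    return Trajectory3D(
        track_id=track_id,
        frames=np.arange(n),
        t=t,
        x=xy[:, 0],
        y=xy[:, 1],
        sigma_loc=sigma_loc,
        z=z,
        z_mem=z_mem,
    )


# ---------------------------------------------------------------------------
# actin z-stack phantom


def synth_actin_zstack(params: ZStackParams) -> ZStack:
    """Build an actin phantom: ellipsoidal cell, apical cortical shell at
    ``cortical_intensity``, basal layer at ``basal_intensity``, plus
    Gaussian noise.  Ground-truth apical surface is returned in the
    :class:`ZStack`."""
    nz, ny, nx = params.shape
    dz, dy, dx = params.voxel_um
    ax, ay, cz = params.half_axes_um
    rng = np.random.default_rng(params.seed)

    xc = (nx - 1) / 2.0 * dx
    yc = (ny - 1) / 2.0 * dy
    xs = (np.arange(nx) * dx - xc) / ax
    ys = (np.arange(ny) * dy - yc) / ay
    r2 = ys[:, None] ** 2 + xs[None, :] ** 2  # (ny, nx)
    inside = r2 < 1.0
    z_top = np.full((ny, nx), np.nan)
    z_top[inside] = cz * np.sqrt(1.0 - r2[inside])

    zs = np.arange(nz) * dz
    data = np.zeros((nz, ny, nx))
    zt = np.where(inside, z_top, -np.inf)
    # apical shell: z within [z_top - shell_thickness, z_top]
    shell = (zs[:, None, None] <= zt[None]) & (
        zs[:, None, None] > zt[None] - params.shell_thickness_um
    )
    data[shell] = params.cortical_intensity
    # basal layer at the coverslip, within the footprint
    basal = (zs[:, None, None] < params.basal_thickness_um) & inside[None]
    data[basal] = params.basal_intensity

    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    return ZStack(data=data, voxel_um=params.voxel_um, apical_z_um=z_top)


def apical_path_for_projection(
    stack: ZStack,
    plane: str,
    center_um: float,
    lateral_fraction: float = 0.6,
) -> np.ndarray:
    """Ground-truth apical polyline for an orthogonal projection.

    Returns an (n, 2) array of (axial_um, lateral_um) samples of the
    apical membrane along the projection's lateral axis, restricted to
    the central ``lateral_fraction`` of the cell footprint where the
    surface is well resolved in a finite-width strip.
    """
    if stack.apical_z_um is None:
        raise ValueError("stack has no ground-truth apical surface")
    dz, dy, dx = stack.voxel_um
    if plane == "xz":
        idx = int(round(center_um / dy))
        profile = stack.apical_z_um[idx, :]
        lat_step = dx
    elif plane == "yz":
        idx = int(round(center_um / dx))
        profile = stack.apical_z_um[:, idx]
        lat_step = dy
    else:
        raise ValueError("plane must be 'xz' or 'yz'")
    valid = np.flatnonzero(np.isfinite(profile))
    if valid.size == 0:
        raise ValueError("strip does not intersect the cell footprint")
    mid = 0.5 * (valid[0] + valid[-1])
    half = 0.5 * lateral_fraction * (valid[-1] - valid[0])
    keep = valid[(valid >= mid - half) & (valid <= mid + half)]
    return np.column_stack([profile[keep], keep * lat_step])


# ---------------------------------------------------------------------------
# wound-closure mask series


def wound_closure_fraction(times_h: np.ndarray, rate_per_h: float) -> np.ndarray:
    """Analytic closure curve f(t) = 1 - exp(-r t), the ground truth the
    mask generator samples from (wound density = outside density * f)."""
    return 1.0 - np.exp(-rate_per_h * np.asarray(times_h, dtype=float))


def synth_wound_series(params: WoundSimParams) -> MaskSeries:
    """Generate binary cell masks of a closing scratch wound.

    Outside the wound, pixels are occupied independently with probability
    ``outside_density`` (fixed monolayer over time).  Inside the wound,
    occupancy density rises as ``outside_density * (1 - exp(-r t))``.
    """
    h, w = params.grid_shape
    rng = np.random.default_rng(params.seed)
    times = np.asarray(params.times_h, dtype=float)
    xs = np.arange(w)
    wound = np.abs(xs - (w - 1) / 2.0) <= params.wound_half_width_px
    wound_region = np.tile(wound, (h, 1))

    outside_mask = rng.uniform(size=(h, w)) < params.outside_density
    outside_mask &= ~wound_region

    f = wound_closure_fraction(times, params.closure_rate_per_h)
    masks = np.empty((len(times), h, w), dtype=bool)
    for i, fi in enumerate(f):
        inside = rng.uniform(size=(h, w)) < params.outside_density * fi
        masks[i] = outside_mask | (inside & wound_region)
    masks[0][wound_region] = False  # exact empty wound at baseline
    return MaskSeries(
        times_h=times, masks=masks, wound_region=wound_region, closure_fraction=f
    )
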