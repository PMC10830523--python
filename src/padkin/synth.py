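"""Synthetic-data generators emulating the microfluidic assay's raw outputs.

Everything the analysis consumes can be generated here with known ground
truth: particle trajectories with two-state (bound/unbound) Markov switching
and an irreversible-binder subpopulation, the 30 s shear phase with
force-dependent detachment, brightfield-like movies with textured cell
regions, SEM-like particle micrographs, and two-channel internalization
events (actin peak followed by acidification).

Defaults mirror the study's acquisition: 1 Hz imaging, a 10 min
sedimentation phase, a 30 s shear phase, ~3 um beads (free diffusion
coefficient ~0.22 um^2/s for a 1.5 um-radius sphere in 37 C water), and on
the order of 550 particles per measurement.

Binding dynamics use the discrete-time transition probabilities
``1 - exp(-k dt)`` of the continuous two-state chain sampled at the frame
interval; at the study's rates (k << 1/s) the discretization error is below
one percent.  Sedimentation is modeled as tracks starting throughout the
early sedimentation phase; there are no vertical dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_trajectories",
    "simulate_shear_phase",
    "render_movie",
    "render_sem_particles",
    "render_internalization_event",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.  Rates in 1/s, lengths um."""

    seed: int = 0
    n_particles: int = 550
    dt: float = 1.0
    sedimentation_duration: float = 600.0
    shear_duration: float = 30.0
    diffusion: float = 0.22            # um^2/s, ~3 um bead in water at 37 C
    localization_noise: float = 0.05   # um, subpixel localization error
    k_on: dict = field(default_factory=lambda: {"cell": 8e-3, "coverslip": 4e-3})
    k_off: dict = field(default_factory=lambda: {"cell": 5e-3, "coverslip": 1e-2})
    p_irreversible: float = 0.0        # per-binding probability of a permanent bond
    p_detach: float = 0.5              # reversible-bond detachment probability in shear
    count_noise_sd: float = 0.0        # counting noise on pre/post shear counts
    field_size: tuple = (330.0, 330.0)  # um (512 px at 0.645 um/px)
    cell_centers: tuple = ((80.0, 80.0), (220.0, 150.0), (120.0, 250.0))
    cell_radii: tuple = (45.0, 55.0, 40.0)
    staggered_starts: bool = True      # tracks appear through early sedimentation
    pixel_size: float = 0.645          # um/px for rendering
    image_shape: tuple = (512, 512)
    snr: float = 20.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.k_on.values()) or any(v < 0 for v in self.k_off.values()):
            raise ValueError("rates must be non-negative")
        if not (0 <= self.p_irreversible <= 1 and 0 <= self.p_detach <= 1):
            raise ValueError("probabilities must be in [0, 1]")


@dataclass
class SimulatedExperiment:
    """Ground-truth output of :func:`simulate_trajectories`.

    Per-particle ragged arrays, one entry per particle: frame times, observed
    positions (um), true bound state, true context label per frame, and
    whether the particle's current bond is irreversible at each frame.
    """

    times: list[np.ndarray]
    positions: list[np.ndarray]
    bound: list[np.ndarray]
    context: list[np.ndarray]
    irreversible_bond: list[np.ndarray]
    config: SimulationConfig

    @property
    def n_particles(self) -> int:
        return len(self.times)

    def truth_events(self) -> list[dict]:
        """Binding/unbinding events from the true state sequences."""
        events = []
        for pid in range(self.n_particles):
            b = self.bound[pid]
            for i in np.nonzero(b[1:] != b[:-1])[0]:
                events.append({
                    "track_id": pid,
                    "direction": "binding" if b[i + 1] else "unbinding",
                    "time": float(self.times[pid][i + 1]),
                    "context": str(self.context[pid][i + 1]),
                    "irreversible": bool(self.irreversible_bond[pid][i + 1]),
                })
        return events

    def final_bound(self) -> np.ndarray:
        return np.array([b[-1] for b in self.bound], dtype=bool)

    def final_irreversible(self) -> np.ndarray:
        return np.array([irr[-1] and b[-1] for irr, b in
                         zip(self.irreversible_bond, self.bound)], dtype=bool)


def _in_cell(x: np.ndarray, y: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    inside = np.zeros(np.shape(x), dtype=bool)
    for (cx, cy), r in zip(cfg.cell_centers, cfg.cell_radii):
        inside |= (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    return inside


def simulate_trajectories(cfg: SimulationConfig,
                          rng: np.random.Generator | None = None) -> SimulatedExperiment:
    """Two-state Brownian/bound dynamics for all particles of one measurement.

    Unbound particles take 2D Brownian steps (per-axis SD sqrt(2 D dt));
    bound particles are stationary.  Transition probabilities per frame are
    ``1 - exp(-k_on dt)`` and ``1 - exp(-k_off dt)`` with context-dependent
    rates; each binding is irreversible with probability ``p_irreversible``
    (its k_off is zero from then on).  Observed positions carry additive
    Gaussian localization noise.  Context is fixed by whether the particle
    lies inside a cell blob.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_particles
    n_frames = int(round(cfg.sedimentation_duration / cfg.dt)) + 1
    wx, wy = cfg.field_size

    if cfg.staggered_starts:
        start = rng.integers(0, max(n_frames // 2, 1), size=n)
    else:
        start = np.zeros(n, dtype=int)

    x = rng.uniform(0, wx, size=n)
    y = rng.uniform(0, wy, size=n)
    bound = np.zeros(n, dtype=bool)
    irr = np.zeros(n, dtype=bool)
    step_sd = np.sqrt(2.0 * cfg.diffusion * cfg.dt)

    pos_hist = np.full((n_frames, n, 2), np.nan)
    bound_hist = np.zeros((n_frames, n), dtype=bool)
    irr_hist = np.zeros((n_frames, n), dtype=bool)
    ctx_hist = np.zeros((n_frames, n), dtype=bool)  # True = cell

    p_on = {c: 1.0 - np.exp(-k * cfg.dt) for c, k in cfg.k_on.items()}
    p_off = {c: 1.0 - np.exp(-k * cfg.dt) for c, k in cfg.k_off.items()}

    for f in range(n_frames):
        alive = start <= f
        in_cell = _in_cell(x, y, cfg)
        pos_hist[f, alive, 0] = x[alive]
        pos_hist[f, alive, 1] = y[alive]
        bound_hist[f] = bound
        irr_hist[f] = irr
        ctx_hist[f] = in_cell

        # state transitions decide the state of the NEXT frame
        u = rng.uniform(size=n)
        p_bind = np.where(in_cell, p_on["cell"], p_on["coverslip"])
        p_unbind = np.where(in_cell, p_off["cell"], p_off["coverslip"])
        binds = alive & ~bound & (u < p_bind)
        unbinds = alive & bound & ~irr & (u < p_unbind)
        irr_draw = rng.uniform(size=n) < cfg.p_irreversible
        irr = np.where(binds, irr_draw, irr)
        bound = (bound | binds) & ~unbinds
        irr &= bound

        # unbound particles diffuse into the next frame (reflected at the field edge)
        moving = alive & ~bound
        nx = x + np.where(moving, rng.normal(0, step_sd, size=n), 0.0)
        ny = y + np.where(moving, rng.normal(0, step_sd, size=n), 0.0)
        # reflect at the field edges (steps are tiny relative to the field)
        nx = np.where(nx < 0, -nx, nx)
        x = np.where(nx > wx, 2 * wx - nx, nx)
        ny = np.where(ny < 0, -ny, ny)
        y = np.where(ny > wy, 2 * wy - ny, ny)

    noise = rng.normal(0, cfg.localization_noise, size=pos_hist.shape)
    obs = pos_hist + noise

    times_l, pos_l, bound_l, ctx_l, irr_l = [], [], [], [], []
    t_axis = np.arange(n_frames) * cfg.dt
    for pid in range(n):
        f0 = int(start[pid])
        times_l.append(t_axis[f0:])
        pos_l.append(obs[f0:, pid, :])
        bound_l.append(bound_hist[f0:, pid].copy())
        ctx_l.append(np.where(ctx_hist[f0:, pid], "cell", "coverslip"))
        irr_l.append(irr_hist[f0:, pid].copy())
    return SimulatedExperiment(times=times_l, positions=pos_l, bound=bound_l,
                               context=ctx_l, irreversible_bond=irr_l, config=cfg)


def simulate_shear_phase(exp: SimulatedExperiment,
                         rng: np.random.Generator | None = None,
                         p_detach: float | None = None) -> dict:
    """Force-dependent detachment over the shear phase.

    Each reversibly bound particle survives the 30 s of applied force with
    probability ``1 - p_detach``; irreversible bonds always survive.  Optional
    Gaussian counting noise on both counts lets the measured remaining
    fraction exceed 1, as particle counting in images does.
    """
    cfg = exp.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if p_detach is None:
        p_detach = cfg.p_detach
    bound = exp.final_bound()
    irr = exp.final_irreversible()
    detach = rng.uniform(size=bound.shape) < p_detach
    survivors = bound & (irr | ~detach)

    pre, post = int(bound.sum()), int(survivors.sum())
    pre_meas, post_meas = float(pre), float(post)
    if cfg.count_noise_sd > 0:
        pre_meas = max(pre + rng.normal(0, cfg.count_noise_sd), 0.0)
        post_meas = max(post + rng.normal(0, cfg.count_noise_sd), 0.0)
    return {"survivors": survivors, "pre_shear": pre, "post_shear": post,
            "pre_shear_measured": pre_meas, "post_shear_measured": post_meas}


def _cell_texture(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Static DIC-like texture: smooth random field inside the cell blobs."""
    ny, nx = cfg.image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    xum, yum = xx * cfg.pixel_size, yy * cfg.pixel_size
    inside = _in_cell(xum, yum, cfg)
    texture = ndimage.gaussian_filter(rng.normal(0, 1, size=(ny, nx)), 2.0)
    texture /= max(texture.std(), 1e-12)
    return np.where(inside, texture, 0.0)


def render_movie(exp: SimulatedExperiment, rng: np.random.Generator | None = None,
                 spot_sigma_px: float = 1.6, spot_amplitude: float | None = None,
                 background: float = 100.0, noise_sd: float = 10.0,
                 texture_amplitude: float = 40.0, with_cells: bool = True,
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Brightfield-like movie of the simulated particles.

    Gaussian-PSF spots at the observed particle positions over an optionally
    textured cell background, plus Gaussian read noise.  The spot amplitude
    defaults to ``snr * noise_sd``.  Returns (frames, true positions in px
    per frame).
    """
    cfg = exp.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if spot_amplitude is None:
        spot_amplitude = cfg.snr * noise_sd
    ny, nx = cfg.image_shape
    if exp.n_particles:
        n_frames = max(len(t) for t in exp.times)
        t0 = min(t[0] for t in exp.times)
    else:
        n_frames = int(round(cfg.sedimentation_duration / cfg.dt)) + 1
        t0 = 0.0
    texture = _cell_texture(cfg, rng) if with_cells else 0.0

    frames = np.empty((n_frames, ny, nx), dtype=float)
    truth: list[np.ndarray] = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    for f in range(n_frames):
        img = np.full((ny, nx), background, dtype=float)
        if with_cells:
            img += texture_amplitude * texture
        pts = []
        t = t0 + f * cfg.dt
        for pid in range(exp.n_particles):
            tt = exp.times[pid]
            if t < tt[0] or t > tt[-1]:
                continue
            i = int(round((t - tt[0]) / cfg.dt))
            px = exp.positions[pid][i, 0] / cfg.pixel_size
            py = exp.positions[pid][i, 1] / cfg.pixel_size
            if not (0 <= px < nx and 0 <= py < ny):
                continue
            pts.append((pid, px, py))
            # render only a local window around the spot
            r = int(np.ceil(5 * spot_sigma_px))
            x0, x1 = max(int(px) - r, 0), min(int(px) + r + 1, nx)
            y0, y1 = max(int(py) - r, 0), min(int(py) + r + 1, ny)
            sub_y, sub_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += spot_amplitude * np.exp(
                -((sub_x - px) ** 2 + (sub_y - py) ** 2) / (2 * spot_sigma_px**2))
        img += rng.normal(0, noise_sd, size=img.shape)
        frames[f] = img
        truth.append(np.array(pts, dtype=float).reshape(-1, 3))
    return frames, truth


def render_sem_particles(n: int, diameter_um: float, boundary_noise_nm: float,
                         pixel_nm: float, rng: np.random.Generator | None = None,
                         axis_ratio: float = 1.0, margin_px: int = 40,
                         supersample: int = 4, n_harmonics: int = 8,
                         ) -> tuple[np.ndarray, list[dict]]:
    """SEM-like micrograph of ``n`` disks/ellipses with perturbed boundaries.

    The boundary radius is modulated by a random low-order Fourier series of
    standard deviation ``boundary_noise_nm``; edges are anti-aliased by
    supersampled rasterization.  Returns (image, truth records).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    r_um = diameter_um / 2.0
    r_px = r_um * 1000.0 / pixel_nm
    a_px = r_px * np.sqrt(axis_ratio)   # major
    b_px = r_px / np.sqrt(axis_ratio)   # minor; geometric mean preserves area
    cell = int(np.ceil(2 * a_px)) + 2 * margin_px
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    img = np.zeros((rows * cell, cols * cell), dtype=float)
    truth: list[dict] = []
    sigma_px = boundary_noise_nm / pixel_nm

    for k in range(n):
        rr, cc = divmod(k, cols)
        cy = rr * cell + cell / 2.0
        cx = cc * cell + cell / 2.0
        amps = rng.normal(0, 1, size=n_harmonics)
        phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
        norm = np.linalg.norm(amps) / np.sqrt(2)
        amps = amps / norm * sigma_px if norm > 0 else amps

        s = supersample
        half = cell // 2
        ax = (np.arange(cell * s) - cell * s / 2 + 0.5) / s
        sx, sy = np.meshgrid(ax, ax)
        theta = np.arctan2(sy, sx)
        rho = np.hypot(sx, sy)
        r_ell = a_px * b_px / np.sqrt((b_px * np.cos(theta)) ** 2
                                      + (a_px * np.sin(theta)) ** 2)
        perturb = np.zeros_like(theta)
        for m in range(n_harmonics):
            perturb += amps[m] * np.cos((m + 2) * theta + phases[m])
        inside = rho <= r_ell + perturb
        tile = inside.reshape(cell, s, cell, s).mean(axis=(1, 3))
        y0, x0 = int(cy - half), int(cx - half)
        img[y0:y0 + cell, x0:x0 + cell] = np.maximum(
            img[y0:y0 + cell, x0:x0 + cell], tile)
        truth.append({"center_px": (cx, cy), "diameter_um": diameter_um,
                      "axis_ratio": axis_ratio})
    return img, truth


def render_internalization_event(peak_time: float, peak_width: float,
                                 onset_time: float, onset_rate: float,
                                 r_px: float, snr: float = 20.0,
                                 n_frames: int = 120, dt: float = 3.125,
                                 size: int = 60, amplitude: float = 1.0,
                                 background: float = 1.0,
                                 rng: np.random.Generator | None = None) -> dict:
    """Two-channel engulfment event around a centered particle.

    LifeAct: transient ring brightening, Gaussian in time around
    ``peak_time``.  LysoTracker: sigmoidal ring brightening with midpoint
    ``onset_time`` and timescale ``onset_rate``.  Both signals live on the
    annulus [r-2, r+2] px around the patch center; the background is uniform.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(n_frames) * dt
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    d = np.hypot(xx - c, yy - c)
    ring = (d >= r_px - 2) & (d <= r_px + 2)

    lifeact_amp = amplitude * np.exp(-((t - peak_time) ** 2) / (2 * peak_width**2))
    lyso_amp = amplitude / (1.0 + np.exp(-(t - onset_time) / onset_rate))
    noise_sd = amplitude / snr

    la = np.full((n_frames, size, size), background)
    ly = np.full((n_frames, size, size), background)
    la += lifeact_amp[:, None, None] * ring[None]
    ly += lyso_amp[:, None, None] * ring[None]
    la += rng.normal(0, noise_sd, size=la.shape)
    ly += rng.normal(0, noise_sd, size=ly.shape)
    centers = np.full((n_frames, 2), c)
    return {"lifeact": la, "lysotracker": ly, "centers": centers, "times": t,
            "truth": {"peak_time": peak_time, "onset_time": onset_time,
                      "r_px": r_px}}
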