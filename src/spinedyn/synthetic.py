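"""Synthetic spine cohorts and image stacks with the model's statistical structure.

``generate_cohort`` produces longitudinal volume tables shaped like an
in-vivo two-photon experiment: per-group drift-diffusion dynamics of the
latent volume between sessions (with elimination by absorption at
``v_min``), fast observation noise on every measurement, dendrite and
animal labels, and optional special modes (10-min fast imaging, fixed-
tissue control).  ``generate_zstack`` renders PSF-blurred fluorescent
spheres onto a voxel grid for the calibration round trip.

Because the fast-fluctuation coefficient is defined as the SD of the
*difference* of two closely spaced volume observations, the per-observation
noise SD is ``sigma_fast(V) / sqrt(2)``; differences of two independent
draws then have SD ``sigma_fast(V)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0e, roots_legendre

from .fp import stationary_density
from .model import KO_SPEC, WT_SPEC, DriftDiffusionSpec
from .sde import SimulationConfig, _fold, simulate_paths
from .calibration import PSFSphereModel
from .estimation import TRAJECTORY_COLUMNS, validate_trajectories

__all__ = ["CohortConfig", "generate_cohort", "generate_zstack"]

#: 10 minutes expressed in 2-day intervals
TEN_MINUTES = 10.0 / (2.0 * 24.0 * 60.0)


def _default_specs():
    return {"WT": WT_SPEC, "KO": KO_SPEC}


def _default_n_spines():
    return {"WT": 754, "KO": 878}


def _default_n_dendrites():
    return {"WT": 15, "KO": 20}


def _default_n_animals():
    return {"WT": 5, "KO": 5}


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale description of a simulated cohort.

    Defaults mirror the in-vivo study design: 754 WT / 878 KO spines on
    15 / 20 dendrites in five mice per group, imaged every 2 days for five
    sessions.  ``mode`` selects the observation protocol:

    * ``"slow"`` -- sessions every 2-day interval, latent volumes evolve;
    * ``"fast"`` -- 7 observations at 10-min spacing, latent volume frozen
      (drift and slow diffusion are negligible within an hour);
    * ``"fixed"`` -- fixed-tissue control: neither dynamics nor noise.
    """

    specs: dict = field(default_factory=_default_specs)
    n_spines: dict = field(default_factory=_default_n_spines)
    n_dendrites: dict = field(default_factory=_default_n_dendrites)
    n_animals: dict = field(default_factory=_default_n_animals)
    n_sessions: int = 5
    mode: str = "slow"
    seed: int = 0
    #: how the latent volume advances from one session to the next.
    #: ``"discrete"`` (default) applies the fitted per-2-d transition kernel
    #: directly -- one Gaussian increment N(mu(V), sigma_slow(V)^2) per
    #: interval, elimination when the step lands at or below v_min.  This is
    #: the model the binned estimators define and estimate, so cohorts are
    #: exactly self-consistent with the coefficient laws.  ``"sde"`` embeds
    #: the laws in a continuous diffusion and integrates with fine Euler
    #: steps (first-passage elimination); its finite-interval moments are
    #: shrunk relative to sigma_slow(V) by mean reversion, by design of the
    #: continuous embedding.
    latent_step: str = "discrete"
    dt: float = 0.005          # Euler step between sessions in "sde" mode
    top_up: bool = False       # replace eliminated spines from stationary f

    def __post_init__(self) -> None:
        if self.mode not in ("slow", "fast", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.latent_step not in ("discrete", "sde"):
            raise ValueError(f"unknown latent_step {self.latent_step!r}")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        for g in self.specs:
            for d in (self.n_spines, self.n_dendrites, self.n_animals):
                if d.get(g, 0) < 1:
                    raise ValueError(f"counts for group {g!r} must be positive")

    def single_group(self, group: str) -> "CohortConfig":
        return replace(
            self,
            specs={group: self.specs[group]},
            n_spines={group: self.n_spines[group]},
            n_dendrites={group: self.n_dendrites[group]},
            n_animals={group: self.n_animals[group]},
        )


def _observe(latent: np.ndarray, spec: DriftDiffusionSpec, rng) -> np.ndarray:
    """Latent volume plus fast observation noise, truncated at zero."""
    sd = spec.sigma_fast(latent) / np.sqrt(2.0)
    return np.clip(latent + sd * rng.standard_normal(latent.size), 0.0, None)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a longitudinal volume table (schema ``TRAJECTORY_COLUMNS``).

    Initial latent volumes are stationary draws for each group's spec.  In
    ``"slow"`` mode the latent volume diffuses between sessions with an
    absorbing boundary at ``v_min``; an absorbed spine appears once more as
    an ``eliminated=True`` record (volume 0) at the following session and
    its series ends.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for group in sorted(config.specs):
        spec = config.specs[group]
        n = config.n_spines[group]
        n_dend = config.n_dendrites[group]
        n_anim = config.n_animals[group]
        dendrite = np.arange(n) % n_dend
        animal = dendrite % n_anim
        f0 = stationary_density(spec, n_grid=4000)
        latent = f0.sample(n, rng)

        if config.mode == "fixed":
            n_obs = config.n_sessions
            for s in range(1, n_obs + 1):
                frames.append(_records(group, animal, dendrite, np.arange(n), s, latent, False))
            continue

        if config.mode == "fast":
            n_obs = 7
            for s in range(1, n_obs + 1):
                obs = _observe(latent, spec, rng)
                frames.append(_records(group, animal, dendrite, np.arange(n), s, obs, False))
            continue

        # slow mode: evolve between sessions, absorb at v_min
        spine_ids = np.arange(n)
        next_id = n
        obs = _observe(latent, spec, rng)
        frames.append(_records(group, animal, dendrite, spine_ids, 1, obs, False))
        for s in range(2, config.n_sessions + 1):
            if config.latent_step == "discrete":
                z = rng.standard_normal(latent.size)
                stepped = latent + spec.mu(latent) + spec.sigma_slow(latent) * z
                gone = stepped <= spec.v_min
                stepped[~gone] = _fold(stepped[~gone], spec.v_min, spec.v_max)
                new_latent = stepped
            else:
                cfg = SimulationConfig(
                    spec=spec, dt=config.dt, n_steps=int(round(1.0 / config.dt)),
                    seed=int(rng.integers(0, 2**31)), lower_boundary="absorbing",
                )
                res = simulate_paths(cfg, latent)
                gone = res.absorbed
                new_latent = res.volumes
            if gone.any():
                frames.append(_records(
                    group, animal[gone], dendrite[gone], spine_ids[gone], s,
                    np.zeros(int(gone.sum())), True,
                ))
            keep = ~gone
            latent, spine_ids = new_latent[keep], spine_ids[keep]
            animal, dendrite = animal[keep], dendrite[keep]
            if config.top_up and gone.any():
                k = int(gone.sum())
                new_ids = np.arange(next_id, next_id + k)
                next_id += k
                new_dend = new_ids % n_dend
                latent = np.concatenate([latent, f0.sample(k, rng)])
                spine_ids = np.concatenate([spine_ids, new_ids])
                dendrite = np.concatenate([dendrite, new_dend])
                animal = np.concatenate([animal, new_dend % n_anim])
            if latent.size == 0:
                break
            obs = _observe(latent, spec, rng)
            frames.append(_records(group, animal, dendrite, spine_ids, s, obs, False))

    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["group", "animal_id", "dendrite_id", "spine_id", "session"],
        ignore_index=True,
    )
    return validate_trajectories(table)


def _records(group, animal, dendrite, spine, session, volumes, eliminated) -> pd.DataFrame:
    animal = np.broadcast_to(animal, np.shape(volumes))
    dendrite = np.broadcast_to(dendrite, np.shape(volumes))
    spine = np.broadcast_to(spine, np.shape(volumes))
    return pd.DataFrame({
        "animal_id": [f"{group.lower()}-m{a}" for a in animal],
        "dendrite_id": [f"{group.lower()}-d{d}" for d in dendrite],
        "spine_id": [f"{group.lower()}-s{k}" for k in spine],
        "group": group,
        "session": session,
        "volume_um3": np.asarray(volumes, dtype=float),
        "eliminated": bool(eliminated),
    }, columns=TRAJECTORY_COLUMNS)


# ---------------------------------------------------------------------------
# synthetic image stacks

def _blurred_disk(rho: np.ndarray, disk_radius: float, sigma: float, n_quad: int = 60):
    """Normalized 2-D Gaussian blur of a unit disk indicator, radially."""
    if disk_radius <= 0:
        return np.zeros_like(rho)
    t, w = roots_legendre(n_quad)
    t = 0.25 * np.pi * (t + 1.0)
    w = 0.25 * np.pi * w
    u = disk_radius * np.sin(t)
    jac = disk_radius * np.cos(t) * w
    z = np.outer(rho, u) / sigma**2
    expo = np.exp(-((u[None, :] - rho[:, None]) ** 2) / (2.0 * sigma**2))
    return ((u * jac)[None, :] * i0e(z) * expo).sum(axis=1) / sigma**2


def generate_zstack(
    spheres,
    psf: PSFSphereModel | None = None,
    pixel_size: float = 0.124,
    z_step: float = 0.4,
    shape: tuple[int, int, int] = (128, 128, 25),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render Gaussian-blurred homogeneous spheres onto a voxel grid.

    ``spheres`` is a list of ``(x, y, z, radius, amplitude)`` in um, with
    the origin at the stack corner.  The returned array has axes
    ``(row, col, z)``; intensities are evaluated analytically (radial
    quadrature of the blurred ball), so total summed fluorescence times the
    voxel volume equals ``amplitude * 4/3 pi R^3`` up to sampling error,
    and the z-summed image of an isolated sphere matches
    :func:`spinedyn.calibration.projected_sphere_profile`.
    """
    psf = psf or PSFSphereModel()
    ny, nx, nz = shape
    stack = np.zeros(shape, dtype=float)
    ygrid = (np.arange(ny) + 0.5) * pixel_size
    xgrid = (np.arange(nx) + 0.5) * pixel_size
    zgrid = (np.arange(nz) + 0.5) * z_step

    spheres = list(spheres)
    for i, a in enumerate(spheres):
        for b in spheres[i + 1:]:
            dist = np.hypot(np.hypot(a[0] - b[0], a[1] - b[1]), a[2] - b[2])
            if dist < a[3] + b[3]:
                warnings.warn("overlapping spheres in synthetic stack", stacklevel=2)

    zp, wzp = roots_legendre(40)
    for (cx, cy, cz, radius, amplitude) in spheres:
        if not (0 < cx < nx * pixel_size and 0 < cy < ny * pixel_size and 0 < cz < nz * z_step):
            raise ValueError("sphere centre outside the field")
        rho = np.hypot(xgrid[None, :] - cx, ygrid[:, None] - cy)
        rho_flat = rho.ravel()
        zp_s = radius * zp          # z' in [-R, R]
        wzp_s = radius * wzp
        disk_r = np.sqrt(np.clip(radius**2 - zp_s**2, 0.0, None))
        lateral = np.stack([
            _blurred_disk(rho_flat, dr, psf.sigma_x) for dr in disk_r
        ])  # (n_zq, ny*nx)
        for iz, z in enumerate(zgrid):
            gz = np.exp(-((z - cz - zp_s) ** 2) / (2 * psf.sigma_z**2))
            gz /= np.sqrt(2 * np.pi) * psf.sigma_z
            stack[:, :, iz] += amplitude * ((wzp_s * gz) @ lateral).reshape(ny, nx)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + noise_sd * rng.standard_normal(stack.shape)
    return stack
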