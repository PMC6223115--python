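"""Fluorescence-to-volume calibration.

Spine-head volume is read out from total GFP fluorescence.  The conversion
coefficient comes from one large, approximately spherical spine per
dendrite: its one-dimensional intensity profile is fitted with the model of
a homogeneous fluorescent ball of radius ``R`` imaged through a Gaussian
point-spread function (lateral SD ``sigma_x``, axial SD ``sigma_z``),

    F(r, R) = A / ((2 pi)^{3/2} sigma_x^2 sigma_z)
              * int_{ball(R)} dx dy dz  int dz'
                exp(-[(x-r)^2 + y^2] / (2 sigma_x^2) - (z-z')^2 / (2 sigma_z^2)),

where ``A`` is the central intensity and ``r`` the lateral offset of the
profile point from the sphere centre.  The axial double integral is
analytic (the z' Gaussian integrates to ``sqrt(2 pi) sigma_z`` and the z
integral gives the chord length ``2 sqrt(R^2 - x^2 - y^2)``), leaving a
lateral Gaussian blur of the projected ball which this module reduces
further to a single radial quadrature through the Bessel identity
``int_0^{2pi} e^{k cos t} dt = 2 pi I0(k)``.

The fitted radius gives the calibration volume ``V = 4/3 pi R^3`` and the
coefficient ``V/F``; volumes on other sessions are ``F * (V/F)`` divided by
a per-session normalization factor that absorbs day-to-day changes in GFP
expression and laser delivery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0e, roots_legendre

__all__ = [
    "PSFSphereModel",
    "ConversionCoefficient",
    "DailyNormalization",
    "CalibrationError",
    "projected_sphere_profile",
    "reference_profile_full_integral",
    "fit_sphere",
    "volume_from_fluorescence",
    "sphere_volume",
]

#: in-vivo point-spread function defaults: 0.56 um lateral and 2.1 um axial
#: full width at half maximum.
DEFAULT_SIGMA_X = 0.24
DEFAULT_SIGMA_Z = 0.91

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class CalibrationError(RuntimeError):
    """Raised when a profile fit or quadrature fails."""


@dataclass(frozen=True)
class PSFSphereModel:
    """Gaussian-PSF-blurred homogeneous sphere."""

    sigma_x: float = DEFAULT_SIGMA_X
    sigma_z: float = DEFAULT_SIGMA_Z
    amplitude: float = 1.0
    radius: float = 0.4

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_z", "amplitude", "radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def fwhm_lateral(self) -> float:
        return _FWHM * self.sigma_x

    @property
    def fwhm_axial(self) -> float:
        return _FWHM * self.sigma_z

    @property
    def volume(self) -> float:
        return sphere_volume(self.radius)


def sphere_volume(radius: float) -> float:
    """``4/3 pi R^3`` (um^3)."""
    return 4.0 / 3.0 * np.pi * radius**3


def projected_sphere_profile(r, model: PSFSphereModel, n_quad: int = 120):
    """Intensity profile of the blurred sphere at lateral offset ``r``.

    The lateral blur of the projected ball in polar coordinates is

        F(r) = A / sigma_x^2 * int_0^R 2 sqrt(R^2 - rho^2) rho
               I0(rho r / sigma_x^2) exp(-(rho^2 + r^2)/(2 sigma_x^2)) d rho

    evaluated with Gauss-Legendre quadrature after ``rho = R sin t``, which
    removes the square-root edge of the integrand.  Even in ``r`` and
    non-increasing for ``r >= 0``.
    """
    r = np.abs(np.atleast_1d(np.asarray(r, dtype=float)))
    if not np.all(np.isfinite(r)):
        raise ValueError("offsets must be finite")
    sx2 = model.sigma_x**2
    R = model.radius
    t, w = roots_legendre(n_quad)
    t = 0.25 * np.pi * (t + 1.0)          # [0, pi/2]
    w = 0.25 * np.pi * w
    rho = R * np.sin(t)
    jac = R * np.cos(t)                    # d rho
    chord = 2.0 * R * np.cos(t)            # 2 sqrt(R^2 - rho^2)
    # I0(z) e^{-z} * e^{z - (rho^2+r^2)/2sx2} = I0e * exp(-(rho-r)^2/2sx2)
    z = np.outer(r, rho) / sx2
    expo = np.exp(-((rho[None, :] - r[:, None]) ** 2) / (2.0 * sx2))
    vals = (chord * rho * jac * w)[None, :] * i0e(z) * expo
    out = model.amplitude / sx2 * vals.sum(axis=1)
    if not np.all(np.isfinite(out)):
        raise CalibrationError("quadrature produced non-finite intensities")
    return out if out.size > 1 else float(out[0])


def reference_profile_full_integral(
    r: float, model: PSFSphereModel, n_quad: int = 48, z_prime_halfwidth: float = 8.0
) -> float:
    """Slow direct evaluation of the four-fold integral, for validation.

    Nested Gauss-Legendre quadrature over the ball with exact section
    bounds (x in [-R, R], y in +-sqrt(R^2-x^2), z in +-sqrt(R^2-x^2-y^2))
    and numerical integration of the auxiliary axial coordinate z'
    (truncated at ``z_prime_halfwidth`` axial SDs) -- no analytic
    reduction is used.
    """
    R, sx, sz = model.radius, model.sigma_x, model.sigma_z
    g, w = roots_legendre(n_quad)
    x = R * g
    wx = R * w
    half_y = np.sqrt(np.clip(R**2 - x**2, 0.0, None))
    # y nodes per x-column: (nx, nq)
    y = half_y[:, None] * g[None, :]
    wy = half_y[:, None] * w[None, :]
    half_z = np.sqrt(np.clip(R**2 - x[:, None] ** 2 - y**2, 0.0, None))
    z = half_z[..., None] * g[None, None, :]
    wz = half_z[..., None] * w[None, None, :]
    zp, wzp = roots_legendre(60)
    zp = z_prime_halfwidth * sz * zp
    wzp = z_prime_halfwidth * sz * wzp
    inner = (wzp[None, None, None, :] * np.exp(
        -((z[..., None] - zp[None, None, None, :]) ** 2) / (2 * sz**2)
    )).sum(axis=-1)
    lat = np.exp(-(((x[:, None] - r) ** 2 + y**2) / (2 * sx**2)))
    total = np.einsum("i,ij,ijk,ijk->", wx, wy * lat, wz, inner)
    return float(model.amplitude / ((2 * np.pi) ** 1.5 * sx**2 * sz) * total)


def fit_sphere(
    profile_samples,
    sigma_x: float = DEFAULT_SIGMA_X,
    sigma_z: float = DEFAULT_SIGMA_Z,
) -> tuple[PSFSphereModel, float]:
    """Least-squares fit of amplitude and radius to a measured profile.

    ``profile_samples`` is a sequence of ``(r, intensity)`` pairs spanning
    both flanks of the peak.  Returns the fitted model and the residual
    norm.  Unweighted least squares; the noise model of the profile
    measurement is unknown.
    """
    samples = np.asarray(profile_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 5:
        raise ValueError("need at least 5 (r, intensity) samples")
    r, intensity = samples[:, 0], samples[:, 1]
    if r.min() >= 0 or r.max() <= 0:
        raise ValueError("samples must span both flanks of the peak")
    if np.ptp(intensity) < 1e-12 * max(abs(intensity).max(), 1.0):
        raise CalibrationError("flat profile: sphere parameters unidentifiable")

    # half-width of the profile -> radius scale; central value -> amplitude
    imax = intensity.max()
    above = np.abs(r[intensity > imax / 2.0])
    r0 = max(above.max() if above.size else 0.2, 0.05)
    a0 = imax / (2.0 * r0)

    def residual(theta):
        a, rad = theta
        m = PSFSphereModel(sigma_x=sigma_x, sigma_z=sigma_z, amplitude=a, radius=rad)
        return projected_sphere_profile(r, m) - intensity

    try:
        res = least_squares(
            residual, x0=[a0, r0], bounds=([1e-12, 1e-4], [np.inf, np.inf])
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise CalibrationError(f"sphere fit failed: {exc}") from exc
    if not res.success:
        raise CalibrationError(f"sphere fit did not converge: {res.message}")
    ss_res = float(res.fun @ res.fun)
    ss_tot = float(np.sum((intensity - intensity.mean()) ** 2))
    if ss_tot <= 0 or 1.0 - ss_res / ss_tot < 0.2:
        raise CalibrationError(
            "profile is not peak-like: sphere model explains almost no variance"
        )
    model = PSFSphereModel(
        sigma_x=sigma_x, sigma_z=sigma_z,
        amplitude=float(res.x[0]), radius=float(res.x[1]),
    )
    return model, float(np.linalg.norm(res.fun))


@dataclass(frozen=True)
class ConversionCoefficient:
    """Volume per fluorescence unit, from one calibration spine."""

    v_over_f: float
    source_spine_id: str = ""
    session_of_origin: int = 0

    def __post_init__(self) -> None:
        if self.v_over_f <= 0:
            raise ValueError("v_over_f must be positive")

    @classmethod
    def from_sphere(
        cls, model: PSFSphereModel, total_fluorescence: float,
        source_spine_id: str = "", session_of_origin: int = 0,
    ) -> "ConversionCoefficient":
        if total_fluorescence <= 0:
            raise ValueError("calibration spine fluorescence must be positive")
        return cls(
            v_over_f=model.volume / total_fluorescence,
            source_spine_id=source_spine_id,
            session_of_origin=session_of_origin,
        )


@dataclass(frozen=True)
class DailyNormalization:
    """Per-session fluorescence scale factors relative to a reference session.

    Factors are the ratio of dendritic-region fluorescence on each session
    to the reference session (typically < 10% variation per day); the
    factor at the reference session is 1 by construction.
    """

    factors: dict = field(default_factory=dict)
    reference_session: int = 1

    def __post_init__(self) -> None:
        factors = dict(self.factors)
        factors.setdefault(self.reference_session, 1.0)
        if any(f <= 0 for f in factors.values()):
            raise ValueError("normalization factors must be positive")
        if not np.isclose(factors[self.reference_session], 1.0):
            raise ValueError("reference-session factor must be 1")
        object.__setattr__(self, "factors", factors)

    def factor(self, session: int) -> float:
        try:
            return self.factors[session]
        except KeyError:
            raise KeyError(f"no normalization factor for session {session}") from None


def volume_from_fluorescence(
    total_f: float,
    coeff: ConversionCoefficient,
    norm: DailyNormalization | None = None,
    session: int | None = None,
) -> float:
    """Convert background-subtracted total fluorescence to volume (um^3).

    ``volume = total_f * v_over_f / session_factor``.  Negative
    post-subtraction fluorescence is clipped to zero with a warning (noise
    can push small backgrounds past the signal).
    """
    if total_f < 0:
        warnings.warn(
            f"negative post-subtraction fluorescence ({total_f}); clipping to 0",
            stacklevel=2,
        )
        total_f = 0.0
    factor = 1.0
    if norm is not None:
        if session is None:
            raise ValueError("session is required when a normalization is supplied")
        factor = norm.factor(session)
    return total_f * coeff.v_over_f / factor
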