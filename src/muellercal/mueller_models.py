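"""Analytic Mueller-matrix models for linear diattenuators and dichroic retarders.

A 3x3 Mueller polarimeter measures only the top-left 3x3 block of the full
4x4 Mueller matrix (the linear-polarization subspace).  The calibration
samples handled here all belong to the dichroic-retarder (DR) family: an
element with attenuations ``q >= r`` along two orthogonal principal axes and
a retardance ``delta`` between them.  A linear polarizer (LP) is the
``delta = 0``, ``q >> r`` limit; a wave plate is the ``q ~ r`` limit.

Two angle conventions coexist and must not be confused:

* ``rot3(phi)`` is the raw rotation operator on the (s0, s1, s2) Stokes
  subspace with rotation argument ``phi``.
* The *orientation* ``theta`` of a physical element (the mount angle of its
  principal axis, in degrees) enters the Mueller matrix as
  ``rot3(-2 theta) @ core @ rot3(2 theta)`` - the standard doubling of the
  polarization azimuth, with the sense fixed so that an ideal polarizer at
  +45 deg produces the Stokes state (1, 0, 1).  All ``theta`` parameters in
  this package are physical orientations in that convention.

Scale convention: the diattenuation core is used without a 1/2 radiometric
prefactor, so an ideal LP (q=1, r=0) has 3x3 eigenvalues (2, 0, 0) and a DR
has the analytic triple (2q, 2r, 2qr cos(delta)).  Absolute scale is
immaterial to the calibration, which is invariant under a global gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarizerSpec",
    "DichroicRetarderSpec",
    "rot3",
    "lp_mueller4",
    "dr_mueller4",
    "dr_mueller3",
    "dr_eigenvalues",
    "sort_eigenvalues",
    "eigs_to_params",
    "m3_from_eigs",
]

# |lam3/(2qr)| may exceed 1 by this much before eigs_to_params refuses to
# clamp; keeps arccos robust to roundoff without masking bad inputs.
ARCCOS_CLAMP_TOL = 1e-6


@dataclass(frozen=True)
class PolarizerSpec:
    """Linear polarizer: orientation ``theta`` (degrees) and attenuations.

    ``q`` and ``r`` are the maximum and minimum intensity attenuations along
    the two principal axes (dimensionless, ``0 <= r <= q <= 1``).  The
    extinction ratio is ``q / r``.
    """

    theta: float
    q: float
    r: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (0.0 <= self.r <= self.q <= 1.0):
            raise ValueError(f"need 0 <= r <= q <= 1, got q={self.q}, r={self.r}")

    @property
    def extinction_ratio(self) -> float:
        return np.inf if self.r == 0 else self.q / self.r

    def as_dr(self) -> "DichroicRetarderSpec":
        """The same element viewed as a zero-retardance dichroic retarder."""
        return DichroicRetarderSpec(self.theta, self.q, self.r, 0.0)


@dataclass(frozen=True)
class DichroicRetarderSpec:
    """Dichroic retarder: diattenuation (q, r) plus retardance ``delta``.

    ``theta`` is the orientation of the fast/principal axis (degrees),
    ``delta`` the retardance in degrees, ``0 <= delta < 360``.
    """

    theta: float
    q: float
    r: float
    delta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (0.0 <= self.r <= self.q <= 1.0):
            raise ValueError(f"need 0 <= r <= q <= 1, got q={self.q}, r={self.r}")
        if not (0.0 <= self.delta < 360.0):
            raise ValueError(f"delta must be in [0, 360), got {self.delta}")


def rot3(phi_deg: float) -> np.ndarray:
    """Rotation operator on the linear-polarization Stokes subspace.

    ``phi_deg`` is the rotation argument in degrees.  Orthogonal with
    determinant 1.  The element builders conjugate their principal-axes
    cores by ``rot3(-2 * theta)`` for a mount angle ``theta``.
    """
    phi = np.deg2rad(phi_deg)
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def _orient3(core: np.ndarray, theta_deg: float) -> np.ndarray:
    """Conjugate a principal-axes core by the mount rotation.

    The azimuth doubles and the sense is chosen so the (0, 2) element of a
    rotated diattenuator is +sin(2 theta), matching the Stokes convention
    s2 = I(45) - I(135).
    """
    R = rot3(-2.0 * theta_deg)
    return R @ core @ R.T


def _orient4(core: np.ndarray, theta_deg: float) -> np.ndarray:
    out = np.eye(4)
    out[:3, :3] = rot3(-2.0 * theta_deg)
    return out @ core @ out.T


def lp_mueller4(spec: PolarizerSpec) -> np.ndarray:
    """4x4 Mueller matrix of a linear polarizer.

    Core matrix ``[[q+r, q-r, 0, 0], [q-r, q+r, 0, 0], [0, 0, 1, 0],
    [0, 0, 0, 1]]`` conjugated by the rotation at twice the orientation.
    """
    q, r = spec.q, spec.r
    core = np.array(
        [
            [q + r, q - r, 0.0, 0.0],
            [q - r, q + r, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return _orient4(core, spec.theta)


def dr_mueller4(spec: DichroicRetarderSpec) -> np.ndarray:
    """4x4 Mueller matrix of a dichroic retarder."""
    q, r = spec.q, spec.r
    d = np.deg2rad(spec.delta)
    tqr = 2.0 * q * r
    core = np.array(
        [
            [q + r, q - r, 0.0, 0.0],
            [q - r, q + r, 0.0, 0.0],
            [0.0, 0.0, tqr * np.cos(d), tqr * np.sin(d)],
            [0.0, 0.0, -tqr * np.sin(d), tqr * np.cos(d)],
        ]
    )
    return _orient4(core, spec.theta)


def dr_mueller3(spec: DichroicRetarderSpec) -> np.ndarray:
    """3x3 (reduced) Mueller matrix of a dichroic retarder.

    Equals the top-left 3x3 block of :func:`dr_mueller4` exactly.  Its
    eigenvalues are independent of the orientation (similarity by rotation).
    """
    q, r = spec.q, spec.r
    lam3 = 2.0 * q * r * np.cos(np.deg2rad(spec.delta))
    core = np.array(
        [
            [q + r, q - r, 0.0],
            [q - r, q + r, 0.0],
            [0.0, 0.0, lam3],
        ]
    )
    return _orient3(core, spec.theta)


def dr_eigenvalues(spec: DichroicRetarderSpec) -> tuple[float, float, float]:
    """Analytic eigenvalue triple (2q, 2r, 2qr cos(delta)) of the 3x3 DR matrix."""
    lam3 = 2.0 * spec.q * spec.r * np.cos(np.deg2rad(spec.delta))
    return (2.0 * spec.q, 2.0 * spec.r, lam3)


def sort_eigenvalues(lams) -> np.ndarray:
    """Sort descending by real part, ties broken by descending magnitude."""
    lams = np.asarray(lams)
    order = np.lexsort((-np.abs(lams), -np.real(lams)))
    return lams[order]


def eigs_to_params(
    lams,
    sample_type: str = "DR",
    imag_tol: float = 1e-8,
) -> tuple[float, float, float]:
    """Invert the analytic eigenvalue relations to (q, r, delta).

    ``lams`` is the eigenvalue triple sorted per :func:`sort_eigenvalues`
    (``lam1 >= lam2``).  Returns ``q = lam1/2``, ``r = lam2/2`` and
    ``delta = arccos(lam3 / (2 q r))`` in degrees, the argument clamped to
    [-1, 1] within :data:`ARCCOS_CLAMP_TOL`.  An ideal polarizer (r = 0)
    reports ``delta = 0`` by convention.

    ``sample_type`` ('LP' | 'QWP' | 'DR') is accepted for interface symmetry
    with the eigenvalue-assignment stage; the inversion itself is identical
    for all types.
    """
    lams = np.asarray(lams)
    scale = max(np.max(np.abs(lams)), 1e-300)
    if np.max(np.abs(np.imag(lams))) > imag_tol * scale:
        raise ValueError(
            "non-real eigenvalues: a dichroic-retarder 3x3 matrix has a real spectrum"
        )
    lam1, lam2, lam3 = np.real(lams)
    q, r = lam1 / 2.0, lam2 / 2.0
    if q <= 0.0:
        raise ValueError("degenerate sample: leading eigenvalue (2q) is not positive")
    if r <= 0.0:
        return q, max(r, 0.0), 0.0
    x = lam3 / (2.0 * q * r)
    if abs(x) > 1.0 + ARCCOS_CLAMP_TOL:
        raise ValueError(
            f"lam3/(2qr) = {x:.6g} outside [-1, 1] beyond clamping tolerance"
        )
    delta = np.rad2deg(np.arccos(np.clip(x, -1.0, 1.0)))
    return q, r, float(delta)


def m3_from_eigs(lams, theta: float) -> np.ndarray:
    """Reconstruct the 3x3 DR Mueller matrix from its eigenvalues and an orientation.

    The eigenvalue triple fixes the matrix up to the orientation ``theta``
    (degrees); this is the 'partial reconstruction' step of the calibration,
    where eigenvalues come from measurement and theta is fitted.  The third
    eigenvalue is placed on the (2, 2) core element directly, so no retardance
    sign information is needed.
    """
    lams = np.asarray(lams)
    lam1, lam2, lam3 = np.real(lams)
    q, r = lam1 / 2.0, lam2 / 2.0
    core = np.array(
        [
            [q + r, q - r, 0.0],
            [q - r, q + r, 0.0],
            [0.0, 0.0, lam3],
        ]
    )
    return _orient3(core, theta)
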