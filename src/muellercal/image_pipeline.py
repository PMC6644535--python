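"""Per-pixel Mueller-matrix reconstruction and derived maps.

With calibrated instrument matrices A (a x 3) and G (3 x g), the reduced
Mueller matrix of a sample follows from its intensity matrix P = A M G by
double least squares, ``M = pinv(A) P pinv(G)``.  For imaging, P becomes an
H x W x a x g stack (one frame per analyzer/generator state pair) and the
two fixed pseudoinverses are applied to every pixel.

Because the calibration determines A and G only up to one reciprocal pair
of gains, Mueller images are compared and post-processed after m00
normalization (dividing each matrix by its total-intensity element).

The anisotropy map uses the rotation-invariant combination of the linear
birefringence/diattenuation block of the normalized matrix: with
``b = (m11 + m22) / 2`` and ``t = sqrt((m11 - m22)^2 + (m12 + m21)^2) / 2``
(0-based indices into the 3x3 matrix), ``Aniso = 2 b t / (b^2 + t^2)``.
This parameter comes from the Mueller-matrix transformation family of
tissue metrics; it is not part of the calibration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mueller_models import PolarizerSpec, dr_mueller3
from .polarimeter_sim import InstrumentPair, add_noise, simulate_measurement

__all__ = [
    "IntensityStack",
    "MuellerImage",
    "reconstruct_mueller",
    "residual_error",
    "anisotropy_map",
    "rotating_lp_series",
    "rotating_lp_residuals",
]


@dataclass
class IntensityStack:
    """H x W x a x g array of per-state intensity frames."""

    frames: np.ndarray
    state_labels: tuple = ()

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be H x W x a x g")


@dataclass
class MuellerImage:
    """H x W x 3 x 3 array of reconstructed Mueller matrices."""

    matrices: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.shape[-2:] != (3, 3):
            raise ValueError("matrices must end in a 3x3 block")

    def m00_normalized(self) -> "MuellerImage":
        m00 = self.matrices[..., 0, 0]
        if np.any(m00 <= 0):
            raise ValueError("m00 <= 0 somewhere: normalization undefined")
        return MuellerImage(self.matrices / m00[..., None, None], normalized=True)


def reconstruct_mueller(P, A: np.ndarray, G: np.ndarray):
    """Invert P = A M G in the least-squares sense, per matrix or per pixel.

    Accepts a single a x g intensity matrix (returns 3 x 3), an
    IntensityStack or a raw H x W x a x g array (returns a MuellerImage).
    The result is invariant to the calibration's global gain pair (s G, A/s).
    """
    A = np.asarray(A, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.linalg.matrix_rank(A) < 3 or np.linalg.matrix_rank(G) < 3:
        raise ValueError("A and G must have rank 3 for reconstruction")
    pA, pG = np.linalg.pinv(A), np.linalg.pinv(G)
    if isinstance(P, IntensityStack):
        P = P.frames
    P = np.asarray(P, dtype=float)
    if P.ndim == 2:
        return pA @ P @ pG
    if P.ndim == 4:
        return MuellerImage(np.einsum("ij,hwjk,kl->hwil", pA, P, pG))
    raise ValueError(f"P must be 2-D or 4-D, got shape {P.shape}")


def _m00_norm(M: np.ndarray) -> np.ndarray:
    m00 = M[..., 0, 0]
    if np.any(m00 <= 0):
        raise ValueError("m00 <= 0: normalization undefined")
    return M / m00[..., None, None]


def residual_error(M_est: np.ndarray, M_ref: np.ndarray):
    """Frobenius difference of m00-normalized matrices divided by 9.

    Applied element-wise over leading (pixel) dimensions when given images.
    """
    M_est = np.asarray(M_est, dtype=float)
    M_ref = np.asarray(M_ref, dtype=float)
    if M_est.shape != M_ref.shape:
        raise ValueError("shape mismatch")
    diff = _m00_norm(M_est) - _m00_norm(M_ref)
    err = np.linalg.norm(diff, axis=(-2, -1)) / 9.0
    return float(err) if err.ndim == 0 else err


def anisotropy_map(M):
    """Rotation-invariant linear anisotropy in [0, 1] per matrix or pixel.

    Zero for the identity (isotropic) matrix; one when the mean and deviator
    of the linear block balance (b = t).
    """
    if isinstance(M, MuellerImage):
        M = M.m00_normalized().matrices if not M.normalized else M.matrices
    else:
        M = _m00_norm(np.asarray(M, dtype=float))
    b = (M[..., 1, 1] + M[..., 2, 2]) / 2.0
    t = np.sqrt((M[..., 1, 1] - M[..., 2, 2]) ** 2 + (M[..., 1, 2] + M[..., 2, 1]) ** 2) / 2.0
    denom = b * b + t * t
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 2.0 * np.abs(b) * t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def rotating_lp_series(
    instrument: InstrumentPair,
    angles=None,
    q: float = 1.0,
    r: float = 0.0001,
    noise_amplitude: float = 0.0,
    rng=None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Simulated validation series: a high-contrast LP rotated step by step.

    Returns (P_list, M_true_list): the measured intensity matrices (optionally
    noisy) and the analytic sample matrices at each angle.  Mirrors the
    classic bench validation where a test polarizer is rotated from 0 to 350
    degrees in 10-degree steps.
    """
    if angles is None:
        angles = np.arange(0.0, 360.0, 10.0)
    rng = np.random.default_rng(rng)
    P_list, M_list = [], []
    for a in angles:
        M = dr_mueller3(PolarizerSpec(float(a), q, r).as_dr())
        P = simulate_measurement(instrument, M)
        if noise_amplitude > 0:
            P = add_noise(P, noise_amplitude, rng)
        P_list.append(P)
        M_list.append(M)
    return P_list, M_list


def rotating_lp_residuals(
    P_list,
    M_true_list,
    A: np.ndarray,
    G: np.ndarray,
) -> np.ndarray:
    """Per-angle residual errors of the reconstructed rotating-LP matrices."""
    return np.array(
        [
            residual_error(reconstruct_mueller(P, A, G), M_true)
            for P, M_true in zip(P_list, M_true_list)
        ]
    )
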