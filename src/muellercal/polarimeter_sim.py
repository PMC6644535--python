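"""Synthetic polarimeter: instrument matrices, forward model, noise model.

The simulator plays the role of the physical bench: it builds the reduced
PSG matrix ``G`` (3 x g, one generated Stokes state per column) and PSA
matrix ``A`` (a x 3, one analysis vector per row), optionally perturbs them
the way real optics deviate from nominal (mount-angle jitter, attenuation
spread, a residually polarized source), and produces the radiometric
intensity matrix ``P = A @ M @ G`` for a sample with reduced Mueller matrix
``M``.  The calibration algorithm never sees the instrument model - only
``P`` matrices - which is the point of the eigenvalue method.

Noise model: each detector reading receives an independent zero-mean
Gaussian perturbation with standard deviation ``amplitude * ||P||_F``
(Frobenius norm of the noise-free intensity matrix).  The default amplitude
for robustness studies is 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mueller_models import PolarizerSpec, lp_mueller4

__all__ = [
    "InstrumentPair",
    "PerturbationSpec",
    "THREE_STATE_ANGLES",
    "FOUR_STATE_ANGLES",
    "state_angles",
    "nominal_psg",
    "nominal_psa",
    "nominal_instrument",
    "perturb_instrument",
    "simulate_measurement",
    "add_noise",
    "DEFAULT_NOISE_AMPLITUDE",
]

#: Polarizer orientations (degrees) of the two standard configurations.
THREE_STATE_ANGLES = (0.0, 60.0, 120.0)
FOUR_STATE_ANGLES = (0.0, 45.0, 90.0, 135.0)

#: Noise amplitude (fraction of ||P||_F) used throughout the robustness studies.
DEFAULT_NOISE_AMPLITUDE = 0.005


@dataclass(frozen=True)
class InstrumentPair:
    """Reduced PSA matrix ``A`` (a x 3) and PSG matrix ``G`` (3 x g)."""

    A: np.ndarray
    G: np.ndarray
    state_labels: tuple = ()

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        G = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "G", G)
        if A.ndim != 2 or A.shape[1] != 3:
            raise ValueError(f"A must be (a, 3), got {A.shape}")
        if G.ndim != 2 or G.shape[0] != 3:
            raise ValueError(f"G must be (3, g), got {G.shape}")
        if A.shape[0] < 3 or G.shape[1] < 3:
            raise ValueError("need at least three analyzer and generator states")
        if np.linalg.matrix_rank(A) < 3 or np.linalg.matrix_rank(G) < 3:
            raise ValueError("A and G must both have full reduced rank 3")

    @property
    def n_analyzers(self) -> int:
        return self.A.shape[0]

    @property
    def n_generators(self) -> int:
        return self.G.shape[1]

    def air_measurement(self) -> np.ndarray:
        """Null response of the system, P_air = A @ G."""
        return self.A @ self.G


@dataclass(frozen=True)
class PerturbationSpec:
    """How far a simulated instrument strays from nominal.

    angle_sigma : per-state Gaussian mount-angle jitter, degrees.
    q_range, r_range : per-state attenuations drawn uniformly from these
        intervals (subsets of [0, 1]).
    source_dop : residual degree of polarization of the source (0 = ideal).
    source_azimuth : azimuth of the residual source polarization, degrees.
    """

    angle_sigma: float = 0.0
    q_range: tuple[float, float] = (1.0, 1.0)
    r_range: tuple[float, float] = (0.0, 0.0)
    source_dop: float = 0.0
    source_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.angle_sigma < 0:
            raise ValueError("angle_sigma must be >= 0")
        for name, (lo, hi) in (("q_range", self.q_range), ("r_range", self.r_range)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if not (0.0 <= self.source_dop <= 1.0):
            raise ValueError("source_dop must be in [0, 1]")


def _stokes3(angle_deg: float, dop: float = 1.0) -> np.ndarray:
    """First three Stokes components of a beam polarized at ``angle_deg``."""
    a = np.deg2rad(2.0 * angle_deg)
    return np.array([1.0, dop * np.cos(a), dop * np.sin(a)])


def state_angles(config: str) -> tuple[float, ...]:
    if config == "three_state":
        return THREE_STATE_ANGLES
    if config == "four_state":
        return FOUR_STATE_ANGLES
    raise ValueError(f"unknown configuration {config!r}")


def nominal_psg(config: str = "four_state") -> np.ndarray:
    """Nominal PSG matrix: column j = Stokes vector of the j-th generated state."""
    return np.column_stack([_stokes3(a) for a in state_angles(config)])


def nominal_psa(config: str = "four_state") -> np.ndarray:
    """Nominal PSA matrix: row i = (1/2)[1, cos 2a, sin 2a] for analyzer angle a."""
    return 0.5 * np.vstack([_stokes3(a) for a in state_angles(config)])


def nominal_instrument(config: str = "four_state") -> InstrumentPair:
    angles = state_angles(config)
    return InstrumentPair(nominal_psa(config), nominal_psg(config), angles)


def perturb_instrument(
    pair: InstrumentPair,
    spec: PerturbationSpec,
    rng: np.random.Generator | int | None = None,
) -> InstrumentPair:
    """Realize an imperfect instrument around the nominal one.

    Each generator column is the (truncated) Stokes vector produced by an
    imperfect polarizer - ``lp_mueller4`` with jittered angle and drawn
    (q, r) - acting on a partially polarized source; each analyzer row is
    half the first row of an analogous imperfect polarizer.  With a zero
    perturbation spec the nominal pair is returned unchanged.
    """
    rng = np.random.default_rng(rng)
    if not pair.state_labels:
        raise ValueError("perturb_instrument needs state_labels (nominal angles)")
    angles = pair.state_labels
    src = np.append(_stokes3(spec.source_azimuth, spec.source_dop), 0.0)

    def draw_lp(nominal_angle: float) -> PolarizerSpec:
        theta = nominal_angle + spec.angle_sigma * rng.standard_normal()
        q = rng.uniform(*spec.q_range)
        r = min(rng.uniform(*spec.r_range), q)
        return PolarizerSpec(theta, q, r)

    G = np.column_stack(
        [(lp_mueller4(draw_lp(a)) @ src)[:3] for a in angles[: pair.n_generators]]
    )
    A = 0.5 * np.vstack(
        [lp_mueller4(draw_lp(a))[0, :3] for a in angles[: pair.n_analyzers]]
    )
    if np.linalg.matrix_rank(G) < 3 or np.linalg.matrix_rank(A) < 3:
        raise ValueError("perturbation produced a rank-deficient instrument")
    return InstrumentPair(A, G, pair.state_labels)


def simulate_measurement(pair: InstrumentPair, M3: np.ndarray) -> np.ndarray:
    """Radiometric intensity matrix P = A @ M @ G for a 3x3 sample matrix."""
    M3 = np.asarray(M3, dtype=float)
    if M3.shape != (3, 3):
        raise ValueError(f"sample matrix must be 3x3, got {M3.shape}")
    return pair.A @ M3 @ pair.G


def add_noise(
    P: np.ndarray,
    amplitude: float = DEFAULT_NOISE_AMPLITUDE,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Add element-wise Gaussian noise with sd ``amplitude * ||P||_F``."""
    if amplitude < 0:
        raise ValueError("noise amplitude must be >= 0")
    P = np.asarray(P, dtype=float)
    if amplitude == 0:
        return P.copy()
    rng = np.random.default_rng(rng)
    return P + amplitude * np.linalg.norm(P) * rng.standard_normal(P.shape)
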