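"""Optimal-design layer: which calibration-sample combinations condition K best.

The merit figure is the SSLE-R, the ratio mu_2 / mu_max between the second
smallest and largest eigenvalues of the K matrix built from the ideal
sample models at trial orientations.  A large SSLE-R means the null
direction of K (which encodes the PSG matrix G) is well separated from the
rest of the spectrum, hence robust to measurement noise.

Nine standard combinations of linear polarizers (LPs) and quarter-wave
plates (QWPs) are searched, the first sample always being an LP fixed at
0 degrees (it defines the angular reference):

===== ======================================
conf  samples (first free orientation onward)
===== ======================================
1     LP + LP
2     LP + QWP
3     LP + LP + LP
4     LP + LP + QWP
5     LP + QWP + QWP
6     LP + LP + LP + LP
7     LP + LP + LP + QWP
8     LP + LP + QWP + QWP
9     LP + QWP + QWP + QWP
===== ======================================

Sample models are normalized to unit transmission (q + r = 1): the QWP is
(q = r = 1/2, delta = 90 deg) and an LP with extinction ratio ER is
(q = ER/(ER+1), r = 1/(ER+1)).  LPs are ideal (r = 0) by default except in
the two-sample sets (confs 1-2), which are modeled with ER 100:1 because in
the ideal limit their K matrix has a double null eigenvalue and G is
unsolvable.

The noise study simulates the full calibration pipeline - forward model,
Gaussian radiometric noise, orientation fitting, null-space solve - many
times and reports the instrument-matrix errors per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ecm_core import (
    CalibrationSample,
    DegenerateCalibrationWarning,
    build_H,
    calibrate,
    instrument_error,
)
from .mueller_models import DichroicRetarderSpec, dr_mueller3
from .polarimeter_sim import (
    DEFAULT_NOISE_AMPLITUDE,
    InstrumentPair,
    add_noise,
    nominal_instrument,
    simulate_measurement,
)

__all__ = [
    "Configuration",
    "SearchResult",
    "NoiseStudyResult",
    "standard_configurations",
    "sample_spec",
    "sslr_of",
    "scan_configuration",
    "table1_report",
    "noise_study",
]

#: Extinction ratio used for LP models in the two-sample sets (confs 1-2);
#: elsewhere LPs are ideal (r = 0) unless overridden.
FINITE_LP_ER = 100.0
DEFAULT_LP_ER = None

#: Orientation period of a linear element (degrees, physical angle).
PERIOD = 180.0


@dataclass(frozen=True)
class Configuration:
    """One calibration-sample combination.

    ``samples`` is an ordered tuple of (type, orientation) pairs where the
    orientation is a fixed angle in degrees or None for a free (searched /
    fitted) orientation.  ``lp_er`` is the extinction ratio used to model
    every LP sample (None or inf for an ideal polarizer).
    """

    id: int
    samples: tuple[tuple[str, float | None], ...]
    lp_er: float | None = DEFAULT_LP_ER

    def __post_init__(self) -> None:
        if not (2 <= len(self.samples) <= 4):
            raise ValueError("a configuration uses 2-4 calibration samples")
        stype, theta = self.samples[0]
        if stype != "LP" or theta != 0.0:
            raise ValueError("the first sample must be an LP fixed at 0 degrees")

    @property
    def free_indices(self) -> tuple[int, ...]:
        return tuple(i for i, (_, th) in enumerate(self.samples) if th is None)

    @property
    def n_free(self) -> int:
        return len(self.free_indices)


def standard_configurations(
    lp_er: float | None = DEFAULT_LP_ER,
    lp_er_two_sample: float | None = FINITE_LP_ER,
) -> dict[int, Configuration]:
    """The nine standard LP/QWP combinations (first sample: LP at 0 deg).

    ``lp_er`` models the LPs of the three- and four-sample sets (None =
    ideal); ``lp_er_two_sample`` models confs 1-2, finite by necessity.
    """
    LP, QWP = "LP", "QWP"
    layout = {
        1: (LP, LP),
        2: (LP, QWP),
        3: (LP, LP, LP),
        4: (LP, LP, QWP),
        5: (LP, QWP, QWP),
        6: (LP, LP, LP, LP),
        7: (LP, LP, LP, QWP),
        8: (LP, LP, QWP, QWP),
        9: (LP, QWP, QWP, QWP),
    }
    return {
        cid: Configuration(
            cid,
            tuple(
                (t, 0.0 if i == 0 else None) for i, t in enumerate(types)
            ),
            lp_er=lp_er_two_sample if cid in (1, 2) else lp_er,
        )
        for cid, types in layout.items()
    }


def sample_spec(
    sample_type: str, theta: float, lp_er: float | None = DEFAULT_LP_ER
) -> DichroicRetarderSpec:
    """Unit-transmission (q + r = 1) model of a design-stage sample."""
    if sample_type == "LP":
        if lp_er is None or np.isinf(lp_er):
            q, r = 1.0, 0.0
        else:
            q, r = lp_er / (lp_er + 1.0), 1.0 / (lp_er + 1.0)
        return DichroicRetarderSpec(theta, q, r, 0.0)
    if sample_type == "QWP":
        return DichroicRetarderSpec(theta, 0.5, 0.5, 90.0)
    raise ValueError(f"unknown sample type {sample_type!r}")


def _design_matrices(config: Configuration, thetas) -> list[np.ndarray]:
    """Ideal 3x3 sample matrices with free orientations filled from ``thetas``."""
    thetas = list(np.atleast_1d(thetas))
    out = []
    for stype, th in config.samples:
        angle = th if th is not None else thetas.pop(0)
        out.append(dr_mueller3(sample_spec(stype, float(angle), config.lp_er)))
    if thetas:
        raise ValueError("more orientations supplied than free samples")
    return out


def _K_term(M: np.ndarray, pinv_air: np.ndarray, A: np.ndarray, G: np.ndarray):
    D = pinv_air @ A @ M @ G
    H = build_H(D, M)
    return H.T @ H


def sslr_of(
    thetas,
    config: Configuration,
    instrument: InstrumentPair | None = None,
) -> float:
    """SSLE-R (mu_2 / mu_max of K) at the given free orientations."""
    if instrument is None:
        instrument = nominal_instrument("four_state")
    A, G = instrument.A, instrument.G
    pinv_air = np.linalg.pinv(A @ G)
    K = sum(_K_term(M, pinv_air, A, G) for M in _design_matrices(config, thetas))
    mu = np.linalg.eigvalsh(K)
    return float(abs(mu[1]) / mu[-1])


@dataclass
class SearchResult:
    config: Configuration
    best_thetas: tuple[float, ...]
    max_sslr: float
    grid: np.ndarray
    landscape: np.ndarray
    grid_maxima: list[tuple[tuple[float, ...], float]] = field(default_factory=list)


def scan_configuration(
    config: Configuration,
    grid_step: float | None = None,
    instrument: InstrumentPair | None = None,
    refine: bool = True,
    maxima_rtol: float = 1e-4,
) -> SearchResult:
    """Dense SSLE-R landscape over the free orientations, plus refinement.

    Default grid: 1 degree for up to two free angles, 2 degrees for three.
    All grid points within ``maxima_rtol`` (relative) of the best are kept as
    equivalent maxima - the landscapes have many symmetric optima.  The best
    grid point is polished with Nelder-Mead; refinement never lowers the max.
    """
    if instrument is None:
        instrument = nominal_instrument("four_state")
    n_free = config.n_free
    if n_free == 0:
        val = sslr_of([], config, instrument)
        return SearchResult(config, (), val, np.array([]), np.array(val))
    if grid_step is None:
        grid_step = 1.0 if n_free <= 2 else 2.0
    grid = np.arange(0.0, PERIOD, grid_step)

    A, G = instrument.A, instrument.G
    pinv_air = np.linalg.pinv(A @ G)
    dim = 3 * G.shape[1]

    fixed_K = np.zeros((dim, dim))
    free_terms = []
    for stype, th in config.samples:
        if th is not None:
            M = dr_mueller3(sample_spec(stype, th, config.lp_er))
            fixed_K += _K_term(M, pinv_air, A, G)
        else:
            terms = np.empty((grid.size, dim, dim))
            for j, angle in enumerate(grid):
                M = dr_mueller3(sample_spec(stype, float(angle), config.lp_er))
                terms[j] = _K_term(M, pinv_air, A, G)
            free_terms.append(terms)

    shape = (grid.size,) * n_free
    landscape = np.empty(shape)
    flat = landscape.reshape(-1)
    idx = np.unravel_index(np.arange(flat.size), shape)
    chunk = max(1, int(4e6 // (dim * dim)))
    for start in range(0, flat.size, chunk):
        sl = slice(start, min(start + chunk, flat.size))
        Ks = np.broadcast_to(fixed_K, (sl.stop - sl.start, dim, dim)).copy()
        for axis in range(n_free):
            Ks += free_terms[axis][idx[axis][sl]]
        mu = np.linalg.eigvalsh(Ks)
        flat[sl] = np.abs(mu[:, 1]) / mu[:, -1]

    best_flat = int(np.argmax(flat))
    best_val = float(flat[best_flat])
    best_thetas = tuple(float(grid[idx[axis][best_flat]]) for axis in range(n_free))

    cutoff = best_val * (1.0 - maxima_rtol)
    eq_idx = np.nonzero(flat >= cutoff)[0]
    grid_maxima = [
        (
            tuple(float(grid[idx[axis][k]]) for axis in range(n_free)),
            float(flat[k]),
        )
        for k in eq_idx
    ]

    if refine:
        res = minimize(
            lambda t: -sslr_of(t, config, instrument),
            np.array(best_thetas),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000},
        )
        if -res.fun >= best_val:
            best_val = float(-res.fun)
            best_thetas = tuple(float(t % PERIOD) for t in res.x)

    return SearchResult(config, best_thetas, best_val, grid, landscape, grid_maxima)


def table1_report(
    instrument_config: str = "four_state",
    lp_er: float | None = DEFAULT_LP_ER,
    grid_step: float | None = None,
    refine: bool = True,
    config_ids=None,
) -> pd.DataFrame:
    """Optimal orientations and maximum SSLE-R for the nine standard sets."""
    instrument = nominal_instrument(instrument_config)
    configs = standard_configurations(lp_er)
    if config_ids is None:
        config_ids = sorted(configs)
    rows = []
    for cid in config_ids:
        cfg = configs[cid]
        res = scan_configuration(cfg, grid_step=grid_step, instrument=instrument, refine=refine)
        rows.append(
            {
                "configuration": cid,
                "n_samples": len(cfg.samples),
                "types": "+".join(t for t, _ in cfg.samples),
                "best_thetas": tuple(round(t, 2) for t in res.best_thetas),
                "max_sslr": res.max_sslr,
            }
        )
    return pd.DataFrame(rows).set_index("configuration")


@dataclass
class NoiseStudyResult:
    config: Configuration
    thetas: tuple[float, ...]
    eps_G: np.ndarray
    eps_A: np.ndarray
    degenerate: np.ndarray
    failed: np.ndarray

    @property
    def mean_error(self) -> float:
        """Pooled mean of the PSG and PSA errors over successful replicates."""
        ok = ~self.failed
        return float(np.mean(np.concatenate([self.eps_G[ok], self.eps_A[ok]])))


def noise_study(
    config: Configuration,
    thetas,
    n_reps: int = 100,
    amplitude: float = DEFAULT_NOISE_AMPLITUDE,
    seed: int = 0,
    instrument: InstrumentPair | None = None,
    grid_step: float | None = None,
) -> NoiseStudyResult:
    """Monte-Carlo robustness of the calibration under radiometric noise.

    For each replicate: simulate the air and sample measurements of the
    configuration (true sample matrices at the supplied orientations), add
    Gaussian noise of the given amplitude to every intensity matrix, run the
    full calibration (including orientation fitting), and record the
    instrument-matrix errors against the simulation truth.  Degenerate and
    failed replicates are flagged, never silently dropped.

    The true orientations are passed to the calibration as rough hints,
    mirroring bench practice where the operator knows where the samples were
    placed to within a few degrees; the fit still determines them precisely.
    """
    if instrument is None:
        instrument = nominal_instrument("four_state")
    thetas = tuple(np.atleast_1d(thetas).astype(float))
    if len(thetas) != config.n_free:
        raise ValueError(
            f"configuration {config.id} needs {config.n_free} free orientations"
        )
    M_true = _design_matrices(config, thetas)
    P_air_clean = instrument.air_measurement()
    P_clean = [simulate_measurement(instrument, M) for M in M_true]

    eps_G = np.full(n_reps, np.nan)
    eps_A = np.full(n_reps, np.nan)
    degenerate = np.zeros(n_reps, dtype=bool)
    failed = np.zeros(n_reps, dtype=bool)
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        air = add_noise(P_air_clean, amplitude, rng)
        free_iter = iter(thetas)
        samples = [
            CalibrationSample(
                stype,
                add_noise(P, amplitude, rng),
                theta_known=th,
                theta_hint=None if th is not None else next(free_iter),
            )
            for (stype, th), P in zip(config.samples, P_clean)
        ]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateCalibrationWarning)
                result = calibrate(air, samples, grid_step=grid_step)
        except ValueError:
            failed[rep] = True
            continue
        degenerate[rep] = result.degenerate
        eps_G[rep] = instrument_error(result.G_cal, instrument.G)
        eps_A[rep] = instrument_error(result.A_cal, instrument.A)
    return NoiseStudyResult(config, thetas, eps_G, eps_A, degenerate, failed)
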