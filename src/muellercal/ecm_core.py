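"""Eigenvalue calibration of a 3x3 Mueller polarimeter.

Given an air (empty-beam) intensity matrix ``P_air = A G`` and intensity
matrices ``P_i = A M_i G`` of a few calibration samples whose dichroic-
retarder parameters and orientations are only approximately known, recover
the reduced instrument matrices ``A`` and ``G``:

1. ``D_i = pinv(P_air) @ P_i`` is similar to the sample matrix ``M_i``
   (``G D_i = M_i G``), so the eigenvalues of ``D_i`` reveal the sample's
   (q, r, delta) regardless of its orientation.
2. Each sample matrix is rebuilt from its measured eigenvalues at a trial
   orientation; the Sylvester relation ``G D_i - M_i G = 0`` becomes
   ``H_i vec(G) = 0`` with ``H_i = D_i^T (x) I_3 - I_g (x) M_i`` (column
   stacking).
3. ``K = sum_i H_i^T H_i`` is symmetric positive semidefinite; ``vec(G)``
   spans its null space when the trial orientations are right.  Free
   orientations are fitted by minimizing mu_1/mu_2, the ratio of the two
   smallest eigenvalues of K.
4. ``G`` is the null eigenvector of the fitted K, and ``A = P_air pinv(G)``.

The recovery is exact up to one global scalar (a gain shared between A and
1/G) which cancels in every downstream Mueller estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .mueller_models import m3_from_eigs, sort_eigenvalues

__all__ = [
    "CalibrationSample",
    "KSpectrum",
    "CalibrationResult",
    "DegenerateCalibrationWarning",
    "intermediate_matrix",
    "sample_eigenvalues",
    "build_H",
    "build_K",
    "solve_G",
    "orientation_objective",
    "fit_orientations",
    "recover_A",
    "calibrate",
    "instrument_error",
]

logger = logging.getLogger(__name__)

#: mu_1/mu_2 above this marks a calibration set that does not pin down G.
DEGENERACY_THRESHOLD = 0.1

#: SSLE-R (mu_2/mu_max) below this means mu_2 is itself numerically null:
#: K has at least a double null space regardless of the mu_1/mu_2 ratio.
SSLR_NULL_THRESHOLD = 1e-6

#: Orientation period (degrees): a linear element's Mueller matrix is
#: invariant under a 180 deg rotation of its principal axis.
ORIENTATION_PERIOD = 180.0


class DegenerateCalibrationWarning(UserWarning):
    """K has more than one (near-)null eigenvalue: G is not uniquely determined."""


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration measurement.

    sample_type : 'LP' | 'QWP' | 'DR' - drives the spurious-eigenvalue
        assignment when the instrument has more than three states.
    measured : the a x g intensity matrix of this sample.
    theta_known : fixed orientation in degrees, or None when the orientation
        is to be fitted.  By convention the first sample of a set is an LP
        fixed at 0 degrees (it defines the instrument's angular reference).
    theta_hint : optional rough orientation (tens of degrees accuracy is
        enough); windows the orientation search and selects the physical
        reflection branch (see :func:`fit_orientations`).
    """

    sample_type: str
    measured: np.ndarray
    theta_known: float | None = None
    theta_hint: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("LP", "QWP", "DR"):
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        object.__setattr__(self, "measured", np.asarray(self.measured, dtype=float))


@dataclass(frozen=True)
class KSpectrum:
    """Ordered spectrum of K plus the two diagnostic ratios."""

    mu: np.ndarray

    @property
    def null_ratio(self) -> float:
        """|mu_1| / |mu_2| - small when K has exactly one null direction."""
        return float(abs(self.mu[0]) / abs(self.mu[1]))

    @property
    def sslr(self) -> float:
        """Second-smallest over largest eigenvalue (conditioning merit)."""
        return float(abs(self.mu[1]) / self.mu[-1])


@dataclass
class CalibrationResult:
    G_cal: np.ndarray
    A_cal: np.ndarray
    fitted_thetas: dict[int, float]
    spectrum: KSpectrum
    sample_params: list[tuple[float, float, float]]
    sample_eigs: list[np.ndarray] = field(default_factory=list)
    degenerate: bool = False


def intermediate_matrix(P_air: np.ndarray, P_i: np.ndarray) -> np.ndarray:
    """D = pinv(P_air) @ P_i, similar to the sample's 3x3 Mueller matrix.

    The Moore-Penrose pseudoinverse handles instruments with more than three
    states, where P_air is not square/invertible; the similarity
    ``G D = M G`` still holds because A has full column rank.  Since the
    reduced instrument model makes P_air exactly rank 3, the pseudoinverse
    is truncated to the three leading singular values - inverting the
    noise-dominated trailing ones would otherwise flood D with spurious
    O(1) eigenvalues.
    """
    P_air = np.asarray(P_air, dtype=float)
    P_i = np.asarray(P_i, dtype=float)
    if P_air.shape != P_i.shape:
        raise ValueError(f"shape mismatch: {P_air.shape} vs {P_i.shape}")
    U, s, Vt = np.linalg.svd(P_air, full_matrices=False)
    if s[2] <= 1e-12 * s[0]:
        raise ValueError("air measurement has rank < 3: system not calibratable")
    inv = np.zeros_like(s)
    inv[:3] = 1.0 / s[:3]
    return (Vt.T * inv) @ U.T @ P_i


def sample_eigenvalues(
    D: np.ndarray,
    sample_type: str = "DR",
    imag_tol: float = 0.1,
) -> np.ndarray:
    """The three eigenvalues of the sample matrix hidden inside D.

    D has g eigenvalues; when g > 3 one of them is a spurious zero from the
    rank deficiency of the air matrix and must be told apart from a genuine
    small sample eigenvalue:

    * 'LP'  - keep the triple most consistent with the zero-retardance
      relation lam3 = lam1 * lam2 / 2 (since 2qr = (2q)(2r)/2).
    * 'QWP' / 'DR' - the two largest eigenvalues are (2q, 2r); of the
      remaining candidates discard the one closest to zero (an imperfect
      wave plate has a small but genuine lam3 that must not be confused
      with the rank-deficiency zero).

    Noise can split near-degenerate real pairs into conjugate pairs; the
    real parts are used, and imaginary parts larger than ``imag_tol`` times
    the spectral radius raise a data-inconsistency error.
    """
    D = np.asarray(D)
    lams = np.linalg.eigvals(D)
    scale = max(np.max(np.abs(lams)), 1e-300)
    if np.max(np.abs(lams.imag)) > imag_tol * scale:
        raise ValueError(
            "intermediate matrix has strongly complex eigenvalues; "
            "measurements are inconsistent with the dichroic-retarder model"
        )
    lams = np.real(sort_eigenvalues(lams))
    g = lams.size
    if g == 3:
        return lams
    if g < 3:
        raise ValueError("intermediate matrix smaller than 3x3")

    # enumerate every way of discarding (g - 3) eigenvalues, score the triples
    from itertools import combinations

    best, best_score = None, np.inf
    for keep in combinations(range(g), 3):
        if keep[0] != 0:
            continue  # the leading eigenvalue (2q) is always genuine
        triple = lams[list(keep)]  # still sorted descending
        lam1, lam2, lam3 = triple
        if sample_type == "LP":
            score = abs(lam3 - lam1 * lam2 / 2.0)
        else:
            # keep the two largest (they are 2q >= 2r >= |lam3| for q <= 1),
            # and prefer the lam3 candidate farthest from the spurious zero
            if keep[0] != 0 or keep[1] != 1:
                continue
            score = -abs(lam3)
        if score < best_score:
            best, best_score = triple, score
    return np.asarray(best)


def build_H(D: np.ndarray, M3: np.ndarray) -> np.ndarray:
    """Kronecker form of the Sylvester relation: H @ vec(G) = vec(G D - M G).

    vec stacks columns, hence H = D^T (x) I_3 - I_g (x) M.
    """
    D = np.asarray(D, dtype=float)
    M3 = np.asarray(M3, dtype=float)
    g = D.shape[0]
    return np.kron(D.T, np.eye(3)) - np.kron(np.eye(g), M3)


def build_K(H_list) -> np.ndarray:
    """K = sum_i H_i^T H_i - symmetric PSD; vec(G) spans its null space."""
    H_list = list(H_list)
    if not H_list:
        raise ValueError("need at least one H matrix")
    K = np.zeros_like(H_list[0], dtype=float)
    for H in H_list:
        K += H.T @ H
    return K


def solve_G(
    K: np.ndarray,
    degeneracy_threshold: float = DEGENERACY_THRESHOLD,
) -> tuple[np.ndarray, KSpectrum]:
    """Null eigenvector of K un-stacked to the 3 x g PSG matrix.

    The returned G has unit Frobenius norm with the sum of its first
    (total-intensity) row positive; the arbitrary scale cancels against A
    in every Mueller estimate.  A ``DegenerateCalibrationWarning`` is issued
    when mu_1/mu_2 exceeds ``degeneracy_threshold``.
    """
    K = np.asarray(K, dtype=float)
    mu, vecs = np.linalg.eigh(K)
    spectrum = KSpectrum(mu)
    g = K.shape[0] // 3
    G = vecs[:, 0].reshape((3, g), order="F")
    if G[0].sum() < 0:
        G = -G
    if spectrum.sslr < SSLR_NULL_THRESHOLD or spectrum.null_ratio > degeneracy_threshold:
        warnings.warn(
            f"mu1/mu2 = {spectrum.null_ratio:.3g}, sslr = {spectrum.sslr:.3g}: "
            "G is not uniquely determined by this calibration set",
            DegenerateCalibrationWarning,
            stacklevel=2,
        )
    logger.info(
        "solve_G: mu1=%.3e mu2=%.3e sslr=%.4f", mu[0], mu[1], spectrum.sslr
    )
    return G, spectrum


def _stack_K_terms(D_list, eig_list, thetas_by_index):
    """K contributions (H^T H) for every sample at given orientations."""
    terms = []
    for i, (D, eigs) in enumerate(zip(D_list, eig_list)):
        M = m3_from_eigs(eigs, thetas_by_index[i])
        H = build_H(D, M)
        terms.append(H.T @ H)
    return terms


def orientation_objective(
    thetas,
    D_list,
    eig_list,
    free_indices,
    fixed_thetas: dict[int, float],
) -> float:
    """mu_1/mu_2 of K with the free samples placed at the trial orientations."""
    all_thetas = dict(fixed_thetas)
    for idx, th in zip(free_indices, np.atleast_1d(thetas)):
        all_thetas[idx] = float(th)
    terms = _stack_K_terms(D_list, eig_list, all_thetas)
    K = np.sum(terms, axis=0)
    mu = np.linalg.eigvalsh(K)
    return float(mu[0] / mu[1])


#: Smallest acceptable sigma_3/sigma_1 of the candidate G: null vectors that
#: un-stack to a (near-)rank-deficient 3 x g matrix are unphysical artifacts
#: of idealized sample models and are rejected during orientation fitting.
G_RANK_TOL = 0.02


def _null_vector_G(K: np.ndarray) -> np.ndarray:
    mu, vecs = np.linalg.eigh(K)
    g = K.shape[0] // 3
    return vecs[:, 0].reshape((3, g), order="F")


def _G_rank_ratio(K: np.ndarray) -> float:
    sv = np.linalg.svd(_null_vector_G(K), compute_uv=False)
    return float(sv[-1] / sv[0])


def _grid_objective(D_list, eig_list, free_indices, fixed_thetas, axes):
    """Vectorized mu1/mu2 over the joint orientation grid (cached K terms).

    ``axes`` is one angle array per free sample.  Returns the flat objective
    values, the flat index tuples and the per-sample K terms so callers can
    re-assemble K at any grid point cheaply.
    """
    n_free = len(free_indices)
    dim = 3 * D_list[0].shape[0]
    fixed_K = np.zeros((dim, dim))
    for idx, th in fixed_thetas.items():
        M = m3_from_eigs(eig_list[idx], th)
        H = build_H(D_list[idx], M)
        fixed_K += H.T @ H
    per_sample = []
    for axis, idx in enumerate(free_indices):
        grid = axes[axis]
        terms = np.empty((grid.size, dim, dim))
        for j, th in enumerate(grid):
            H = build_H(D_list[idx], m3_from_eigs(eig_list[idx], th))
            terms[j] = H.T @ H
        per_sample.append(terms)

    shape = tuple(ax.size for ax in axes)
    n_total = int(np.prod(shape))
    vals = np.empty(n_total)
    idx_flat = np.unravel_index(np.arange(n_total), shape)
    chunk = max(1, int(2e6 // (dim * dim)))
    for start in range(0, n_total, chunk):
        sl = slice(start, min(start + chunk, n_total))
        Ks = np.broadcast_to(fixed_K, (sl.stop - sl.start, dim, dim)).copy()
        for axis in range(n_free):
            Ks += per_sample[axis][idx_flat[axis][sl]]
        mu = np.linalg.eigvalsh(Ks)
        vals[sl] = mu[:, 0] / mu[:, 1]

    def K_at(flat_index: int) -> np.ndarray:
        K = fixed_K.copy()
        for axis in range(n_free):
            K += per_sample[axis][idx_flat[axis][flat_index]]
        return K

    return vals, idx_flat, K_at


def fit_orientations(
    D_list,
    eig_list,
    free_indices,
    fixed_thetas: dict[int, float],
    grid_step: float | None = None,
    refine: bool = True,
    hints: dict[int, float] | None = None,
    hint_window: float = 20.0,
    rank_tol: float = G_RANK_TOL,
) -> dict[int, float]:
    """Fit the unknown sample orientations by minimizing mu_1/mu_2 of K.

    A joint exhaustive grid (default step: 2 degrees for up to two free
    angles, 6 degrees for three) locates the basin; Nelder-Mead then
    polishes the best grid point.  Refinement never increases the objective.

    Without hints each free angle is searched over the full period
    [0, 180).  The intensity data determine the orientations only up to a
    global reflection (theta_i -> -theta_i with the 0-degree reference
    unchanged, which mirrors G by a sign flip of its last row), and with
    idealized rank-deficient sample models the objective acquires spurious
    zeros at coincident trial angles.  Candidate minima whose K null vector
    un-stacks to a near-rank-deficient G are therefore rejected
    (``rank_tol`` on the singular-value ratio), and approximate orientations
    may be supplied via ``hints`` - the search is then windowed to
    ``hint_window`` degrees around each hint, which also picks the physical
    reflection branch.  Rough knowledge (tens of degrees) suffices, in
    keeping with the method's premise that precise orientations are unknown.
    """
    if not free_indices:
        return dict(fixed_thetas)
    n_free = len(free_indices)
    if grid_step is None:
        grid_step = 2.0 if n_free <= 2 else 6.0
    hints = hints or {}
    axes = []
    for idx in free_indices:
        if idx in hints:
            lo = hints[idx] - hint_window
            axes.append(lo + np.arange(0.0, 2 * hint_window + grid_step, grid_step))
        else:
            axes.append(np.arange(0.0, ORIENTATION_PERIOD, grid_step))
    vals, idx_flat, K_at = _grid_objective(
        D_list, eig_list, free_indices, fixed_thetas, axes
    )

    # pick the best grid point whose null vector is a genuine rank-3 G
    order = np.argsort(vals)
    best_flat = int(order[0])
    for k in order[: max(200, n_free * 80)]:
        if _G_rank_ratio(K_at(int(k))) >= rank_tol:
            best_flat = int(k)
            break
    best_val = float(vals[best_flat])
    thetas = np.array(
        [axes[a][idx_flat[a][best_flat]] for a in range(n_free)], dtype=float
    )

    if refine:
        res = minimize(
            orientation_objective,
            thetas,
            args=(D_list, eig_list, free_indices, fixed_thetas),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 1000},
        )
        if res.fun <= best_val:
            all_thetas = dict(fixed_thetas)
            for idx, th in zip(free_indices, np.atleast_1d(res.x)):
                all_thetas[idx] = float(th)
            K_ref = np.sum(_stack_K_terms(D_list, eig_list, all_thetas), axis=0)
            if _G_rank_ratio(K_ref) >= rank_tol:
                thetas = np.atleast_1d(res.x)
    out = dict(fixed_thetas)
    for idx, th in zip(free_indices, np.atleast_1d(thetas)):
        out[idx] = float(th % ORIENTATION_PERIOD)
    return out


def _polish_orientations(
    D_list, eig_list, free_indices, thetas: dict[int, float]
) -> dict[int, float]:
    """Joint Gauss-Newton refinement of the fitted orientations.

    Minimizes the stacked Sylvester residuals ``H_i(theta) vec(G)`` over the
    free orientations and vec(G) together (with a unit-norm gauge row).
    This is the quantity whose minimum over G alone is mu_1 of K, but
    treating (theta, G) jointly makes the residual exactly zero at the
    noiseless solution, so a least-squares step converges quadratically to
    machine precision where the mu_1/mu_2 landscape has long bottomed out
    in eigensolver noise.
    """
    from scipy.optimize import least_squares

    thetas = dict(thetas)
    K = np.sum(_stack_K_terms(D_list, eig_list, thetas), axis=0)
    mu, vecs = np.linalg.eigh(K)
    g = K.shape[0] // 3
    vG0 = vecs[:, 0]
    n_free = len(free_indices)

    def residuals(x):
        th = dict(thetas)
        for j, idx in enumerate(free_indices):
            th[idx] = x[j]
        vG = x[n_free:]
        res = [
            build_H(D_list[i], m3_from_eigs(eig_list[i], th[i])) @ vG
            for i in range(len(D_list))
        ]
        res.append(np.atleast_1d(vG @ vG - 1.0))
        return np.concatenate(res)

    x0 = np.concatenate([[thetas[i] for i in free_indices], vG0])
    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=300,
    )
    if np.linalg.norm(sol.fun) <= np.linalg.norm(residuals(x0)):
        for j, idx in enumerate(free_indices):
            thetas[idx] = float(sol.x[j])
    return thetas


def recover_A(P_air: np.ndarray, G: np.ndarray, check_rank: bool = True) -> np.ndarray:
    """Least-squares solution of P_air = A G, i.e. A = P_air @ pinv(G).

    With ``check_rank`` (the default) a rank-deficient G is an error; the
    calibration orchestrator disables the check for degenerate sets so the
    (meaningless but well-defined) minimum-norm solution can be scored.
    """
    G = np.asarray(G, dtype=float)
    if check_rank and np.linalg.matrix_rank(G) < 3:
        raise ValueError("G is rank deficient; cannot recover A")
    return np.asarray(P_air, dtype=float) @ np.linalg.pinv(G)


def calibrate(
    air: np.ndarray,
    samples: list[CalibrationSample],
    grid_step: float | None = None,
    refine: bool = True,
    degeneracy_threshold: float = DEGENERACY_THRESHOLD,
    imag_tol: float = 0.1,
    hint_window: float = 20.0,
) -> CalibrationResult:
    """Run the full eigenvalue calibration on one set of measurements.

    Requires at least two samples, exactly one of which (the angular
    reference, conventionally the first) has ``theta_known`` set.
    """
    if len(samples) < 2:
        raise ValueError("need at least two calibration samples")
    n_known = sum(s.theta_known is not None for s in samples)
    if n_known == 0:
        raise ValueError("one sample must have a known orientation (the reference)")

    D_list = [intermediate_matrix(air, s.measured) for s in samples]
    eig_list = [
        sample_eigenvalues(D, s.sample_type, imag_tol=imag_tol)
        for D, s in zip(D_list, samples)
    ]
    fixed = {
        i: float(s.theta_known)
        for i, s in enumerate(samples)
        if s.theta_known is not None
    }
    free = [i for i, s in enumerate(samples) if s.theta_known is None]
    hints = {
        i: float(s.theta_hint)
        for i, s in enumerate(samples)
        if s.theta_known is None and s.theta_hint is not None
    }
    thetas = fit_orientations(
        D_list, eig_list, free, fixed, grid_step=grid_step, refine=refine,
        hints=hints, hint_window=hint_window,
    )
    if refine and free:
        # accepts internally only if the Sylvester residual decreases
        polished = _polish_orientations(D_list, eig_list, free, thetas)
        thetas = {k: float(v % ORIENTATION_PERIOD) for k, v in polished.items()}

    terms = _stack_K_terms(D_list, eig_list, thetas)
    K = np.sum(terms, axis=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateCalibrationWarning)
        G_cal, spectrum = solve_G(K, degeneracy_threshold)
        degenerate = any(
            issubclass(w.category, DegenerateCalibrationWarning) for w in caught
        )
    sv = np.linalg.svd(G_cal, compute_uv=False)
    if sv[-1] < 1e-6 * sv[0]:
        # the null direction un-stacked to a rank-deficient G: the set did
        # not determine the instrument even if the K spectrum looked benign
        degenerate = True
    if degenerate:
        warnings.warn(
            "calibration set is degenerate (see K spectrum diagnostics)",
            DegenerateCalibrationWarning,
            stacklevel=2,
        )
    A_cal = recover_A(air, G_cal, check_rank=not degenerate)

    from .mueller_models import eigs_to_params

    params = []
    for eigs in eig_list:
        try:
            params.append(eigs_to_params(eigs, imag_tol=np.inf))
        except ValueError:
            # noise can push lam3 outside the arccos domain for a
            # near-ideal polarizer; report the attenuations anyway
            lam1, lam2 = np.real(eigs[0]), np.real(eigs[1])
            params.append((lam1 / 2.0, max(lam2, 0.0) / 2.0, np.nan))
    return CalibrationResult(
        G_cal=G_cal,
        A_cal=A_cal,
        fitted_thetas={i: thetas[i] for i in free},
        spectrum=spectrum,
        sample_params=params,
        sample_eigs=eig_list,
        degenerate=degenerate,
    )


def instrument_error(X_cal: np.ndarray, X_true: np.ndarray) -> float:
    """Frobenius error per element between scale-matched matrices.

    The calibrated matrix carries an arbitrary scale (and sign), so it is
    first matched to the truth by the least-squares scalar
    ``s = <X_cal, X_true> / <X_cal, X_cal>``; the error is
    ``||s X_cal - X_true||_F / N`` with N the number of elements.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_true = np.asarray(X_true, dtype=float)
    if X_cal.shape != X_true.shape:
        raise ValueError(f"shape mismatch: {X_cal.shape} vs {X_true.shape}")
    denom = float(np.sum(X_cal * X_cal))
    s = float(np.sum(X_cal * X_true)) / denom if denom > 0 else 0.0
    return float(np.linalg.norm(s * X_cal - X_true) / X_cal.size)
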