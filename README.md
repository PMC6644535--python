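# muellercal

Eigenvalue calibration and optimal experiment design for 3×3 Mueller
polarimeters.

A 3×3 Mueller polarimeter uses only linear polarizers in its polarization
state generator (PSG) and analyzer (PSA) and measures the top-left 3×3
block of a sample's Mueller matrix — enough for linear diattenuation and
retardance imaging of tissue and other scattering media, at a fraction of
the complexity of a full 4×4 instrument. The catch is calibration: the
polarizer orientations θ, attenuations (q, r) and the source polarization
all deviate from nominal, and classical null-intensity alignment corrects
only θ.

`muellercal` implements the eigenvalue calibration method for such
instruments. From an air (empty-beam) measurement `P_air = A G` and a few
measurements `P_i = A M_i G` of calibration samples whose properties and
orientations need only be *roughly* known, it recovers the reduced
instrument matrices `A` (a×3) and `G` (3×g) without modeling the PSG or
PSA at all:

1. `D_i = P_air⁺ P_i` is similar to the sample matrix `M_i`, so the
   eigenvalues of `D_i` equal those of `M_i` — for any dichroic-retarder
   sample the analytic triple (2q, 2r, 2qr·cosΔ), independent of
   orientation. Each sample matrix is rebuilt from measured eigenvalues up
   to its orientation θᵢ.
2. The Sylvester relation `G Dᵢ − Mᵢ G = 0` vectorizes to
   `Hᵢ vec(G) = 0` with `Hᵢ = Dᵢᵀ ⊗ I₃ − I_g ⊗ Mᵢ`, and
   `K = Σ Hᵢᵀ Hᵢ` is positive semidefinite with `vec(G)` as its null
   eigenvector. Unknown orientations are fitted by minimizing μ₁/μ₂, the
   ratio of the two smallest eigenvalues of K.
3. `A = P_air G⁺` closes the loop; per-pixel Mueller images follow as
   `M = A⁺ P G⁺`.

The package also answers the design question *which calibration samples
should one use*: it maximizes the SSLE-R — the ratio μ₂/μ_max of the
second-smallest to largest eigenvalue of K — over the sample orientations
for nine standard combinations of linear polarizers (LP) and quarter-wave
plates (QWP), and quantifies noise robustness by Monte-Carlo simulation of
the full calibration loop. A synthetic polarimeter (nominal or perturbed
instruments, forward model, Gaussian radiometric noise) makes every study
self-contained; no external data are needed.

## Worked example

Calibrate a deliberately imperfect four-state instrument from four
finite-extinction polarizer samples near 0°/45°/90°/135° (orientations
supplied only as integer-degree hints), with 0.5 % radiometric noise:

```python
import numpy as np
import muellercal as mc
from muellercal.mueller_models import DichroicRetarderSpec, dr_mueller3

rng = np.random.default_rng(7)
truth = mc.perturb_instrument(
    mc.nominal_instrument("four_state"),
    mc.PerturbationSpec(angle_sigma=1.0, q_range=(0.85, 1.0),
                        r_range=(0.0, 0.02), source_dop=0.03,
                        source_azimuth=30.0),
    rng,
)
specs = [DichroicRetarderSpec(t, q, r, 0.0) for t, q, r in
         [(0.0, 0.98, 0.004), (44.0, 0.97, 0.005),
          (91.0, 0.99, 0.003), (136.0, 0.96, 0.006)]]
air = mc.add_noise(truth.air_measurement(), 0.005, rng)
samples = [
    mc.CalibrationSample(
        "LP",
        mc.add_noise(mc.simulate_measurement(truth, dr_mueller3(s)), 0.005, rng),
        theta_known=0.0 if i == 0 else None,
        theta_hint=None if i == 0 else round(s.theta),
    )
    for i, s in enumerate(specs)
]
result = mc.calibrate(air, samples)
```

This prints (via the fields of `result`):

```
fitted orientations: {1: 44.187, 2: 90.967, 3: 136.409}
mu1=1.833e-03  mu2=3.021e+00  SSLE-R=0.2401
eps_G=0.00438  eps_A=0.00190
```

The fitted orientations land within ~0.4° of the simulated truth
(44°/91°/136°), the K spectrum shows one well-isolated null direction
(μ₁/μ₂ ≈ 6×10⁻⁴) with the healthy SSLE-R expected of the four-LP sample
set, and the recovered instrument matrices agree with the truth to a few
parts in 10³ per element (`eps_G`, `eps_A` are Frobenius errors against the
scale-matched truth divided by the number of matrix elements) — entirely
noise-limited: with the noise turned off the same run recovers `A` and `G`
to machine precision.

## Command line

```bash
muellercal simulate --configuration 6 --noise 0.005 --seed 1 --outdir run1
muellercal calibrate run1           # K diagnostics + calibration.npz
muellercal search --outdir design   # optimal-orientation table, all 9 sets
muellercal noise-study --configuration 6 --reps 100 --outdir noise6
muellercal reconstruct stack.npz run1/calibration.npz --outdir images
```

Every run writes a JSON manifest (config hash, seed, package version);
reruns with the same seed reproduce stochastic outputs exactly, and
`calibrate` exits with status 3 when the sample set leaves G undetermined
(as the two-sample sets do).

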