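# whiskmech

Mechanical fingerprinting of rodent whiskers.

Rodents sense the world through their facial vibrissae, and an increasing
number of behavioural studies need to track individual whiskers in
high-speed video — for example after marking them with a fluorescent dye.
Any surface treatment, however, might change a whisker's mass or stiffness
and therefore the vibrotactile signal reaching the follicle. `whiskmech`
implements a complete analysis for settling that question *mechanically*:
it characterises a whisker by its dynamic response and quantifies whether a
treatment changed it.

The package is aimed at sensory-neuroscience and biomechanics labs working
with whisker vibration data, and it ships a synthetic-data module that
emulates the whole ex vivo experiment (shaker, camera, fluorescence decay,
behavioural sessions), so every stage can be validated end to end without
any raw video.

## The model and the fingerprint

A whisker is modelled as a linearly tapered Euler-Bernoulli cantilever with
Rayleigh damping, clamped at the base and driven by an imposed transverse
base displacement δ(t):

    ρA(x)(v_tt + α v_t) + ∂²/∂x²[E J(x)(v_xx + β v_txx)] = 0
    v(0,t) = δ(t),  v_x(0,t) = 0,  v_xx(L,t) = v_xxx(L,t) = 0

with radius r(x) = r_b − (r_b − r_t)x/L, A = πr², J = πr⁴/4. The model is
discretised with 200 Hermite-cubic beam elements and solved in the
frequency domain, giving the frequency response function H(x, ω) =
V(x, iω)/Δ(iω).

The magnitude |H| over a (frequency × normalised position) grid — the
**mFRF** — is the whisker's mechanical fingerprint. From video, the mFRF is
estimated per shaft segment with the Welch/H1 cross-spectral estimator
H_i(f) = S_{xy_i}(f)/S_{xx}(f), where x is the tracked base motion, and
averaged over 10 white-noise trials. Two fingerprints are compared by
vectorising their log₁₀-magnitude matrices and computing the squared
Pearson correlation **R²** — 1 for identical dynamics, 0 for uncorrelated
responses. For a whisker set ordered by length, the mean of each similarity
sub/super-diagonal (θ_i) summarises how similarity decays with length
disparity.

## Worked example

```python
import numpy as np
import whiskmech as wm
from whiskmech.config import beam_setup
from whiskmech.spectral import magnitude_from_complex

# default D2-like whisker: L = 30 mm, r_b = 60 um, r_t = 3 um,
# E = 3 GPa, rho = 1200 kg/m^3, alpha = 10 1/s, beta = 2e-5 s
geom, mat, mesh, grid = beam_setup(None)

modes = wm.modal_frequencies(geom, mat, mesh, 3)
print(np.round(modes.modal_frequencies, 1))   # [ 66.2 163.1 306.2]

# simulate 10 shaker trials and recover the fingerprint from them
frf = wm.solve_frf(geom, mat, mesh, grid)
trials = []
for t in range(10):
    stim = wm.gen_stimulus(seed=t)            # 2.25 s of 1 kHz-limited noise
    field = wm.synth_deflection_field(frf, stim, n_positions=25)
    trials.append(wm.estimate_mfrf(field))
est = wm.average_mfrf(trials)
truth = magnitude_from_complex(frf, frequencies=est.frequencies,
                               positions=est.positions)
print(round(wm.similarity_r2(est, truth), 4))  # 0.9996

# treatment contrast: dye-analog (+0.7% density) vs polish-analog
pos = np.linspace(0, 1, 25)
base = magnitude_from_complex(frf, positions=pos)
for name in ("dye", "polish"):
    _, treated = wm.perturb_whisker(geom, mat, name)
    frf_t = wm.solve_frf(geom, treated, mesh, grid)
    print(name, round(wm.similarity_r2(base,
          magnitude_from_complex(frf_t, positions=pos)), 3))
# dye 0.999
# polish 0.298
```

The first three resonances of the default whisker sit at 66, 163 and
306 Hz. The Welch/H1 estimate recovers the analytic fingerprint almost
perfectly (R² = 0.9996) from ten 2.25 s trials. A density increase matching
the measured dye mass bound (0.7%) leaves the fingerprint unchanged
(R² = 0.999), whereas a severe coating analog (+30% density, +200% Young's
modulus) destroys it (R² = 0.298) — the fingerprint is stable exactly where
it should be and sensitive exactly where it should be.

A command-line interface mirrors the library:

```bash
whiskmech modes --n 3
whiskmech frf --out frf.csv
whiskmech synth stimulus --seed 1 --out stim.csv
whiskmech sim-study --config study.yaml --out results/
```

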