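# hpmrf

MR fingerprinting for hyperpolarized [1-¹³C]pyruvate MRI: simulate
metabolite-specific bSSFP/GRE acquisitions with a two-pool Bloch-McConnell
exchange model, build k_PL fingerprint dictionaries, and estimate the
pyruvate→lactate conversion rate by template matching.

## The problem

Hyperpolarized [1-¹³C]pyruvate MRI watches a single injected bolus of
non-renewable magnetization convert to lactate in vivo. The apparent
first-order conversion rate k_PL (s⁻¹) is the quantitative readout, but
every RF excitation and every second of T₁ relaxation spends the same
magnetization that carries the signal — so acquisition design and kinetic
quantification cannot be separated. The MR fingerprinting (MRF) approach
handles this by simulating the *entire* acquisition: a dictionary of signal
time courses ("fingerprints") is computed over a grid of k_PL values for
the exact pulse sequence used, and an observed signal is assigned the k_PL
of the dictionary entry with the largest complex inner-product magnitude,

  k̂_PL = arg max over entries d of |⟨s, d/‖d‖⟩| .

The package implements three interleaved pyruvate/lactate experiment
designs — a variable-flip-angle bSSFP design whose pyruvate excitation
follows a sigmoid α(t) = α_min + (α_max − α_min)/(1 + e^(20−t)) from 5° to
80°, a constant-flip bSSFP design (30°), and a prior-generation hybrid with
spoiled-GRE pyruvate sampling — and the analyses that characterize the
estimator: Monte Carlo precision/bias under complex Gaussian noise,
fixed-parameter sensitivity sweeps, a direct nonlinear-least-squares
comparator, and voxel-wise k_PL mapping on synthetic dynamic images.

The forward model is a one-way two-pool Bloch-McConnell system with a
gamma-variate bolus input, solved exactly per piecewise-constant interval
with closed-form matrix exponentials, including RF rotations, relaxation,
chemical-shift precession, an intravoxel off-resonance (linewidth)
distribution, and exchange acting on all magnetization components. See
`docs/methods.md` for the model, conventions and limitations.

Who it is for: researchers developing hyperpolarized ¹³C acquisition
strategies or k_PL estimation methods who need a fast, deterministic,
fully scriptable simulation and estimation stack.

## Worked example

```python
import numpy as np
from hpmrf import (build_schedule, KineticParams, simulate_fingerprint,
                   DictionarySpec, generate_dictionary, match, add_noise, NoiseSpec)

schedule = build_schedule("mrf_sigmoid")
fp = simulate_fingerprint(schedule, KineticParams(kPL=0.02))
print(f"fingerprint: {fp.n_pyr} pyruvate + {fp.n_lac} lactate samples")
print(f"peak |pyruvate| = {np.abs(fp.pyr).max():.2f} at t = {fp.times[np.argmax(np.abs(fp.pyr))]:.1f} s")

dictionary = generate_dictionary(DictionarySpec(schedule=schedule))
print(f"dictionary: {len(dictionary)} entries, step {dictionary.spec.kpl_res} 1/s")

noisy = add_noise(fp.signal, NoiseSpec(sigma=0.1, seed=7), draw_index=0)
result = match(noisy, dictionary)
print(f"true kPL = 0.0200 1/s, matched kPL = {result.kpl_hat:.4f} 1/s "
      f"(score {result.score:.1f})")
```

prints

```
fingerprint: 15 pyruvate + 15 lactate samples
peak |pyruvate| = 10.94 at t = 21.5 s
dictionary: 1001 entries, step 0.0001 1/s
true kPL = 0.0200 1/s, matched kPL = 0.0203 1/s (score 15.6)
```

The fingerprint holds one complex sample per acquisition block (the total
demodulated echo-train signal, in units of the total bolus magnetization);
the sigmoid design's pyruvate signal peaks near the 20 s flip-angle
midpoint. With noise SD 0.1 on each complex channel, template matching
recovers k_PL to within a few grid steps (here +0.0003 s⁻¹).

The same operations are available from the shell:

```
hpmrf dictionary --design mrf_sigmoid --out dict.h5
hpmrf montecarlo --dict dict.h5 --sigmas 0.1,0.3 --n 1000 --kpl 0.01,0.05 --out mc.csv
hpmrf sensitivity --dict dict.h5 --param bolus_duration --out sens.csv
hpmrf phantom --design mrf_sigmoid --sigma 0.1 --prefix scratch/ph
hpmrf fit --dict dict.h5 --prefix scratch/ph --noise-sd 0.1 --out-prefix scratch/fit
```

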