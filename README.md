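# triplexkit

Rigid-body helical analysis and base-flipping free energetics for duplex
and triplex DNA.

## What this is for

Triplex-forming oligonucleotides (TFOs) bind the major groove of a DNA
duplex at homo-purine tracts, forming G-G·C and A-A·T base triplets
through reverse-Hoogsteen pairs. Understanding what the third strand does
to the host duplex — how far the helix moves from B toward A form, how
the major groove widens, how base-pair breathing changes — requires two
kinds of machinery:

1. **Rigid-body structural analysis.** Each base gets an orthonormal
   reference frame by least-squares fit of a standard base geometry to
   its ring atoms. Base-pair frames and the six step parameters (Shift,
   Slide *Dx*, Rise; Tilt, Roll *ρ*, Twist *ω*) follow from the symmetric
   mid-frame decomposition of the inter-frame rigid motion, local helical
   parameters (x-displacement *dx*, inclination *η*, helical twist/rise)
   from its screw axis, and the Zp / Zp(h) metrics from projecting the
   inter-strand P→P vector on the mid-step frame and the local helical
   axis. On top of these: region-averaged statistics with block-averaged
   standard errors, groove widths as raw inter-strand P–P distances,
   endo-/exocyclic stacking overlap areas, bend angles about the central
   base pair, Roll–Slide covariance ellipses and variabilities, and
   all-atom PCA of superposed ensembles.

2. **Base-pair opening thermodynamics.** The flipping of a base out of
   the stack is followed along a pseudo-dihedral angle over four centres
   of mass (flipping base, its sugar, the first neighbouring sugar, the
   first neighbouring base pair). Umbrella windows with harmonic biases
   *w_i = k(x − x_i)²/2* are unbiased with a periodic WHAM
   (self-consistent window constants, 10⁻⁶ tolerance, 720 bins), errors
   come from 4-block splitting, open/closed states are defined by the
   solvent accessibility of the pair's buried reporter proton/nitrogen
   (closed ⇔ SASA < 0.001 nm²), and the opening free energy is
   ΔG = −kT ln(∫_open e^{−W/kT} / ∫_closed e^{−W/kT}).

Because atomistic trajectories are too expensive to regenerate at desk
scale, the package ships synthetic generators with *exact known ground
truth*: fiber helices rebuilt from step parameters (the analysis layer is
their exact inverse), an idealized reverse-Hoogsteen third-strand
builder, Gaussian step-parameter ensembles, and a Markov-chain sampler
that draws umbrella-window series from any declared periodic free-energy
surface. Every analysis can therefore be validated end to end against
numbers that are known before the analysis runs.

## Worked example

The bundled study system is a 30-mer duplex
(5′-AACTGCTAAA·GAGGGAGGGA·CTTGATGTAT-3′, base pairs numbered 1–30 on the
leading strand, 31–60 on the complement with *i* pairing 61 − *i*) whose
central homo-purine tract (bp 11–20) binds the 10-mer TFO
5′-AGGGAGGGAG-3′ antiparallel (residues 61–70):

```python
import numpy as np
from triplexkit import (CANONICAL_B, annotate_system, build_triplex,
                        groove_widths, helix_step_table, rebuild_helix,
                        triplex_30mer_system)

system = triplex_30mer_system()
duplex = rebuild_helix(system.duplex_seq, CANONICAL_B)
triplex = build_triplex(duplex, system.tfo_seq, target_start=11)

tab = helix_step_table(duplex, annotate_system(duplex, system))
print("duplex steps: twist %.2f deg  rise %.2f A  slide %.2f A"
      % (tab.twist.mean(), tab.rise.mean(), tab.slide.mean()))

tfo = helix_step_table(triplex, annotate_system(triplex, system), strand="tfo")
print("third-strand steps: twist %.1f +/- %.1f deg  rise %.2f A"
      % (tfo.twist.mean(), tfo.twist.std(), tfo.rise.mean()))
```

prints

```
duplex steps: twist 36.00 deg  rise 3.32 A  slide 0.37 A
third-strand steps: twist 36.2 +/- 1.7 deg  rise 3.29 A
```

The duplex analyzes back to exactly the canonical B-form values it was
built from (twist 36.0°, rise 3.32 Å — the A-form references are 31.1°
and 3.31 Å), and the placed third strand stacks with duplex-like step
geometry. A free-energy run on the built-in double-well demo surface:

```python
from triplexkit import (BiasedSamplerSpec, delta_g_open,
                        sample_biased_windows, schedule_windows, wham)
from triplexkit.flipping import barrier, wrap_angle
from triplexkit.pipeline import demo_pmf

windows = sample_biased_windows(BiasedSamplerSpec(
    true_pmf=demo_pmf, window_centers=schedule_windows(),
    force_constant=2000.0, n_samples=5000, seed=7))
profile = wham(windows, n_bins=720, tolerance=1e-6)
closed = np.abs(wrap_angle(profile.bin_centers)) < 90.0
print("dG(open) = %.2f kcal/mol   barrier = %.2f kcal/mol"
      % (delta_g_open(profile, closed), barrier(profile)["barrier"]))
```

prints

```
dG(open) = 2.11 kcal/mol   barrier = 6.63 kcal/mol
```

against a generator truth of ΔG = 1.93 and barrier 6.05 kcal/mol at this
smoke scale (5 000 samples/window; the production protocol of 50 000
samples/window recovers the surface to better than 0.3 kcal/mol
pointwise).

There is also a CLI:

```bash
triplexkit demo --seed 1 --full        # synthetic dataset + full analysis bundle
triplexkit build --form B --with-tfo --out triplex.pdb
triplexkit analyze-helix --pdb triplex.pdb --out-dir out/
triplexkit analyze-pmf --windows-dir demo_data/windows --out-dir out/
```

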