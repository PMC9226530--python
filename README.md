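# ahyflex

Flexibility analysis of CpG-modified DNA duplex conformational ensembles.

Cytosines at CpG sites can carry 5-substituents — the natural 5-methyl (mC)
and 5-hydroxymethyl (hmC) groups, or the synthetic, enzymatically installed
5-(6-azidohex-2-ynyl) group (ahyC), whose long azide-terminated side chain
measurably changes local DNA mechanics.  `ahyflex` implements the
computational side of that question for people working with duplex
ensembles (molecular-dynamics trajectories or synthetic stand-ins):

* **Helical parameters.**  Base reference frames are fitted to ring atoms
  by least-squares superposition of standard base geometries; intra-base-pair
  (shear, stretch, stagger, buckle, propeller, opening) and base-pair-step
  (shift, slide, rise, tilt, roll, twist) parameters follow the
  mid-step-triad (CEHS) construction used by the 3DNA family of programs,
  with an exact inverse (`rebuild_duplex`) for round-trip validation.
  Groove widths are cross-strand P–P distances minus a 5.8 Å van der Waals
  correction.
* **Flexibility statistics.**  Flexibility at a base-pair step is the
  sample standard deviation of a parameter over the frames of a replica:
  SD(θ) = √(Σ(θᵢ − θ̄)²/(n−1)).  SDs are pooled over the modified-site
  windows (the CpG and one base pair on each side: one observation per
  replica × window step) and compared across substrates by single-factor
  ANOVA.  A static nucleosome structure can serve as a spatial-SD
  flexibility yardstick.
* **Contact conditioning.**  Frames of an azide-carrying ensemble are
  classified "any touch"/"no touch" by whether any terminal azide nitrogen
  lies within 4.5 Å (strict) of a DNA heavy atom; per-step parameter
  distributions are summarised in each class, with a seeded random split of
  the same frames as the null control, plus per-residue interaction
  frequencies and touch dwell-length statistics.
* **Synthetic ensembles.**  A generator plants known effects — per-step
  Gaussian fluctuations with a configurable SD multiplier at modified-site
  windows, and a two-state touch Markov chain that shifts local
  roll/twist/slide while touching — so every analysis stage can be scored
  against ground truth without any MD input.

## Worked example

```python
from ahyflex import (EnsembleConfig, FlexibilityProfile, anova_single_factor,
                     find_cpg_sites, generate_ensemble, modification_windows,
                     side_chain_extension, window_sd_samples)
from ahyflex.ensemble import reference_fragment_set

find_cpg_sites("GCTCTCTCGAAGCAACGAGAACAGT")   # -> [8, 16]
side_chain_extension("ahy")                    # -> 10.547 (Å, C5 to azide N)

frags = reference_fragment_set(seed=1, n_frames=2000, n_replicas=5)
windows = modification_windows(frags["ahyCx4"].duplex)
# -> step windows (7, 9) and (15, 17)

profiles = []
for k, name in enumerate(("C", "mCx4", "ahyCx4")):
    cfg = frags[name]; cfg.seed = 1 + k
    ens = generate_ensemble(cfg)
    profiles.append(FlexibilityProfile.from_trajectories(ens.trajectories, name))
samples = window_sd_samples(profiles, windows, ("roll",))
result = anova_single_factor(samples)
```

printing, per fragment, the mean roll SD over the 30 window observations
(5 replicas × 6 window steps) and the joint test:

```
C        mean window roll SD = 5.47 deg  (n=30)
mCx4     mean window roll SD = 4.42 deg  (n=30)
ahyCx4   mean window roll SD = 8.67 deg  (n=30)
ANOVA: F = 11280.7, df = (2, 87), p = 8.41e-106 **
```

The unmodified control sits at the baseline roll SD, the methylated
fragment is modestly stiffer (planted multiplier 0.8), and the
azide-modified fragment is markedly more flexible (planted multiplier 1.5
plus contact-coupled mean shifts); the ANOVA stars follow the
* P < 0.1 / ** P < 0.05 convention.

## Command line

Five subcommands compose into a pipeline (`--help` on each for options):

```sh
ahyflex simulate --config ahycx4.json --out sim/        # ensembles + latent truth
ahyflex analyze sim/replica0.pdb --out params/           # helical-parameter CSVs
ahyflex flex --input ahyCx4=... --input C=... --out flex/  # SDs, violins, ANOVA
ahyflex contacts --trajectory sim/replica0.pdb --out con/  # touch partition + profiles
ahyflex report flex/ --out report.txt
```

All tables are 1-based and CSV; every run writes a `manifest.json` with the
arguments, seed and input checksums.  Sequences are read from single-record
FASTA; modifications from a tab-separated sidecar
(`position<TAB>strand<TAB>code`, 1-based positions, strand `top`/`bottom`,
code `m`/`hm`/`ahy`, `#` comments).

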