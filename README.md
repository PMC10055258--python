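# damfretkit

Quantitative analysis of **DAmFRET** (distributed amphifluoric FRET)
single-cell flow cytometry, the assay that reads out concentration-dependent
protein self-assembly: each cell reports its expression level (acceptor
fluorescence) and its assembly state (AmFRET = FRET intensity / acceptor
intensity). Across a population spanning several decades of expression, a
protein that assembles by a simple continuous equilibrium produces a smooth
AmFRET-vs-expression cloud, while a protein whose assembly is
nucleation-limited leaves cells *supersaturated*: at the same concentration
some cells have nucleated (high AmFRET) and some have not (low AmFRET),
producing a discontinuous, bimodal profile. Distinguishing the two — and
measuring where assembly saturates — is how one quantifies nucleation
barriers in proteins such as the death-fold-domain (DFD) adaptors of innate
immune signaling.

The package implements, as a tested pipeline:

- **Event gating and QC** — logicle/asinh display transforms, scatter /
  singlet / expression gates (flags, never row deletion), AmFRET computation,
  per-well QC (>= 2500 expressing events, mean acceptor >= 3.5 p.d.u.), and
  the 25% instance-retention rule for screens.
- **DAmFRET profiles** — 64 log-spaced expression bins, a per-bin
  FRET-positive gate set at the 99th percentile of a monomer-only control,
  per-bin assembled fractions, and the gross fraction `fgate`.
- **Continuity classification** — Scott-rule binning with a density cutoff,
  a 100-fold bootstrapped, low-pass-filtered median-AmFRET spline, transition
  point/range from the spline derivatives, and Hartigan's dip test of the
  AmFRET distribution inside the transition range (p < 0.05 =>
  discontinuous). Continuous profiles are subtyped low / high / low-to-high.
  The dip statistic is implemented from its definition (greatest convex
  minorant / least concave majorant iteration) with Monte-Carlo uniform-null
  p-values.
- **Saturation concentration (C50)** — the mean AmFRET curve (bins with
  >= 100 cells) is fit to the stretched exponential

      AmFRET(c) = Amp (1 - exp(-ln2 (c/C50)^a)),    a in [0.1, 10]

  so that AmFRET(C50) = Amp/2 exactly; parameter errors by Monte-Carlo
  refits; supersaturability = C50_stochastic / C50_seeded within a batch.
- **Seedability screen** — per-batch standardization, per-DFD directional
  IQR outlier degrees of (lowered) log10 C50 and (raised) fgate, seedability
  = their mean, hits at >= mean + 3 SD, and replicate consistency (Pearson R,
  Wald binomial CI).
- **Morphology** — brightest z-plane, rolling-ball background subtraction,
  ImageJ-"Default" intermeans thresholding, per-object CV and aspect ratio,
  and the printed CV/AR rules for diffuse / punctate / fibrillar calls.
- **Network statistics** — STRING-style physical-edge networks (score >=
  900), degree/betweenness centralities, Mann-Whitney, chi-square with
  Cramer's V, Spearman, Wald intervals, log-log power-law fits, Ward
  clustering of seedability matrices.
- **Synthetic data** (`damfretkit.synth`) — event tables, full screens, and
  microscopy objects with serialized ground truth, so the whole pipeline is
  testable without instrument data.

## Worked example

Simulate a nucleation-limited protein (true C50 = 1000 p.d.u., amplitude
0.3), classify its profile, and fit its saturation curve:

```python
import numpy as np
from damfretkit.synth import PhenotypeSpec, simulate_events
from damfretkit.pipeline import prepare_events
from damfretkit.profiles import bin_events
from damfretkit.continuity import classify_well
from damfretkit.weibull import fit_weibull, mean_curve

events = prepare_events(simulate_events(
    PhenotypeSpec(behavior="discontinuous", true_c50=1000.0, true_amp=0.3),
    n_cells=100_000, rng_seed=1))
sub = events[events.gate_all & events.amfret_valid]

result = classify_well(np.log10(sub.acceptor), sub.amfret, rng_seed=1)
print(result.label, round(result.dip_p, 4))
# discontinuous 0.0005

fit = fit_weibull(mean_curve(bin_events(events)))
print(round(fit.c50, 1), round(fit.amp, 3))
# 1006.6 0.291
```

The dip test rejects unimodality (p = 0.0005 < 0.05) inside the transition
range near log10 C50 = 3, so the well is called discontinuous — the
signature of a nucleation barrier. The Weibull fit of the mean curve places
the half-asymptote concentration (C50) within 1% of the planted 1000 p.d.u.
and recovers the planted amplitude. The same calls run from the shell:

```sh
damfret simulate --behavior discontinuous --n-cells 100000 --seed 1 --out well/
damfret classify --events well/discontinuous_s1.csv --out result.json
damfret screen --demo --out screen_run/   # simulated 10x12 seedability screen
```

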