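# borealrings

Tree-ring analysis for moisture-limited boreal spruce: signal-free
regional-curve-standardization (RCS) chronologies, climate–growth
correlation over a century-scale station record, carbon-isotope
gas-exchange physiology, and habitat-stratified growth sensitivity —
exercised end to end on synthetic cohorts with known ground truth.

## Who this is for

Dendroecologists and ecophysiologists who want a tested, reproducible
Python implementation of the boreal tree-ring workflow: read Tucson/RWL
ring widths, correct cores that missed the pith, detrend with
multi-curve signal-free RCS, correlate growth indices with monthly
climate (static and 25-year moving windows, bootstrap significance),
derive Δ¹³C → Ci/Ca → iWUE from tree-ring cellulose, and ask whether
trees in good and poor habitats respond to climate differently.

## The science in brief

**Detrending.** A ring formed at cambial age *a* in calendar year *y* is
modeled multiplicatively: `w = f(a) · C(y) · ε`, with `f` the age-related
width decline (one empirical curve per growth-rate class, >40 series per
class) and `C` the common year signal. RCS divides each width by the
age-expected width; the chronology is the Tukey biweight robust mean of
those ring-width indices per year, truncated where fewer than 50 trees
contribute and rescaled to mean 1.0. Because part of `C` leaks into the
fitted age curves, the signal-free iteration repeatedly divides the raw
measurements by the current chronology, refits the curves from those
signal-free measurements, and recomputes the indices from the raw
widths — stopping when the chronology changes by less than 0.002
(at most 9 iterations).

**Climate–growth.** Pearson correlations of the chronology with monthly
May–August temperature and precipitation of the growth and previous
year plus seasonal precipitation totals (precipitation log-transformed);
significance from a stationary-block bootstrap null; 25-year moving
windows with a variance-based test for low-frequency change; boosted
regression trees (tree complexity 2, learning rate 0.001, bag fraction
0.5, up to 30 000 trees by 10-fold CV) for response shapes and
interactions.

**Isotope physiology.** Δ¹³C = (δ¹³Cₐ − δ¹³C_tree)/(1 + δ¹³C_tree/1000);
Ci/Ca = (Δ − a)/(b − a) with a = 4.4‰, b = 27‰ (a −1.33‰ cellulose
offset applied first); iWUE = (Ca − Ci)/1.6. A random-forest regression
of Δ¹³C on ring age and time period separates the juvenile decline from
the temporal signal, reporting period values at a ring age of 100 years.

**Habitat.** Per-tree mean index over 2003–2012 against plot covariates
(BRT); fixed thresholds classify habitat (white spruce good: moss < 50%
and duff < 10 cm; black spruce good: slope > 15% and moss > 60%;
strict inequalities, boundaries unclassified); stratified chronologies
are correlated with the same climate variables.

## Worked example

```python
from borealrings import synth, ringio, detrend
import numpy as np

cfg = synth.SynthConfig(seed=11)                 # 150 trees, 1864-2013
climate, _ = synth.generate_climate(cfg)
series, truth = synth.generate_cohort(cfg, climate)
series = ringio.correct_missing_pith(series, truth.arcs)

result = detrend.signal_free_rcs(series, seed=11)
chron = result.chronology
target = truth.common_signal.loc[chron.years]
target = target / target.mean()
print(f"span {chron.years[0]}-{chron.years[-1]}, "
      f"mean {chron.index.mean():.6f}, "
      f"r to true signal {np.corrcoef(chron.index, target)[0, 1]:.3f}")
```

prints

```
span 1891-2013, mean 1.000000, r to true signal 0.977
```

— the retained span starts where 50 trees are available, the chronology
mean is exactly 1.0 by construction, and the detrended chronology tracks
the cohort's true (generated) year signal at r ≈ 0.97.

The full study is scripted in `analysis/`:

```bash
python analysis/01_generate_data.py      --seed 0   # 339 + 213 tree cohort
python analysis/02_build_chronologies.py --seed 0
python analysis/03_climate_growth.py     --seed 0
python analysis/04_isotope_physiology.py --seed 0
python analysis/05_habitat_analysis.py   --seed 0
```

or in one command via the CLI: `borealrings run --profile paper --seed 0
--out results/pipeline`.

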