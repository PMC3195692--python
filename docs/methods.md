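# Methods

`stretchalign` simulates how adherent cells (the motivating system is
human airway smooth muscle) reorient when the elastic substrate they sit
on is stretched cyclically in one direction, and reproduces the axial
orientation statistics used to quantify such experiments.

## Substrate strain field

The membrane is stretched uniaxially with a raised-cosine waveform

    delta(t) = delta_max * (1 - cos(2 pi f t)) / 2,

default `delta_max = 0.20` (20% stretch) at `f = 30` cycles/min.  The
waveform starts from rest length and never compresses the membrane; the
experimental description ("sinusoidal, 20% in strain") is ambiguous
between 0–20% and ±10% about a midpoint, and the 0–20% reading matches an
apparatus that stretches from rest.  The waveform is a configurable
parameterization, not a claim about the hardware.

The normal strain at angle `alpha` from the stretch axis is

    eps(alpha) = delta * (cos^2 alpha - nu * sin^2 alpha),

with effective Poisson ratio `nu = 0.15` (3% lateral contraction at 20%
stretch).  `|eps|` vanishes at `atan(1/sqrt(nu)) = 68.8 deg`, which is the
attractor of the whole model: it coincides with the ~70 deg peak of
measured post-stretch orientation histograms.

## Cytoskeletal mechanics at one focal adhesion

Each focal adhesion (FA) is a stiff spring `K_FA` in series with two
parallel fiber populations: stress fibers (`K_SF`) and microtubules
(`K_MT`).  Per-fiber stiffnesses are 2.6 (SF) and 1.7 (MT) in relative
units (the ratio of the measured Young's moduli; only ratios matter).
`K_FA = k_fa_ratio x` (full-cohort cytoskeletal stiffness), default
`k_fa_ratio = 10`: stiff enough that most substrate strain is transmitted
(T = K_FA/(K_FA+K_SF+K_MT) ≈ 0.9–0.95), finite so that microtubule
recruitment measurably unloads the stress fibers.

Stochastic rules per substep (default 4 substeps per stretch cycle,
evaluated at the strain at the start of each substep):

* **SF attachment**: constant probability per free slot, `p_attach_sf`
  per cycle (converted to a per-substep probability).
* **MT attachment**: `min(1, mt_attach_slope * mean |SF strain|)` per free
  slot — microtubules polymerize toward adhesions whose stress fibers are
  strained.  The pre-detachment mean over attached SFs is used; an empty
  SF cohort contributes strain 0, pausing MT recruitment.
* **Rest length**: a fiber attaching under transmitted strain `eps`
  records rest length `1 + eps`; its strain later is
  `x = (1 + eps')/(1 + eps) - 1`, so cohort members desynchronize over the
  stretch cycle.
* **Detachment**: `P_d = 1 - exp(-x^2 / 0.2)` per substep (a normally
  distributed breaking threshold, zero mean, 10% variance; symmetric in
  tension and compression).  These two rupture-statistics constants are
  the model's only fitted parameters and are kept fixed.
* Slots free at the *start* of a substep are eligible for attachment;
  slots freed by detachment within the substep wait one substep.

## Cell state and turnover

A cell is `n_fa = 100` focal adhesions at axial angles in [0, 180),
initially wrapped-Gaussian around the cell's orientation with SD 5 deg
(the stated FA angular spread; the printed "variance of 5 deg" is
dimensionally an SD and is treated as one).  Readouts:

* orientation `theta` = mode of the folded FA angle density on a 5-deg
  histogram (ties broken toward the axial circular mean, then the lower
  bin; deterministic);
* circularity `cv` = 1 - |mean exp(2i alpha)| (axial circular variance):
  0 = elongated, 1 = round.

An FA whose SF **and** MT cohorts are both empty carries no load and
dissolves; it re-forms immediately at an angle drawn *uniformly* on
[0, 180) with a seed cohort of `n_seed_sf = 5` stress fibers attached at
the current transmitted strain.  N_FA is conserved.  Alignment therefore
emerges purely from differential survival: FAs near 68.8 deg see almost no
strain, never lose their fibers and persist; FAs at strained angles churn
until they happen to land in the low-strain band.  Re-insertion is
unbiased by construction — the minimal assumption, stated prominently
because it is the engine of every population-level result.

## Population simulation and scenarios

Cells are independent.  One master seed; cell `i` uses the substream
`SeedSequence(entropy=seed, spawn_key=(i,))`, so results are independent
of batching order and bit-reproducible.  The batched numba kernel is an
exact transcription of the per-fiber reference update (same arithmetic,
same draw layout, float32 uniforms, series branch of the rupture law below
exponent 1e-3); the test suite verifies bit-for-bit equality.

Scenarios are parameter switches only (no pharmacokinetics):

* `control` — parameters as configured;
* `mt_disrupted` (nocodazole / colchicine class) — MT attachment
  probability 0, MT cohorts start empty: `K_MT = 0` throughout;
* `mt_stabilized` (paclitaxel class) — MT attachment *and* detachment
  probability 0, MT cohorts start at capacity: MT counts frozen.

## Calibration (one-time)

Two attachment parameters are unreported by the emulated experiments and
were calibrated once against the 2 h control endpoint (population mean
69 deg, SD 11 deg), then frozen:

* `p_attach_sf = 0.002` per free slot per cycle.  Larger values
  (including 0.1) keep SF cohorts so full that FAs at intermediate angles
  never empty — turnover freezes and no alignment occurs at all.  The
  dissolution probability scales roughly like
  `(P_detach / (P_attach + P_detach))^capacity`, so the attachment rate
  sets the width of the angular band within which FAs are effectively
  immortal over 2 h; 0.002 puts that band edge near 55 deg, giving the
  observed mean ~70 and SD ~11.
* `mt_attach_slope = 0.05` per unit strain.  Because dissolution requires
  *both* cohorts empty, abundant microtubules at strained FAs block
  turnover; slopes of order 1 or larger freeze the control population.
  0.05 keeps MT load-sharing active without suppressing realignment.

With these defaults, 5 independent 100-cell runs give a median 2 h
endpoint of mean ~71 deg, SD ~11.5 deg (recomputed from scratch by
`scripts/acceptance.py` and the acceptance tests).

## What the synthetic data does and does not emulate

`synthetic_data` generates unstretched orientation samples: uniform on
[0, 90] (default; the minimal reading of "randomly distributed"), or a
scaled unimodal beta matched to the printed moments (mean 43, SD 24).
Angles are rounded to whole degrees, matching the integer-degree
measurement convention implied by the histogram's singleton 0-deg bin.
It emulates sample sizes (>=100 cells/replicate, 5 replicates) and
replicate independence.  It does **not** emulate optical measurement
error, within-field spatial correlation between neighboring cells, or
day-to-day baseline shifts between cultures — so a green test establishes
that the pipeline reproduces the model's statistics, not that it would
survive every artifact of real image-derived data.

## Numerical choices

* Angles: degrees at all interfaces, radians internally; time: minutes
  internally, hours at the population interface.
* Strain is evaluated at the start of each substep; `delta(0) = 0`, so the
  first substep is unloaded, matching the zero-attach-strain seeding.
* Rupture probability: exact `1 - exp(-y)` for `y >= 1e-3`, second-order
  series `y(1 - y/2)` below (absolute error < 2e-10); uniforms are
  float32.  Events rarer than ~6e-8 per substep are therefore never
  sampled — irrelevant over the 1.4e4 substeps of a 2 h run.
* Mode ties and all other tie-breaks are deterministic (documented in the
  docstrings).

## Known limitations

* **Capacity sensitivity.** Because FA dissolution probability is
  exponential in cohort capacity, results are *not* insensitive to
  `capacity_sf`/`capacity_mt`; capacity and attachment rate jointly set
  the turnover timescale.  Treat `(capacity, p_attach_sf)` as one
  calibrated pair.
* **Microtubule disruption does not de-align.** In this architecture
  microtubules can only shield strained FAs (they reduce transmitted
  strain and add a cohort that must also empty before dissolution), so
  the nocodazole-class scenario *accelerates* selective turnover and
  still aligns — opposite to the experimental observation the scenario
  is named after.  The stabilized scenario (frozen full MT cohorts) does
  block alignment, as observed for paclitaxel.  Capturing the
  nocodazole phenotype would require a mechanism outside the stated
  model, e.g. MT-dependent FA maturation or re-insertion bias.
* Fibers are linear springs in tension and compression; no microtubule
  buckling, no explicit polymerization speeds or catastrophe kinetics —
  these are abstracted into the per-substep probabilities.
* Cell shape is tracked only through `cv`; there is no explicit ellipse
  geometry or projected-area readout.
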