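# Methods

## The measurement model

Flow cytometry of propidium-iodide-stained nuclei yields a 1D fluorescence
histogram in which peak position is proportional to DNA amount.  In most
plants, endopolyploid tissue produces peaks at 2C·2^k.  Orchids instead
show *partial endoreplication* (PE): only a species-specific part of the
genome, of size P (pg), re-replicates per endocycle, so nuclei that have
undergone k endocycles fluoresce at

    I_k ∝ 2C + k·P,      k = 0, 1, …, K

an *arithmetic* progression with common difference ∝ P.  A co-chopped
internal standard of known 2C calibrates the arbitrary fluorescence axis
to picograms: 2C_sample = (position_sample / position_standard) ·
2C_standard.  The shipped standards are Pisum sativum 'Ctirad' (2C =
8.76 pg, primary) and Solanum pseudocapsicum (2C = 2.57 pg, secondary,
calibrated against the primary); `calibrate_secondary_standard` reproduces
that calibration from repeated co-run ratios.

Two numbers summarize each tube: the genome size 2C and the
endoreplicated-part size P, with P% = 100·P/2C.  Their joint pattern is
the delineation marker:

* ploidy changes scale P by the same fold as the ploidy (a triploid holds
  1.5×, a tetraploid 2× the diploid P);
* homoploid lineages shift 2C at essentially constant P (the
  cryptic-lineage signal);
* an individual whose 2C deviates strongly from its taxon mean at
  unchanged P, lying toward another taxon's mean, is a hybrid suspect.

## Per-tube estimation

1. **Binning** — events are binned onto a linear axis (default 1024
   channels, gain 1 unit/channel).  Overflowing events accumulate in the
   top channel and are tallied; counts are always conserved.
2. **Peak detection** (`GaussianPeakDetector`) — iterative peak
   stripping: smooth with a moving-window quadratic (Savitzky–Golay)
   filter (window 9 channels), take the largest remaining maximum, fit a
   single Gaussian by weighted least squares (Poisson weights) on a
   window of ±2.5 preliminary sd, subtract, repeat until no maximum
   exceeds the amplitude floor (default 2 counts/channel).  The
   preliminary width starts from the half-width at half-maximum of the
   *cleaner* flank and, once peaks exist, is clamped toward the width
   implied by a shared coefficient of variation (sd ∝ position) — on a
   linear axis all peaks of a tube carry nearly the same CV.  A final
   *joint* refit of all retained components shares a single relative
   width c (sd_i = c·μ_i); this removes the first-order contamination
   between neighbouring endocycle peaks and keeps weak high-k components
   from drifting.  Quality gates: fitted area ≥ `min_peak_events`
   (default 100 events) and CV ≤ `cv_max` (default 0.10).  Peaks closer
   than 2·(sd₁+sd₂) are flagged `merged`, never force-split.
3. **Role assignment** (`assign_peaks`) — the standard peak is the one
   whose removal leaves the remaining peaks closest to an arithmetic
   progression (max relative residual < 2% per peak, configurable);
   candidates implying a step P ≥ 2C are rejected as unphysical.  An
   operator hint (expected 2C range) can pin the choice, mirroring real
   practice where the standard is known.  A standard overlapping the
   sample 2C peak raises an error that advises a secondary standard.
4. **Estimation** — 2C from the position ratio; P as the slope of an
   area-weighted least-squares line of peak position (pg) on endocycle
   index k (`p_mode: regression`, default), which reduces *exactly* to
   the classical second-minus-first-peak difference when only two sample
   peaks exist (`p_mode: first_two` forces that behaviour).  The
   regression intercept is reported as a 2C consistency check.

## Delineation and summaries

`PloidyClassifier` infers ploidy as the nearest integer fold of a diploid
reference P.  When no reference is configured it is bootstrapped as the
median P of inferred diploids (valid when diploids dominate the cohort,
as in mixed field samples; override `p_diploid_ref` otherwise).
`joint_classify` labels each individual consistent / ploidy-variant /
homoploid-divergent against *leave-one-out* taxon means, so an outlier
cannot mask itself; deviation percentages are reported both against the
individual's own value (the convention behind "deviating by ~18%") and
against the leave-one-out mean (the flagging statistic, threshold
`gs_hybrid_dev` = 0.15).  `p_tol` = 0.10 bounds "same P".  Both
thresholds are heuristics, not biology, and are configurable.
`diploid_P_band` checks the empirical rule that diploid P stays below
4 pg regardless of genome size.

`summarize` aggregates measurements per (taxon, ploidy, region/variant):
arithmetic means, sample sd (n−1), P% recomputed from the stored means
(never copied) and rounded to 1 d.p.; pg values print at 2 d.p.
`tukey_groups` runs one-way ANOVA plus pairwise Tukey HSD (statsmodels,
Tukey–Kramer correction for the strongly unbalanced group sizes) and
builds compact letters with the greedy insert-and-absorb algorithm,
letters ordered by ascending group mean; groups with fewer than two
observations are summarized but excluded from the HSD, and letters are
attached to diploid rows only.  HSD runs on individuals by default
(`summary.hsd_unit`), since the underlying per-population assignment of
the original measurements is not recoverable.

## The synthetic-data generator

`simulate_sample` draws each tube from a mixture whose component sizes
are multinomial:

* debris: truncated exponential on [0, standard position], scale 0.2× the
  standard position, default 5% of events;
* the standard peak: Gaussian at the standard 2C, sd = CV·mean, default
  30% of non-debris events;
* the sample series: Gaussians at 2C + k·P (k = 0..K, default K = 3) with
  geometrically decaying areas (ratio 0.5) and sd = CV·mean.

Defaults: CV 3% (mid-range of routine plant FCM quality), 5,000 events
per tube, gain 0.05 pg/channel-unit so the largest reference genomes stay
on a 1024-channel scale.  Intensities are emitted in uncalibrated channel
units, so the analysis must recover pg through the standard exactly as
with real data.  Side scatter is simulated (nuclei high, debris low) only
so that 2D gating has something to act on.  Everything is seeded; equal
parameters and seed give bit-identical events.

`simulate_cohort` draws per-individual (2C, P) from zero-truncated
normals around per-lineage means/sd and simulates each tube with a
sub-seed; impossible draws (P ≥ 2C) are redrawn at most 100 times before
a parameter error.

The built-in reference table (`peflow.reference`) carries the published
per-lineage statistics of the orchid genus *Neotinea* (11 lineages, 349
individuals, genome sizes 7.1–28.7 pg, diploid P ≈ 2.9–3.7 pg, one
triploid and one tetraploid lineage).  Lineages whose mean 2C lies within
1.5× of the Pisum standard are simulated against the Solanum secondary
standard — the operator decision documented for N. maculata, whose 2C
nearly coincides with Pisum's — so the standard peak never collides with
a sample 2C peak.

**What the generator does not emulate:** S-phase nuclei between peaks,
doublets/aggregates, fluorochrome base-content bias, drift within a run,
and non-exponential debris shapes.  Passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated mixture
model, not robustness to every artefact of real cytometry.

## Numerical choices

* Gaussian fits: Levenberg–Marquardt with analytic Jacobians; Poisson
  (√count) weights; a fit is degenerate if the center leaves the window
  or the width collapses; windows need ≥ 5 nonzero channels.
* Tie-breaks: equal-height adjacent smoothed maxima keep the lower
  channel; tied standard-candidate scores prefer physically plausible
  series, then the lower peak.
* Components whose centers sit closer than the wider of their sds are
  unresolvable and deduplicated (larger area wins).
* The P regression is solved by least squares on the √weight-scaled
  design; tests pin it to explicit normal equations at 1e-10.
* Zero within-group variance in the HSD degenerates the studentized
  range; pairs with unequal means are then declared distinct outright.

## Verification scale

The recovery bench simulates 20 replicate cohorts of the full 349
reference individuals (CV 3%, 5,000 events, K = 3; ≈15 s per cohort on
one CPU) and requires ≥ 95% of individuals to recover both 2C and P
within 2% relative error, with all inferred 2x/3x/4x ploidy labels
correct.  Measured medians are ≈0.1% (2C) and ≈0.6% (P); failures
concentrate in the largest-genome lineages, where the endocycle peaks
overlap most strongly relative to their spacing.

## Scope and limitations

The package covers the cytometric arm of a biosystematic workflow only.
Sequencing analyses (RADseq locus assembly, SNP phylogenies, ordinations)
and multivariate or geometric morphometrics are out of scope: they depend
on external raw data and published third-party tools and are deliberately
not reimplemented or wrapped here.  Chromosome counting is a wet-lab
matter; ploidy here is *DNA-ploidy*, inferred from P folds.  Heavily
overlapped peak complexes are flagged, not deconvolved — the honest
remedy, as with real instruments, is re-measurement against a secondary
standard.  FCS support is a minimal open subset (list-mode, linear,
single dataset, 32-bit float); anything else is rejected loudly.
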