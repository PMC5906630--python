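# Methods

This note records the models, parameter choices and numerical conventions
behind `dvnpchrom`, and what the synthetic-data experiments do and do not
establish about real data.

## Coordinates and tracks

All coordinates are 0-based half-open, in memory and on disk (BED,
bedGraph); bedGraph zero runs are written explicitly so a track's
genome-wide mean is reconstructible from the file alone. Occupancy tracks
are built from fragment midpoints (floor of the arithmetic mean for
even-length fragments — deterministic and consistent with the half-open
convention). Gaussian smoothing uses a kernel truncated at |d| ≤ 4σ and
renormalized (mass loss < 1e-4); at chromosome ends the kernel is
renormalized over existing bases rather than padding, so no signal is
fabricated outside the genome; a circular mode exists for exact
mass-conservation checks. Smoothing and genome-mean normalization are
both linear and commute; the pipeline normalizes first and smooths
second. Default fragment-size windows are 120–200 bp (mononucleosomal
MNase) and 50–500 bp (ChIP); the filtering rule is principled but the
bounds are data-dependent, so both are configuration-exposed. Optional
duplicate-fragment removal defaults to off.

## Metagene profiles

Profiles average the normalized signal from 500 bp upstream to 2500 bp
downstream of the TSS in transcription orientation. Each gene contributes
an offset only while it is still transcribed there: contributions stop at
the polyadenylation site (minus an end buffer where used), and per-offset
means divide by the number of genes still contributing (ragged
averaging). Zero-filling short genes would fabricate apparent depletion
beyond their 3′ ends, which is why it is not done. Upstream flanks are
never truncated by neighbouring genes, and window overlap with adjacent
genes is permitted — no such exclusions are part of the averaging rule.
Replicates are combined at the fragment level before coverage; combining
after per-replicate normalization would differ only by depth weighting.

Peak calling on profiles is deliberately simple: the −1/+1 peaks are
argmaxima within fixed search windows ([−350,−80] and [−20,200] bp), the
NDR trough is the minimum between them, and the nucleosome repeat length
is the mean spacing of local maxima (prominence ≥ 10% of the profile
maximum) within the first 700 bp of gene bodies, where hundreds of genes
still contribute.

## Window and site association

The genome is tiled into 500 bp windows every 250 bp (windows past the
chromosome end dropped; count = ⌊(L−size)/step⌋+1). Window enrichment is
the ratio of window means of the mean-normalized IP and input tracks
(IP-only mode available, since the association should also hold
independent of inputs). Occupancy change is the simple difference
occ_control − occ_treatment of mean-normalized MNase signal, chosen over
a log-ratio because it is defined at zero-coverage windows; a log2 mode
with pseudocount is provided. Positive values mean loss. Because both
tracks are normalized to mean 1 at matched depth, a genome-wide uniform
loss cancels; what the statistic measures is *differential* loss, and
windows losing less than average show negative change (apparent gain).
This is intrinsic to within-sample normalization — it is exactly the
blind spot the spike-in module exists to remove.

Quantile bins split ranks at ⌈k·n/5⌉ boundaries with stable-order tie
breaking (bin sizes differ by ≤ 1); binning is invariant under monotone
transforms of the ranking variable. Box summaries use Tukey hinges
(midpoint rule — the quartile convention is configuration-exposed since
several are defensible), whiskers at the most extreme data within
1.5·IQR, and notches ±1.58·IQR/√n approximating a 95% CI of the median.
The accessibility control re-bins enrichment *within* each input-signal
quintile stratum and reports per-stratum trends.

Nucleosomal sites are externally supplied dyads (from the simulation
truth or a user BED); de novo positioning is out of scope. Per-site
occupancy uses the 147 bp window [dyad−73, dyad+74). Predicted occupancy
is the GC fraction of that window (N bases excluded from both numerator
and denominator): a deliberately transparent proxy for sequence-encoded
nucleosome stability — GC-rich DNA is predicted to form more stable
nucleosomes — standing in for heavier thermodynamic models.

Welch's *t* (two-sided, Welch–Satterthwaite df) is implemented directly
from the formulas and cross-checked in the tests against an independent
reference implementation to 1e-10. With overlapping windows (250 bp
step), neighbouring windows share fragments, so q5-vs-q1 *p*-values are
mildly anticonservative; the null-calibration experiments therefore use
non-overlapping tiles, which satisfy the test's independence premise, and
the overlapping default should be read as descriptive ranking rather than
exact inference.

## Spike-in normalization and global RNAP II change

Scale factors are computed from a declared count table
(factor_s = (spike_ref/spike_s)·(mass_s·dilution_s)/(mass_ref·dilution_ref))
rather than by aligning spike reads to a second genome — the minimal
faithful interface when spike-ins are defined oligo amounts. Gene-body
occupancy averages the spike-scaled track over TSS..(polyA − 300 bp); the
3′ buffer avoids the large polyadenylation-site peaks that otherwise skew
quantification, and shorter genes are excluded with a report. The global
change is summarized as the ratio of condition means over genes (robust
to low-coverage genes); the mean of per-gene ratios is reported
alongside, since the two arithmetics differ slightly and both are
informative. The designed failure mode — running the same estimator
without spike-in factors on depth-matched libraries — returns ≈ 0% and is
kept as a first-class option because it demonstrates that the
normalization, not the estimator, carries the signal.

## SGA screen

Colony sizes are normalized by their plate medians (the minimal
defensible core of spatial correction; a strain's value is invariant to
per-plate multiplicative effects), and relative growth is the ratio of
per-strain medians across replicates. Default thresholds are 1 ± 2 robust
SD (1.4826·MAD) of the screen and are configuration-exposed, as the
upstream tool's numeric defaults are not published. H01 is a χ² on the
2×3 (in-set vs rest) × (rescuer/neutral/sensitizer) table; H02 a 2×2 χ²
(set polarity × threshold side) without continuity correction, with a
Fisher exact fallback (and warning) when an expected cell is below 5.
Category enrichment is an upper-tail hypergeometric test per category
with Bonferroni adjustment.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with planted parameters recorded in a truth manifest:

* **Genome** — nucleotides drawn with a blockwise GC target (default mean
  0.40, 1 kb blocks, smoothed Gaussian deviations of sd 0.06), giving the
  smooth GC drift the stability proxy needs.
* **Genes** — stochastic dense packing: bodies in coordinate order with
  ≥ 500 bp clearance and the slack length distributed randomly among
  gaps. The default study places 560 genes of 800–2000 bp on two 650 kb
  chromosomes (one gene per ~2.3 kb, the density of a compact fungal
  genome). Density matters: sparse random placement leaves long bare
  stretches whose windows carry degenerate zero signal.
* **Nucleosomes** — per gene: a 140 bp NDR just upstream of the TSS, a −1
  dyad beyond it, the +1 dyad 80 bp into the gene, then a 165 bp repeat
  to the polyA site; remaining chromatin (outside arrays and NDRs) is
  filled with phased nucleosomes, since real chromatin is nucleosomal
  nearly everywhere outside NDRs. Site weights are
  base_occupancy·(1 + γ·(GC147 − mean)) clipped to (0,1] (γ =
  stability_coupling, default 1.5; base 0.8).
* **Binding affinity** — Gaussian bumps (sd 40 bp) at every dyad: high
  over nucleosomal DNA, low at NDRs, encoding nucleosome-directed binding
  as the generative truth (a free-DNA mode exists to show the pipeline
  distinguishes the opposite hypothesis). The −1/+1 bumps carry a 2×
  promoter boost (TSS-flanking enrichment, hence concentrated −1/+1
  displacement), per-gene lognormal factors (sd 0.6) plant between-gene
  binding heterogeneity, and the landscape is scaled so mean affinity at
  dyads is 0.5 — keeping planted loss fractions stable across draws.
* **MNase libraries** — sites sampled ∝ weight (control) or
  ∝ weight·max(0, 1 − loss) (treatment) with loss = β·affinity, scaled by
  mean_weight/weight when stability protection is on (weak nucleosomes
  lose more); β defaults to 0.5. Midpoint jitter is Normal(0, 10 bp)
  (realistic peak widths without obscuring phasing), lengths
  Normal(147, 10) truncated to 120–200 bp (the truncation shifts the mean
  by < 0.2 bp), and 5% of fragments are uniform background. A
  digestion-level nuisance parameter exists but defaults to matched
  between conditions.
* **RNAP II libraries** — control midpoints uniform over gene bodies with
  lognormal per-gene expression; the treatment multiplies every gene's
  rate by the planted ratio r (default 0.65, i.e. a 35% global
  reduction), then both genomic libraries are resampled to the identical
  size, making the change invisible to depth normalization by
  construction. Spike reads are Poisson with expectation
  n_genomic·mass/yield and yield_treatment = r·yield_control, so the
  treatment spike share exceeds control by 1/r. The default spike mass
  (0.3 vs control yield 1.0, a ~23% spike read share) is higher than
  typical practice; it is chosen so that spike-count noise contributes
  well under 1 percentage point to the recovered reduction at 1e5 reads,
  keeping the estimator's precision limited by design rather than by the
  spike-in itself.
* **SGA tables** — relative growth 1 + effect + Normal(0, 0.05) planted
  multiplicatively into colony sizes (default 42-gene rescue set at +0.3,
  30-gene sensitizer set at −0.3, matching a two-polarity histone-dosage
  scenario), with per-plate lognormal factors (sd 0.15) so plate
  normalization is exercised; per-colony measurement noise is exposed but
  defaults to 0 so the planted Gaussian tail mass is exactly recoverable.

Problem sizes in the recovery suite — a 1.3 Mb genome (~5200 windows,
~7300 nucleosomes), 3×10⁵ MNase fragments per condition, 10⁵ RNAP II
reads per sample, 5000-strain screens, and 200-replicate null
calibrations — are chosen so each experiment carries decisive power for
its planted effect while the whole suite runs in minutes on one CPU.

## What passing tests do and do not show

The generator plants clean, parametrically controlled effects:
independent fragments (no PCR duplicates or batch effects), perfectly
known TSS/polyA anchors and dyad positions, unimodal noise, and a
strictly multiplicative global RNAP II change. Passing recovery tests
therefore demonstrates that the *estimators* are correct and calibrated
under their stated assumptions — not that real libraries satisfy those
assumptions. In particular: real MNase digestion biases, fragment-length
structure, replicate batch effects, imperfect annotations and genuinely
non-uniform global transcription changes are all outside the generator;
the GC proxy is a stand-in for real sequence-preference models; and the
plate-median normalization omits the row/column spatial artefacts real
screens contain (an optional median-polish mode addresses part of this).

## Known limitations

* Nucleosome positions are inputs, not inferred; fuzziness/positioning
  analysis is out of scope.
* Enrichment ratios at base resolution divide smoothed tracks and are
  unstable where input coverage is near zero; the window-level ratio of
  means is the supported statistic.
* The spike-in interface is a count table; aligning spike reads to a
  second genome is not implemented.
* χ² tests assume large cells; the Fisher fallback covers only the 2×2
  case, and small 2×3 tables warn rather than switch to an exact test.
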