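# Methods

## The measurement model

A two-color CGH array measures, per probe g and test strain s, the
normalized log2 ratio of test over reference signal across technical
replicates r.  The package models the replicate-averaged ratio x̄(g,s) as a
mixture of three gene classes: *present* (peak near 0), *absent* (strongly
left-shifted; no cross-hybridization) and *diverged* (intermediate;
sequence divergence weakens but does not abolish hybridization).  Because
the probes derive from the reference genome, the reference itself carries
every probe by construction, and the array cannot distinguish loss from
strong divergence — both are reported as "absent/modified", and downstream
scoring folds diverged into absent.

Normalized log-ratios are the input boundary: scanner-level normalization
(background subtraction, dye-bias correction) is assumed done upstream.

## Probe QC

* **Self-self background filter.**  On the reference-vs-reference arrays a
  probe is kept only when its replicate-mean raw signal strictly exceeds
  `mean(background) + k·SD(background)` in *both* channels (default k = 3).
  "Well above background" has no canonical numeric definition; k is a
  config key.  Without raw signals the stage is skipped with a warning.
* **Per-probe ANOVA.**  A one-way fixed-effects ANOVA of log-ratios across
  strains with Bonferroni adjustment `p_adj = min(1, p·G)` at α = 0.01 is
  available in three policies: `keep_significant` (retain probes whose
  ratios differ between strains), `drop_significant`, and `none`.  The
  pipeline default is `none`: on presence/absence data a strain-effect test
  retains exactly the probes that vary between strains, i.e. it would
  discard the invariant core genes the downstream partition is meant to
  count, so applying either active policy before a core-genome analysis is
  internally inconsistent.  The report (with adjusted p-values) is computed
  and logged regardless, and both active policies remain selectable for
  replication of other workflows.
* Degenerate probes: no variation at all → p = 1; zero within-group
  variance with a between-group difference → p = 0.

## Presence calling (dynamic cutoff / EPP)

Per strain, on the replicate-averaged ratios:

1. Gaussian KDE with Silverman's bandwidth
   `h = 0.9·min(sd, IQR/1.349)·n^(−1/5)`, evaluated on a 512-point grid
   spanning the data range ± 3h.
2. The presence peak is the **rightmost** local maximum whose height is
   ≥ 10% of the global maximum *and* whose topographic prominence is ≥ 5%
   of it.  The rightmost-peak rule protects against massive-deletion
   strains whose absent class dominates the histogram; the prominence
   requirement keeps finite-sample wiggle on the peak's shoulder from
   masquerading as that peak.
3. The presence component is a Gaussian fitted to the KDE around the peak
   by log-quadratic regression over the contiguous grid region with
   density ≥ 15% of the peak — jointly estimating refined center m, peak
   height ĝ and *kernel-convolved* width σ_g.  The width is cross-checked
   against the mirrored right half of the data about m (assumed
   uncontaminated, plus h² for the kernel), and the wider of the two is
   used: understating the component width spuriously demotes present
   genes, overstating it merely defers the EPP decline to where real
   contamination appears.  The mirrored rule alone is the fallback when
   the parabola is ill-conditioned.  The reported per-strain scale is the
   deconvolved `sqrt(σ_g² − h²)`.
4. EPP(x) = 1 for x ≥ m; left of m it is the ratio of the fitted component
   to a **one-SE lower confidence bound** of the KDE
   (`SE = sqrt(f·R(K)/(n·h))`), capped at 1.  The confidence bound makes
   the demotion one-sided in the right way: a gene is only called doubtful
   where the observed density *significantly* exceeds what the presence
   component explains.
5. The curve is monotonized by density-weighted isotonic regression
   (non-decreasing in x) and floored at 1e-12.  Isotonic averaging removes
   KDE wiggle without the downward ratchet a running minimum would
   introduce (a single 2-SE dip below the cutoff would otherwise truncate
   the whole present region to its left).

A gene is present when EPP strictly exceeds the cutoff (default 0.95).
The fit refuses fewer than 200 finite values (too little data to place the
mode; an explicit manual cutoff is required instead), a vanishing scale
(< 1e-3 log2 units), and — optionally, via `max_gaussian_misfit` — fits
whose density deviates from the fitted Gaussian near the peak by more than
a set fraction of the peak height.  That gate is the automated analog of
rejecting a hybridization whose presence peak is visibly misplaced; its
threshold is a user choice, off by default.

All constants (bandwidth rule, grid size, peak height/prominence/fit
fractions, confidence-bound z, ε) are keyword arguments.

Calibration at the defaults: on the canonical 85/15 present/absent mixture
(Normal(0, 0.3) vs Normal(−2.5, 0.5)) the caller's balanced accuracy
exceeds 99% at 10,000 probes, and its EPP curve deviates from the same
formula evaluated with the true mixture densities by < 0.001 on average at
50,000 probes (both recomputed by `scripts/acceptance.py` and the test
suite).

## Pan-genome partition

Core = column-wise intersection of presence over the conspecific strain
scope (outgroups excluded by default; the scope is a config list).
Reference-specific = present in the reference, absent everywhere else
including hybridized outgroups (the outgroup requirement is toggleable).
Overlaps O(s,t) = Σ_g P(g,s)·P(g,t); dissimilarity
d(s) = 100·#{g: present in ref, absent in s}/#{g: present in ref}, and the
identity d(s) = 100·(1 − O(ref,s)/O(ref,ref)) is asserted on every run.
The reference column is 1 on every QC-kept probe by construction.

## Dendrogram

Distances are mismatch proportions (Hamming) over the binary matrix —
the most direct reading of a distance "computed from a matrix of ones and
zeros" — with Jaccard as an option.  Neighbour joining is the classical
Saitou–Nei agglomeration; ties in the Q criterion are broken by the
lexicographically smallest pair of node identifiers, which makes the
output invariant to input order, and negative branch lengths are clamped
to zero with a warning (common practice).  On additive matrices the
recovered path lengths reproduce the input to < 1e-9.

The bootstrap resamples genes (matrix rows) with replacement B times
(default 1000), recomputes distances and the NJ tree, and counts
bipartition frequencies.  Two presentations are produced, since a
"consensus dendrogram with bootstrap values" can mean either: the
strict-majority (> 50%) consensus tree with supports as internal labels,
and the full-data NJ tree with the same supports painted on its edges.
Supports attach to bipartitions canonicalized as the side not containing
the alphabetically first strain.

## Trait association

With strains split into phenotype groups A (trait-positive) and B, a gene
is a hit when it is present in A and absent in B up to the mismatch
tolerance fn ≤ max_fn, fp ≤ max_fp, fn + fp ≤ max_total (defaults 1, 1, 1).
The default cap implements "one false negative *or* one false positive" as
an exclusive-or; setting max_total = 2 gives the one-of-each reading.  The
reference strain and outgroups are always excluded from scoring.  Only the
A-present direction is searched: every probe derives from the reference
genome, which belongs to group A for both phenotypes studied, so genes
private to group B are unobservable on this array design.

The published record does not state how the 16×9 virus-lysis matrix was
collapsed into susceptible/resistant (one strain is lysed by exactly one
of nine viruses); the fixture therefore exposes the rule as a parameter
(`min_lysed`, default 1) rather than hard-coding a guess.

## The simulator

The generator emulates the structure of a 16-strain + outgroup CGH study
with technical triplicates and self-self reference arrays.

* **Tree and loss.**  A random topology over the non-reference strains by
  sequential random attachment with Exp(1) pendant lengths; the reference
  sits at the root (its genome defines the probes, so it loses nothing).
  Each variable gene starts present at the root and is lost on a branch of
  length b with probability 1 − exp(−rate·b), irreversibly — so content
  covaries with phylogeny and the dendrogram stage has signal to recover.
  A star-tree mode (all branch lengths 1) gives i.i.d. loss instead.
  Outgroup taxa share a long basal branch (default length 14, i.e. ~30%
  gene-content dissimilarity versus the reference, the genus-level
  divergence the design emulates); with two or more outgroups this makes
  the outgroup side a genuine internal bipartition.
* **Classes and noise.**  Gene × strain latent ratios are drawn
  Normal(μ_class, sd_class) — defaults: present 0 ± 0.3, absent −2.5 ± 0.5,
  diverged −1.0 ± 0.5 (log2 units; the classes sit ~5σ apart, the clean
  bimodality the dynamic-cutoff method assumes) — and each replicate adds
  Normal(0, 0.1) technical noise.  A fraction (default 2%) of loss events
  is relabelled "diverged" to exercise the caller's grey zone; diverged
  genes overlapping the presence peak are the dominant, irreducible source
  of calling error, which is why the default fraction is small — under a
  perfect caller evaluated on the true densities, core-genome recovery
  stays ≥ 95% only for diverged fractions around 2% or below, and the
  package treats that oracle ceiling as part of the study conditions.
* **Scale.**  10,000 probes by default — a desk-scale stand-in for the
  ~32,000–38,000-probe whole-genome designs this emulates, keeping the
  full test suite and the acceptance script in the tens of seconds.  60%
  core, 50 reference-specific genes, 20 planted trait genes on a 7/8
  strain split, 2% of probes planted below background on the self-self
  arrays (flagged exactly by QC), one root seed determining every byte of
  output.

What the simulator does **not** model: dye bias, spatial artifacts, probe
cross-hybridization, gene duplication (copy-number gains), or
sequence-level evolution.  Passing tests therefore demonstrate that the
inference chain is correct and well calibrated under a clean two-component
noise model with phylogenetic loss — not that real arrays meet those
assumptions; on real data the QC stage and the per-strain fit diagnostics
(`gaussian_misfit`, fit report) carry that burden.

## Determinism

One root seed drives each run: the simulator derives independent child
streams for content and arrays via seed sequences, the bootstrap uses the
run config's seed, and all writers emit bytes deterministically (fixed
float formats, sorted JSON keys, no timestamps).  Rerunning an identical
config on identical inputs is bit-identical, manifest included.

## Known limitations

* EPP is a density-ratio heuristic, not a posterior from a fitted mixture;
  its absolute scale is only as good as the presence-component fit, and
  the one-SE confidence bound deliberately trades a little specificity in
  the diverged grey zone for robustness of present calls.
* Strains with fewer than 200 QC-passing probes cannot be fitted.
* The consensus tree carries supports but no branch lengths (the full-data
  NJ tree with painted supports carries both).
* The ANOVA filter's intent in the original workflow is ambiguous; all
  three policies are provided but none is asserted as the original's.
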