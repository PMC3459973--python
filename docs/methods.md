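# Methods

## The label-swap pull-down model

One SNP comparison consists of two allele baits (the SNP's flanking
sequence with either variant base at offset `len(left_flank)`), each
incubated with differentially SILAC-labelled nuclear extract and pooled
before mass spectrometry. In the *forward* orientation the first allele's
bait meets the heavy extract; in the *reverse* orientation the labels are
switched. Each orientation therefore comprises two physical pull-downs and
yields one evidence table of peptide-level heavy/light ratios; a 12-SNP
panel gives 24 experiment pairs and 48 pull-downs.

For a protein whose binding is independent of the allele, the expected
heavy/light ratio is 1 in both orientations. A protein preferring allele X
with fold change f has expected ratio f where X is heavy and 1/f where X is
light, so its log-ratio *inverts* under the label swap. An unlabelled
contaminant (keratin-like) contributes only light signal and keeps a
heavy/light ratio well below 1 in both orientations. These three signatures
are what the downstream statistics separate.

## Synthetic evidence generator

The generator emulates a MaxQuant-style evidence export at the peptide
level. Study conditions (defaults):

| parameter | default | meaning |
|---|---|---|
| `n_background` | 1000 | nonspecific proteins, true ratio 1 |
| `n_contaminants` | 50 | unlabelled proteins |
| `contaminant_hl_ratio` | 0.2 | their H/L ratio in both orientations |
| `peptide_noise_sd` | 0.3 | sd of peptide log₂-ratio noise |
| `mean_peptides` | 3.0 | mean of the geometric peptides-per-protein law (min 1) |
| `unique_fraction` | 0.9 | fraction of peptides flagged unique |
| intensity | log-uniform 10⁵–10⁹ | quantitation-event intensity |
| `seed` | none | mandatory; no silent default |

Peptide ratios are lognormal around the protein's true ratio —
multiplicative noise, symmetric in log space, which is how SILAC ratio
error behaves. Peptide counts follow a geometric law with floor 1 so that
single-event identifications (dropped by the event filter) are common, as
they are in real data. Binder peptide counts are fixed by their spec so
power statements are exact. Everything is reproducible from the seed;
per-SNP seeds in a study are spawned deterministically from the study seed.

What the generator does **not** model: spectrum-level effects, shared
peptides between proteins (each synthetic peptide token belongs to one
protein), missing-value mechanisms beyond the peptide-count draw,
ratio-intensity dependence, and replicate-to-replicate batch effects.
Passing tests on this generator therefore demonstrate the statistical
machinery under the stated noise model, not performance on raw instrument
output.

## Quantification

Per experiment and protein: the number of quantitation events, the number
of distinct unique-flagged peptides, and the median of peptide log₂
ratios. Proteins with fewer than 2 events or no unique peptide are dropped
(counts go to the run log). The median is robust to a single outlier
peptide; even counts use the mean of the central pair. Ratios are
re-expressed on a common allele-1/allele-2 scale (negated in the reverse
orientation) and each experiment's oriented ratios are median-centred
(offset logged), because the extracts are nominally mixed 1:1 and the
nonspecific majority defines the true zero. The raw heavy/light column is
kept un-centred so the contaminant rule can read it. Normalization is
skipped with a warning below 20 proteins.

## Outlier significance and label-swap combination

Within one experiment a specific binder is an outlier of the
experiment-wide oriented log-ratio distribution. Each protein gets a robust
z-score: distance from the median scaled by the 84.13th-percentile spread
on the right and the 15.87th-percentile spread on the left (these
percentiles bracket ±1 sd of a normal, so the two sides get separate
scales and skewed clouds are handled). The reported per-experiment p-value
is the upper normal tail of the *signed* z — the one-sided p for allele-1
preference. This convention keeps the p-value uniform on (0,1) under the
null (a requirement for honest combination) while still giving 0.5 at the
median and ≈0.1587 one scale unit above it; allele-2 preference simply
shows up as p near 1, and the protein's direction (sign of the oriented
ratio) is carried separately.

The two orientations are combined by Fisher's method (−2(ln p₁ + ln p₂)
against χ²₄), using the upper tails when both directions are positive and
the lower tails (1 − p) when both are negative. If the directions
disagree, the protein cannot be a consistent allele-specific binder and
the combined p is 1. p-values are floored at 10⁻³⁰⁰ to keep logarithms
finite. The decision threshold defaults to 10⁻⁷ and is applied as a fixed
cutoff (no FDR procedure); a Bonferroni-style column can be derived by the
caller if wanted. The exact outlier statistic is a documented design
choice validated by its calibration properties (uniform null p-values,
no null crossings at default scale) rather than by matching any external
protein list.

## Classification

Axis convention for the 2D interaction plot: x is the forward oriented
log₂(allele1/allele2) ratio, y the reverse raw log₂(heavy/light) ratio.
Allele-1 binders then fall lower-right, allele-2 binders upper-left,
contaminants lower-left. Precedence: contaminant, then specific, then
background; proteins quantified in only one orientation are `not_callable`.

The contaminant rule requires the raw (pre-normalization) heavy/light
ratio below `contaminant_max_hl` in **both** orientations. The cutoff
defaults to 0.5 rather than 1.0: with symmetric noise, a quarter of true
background proteins drift below 1 in both orientations by chance, and a
literal <1 rule would sweep them into the contaminant class (measured
accuracy against ground truth drops to ~80–90%); 0.5 cleanly separates the
unlabelled cloud (H/L ≈ 0.2) from the origin cluster and restores ~100%
accuracy at default conditions. Any protein below the cutoff in both
orientations necessarily has conflicting oriented directions, so the
contaminant and specific rules cannot compete.

The fold estimate is the geometric mean of the two orientations' implied
folds, `2^((|x| + |y_oriented|)/2)`, chosen for symmetry under the label
swap; screen summaries report per-SNP specific-call counts by allele and
the SNPs with no specific call.

## Motif scanning

Consensus matching is degeneracy-set based (IUPAC codes; B = C/G/T,
H = A/C/T, N = any), not PWM-scored: the shipped motifs are deposited
consensus strings (CREB1 `TGACG`, RUNX1 `TGTGGBH`), and the question asked
is presence/absence of a site across the SNP. Both strands are scanned by
matching the consensus and its reverse complement along the plus strand;
all offsets are 0-based plus-strand coordinates so allele comparisons use
one frame. Default mismatch budget is 0, with an explicit 1-mismatch mode
for near-miss sites. A motif is *allele-differential* when the presence of
a perfect SNP-overlapping hit differs between alleles. The scanner is
checked against an exhaustive brute-force enumeration in the tests.

## Bait concatemers

Concatemer construction returns the top strand of a head-to-tail n-mer in
which each unit contributes the bait plus one copy of the 2-nt overhang
(`len = copies × (len(bait) + len(overhang))`): the overhang appears once
per junction and once as the terminal sticky end. An overhang is accepted
when it is palindromic (anneals directly between identical units) or a
homopolymer of A or T — the asymmetric TT/AA two-oligo scheme, preferred
in practice because the junctions then template adenine-directed fill-in
labelling. Other overhangs (e.g. `GG`) have no annealing partner within a
single symmetric unit design and are rejected.

## Validation statistics

Comparative Ct: replicate Ct values are averaged per (sample, gene) before
differencing; ΔCt = Ct(target) − Ct(reference), ΔΔCt = ΔCt(treated) −
ΔCt(control), relative expression 2^(−ΔΔCt). The spread is the sd of
replicate-wise ΔΔCt values (replicates paired by identifier), reported on
both the Ct and expression scales; machine offsets cancel exactly.

Reporter activation: activity = firefly/renilla per replicate; each
knock-down replicate's percent change is taken relative to the allele's
mock mean, and the two alleles are compared by a two-sided Welch t-test on
those replicate percent changes. Computing changes per replicate (rather
than on condition means alone) preserves a spread estimate from
triplicates; the choice of test is a documented convention, not a
reproduction of any particular published analysis.

## Problem sizes and numerical choices

The test suite and the acceptance script run the generator at the stated
study conditions: the null-calibration check uses 50 simulated experiment
pairs of 10,000 background proteins; recovery uses 20 seeds with spiked
folds {4, 5, 8, 10} at 5 peptides; the classification-invariant check uses
20 random studies of three SNPs at 400 background proteins each. Medians
and percentiles use numpy's linear-interpolation defaults, which are
symmetric under sign flips — this makes the label-swap antisymmetry of the
classifier exact, not approximate.

## Known limitations

* The robust-z/normal-tail p-value treats every protein identically, but
  proteins quantified by only 2–3 events have slightly heavier-tailed
  aggregated ratios than the experiment-wide scale implies. Per-experiment
  p-values still pass KS uniformity comfortably, and at the default
  1000-protein scale null threshold crossings are absent in ≥99% of runs;
  at 10,000 proteins per experiment a residual ~4×10⁻² expected crossings
  per run remains. An events-aware or intensity-binned variance model
  would remove this at the cost of departing from the simple
  experiment-wide outlier statistic.
* Protein inference is out of scope: evidence rows carry a protein id and
  shared-peptide grouping is not modelled.
* The contaminant call is a quadrant rule, not a mixture model; heavily
  allele-biased binders that are also partly unlabelled would confuse it.
* Consensus motif scanning deliberately ignores binding-strength
  gradations; a PWM layer could be added on top of the hit coordinates.
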