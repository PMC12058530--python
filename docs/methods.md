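# Methods

This note documents the models, parameter choices and numerical conventions
behind `heterokit`, and what the synthetic-data tests do and do not show
about real assemblies.

## Coordinate and rounding conventions

All intervals are 0-based half-open (BED). A CpG site is addressed by the
position of the C of the forward-strand CG. Printed summaries round half-up
at the conventional precision (2 decimals for Gb/Mb columns, 1 for counts
and QV; 146.375 → 146.38); percentages from count ratios are half-up at one
decimal (79/114 → 69.3). Integer arithmetic is kept until the final division
in any percentage, so fixture percentages carry no floating drift.

## Synthetic genomes (`synthio`)

The simulator emulates the architectural features of hominoid chromosomes at
reduced scale, not their sequence content. Per chromosome it lays out: a
telomeric `TTAGGG` run at each terminus (reverse complement at the 5′ end;
runs are whole motif copies so exact tandem detection recovers the truth
interval exactly), an optional subterminal cap, a centromeric α-satellite
HOR array, optional rDNA, and i.i.d.-uniform ACGT background. Background is
deliberately structureless so no accidental satellite arises. Assembly gaps
are N runs punched into background only, never into features.

Key defaults and their motivation (all configurable in `SimConfig`):

* **Chromosomes** — 3 per haplotype of 16 Mb, two haplotypes. Real ape
  chromosomes are 40–250 Mb; 16 Mb is the smallest scale that holds a 6 Mb
  cap plus the largest centromere draw with realistic proportions while the
  full test suite runs in tens of seconds on one CPU.
* **Telomere** — 5 kb runs (rounded down to whole 6-mers → 4,998 bp).
* **Centromere** — HOR unit of 12 × 171 bp monomers, exact tandem repeats
  (optional per-base substitution rate, default 0, so identity-based checks
  have a clean baseline). Array lengths follow the bonobo-like two-component
  lognormal mixture: a minicentromere component (mean 110 kb, clipped to
  ≥ 15 kb) with weight 27/48 and a normal component (mean 3.6 Mb, clipped to
  ≤ 6.7 Mb), matching the reported bimodal range.
* **Cap** — 32 bp AT-rich monomer (one CpG forced per monomer so tract
  methylation is defined), tracts of mean 400 kb (sd 50 kb; reported range
  335–536 kb) separated by 34 kb spacers of random non-satellite sequence,
  building a 6 Mb p-arm cap. A `spacer_period_bp` mode makes tract + spacer
  a fixed period (the 750 kb siamang-like layout), and `n_tracts` builds an
  exact tract count without end truncation for unbiased tract statistics.
* **rDNA** — 45 kb unit, 20 copies on the first chromosome.
* **Methylation** — per-CpG fractions Normal(0.9, 0.05) clipped to [0, 1];
  truth CDRs (one per centromeric array, length = 0.3 × array length +
  Normal(0, 10 kb) noise, ≥ 15 kb) and spacer pockets at mean 0.1. Coverage
  is Poisson(30), carried but not weighted (each CpG counts equally, which
  matches the simulation's semantics).
* **Inversions** — events placed on tree branches with probability
  proportional to branch length (Poisson at 2 events/Ma by default, or a
  fixed count); a configurable recurrent fraction (default 0) adds a second
  branch and leaves carry the parity of event branches on their root path.
* **Seeding** — one top-level seed; each feature class derives a child seed
  by a fixed offset, so adding or removing one feature class does not
  perturb the others, and identical (config, seed) reproduce byte-identical
  FASTA/BED/track outputs.

What passing the round-trip tests shows: the analysis operations implement
their stated definitions exactly on clean signals of realistic scale. What
it does not show: robustness to monomer divergence, annotation error,
mapping noise, or coverage bias — none of which the generator models.

## Assembly QC (`asmqc`)

A chromosome is **t2t** iff it has zero gaps (runs of ≥ 10 N; the threshold
is configurable since assemblers differ) and a telomere interval at both
termini; ≥ 1 gap classifies **gapped** (taking precedence), else
**missing_telomere**. Telomere detection reports maximal exact tandem runs
of the motif or its reverse complement, ≥ 2 kb long, whose nearer end lies
within 10 kb of a terminus, at most one per terminus; an optional divergence
mode accepts sliding 100-mers with ≤ 10% positions uncovered by exact motif
copies. Detection parameters are package choices — the criterion itself
("gapless with a telomere on both ends") is the fixed definition. Gaps
overlapping an annotated rDNA interval are exempt from the "non-rDNA
issues" count, because rDNA array interiors are left unresolved by design;
each missing terminus telomere adds one issue.

## Satellite arrays (`satarch`)

Same-family annotations merge while their gap is ≤ `max_gap_bp` (default
10 kb); arrays < 10 kb are discarded. For cap-scale analyses the pipeline
merges with 50 kb (above the 34 kb spacer scale) so a cap is one array.
Classification: rDNA by family; subterminal within 500 kb of a terminus
(arm p/q); the **largest** non-subterminal α-satellite array per chromosome
is the centromeric HOR array — a deliberate simplification of active-array
identification, which in real genomes uses HOR/SF annotation and CDR
evidence; everything else is interstitial. The minicentromere threshold is
700 kb (strict `<`). Haplotype fold ratios use max/min, avoiding direction
ambiguity; pairs without a divergence estimate leave the divergence
denominator.

## CDR calling (`methdip`)

No published caller is pinned for this analysis class, so the module defines
one, entirely via parameters: window means (5 kb windows, 1 kb step) over
the array; baseline = median of defined window means; dip windows fall below
baseline − 0.20; dips merge across ≤ 2 intervening non-dip windows; merged
dips are refined at step (1 kb) resolution — without refinement the window
grid inflates dip bounds by up to window − step, which would break the
intended ≥ 0.9 truth Jaccard for dips of length 3 windows; dips < 1 kb are
dropped, and a dip must be hypomethylated relative to its ± 25 kb flanks
within the array. Because the baseline is median-relative, a uniformly
hypomethylated array has no dip by definition (documented behaviour). For
the regression, "CDR length" is the **sum** of dip lengths per array, which
handles multi-dip arrays deterministically; R² = 1 − SS_res/SS_tot.

## Subterminal caps (`capstruct`)

Caps are the merged subterminal array blocks nearest each terminus with
≥ 1 Mb of satellite. Spacers are the unannotated gaps (5–200 kb) between
consecutive tracts — an annotation-gap proxy for the segmental-duplication
spacer sequences of real caps. Modal spacer length uses 1 kb floor bins,
ties broken toward the smaller bin for determinism. Periodicity is the mean
distance between consecutive spacer midpoints. The methylation profile
aligns ± 25 kb windows on spacer midpoints (500 bp bins); the pocket
statistic is mean(CpG fraction inside spacers) − mean(flanking satellite
CpGs within the window, excluding CpGs inside any spacer, which prevents
contamination in short-period caps), tested one-sided (spacer < flank) by
Mann–Whitney rank sum. Fully tied inputs report p = 0.5 rather than the
degenerate tie-corrected value.

## rDNA and NORs (`rdnanor`)

Copy number = array span / unit length (default 45 kb), rounded half-up —
exact on assemblies whose arrays are tandem unit multiples; read-depth
refinement is out of scope. NOR⁺ requires an rDNA array of ≥ 1 estimated
unit (single-unit arrays count, as observed on real Y chromosomes); DJ
palindrome detection is not attempted.

## Inversion phylogenetics (`invphylo`)

The default dated tree spans human, chimpanzee, bonobo, gorilla and the two
orangutans with splits at 6 / 10.75 / 19 Ma and within-genus splits at 1.7
(Pan) and 0.9 Ma (Pongo). The siamang split is not among those dates; the
`include_siamang` variant adds it as an outgroup at 22 Ma, a fixture value
chosen once for the simulator. Characters are species presence/absence;
heterozygous species are missing by default (only homozygous carriers are
confidently inverted in a two-haplotype comparison; `het_as_present`
includes them for sensitivity analysis). Parsimony is unit-cost Sankoff with
the **root fixed to the reference state** — inversions are derived, and
branch assignment needs that polarity; an unrooted Fitch pass would not
place events. Exactly one change assigns the event to the unique branch
whose clade (restricted to non-missing leaves) equals the present set (with
missing leaves, nested branches can become indistinguishable; the most
ancestral compatible branch is reported). Two or more changes flag
recurrence.

Breakpoint enrichment: the observed statistic counts inversions with ≥ 1
breakpoint within ± 10 kb (configurable; breakpoints in assembly comparisons
are not base-precise) of a feature. The null redraws each inversion
uniformly on its own chromosome, preserving length and avoiding assembly
gaps; chromosomes are never shuffled, which conserves per-chromosome feature
density. Fold = observed/mean(null); the one-sided empirical P carries the
+1 correction, so P ≥ 1/(n_perm + 1). Note that when inversion lengths are
commensurate with a periodic feature spacing, the two breakpoint hits are
correlated under this null and the fold departs from the independence
expectation 1/(1 − (1 − c)²) for cover c; the calibration fixtures use
irregular feature spacing for that reason.

## Pipeline (`report`)

Stages run as inputs permit; each stage logs parameters and seed, and every
output file lands in a JSON manifest with SHA-256 checksums — two runs with
identical config and seed are byte-identical. Configs are JSON with a
versioned schema; unknown keys fail fast. CLI exit codes: 0 success, 2
config error, 3 stage failure.

## Problem sizes

The published genome-scale quantities (e.g. R² values on real arrays,
genome-wide enrichment folds) depend on multi-gigabase assemblies and are
not reproducible at this scale. The acceptance script therefore combines
exact worked examples whose inputs are fully printed counts with property
analyses at the simulator's default scale: a 2 × 2 × 16 Mb diploid genome,
40 centromere-only chromosomes for the CDR regression, 200 tree events for
branch recovery, and 1,000-permutation enrichment on a 10 Mb fixture —
sizes chosen so the whole script completes in well under a minute while
every statistic is estimated from hundreds to thousands of draws.

## Known limitations

* No sequence-evolution realism: no indels, transposable elements, HOR
  monomer phylogeny, or read-level noise.
* The "largest α-satellite array = centromere" rule misclassifies genuinely
  acentric or neocentromeric configurations.
* Spacer detection trusts the annotation; unannotated satellite diverging
  below the annotator's threshold would masquerade as spacer sequence.
* The CDR caller's median baseline assumes dips occupy < 50% of array
  windows; arrays that are mostly dip return nothing.
* QV is consumed as an input column only; no accuracy estimation from reads.
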