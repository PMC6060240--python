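# Methods

## Scope and model

`microdiv` analyzes a small set (typically ~8) of complete genomes from one
bacterial species whose strains are nearly identical (ANI ≥ 98%) but
exchange core-genome DNA by homologous recombination (HR) and accessory
DNA through island hotspots and plasmids. The population model behind both
the simulator and the estimators is:

* a clonal genealogy relates the strains; strains cluster into clonal
  frames (CFs), near-identical groups separated by deeper branches;
* clonal point mutations accrue on branches (Jukes–Cantor single-hit, no
  indels in the core);
* HR events replace a contiguous core tract on a branch with a donor
  haplotype from an external pool at divergence ν, importing
  Binomial(tract length, ν) substitutions;
* accessory gene families are gained on lineages and concentrate at a few
  chromosomal hotspot loci; plasmids carry strain-specific families.

The two impact ratios are count ratios on this model:
`rho/theta` = HR events per clonal mutation, and
`r/m` = imported substitutions per clonal mutation.

## Simulator

`SimParams` defaults describe the study conditions the toolkit targets:
8 strains in 5 CFs on a 500 kb core (a desk-scale stand-in for a multi-Mb
core genome), `theta_site = 2.5e-4` expected substitutions/site over the
whole tree, `rho_rel = 0.3` events per mutation, geometric tracts with
mean 5 kb and donor divergence ν = 0.02. Jointly these give ~125 clonal
mutations, ~38 imports, ~31% of the core covered by HR, pairwise ANI
≥ 99.5% and realized rho/theta ≈ 0.3. The donor divergence is chosen for
detector testability (imports must stand out against the clonal
background); as a consequence the realized r/m of the default scenario
(≈ 20–25) is far above what a natural isolate set with this event density
would show — r/m is therefore validated through the exact truth-bypass
route, not through a "realistic" absolute value.

Two design constraints make the realized ratios *exactly* recoverable:

1. **Donors copy the recipient.** Each donor haplotype is the recipient's
   current sequence plus ν-substitutions, so imports never silently erase
   unrelated variation and `imported_substitutions` is an exact count.
2. **Mutations stay identifiable.** A clonal mutation is only placed at a
   position where, after masking every tract for its recipient lineage, at
   least one carrier and one non-carrier remain visible. Without this, a
   mutation inside an ancestral lineage's import would vanish for every
   carrier under masking and the truth ratios would be unrecoverable by
   *any* estimator.

Consequence (a deliberate limitation): because imports never erase
lineage-specific variation, the generator does not reproduce the cohesive
effect by which HR in nature *reduces* within-CF divergence variance. The
generator tests detection and estimation, not population cohesion
dynamics.

Emitted data: per-strain FASTA (chromosome with islands inserted at
hotspots, optional plasmid), gene tables with COG letters, the true core
alignment as gap-free XMFA blocks split at hotspot loci, an ortholog
presence/absence matrix, and full truth tables (tree, mutation sites,
tracts with imported-substitution positions, accessory gains). Byte-level
determinism given `seed`.

## ANIb and TETRA

ANIb follows the fragment-table recipe: local matches (exact 15-mer
anchors, same-diagonal chaining, ungapped X-drop extension, identity
recomputed by direct comparison — or a parsed `show-coords` table),
then post-processing: drop fragments contained in a larger fragment; join
fragments overlapping by >10% of the shorter fragment's length (the
`overlap_basis` option also offers the longer/either readings, since the
original recipe does not say which length the 10% refers to); joined
fragments take the interval union and an identity weighted over disjoint
reference coverage (the overlap counted once, with the longer fragment's
identity, so shared bases are not double-weighted). ANIb is the
length-weighted mean identity; both directions are computed and the
symmetric mean is the headline value.

TETRA counts tetranucleotides on each sequence plus its reverse
complement, takes expected counts from the maximal-order Markov model
`E[n(abcd)] = n(abc)·n(bcd)/n(bc)` with the model's variance, and
correlates the 256 z-scores between genomes (Pearson, percent). z-score
noise shrinks with sequence length: at the 500 kb default scale,
within-species correlations are ≥ 99; on the 60 kb test fixtures they sit
near 90.

## Recombination detection

All scans run on the gap-free columns of alignment blocks that contain
every strain and are ≥ 500 bp long; the variable (polymorphic) columns are
the site series.

* **MaxChi** (per pair): the match/mismatch series over variable sites is
  scanned with a 210-variable-site window (105 per side); the 2×2
  chi-square of left/right mismatch counts is maximized over candidate
  breakpoints. Significance comes from the permutation null of the
  *maximum* statistic — family-wise valid by construction, which plays the
  role of the per-breakpoint correction. The null is sampled exactly and
  cheaply as multivariate-hypergeometric bin counts (under permutation the
  statistic depends only on how mismatches fall into the window-boundary
  bins), with 1023 draws so the smallest attainable p (1/1024) clears the
  0.001 consensus cutoff, and an early exit once two draws beat the
  observed maximum (the p can then no longer reach the cutoff).
* **Chimaera-style** (per triplet): for each member as putative
  recombinant, the binary series "matches parent 1 vs parent 2" at sites
  where the parents differ and the recombinant matches one of them, scanned
  exactly like MaxChi; overlapping peaks across the three orientations keep
  the strongest.
* **RDP-style** (per triplet): informative sites (exactly two of three
  agree) are labelled by the agreeing pairing; 90-nt windows where *any*
  pairing is over-represented relative to its genome-wide proportion are
  chained (gap tolerance 8 windows) and each chained region is tested with
  the exact binomial tail, Bonferroni-corrected over regions. Testing every
  pairing (not only the genome-wide minority) is what gives power against
  imports from outside the sample, where the two non-recipients agree
  locally.

Significant peaks partition each series; each breakpoint claims the flank
deviating more from the series mean, trimmed to its divergent core by a
maximum-sum-subarray pass against the local flank-density midpoint.

**Consensus.** The scans *certify* regions: maximal column runs covered by
≥ k (default 2 of 3) distinct methods at p < 0.001. Window-scale scans
smear intervals and can attribute a signal to either member of a pairing,
so the final calls are delineated inside each certified region from the
per-strain divergence profile: a strain's mismatch series against the
majority consensus of the others, smoothed (9 sites), with runs above 1/2
(majority divergence, ≥ 5 sites, gap tolerance 5) becoming that strain's
tract calls. Per-strain calls are merged (gap ≤ 200 columns) and joined
across strains when reciprocally concordant (overlap ≥ 70% of the shorter
and ≥ 50% of the longer), yielding **one event per import** whose
recipients are all strains carrying it — essential downstream, where every
carrying lineage must be masked. Breakpoints are refined by maximizing the
MaxChi contrast of the recipient-vs-nonrecipient-consensus series near
each edge. The donor is the non-recipient strain closest to the recipient
within the event, or `external` when no strain is closer inside the event
than its genome-wide background (the signature of an import from outside
the sample). Imports carried by a majority of strains (the minority then
looks like the "recipient" of the ancestral allele) are called from the
minority side; perfectly balanced splits can fire from both sides and are
collapsed by the concordant-join rule.

## Clonal genealogy and impact ratios

Event intervals are masked per recipient (padded by `mask_pad = 1000`
columns to absorb breakpoint error; with exact truth intervals a pad of 0
is used and the estimators are exact). Pairwise Jukes–Cantor distances on
co-unmasked columns feed neighbor joining (scikit-bio), midpoint-rooted.
Masking that removes > 90% of columns raises an error instead of returning
a meaningless tree.

`n_clonal_mutations` is the Fitch-parsimony substitution count over
variable columns with masked tips as wildcards; `n_imported_subs` uses the
event table's exact counts when present and otherwise counts
recipient-vs-nearest-sibling differences inside each event;
`n_events` deduplicates per-recipient rows into regions when exact counts
are absent. `r/m` and `rho/theta` are the corresponding ratios; zero
observed mutations flags them undefined.

Clonal frames are single-linkage clusters of the ANIb matrix at a
threshold (default 99.5; the acceptance script places it in the widest gap
of the observed pairwise values).

## dN/dS

Nei–Gojobori counting: per-position synonymous fractions exclude changes
to stop codons (each codon still contributes 3 sites, so N + S = 3 ×
codons); multi-hit codons average over all orderings of the differing
positions, excluding pathways through stop codons (falling back to all
pathways only if every one is blocked); proportions are Jukes–Cantor
corrected, `d = -3/4·ln(1 - 4p/3)`. Saturation (p ≥ 0.75) and dS = 0 flag
the result undefined rather than returning a number. This is a counting
stand-in for likelihood codon models: adequate for comparing divergence
within/between clonal frames, not numerically interchangeable with ML
estimates.

## Enrichment

Genes overlapping any event interval (≥ 1 bp by default; a minimum overlap
fraction is available) form the foreground; the two-sided Fisher exact
test per COG category against the background gene set is BH-adjusted, and
significance uses the dual threshold p < 0.05 and q < 0.05. The default
background is all genes of the analyzed strains.

## Numerical and testing notes

* Every stochastic step flows from an explicit seed through independent
  crc32-salted generator streams; identical inputs give identical outputs.
* Test and benchmark problem sizes are desk-scale by design: 60–200 kb
  fixtures for unit tests; 8 × 100 kb recombination-free populations
  (theta 5e-3) for type-I control; 8 × 200 kb with forced ≥ 5 kb imports
  for breakpoint accuracy; the 500 kb default scenario for rate recovery.
  Passing these shows the statistics and estimators are correctly
  implemented and calibrated on data satisfying the generator's
  assumptions (gap-free core, neutral evolution, external donor pool);
  real genomes add rearrangements, indels, selection and annotation error
  that the simulator does not emulate.
* The readers reject malformed input rather than repairing it; all
  internal coordinates are 0-based half-open, converted at the format
  boundary (XMFA and GFF3 are 1-based inclusive on disk).
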