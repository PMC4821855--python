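# Methods

This note records the models, defaults and design decisions behind
`flaxsrna`, and what the synthetic-data experiments do and do not
demonstrate.

## Read processing

A 3'-adapter sequencing protocol is assumed: a genuine small-RNA insert is
shorter than the read, so the adapter must be visible. Trimming takes the
insert upstream of the left-most full adapter occurrence, or of the longest
read-suffix matching an adapter prefix of at least `min_overlap` (default
8) bases; matching is exact (0 mismatches) so results are deterministic.
Reads without adapter evidence, or with an empty insert, are rejected.
The quality gate drops reads containing N or with mean Phred below 20 —
a conventional choice, configurable, since "low-quality" is not otherwise
defined by the protocols this emulates. Tags are stored as uppercase DNA
(U converted to T) so one internal alphabet serves FASTA/FASTQ and RNA
inputs alike. Collapsing keeps inserts of 16–30 nt; the abundance filter
(default: six or more reads) is applied per library, matching per-library
"unique sequences at threshold" accounting; a max-across-libraries variant
is available.

## Genome mapping

Mapping is exact-match on both strands via a k-mer (default k = 12)
seed-and-verify index, reporting all occurrences sorted by position with a
multi-hit cap (default 20) and an explicit overflow flag. Exact matching is
the appropriate model for abundance-collapsed tags where the question is
presence/absence of a genomic source; mismatch alignment is out of scope.
Coordinates are 0-based half-open internally and 1-based inclusive in GFF3.

## Annotation

Conserved-miRNA homology is ungapped comparison at every offset with at
least 18 nt overlap and length difference ≤ 2, keeping the minimum-mismatch
database entry when it has ≤ 2 mismatches (ties: first database record).
Non-coding classification is exact substring containment (either strand) in
a class-labelled database, first record wins. Precedence when both match:
a perfect conserved hit outranks everything; otherwise exact non-coding
containment outranks a mismatched conserved hit — non-miRNA sRNAs are
filtered before miRNA calling, so containment evidence is stronger than
approximate homology. Family names are parsed from database identifiers
(`miR` + number) with the conventional merges miR165/166, miR156/157,
miR170/171. Summary percentages divide per-category unique-tag counts by
the per-library unique-tag total at the abundance threshold and round
half-up to two decimals, the convention that reproduces printed annotation
tables exactly from their printed counts.

The target scorer is a global alignment of the miRNA against the
reverse-complemented site with penalties mismatch 1.0, G:U wobble 0.5,
indel 2.0, doubled at miRNA positions 2–13; it is plumbing for target
*ranking*, not a thermodynamic model (no expectation or accessibility
terms).

## Hairpin folding and precursor criteria

Folding is nested base-pair maximization over AU, GC and GU pairs with
hairpin loops of at least 3 nt — exactly testable against brute-force
enumeration, unlike thermodynamic folding. The maximal pair count is,
however, highly degenerate on windows of ~186 nt: many co-optimal
structures exist and an arbitrary one is useless for judging stem-loops.
Two measures make the judgement stable:

* the traceback resolves ties by preferring stacked (helical) pairs before
  the 5'-most-pairing rule, so planted stems are recovered rather than an
  arbitrary co-optimal scatter; the pair count remains the exact maximum;
* the precursor criteria judge the mature tag against its *dominant
  partner block* — the compact window (mature length + 4 nt of bulge slack)
  of partner positions receiving the most mature pairing partners, i.e. the
  star arm. Stray pairs of individual mature bases to distant positions,
  which maximum pairing produces freely, do not disqualify a real stem.

A candidate passes when (a) the dominant block lies entirely on one side of
the mature and the mature overlaps no hairpin loop, (b) at least 60 % of
mature bases pair into the block, (c) no run of more than 4 mature bases is
unpaired with respect to the block, and (d) the window forms at least 15
pairs. These thresholds are explicit, configurable stand-ins for the
"typical stem-loop" judgement of interactive folding tools; they are
reported in the candidate output. Windows are 15 nt proximal / 150 nt
distal on either side of the tag (both orientations tried), clamped at
contig ends, reverse-complemented for minus-strand hits.

Discovery evaluates every window of every hit (up to the multi-hit cap) of
every unannotated mapped tag and reports the best passing candidate per tag
(highest mature paired fraction, then smallest window start).

## Insertion screen

Tags at or above the abundance threshold are matched exactly (both strands)
against the insertion and flank sequences. "Shared with insertion-free
libraries" is operationalized as reaching the abundance threshold in any
insertion-absent library — the simplest faithful reading of
similar-abundance sharing; a ratio test would add a tunable constant
without changing the worked example. Surviving candidates are folded in
their region context with the same window geometry and criteria as novel
discovery; the overall verdict is true iff any candidate passes.

## Differential expression

The Audic–Claverie posterior-predictive distribution of the second count
given the first is the negative binomial NB(n = x+1, p = N1/(N1+N2));
tails are computed by scipy's log-space negative-binomial CDF/SF, which is
overflow-safe for any count. The two-sided p doubles the smaller tail and
caps at 1 (sidedness is a flag; two-sided is the default so calls can be
made in both directions). Fold changes are log2 RPM ratios; when either
RPM is zero a pseudocount equal to the RPM of one read in the smaller
library is added to both terms, otherwise the raw ratio is used. No
multiple-testing correction is applied by default (raw p-values are
reported); a Benjamini–Hochberg helper is available.

## qPCR quantification

The chain Cteff = Ct·log2(1+E), dCteff = target − mean(references),
ddCteff = normal − stress reduces to classical ddCt at E = 1 (verified as a
property test). Multiple references combine by arithmetic mean in Cteff
space, i.e. geometric mean in quantity space. SDs propagate in independent
quadrature with replicate SD on n−1; whether original error bars pooled
variances is unknowable from summaries, so plain quadrature is used and
documented. Efficiency comes from the standard dilution-curve slope
(E = 10^(−1/m) − 1, ≥ 3 points, negative slope required); other estimation
methods are not implemented. Condition-level ddCteff uses condition medians
of per-sample dCteff. Quantiles use linear interpolation (numpy's
inclusive method); Mann–Whitney is exact by full enumeration of rank
assignments (midranks for ties) up to a pooled size of 14, then the tie-
and continuity-corrected normal approximation; Spearman is Pearson on
midranks with exact permutation p up to n = 8, then the t-approximation.

## Reference stability

BestKeeper runs on raw mean Ct (its native convention): candidate SD
(n−1), CV as percent of mean Ct, Pearson r against the per-sample
geometric-mean index, ranked by ascending SD. geNorm and NormFinder run on
efficiency-corrected log2 quantities (−Cteff up to a constant). geNorm's
M_j is the mean SD of pairwise log ratios, with iterative exclusion of the
highest-M candidate until two remain; those two share rank 1 (the next best
is rank 3), and pairwise variations V_{n/n+1} are SDs of the change in
log2 normalization factor along the best-first order. NormFinder here is
the simplified two-way additive decomposition — stability_j =
sqrt(Σ_i r_ij² · g/((n−1)(g−1))) on the residuals — with the mean absolute
group-mean residual added as an intergroup term when condition groups are
supplied. These are faithful-in-spirit re-implementations, not
bit-compatible clones of the published spreadsheets/tools. The consensus is
the mean of the three ranks, ties broken alphabetically.

## Synthetic data

The generator emulates the study design at desk scale: three libraries
(N/P/NPK) at depths 45k/72k/48k reads (preserving the ~7.2/11.6/7.6 M
ratios of the emulated experiment at ~1/160 scale), a 40 kb background
genome at GC 0.5, eight planted conserved miRNAs (incl. a dominant
miR165/166-family tag), four planted non-coding sRNAs, five planted
stem-loop precursors, six planted non-hairpin decoy loci, two verified
unmappable tags, and an insertion region with three insertion-unique tags
(present only in P) plus nine insertion-shared and three flank-shared tags
(present everywhere) — reproducing the twelve-matched/nine-shared/three-
unique exclusion structure as the default condition. Reads are drawn
multinomially from an RPM profile with the remainder as genomic background;
planted stress responses are a 6-fold miR399 increase and 4-fold lus-miR-N1
decrease under P.

Planted labels are verified at generation time, in the same spirit as
verified non-occurring negative controls: precursor blocks are redrawn
until they pass the criteria in their exact final window context, decoys
until both windows fail, unmappable tags until absent from the genome.
This makes planted-truth recovery exact by construction for any seed while
the evaluator itself stays fixed.

The qPCR generator produces Ct = baseline − effect/log2(1+E) + per-sample
shift + biological noise + replicate noise, so a planted condition effect
in log2 units equals the expected ddCteff against zero-effect references.
Defaults: replicate SD 0.15 cycles, per-sample shift SD 0.5 (cancelled by
referencing), per-transcript biological SD 0.08–0.1 for stable transcripts
(controlled-chamber replication) and 0.3–0.6 for deliberately unstable
candidate references; sample sizes 14/12/7 per condition as in the
emulated extended sampling. Randomness derives from one master seed via
SHA-256-derived named child seeds, so fixtures are bit-stable across
platforms.

What passing recovery tests shows: the pipeline's logic — trimming,
collapsing, thresholding, mapping, classification precedence, stem-loop
judgement, exclusion logic, the quantification chain — is internally
consistent and recovers known truth. What it does not show: performance on
real data, where adapters contain sequencing errors, miRNA families differ
by more than planted mismatch counts, genomes are repetitive and
methylation-driven 24-nt siRNA populations dominate, and real precursor
structures are thermodynamic rather than combinatorial. Counts of
conserved/novel miRNAs from the original libraries are not reproducible
without the raw reads and are reproduced in form only.

## Numerical and policy choices

* Percentage rounding: decimal half-up, two decimals.
* Folding tie-breaks are fully deterministic, so all outputs are
  bit-stable; repeated runs with one config and seed produce identical
  files.
* The exact/asymptotic cutoffs (Mann–Whitney pooled n ≤ 14, Spearman
  n ≤ 8) trade enumeration cost against exactness and are configurable.
* Degenerate inputs raise ValueError early (empty tables, zero library
  totals, invalid efficiencies, non-negative standard-curve slopes,
  constant-rank correlations flagged as undefined NaN).

## Known limitations

* Exact-match mapping and adapter trimming: no mismatch tolerance.
* Base-pair maximization has no notion of stability; the stem-loop
  criteria compensate structurally but real pre-miRNA calling should use
  thermodynamic folding.
* NormFinder's full mixed-model intergroup variance is simplified.
* The Audic–Claverie test assumes one library per condition (no
  replicate-aware dispersion modelling).
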