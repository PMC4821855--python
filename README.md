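# flaxsrna

Small-RNA discovery and expression analysis for plant nutrient-stress
studies, built around the flax (*Linum usitatissimum*) experimental design:
sequencing libraries from plants grown under normal (N), phosphate-deficient
(P) and nutrient-excess (NPK) conditions, a question about whether any small
RNAs are transcribed from a genomic insertion (LIS-1, the 5.7-kb element of
small flax genotrophs), and qPCR follow-up with careful reference-gene
selection.

The package is aimed at bioinformaticians who want the complete desk-side
half of such a study as tested, composable library code: every stage from
raw FASTQ to a reference-gene stability table, plus a seeded synthetic-data
generator that produces all inputs with exported ground truth, so the whole
pipeline can be validated by planted-truth recovery.

## What it computes

**Tag processing.** Reads are 3'-adapter trimmed (exact match, configurable
minimum overlap), quality filtered, collapsed to unique tags with
per-library counts, and abundance filtered (default: counts of six or more).

**Genome mapping.** Exact-match k-mer seed-and-verify mapping of tags to a
genome on both strands, multi-hit with an overflow cap.

**Annotation.** Tags are classified as conserved miRNAs (ungapped homology
to a mature-miRNA database, ≤ 2 mismatches, ≥ 18 nt overlap), known
non-miRNA sRNAs (exact containment in a labelled Rfam-style database:
5S rRNA, tRNA, snoRNA, other), or unannotated; summaries report per-library
category counts and percentages. A minimal miRNA–target complementarity
scorer (mismatch 1, G:U wobble 0.5, indel 2, doubled over miRNA positions
2–13) is included for target-prediction plumbing.

**Novel miRNA discovery.** Windows of 15 nt proximal / 150 nt distal flank
are excised around each genome hit of an unannotated tag and folded by
nested base-pair maximization (Watson–Crick + G:U, hairpin loops ≥ 3 nt;
ties broken toward stacked helices). A candidate passes when the mature tag
lies on one arm of a stem-loop, ≥ 60 % of its bases pair into the star arm,
no unpaired run inside it exceeds 4 nt, and the window forms ≥ 15 pairs.

**Insertion screen.** Abundant tags are matched exactly against the
insertion and its 5'/3' flanks; candidates present at threshold abundance in
any insertion-free library are excluded (they must originate elsewhere), and
the survivors are folded in context — without a stem-loop precursor there is
no insertion-derived miRNA.

**Differential expression.** RPM normalization
(`count / library_total x 10^6`), `log2(RPM_stress / RPM_N)` fold changes,
and the Audic–Claverie test with point mass

    p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1

(the negative binomial NB(x+1, 1/(1+r))), two-sided p as the doubled smaller
tail, capped at 1.

**qPCR quantification.** Efficiency-corrected threshold cycles

    Cteff = Ct x log2(1+E)
    dCteff = Cteff(target) − mean Cteff(references)
    ddCteff = dCteff(normal) − dCteff(stress)

with quadrature error propagation, standard-curve efficiency estimation
(`E = 10^(−1/slope) − 1`), percentile summaries, exact Mann–Whitney and
Spearman tests for small samples. A higher dCteff means lower expression; a
positive ddCteff means up-regulation under stress.

**Reference stability.** BestKeeper (raw-Ct SD/CV and correlation with the
geometric-mean index), geNorm (pairwise-ratio M values with iterative
exclusion and pairwise variations V_{n/n+1}) and a simplified model-based
NormFinder, merged into a consensus ranking.

## Worked example

Generate a synthetic study and run stages from the shell (the same
functions are importable from Python):

```
$ flaxsrna simulate --out demo --seed 11
fixture in demo: 8 conserved tags, 5 novel precursors, 3 insertion-unique tags

$ flaxsrna process --fastq N=demo/N.fastq --fastq P=demo/P.fastq \
    --fastq NPK=demo/NPK.fastq --adapter TGGAATTCTCGGGTGCCAAGG \
    --out demo/tags.tsv
N: 45000/45000 reads kept, 39518 unique tags
P: 72000/72000 reads kept, 61247 unique tags
NPK: 48000/48000 reads kept, 41952 unique tags
40 tags at abundance >= 6 -> demo/tags.tsv

$ flaxsrna qpcr --ct demo/ct.tsv --targets miR399,lus-miR-N1 \
    --references ETIF3E,ETIF3H --out demo/qpcr.tsv
miR399 P vs N: ddCteff=+1.46 (p=1.75e-05)
miR399 NPK vs N: ddCteff=+0.14 (p=0.126)
lus-miR-N1 P vs N: ddCteff=-1.72 (p=1.75e-05)
lus-miR-N1 NPK vs N: ddCteff=-0.31 (p=0.000395)
```

The fixture plants a +1.4 log2 up-regulation of miR399 and a −1.7
down-regulation of lus-miR-N1 under phosphate deficiency; the estimates
above recover both within sampling error, with exact Mann–Whitney p-values
across the per-sample dCteff distributions. The reference-gene panel ranks
the two planted stable genes first:

```
$ flaxsrna refstab --ct demo/ct.tsv \
    --candidates ETIF3E,ETIF3H,GAPDH,EF1A,lus-miR-N3,lus-miR-N12,lus-miR-N306 \
    --out demo/stab.tsv
              bk_rank  genorm_rank  nf_rank  consensus_rank
ETIF3E              2            1        1               1
ETIF3H              1            1        2               2
EF1A                4            3        3               3
...
```

`flaxsrna run-all --config config.yaml --out rundir` executes every stage in
order and writes a manifest with all parameters and input checksums.

## Layout

```
src/flaxsrna/
  read_processing.py   FASTQ I/O, trimming, collapsing, abundance filter
  genome_map.py        exact-match k-mer mapping, GFF3 output
  annotate.py          conserved/non-coding classification, summaries, targets
  hairpin.py           base-pair-maximization folding, precursor criteria
  insertion_screen.py  insertion matching, cross-library exclusion, verdict
  diffexpr.py          RPM, fold change, Audic-Claverie test
  qpcr_quant.py        Cteff chain, efficiency, Mann-Whitney, Spearman
  refstab.py           BestKeeper / geNorm / NormFinder, consensus
  synthetic_data.py    seeded generators with exported ground truth
  cli.py               click CLI over all stages
```

See `docs/methods.md` for the modelling choices, defaults and limitations.
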