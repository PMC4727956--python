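# Methods

This note documents the models and procedures implemented in `exoncap`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Probe design (`exoncap.baitdesign`)

Candidate exons come from one annotated reference genome (sequence,
gene, chromosome, genomic coordinates, CDS frame). Transcriptome
evidence from each non-reference lineage is assigned to exons with a
k-mer index and aligned semi-globally at a **lenient identity floor
(default 0.70)** — chosen to sit safely below the ~0.73–0.86 identities
observed between deeply divergent lineages and a single plant reference
in array-capture studies, so that genuinely homologous but divergent
transcripts still map. The per-lineage consensus takes the evidence
majority base per position (ties become IUPAC codes, a lossless choice),
`N` where nothing maps; its `covered_fraction` feeds the family-coverage
filter.

The five candidate filters, applied in declared order but with all
reasons always evaluated (so decisions are order-independent):

| filter | rule | default |
|---|---|---|
| family coverage | ≥ `n_required` lineages with covered fraction ≥ `min_overlap_fraction` | 7 lineages, 0.90 |
| length | strictly longer than `min_len` | 150 bp |
| GC | inclusive bounds on GC over unambiguous bases | 0.30–0.70 |
| uniqueness | reciprocal best cross-gene hit at ≥ identity over ≥ coverage of length | 0.90 / 0.80 |
| repeats | shared k-mer fraction with a repeat library, or low-complexity windows | k=15, 0.25; triplet-entropy < 2 bits in > 50% of windows |

Length is strict (">") and GC inclusive because that is the natural
reading of the published thresholds these defaults mirror. The
whole-exon coverage threshold (0.90) resolves an ambiguity — "evidence
coverage" could mean any overlap or near-complete overlap; near-complete
is the conservative choice for bait design and is configurable.

Probes tile each retained lineage consensus (and the reference sequence
itself) at `probe_length` 60 (a standard long-oligo array length;
configurable), step 1, two replicates per probe; probes containing `N`
are dropped and logged.

## Read processing (`exoncap.readproc`)

Cleaning trims adapter suffixes by overlap matching (≤ 10% mismatches,
≥ 5 bp overlap), drops short (< 40 bp) and low-complexity reads, and
collapses exact duplicate pairs, recording the multiplicity so that
on-target statistics — which are defined *prior to* duplicate removal —
stay unbiased.

The **iterative reference adjustment** is the core of assembly-free
genotyping of divergent individuals: each round maps both mates of every
assigned pair at the lenient identity (0.70), substitutes
majority-vs-reference differences supported at ≥ 2× into the reference,
and repeats until a fixed point (≤ `max_rounds`, default 3). Optional
greedy k-mer flank extension (off by default) plays the local-assembly
role for recovering sequence beyond the target boundary. The adjusted
reference then receives a strict mapping pass (identity ≥ 0.93; when the
final lenient round introduced no changes, this pass reduces to an
identity filter on its alignments). The two identity thresholds
re-express the lenient/strict alignment-score pair of production mappers
as alignment-identity fractions, since mapper-native scores are not
portable.

PCR duplicates are identified by identical **fragment** coordinates
(start, end, orientation of the mate-pair span) — per-read coordinates
would collapse distinct fragments that happen to share one end — keeping
the highest-mean-quality pair (ties: first id).

Variant calling is a frequency-threshold diploid caller: positions at
depth ≥ 20 with an alternate fraction ≥ 0.25 are called, hom-alt at
≥ 0.80, het below. Phasing and base-quality recalibration are omitted:
the downstream consumer is a single consensus per individual, and
recalibration requires a known-variant set that non-model organisms lack.
The het/hom boundary and minimum alternate fraction are configurable and
explicitly *not* fixed by the published workflows this mirrors. Consensus
rules are exactly the coverage rules stated above (README); discarded
(< 5×) positions are written as `-` so every consensus stays in
reference coordinates, and `retained_fraction` records the loss at
single-position granularity.

The internal mapper (edlib-backed, unit costs) canonicalises cost-tied
alignments to the substitution representation: clustered substitutions
can equally be explained as insertion+deletion shifts, and choosing the
shift corrupts reference-coordinate pileups (this was measurable as a
~1% consensus error before the tie-break; 0.05% after). Queries are
assigned to targets by a both-strand k=11 seed index with de-correlated
voting (overlapping seed hits count once) and identity-based
disambiguation among candidates; the short k is what lets reads from
lineages ~11% divergent from the reference — and planted paralogs beyond
20% — still reach the aligner.

## Alignment and exclusion (`exoncap.alignfilter`)

`trim_to_reference` drops columns where the reference row is gapped
(idempotent by construction). `assign_reading_frame` inherits codon
boundaries from the reference CDS and flags any indel whose length is
not a multiple of 3. `codon_align` translates framed sequences, aligns
each peptide to the reference peptide (global, unit costs), and threads
codons back, so gaps occur only as whole codons and stripping gaps
reproduces every input exactly; internal stops are excluded and
reported. Plastid-role intron removal is coordinate-based
(`splice_introns`) rather than manual.

The exclusion cascade evaluates, for every gene, **all** of:

* coverage outliers: mean coverage > 200× (hard), or
  > median + 4×MAD across genes (MAD = median absolute deviation; when
  MAD is 0 only the hard cutoff applies). The `median + 4×MAD` reading
  of the outlier rule is chosen because it makes the 200× hard cutoff a
  consistent upper guard; both apply with OR.
* contaminant classes by k-mer containment (k=21, shared fraction
  ≥ 0.30) against labeled plastid / mitochondrial / rDNA / transposon
  libraries; the best-scoring class is assigned. rDNA and mitochondrial
  hits are removable-by-default with a config switch to retain them.
* frameshift flags from frame assignment.
* alignment anomalies: internal stops, pairwise-overlap failures
  (a taxon pair sharing no unambiguous column), and gap-dominated
  alignments — a gene is flagged only when more than 25% of rows are
  each > 50% gaps, because a single data-poor individual is missing
  data, not an alignment problem.
* tree-length skew: rows with under 30% unambiguous content are
  excluded as missing data, then an NJ gene tree on Jukes–Cantor
  distances (computed
  over mutually unambiguous positions, saturated pairs capped at 5
  substitutions/site, negative branch lengths clamped to 0); the gene is
  flagged when any single terminal branch exceeds 15% (strict) of total
  tree length. NJ rather than ML because the filter consumes only
  branch-length proportions; the terminal-branch (not total-path)
  reading is implemented.

Removal requires ≥ 1 reason; all reasons and their metric values are
recorded, so the per-reason accounting table is exact even for genes
violating several rules.

Parsimony-informative sites are columns with ≥ 2 unambiguous states
(A/C/G/T only) each present in ≥ 2 taxa; gaps, N and IUPAC codes never
count as states — the conservative convention, chosen because published
matrix summaries rarely state theirs.

## Phylogenetics (`exoncap.phylo`)

Concatenation fills missing taxa with `?`; the boundary table makes
gene-block slicing lossless. Partitions are gene-by-codon (3 subsets per
gene; 1-based inclusive ranges with `\3` strides in the exported
partition file — the dialect partitioned-ML tools consume). Fitch
parsimony is exact and vectorised over site patterns; ambiguity codes
are partial state sets and missing data the full set. The heuristic
search is random stepwise addition (default 100 replicates) with NNI
branch swapping — NNI rather than TBR, with correctness anchored by
exhaustive-enumeration tests so the swap radius is not load-bearing.
Bootstrap resamples columns with replacement (weighted-column
implementation, so no replicate matrices are materialised) and reports,
for each internal bipartition of the reference tree, the percentage of
replicate trees containing it. Zero-length internal branches are treated
as unresolved when bipartitions are read off a tree with branch lengths.
Majority-rule consensus keeps exactly the bipartitions above the
threshold frequency. Likelihood and coalescent analyses are exported
(relaxed PHYLIP, NEXUS with charsets, per-gene FASTA), not reimplemented:
they are the external tools' own published algorithms.

## The simulator (`exoncap.simdata`)

The generator's defaults are the study conditions of the scaled-down
synthetic experiment:

* **Tree**: 8 families × 6 taxa, ultrametric, root-to-tip depth 0.06
  expected substitutions/site. Family stems split within a basal window
  of 15% of the depth (an ancient rapid radiation: basal internals
  ~25× shorter than the stems) and family crowns occupy the most recent
  20%. These depths put cross-family identity near 89% and
  within-family identity at 96–99%, matching the divergence regime
  array-capture across a ~100 Myr-old order has to operate in, while
  leaving each basal internal branch ~70–80 expected substitutions of
  signal in the ~50 kb retained matrix — comparable per-branch
  information to the full-scale studies the desk-scale run stands in
  for.
* **Sequences**: HKY (κ=3, base frequencies 0.27/0.23/0.23/0.27 ≈ 46%
  GC), evolved codon-wise with stop codons reverted (a purifying
  -selection stand-in, so clean coding exons never carry in-frame
  stops). HKY rather than GTR because its expectations are cheap to
  verify independently (the transition matrix is checked against a
  direct matrix exponential, and the κ=1 equal-frequency special case
  against the closed-form Jukes–Cantor expectation). Exon lengths are
  ~N(300, 60) clipped at 180 bp, in whole codons. Indel machinery
  (codon-unit geometric lengths in coding mode) exists but the default
  rate is 0: the consensus caller is reference-coordinate based, so
  indel handling belongs to — and is tested at — the alignment stage.
* **Capture**: per-exon×individual fragment counts are Poisson around
  `30× × capturability × library-factor × exp(-3 × divergence-to-bait)
  × high-copy multiplier`, where capturability ~ Uniform(0.8, 1.2) is a
  bounded per-exon probe-efficiency factor (bounded so that the 4×MAD
  coverage-outlier rule cannot fire on clean genes by chance), the
  library factor is lognormal (σ=0.3) per individual, and the
  exponential divergence decay reproduces the observed pattern that
  lineages closest to the bait capture best. Fragments are 150 ± 20 bp
  (≥ read length, ≤ exon length; short enough that fragment coordinates
  do not saturate on minimum-length exons, which would make real depth
  indistinguishable from PCR duplication), reads 100 bp paired-end,
  base errors uniform at 0.002, PCR duplicates re-emit a fragment with
  probability 0.15 per copy, and off-target background reads are added
  so that 26% of sequenced bases are on target.
* **Planted violations** (defaults: 3 short, 3 GC, 2 duplication events
  = 4 non-unique genes, 3 repeat, 3 high-copy ×10, 3 paralog swaps at
  0.22 substitutions/site, 2 of each contaminant class at 0.01
  divergence from stop-free libraries). Margins are set so every
  planted violation exceeds its filter's threshold by construction —
  e.g. the paralog divergence puts the expected NJ terminal-branch
  fraction near 0.2 against the 0.15 threshold, while staying within
  the lenient mapper's reach of the reference. Paralogs are planted
  only on non-bait individuals: a paralog in the bait itself would
  degrade capture for the whole lineage, which is a bait-design QC
  problem, not the single-outlier-taxon failure mode the skew filter
  exists for.

What the generator does **not** emulate: empirical base-quality
profiles, indel sequencing errors, structural variation, recombination,
heterozygosity (individuals are haploid, so het calling is exercised on
constructed pileups, not end-to-end), real repeat families, or GC bias
in coverage. Passing end-to-end tests therefore demonstrates that the
pipeline's logic recovers planted signal under the stated statistical
conditions — not that it is robust to every artefact of real
sequencing.

## Problem sizes

The headline synthetic run uses 8 families × 6 taxa (48 individuals),
200 genes and ~30× target depth — about 1.5 M read pairs — and completes
in roughly eight minutes on one CPU; bootstrap analyses in tests and in
the acceptance script use 200 replicates, and the family-level parsimony
check runs on one representative per family. Unit and property tests
run at much smaller sizes with exhaustive or closed-form oracles.

## Known limitations

* The mapper is unit-cost (no affine gaps, no quality-aware scoring)
  and rejects rather than clips overhanging reads, so coverage tapers
  at target boundaries.
* The uniqueness filter's coverage criterion uses whole-shorter-sequence
  alignment; partial-overlap duplications below the coverage threshold
  pass.
* NNI swapping can in principle be trapped where TBR would escape;
  random-addition replicates mitigate this and the family-level
  analyses operate far from that regime.
* The MAD coverage rule is computed across genes within one run; with
  very few genes (< ~10) it is unstable, and the hard cutoff is the
  effective guard.
* The tree-length skew filter presumes reasonably dense within-lineage
  taxon sampling. With one individual per lineage every terminal branch
  is a long stem, terminal fractions cluster near the 15% threshold,
  and the filter removes essentially everything — so studies sampled
  that sparsely should raise the threshold or disable the filter.
* Bootstrap support on the shortest basal branches of the synthetic
  radiation sits near the resolution limit of the desk-scale matrix and
  fluctuates between simulation realizations; the deepest splits are
  exactly the ones a real study of this design resolves last.
* Parsimony on one representative per lineage can prefer a non-generating
  resolution of the radiation even with a perfect search (verified by
  exhaustive enumeration); the family-level parsimony check therefore
  runs on the full taxon set, where dense sampling breaks up the long
  stems.
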