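# Methods

This note documents the models and procedures implemented in `codonsig`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not establish.

## HE-gene prediction

### Feature vectors

A gene's codon usage is summarised as within-family fractions over the 59
synonymous codons (ATG, TGG, and stops excluded; start codon and terminal
stop not counted; codons containing ambiguity characters skipped).
Families absent from a gene are imputed family-uniform so that vectors
have a fixed 59 dimensions, and an 18-element family-presence mask is
appended so a classifier can distinguish imputation from observation.
Genes shorter than 30 countable codons are flagged.

The local mutational background of a gene is summarised identically from
pseudo-codons read at every offset, in all three frames, on both strands
of its flanking intergenic DNA (up to 400 nt per side, bounded by the
nearest annotated neighbor). Reading both strands makes the background
strand-symmetric, which is appropriate since mutational pressure does not
know about coding strand choice. The 400-nt window is a package default;
longer windows average away local composition, shorter ones are noisy.

### Paired classifier runs

Per genome, each of `n_runs` (default 200) runs trains two Random Forests
(500 trees, √features per split, fixed per-run seeds): classifier A on
codon vectors and classifier B on background vectors of the same training
genes — the reference set (known HE genes; ribosomal proteins and
chaperones, minimum 10 per genome or the genome is skipped) as positives
and an equal-size bootstrap of non-reference genes as negatives. The
size-matched bootstrap prevents class imbalance from dominating the
probability scale. Every gene is scored by both classifiers; genes inside
the training set are scored out-of-bag so no gene is scored by trees that
saw it. The run-averaged probabilities (`codon_score`,
`background_score`) are the ranking statistics reported per gene.

### Significance: the codon-paired sign test

Significance is **not** computed by counting runs in which
`codon_score > background_score`. We implemented that construction first
and measured it on null genomes (no planted bias): about one gene in five
reached q ≤ 0.05, because a gene's fixed codon vector makes run outcomes
persistent — runs are repeated looks at the same comparison, not
independent trials. No run count fixes this, and run-level trials can
never reach the default q ≤ 10⁻¹² threshold anyway (min p = 0.5^runs).

Instead, trials are codon positions. For each countable codon of a gene,
one partner codon is drawn from the family-conditional pseudo-codon
composition of the gene's own intergenic flank, and the codon preferred
by the reference set (higher smoothed within-family fraction in the
pooled reference codon counts, +0.5 pseudocount) wins; equal preference
is a tie and is excluded. Two properties matter:

* **Exact null calibration.** Under the null hypothesis that a gene's
  codons reflect only its local background composition, observed codon
  and drawn codon are identically distributed within each family, so for
  any fixed preference ordering wins and losses are exactly symmetric:
  wins ~ Binomial(n, ½). The background control lives entirely in the
  *draw*; deliberately, the preference score does not involve the
  background, because a score sharing estimation noise with the draw
  distribution would be biased (we measured a +0.08 win-rate shift for a
  log-ratio score drawn from the same empirical background).
* **Resolution.** A typical gene contributes a few hundred trials, so
  strongly biased genes reach the 10⁻¹² FDR scale that run-level trials
  cannot.

One-tailed binomial P values are Benjamini–Hochberg corrected across the
genes of a genome (BH is a package choice; no specific procedure is
mandated by the method). A gene is labeled HE iff q ≤ threshold (default
10⁻¹²) and it won a majority of non-tied trials. Lowering the threshold
can only remove labels (monotonicity).

### CAI

The codon adaptation index is included as the classical comparison index:
relative adaptiveness w = count/max-count within each family over the
reference set, zero counts replaced by 0.5 before normalization, CAI =
geometric mean of w over countable codons.

## Enrichment screen

COGs with fewer than 20 or more than 10,000 genes in total (across all
genomes, regardless of phenotype) are excluded. Counting is gene-level:
every gene, including paralogs within a genome, is one observation; this
matches the dataset definition used by the randomization test. For each
COG × phenotype, organisms with the phenotype missing are excluded and
the 2×2 table (HE/non-HE × positive/negative organisms) is tested.

* Fold = (a/(a+b)) / (c/(c+d)). If either organism group has no genes
  the COG is not testable for that phenotype; if neither group has an HE
  gene the fold is undefined and the COG does not count toward n_tested;
  if only the negatives lack HE genes the fold is +∞, which satisfies the
  ≥ 2 criterion. This mirrors the behavior on gene families that are
  nearly absent from one phenotype group (e.g. catalase-like cases).
* The two-tailed Fisher exact P sums hypergeometric point probabilities
  ≤ the observed one, with 1e-7 relative slack for floating-point ties.
  The implementation is verified against exact integer-arithmetic
  enumeration for every table with margins ≤ 30.
* A COG passes at (fold ≥ 2 or ≤ 0.5) **and** P < 10⁻². Fold screen and
  significance test are a conjunction; order is immaterial.
* Screen FDR = 100·α·n_tested/n_significant — the expected number of
  false positives at the per-test threshold over the observed number of
  significant results. It is undefined when nothing is significant.

Organism features are binary with missing values: 24 phenotypes, 70
taxonomy indicators (domain/phylum/class/order-style subdivisions), and 6
descriptors obtained by discretizing GC content and genome size. The
descriptor encoding is three cumulative quartile indicators per variable
(≥ Q1, ≥ Q2, ≥ Q3, quartiles computed once over the analysed genome set)
— a package choice that yields exactly the stated 6 features; other
4-class encodings would serve equally.

## Randomization test for independent contribution

The dataset for a COG has one instance per gene (paralogs included), the
100 organism features of the gene's genome, and the gene's HE label as
class. Genomes in which the tested phenotype is missing are retained —
missingness is an explicit third category (ordinal encoding no/yes/missing
= 0/1/2; Random Forests split on it natively).

AUC is measured by stratified 10-fold cross-validation with pooled
out-of-fold probabilities (10-fold is the convention of the classifier
toolkits this test descends from; the fold count drops to the minority
class size when necessary). The tested feature is then shuffled 30 times
and the AUC remeasured each time. Shuffling is genome-wise — all
instances of a genome receive the value of a single other genome — which
preserves the within-genome tying of organism descriptors; instance-wise
shuffling would break that structure and is not what "relabel the
organisms" means. Z = (AUC_original − mean)/sd over the 30 shuffled AUCs,
P = 1 − Φ(Z), and P < 10⁻² declares the phenotype an independent
contributor. A shuffled sd < 10⁻⁹ is flagged degenerate (P collapses to
0 or 1). No multiple-testing correction is applied at this stage; the
plain P < 10⁻² cut is part of the method.

The logic: if shuffling a feature does not hurt the cross-validated AUC,
everything that feature knew about the labels was recoverable from the
remaining features — the enrichment is confounded.

## tRNA concordance

For the nine twofold-degenerate amino acids (Phe, Tyr, His, Gln, Asn,
Lys, Asp, Glu, Cys) the expression-derived optimal codon is the one
over-represented in HE vs non-HE genes at two-tailed Fisher P < 0.001 on
pooled, unweighted codon counts; a non-significant family has no optimal
codon. The tRNA-implied optimal codon is defined in genomes carrying only
one of the family's two possible anticodons: the Watson–Crick-matched
codon is tRNA-optimal, the other is read by wobble. Genomes whose two
call sets disagree for ≥ 3 of the 9 testable families are flagged — their
apparent expression-related codon bias may not reflect translational
selection. Anticodon inventories are inputs (tRNA gene scanning is an
external tool's job); DNA is used for codons, RNA for anticodons, with
explicit conversion. A `sensitivity_rerun` re-runs the screen without
flagged genomes and reports per-link fold/P deltas.

## Synonymous de-optimization with profile preservation

Codon optimality is the codon's usage percentage among synonymous
alternatives in a ribosomal-protein reference set (per family, sums to
100). A replacement for codon c must satisfy percent ≤ 0.7·percent(c)
and percent ≥ 3 — many moderate de-optimizations rather than a few
drastic ones, and never the near-absent codons. Eligibility is always
evaluated against the *original* codon, and once changed a codon is
frozen.

The search replaces `step_size` codons per step (default ≈ n_target/3
clamped to [1, 7], generalizing the 5-of-15 / 7-of-21 pattern), drawing
`n_samples` (default 100) random candidates per step and keeping the one
whose 42-nt-window folding profile has the smallest RMSD to wild type;
Pearson r is reported alongside but RMSD drives selection. Profiles are
computed on the transcript with the fixed 14-nt Shine–Dalgarno-containing
ribosome binding site AGGAGGUAAAACAU prepended, one window per
nucleotide position. A motif-removal helper (`abolish_site`) breaks a
restriction site by a single synonymous change, preferring rule-eligible
replacements.

### Folding backends

The default backend is the ViennaRNA Turner-parameter MFE (`RNA.fold`)
when its Python bindings are importable. A self-contained simplified
nearest-neighbor dynamic program is also provided and used as the
fallback: per-pair energies (GC −3, AU −2, GU −1 kcal/mol), a hairpin
penalty of 3.5, an interior/bulge penalty of 1.5, minimum hairpin loop 3,
interior loops bounded at 3 nt per side, and no multibranch loops — a
deliberate simplification that is adequate inside a 42-nt window. Its
energy model is simple enough to be verified against exhaustive
enumeration of all admissible secondary structures on short sequences,
which the test suite does. Both backends are deterministic, return
MFE ≤ 0 (the open chain is the zero reference), and memoise windows —
important in the design search, where candidate variants share most of
their windows. Bit-level agreement with any particular external folding
program is not promised; profile *differences* (RMSD, r), not absolute
energies, drive the design.

## Synthetic worlds

The generator plants exactly the structure the analysis assumes, with
full ground truth:

* Proteins are sampled from a fixed amino-acid frequency profile
  (enterobacteria-like), lengths uniform on 100–400 codons (mean ≈ 250,
  matching typical bacterial proteins), so codon-level bias is the *only*
  HE signal. Non-HE genes draw codons from the family-conditional
  distribution implied by iid GC-parameterized DNA — the same composition
  their intergenic flanks (200 nt default, shared between neighbors) are
  drawn from. HE genes mix that distribution with a point mass on a
  designated optimal codon per family with weight `bias_strength`.
* Reference-HE flags go to a random subset (default 15) of the planted
  HE genes of each genome, playing the ribosomal-protein role.
* Taxonomy is a random nested partition exported as 70 binary membership
  indicators; phenotypes copy a parent variable (taxonomy group or
  another phenotype) with a specified agreement, plus missingness. A
  confounded COG–phenotype link is a directed chain taxonomy → A → HE
  with A → B, making "B is associated but carries no independent
  information" literally true by construction.
* The tRNA inventory contains, for each twofold family, only the
  Watson–Crick anticodon of the planted optimal codon.
* Emitted artifacts (FASTA with random gene strands, coordinate gene
  tables, phenotype and tRNA TSVs, ground-truth JSON) load back through
  the package's own readers with zero rejections; a fixed seed reproduces
  the world bitwise.

What the generator does **not** emulate: sequence evolution along the
phylogeny (taxonomy structures the phenotypes, not the sequences), operon
structure and overlapping genes, genome-wide GC heterogeneity, amino-acid
composition differences between genes, and tRNA modifications. Passing
the recovery and calibration suites therefore shows that the statistics
behave correctly under the model's assumptions — not that real genomes
satisfy those assumptions.

## Problem sizes and numerical choices

Simulations in the test suite and `scripts/acceptance.py` are sized for a
single CPU: HE recovery uses one 1,000-gene genome (bias 0.7, HE fraction
0.1, 50 classifier runs of 100 trees); null calibration pools 20
200-gene genomes; the confounder scenario uses 120 genomes (~126 COG
instances) with 30-tree forests, 30 shuffles × 10 folds, and 20
replicates; the design comparison uses a 62-codon gene, 9 replacements,
25 candidates per step, and 20 paired runs. Thresholds and test
statistics are never scaled — only sample sizes and forest sizes are.
Forests of 30–100 trees on these instance counts sit on the AUC variance
plateau; the production default stays at 500 trees.

Other numerical conventions: pseudocount 0.5 wherever zero counts are
smoothed (CAI, reference preference); 10⁻⁷ relative slack for
floating-point ties in the Fisher tail sum; sign-test ties excluded;
per-stage seeds fanned out from one master seed via `SeedSequence`;
gene-table coordinates 1-based inclusive on disk, 0-based half-open in
memory.

## Limitations

The headline numbers reported for real data by analyses of this kind —
genome-wide HE fractions of a few percent to ~20%, several-fold
expression differences of HE genes on microarrays, catalogues of hundreds
of COG–phenotype links, lists of genomes with tRNA-discordant codon
bias, and folding-profile correlations of specific redesigned genes —
require a multi-hundred-genome corpus with curated phenotype annotations,
expression datasets, and the actual gene sequences. They cannot be
reproduced from synthetic worlds at desk scale and are deliberately out
of scope here; the synthetic recovery, calibration, and discrimination
suites above are the package's evidence that each statistical component
does what it claims under controlled conditions.
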