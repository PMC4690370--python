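# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind straindelta. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Assembly-level variant calling

The diff replaces read mapping with a direct comparison of two finished
assemblies. It assumes the genomes are near-identical (point mutations and
short indels, no rearrangements):

1. **Anchoring.** Every k-mer (default k = 31) occurring exactly once in
   *each* genome is an anchor. k = 31 is long enough that unique matches
   are effectively never spurious in a desk-scale AT-rich genome, and short
   enough to tile the sequence between nearby variants.
2. **Chaining.** The maximum-cardinality subset of anchors strictly
   increasing in both coordinates is taken (longest increasing subsequence
   on the second coordinate after sorting by the first; ties resolved
   toward the smaller second coordinate). Same-diagonal overlapping
   anchors are merged; residual overlaps across diagonals are trimmed.
3. **Gap alignment.** Sequence between consecutive chain anchors is
   aligned by unit-cost edit distance after stripping common prefixes and
   suffixes. The DP fills full score matrices row-by-row in numpy; the
   in-row dependency of a horizontal gap is folded into a prefix
   minimum/maximum scan, so rows are vector operations.
4. **Normalization.** The edit script becomes VCF-style calls
   (substitutions single-base; indels anchored on the preceding base) and
   every indel is left-aligned: shifted one base left while the base before
   the event equals the last base of the shifted unit. Normalization is
   idempotent and preserves the reference→alternate transformation.

Tie-breaking among co-optimal tracebacks is fixed: first *extend the gap
opened by the following operation*, then diagonal (mismatch), then deletion,
then insertion. The gap-extension preference keeps a multi-base indel
contiguous instead of fragmenting it around bases that coincidentally match
inside the gap; without it, equally optimal but fragmented representations
of the same deletion appear. The same policy is implemented independently
in the test suite's full-matrix DP oracle, and the anchored pipeline
reproduces that oracle's normalized variant set exactly on small instances;
on larger random pairs the emitted edit cost is checked against an
independent edit-distance library and the calls are verified to
reconstruct the second assembly.

**Circular genomes.** Both assemblies are circular chromosomes whose FASTA
start is arbitrary. The modal anchor diagonal estimates the relative
rotation; the candidate rotation is adopted only if it increases collinear
anchor coverage (small indels also shift diagonals, so the mode alone can
be misleading — e.g. a single deletion early in the genome shifts *most*
diagonals without any true rotation). Inter-anchor gaps longer than 50 kb
abort with a structural-variation error: rearrangements are out of scope
and should fail loudly rather than produce base-level nonsense.

## Effect classification

Substitutions are mapped strand-aware to their codon (codons read on the
coding strand; minus-strand genes via reverse complement) and translated
with the standard genetic code. The partition is: silent (same residue),
nonsense (stop gained), conservative (BLOSUM62 score of the residue pair
> 0), nonconservative (otherwise). Published annotation practice for
"conservative" is inconsistent; a positive BLOSUM62 score is a published,
reproducible rule, and the synthetic generator plants its quotas under the
same rule, so recovery tests are self-consistent. Start codons are treated
as ordinary codons. Deletions wholly inside one CDS are in-frame iff their
length is a multiple of 3; deletions spanning a CDS boundary are
conservatively classified frameshift with a warning. In-frame insertions
inside a CDS receive the class `inframe_insertion` (an addition to the
substitution-centric partition; the generator never plants one).

**Residue range of an in-frame deletion.** The deleted residue block is
found by translating the reference and deleted CDS and locating the
leftmost contiguous residue block whose removal converts one protein into
the other. This handles codon phase uniformly: a deletion that starts
mid-codon still removes d/3 residues, but which residues disappear depends
on the surrounding protein sequence, not on nucleotide coordinates alone.

**Flanking direct repeats.** For a left-aligned deletion starting at
0-based s with length d, the repeat length is the largest m ≤ d with
genome[s, s+m) = genome[s+d, s+d+m). Two identical flanking copies are the
signature of homologous recombination between short direct repeats, which
excises the spacer plus one copy.

## Synthetic data generator

The generator emulates the study system: an AT-rich (30% GC) circular
chromosome with non-overlapping CDSs on both strands, a mutant genome
carrying a configured mix of substitutions by effect class plus one
repeat-flanked in-frame deletion, and per-strand SMRT kinetics.

- **Geometry.** Intergenic spacers are i.i.d. bases at the profile GC
  (minimum 25 bp); CDSs are built codon-by-codon from stop-free codons,
  beginning ATG and ending a stop, so non-overlap and absence of internal
  stops hold by construction. The desk-scale default ("table1" profile) is
  200 kb, 30% GC, 150 genes of mean length 900 bp — a stand-in for a
  4.35-Mb chromosome that still supplies enough codons for every quota.
- **Substitutions.** Each planted substitution is rejection-sampled (cap
  10,000 attempts, then an error naming the class) until the *shared*
  classifier assigns exactly the requested class, with a minimum 12 bp
  separation between planted sites so calls stay independent.
- **The deletion.** The deleted allele is `repeat + spacer` (default the
  24-mer `ATACCATAAATAAATTATTTGGAT` with repeat `ATACCATA`); the reference
  receives `repeat + spacer + repeat` written into the target CDS and the
  mutant loses `repeat + spacer`. Read in frame 0 the default payload
  contains a stop codon, so the block is embedded at codon phase 1 with
  deterministic filler bases chosen so that (i) neither the reference nor
  post-deletion block contains a stop, (ii) the base before the deleted
  segment differs from its last base (left-alignment cannot shift the
  call), and (iii) the base after the second repeat copy breaks any longer
  repeat match — the flanking repeat is exactly 8 bp.
- **Kinetics.** Per position and strand one IPD ratio is drawn log-normal
  with the arithmetic mean set by the most specific cytosine context
  (first C of CGCG 1.25, second C 1.11, CG 0.89, other C 0.86; background
  1.0) and σ = 0.25 on the log scale; the literature reports context
  *averages* but no dispersion, so σ is a stated assumption of this
  package. Log-normals are parameterized as μ = ln(mean) − σ²/2 so the
  arithmetic mean matches the configured value. Modification QVs are
  Gaussian (sd 10) around 85 for methylated and 5 for unmethylated sites,
  with a call threshold of 30; per-motif detection fractions default to the
  published detected percentages (GATC 99.14%, GRTAAAG 99.65%,
  AAGNNNNNCTCC 99.61%, GGAGNNNNNCTT 99.03%, CAAAAAR 97.10%). Coverage is
  Poisson with mean 58 and is carried but never filtered on.
- **Seeds.** Defaults are 42 (genome/variants) and 7 (kinetics); all
  randomness flows through `numpy.random.default_rng`, so identical
  profile + seed gives byte-identical outputs.

What the generator does **not** emulate: sequencing error, read-level
artifacts, repeat families long enough to defeat 31-mer anchoring,
rearrangements, multi-replicon genomes, or chemistry-specific kinetics
beyond the context-mean mechanism. Passing tests therefore demonstrate the
*analysis logic* on data with the assumed statistical structure, not
robustness to assembly error or to motif discovery from scratch.

## Methylome analysis choices

- Motif site counts are per-strand occurrence counts; a palindromic duplex
  site (e.g. GATC) contributes one site per strand. This convention
  reproduces the expected order of magnitude of published per-genome motif
  counts for a ~4.35-Mb, ~30%-GC chromosome.
- Cytosine context groups are mutually exclusive by specificity
  (CGCG-first > CGCG-second > CG > other C); the plain-C group therefore
  excludes every C followed by G, so the elevated contexts are never
  counted inside their own background. Both strands are pooled.
- Statistical comparison uses a two-sided Welch (heteroscedastic) t-test
  computed from group summary statistics, with Welch–Satterthwaite degrees
  of freedom. Exact p-values published for such contrasts depend on the
  underlying raw kinetics and are not reproducible from summaries; the
  package's significance checks are therefore directional (elevated CGCG
  context, rejection at α = 1e-4 on simulated data).
- Kinetics calibration runs use a 600-kb, 50%-GC i.i.d. genome: CGCG
  density at 30% GC is too low to yield the several thousand first-C
  observations needed for tight recovery of the configured means, and the
  context machinery is composition-agnostic.
- Defaults documented as configuration, not derived: QV call threshold 30,
  overspecification minimum count 30, upstream 0A-box window 300 bp.

## Locus comparison choices

Percent identity is identical columns over total alignment columns (gaps
count in the denominator) under global alignment — DNA +1/−1 with gap −2,
protein BLOSUM62 with gap −8. Conventions for published percent-identity
figures are rarely stated, so cross-study comparisons should be treated as
±a few percentage points. 0A-box scans consider both strands within the
window upstream of the translational start (strand-aware for minus-strand
genes, wrapping on circular genomes); the reported distance runs from the
gene start to the box edge farthest from the gene, and boxes overlapping
the start are excluded.

## Problem sizes and determinism

The shipped profiles are desk-scale by design: the 200-kb synthetic
chromosome exercises every code path of the variant pipeline in a few
seconds, and the 600-kb calibration genome yields ~4,700 CGCG first-C
observations (standard error ≈ 0.005 on a mean of 1.25). All stochastic
components take explicit seeds; the pipeline's report bundle is
byte-identical across runs with the same configuration, and the effective
configuration plus version is echoed into every output directory.
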