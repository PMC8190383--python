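# Methods

`ighrep` analyses immunoglobulin heavy-chain (IGH) B-cell receptor
repertoires from bulk sequencing reads: it assigns V/D/J/C germline
segments, extracts the CDR-H3 junction, filters productive rearrangements,
summarizes each sample into repertoire indices, and compares samples
between groups with rank statistics. Because clinical repertoire data are
rarely shareable, the package ships a generative V(D)J simulator with
per-read ground truth; every analysis stage is validated by recovering the
simulator's known parameters.

## Generative model (simulator)

A clone's rearrangement is assembled as

```
V[0 : L_V - t_V] · P_V · N1 · P_D5 · D[t_D5 : L_D - t_D3] · P_D3 · N2 · P_J · J[t_J :] · C
```

* **Segment choice** is multinomial at the *clone* level from configurable
  usage vectors (default uniform over the reference). Read-level
  frequencies are then weighted by clone size, as in real repertoires where
  expanded clones dominate.
* **Trimming** `t_*` is geometric per junction end (support 0, 1, 2, …)
  with configurable mean (default 2 nt). A trim that would cross the V
  2nd-CYS or J-TRP anchor codon is resampled, so the C…W junction rule is
  always satisfiable on truth — annotator failures are therefore
  attributable to the annotator.
* **P nucleotides** are reverse-complement extensions of an *untrimmed*
  end, present with probability 0.5 and length 1–2 nt (TdT adds short
  palindromes only at blunt, untrimmed coding ends).
* **N insertions** at the V–D and D–J joins are Poisson with mean 4 nt
  each (typical adult IGH junctions carry ~5–10 non-templated bases).
* **Reading frame**: 90% of rearrangements are driven in frame (junction
  length ≡ 0 mod 3), 10% out of frame. Frame control is implemented by
  rejection-sampling the two N lengths until the junction lands in the
  target class. This keeps the marginal N-length distribution at its
  configured mean — padding the insert instead would inflate it by ~1 nt
  per read. The mod-3 conditioning bias on a Poisson(8) total is of order
  e^(−12), i.e. unmeasurable.
* **SHM** is a per-base substitution process over the V region strictly 5′
  of the anchor codon, at an isotype-keyed rate (defaults: IGHM/IGHD 1%,
  class-switched 3%; the isotype is drawn per clone from the C usage
  vector). Substitutions go uniformly to the 3 alternative bases.
  Confining SHM to the pre-anchor V region keeps the recorded junction
  truth exact and matches the analysis convention that junction mismatches
  are N/P material, not SHM. Consequence: simulated anchor codons can only
  be destroyed by sequencing error; the annotator's lost-anchor paths are
  exercised by explicitly mutated reads in the tests.
* **Clone sizes** follow a discrete power law (Zipf weights, exponent 2.5
  by default), normalized by largest remainder to the requested read total
  with every clone at size ≥ 1.
* **Sequencing error** is independent per read and base (default 0.1%),
  drawn disjoint from SHM positions so the two processes are separable in
  truth; error positions are flagged Q15 in otherwise-Q37 FASTQ.

Ground truth per read records segment ids, all trim/P/N lengths, the
junction and its germline-encoded base count, SHM and error positions, and
the productive flag (in frame and stop-free through the junction).

**What the simulator does not model**: SHM hotspot motifs (WRCY/RGYW) and
indel SHM, UMI structure, paired-end reads, chimeras — and clonal
*selection*. Random N/D-derived junctions often contain stop codons, so
the productive fraction (~0.35–0.45 at default settings) is lower than in
real selected repertoires (typically > 0.8). Passing recovery tests
therefore certifies the measurement machinery, not biological realism of
the productive fraction.

## Reference handling

Germline sets are validated at load time: uppercase ACGT only (records
containing N are skipped with a warning — mismatch counting must be
exact), unique ids, and anchor codons checked (V anchor ∈ {TGT, TGC}, J
anchor = TGG). IMGT-gapped V FASTA places the 2nd-CYS at gapped codon 104;
J anchors are found via the canonical W-G-x-G FR4 motif. Families are the
id truncated at the first `-` after stripping the `*allele` suffix, so
IGHV3-30-3 → IGHV3.

The synthetic reference builder emits structurally valid segments
(stop-free V/J frames, correct anchor codons, W-G-x-G on J) with all
within-class pairwise identities ≤ 1 − `min_pairwise_divergence`
(default 0.15). Default sizes — 30 V, 15 D, 6 J, 10 C (the nine canonical
human isotype genes plus the IGHGP pseudogene) — are the package's
desk-scale reference conditions; they preserve the locus structure
(multi-member V families, short D segments, one anchor per V/J) at a size
where a full simulate–annotate round trip runs in seconds.

## Annotation

Alignment is an exact affine-gap Smith–Waterman (Gotoh) with match +2,
mismatch −2, gap open −5, gap extend −1 (a length-L gap costs
5 + (L−1)·1), numba-compiled and verified against a quadratic-time
pure-Python oracle. Acceptance floors are score 30 for V/J/C and 12 for D;
ties break by fewer mismatches, then lexicographically smaller id, making
calls deterministic. V is called on the full read, J 3′ of the V
alignment, C 3′ of J; a read lacking any of V, J, C is rejected with a
reason. D is sought only strictly between the anchor codons and is
best-effort: with no D above floor, the germline junction coverage counts
only V/J-aligned bases.

The junction runs from the first base of the V 2nd-CYS codon to the last
base of the J-TRP codon inclusive (so reported "CDR-H3 lengths" include
both anchor residues — one residue longer at each end than the IMGT CDR3;
output headers state this). Anchors are mapped through the alignment; if
either anchor codon is absent or no longer encodes C/W the junction is
withheld and the record flagged (`lost_2nd_cys` / `lost_j_trp`).
Productive = junction length divisible by 3 and no stop codon in the
V-framed translation through the junction.

V mutation counting excludes the junction window: junction mismatches
conflate N/P nucleotides with SHM. Identical read sequences are annotated
once and fanned out; duplicates collapse on
(v_call, j_call, c_call, junction, translated sequence), conserving read
counts. At default simulator noise the annotator recovers the true V call
and the exact junction on > 99% of reads (measured in the acceptance
suite); the alignment-coverage estimate of the germline index runs a few
percent above truth because chance matches extend alignments into N
territory.

## Repertoire indices

With n_i the read count of clonotype i and N the total:
Shannon = −Σ (n_i/N) log₂(n_i/N) (bits); inverse Simpson =
1/Σ (n_i/N)² (≥ 1). The diversity species is the collapsed clonotype
weighted by duplicate count. Other junction summaries
(CDR-H3 length, hydrophobicity, GI) default to clonotype weighting (each
clonotype once); read weighting is a flag.

Hydrophobicity is the mean Kyte–Doolittle hydropathy over junction
residues divided by 4.5, mapping to [−1, 1] (Ile → +1, Arg → −1); the
residue table is an editable two-column TSV, so any other normalized scale
can be substituted. SHM rate is the pooled ratio
100·Σmutations/ΣV-nucleotides — a literal reading of "point mutations per
V-gene nucleotide" that weights long alignments more than a mean of
per-read ratios would. GI is germline-covered junction nt / junction
length per record, averaged per sample; per-isotype stratifications
collapse IGHG1–4 → IGHG and IGHA1–2 → IGHA while retaining subclass usage
separately.

## Statistics

Two-sided rank tests throughout: Mann–Whitney U for unpaired contrasts
(exact null when n_x·n_y ≤ 400 and tie-free, else normal approximation
with tie and continuity correction), Wilcoxon signed rank for paired
designs (zeros dropped, exact when effective n ≤ 25 and tie-free),
Spearman's ρ with the t approximation for covariate association. The
exact paths are verified against full permutation / sign-pattern
enumeration to 1e-9. Degenerate inputs: a feature constant across all
samples reports U = n_x·n_y/2 with p = 1 rather than failing.

Feature tables zero-fill usage of segments absent from a sample (absence
is signal) and drop NaN-valued samples pairwise for per-isotype features.
Multiple-testing correction defaults to *none* — mirroring univariate
repertoire reports — with Benjamini–Hochberg as an explicit flag; each
output states which was used. Null calibration of the whole layer
(fraction of p < 0.05 under no effect ≈ 0.04, slightly conservative from
exact-test discreteness) and power on a planted clone-level usage shift
(0.05 → 0.20 at n = 15/15 ranked minimum-p in ≥ 90% of replicates) are
computed by the acceptance script.

## Problem sizes and numerics

Validation runs use 3,000–5,000 reads over 400–700 clones (annotation
recovery), ~114,000 pooled V nucleotides (SHM recovery at 2% ± 0.3
percentage points), 200 null datasets × 20 features (calibration), and 50
replicates (power); all complete in about a minute on one core. All
randomness flows through `numpy.random.default_rng` seeds recorded in
output headers; reruns are byte-identical. Alignment scores are integer
arithmetic, so oracle comparisons are exact; diversity closed forms hold
to 1e-12.
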