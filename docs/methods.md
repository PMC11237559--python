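# Methods

This note documents the models and procedures implemented in `soxyprof`,
the defaults and why they were chosen, what the synthetic cohorts emulate,
and the package's known limitations.

## Profile search and e-value calibration

SoxY homologs are found with a position-specific scoring profile (PSSM)
rather than a full profile HMM. The profile is built from a seed alignment
by

```
emission(j, a) = log2( (count_a(j) + κ·q_a) / (n_j + κ) / q_a )
```

with pseudocount weight κ = 1 and background `q` uniform (1/20); columns
with a majority of gaps are dropped, and the column holding the conserved
sulfur-binding cysteine of the canonical reference (position 110) is
recorded as the anchor. The default seed alignment contains perturbed
copies of the canonical sequence *and* of all six signature exemplars —
a family-wide profile, like the public SoxY family models it stands in
for — which is what lets a single search recover divergent variants at
~17–30% identity to the canonical sequence.

Alignment of a protein to the profile is an affine-gap dynamic programme,
global across the profile columns (every column matched or deleted) with
sequence residues flanking the matched domain left unpenalized. The
domain-style flanks matter: a SoxYZ fusion protein would otherwise pay
~29 bits of insertion penalty for its SoxZ moiety, systematically
handicapping exactly the proteins this analysis is about. Gap penalties
are 4 bits to open and 0.25 bits to extend; a deletion run switching
directly into an insertion run re-opens the gap. On instances small
enough to enumerate, the DP provably equals brute-force search over all
alignment paths (tested).

E-values are empirical. Scores of ≥1,000 composition-matched random
decoys (lengths resampled from the search database) are fitted with a
Gumbel distribution by the method of moments (λ = π/(σ√6),
μ = mean − γ/λ), and `E(s) = N·(1 − exp(−exp(−λ(s−μ))))` for a database
of N sequences. An empirical null is honest for arbitrary gap penalties,
where closed-form Karlin–Altschul statistics do not apply. Method-of-
moments recovery is verified on synthetic Gumbel draws (μ within ±0.1,
λ within ±0.05 at n = 10,000), and the realized false-positive count on
fresh decoys at the 1e-5 cutoff is ~0.1 per 10,000 (tested ≤ 3).

Pairwise local and global alignment (fusion probing, percent identity,
sulfur panel search) use BLOSUM62 with gap open 11 / extend 1 via
`Bio.Align.PairwiseAligner`. Percent identity is matches over the
terminal-gap-trimmed global alignment length; because co-optimal
alignments depend on argument order, the pair is canonicalized
(lexicographic order) before aligning so identity is exactly symmetric.

## Screening rules

Putative SoxY hits are kept when the full protein is at least 140 aa
(inclusive boundary), contains `GGC` anywhere in the sequence, and scores
e ≤ 1e-5. Identical sequences are collapsed to one representative (the
lexicographically smallest id) for tree building only; per-genome copy
numbers are counted before deduplication, since deduplication serves the
phylogeny, not the repertoire.

## Arm signatures and fusions

The swinging arm is read off the profile alignment as the 6 columns
ending at the conserved-cysteine anchor (window width configurable).
Classification is Hamming distance to an ordered motif table; a gap
counts as a mismatch, the best entry within its own mismatch tolerance
wins, ties resolve by table order, and anything else — including arms the
alignment could not resolve — is reported as `unclassified`, never
dropped. Defaults: S1a = `VTIGGC` with tolerance 0; S1b/S1c single-residue
variants (`VTVGGC`, `VSIGGC`, tolerance 0 — they differ from S1a by one
residue, so any tolerance would create ambiguity); S2/S3/S4 divergent
variants (`AKMGGC`, `TSLGGC`, `PNVGGC`, tolerance 1). Only the canonical
arm, the single- vs multiple-change structure, and the shared `GGC` core
are biologically fixed; the exact variant residues are placeholders and
real-data use should supply the observed table via config.

A SoxYZ fusion is called when local searches with the canonical SoxY and
SoxZ references both pass a per-domain e-value cutoff (1e-5), the Y
envelope precedes the Z envelope, and they overlap by at most 10 aa.
Signature assignment is motif-based only; clade membership is reported
separately because arm signatures are not guaranteed to be monophyletic.

## Phylogeny

Sequences are stacked in profile coordinates (insertions relative to the
profile discarded, deletions as gaps). Distances are p-distances with
pairwise deletion, optionally Poisson-corrected (−ln(1−p)); pairs sharing
no columns, or saturated pairs under Poisson, are errors rather than
silently patched. Trees come from Saitou–Nei neighbor joining with the
Studier–Keppler Q criterion; tie joins take the smallest index pair,
negative branch lengths clamp to zero, and the result is an unrooted tree
with a trifurcating root, serialized as Newick with 6-significant-digit
branch lengths (write → read → write is byte-identical). Distance-based
NJ with a standard column bootstrap (default 100 replicates, configurable
to 10,000) deliberately replaces likelihood inference: the clade-level
claims this pipeline makes are robust to the substitution, and an
implemented algorithm can be held to exact oracles — NJ provably recovers
the generating topology of additive matrices and matches a brute-force
least-squares search over all 15 five-taxon topologies (tested, plus an
independent cross-check against scikit-bio's NJ).

Clades are assigned by minimum mean distance to exemplar sets (the four
clade exemplars S1a/S1b/S1c → clade 1, S2 → 2, S3 → 3, S4 → 4), ties to
the lowest clade number, with per-clade monophyly evaluated on the tree.

## Synthetic cohorts — what they emulate, and what they do not

The generator is the package's study condition. A cohort genome carries
0–5 planted soxY copies; each copy is drawn as a 3–12% perturbation of its
signature's full-length exemplar, and exemplars in turn sit at the
identity ranges reported for the variants (S1a 52–64%, S1b 45–55%, S1c
33–44%, S2 24–33%, S3 29–32%, S4 26–36% to the canonical sequence), with
arms never mutated. S2/S4 copies are fused to a perturbed SoxZ. Decoys are
Fisher–Yates shuffles of real family/panel sequences — composition-matched,
position-free, the standard calibration null. Genomes are one contig of
60–120 genes with intergenic gaps uniform on 20–400 bp; planted copies sit
inside named neighborhood layouts (a contiguous same-strand `soxABXYZ`
operon with gaps ≤ 150 bp preceded by LuxR/histidine-kinase regulators; a
dispersed architecture with `soxB`, `soxAX` and `soxYZ` clusters separated
by ≥ 12 genes; and satellite layouts placing divergent copies next to DMSO
reductase, alcohol dehydrogenase, octaheme tetrathionate reductase, or
methanol/formate dehydrogenase genes). The ecology model plants divergent
signatures only in generalist-labelled genomes (probability 0.9 of at
least one divergent copy) and restricts specialists to S1a/S1b
repertoires; environments are `specialized` for specialists and
seagrass/coral-reef/mangrove for generalists. All draws descend from a
single seed; identical (spec, seed) reproduce byte-identical files.

Passing on these cohorts shows the machinery is correct, not that real
data are this clean. The generator has no indels outside fusions, no
sequencing or binning artifacts, no fragmented loci, no annotation noise
in product labels, and its divergent lineages radiate independently from
the canonical ancestor. That last point has a visible consequence: the
variant groups form a star at near-saturated distances, so while each
signature group is sharply monophyletic, the deep stem uniting S1a/S1b/S1c
into a single clade-1 carries little bootstrap support under distance
methods. Bootstrap *machinery* is therefore validated on a four-clade
alignment generated with shared within-clade ancestry (members 4–10%
diverged from one ancestor per clade), where all four stems reach support
~1.0; on full cohorts the package asserts clade assignment and tree
monophyly, not deep-stem support.

## Repertoires, presence, ecology

Per-genome repertoires count filtered, pre-dedup loci by signature, plus
fusion and unclassified counts. Sulfur-gene presence uses the best local
alignment of each reference panel protein against the proteome: present
iff e ≤ 1e-30, relaxed to 1e-6 for panel entries under 120 aa (short
proteins cannot reach deep-tail scores). The synthetic panel spans
sqr, fccAB, soxAXB, soxYZ, dsrAB, aprAB, sat and the complementary
aprM vs qmoAB/hdrBC modules, reported as separate columns. The ecology
association is a 2×k chi-square (divergent-signature presence ×
environment) with a label-permutation p-value,
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)` — an explicit addition of this
pipeline, labelled as such in its output, since the original pattern was
argued qualitatively. The permutation p is exact up to Monte Carlo error
and verified super-uniform under shuffled labels (with a 3.5σ binomial
allowance at 200 repeats).

## Neighborhoods and operons

GFF3 CDS features are ingested to 0-based half-open coordinates (1-based
inclusive on disk; round-trip tested). Neighborhoods take up to k = 10
genes each side of the focal locus on its contig — a proxy for the visual
span of genomic-island figures — with contig-edge truncation flagged.
Categories come from an ordered, case-insensitive keyword table over
product labels (rhodanese rules precede the generic sulfur keywords so
`sulfurtransferase` does not shadow them); unknown or hypothetical
products fall through to `hypothetical`. An operon call grows the maximal
same-strand run around the locus with intergenic gaps ≤ 200 bp and
verdicts true iff the run's sox labels cover {soxA, soxB, soxX, soxY,
soxZ} (fused labels like `SoxYZ` expand to their components). The 200-bp
gap and same-strand rule are an operational directon proxy — the original
calls were made by eye from annotation browsers — and are configurable.
Synteny between two categorized neighborhoods is the longest common
subsequence of category strings, strand-normalized, over the longer
neighborhood length.

## Numerical and procedural choices

- Tie-breaks are deterministic everywhere: ascending e-value then
  lexicographic id for hits; table order for signature ties; smallest
  index pair for NJ joins; lowest clade number for assignment ties.
- Traceback prefers match over deletion over insertion on exact ties,
  with a 1e-9 tolerance for floating-point comparisons.
- All randomness flows from `numpy.random.default_rng` seeded per run;
  child seeds are drawn below 2³¹. Reruns with identical config + seed
  produce byte-identical output bundles (checksummed in the manifest).
- Pipeline problem sizes: 50-genome cohorts (~3,800 proteins, ~70 planted
  copies), 1,000-decoy calibrations, 100 bootstrap replicates and 999
  permutations — sizes at which every stage's ground truth is exactly
  checkable while a full run stays in the minutes range on one core.
- Degenerate inputs fail loudly: zero-variance decoy scores, saturated
  Poisson distances, single-environment association tests, duplicate gene
  ids, and missing signature calls all raise typed errors.

## Known limitations

- The PSSM has no insert/delete state probabilities and one domain
  envelope per protein; tandem multi-copy fusions beyond Y+Z would need
  envelope extraction the package does not do.
- Real swinging-arm variant residues (beyond the canonical `VTIGGC`) must
  be supplied by the user for real data; the shipped motifs are
  structural placeholders.
- Distance NJ underestimates deep-stem support near saturation (see
  above); likelihood methods are out of scope by design.
- Species-level dereplication, taxonomy, and assembly/binning QC are
  upstream concerns; the pipeline consumes annotated proteomes as given.
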