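# soxyprof

Gene-family expansion profiling for *soxY*, the sulfur-carrier subunit of
the Sox (sulfur-oxidation) multienzyme system, in annotated bacterial
(meta)genomes.

Sulfur-oxidizing symbionts of marine invertebrates carry up to five
divergent copies of *soxY*. The copies differ in the substrate-binding
"swinging arm" — the C-terminal motif (canonically `VTIGGC`) ending at the
conserved sulfur-binding cysteine (position 110 of the canonical
reference) — and fall into six named signature variants (SoxY-S1a, -S1b,
-S1c, SoxYZ-S2, SoxY-S3, SoxYZ-S4), two of which are fusions of the SoxY
and SoxZ carrier subunits. Repertoire breadth tracks host/environment
breadth: symbionts with only the canonical signature are habitat
specialists, symbionts with divergent copies are generalists.

`soxyprof` re-implements that analysis as a tested pipeline over protein
FASTA + GFF3 inputs:

1. **Profile search** — an in-house position-specific scoring profile
   (log-odds in bits, affine gaps, global across profile columns with
   unpenalized flanking sequence) with *empirical* e-values: a Gumbel null
   `P(S ≥ s) = 1 − exp(−exp(−λ(s−μ)))` fitted by method of moments to
   composition-matched decoys, `E = N·P(S ≥ s)`.
2. **Screening** — the published quality filters: drop hits under 140 aa or
   lacking the `GGC` functional motif, e-value cutoff 1e-5, exact-duplicate
   collapse (copy numbers are counted before deduplication).
3. **Signature classification** — extract the 6-column arm window at the
   conserved-cysteine anchor from the profile alignment and classify by
   Hamming distance against a configurable motif table; detect SoxYZ
   fusions as a significant SoxY domain followed by a significant SoxZ
   domain (per-domain e ≤ 1e-5, envelope overlap ≤ 10 aa).
4. **Phylogeny** — stacked profile-coordinate alignment, p/Poisson
   distances with pairwise deletion, Saitou–Nei neighbor joining
   (Studier–Keppler `Q`), column-resampling bootstrap, and distance-based
   assignment to the four major SoxY clades.
5. **Repertoires & ecology** — per-genome copy numbers by signature,
   sulfur-gene presence/absence against a reference panel (e ≤ 1e-30, or
   1e-6 for reference proteins under 120 aa), and a permutation chi-square
   test of divergent-signature presence against environment.
6. **Neighborhoods** — gene-context maps around each *soxY* locus with
   keyword categories (sulfur / carbon / regulatory / other /
   hypothetical), operon detection (same-strand runs, intergenic gaps
   ≤ 200 bp, required *soxABXYZ* labels), and LCS-based synteny scores.

A first-class synthetic-data module generates seeded cohorts with planted
ground truth (signatures, fusions, neighborhoods, ecology labels), so the
whole pipeline is verifiable offline; real NCBI data are never required.

## Worked example

```bash
soxyprof run-all --out results/run --seed 1 --n-genomes 50
```

or equivalently, step by step with the numbered drivers:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_search_and_filter.py
...
python analysis/06_neighborhoods.py
```

On the seed-1 cohort (50 genomes, 3,792 proteins, 72 planted copies) the
search stage prints:

```
profile: 150 columns, conserved cysteine anchored at column 110
decoy calibration: Gumbel mu=11.30 bits, lambda=0.161 /bit (1000 decoys)

search: 3792 proteins -> 72 hits at e<=1e-5 -> 72 after quality filter -> 72 unique sequences
recall vs planted truth: 72/72 (missed 0, false 0)
```

Every planted copy is recovered with no false hits; classification then
reports `signature accuracy vs truth: 72/72` and
`SoxYZ fusions called: 13 (planted: 13)`; the tree stage reports all four
clades monophyletic with `clade agreement with planted truth: 72/72`; and
the ecology stage prints the contingency table with
`permutation chi-square = 36.9, p = 0.0010 (999 permutations)` — divergent
signatures occur only in generalist-labelled genomes, the planted pattern.
Neighborhood analysis discriminates all 13 operon-layout loci from the 59
dispersed/satellite loci (`architecture discrimination: 72/72`).

Outputs are tab-separated tables (`hits.tsv`, `calls.tsv`,
`repertoire.tsv`, `presence.tsv`, `cohort_matrix.tsv`,
`neighborhoods.tsv`, `operons.tsv`), a Newick tree with bootstrap
supports, `association.json`, and a `run_manifest.json` with the config
echo, seed and output checksums (identical config + seed ⇒ identical
bundle).

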