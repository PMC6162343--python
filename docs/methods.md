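# Methods

## Problem setting

METTL16 methylates the fourth adenosine of the nonamer UACAGAGAA only in
a structural context where that adenosine is unpaired and flanked by
double-stranded RNA. The package analyses (and simulates) a selection
experiment on a randomized 30-nt library, N₁₁-UACAGAGAA-N₁₀: after in
vitro methylation, anti-m⁶A immunoprecipitation and sequencing, the
representation of each predicted secondary structure is compared between
IP and input libraries, and the positional structure of the enriched
class reveals the substrate rule. The same codebase also covers two
satellite tasks from the same study design: genotyping embryo RNA-seq
read sets via knockout-allele diagnostic 22-mers, and screening
transcripts for nonamer occurrences in a competent structural context.

## Library design and read filter

The oligo layout is `left_flank (11 nt) + UACAGAGAA + right_flank (10 nt)`,
30 nt total, with the methyl acceptor at oligo position 15 and the DNA
motif TACAGAGAA spanning positions 12–20 (all coordinates 1-based
inclusive, matching how sequencing reads are described). Reads enter the
analysis only if they are exactly 30 nt, contain no N, and carry the
motif exactly at its window; rejections are attributed to the first
failing rule in the fixed order length → N → motif so filter reports are
deterministic. The filter is idempotent and partitions its input
exactly. Reads are modelled post-adapter-trimming; adapter removal
itself is routine and out of scope.

## Folding model

The native folder maximizes a pair-weight score — GC = 3, AU = 2,
GU = 1, all symmetric — plus a stacking bonus of +1 for every pair whose
inner neighbour is also paired, over all non-pseudoknotted structures
with hairpin loops of at least 3 unpaired bases (the standard steric
constraint). This is a Nussinov-style interval dynamic program with a
second "closed" channel so the stacking bonus is credited exactly once
per stacked pair. It is not a thermodynamic nearest-neighbour model:
free energies, temperature, dangling ends and suboptimal ensembles are
deliberately out of scope. The score ordering it induces is sufficient
to express the qualitative structure classes the analysis consumes
(stems, loops, bulges, junctions); for exact replication with a
thermodynamic folder, Vienna-format output (e.g. from RNAfold) can be
ingested via `read_vienna` and substituted at the fold stage.

Determinism: ties are broken by preferring a position unpaired over
paired, and among score-equivalent partners the 5′-most partner; the
inner loop prefers the generic interior over the stacked channel unless
the stacked channel is strictly better. Outputs are therefore
byte-reproducible. Correctness is established against an independent
exhaustive-enumeration oracle (all valid structures, lengths ≤ 18); a
property test also checks that re-scoring the traceback structure
reproduces the DP score, and that appending bases never decreases the
optimal score. The DP fill is JIT-compiled with numba when available
(~50 µs per 30-mer); a pure-Python fallback with identical semantics is
retained.

## Feature classification

Positions are classified from the pair table by loop decomposition.
Paired positions are `stem`. An unpaired position takes the type of its
enclosing loop: `hairpin_loop` (closing pair, no inner helices), `bulge`
(helix interruption with all unpaired bases on one strand),
`internal_loop` (unpaired bases on both strands), `multiloop` (≥ 3
emanating helices), `exterior` (not enclosed by any pair). Two derived
flags describe the methyl-acceptor context:

- `single_nt_bulge` — a bulge whose unpaired run has length exactly 1;
- `between_two_stems` — an unpaired position whose immediate 5′ and 3′
  neighbours are both paired, *regardless of loop type*. This
  deliberately includes single-nt bulges as well as junction
  nucleotides in multiloops and the exterior, because "1-nt bulge" and
  "between two stems" are overlapping descriptions of the preferred
  target context. Terminal positions can never carry the flag.

Helices are maximal runs of stacked pairs; helix lengths support the
optional minimum-stem requirement of the substrate scanner. Because a
1-nt interruption can be read either as a bulge or as a degenerate
internal-loop side, both the exclusive category and the overlapping
flags are always reported, so either reading can be reproduced.

## Simulated IP experiment

Flank bases are i.i.d. uniform over {A, C, G, T} (no synthesis bias is
modelled). Each oligo is folded with the same folder and parameters the
analysis pipeline uses, and its ground-truth class is the
`between_two_stems` flag at position 15 — ground truth and pipeline are
self-consistent by construction rather than tied to an external truth.
Input replicates draw reads uniformly with replacement; IP replicates
draw proportionally to the capture probability: `p_ip_structured = 0.9`
for oligos with the target context, `p_ip_background = 0.05` otherwise.
The expected IP/input representation ratio of structured relative to
background oligos is therefore `0.9 / 0.05 = 18` before normalization.
Defaults: 2 input + 2 IP replicates, 100,000 reads each.

Sequencing artifacts are injected per read, each with probability 0.005
(typical post-trimming short-read artifact scale; the underlying study
does not report rates): an N substitution at a random position, a
length change (single-base deletion or duplication), and a single-base
mismatch inside the motif window. All three artifact types fail the
read filter by construction, so with zero error rates every emitted
read passes. All randomness flows through one seeded generator per
operation.

What the simulator does **not** emulate: antibody sequence bias, PCR
duplicates, ligation bias, incomplete methylation of competent oligos,
and — most importantly — any mismatch between predicted and true
structure. Real selection acts on the physical ensemble; the simulation
acts on the predicted MFE structure. Passing recovery tests therefore
demonstrate that the pipeline correctly inverts its own generative
model, not that the folder predicts physical structures.

## Enrichment statistics

Reads are aggregated by unique dot-bracket (sequences folding
identically are pooled) and counts are pooled within condition. The
original analysis used a negative-binomial shrinkage model; here the
decision rule is kept (BH-adjusted p ≤ 0.1, sign of the fold change)
but the test is a library-size-conditioned exact binomial: given a
structure's total count, its IP share is Binomial with success
probability `N_ip / (N_ip + N_in)` under the null. The log₂ fold change
uses a pseudocount of 0.5 inside the ratio only, never inside the test.
Replicate dispersion is not modelled; per-structure replicate
discordance (max |log₂ ratio| of normalized replicate counts) is
reported as a diagnostic column instead. Structures with fewer than
`min_total = 10` reads are excluded from testing (an independent-
filtering stand-in); excluded structures keep the label `nondiff` in the
results table but carry `tested = False` and belong to **no** class in
downstream profiling — the non-differential profile class means
"tested and not significant", matching independent-filtering semantics.
The discrete exact test is conservative: on null simulations the
called fraction at α = 0.1 is far below α.

## Positional profiles and the floor rule

Per-class, per-position feature frequencies are computed either
per-structure (every unique structure counts once — used for
structure-class comparisons) or per-read (structures weighted by read
counts — used for direct oligo-level library comparisons); with equal
weights the two coincide. Class comparisons are log₂ ratios with both
frequencies floored at 0.005 (0.5%), bounding ratios by ±log₂(200) and
preventing degenerate ratios at zero frequencies. Nucleotide-frequency
comparisons between IP and input reads report motif positions but flag
them as constant (the filter guarantees frequency 1 for the motif base).

## Genotyping

The knockout allele carries the triple-stop cassette ATGTAAATAGATGA in
Mettl16 exon 3 (introduced by a 170-nt single-stranded repair template
with 81/75-nt homology arms, stored verbatim in `fixtures`). Each
allele is represented by two reverse-complementary diagnostic 22-mers
(the embryo libraries are non-strand-specific), so counting is invariant
under read orientation. A read supports an allele if it contains any of
that allele's k-mers exactly; reads matching both alleles are counted as
ambiguous and excluded. Calls: WT / KO when only one allele reaches
`min_reads`, HET when both do, indeterminate otherwise. The default
`min_reads = 2` guards against index hopping; `min_reads = 1` reproduces
a literal presence/absence rule. Matching is exact only — the 22-mers
are long enough that a one-mismatch policy was judged unnecessary and is
not implemented.

## Substrate scanner

Every exact nonamer occurrence (T ≡ U) is evaluated by folding a window
of ±30 nt around the motif (clipped at sequence ends; the window default
covers the length scale of the validated hairpin substrates) and
annotating the methyl acceptor. A hit is a candidate when the acceptor
is unpaired with both neighbours paired; optionally both flanking
helices must contain at least `min_stem` stacked pairs (default 1;
activity requires stems of about three base pairs, so `min_stem = 3` is
a natural stricter setting). No free-energy threshold is applied. The
candidate flag encodes a qualitative substrate rule and is a screening
aid, not a validated predictor of methylation efficiency.

## Pipeline and provenance

`run_pipeline` executes simulate (or load) → filter → fold → annotate →
enrich → profile, writing plain-text artifacts per stage so any stage
can be re-run standalone or swapped for an external tool. The resolved
configuration is serialized next to the outputs; a 16-hex-digit SHA-256
hash of the analysis parameters (excluding the output path) is embedded
as a comment line in every TSV and recorded, together with per-file
checksums, in `manifest.json`, so outputs produced under different
configurations are detectable. Reruns with the same configuration are
byte-identical except for wall-clock stage timings in `summary.json`.

## Problem sizes

The verification suite uses: 500 random sequences of length 10–18 for
folding-oracle equivalence; 1,000 random 20–40-mers for annotation
invariants; a null simulation of 6,000 oligos at 60,000 reads per
replicate (≈ 6,000 tested structures) for calibration; the full
50,000-oligo simulation at default depth for preference recovery; and
spiked read sets of 50 diagnostic reads per sample for genotype
recovery. These sizes make the whole suite run in well under a minute
of simulation time while keeping every estimate's sampling error small
relative to the effects being checked.

## Known limitations

- The folder's score is not a free energy; structures agree with
  thermodynamic folders qualitatively, not base-by-base. Use the Vienna
  ingestion path when exact structures matter.
- The binomial enrichment test ignores replicate dispersion; with noisy
  replicates it is anti-conservative relative to a dispersion-aware
  model. The replicate-discordance diagnostic should be inspected.
- Exact k-mer genotyping has no mismatch tolerance; highly degraded
  reads reduce sensitivity but not specificity.
- The scanner folds an isolated window; long-range pairing outside the
  window is invisible to it.
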