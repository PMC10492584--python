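# Methods

This note documents the models and numerical choices behind `sgrtyping`:
what each stage assumes, which knobs matter, what the synthetic panels do
and do not emulate, and where the design was genuinely open.

## The amplicon model

The analysed fragment is intron 3 of the *STAYGREEN* locus, amplified from
*Pisum fulvum* accessions. Its architecture, as the package models it:

```
[conserved 5' block ~80 nt] [unit 1][unit 2] ... [unit k] [conserved 3' block ~130 nt]
        poly-T, CTTTT        k = 5..20 imperfect head-to-tail repeats, 60..100 nt each
```

Each major repeat unit typically opens with a start motif (`CTCTTCTAAT` or
`GTAAGTCTAAT`), carries one or occasionally two GA-rich segments
(approximately `AGAAGAGGAGGAGAGA`), sometimes a GA-rich extension
(`CAAGAGGATAAA`), and often closes with a motif near `CTTGTTTGTGTCTGGT`.
Two 5'-end features — a poly-T run (7–11 T's) and the CTTTT sequence —
plus DraI (`TTTAAA`) and HindIII (`AAGCTT`) sites complete the diagnostic
vocabulary. An allele is an exact amplicon sequence; an indel class is a
set of alleles inter-convertible by substitutions alone.

## Motif annotation

Motif scanning is windowed Hamming matching: every window within the
per-family mismatch budget is a hit; overlapping hits are merged keeping
the lower-mismatch (ties: leftmost) one. `N` matches nothing, including
another `N`. Default budgets — GA-rich 3, extension 2, GTAAGT 2,
unit-start 2, unit-end 4 — admit the "slight variants" seen between
accessions while the shorter diagnostic motifs stay specific; all budgets
are exposed in `AnnotatorParams`. The GA-rich scan additionally requires
window G+A content ≥ 0.75, which suppresses hits in unrelated purine-rich
runs. Indel-free matching inside a window is a deliberate simplification:
an indel inside a motif instance costs the hit, which the classifier's
weighted voting absorbs.

The CTTTT feature is tri-state: `present` (C followed by ≥ 4 T's in the
sequence window 30–100), `deleted` (the two canonical context flanks
adjacent, each within 1 mismatch, with the T-run gone — the signature of
the subgroup-B-7-type 5' deletion), else `absent`. The exact printed
coordinates of this feature are alignment-dependent, so a sequence-space
search window is used instead.

Repeat decomposition cuts the interior at unit-start anchors (start-motif
hits, with GA-rich hits as fallback anchors when no start motif precedes
them within 100 nt); anchors closer than 30 nt are pruned, a leading
remnant shorter than 55 nt joins the first unit (real units are ≥ 60 nt),
and an anchor-free interior becomes a single unit flagged degenerate.
Spans partition the interior exactly, which is what makes the downstream
alignment projection lossless.

## Allele calling and the SNP-only collapse

Alleles are named `<length><letter>` with letters assigned in order of
first occurrence over lexicographically sorted accession ids — discovery
order of any particular survey is not reproducible, so names are internally
consistent only. "Differs only by SNPs" is operationalised as: the optimal
global alignment (match +1, mismatch 0, gap open −4, gap extend −1; N
scores 0 against everything) contains no gaps, which for equal-length
sequences is equivalent to the direct ungapped score attaining the optimum.
The relation is closed transitively (union–find) so indel-class counts
describe a partition; classes can therefore chain through intermediate
alleles. Different lengths force gaps, so the collapse can never merge
lengths.

## Group and subgroup classification

Group assignment is a weighted vote rather than a decision tree because
the two lineages are defined by co-occurring features with documented
exceptions, and single features can be lost to point mutations. The
GA-rich extension rules carry weight 2 (it is the exceptionless diagnostic:
present in every group-A sequence, absent from every group-B sequence);
GTAAGT multiplicity, GA-rich count (6–13 vs 13–18), and the DraI/HindIII
diagnostics carry weight 1. A relative margin below 0.2 yields `atypical`
— the expected outcome for hybrid-derived alleles mixing A and B features,
and occasionally for heavily drifted sequences; it is a first-class result,
not an error.

Subgroups are ordered rule chains (first match wins):

* A side — A-3 (CTTTT lost, exactly one GTAAGT) → A-4-a/A-4-b (CTTTT
  kept, split by fuzzy probe detection of the 65-nt vs 39-nt diagnostic
  insert) → A-1-a (≤ 6 GA repeats and ≤ 560 nt) → A-1-b (7–9 GA repeats)
  → A-2 (fallback).
* B side — B-7 (CTTTT deleted) → B-6 (HindIII present and the 43-nt
  fragment in ≥ 2.5 tandem copies: ≥ 2 full fuzzy hits plus an extra
  half-length hit) → B-5 (poly-T > 10 and < 13 GA repeats) → B-8
  (explicitly the collection of sequences fitting no other rule).

Coordinate-based indel diagnostics are re-expressed as probe subsequences
with fuzzy matching because the classifier sees unaligned input; the
shipped probes are those of the synthetic archetypes, and real collections
supply their own through `ProbeLibrary`.

## Repeat-aware alignment

The aligner encodes two curation priorities. *Tandem preservation*:
head-to-tail runs of highly similar units are presumed recent duplications
and kept contiguous. *Homology over length*: candidate alignments are
ranked by base match fraction first, total length second.

Mechanics: sequences are tokenized into units; unit similarity is
global-alignment identity (matches / alignment length; nucleotide scoring
match +1, mismatch −1, gap −2). Token-level Needleman–Wunsch uses a flat
per-unit gap penalty (default 0.45) — the manual method treats whole units
as insertion atoms — and a homology-thresholded substitution score: at or
above the tandem threshold (default 0.90) similarity scores at face value;
below it the score is `0.1·sim − 2·gap`, marginally better than the two
gap columns a substitution replaces. The threshold implements the
between-set versus within-set homology distinction: units of one amplicon
share motif scaffolding (baseline identity ≈ 0.75), and without the
threshold the DP would stack such paralogous units in preference to
gapping them, scattering true duplications. A consequence of the chosen
form: two completely dissimilar single units align as one substitution
column exactly when 2·gap > 1.

Multiple alignment is progressive against a growing profile (guide order:
descending token count; token-vs-column score is mean similarity plus an
infinitesimal occupancy bonus so ties between identical tandem copies are
resolved the same way by every joiner). After each join, a re-pack pass
moves matched partners to the leftmost columns of each ≥ threshold tandem
run (within consecutive column segments only, so no token is leap-frogged),
and adjacent columns with disjoint row support and mutually ≥ threshold
tokens are merged. The MSA is not sum-of-pairs-optimal and makes no claim
of column-level agreement with any hand alignment; the tandem-preservation
guarantee — every inserted unit ends up beside a ≥ threshold-similar unit —
is asserted (and tested) on the pairwise alignments, where it holds for
100 % of duplication events in duplication-only simulations. Projection to
nucleotides aligns each unit column base-by-base (progressive profile NW),
turns unit-level gaps into whole-unit gap blocks, aligns the conserved
ends as anchored blocks, and is exactly lossless: ungapping any row
reproduces its input.

## Parsimony statistics

Step counts use Hartigan's bottom-up algorithm, which reduces to two-pass
Fitch on binary trees and stays exact on multifurcations (a star tree with
three observed states counts two steps, as it must so that the per-column
bound m ≤ s holds). Missing data (N, and gaps under `gap_mode="missing"`)
contributes no state and never forces a change. Per column: m = (observed
states − 1), g = (non-missing leaves − count of the most frequent state);
S, M, G are summed over variable columns; CI = M/S; RI = (G−S)/(G−M) with
columns where g = m excluded from the RI sums (they carry no retention
information — this makes RI insensitive to singleton-only columns, the
standard behaviour). Gap treatment is the main lever when comparing RI or
informative-site counts against published numbers, so `missing` and
`fifth_state` are both first-class; they provably agree on gapless
alignments. Exhaustive most-parsimonious search is feasible to 9 taxa
(135 135 topologies, enumerated by stepwise addition); beyond that a
user-supplied tree is required.

## The synthetic panel generator

The generator is the package's test-bed: it produces panels with known
group, subgroup, and allele truth plus the generating tree. Ten archetypes
encode the subgroup architectures (GA-repeat counts 6–15, GTAAGT budgets
0–12, CTTTT state, poly-T length, diagnostic inserts, restriction sites —
the B-5-type archetype runs below 13 GA repeats with its long poly-T, the
documented exception to the group-B range). Conserved end blocks are fixed
library constants: the analysis depends only on their conservation, not
their exact sequence, so real reference sequence is not reproduced. Every
built archetype is verified against the annotator (motif counts,
restriction sites, unit count) and re-drawn on the rare filler collision,
making "by construction" tests meaningful. The HindIII site is spliced at
1-based position 95 with a neutral pad opening the interior so the splice
never damages a unit-start motif.

Mutation along a tree (branch lengths = expected substitutions per site;
indel processes scale linearly on the same axis): SNPs
(Poisson, rate 1.0 per site per unit length), SSR slippage (period ≤ 6,
run length ≥ 8; ±1 period per event, geometrically extended with p = 0.2 —
the standard stepwise model; rate 5 per SSR per unit length), and
whole-unit duplication/deletion plus 2–3-unit block duplication (rates
1.0 / 0.5 / 0.2 per unit per unit length). Duplications insert the copy
head-to-tail after its template; unit events never touch the conserved
ends, act only on proper units (the irregular first line of the repeat
structure is excluded), and respect the 500–1400 nt length envelope.
Default panels use subgroup subtrees with Exp(0.004) branch lengths joined
by 0.008 stems — leaves then differ by a handful of SNPs plus occasional
indel events, the regime the fingerprint operates in. Subgroup divergence
is carried by the archetype differences, not by simulated stem mutations,
so deep-branch statistics of the generating tree should not be
over-interpreted. Rates are not calibrated to any empirical measurement
(none is published for this locus); all are `MutationModel` fields.

What the simulations do not emulate: PCR/sequencing artefacts and
chromatogram ambiguity, the gradual "erosion" of unit identity over deep
time (archetype units are eroded by a fixed per-unit degeneracy of one
substitution in the GA segment), morphology trait evolution, and real
geographic structure. Passing tests therefore demonstrate the pipeline's
internal correctness and its behaviour under the modelled mutation
processes — not classifier accuracy on any particular germplasm
collection, for which the probe library and mismatch budgets may need
retuning.

## Validation experiments (what `scripts/acceptance.py` measures)

* Parsimony-engine oracle agreement: 500 random (≤ 7-leaf tree, column)
  cases against exhaustive internal-state-assignment minimisation; 100
  random alignments against an independent per-column informative-site
  audit.
* RI calibration: a panel with one substitution per internal edge at
  distinct positions (tree-compatible by construction) must give RI = 1.0
  exactly; each injected convergent substitution must strictly decrease RI.
* Label recovery: pooled group-level and subgroup-level accuracy over
  twenty 15+15 panels under the default mutation model (typically ≈ 98 %
  and ≈ 95 %; the targets are ≥ 95 % and ≥ 80 %).
* Tandem preservation: on duplication-only panels, the fraction of
  pairwise-alignment gap blocks whose inserted units sit beside a
  ≥ 0.90-similar unit (100 %).
* Allele contract: duplicated-leaf synonym fixtures always report the same
  allele; the SNP-only collapse never merges alleles of different length.
* One end-to-end pipeline pass reporting percent-unique alleles, indel
  classes, RI and informative sites on a default 30-leaf panel.

Problem sizes (20 panels of 30, 6-leaf alignment panels, ≤ 7-leaf oracle
trees) are chosen so the full validation completes in well under a minute
while every code path — including the O(4^internal) brute-force oracles —
is exercised meaningfully.

## Known limitations

* The progressive MSA can misplace insertions relative to a pairwise
  optimum when more than two sequences carry different duplication
  histories; pairwise alignments carry the tandem guarantee.
* Motif hits are substitution-only within a window; a 1-nt indel inside a
  motif instance loses the hit.
* `best_tree_small` is exact but explodes combinatorially; 10+ taxa need
  an external tree.
* Classifier probes ship for the synthetic archetypes; real collections
  must provide their own insert/fragment probes.
* Allele letters depend on the id sort, so names are stable within a
  dataset but not comparable across datasets with different id sets.
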