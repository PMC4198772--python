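# Methods

This note documents the models behind `ervkit`, the parameter defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results deterministic.
Nothing here quotes results that the test suite or `scripts/acceptance.py`
do not themselves recompute.

## The decay model and the simulator

An endogenous retrovirus is modelled as a neutral locus from the moment of
germline integration. The generator (`ervkit.simgenome`) implants elements
into an i.i.d. background (default GC 0.40) and ages them under:

* **Substitutions** — Jukes–Cantor, site-independent, with per-site hit
  probability `3/4·(1 − exp(−4μt/3))`. The default rate μ = 3.0×10⁻⁹
  /site/yr sits in the middle of the mammalian neutral range
  2.2–4.5×10⁻⁹ used for dating.
* **Indels** — a Poisson process at 2×10⁻¹¹ /site/yr with geometric
  lengths (mean 3), half insertions, half deletions; by default applied to
  internal regions only, so LTR-clock experiments stay indel-free (an
  `ltr_indels` flag turns them on).
* **Nested insertions** — SINE-like (150–600 nt) and LINE-like (1–3 kb)
  fragments drawn from a private two-sequence repeat library, inserted into
  the internal region at 10⁻⁷ /provirus/yr (≈1–2 per provirus over 10–20
  Myr, matching the nested-retroelement load typical of ancient
  proviruses). Family classification of nested content is out of scope.
* **TSDs** — the integration duplicates a 5 nt target site (length a free
  parameter, 4–6 supported; real TSD length is integrase-specific and was
  not fixed by prior observations). Both copies age with the insertion, so
  old insertions show "almost perfect" duplications while zero-age ones are
  exact. Flanking host DNA is emitted in its present-day state.
* **Solo LTRs** — a single aged LTR between two TSD copies (the product of
  LTR–LTR ectopic recombination). Default census: 100 solos vs 3 full
  proviruses, the ~30:1 excess characteristic of old ERV families.
* **Segmental duplications** — a window (800 nt flanks) containing a solo
  LTR is duplicated at a random time after insertion; both copies then
  diverge independently, so flank divergence dates the duplication and
  lower-bounds the insertion age.
* **Empty pre-integration sites** — for half the insertions (configurable)
  a separate contig carries flank + one target-site copy + flank at 5%
  ortholog divergence, emulating the locus in a related species.

Default provirus ages are 7.7, 15.4 and 20.1 Myr — the midpoints of the
dating intervals typical for the oldest known endogenous lentiviruses — and
solo ages are uniform on 2–15 Myr.

**Boundary identifiability.** When the last base of an LTR equals the host
base before the 5' TSD (or symmetric cases), a (TSD, LTR) assignment
shifted by one base is *equally consistent* with the sequence and the truth
record would be ill-defined. The generator therefore nudges full-provirus
insertion sites (by single bases, within the placement margin) until all
four edge inequalities hold. This is a property of the ground truth, not of
the caller.

What the generator does **not** emulate: real host repeat landscapes,
selection, CpG hypermutability, population polymorphism of insertions, and
assembly artefacts (collapsed repeats, chimeric contigs). Passing tests
therefore demonstrate algorithmic correctness on clean neutral decay, not
robustness to mis-assembly.

## Search statistics

`ervkit.seqsearch` computes optimal Smith–Waterman alignments (Biopython's
`PairwiseAligner` backend) under +1/−2 with gap 5/2 (nucleotide) or
BLOSUM62 with gap 11/1 (protein). `N` scores as a mismatch against
everything, including itself, in nucleotide space only. Bit scores use
fixed, documented ungapped-style constants per scheme (λ=1.33, K=0.621
nucleotide; λ=0.267, K=0.041 protein) and E = mn·2^(−bits) with the full
database length as n. The goal is monotone consistency of thresholds, not
numeric parity with any external search engine; E-values are conservative
enough that an i.i.d. 30 kb background yields zero forward hits at
E < 10⁻⁵ while implants at up to ~20% amino-acid divergence are found with
E ≪ 10⁻¹⁰.

Translated search segments each of the six frame translations at stop
codons (segments ≥ 15 aa) and aligns the bait to every segment. Ancient
ORFs carry nonsense mutations, so one implant surfaces as several abutting
hits; the screen therefore merges same-strand hits within 300 nt into one
locus (a deliberate consolidation rule). Backward classification takes the
best-bit panel match with the deterministic tie-break (bit score, alignment
length, lexicographic name); candidates below 100 bits are flagged
low-confidence rather than dropped.

The bundled bait and panel sequences are deterministic synthetic
placeholders with a realistic divergence structure (~45% between genus
representatives, ~15% within a genus, the six named baits 12–25% from the
lentiviral representative); users mining real genomes should substitute
curated records.

## Structural calling

Provirus calling finds direct-repeat pairs by 13-mer seed clustering in a
±16.5 kb window around a candidate locus (pair offsets 4.1–14 kb; clusters
split at >500 nt positional gaps because several distinct repeat pairs can
share an offset band). Boundaries are refined by a joint search over outer
edge shifts (±15) and repeat length (±35) scoring `matches − mismatches`
(edit-distance based, mismatch weight 2) **plus** a bonus for a perfect
flanking TSD (weight 1 per base). The TSD bonus pins the outer edges: at
zero divergence it breaks the ±1 ambiguities exactly, which is why the
zero-age recovery experiment demands — and achieves — exact intervals.
Mismatch-tolerant TSD credit was tried and rejected: it lets chance motifs
outbid the true boundary.

Two guards matter in solo-dense genomes: a candidate pair is rejected
unless its internal span covers the protein-homology anchor (pairs of
nearby solo LTRs otherwise masquerade as proviruses), and calls carrying a
detected TSD rank ahead of bare pairs (TSD agreement is the evidence that
both repeats belong to one integration event). The internal-span window
[4, 13] kb brackets a ~10 kb element with indel slack; minimum LTR length
100 nt and pair identity 0.75 leave margin well beyond the ages the clock
can date.

Solo-LTR scanning slides 2 kb windows (step 1 kb) over both strands,
local-aligns the reference LTR, deduplicates overlapping window hits, and
applies the three conjunctive filters (E < 10⁻¹⁰⁰, identity ≥ 0.80, query
coverage ≥ 0.50). Coverage is of the *reference* (query); which coverage
the classical filter meant is ambiguous, so query coverage is the filtered
quantity and configurable. Output is sorted by (contig, start), hence
invariant to contig order.

Empty-site checking aligns both flanks of a called insertion to a candidate
region: "empty" if they join across ≤ 25 nt (a TSD-sized gap), "occupied"
if ≥ 100 nt intervenes, otherwise "ambiguous"; flanks that fail a 30%-of-
maximum score floor are unalignable → "ambiguous".

## Consensus

Center-star MSA (center = member with maximal summed pairwise identity,
edit-distance based; fragments aligned semi-globally with free terminal
gaps) followed by column majority: the gap is an ordinary symbol that loses
every tie, base ties break alphabetically (IUPAC output behind a flag),
gap-majority columns are dropped, and columns under 50% support are kept
but flagged. One refinement round re-aligns members against the first-round
consensus as a non-voting center; this heals the center-star artefact where
equivalent insertions from different members land in adjacent gap columns
and are individually outvoted.

Majority-of-3 has an irreducible error floor: two copies hit at the same
site by the same base occur at rate ≈ p²(1−p) per site, and 1/1/1 ties cost
another ≈ 2p²/3·(2/3). At 1% per-copy divergence this predicts ~99.95%
consensus identity for a 10 kb element (the recovery experiment measures
the mean across 50 replicates ≥ 99.9%); above ~2.5% per-copy divergence the
floor alone exceeds 0.1%, so no consensus rule of three copies can reach
99.9% there. Coincident overlapping deletions in two copies are likewise
unrecoverable and show up as occasional sub-threshold replicates.

## Annotation

ORFs (ATG→stop, both strands) are labelled positionally: the three longest
non-nested long ORFs (≥300 aa, a threshold that passes retroviral
gag/pol/env but not accessory ORFs) become gag/pol/env in 5'→3' order, with
the pol label additionally requiring a different-frame overlap with gag —
the −1 ribosomal-frameshift signature. Short ORFs (≥70 aa) between the pol
tail (start ≥ pol end − 150) and env become orf1/orf2 analogs; a short ORF
spanning env's stop becomes the orf3 analog. The PBS is the best
reverse-complement match (≤3 mismatches over 18 nt) to a small bundled set
of generic tRNA 3'-tails within 30 nt of the 5' LTR and is always reported
as putative (the priming tRNA is unknown a priori); the PPT is the longest
window ≥ 11 nt with purine fraction ≥ 0.9 ending within 10 nt of the 3'
LTR. Homology-based labelling is available through the search module but
not required.

## Dating

The clock deliberately uses the raw difference count: T = D/(2Lμ) with
μ ∈ [2.2, 4.5]×10⁻⁹ /site/yr, matching how such intervals are
conventionally printed (a Jukes–Cantor-corrected variant sits behind
`jc_correct=True`). Gap columns are excluded from both D and L. Pairs whose
unit-cost edit distance exceeds 0.45/site are rejected as non-orthologous
*before* column counting — unrelated sequences align at ~0.5 edits/site and
a unit-cost path would overstate their column identity. Ages are reported
in Myr at 0.1 precision.

Two statistical facts shape expectations. (i) The point estimate is
JC-biased low at old ages (−6% at 15 Myr), which the ≤10% per-bin error
bound absorbs. (ii) The probability that the true age falls inside the
[2.2, 4.5]×10⁻⁹ interval is only ~84% over ages 2–15 Myr at L=450
(binomial noise in D dominates below ~11 Myr; exact Monte Carlo of the
model gives 84.2% raw, 85.1% JC-corrected). A ≥90% coverage expectation is
therefore unattainable under these conditions, and the corresponding
acceptance check is expected to fail by ~6 points; the measured coverage is
reported as-is.

Duplication bounds locate the shared solo LTR in both regions by local
alignment, excise it, and date the concatenated flanks with the same
formula (`method="duplication_bound"`), a lower bound because integration
predates duplication.

## Phylogenetics

Distances use pairwise deletion (per-pair shared non-gap columns):
p-distance, Poisson −ln(1−p) for proteins, JC −(3/4)ln(1−4p/3) for
nucleotides, with saturation errors naming the offending pair.
Neighbor-joining is the Saitou–Nei algorithm with the smallest-(i,j)
tie-break and zero-clamped branch lengths; it reproduces additive matrices
exactly (the acceptance oracle) and agrees with an independent
implementation on general metric matrices. Bootstrap resamples columns and
counts original bipartitions in replicate NJ trees; saturated replicates
contribute no support. ML/Bayesian inference is intentionally not
re-implemented; external trees can be imported as newick (dendropy). The
pipeline's placement stage extracts the element's Pol — via the labelled
ORF when intact, else by stitching translated homology segments, which is
the usual case for Myr-old elements — and places it among the genus panel
with bootstrap support for the lentivirus clade.

## Determinism and problem sizes

One integer seed drives everything: simulation, bootstrap, and the
acceptance runner (which derives per-experiment sub-seeds). Re-running any
pipeline stage from a run directory reproduces its outputs byte-for-byte.
The validation experiments use 200 LTR-pair replicates, 20 paired-implant
genomes (18 kb contigs), 100 zero-age structure fixtures (26 kb), a
100-solo filter audit (400 kb), 50 consensus replicates, 1000 alignment
oracle pairs, 100 additive matrices, and one full 400 kb end-to-end run
with 500 bootstrap replicates — sizes chosen so the whole suite validates
every stage on a single CPU in minutes while keeping counting statistics
meaningful.

## Known limitations

* Tandem or recombined multi-provirus loci and tRNA-database LTR boundary
  typing are out of scope; so are Pol domain sub-annotation, RNA secondary
  structure (frameshift hairpin, TAR), and ENV topology.
* The screen's statistics are calibrated for desk-scale genomes; screening
  gigabase assemblies would need the seeded search mode and chunked I/O.
* Gene labelling is positional; a degraded element whose long ORFs fall
  below 300 aa yields no gag/pol/env labels (homology evidence still
  locates the coding regions, as the pipeline's phylo stage does).
* The consensus is a majority reconstruction, not an ancestral-state
  estimate over a tree; above ~2.5% per-copy divergence its error floor
  exceeds 0.1% regardless of implementation.
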