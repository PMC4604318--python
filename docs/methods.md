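# Methods

## Model and assumptions

The package operationalises one biological premise: two unigenes that are
fragments of the same transcript sample reads from the same molecule
population. Under uniform read sampling, a fragment of length L with C
mapped reads in a library of N total mapped reads has
RPKM = 10⁹·C/(N·L), and the fragment's length cancels — both fragments
inherit the transcript's abundance. Their RPKM values are therefore equal
in every sample and, more robustly, their expression *patterns* across
samples coincide even when per-sample values are biased. The pipeline
exploits this as a cheap pre-filter before any sequence comparison.

The remaining stages assume: (i) a family annotation is available per
unigene and fragments of one transcript share it; (ii) each unigene has a
translated alignment to a reference proteome placing it in protein
coordinates; (iii) a bridging sequence (in practice a sequenced PCR
product, here a simulated read) can be obtained that overlaps both
fragments.

## Coordinates and the gap convention

All file and in-memory coordinates are 1-based inclusive. For an ordered
pair whose 5′ member ends at reference residue e₅ and whose 3′ member
starts at s₃, the gap is **s₃ − e₅** amino acids when positive; otherwise
the spans overlap by e₅ − s₃ + 1 residues (capped by the shorter span).
This convention counts one residue more than the strictly uncovered
stretch, but it is the convention the product-size rule is defined
against — estimated = designed + 3·gap — and the two are used only as a
consistent pair. A consequence worth knowing: for codon-aligned fragment
boundaries the true bridged product is exactly estimated − 3 bp. The
synthetic generator records true product sizes so this relation is
asserted, not hidden.

Terminal labels ("5′", "3′" in location strings) are display-level: a span
is called 5′-terminal when start ≤ 15 aa and 3′-terminal when it ends
within 15 aa of the reference's length. Pairing decisions use relative
positions, never these labels; the 15-aa tolerance only affects the
same-terminus exclusion and the printed strings.

## Grouping

Within one family, profiles are log-transformed (log₂(RPKM + 1); the
pseudocount keeps zeros finite and ordering intact) and clustered
agglomeratively with average linkage (UPGMA) on 1 − Pearson correlation, a
distance in [0, 2]. Spearman and Euclidean variants are config-exposed.
Zero-variance log vectors carry no pattern information: two equal constant
vectors get distance 0, anything else 2. Profiles are sorted
lexicographically by id before linkage, which makes the dendrogram — and
everything downstream — invariant to input order.

Groups are **maximal subtrees with 2–5 leaves**: walking down from the
root, a node becomes a group as soon as its leaf count falls in range, so
groups are disjoint and maximal. This formalises the manual practice of
boxing tight clusters on a heatmap; an optional maximum merge height can
tighten it. Leaves in no qualifying subtree stay ungrouped.

## Pair selection

Every unordered pair inside a group is considered exactly once and either
emitted or excluded with one reason (the two sets partition the
considered combinations):

- `cross_reference` — members align to different reference proteins;
- `both_complete` — a member already carries a complete CDS (by flag, or
  by spanning both reference termini);
- `containment` — one footprint inside the other, or an overlap whose
  codon mapping leaves a unigene's sequence;
- `same_end` — both footprints anchored at the same reference terminus;
- `mismatched_overlap` — overlapping footprints whose nucleotide
  sequences disagree.

Overlap consistency extracts the codon-mapped nucleotide sub-sequences
under the shared residue interval and aligns them globally
(match +1, mismatch −1, gap −2); the pair passes at ≥ 95% identity over
aligned columns (config-exposed). Windows containing N fail. The 95%
default tolerates occasional assembler errors while rejecting paralogs
at ≥ 10% divergence by a wide margin.

## Primer design and product sizes

The search is exhaustive over primer windows (17–24 nt) whose product
would retain ≥ 200 bp of each unigene — the anchoring constraint that
makes a positive band attributable to both members. Quality rules are
deliberately wide (GC 35–65%, no mononucleotide run > 4, no N) because
several published bridging primers are permissive 17–20-mers. Tm is
nearest-neighbor (50 mM Na⁺, 250 nM primer) with a Wallace-rule mode for
fast tests; the accepted window is 50–65 °C. Among feasible combinations
the pair minimising |Tm_f − Tm_r| wins, ties broken by larger
product–unigene coverage, then leftmost coordinates — fully
deterministic. Product sizes: designed = (len₅ − f_start + 1) + r_end −
3·overlap_aa on the butted template; estimated adds 3·gap.

## Merge and ORF analysis

The bridge merge is overlap-layout-consensus at three-sequence scale. A
suffix–prefix dynamic program (free end gaps on the outer ends, +1/−1/−2
linear scoring; rows vectorised with a prefix-max trick valid for linear
gap costs) aligns the 5′ unigene's suffix to the bridge's prefix and the
bridge's suffix to the 3′ unigene's prefix. Both bridge orientations are
tried. Each flank must reach ≥ 40 aligned nt at ≥ 95% identity (defaults;
conservative given the ≥ 200 bp anchoring above). Conflicts inside a
flank overlap are resolved toward the unigene, concretely by keeping the
unigene sub-sequence verbatim — unigenes come from deep short-read
consensus, the bridge from a single Sanger-like read; a flag prefers the
bridge instead. When the two flank regions collide on the bridge (the
unigenes themselves overlap), the bridge arbitrates the junction offset
and the merged sequence is the 5′ unigene followed by the 3′ unigene's
unshared suffix.

ORFs are scanned in all six frames (ATG starts only, translation table
1): one ORF per stop-delimited segment, from the segment's first ATG to
the next in-frame stop or the sequence end. The longest by protein length
wins; ties break by leftmost start, then frame order +1, +2, +3, −1, −2,
−3. A complete CDS requires (a) a terminal stop, (b) 5′ evidence — an
upstream in-frame stop, or an ORF starting after the first base so a 5′
UTR exists — and (c) protein length inside the family's homolog range
(strict by default; a tolerance is config-exposed). The range test is
necessary but not sufficient on real data: termini evidence can fail for
proteins whose length happens to fall in range, which is why (a) and (b)
are primary.

## Synthetic data

`generate(config, seed)` builds, deterministically per seed: transcripts
with uniform-codon CDSs (fixed ATG, one stop, 420–650 aa) and random
UTRs; the first `n_pairs` transcripts split into a 5′ and a 3′ fragment
with a planted gap (30–250 aa drawn uniformly, clamped to keep the 3′
fragment ≥ ~280 nt) or, for about one pair in six, a 10–40 aa overlap;
decoy paralogs covering the junction with exactly 12% substitutions and
the parent's expression profile; and singleton full-length transcripts.
About 30% of unigenes are emitted reverse-complemented with negative
alignment frames. Per-sample abundances are lognormal (μ=3.5, σ=1,
rounded to integers ≥ 1) over four samples named after the motivating
study's libraries (200S, CKS, 200R, CKR); counts are length × abundance
exactly (so the fragment-equality property is exact at noise 0), with
multiplicative lognormal noise followed by Poisson sampling when noise
> 0; library totals add a 5×10⁶ background so totals exceed column sums
as in a real library. Family length ranges are derived from the generated
references ±10%. `simulate_bridge` returns the transcript segment
spanning the junction plus a chosen flank into each fragment, with an
exact number of point errors (round(rate·len)) and random strand.

What passing tests on this generator show: the geometry, arithmetic and
filtering logic are correct under the model's assumptions. What they do
not show: robustness to positional coverage bias, mapping ambiguity
between paralogs, isoforms sharing exons, or chimeric unigenes — none of
which the generator emulates.

## Problem sizes and determinism

Default simulations are 20 transcripts × 4 samples with 6 planted pairs
and 3 decoys (≈ 29 unigenes), the scale at which a gene-family analysis
runs interactively; the recovery properties are checked across 10 seeds,
the overlap DP against a brute-force scan on 500 planted instances, and
the ORF scanner against six-frame translation on 1,000 random 2-kb
sequences. All randomness flows through `numpy.random.default_rng(seed)`;
identical seeds give byte-identical generator output.

## Known limitations

- Overlap consistency maps residues to nucleotides assuming a colinear,
  ungapped alignment within the HSP; indel-containing HSPs would shift
  the mapping (real BLAST coordinates per residue would fix this).
- The primer Tm model is informational; no specificity screening against
  the full transcriptome is attempted.
- The merge consensus is two-sequence-per-column and therefore
  arbitration, not voting; with a single bridge read there is no
  majority to take.
- Complete-CDS judgement against a family-wide length range is coarse
  for families with broad ranges; a closest-homolog comparison would be
  sharper but needs a homolog database.
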