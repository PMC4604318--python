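"""The whole workflow on a simulated transcriptome with known truth.

Generates 20 transcripts (6 split into fragment pairs, 3 decoy
paralogs), runs RPKM -> clustering -> pair selection -> primer design,
and compares the emitted candidate pairs with the planted truth.
"""

from unibridge import expression, pipeline, synthetic_data

truth = synthetic_data.generate(seed=0)
matrix = expression.rpkm_matrix(truth.counts)
result = pipeline.run_pipeline(truth.records, matrix, truth.alignments, truth.reference)

print("filtering funnel:")
for stage, count in result.stage_counts.items():
    print(f"  {stage}: {count}")

want = {(t.five_prime_id, t.three_prime_id) for t in truth.true_pairs}
got = {(p.five_prime_id, p.three_prime_id) for p in result.pairs}
print(f"\nplanted pairs recovered: {len(got & want)}/{len(want)}, "
      f"false positives: {len(got - want)}")
for p in result.pairs:
    primers = result.primers.get((p.five_prime_id, p.three_prime_id))
    gap = "none" if p.gap_aa is None else f"{p.gap_aa} aa"
    line = f"  {p.five_prime_id} + {p.three_prime_id}  {p.reference_location}  gap {gap}"
    if primers:
        line += (f"  {primers.forward_seq}/{primers.reverse_seq}"
                 f"  designed {primers.designed_size_bp} bp"
                 f"  estimated {primers.estimated_size_bp} bp")
    print(line)
# Exclusion counts show why the remaining combinations were dropped:
# different reference proteins, complete members, or overlaps whose
# sequences disagree (the decoys).
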