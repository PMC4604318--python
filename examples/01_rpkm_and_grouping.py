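"""RPKM profiles and expression grouping on a small simulated library.

Two unigenes that are fragments of one transcript receive read counts
proportional to their lengths, so after RPKM normalisation their
expression patterns coincide and hierarchical clustering puts them in
the same small group.
"""

from unibridge import expression, grouping, synthetic_data

truth = synthetic_data.generate(synthetic_data.SimulationConfig(n_transcripts=8, n_pairs=3), seed=42)
matrix = expression.rpkm_matrix(truth.counts)

pair = truth.true_pairs[0]
a = expression.ExpressionProfile.from_matrix(matrix, pair.five_prime_id)
b = expression.ExpressionProfile.from_matrix(matrix, pair.three_prime_id)
print(f"fragments of one transcript: {pair.five_prime_id}, {pair.three_prime_id}")
print("RPKM", pair.five_prime_id, [round(float(v), 1) for v in a.values])
print("RPKM", pair.three_prime_id, [round(float(v), 1) for v in b.values])
print(f"profile distance (1 - Pearson r on log2): {expression.profile_distance(a, b):.3f}")

# cluster one family and cut the tree into groups of 2-5
family = truth.records[0].annotation
ids = [r.id for r in truth.records if r.annotation == family]
profiles = [expression.ExpressionProfile.from_matrix(matrix, u) for u in ids]
dendro = grouping.cluster_family(profiles, family=family)
for g in grouping.extract_groups(dendro):
    print(f"group ({g.family}): {', '.join(g.member_ids)}")
# Equal RPKM vectors give distance 0, so planted fragment pairs always
# share a group; unrelated unigenes join only if their patterns happen
# to correlate.
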