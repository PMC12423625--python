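"""Entropy-weighted CoCoSo ranking of a synthetic assessment.

Generates a 27-country, 6-indicator decision matrix on the 0-100 scale,
weights the indicators by entropy and ranks the countries by the
Combined Compromise Solution.  Prints the top and bottom of the table
with all intermediate quantities.
"""

from hesrank import GeneratorSpec, compute_entropy_weights, generate_matrix, run_cocoso

matrix = generate_matrix(
    GeneratorSpec(m=27, n=6, dispersion=(0.05, 0.1, 0.2, 0.4, 0.8, 1.6), seed=11)
)
weights = compute_entropy_weights(matrix)
result = run_cocoso(matrix, weights, lam=0.5)

frame = result.to_frame().sort_values("rank")
print("entropy weights:",
      {k: round(float(v), 3)
       for k, v in zip(weights.indicator_ids, weights.weights)})
print("\nrank  country      S      P      k_a     k_b     k_c     C")
for _, row in frame.head(3).iterrows():
    print(f"{row['rank']:>4}  {row['country']:<10} {row.S:.3f}  {row.P:.3f}"
          f"  {row.k_a:.4f}  {row.k_b:.3f}  {row.k_c:.3f}  {row.C:.3f}")
print("...")
for _, row in frame.tail(2).iterrows():
    print(f"{row['rank']:>4}  {row['country']:<10} {row.S:.3f}  {row.P:.3f}"
          f"  {row.k_a:.4f}  {row.k_b:.3f}  {row.k_c:.3f}  {row.C:.3f}")
# C blends a share-of-total score (k_a), a distance-from-worst score (k_b)
# and a distance-from-best score (k_c); rank 1 has the largest C.
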