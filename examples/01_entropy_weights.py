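"""Objective criterion weights from score dispersion.

Builds a tiny decision matrix of four countries on three indicators and
computes entropy weights.  The 'flat' indicator, on which every country
scores the same, carries no information and gets weight 0; the widest
column gets the largest weight.
"""

import numpy as np

from hesrank import DecisionMatrix, Indicator, compute_entropy_weights

matrix = DecisionMatrix(
    countries=("Alba", "Beria", "Cydonia", "Dalia"),
    indicators=(
        Indicator("flat", "Identical everywhere"),
        Indicator("narrow", "Mild differences"),
        Indicator("wide", "Large differences"),
    ),
    scores=np.array(
        [
            [50.0, 48.0, 90.0],
            [50.0, 52.0, 10.0],
            [50.0, 50.0, 70.0],
            [50.0, 49.0, 25.0],
        ]
    ),
    region="demo",
    period="2021",
)

wv = compute_entropy_weights(matrix)
print("indicator  entropy  divergence  weight")
for ind, e, d, w in zip(wv.indicator_ids, wv.entropy, wv.divergence, wv.weights):
    print(f"{ind:<9}  {e:.4f}   {d:.4f}      {w:.4f}")
print(f"\nweights sum to {wv.weights.sum():.12f}")
# The flat column has entropy 1 (uniform shares) hence weight 0; the wide
# column's shares are most uneven, so it dominates the weighting.
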