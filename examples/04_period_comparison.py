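"""Cross-period comparison: weight deltas and rank shifts.

Uses the bundled published tables: differences the 2019 and 2021
entropy-weight rows per region, and classifies each of the 27 countries
as improved / stable / declined between the two printed rankings.
"""

from hesrank import rank_shifts, weight_deltas
from hesrank.published import (
    REGIONS,
    published_ranks,
    published_weight_vectors,
)

for region in REGIONS:
    vectors = {wv.period: wv for wv in published_weight_vectors(region)}
    delta = weight_deltas(vectors["2019"], vectors["2021"])
    cells = ", ".join(
        f"{ind}={d:+.3f}" for ind, d in zip(delta.indicator_ids, delta.deltas)
    )
    print(f"{region:<8} 2019->2021: {cells}")

report = rank_shifts(published_ranks("2019"), published_ranks("2021"))
print()
for direction in ("improved", "stable", "declined"):
    pct = report.percentages[direction]
    print(f"{direction:<9} {report.counts[direction]:>2} countries "
          f"({pct:.2f}%)")
# A positive delta means the indicator gained prioritisation (its score
# dispersion across countries grew); 'improved' means the country's rank
# number moved toward 1.
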