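"""Score the two behavioural instruments.

The comparison task pairs every 7-element series with its last-element
twin; the correctness index is the share of pairs where the responder
picked the more complex member.  The complex-span run scores recalls
under an adaptive length schedule.
"""

import numpy as np

from humanrand import load_ctm_table, simulate_comparison_responses, simulate_span_test
from humanrand.tasks import build_comparison_pairs, correctness_index, partial_span_score

table = load_ctm_table()
rng = np.random.default_rng(3)

pairs = build_comparison_pairs(table, seed=11)
print(f"{len(pairs)} pairs; example: {pairs[0].left} vs {pairs[0].right}")

for alpha in (0.0, 0.8, 1.6):
    responses = simulate_comparison_responses(alpha, 6.0, pairs, table, rng)
    print(f"discrimination {alpha:.1f} -> correctness index "
          f"{correctness_index(responses, pairs):.3f}")

print()
for capacity in (5.0, 8.0, 11.0):
    records, _ = simulate_span_test(capacity, 1.5, rng)
    print(
        f"latent capacity {capacity:4.1f} -> trial-level span "
        f"{partial_span_score(records, level='trial'):2d}, "
        f"letter-level {partial_span_score(records):3d} "
        f"({len(records)} trials)"
    )
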