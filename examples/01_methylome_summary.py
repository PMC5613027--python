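"""Genome-wide methylation summary on simulated bisulfite calls.

Simulates cytosine-report tables at the cotyledon-average and leaf
conditions, then reports the call-weighted percent methylation per context,
the composition of methylated calls, and the spike-in conversion control.
"""

import pandas as pd

from methylseed import (
    composition_of_methylcytosines,
    conversion_rate,
    simulate_preset_context,
    simulate_spike_in,
    weighted_level,
)

# CHH sites outnumber CG/CHG in an AT-rich plant genome; that is what makes
# weakly methylated CHH a large share of all methylated calls
site_counts = {"CG": 30_000, "CHG": 30_000, "CHH": 140_000}
cotyledon = pd.concat(
    [
        simulate_preset_context("cotyledon", ctx, n, seed=1)
        for ctx, n in site_counts.items()
    ],
    ignore_index=True,
)

print("cotyledon-average weighted methylation (percent of evaluated calls):")
for context in ("CG", "CHG", "CHH"):
    level = weighted_level(cotyledon, context)
    print(f"  {context}: {level.percent:5.2f}%  ({level.total_calls:,} calls)")

print("\ncomposition of methylated calls (fractions sum to 1):")
for context, frac in composition_of_methylcytosines(cotyledon).items():
    print(f"  m{context}: {frac:.3f}")

leaf = simulate_preset_context("leaf", "CHH", 50_000, seed=1)
print(f"\nleaf CHH level: {weighted_level(leaf, 'CHH').percent:.2f}% "
      "(leaf carries the lowest CHH methylation)")

spike = simulate_spike_in(n_sites=5000, conversion_rate=0.995, seed=1)
print(f"spike-in conversion rate: {conversion_rate(spike):.2f}% "
      "(methylated calls on the unmethylated genome are conversion failures)")
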