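"""Probe-trial chance geometry and the retained-memory statistic.

Computes the analytic chance levels for the circular water maze and
square open field, then generates a synthetic cohort forgetting the
old platform position at 85% retention per day and summarizes the
group retained-memory curve.
"""

from transchrom.behavior import (
    chance_level_circular,
    chance_level_square,
    retained_memory_summary,
    transmission_rate,
)
from transchrom.simulate import generate_probe_trials

print(f"water-maze chance level: {100 * chance_level_circular():.2f}% "
      "(largest circle inscribed in the platform quadrant)")
print(f"open-field center zone:  {100 * chance_level_square(37.0, 21.6):.2f}% "
      "(21.6 cm zone in a 37 cm arena)")

trials = generate_probe_trials(
    n_animals=9, baseline_fraction=0.30, retention_decay_per_day=0.85, seed=1
)
summary = retained_memory_summary(trials)
print("\nretained memory of the old target zone (group mean +/- SEM):")
for row in summary.itertuples():
    print(f"  day {row.day}: {row.mean_retained_pct:6.1f}% +/- {row.sem:.1f}")
# Day 1 is each animal's own 100% baseline; the decline tracks the
# planted 85%/day forgetting rate.

out = transmission_rate(90, 43)
print(
    f"\ntransmission: {100 * out['proportion']:.1f}% of 90 pups "
    f"[{100 * out['ci_low']:.1f}%, {100 * out['ci_high']:.1f}%], "
    f"p = {out['p_value_vs_mendelian']:.2f} vs Mendelian 50%"
)
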