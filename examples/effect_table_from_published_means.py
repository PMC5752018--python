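"""Recompute the published allelic-effect table from the published line means.

For each substitution line, the additive effect is half the difference
between its mean days-to-heading and the recurrent parent's, and the
contribution is that effect as a percentage of the recurrent parent mean.
"""

from sssltools.qtl_mapping import additive_contribution, additive_effect, round_report
from sssltools.reported import LINE_MEANS, RECIPIENT

for year in ("2014", "2015"):
    recipient = LINE_MEANS[year][RECIPIENT]
    print(f"{year} (recurrent parent mean {recipient} days):")
    for line, mean in LINE_MEANS[year].items():
        if line == RECIPIENT:
            continue
        eff = additive_effect(mean, recipient)
        contrib = additive_contribution(eff, recipient)
        print(
            f"  {line:8s} mean {mean:7.2f} d  ->  effect {round_report(eff):+6.2f} d,"
            f" contribution {round_report(contrib):+6.2f}%"
        )
print(
    "\nPositive effects are later heading than the recurrent parent (donor"
    " allele delays flowering); negative effects are earlier heading."
)
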