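"""Inter-needle gaps of the bundled electrode variants versus deployment.

Builds the gap table for the three bundled electrodes over the
20/30/40 mm deployment schedule.  For the zero-divergence array the
gaps are constant; for divergent variants they grow linearly with
(e + h_t) tan(alpha), which is what makes segmented treatment possible
with a single small shaft.
"""

from expandep.reporting import gaps_table

table = gaps_table(["5n-0deg", "4n-10deg", "5n-20deg"], [20.0, 30.0, 40.0])
print(table.to_string(index=False))
print(
    "\nGaps are in mm (side = consecutive peripherals, diagonal = opposite "
    "peripherals,\nsemi-diagonal = peripheral to central); voltages are the "
    "planned per-pair settings\nfor each model's default regime and target field."
)
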