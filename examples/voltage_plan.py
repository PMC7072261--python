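"""Per-pair voltage plan for a segmented irreversible-electroporation run.

Plans the 10-degree four-needle electrode over three deployments at the
1500 V/cm lethal target.  Each step's voltages derive from that step's
own gaps; the pulse budget (80 pulses of 100 us at 5 kHz) is split
across steps and pairs.
"""

from expandep import Protocol, build_plan, get_model

preset = get_model("4n-10deg")
protocol = Protocol.ire(1500.0, pulse_count=preset.default_pulse_count)
plans = build_plan(
    preset.spec, [20.0, 30.0, 40.0], protocol,
    granularity_V=preset.voltage_granularity_V,
)

for plan in plans:
    print(f"deployment {plan.deployment.exposure_mm:g} mm:")
    for entry in plan.entries:
        print(
            f"  {entry.pair.pair_id:6s} {entry.pair.pair_class:9s}"
            f" gap {entry.gap_mm:6.2f} mm -> {entry.voltage_V:5d} V"
            f"  ({entry.n_pulses} pulses)"
        )
print(
    "\nVoltage = gap [cm] x 1500 V/cm rounded half-up to 100 V, so the "
    "field between\neach pair reaches the irreversible-electroporation "
    "threshold at every step."
)
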