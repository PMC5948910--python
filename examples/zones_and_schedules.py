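"""Zone geometry and stage scheduling for the built-in experiments.

Shows how each experiment quantizes its behavior axis into five zones,
and how the mean baseline behavior picks the intervention order
(always ending on the middle zone O2).
"""

import nof1zones as nz
from nof1zones.specs import Zone

specs = nz.builtin_specs()
sleep = specs["sleep_productivity"]

print("Sleep-duration zones (hours):")
for zone in Zone:
    iv = nz.zone_interval(sleep, zone)
    print(f"  {zone.value:<6} [{iv.lo:g}, {iv.hi:g})")

for baseline_mean in (6.75, 8.75):
    zone = nz.classify_baseline(sleep, baseline_mean)
    plan = nz.stage_targets(zone)
    centers = [sleep.zone_centers[z] for z in plan.targets]
    print(
        f"Baseline mean {baseline_mean} h is in {zone.value}; "
        f"stages 2-4 target {centers[0]}, {centers[1]}, {centers[2]} h."
    )

# A short sleeper (baseline under 6 h) is first nudged to the nearest
# zone, then across, then to the middle.
plan = nz.stage_targets(nz.classify_baseline(sleep, 5.5))
print(f"Baseline 5.5 h (Under): targets {[z.value for z in plan.targets]}")
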