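"""Simulate one driving session and recover its fatigue-stage timeline.

Builds an 81-minute active-paradigm session (1 min rest + 80 min drive),
then reconstructs the NonF/ModF/SevF timeline from the behavioral streams
alone: coarse segmentation from the 10-minute self-reports, refined by
PERCLOS derivatives and yawn onsets.
"""
import warnings

from fatigue3 import label_recording, make_scenario, simulate_session

warnings.filterwarnings("ignore")

spec = make_scenario("active", seed=1)
print(f"programmed transitions (min into drive): "
      f"{spec.transition_times_min[0]:.1f}, {spec.transition_times_min[1]:.1f}")

recording, truth = simulate_session(spec)
timeline = label_recording(recording)

for interval in timeline.intervals:
    print(f"  {interval.label}: {interval.start_s:7.1f} .. {interval.end_s:7.1f} s")
for point in timeline.transitions:
    drive_min = (point.time_s - 60.0) / 60.0
    print(f"  transition {point.direction} at {drive_min:5.1f} min  ({point.evidence})")

# The recovered transition times should sit within one 8-second PERCLOS
# block of the programmed ones; with a yawn at the exact change they match.
for got, true in zip(timeline.transitions, truth.timeline.transitions):
    print(f"  recovery error: {abs(got.time_s - true.time_s):.2f} s")
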