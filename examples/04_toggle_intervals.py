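"""Segment a recording into AI-on / AI-off intervals from the toggle log
and summarize fixation activity in each state."""

from gazekit import (
    build_intervals,
    detect_fixations,
    generate_recording,
    generate_toggles,
    summarize_toggles,
)
from gazekit.io import ToggleState
from gazekit.synth import ToggleModel, ai_scanpath_model

model = ai_scanpath_model(dropout_rate=0.0)
recording, _ = generate_recording(model, task_time_ms=110_000, seed=13)
fixations = detect_fixations(recording)

toggle_log = generate_toggles(ToggleModel(), recording.duration_ms, seed=13)
intervals = build_intervals(toggle_log, task_end=recording.duration_ms)
summary = summarize_toggles(intervals, fixations)

print(f"AI activations          : {summary.n_activations}")
print(f"AI on-time              : {summary.pct_on:.1f} % of task")
print(f"first activation        : {summary.first_on_pct:.1f} % into the task")
on = summary.by_state[ToggleState.ON]
off = summary.by_state[ToggleState.OFF]
print(f"fixations  on / off     : {on.fix_count} / {off.fix_count}")
print(f"median dur on / off [ms]: {on.median_fix_duration:.0f} / {off.median_fix_duration:.0f}")

# Readers typically inspect the image unaided first (first activation
# near mid-task) and keep the overlay on for roughly a quarter of the
# session, consistent with using the AI as a second reviewer.
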