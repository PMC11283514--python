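"""Count between-AOI gaze transitions over consecutive fixations.

Within-AOI transitions are excluded (zero diagonal); a fixation landing
outside every AOI breaks the chain."""

from gazekit import (
    assign_fixations,
    detect_fixations,
    generate_recording,
    pad_aois,
    transitions,
)
from gazekit.synth import ai_scanpath_model

model = ai_scanpath_model(dropout_rate=0.0)
recording, _ = generate_recording(model, task_time_ms=120_000, seed=3)
fixations = detect_fixations(recording)
padded = pad_aois(model.layout, model.geometry)
assignments = assign_fixations(fixations, padded)

matrix = transitions(assignments, labels=model.layout.names)
print(matrix.to_dataframe().to_string())
print(f"\ntotal between-AOI transitions: {matrix.total}")
print(
    "findings -> bitewing:", matrix.get("ai_findings", "bitewing"),
    "| bitewing -> findings:", matrix.get("bitewing", "ai_findings"),
)

# The dominant counts run between the radiograph and the AI findings
# panel: the back-and-forth of checking AI suggestions against the image.
# The matrix need not be symmetric.
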