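"""End-to-end ocular myasthenia gravis screening on synthetic subjects.

Generates one healthy and one affected two-eyed subject and runs the full
pipeline: indicator computation per eye, the 3% scleral-proportion rule,
and the OR combination into a subject-level report.
"""

from omgeye import full_pipeline, generate_cohort

for phenotype in ("normal", "omg"):
    subj = generate_cohort(1, phenotype, seed=42)[0]
    report = full_pipeline(subj.left_mask, subj.right_mask, subj.gaze)
    print(f"--- {phenotype} subject (gaze {subj.gaze}) ---")
    print(report.narrative)
    print()
print("An eye is flagged when its gaze-side scleral proportion exceeds 3%;")
print("the subject is flagged when either eye is.")
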