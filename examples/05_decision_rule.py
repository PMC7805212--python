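"""The two-stage decision rule on individual subjects.

Stage 1 gates on the exogenous AD-RAI score: at or below 0.75 the subject is
called NC.  Stage 2 splits the remaining dementia cases by FTDI: above 1.08
calls FTD, otherwise AD.  Applied here to one subject per group from a
synthetic cohort, using a model fitted on the same cohort.
"""

from ftdindex import (
    decide,
    default_nacc_params,
    fit_ftdi,
    identify_dominant_sets,
    score_cohort,
    simulate_cohort,
)

records, matrix = simulate_cohort(default_nacc_params(seed=7))
model = fit_ftdi(matrix, identify_dominant_sets(matrix))
scores = score_cohort(model, matrix).set_index("subject_id")

for sid in ("train-NC-000", "train-AD-000", "train-FTD-000"):
    rec = next(r for r in records if r.subject_id == sid)
    ftdi = scores.loc[sid, "ftdi"]
    d = decide(rec.ad_rai, ftdi)
    print(f"{sid}: true={rec.group:3s} ad_rai={rec.ad_rai:.2f} ftdi={ftdi:.2f} "
          f"-> {d.label:3s} ({d.rationale})")
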