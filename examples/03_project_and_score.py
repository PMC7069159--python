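"""Fit the SC/LDA projection and read it the way an analyst would.

The 2-D LDA mapping is displayed as star-coordinates axis vectors: one
2-D vector per feature.  A feature is discriminative for a class when its
vector is long and points along the direction separating that class from
the rest; the score column is exactly |v_i . d_hat(class)|.
"""

from sctree import (default_paper_like_spec, discriminative_scores,
                    fit_lda_projection, generate_cohort)
from sctree.viz import render_sc_plot

cohort = generate_cohort(default_paper_like_spec(), seed=0)
model = fit_lda_projection(cohort.X, cohort.y, schema=cohort.schema)
scores = discriminative_scores(model)

print("overall feature ranking:", scores.ranking()[:6])
for cls in model.classes:
    t = scores.table
    best = (t[t.target_class == cls].sort_values("score", ascending=False)
            .head(3)[["feature", "length", "score"]])
    print(f"\nmost discriminative for {cls}:")
    print(best.round(3).to_string(index=False))

render_sc_plot(model, cohort, "sc_plot.svg")
print("\nwrote sc_plot.svg: samples colored by class, axis vectors labeled")
# '250' (diabetes) separates healthy+hypertensive from the diabetic
# statuses; '401'/'C09AA' pull toward the hypertensive side.
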