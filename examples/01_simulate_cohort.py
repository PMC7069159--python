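"""Generate a synthetic five-class chronic-patient cohort and inspect it.

The default spec emulates a population stratified into mutually exclusive
health statuses: healthy, hypertension, diabetes, both, and both plus
another dominant chronic disease.  Each class has its own code presence
rates (with under-coding: ~25% of hypertensives lack the hypertension code
'401'), a Gaussian age truncated at zero, and balanced gender.
"""

from sctree import default_paper_like_spec, generate_cohort

spec = default_paper_like_spec()
cohort = generate_cohort(spec, seed=0)

print(f"cohort: {cohort.n_samples} patients x {cohort.schema.n} features")
for label, size in spec.classes:
    mask = cohort.y == label
    age = cohort.column("age")[mask]
    r401 = cohort.column("401")[mask].mean()
    print(f"  {label}: n={mask.sum():4d}  age {age.mean():.1f} ({age.std():.1f})"
          f"  '401' presence {r401:.2f}")
# The '401' rate in CRG-5192 sits near 0.75, not 1.0: the generator drops
# the diagnosis code in a quarter of truly hypertensive patients, the
# under-coding pattern real claims data shows.
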