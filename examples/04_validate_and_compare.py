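"""Judge whether an equation set suits a population, and rank competitors.

A validation-phase-shaped cohort (344 subjects, 164 male / 180 female) is
generated from the packaged equations, then scored against (a) the
packaged set itself and (b) a copy whose FVC median is inflated by 10%
(a stand-in for a mismatched foreign reference). The suitability rule is
the population criterion |mean z| < 0.5; a negative mean z flags
overestimation. The true set should pass and rank first, the inflated
copy should show a clearly negative mean z.
"""

import numpy as np

from spirolms import (
    CohortSpec,
    compare_equation_sets,
    generate_cohort,
    load_ise,
    sample_size_check,
    validation_report,
)
from spirolms.equations import equation_set_to_dict, load_equation_set

cohort = generate_cohort(CohortSpec(n=344, female_fraction=180 / 344, seed=12))
print("minimum-sample rule:", sample_size_check(cohort))

ise = load_ise()
report = validation_report(ise, cohort)
print(f"\n{'sex':<8}{'index':<10}{'mean z':>8}{'SD z':>7}  suitable")
for row in report["rows"]:
    print(f"{row['sex']:<8}{row['index']:<10}{row['mean_z']:>8.3f}{row['sd_z']:>7.3f}  "
          f"{'yes' if row['suitable'] else 'NO'}")
print("all suitable:", report["all_suitable"])

doc = equation_set_to_dict(ise["male"])
doc["indices"]["fvc"]["mu"]["intercept"] += float(np.log(1.10))
doc["name"] = "inflated-10pct"
inflated = load_equation_set(doc)

table = compare_equation_sets(
    cohort[cohort["sex"] == "male"], {"packaged": ise["male"], "inflated": inflated}, "fvc"
)
print("\nranking on male FVC (best first):")
print(table[["rank", "equation_set", "mean_z", "sd_z", "bias", "suitable"]].to_string(index=False))
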