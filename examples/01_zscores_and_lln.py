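"""Score one subject's spirometry against the packaged reference equations.

A 28.6-year-old, 174 cm man blows FEV1 4.10 L, FVC 4.64 L. The packaged
equations give, for each index, the predicted median for his sex/age/height,
the percent predicted, the z-score (his position in the healthy reference
distribution, in SD units) and the lower limit of normal (5th centile, the
conventional abnormality threshold). A z-score near 0 is a typical healthy
value; below about -1.645 it falls under the LLN.
"""

from spirolms import SpiroRecord, Subject, lln_for, load_ise, percent_predicted, predict_median, zscore_for

ise = load_ise("male")
subject = Subject(sex="male", age=28.57, height=174.0)
record = SpiroRecord(
    sex="male", age=28.57, height=174.0,
    fev1=4.10, fvc=4.64, fev1_fvc=4.10 / 4.64, fef2575=4.50,
)

print(f"{'index':<10}{'measured':>9}{'median':>9}{'%pred':>8}{'z':>7}{'LLN':>8}")
for index, measured in (("fev1", 4.10), ("fvc", 4.64), ("fev1_fvc", 4.10 / 4.64), ("fef2575", 4.50)):
    median = predict_median(ise, subject, index)
    print(
        f"{index:<10}{measured:>9.3f}{median:>9.3f}"
        f"{float(percent_predicted(measured, median)):>8.1f}"
        f"{zscore_for(ise, record, index):>7.2f}"
        f"{lln_for(ise, subject, index):>8.3f}"
    )
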