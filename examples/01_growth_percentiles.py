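"""Convert a child's BMI visits to age- and sex-specific percentiles.

The LMS method maps a BMI measurement to a z-score via the reference's
Box-Cox power (L), median (M) and coefficient of variation (S) at the
child's age and sex; the percentile is 100*Phi(z).  Percentiles exist only
from age 2 years, so the 18-month visit is dropped from the output.
"""

from cordbmi.growth import GrowthSeries, LMSReference, bmi_percentile, percentile_to_bmi
from cordbmi.synthetic import generate_reference

ref = LMSReference(generate_reference())

child = GrowthSeries(
    child_id="demo",
    sex="F",
    ages=[18.0, 30.0, 60.0, 120.0, 180.0],  # months
    bmi=[16.8, 16.9, 17.4, 19.5, 23.0],
)

print("visit percentiles (age >= 2y only):")
print(bmi_percentile(child, ref).round(2).to_string(index=False))

bmi85 = percentile_to_bmi(85.0, "F", 120.0, ref)
print(f"\nBMI at the 85th percentile (girl, age 10y): {bmi85:.2f} kg/m^2")
print("(values at/above this threshold are conventionally overweight)")
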