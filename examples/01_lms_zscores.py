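"""Convert heights and birthweights to SDS with the LMS method.

Builds the packaged synthetic references and converts a few measurements.
An SDS (z-score) says how many reference SDs a child is above or below
the median for her age; -2 SDS is the conventional short-stature cut-off.
"""

from turnerscreen import (
    Measurement,
    centile_to_z,
    lms_value,
    lms_zscore,
    synthetic_birthweight_reference,
    synthetic_female_height_reference,
    Sex,
)

height_ref = synthetic_female_height_reference()
bw_ref = synthetic_birthweight_reference()

for value, age in [(95.0, 4.0), (110.0, 7.5), (150.0, 20.0)]:
    z = lms_zscore(Measurement(value, age), height_ref)
    print(f"height {value:6.1f} cm at {age:4.1f} y  ->  SDS {z:+.2f}")

z = lms_zscore(Measurement(2300.0, 39.0), bw_ref)
print(f"birthweight 2300 g at 39 weeks      ->  SDS {z:+.2f}")

# the inverse transform gives centile lines: here the 3rd-centile height at 7 y
z3 = centile_to_z(3.0)
h3 = lms_value(z3, 7.0, Sex.FEMALE, height_ref)
print(f"3rd centile (z = {z3:.2f}) height at 7 y: {h3:.1f} cm")
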