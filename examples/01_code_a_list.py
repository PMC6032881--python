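"""Code a single theatre list by hand.

Builds the five-case interleaved list (two procedures alternating),
cleans it, reconstructs the list and prints the three order codes each
case receives.
"""

import pandas as pd

import theatreflow as tf

cases = ["LC", "OIH", "LC", "LC", "OIH"]
raw = pd.DataFrame(
    [
        {
            "record_id": f"r{i}",
            "surgeon_id": "S1",
            "hospital_id": "H1",
            "list_date": "2014-01-15",
            "start_time": f"{8 + i:02d}:00",
            "procedure_code": code,
            "age_group": "45-54",
            "asa_grade": "II",
            "duration_min": "60",
            "los_min": "600",
        }
        for i, code in enumerate(cases)
    ],
    dtype=str,
)

clean, summary = tf.clean_records(raw)
coded = tf.assign_list_numbers(tf.build_lists(clean))

print(coded[["procedure_code", "absolute_list_no", "procedure_specific_list_no", "switch"]])
print(f"\nswitch fraction: {tf.switch_fraction(coded):.2f}")
# The absolute number is the case's position on the list (1..5); the
# procedure-specific number counts repetitions of that procedure so far;
# switch marks any case preceded by a different procedure (3 of 5 here).
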