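"""Small factories shared by the test modules."""

import numpy as np

from hkecg.preprocess import Label, LabeledRecord


def make_subject_records(n_subjects: int, records_each: int = 2):
    return [LabeledRecord(record_id=f"S{i:03d}_r{j}", subject_id=f"S{i:03d}",
                          potassium=4.0, label=Label.NORMO,
                          signal=np.zeros(10), fs=125.0)
            for i in range(n_subjects) for j in range(records_each)]
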