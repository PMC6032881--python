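import numpy as np
import pandas as pd
import pytest

import theatreflow as tf


def make_raw(rows: list[dict]) -> pd.DataFrame:
    """Raw-record frame from partial row dicts, with sane defaults."""
    defaults = {
        "surgeon_id": "S1",
        "hospital_id": "H1",
        "list_date": "2014-01-15",
        "start_time": "09:00",
        "procedure_code": "LC",
        "age_group": "45-54",
        "asa_grade": "II",
        "duration_min": "60",
        "los_min": "600",
    }
    out = []
    for i, row in enumerate(rows):
        d = {"record_id": f"r{i}", **defaults, **row}
        out.append(d)
    return pd.DataFrame(out, columns=tf.records.RECORD_COLUMNS, dtype=str)


@pytest.fixture
def table1_raw() -> pd.DataFrame:
    """The five-case worked example: one list, two procedures interleaved."""
    codes = ["LC", "OIH", "LC", "LC", "OIH"]
    return make_raw(
        [{"procedure_code": c, "start_time": f"{8 + i:02d}:00"} for i, c in enumerate(codes)]
    )


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """A cleaned, coded ~4000-record synthetic dataset (shared, read-only)."""
    cfg = tf.GeneratorConfig(seed=77, n_lists=1000)
    raw = tf.generate_dataset(cfg)
    clean, _ = tf.clean_records(raw)
    coded = tf.assign_list_numbers(tf.build_lists(clean))
    from theatreflow.synthetic import catalogue_mapping

    return tf.classify(coded, catalogue_mapping(cfg.catalogue))


def code_raw(raw: pd.DataFrame) -> pd.DataFrame:
    clean, _ = tf.clean_records(raw)
    return tf.assign_list_numbers(tf.build_lists(clean))
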