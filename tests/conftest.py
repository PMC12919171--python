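import numpy as np
import pandas as pd
import pytest

from bbbtraj.cohort import CohortTable, DEFAULT_TIMEPOINTS


def make_table(rows, timepoint_order=("1h", "6h", "1d", "3d", "7d")):
    """Build a CohortTable from (animal_id, group, sex, timepoint, {feat: val})."""
    records = []
    feature_names = sorted({k for *_, feats in rows for k in feats})
    for animal_id, group, sex, tp, feats in rows:
        rec = {"animal_id": animal_id, "group": group, "sex": sex, "timepoint": tp}
        for f in feature_names:
            rec[f] = feats.get(f, np.nan)
        records.append(rec)
    df = pd.DataFrame(records)
    order = [tp for tp in timepoint_order if tp in set(df["timepoint"])]
    return CohortTable(df, order, {k: DEFAULT_TIMEPOINTS.get(k, 0.0) for k in order})


@pytest.fixture
def tiny_table():
    """Six injured animals at one timepoint, one fully observed feature."""
    rows = [
        ("m1", "injured", "male", "1h", {"x": 1.0}),
        ("m2", "injured", "male", "1h", {"x": 2.0}),
        ("m3", "injured", "male", "1h", {"x": 3.0}),
        ("f1", "injured", "female", "1h", {"x": 4.0}),
        ("f2", "injured", "female", "1h", {"x": 5.0}),
        ("f3", "injured", "female", "1h", {"x": 6.0}),
    ]
    return make_table(rows)
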