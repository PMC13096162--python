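import numpy as np
import pandas as pd
import pytest

from fibconn.grammar import generate
from fibconn.signals import ROI_LABELS
from fibconn.simulate import sample_cohort


@pytest.fixture(scope="session")
def generations():
    """Generations 0..15 of the default grammar."""
    return {n: generate(n=n) for n in range(16)}


@pytest.fixture(scope="session")
def cohort28():
    return sample_cohort(28, seed=11)


def make_edge_table(cohort: pd.DataFrame, gc_fn, condition: str = "pre") -> pd.DataFrame:
    """Long-form edge table with gc = gc_fn(profile_row, from_roi, to_roi)."""
    rows = []
    for _, p in cohort.iterrows():
        for a in ROI_LABELS:
            for b in ROI_LABELS:
                if a == b:
                    continue
                rows.append(
                    {
                        "participant_id": p["participant_id"],
                        "condition": condition,
                        "from_roi": a,
                        "to_roi": b,
                        "gc": float(gc_fn(p, a, b)),
                        "lsbq": p["lsbq"],
                        "age": p["age"],
                        "l2_aoa": p["l2_aoa"],
                        "education": p["education"],
                        "gender": p["gender"],
                        "handedness": p["handedness"],
                        "task_order": p["task_order"],
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_edge_table(cohort28):
    rng = np.random.default_rng(42)
    return make_edge_table(cohort28, lambda p, a, b: 0.01 + 0.002 * rng.standard_normal())
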