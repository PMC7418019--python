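import numpy as np
import pandas as pd
import pytest

from dupboard import Hospital, IndicatorPanel


def make_panel(rows, quarters=None, drug="antihypertension"):
    """Build a small IndicatorPanel from (Hospital, series) pairs."""
    n_q = len(rows[0][1])
    quarters = quarters or [str(pd.Period("2010Q3", freq="Q") + i) for i in range(n_q)]
    hospitals = [h for h, _ in rows]
    rates = pd.DataFrame(
        np.asarray([s for _, s in rows], dtype=float),
        index=pd.Index([h.id for h in hospitals], name="id"),
        columns=quarters,
    )
    return IndicatorPanel(drug=drug, hospitals=hospitals, rates=rates)


def hospital(i, htype="district", region="Central", coords=True):
    return Hospital(
        id=f"H{i:03d}",
        name=f"Hospital {i}",
        htype=htype,
        region=region,
        lat=23.5 if coords else None,
        lon=120.5 if coords else None,
    )


@pytest.fixture
def tiny_panel():
    """3 hospitals x 25 quarters, fully observed."""
    rng = np.random.default_rng(11)
    rows = [
        (hospital(1, "medical_center", "Taipei"), 0.58 + 0.01 * np.arange(25) + rng.normal(0, 0.02, 25)),
        (hospital(2, "regional", "North"), np.full(25, 0.43) + rng.normal(0, 0.02, 25)),
        (hospital(3, "district", "South"), 0.59 - 0.01 * np.arange(25) + rng.normal(0, 0.02, 25)),
    ]
    return make_panel([(h, np.maximum(0, s)) for h, s in rows])
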