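import numpy as np
import pandas as pd
import pytest

from rxpatterns import classify, cohort, synthetic
from rxpatterns.config import SimConfig


def claims_frame(rows):
    """(fill_day, drug_class, days_supply[, units]) tuples -> pharmacy frame."""
    recs = []
    for row in rows:
        day, cls, supply = row[:3]
        units = row[3] if len(row) > 3 else np.nan
        recs.append(
            {"fill_day": day, "drug_class": cls, "days_supply": supply, "units": units}
        )
    return pd.DataFrame(recs, columns=["fill_day", "drug_class", "days_supply", "units"])


@pytest.fixture(scope="session")
def small_sim():
    """A default-config simulation shared across tests (n = 600)."""
    cfg = SimConfig(n_patients=600, seed=11)
    return cfg, synthetic.simulate(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    cfg, data = small_sim
    coh, excl = cohort.build_cohort(
        data.patients, data.enrollment, data.pharmacy, data.medical, cfg.index_window
    )
    return coh, excl


@pytest.fixture(scope="session")
def small_events(small_sim, small_cohort):
    _, data = small_sim
    coh, _ = small_cohort
    return classify.classify_cohort(data.pharmacy, coh)
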