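import numpy as np
import pandas as pd
import pytest

from proxdet import AggregationConfig

WOMAN_DEFAULTS = {
    "dob_cmc": 990,
    "interview_cmc": 1338,  # age 29.0 at interview
    "currently_married": True,
    "age_at_first_marriage_years": np.nan,
    "current_method": "none",
    "amenorrheic": False,
    "abstaining": False,
    "residence": "rural",
    "education": "illiterate",
    "weight": 1.0,
}


def make_women(rows):
    """Build a women table from partial row dicts (defaults filled in)."""
    out = []
    for j, row in enumerate(rows):
        rec = dict(WOMAN_DEFAULTS)
        rec.setdefault("woman_id", f"w{j:03d}")
        rec.update(row)
        out.append(rec)
    cols = ["woman_id"] + list(WOMAN_DEFAULTS)
    return pd.DataFrame(out)[cols]


def make_births(rows):
    if not rows:
        return pd.DataFrame({"woman_id": pd.Series(dtype=str),
                             "birth_cmc": pd.Series(dtype=int)})
    return pd.DataFrame(rows)[["woman_id", "birth_cmc"]]


@pytest.fixture
def cfg():
    return AggregationConfig()


@pytest.fixture
def cfg_unweighted():
    return AggregationConfig(weighted=False)


def asfr_ledger(women, births, cfg):
    """Brute-force month-by-month exposure/births ledger.

    Independent oracle for compute_asfr on tiny fixtures: walks every
    woman through every month of her window and tallies weighted
    exposure and births per age group.
    """
    groups = [(lo * 12, hi * 12) for lo, hi in cfg.age_groups]
    W = cfg.asfr_window_months
    exposure = [0.0] * len(groups)
    n_births = [0.0] * len(groups)
    for row in women.itertuples():
        w = row.weight if cfg.weighted else 1.0
        for t in range(row.interview_cmc - W, row.interview_cmc):
            age = t - row.dob_cmc
            for k, (lo, hi) in enumerate(groups):
                if lo <= age < hi:
                    exposure[k] += w
    mothers = women.set_index("woman_id")
    for row in births.itertuples():
        mom = mothers.loc[row.woman_id]
        w = mom["weight"] if cfg.weighted else 1.0
        if mom["interview_cmc"] - W <= row.birth_cmc < mom["interview_cmc"]:
            age = row.birth_cmc - mom["dob_cmc"]
            for k, (lo, hi) in enumerate(groups):
                if lo <= age < hi:
                    n_births[k] += w
    return np.array(
        [b / (e / 12.0) if e > 0 else 0.0 for b, e in zip(n_births, exposure)]
    )
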