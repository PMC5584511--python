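"""Report shaping and rounding.

All computation elsewhere is full precision; rounding to the published
table precision (indices and MTFR to 2 decimals, percentages to 1
decimal, half-up) happens only here.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .decomposition import DecompositionResult
from .model import IndexSet

FACTOR_ORDER = ("Marriage", "PPI", "Contraception", "Residual", "Interaction")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (0.005 → 0.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def indices_table(
    indexsets: Mapping[str, Mapping[str, IndexSet]], ndigits: int = 2
) -> pd.DataFrame:
    """Index summary shaped rows = strata, columns = survey × index.

    ``indexsets`` is keyed survey → stratum → IndexSet.
    """
    surveys = list(indexsets)
    strata: list[str] = []
    for sv in surveys:
        for st in indexsets[sv]:
            if st not in strata:
                strata.append(st)
    cols = pd.MultiIndex.from_product(
        [surveys, ["Cm", "Ci", "Cc", "MTFR"]], names=["survey", "index"]
    )
    table = pd.DataFrame(index=pd.Index(strata, name="stratum"), columns=cols,
                         dtype=float)
    for sv in surveys:
        for st, idx in indexsets[sv].items():
            table.loc[st, (sv, "Cm")] = round_half_up(idx.cm, ndigits)
            table.loc[st, (sv, "Ci")] = round_half_up(idx.ci, ndigits)
            table.loc[st, (sv, "Cc")] = round_half_up(idx.cc, ndigits)
            table.loc[st, (sv, "MTFR")] = round_half_up(idx.mtfr, ndigits)
    return table


def decomposition_table(
    results: Mapping[str, Sequence[DecompositionResult]], ndigits: int = 1
) -> pd.DataFrame:
    """Long-format decomposition table.

    ``results`` is keyed stratum → list of DecompositionResult. Columns:
    period, stratum, factor, value_percent (1 decimal, half-up); the
    final factor row per block is the total fertility change (MTFR or
    TFR depending on the basis).
    """
    rows = []
    for stratum, res_list in results.items():
        for res in res_list:
            pct = res.as_percent()
            for factor, value in pct.items():
                if factor == "Residual" and res.basis == "model_tfr":
                    continue
                rows.append(
                    {
                        "period": res.period,
                        "stratum": stratum,
                        "factor": factor,
                        "value_percent": round_half_up(value, ndigits),
                    }
                )
    return pd.DataFrame(rows, columns=["period", "stratum", "factor", "value_percent"])
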