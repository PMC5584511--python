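"""Aggregate model inputs from woman-level microdata.

Everything the index model consumes is estimated here: age-specific
fertility rates f(a) from retrospective birth histories, proportions
currently married m(a), contraceptive prevalence u and method mix u(i)
among currently married women, and the mean duration of postpartum
insusceptibility i. All estimators are weighted by the sampling weight
by default and accept an optional stratum predicate.

Date arithmetic is exact in months on century-month codes; a woman's
exposure inside the fertility window is split across age groups as she
ages through it, and a birth is classified by the mother's age at the
birth, not at the interview.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import METHODS, NO_METHOD, AggregationConfig
from .errors import StratumError, UndefinedEstimateError

logger = logging.getLogger(__name__)

#: Predicate over the women table: returns a boolean mask.
StratumPredicate = Callable[[pd.DataFrame], np.ndarray]


def stratum_equals(column: str, value) -> StratumPredicate:
    """Predicate selecting women whose ``column`` equals ``value``."""

    def predicate(women: pd.DataFrame) -> np.ndarray:
        return (women[column] == value).to_numpy()

    predicate.__name__ = f"{column}=={value!r}"
    return predicate


@dataclass
class ModelInputs:
    """Aggregate quantities consumed by the index model for one universe.

    ``f`` and ``m`` are vectors over the configured age groups (births
    per woman-year and proportion currently married; ``m`` entries are
    NaN for empty groups). ``u`` is contraceptive prevalence among
    currently married women 15–49, ``mix`` the per-method proportions
    (summing to ``u``), ``i_months`` the mean postpartum-insusceptibility
    duration in months, and ``n_women`` the unweighted count of currently
    married women in the universe.
    """

    f: np.ndarray
    m: np.ndarray
    u: float
    mix: dict[str, float]
    i_months: float
    n_women: int
    label: Optional[str] = None
    stratum: Optional[str] = None
    age_groups: tuple = field(default=None)

    def validate(self) -> None:
        f = np.asarray(self.f, dtype=float)
        m = np.asarray(self.m, dtype=float)
        if f.shape != m.shape:
            raise ValueError("f and m must have the same length")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("f entries must be finite and nonnegative")
        mm = m[np.isfinite(m)]
        if np.any(mm < 0) or np.any(mm > 1):
            raise ValueError("m entries must lie in [0, 1]")
        if not 0 <= self.u <= 1:
            raise ValueError("u must lie in [0, 1]")
        if abs(sum(self.mix.values()) - self.u) > 1e-9:
            raise ValueError("method mix must sum to u")
        if any(v < 0 for v in self.mix.values()):
            raise ValueError("mix entries must be nonnegative")
        if self.i_months < 0:
            raise ValueError("i_months must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "f": [float(x) for x in self.f],
            "m": [None if not np.isfinite(x) else float(x) for x in self.m],
            "u": float(self.u),
            "mix": {k: float(v) for k, v in self.mix.items()},
            "i_months": float(self.i_months),
            "n_women": int(self.n_women),
        }

    @classmethod
    def from_dict(cls, d: Mapping, label=None, stratum=None) -> "ModelInputs":
        m = np.array(
            [np.nan if x is None else float(x) for x in d["m"]], dtype=float
        )
        obj = cls(
            f=np.asarray(d["f"], dtype=float),
            m=m,
            u=float(d["u"]),
            mix={k: float(v) for k, v in d["mix"].items()},
            i_months=float(d["i_months"]),
            n_women=int(d["n_women"]),
            label=label,
            stratum=stratum,
        )
        obj.validate()
        return obj


def _weights(women: pd.DataFrame, cfg: AggregationConfig) -> np.ndarray:
    if cfg.weighted:
        return women["weight"].to_numpy(dtype=float)
    return np.ones(len(women))


def _group_bounds_months(cfg: AggregationConfig) -> list[tuple[int, int]]:
    return [(lo * 12, hi * 12) for lo, hi in cfg.age_groups]


def compute_asfr(
    women: pd.DataFrame, births: pd.DataFrame, cfg: AggregationConfig
) -> np.ndarray:
    """Age-specific fertility rates over the retrospective window.

    For each age group a, f(a) = weighted births whose mother was in
    group a at the birth, occurring in the ``asfr_window_months`` months
    before her interview, divided by the weighted woman-years all women
    spent in group a during that window.
    """
    if len(women) == 0:
        raise ValueError("women table is empty")
    W = cfg.asfr_window_months
    bounds = _group_bounds_months(cfg)
    w = _weights(women, cfg)
    start_age = (
        women["interview_cmc"].to_numpy() - women["dob_cmc"].to_numpy() - W
    )
    exposure_months = np.empty(len(bounds))
    for k, (lo, hi) in enumerate(bounds):
        overlap = np.clip(
            np.minimum(start_age + W, hi) - np.maximum(start_age, lo), 0, None
        )
        exposure_months[k] = float(np.sum(w * overlap))

    birth_w = np.zeros(len(bounds))
    if len(births):
        cols = ["woman_id", "dob_cmc", "interview_cmc", "weight"]
        merged = births.merge(women[cols], on="woman_id", how="inner")
        bw = merged["weight"].to_numpy(dtype=float) if cfg.weighted else np.ones(
            len(merged)
        )
        in_window = (
            merged["birth_cmc"] >= merged["interview_cmc"] - W
        ) & (merged["birth_cmc"] < merged["interview_cmc"])
        age_at_birth = (merged["birth_cmc"] - merged["dob_cmc"]).to_numpy()
        for k, (lo, hi) in enumerate(bounds):
            sel = in_window.to_numpy() & (age_at_birth >= lo) & (age_at_birth < hi)
            birth_w[k] = float(np.sum(bw[sel]))

    f = np.zeros(len(bounds))
    for k in range(len(bounds)):
        if exposure_months[k] > 0:
            f[k] = birth_w[k] / (exposure_months[k] / 12.0)
        elif birth_w[k] > 0 or exposure_months[k] == 0:
            logger.warning(
                "zero exposure in age group %s; f reported as 0",
                cfg.age_groups[k],
            )
    return f


def compute_marriage_proportions(
    women: pd.DataFrame, cfg: AggregationConfig
) -> np.ndarray:
    """Proportion currently married m(a) by age group at interview.

    Empty groups yield NaN (flagged missing), never 0.
    """
    if len(women) == 0:
        raise ValueError("women table is empty")
    bounds = _group_bounds_months(cfg)
    w = _weights(women, cfg)
    age_m = women["interview_cmc"].to_numpy() - women["dob_cmc"].to_numpy()
    married = women["currently_married"].to_numpy(dtype=bool)
    m = np.full(len(bounds), np.nan)
    for k, (lo, hi) in enumerate(bounds):
        sel = (age_m >= lo) & (age_m < hi)
        denom = float(np.sum(w[sel]))
        if denom > 0:
            m[k] = float(np.sum(w[sel & married])) / denom
        else:
            logger.warning("no women in age group %s; m flagged missing", cfg.age_groups[k])
    return m


def compute_contraception_inputs(
    women: pd.DataFrame, cfg: Optional[AggregationConfig] = None
) -> tuple[float, dict[str, float]]:
    """Prevalence u and method mix u(i) on an already-restricted universe.

    The caller passes the analysis universe (currently married women
    15–49). ``mix`` maps every known method to its weighted proportion of
    the universe; the values sum to ``u``.
    """
    cfg = cfg or AggregationConfig()
    w = _weights(women, cfg)
    total = float(np.sum(w))
    mix = {meth: 0.0 for meth in METHODS}
    if total == 0:
        return 0.0, mix
    method = women["current_method"].to_numpy()
    for meth in METHODS:
        mix[meth] = float(np.sum(w[method == meth])) / total
    u = float(np.sum(w[method != NO_METHOD])) / total
    # remove float summation drift so that sum(mix) == u exactly
    s = sum(mix.values())
    if s > 0 and abs(s - u) > 0:
        mix = {k: v * (u / s) for k, v in mix.items()}
    return u, mix


def _births_in_window(
    women: pd.DataFrame, births: pd.DataFrame, W: int
) -> pd.DataFrame:
    cols = ["woman_id", "interview_cmc", "weight", "amenorrheic", "abstaining"]
    merged = births.merge(women[cols], on="woman_id", how="inner")
    sel = (merged["birth_cmc"] >= merged["interview_cmc"] - W) & (
        merged["birth_cmc"] < merged["interview_cmc"]
    )
    return merged[sel]


def compute_mean_insusceptibility(
    women: pd.DataFrame, births: pd.DataFrame, cfg: AggregationConfig
) -> float:
    """Mean duration of postpartum insusceptibility i, in months.

    ``prevalence_incidence`` (default): i = P / B, where P is the
    weighted number of currently amenorrheic-or-abstaining women among
    mothers with a birth in the window and B the weighted births in the
    window per month. Under a stationary flow of births this ratio equals
    the mean spell length (the prevalence/incidence identity).

    ``current_status_sum``: i = Σ_d p(d) over months-since-last-birth
    d = 0 … window−1, where p(d) is the weighted proportion insusceptible
    among women whose most recent birth was d months before interview.
    """
    W = cfg.asfr_window_months
    in_win = _births_in_window(women, births, W)
    bw = in_win["weight"].to_numpy(dtype=float) if cfg.weighted else np.ones(len(in_win))

    if cfg.insusceptibility_estimator == "prevalence_incidence":
        births_total = float(np.sum(bw))
        if births_total == 0:
            raise UndefinedEstimateError(
                "no births in the window; widen asfr_window_months"
            )
        B = births_total / W  # births per month
        mother_ids = set(in_win["woman_id"])
        is_mother = women["woman_id"].isin(mother_ids).to_numpy()
        insusc = (
            women["amenorrheic"].to_numpy(dtype=bool)
            | women["abstaining"].to_numpy(dtype=bool)
        )
        w = _weights(women, cfg)
        P = float(np.sum(w[is_mother & insusc]))
        return P / B

    # current_status_sum
    cols = ["woman_id", "interview_cmc", "weight", "amenorrheic", "abstaining"]
    merged = births.merge(women[cols], on="woman_id", how="inner")
    last = merged.groupby("woman_id").agg(
        birth_cmc=("birth_cmc", "max"),
        interview_cmc=("interview_cmc", "first"),
        weight=("weight", "first"),
        amenorrheic=("amenorrheic", "first"),
        abstaining=("abstaining", "first"),
    )
    d = (last["interview_cmc"] - last["birth_cmc"]).to_numpy()
    keep = (d >= 0) & (d < W)
    last = last[keep]
    d = d[keep]
    w = last["weight"].to_numpy(dtype=float) if cfg.weighted else np.ones(len(last))
    insusc = (
        last["amenorrheic"].to_numpy(dtype=bool)
        | last["abstaining"].to_numpy(dtype=bool)
    )
    total = 0.0
    for dur in range(W):
        sel = d == dur
        denom = float(np.sum(w[sel]))
        if denom > 0:
            total += float(np.sum(w[sel & insusc])) / denom
    return total


def aggregate(
    women: pd.DataFrame,
    births: pd.DataFrame,
    cfg: Optional[AggregationConfig] = None,
    stratum: Optional[StratumPredicate] = None,
    label: Optional[str] = None,
) -> ModelInputs:
    """Estimate all model inputs on one (optionally stratified) universe.

    Fertility and marriage proportions use every selected woman;
    contraceptive prevalence/mix and insusceptibility use the currently
    married subset, matching the analysis universe of the index model.
    """
    cfg = cfg or AggregationConfig()
    stratum_name = None
    if stratum is not None:
        mask = np.asarray(stratum(women), dtype=bool)
        stratum_name = getattr(stratum, "__name__", "predicate")
        women = women[mask]
        if len(women) == 0:
            raise StratumError(f"stratum {stratum_name} selects no women")
        births = births[births["woman_id"].isin(set(women["woman_id"]))]
    if len(women) == 0:
        raise StratumError("empty universe")

    married = women[women["currently_married"]]
    married_births = births[births["woman_id"].isin(set(married["woman_id"]))]

    f = compute_asfr(women, births, cfg)
    m = compute_marriage_proportions(women, cfg)
    u, mix = compute_contraception_inputs(married, cfg)
    try:
        i_months = compute_mean_insusceptibility(married, married_births, cfg)
    except UndefinedEstimateError:
        if births.empty and (
            not women["amenorrheic"].any() and not women["abstaining"].any()
        ):
            i_months = 0.0
        else:
            raise
    inputs = ModelInputs(
        f=f,
        m=m,
        u=u,
        mix=mix,
        i_months=i_months,
        n_women=int(len(married)),
        label=label,
        stratum=stratum_name,
        age_groups=cfg.age_groups,
    )
    inputs.validate()
    return inputs
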