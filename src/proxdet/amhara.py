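"""Published aggregate inputs for Amhara National Regional State, Ethiopia.

These are the survey-report aggregates for currently married women aged
15–49 from the 2000, 2005 and 2011 Ethiopia Demographic and Health
Surveys (Amhara region): modern contraceptive prevalence and method mix
(percent of currently married women), mean durations of postpartum
amenorrhea, abstinence and insusceptibility (months), and the number of
currently married respondents. They are the printed inputs the index
model runs on when no microdata are available, plus the published index
values used as cross-checks.

The 2000 method-mix percentages sum to 6.7 while the published
prevalence is 6.6 (independent rounding in the source);
:func:`contraception_inputs` rescales the mix proportionally so it sums
to the published prevalence. The contraception index is unaffected at
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

SURVEY_YEARS = ("2000", "2005", "2011")


@dataclass(frozen=True)
class SurveyAggregates:
    """Published aggregates for one survey (total, currently married 15–49)."""

    year: str
    u_percent: float                      # modern contraceptive prevalence, %
    mix_percent: Mapping[str, float]      # method -> % of married women
    amenorrhea_months: float
    abstinence_months: float
    insusceptibility_months: float
    n_observations: int
    median_age_first_marriage: float
    published_cm: float
    published_ci: float
    published_cc: float
    published_mtfr: float
    observed_tfr: float | None            # region-level survey TFR where published


SURVEYS: dict[str, SurveyAggregates] = {
    "2000": SurveyAggregates(
        year="2000",
        u_percent=6.6,
        mix_percent={
            "sterilization_f": 0.2,
            "pill": 3.0,
            "iud": 0.0,
            "injectable": 3.4,
            "implant": 0.1,
            "condom_m": 0.0,
            "other": 0.0,
        },
        amenorrhea_months=22.4,
        abstinence_months=2.2,
        insusceptibility_months=22.6,
        n_observations=2587,
        median_age_first_marriage=14.5,
        published_cm=0.71,
        published_ci=0.49,
        published_cc=0.93,
        published_mtfr=5.50,
        observed_tfr=5.9,
    ),
    "2005": SurveyAggregates(
        year="2005",
        u_percent=15.7,
        mix_percent={
            "sterilization_f": 0.1,
            "pill": 3.6,
            "iud": 0.1,
            "injectable": 11.7,
            "implant": 0.1,
            "condom_m": 0.1,
            "other": 0.0,
        },
        amenorrhea_months=20.8,
        abstinence_months=2.4,
        insusceptibility_months=21.4,
        n_observations=2330,
        median_age_first_marriage=14.4,
        published_cm=0.73,
        published_ci=0.50,
        published_cc=0.83,
        published_mtfr=5.12,
        observed_tfr=None,
    ),
    "2011": SurveyAggregates(
        year="2011",
        u_percent=33.0,
        mix_percent={
            "sterilization_f": 0.6,
            "pill": 1.5,
            "iud": 0.3,
            "injectable": 26.5,
            "implant": 4.0,
            "condom_m": 0.1,
            "other": 0.0,
        },
        amenorrhea_months=18.4,
        abstinence_months=2.7,
        insusceptibility_months=19.0,
        n_observations=2776,
        median_age_first_marriage=15.1,
        published_cm=0.70,
        published_ci=0.54,
        published_cc=0.65,
        published_mtfr=4.20,
        observed_tfr=4.2,
    ),
}


def contraception_inputs(year: str) -> tuple[float, dict[str, float]]:
    """Prevalence u and method mix u(i) as proportions summing to u.

    The published per-method percentages are rescaled proportionally so
    their sum equals the published prevalence exactly (they can differ
    in the last printed digit through independent rounding).
    """
    s = SURVEYS[year]
    u = s.u_percent / 100.0
    mix = {k: v / 100.0 for k, v in s.mix_percent.items()}
    total = sum(mix.values())
    if total > 0:
        mix = {k: v * (u / total) for k, v in mix.items()}
    return u, mix


def user_mix_weights(year: str) -> dict[str, float]:
    """Method distribution among users (weights summing to 1)."""
    s = SURVEYS[year]
    total = sum(s.mix_percent.values())
    return {k: v / total for k, v in s.mix_percent.items() if v > 0}
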