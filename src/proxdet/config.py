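"""Configuration objects: aggregation settings, model constants, effectiveness.

The model constants follow the classical Bongaarts parameterisation:
total fecundity TF ≈ 15.3 births per woman, the 1.08 sterility
adjustment in the contraception index, and the 20 / 18.5-month birth
interval constants in the insusceptibility index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Contraceptive method codes recognised in microdata (besides ``none``).
METHODS: tuple[str, ...] = (
    "sterilization_f",
    "pill",
    "iud",
    "injectable",
    "implant",
    "condom_m",
    "other",
)
NO_METHOD = "none"

RESIDENCE_LEVELS: tuple[str, ...] = ("urban", "rural")
EDUCATION_LEVELS: tuple[str, ...] = ("illiterate", "primary", "secondary_plus")

#: Seven conventional five-year reproductive age groups, half-open [a, a+5).
DEFAULT_AGE_GROUPS: tuple[tuple[int, int], ...] = tuple(
    (a, a + 5) for a in range(15, 50, 5)
)

#: Method use-effectiveness e(i). Pill 0.90, IUD 0.95, female sterilization
#: 1.00, male condom 0.62 and "other" 0.70 are the classical Bongaarts
#: values; injectables and implants are long-acting hormonal methods and
#: carry 1.00 by default (overridable).
DEFAULT_EFFECTIVENESS: Mapping[str, float] = {
    "pill": 0.90,
    "iud": 0.95,
    "sterilization_f": 1.00,
    "condom_m": 0.62,
    "injectable": 1.00,
    "implant": 1.00,
    "other": 0.70,
}


@dataclass(frozen=True)
class AggregationConfig:
    """Settings for the microdata aggregation stage.

    Parameters
    ----------
    asfr_window_months:
        Length of the retrospective fertility window before each woman's
        interview, in months. 36 months matches the three-year rates DHS
        reports publish.
    age_groups:
        Ordered, disjoint half-open intervals in years covering [15, 50).
    insusceptibility_estimator:
        ``prevalence_incidence`` (current-status prevalence divided by
        mean monthly births — the standard DHS estimator) or
        ``current_status_sum`` (sum over months-since-birth of the
        proportion still insusceptible).
    weighted:
        Use sampling weights (default). Unweighted mode exists for
        oracle tests against hand counts.
    min_m_for_g:
        Proportion married below which an age group's marital fertility
        rate g(a) = f(a)/m(a) is considered unstable.
    g_unstable_rule:
        How to handle a fertile group with unstable m(a): ``impute``
        (g = 0.75 × g of the next older stable group), ``drop``
        (exclude the group) or ``error``.
    """

    asfr_window_months: int = 36
    age_groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS
    insusceptibility_estimator: str = "prevalence_incidence"
    weighted: bool = True
    min_m_for_g: float = 0.01
    g_unstable_rule: str = "impute"

    def __post_init__(self) -> None:
        if self.asfr_window_months <= 0:
            raise ConfigurationError("asfr_window_months must be positive")
        if self.insusceptibility_estimator not in (
            "prevalence_incidence",
            "current_status_sum",
        ):
            raise ConfigurationError(
                f"unknown insusceptibility_estimator "
                f"{self.insusceptibility_estimator!r}"
            )
        if self.g_unstable_rule not in ("impute", "drop", "error"):
            raise ConfigurationError(
                f"unknown g_unstable_rule {self.g_unstable_rule!r}"
            )
        if not 0 < self.min_m_for_g < 1:
            raise ConfigurationError("min_m_for_g must lie in (0, 1)")
        groups = tuple(tuple(g) for g in self.age_groups)
        for (lo, hi) in groups:
            if hi <= lo:
                raise ConfigurationError(f"degenerate age group [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(groups, groups[1:]):
            if lo2 != hi:
                raise ConfigurationError("age groups must be contiguous and ordered")
        if groups[0][0] != 15 or groups[-1][1] != 50:
            raise ConfigurationError("age groups must cover [15, 50)")
        object.__setattr__(self, "age_groups", groups)


@dataclass(frozen=True)
class EffectivenessTable:
    """Method → use-effectiveness map e(i), each value in [0, 1]."""

    values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTIVENESS)
    )

    def __post_init__(self) -> None:
        for method, e in self.values.items():
            if not 0.0 <= e <= 1.0:
                raise ConfigurationError(
                    f"effectiveness of {method!r} must be in [0, 1], got {e}"
                )

    def __getitem__(self, method: str) -> float:
        try:
            return self.values[method]
        except KeyError:
            raise ConfigurationError(
                f"no effectiveness entry for method {method!r}"
            ) from None

    def with_overrides(self, overrides: Mapping[str, float]) -> "EffectivenessTable":
        merged = dict(self.values)
        merged.update(overrides)
        return EffectivenessTable(merged)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed constants of the aggregate fertility model.

    ``tf`` is total fecundity (births per woman in the absence of
    marriage limits, contraception, abortion and postpartum
    insusceptibility beyond 1.5 months); empirical populations fall in
    [13, 17] with mean ≈ 15.3. ``sterility_adjustment`` removes infecund
    couples from the contraception index so that it reaches zero at an
    effective prevalence of 92.5% (1/1.08). ``birth_interval_no_ppi`` and
    ``interval_base`` are the 20- and 18.5-month birth-interval constants
    of the insusceptibility index. ``ca`` is the induced-abortion index,
    fixed at 1 (no data on abortion incidence).
    """

    tf: float = 15.3
    sterility_adjustment: float = 1.08
    birth_interval_no_ppi: float = 20.0
    interval_base: float = 18.5
    ca: float = 1.0

    def __post_init__(self) -> None:
        if self.tf <= 0:
            raise ConfigurationError("total fecundity tf must be positive")
        if not 13.0 <= self.tf <= 17.0:
            warnings.warn(
                f"total fecundity tf={self.tf} is outside the empirical "
                "range [13, 17]",
                stacklevel=2,
            )
        if not 0.0 <= self.ca <= 1.0:
            raise ConfigurationError("ca must lie in [0, 1]")


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Recognised keys: ``effectiveness`` (method → e(i) overrides), ``tf``,
    ``ca``, ``asfr_window_months``, ``insusceptibility_estimator``,
    ``weighted``, ``min_m_for_g``, ``g_unstable_rule``. Returns a dict
    with instantiated ``aggregation``, ``effectiveness`` and
    ``constants`` objects.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a YAML mapping")
    return build_config(raw)


def build_config(raw: Mapping) -> dict:
    agg_keys = (
        "asfr_window_months",
        "insusceptibility_estimator",
        "weighted",
        "min_m_for_g",
        "g_unstable_rule",
    )
    agg = replace(
        AggregationConfig(), **{k: raw[k] for k in agg_keys if k in raw}
    )
    eff = EffectivenessTable().with_overrides(raw.get("effectiveness", {}) or {})
    const_keys = ("tf", "ca")
    constants = replace(
        ModelConstants(), **{k: raw[k] for k in const_keys if k in raw}
    )
    return {"aggregation": agg, "effectiveness": eff, "constants": constants}
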