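"""Decomposition of fertility change into proximate-determinant components.

For two time points t1, t2 the ratio of total fertility rates factors as

    TFR(t2)/TFR(t1) = Cm(t2)/Cm(t1) · Ci(t2)/Ci(t1) · Cc(t2)/Cc(t1) · R(t2)/R(t1)

where R(t) = TFR(t) / (TF·Cm·Cc·Ca·Ci) is a residual factor absorbing
the proximate variables outside the model (fecundability, intrauterine
mortality, sterility). Each component's proportional change is its ratio
minus one (P_m, P_i, P_c, P_r); the total proportional fertility change
P_f closes additively through an interaction term:

    P_f = P_m + P_i + P_c + P_r + I.

The interaction is always computed as this additive closure, which stays
exact even when the inputs are externally rounded index values. Negative
percentages mark determinants that inhibited fertility over the period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .config import ModelConstants
from .errors import ConfigurationError, UndefinedEstimateError
from .model import IndexSet


@dataclass(frozen=True)
class DecompositionResult:
    """Proportional changes (fractions, not percent) between two surveys."""

    pf: float
    pm: float
    pi_: float
    pc: float
    pr: float
    interaction: float
    basis: str  # "model_tfr" | "observed_tfr"
    label1: Optional[str] = None
    label2: Optional[str] = None

    def __post_init__(self) -> None:
        closure = self.pm + self.pi_ + self.pc + self.pr + self.interaction
        if abs(self.pf - closure) > 1e-12:
            raise ValueError("components must close additively to pf")

    @property
    def period(self) -> str:
        return f"{self.label1}-{self.label2}"

    def as_percent(self) -> dict[str, float]:
        return {
            "Marriage": 100 * self.pm,
            "PPI": 100 * self.pi_,
            "Contraception": 100 * self.pc,
            "Residual": 100 * self.pr,
            "Interaction": 100 * self.interaction,
            "MTFR" if self.basis == "model_tfr" else "TFR": 100 * self.pf,
        }


def residual_factor(
    tfr_observed: float, idx: IndexSet, k: Optional[ModelConstants] = None
) -> float:
    """R = observed TFR / (TF·Cm·Cc·Ca·Ci)."""
    tf = k.tf if k is not None else idx.tf
    denom = tf * idx.cm * idx.cc * idx.ca * idx.ci
    if denom == 0:
        raise UndefinedEstimateError(
            "residual factor undefined: an index is zero"
        )
    if tfr_observed <= 0:
        raise ValueError("observed TFR must be positive")
    return tfr_observed / denom


def decompose(
    idx1: IndexSet,
    idx2: IndexSet,
    tfr1: Optional[float] = None,
    tfr2: Optional[float] = None,
) -> DecompositionResult:
    """Decompose the fertility change from ``idx1`` to ``idx2``.

    Without observed TFRs the change in the model TFR is decomposed and
    the residual term is zero; with both observed TFRs supplied the
    observed change is decomposed and the residual ratio absorbs what
    the indices do not explain.
    """
    if idx1.tf != idx2.tf or idx1.ca != idx2.ca:
        raise ConfigurationError(
            "both index sets must be computed with the same model constants"
        )
    if (tfr1 is None) != (tfr2 is None):
        raise ConfigurationError(
            "observed TFRs must be supplied for both surveys or neither"
        )
    for name, (a, b) in {
        "cm": (idx1.cm, idx2.cm),
        "ci": (idx1.ci, idx2.ci),
        "cc": (idx1.cc, idx2.cc),
    }.items():
        if a == 0:
            raise UndefinedEstimateError(f"cannot decompose: {name}(t1) = 0")
    pm = idx2.cm / idx1.cm - 1.0
    pi_ = idx2.ci / idx1.ci - 1.0
    pc = idx2.cc / idx1.cc - 1.0
    if tfr1 is not None:
        basis = "observed_tfr"
        r1 = residual_factor(tfr1, idx1)
        r2 = residual_factor(tfr2, idx2)
        pr = r2 / r1 - 1.0
        pf = tfr2 / tfr1 - 1.0
    else:
        basis = "model_tfr"
        pr = 0.0
        if idx1.mtfr == 0:
            raise UndefinedEstimateError("cannot decompose: mtfr(t1) = 0")
        pf = idx2.mtfr / idx1.mtfr - 1.0
    interaction = pf - (pm + pi_ + pc + pr)
    return DecompositionResult(
        pf=pf, pm=pm, pi_=pi_, pc=pc, pr=pr, interaction=interaction,
        basis=basis, label1=idx1.label, label2=idx2.label,
    )


def decompose_series(
    indexsets: Mapping[str, IndexSet],
    pairs: Sequence[tuple[str, str]],
    observed_tfr: Optional[Mapping[str, float]] = None,
) -> list[DecompositionResult]:
    """One decomposition per ordered survey pair.

    ``observed_tfr``, when given, must cover every survey referenced in
    ``pairs``; the decomposition then runs on the observed basis.
    """
    results = []
    for a, b in pairs:
        for lbl in (a, b):
            if lbl not in indexsets:
                raise LookupError(f"unknown survey label {lbl!r}")
        idx1 = indexsets[a]
        idx2 = indexsets[b]
        if idx1.label is None:
            idx1 = IndexSet(**{**idx1.__dict__, "label": a})
        if idx2.label is None:
            idx2 = IndexSet(**{**idx2.__dict__, "label": b})
        t1 = t2 = None
        if observed_tfr is not None:
            try:
                t1, t2 = observed_tfr[a], observed_tfr[b]
            except KeyError as exc:
                raise LookupError(f"no observed TFR for survey {exc}") from None
        results.append(decompose(idx1, idx2, t1, t2))
    return results
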