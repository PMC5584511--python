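"""The multiplicative proximate-determinants fertility model.

Total fertility is expressed as the product

    TFR = TF · Cm · Cc · Ca · Ci

where TF is total fecundity and the four indices in [0, 1] measure the
fertility-inhibiting effect of marriage patterns (Cm), contraception
(Cc), induced abortion (Ca, fixed at 1 here) and postpartum
insusceptibility (Ci). One minus an index is the proportionate fertility
reduction attributed to that determinant.

    Cm = Σ m(a)·g(a) / Σ g(a),   g(a) = f(a) / m(a)
    Cc = 1 − 1.08·u·e,           e = Σ e(i)·u(i) / u
    Ci = 20 / (18.5 + i)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .aggregation import ModelInputs
from .config import AggregationConfig, EffectivenessTable, ModelConstants
from .errors import UndefinedEstimateError, UnstableEstimateError


@dataclass(frozen=True)
class IndexSet:
    """The four indices plus total fecundity and the model TFR.

    ``from_indices`` guarantees ``mtfr == tf·cm·cc·ca·ci`` exactly;
    direct construction also accepts externally supplied (e.g. rounded,
    published) values, whose internal consistency can be checked with
    :meth:`consistent`.
    """

    cm: float
    cc: float
    ci: float
    ca: float
    tf: float
    mtfr: float
    e_bar: float = float("nan")
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("cm", "cc", "ci", "ca"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.mtfr <= self.tf + 1e-12:
            raise ValueError(f"mtfr={self.mtfr} outside [0, tf={self.tf}]")

    @classmethod
    def from_indices(
        cls,
        cm: float,
        cc: float,
        ci: float,
        ca: float = 1.0,
        tf: float = 15.3,
        e_bar: float = float("nan"),
        label: Optional[str] = None,
    ) -> "IndexSet":
        mtfr = compute_mtfr(cm, cc, ci, ca, ModelConstants(tf=tf, ca=ca))
        return cls(cm=cm, cc=cc, ci=ci, ca=ca, tf=tf, mtfr=mtfr,
                   e_bar=e_bar, label=label)

    def product(self) -> float:
        """tf · cm · cc · ca · ci (may differ from a user-supplied mtfr)."""
        return self.tf * self.cm * self.cc * self.ca * self.ci

    def consistent(self, tol: float = 1e-12) -> bool:
        return abs(self.mtfr - self.product()) <= tol

    def to_dict(self) -> dict:
        return {
            "cm": self.cm,
            "cc": self.cc,
            "ci": self.ci,
            "ca": self.ca,
            "tf": self.tf,
            "mtfr": self.mtfr,
            "e_bar": None if math.isnan(self.e_bar) else self.e_bar,
        }

    @classmethod
    def from_dict(cls, d: Mapping, label=None) -> "IndexSet":
        e_bar = d.get("e_bar")
        return cls(
            cm=float(d["cm"]),
            cc=float(d["cc"]),
            ci=float(d["ci"]),
            ca=float(d.get("ca", 1.0)),
            tf=float(d.get("tf", 15.3)),
            mtfr=float(d["mtfr"]),
            e_bar=float("nan") if e_bar is None else float(e_bar),
            label=label,
        )


def compute_cm(
    f: np.ndarray, m: np.ndarray, cfg: Optional[AggregationConfig] = None
) -> float:
    """Index of marriage Cm = Σ m(a)g(a) / Σ g(a) = Σ f(a) / Σ f(a)/m(a).

    Groups with f(a) = 0 contribute nothing. A fertile group whose
    proportion married falls below ``cfg.min_m_for_g`` has an unstable
    marital fertility rate g(a); it is handled per ``cfg.g_unstable_rule``
    (default: impute g(a) = 0.75 × g of the next older stable group, the
    standard correction for the small-denominator instability at young
    ages).
    """
    cfg = cfg or AggregationConfig()
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    if f.shape != m.shape:
        raise ValueError("f and m must have the same length")
    fertile = f > 0
    if not fertile.any():
        raise ValueError("at least one age group must have f(a) > 0")
    stable = fertile & np.isfinite(m) & (m >= cfg.min_m_for_g)
    unstable = fertile & ~stable
    if not stable.any():
        raise UnstableEstimateError(
            "every fertile age group has an unstable proportion married"
        )
    g = np.zeros_like(f)
    g[stable] = f[stable] / m[stable]
    include = stable.copy()
    for k in np.flatnonzero(unstable):
        if cfg.g_unstable_rule == "error":
            raise UnstableEstimateError(
                f"unstable g(a) in age group {k} (m={m[k]!r}, f={f[k]!r})"
            )
        if cfg.g_unstable_rule == "drop":
            warnings.warn(
                f"dropping age group {k} from Cm: unstable proportion married",
                stacklevel=2,
            )
            continue
        # impute: borrow three quarters of the next older stable group's g
        donor = next((j for j in range(k + 1, len(f)) if stable[j]), None)
        if donor is None:
            raise UnstableEstimateError(
                f"cannot impute g(a) for group {k}: no older stable group"
            )
        g[k] = 0.75 * g[donor]
        include[k] = True
        warnings.warn(
            f"imputed g(a) for age group {k} as 0.75 x g(group {donor})",
            stacklevel=2,
        )
    num = float(np.sum(f[include]))
    den = float(np.sum(g[include]))
    if den <= 0:
        raise UnstableEstimateError("marital fertility sums to zero")
    cm = num / den
    if cm > 1.0:
        warnings.warn(f"Cm={cm:.4f} > 1 clipped to 1", stacklevel=2)
        cm = 1.0
    return cm


def compute_e(
    mix: Mapping[str, float], u: float, eff: Optional[EffectivenessTable] = None
) -> float:
    """Average use-effectiveness e = Σ e(i)·u(i) / u."""
    eff = eff or EffectivenessTable()
    if u <= 0:
        raise UndefinedEstimateError(
            "average effectiveness is undefined at zero prevalence"
        )
    total = sum(mix.values())
    if abs(total - u) > 1e-9:
        raise ValueError(f"method mix sums to {total}, expected u={u}")
    return sum(eff[meth] * ui for meth, ui in mix.items() if ui > 0) / u


def compute_cc(
    u: float, e_bar: float, k: Optional[ModelConstants] = None
) -> float:
    """Index of contraception Cc = 1 − 1.08·u·e, clipped to [0, 1]."""
    k = k or ModelConstants()
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u={u} outside [0, 1]")
    if u == 0:
        return 1.0
    if not 0.0 <= e_bar <= 1.0:
        raise ValueError(f"e_bar={e_bar} outside [0, 1]")
    cc = 1.0 - k.sterility_adjustment * u * e_bar
    if cc < 0.0:
        warnings.warn(
            f"effective prevalence u·e={u * e_bar:.4f} exceeds "
            f"{1 / k.sterility_adjustment:.4f}; Cc clipped to 0",
            stacklevel=2,
        )
        cc = 0.0
    return cc


def compute_ci(i_months: float, k: Optional[ModelConstants] = None) -> float:
    """Index of postpartum insusceptibility Ci = 20 / (18.5 + i)."""
    k = k or ModelConstants()
    if i_months < 0:
        raise ValueError(f"i_months={i_months} must be nonnegative")
    return k.birth_interval_no_ppi / (k.interval_base + i_months)


def compute_mtfr(
    cm: float, cc: float, ci: float, ca: float = 1.0,
    k: Optional[ModelConstants] = None,
) -> float:
    """Model total fertility rate TF·Cm·Cc·Ca·Ci."""
    k = k or ModelConstants()
    for name, v in (("cm", cm), ("cc", cc), ("ci", ci), ("ca", ca)):
        if not 0.0 <= v <= 1.0 + 1e-12:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return k.tf * cm * cc * ca * ci


def indices_from_inputs(
    inputs: ModelInputs,
    eff: Optional[EffectivenessTable] = None,
    k: Optional[ModelConstants] = None,
    cfg: Optional[AggregationConfig] = None,
) -> IndexSet:
    """Compute the full index set from aggregate model inputs."""
    eff = eff or EffectivenessTable()
    k = k or ModelConstants()
    cfg = cfg or AggregationConfig()
    inputs.validate()
    cm = compute_cm(inputs.f, inputs.m, cfg)
    if inputs.u > 0:
        e_bar = compute_e(inputs.mix, inputs.u, eff)
    else:
        e_bar = float("nan")
    cc = compute_cc(inputs.u, e_bar, k)
    ci = compute_ci(inputs.i_months, k)
    # Ci may exceed 1 when i < 1.5 months (shorter than the natural
    # minimum the 20/18.5 constants assume); cap at 1 for index semantics.
    ci = min(ci, 1.0)
    return IndexSet.from_indices(
        cm=cm, cc=cc, ci=ci, ca=k.ca, tf=k.tf, e_bar=e_bar, label=inputs.label
    )
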