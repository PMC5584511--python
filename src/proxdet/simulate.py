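"""Synthetic DHS-like microdata with known proximate-determinant truth.

The generator simulates each woman's reproductive history month by month
backwards-compatible with the aggregation schema, so that every pipeline
stage has a parameter-recovery test without any survey download. The
default configuration mirrors the 2011 Amhara survey conditions:
prevalence 33.0% with the published method mix among users, mean
postpartum insusceptibility 19.0 months, and an early-marriage age
schedule.

Mechanics: a woman's age at interview is uniform over [15, 50) in
months; she is currently married with the age-group probability
``m_by_age`` and, if married, a contraceptive user with probability
``u_target`` (method drawn from ``mix_weights``). Her history runs over
``burn_in_months + window_months`` months; while married, aged 15+, not
pregnant and not postpartum-insusceptible she conceives with monthly
probability ``natural_fecundability × (1 − e(method))``. Gestation is
nine months; each birth starts an insusceptible spell drawn from an
exponential capped at ``insusceptibility_cap_months``, whose scale is
solved so the realised mean equals ``i_mean_months`` exactly. The
amenorrheic flag records spell state at interview; weights are 1.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import __version__
from .aggregation import aggregate
from .config import (
    METHODS,
    NO_METHOD,
    AggregationConfig,
    EffectivenessTable,
    ModelConstants,
)
from .errors import ConfigurationError
from .io import write_microdata
from .model import compute_cc, compute_ci, indices_from_inputs

#: 2011 Amhara method distribution among users (injectables dominate).
DEFAULT_MIX_WEIGHTS: Mapping[str, float] = {
    "injectable": 26.5 / 33.0,
    "implant": 4.0 / 33.0,
    "pill": 1.5 / 33.0,
    "sterilization_f": 0.6 / 33.0,
    "iud": 0.3 / 33.0,
    "condom_m": 0.1 / 33.0,
}

#: Early-marriage age schedule m(a) plausible for the study region
#: (median age at first marriage ~15, near-universal marriage by the
#: late twenties, modest attrition at older ages from widowhood/divorce).
DEFAULT_M_BY_AGE: tuple[float, ...] = (0.45, 0.80, 0.90, 0.92, 0.90, 0.85, 0.80)


@dataclass(frozen=True)
class StratumSpec:
    """Per-stratum overrides for a two-or-more stratum population."""

    residence: str = "rural"
    education: str = "illiterate"
    share: float = 1.0
    overrides: Mapping = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticConfig:
    n_women: int = 8000
    seed: int = 0
    interview_cmc: int = 1338            # mid-2011
    m_by_age: tuple[float, ...] = DEFAULT_M_BY_AGE
    u_target: float = 0.330
    mix_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX_WEIGHTS)
    )
    i_mean_months: float = 19.0
    natural_fecundability: float = 0.20
    window_months: int = 60
    burn_in_months: int = 60
    insusceptibility_cap_months: int = 36
    residence: str = "rural"
    education: str = "illiterate"
    strata_specs: Optional[Sequence[StratumSpec]] = None

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise ConfigurationError("n_women must be positive")
        if len(self.m_by_age) != 7:
            raise ConfigurationError("m_by_age must have 7 entries")
        if not all(0.0 <= p <= 1.0 for p in self.m_by_age):
            raise ConfigurationError("m_by_age entries must lie in [0, 1]")
        if not 0.0 <= self.u_target <= 1.0:
            raise ConfigurationError("u_target must lie in [0, 1]")
        if self.u_target > 0 and all(p == 0 for p in self.m_by_age):
            raise ConfigurationError(
                "infeasible: u_target > 0 with nobody married"
            )
        if self.i_mean_months < 0:
            raise ConfigurationError("i_mean_months must be nonnegative")
        if self.i_mean_months >= self.insusceptibility_cap_months:
            raise ConfigurationError(
                "i_mean_months must be below insusceptibility_cap_months"
            )
        if self.u_target > 0:
            total = sum(self.mix_weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError("mix_weights must sum to 1")
            unknown = set(self.mix_weights) - set(METHODS)
            if unknown:
                raise ConfigurationError(f"unknown methods in mix: {unknown}")
        if not 0.0 < self.natural_fecundability <= 1.0:
            raise ConfigurationError("natural_fecundability must be in (0, 1]")
        if self.window_months <= 0 or self.burn_in_months < 0:
            raise ConfigurationError("invalid history lengths")


def _capped_exponential_scale(target_mean: float, cap: float) -> float:
    """Scale s such that E[min(Exp(s), cap)] = s·(1 − exp(−cap/s)) = target."""
    if target_mean <= 0:
        return 0.0
    if target_mean >= cap:
        raise ConfigurationError("target mean must be below the cap")
    return brentq(
        lambda s: s * (1.0 - math.exp(-cap / s)) - target_mean, 1e-9, 1e9,
        xtol=1e-10,
    )


def true_indices(cfg: SyntheticConfig, eff: Optional[EffectivenessTable] = None,
                 k: Optional[ModelConstants] = None) -> dict[str, float]:
    """Index values implied by the generator's parameters.

    Cm uses a flat marital-fertility weighting (the generator's single
    fecundability constant makes g(a) approximately age-invariant), so
    the true index of marriage is the unweighted mean of ``m_by_age``.
    """
    eff = eff or EffectivenessTable()
    k = k or ModelConstants()
    e_true = (
        sum(eff[m] * w for m, w in cfg.mix_weights.items())
        if cfg.u_target > 0
        else float("nan")
    )
    cc = compute_cc(cfg.u_target, e_true if cfg.u_target > 0 else 0.0, k)
    ci = min(compute_ci(cfg.i_mean_months, k), 1.0)
    cm = float(np.mean(cfg.m_by_age))
    return {"cm": cm, "cc": cc, "ci": ci, "e_bar": e_true}


def _simulate_block(
    cfg: SyntheticConfig,
    n: int,
    rng: np.random.Generator,
    eff: EffectivenessTable,
    id_offset: int,
    residence: str,
    education: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    itv = cfg.interview_cmc
    age_m = rng.integers(180, 600, size=n)
    dob = itv - age_m
    gidx = age_m // 60 - 3
    m_arr = np.asarray(cfg.m_by_age, dtype=float)
    married = rng.random(n) < m_arr[gidx]
    user = married & (rng.random(n) < cfg.u_target)
    method = np.full(n, NO_METHOD, dtype=object)
    if user.any():
        names = list(cfg.mix_weights)
        probs = np.array([cfg.mix_weights[m] for m in names], dtype=float)
        probs = probs / probs.sum()
        method[user] = rng.choice(names, size=int(user.sum()), p=probs)
    eff_arr = np.array([eff[m] if m != NO_METHOD else 0.0 for m in method])
    p_conceive = cfg.natural_fecundability * (1.0 - eff_arr)

    scale = _capped_exponential_scale(
        cfg.i_mean_months, cfg.insusceptibility_cap_months
    )
    preg = np.zeros(n, dtype=int)     # months of gestation remaining
    insusc = np.zeros(n, dtype=int)   # insusceptible months remaining
    start = itv - cfg.window_months - cfg.burn_in_months
    rows_id: list[int] = []
    rows_cmc: list[int] = []
    for t in range(start, itv):
        deliver = preg == 1
        if deliver.any():
            nd = int(deliver.sum())
            if t >= itv - cfg.window_months:
                rows_id.extend(np.flatnonzero(deliver).tolist())
                rows_cmc.extend([t] * nd)
            if scale > 0:
                d = np.minimum(
                    rng.exponential(scale, nd),
                    float(cfg.insusceptibility_cap_months),
                )
                # unbiased integer months: floor plus Bernoulli(frac)
                frac = d - np.floor(d)
                dur = np.floor(d).astype(int) + (rng.random(nd) < frac)
            else:
                dur = np.zeros(nd, dtype=int)
            insusc[deliver] = dur
            preg[deliver] = 0
        ongoing = preg > 1
        preg[ongoing] -= 1
        waning = (insusc > 0) & ~deliver
        insusc[waning] -= 1
        exposed = (
            married
            & (preg == 0)
            & (insusc == 0)
            & ((t - dob) >= 180)
        )
        conceive = exposed & (rng.random(n) < p_conceive)
        preg[conceive] = 9

    amen = insusc > 0
    age_years = age_m / 12.0
    afm = np.full(n, np.nan)
    if married.any():
        draws = rng.normal(15.1, 2.0, size=int(married.sum()))
        afm[married] = np.clip(
            np.round(draws, 1), 10.0, np.floor(age_years[married] * 10) / 10
        )
    ids = [f"w{(id_offset + j):06d}" for j in range(n)]
    women = pd.DataFrame(
        {
            "woman_id": ids,
            "dob_cmc": dob.astype(int),
            "interview_cmc": np.full(n, itv, dtype=int),
            "currently_married": married,
            "age_at_first_marriage_years": afm,
            "current_method": method,
            "amenorrheic": amen,
            "abstaining": np.zeros(n, dtype=bool),
            "residence": residence,
            "education": education,
            "weight": np.ones(n),
        }
    )
    births = pd.DataFrame(
        {
            "woman_id": [ids[j] for j in rows_id],
            "birth_cmc": np.asarray(rows_cmc, dtype=int),
        }
    )
    return women, births


def generate(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a survey population; deterministic under a fixed seed."""
    eff = EffectivenessTable()
    if cfg.strata_specs:
        shares = [s.share for s in cfg.strata_specs]
        if not math.isclose(sum(shares), 1.0, abs_tol=1e-9):
            raise ConfigurationError("stratum shares must sum to 1")
        seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.strata_specs))
        women_parts, birth_parts = [], []
        offset = 0
        remaining = cfg.n_women
        for j, spec in enumerate(cfg.strata_specs):
            n_j = (
                remaining
                if j == len(cfg.strata_specs) - 1
                else int(round(cfg.n_women * spec.share))
            )
            remaining -= n_j
            sub = replace(
                cfg, strata_specs=None, **dict(spec.overrides)
            )
            w, b = _simulate_block(
                sub, n_j, np.random.default_rng(seeds[j]), eff, offset,
                spec.residence, spec.education,
            )
            offset += n_j
            women_parts.append(w)
            birth_parts.append(b)
        women = pd.concat(women_parts, ignore_index=True)
        births = pd.concat(birth_parts, ignore_index=True)
        return women, births
    rng = np.random.default_rng(cfg.seed)
    return _simulate_block(
        cfg, cfg.n_women, rng, eff, 0, cfg.residence, cfg.education
    )


def generate_csv(cfg: SyntheticConfig, out_dir) -> tuple[str, str]:
    """Generate and write women.csv / births.csv plus a manifest."""
    women, births = generate(cfg)
    wpath, bpath = write_microdata(women, births, out_dir)
    manifest = {
        "generator": "proxdet.simulate",
        "version": __version__,
        "seed": cfg.seed,
        "n_women": cfg.n_women,
        "config": {
            "interview_cmc": cfg.interview_cmc,
            "m_by_age": list(cfg.m_by_age),
            "u_target": cfg.u_target,
            "mix_weights": dict(cfg.mix_weights),
            "i_mean_months": cfg.i_mean_months,
            "natural_fecundability": cfg.natural_fecundability,
            "window_months": cfg.window_months,
            "burn_in_months": cfg.burn_in_months,
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return wpath, bpath


#: Reference sample size at which the base recovery tolerances hold.
_REFERENCE_N = 20000
_BASE_TOL = {
    "u": 0.015,
    "i_months": 1.0,
    "m(a)": 0.04,
    "mix": 0.01,
    "cm": 0.03,
    "cc": 0.02,
    "ci": 0.02,
}


def recovery_report(
    cfg: SyntheticConfig,
    agg_cfg: Optional[AggregationConfig] = None,
    eff: Optional[EffectivenessTable] = None,
    k: Optional[ModelConstants] = None,
) -> pd.DataFrame:
    """Truth-versus-estimate table for the full pipeline.

    Tolerances are the base Monte-Carlo tolerances at n = 20000 women,
    widened by sqrt(20000/n) for smaller samples (the ``widened`` column
    flags this).
    """
    agg_cfg = agg_cfg or AggregationConfig()
    eff = eff or EffectivenessTable()
    k = k or ModelConstants()
    women, births = generate(cfg)
    inputs = aggregate(women, births, agg_cfg)
    idx = indices_from_inputs(inputs, eff, k, agg_cfg)
    truth = true_indices(cfg, eff, k)
    scale = max(1.0, math.sqrt(_REFERENCE_N / cfg.n_women))

    rows = []

    def add(name, true_v, est_v, base_tol):
        tol = base_tol * scale
        err = abs(est_v - true_v)
        rows.append(
            {
                "parameter": name,
                "truth": true_v,
                "estimate": est_v,
                "abs_error": err,
                "tolerance": tol,
                "within": err <= tol,
                "widened": scale > 1.0,
            }
        )

    for a, (lo, hi) in enumerate(agg_cfg.age_groups):
        est = inputs.m[a]
        if np.isfinite(est):
            add(f"m[{lo}-{hi - 1}]", cfg.m_by_age[a], float(est), _BASE_TOL["m(a)"])
    add("u", cfg.u_target, inputs.u, _BASE_TOL["u"])
    for meth, w_true in sorted(cfg.mix_weights.items()):
        add(
            f"mix[{meth}]",
            cfg.u_target * w_true,
            inputs.mix.get(meth, 0.0),
            _BASE_TOL["mix"],
        )
    add("i_months", cfg.i_mean_months, inputs.i_months, _BASE_TOL["i_months"])
    add("cm", truth["cm"], idx.cm, _BASE_TOL["cm"])
    add("cc", truth["cc"], idx.cc, _BASE_TOL["cc"])
    add("ci", truth["ci"], idx.ci, _BASE_TOL["ci"])
    return pd.DataFrame(rows)
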