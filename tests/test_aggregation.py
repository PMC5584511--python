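import numpy as np
import pandas as pd
import pytest

from proxdet import (
    AggregationConfig,
    aggregate,
    compute_asfr,
    compute_contraception_inputs,
    compute_marriage_proportions,
    compute_mean_insusceptibility,
    stratum_equals,
)
from proxdet.errors import StratumError, UndefinedEstimateError

from conftest import asfr_ledger, make_births, make_women

ITV = 1338


def age(years_months):
    """dob_cmc for a woman of given (years, extra months) at interview."""
    y, m = years_months
    return ITV - (12 * y + m)


class TestASFR:
    def test_single_birth_inside_one_group(self, cfg_unweighted):
        # age 24y9m at interview: the whole 36-month window sits in [20,25)
        women = make_women([{"dob_cmc": age((24, 9))}])
        births = make_births([{"woman_id": "w000", "birth_cmc": ITV - 12}])
        f = compute_asfr(women, births, cfg_unweighted)
        assert f[1] == pytest.approx(1.0 / 3.0)
        assert np.all(f[[0, 2, 3, 4, 5, 6]] == 0)

    def test_boundary_straddling_woman_splits_exposure(self, cfg_unweighted):
        # exactly 22.0 at interview: 12 window months in [15,20), 24 in [20,25)
        women = make_women([{"dob_cmc": age((22, 0))}])
        births = make_births([{"woman_id": "w000", "birth_cmc": ITV - 12}])
        f = compute_asfr(women, births, cfg_unweighted)
        assert f[1] == pytest.approx(0.5)  # 1 birth over 2 woman-years
        assert f[0] == 0.0
        np.testing.assert_allclose(
            f, asfr_ledger(women, births, cfg_unweighted)
        )

    def test_no_births_gives_zero_everywhere(self, cfg_unweighted):
        women = make_women([{"dob_cmc": age((30, 0))}])
        f = compute_asfr(women, make_births([]), cfg_unweighted)
        assert np.all(f == 0)

    def test_five_woman_fixture_matches_bruteforce_ledger(self, cfg):
        women = make_women(
            [
                {"dob_cmc": age((19, 11)), "weight": 1.0},
                {"dob_cmc": age((20, 1)), "weight": 2.0},
                {"dob_cmc": age((24, 6)), "weight": 0.5},
                {"dob_cmc": age((35, 0)), "weight": 1.5},
                {"dob_cmc": age((47, 2)), "weight": 1.0},
            ]
        )
        births = make_births(
            [
                {"woman_id": "w000", "birth_cmc": ITV - 30},
                {"woman_id": "w001", "birth_cmc": ITV - 1},
                {"woman_id": "w002", "birth_cmc": ITV - 36},
                {"woman_id": "w003", "birth_cmc": ITV - 24},
                {"woman_id": "w004", "birth_cmc": ITV - 6},
            ]
        )
        f = compute_asfr(women, births, cfg)
        np.testing.assert_allclose(f, asfr_ledger(women, births, cfg))
        assert f.sum() > 0

    def test_total_exposure_is_conserved_for_interior_ages(self, cfg):
        # women aged 18-46 at interview: no window month falls outside [15,50)
        rng = np.random.default_rng(11)
        ages = rng.integers(18 * 12, 46 * 12, size=40)
        weights = rng.uniform(0.5, 2.0, size=40)
        women = make_women(
            [
                {"dob_cmc": ITV - int(a), "weight": float(w)}
                for a, w in zip(ages, weights)
            ]
        )
        f = compute_asfr(women, make_births([]), cfg)  # exposure path only
        # recompute exposures via the ledger denominator identity
        ledger_exp = 0.0
        for row in women.itertuples():
            ledger_exp += row.weight * 36
        # exposure is embedded in f's denominator; check via a one-birth probe
        # by conservation: sum of per-group weighted months equals total
        groups = [(lo * 12, hi * 12) for lo, hi in cfg.age_groups]
        start = ages - 36
        total = 0.0
        for lo, hi in groups:
            total += np.sum(
                weights * np.clip(np.minimum(start + 36, hi) - np.maximum(start, lo), 0, None)
            )
        assert total == pytest.approx(float(np.sum(weights)) * 36, abs=1e-9)


class TestMarriageProportions:
    def test_all_married_gives_one_in_populated_groups(self, cfg):
        women = make_women([{"dob_cmc": age((20 + 5 * k, 2))} for k in range(6)])
        m = compute_marriage_proportions(women, cfg)
        assert np.all(m[1:] == 1.0)
        assert np.isnan(m[0])  # empty group flagged missing, not 0

    def test_unweighted_simple_count(self, cfg_unweighted):
        women = make_women(
            [{"dob_cmc": age((22, k)), "currently_married": k != 0}
             for k in range(4)]
        )
        m = compute_marriage_proportions(women, cfg_unweighted)
        assert m[1] == pytest.approx(0.75)

    def test_weighted_proportions_match_hand_tally(self, cfg):
        women = make_women(
            [
                {"dob_cmc": age((22, 0)), "weight": 1.0, "currently_married": True},
                {"dob_cmc": age((22, 1)), "weight": 2.0, "currently_married": False},
                {"dob_cmc": age((22, 2)), "weight": 3.0, "currently_married": True},
            ]
        )
        m = compute_marriage_proportions(women, cfg)
        assert m[1] == pytest.approx(4.0 / 6.0)


class TestContraception:
    def test_nobody_using(self, cfg):
        women = make_women([{"dob_cmc": age((25, 0))}] * 3)
        u, mix = compute_contraception_inputs(women, cfg)
        assert u == 0.0 and all(v == 0.0 for v in mix.values())

    def test_weighted_prevalence(self, cfg):
        women = make_women(
            [
                {"dob_cmc": age((25, 0)), "weight": 1.0},
                {"dob_cmc": age((25, 1)), "weight": 1.0},
                {"dob_cmc": age((25, 2)), "weight": 2.0, "current_method": "pill"},
            ]
        )
        u, mix = compute_contraception_inputs(women, cfg)
        assert u == pytest.approx(0.5)
        assert mix["pill"] == pytest.approx(0.5)

    def test_published_2011_method_mix_recovers_prevalence(self, cfg):
        # counts out of 2000 married women proportional to the 2011 column
        counts = {
            "sterilization_f": 12, "pill": 30, "iud": 6,
            "injectable": 530, "implant": 80, "condom_m": 2,
        }
        rows = []
        for meth, n in counts.items():
            rows += [{"dob_cmc": age((25, 0)), "current_method": meth}] * n
        rows += [{"dob_cmc": age((25, 0))}] * (2000 - sum(counts.values()))
        u, mix = compute_contraception_inputs(make_women(rows), cfg)
        assert u == pytest.approx(0.330)
        assert mix["injectable"] == pytest.approx(0.265)
        assert sum(mix.values()) == pytest.approx(u, abs=1e-12)


class TestInsusceptibility:
    def test_prevalence_incidence_ratio_definition(self, cfg_unweighted):
        # P = 50 insusceptible mothers, 90 births in 36 months -> B = 2.5/month
        rows, births = [], []
        for j in range(90):
            rows.append(
                {"woman_id": f"m{j}", "dob_cmc": age((30, j % 12)),
                 "amenorrheic": j < 50}
            )
            births.append({"woman_id": f"m{j}", "birth_cmc": ITV - 1 - (j % 36)})
        i = compute_mean_insusceptibility(
            make_women(rows), make_births(births), cfg_unweighted
        )
        assert i == pytest.approx(20.0)

    def test_abstaining_flag_counts_toward_insusceptibility(self, cfg_unweighted):
        rows = [
            {"woman_id": "a", "dob_cmc": age((30, 0)), "abstaining": True},
            {"woman_id": "b", "dob_cmc": age((30, 1))},
        ]
        births = [
            {"woman_id": "a", "birth_cmc": ITV - 3},
            {"woman_id": "b", "birth_cmc": ITV - 3},
        ]
        i = compute_mean_insusceptibility(
            make_women(rows), make_births(births), cfg_unweighted
        )
        # P = 1, B = 2/36 births per month
        assert i == pytest.approx(18.0)

    def test_no_insusceptible_women_gives_zero(self, cfg_unweighted):
        rows = [{"woman_id": "a", "dob_cmc": age((30, 0))}]
        births = [{"woman_id": "a", "birth_cmc": ITV - 5}]
        i = compute_mean_insusceptibility(
            make_women(rows), make_births(births), cfg_unweighted
        )
        assert i == 0.0

    def test_no_births_in_window_is_undefined(self, cfg_unweighted):
        rows = [{"woman_id": "a", "dob_cmc": age((30, 0))}]
        with pytest.raises(UndefinedEstimateError, match="window"):
            compute_mean_insusceptibility(
                make_women(rows), make_births([]), cfg_unweighted
            )

    def test_current_status_sum_matches_hand_computation(self):
        cfg = AggregationConfig(
            weighted=False, insusceptibility_estimator="current_status_sum"
        )
        rows = [
            # duration 0: two women, one insusceptible -> 0.5
            {"woman_id": "a", "dob_cmc": age((30, 0)), "amenorrheic": True},
            {"woman_id": "b", "dob_cmc": age((30, 1))},
            # duration 3: one woman, insusceptible -> 1.0
            {"woman_id": "c", "dob_cmc": age((30, 2)), "abstaining": True},
        ]
        births = [
            {"woman_id": "a", "birth_cmc": ITV},
            {"woman_id": "b", "birth_cmc": ITV},
            {"woman_id": "c", "birth_cmc": ITV - 3},
        ]
        i = compute_mean_insusceptibility(
            make_women(rows), make_births(births), cfg
        )
        assert i == pytest.approx(1.5)


class TestAggregate:
    def _population(self):
        rng = np.random.default_rng(5)
        rows, births = [], []
        for j in range(60):
            res = "urban" if j % 3 == 0 else "rural"
            married = j % 5 != 0
            method = "injectable" if married and j % 4 == 0 else "none"
            rows.append(
                {
                    "woman_id": f"w{j:03d}",
                    "dob_cmc": ITV - int(rng.integers(18 * 12, 46 * 12)),
                    "currently_married": married,
                    "current_method": method,
                    "amenorrheic": j % 7 == 0,
                    "residence": res,
                    "weight": float(rng.uniform(0.5, 2.0)),
                }
            )
            if married and j % 2 == 0:
                births.append(
                    {"woman_id": f"w{j:03d}",
                     "birth_cmc": ITV - 1 - int(rng.integers(0, 36))}
                )
        return make_women(rows), make_births(births)

    def test_no_predicate_equals_trivial_stratum(self, cfg):
        women, births = self._population()
        full = aggregate(women, births, cfg)
        trivial = aggregate(
            women, births, cfg, stratum=lambda df: np.ones(len(df), bool)
        )
        np.testing.assert_allclose(full.f, trivial.f)
        np.testing.assert_allclose(full.m, trivial.m)
        assert full.u == trivial.u and full.i_months == trivial.i_months

    def test_partition_additivity_of_weighted_counts(self, cfg):
        women, births = self._population()
        parts = [
            aggregate(women, births, cfg, stratum=stratum_equals("residence", r))
            for r in ("urban", "rural")
        ]
        full = aggregate(women, births, cfg)
        assert sum(p.n_women for p in parts) == full.n_women
        # weighted births per age group sum across strata exactly:
        # f * exposure is additive, so reconstruct numerators
        groups = [(lo * 12, hi * 12) for lo, hi in cfg.age_groups]

        def numerators(sub_mask):
            sub = women[sub_mask]
            b = births[births["woman_id"].isin(set(sub["woman_id"]))]
            led = np.zeros(len(groups))
            mothers = sub.set_index("woman_id")
            for row in b.itertuples():
                mom = mothers.loc[row.woman_id]
                if mom["interview_cmc"] - 36 <= row.birth_cmc < mom["interview_cmc"]:
                    a = row.birth_cmc - mom["dob_cmc"]
                    for k, (lo, hi) in enumerate(groups):
                        if lo <= a < hi:
                            led[k] += mom["weight"]
            return led

        total = numerators(np.ones(len(women), bool))
        split = numerators((women["residence"] == "urban").to_numpy()) + numerators(
            (women["residence"] == "rural").to_numpy()
        )
        np.testing.assert_allclose(total, split, atol=1e-12)

    def test_weight_scale_invariance(self, cfg):
        women, births = self._population()
        base = aggregate(women, births, cfg)
        scaled_women = women.assign(weight=women["weight"] * 3.7)
        scaled = aggregate(scaled_women, births, cfg)
        np.testing.assert_allclose(base.f, scaled.f, rtol=1e-12)
        np.testing.assert_allclose(base.m, scaled.m, rtol=1e-12)
        assert base.u == pytest.approx(scaled.u, rel=1e-12)
        assert base.i_months == pytest.approx(scaled.i_months, rel=1e-12)

    def test_empty_stratum_raises_naming_the_predicate(self, cfg):
        women, births = self._population()
        pred = stratum_equals("education", "secondary_plus")
        with pytest.raises(StratumError, match="secondary_plus"):
            aggregate(women, births, cfg, stratum=pred)
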