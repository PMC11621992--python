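from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from rfjem import cohort, exposure
from rfjem import synthetic as syn
from rfjem.errors import ContractViolation, DataError
from rfjem.exposure import (
    PRIMARY_LABELS,
    YearlySeries,
    compute_profiles,
    cumulative_exposure,
    twa_exposure,
    window_exposure,
    yearly_series,
    years_worked,
)


def spell(start, end, isco88="1000", nonstandard=False, source_reported=False):
    return SimpleNamespace(pid="p1", start_year=start, end_year=end,
                           isco88=isco88, nonstandard=nonstandard,
                           source_reported=source_reported,
                           source_uncertain=False)


class TestYearlySeries:
    def test_single_spell_attribution(self, tiny_jem):
        s = yearly_series("p1", [spell(1990, 1994)], tiny_jem, "M1", "E")
        assert s.values == {y: 2.0 for y in range(1990, 1995)}

    def test_overlap_years_average_including_zeros(self, tiny_jem):
        # code 3000 has prevalence 0 -> contributes 0; mean of {2, 0} = 1
        spells = [spell(1990, 1991, "1000"), spell(1990, 1991, "3000")]
        s = yearly_series("p1", spells, tiny_jem, "M1", "E")
        assert s.values == {1990: 1.0, 1991: 1.0}

    def test_prevalence_threshold_gates_method2(self, tiny_jem):
        # code 2000: prevalence 0.03 < threshold 0.05
        sp = [spell(1990, 1990, "2000")]
        m2 = yearly_series("p1", sp, tiny_jem, "M2", "E", threshold=0.05)
        m1 = yearly_series("p1", sp, tiny_jem, "M1", "E")
        assert m2.values == {1990: 0.0}
        assert m1.values == {1990: 0.5}

    def test_method2_threshold_boundary_is_inclusive(self, tiny_jem):
        sp = [spell(1990, 1990, "1000")]  # prevalence exactly 0.10
        s = yearly_series("p1", sp, tiny_jem, "M2", "E", threshold=0.10)
        assert s.values == {1990: 2.0}

    def test_method3_requires_source_report(self, tiny_jem):
        sp = [spell(1990, 1990, "1000", source_reported=False)]
        assert yearly_series("p1", sp, tiny_jem, "M3", "E").values == {1990: 0.0}
        sp = [spell(1990, 1990, "1000", source_reported=True)]
        assert yearly_series("p1", sp, tiny_jem, "M3", "E").values == {1990: 2.0}

    def test_nonstandard_and_absent_codes_contribute_zero(self, tiny_jem):
        sp = [spell(1990, 1990, None, nonstandard=True),
              spell(1990, 1990, "9999")]
        s = yearly_series("p1", sp, tiny_jem, "M1", "E")
        assert s.values == {1990: 0.0}
        assert s.worked == {1990: True}

    def test_unknown_years_violate_contract(self, tiny_jem):
        with pytest.raises(ContractViolation):
            yearly_series("p1", [spell(pd.NA, 1990)], tiny_jem, "M1", "E")


def series(values, worked=None):
    return YearlySeries("p1", "E", "M1", values,
                        worked if worked is not None
                        else {y: True for y in values})


class TestMetrics:
    def test_cumulative_full_and_empty(self):
        s = series({1998: 1.0, 1999: 1.0, 2000: 1.0})
        assert cumulative_exposure(s, 2001, 1) == 3.0
        assert cumulative_exposure(s, 2001, 10) == 0.0

    def test_cumulative_lag_boundary(self):
        s = series({y: 0.5 for y in range(1990, 2000)})
        # lag 5 from 2000 keeps 1990..1995: six years
        assert cumulative_exposure(s, 2000, 5) == pytest.approx(3.0)

    def test_window_boundaries(self):
        s = series({y: 1.0 for y in range(1991, 2001)})
        assert window_exposure(s, 2001, 1, 4) == 4.0   # 1997..2000
        assert window_exposure(s, 2001, 5, 9) == 5.0   # 1992..1996
        assert window_exposure(s, 1990, 1, 4) == 0.0

    def test_years_worked_counts_gaps_correctly(self):
        worked = {y: True for y in range(1970, 1997)}
        s = series({}, worked)
        assert years_worked(s, 1998, "lag1") == 27  # 1970..1996, all <= ref-1
        gappy = dict(worked)
        del gappy[1980], gappy[1981]
        assert years_worked(series({}, gappy), 1998, "lag1") == 25
        assert years_worked(s, 1998, "win1_4") == 3  # 1994..1996 of 1994..1997
        full = series({}, {y: True for y in range(1994, 1998)})
        assert years_worked(full, 1998, "win1_4") == 4

    def test_twa(self):
        assert twa_exposure(6.0, 3) == 2.0
        assert twa_exposure(0.0, 0) == 0.0
        with pytest.raises(ContractViolation):
            twa_exposure(1.0, 0)
        with pytest.raises(DataError):
            cumulative_exposure(series({}), 2000, 0)


def naive_metric(spell_rows, jem, method, fk, threshold, ref, label):
    """Brute-force oracle: materialize every (year, spell) pair, average
    concurrent spells, then sum over the label's range."""
    per_year = {}
    for sp in spell_rows:
        for y in range(int(sp.start_year), int(sp.end_year) + 1):
            if sp.nonstandard:
                val = 0.0
            else:
                val = jem.intensity(str(sp.isco88), fk)
                if method == "M2" and jem.prevalence(str(sp.isco88), fk) < threshold:
                    val = 0.0
                if method == "M3" and not sp.source_reported:
                    val = 0.0
            per_year.setdefault(y, []).append(val)
    kind = exposure.LABELS[label]
    if kind[0] == "lag":
        yrs = [y for y in per_year if y <= ref - kind[1]]
    else:
        yrs = [y for y in per_year if ref - kind[2] <= y <= ref - kind[1]]
    cum = sum(float(np.mean(per_year[y])) for y in yrs)
    return cum, len(yrs)


class TestAgainstBruteForce:
    def test_random_cohort_matches_naive_enumeration(self, small_study):
        cfg, jem, pdf, jdf, _ = small_study
        inc_p, inc_j, _ = cohort.apply_exclusions(pdf, jdf)
        sub = inc_p.head(120)
        jobs = inc_j[inc_j["pid"].isin(set(sub["pid"]))]
        ref = pd.Series(2000, index=sub["pid"].to_numpy())
        thr = 0.04
        prof = compute_profiles(sub, jobs, jem, ref,
                                methods=("M1", "M2", "M3"), fields=("E", "H"),
                                labels=("lag1", "lag10", "win1_4", "win5_9"),
                                thresholds={"E": thr, "H": thr})
        spells_by_pid = {pid: list(g.itertuples(index=False))
                         for pid, g in jobs.groupby("pid")}
        for row in prof.itertuples(index=False):
            cum, yrs = naive_metric(spells_by_pid.get(row.pid, []), jem,
                                    row.method, row.field_kind, thr,
                                    2000, row.label)
            assert row.cumulative == pytest.approx(cum, abs=1e-9)
            assert row.years_worked == yrs
            expected_twa = cum / yrs if yrs else 0.0
            assert row.twa == pytest.approx(expected_twa, abs=1e-9)


@pytest.fixture(scope="module")
def profiles(small_study):
    cfg, jem, pdf, jdf, _ = small_study
    inc_p, inc_j, _ = cohort.apply_exclusions(pdf, jdf)
    gap = cohort.median_diagnosis_interview_gap(
        inc_p[inc_p["status"] != "control"])
    ref = cohort.reference_years(inc_p, gap)
    return compute_profiles(inc_p, inc_j, jem, ref,
                            methods=("M1", "M2", "M3"),
                            fields=("E", "H"),
                            labels=("lag1", "lag5", "lag10",
                                    "win1_4", "win5_9"))


class TestInvariants:
    def test_conservation_partition(self, profiles):
        piv = profiles.pivot_table(index=["pid", "field_kind", "method"],
                                   columns="label", values="cumulative")
        err = (piv["lag1"] - (piv["win1_4"] + piv["win5_9"] + piv["lag10"]))
        assert err.abs().max() < 1e-9

    def test_lag_monotonicity(self, profiles):
        piv = profiles.pivot_table(index=["pid", "field_kind", "method"],
                                   columns="label", values="cumulative")
        assert (piv["lag10"] <= piv["lag5"] + 1e-12).all()
        assert (piv["lag5"] <= piv["lag1"] + 1e-12).all()

    def test_method_nesting(self, profiles):
        piv = profiles.pivot_table(index=["pid", "field_kind", "label"],
                                   columns="method", values="cumulative")
        assert (piv["M2"] <= piv["M1"] + 1e-12).all()
        assert (piv["M3"] <= piv["M1"] + 1e-12).all()
        exp = profiles.pivot_table(index=["pid", "field_kind", "label"],
                                   columns="method", values="exposed")
        assert not (exp["M2"].astype(bool) & ~exp["M1"].astype(bool)).any()
        assert not (exp["M3"].astype(bool) & ~exp["M1"].astype(bool)).any()

    def test_twa_bounded_by_max_yearly_intensity(self, small_study):
        cfg, jem, pdf, jdf, _ = small_study
        inc_p, inc_j, _ = cohort.apply_exclusions(pdf, jdf)
        sub = inc_p.head(80)
        jobs = inc_j[inc_j["pid"].isin(set(sub["pid"]))]
        spells_by_pid = {pid: list(g.itertuples(index=False))
                         for pid, g in jobs.groupby("pid")}
        for pid, spells in spells_by_pid.items():
            s = yearly_series(pid, spells, jem, "M1", "E")
            if not s.values:
                continue
            vmax = max(s.values.values())
            for label in PRIMARY_LABELS:
                kind = exposure.LABELS[label]
                if kind[0] == "lag":
                    cum = cumulative_exposure(s, 2000, kind[1])
                else:
                    cum = window_exposure(s, 2000, kind[1], kind[2])
                yrs = years_worked(s, 2000, label)
                assert twa_exposure(cum, yrs) <= vmax + 1e-12
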