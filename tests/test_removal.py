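"""Removal-efficiency computation, classing and the consensus vote."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppcpscreen.records import (
    ChemicalIdentity,
    ConcentrationMeasurement,
    LiteratureRecord,
    MassBalanceInputs,
    PlantType,
    WWTPInfo,
    score_quality,
)
from ppcpscreen.removal import (
    CensoringPolicy,
    REClass,
    classify_re,
    consensus_re,
    is_resistant,
    re_mass_balance,
    re_simple,
    select_re,
)


class TestRESimple:
    @pytest.mark.parametrize("infl, effl, expected", [
        (100.0, 25.0, 75.0),
        (100.0, 100.0, 0.0),
        (100.0, 150.0, -50.0),  # apparent in-plant formation
    ])
    def test_ratio(self, infl, effl, expected):
        assert re_simple(infl, effl) == pytest.approx(expected)

    @pytest.mark.parametrize("infl, effl", [(0.0, 10.0), (None, 10.0),
                                            (100.0, None)])
    def test_uncomputable_yields_none(self, infl, effl):
        assert re_simple(infl, effl) is None

    @given(st.floats(1e-3, 1e6), st.floats(0, 1e6), st.floats(0, 1e6))
    def test_decreasing_in_effluent_and_bounded(self, infl, e1, e2):
        r1, r2 = re_simple(infl, e1), re_simple(infl, e2)
        assert r1 <= 100.0 and r2 <= 100.0
        if e1 < e2:
            assert r1 >= r2


class TestREMassBalance:
    @pytest.mark.parametrize("mb, expected", [
        (dict(ci=100, ce=20, cs=0, f=1000, tsp=500), 80.0),
        (dict(ci=100, ce=20, cs=10, f=1000, tsp=1000), 70.0),
        (dict(ci=100, ce=100, cs=10, f=1000, tsp=1000), -10.0),
    ])
    def test_load_balance(self, mb, expected):
        assert re_mass_balance(MassBalanceInputs(**mb)) == pytest.approx(expected)

    @given(st.floats(1e-3, 1e5), st.floats(0, 1e5), st.floats(1e-3, 1e7))
    def test_reduces_to_ratio_without_sludge_term(self, ci, ce, f):
        """With Cs*TSP = 0 the load balance equals the concentration ratio."""
        mb = MassBalanceInputs(ci=ci, ce=ce, cs=0.0, f=f, tsp=1000.0)
        assert re_mass_balance(mb) == re_simple(ci, ce)


class TestClassifyRE:
    @pytest.mark.parametrize("percent, expected", [
        (-50.0, REClass.OTHER),
        (0.0, REClass.OTHER),
        (1e-9, REClass.LOW),
        (50.0, REClass.LOW),
        (75.0, REClass.MODERATE),
        (95.0, REClass.HIGH),
        (95.001, REClass.EXCELLENT),
        (None, REClass.NODATA),
        (float("nan"), REClass.NODATA),
    ])
    def test_bins_closed_above(self, percent, expected):
        assert classify_re(percent) is expected

    @given(st.floats(-1e4, 100, allow_nan=False))
    def test_partitions_the_line(self, percent):
        assert classify_re(percent) in set(REClass) - {REClass.NODATA}


def _record(*, reported=None, mb=None, infl=None, effl=None):
    return LiteratureRecord(
        chemical=ChemicalIdentity(cas="1", name="x", smiles="CCO",
                                  molecular_weight=100.0),
        plant=WWTPInfo(plant_id="p", continent="Asia",
                       declared_level="secondary",
                       classification=PlantType.WWTP1),
        source_id="s",
        quality=score_quality(2, 2, 2),
        reported_re=reported,
        mass_balance=MassBalanceInputs(**mb) if mb else None,
        influent=infl,
        effluent=effl,
    )


_MB = dict(ci=100, ce=20, cs=10, f=1000, tsp=1000)


class TestSelectRE:
    def test_reported_takes_precedence(self):
        rev = select_re(_record(reported=62.0, mb=_MB))
        assert (rev.percent, rev.method) == (62.0, "reported")

    def test_mass_balance_when_no_reported(self):
        rev = select_re(_record(mb=_MB))
        assert rev.method == "eq2"
        assert rev.percent == pytest.approx(70.0)

    def test_ratio_as_fallback(self):
        rev = select_re(_record(
            infl=ConcentrationMeasurement(value=100.0, statistic="median"),
            effl=ConcentrationMeasurement(value=25.0, statistic="median")))
        assert (rev.method, rev.percent) == ("eq1", pytest.approx(75.0))

    def test_censored_effluent_gives_nodata(self):
        rev = select_re(_record(
            infl=ConcentrationMeasurement(value=100.0),
            effl=ConcentrationMeasurement(censored=True)))
        assert rev.re_class is REClass.NODATA

    def test_formation_policy_reads_censored_influent_as_other(self):
        rec = _record(infl=ConcentrationMeasurement(censored=True),
                      effl=ConcentrationMeasurement(value=40.0))
        assert select_re(rec).re_class is REClass.NODATA
        assert select_re(
            rec, censoring_policy=CensoringPolicy.FORMATION
        ).re_class is REClass.OTHER

    def test_nothing_available_gives_nodata(self):
        assert select_re(_record()).re_class is REClass.NODATA


def consensus_oracle(classes):
    """Naive mode-then-worst vote, written independently of the implementation."""
    worst_first = [REClass.OTHER, REClass.LOW, REClass.MODERATE,
                   REClass.HIGH, REClass.EXCELLENT]
    pool = list(classes)
    while True:
        if all(c is REClass.NODATA for c in pool):
            return REClass.NODATA
        top = max(pool.count(c) for c in set(pool))
        modal = {c for c in set(pool) if pool.count(c) == top}
        if REClass.NODATA in modal:
            pool = [c for c in pool if c is not REClass.NODATA]
            continue
        for c in worst_first:
            if c in modal:
                return c


class TestConsensus:
    def test_tie_breaks_to_worst_class(self):
        # one Low and one Other record: the worst class wins
        res = consensus_re([REClass.LOW, REClass.OTHER], PlantType.WWTP2)
        assert res.consensus_class is REClass.OTHER
        assert res.tie_broken

    def test_unanimity(self):
        res = consensus_re([REClass.HIGH] * 3, PlantType.WWTP1)
        assert res.consensus_class is REClass.HIGH
        assert not res.tie_broken

    def test_nodata_mode_defers_to_next_class(self):
        classes = [REClass.NODATA] * 3 + [REClass.LOW] * 2 + [REClass.MODERATE]
        res = consensus_re(classes, PlantType.WWTP1)
        assert res.consensus_class is REClass.LOW

    def test_all_nodata(self):
        res = consensus_re([REClass.NODATA] * 2, PlantType.WWTP1)
        assert res.consensus_class is REClass.NODATA

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_re([], PlantType.WWTP1)

    def test_counts_sum_to_contributing_records(self):
        classes = [REClass.LOW, REClass.LOW, REClass.HIGH, REClass.NODATA]
        res = consensus_re(classes, PlantType.WWTP1)
        assert sum(res.class_counts.values()) == len(classes)

    @given(st.lists(st.sampled_from(list(REClass)), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_matches_oracle(self, classes, rnd):
        shuffled = list(classes)
        rnd.shuffle(shuffled)
        a = consensus_re(classes, PlantType.WWTP1).consensus_class
        b = consensus_re(shuffled, PlantType.WWTP1).consensus_class
        assert a is b is consensus_oracle(classes)


class TestResistance:
    @pytest.mark.parametrize("cls, expected", [
        (REClass.LOW, True), (REClass.OTHER, True),
        (REClass.MODERATE, False), (REClass.HIGH, False),
        (REClass.EXCELLENT, False), (REClass.NODATA, False),
    ])
    def test_resistant_iff_low_or_other(self, cls, expected):
        assert is_resistant(cls) is expected
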