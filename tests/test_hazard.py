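"""Prediction aggregation, threshold rules and verdict combination."""

import dataclasses

import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from ppcpscreen.hazard import (
    HazardFlags,
    ModelPrediction,
    PropertyBundle,
    ThresholdProfile,
    aggregate_endpoint,
    assess,
    combine_labels,
    convert_toxicity,
    flag_bioaccumulation,
    flag_ed,
    flag_mobility,
    flag_persistence,
    flag_toxicity,
    load_profiles_yaml,
)

CONS = ThresholdProfile.conservative_2019()
EU = ThresholdProfile.eu_2023()


def _bundle(preds, *, mw=315.58, exp_kow=None, exp_koc=None, **ed):
    return PropertyBundle(cas="X", molecular_weight=mw,
                          exp_log_kow=exp_kow, exp_log_koc=exp_koc,
                          predictions=preds, **ed)


def _pred(model_id, endpoint, value, *, in_ad=True, units="log10", level="L1"):
    return ModelPrediction(model_id=model_id, endpoint=endpoint, value=value,
                           in_ad=in_ad, units=units, screening_level=level)


class TestAggregateEndpoint:
    def test_mean_of_in_domain_models(self):
        # two octanol-water predictions, 4.9 and 4.34, average to 4.62
        bundle = _bundle([_pred("KOWWIN", "log_kow", 4.9),
                          _pred("OPERA_LOGP", "log_kow", 4.34)])
        value, source = aggregate_endpoint(bundle, "log_kow")
        assert value == pytest.approx(4.62)
        assert source == "mean-of-models"

    def test_experimental_takes_precedence(self):
        bundle = _bundle([_pred("KOWWIN", "log_kow", 5.0)], exp_kow=3.0)
        assert aggregate_endpoint(bundle, "log_kow") == (3.0, "experimental")

    def test_koc_fallback_when_mci_out_of_domain(self):
        bundle = _bundle([_pred("KOCWIN_MCI", "log_koc", 6.0, in_ad=False),
                          _pred("SOIL_KOC", "log_koc", 2.8)])
        assert aggregate_endpoint(bundle, "log_koc") == (2.8, "fallback-model")

    def test_koc_mean_when_both_in_domain(self):
        bundle = _bundle([_pred("KOCWIN_MCI", "log_koc", 3.0),
                          _pred("SOIL_KOC", "log_koc", 4.0)])
        value, source = aggregate_endpoint(bundle, "log_koc")
        assert value == pytest.approx(3.5)
        assert source == "mean-of-models"

    def test_no_usable_value_is_absent(self):
        bundle = _bundle([_pred("KOWWIN", "log_kow", 5.0, in_ad=False)])
        assert aggregate_endpoint(bundle, "log_kow") == (None, "absent")

    @given(st.lists(st.floats(-2, 10), min_size=1, max_size=5),
           st.lists(st.floats(-100, 100), max_size=3))
    def test_mean_within_range_and_immune_to_out_of_domain(self, in_vals,
                                                           out_vals):
        """Out-of-domain predictions never influence the aggregate."""
        preds = [_pred("KOWWIN", "log_kow", v) for v in in_vals]
        clean, _ = aggregate_endpoint(_bundle(list(preds)), "log_kow")
        span = 1e-12 * max(1.0, max(abs(v) for v in in_vals))
        assert min(in_vals) - span <= clean <= max(in_vals) + span
        perturbed = preds + [_pred("OPERA_LOGP", "log_kow", v, in_ad=False)
                             for v in out_vals]
        assert aggregate_endpoint(_bundle(perturbed), "log_kow")[0] == clean


class TestConvertToxicity:
    @pytest.mark.parametrize("p, units, mw, expected", [
        (6.0, "mol/L", 100.0, 0.1),
        (3.0, "mmol/L", 100.0, 0.1),
        (0.0, "mol/L", 1.0, 1000.0),
    ])
    def test_molar_to_mg_per_l(self, p, units, mw, expected):
        assert convert_toxicity(p, units, mw) == pytest.approx(expected)

    def test_unknown_units_rejected(self):
        with pytest.raises(ValueError):
            convert_toxicity(6.0, "ug/L", 100.0)


class TestFlagRules:
    @pytest.mark.parametrize("b2, b3, b6, expected", [
        (0.3, 2.0, 0.4, True),
        (0.3, 3.0, 0.4, False),   # ultimate timeframe criterion fails
        (0.6, 2.0, 0.6, False),   # both fast probabilities too high
        (0.6, 2.0, 0.4, True),    # one fast probability suffices (or-rule)
        (None, 2.0, None, None),  # no fast probability: unassessable
        (0.3, None, 0.4, None),
    ])
    def test_persistence(self, b2, b3, b6, expected):
        assert flag_persistence(b2, b3, b6, CONS) is expected

    def test_persistence_and_rule_variant(self):
        strict = ThresholdProfile.conservative_2019(
            fast_probability_rule="and")
        assert flag_persistence(0.6, 2.0, 0.4, strict) is False
        assert flag_persistence(0.4, 2.0, 0.4, strict) is True

    @pytest.mark.parametrize("kow, bcf, b, vb", [
        (4.62, None, True, None),   # slightly above the Kow screen
        (4.5, None, False, None),   # boundary is strict
        (None, 3.8, True, True),
        (2.0, 3.0, False, False),
        (None, None, None, None),
    ])
    def test_bioaccumulation(self, kow, bcf, b, vb):
        assert flag_bioaccumulation(kow, bcf, CONS) == (b, vb)

    @pytest.mark.parametrize("koc, profile, m, vm", [
        (3.25, CONS, True, False),  # mobile under the conservative screen only
        (3.25, EU, False, False),
        (1.5, EU, True, True),
        (None, CONS, None, None),
    ])
    def test_mobility(self, koc, profile, m, vm):
        assert flag_mobility(koc, profile) == (m, vm)

    @pytest.mark.parametrize("values, threshold, t", [
        ([0.05, 2.0], 0.1, True),
        ([0.05], 0.01, False),
        ([0.1], 0.1, False),  # boundary is strict
        ([], 0.1, None),
    ])
    def test_toxicity(self, values, threshold, t):
        profile = ThresholdProfile.conservative_2019(
            t_ec50_max_mg_l=threshold)
        flag, minimum = flag_toxicity(values, profile)
        assert flag is t
        assert minimum == (min(values) if values else None)

    @pytest.mark.parametrize("er, ar, httr, expected", [
        (False, True, "none", True),
        (False, False, "none", False),
        (False, False, "moderate", True),
        (True, False, "weak", True),
    ])
    def test_endocrine_disruption(self, er, ar, httr, expected):
        assert flag_ed(er, ar, httr) is expected


class TestCombineLabels:
    def test_pmt_and_pbt_conjunctions(self):
        flags = HazardFlags(p=True, b=True, m=True, t=True)
        assert combine_labels(flags) == {"PBT", "PMT"}

    def test_very_labels_require_explicit_very_persistence(self):
        screened = HazardFlags(p=True, vb=True, vm=True, m=True, t=True)
        assert "vPvM" not in combine_labels(screened)
        confirmed = dataclasses.replace(screened, vp=True)
        assert {"vPvB", "vPvM"} <= combine_labels(confirmed)

    def test_all_false_gives_empty_set(self):
        assert combine_labels(HazardFlags()) == frozenset()

    @given(st.builds(HazardFlags,
                     p=st.booleans(), vp=st.booleans(), b=st.booleans(),
                     vb=st.booleans(), m=st.booleans(), vm=st.booleans(),
                     t=st.booleans()))
    def test_monotone_in_flags(self, flags):
        """Removing a true flag never adds a label."""
        base = combine_labels(flags)
        for name in ("p", "vp", "b", "vb", "m", "vm", "t"):
            if getattr(flags, name):
                weakened = dataclasses.replace(flags, **{name: False})
                assert combine_labels(weakened) <= base


def _screening_bundle(*, kow, koc, bcf=1.0, tox_p=7.5, mw=300.0):
    """A persistent+toxic bundle with configurable partitioning values."""
    return _bundle([
        _pred("BIOWIN2", "biowin2", 0.3, units="probability"),
        _pred("BIOWIN3", "biowin3", 2.0, units="score"),
        _pred("BIOWIN6", "biowin6", 0.4, units="probability"),
        _pred("KOWWIN", "log_kow", kow),
        _pred("KOCWIN_MCI", "log_koc", koc),
        _pred("LOGBCF", "log_bcf", bcf, level="L2"),
        _pred("FISH_MOD1", "plc50_fish", tox_p, units="mol/L"),
    ], mw=mw)


class TestAssess:
    def test_borderline_b_and_m_gets_both_labels_conservatively(self):
        # Kow just above 4.5 plus Koc between 3 and 4: PBT and PMT under the
        # conservative profile, PBT only under the 2023 cut-offs
        bundle = _screening_bundle(kow=4.62, koc=3.25)
        assert assess(bundle, CONS).labels == {"PBT", "PMT"}
        assert assess(bundle, EU).labels == {"PBT"}

    def test_mobile_non_bioaccumulative_is_pmt_only(self):
        bundle = _screening_bundle(kow=2.5, koc=2.4)
        verdict = assess(bundle, CONS)
        assert verdict.labels == {"PMT"}
        assert verdict.flags.vm is True  # below the very-mobile cut-off too

    def test_benign_bundle_has_no_labels(self):
        bundle = _screening_bundle(kow=2.0, koc=5.5, tox_p=2.0)
        assert assess(bundle, CONS).labels == frozenset()

    def test_unassessable_endpoint_propagates_as_not_flagged(self):
        bundle = _screening_bundle(kow=4.62, koc=3.25)
        bundle = bundle.model_copy(update={"predictions": [
            p if p.endpoint != "log_koc"
            else p.model_copy(update={"in_ad": False})
            for p in bundle.predictions
        ]})
        verdict = assess(bundle, CONS)
        assert verdict.flags.m is None
        assert verdict.labels == {"PBT"}
        assert verdict.provenance["log_koc"] == (None, "absent")

    @given(st.floats(0, 8), st.floats(0, 8))
    def test_conservative_mobility_superset_of_eu(self, koc, kow):
        """Any chemical mobile under the 2023 cut-off is mobile under the
        conservative one."""
        m_cons, vm_cons = flag_mobility(koc, CONS)
        m_eu, vm_eu = flag_mobility(koc, EU)
        assert (not m_eu) or m_cons
        assert (not vm_eu) or vm_cons


class TestProfiles:
    def test_builtin_mobility_cutoffs(self):
        assert (CONS.m_logkoc_max, CONS.vm_logkoc_max) == (4.0, 3.0)
        assert (EU.m_logkoc_max, EU.vm_logkoc_max) == (3.0, 2.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ThresholdProfile(name="bad", m_logkoc_max=2.0, vm_logkoc_max=3.0)

    def test_yaml_overrides(self, tmp_path):
        path = tmp_path / "profiles.yaml"
        path.write_text(yaml.safe_dump({
            "eu_2023": {"t_ec50_max_mg_l": 0.01},
            "custom": {"m_logkoc_max": 5.0, "vm_logkoc_max": 4.0},
        }))
        profiles = load_profiles_yaml(path)
        assert profiles["eu_2023"].t_ec50_max_mg_l == 0.01
        assert profiles["eu_2023"].m_logkoc_max == 3.0  # builtin preserved
        assert profiles["custom"].m_logkoc_max == 5.0
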