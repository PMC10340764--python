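import warnings

import pytest

from coixpep import (
    AminoAcidProfile,
    ReferencePattern,
    aas,
    class_sums,
    nutrition_report,
    per,
    tav,
)
from coixpep.nutrition import FAO_WHO_ADULT_PATTERN, limiting_order
from conftest import PRINTED_TABLE3, make_profile


def quiet_profile(content, sample="s"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AminoAcidProfile(sample_id=sample, content=content)


class TestPer:
    def test_raw_sample_reproduces_published_values(self, raw_profile):
        per1, per2, per3 = per(raw_profile)
        assert per1 == pytest.approx(6.96, abs=0.01)
        assert per2 == pytest.approx(7.02, abs=0.01)
        assert per3 == pytest.approx(8.11, abs=0.01)

    def test_zero_profile_gives_intercepts(self):
        p = quiet_profile({"G": 0.0})
        per1, per2, per3 = per(p)
        assert per1 == pytest.approx(-0.684)
        assert per2 == pytest.approx(-0.468)
        assert per3 == pytest.approx(-1.816)


class TestClassSums:
    @pytest.mark.parametrize("sample", list(PRINTED_TABLE3))
    def test_reproduces_published_rows(self, sample):
        sums = class_sums(make_profile(sample))
        for key, printed in PRINTED_TABLE3[sample].items():
            if key.startswith("per") or key in ("tft", "tbt", "tst"):
                continue
            assert sums[key] == pytest.approx(printed, rel=5e-3), (sample, key)

    def test_worked_anchors(self, raw_profile):
        sums = class_sums(raw_profile)
        assert sums["eaa"] == pytest.approx(35.31, abs=0.02)
        assert sums["haa"] == pytest.approx(53.50, abs=0.02)
        assert sums["d_t"] == pytest.approx(75.33, abs=0.02)
        assert sums["eaa_taa"] == pytest.approx(34.40, abs=0.02)

    def test_taa_is_eaa_plus_neaa(self, raw_profile):
        sums = class_sums(raw_profile)
        assert sums["taa"] == pytest.approx(sums["eaa"] + sums["neaa"], abs=1e-9)

    def test_single_residue_profile(self):
        sums = class_sums(quiet_profile({"E": 1.0}))
        assert sums["f"] == 1.0 and sums["b"] == 0.0 and sums["s"] == 0.0

    def test_linearity_under_scaling(self, raw_profile):
        base = class_sums(raw_profile)
        scaled = class_sums(
            quiet_profile({r: 3.0 * v for r, v in raw_profile.content.items()})
        )
        for key in ("taa", "eaa", "neaa", "haa", "f", "b", "s", "d"):
            assert scaled[key] == pytest.approx(3.0 * base[key])
        for key in ("eaa_taa", "f_t", "d_t"):  # ratios are scale-free
            assert scaled[key] == pytest.approx(base[key])


class TestTav:
    def test_glutamate_worked_example(self, raw_profile):
        flavour = tav(raw_profile)
        assert flavour["tav"]["E"] == pytest.approx(27290.0 / 30.0, abs=0.01)
        assert flavour["significant"]["E"]

    def test_content_at_threshold_gives_unity(self):
        flavour = tav(quiet_profile({"E": 0.03}))  # 30 mg/100 g threshold
        assert flavour["tav"]["E"] == pytest.approx(1.0)
        assert not flavour["significant"]["E"]  # strictly greater than 1

    @pytest.mark.parametrize("sample", list(PRINTED_TABLE3))
    def test_class_totals_reproduce_published(self, sample):
        flavour = tav(make_profile(sample))
        printed = PRINTED_TABLE3[sample]
        assert flavour["tft"] == pytest.approx(printed["tft"], rel=5e-3)
        assert flavour["tbt"] == pytest.approx(printed["tbt"], rel=5e-3)
        assert flavour["tst"] == pytest.approx(printed["tst"], rel=5e-3)

    def test_sweet_total_excludes_alanine_by_default(self, raw_profile):
        default = tav(raw_profile)
        with_ala = tav(raw_profile, sweet_set=frozenset("TSGA"))
        assert with_ala["tst"] == pytest.approx(
            default["tst"] + 1000.0 * raw_profile.get("A") / 60.0
        )

    def test_scaling_linearity(self, raw_profile):
        base = tav(raw_profile)
        scaled = tav(quiet_profile({r: 2.0 * v for r, v in raw_profile.content.items()}))
        assert scaled["tft"] == pytest.approx(2.0 * base["tft"])
        assert scaled["tbt"] == pytest.approx(2.0 * base["tbt"])


class TestAas:
    def test_identity_profile_scores_100(self):
        ref = ReferencePattern({"L": 59.0, "K": 45.0})
        p = quiet_profile({"L": 59.0, "K": 45.0})
        scores = aas(p, ref, normalise=False)
        assert scores == pytest.approx({"L": 100.0, "K": 100.0})

    def test_lys_then_met_limiting_on_raw_sample(self, raw_profile):
        scores = aas(raw_profile, FAO_WHO_ADULT_PATTERN)
        order = limiting_order(scores)
        assert order[0] == "K" and order[1] == "M+C"
        # Trp was not detected, so it must not appear as spuriously limiting
        assert "W" not in scores

    def test_doubling_contents_doubles_ratio_scores(self, raw_profile):
        ref = FAO_WHO_ADULT_PATTERN
        base = aas(raw_profile, ref, normalise=False)
        doubled = aas(
            quiet_profile({r: 2.0 * v for r, v in raw_profile.content.items()}),
            ref,
            normalise=False,
        )
        for key in base:
            assert doubled[key] == pytest.approx(2.0 * base[key])

    def test_normalised_scores_scale_free(self, raw_profile):
        base = aas(raw_profile)
        scaled = aas(
            quiet_profile({r: 2.0 * v for r, v in raw_profile.content.items()})
        )
        for key in base:
            assert scaled[key] == pytest.approx(base[key])

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferencePattern({"L": 0.0})


def test_full_report_is_consistent(raw_profile):
    report = nutrition_report(raw_profile)
    assert report.per1 == pytest.approx(per(raw_profile)[0])
    assert report.sums == class_sums(raw_profile)
    assert report.limiting[0] == "K"
    d = report.as_dict()
    assert d["tft"] == report.tft and d["eaa"] == report.sums["eaa"]


def test_negative_content_rejected():
    with pytest.raises(ValueError):
        AminoAcidProfile(sample_id="bad", content={"L": -1.0})
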