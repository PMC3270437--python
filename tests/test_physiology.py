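"""Lipid-basis physiology: NLE scaling, allometry, growth interpolation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidpbtk.physiology import (
    DEFAULT_CONVENTIONAL,
    DEFAULT_LIPID_CONTENT,
    ConfigurationError,
    ConventionalPhysiology,
    LipidContent,
    RatCovariates,
    body_weight_at,
    scale_for_body_weight,
    scale_to_nle,
)


class TestScaleToNLE:
    def test_reproduces_published_nle_volumes(self):
        """Conventional volumes x tissue NLE ratios give the tabulated lipid volumes."""
        nle = scale_to_nle(DEFAULT_CONVENTIONAL, DEFAULT_LIPID_CONTENT)
        assert nle.nle_volumes["fat"] == pytest.approx(14.938, abs=5e-4)
        assert nle.nle_volumes["liver"] == pytest.approx(0.425, abs=5e-4)
        assert nle.nle_volumes["slow"] == pytest.approx(2.010, abs=5e-4)
        assert nle.nle_volumes["blood"] == pytest.approx(0.038, abs=5e-4)
        assert round(nle.nle_volumes["rapid"], 3) == 0.531

    def test_reproduces_published_fat_lipid_flow(self):
        """All flows scale with the blood NLE ratio (fat: 0.85 mL lipid/h)."""
        nle = scale_to_nle(DEFAULT_CONVENTIONAL, DEFAULT_LIPID_CONTENT)
        assert nle.nle_flows["fat"] == pytest.approx(0.85, abs=5e-3)
        # every flow uses the same blood ratio
        for tissue, q in DEFAULT_CONVENTIONAL.tissue_flows.items():
            assert nle.nle_flows[tissue] == pytest.approx(q * 0.0019, rel=1e-12)
        assert nle.nle_cardiac_output == pytest.approx(4980 * 0.0019, rel=1e-12)

    def test_total_lipid_ratio_matches_lipid_content(self):
        """V_nlt/V_tlt equals each tissue's NLE per total lipid fraction."""
        nle = scale_to_nle(DEFAULT_CONVENTIONAL, DEFAULT_LIPID_CONTENT)
        for tissue in DEFAULT_CONVENTIONAL.tissue_volumes:
            expected = DEFAULT_LIPID_CONTENT[tissue].nle_per_total_lipid
            assert nle.nle_per_total_lipid(tissue) == pytest.approx(expected, abs=5e-4)

    def test_unit_nle_ratio_is_identity(self):
        lipids = {
            "blood": LipidContent("blood", 0.9999999, 1.0),
            "fat": LipidContent("fat", 0.9999999, 1.0),
        }
        conv = ConventionalPhysiology(
            tissue_flows={"fat": 100.0},
            tissue_volumes={"blood": 5.0, "fat": 10.0},
            cardiac_output=100.0,
        )
        nle = scale_to_nle(conv, lipids)
        assert nle.nle_volumes["fat"] == pytest.approx(10.0, rel=1e-6)
        assert nle.nle_flows["fat"] == pytest.approx(100.0, rel=1e-6)

    def test_missing_compartment_names_it(self):
        lipids = {k: v for k, v in DEFAULT_LIPID_CONTENT.items() if k != "liver"}
        with pytest.raises(ConfigurationError, match="liver"):
            scale_to_nle(DEFAULT_CONVENTIONAL, lipids)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(factor=st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneous_of_degree_one(self, factor):
        """Doubling all conventional values doubles all NLE values."""
        conv = DEFAULT_CONVENTIONAL
        scaled = ConventionalPhysiology(
            tissue_flows={t: q * factor for t, q in conv.tissue_flows.items()},
            tissue_volumes={t: v * factor for t, v in conv.tissue_volumes.items()},
            cardiac_output=conv.cardiac_output * factor,
        )
        a = scale_to_nle(conv, DEFAULT_LIPID_CONTENT)
        b = scale_to_nle(scaled, DEFAULT_LIPID_CONTENT)
        for t in conv.tissue_volumes:
            assert b.nle_volumes[t] == pytest.approx(a.nle_volumes[t] * factor, rel=1e-9)
        for t in conv.tissue_flows:
            assert b.nle_flows[t] == pytest.approx(a.nle_flows[t] * factor, rel=1e-9)


class TestBodyWeightScaling:
    def test_identity_at_reference_weight(self, phys):
        out = scale_for_body_weight(phys, phys.reference_body_weight)
        for t, v in phys.nle_volumes.items():
            assert out.nle_volumes[t] == pytest.approx(v, rel=1e-12)
        for t, q in phys.nle_flows.items():
            assert out.nle_flows[t] == pytest.approx(q, rel=1e-12)

    def test_doubling_weight(self, phys):
        out = scale_for_body_weight(phys, 450.0, reference_bw=225.0)
        assert out.nle_volumes["fat"] == pytest.approx(
            phys.nle_volumes["fat"] * 2.0, rel=1e-12
        )
        assert out.nle_flows["fat"] == pytest.approx(
            phys.nle_flows["fat"] * 2.0**0.75, rel=1e-12
        )

    def test_midstudy_interpolated_weight(self, phys):
        """225 -> 450 g over 90 d evaluated at day 45 scales volumes by 1.5."""
        cov = RatCovariates(225.0, 450.0, 90, 0.04)
        bw45 = body_weight_at(cov, 45.0)
        assert bw45 == pytest.approx(337.5)
        out = scale_for_body_weight(phys, bw45)
        assert out.nle_volumes["slow"] == pytest.approx(
            phys.nle_volumes["slow"] * 337.5 / 225.0, rel=1e-12
        )

    def test_liver_override_uses_measured_ratio(self, phys):
        cov = RatCovariates(225.0, 300.0, 90, 0.05)
        out = scale_for_body_weight(phys, 300.0, covariates=cov)
        liver_ratio = phys.lipid_content["liver"].nle_ratio
        assert out.nle_volumes["liver"] == pytest.approx(0.05 * 300.0 * liver_ratio)
        # total-lipid volume stays consistent with the NLE/total-lipid fraction
        assert out.nle_per_total_lipid("liver") == pytest.approx(
            phys.nle_per_total_lipid("liver")
        )

    def test_nonpositive_weight_rejected(self, phys):
        with pytest.raises(ValueError):
            scale_for_body_weight(phys, -1.0)


class TestBodyWeightAt:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 200.0), (90.0, 380.0), (45.0, 290.0), (-5.0, 200.0), (120.0, 380.0)],
    )
    def test_linear_with_constant_extrapolation(self, t, expected):
        cov = RatCovariates(200.0, 380.0, 90, 0.04)
        assert body_weight_at(cov, t) == pytest.approx(expected)


class TestConfigLoading:
    def test_yaml_overrides_merge_with_defaults(self, tmp_path):
        from lipidpbtk.physiology import load_physiology_config

        cfg = tmp_path / "phys.yaml"
        cfg.write_text(
            "lipid_content:\n"
            "  blood: {nle_ratio: 0.0018976, nle_per_total_lipid: 0.576}\n"
            "cardiac_output: 4980\n"
        )
        conv, lipids = load_physiology_config(cfg)
        # the back-calculated blood ratio override takes effect ...
        assert lipids["blood"].nle_ratio == pytest.approx(0.0018976)
        nle = scale_to_nle(conv, lipids)
        assert nle.nle_cardiac_output == pytest.approx(9.45, abs=5e-3)
        # ... while unlisted tissues keep their defaults
        assert lipids["fat"].nle_ratio == pytest.approx(0.8536)
        assert conv.tissue_volumes == DEFAULT_CONVENTIONAL.tissue_volumes


class TestValidation:
    def test_flow_imbalance_rejected(self):
        with pytest.raises(ValueError, match="cardiac output"):
            ConventionalPhysiology(
                tissue_flows={"fat": 100.0, "liver": 100.0},
                tissue_volumes={"fat": 1.0, "liver": 1.0, "blood": 1.0},
                cardiac_output=300.0,
            )

    def test_lipid_content_bounds(self):
        with pytest.raises(ValueError):
            LipidContent("fat", 1.5, 0.9)
        with pytest.raises(ValueError):
            LipidContent("fat", 0.5, 0.0)

    def test_liver_weight_ratio_bounds(self):
        with pytest.raises(ValueError):
            RatCovariates(225.0, 300.0, 90, 0.5)
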