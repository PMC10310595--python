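"""Registry constants, sample parsing, and round-trip I/O."""
import warnings

import pytest

import soilrisk as sr


class TestRegistry:
    def test_analysis_set_is_the_12_retained_metals(self, registry):
        assert set(sr.ANALYSIS_ELEMENTS) == {
            "Ag", "As", "Au", "Cd", "Cr", "Cu", "Mo", "Ni", "Pb", "Sb", "Sn", "Zn"}
        assert set(sr.ANALYSIS_ELEMENTS) <= set(registry)

    def test_packaged_constants(self, registry):
        assert registry["As"].ccme_residential == 12.0
        assert registry["As"].tdi == 0.0003
        assert registry["As"].csf == 1.8
        assert registry["Pb"].ccme_residential == 140.0
        assert registry["Pb"].tdi == 0.0036
        assert registry["Cr"].dutch_intervention == 380.0
        assert registry["Sb"].rba_rule is sr.RbaRule.FIXED_ONE
        assert registry["As"].rba_rule is sr.RbaRule.REGRESSION_AS
        assert registry["Pb"].rba_rule is sr.RbaRule.REGRESSION_PB
        for e in ("Ag", "Cr", "Cu", "Ni", "Zn"):
            assert registry[e].rba_rule is sr.RbaRule.DIRECT_IVBA
        for e in ("Cd", "Mo", "Sb", "Sn"):
            assert registry[e].rba_rule is sr.RbaRule.FIXED_ONE

    def test_csf_only_for_arsenic(self, registry):
        assert [e for e, info in registry.items() if info.csf is not None] == ["As"]

    def test_backgrounds_attach(self):
        reg = sr.builtin_registry({"Pb": 25.0})
        assert reg["Pb"].background_mean == 25.0
        with pytest.raises(KeyError):
            sr.builtin_registry({"Xx": 1.0})


class TestReadSamples:
    def test_mixed_censoring_row(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb,As\nS1,burning,6534,<4\n")
        (rec,) = sr.read_samples(p, registry)
        assert rec.measurements["Pb"].value == 6534.0
        assert not rec.measurements["Pb"].censored
        m = rec.measurements["As"]
        assert m.censored and m.detection_limit == 4.0 and m.value is None

    def test_header_only_file(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb\n")
        assert sr.read_samples(p, registry) == []

    def test_unknown_site_group_names_row(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb\nS1,downtown,5\n")
        with pytest.raises(sr.ParseError, match="row 2"):
            sr.read_samples(p, registry)

    def test_nonpositive_concentration_rejected(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb\nS1,burning,-3\n")
        with pytest.raises(sr.ValidationError):
            sr.read_samples(p, registry)

    def test_unknown_element_warns_and_ignores(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb,Kr\nS1,burning,5,9\n")
        with pytest.warns(UserWarning, match="Kr"):
            (rec,) = sr.read_samples(p, registry)
        assert "Kr" not in rec.measurements

    def test_duplicate_sample_id_rejected(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb\nS1,burning,5\nS1,burning,6\n")
        with pytest.raises(sr.ParseError, match="duplicate"):
            sr.read_samples(p, registry)

    def test_paired_flag_column_dialect(self, registry, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,site_group,Pb,Pb_censored\nS1,burning,4,true\nS2,burning,9,0\n")
        recs = sr.read_samples(p, registry)
        assert recs[0].measurements["Pb"].censored
        assert recs[0].measurements["Pb"].detection_limit == 4.0
        assert recs[1].measurements["Pb"].value == 9.0


class TestRoundTrip:
    def test_samples_round_trip_with_censoring(self, registry, tmp_path, small_dataset):
        path = tmp_path / "out.csv"
        sr.write_samples(small_dataset.samples, path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Fe column has no LOD issues
            back = sr.read_samples(path, registry)
        assert len(back) == len(small_dataset.samples)
        for a, b in zip(small_dataset.samples, back):
            assert a.sample_id == b.sample_id and a.site_group == b.site_group
            for e, m in a.measurements.items():
                m2 = b.measurements[e]
                assert m.censored == m2.censored
                if m.censored:
                    assert m2.detection_limit == pytest.approx(m.detection_limit)
                else:
                    assert m2.value == pytest.approx(m.value, rel=1e-6)

    def test_results_round_trip_and_header(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({"a": [1.5, 2.0], "b": ["x", "y"]})
        path = tmp_path / "t.csv"
        sr.write_results(df, path, header_lines=["soilrisk test", "seed=1"])
        text = path.read_text()
        assert text.startswith("# soilrisk test")
        back = sr.read_results(path)
        pd.testing.assert_frame_equal(back, df)

    def test_empty_table_allowed_explicitly(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({"a": [], "b": []})
        sr.write_results(df, tmp_path / "e.csv", allow_empty=True)
        assert sr.read_results(tmp_path / "e.csv").empty


class TestMeasurementAndReceptor:
    def test_measurement_invariants(self):
        with pytest.raises(sr.ValidationError):
            sr.Measurement(0.0)
        with pytest.raises(sr.ValidationError):
            sr.Measurement(None, censored=True, detection_limit=-1.0)
        with pytest.raises(sr.ValidationError):
            sr.Measurement(5.0, censored=True, detection_limit=4.0)

    def test_resolved_conventions(self):
        m = sr.Measurement(None, censored=True, detection_limit=4.0)
        assert m.resolved("half_lod") == 2.0
        assert m.resolved("lod") == 4.0
        assert m.resolved("zero") == 0.0
        with pytest.raises(ValueError):
            m.resolved("mean")

    def test_receptor_constraints(self):
        with pytest.raises(sr.ValidationError):
            sr.ReceptorProfile("x", ing_rate=0.0001, body_weight=70, days_per_week=8)
        with pytest.raises(sr.ValidationError):
            sr.ReceptorProfile("x", ing_rate=0.0001, body_weight=70,
                               exposure_duration=70, life_expectancy=64)
        assert sr.CHILD.exposure_fraction == 1.0
        assert sr.ADULT.carcinogen_years_fraction == 1.0


def test_config_defaults_and_thresholds(tmp_path):
    p = tmp_path / "c.yaml"
    p.write_text("backgrounds:\n  Pb: 25\nthresholds:\n  hi_limit: 2\nseed: 9\n")
    cfg = sr.read_config(p)
    assert cfg["backgrounds"]["Pb"] == 25
    assert cfg["thresholds"]["hi_limit"] == 2
    assert cfg["thresholds"]["cr_limit"] == 1e-5
    assert cfg["seed"] == 9
    assert {r.name for r in cfg["receptors"]} == {"child", "adult"}
    p2 = tmp_path / "bad.yaml"
    p2.write_text("thresholds:\n  hi_limit: -1\n")
    with pytest.raises(sr.ValidationError):
        sr.read_config(p2)
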