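import io
import textwrap

import pytest

from gojirisk.data_model import (
    ChemicalSpec,
    ConcentrationRecord,
    ConcentrationDataset,
    ExposureFactors,
    RiskConfig,
    load_config,
    read_concentrations,
    write_concentrations,
)
from gojirisk.errors import ConfigurationError, SchemaError, ValidationError
from gojirisk.synthetic_data import DEFAULT_PLANTATION, generate_concentrations


class TestRegistry:
    def test_default_adis_match_reference_values(self, registry):
        """ADIs in µg/(kg·day) for all six pesticides and six metals."""
        expected = {
            "dichlorvos": 4, "omethoate": 3, "malathion": 300,
            "cypermethrin": 20, "fenvalerate": 20, "deltamethrin": 10,
            "Pb": 3.6, "Cd": 1, "Cu": 40, "Ni": 20, "Zn": 300, "As": 0.3,
        }
        assert {c: s.adi for c, s in registry.items()} == expected

    def test_arsenic_is_the_only_carcinogen_with_slope_factor(self, registry):
        assert registry["As"].carcinogenic
        assert registry["As"].slope_factor == 1.5
        assert sum(s.carcinogenic for s in registry.values()) == 1

    def test_carcinogen_without_slope_factor_rejected(self):
        with pytest.raises(ValidationError):
            ChemicalSpec("x", "X", "metal", lod=0.01, mrl=1.0, adi=1.0,
                         carcinogenic=True, slope_factor=None)

    def test_slope_factor_on_non_carcinogen_rejected(self):
        with pytest.raises(ValidationError):
            ChemicalSpec("x", "X", "metal", lod=0.01, mrl=1.0, adi=1.0,
                         slope_factor=1.5)


TOY_CSV = textwrap.dedent(
    """\
    sample_id,source,chemical,value_mg_per_kg,censored
    s1,plantation,As,0.15,false
    s2,plantation,As,0.30,false
    s3,plantation,As,ND,true
    """
)


class TestConcentrationIO:
    def test_toy_csv_parses_with_censoring(self, registry):
        ds = read_concentrations(io.StringIO(TOY_CSV), registry)
        assert ds.source == "plantation"
        assert ds.n_samples("As") == 3
        assert [r.censored for r in ds.records_for("As")] == [False, False, True]

    def test_unknown_chemical_is_schema_error(self, registry):
        bad = TOY_CSV.replace("As", "mercury")
        with pytest.raises(SchemaError):
            read_concentrations(io.StringIO(bad), registry)

    def test_negative_value_rejected(self, registry):
        bad = TOY_CSV.replace("0.15", "-0.15")
        with pytest.raises((ValidationError, ValueError)):
            read_concentrations(io.StringIO(bad), registry)

    def test_duplicate_sample_chemical_rejected(self, registry):
        bad = TOY_CSV.replace("s2", "s1")
        with pytest.raises(ValidationError):
            read_concentrations(io.StringIO(bad), registry)

    def test_write_read_round_trip_is_identity(self, registry, plantation_dataset, tmp_path):
        path = tmp_path / "conc.csv"
        write_concentrations(plantation_dataset, path)
        back = read_concentrations(path, registry)
        assert back.source == plantation_dataset.source
        assert len(back.records) == len(plantation_dataset.records)
        for a, b in zip(back.records, plantation_dataset.records):
            assert (a.sample_id, a.chem_id, a.censored) == (b.sample_id, b.chem_id, b.censored)
            assert a.value == pytest.approx(b.value, rel=1e-5)

    def test_generator_round_trip_has_per_chemical_n(self, registry, tmp_path):
        ds = generate_concentrations(DEFAULT_PLANTATION, 3)
        path = tmp_path / "plant.csv"
        write_concentrations(ds, path)
        back = read_concentrations(path, registry)
        assert all(back.n_samples(c) == 37 for c in back.chemicals())
        assert len(back.chemicals()) == 12


class TestExposureFactors:
    @pytest.mark.parametrize(
        "kw",
        [
            {"di": 0.0}, {"ef": 0.0}, {"ef": 366.0}, {"ed": -1.0},
            {"bw": 0.0}, {"lt": 1.0}, {"dissolution": 0.0}, {"dissolution": 1.2},
        ],
    )
    def test_invalid_factors_rejected(self, kw):
        base = dict(di=1.37, ef=145.7, ed=5.93, bw=64.81)
        base.update(kw)
        with pytest.raises(ValidationError):
            ExposureFactors(**base)

    def test_default_lifespan(self, factors):
        assert factors.lt == pytest.approx(76.34)


class TestRiskConfig:
    def test_iteration_floor_and_percentile_ordering(self):
        with pytest.raises(ConfigurationError):
            RiskConfig(mc_iterations=10)
        with pytest.raises(ConfigurationError):
            RiskConfig(percentiles=(0.5, 0.1))
        with pytest.raises(ConfigurationError):
            RiskConfig(percentiles=(0.0, 0.5))

    def test_yaml_config_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("mc_iterations: 2000\nseed: 7\nnd_policy: half_lod\n")
        cfg = load_config(p)
        assert (cfg.mc_iterations, cfg.seed, cfg.nd_policy) == (2000, 7, "half_lod")
        with pytest.raises(ConfigurationError):
            load_config(io.StringIO("bogus_key: 1\n"))
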