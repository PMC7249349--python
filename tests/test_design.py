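import numpy as np
import pytest

from scsim import (SampleType, load_design, read_reference, serialize_design)
from scsim.errors import (ConfigurationError, DimensionError, FormatError,
                          RangeError)


class TestLoadDesign:
    def test_results_protocol_parses(self, results_design_yaml):
        d = load_design(results_design_yaml)
        assert d.K == 3 and d.n_snv == 100
        assert d.alpha == (0.1, 0.3, 0.6)
        assert d.n_samples == 8
        types = [s.type for _, s in d.samples]
        assert types.count(SampleType.BULK) == 4
        assert types.count(SampleType.SINGLE_CELL) == 4
        # per-unit sample count N_i sums to the total
        assert sum(len(u.samples) for u in d.units) == 8

    def test_wga_defaults_filled(self):
        d = load_design(
            "region: {start: 0, length: 1000}\n"
            "prototypes: {K: 1, n_snv: 5}\n"
            "alpha: [0.5]\n"
            "units:\n"
            "  - id: u\n    beta: 1.0\n"
            "    samples:\n"
            "      - {id: s, type: single_cell, gamma: 1.0, coverage: 2}\n"
        )
        assert d.wga.ado_rate == 0.20
        assert d.wga.fp_rate == 3.2e-5
        assert d.reads.read_length == 100

    def test_single_prototype_degenerate(self):
        d = load_design(
            "region: {start: 0, length: 1000}\n"
            "prototypes: {K: 1, n_snv: 5}\n"
            "alpha: [0.5]\n"
            "units:\n"
            "  - {id: u, beta: 1.0, samples: [{id: s, type: single_cell, gamma: 1.0, coverage: 2}]}\n"
        )
        assert d.K == 1 and d.alpha == (0.5,)

    @pytest.mark.parametrize("mutation, exc, fragment", [
        ("gamma: 1.0", None, None),  # baseline sanity (no exception)
        ("gamma: -1", RangeError, "gamma"),
        ("gamma: 1.0, n_bulk_reads: 10", ConfigurationError, "n_bulk_reads"),
    ])
    def test_sample_field_validation(self, mutation, exc, fragment):
        yaml_text = (
            "region: {start: 0, length: 1000}\n"
            "prototypes: {K: 2, n_snv: 5}\n"
            "alpha: [0.5, 0.5]\n"
            "units:\n"
            "  - {id: u, beta: 1.0, samples: [{id: s, type: single_cell, "
            f"coverage: 2, {mutation}}}]}}\n"
        )
        if exc is None:
            load_design(yaml_text)
        else:
            with pytest.raises(exc, match=fragment):
                load_design(yaml_text)

    def test_missing_field_names_it(self):
        with pytest.raises(ConfigurationError, match="region"):
            load_design("prototypes: {K: 1, n_snv: 5}\nalpha: [1]\nunits: []\n")

    def test_alpha_length_mismatch(self):
        with pytest.raises(DimensionError, match="alpha"):
            load_design(
                "region: {start: 0, length: 1000}\n"
                "prototypes: {K: 3, n_snv: 5}\n"
                "alpha: [0.5, 0.5]\n"
                "units:\n"
                "  - {id: u, beta: 1.0, samples: [{id: s, type: single_cell, gamma: 1, coverage: 2}]}\n"
            )

    def test_bulk_requires_read_count(self):
        with pytest.raises(ConfigurationError, match="n_bulk_reads"):
            load_design(
                "region: {start: 0, length: 1000}\n"
                "prototypes: {K: 1, n_snv: 5}\n"
                "alpha: [1]\n"
                "units:\n"
                "  - {id: u, beta: 1.0, samples: [{id: s, type: bulk, gamma: 1, coverage: 2}]}\n"
            )

    def test_region_too_small_for_sites(self):
        with pytest.raises(RangeError, match="region"):
            load_design(
                "region: {start: 0, length: 8}\n"
                "prototypes: {K: 1, n_snv: 5}\n"
                "alpha: [1]\n"
                "units:\n"
                "  - {id: u, beta: 1.0, samples: [{id: s, type: single_cell, gamma: 1, coverage: 2}]}\n"
            )

    def test_yaml_round_trip(self, results_design_yaml):
        d = load_design(results_design_yaml)
        d2 = load_design(serialize_design(d))
        assert d2.alpha == d.alpha
        assert d2.units == d.units
        assert d2.wga == d.wga and d2.reads == d.reads
        assert np.array_equal(d2.subst.subst_matrix, d.subst.subst_matrix)
        assert (d2.region_start, d2.region_length, d2.seed) == \
               (d.region_start, d.region_length, d.seed)


class TestReadReference:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">chrX\n" + "ACGT" * 250 + "\n")
        name, seq = read_reference(p)
        assert name == "chrX" and len(seq) == 1000

    def test_multi_record_uses_first(self, tmp_path, caplog):
        p = tmp_path / "r.fa"
        p.write_text(">one\nACGTACGT\n>two\nTTTT\n")
        with caplog.at_level("WARNING"):
            name, seq = read_reference(p)
        assert name == "one" and seq == "ACGTACGT"
        assert any("multiple records" in r.message for r in caplog.records)

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">c\nacgtn\n")
        assert read_reference(p)[1] == "ACGTN"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_reference(p)

    def test_non_iupac_rejected(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">c\nACGTZ\n")
        with pytest.raises(FormatError, match="non-IUPAC"):
            read_reference(p)
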