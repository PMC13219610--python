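import numpy as np
import pytest

from toxqsar.datamodel import (CompoundTable, DescriptorSpec, PredictionSet,
                               ValidationError, read_table, write_table,
                               summarize, reference_specs, target_spec)

from conftest import random_table


def write_csv(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


CSV3 = """compound_id,NRB,nROH,nDB,MW,A,LogP,GATS1p,B,pIGC50
c1,1,0,0,150.0,0.2,1.5,1.0,0.4,3.2
c2,2,1,0,180.0,0.3,2.5,1.2,0.5,3.9
c3,0,0,1,120.0,0.1,0.5,0.9,0.3,2.8
"""


class TestDescriptorSpec:
    def test_table1_defaults_valid(self):
        specs = reference_specs()
        assert [s.name for s in specs] == ["NRB", "nROH", "nDB", "MW", "A",
                                           "LogP", "GATS1p", "B"]
        directions = {s.name: s.monotone_direction for s in specs}
        assert directions["LogP"] == directions["MW"] == directions["nDB"] == 1
        assert directions["nROH"] == -1
        assert directions["NRB"] == directions["A"] == 0

    def test_variance_sd_consistency_enforced(self):
        with pytest.raises(ValidationError):
            DescriptorSpec("x", "continuous", 0, 1, 0.5, 0.5, 0.1, 0.5, 0.0)

    def test_discrete_bounds_must_be_integer(self):
        with pytest.raises(ValidationError):
            DescriptorSpec("x", "discrete", 0.5, 3, 1, 1, 1, 1, 0.0)

    def test_mode_within_bounds(self):
        with pytest.raises(ValidationError):
            DescriptorSpec("x", "continuous", 0, 1, 2.0, 0.5, 0.1, 0.01, 0.0)


class TestReadWrite:
    def test_identity_roundtrip_three_rows(self, tmp_path):
        t = read_table(write_csv(tmp_path, CSV3))
        assert t.n == 3 and t.p == 8
        assert t.y is not None and t.y[1] == pytest.approx(3.9)

    def test_duplicate_identical_rows_collapsed(self, tmp_path, caplog):
        dup = CSV3 + "c3,0,0,1,120.0,0.1,0.5,0.9,0.3,2.8\n"
        with caplog.at_level("INFO", logger="toxqsar"):
            t = read_table(write_csv(tmp_path, dup))
        assert t.n == 3
        assert any("collapsed 1" in r.getMessage() for r in caplog.records)

    def test_conflicting_duplicate_ids_error(self, tmp_path):
        dup = CSV3 + "c3,0,0,1,999.0,0.1,0.5,0.9,0.3,2.8\n"
        with pytest.raises(ValidationError, match="conflicting"):
            read_table(write_csv(tmp_path, dup))

    def test_missing_cell_names_row_and_column(self, tmp_path):
        bad = CSV3.replace("180.0,0.3,2.5", "180.0,0.3,")
        with pytest.raises(ValidationError, match=r"row 1.*LogP"):
            read_table(write_csv(tmp_path, bad))

    def test_roundtrip_without_target(self, tmp_path):
        rng = np.random.default_rng(0)
        t = random_table(rng, with_y=False)
        path = tmp_path / "nt.csv"
        write_table(t, path)
        assert "pIGC50" not in path.read_text().splitlines()[0]
        back = read_table(path)
        assert back.y is None
        np.testing.assert_allclose(back.X, t.X, rtol=1e-12)

    def test_empty_table_roundtrip(self, tmp_path):
        t = CompoundTable(np.array([], dtype=object), np.empty((0, 2)),
                          [DescriptorSpec("a", "continuous", 0, 1, 0.5, 0.5,
                                          0.1, 0.01, 0.0),
                           DescriptorSpec("b", "continuous", 0, 1, 0.5, 0.5,
                                          0.1, 0.01, 0.0)], None)
        path = tmp_path / "empty.csv"
        write_table(t, path)
        back = read_table(path)
        assert back.n == 0 and back.p == 2

    def test_roundtrip_identity_100_random_tables(self, tmp_path):
        rng = np.random.default_rng(42)
        for i in range(100):
            t = random_table(rng, n=int(rng.integers(2, 15)),
                             p=int(rng.integers(1, 6)))
            path = tmp_path / f"r{i}.csv"
            write_table(t, path)
            back = read_table(path)
            np.testing.assert_allclose(back.X, t.X, rtol=1e-12)
            np.testing.assert_allclose(back.y, t.y, rtol=1e-12)
            assert list(back.ids) == list(t.ids)

    def test_dedup_idempotent(self, tmp_path):
        dup = CSV3 + "c3,0,0,1,120.0,0.1,0.5,0.9,0.3,2.8\n"
        t1 = read_table(write_csv(tmp_path, dup, "a.csv"))
        path2 = tmp_path / "b.csv"
        write_table(t1, path2)
        t2 = read_table(path2)
        assert t2.n == t1.n
        np.testing.assert_array_equal(t1.X, t2.X)


class TestSummarize:
    def test_constant_column(self):
        spec = DescriptorSpec("c", "continuous", 0, 2, 1, 1, 0, 0, 0.0)
        t = CompoundTable(np.array(["a", "b", "c", "d"], dtype=object),
                          np.ones((4, 1)), [spec], None)
        s = summarize(t)
        assert s["c"]["sd"] == 0 and s["c"]["variance"] == 0

    def test_hand_arithmetic(self):
        spec = DescriptorSpec("v", "continuous", 0, 4, 2, 2, 1, 1, 0.0)
        t = CompoundTable(np.array(["a", "b", "c"], dtype=object),
                          np.array([[1.0], [2.0], [3.0]]), [spec], None)
        s = summarize(t)["v"]
        assert s["mean"] == pytest.approx(2.0)
        assert s["sd"] == pytest.approx(1.0)     # sample convention
        assert s["median"] == pytest.approx(2.0)

    def test_n1_rejected(self):
        spec = DescriptorSpec("v", "continuous", 0, 4, 2, 2, 1, 1, 0.0)
        t = CompoundTable(np.array(["a"], dtype=object),
                          np.array([[1.0]]), [spec], None)
        with pytest.raises(ValidationError):
            summarize(t)

    def test_variance_equals_sd_squared(self, table_medium):
        s = summarize(table_medium)
        for col in s.values():
            assert col["variance"] == pytest.approx(col["sd"] ** 2,
                                                    rel=1e-9)

    def test_generated_target_mean_near_reference(self, gen_config):
        from toxqsar.synthetic import generate
        t = generate(gen_config, 1792, seed=77)
        s = summarize(t)
        assert abs(s["pIGC50"]["mean"] - 3.267) < 0.05


class TestPredictionSet:
    def test_bounds_must_bracket(self):
        with pytest.raises(ValidationError):
            PredictionSet(np.zeros(3), np.zeros(3),
                          lower=np.full(3, 0.5), upper=np.ones(3))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            PredictionSet(np.zeros(3), np.zeros(3), sigma=np.full(3, -1.0))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            PredictionSet(np.zeros(3), np.zeros(4))


class TestCompoundTable:
    def test_duplicate_ids_rejected(self):
        spec = DescriptorSpec("v", "continuous", 0, 4, 2, 2, 1, 1, 0.0)
        with pytest.raises(ValidationError):
            CompoundTable(np.array(["a", "a"], dtype=object),
                          np.array([[1.0], [2.0]]), [spec], None)

    def test_discrete_integer_enforced(self):
        spec = DescriptorSpec("d", "discrete", 0, 5, 1, 1, 1, 1, 0.0)
        with pytest.raises(ValidationError):
            CompoundTable(np.array(["a"], dtype=object),
                          np.array([[1.5]]), [spec], None)

    def test_target_spec_reference_values(self):
        ts = target_spec()
        assert ts.mean == pytest.approx(3.267)
        assert ts.sd == pytest.approx(1.051)
        assert (ts.lower, ts.upper) == (0.33, 6.36)
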