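import numpy as np
import pytest

import topostats as ts
from topostats.data_io import (AsciiFormatError, ImportError_, Session,
                               apply_average_reference, import_dataset,
                               read_ascii_map_series, read_montage,
                               write_ascii_map_series)
from topostats.measures import gfp
from topostats.simulate import GenerativeSpec, generate, write_ascii_directory


class TestAsciiMapSeries:
    def test_direct_parse(self, tmp_path):
        f = tmp_path / "m.asc"
        f.write_text("1 2\n3 4\n")
        assert read_ascii_map_series(f).tolist() == [[1.0, 2.0], [3.0, 4.0]]

    def test_tabs_and_blank_lines(self, tmp_path):
        f = tmp_path / "m.asc"
        f.write_text("1\t2\n\n  3   4  \n")
        assert read_ascii_map_series(f).shape == (2, 2)

    @pytest.mark.parametrize("content, match", [
        ("1 2\n3\n", "line 2"),
        ("1 2\nx 4\n", "non-numeric"),
        ("", "no data"),
    ])
    def test_malformed_files(self, tmp_path, content, match):
        f = tmp_path / "bad.asc"
        f.write_text(content)
        with pytest.raises(AsciiFormatError, match=match):
            read_ascii_map_series(f)

    def test_write_read_round_trip(self, tmp_path, rng):
        m = rng.standard_normal((10, 8)) * 37.0
        f = tmp_path / "rt.asc"
        write_ascii_map_series(m, f)
        back = read_ascii_map_series(f)
        assert np.allclose(back, m, rtol=1e-12, atol=1e-12)


class TestImportDataset:
    @pytest.fixture()
    def ascii_dir(self, tmp_path):
        ds, _ = generate(GenerativeSpec(
            n_subjects=3, design_shape=(2,), n_time=6, n_sensors=4, seed=9))
        write_ascii_directory(ds, tmp_path)
        return tmp_path, ds

    def test_round_trip_equals_source(self, ascii_dir):
        directory, ds = ascii_dir
        back = import_dataset(directory, "S*_C1.asc", ["C1", "C2"],
                              apply_reference=False)
        assert back.n_subjects == 3 and back.n_conditions == 2
        assert np.allclose(back.data, ds.data, rtol=1e-12, atol=1e-10)
        assert back.condition_labels == ("C1", "C2")

    def test_subject_order_is_lexicographic(self, ascii_dir):
        directory, _ = ascii_dir
        back = import_dataset(directory, "S*_C1.asc", ["C1", "C2"])
        assert list(back.subject_labels) == sorted(back.subject_labels)

    def test_missing_file_listed(self, ascii_dir):
        directory, _ = ascii_dir
        (directory / "S02_C2.asc").unlink()
        with pytest.raises(ImportError_, match="S02_C2.asc"):
            import_dataset(directory, "S*_C1.asc", ["C1", "C2"])

    def test_mask_without_tag_rejected(self, ascii_dir):
        directory, _ = ascii_dir
        with pytest.raises(ImportError_, match="condition tags"):
            import_dataset(directory, "S*_X9.asc", ["C1", "C2"])

    def test_no_match_rejected(self, tmp_path):
        with pytest.raises(ImportError_, match="matched no files"):
            import_dataset(tmp_path, "S*_C1.asc", ["C1"])

    def test_inconsistent_shapes_rejected(self, ascii_dir):
        directory, _ = ascii_dir
        (directory / "S03_C2.asc").write_text("1 2 3 4\n")
        with pytest.raises(ImportError_, match="shape"):
            import_dataset(directory, "S*_C1.asc", ["C1", "C2"])


class TestAverageReference:
    def test_subtracts_spatial_mean(self):
        ds = ts.ErpDataset(np.array([1.0, 2.0, 3.0]).reshape(1, 1, 1, 3))
        ref = apply_average_reference(ds)
        assert ref.data.ravel() == pytest.approx([-1.0, 0.0, 1.0])
        assert ref.average_referenced

    def test_idempotent_and_gfp_preserving(self, rng):
        ds = ts.ErpDataset(rng.standard_normal((2, 2, 5, 8)) + 4.0)
        once = apply_average_reference(ds)
        twice = apply_average_reference(once)
        assert np.allclose(once.data, twice.data)
        for s, c, t in [(0, 0, 0), (1, 1, 4)]:
            assert gfp(once.data[s, c, t]) == pytest.approx(
                gfp(ds.data[s, c, t]), rel=1e-12)
        assert np.max(np.abs(once.data.mean(axis=3))) < 1e-10

    def test_single_sensor_rejected(self):
        ds = ts.ErpDataset(np.ones((1, 1, 2, 1)))
        with pytest.raises(ValueError):
            apply_average_reference(ds)


class TestDatasetInvariants:
    def test_non_finite_rejected(self):
        bad = np.ones((1, 1, 2, 3))
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing data"):
            ts.ErpDataset(bad)

    def test_window_to_samples_half_open(self):
        ds = ts.ErpDataset(np.zeros((1, 1, 250, 2)), sampling_rate=250.0)
        lo, hi = ds.window_to_samples(780.0, 890.0)
        assert (lo, hi) == (195, 223)  # [780, 890) ms at 4 ms/sample

    def test_times_axis(self):
        ds = ts.ErpDataset(np.zeros((1, 1, 4, 2)), sampling_rate=500.0,
                           onset_latency=-10.0)
        assert ds.times_ms == pytest.approx([-10.0, -8.0, -6.0, -4.0])


class TestSession:
    def test_full_round_trip_bitwise(self, tmp_path, within_2x2, groups_2,
                                     small_null_dataset):
        opts = ts.RandomizationOptions(n_runs=20, seed=5)
        with pytest.warns(UserWarning):
            res = ts.run_tanova(small_null_dataset, within_2x2, groups_2,
                                opts)
        gi = ts.infer_global(res)
        sess = Session(small_null_dataset, within=within_2x2,
                       between=groups_2,
                       results={"randomization": res, "global": gi})
        path = tmp_path / "analysis.tss"
        ts.save_session(sess, path)
        back = ts.load_session(path)
        assert np.array_equal(back.dataset.data, small_null_dataset.data)
        assert back.within == within_2x2
        assert back.between == groups_2
        for eid in res.p:
            assert np.array_equal(back.results["randomization"].null[eid],
                                  res.null[eid])
            assert np.array_equal(back.results["randomization"].p[eid],
                                  res.p[eid])
        assert back.results["global"]["GxA"].count_p == gi["GxA"].count_p

    def test_truncated_archive_is_an_error(self, tmp_path,
                                           small_null_dataset):
        path = tmp_path / "s.tss"
        ts.save_session(Session(small_null_dataset), path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(ValueError, match="session archive"):
            ts.load_session(path)

    def test_missing_path_is_file_not_found(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ts.load_session(tmp_path / "absent.tss")

    def test_version_mismatch_rejected(self, tmp_path, small_null_dataset):
        import json
        import zipfile
        path = tmp_path / "s.tss"
        ts.save_session(Session(small_null_dataset), path)
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            arrays = {n: zf.read(n) for n in zf.namelist() if n != "manifest.json"}
        manifest["format"] = "topostats-session/99"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest))
            for n, blob in arrays.items():
                zf.writestr(n, blob)
        with pytest.raises(ValueError, match="format"):
            ts.load_session(path)


def test_montage_round_trip(tmp_path):
    f = tmp_path / "montage.txt"
    f.write_text("# name x y\nFz 0.0 0.8\nCz 0.0 0.0\nPz 0.0 -0.8\n")
    mont = read_montage(f)
    assert mont.names == ("Fz", "Cz", "Pz")
    assert mont.positions.shape == (3, 2)
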