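"""Manifest, AU-table, count-table, and config round trips and validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmex.manifests import (AU_COLUMNS, BENCHMARK_COUNTS, LABELS, CountTable,
                                ManifestFormatError, ManifestValidationError,
                                RunConfig, SampleRecord, as_au_vector,
                                count_table_from_manifest, map_raw_labels,
                                read_au_table, read_manifest, write_au_table,
                                write_manifest)


def _rec(i, dataset="ds1", label="Positive", **kw):
    kw.setdefault("image_ref", f"img_{i}.png")
    return SampleRecord(sample_id=f"s{i}", source_dataset=dataset, label=label, **kw)


class TestSampleRecord:
    def test_unknown_label_rejected(self):
        with pytest.raises(ManifestValidationError, match="Happiness"):
            SampleRecord(sample_id="a", source_dataset="d", label="Happiness",
                         image_ref="x.png")

    def test_requires_some_modality(self):
        with pytest.raises(ManifestValidationError, match="at least one"):
            SampleRecord(sample_id="a", source_dataset="d", label="Positive")

    def test_au_attached_is_validated(self):
        r = SampleRecord(sample_id="a", source_dataset="d", label="Positive",
                         au=np.full(17, 2.0))
        assert r.au.shape == (17,)
        with pytest.raises(ManifestValidationError):
            SampleRecord(sample_id="a", source_dataset="d", label="Positive",
                         au=np.zeros(5))


class TestManifestIO:
    def test_three_row_round_trip(self, tmp_path):
        recs = [_rec(0), _rec(1, label="Negative"), _rec(2, dataset="ds2",
                                                         label="Surprise")]
        path = write_manifest(recs, tmp_path / "m.csv")
        back = read_manifest(path)
        assert len(back) == 3
        assert [r.sample_id for r in back] == ["s0", "s1", "s2"]
        assert [r.label for r in back] == ["Positive", "Negative", "Surprise"]

    def test_duplicate_sample_id_rejected(self, tmp_path):
        df = pd.DataFrame({
            "sample_id": ["a", "a"], "dataset": ["d", "d"],
            "label": ["Positive", "Negative"], "image_path": ["x", "y"],
            "flow_path": ["", ""], "split": ["train", "train"]})
        df.to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ManifestValidationError, match="duplicate"):
            read_manifest(tmp_path / "m.csv")

    def test_missing_column_is_format_error(self, tmp_path):
        pd.DataFrame({"sample_id": ["a"]}).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ManifestFormatError, match="missing column"):
            read_manifest(tmp_path / "m.csv")

    def test_raw_label_in_file_names_offending_row(self, tmp_path):
        df = pd.DataFrame({
            "sample_id": ["a", "b"], "dataset": ["d", "d"],
            "label": ["Positive", "happiness"], "image_path": ["x", "y"],
            "flow_path": ["", ""], "split": ["train", "train"]})
        df.to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ManifestValidationError, match="row 3"):
            read_manifest(tmp_path / "m.csv")

    @settings(max_examples=25, deadline=None)
    @given(rows=st.lists(
        st.tuples(st.sampled_from(["dsA", "dsB", "dsC"]),
                  st.sampled_from(LABELS),
                  st.sampled_from(["train", "test"]),
                  st.booleans()),
        min_size=1, max_size=20))
    def test_round_trip_is_lossless(self, rows, tmp_path_factory):
        recs = [SampleRecord(sample_id=f"s{i}", source_dataset=d, label=lab,
                             image_ref=f"{i}.png", split=split, synthetic=syn)
                for i, (d, lab, split, syn) in enumerate(rows)]
        path = tmp_path_factory.mktemp("rt") / "m.csv"
        back = read_manifest(write_manifest(recs, path), resolve_paths=False)
        assert [(r.sample_id, r.source_dataset, r.label, r.image_ref, r.split,
                 r.synthetic) for r in back] == \
               [(r.sample_id, r.source_dataset, r.label, r.image_ref, r.split,
                 r.synthetic) for r in recs]


class TestAUTable:
    def test_zero_row_round_trip(self, tmp_path):
        path = write_au_table({"a": np.zeros(17)}, tmp_path / "au.csv")
        assert np.array_equal(read_au_table(path)["a"], np.zeros(17))

    def test_out_of_range_clipped_with_warning(self, tmp_path, caplog):
        df = pd.DataFrame([{"sample_id": "a", **{c: 0.0 for c in AU_COLUMNS}}])
        df["AU12_r"] = 7.2
        df.to_csv(tmp_path / "au.csv", index=False)
        with caplog.at_level("WARNING", logger="crossmex"):
            au = read_au_table(tmp_path / "au.csv")
        assert au["a"][AU_COLUMNS.index("AU12_r")] == 5.0
        assert any("clipped" in m for m in caplog.messages)

    def test_missing_au_column_is_format_error(self, tmp_path):
        df = pd.DataFrame([{"sample_id": "a",
                            **{c: 0.0 for c in AU_COLUMNS[:-1]}}])
        df.to_csv(tmp_path / "au.csv", index=False)
        with pytest.raises(ManifestFormatError, match="AU45_r"):
            read_au_table(tmp_path / "au.csv")

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        df = pd.DataFrame([{"sample_id": "a", **{c: 0.0 for c in AU_COLUMNS}}])
        df["AU01_r"] = "oops"
        df.to_csv(tmp_path / "au.csv", index=False)
        with pytest.raises(ManifestFormatError, match="non-numeric"):
            read_au_table(tmp_path / "au.csv")

    def test_generator_ground_truth_round_trips(self, toy_bench_dir):
        out, bench = toy_bench_dir
        back = read_au_table(out / "au_table.csv")
        for sid, au in bench.au_map.items():
            assert np.allclose(back[sid], au, atol=1e-9)


class TestCountTable:
    def test_benchmark_counts_grand_total(self, table1_records):
        table = count_table_from_manifest(table1_records)
        assert table.grand_total == 731
        assert table.row_totals().tolist() == [164, 83, 129, 121, 234]

    def test_empty_manifest_zero_table(self):
        table = count_table_from_manifest([], datasets=["d1"])
        assert table.grand_total == 0

    def test_matches_brute_force_tally_and_order_invariant(self):
        rng = np.random.default_rng(0)
        datasets = ["d1", "d2", "d3"]
        recs = [_rec(i, dataset=rng.choice(datasets), label=rng.choice(LABELS))
                for i in range(120)]
        table = count_table_from_manifest(recs, datasets=datasets)
        for d in datasets:
            for c in LABELS:
                expected = sum(1 for r in recs
                               if r.source_dataset == d and r.label == c)
                assert table[d, c] == expected
        shuffled = list(recs)
        rng.shuffle(shuffled)
        table2 = count_table_from_manifest(shuffled, datasets=datasets)
        assert np.array_equal(table.counts, table2.counts)

    def test_csv_round_trip(self, tmp_path):
        path = BENCHMARK_COUNTS.to_csv(tmp_path / "c.csv")
        back = CountTable.from_csv(path)
        assert back.datasets == BENCHMARK_COUNTS.datasets
        assert np.array_equal(back.counts, BENCHMARK_COUNTS.counts)


class TestLabelMapping:
    def test_default_mapping(self):
        mapped, excluded = map_raw_labels(
            ["happiness", "Disgust", "repression", "surprise", "other"])
        assert mapped == ["Positive", "Negative", "Negative", "Surprise", None]
        assert excluded == 1


class TestRunConfig:
    def test_lambda_must_keep_ce_weight(self):
        with pytest.raises(ValueError, match="lambda"):
            RunConfig(lambda_weight=1.0)

    def test_brl_start_within_schedule(self):
        with pytest.raises(ValueError, match="brl_start"):
            RunConfig(epochs=10, brl_start_epoch=11)

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_file_round_trip(self, tmp_path, suffix):
        cfg = RunConfig(lambda_weight=0.3, epochs=7, brl_start_epoch=2, seed=5)
        back = RunConfig.from_file(cfg.to_file(tmp_path / f"c{suffix}"))
        assert back == cfg

    def test_paper_operating_point_is_default(self):
        cfg = RunConfig()
        assert (cfg.lambda_weight, cfg.epochs, cfg.brl_start_epoch) == (0.5, 100, 50)
        assert (cfg.learning_rate, cfg.weight_decay) == (2e-4, 5e-4)


def test_au_vector_validation():
    assert as_au_vector(np.full(17, 2.5)).tolist() == [2.5] * 17
    with pytest.raises(ManifestValidationError):
        as_au_vector(np.full(17, np.nan))
    with pytest.raises(ManifestValidationError):
        as_au_vector(np.full(17, 6.0), clip=False)
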