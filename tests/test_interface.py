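import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner
from PIL import Image

from fundusseg import io as fio
from fundusseg.cli import main as cli_main
from fundusseg.crossval import kfold_splits, run_crossval
from fundusseg.network import NetworkConfig
from fundusseg.phantom import generate_dataset
from fundusseg.training import MMLMConfig


class TestKfoldSplits:
    def test_unlabelled_items_split_in_order(self):
        splits = kfold_splits([0] * 50, k=5)
        for f, (train, test) in enumerate(splits):
            assert test == list(range(10 * f, 10 * (f + 1)))
            assert len(train) == 40

    def test_stratified_counts_per_fold(self):
        labels = [0, 0, 1, 0, 1, 0, 0, 1, 0]  # 6 class-0, 3 class-1
        splits = kfold_splits(labels, k=3)
        for _, test in splits:
            assert sum(1 for i in test if labels[i] == 0) == 2
            assert sum(1 for i in test if labels[i] == 1) == 1

    def test_folds_disjoint_and_cover(self):
        labels = [i % 3 for i in range(23)]
        splits = kfold_splits(labels, k=5)
        seen = []
        for train, test in splits:
            assert set(train).isdisjoint(test)
            seen.extend(test)
        assert sorted(seen) == list(range(23))

    def test_scarce_label_concentrates_early(self):
        labels = [0] * 10 + [1]  # one class-1 item, k=5
        splits = kfold_splits(labels, k=5)
        assert 10 in splits[0][1]

    def test_too_few_items_raises(self):
        with pytest.raises(ValueError):
            kfold_splits([0, 1], k=3)


class TestMaskIO:
    def test_write_read_round_trip(self, tmp_path):
        mask = (np.random.default_rng(0).random((32, 32)) > 0.5).astype(np.uint8)
        path = tmp_path / "m.png"
        fio.write_mask(path, mask)
        assert np.array_equal(fio.read_mask(path), mask)

    def test_rgb_mask_rejected(self, tmp_path):
        path = tmp_path / "rgb.png"
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(path)
        with pytest.raises(ValueError):
            fio.read_mask(path)

    def test_sixteen_bit_mask_normalised(self, tmp_path):
        arr = np.zeros((8, 8), dtype=np.uint16)
        arr[2:5, 2:5] = 65535
        arr[0, 0] = 20000  # below half range -> 0
        path = tmp_path / "m16.png"
        Image.fromarray(arr).save(path)
        got = fio.read_mask(path)
        expected = (arr > 32767).astype(np.uint8)
        assert np.array_equal(got, expected)

    def test_image_round_trip(self, tmp_path):
        img = np.random.default_rng(1).integers(0, 255, (16, 16, 3), dtype=np.uint8)
        path = tmp_path / "img.png"
        fio.write_image(path, img)
        assert np.array_equal(fio.read_image(path), img)


class TestConfigIO:
    def test_round_trip(self, tmp_path):
        net_cfg = NetworkConfig(input_side=64, base_width=4, seed=3)
        train_cfg = MMLMConfig(epochs=7, lambda2=1.5, seed=3)
        path = tmp_path / "cfg.yaml"
        fio.save_configs(path, net_cfg, train_cfg)
        n2, t2 = fio.load_configs(path)
        assert n2 == net_cfg
        assert t2 == train_cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("input_side: 64\nbogus_key: 1\n")
        with pytest.raises(ValueError):
            fio.load_configs(path)

    def test_missing_input_side_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("epochs: 3\n")
        with pytest.raises(ValueError):
            fio.load_configs(path)


class TestCrossval:
    def test_smoke_run_emits_both_tables(self):
        samples = generate_dataset(15, 0.2, side=32, seed=8)
        net_cfg = NetworkConfig(input_side=32, base_width=2, seed=0)
        cfg = MMLMConfig(epochs=1, n_max=4, n_min=2, k_max=2, k_min=1, seed=0)
        od_table, oc_table = run_crossval(samples, net_cfg, net_cfg, cfg, strategy="alm", k=3)
        assert len(od_table) == len(samples)
        assert len(oc_table) == len(samples)
        fold_means = od_table.groupby("fold")["f_score"].mean()
        grand = od_table["f_score"].groupby(od_table["fold"]).mean().mean()
        assert grand == pytest.approx(fold_means.mean())
        assert set(od_table.columns) >= {"index", "fold", "f_score", "iou", "sensitivity", "specificity"}


@pytest.fixture
def cli_dataset(tmp_path):
    runner = CliRunner()
    out = tmp_path / "data"
    res = runner.invoke(cli_main, ["generate", "--n", "6", "--side", "32", "--seed", "5", "--rare-fraction", "0.2", "--out-dir", str(out)])
    assert res.exit_code == 0, res.output
    return out


class TestCli:
    def test_generate_writes_manifest_and_files(self, cli_dataset):
        manifest = pd.read_csv(cli_dataset / "manifest.csv")
        assert len(manifest) == 6
        for _, row in manifest.iterrows():
            assert (cli_dataset / row["image"]).exists()
            assert (cli_dataset / row["od_mask"]).exists()
            assert (cli_dataset / row["oc_mask"]).exists()

    def test_generate_reproducible_with_equal_seeds(self, tmp_path):
        runner = CliRunner()
        for name in ("a", "b"):
            res = runner.invoke(cli_main, ["generate", "--n", "5", "--side", "32", "--seed", "3", "--out-dir", str(tmp_path / name)])
            assert res.exit_code == 0, res.output
        csv_a = (tmp_path / "a" / "manifest.csv").read_bytes()
        csv_b = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert csv_a == csv_b
        img_a = (tmp_path / "a" / "phantom_0000.png").read_bytes()
        img_b = (tmp_path / "b" / "phantom_0000.png").read_bytes()
        assert img_a == img_b

    def test_train_segment_evaluate_screen_chain(self, cli_dataset, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        yaml.safe_dump(
            dict(input_side=32, base_width=2, epochs=2, n_max=3, n_min=2, k_max=2, k_min=1, seed=1),
            cfg.open("w"),
        )
        weights_od = tmp_path / "od.npz"
        weights_oc = tmp_path / "oc.npz"
        for which, wpath in (("train-od", weights_od), ("train-oc", weights_oc)):
            res = runner.invoke(
                cli_main,
                [which, "--manifest", str(cli_dataset / "manifest.csv"), "--config", str(cfg),
                 "--strategy", "mmlm", "--out-weights", str(wpath), "--history-csv", str(tmp_path / f"{which}.csv")],
            )
            assert res.exit_code == 0, res.output
            hist = pd.read_csv(tmp_path / f"{which}.csv")
            assert list(hist.columns) == ["t", "n_t", "k_t", "mean_loss", "mean_F", "min_F"]
            assert len(hist) == 2
        seg_out = tmp_path / "seg"
        res = runner.invoke(
            cli_main,
            ["segment", "--image", str(cli_dataset / "phantom_0000.png"), "--od-weights", str(weights_od),
             "--oc-weights", str(weights_oc), "--out-dir", str(seg_out)],
        )
        assert res.exit_code == 0, res.output
        assert (seg_out / "phantom_0000_od.png").exists()
        res = runner.invoke(
            cli_main,
            ["evaluate", "--manifest", str(cli_dataset / "manifest.csv"), "--od-weights", str(weights_od),
             "--oc-weights", str(weights_oc), "--out", str(tmp_path / "eval.csv")],
        )
        assert res.exit_code == 0, res.output
        ev = pd.read_csv(tmp_path / "eval.csv")
        assert len(ev) == 12  # 6 images x {od, oc}
        # screening on the ground-truth masks in the dataset dir
        masks_dir = tmp_path / "masks"
        masks_dir.mkdir()
        manifest = pd.read_csv(cli_dataset / "manifest.csv")
        label_rows = []
        for i, row in manifest.iterrows():
            stem = f"p{i:02d}"
            (masks_dir / f"{stem}_od.png").write_bytes((cli_dataset / row["od_mask"]).read_bytes())
            (masks_dir / f"{stem}_oc.png").write_bytes((cli_dataset / row["oc_mask"]).read_bytes())
            label_rows.append(dict(stem=stem, label=row["label"]))
        labels_csv = tmp_path / "labels.csv"
        pd.DataFrame(label_rows).to_csv(labels_csv, index=False)
        res = runner.invoke(
            cli_main,
            ["screen", "--masks-dir", str(masks_dir), "--labels", str(labels_csv), "--out", str(tmp_path / "screen.csv")],
        )
        assert res.exit_code == 0, res.output
        sc = pd.read_csv(tmp_path / "screen.csv")
        assert len(sc) == 6
        assert (sc["vcdr"] >= 0).all() and (sc["vcdr"] <= 1).all()

    def test_training_history_reproducible_with_equal_seeds(self, cli_dataset, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        yaml.safe_dump(
            dict(input_side=32, base_width=2, epochs=2, n_max=3, n_min=2, k_max=2, k_min=1, seed=4),
            cfg.open("w"),
        )
        hists = []
        for name in ("h1.csv", "h2.csv"):
            res = runner.invoke(
                cli_main,
                ["train-od", "--manifest", str(cli_dataset / "manifest.csv"), "--config", str(cfg),
                 "--out-weights", str(tmp_path / (name + ".npz")), "--history-csv", str(tmp_path / name)],
            )
            assert res.exit_code == 0, res.output
            hists.append((tmp_path / name).read_bytes())
        assert hists[0] == hists[1]
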