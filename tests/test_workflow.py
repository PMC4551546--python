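"""End-to-end workflow: the Model/Results facade, bundle replay, PCM path, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from qsarkit import (
    DescriptorConfig,
    ModelBundle,
    QsarModel,
    WorkflowConfig,
    predict_external,
)
from qsarkit.cli import main as cli_main
from qsarkit.model import ensemble_from_bundles
from qsarkit.synthetic import SyntheticSpec, make_qspr_fixture

MINIMAL = DescriptorConfig(physchem="rdkit_minimal")


@pytest.fixture(scope="module")
def noisy_results():
    table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=120, noise_sd=0.3, seed=5))
    cfg = WorkflowConfig(
        descriptors=MINIMAL,
        learners={"linear": None, "rf": {"n_estimators": [50]}, "knn": {"n_neighbors": [3, 5]}},
    )
    return QsarModel.from_dataframe(table, config=cfg).fit(seed=4)


class TestFacade:
    def test_noise_free_linear_recovery(self):
        table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=100, noise_sd=0.0, seed=3))
        cfg = WorkflowConfig(descriptors=MINIMAL, learners={"linear": None})
        res = QsarModel.from_dataframe(table, config=cfg).fit(seed=0)
        assert res.learners["linear"].report.rmse < 1e-6

    def test_summary_contains_metrics_table(self, noisy_results):
        text = noisy_results.summary()
        assert "rmse_test" in text and "linear" in text and "lowest test RMSE" in text

    def test_fit_is_deterministic(self):
        table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=60, noise_sd=0.2, seed=8))
        cfg = WorkflowConfig(descriptors=MINIMAL, learners={"rf": {"n_estimators": [30]}})
        r1 = QsarModel.from_dataframe(table, config=cfg).fit(seed=2)
        r2 = QsarModel.from_dataframe(table, config=cfg).fit(seed=2)
        assert np.array_equal(
            r1.learners["rf"].test_predictions, r2.learners["rf"].test_predictions
        )

    def test_metrics_frame_has_one_row_per_model(self, noisy_results):
        frame = noisy_results.metrics_frame()
        assert set(frame["model"]) >= {"linear", "rf", "knn"}

    def test_ensembles_via_results(self, noisy_results):
        from qsarkit.validate import rmse

        ens = noisy_results.add_greedy_ensemble()
        P = noisy_results.oof_matrix()
        best_single = min(rmse(noisy_results.y_train, P[:, j]) for j in range(P.shape[1]))
        assert noisy_results.ensembles["greedy"]["rmse_cv"] <= best_single + 1e-12
        assert ens.weights.sum() == pytest.approx(1.0)
        noisy_results.add_stacking_ensemble("linear")
        assert "stack_linear" in noisy_results.ensembles


class TestBundleReplay:
    def test_training_file_reproduces_in_sample_predictions(self, tmp_path, noisy_results):
        table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=120, noise_sd=0.3, seed=5))
        p = tmp_path / "train.csv"
        table.to_csv(p, index=False)
        preds = noisy_results.predict(p, learner="linear", property_column="property")
        fl = noisy_results.learners["linear"]
        # test-set rows of the replay must equal the in-sample test predictions
        ids = np.array([r.id for r in noisy_results.records])
        kept_ids = [r.id for r in noisy_results.records if r.status == "kept"]
        test_ids = [kept_ids[i] for i in noisy_results.test_idx]
        replayed = preds.set_index("id").loc[test_ids, "prediction"].to_numpy()
        assert np.array_equal(replayed, fl.test_predictions)

    def test_save_load_round_trip(self, tmp_path, noisy_results):
        p = tmp_path / "model.joblib"
        noisy_results.save(p, learner="rf")
        bundle = ModelBundle.load(p)
        assert bundle.learner == "rf"
        table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=120, noise_sd=0.3, seed=5))
        mols = tmp_path / "mols.csv"
        table.head(20).to_csv(mols, index=False)
        out1 = noisy_results.predict(mols, learner="rf", property_column="property")
        out2 = predict_external(bundle, mols, property_column="property")
        assert np.array_equal(out1["prediction"].to_numpy(), out2["prediction"].to_numpy())

    def test_filtered_molecule_gets_status_not_prediction(self, tmp_path, noisy_results):
        mols = tmp_path / "ext.csv"
        pd.DataFrame({"id": ["ok", "bad"], "smiles": ["CCCO", "xxxx"]}).to_csv(mols, index=False)
        out = noisy_results.predict(mols, learner="linear")
        assert out.loc[out["id"] == "bad", "status"].iloc[0] == "removed_parse"
        assert np.isnan(out.loc[out["id"] == "bad", "prediction"].iloc[0])
        assert np.isfinite(out.loc[out["id"] == "ok", "prediction"].iloc[0])

    def test_unseen_substructures_still_predicted(self, tmp_path):
        table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=40, noise_sd=0.1, seed=1))
        cfg = WorkflowConfig(
            descriptors=DescriptorConfig(physchem=None, morgan_unhashed={"radius": 2, "mode": "count"}),
            corr_cutoff=1.1,  # keep all fingerprint columns: replay contract is the point here
            learners={"linear": None},
        )
        res = QsarModel.from_dataframe(table, config=cfg).fit(seed=0)
        ext = tmp_path / "ext.csv"
        pd.DataFrame({"id": ["new"], "smiles": ["OC(=O)c1ccccc1N"]}).to_csv(ext, index=False)
        out = res.predict(ext)
        assert np.isfinite(out["prediction"].iloc[0])

    def test_ensemble_from_bundles_requires_shared_folds(self, noisy_results):
        bundles = [fl.bundle for fl in noisy_results.learners.values()]
        ens = ensemble_from_bundles(bundles, method="greedy")
        assert ens.weights.sum() == pytest.approx(1.0)


class TestCli:
    def test_fixture_summarize_round_trip(self, tmp_path):
        runner = CliRunner()
        prefix = str(tmp_path / "pcm")
        r = runner.invoke(
            cli_main,
            ["fixture", "--kind", "pcm", "--n-molecules", "50", "--n-targets", "5",
             "--completeness", "0.4", "--out-prefix", prefix],
        )
        assert r.exit_code == 0, r.output
        r2 = runner.invoke(cli_main, ["summarize", prefix + ".csv"])
        assert r2.exit_code == 0
        stats = json.loads(r2.output)
        assert stats["n_targets"] == 5 and stats["completeness_pct"] == 40.0

    def test_train_and_predict_commands(self, tmp_path):
        runner = CliRunner()
        table, _ = make_qspr_fixture(SyntheticSpec(n_molecules=60, noise_sd=0.2, seed=9))
        mols = tmp_path / "mols.csv"
        table.to_csv(mols, index=False)
        cfg = {
            "descriptors": {"physchem": "rdkit_minimal"},
            "learners": {"linear": None},
            "property_column": "property",
        }
        cfg_path = tmp_path / "cfg.json"
        cfg_path.write_text(json.dumps(cfg))
        out_dir = tmp_path / "out"
        r = runner.invoke(
            cli_main,
            ["train", str(cfg_path), "--molecules", str(mols), "--out-dir", str(out_dir),
             "--seed", "3"],
        )
        assert r.exit_code == 0, r.output
        assert (out_dir / "linear.bundle.joblib").exists()
        preds_csv = tmp_path / "preds.csv"
        r2 = runner.invoke(
            cli_main,
            ["predict", str(out_dir / "linear.bundle.joblib"), str(mols),
             "--out", str(preds_csv)],
        )
        assert r2.exit_code == 0, r2.output
        assert len(pd.read_csv(preds_csv)) == 60

    def test_validate_command(self, tmp_path):
        runner = CliRunner()
        preds = tmp_path / "p.csv"
        pd.DataFrame(
            {"id": list("abcd"), "observed": [1.0, 2, 3, 4], "predicted": [1.1, 1.9, 3.2, 3.8]}
        ).to_csv(preds, index=False)
        r = runner.invoke(
            cli_main,
            ["validate", str(preds), "--train-mean", "2.5", "--train-n", "16", "--q2-cv", "0.8"],
        )
        assert r.exit_code == 0, r.output
        rep = json.loads(r.output)
        assert rep["tropsha"]["q2_cv_gt_0.5"] is True
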