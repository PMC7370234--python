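"""Readers/writers, containers, vocabulary and configuration."""

import numpy as np
import pytest

from trailstrat import (
    DoseResponseGrid,
    ExpressionPanel,
    FormatError,
    PanelSpec,
    PanelValueError,
    Prediction,
    ResponseTable,
    RunConfig,
    StructureError,
    VocabularyError,
    canonical_protein,
    gen_panel,
    read_panel,
    read_predictions,
    read_responses,
    write_panel,
    write_predictions,
    write_responses,
)


class TestReadPanel:
    def test_round_trip_of_handwritten_fixture(self, tiny_panel_text):
        panel = read_panel(tiny_panel_text)
        assert panel.shape == (3, 2)
        assert panel.sample_ids == ("s1", "s2", "s3")
        assert panel.protein_ids == ("XIAP", "Bax")
        np.testing.assert_array_equal(panel.values, [[1, 4], [2, 5], [3, 9]])

    def test_orientation_symmetry(self, tiny_panel_text, tmp_path):
        panel = read_panel(tiny_panel_text)
        transposed = tmp_path / "t.tsv"
        panel.to_dataframe().T.to_csv(transposed, sep="\t", index_label="protein")
        again = read_panel(transposed, orientation="proteins-in-rows")
        assert again == panel

    def test_comma_separated_accepted(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("sample,XIAP,Bax\ns1,1,2\ns2,3,4\n")
        assert read_panel(path).shape == (2, 2)

    def test_na_cell_names_offender(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample\tXIAP\tBax\ns1\t1\tNA\ns2\t3\t4\n")
        with pytest.raises(PanelValueError, match="s1.*Bax"):
            read_panel(path)

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample\tXIAP\tBax\ns1\t1\t-2\ns2\t3\t4\n")
        with pytest.raises(PanelValueError, match="negative"):
            read_panel(path)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample\tXIAP\tBax\ns1\t1\t2\ns1\t3\t4\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_panel(path)

    def test_round_trip_preserves_values(self, tmp_path, random_panel):
        panel = random_panel(6, 5, seed=3)
        path = tmp_path / "p.tsv"
        write_panel(panel, path)
        again = read_panel(path)
        assert again.sample_ids == panel.sample_ids
        np.testing.assert_allclose(again.values, panel.values, rtol=1e-12)


class TestResponses:
    def test_two_row_table(self, tmp_path):
        path = tmp_path / "l.tsv"
        path.write_text("MeWo\tlow\nMel Juso\tsynergistic\n")
        table = read_responses(path)
        assert len(table) == 2
        assert table.label_of("MeWo") == "low"

    def test_header_row_tolerated(self, tmp_path):
        path = tmp_path / "l.tsv"
        path.write_text("sample\tlabel\ns1\tlow\ns2\tsynergistic\n")
        assert len(read_responses(path)) == 2

    def test_unknown_label_is_vocabulary_error(self, tmp_path):
        path = tmp_path / "l.tsv"
        path.write_text("s1\tlow\ns2\tresistant\n")
        with pytest.raises(VocabularyError, match="resistant"):
            read_responses(path)

    def test_sixteen_line_panel_labels(self, tmp_path):
        """The cell-line panel splits 12 synergistic / 4 low responders."""
        synergistic = ["WM1366", "SkMel5", "SkMel2", "Malme3M", "Mel Juso", "WM3060",
                       "WM115", "WM35", "SkMel147", "WM793", "WM1346", "WM3248"]
        low = ["WM3211", "MeWo", "WM1791c", "WM852"]
        path = tmp_path / "l.tsv"
        path.write_text("".join(f"{s}\tsynergistic\n" for s in synergistic)
                        + "".join(f"{s}\tlow\n" for s in low))
        table = read_responses(path)
        assert len(table) == 16
        assert table.class_counts() == {"synergistic": 12, "low": 4}

    def test_write_read_round_trip(self, tmp_path):
        table = ResponseTable(("a", "b"), ("low", "synergistic"))
        path = tmp_path / "l.tsv"
        write_responses(table, path)
        assert read_responses(path) == table


class TestPredictionsIO:
    def _preds(self, k=1):
        return [Prediction("s1", "synergistic", 0.875, np.arange(3, dtype=float))] * k

    def test_single_row(self, tmp_path):
        path = tmp_path / "pred.tsv"
        write_predictions(self._preds(), path)
        df = read_predictions(path)
        assert len(df) == 1 and list(df["predicted_label"]) == ["synergistic"]

    def test_round_trip_lossless(self, tmp_path):
        path = tmp_path / "pred.tsv"
        preds = [Prediction("s1", "low", 1 / 3, np.array([0.1, -2.5]))]
        write_predictions(preds, path)
        df = read_predictions(path)
        assert df.loc[0, "posterior"] == 1 / 3
        assert df.loc[0, "PC2"] == -2.5

    def test_empty_table_refused(self, tmp_path):
        with pytest.raises(FormatError):
            write_predictions([], tmp_path / "pred.tsv")
        assert not (tmp_path / "pred.tsv").exists()


class TestContainers:
    def test_panel_rejects_nonfinite(self):
        with pytest.raises(PanelValueError):
            ExpressionPanel(("a", "b"), ("x", "y"), [[1, np.nan], [2, 3]])

    def test_alias_canonicalization(self):
        assert canonical_protein("SMAC/DIABLO") == "Smac"
        assert canonical_protein("bcl-xl") == "Bcl-xL"
        assert canonical_protein("NotAPanelProtein") == "NotAPanelProtein"
        panel = ExpressionPanel(("a", "b"), ("smac/diablo", "XIAP"), [[1, 2], [3, 4]])
        assert panel.protein_ids == ("Smac", "XIAP")

    def test_subset_reorders(self, random_panel):
        panel = random_panel(4, 3)
        sub = panel.subset(["prot2", "prot0"])
        np.testing.assert_array_equal(sub.values[:, 0], panel.values[:, 2])

    def test_grid_requires_monotherapy_partners(self):
        with pytest.raises(StructureError):
            DoseResponseGrid("s", [1.0, 0.0], [1.0, 1.0], [0.5, 0.2])

    def test_grid_fraction_domain(self):
        with pytest.raises(Exception, match="\\[0, 1\\]"):
            DoseResponseGrid("s", [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.5, 0.2, 0.0])


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = RunConfig(synergy_threshold=0.2, cv_folds=5)
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        assert RunConfig.from_yaml(path) == config

    def test_hash_changes_with_content(self):
        assert RunConfig().config_hash != RunConfig(n_pcs_max=3).config_hash

    def test_invalid_fields_rejected(self):
        with pytest.raises(Exception):
            RunConfig(cv_folds=1)
        with pytest.raises(Exception):
            RunConfig(lda_priors="flat")


def test_generated_panel_satisfies_invariants():
    panel, labels = gen_panel(PanelSpec(seed=5))
    assert panel.shape == (16, 19)
    assert np.all(panel.values > 0)
    assert labels.aligned_to(panel).labels.count("synergistic") == 12
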