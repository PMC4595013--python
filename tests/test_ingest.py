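"""Reading expression tables, MaxQuant filtering and protein-centric merging."""

import numpy as np
import pandas as pd
import pytest

from triomic.containers import SampleDescriptor, make_samples
from triomic.ingest import (
    merge_multiomic,
    read_expression_table,
    read_id_map,
    read_maxquant_protein_groups,
    read_sample_sheet,
    summarize_dataset,
    write_expression_table,
)


def _spec(layer, cols):
    out = {}
    for c in cols:
        phase, rep = c.rsplit("_", 1)
        out[c] = SampleDescriptor(layer, phase, int(rep))
    return out


COLS9 = [f"{p}_{r}" for p in ("G1", "S", "G2M") for r in (1, 2, 3)]


def _write_tsv(path, genes, values):
    df = pd.DataFrame(values, columns=COLS9[: np.shape(values)[1]])
    df.insert(0, "id", genes)
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadExpressionTable:
    def test_parses_genes_and_samples(self, tmp_path):
        p = _write_tsv(tmp_path / "t.tsv", ["g1", "g2", "g3"], np.arange(27.0).reshape(3, 9))
        lm = read_expression_table(p, "mRNA", _spec("mRNA", COLS9))
        assert lm.values.shape == (3, 9)
        assert len(lm.samples) == 9
        assert lm.samples[0].key == ("mRNA", "G1", 1)
        assert lm.values.loc["g2"].iloc[0] == 9.0

    def test_empty_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\tG1_1\tG1_2\ng1\t\t2.0\n")
        lm = read_expression_table(p, "mRNA", _spec("mRNA", ["G1_1", "G1_2"]))
        assert np.isnan(lm.values.loc["g1", "mRNA|G1|rep1"])
        assert lm.values.loc["g1", "mRNA|G1|rep2"] == 2.0

    def test_duplicate_identifier_is_named_in_error(self, tmp_path):
        p = _write_tsv(tmp_path / "t.tsv", ["geneX", "geneX"], np.ones((2, 9)))
        with pytest.raises(ValueError, match="geneX"):
            read_expression_table(p, "mRNA", _spec("mRNA", COLS9))

    def test_missing_declared_column_errors(self, tmp_path):
        p = _write_tsv(tmp_path / "t.tsv", ["g1"], np.ones((1, 9)))
        spec = _spec("mRNA", COLS9 + ["G2M_4"])
        with pytest.raises(ValueError, match="G2M_4"):
            read_expression_table(p, "mRNA", spec)

    def test_round_trip_is_bit_exact(self, tmp_path, sim):
        sd, _ = sim
        lm = sd.layers["mRNA"]
        p = tmp_path / "roundtrip.tsv"
        write_expression_table(lm, p)
        spec = {s.label: s for s in lm.samples}
        back = read_expression_table(p, "mRNA", spec)
        pd.testing.assert_frame_equal(back.values, lm.values, check_exact=False, rtol=1e-9)
        assert [s.key for s in back.samples] == [s.key for s in lm.samples]


class TestMaxQuant:
    def _write_pg(self, path, extra_rows=()):
        rows = [
            {"Majority protein IDs": "P1;P1-2", "Reverse": "", "Potential contaminant": "",
             "LFQ intensity G1_1": 2.0, "LFQ intensity S_1": 4.0},
            {"Majority protein IDs": "P2", "Reverse": "+", "Potential contaminant": "",
             "LFQ intensity G1_1": 8.0, "LFQ intensity S_1": 8.0},
            {"Majority protein IDs": "P3", "Reverse": "", "Potential contaminant": "+",
             "LFQ intensity G1_1": 8.0, "LFQ intensity S_1": 8.0},
            {"Majority protein IDs": "P4", "Reverse": "", "Potential contaminant": "",
             "LFQ intensity G1_1": 0.0, "LFQ intensity S_1": 8.0},
            *extra_rows,
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    def test_reverse_and_contaminant_rows_removed(self, tmp_path):
        lm = read_maxquant_protein_groups(self._write_pg(tmp_path / "pg.txt"))
        assert list(lm.gene_ids) == ["P1", "P4"]
        assert lm.group_ids["P1"] == "P1;P1-2"

    def test_zero_intensity_is_missing_and_log2_applied(self, tmp_path):
        lm = read_maxquant_protein_groups(self._write_pg(tmp_path / "pg.txt"))
        assert np.isnan(lm.values.loc["P4", "protein|G1|rep1"])
        assert lm.values.loc["P1", "protein|G1|rep1"] == 1.0  # log2(2)
        assert lm.values.loc["P1", "protein|S|rep1"] == 2.0  # log2(4)

    def test_unmatched_prefix_errors(self, tmp_path):
        with pytest.raises(ValueError, match="iBAQ "):
            read_maxquant_protein_groups(self._write_pg(tmp_path / "pg.txt"), intensity_prefix="iBAQ ")


class TestMerge:
    def _mrna(self, genes, values):
        samples = make_samples("mRNA", replicates=(1,))
        return pd.DataFrame(values, index=pd.Index(genes), columns=[s.label for s in samples]), samples

    def _layer(self, layer, genes, values, reps=(1,)):
        from triomic.containers import LayerMatrix

        samples = make_samples(layer, replicates=reps)
        return LayerMatrix(
            values=pd.DataFrame(np.asarray(values, float), index=pd.Index(genes),
                                columns=[s.label for s in samples]),
            samples=samples,
        )

    def test_max_mean_probeset_selected(self):
        mrna = self._layer("mRNA", ["ps_lo", "ps_hi"], [[5.0, 5, 5], [7.0, 7, 7]])
        trans = self._layer("translation", ["P1"], [[1.0, 1, 1]])
        prot = self._layer("protein", ["P1"], [[1.0, 1, 1]])
        idmap = pd.DataFrame(
            {"probeset_id": ["ps_lo", "ps_hi"], "protein_group_id": ["P1", "P1"]}
        )
        ds = merge_multiomic(mrna, trans, prot, idmap)
        assert (ds.layers["mRNA"].values.loc["P1"] == 7.0).all()

    def test_idmap_order_does_not_change_result(self):
        mrna = self._layer("mRNA", ["a", "b", "c"], [[5.0] * 3, [7.0] * 3, [7.0] * 3])
        trans = self._layer("translation", ["P1"], [[1.0] * 3])
        prot = self._layer("protein", ["P1"], [[1.0] * 3])
        maps = pd.DataFrame({"probeset_id": ["a", "b", "c"], "protein_group_id": ["P1"] * 3})
        r1 = merge_multiomic(mrna, trans, prot, maps)
        r2 = merge_multiomic(mrna, trans, prot, maps.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(r1.layers["mRNA"].values, r2.layers["mRNA"].values)

    def test_union_rule_and_unmapped_gene(self):
        mrna = self._layer("mRNA", ["ps1"], [[5.0] * 3])
        trans = self._layer("translation", ["P1"], [[1.0] * 3])
        prot = self._layer("protein", ["P2"], [[1.0] * 3])
        ds = merge_multiomic(mrna, trans, prot, pd.DataFrame(
            {"probeset_id": ["ps1"], "protein_group_id": ["P1"]}))
        assert set(ds.gene_index) == {"P1", "P2"}
        assert ds.layers["mRNA"].values.loc["P2"].isna().all()
        assert not ds.provenance.loc["P2", "in_transcriptome"]
        assert ds.layers["translation"].values.loc["P2"].isna().all()

    def test_empty_idmap_keeps_all_genes_with_missing_mrna(self):
        mrna = self._layer("mRNA", ["ps1"], [[5.0] * 3])
        trans = self._layer("translation", ["P1"], [[1.0] * 3])
        prot = self._layer("protein", ["P1"], [[1.0] * 3])
        ds = merge_multiomic(mrna, trans, prot, pd.DataFrame(columns=["probeset_id", "protein_group_id"]))
        assert list(ds.gene_index) == ["P1"]
        assert ds.layers["mRNA"].values.isna().all().all()


class TestSummarizeAndSheets:
    def test_counts_on_toy(self):
        from tests.conftest import toy_dataset

        vals = np.ones((10, 9))
        prot_only = np.ones((10, 9))
        prot_only[:7] = np.nan  # genes 0-6 not in proteome
        trans = np.ones((10, 9))
        trans[7:] = np.nan  # genes 7-9 proteome-only
        mrna = np.ones((10, 9))
        mrna[7:] = np.nan
        ds = toy_dataset({"mRNA": mrna, "translation": trans, "protein": prot_only},
                         [f"g{i}" for i in range(10)])
        counts = summarize_dataset(ds)
        assert counts["genes_total"] == 10
        assert counts["proteome_only"] == 3
        assert counts["combined"] == 7

    def test_empty_dataset_counts_zero(self):
        from tests.conftest import toy_dataset

        ds = toy_dataset({"mRNA": np.empty((0, 9)), "translation": np.empty((0, 9)),
                          "protein": np.empty((0, 9))}, [])
        assert all(v == 0 for v in summarize_dataset(ds).values())

    def test_sample_sheet_round_trip(self, tmp_path):
        import yaml

        sheet = [{"column": "c1", "layer": "mRNA", "phase": "G1", "replicate": 1,
                  "timepoint_h": 2.0}]
        p = tmp_path / "sheet.yaml"
        p.write_text(yaml.safe_dump(sheet))
        spec = read_sample_sheet(p)
        assert spec["c1"].key == ("mRNA", "G1", 1)
        assert spec["c1"].timepoint_h == 2.0

    def test_id_map_rejects_empty_identifiers(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("probeset_id\tprotein_group_id\nps1\t\n")
        with pytest.raises(ValueError, match="empty identifier"):
            read_id_map(p)
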