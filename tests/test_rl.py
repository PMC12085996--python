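"""Ligand–target pair prediction by thresholded Pearson correlation."""

import numpy as np
import pandas as pd
import pytest

import roicell as rc
from roicell.errors import InsufficientReplicatesError, ParameterError


def _matrix(seed=0, n_segments=7):
    """Small matrix with one strongly correlated (LIG, TGT) pair planted."""
    rng = np.random.default_rng(seed)
    segs = [f"s{j}" for j in range(n_segments)]
    lig = rng.uniform(10, 100, n_segments)
    tgt = 0.9 * lig + rng.normal(0, 1.0, n_segments)
    data = {
        "LIG": lig,
        "TGT": np.clip(tgt, 0, None),
        "AAA": rng.uniform(10, 100, n_segments),
        "BBB": rng.uniform(10, 100, n_segments),
        "FLAT": np.full(n_segments, 42.0),
    }
    values = pd.DataFrame(data).T
    values.columns = segs
    return rc.ExpressionMatrix.from_counts(values)


def _table(rows):
    return pd.DataFrame(rows, columns=["ligand", "target", "source_kind"])


class TestPredictRlPairs:
    def test_planted_pair_retained(self):
        m = _matrix()
        table = _table([("LIG", "TGT", "curated"), ("AAA", "BBB", "curated")])
        res = rc.predict_rl_pairs(m, list(m.segment_ids), table)
        assert ("LIG", "TGT") in res.pair_set
        assert (res.pairs["pearson_r"] > 0.75).all()

    def test_ppi_prediction_excluded(self):
        m = _matrix()
        table = _table([("LIG", "TGT", "ppi_prediction")])
        res = rc.predict_rl_pairs(m, list(m.segment_ids), table)
        assert len(res.pairs) == 0

    def test_constant_gene_skipped_with_warning(self):
        m = _matrix()
        table = _table([("LIG", "FLAT", "curated")])
        with pytest.warns(UserWarning, match="FLAT"):
            res = rc.predict_rl_pairs(m, list(m.segment_ids), table)
        assert res.n_skipped_degenerate == 1

    def test_missing_gene_counted_not_fatal(self):
        m = _matrix()
        table = _table([("NOPE", "TGT", "curated"), ("LIG", "TGT", "curated")])
        res = rc.predict_rl_pairs(m, list(m.segment_ids), table)
        assert res.n_skipped_missing == 1
        assert ("LIG", "TGT") in res.pair_set

    def test_too_few_segments_raises(self):
        m = _matrix()
        table = _table([("LIG", "TGT", "curated")])
        with pytest.raises(InsufficientReplicatesError):
            rc.predict_rl_pairs(m, ["s0", "s1"], table)

    def test_empty_table_raises(self):
        m = _matrix()
        with pytest.raises(ParameterError):
            rc.predict_rl_pairs(m, list(m.segment_ids), _table([]))

    def test_threshold_monotonicity(self):
        fx = rc.make_expression(
            n_genes=60,
            n_segments=12,
            planted_pairs=(("L1", "T1", 0.95), ("L2", "T2", 0.85), ("L3", "T3", 0.6)),
            n_decoy_pairs=10,
            seed=9,
        )
        m = rc.preprocess(fx.probe_matrix, fx.probe_to_gene)
        counts = [
            len(
                rc.predict_rl_pairs(
                    m, list(m.segment_ids), fx.table, r_threshold=t
                ).pairs
            )
            for t in (0.0, 0.25, 0.5, 0.75, 0.9, 0.99)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_order_invariance(self):
        fx = rc.make_expression(
            n_genes=40, n_segments=10, planted_pairs=(("L1", "T1", 0.95),), seed=10
        )
        m = rc.preprocess(fx.probe_matrix, fx.probe_to_gene)
        res1 = rc.predict_rl_pairs(m, list(m.segment_ids), fx.table)
        shuffled = rc.ExpressionMatrix.from_counts(
            m.values.sample(frac=1, axis=0, random_state=1).sample(
                frac=1, axis=1, random_state=2
            )
        )
        res2 = rc.predict_rl_pairs(shuffled, list(m.segment_ids), fx.table)
        assert res1.pair_set == res2.pair_set

    def test_matches_all_pairs_oracle(self):
        fx = rc.make_expression(
            n_genes=100,
            n_segments=12,
            planted_pairs=(("L1", "T1", 0.95), ("L2", "T2", 0.9)),
            n_decoy_pairs=20,
            seed=11,
        )
        m = rc.preprocess(fx.probe_matrix, fx.probe_to_gene)
        res = rc.predict_rl_pairs(m, list(m.segment_ids), fx.table, r_threshold=0.75)

        # oracle: full all-pairs correlation matrix, then table intersection
        corr = np.corrcoef(m.values.to_numpy())
        gene_idx = {g: i for i, g in enumerate(m.gene_ids)}
        expected = set()
        tab = fx.table[fx.table["source_kind"] != "ppi_prediction"]
        for ligand, target in tab[["ligand", "target"]].itertuples(index=False):
            if ligand in gene_idx and target in gene_idx:
                r = corr[gene_idx[ligand], gene_idx[target]]
                if r > 0.75:
                    expected.add((ligand, target))
        assert res.pair_set == expected


class TestLoadTable:
    def test_source_mapping_and_dedup(self):
        raw = pd.DataFrame(
            {
                "ligand": ["tnf", "tnf", "il6"],
                "target": ["icam1", "icam1", "stat3"],
                "source": ["kegg", "kegg", "ppi_lit"],
            }
        )
        table = rc.load_ligand_target_table(
            raw, source_col="source", ppi_sources=("ppi_lit",)
        )
        assert len(table) == 2
        assert (table["ligand"] == table["ligand"].str.upper()).all()
        assert set(table["source_kind"]) == {"curated", "ppi_prediction"}

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "lt.tsv"
        _table([("LIG", "TGT", "curated")]).to_csv(path, sep="\t", index=False)
        table = rc.load_ligand_target_table(path)
        assert table.iloc[0]["ligand"] == "LIG"


class TestCompareGroups:
    def _result(self, group, pairs):
        df = pd.DataFrame(
            [
                {
                    "ligand": l,
                    "target": t,
                    "pearson_r": 0.9,
                    "n_segments": 5,
                    "mean_expr_ligand": 1.0,
                    "mean_expr_target": 1.0,
                }
                for l, t in pairs
            ],
            columns=rc.rl.PAIR_COLUMNS,
        )
        return rc.RLPairResult(group=group, pairs=df, n_segments=5)

    def test_set_arithmetic(self):
        a = self._result("A", [("L1", "T1"), ("L2", "T2"), ("L3", "T3")])
        b = self._result("B", [("L1", "T1")])
        rep = rc.compare_groups(a, b)
        assert (rep.n_a, rep.n_b, rep.n_shared) == (3, 1, 1)
        assert (rep.n_unique_a, rep.n_unique_b) == (2, 0)
        assert set(rep.table["group"]) == {"A", "B"}

    def test_identical_results_all_shared(self):
        a = self._result("A", [("L1", "T1"), ("L2", "T2")])
        b = self._result("B", [("L1", "T1"), ("L2", "T2")])
        rep = rc.compare_groups(a, b)
        assert rep.n_shared == 2 and rep.n_unique_a == rep.n_unique_b == 0

    def test_mixture_group_has_more_pairs_than_separative(self):
        # generator plants more correlated table pairs for one group,
        # mirroring tumor-stroma interfaces with richer crosstalk
        mix_pairs = tuple((f"ML{i}", f"MT{i}", 0.95) for i in range(6))
        sep_pairs = tuple((f"SL{i}", f"ST{i}", 0.95) for i in range(2))
        fx_mix = rc.make_expression(
            n_genes=60, n_segments=10, planted_pairs=mix_pairs, seed=21
        )
        fx_sep = rc.make_expression(
            n_genes=60, n_segments=10, planted_pairs=sep_pairs, seed=22
        )
        m_mix = rc.preprocess(fx_mix.probe_matrix, fx_mix.probe_to_gene)
        m_sep = rc.preprocess(fx_sep.probe_matrix, fx_sep.probe_to_gene)
        res_mix = rc.predict_rl_pairs(
            m_mix, list(m_mix.segment_ids), fx_mix.table, group="Mixture"
        )
        res_sep = rc.predict_rl_pairs(
            m_sep, list(m_sep.segment_ids), fx_sep.table, group="Separative"
        )
        rep = rc.compare_groups(res_mix, res_sep)
        assert rep.n_a > rep.n_b
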