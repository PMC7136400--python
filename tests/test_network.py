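import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import filter_de, moderated_t_test
from cernet.io import Interaction, InteractionTable, ValidationError
from cernet.network import (
    CeRNATriplet,
    CorrelationTable,
    MissingCorrelationError,
    NetworkSummary,
    build_network,
    candidate_pairs,
    mediation_filter,
    network_summary,
    pairwise_pcc,
    read_edge_list,
    write_network,
)
from cernet.synthetic import SynthConfig, generate_dataset

from conftest import brute_force_triplets, make_matrix


def de_sets_for(dataset, alpha=0.05):
    out = {}
    for cls, m in (("mRNA", dataset.mrna), ("lncRNA", dataset.lncrna), ("miRNA", dataset.mirna)):
        table = moderated_t_test(m, dataset.labels)
        out[cls] = set(filter_de(table, alpha)["gene_id"])
    return out


def pipeline_triplets(dataset, de_sets, pcc=0.5, neg=0.0):
    lnc, mrna, mir = sorted(de_sets["lncRNA"]), sorted(de_sets["mRNA"]), sorted(de_sets["miRNA"])
    if not (lnc and mrna):
        return []
    corr_lm = pairwise_pcc(dataset.lncrna, dataset.mrna, lnc, mrna)
    cand = candidate_pairs(corr_lm, pcc)
    if not len(cand) or not mir:
        return []
    corr_im = pairwise_pcc(dataset.mirna, dataset.mrna, mir, mrna)
    corr_il = pairwise_pcc(dataset.mirna, dataset.lncrna, mir, lnc)
    return mediation_filter(cand, dataset.interactions, corr_im, corr_il, mir, neg)


class TestPairwisePCC:
    def test_identity_r_one(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(3, 6)))
        corr = pairwise_pcc(m, m, ["G001"], ["G001"])
        assert corr.r("G001", "G001") == pytest.approx(1.0)

    def test_antisymmetry_r_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        m = make_matrix(np.vstack([x, -x]))
        corr = pairwise_pcc(m, m, ["G001"], ["G002"])
        assert corr.r("G001", "G002") == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self):
        # 4-sample toy checked against the definitional covariance/(sd*sd) form
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        m = make_matrix(np.vstack([x, y]))
        corr = pairwise_pcc(m, m, ["G001"], ["G002"])
        assert corr.r("G001", "G002") == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged_not_nan_propagated(self):
        values = np.vstack([np.full(5, 2.0), np.arange(5.0)])
        m = make_matrix(values)
        corr = pairwise_pcc(m, m, ["G001"], ["G002"])
        assert not corr.defined("G001", "G002")
        assert len(candidate_pairs(corr, -1.0)) == 0  # undefined never passes

    def test_sample_mismatch(self):
        a = make_matrix(np.ones((2, 6)))
        b = make_matrix(np.ones((2, 4)))
        with pytest.raises(ValidationError, match="sample"):
            pairwise_pcc(a, b)

    def test_too_few_samples(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(2, 2)))
        with pytest.raises(ValidationError, match=">= 3"):
            pairwise_pcc(m, m)

    def test_symmetric_lookup(self):
        rng = np.random.default_rng(1)
        a = make_matrix(rng.normal(size=(2, 5)), "lncRNA", prefix="L")
        b = make_matrix(rng.normal(size=(2, 5)), "mRNA", prefix="M")
        corr = pairwise_pcc(a, b)
        assert corr.r("L001", "M002") == corr.r("M002", "L001")
        with pytest.raises(MissingCorrelationError):
            corr.r("L001", "Mxxx")


class TestCandidatePairs:
    def frame(self, rows):
        return CorrelationTable(
            pd.DataFrame(rows, columns=["id_a", "id_b", "r", "n", "defined"])
        )

    def test_boundary_strict(self):
        corr = self.frame([("l1", "m1", 0.5, 10, True), ("l2", "m2", 0.5000001, 10, True)])
        kept = candidate_pairs(corr, 0.5)
        assert list(kept["lncrna_id"]) == ["l2"]

    def test_vacuous_threshold(self):
        corr = self.frame([("l1", "m1", -0.9, 10, True), ("l2", "m2", 0.2, 10, True)])
        assert len(candidate_pairs(corr, -1.0)) == 2

    def test_planted_pairs_retained_at_default_threshold(self):
        retained = total = 0
        for seed in range(5):
            ds = generate_dataset(
                SynthConfig(n_per_group=10, coupling=0.9, noise_sd=0.3,
                            n_triplets=5, seed=seed)
            )
            corr = pairwise_pcc(
                ds.lncrna, ds.mrna,
                sorted(ds.truth.de_ids("lncRNA")), sorted(ds.truth.de_ids("mRNA")),
            )
            cand = set(zip(*[candidate_pairs(corr, 0.5)[c] for c in ("lncrna_id", "mrna_id")]))
            planted = {(l, m) for l, m, _ in ds.truth.triplets}
            retained += len(planted & cand)
            total += len(planted)
        assert retained == total


class TestMediationFilter:
    def base_inputs(self):
        candidates = pd.DataFrame({"lncrna_id": ["l1"], "mrna_id": ["m1"], "r": [0.8]})
        interactions = InteractionTable(
            frozenset({Interaction("i1", "m1", "mRNA"), Interaction("i1", "l1", "lncRNA")})
        )
        return candidates, interactions

    def corr(self, rows):
        return CorrelationTable(
            pd.DataFrame(rows, columns=["id_a", "id_b", "r", "n", "defined"])
        )

    def test_sign_violation_no_triplet(self):
        candidates, interactions = self.base_inputs()
        corr_im = self.corr([("i1", "m1", 0.2, 10, True)])
        corr_il = self.corr([("i1", "l1", -0.5, 10, True)])
        assert mediation_filter(candidates, interactions, corr_im, corr_il, {"i1"}) == []

    def test_non_de_mirna_no_triplet(self):
        candidates, interactions = self.base_inputs()
        corr_im = self.corr([("i1", "m1", -0.6, 10, True)])
        corr_il = self.corr([("i1", "l1", -0.5, 10, True)])
        assert mediation_filter(candidates, interactions, corr_im, corr_il, set()) == []

    def test_qualifying_mirna_yields_triplet(self):
        candidates, interactions = self.base_inputs()
        corr_im = self.corr([("i1", "m1", -0.6, 10, True)])
        corr_il = self.corr([("i1", "l1", -0.5, 10, True)])
        triplets = mediation_filter(candidates, interactions, corr_im, corr_il, {"i1"})
        assert [t.key for t in triplets] == [("l1", "m1", "i1")]
        assert triplets[0].r_im == -0.6

    def test_k_mirnas_yield_k_triplets(self):
        candidates, _ = self.base_inputs()
        interactions = InteractionTable(
            frozenset(
                Interaction(i, t, c)
                for i in ("i1", "i2")
                for t, c in (("m1", "mRNA"), ("l1", "lncRNA"))
            )
        )
        corr_im = self.corr([("i1", "m1", -0.6, 10, True), ("i2", "m1", -0.4, 10, True)])
        corr_il = self.corr([("i1", "l1", -0.5, 10, True), ("i2", "l1", -0.3, 10, True)])
        triplets = mediation_filter(candidates, interactions, corr_im, corr_il, {"i1", "i2"})
        assert len(triplets) == 2

    def test_missing_correlation_reported(self):
        candidates, interactions = self.base_inputs()
        corr_im = self.corr([("i1", "m1", -0.6, 10, True)])
        corr_il = self.corr([])  # missing (i1, l1)
        with pytest.raises(MissingCorrelationError, match="i1"):
            mediation_filter(candidates, interactions, corr_im, corr_il, {"i1"})

    def test_neg_threshold_strict(self):
        candidates, interactions = self.base_inputs()
        corr_im = self.corr([("i1", "m1", 0.0, 10, True)])
        corr_il = self.corr([("i1", "l1", -0.5, 10, True)])
        assert mediation_filter(candidates, interactions, corr_im, corr_il, {"i1"}, 0.0) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        ds = generate_dataset(
            SynthConfig(
                n_per_group=6, n_mrna=30, n_lncrna=30, n_mirna=10,
                n_de_per_class=10, n_triplets=6, coupling=0.7,
                n_decoy_interactions=120, noise_sd=0.5, seed=seed,
            )
        )
        de = de_sets_for(ds)
        found = {t.key for t in pipeline_triplets(ds, de)}
        oracle = brute_force_triplets(
            ds.lncrna, ds.mrna, ds.mirna, ds.interactions,
            de["lncRNA"], de["mRNA"], de["miRNA"],
        )
        assert found == oracle

    def test_threshold_tightening_never_adds_triplets(self):
        ds = generate_dataset(
            SynthConfig(n_per_group=8, n_triplets=5, coupling=0.8,
                        n_decoy_interactions=100, seed=13)
        )
        de = de_sets_for(ds)
        loose = {t.key for t in pipeline_triplets(ds, de, pcc=0.3, neg=0.0)}
        tighter_pcc = {t.key for t in pipeline_triplets(ds, de, pcc=0.6, neg=0.0)}
        tighter_neg = {t.key for t in pipeline_triplets(ds, de, pcc=0.3, neg=-0.3)}
        assert tighter_pcc <= loose
        assert tighter_neg <= loose


class TestBuildNetwork:
    def triplet(self, l, m, i):
        return CeRNATriplet(l, m, i, 0.8, -0.5, -0.5)

    def test_empty(self):
        net = build_network([])
        assert net.n_nodes == 0 and net.n_edges == 0
        summary = network_summary(net)
        assert summary.n_nodes == 0 and summary.n_edges == 0

    def test_single_triplet_three_nodes_three_edges(self):
        net = build_network([self.triplet("l1", "m1", "i1")])
        assert net.n_nodes == 3
        assert net.n_edges == 3
        kinds = {kind for _, _, kind in net.edges}
        assert kinds == {"lnc_m_cerna", "mi_m_target", "mi_l_target"}

    def test_shared_mirna_and_mrna_hand_enumeration(self):
        # two triplets sharing miRNA and mRNA: nodes {i, m, l1, l2} = 4;
        # edges (l1,m),(l2,m) ceRNA + (i,m) dedup + (i,l1),(i,l2) = 5
        net = build_network(
            [self.triplet("l1", "m1", "i1"), self.triplet("l2", "m1", "i1")]
        )
        assert net.n_nodes == 4
        assert net.n_edges == 5

    def test_no_orphan_nodes(self, small_dataset):
        de = de_sets_for(small_dataset)
        triplets = pipeline_triplets(small_dataset, de)
        net = build_network(triplets)
        members = set()
        for t in triplets:
            members.update(t.key)
        assert set(net.nodes) == members

    def test_summary_counts_sum(self):
        summary = NetworkSummary(n_mirna=8, n_mrna=24, n_lncrna=73)
        assert summary.n_nodes == 105

    def test_summary_matches_hand_enumeration(self):
        net = build_network(
            [self.triplet("l1", "m1", "i1"), self.triplet("l2", "m1", "i1")]
        )
        summary = network_summary(net)
        assert (summary.n_mirna, summary.n_mrna, summary.n_lncrna) == (1, 1, 2)
        assert summary.n_cerna_edges == 2
        assert summary.n_mi_mrna_edges == 1
        assert summary.n_mi_lncrna_edges == 2
        assert summary.n_edges == 5
        assert dict(summary.degree_distribution)["m1"] == 3


class TestWriteNetwork:
    def network(self):
        return build_network([CeRNATriplet("l1", "m1", "i1", 0.8, -0.5, -0.4)])

    def test_sif_three_lines(self, tmp_path):
        path = tmp_path / "net.sif"
        write_network(self.network(), path, "sif")
        assert len(path.read_text().splitlines()) == 3

    def test_edge_list_round_trip(self, tmp_path):
        net = self.network()
        path = tmp_path / "net.tsv"
        write_network(net, path, "edge_list")
        edges, nodes = read_edge_list(path)
        assert edges == net.edges
        assert nodes == net.nodes

    def test_graphml_parse_round_trip(self, tmp_path):
        import networkx as nx

        net = self.network()
        path = tmp_path / "net.graphml"
        write_network(net, path, "graphml")
        graph = nx.read_graphml(path)
        assert set(graph.nodes) == set(net.nodes)
        assert graph.nodes["l1"]["rna_class"] == "lncRNA"
        assert graph.edges[("l1", "m1")]["kind"] == "lnc_m_cerna"

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValidationError, match="unknown network format"):
            write_network(self.network(), tmp_path / "x", "dot")


class TestNullControl:
    def test_false_positive_rate_within_analytic_bound(self):
        # coupling 0, no DE shift, DE filter bypassed: triplet count should
        # respect the bound implied by the two correlation thresholds
        from scipy import stats as sstats

        n_samples = 12
        t_crit = 0.5 * np.sqrt(n_samples - 2) / np.sqrt(1 - 0.25)
        p_pos = sstats.t.sf(t_crit, n_samples - 2)  # P[r > 0.5] under the null
        counts = []
        bounds = []
        for seed in range(30):
            ds = generate_dataset(
                SynthConfig(
                    n_per_group=6, n_mrna=15, n_lncrna=15, n_mirna=8,
                    n_de_per_class=0, n_triplets=0, de_effect=0.0, coupling=0.0,
                    n_decoy_interactions=150, noise_sd=0.5, seed=seed,
                )
            )
            all_sets = {
                "mRNA": set(ds.mrna.gene_ids),
                "lncRNA": set(ds.lncrna.gene_ids),
                "miRNA": set(ds.mirna.gene_ids),
            }
            found = pipeline_triplets(ds, all_sets)
            counts.append(len(found))
            n_combos = sum(
                len(
                    ds.interactions.mirnas_targeting(m, "mRNA")
                    & ds.interactions.mirnas_targeting(l, "lncRNA")
                )
                for l in all_sets["lncRNA"]
                for m in all_sets["mRNA"]
            )
            bounds.append(n_combos * p_pos * 0.25)
        # empirical mean below the analytic expectation (with MC slack)
        assert np.mean(counts) <= np.mean(bounds) * 2.0 + 0.5
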