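import numpy as np
import pandas as pd
import pytest

from chromdyn import motifs as mo
from chromdyn import network as nw
from chromdyn.io import (
    ExpressionMatrix,
    GenomicInterval,
    MotifSet,
    PWM,
    PeakSet,
    ValidationError,
)

DAYS = [7, 14, 19, 21, 24, 26, 28, 35]

# profile pair with a float-exact Pearson correlation of 0.4
X_04 = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
Y_04 = np.array([
    -0.44590580634661575, -0.3096699654419982, 0.06861007121984976,
    0.39990772201091573, -0.14113752602161947, 0.6084918491113103,
    -0.3491882065855181, 0.16889186205367596,
])


def expr_matrix(profiles: dict) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame(profiles, index=DAYS).T.astype(float),
        tf_flags=frozenset(profiles),
    )


class TestPromoters:
    def _tss(self, strand, pos=5000):
        return PeakSet([GenomicInterval("chr1", pos, pos + 1, "g1", strand)])

    def test_plus_strand_upstream(self):
        out = nw.promoter_regions(self._tss("+"), {"chr1": 100_000})
        assert (out["g1"].start, out["g1"].end) == (3000, 5000)

    def test_minus_strand_upstream(self):
        out = nw.promoter_regions(self._tss("-"), {"chr1": 100_000})
        assert (out["g1"].start, out["g1"].end) == (5000, 7000)

    def test_clipped_at_chromosome_start(self):
        out = nw.promoter_regions(self._tss("+", pos=500), {"chr1": 100_000})
        assert (out["g1"].start, out["g1"].end) == (0, 500)

    def test_missing_strand_rejected(self):
        with pytest.raises(ValidationError):
            nw.promoter_regions(self._tss("."), {"chr1": 100_000})


class TestCandidates:
    def _enrichment(self, p_m1=0.001, p_m2=0.5):
        return {"I": pd.DataFrame(
            {"p_value": [p_m1, p_m2], "signed_score": [3.0, 0.1]}, index=["M1", "M2"]
        )}

    def test_enriched_but_silent_tf_excluded(self):
        expr = expr_matrix({"TF1": [0.0] * 8, "OTHER": [10.0] * 8})
        cands = nw.candidate_tfs(
            self._enrichment(), expr, {"TF1": "TF1"}, {"M1": "TF1", "M2": "TF2"}
        )
        assert cands == set()

    def test_expressed_but_not_enriched_excluded(self):
        expr = expr_matrix({"TF2": [10.0] * 8, "OTHER": [0.0] * 8})
        cands = nw.candidate_tfs(
            self._enrichment(), expr, {"TF2": "TF2"}, {"M1": "TF1", "M2": "TF2"}
        )
        assert cands == set()

    def test_enriched_and_expressed_retained(self):
        expr = expr_matrix({"TF1": [10.0] * 8, "OTHER": [0.0] * 8})
        cands = nw.candidate_tfs(
            self._enrichment(), expr, {"TF1": "TF1"}, {"M1": "TF1", "M2": "TF2"}
        )
        assert cands == {"TF1"}

    def test_planted_tfs_retained_decoys_excluded(self, dataset42):
        ds = dataset42
        # enrichment built from the planted hits (decoys have none)
        hits = {
            p.motif_id: {} for p in ds.motifs
        }
        for h in ds.planted_hits:
            if h.interval.chrom != "chrA":
                continue
            for iv in ds.peaks:
                if iv.start <= h.interval.start < iv.end:
                    hits[h.motif_id].setdefault(iv.name, []).append(h)
                    break
        lab = pd.Series(ds.truth["cluster_labels"])
        enr = {
            c: mo.enrich(ds.peaks.subset(list(lab.index[lab == c])), ds.peaks, hits)
            for c in ("I", "II")
        }
        motif_tf = {p.motif_id: p.tf_name for p in ds.motifs}
        cands = nw.candidate_tfs(enr, ds.expression, ds.tf_gene_map, motif_tf)
        planted = set(ds.truth["tf_day"])
        decoys = set(ds.truth["decoy_tfs"])
        assert planted <= cands
        assert len(cands & decoys) <= 0.2 * len(decoys)


class TestStageSpecificTFs:
    def test_flat_profile_never_specific(self):
        expr = expr_matrix({"TF1": [5.0] * 8, "TF2": list(range(8))})
        sets = nw.stage_specific_tfs(expr, {"TF1", "TF2"}, {"TF1": "TF1", "TF2": "TF2"})
        assert all("TF1" not in s for s in sets.values())

    def test_single_day_spike_specific_there(self):
        prof = [1.0] * 8
        prof[-1] = 1.0 + np.log2(10)  # 10x on the linear scale at day 35
        expr = expr_matrix({"TF1": prof, "TF2": [3.0] * 8})
        sets = nw.stage_specific_tfs(expr, {"TF1", "TF2"}, {"TF1": "TF1", "TF2": "TF2"})
        assert "TF1" in sets[35]
        assert all("TF1" not in sets[d] for d in DAYS[:-1])

    def test_daywise_sets_disjoint(self, dataset42):
        ds = dataset42
        sets = nw.stage_specific_tfs(ds.expression, set(ds.truth["tf_day"]), ds.tf_gene_map)
        seen = set()
        for d, tfs in sets.items():
            assert not (tfs & seen)
            seen |= tfs


class TestEdges:
    def _toy(self):
        # TFA's motif planted in TFB's promoter and in its own
        motif_a = PWM("MA", "TFA", self._mat("ACGTACGTAC"))
        motif_b = PWM("MB", "TFB", self._mat("GGGTTTCCCA"))
        genome = {"chr1": "T" * 6000}
        seq = list(genome["chr1"])
        seq[3500:3510] = "ACGTACGTAC"      # inside TFB promoter [3000, 5000)
        seq[1200:1210] = "ACGTACGTAC"      # inside TFA promoter [1000, 3000)... no: define below
        genome["chr1"] = "".join(seq)
        tss = PeakSet([
            GenomicInterval("chr1", 3000, 3001, "TFA", "+"),   # promoter [1000, 3000)
            GenomicInterval("chr1", 5000, 5001, "TFB", "+"),   # promoter [3000, 5000)
        ])
        promoters = nw.promoter_regions(tss, {"chr1": 6000})
        motifs = MotifSet([motif_a, motif_b])
        return genome, promoters, motifs

    @staticmethod
    def _mat(consensus):
        m = np.full((4, len(consensus)), 0.05)
        for j, b in enumerate(consensus):
            m["ACGT".index(b), j] = 0.85
        return m / m.sum(axis=0, keepdims=True)

    def test_edges_from_promoter_hits_with_self_loop(self):
        genome, promoters, motifs = self._toy()
        tf_map = {"TFA": "TFA", "TFB": "TFB"}
        edges = nw.infer_edges({"TFA", "TFB"}, promoters, genome, motifs, tf_map)
        pairs = {(r.source, r.target): r.self_loop for r in edges.itertuples()}
        assert ("TFA", "TFB") in pairs and not pairs[("TFA", "TFB")]
        assert ("TFA", "TFA") in pairs and pairs[("TFA", "TFA")]
        assert ("TFB", "TFA") not in pairs and ("TFB", "TFB") not in pairs

    def test_no_hits_empty_edge_list(self):
        genome, promoters, _ = self._toy()
        motifs = MotifSet([PWM("MC", "TFC", self._mat("ACACACACAC"))])
        genome = {"chr1": "T" * 6000}
        edges = nw.infer_edges({"TFC"}, promoters, genome, motifs, {"TFC": "TFA"})
        assert edges.empty

    def test_tf_without_motif_warns(self):
        genome, promoters, motifs = self._toy()
        with pytest.warns(UserWarning, match="TFZ"):
            edges = nw.infer_edges(
                {"TFZ"}, promoters, genome, motifs, {"TFZ": "TFA"}
            )
        assert edges.empty


class TestClassifyEdges:
    def _edges(self):
        return pd.DataFrame([{"source": "A", "target": "B", "n_hits": 1,
                              "best_score": 1.0, "self_loop": False}])

    def test_identical_profiles_positive(self):
        expr = expr_matrix({"A": list(range(8)), "B": list(range(8))})
        typed = nw.classify_edges(self._edges(), expr, {"A": "A", "B": "B"})
        assert typed.loc[0, "edge_type"] == "positive"
        assert typed.loc[0, "pcc"] == pytest.approx(1.0)

    def test_negated_profiles_negative(self):
        expr = expr_matrix({"A": list(range(8)), "B": list(range(8, 0, -1))})
        typed = nw.classify_edges(self._edges(), expr, {"A": "A", "B": "B"})
        assert typed.loc[0, "edge_type"] == "negative"

    def test_pcc_exactly_at_threshold_is_none(self):
        # the interval [-0.4, 0.4] is closed: a PCC of exactly 0.4 is "none"
        expr = expr_matrix({"A": X_04, "B": Y_04})
        typed = nw.classify_edges(self._edges(), expr, {"A": "A", "B": "B"})
        assert typed.loc[0, "pcc"] == 0.4
        assert typed.loc[0, "edge_type"] == "none"

    def test_zero_variance_profile_flagged_none(self):
        expr = expr_matrix({"A": [1.0] * 8, "B": list(range(8))})
        typed = nw.classify_edges(self._edges(), expr, {"A": "A", "B": "B"})
        assert typed.loc[0, "edge_type"] == "none" and typed.loc[0, "pcc_undefined"]


class TestBuildNetwork:
    def _inputs(self):
        expr = expr_matrix({
            "A": [9, 1, 1, 1, 1, 1, 1, 1],
            "B": [9, 1, 1, 1, 1, 1, 1, 1],
            "C": [1, 1, 1, 1, 1, 1, 1, 9],
        })
        typed = pd.DataFrame([
            {"source": "A", "target": "B", "pcc": 0.9, "edge_type": "positive", "self_loop": False},
            {"source": "A", "target": "C", "pcc": -0.5, "edge_type": "negative", "self_loop": False},
        ])
        stage_tfs = {7: {"A", "B"}, 35: {"C"}}
        return expr, typed, stage_tfs

    def test_early_subnetwork_only_at_early_day(self):
        expr, typed, stage_tfs = self._inputs()
        net7 = nw.build_timepoint_network(
            7, {"A", "B", "C"}, stage_tfs, typed, expr, {"A": 2.0}, {t: t for t in "ABC"}
        )
        assert set(net7.tfs) == {"A", "B"} and net7.n_edges == 1
        net35 = nw.build_timepoint_network(
            35, {"A", "B", "C"}, stage_tfs, typed, expr, {}, {t: t for t in "ABC"}
        )
        assert set(net35.tfs) == {"C"} and net35.n_edges == 0

    def test_nonstrict_adds_expressed_candidates(self):
        expr, typed, stage_tfs = self._inputs()
        net = nw.build_timepoint_network(
            7, {"A", "B", "C"}, stage_tfs, typed, expr, {}, {t: t for t in "ABC"},
            strict=False, expressed_cutoff=0.5,
        )
        assert set(net.tfs) == {"A", "B", "C"}
        assert net.n_edges == 2

    def test_edge_count_bounded_by_global(self):
        expr, typed, stage_tfs = self._inputs()
        for t in DAYS:
            net = nw.build_timepoint_network(
                t, {"A", "B", "C"}, stage_tfs, typed, expr, {}, {x: x for x in "ABC"}
            )
            assert net.n_edges <= len(typed)

    def test_empty_node_set_warns_valid_empty(self):
        expr, typed, _ = self._inputs()
        with pytest.warns(UserWarning, match="empty"):
            net = nw.build_timepoint_network(
                21, {"A"}, {}, typed, expr, {}, {"A": "A"}
            )
        assert net.tfs == [] and net.n_edges == 0

    def test_graphml_bytes_reproducible(self, tmp_path):
        from chromdyn.io import write_network

        expr, typed, stage_tfs = self._inputs()
        paths = []
        for i in (1, 2):
            net = nw.build_timepoint_network(
                7, {"A", "B", "C"}, stage_tfs, typed, expr, {"A": 2.0}, {t: t for t in "ABC"}
            )
            p = tmp_path / f"n{i}.graphml"
            write_network(net, p, format="graphml")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestPlantedRecovery:
    def test_edge_f1_on_default_dataset(self, dataset42):
        ds = dataset42
        cands = set(ds.truth["tf_day"])
        promoters = nw.promoter_regions(ds.tss, ds.chrom_sizes)
        edges = nw.infer_edges(cands, promoters, ds.genome, ds.motifs, ds.tf_gene_map)
        planted = {(s, t) for s, t, _ in ds.planted_network}
        pred = {(r.source, r.target) for r in edges.itertuples() if not r.self_loop}
        tp = len(planted & pred)
        precision, recall = tp / len(pred), tp / len(planted)
        assert recall >= 0.95
        assert precision >= 0.8
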