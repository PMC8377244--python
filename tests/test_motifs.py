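import math

import numpy as np
import pandas as pd
import pytest

from chromdyn import motifs as mo
from chromdyn.io import PWM, MotifSet, PeakSet, GenomicInterval, normalize_pfm, reverse_complement
from chromdyn.simulate import SimulationConfig, generate_dataset


def sharp_pwm(consensus: str, motif_id="M1", tf="TFX", hi=0.85) -> PWM:
    lo = (1.0 - hi) / 3.0
    mat = np.full((4, len(consensus)), lo)
    for j, base in enumerate(consensus):
        mat["ACGT".index(base), j] = hi
    return PWM(motif_id, tf, mat)


def brute_force_scan(seq, pwm, threshold_frac=0.8):
    """Independent reference scanner: python loops, explicit both strands."""
    lom = mo.pwm_logodds(pwm)
    L = pwm.length
    maxs = sum(max(lom[i, j] for i in range(4)) for j in range(L))
    hits = {}
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for i in range(len(s) - L + 1):
            window = s[i : i + L]
            if any(b not in "ACGT" for b in window):
                continue
            score = sum(lom["ACGT".index(b), j] for j, b in enumerate(window))
            if score >= threshold_frac * maxs:
                start = i if strand == "+" else len(seq) - i - L
                hits[(start, strand)] = score
    return hits


class TestLogodds:
    def test_uniform_pwm_near_zero(self):
        pwm = PWM("M", "T", np.full((4, 6), 0.25))
        assert np.allclose(mo.pwm_logodds(pwm), 0.0, atol=0.01)

    def test_certain_base_two_bits(self):
        mat = np.zeros((4, 1))
        mat[0, 0] = 1.0
        pwm = PWM("M", "T", mat)
        assert mo.pwm_logodds(pwm)[0, 0] == pytest.approx(2.0, abs=0.01)

    def test_max_score_is_column_maxima_sum(self):
        pwm = sharp_pwm("ACGTAC")
        lom = mo.pwm_logodds(pwm)
        assert mo.max_score(pwm) == pytest.approx(lom.max(axis=0).sum())


class TestScan:
    def test_consensus_scores_max_at_origin(self):
        pwm = sharp_pwm("ACGGTACA")
        hits = mo.scan_sequence(pwm.consensus, pwm, threshold_frac=0.99)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].interval.start == 0
        assert fwd[0].score == pytest.approx(mo.max_score(pwm))

    def test_palindrome_hits_both_strands(self):
        pwm = sharp_pwm("ACGCGT")  # reverse complement of ACGCGT is ACGCGT
        hits = mo.scan_sequence("ACGCGT", pwm, threshold_frac=0.99)
        assert {h.strand for h in hits} == {"+", "-"}
        assert {h.interval.start for h in hits} == {0}

    def test_short_sequence_empty(self):
        pwm = sharp_pwm("ACGTACGT")
        assert mo.scan_sequence("ACG", pwm) == []

    def test_windows_with_n_skipped(self):
        pwm = sharp_pwm("ACGT")
        hits = mo.scan_sequence("ACNT" + pwm.consensus, pwm, threshold_frac=0.9)
        assert all(h.interval.start >= 4 or h.strand == "-" for h in hits)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
        consensus = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 7)])
        pwm = sharp_pwm(consensus, hi=0.7)
        got = {(h.interval.start, h.strand): h.score
               for h in mo.scan_sequence(seq, pwm, threshold_frac=0.6)}
        expected = brute_force_scan(seq, pwm, threshold_frac=0.6)
        assert got.keys() == expected.keys()
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_reverse_complement_genome_mirrors_hits(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        pwm = sharp_pwm("ACGGTAC", hi=0.7)
        fwd = mo.scan_sequence(seq, pwm, threshold_frac=0.6)
        rev = mo.scan_sequence(reverse_complement(seq), pwm, threshold_frac=0.6)
        mirror = {(len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand]) for h in fwd}
        assert {(h.interval.start, h.strand) for h in rev} == mirror


def hits_on_universe(universe, with_hit, motif_id="M1"):
    return {
        motif_id: {
            name: [  # one dummy hit per peak carrying the motif
                None
            ]
            for name in with_hit
        }
    }


def make_universe(n):
    return PeakSet(
        GenomicInterval("chr1", i * 1000, i * 1000 + 100, f"p{i}") for i in range(n)
    )


class TestEnrich:
    def test_exact_probability_all_targets_hit(self):
        universe = make_universe(100)
        target = universe.subset([f"p{i}" for i in range(10)])
        res = mo.enrich(target, universe, hits_on_universe(universe, [f"p{i}" for i in range(10)]))
        assert res.loc["M1", "p_value"] == pytest.approx(1 / math.comb(100, 10), rel=1e-12)
        assert res.loc["M1", "signed_score"] > 0

    def test_matched_fraction_not_significant(self):
        universe = make_universe(100)
        target = universe.subset([f"p{i}" for i in range(10)])
        # hit fraction identical in target (5/10) and universe (50/100)
        with_hit = [f"p{i}" for i in range(5)] + [f"p{i}" for i in range(10, 55)]
        res = mo.enrich(target, universe, hits_on_universe(universe, with_hit))
        assert abs(res.loc["M1", "signed_score"]) <= -np.log10(0.5) + 0.35

    def test_depletion_negative_score(self):
        universe = make_universe(100)
        target = universe.subset([f"p{i}" for i in range(20)])
        with_hit = [f"p{i}" for i in range(20, 80)]  # none in target
        res = mo.enrich(target, universe, hits_on_universe(universe, with_hit))
        assert res.loc["M1", "signed_score"] < 0

    def test_target_outside_universe_rejected(self):
        universe = make_universe(10)
        stray = PeakSet([GenomicInterval("chr9", 0, 10, "zzz")])
        with pytest.raises(ValueError):
            mo.enrich(stray, universe, hits_on_universe(universe, []))

    def test_planted_motifs_rank_top_and_decoys_null(self, dataset42):
        ds = dataset42
        lab = pd.Series(ds.truth["cluster_labels"])
        motif_of = ds.truth["motif_of_tf"]
        tf_day = ds.truth["tf_day"]
        late_tf = max(tf_day, key=tf_day.get)
        early_tf = min(tf_day, key=tf_day.get)
        decoys = ds.truth["decoy_tfs"][:2]
        subset = MotifSet(
            [ds.motifs[motif_of[tf]] for tf in (late_tf, early_tf, *decoys)]
        )
        hits = mo.scan_peaks(ds.peaks, ds.genome, subset)
        cl2 = ds.peaks.subset(list(lab.index[lab == "II"]))
        res = mo.enrich(cl2, ds.peaks, hits)
        assert res["signed_score"].idxmax() == motif_of[late_tf]
        for d in decoys:
            assert res.loc[motif_of[d], "fdr"] > 0.05
        assert res.loc[motif_of[early_tf], "signed_score"] < 0  # depleted in II


class TestModuleMap:
    def test_columns_match_per_set_enrichment(self):
        universe = make_universe(60)
        hits = hits_on_universe(universe, [f"p{i}" for i in range(15)])
        sets = {
            "s1": universe.subset([f"p{i}" for i in range(10)]),
            "s2": universe.subset([f"p{i}" for i in range(30, 40)]),
        }
        mm = mo.module_map(sets, universe, hits, cluster_rows=False)
        for name, pset in sets.items():
            expected = mo.enrich(pset, universe, hits)["signed_score"]
            assert np.allclose(mm[name].values, expected.values)

    def test_identical_sets_identical_columns(self):
        universe = make_universe(40)
        hits = hits_on_universe(universe, [f"p{i}" for i in range(8)])
        same = universe.subset([f"p{i}" for i in range(5)])
        mm = mo.module_map({"a": same, "b": same}, universe, hits, cluster_rows=False)
        assert np.allclose(mm["a"].values, mm["b"].values)

    def test_empty_set_zero_column_flagged(self):
        universe = make_universe(40)
        hits = hits_on_universe(universe, [f"p{i}" for i in range(8)])
        mm = mo.module_map(
            {"a": universe.subset(["p0"]), "empty": PeakSet([])},
            universe,
            hits,
            cluster_rows=False,
        )
        assert (mm["empty"] == 0).all()
        assert mm.attrs["empty"] == ["empty"]


class TestBubbleTable:
    def _expression(self):
        from chromdyn.io import ExpressionMatrix

        vals = pd.DataFrame(
            [[1.0 * t for t in range(8)]], index=["GENE1"],
            columns=[7, 14, 19, 21, 24, 26, 28, 35],
        )
        return ExpressionMatrix(values=vals, tf_flags=frozenset({"GENE1"}))

    def _enrichment(self):
        return pd.DataFrame({"p_value": [1e-4, 1e-2]}, index=["M1", "M2"])

    def test_one_tf_eight_rows_values_unchanged(self):
        table = mo.tf_bubble_table(
            self._enrichment().iloc[:1],
            self._expression(),
            {"TF1": "GENE1"},
            motif_tf={"M1": "TF1"},
        )
        assert len(table) == 8
        assert table["neg_log10_p"].unique() == pytest.approx([4.0])
        assert list(table["expression"]) == [0, 1, 2, 3, 4, 5, 6, 7]

    def test_unmapped_tf_warned_and_dropped(self):
        with pytest.warns(UserWarning, match="TF2"):
            table = mo.tf_bubble_table(
                self._enrichment(),
                self._expression(),
                {"TF1": "GENE1"},
                motif_tf={"M1": "TF1", "M2": "TF2"},
            )
        assert set(table["tf"]) == {"TF1"}

    def test_empty_join_rejected(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                mo.tf_bubble_table(
                    self._enrichment(), self._expression(), {}, motif_tf={"M1": "TFX", "M2": "TFY"}
                )
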