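import numpy as np
import pandas as pd
import pytest

from bilnc.io_formats import TranscriptModel, revcomp
from bilnc.targets import (
    CIS_DOWN,
    CIS_OVERLAP,
    CIS_UP,
    DISTAL,
    PositionTaxonomy,
    classify_position,
    correlation_filter,
    duplex_energy,
)
from oracles import classify_oracle, duplex_oracle


def span_model(tid, start, end, strand="+", chrom="Chr1", exons=None):
    return TranscriptModel(tid, f"g_{tid}", chrom, strand, exons or [(start, end)])


def random_geometry(rng):
    chrom = "Chr1" if rng.random() < 0.9 else "Chr2"
    m_strand = "+" if rng.random() < 0.5 else "-"
    l_strand = "+" if rng.random() < 0.5 else "-"
    ms = int(rng.integers(25_000, 35_000))
    n_exons = int(rng.integers(1, 4))
    exons, pos = [], ms
    for _ in range(n_exons):
        e = int(rng.integers(100, 1200))
        exons.append((pos, pos + e))
        pos += e + int(rng.integers(200, 1500))
    mrna = span_model("m", 0, 1, m_strand, "Chr1", exons=exons)
    ls = int(rng.integers(0, 70_000))
    le = ls + int(rng.integers(50, 4000))
    lnc = span_model("l", ls, le, l_strand, chrom)
    return lnc, mrna


class TestClassifyPosition:
    def test_downstream_window(self):
        mrna = span_model("m", 10_000, 15_000, "+")
        lnc = span_model("l", 15_500, 16_500)
        call = classify_position(lnc, mrna)
        assert call.reg_class == CIS_DOWN
        assert call.distance == 500

    def test_strand_flip_makes_it_upstream(self):
        mrna = span_model("m", 10_000, 15_000, "-")
        lnc = span_model("l", 15_500, 16_500)
        call = classify_position(lnc, mrna)
        assert call.reg_class == CIS_UP
        assert call.distance == -500

    def test_antisense_intron_containment(self):
        mrna = span_model("m", 0, 1, "+", exons=[(1000, 2000), (3000, 4000)])
        lnc = span_model("l", 2100, 2900, "-")
        call = classify_position(lnc, mrna)
        assert call.reg_class == CIS_OVERLAP
        assert (call.strand_relation, call.geometry) == ("antisense", "lnc_in_intron")

    def test_window_edges_inclusive(self):
        mrna = span_model("m", 100_000, 103_000, "+")
        at_edge = classify_position(span_model("l", 89_000, 90_000), mrna)
        assert at_edge.reg_class == CIS_UP and at_edge.distance == -10_000
        past_edge = classify_position(span_model("l", 88_999, 89_999), mrna)
        assert past_edge.reg_class == DISTAL

    def test_zero_windows_force_distal(self):
        taxonomy = PositionTaxonomy(window_up=0, window_down=0)
        mrna = span_model("m", 10_000, 15_000, "+")
        lnc = span_model("l", 15_100, 15_800)
        assert classify_position(lnc, mrna, taxonomy).reg_class == DISTAL
        touching = span_model("l", 9_000, 10_000)
        assert classify_position(touching, mrna, taxonomy).reg_class == CIS_UP

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            lnc, mrna = random_geometry(rng)
            call = classify_position(lnc, mrna)
            reg, sub = classify_oracle(lnc, mrna)
            assert call.reg_class == reg
            if sub is not None:
                assert (call.strand_relation, call.geometry) == sub


class TestCorrelationFilter:
    def design_matrix(self, vectors):
        return pd.DataFrame(vectors, columns=[f"s{i}" for i in range(15)])

    def test_identical_vectors_retained(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(3, 1, 15)
        fpkm = self.design_matrix({"l1": v, "m1": v}).T
        fpkm = pd.DataFrame({"l1": v, "m1": v}).T
        fpkm.columns = [f"s{i}" for i in range(15)]
        out = correlation_filter(fpkm, ["l1"], ["m1"])
        assert len(out) == 1
        assert out["pearson"].iloc[0] == pytest.approx(1.0)
        assert out["spearman"].iloc[0] == pytest.approx(1.0)

    def test_monotone_convex_relation(self):
        x = np.linspace(0.1, 8, 15)
        fpkm = pd.DataFrame({"l1": x, "m1": np.exp(x)}).T
        fpkm.columns = [f"s{i}" for i in range(15)]
        out = correlation_filter(fpkm, ["l1"], ["m1"])
        lx, ly = np.log2(x + 1), np.log2(np.exp(x) + 1)
        pearson = np.corrcoef(lx, ly)[0, 1]
        assert (len(out) == 1) == (pearson >= 0.6)
        if len(out):
            assert out["spearman"].iloc[0] == pytest.approx(1.0)
            assert out["pearson"].iloc[0] == pytest.approx(pearson)

    def test_negative_correlation_excluded(self):
        x = np.linspace(1, 10, 15)
        fpkm = pd.DataFrame({"l1": x, "m1": x[::-1]}).T
        fpkm.columns = [f"s{i}" for i in range(15)]
        assert len(correlation_filter(fpkm, ["l1"], ["m1"])) == 0

    def test_constant_vector_skipped(self):
        x = np.linspace(1, 10, 15)
        fpkm = pd.DataFrame({"l1": np.ones(15), "m1": x}).T
        fpkm.columns = [f"s{i}" for i in range(15)]
        assert len(correlation_filter(fpkm, ["l1"], ["m1"])) == 0


class TestDuplexEnergy:
    def test_no_complementarity_gives_zero(self):
        assert duplex_energy("A" * 10, "A" * 10) == 0.0

    def test_perfect_30mer_duplex_below_trans_threshold(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 30))
        assert duplex_energy(seq, revcomp(seq)) < -30.0

    def test_matches_exhaustive_window_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(15, 50))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(15, 50))))
            assert duplex_energy(a, b) == pytest.approx(duplex_oracle(a, b))

    def test_short_sequences_rejected(self):
        with pytest.raises(Exception):
            duplex_energy("ACGT", "ACGTACGTACGT")


class TestPredictTargets:
    def test_planted_pairs_recovered_exactly(self, noiseless_run):
        ds, results, _ = noiseless_run
        got = {
            (r.lncrna_id, r.mrna_id): (r.reg_class, r.subclass)
            for r in results["targets"]["pairs"].itertuples()
        }
        taxonomy = PositionTaxonomy()
        for lnc, mrna, reg_class, rel, geom in ds.truth.pairs:
            assert (lnc, mrna) in got
            got_class, got_sub = got[(lnc, mrna)]
            assert got_class == reg_class
            if reg_class == "cis_mRNA_overlap":
                assert got_sub == taxonomy.label(rel, geom)

    def test_no_spurious_cis_pairs(self, noiseless_run):
        ds, results, _ = noiseless_run
        planted = {(l, m) for l, m, *_ in ds.truth.pairs}
        for r in results["targets"]["pairs"].itertuples():
            if (r.lncrna_id, r.mrna_id) not in planted:
                assert r.reg_class == "trans"  # never a false positional call

    def test_reported_pairs_satisfy_correlation_thresholds(self, noiseless_run):
        _, results, _ = noiseless_run
        pairs = results["targets"]["pairs"]
        assert (pairs["pearson"] >= 0.6).all()
        assert (pairs["spearman"] >= 0.6).all()

    def test_distal_without_complementarity_not_reported(self):
        # correlated pair 25 kb downstream: outside both windows, random
        # sequences, so no trans promotion either
        rng = np.random.default_rng(3)
        mrna = span_model("m", 10_000, 13_000, "+")
        lnc = span_model("l", 38_000, 38_800)
        from bilnc.targets import predict_targets

        x = rng.lognormal(3, 1, 15)
        fpkm = pd.DataFrame({"l": x, "m": x * 2}).T
        fpkm.columns = [f"s{i}" for i in range(15)]
        seqs = {
            "l": "".join(rng.choice(list("ACGT"), 800)),
            "m": "".join(rng.choice(list("ACGT"), 1500)),
        }
        pairs, census = predict_targets([lnc], [mrna], fpkm, sequences=seqs)
        assert len(pairs) == 0
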