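import numpy as np
import pandas as pd
import pytest

from bilnc.datasets import (
    load_mirna_lncrna_targets,
    load_precursor_hits,
    targets_as_edge_table,
)
from bilnc.io_formats import ValidationError, revcomp
from bilnc.mirna import (
    build_network,
    find_precursors,
    find_target_edges,
    mirna_target_score,
    precursor_census,
    self_targeting,
    smith_waterman,
)
from oracles import sw_score_oracle


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSmithWaterman:
    def test_identical_sequences(self):
        rng = np.random.default_rng(0)
        seq = rand_seq(rng, 20)
        aln = smith_waterman(seq, seq)
        assert aln.score == 20
        assert aln.alignment_length == 20
        assert aln.identity == 1.0

    def test_no_homology_single_match(self):
        aln = smith_waterman("ACGTACGT", "TTTTTTTT")
        assert aln is not None and aln.score == 1.0
        assert aln.alignment_length == 1

    def test_matches_independent_dp(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            q, s = rand_seq(rng, 30), rand_seq(rng, 30)
            aln = smith_waterman(q, s)
            score = aln.score if aln else 0.0
            assert score == pytest.approx(sw_score_oracle(q, s))
            if aln:
                assert aln.alignment_length <= min(len(q), len(s)) + 5

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            smith_waterman("ACGU", "ACGT")


class TestFindPrecursors:
    def test_verbatim_embedding_has_full_coverage(self):
        rng = np.random.default_rng(2)
        pre = rand_seq(rng, 120)
        host = rand_seq(rng, 200) + pre + rand_seq(rng, 180)
        hits = find_precursors({"mir1": pre}, {"lnc1": host})
        assert len(hits) == 1
        assert hits["coverage_ratio"].iloc[0] == pytest.approx(1.0)
        assert hits["identity"].iloc[0] == pytest.approx(1.0)

    def test_partial_embedding_below_ratio_rejected(self):
        rng = np.random.default_rng(3)
        pre = rand_seq(rng, 100)
        host = rand_seq(rng, 200) + pre[:85] + rand_seq(rng, 180)
        hits = find_precursors({"mir1": pre}, {"lnc1": host})
        assert len(hits) == 0

    def test_low_identity_rejected(self):
        rng = np.random.default_rng(4)
        pre = rand_seq(rng, 100)
        mutated = list(pre)
        for i in range(0, 100, 6):  # ~17% mismatches spread along the precursor
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        host = rand_seq(rng, 150) + "".join(mutated) + rand_seq(rng, 150)
        hits = find_precursors({"mir1": pre}, {"lnc1": host})
        assert len(hits) == 0


class TestPublishedTables:
    def test_precursor_table_census_matches_printed_claims(self):
        hits = load_precursor_hits()
        census = precursor_census(hits)
        assert census["n_hits"] == 24
        assert census["n_lncrnas"] == 22
        assert census["n_mirnas"] == 20
        assert census["n_de_lncrnas"] == 18
        assert census["n_multi_mirna_lncrnas"] == 2
        # more than half of the precursor lncRNAs come from chromosome 2
        assert census["lncrnas_per_chrom"]["Chr2"] / census["n_lncrnas"] > 0.5
        assert (hits["coverage_ratio"] > 0.9).all()

    def test_self_targeting_flags_reproduce_published_pattern(self):
        hits = load_precursor_hits()
        published = load_mirna_lncrna_targets()
        edges = targets_as_edge_table(published)
        out = self_targeting(edges, hits)
        recomputed = dict(zip(zip(out["mirna_id"], out["target_id"]), out["self_pair"]))
        expected = dict(
            zip(
                zip(published["mirna_id"], published["target_lncrna_id"]),
                published["precursor_of_same_mirna"],
            )
        )
        assert recomputed == expected
        assert len(set(out["mirna_id"])) == 7


class TestAllenScoring:
    def test_perfect_site_scores_zero(self):
        rng = np.random.default_rng(5)
        mature = rand_seq(rng, 21)
        transcript = rand_seq(rng, 300) + revcomp(mature) + rand_seq(rng, 300)
        score, pos = mirna_target_score(mature, transcript)
        assert score == 0.0
        assert pos == 300

    def test_wobble_outside_core_scores_half(self):
        # G at miRNA position 16 (1-based, outside 2-13); give the site a T
        # there so the pair is G:U
        mature = "A" * 15 + "G" + "A" * 5
        site = list(revcomp(mature))
        assert site[21 - 16] == "C"
        site[21 - 16] = "T"
        transcript = "G" * 100 + "".join(site) + "G" * 100
        score, _ = mirna_target_score(mature, transcript)
        assert score == pytest.approx(0.5)

    def test_core_mismatch_doubled(self):
        mature = "A" * 21
        site = list(revcomp(mature))  # all T
        site[21 - 5] = "C"  # mismatch opposite miRNA position 5 (core)
        transcript = "G" * 50 + "".join(site) + "G" * 50
        score, _ = mirna_target_score(mature, transcript)
        assert score == pytest.approx(2.0)

    def test_random_transcripts_score_above_cutoff(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            mature = rand_seq(rng, 21)
            transcript = rand_seq(rng, 600)
            score, _ = mirna_target_score(mature, transcript)
            assert score > 4.0

    def test_length_bounds_enforced(self):
        with pytest.raises(ValidationError):
            mirna_target_score("ACGT", "ACGT" * 50)


class TestNetwork:
    def edges(self, spec):
        rows = [
            {"mirna_id": m, "target_id": t, "target_kind": k, "score": 0.0, "site_start": 0}
            for m, t, k in spec
        ]
        return pd.DataFrame(rows)

    def hits(self, spec):
        rows = [
            {
                "mirna_id": m,
                "lncrna_id": l,
                "alignment_length": 120,
                "coverage_ratio": 1.0,
                "identity": 1.0,
                "location": "Chr1",
                "de_lncrna": False,
            }
            for m, l in spec
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "mirna_id",
                "lncrna_id",
                "alignment_length",
                "coverage_ratio",
                "identity",
                "location",
                "de_lncrna",
            ],
        )

    def test_both_class_with_more_mrnas(self):
        spec = [("m1", f"x{i}", "lncRNA") for i in range(2)]
        spec += [("m1", f"y{i}", "mRNA") for i in range(7)]
        _, classes, census = build_network(self.edges(spec), self.hits([]))
        row = classes.iloc[0]
        assert row["mirna_class"] == "both"
        assert row["both_subclass"] == "more-mRNAs"

    def test_single_kind_classes_and_partition(self):
        spec = [
            ("m1", "y1", "mRNA"),
            ("m2", "x1", "lncRNA"),
            ("m3", "x2", "lncRNA"),
            ("m3", "y2", "mRNA"),
        ]
        _, classes, census = build_network(self.edges(spec), self.hits([]))
        assert (
            census["only_mrna"] + census["only_lncrna"] + census["both"]
            == census["n_mirnas"]
            == 3
        )

    def test_self_targeting_definition(self):
        edges = self.edges([("m1", "x1", "lncRNA"), ("m2", "x2", "lncRNA")])
        hits = self.hits([("m1", "x1"), ("m2", "x9")])
        out = self_targeting(edges, hits)
        assert set(out["mirna_id"]) == {"m1"}
        assert bool(out["self_pair"].iloc[0]) is True


def test_synthetic_precursors_and_self_targeting_recovered(noiseless_run):
    ds, results, _ = noiseless_run
    hits = results["mirna"]["precursor_hits"]
    got = set(zip(hits["mirna_id"], hits["lncrna_id"]))
    assert got == set(ds.truth.precursors)
    assert (hits["coverage_ratio"] == 1.0).all()
    edges = results["mirna"]["target_edges"]
    got_edges = set(zip(edges["mirna_id"], edges["target_id"]))
    assert got_edges == {(m, t) for m, t, _ in ds.truth.target_edges}
    selfing = results["mirna"]["self_targeting"]
    truth_self = {
        m
        for m, lnc in ds.truth.precursors
        if (m, lnc, "lncRNA") in ds.truth.target_edges
    }
    assert set(selfing.loc[selfing["self_pair"], "mirna_id"]) == truth_self
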