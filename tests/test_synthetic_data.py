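import hashlib

import numpy as np
import pandas as pd
import pytest

from bilnc.diffexp import call_de
from bilnc.io_formats import TranscriptModel
from bilnc.mirna import mirna_target_score
from bilnc.synthetic_data import (
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    make_design,
    null_config,
    simulate_annotation,
    simulate_counts,
    simulate_dataset,
    write_dataset,
)


class TestCensusConservation:
    def test_truth_counts_equal_configured_counts(self, noiseless_sim):
        ds = noiseless_sim
        cfg = ds.config
        census = ds.truth.pair_census()
        for key, n in cfg.planted_cis_counts.items():
            assert census.get(key, 0) == n
        assert census.get("trans", 0) == cfg.planted_trans_count
        eld_per_cat = {}
        for (progeny, _), cat in ds.truth.eld.items():
            eld_per_cat.setdefault(cat, set()).add(progeny)
        planted = {}
        for (_, tid), cat in ds.truth.eld.items():
            planted.setdefault(cat, set()).add(tid)
        for cat, n in cfg.planted_eld_counts.items():
            assert len(planted.get(cat, set())) == n
        assert len(ds.truth.precursors) == cfg.n_mirna_precursors_embedded

    def test_every_truth_entry_references_an_emitted_transcript(self, noiseless_sim):
        ds = noiseless_sim
        tids = {t.transcript_id for t in ds.transcripts}
        for lnc, mrna, *_ in ds.truth.pairs:
            assert {lnc, mrna} <= tids
        assert {tid for _, tid in ds.truth.eld} <= tids
        assert {lnc for _, lnc in ds.truth.precursors} <= tids
        assert {tid for _, tid, _ in ds.truth.target_edges} <= tids


class TestDeterminism:
    def test_identical_files_at_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=3)
        digests = []
        for name in ("a", "b"):
            out = tmp_path / name
            files = write_dataset(simulate_dataset(cfg), out)
            digests.append(
                {
                    f.relative_to(out).as_posix(): hashlib.sha256(
                        f.read_bytes()
                    ).hexdigest()
                    for f in files
                }
            )
        assert digests[0] == digests[1]

    def test_seeds_change_coordinates_not_census(self):
        a = simulate_annotation(SimulationConfig(seed=1))
        b = simulate_annotation(SimulationConfig(seed=2))
        assert GroundTruth.pair_census(a[2]) == GroundTruth.pair_census(b[2])
        spans_a = sorted(t.span for t in a[1])
        spans_b = sorted(t.span for t in b[1])
        assert spans_a != spans_b


class TestGeometryByConstruction:
    def test_planted_classes_satisfy_their_definitions(self, noiseless_sim):
        ds = noiseless_sim
        models = {t.transcript_id: t for t in ds.transcripts}
        for lnc_id, mrna_id, reg_class, rel, geom in ds.truth.pairs:
            lnc, mrna = models[lnc_id], models[mrna_id]
            if reg_class == "trans":
                assert lnc.chrom != mrna.chrom
                continue
            assert lnc.chrom == mrna.chrom
            ls, le = lnc.span
            ms, me = mrna.span
            if reg_class == "cis_mRNA_overlap":
                assert max(ls, ms) < min(le, me)
                expected_rel = "sense" if lnc.strand == mrna.strand else "antisense"
                assert rel == expected_rel
                if geom == "lnc_in_intron":
                    assert any(i0 <= ls and le <= i1 for i0, i1 in mrna.introns)
                elif geom == "mrna_in_lnc":
                    assert ls <= ms and me <= le
            else:
                # disjoint, strand-aware window, inclusive
                gap = ms - le if le <= ms else ls - me
                assert gap >= 0
                lnc_left = le <= ms
                upstream = lnc_left == (mrna.strand == "+")
                if reg_class == "cis_mRNA_up10k":
                    assert upstream and gap <= 10_000
                else:
                    assert not upstream and gap <= 20_000

    def test_unplaceable_geometry_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_annotation(SimulationConfig(chrom_length=10_000))


class TestCounts:
    def test_null_config_log2fc_centered_at_zero(self):
        cfg = null_config(1200, seed=4)
        genome, transcripts, truth = simulate_annotation(cfg)
        em = simulate_counts(transcripts, truth, make_design(cfg), cfg)
        de = call_de(em, [("A", "B")])
        assert abs(de["log2fc"].mean()) < 0.05

    def test_planted_pairs_exceed_correlation_threshold(self):
        # 200 planted pairs on hand-built transcripts; expect >= 95% recovery
        cfg = SimulationConfig(seed=9)
        transcripts = [
            TranscriptModel(f"T{i:04d}", f"G{i:04d}", "Chr1", "+", [(i * 5000, i * 5000 + 600)])
            for i in range(400)
        ]
        truth = GroundTruth(
            biotype={t.transcript_id: "lncRNA" for t in transcripts},
            pairs=[
                (f"T{2 * i:04d}", f"T{2 * i + 1:04d}", "trans", "", "")
                for i in range(200)
            ],
        )
        em = simulate_counts(transcripts, truth, make_design(cfg), cfg)
        x = np.log2(em.to_fpkm().values + 1.0)
        ok = 0
        for lnc, mrna, *_ in truth.pairs:
            r = np.corrcoef(x.loc[lnc], x.loc[mrna])[0, 1]
            ok += r >= 0.6
        assert ok / len(truth.pairs) >= 0.95

    def test_eld_means_follow_category_in_noiseless_limit(self):
        # dispersion ~0 and no depth rescaling: raw-count line-mean ratios
        # approach the planted effect directly
        cfg = SimulationConfig(
            seed=6, nb_dispersion=1e-9, eld_effect_log2=1.0, library_size_range=None
        )
        genome, transcripts, truth = simulate_annotation(cfg)
        em = simulate_counts(transcripts, truth, make_design(cfg), cfg)
        counts = em.values
        design = em.design
        line_means = {
            line: counts[list(sub["sample_id"])].mean(axis=1)
            for line, sub in design.groupby("line")
        }
        checked = 0
        for (progeny, tid), cat in truth.eld.items():
            if cat != "IX":  # ELD-B with A above B: progeny tracks B
                continue
            ratio = np.log2(line_means[progeny][tid] / line_means["B"][tid])
            assert abs(ratio) < 0.35
            ratio_a = np.log2(line_means["A"][tid] / line_means["B"][tid])
            assert ratio_a == pytest.approx(1.0, abs=0.35)
            checked += 1
        assert checked > 0


class TestMirnaEmbedding:
    def test_precursors_inserted_verbatim(self, noiseless_sim):
        ds = noiseless_sim
        seqs = ds.sequences
        for mirna_id, lnc_id in ds.truth.precursors:
            assert ds.precursors[mirna_id] in seqs[lnc_id]

    def test_planted_sites_score_zero(self, noiseless_sim):
        ds = noiseless_sim
        seqs = ds.sequences
        for mirna_id, tid, _ in ds.truth.target_edges:
            score, _ = mirna_target_score(ds.matures[mirna_id], seqs[tid])
            assert score == 0.0

    def test_hairpin_arm_alone_is_not_a_target_site(self, noiseless_sim):
        # hosts without a planted clean site must not self-target via the stem
        ds = noiseless_sim
        planted = {(m, t) for m, t, _ in ds.truth.target_edges}
        seqs = ds.sequences
        for mirna_id, lnc_id in ds.truth.precursors:
            if (mirna_id, lnc_id) not in planted:
                score, _ = mirna_target_score(ds.matures[mirna_id], seqs[lnc_id])
                assert score > 4.0


class TestWriteDataset:
    def test_file_set_complete_and_conserved(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(seed=5))
        outdir = tmp_path / "ds"
        files = write_dataset(ds, outdir)
        for name in (
            "genome.fa",
            "transcripts.fa",
            "annotation.gtf",
            "counts.tsv",
            "design.tsv",
            "mirna_mature.fa",
            "mirna_precursor.fa",
            "truth/pairs.tsv",
        ):
            path = outdir / name
            assert path.exists() and path.stat().st_size > 0
        pairs = pd.read_csv(outdir / "truth" / "pairs.tsv", sep="\t")
        expected = sum(ds.config.planted_cis_counts.values()) + ds.config.planted_trans_count
        assert len(pairs) == expected
        assert len(files) == 14
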