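"""Deterministic miniature five-line dataset with planted ground truth.

Emulates the downstream products of a two-parent / three-progeny rice
backcross-introgression design (5 lines x 3 replicates): a genome with mRNA
and lncRNA loci placed in known positional relationships, negative-binomial
fragment counts with planted pair correlations and parental
expression-level-dominance (ELD) patterns, lncRNAs with embedded miRNA
hairpins, and transcripts carrying planted miRNA target sites.

Placement uses fixed-size slots laid out round-robin across chromosomes so
that transcripts of different slots are always farther apart than the
cis windows — planted pairs are therefore the only cis geometries, and
class recovery is exact by construction.

Counts are negative binomial (gamma-Poisson) around per-line log2 means.
``eld_effect_log2`` is the minimum planted |delta log2| between any two
groups an ELD category requires to differ; for additivity categories the
parents are separated by twice the effect with the progeny at the midpoint.
Planted regulatory pairs share a per-sample lognormal latent factor, which
drives their expression correlation above the 0.6 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    SequenceRecord,
    TranscriptModel,
    ValidationError,
    revcomp,
    write_fasta,
    write_gtf,
)
from .quantify import ExpressionMatrix
from .targets import GEOMETRIES

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")

CIS_UP_KEY, CIS_DOWN_KEY = "cis_up10k", "cis_dw20k"


def _overlap_key(rel: str, geom: str) -> str:
    return f"overlap:{rel}:{geom}"


def default_cis_counts() -> dict[str, int]:
    counts = {CIS_UP_KEY: 2, CIS_DOWN_KEY: 2}
    for rel in ("sense", "antisense"):
        for geom in GEOMETRIES:
            counts[_overlap_key(rel, geom)] = 1
    return counts


def default_eld_counts() -> dict[str, int]:
    return {cat: 2 for cat in ROMAN}


class ConfigurationError(ValueError):
    """The requested simulation geometry cannot be realised."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int | None = None  # None: auto-sized to fit all slots
    slot_length: int = 50_000
    n_mrna: int = 45
    n_lncrna: int = 44
    gc_content: float = 0.44
    planted_cis_counts: dict[str, int] = field(default_factory=default_cis_counts)
    planted_trans_count: int = 2
    planted_eld_counts: dict[str, int] = field(default_factory=default_eld_counts)
    nb_dispersion: float = 0.02
    base_mean_log2: float = 7.0
    base_mean_sd_log2: float = 1.2
    planted_base_log2_range: tuple[float, float] = (7.0, 8.0)
    eld_effect_log2: float = 2.0
    latent_log2_sd: float = 1.5
    latent_clip: float = 2.0  # truncation of the per-line latent factor, in SD
    n_mirna_precursors_embedded: int = 3
    n_target_sites_planted: int = 4
    n_self_targeting: int = 2
    precursor_stem_len: int = 50
    precursor_loop_len: int = 20
    mature_len: int = 21
    target_site_mismatches: int = 0
    library_size_range: tuple[int, int] | None = (30_000, 50_000)
    parent_a: str = "A"
    parent_b: str = "B"
    progenies: tuple[str, ...] = ("H1", "H2", "H3")
    n_replicates: int = 3

    def noiseless(self) -> "SimulationConfig":
        """Variant with negligible count noise (near-exact correlations)."""
        return replace(self, nb_dispersion=1e-9)


def null_config(n_transcripts: int = 2500, seed: int = 0) -> SimulationConfig:
    """A no-effect configuration: independent, identically-expressed lncRNAs."""
    return SimulationConfig(
        seed=seed,
        n_lncrna=n_transcripts,
        n_mrna=0,
        planted_cis_counts={},
        planted_trans_count=0,
        planted_eld_counts={},
        n_mirna_precursors_embedded=0,
        n_target_sites_planted=0,
        n_self_targeting=0,
        slot_length=4000,
        # no depth rescaling: under the null every line has the same
        # expected composition, so realised totals are already balanced
        library_size_range=None,
    )


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    biotype: dict[str, str] = field(default_factory=dict)
    # (lncrna_id, mrna_id, reg_class, strand_relation, geometry)
    pairs: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    eld: dict[tuple[str, str], str] = field(default_factory=dict)  # (progeny, tid) -> cat
    precursors: list[tuple[str, str]] = field(default_factory=list)  # (mirna, lncrna)
    target_edges: list[tuple[str, str, str]] = field(default_factory=list)  # (mirna, tid, kind)

    def pair_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for _, _, reg_class, rel, geom in self.pairs:
            key = (
                _overlap_key(rel, geom)
                if reg_class == "cis_mRNA_overlap"
                else {"cis_mRNA_up10k": CIS_UP_KEY, "cis_mRNA_dw20k": CIS_DOWN_KEY}.get(
                    reg_class, "trans"
                )
            )
            census[key] = census.get(key, 0) + 1
        return census


# ---------------------------------------------------------------------------
# sequence helpers (genome held as int8 code arrays, A=0 C=1 G=2 T=3)
# ---------------------------------------------------------------------------

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()

def _encode(seq: str) -> np.ndarray:
    codes = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValidationError("payload contains characters outside ACGT")
    return codes


def _extract_codes(genome: dict[str, np.ndarray], model: TranscriptModel) -> str:
    chrom = genome[model.chrom]
    seq = "".join(_decode(chrom[s:e]) for s, e in model.exons)
    return revcomp(seq) if model.strand == "-" else seq


def _write_payload(
    genome: dict[str, np.ndarray], model: TranscriptModel, tx_offset: int, payload: str
) -> None:
    """Overwrite transcript positions [tx_offset, tx_offset+len) with payload.

    Only single-exon models are supported (all engineered lncRNAs are
    single-exon); the genome strand copy is reverse-complemented as needed.
    """
    if model.exon_count != 1:
        raise ValidationError("payloads can only be written into single-exon models")
    s, e = model.exons[0]
    n = len(payload)
    if tx_offset + n > e - s:
        raise ValidationError(
            f"payload of {n} nt does not fit {model.transcript_id} at offset {tx_offset}"
        )
    if model.strand == "+":
        genome[model.chrom][s + tx_offset : s + tx_offset + n] = _encode(payload)
    else:
        g0 = e - tx_offset - n
        genome[model.chrom][g0 : g0 + n] = _encode(revcomp(payload))


def _write_payload_exonic(
    genome: dict[str, np.ndarray], model: TranscriptModel, payload: str
) -> None:
    """Overwrite part of one sufficiently large exon with payload (any model)."""
    n = len(payload)
    for s, e in model.exons:
        if e - s >= n + 10:
            if model.strand == "+":
                genome[model.chrom][s + 5 : s + 5 + n] = _encode(payload)
            else:
                genome[model.chrom][e - 5 - n : e - 5] = _encode(revcomp(payload))
            return
    raise ValidationError(
        f"no exon of {model.transcript_id} can host a {n} nt payload"
    )


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    codes = rng.choice(4, size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _decode(codes.astype(np.int8))


# ---------------------------------------------------------------------------
# annotation geometry
# ---------------------------------------------------------------------------


def _mrna_exons(rng: np.random.Generator, origin: int) -> list[tuple[int, int]]:
    e = rng.integers(250, 551, size=3)
    i = rng.integers(700, 901, size=2)
    s0 = origin
    return [
        (s0, s0 + e[0]),
        (s0 + e[0] + i[0], s0 + e[0] + i[0] + e[1]),
        (s0 + e[0] + i[0] + e[1] + i[1], s0 + e[0] + i[0] + e[1] + i[1] + e[2]),
    ]


def _bg_lnc_exons(rng: np.random.Generator, origin: int) -> list[tuple[int, int]]:
    total = int(rng.integers(450, 901))
    if rng.random() < 0.4:  # two-exon lncRNA
        cut = total // 2
        intron = int(rng.integers(200, 401))
        return [(origin, origin + cut), (origin + cut + intron, origin + total + intron)]
    return [(origin, origin + total)]


_CLASS_ORDER = [CIS_UP_KEY] + [
    _overlap_key(rel, geom) for rel in ("sense", "antisense") for geom in GEOMETRIES
] + [CIS_DOWN_KEY]


def _build_cis_pair(
    rng: np.random.Generator, class_key: str, origin: int
) -> tuple[list[tuple[int, int]], str, list[tuple[int, int]], str, str, str, str]:
    """Returns (mrna_exons, mrna_strand, lnc_exons, lnc_strand, reg_class, rel, geom)."""
    mrna_strand = "+" if rng.random() < 0.5 else "-"
    if class_key in (CIS_UP_KEY, CIS_DOWN_KEY):
        lnc_len = int(rng.integers(400, 801))
        gap = int(
            rng.integers(500, 8001) if class_key == CIS_UP_KEY else rng.integers(500, 18001)
        )
        lnc_strand = "+" if rng.random() < 0.5 else "-"
        lnc_left = (mrna_strand == "+") == (class_key == CIS_UP_KEY)
        if lnc_left:
            lnc_exons = [(origin, origin + lnc_len)]
            mrna_exons = _mrna_exons(rng, origin + lnc_len + gap)
        else:
            mrna_exons = _mrna_exons(rng, origin)
            m_end = mrna_exons[-1][1]
            lnc_exons = [(m_end + gap, m_end + gap + lnc_len)]
        reg = "cis_mRNA_up10k" if class_key == CIS_UP_KEY else "cis_mRNA_dw20k"
        return mrna_exons, mrna_strand, lnc_exons, lnc_strand, reg, "", ""

    _, rel, geom = class_key.split(":")
    lnc_strand = mrna_strand if rel == "sense" else ("-" if mrna_strand == "+" else "+")
    mrna_exons = _mrna_exons(rng, origin + 600)
    ms, me = mrna_exons[0][0], mrna_exons[-1][1]
    if geom == "partial5":
        anchor = ms if mrna_strand == "+" else me
        lnc_exons = [(anchor - 300, anchor + 300)]
    elif geom == "partial3":
        anchor = me if mrna_strand == "+" else ms
        lnc_exons = [(anchor - 300, anchor + 300)]
    elif geom == "lnc_in_mrna":
        e1_end = mrna_exons[0][1]  # crosses the exon1/intron1 boundary
        lnc_exons = [(e1_end - 200, e1_end + 300)]
    elif geom == "lnc_in_intron":
        i0, i1 = mrna_exons[0][1], mrna_exons[1][0]
        lnc_exons = [(i0 + 100, i0 + 100 + min(400, (i1 - i0) - 200))]
    elif geom == "mrna_in_lnc":
        lnc_exons = [(ms - 300, me + 300)]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown overlap geometry {geom!r}")
    return mrna_exons, mrna_strand, lnc_exons, lnc_strand, "cis_mRNA_overlap", rel, geom


# ---------------------------------------------------------------------------
# simulate_annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], list[TranscriptModel], GroundTruth]:
    """Genome, transcript models and positional/biotype ground truth.

    The genome is returned as per-chromosome integer code arrays (use
    :func:`genome_records` for FASTA-ready sequences) so that downstream
    feature embedding can edit it in place before sequences are extracted.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = GroundTruth()

    for key in config.planted_cis_counts:
        if key not in _CLASS_ORDER:
            raise ConfigurationError(f"unknown cis class key {key!r}")
    for cat in config.planted_eld_counts:
        if cat not in ROMAN:
            raise ConfigurationError(f"unknown ELD category {cat!r}")

    n_cis = sum(config.planted_cis_counts.values())
    n_eld = sum(config.planted_eld_counts.values())
    planted_lnc = n_cis + config.planted_trans_count
    planted_mrna = n_cis + config.planted_trans_count
    if config.n_lncrna < planted_lnc + n_eld:
        raise ConfigurationError(
            f"n_lncrna={config.n_lncrna} too small for {planted_lnc} planted pair "
            f"lncRNAs plus {n_eld} ELD lncRNAs"
        )
    if config.n_mrna < planted_mrna:
        raise ConfigurationError("n_mrna smaller than the planted pair mRNAs")
    if config.planted_trans_count and config.n_chroms < 2:
        raise ConfigurationError("trans pairs need at least 2 chromosomes")

    jobs: list[tuple] = []
    for class_key in _CLASS_ORDER:
        for _ in range(config.planted_cis_counts.get(class_key, 0)):
            jobs.append(("pair", class_key))
    for i in range(config.planted_trans_count):
        jobs.append(("trans_lnc", i))
        jobs.append(("trans_mrna", i))
    for cat in ROMAN:
        for _ in range(config.planted_eld_counts.get(cat, 0)):
            jobs.append(("eld_lnc", cat))
    n_bg_mrna = config.n_mrna - planted_mrna
    n_bg_lnc = config.n_lncrna - planted_lnc - n_eld
    bg_mrna_units = 0
    mrna_budget = n_bg_mrna
    while mrna_budget > 0:
        with_isoform = bg_mrna_units % 7 == 6 and mrna_budget >= 2
        jobs.append(("bg_mrna", with_isoform))
        mrna_budget -= 2 if with_isoform else 1
        bg_mrna_units += 1
    for _ in range(n_bg_lnc):
        jobs.append(("bg_lnc", None))

    rows_needed = -(-len(jobs) // config.n_chroms)
    chrom_length = config.chrom_length or rows_needed * config.slot_length
    if rows_needed * config.slot_length > chrom_length:
        raise ConfigurationError(
            f"{len(jobs)} loci need {rows_needed} slots of {config.slot_length} nt "
            f"per chromosome but chrom_length={chrom_length}"
        )

    gc = config.gc_content
    genome = {
        f"Chr{c + 1}": rng.choice(
            4, size=chrom_length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        ).astype(np.int8)
        for c in range(config.n_chroms)
    }
    chrom_names = list(genome)

    transcripts: list[TranscriptModel] = []
    mrna_n = lnc_n = 0
    trans_members: dict[int, dict[str, TranscriptModel]] = {}

    def new_mrna(chrom, strand, exons, gene_id=None):
        nonlocal mrna_n
        mrna_n += 1
        tid = f"MRNA_{mrna_n:04d}"
        model = TranscriptModel(
            tid,
            gene_id or f"GM_{mrna_n:04d}",
            chrom,
            strand,
            exons,
            assembly_coverage=float(rng.uniform(2, 50)),
        )
        transcripts.append(model)
        truth.biotype[tid] = "mRNA"
        return model

    def new_lnc(chrom, strand, exons):
        nonlocal lnc_n
        lnc_n += 1
        tid = f"LNC_{lnc_n:04d}"
        model = TranscriptModel(
            tid,
            f"GL_{lnc_n:04d}",
            chrom,
            strand,
            exons,
            assembly_coverage=float(rng.uniform(2, 50)),
        )
        transcripts.append(model)
        truth.biotype[tid] = "lncRNA"
        return model

    for unit_idx, job in enumerate(jobs):
        chrom = chrom_names[unit_idx % config.n_chroms]
        row = unit_idx // config.n_chroms
        origin = row * config.slot_length + 1000 + int(
            rng.integers(0, max(2, config.slot_length // 12))
        )
        kind = job[0]
        if kind == "pair":
            m_ex, m_strand, l_ex, l_strand, reg, rel, geom = _build_cis_pair(
                rng, job[1], origin
            )
            mrna = new_mrna(chrom, m_strand, m_ex)
            lnc = new_lnc(chrom, l_strand, l_ex)
            truth.pairs.append((lnc.transcript_id, mrna.transcript_id, reg, rel, geom))
        elif kind == "trans_lnc":
            lnc_len = int(rng.integers(400, 801))
            strand = "+" if rng.random() < 0.5 else "-"
            lnc = new_lnc(chrom, strand, [(origin, origin + lnc_len)])
            trans_members.setdefault(job[1], {})["lnc"] = lnc
        elif kind == "trans_mrna":
            strand = "+" if rng.random() < 0.5 else "-"
            mrna = new_mrna(chrom, strand, _mrna_exons(rng, origin))
            trans_members.setdefault(job[1], {})["mrna"] = mrna
        elif kind == "eld_lnc":
            strand = "+" if rng.random() < 0.5 else "-"
            lnc_len = int(rng.integers(450, 901))
            lnc = new_lnc(chrom, strand, [(origin, origin + lnc_len)])
            for progeny in config.progenies:
                truth.eld[(progeny, lnc.transcript_id)] = job[1]
        elif kind == "bg_mrna":
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _mrna_exons(rng, origin)
            mrna = new_mrna(chrom, strand, exons)
            if job[1]:  # second isoform of the same gene (first two exons)
                new_mrna(chrom, strand, exons[:2], gene_id=mrna.gene_id)
        elif kind == "bg_lnc":
            strand = "+" if rng.random() < 0.5 else "-"
            new_lnc(chrom, strand, _bg_lnc_exons(rng, origin))

    # trans pairs: different chromosomes plus an engineered antisense window
    for i in sorted(trans_members):
        lnc, mrna = trans_members[i]["lnc"], trans_members[i]["mrna"]
        if lnc.chrom == mrna.chrom:  # pragma: no cover - round-robin prevents this
            raise ConfigurationError("trans pair landed on one chromosome")
        mrna_seq = _extract_codes(genome, mrna)
        window = mrna_seq[100:160]
        _write_payload(genome, lnc, 50, revcomp(window))
        truth.pairs.append((lnc.transcript_id, mrna.transcript_id, "trans", "", ""))

    return genome, transcripts, truth


def genome_records(genome: dict[str, np.ndarray]) -> list[SequenceRecord]:
    return [SequenceRecord(chrom, _decode(codes)) for chrom, codes in genome.items()]


def transcript_sequences(
    genome: dict[str, np.ndarray], transcripts: list[TranscriptModel]
) -> dict[str, str]:
    return {t.transcript_id: _extract_codes(genome, t) for t in transcripts}


# ---------------------------------------------------------------------------
# miRNA features
# ---------------------------------------------------------------------------

_WC_PARTNER = {"A": "T", "T": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}


def embed_mirna_features(
    genome: dict[str, np.ndarray],
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str]]:
    """Embed miRNA hairpins and target sites; returns (matures, precursors).

    Each precursor is a designed inverted repeat (5' arm + loop + mutated
    3' arm) inserted verbatim into a host lncRNA; the mature miRNA is the 5'
    arm prefix.  Three core-region mutations in the 3' arm prevent the
    hairpin itself from scoring as a target site, so self-targeting is
    decided solely by the separately planted clean sites.  Target sites are
    reverse complements of a mature miRNA written into chosen transcripts;
    the first ``n_self_targeting`` hosts also carry a site for their own
    miRNA.  Updates ``truth`` in place.
    """
    if config.n_mirna_precursors_embedded == 0:
        return {}, {}
    rng = np.random.default_rng([config.seed, 2])
    paired = {tid for pair in truth.pairs for tid in pair[:2]}
    pre_len = 2 * config.precursor_stem_len + config.precursor_loop_len
    hosts_pool = [
        t
        for t in transcripts
        if truth.biotype[t.transcript_id] == "lncRNA"
        and t.transcript_id not in paired
        and t.exon_count == 1
        and t.length >= pre_len + config.mature_len + 80
    ]
    if len(hosts_pool) < config.n_mirna_precursors_embedded:
        raise ConfigurationError("not enough lncRNAs to host the requested precursors")
    hosts = [
        hosts_pool[i]
        for i in sorted(
            rng.choice(len(hosts_pool), config.n_mirna_precursors_embedded, replace=False)
        )
    ]

    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    for i, host in enumerate(hosts):
        mirna_id = f"miR-sim{i + 1}"
        arm5 = _random_seq(rng, config.precursor_stem_len)
        mature = arm5[: config.mature_len]
        arm3 = list(revcomp(arm5))
        for p in (2, 5, 8):  # mature positions inside the doubled-weight core
            j = config.precursor_stem_len - 1 - p
            forbidden = {
                arm3[j],
                _WC_PARTNER[mature[p]],
                _WOBBLE_PARTNER.get(mature[p], ""),
            }
            choices = [b for b in "ACGT" if b not in forbidden]
            arm3[j] = choices[int(rng.integers(len(choices)))]
        loop = _random_seq(rng, config.precursor_loop_len)
        precursor = arm5 + loop + "".join(arm3)
        if len(precursor) + 20 > host.length:
            raise ConfigurationError(
                f"precursor longer than host lncRNA {host.transcript_id}"
            )
        _write_payload(genome, host, 20, precursor)
        matures[mirna_id] = mature
        precursors[mirna_id] = precursor
        truth.precursors.append((mirna_id, host.transcript_id))

    # planted target sites on non-host transcripts (alternating mRNA / lncRNA)
    host_ids = {h.transcript_id for h in hosts}
    mrna_candidates = [
        t
        for t in transcripts
        if truth.biotype[t.transcript_id] == "mRNA"
        and t.transcript_id not in paired
        and any(e - s >= config.mature_len + 10 for s, e in t.exons)
    ]
    lnc_candidates = [
        t
        for t in transcripts
        if truth.biotype[t.transcript_id] == "lncRNA"
        and t.transcript_id not in paired
        and t.transcript_id not in host_ids
        and t.exon_count == 1
        and t.length >= 240
    ]
    mirna_ids = sorted(matures)

    def make_site(mature: str) -> str:
        site = list(revcomp(mature))
        for _ in range(config.target_site_mismatches):
            j = int(rng.integers(len(site)))
            site[j] = "ACGT"[int(rng.integers(4))]
        return "".join(site)

    mi = li = 0
    for k in range(config.n_target_sites_planted):
        mirna_id = mirna_ids[k % len(mirna_ids)]
        use_mrna = k % 2 == 0
        if use_mrna and mi < len(mrna_candidates):
            target = mrna_candidates[mi]
            mi += 1
            _write_payload_exonic(genome, target, make_site(matures[mirna_id]))
            kind = "mRNA"
        elif li < len(lnc_candidates):
            target = lnc_candidates[li]
            li += 1
            _write_payload(genome, target, 200, make_site(matures[mirna_id]))
            kind = "lncRNA"
        else:
            raise ConfigurationError("not enough transcripts for planted target sites")
        truth.target_edges.append((mirna_id, target.transcript_id, kind))

    for i, host in enumerate(hosts[: config.n_self_targeting]):
        mirna_id = f"miR-sim{i + 1}"
        offset = 20 + pre_len + 20
        _write_payload(genome, host, offset, revcomp(matures[mirna_id]))
        truth.target_edges.append((mirna_id, host.transcript_id, "lncRNA"))

    return matures, precursors


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

# category -> (parent A, parent B, progeny) offsets in units of eld_effect_log2
_CATEGORY_OFFSETS = {
    "I": (-1, 1, 0),
    "XII": (1, -1, 0),
    "II": (0, 1, 0),
    "XI": (0, -1, 0),
    "IV": (-1, 0, 0),
    "IX": (1, 0, 0),
    "III": (-1, 0, 1),
    "VII": (0, 0, 1),
    "X": (0, -1, 1),
    "V": (0, 1, -1),
    "VI": (0, 0, -1),
    "VIII": (1, 0, -1),
}


def make_design(config: SimulationConfig) -> pd.DataFrame:
    lines = [config.parent_a, config.parent_b, *config.progenies]
    rows = [
        {"sample_id": f"{line}_r{rep}", "line": line, "replicate": rep}
        for line in lines
        for rep in range(1, config.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Negative-binomial fragment counts realising the planted effects.

    Per-line log2 means implement the ELD categories; planted regulatory
    pairs share a per-line standard-normal latent factor scaled by
    ``latent_log2_sd`` (replicates of a line see the same factor, which is
    what couples the pair across the 15 samples without degrading replicate
    correlation); all other transcripts are independent with one mean
    across lines.  Planted (pair and ELD) transcripts draw their baseline
    from ``planted_base_log2_range`` so the stated recovery conditions
    (mean counts >= 100) hold; background transcripts draw from a wide
    lognormal emulating the dynamic range of real libraries.  Library sizes
    are the realised column totals (optionally rescaled into
    ``library_size_range``).
    """
    lines = list(dict.fromkeys(design["line"]))
    for line in (config.parent_a, config.parent_b, *config.progenies):
        if line not in lines:
            raise ValidationError(f"design lacks line {line!r} referenced by the truth")
    rng = np.random.default_rng([config.seed, 3])
    tids = [t.transcript_id for t in transcripts]
    n_t, n_s = len(tids), len(design)
    sample_lines = design["line"].tolist()

    base = rng.normal(config.base_mean_log2, config.base_mean_sd_log2, n_t)
    tid_index = {tid: i for i, tid in enumerate(tids)}
    planted = {tid for pair in truth.pairs for tid in pair[:2]}
    planted |= {tid for (_, tid) in truth.eld}
    lo, hi = config.planted_base_log2_range
    for i, tid in enumerate(tids):
        if tid in planted:
            base[i] = rng.uniform(lo, hi)
    log2_mu = np.tile(base[:, None], (1, n_s))
    e = config.eld_effect_log2
    for (progeny, tid), cat in truth.eld.items():
        da, db, dp = _CATEGORY_OFFSETS[cat]
        i = tid_index[tid]
        for s, line in enumerate(sample_lines):
            if line == config.parent_a:
                log2_mu[i, s] = base[i] + da * e
            elif line == config.parent_b:
                log2_mu[i, s] = base[i] + db * e
            elif line == progeny:
                log2_mu[i, s] = base[i] + dp * e

    line_of_sample = np.array([lines.index(l) for l in sample_lines])
    clip = config.latent_clip
    for lnc_id, mrna_id, *_ in truth.pairs:
        z = np.clip(rng.normal(0.0, 1.0, len(lines)), -clip, clip)[line_of_sample]
        for tid in (lnc_id, mrna_id):
            log2_mu[tid_index[tid]] += config.latent_log2_sd * z

    mu = np.power(2.0, log2_mu)
    if config.library_size_range is not None:
        lo, hi = config.library_size_range
        targets = rng.integers(lo, hi + 1, size=n_s)
        mu *= targets / mu.sum(axis=0)

    phi = config.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)

    values = pd.DataFrame(counts, index=tids, columns=design["sample_id"].tolist())
    library_sizes = values.sum(axis=0).astype(float)
    if (library_sizes <= 0).any():
        raise ValidationError("a simulated library came out empty")
    lengths = pd.Series({t.transcript_id: t.length for t in transcripts}, dtype=float)
    return ExpressionMatrix(
        values=values,
        design=design,
        kind="counts",
        library_sizes=library_sizes,
        lengths=lengths,
    )


def simulate_terms(truth: GroundTruth, transcripts: list[TranscriptModel],
                   config: SimulationConfig, n_terms: int = 8) -> pd.DataFrame:
    """Random functional-term assignments over the mRNA genes."""
    rng = np.random.default_rng([config.seed, 4])
    genes = sorted(
        {t.gene_id for t in transcripts if truth.biotype[t.transcript_id] == "mRNA"}
    )
    categories = ("cellular component", "molecular function", "biological process")
    rows = []
    for i in range(n_terms):
        if not genes:
            break
        size = int(rng.integers(5, min(12, len(genes)) + 1))
        members = [genes[j] for j in sorted(rng.choice(len(genes), size, replace=False))]
        for g in members:
            rows.append(
                {
                    "term_id": f"TERM:{i + 1:04d}",
                    "term_name": f"simulated term {i + 1}",
                    "category": categories[i % 3],
                    "gene_id": g,
                }
            )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene_id"])


# ---------------------------------------------------------------------------
# bundling and writing
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, np.ndarray]
    transcripts: list[TranscriptModel]
    truth: GroundTruth
    counts: ExpressionMatrix
    matures: dict[str, str]
    precursors: dict[str, str]
    terms: pd.DataFrame

    @property
    def sequences(self) -> dict[str, str]:
        return transcript_sequences(self.genome, self.transcripts)

    def verdict_table(self) -> pd.DataFrame:
        """Faithful coding-potential verdicts derived from the true biotypes."""
        rows = []
        for t in self.transcripts:
            coding = self.truth.biotype[t.transcript_id] == "mRNA"
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "cpc": 1.5 if coding else -1.2,
                    "cnci": 0.8 if coding else -0.6,
                    "txcds": 650.0 if coding else 320.0,
                    "pfam": int(coding),
                }
            )
        return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: annotation, miRNA features, counts, terms."""
    genome, transcripts, truth = simulate_annotation(config)
    matures, precursors = embed_mirna_features(genome, transcripts, truth, config)
    counts = simulate_counts(transcripts, truth, make_design(config), config)
    terms = simulate_terms(truth, transcripts, config)
    return SimulatedDataset(
        config, genome, transcripts, truth, counts, matures, precursors, terms
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> list[Path]:
    """Write the complete file set; byte-identical across runs at one seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    emit("genome.fa", lambda p: write_fasta(genome_records(ds.genome), p))
    seqs = ds.sequences
    emit(
        "transcripts.fa",
        lambda p: write_fasta(
            [SequenceRecord(tid, seq) for tid, seq in seqs.items()], p
        ),
    )
    emit("annotation.gtf", lambda p: write_gtf(ds.transcripts, p))
    emit(
        "counts.tsv",
        lambda p: ds.counts.values.rename_axis("transcript_id").to_csv(p, sep="\t"),
    )
    emit("design.tsv", lambda p: ds.counts.design.to_csv(p, sep="\t", index=False))
    emit(
        "mirna_mature.fa",
        lambda p: write_fasta(
            [SequenceRecord(k, v) for k, v in ds.matures.items()], p
        )
        if ds.matures
        else p.write_text(""),
    )
    emit(
        "mirna_precursor.fa",
        lambda p: write_fasta(
            [SequenceRecord(k, v) for k, v in ds.precursors.items()], p
        )
        if ds.precursors
        else p.write_text(""),
    )
    emit("verdicts.tsv", lambda p: ds.verdict_table().to_csv(p, sep="\t", index=False))
    emit("terms.tsv", lambda p: ds.terms.to_csv(p, sep="\t", index=False))

    truth = ds.truth
    emit(
        "truth/biotypes.tsv",
        lambda p: pd.DataFrame(
            sorted(truth.biotype.items()), columns=["transcript_id", "biotype"]
        ).to_csv(p, sep="\t", index=False),
    )
    emit(
        "truth/pairs.tsv",
        lambda p: pd.DataFrame(
            truth.pairs,
            columns=["lncrna_id", "mrna_id", "reg_class", "strand_relation", "geometry"],
        ).to_csv(p, sep="\t", index=False),
    )
    emit(
        "truth/eld.tsv",
        lambda p: pd.DataFrame(
            [(pr, tid, cat) for (pr, tid), cat in sorted(truth.eld.items())],
            columns=["progeny", "transcript_id", "category"],
        ).to_csv(p, sep="\t", index=False),
    )
    emit(
        "truth/precursors.tsv",
        lambda p: pd.DataFrame(
            truth.precursors, columns=["mirna_id", "lncrna_id"]
        ).to_csv(p, sep="\t", index=False),
    )
    emit(
        "truth/target_edges.tsv",
        lambda p: pd.DataFrame(
            truth.target_edges, columns=["mirna_id", "target_id", "target_kind"]
        ).to_csv(p, sep="\t", index=False),
    )
    return written
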