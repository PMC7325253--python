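"""FPKM computation, replicate-correlation QC and per-line expressed sets.

FPKM follows the fragment-count normalisation FPKM = 10^6 * C / (N * L / 10^3)
with C the fragment count of a transcript in one library, N the library's
total matched fragments and L the transcript length in nt.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ValidationError, validate_design


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expression values with the sampling design.

    ``kind`` is ``"counts"`` (nonnegative integer fragment counts) or
    ``"fpkm"``.  ``library_sizes`` (per sample) and ``lengths`` (per
    transcript, nt) are required to convert counts to FPKM.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    kind: str = "counts"
    library_sizes: pd.Series | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "fpkm"):
            raise ValidationError(f"ExpressionMatrix kind must be counts|fpkm, got {self.kind!r}")
        validate_design(self.design)
        missing = set(self.design["sample_id"]) - set(self.values.columns)
        if missing:
            raise ValidationError(f"samples in design but not in matrix: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be nonnegative")
        if self.library_sizes is not None and (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValidationError("every transcript needs a positive length")

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    def samples_of_line(self, line: str) -> list[str]:
        sel = self.design[self.design["line"] == line]
        if sel.empty:
            raise ValidationError(f"unknown line {line!r}")
        return list(sel["sample_id"])

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.design["line"]))

    def to_fpkm(self) -> "ExpressionMatrix":
        if self.kind == "fpkm":
            return self
        if self.library_sizes is None or self.lengths is None:
            raise ValidationError("counts -> FPKM needs library sizes and lengths")
        fpkm = fpkm_matrix(self.values, self.library_sizes, self.lengths)
        return ExpressionMatrix(
            values=fpkm,
            design=self.design,
            kind="fpkm",
            library_sizes=self.library_sizes,
            lengths=self.lengths,
        )


def compute_fpkm(c: float, n: float, length: float) -> float:
    """FPKM = 10^6 * C / (N * L / 10^3) for a single (count, library, length)."""
    if n <= 0:
        raise ValidationError("library size N must be positive")
    if length <= 0:
        raise ValidationError("transcript length L must be positive")
    if c < 0:
        raise ValidationError("fragment count C must be nonnegative")
    return 1e6 * c / (n * length / 1e3)


def fpkm_matrix(
    counts: pd.DataFrame, library_sizes: pd.Series, lengths: pd.Series
) -> pd.DataFrame:
    """Elementwise FPKM for a counts matrix (transcripts x samples)."""
    n = library_sizes.reindex(counts.columns)
    if n.isna().any():
        raise ValidationError(
            f"missing library sizes for samples: {list(n[n.isna()].index)}"
        )
    if (n <= 0).any():
        raise ValidationError("library size N must be positive")
    ell = lengths.reindex(counts.index)
    if ell.isna().any():
        raise ValidationError(
            f"missing lengths for transcripts: {list(ell[ell.isna()].index)[:10]}"
        )
    if (ell <= 0).any():
        raise ValidationError("transcript length L must be positive")
    return 1e6 * counts.div(n, axis=1).div(ell / 1e3, axis=0)


def replicate_correlation(
    fpkm: pd.DataFrame, design: pd.DataFrame, log_transform: bool = True
) -> tuple[pd.DataFrame, float]:
    """Pairwise replicate correlations within each line.

    Pearson r is computed on log2(FPKM+1) (raw scale behind
    ``log_transform=False``); both r and r^2 are reported per replicate pair,
    plus the grand mean r^2 over defined pairs.  A pair with a constant
    vector is flagged undefined (NaN) and excluded from the mean.
    """
    x = np.log2(fpkm + 1.0) if log_transform else fpkm
    rows = []
    for line, sub in design.groupby("line", sort=False):
        sample_ids = list(sub["sample_id"])
        for a, b in itertools.combinations(sample_ids, 2):
            va, vb = x[a].values, x[b].values
            if np.std(va) == 0 or np.std(vb) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            rows.append({"line": line, "sample_1": a, "sample_2": b, "r": r, "r2": r * r})
    table = pd.DataFrame(rows)
    grand_mean = float(table["r2"].mean(skipna=True)) if len(table) else float("nan")
    return table, grand_mean


def expressed_sets(
    fpkm: pd.DataFrame, design: pd.DataFrame, min_mean_fpkm: float = 0.5
) -> dict[str, set[str]]:
    """Per-line expressed transcript sets.

    "Expressed in a line" means mean FPKM across the line's replicates at or
    above ``min_mean_fpkm`` (default reuses the 0.5 identification cutoff).
    """
    sets: dict[str, set[str]] = {}
    for line, sub in design.groupby("line", sort=False):
        cols = list(sub["sample_id"])
        mean = fpkm[cols].mean(axis=1)
        sets[line] = set(mean.index[mean >= min_mean_fpkm])
    return sets


@dataclass
class PresenceCensus:
    """Venn-region census over per-line expressed sets.

    ``regions`` maps each nonempty line subset (frozenset) to the number of
    transcripts expressed in exactly those lines; regions partition the union.
    """

    sets: dict[str, set[str]]
    regions: dict[frozenset, int]
    union_size: int

    @property
    def expressed_in_all(self) -> int:
        return self.regions.get(frozenset(self.sets), 0)

    def only_in(self, line: str) -> int:
        return self.regions.get(frozenset([line]), 0)


def presence_sets(
    fpkm: pd.DataFrame, design: pd.DataFrame, min_mean_fpkm: float = 0.5
) -> PresenceCensus:
    """Per-line expressed sets plus the full 2^k - 1 Venn-region census."""
    sets = expressed_sets(fpkm, design, min_mean_fpkm)
    lines = list(sets)
    regions: dict[frozenset, int] = {}
    union = set().union(*sets.values()) if sets else set()
    for tid in union:
        member = frozenset(line for line in lines if tid in sets[line])
        regions[member] = regions.get(member, 0) + 1
    return PresenceCensus(sets=sets, regions=regions, union_size=len(union))
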