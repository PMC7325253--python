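"""Parental expression-level-dominance (ELD) classification.

For each transcript and each progeny line the three DE statuses — progeny
vs parent A, progeny vs parent B, and A vs B, all at the pipeline's own
thresholds (|log2FC| >= 1, FDR <= 0.001) — are mapped onto twelve expression
patterns:

* additivity (I, XII): the progeny differs from both parents and sits
  strictly between them (I: A < B, XII: A > B);
* ELD-A (II, XI): progeny statistically indistinguishable from parent A but
  different from B (II: A < B, XI: A > B);
* ELD-B (IV, IX): the mirror image (IV: A < B, IX: A > B);
* transgressive-up (III, VII, X): progeny above both parents
  (A < B / A = B / A > B respectively);
* transgressive-down (V, VI, VIII): progeny below both parents
  (A < B / A = B / A > B).

All-ns triples are "no-change"; any internally inconsistent triple (for
example progeny above both parents is impossible when it also equals one)
is "ambiguous" and never raises.  "Close to one parent" is operationalised
as statistical non-difference at the stated thresholds; betweenness for
additivity follows from the two progeny-parent status signs being opposite.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import ValidationError

STATUSES = ("up", "down", "ns")

CATEGORY_GROUPS = {
    "I": "additivity",
    "XII": "additivity",
    "II": "ELD-A",
    "XI": "ELD-A",
    "IV": "ELD-B",
    "IX": "ELD-B",
    "III": "transgressive-up",
    "VII": "transgressive-up",
    "X": "transgressive-up",
    "V": "transgressive-down",
    "VI": "transgressive-down",
    "VIII": "transgressive-down",
}

GROUPS = (
    "additivity",
    "ELD-A",
    "ELD-B",
    "transgressive-up",
    "transgressive-down",
    "no-change",
    "ambiguous",
)

# (progeny vs A, progeny vs B, A vs B) -> category; every triple not listed
# is no-change (all ns) or ambiguous
_TRIPLE_TO_CATEGORY = {
    ("up", "down", "down"): "I",
    ("down", "up", "up"): "XII",
    ("ns", "down", "down"): "II",
    ("ns", "up", "up"): "XI",
    ("up", "ns", "down"): "IV",
    ("down", "ns", "up"): "IX",
    ("up", "up", "down"): "III",
    ("up", "up", "ns"): "VII",
    ("up", "up", "up"): "X",
    ("down", "down", "down"): "V",
    ("down", "down", "ns"): "VI",
    ("down", "down", "up"): "VIII",
}


def classify_eld(s_pa: str, s_pb: str, s_ab: str) -> tuple[str, str]:
    """Map one status triple to (category, group).

    ``s_pa``/``s_pb`` are the progeny-vs-parent statuses, ``s_ab`` the
    A-vs-B status, each in {up, down, ns}.  Returns ("none", "no-change"),
    ("none", "ambiguous") or one of the twelve roman-numeral categories with
    its group.
    """
    triple = (s_pa, s_pb, s_ab)
    for s in triple:
        if s not in STATUSES:
            raise ValidationError(f"unknown status {s!r}")
    if triple == ("ns", "ns", "ns"):
        return "none", "no-change"
    category = _TRIPLE_TO_CATEGORY.get(triple)
    if category is None:
        return "none", "ambiguous"
    return category, CATEGORY_GROUPS[category]


def eld_calls(
    de: pd.DataFrame,
    progenies: list[str],
    parent_a: str,
    parent_b: str,
) -> pd.DataFrame:
    """ELD calls for every transcript in every progeny from a DE table.

    ``de`` must contain the comparisons (progeny, parent_a), (progeny,
    parent_b) for each progeny and (parent_a, parent_b), as produced by
    :func:`bilnc.diffexp.call_de`.
    """
    def status_map(line1: str, line2: str) -> dict[str, str]:
        sub = de[(de["line1"] == line1) & (de["line2"] == line2)]
        if sub.empty:
            raise ValidationError(f"missing comparison {line1}:{line2} in DE results")
        return dict(zip(sub["transcript_id"], sub["status"]))

    s_ab = status_map(parent_a, parent_b)
    rows = []
    for progeny in progenies:
        s_pa = status_map(progeny, parent_a)
        s_pb = status_map(progeny, parent_b)
        for tid in s_ab:
            category, group = classify_eld(
                s_pa.get(tid, "ns"), s_pb.get(tid, "ns"), s_ab[tid]
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "progeny": progeny,
                    "category": category,
                    "group": group,
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "progeny", "category", "group"])


def eld_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-progeny fractions of each group (fractions sum to 1 per progeny)."""
    rows = []
    for progeny, sub in calls.groupby("progeny", sort=False):
        n = len(sub)
        row = {"progeny": progeny, "n_transcripts": n}
        for group in GROUPS:
            row[group] = float((sub["group"] == group).sum()) / n if n else 0.0
        row["eld_fraction"] = row["ELD-A"] + row["ELD-B"]
        rows.append(row)
    return pd.DataFrame(rows)
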