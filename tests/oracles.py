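"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a different route than the package
(brute force, exhaustive enumeration, or hand-executed procedure) so that
agreement is a genuine cross-check rather than a tautology.
"""

from math import comb

from bilnc.io_formats import TranscriptModel
from bilnc.targets import _PAIRS, _STACK  # shared parameter tables, not logic

STOPS = {"TAA", "TAG", "TGA"}


def sw_score_oracle(q: str, s: str, match=1.0, mismatch=-2.0, gap=-2.0) -> float:
    """Full dynamic-programming matrix, best local score."""
    n, m = len(q), len(s)
    best = 0.0
    prev = [0.0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if q[i - 1] == s[j - 1] else mismatch)
            cur[j] = max(0.0, diag, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def classify_oracle(lnc: TranscriptModel, mrna: TranscriptModel, up=10_000, down=20_000):
    """Exhaustive case analysis of the positional taxonomy.

    Returns (reg_class, (strand_relation, geometry) or None).
    """
    if lnc.chrom != mrna.chrom:
        return "distal", None
    ls, le = lnc.span
    ms, me = mrna.span
    if max(ls, ms) < min(le, me):
        rel = "sense" if lnc.strand == mrna.strand else "antisense"
        if any(i0 <= ls and le <= i1 for i0, i1 in mrna.introns):
            geom = "lnc_in_intron"
        elif ms <= ls and le <= me:
            geom = "lnc_in_mrna"
        elif ls <= ms and me <= le:
            geom = "mrna_in_lnc"
        elif ls < ms:
            geom = "partial5" if mrna.strand == "+" else "partial3"
        else:
            geom = "partial3" if mrna.strand == "+" else "partial5"
        return "cis_mRNA_overlap", (rel, geom)
    if le <= ms:
        gap, side = ms - le, "left"
    else:
        gap, side = ls - me, "right"
    upstream = (side == "left") == (mrna.strand == "+")
    if upstream:
        return ("cis_mRNA_up10k", None) if gap <= up else ("distal", None)
    return ("cis_mRNA_dw20k", None) if gap <= down else ("distal", None)


def bh_oracle(pvals):
    """Hand-executed Benjamini-Hochberg step-up with monotonicity."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = running
    return q


def binom_p_oracle(k1: int, k2: int, n1: float, n2: float) -> float:
    """Two-sided minimum-likelihood p by full outcome enumeration."""
    k = k1 + k2
    p0 = n1 / (n1 + n2)
    probs = [comb(k, j) * p0**j * (1 - p0) ** (k - j) for j in range(k + 1)]
    obs = probs[k1]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)))


def hypergeom_oracle(overlap: int, background: int, term: int, target: int) -> float:
    """Upper-tail hypergeometric P by direct combinatorial evaluation."""
    total = comb(background, target)
    return sum(
        comb(term, j) * comb(background - term, target - j)
        for j in range(overlap, min(term, target) + 1)
    ) / total


def orf_oracle(seq: str) -> int:
    """All start/stop pairs in all forward frames, longest complete ORF."""
    best = 0
    for frame in range(3):
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] == "ATG":
                for j in range(i + 3, len(seq) - 2, 3):
                    if seq[j : j + 3] in STOPS:
                        best = max(best, j + 3 - i)
                        break
    return best


def duplex_oracle(x: str, y: str) -> float:
    """Exhaustive enumeration of every gapless antiparallel window."""
    best = 0.0
    for i in range(len(x)):
        for j in range(len(y)):
            prev = _PAIRS.get((x[i], y[j]))
            if prev is None:
                continue
            energy = 0.0
            k = 1
            while i + k < len(x) and j - k >= 0:
                cur = _PAIRS.get((x[i + k], y[j - k]))
                if cur is None:
                    break
                energy += _STACK[prev, cur]
                best = min(best, energy)
                prev = cur
                k += 1
    return best


def venn_oracle(sets: dict):
    """Per-element brute-force region census."""
    regions = {}
    for element in set().union(*sets.values()):
        member = frozenset(name for name, s in sets.items() if element in s)
        regions[member] = regions.get(member, 0) + 1
    return regions
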