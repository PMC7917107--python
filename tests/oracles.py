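"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the rule definitions directly, in a different
style from the library code (dict-driven lookups, exhaustive enumeration),
so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np

WC = {"AT": 1, "TA": 1, "GC": 1, "CG": 1}
GU = {"GT": 1, "TG": 1}


def oracle_duplex_score(mirna: str, window: str) -> float:
    """Plant-miRNA penalty score by direct rule lookup.

    miRNA 5'->3', window 5'->3'; miRNA base i aligns with window base
    L-i+1; penalties 0 / 0.5 / 1 (match / wobble / mismatch), doubled at
    miRNA positions 2-13.
    """
    m = mirna.upper().replace("U", "T")
    w = window.upper().replace("U", "T")
    assert len(m) == len(w)
    total = 0.0
    for i, base in enumerate(m, start=1):
        partner = w[len(w) - i]
        duo = base + partner
        if duo in WC:
            pen = 0.0
        elif duo in GU:
            pen = 0.5
        else:
            pen = 1.0
        total += pen * (2 if 2 <= i <= 13 else 1)
    return total


def oracle_find_sites(mirna: str, transcript: str, max_score: float) -> list[tuple[int, float]]:
    """(start, score) for every window scoring <= max_score, by rescoring
    each window independently."""
    L = len(mirna)
    out = []
    for start in range(1, len(transcript) - L + 2):
        s = oracle_duplex_score(mirna, transcript[start - 1 : start - 1 + L])
        if s <= max_score:
            out.append((start, s))
    return out


def oracle_category(counts: list[int], position: int) -> int | None:
    """Degradome category by literal rule enumeration (position 1-based)."""
    r = counts[position - 1]
    if r == 0:
        return None
    if r == 1:
        return 4
    m = max(counts)
    covered = sorted(c for c in counts if c >= 1)
    mid = len(covered) // 2
    if len(covered) % 2:
        med = covered[mid]
    else:
        med = (covered[mid - 1] + covered[mid]) / 2
    if r == m:
        return 0 if counts.count(m) == 1 else 1
    if r > med:
        return 2
    return 3


def oracle_classify(
    sig_f1p1: bool,
    sig_f1p2: bool,
    sig_p1p2: bool,
    mean_p1: float,
    mean_f1: float,
    mean_p2: float,
) -> tuple[str, bool]:
    """(label, ambiguous) by walking the eight-pattern rule list in order.

    Directions are taken from the means themselves (the library uses the
    test's log2fc; for the oracle's synthetic calls the two agree by
    construction as long as means differ).
    """
    if sig_p1p2 and mean_p1 == mean_p2:
        return "conserved", True
    if sig_p1p2 and not sig_f1p1 and sig_f1p2:
        return ("ELD-P1-high" if mean_p1 > mean_p2 else "ELD-P1-low"), False
    if sig_p1p2 and not sig_f1p2 and sig_f1p1:
        return ("ELD-P2-high" if mean_p2 > mean_p1 else "ELD-P2-low"), False
    if sig_f1p1 and sig_f1p2 and mean_f1 > mean_p1 and mean_f1 > mean_p2:
        return "transgressive-up", False
    if sig_f1p1 and sig_f1p2 and mean_f1 < mean_p1 and mean_f1 < mean_p2:
        return "transgressive-down", False
    if (
        sig_p1p2
        and sig_f1p1
        and sig_f1p2
        and min(mean_p1, mean_p2) < mean_f1 < max(mean_p1, mean_p2)
    ):
        return "additive", False
    if not (sig_f1p1 or sig_f1p2 or sig_p1p2):
        return "conserved", False
    return "conserved", True


def oracle_nb_wald_p(counts_a, counts_b, alpha: float) -> float:
    """Two-sided normal Wald p for one feature, written out longhand."""
    from math import erf, log, log2, sqrt

    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    ma, mb = a.mean(), b.mean()
    lfc = log2((mb + 0.5) / (ma + 0.5))
    ln2sq = log(2.0) ** 2

    def var(m, n):
        m = max(m, 0.5)
        return (m + alpha * m * m) / (n * m * m * ln2sq)

    se = sqrt(var(ma, len(a)) + var(mb, len(b)))
    z = abs(lfc) / se if se > 0 else 0.0
    return 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))


def oracle_bh(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj
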