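"""miRNA target-site discovery and degradome cleavage-site categorization.

Target sites are found by sliding an ungapped complementarity window over
the transcript and scoring each window with the standard plant-miRNA
penalty scheme: 0 per Watson-Crick pair, 0.5 per G:U wobble, 1 per
mismatch, with penalties doubled across miRNA positions 2-13 (the seed
and cleavage-critical region).  Degradome 5'-end tag profiles are then
used to rank each predicted cleavage position against the rest of the
transcript (categories 0-4, category 0 being a unique transcript-wide
maximum with more than one read).

Conventions: miRNA position 1 is its 5' end; miRNA position i pairs with
window position L - i + 1; the reported cleavage coordinate is the
transcript position paired with miRNA position 10 (the 5' side of the
10-11 junction).  All transcript coordinates are 1-based inclusive.
U and T are interchangeable throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}

# duplex rules on the DNA alphabet (U folded onto T)
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA G : target U  /  miRNA U : target G

DEFAULT_MAX_SCORE = 7.0


def reverse_complement(seq: str) -> str:
    """Reverse complement on the DNA alphabet (U treated as T)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol {exc.args[0]!r}") from None


def _canon(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGUTN symbols in sequence: {sorted(bad)}")
    return seq


@dataclass
class TargetAlignment:
    """One ungapped miRNA/transcript duplex.

    ``target_start``/``target_end`` are 1-based inclusive transcript
    coordinates of the paired window; ``pairing`` is a per-miRNA-position
    string over {'|', 'o', 'x'} (match, G:U wobble, mismatch), position 1
    first; ``predicted_cleavage`` is the transcript position opposite
    miRNA position 10.
    """

    mirna_id: str
    transcript_id: str
    target_start: int
    target_end: int
    pairing: str
    score: float
    predicted_cleavage: int


def score_alignment(
    mirna: str,
    target_window: str,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
    target_start: int = 1,
) -> TargetAlignment:
    """Score one miRNA against one equal-length transcript window.

    Both sequences are given 5'->3'.  miRNA position i (1-based from the
    miRNA 5' end) pairs with window position L - i + 1.  Penalties:
    Watson-Crick 0, G:U 0.5, otherwise 1; doubled for miRNA positions
    2-13.  N never pairs.
    """
    mir = _canon(mirna)
    win = _canon(target_window)
    L = len(mir)
    if len(win) != L:
        raise ValueError(f"length mismatch: miRNA {L} nt vs window {len(win)} nt")
    score = 0.0
    pairing = []
    for i in range(1, L + 1):
        m = mir[i - 1]
        t = win[L - i]
        if (m, t) in _PAIRS:
            penalty, sym = 0.0, "|"
        elif (m, t) in _WOBBLE:
            penalty, sym = 0.5, "o"
        else:
            penalty, sym = 1.0, "x"
        if 2 <= i <= 13:
            penalty *= 2
        score += penalty
        pairing.append(sym)
    return TargetAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        target_start=target_start,
        target_end=target_start + L - 1,
        pairing="".join(pairing),
        score=score,
        predicted_cleavage=target_start + (L - 10),
    )


def find_target_sites(
    mirna: str,
    transcript: str,
    max_score: float = DEFAULT_MAX_SCORE,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
) -> list[TargetAlignment]:
    """All windows of the transcript scoring <= ``max_score``."""
    mir = _canon(mirna)
    txt = _canon(transcript)
    L = len(mir)
    if len(txt) < L:
        raise ValueError(
            f"transcript {transcript_id!r} shorter ({len(txt)} nt) than miRNA ({L} nt)"
        )
    hits = []
    for start in range(1, len(txt) - L + 2):
        aln = score_alignment(
            mir, txt[start - 1 : start - 1 + L],
            mirna_id=mirna_id, transcript_id=transcript_id, target_start=start,
        )
        if aln.score <= max_score:
            hits.append(aln)
    return hits


@dataclass
class DegradomeProfile:
    """Per-transcript degradome 5'-end tag counts, 1-based positions."""

    transcript_id: str
    counts: np.ndarray  # length == transcript length

    @property
    def total_tags(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


def build_profile(
    tag_positions: dict[str, list[int]] | pd.DataFrame,
    transcript_lengths: dict[str, int],
) -> dict[str, DegradomeProfile]:
    """Bin 5'-end tag positions into per-transcript count vectors.

    ``tag_positions`` is either {transcript: [pos, ...]} (one entry per
    tag) or a (transcript, position, count) DataFrame.  Positions are
    1-based; out-of-range positions raise.
    """
    per_transcript: dict[str, np.ndarray] = {
        t: np.zeros(length, dtype=np.int64) for t, length in transcript_lengths.items()
    }

    def add(transcript: str, position: int, count: int) -> None:
        if transcript not in per_transcript:
            raise ValueError(f"tags for unknown transcript {transcript!r}")
        length = len(per_transcript[transcript])
        if not 1 <= position <= length:
            raise ValueError(
                f"tag position {position} outside transcript {transcript!r} (length {length})"
            )
        per_transcript[transcript][position - 1] += count

    if isinstance(tag_positions, pd.DataFrame):
        for row in tag_positions.itertuples(index=False):
            add(str(row.transcript), int(row.position), int(row.count))
    else:
        for transcript, positions in tag_positions.items():
            for pos in positions:
                add(transcript, int(pos), 1)
    return {t: DegradomeProfile(t, c) for t, c in per_transcript.items()}


@dataclass
class CategorizedSite:
    """A target alignment annotated with its degradome evidence class."""

    alignment: TargetAlignment
    category: int
    site_reads: int
    transcript_max: int
    transcript_median: float


def categorize_site(profile: DegradomeProfile, position: int) -> CategorizedSite | None:
    """Assign the degradome category (0-4) of one cleavage position.

    With r = reads at the position, M = transcript-wide maximum and
    med = median over positions carrying at least one read:

    * 4 - r == 1 (single read);
    * 0 - r > 1 and r == M, the maximum attained at exactly one position;
    * 1 - r > 1 and r == M, the maximum tied across several positions;
    * 2 - 1 < r < M and r > med;
    * 3 - 1 < r <= med.

    Positions with no reads are unsupported: returns None (the caller
    drops the site).
    """
    counts = profile.counts
    if not 1 <= position <= len(counts):
        raise ValueError(
            f"position {position} outside transcript {profile.transcript_id!r}"
        )
    r = int(counts[position - 1])
    if r == 0:
        return None
    covered = counts[counts >= 1]
    M = int(counts.max())
    med = float(np.median(covered))
    if r == 1:
        category = 4
    elif r == M:
        category = 0 if int((counts == M).sum()) == 1 else 1
    elif r > med:
        category = 2
    else:
        category = 3
    return CategorizedSite(
        alignment=None,  # type: ignore[arg-type]  # filled by callers that have one
        category=category,
        site_reads=r,
        transcript_max=M,
        transcript_median=med,
    )


def categorize_alignments(
    alignments: list[TargetAlignment],
    profiles: dict[str, DegradomeProfile],
) -> list[CategorizedSite]:
    """Categorize each alignment's predicted cleavage site; sites without
    degradome support (0 reads, or transcript without a profile) are
    dropped."""
    out = []
    for aln in alignments:
        profile = profiles.get(aln.transcript_id)
        if profile is None:
            continue
        site = categorize_site(profile, aln.predicted_cleavage)
        if site is None:
            continue
        site.alignment = aln
        out.append(site)
    return out


def tplot_table(
    profile: DegradomeProfile, sites: list[TargetAlignment]
) -> pd.DataFrame:
    """Per-position tag counts with predicted-cleavage annotations —
    the tabular form of a T-plot (positions 1-based)."""
    cleavages = {s.predicted_cleavage: s.mirna_id for s in sites}
    positions = np.arange(1, len(profile) + 1)
    return pd.DataFrame(
        {
            "position": positions,
            "count": profile.counts,
            "is_predicted_cleavage": [p in cleavages for p in positions],
            "mirna_id": [cleavages.get(p, "") for p in positions],
        }
    )


def sites_table(sites: list[CategorizedSite]) -> pd.DataFrame:
    """Flatten categorized sites for TSV output (1-based coordinates)."""
    rows = [
        {
            "mirna_id": s.alignment.mirna_id,
            "transcript_id": s.alignment.transcript_id,
            "target_start": s.alignment.target_start,
            "target_end": s.alignment.target_end,
            "score": s.alignment.score,
            "cleavage_position": s.alignment.predicted_cleavage,
            "category": s.category,
            "site_reads": s.site_reads,
            "transcript_max": s.transcript_max,
            "transcript_median": s.transcript_median,
        }
        for s in sites
    ]
    columns = [
        "mirna_id", "transcript_id", "target_start", "target_end", "score",
        "cleavage_position", "category", "site_reads", "transcript_max",
        "transcript_median",
    ]
    return pd.DataFrame(rows, columns=columns)
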