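"""Eight-way P1-hybrid-P2 expression-pattern classification.

Each feature at each stage is placed in exactly one of eight classes from
the significance and direction of three pairwise comparisons (F1 vs P1,
F1 vs P2, P1 vs P2):

* ``ELD-P1-high`` / ``ELD-P1-low`` — expression-level dominance toward
  P1: parents differ, the hybrid matches P1 (statistically
  indistinguishable) and differs from P2; "high"/"low" says whether P1 is
  the higher- or lower-expressing parent (symmetrically for P2);
* ``transgressive-up`` / ``transgressive-down`` — the hybrid is
  significantly above (below) both parents;
* ``additive`` — parents differ, the hybrid differs from both and sits
  strictly between them (near the mid-parent expectation);
* ``conserved`` — no comparison is significant;
* any remaining combination is ``conserved`` with an ambiguity flag, so
  the classification is total and unclassifiable evidence is preserved
  rather than forced.

Nonadditive expression is a separate, orthogonal call: significant
F1 vs MPV at the same thresholds (the MPV-DEM / MPV-DEG definition),
tallied by direction in the stage summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .de import CallThresholds, TriadDE, call_differential

PATTERN_LABELS = (
    "additive",
    "ELD-P1-high",
    "ELD-P1-low",
    "ELD-P2-high",
    "ELD-P2-low",
    "transgressive-up",
    "transgressive-down",
    "conserved",
)

ELD_LABELS = ("ELD-P1-high", "ELD-P1-low", "ELD-P2-high", "ELD-P2-low")


@dataclass
class ComparisonCall:
    """Significance + direction of one pairwise comparison.

    ``log2fc`` is B over A for the tag "B_vs_A" (so F1_vs_P1 > 0 means the
    hybrid is higher than P1).
    """

    significant: bool
    log2fc: float


@dataclass
class PatternCall:
    feature_id: str
    stage: str
    label: str
    ambiguous: bool
    mean_p1: float
    mean_f1: float
    mean_p2: float
    calls: dict[str, ComparisonCall] = field(default_factory=dict)


def classify_triad(
    feature_id: str,
    stage: str,
    means: tuple[float, float, float],
    f1_vs_p1: ComparisonCall,
    f1_vs_p2: ComparisonCall,
    p1_vs_p2: ComparisonCall,
) -> PatternCall:
    """Classify one feature from its three pairwise comparison calls.

    ``means`` is (mean_P1, mean_F1, mean_P2) on the normalized scale.
    Decision order: ELD (either parent), transgressive, additive,
    conserved; combinations that fit none are conserved with the
    ambiguity flag.  A tie in parent means alongside a significant
    parent-parent test is also flagged ambiguous.
    """
    mean_p1, mean_f1, mean_p2 = means
    s_p1, s_p2, s_pp = f1_vs_p1.significant, f1_vs_p2.significant, p1_vs_p2.significant

    label, ambiguous = None, False
    if s_pp and mean_p1 == mean_p2:
        label, ambiguous = "conserved", True
    elif s_pp and not s_p1 and s_p2:
        label = "ELD-P1-high" if mean_p1 > mean_p2 else "ELD-P1-low"
    elif s_pp and not s_p2 and s_p1:
        label = "ELD-P2-high" if mean_p2 > mean_p1 else "ELD-P2-low"
    elif s_p1 and s_p2 and f1_vs_p1.log2fc > 0 and f1_vs_p2.log2fc > 0:
        label = "transgressive-up"
    elif s_p1 and s_p2 and f1_vs_p1.log2fc < 0 and f1_vs_p2.log2fc < 0:
        label = "transgressive-down"
    elif (
        s_pp and s_p1 and s_p2
        and min(mean_p1, mean_p2) < mean_f1 < max(mean_p1, mean_p2)
    ):
        label = "additive"
    elif not (s_p1 or s_p2 or s_pp):
        label = "conserved"
    else:
        label, ambiguous = "conserved", True
    return PatternCall(
        feature_id=feature_id,
        stage=stage,
        label=label,
        ambiguous=ambiguous,
        mean_p1=mean_p1,
        mean_f1=mean_f1,
        mean_p2=mean_p2,
        calls={
            "F1_vs_P1": f1_vs_p1,
            "F1_vs_P2": f1_vs_p2,
            "P1_vs_P2": p1_vs_p2,
        },
    )


def classify_stage(de: TriadDE, thresholds: CallThresholds) -> pd.DataFrame:
    """Classify every feature of one stage's triad DE results.

    Returns a DataFrame with the label, the ambiguity flag, the three
    pairwise p-values/log2fc and the F1-vs-MPV nonadditivity call.
    """
    needed = {"F1_vs_P1", "F1_vs_P2", "P1_vs_P2", "F1_vs_MPV"}
    missing = needed - set(de.results)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    called = {tag: call_differential(res, thresholds) for tag, res in de.results.items()}
    r_p1, r_p2 = called["F1_vs_P1"], called["F1_vs_P2"]
    r_pp, r_mpv = called["P1_vs_P2"], called["F1_vs_MPV"]

    rows = []
    for i in range(len(r_p1)):
        fid = r_p1["feature_id"].iloc[i]
        call = classify_triad(
            feature_id=fid,
            stage=de.stage,
            means=(
                float(r_p1["mean_A"].iloc[i]),   # P1
                float(r_p1["mean_B"].iloc[i]),   # F1
                float(r_p2["mean_A"].iloc[i]),   # P2
            ),
            f1_vs_p1=ComparisonCall(bool(r_p1["called"].iloc[i]), float(r_p1["log2fc"].iloc[i])),
            f1_vs_p2=ComparisonCall(bool(r_p2["called"].iloc[i]), float(r_p2["log2fc"].iloc[i])),
            p1_vs_p2=ComparisonCall(bool(r_pp["called"].iloc[i]), float(r_pp["log2fc"].iloc[i])),
        )
        rows.append(
            {
                "feature_id": fid,
                "stage": de.stage,
                "label": call.label,
                "ambiguous": call.ambiguous,
                "mean_P1": call.mean_p1,
                "mean_F1": call.mean_f1,
                "mean_P2": call.mean_p2,
                "p_F1_vs_P1": float(r_p1["p_raw"].iloc[i]),
                "p_F1_vs_P2": float(r_p2["p_raw"].iloc[i]),
                "p_P1_vs_P2": float(r_pp["p_raw"].iloc[i]),
                "p_F1_vs_MPV": float(r_mpv["p_raw"].iloc[i]),
                "nonadditive": bool(r_mpv["called"].iloc[i]),
                "nonadditive_direction": r_mpv["direction"].iloc[i],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PatternSummary:
    stage: str
    label_counts: dict[str, int]
    n_nonadditive_up: int
    n_nonadditive_down: int
    n_high_eld: int
    n_low_eld: int

    @property
    def n_eld(self) -> int:
        return self.n_high_eld + self.n_low_eld

    @property
    def high_eld_percent(self) -> float:
        return high_eld_percent(self.n_high_eld, self.n_eld)


def high_eld_percent(n_high: int, n_eld_total: int) -> float:
    """Percentage of ELD features matching the higher-expressing parent."""
    if n_eld_total == 0:
        return float("nan")
    return 100.0 * n_high / n_eld_total


def summarize_patterns(calls: pd.DataFrame, stage: str) -> PatternSummary:
    """Tally one stage's pattern calls.

    Nonadditive up/down counts come from the F1-vs-MPV call (direction by
    sign of F1 minus MPV); high/low ELD counts aggregate the four ELD
    labels by whether the matched parent is the higher or lower one.
    """
    sub = calls[calls["stage"] == stage]
    label_counts = {lab: int((sub["label"] == lab).sum()) for lab in PATTERN_LABELS}
    n_up = int(((sub["nonadditive"]) & (sub["nonadditive_direction"] == "up")).sum())
    n_down = int(((sub["nonadditive"]) & (sub["nonadditive_direction"] == "down")).sum())
    n_high = label_counts["ELD-P1-high"] + label_counts["ELD-P2-high"]
    n_low = label_counts["ELD-P1-low"] + label_counts["ELD-P2-low"]
    return PatternSummary(
        stage=stage,
        label_counts=label_counts,
        n_nonadditive_up=n_up,
        n_nonadditive_down=n_down,
        n_high_eld=n_high,
        n_low_eld=n_low,
    )


def stage_overlap(
    calls_s: pd.DataFrame,
    calls_h: pd.DataFrame,
    label_filter: str | None = None,
    nonadditive_only: bool = False,
) -> set[str]:
    """Features appearing in both stages' call sets, optionally restricted
    to one label or to nonadditive (MPV-significant) features."""

    def pick(calls: pd.DataFrame) -> set[str]:
        sub = calls
        if label_filter is not None:
            sub = sub[sub["label"] == label_filter]
        if nonadditive_only:
            sub = sub[sub["nonadditive"]]
        return set(sub["feature_id"])

    return pick(calls_s) & pick(calls_h)
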