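"""Two-group negative-binomial differential expression testing.

The counts are modelled as NB with Var = mu + alpha * mu^2.  Dispersion
is estimated per feature by the method of moments on size-factor-scaled
counts, pooled across the two groups and shrunk halfway toward the
trimmed mean across features (a light stabilization for the tiny
replicate numbers typical of triad designs).  The test is a Wald test on
the log2 ratio of group means with a delta-method standard error; this
keeps the statistic fully closed-form and calibratable by simulation.

Mid-parent values (MPV) — the additive expectation for the hybrid — are
materialized as pseudo-samples: replicate-paired averages of the two
parents' normalized counts, rounded back to integers with size factor 1.
The hybrid-vs-MPV comparison then reuses the same two-group code path,
and a significant call at the usual thresholds defines nonadditive
expression (MPV-DEM / MPV-DEG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import TriadCountMatrix
from .normalization import size_factors as compute_size_factors

LOG2FC_PSEUDOCOUNT = 0.5
ALPHA_FLOOR = 1e-8

COMPARISONS = ("F1_vs_P1", "F1_vs_P2", "F1_vs_MPV", "P1_vs_P2")


@dataclass
class CallThresholds:
    """Differential-calling thresholds: fold-change >= ``min_fold`` and
    p <= ``max_p`` (both inclusive).  ``use_adjusted`` selects BH-adjusted
    p (typical for mRNA) vs raw p (typical for small miRNA panels)."""

    min_fold: float = 1.5
    max_p: float = 0.05
    use_adjusted: bool = False

    def validate(self) -> list[str]:
        problems = []
        if not self.min_fold > 1:
            problems.append(f"min_fold must be > 1, got {self.min_fold}")
        if not 0 < self.max_p < 1:
            problems.append(f"max_p must be in (0, 1), got {self.max_p}")
        return problems


def estimate_dispersion(
    counts_a: np.ndarray, counts_b: np.ndarray, sf_a: np.ndarray, sf_b: np.ndarray
) -> pd.Series | np.ndarray:
    """Per-feature moment estimate of the NB dispersion alpha.

    ``counts_a``/``counts_b``: features x replicates arrays.  The raw
    per-group estimate (s^2 - m) / m^2 on normalized counts is pooled by
    degrees of freedom, floored at zero, then shrunk 50/50 toward a
    common-dispersion center shared by all features.  The center is the
    ratio-of-sums moment estimate sum(s^2 - m) / sum(m^2 - s^2/n) over
    all groups and features — the denominator correction accounts for
    E[m^2] = mu^2 + Var(m) — which is far less noisy and less biased than
    averaging per-feature ratios at two or three replicates.  Features
    with zero mean in both groups get NaN (untestable).
    """
    a = np.asarray(counts_a, dtype=float) / np.asarray(sf_a, dtype=float)
    b = np.asarray(counts_b, dtype=float) / np.asarray(sf_b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates per group")

    def group_raw(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(m > 0, (s2 - m) / m**2, np.nan)

    raw_a, raw_b = group_raw(a), group_raw(b)
    df_a, df_b = a.shape[1] - 1, b.shape[1] - 1
    num = np.where(np.isnan(raw_a), 0.0, raw_a * df_a) + np.where(
        np.isnan(raw_b), 0.0, raw_b * df_b
    )
    den = np.where(np.isnan(raw_a), 0, df_a) + np.where(np.isnan(raw_b), 0, df_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    pooled = np.where(np.isnan(pooled), np.nan, np.maximum(pooled, 0.0))

    means = np.concatenate([a.mean(axis=1), b.mean(axis=1)])
    variances = np.concatenate([a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)])
    n_reps = np.concatenate(
        [np.full(a.shape[0], a.shape[1]), np.full(b.shape[0], b.shape[1])]
    )
    denominator = float((means**2 - variances / n_reps).sum())
    numerator = float((variances - means).sum())
    center = max(numerator / denominator, 0.0) if denominator > 0 else 0.0

    shrunk = 0.5 * pooled + 0.5 * center
    return np.where(np.isnan(shrunk), np.nan, np.maximum(shrunk, ALPHA_FLOOR))


def nb_wald_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    alpha: np.ndarray,
    feature_ids: list[str] | None = None,
    comparison: str = "B_vs_A",
) -> pd.DataFrame:
    """Wald test of group B against group A on size-factor-scaled counts.

    log2fc = log2((mean_B + c) / (mean_A + c)) with pseudocount c = 0.5;
    Var(log2 mean_g) = (m_g + alpha m_g^2) / (n_g m_g^2 ln^2 2) evaluated
    at the pseudocounted mean; z = log2fc / sqrt(Var_A + Var_B); p is
    two-sided normal.  Untestable features (NaN alpha) keep p = NaN.

    Returns a DataFrame with columns feature_id, mean_A, mean_B, log2fc,
    alpha, p_raw, p_adj (BH), comparison.
    """
    a = np.asarray(counts_a, dtype=float) / np.asarray(sf_a, dtype=float)
    b = np.asarray(counts_b, dtype=float) / np.asarray(sf_b, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    c = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((m_b + c) / (m_a + c))
    ln2sq = np.log(2.0) ** 2

    def var_log2(m: np.ndarray, n: int) -> np.ndarray:
        mc = np.maximum(m, c)  # pseudocount only guards the m = 0 singularity
        return (mc + alpha * mc**2) / (n * mc**2 * ln2sq)

    se = np.sqrt(var_log2(m_a, n_a) + var_log2(m_b, n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(alpha), np.nan, np.minimum(p, 1.0))
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(len(m_a))]
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "mean_A": m_a,
            "mean_B": m_b,
            "log2fc": log2fc,
            "alpha": alpha,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "comparison": comparison,
        }
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are excluded
    from the hypothesis count and propagate as NaN."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        vals = p[mask]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def make_mpv_pseudosamples(
    m: TriadCountMatrix, stage: str, factors: pd.Series | None = None
) -> TriadCountMatrix:
    """Append mid-parent pseudo-samples for one stage.

    Pseudo-replicate i is round((P1_i/sf_P1i + P2_i/sf_P2i) / 2) with size
    factor 1 and genotype label "MPV".  Parents' replicates are paired by
    sorted replicate index; unequal counts are truncated to the smaller
    with a warning.
    """
    p1 = m.samples_for("P1", stage)
    p2 = m.samples_for("P2", stage)
    if not p1 or not p2:
        raise ValueError(f"both parents required at stage {stage!r}")
    if len(p1) != len(p2):
        warnings.warn(
            f"unequal parent replicate counts at stage {stage!r} "
            f"({len(p1)} vs {len(p2)}); pairing up to the smaller",
            stacklevel=2,
        )
    r = min(len(p1), len(p2))
    p1, p2 = p1[:r], p2[:r]
    if factors is None:
        factors = compute_size_factors(m.subset_stage(stage))
    counts = m.counts.copy()
    meta = m.sample_meta.copy()
    for i in range(r):
        name = f"MPV_{stage}_r{i + 1}"
        a = m.counts[p1[i]].astype(float) / float(factors[p1[i]])
        b = m.counts[p2[i]].astype(float) / float(factors[p2[i]])
        counts[name] = np.round((a + b) / 2.0).astype(np.int64)
        meta.loc[name] = {
            "genotype": "MPV",
            "stage": stage,
            "replicate": i + 1,
            **{k: meta[k].iloc[0] for k in meta.columns
               if k not in ("genotype", "stage", "replicate")},
        }
    return TriadCountMatrix(counts=counts, sample_meta=meta, feature_lengths=m.feature_lengths)


def call_differential(results: pd.DataFrame, thresholds: CallThresholds) -> pd.DataFrame:
    """Flag features passing both thresholds; adds ``called`` (bool) and
    ``direction`` ('up'/'down'/'' by sign of log2fc)."""
    problems = thresholds.validate()
    if problems:
        raise ValueError("; ".join(problems))
    out = results.copy()
    p = out["p_adj"] if thresholds.use_adjusted else out["p_raw"]
    fold = 2.0 ** out["log2fc"].abs()
    out["called"] = (fold >= thresholds.min_fold) & (p <= thresholds.max_p) & p.notna()
    out["direction"] = np.where(
        ~out["called"], "", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


@dataclass
class TriadDE:
    """All four triad comparisons at one stage, on a shared dispersion."""

    stage: str
    results: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_triad_de(
    m: TriadCountMatrix, stage: str, factors: pd.Series | None = None
) -> TriadDE:
    """Run F1 vs P1, F1 vs P2, P1 vs P2 and F1 vs MPV for one stage.

    Size factors are median-of-ratios over the stage's real samples;
    dispersion per comparison is estimated from its own two groups.
    """
    staged = m.subset_stage(stage)
    if factors is None:
        factors = compute_size_factors(staged)
    aug = make_mpv_pseudosamples(m, stage, factors=factors)
    factors = pd.concat(
        [factors, pd.Series(1.0, index=[s for s in aug.sample_ids if s.startswith("MPV_")])]
    )

    def group(genotype: str) -> tuple[np.ndarray, np.ndarray]:
        names = aug.samples_for(genotype, stage)
        return aug.counts[names].to_numpy(), factors[names].to_numpy()

    groups = {g: group(g) for g in ("P1", "F1", "P2", "MPV")}
    plan = {
        "F1_vs_P1": ("P1", "F1"),
        "F1_vs_P2": ("P2", "F1"),
        "P1_vs_P2": ("P2", "P1"),
        "F1_vs_MPV": ("MPV", "F1"),
    }
    out = TriadDE(stage=stage)
    ids = aug.feature_ids
    for tag, (ga, gb) in plan.items():
        (ca, fa), (cb, fb) = groups[ga], groups[gb]
        alpha = estimate_dispersion(ca, cb, fa, fb)
        out.results[tag] = nb_wald_test(ca, cb, fa, fb, alpha, feature_ids=ids, comparison=tag)
    return out
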