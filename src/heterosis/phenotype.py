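"""Heterosis indices and trait statistics from plant-level phenotypes.

Mid-parent heterosis MPH = 100 * (F1 - MP) / MP with MP the mean of the
two parental means; better-parent heterosis BPH = 100 * (F1 - BP) / BP
with BP the better (here: larger) parental mean.  Since BP >= MP for
positive means and x -> F1/x - 1 is decreasing, BPH <= MPH always holds
on positive data.  Trait means are pooled over all measured plants per
genotype, and significance of the hybrid's advantage over the better
parent is assessed with a two-sample t-test (Student's by default,
Welch optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PhenotypeTable


@dataclass
class HeterosisResult:
    trait: str
    stage: str
    mean_p1: float
    mean_f1: float
    mean_p2: float
    mp: float
    bp: float
    mph: float
    bph: float
    t_p_value_f1_vs_bp: float


def compute_mph(mean_f1: float, mean_p1: float, mean_p2: float) -> float:
    """Mid-parent heterosis in percent: 100 * (F1 - MP) / MP."""
    mp = (mean_p1 + mean_p2) / 2.0
    if mp <= 0:
        raise ValueError(f"mid-parent mean must be positive, got {mp}")
    return 100.0 * (mean_f1 - mp) / mp


def compute_bph(mean_f1: float, mean_p1: float, mean_p2: float) -> float:
    """Better-parent heterosis in percent: 100 * (F1 - BP) / BP with BP
    the larger parental mean."""
    bp = max(mean_p1, mean_p2)
    if bp <= 0:
        raise ValueError(f"better-parent mean must be positive, got {bp}")
    return 100.0 * (mean_f1 - bp) / bp


def _t_test(x: np.ndarray, y: np.ndarray, welch: bool) -> float:
    if np.var(x) == 0 and np.var(y) == 0:
        return float("nan")  # zero-variance fixture; test undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)


def heterosis_report(tbl: PhenotypeTable, welch: bool = False) -> pd.DataFrame:
    """Per-trait (and stage, when present) heterosis summary.

    Columns: trait, stage, mean_P1, mean_F1, mean_P2, MP, BP, MPH, BPH,
    t_p_value_F1_vs_BP.  All three genotypes must be present per trait.
    """
    data = tbl.data.copy()
    if "stage" not in data.columns:
        data["stage"] = ""
    rows = []
    for (trait, stage), sub in data.groupby(["trait", "stage"], sort=True):
        groups = {g: sub.loc[sub["genotype"] == g, "value"].to_numpy() for g in ("P1", "F1", "P2")}
        for g, v in groups.items():
            if v.size == 0:
                raise ValueError(f"genotype {g} missing for trait {trait!r}")
        m1, mf, m2 = (float(groups[g].mean()) for g in ("P1", "F1", "P2"))
        bp_genotype = "P1" if m1 >= m2 else "P2"
        rows.append(
            {
                "trait": trait,
                "stage": stage,
                "mean_P1": m1,
                "mean_F1": mf,
                "mean_P2": m2,
                "MP": (m1 + m2) / 2.0,
                "BP": max(m1, m2),
                "MPH": compute_mph(mf, m1, m2),
                "BPH": compute_bph(mf, m1, m2),
                "t_p_value_F1_vs_BP": _t_test(groups["F1"], groups[bp_genotype], welch),
            }
        )
    return pd.DataFrame(rows)


def trait_correlations(tbl: PhenotypeTable) -> pd.DataFrame:
    """Pearson correlation matrix between traits across plants.

    Observations are paired by genotype and within-genotype rank so the
    correlation reflects co-variation of traits over the same plants.
    Zero-variance traits give NA rows/columns with a warning.
    """
    data = tbl.data
    traits = sorted(data["trait"].unique())
    wide = {}
    for trait in traits:
        sub = data[data["trait"] == trait].sort_values(["genotype", "plant_id"])
        wide[trait] = sub["value"].to_numpy()
    n = min(len(v) for v in wide.values())
    if n < 3:
        raise ValueError("need >= 3 paired observations per trait pair")
    mat = pd.DataFrame({t: v[:n] for t, v in wide.items()})
    out = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, ti in enumerate(traits):
        for j, tj in enumerate(traits):
            if j <= i:
                continue
            x, y = mat[ti], mat[tj]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                warnings.warn(f"zero variance for trait pair ({ti}, {tj}); r = NA", stacklevel=2)
                r = float("nan")
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            out.loc[ti, tj] = out.loc[tj, ti] = r
    return out
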