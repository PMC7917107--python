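"""miRNA-target expression correlation and closed-form assay formulas.

Covers the small quantitative assays that accompany a triad expression
study: Pearson anticorrelation between a miRNA and its degradome-
confirmed target across samples, spectrophotometric chlorophyll
quantification from 80% acetone extracts, relative qPCR quantification
by 2^-ddCt, and mean epidermal cell size from a count per imaged area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix


@dataclass
class PairCorrelation:
    mirna_id: str
    target_id: str
    r: float
    n_samples: int
    negative_flag: bool


def pair_correlations(
    mirna_matrix: NormalizedMatrix,
    gene_matrix: NormalizedMatrix,
    pairs: list[tuple[str, str]],
    differential_mirnas: set[str] | None = None,
    differential_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Pearson r between each (miRNA, target) pair across shared samples.

    Expression is taken as log2(normalized + 1).  ``negative_flag`` marks
    pairs with r < 0 where both members are in the supplied differential
    sets (both default to "all features").  Zero variance in either
    member yields r = NA.
    """
    shared = [s for s in mirna_matrix.values.columns if s in set(gene_matrix.values.columns)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    if not pairs:
        raise ValueError("no miRNA/target pairs supplied")
    mlog = np.log2(mirna_matrix.values[shared] + 1.0)
    glog = np.log2(gene_matrix.values[shared] + 1.0)
    rows = []
    for mirna_id, target_id in pairs:
        if mirna_id not in mlog.index or target_id not in glog.index:
            raise KeyError(f"pair ({mirna_id!r}, {target_id!r}) not present in matrices")
        x = mlog.loc[mirna_id].to_numpy()
        y = glog.loc[target_id].to_numpy()
        if x.std() == 0 or y.std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        diff_ok = (differential_mirnas is None or mirna_id in differential_mirnas) and (
            differential_genes is None or target_id in differential_genes
        )
        rows.append(
            {
                "mirna_id": mirna_id,
                "target_id": target_id,
                "r": r,
                "n_samples": len(shared),
                "negative_flag": bool(r < 0 and diff_ok) if not np.isnan(r) else False,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PigmentMeasurement:
    """Chlorophyll a/b concentrations (ug/mL) from a two-wavelength
    absorbance reading of an 80% acetone extract."""

    a663_6: float
    a646_6: float
    chlorophyll_a: float
    chlorophyll_b: float
    total: float
    flagged_negative: bool


def chlorophyll(a663_6: float, a646_6: float) -> PigmentMeasurement:
    """Chlorophyll a/b from absorbances at 663.6 and 646.6 nm:

    a = 12.25 * A663.6 - 2.55 * A646.6
    b = 20.31 * A646.6 - 4.91 * A663.6

    Negative computed concentrations (possible on noisy readings) are
    flagged, never clamped.
    """
    if a663_6 < 0 or a646_6 < 0:
        raise ValueError("absorbances must be >= 0")
    chl_a = 12.25 * a663_6 - 2.55 * a646_6
    chl_b = 20.31 * a646_6 - 4.91 * a663_6
    return PigmentMeasurement(
        a663_6=a663_6,
        a646_6=a646_6,
        chlorophyll_a=chl_a,
        chlorophyll_b=chl_b,
        total=chl_a + chl_b,
        flagged_negative=chl_a < 0 or chl_b < 0,
    )


def ddct_fold(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt_test -
    dCt_calibrator; fold = 2^-ddCt.
    """
    for ct in (ct_target_test, ct_reference_test, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    dct_test = ct_target_test - ct_reference_test
    dct_cal = ct_target_calibrator - ct_reference_calibrator
    return float(2.0 ** -(dct_test - dct_cal))


def mean_cell_size(area: float, cell_count: int) -> float:
    """Average cell size (area units per cell) from a cell count over an
    imaged area."""
    if area <= 0:
        raise ValueError("area must be positive")
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    return area / cell_count
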