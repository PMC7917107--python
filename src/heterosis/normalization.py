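"""Library-size and length normalization.

Three schemes are provided:

* median-of-ratios size factors — the between-sample normalization the
  negative-binomial test assumes; computed over features with strictly
  positive counts in every sample, rescaled to geometric mean 1;
* TPM — within-sample, length-aware (reads-per-kb rates rescaled to sum
  to one million per column).  Short-RNA matrices, where every mature
  miRNA has essentially the same length, may omit feature lengths, in
  which case the length term cancels and the result is counts-per-million
  carrying the tag ``TPM(length-free)``;
* FPKM — within-sample, 1e9 * count / (length_bp * column_total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TriadCountMatrix


@dataclass
class NormalizedMatrix:
    """Normalized expression values with the same shape as the source
    counts and a tag recording the method used."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    method: str


def size_factors(m: TriadCountMatrix) -> pd.Series:
    """Median-of-ratios size factors with geometric mean 1.

    Each sample's factor is the median, over features with all-positive
    counts, of the ratio of the sample's count to the feature's geometric
    mean across samples.  When no feature is positive in every sample the
    estimate falls back to total-count ratios, with a warning.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        sub = counts[all_pos]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        ratios = sub / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no feature with positive counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count; size factors undefined")
        factors = totals / totals.mean()
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def tpm(m: TriadCountMatrix) -> NormalizedMatrix:
    """Transcripts-per-million.  Columns sum to 1e6 exactly (up to float
    rounding).  Without feature lengths this degrades to counts-per-million
    (appropriate for mature miRNAs of uniform length)."""
    counts = m.counts.astype(float)
    if m.feature_lengths is not None:
        lengths_kb = m.feature_lengths.astype(float) / 1000.0
        if (lengths_kb <= 0).any():
            raise ValueError("zero or negative feature length")
        rates = counts.div(lengths_kb, axis=0)
        method = "TPM"
    else:
        rates = counts
        method = "TPM(length-free)"
    col_sums = rates.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("sample with zero total; TPM undefined")
    values = rates.div(col_sums, axis=1) * 1e6
    return NormalizedMatrix(values=values, sample_meta=m.sample_meta, method=method)


def fpkm(m: TriadCountMatrix) -> NormalizedMatrix:
    """Fragments per kilobase per million mapped reads."""
    if m.feature_lengths is None:
        raise ValueError("FPKM requires feature lengths")
    counts = m.counts.astype(float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total count; FPKM undefined")
    lengths = m.feature_lengths.astype(float)
    if (lengths <= 0).any():
        raise ValueError("zero or negative feature length")
    values = counts.div(lengths, axis=0).div(totals, axis=1) * 1e9
    return NormalizedMatrix(values=values, sample_meta=m.sample_meta, method="FPKM")


def normalized_counts(m: TriadCountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors (the scale the NB test
    statistics are computed on)."""
    if factors is None:
        factors = size_factors(m)
    return m.counts.astype(float).div(factors, axis=1)
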