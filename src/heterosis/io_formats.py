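"""Readers and writers for the pipeline's tabular and sequence artifacts.

All externally visible coordinates (degradome positions, target-site
intervals) are 1-based inclusive; this module owns the only conversion
point between file and in-memory representations.  Missing numeric values
are serialized as the string ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPES = ("P1", "F1", "P2")
STAGES = ("S", "H")

NA_STRING = "NA"


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class TriadCountMatrix:
    """Raw integer counts (features x samples) with triad sample metadata.

    ``counts`` is a features-by-samples DataFrame of nonnegative integers.
    ``sample_meta`` is indexed by sample id with columns ``genotype``
    (P1/F1/P2, plus MPV for pseudo-samples), ``stage`` (S/H) and
    ``replicate`` (integer).  ``feature_lengths`` (bp) is optional and only
    required for length-aware normalization (TPM/FPKM).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if not counts.index.is_unique:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if (counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        missing = set(counts.columns) - set(self.sample_meta.index)
        if missing:
            raise FormatError(f"samples missing from sample sheet: {sorted(missing)}")
        bad = set(self.sample_meta["genotype"]) - {"P1", "F1", "P2", "MPV"}
        if bad:
            raise FormatError(f"unknown genotype labels: {sorted(bad)}")
        self.sample_meta = self.sample_meta.loc[list(counts.columns)]
        self.counts.index.name = "feature_id"
        self.counts.columns.name = None
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(counts.index)
            if (self.feature_lengths <= 0).any():
                raise FormatError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, genotype: str, stage: str | None = None) -> list[str]:
        """Sample ids of one genotype (optionally restricted to a stage),
        ordered by replicate index."""
        meta = self.sample_meta
        mask = meta["genotype"] == genotype
        if stage is not None:
            mask &= meta["stage"] == stage
        sub = meta[mask].sort_values("replicate")
        return list(sub.index)

    def subset_stage(self, stage: str) -> "TriadCountMatrix":
        keep = self.sample_meta.index[self.sample_meta["stage"] == stage]
        return TriadCountMatrix(
            counts=self.counts[list(keep)].copy(),
            sample_meta=self.sample_meta.loc[list(keep)].copy(),
            feature_lengths=self.feature_lengths,
        )


def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> TriadCountMatrix:
    """Read a tab-separated count matrix plus its sample sheet.

    The matrix has feature ids in the first column and one column per
    sample; every cell must be a nonnegative integer.  The sample sheet is
    a TSV with columns ``sample``, ``genotype``, ``stage``, ``replicate``.
    """
    path, sheet = Path(path), Path(sample_sheet_path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    values = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, (row, cell) in enumerate(raw[col].items()):
            try:
                values[i, j] = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at feature {row!r}, sample {col!r} in {path}"
                ) from None
    ints = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    meta = pd.read_csv(sheet, sep="\t", dtype={"sample": str, "genotype": str, "stage": str}, comment="#")
    required = {"sample", "genotype", "stage", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(f"sample sheet missing columns: {sorted(required - set(meta.columns))}")
    meta = meta.set_index("sample")
    return TriadCountMatrix(counts=ints, sample_meta=meta)


def write_count_matrix(m: TriadCountMatrix, path: str | Path, sample_sheet_path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="feature_id")
    m.sample_meta.to_csv(sample_sheet_path, sep="\t", index_label="sample")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping.

    Ids are the first whitespace token of the header; duplicate ids and
    empty sequences are rejected.  U and T are both accepted (pairing code
    treats them as equivalent).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        bad = set(seq) - set("ACGUTN")
        if bad:
            raise FormatError(f"invalid symbols {sorted(bad)} in sequence {rec.id!r}")
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _format_value(v) -> str:
    if v is None:
        return NA_STRING
    if isinstance(v, float):
        if math.isnan(v):
            return NA_STRING
        return f"{v:.6g}"
    return str(v)


def write_results(table: pd.DataFrame, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a result table as TSV: header row, stable column order, floats
    at 6 significant digits, NaN as ``NA``.  Optional ``header_comments``
    are emitted as leading ``#`` lines (used for seed/config provenance)."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(map(str, table.columns)) + "\n")
        for _, row in table.iterrows():
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_STRING])


def read_tag_positions(path: str | Path) -> pd.DataFrame:
    """Read degradome tag positions: TSV of (transcript, position, count),
    positions 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript", "position", "count"}
    if not required.issubset(df.columns):
        raise FormatError(f"tag table missing columns: {sorted(required - set(df.columns))}")
    if (df["position"] < 1).any():
        raise FormatError("tag positions must be >= 1 (1-based)")
    return df


@dataclass
class PhenotypeTable:
    """Plant-level phenotype observations.

    ``data`` columns: ``plant_id``, ``genotype`` (P1/F1/P2), ``trait``,
    ``value`` (> 0 for ratio-based indices), optional ``stage`` and
    ``location``.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"plant_id", "genotype", "trait", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
        bad = set(self.data["genotype"]) - set(GENOTYPES)
        if bad:
            raise FormatError(f"unknown genotype labels: {sorted(bad)}")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", comment="#"))


def write_phenotypes(tbl: PhenotypeTable, path: str | Path) -> None:
    tbl.data.to_csv(path, sep="\t", index=False)
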