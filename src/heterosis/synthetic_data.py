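"""Generators for triad count matrices, phenotype tables and degradome
data with planted ground truth.

These emulate the study design every downstream stage expects: two inbred
parents and their F1 hybrid, sampled with a few biological replicates at
one or two vegetative stages, miRNA/mRNA counts that are negative-
binomially dispersed, heterotic phenotypes with known mid-parent and
better-parent heterosis, and degradome tag profiles concentrated at
planted miRNA cleavage sites.  Every generator is deterministic given its
seed.

Planted expression classes pin the triad means analytically:

* parents of a differential feature sit at base * 2^(+-effect/2), so the
  parent-parent log2 fold change equals ``effect_log2fc``;
* ELD classes place the hybrid mean exactly on the matched parent;
* additive places it on the mid-parent;
* transgressive places it at the extreme parent scaled by a further
  2^(+-effect/2);
* conserved features share one mean across all genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degradome import DegradomeProfile, reverse_complement
from .io_formats import PhenotypeTable, TriadCountMatrix
from .patterns import PATTERN_LABELS


class ConfigError(ValueError):
    """Invalid simulation configuration."""


DEFAULT_PROPORTIONS = {label: 1.0 / len(PATTERN_LABELS) for label in PATTERN_LABELS}


@dataclass
class TriadSimConfig:
    """Configuration for the triad count simulator.

    ``class_proportions`` maps the eight pattern labels to fractions
    summing to 1; ``base_mean_log_range`` is the log10 range baseline
    expression is drawn from; ``effect_log2fc`` is the planted
    parent/hybrid separation; ``dispersion`` is the NB alpha in
    Var = mu + alpha mu^2 (0 gives Poisson counts).
    """

    n_features: int = 1000
    n_reps: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    base_mean_log_range: tuple[float, float] = (1.0, 3.0)
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    library_size_factors: dict[str, float] | None = None
    stages: tuple[str, ...] = ("S",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.effect_log2fc <= 0:
            raise ConfigError("effect_log2fc must be > 0")
        unknown = set(self.class_proportions) - set(PATTERN_LABELS)
        if unknown:
            raise ConfigError(f"unknown pattern labels: {sorted(unknown)}")
        for label, frac in self.class_proportions.items():
            if frac < 0:
                raise ConfigError(f"negative proportion for {label!r}: {frac}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"class proportions must sum to 1 (got {total!r}): "
                f"{self.class_proportions}"
            )


def _planted_means(
    label: str, base: float, effect_log2fc: float, flip: bool
) -> tuple[float, float, float]:
    """(mu_P1, mu_F1, mu_P2) for one feature of a planted class.

    ``flip`` swaps which parent is the higher-expressing one for the
    parent-symmetric classes (additive, transgressive); ELD labels name a
    parent explicitly, so their orientation is fixed by the label.
    Randomizing the orientation keeps the two parents exchangeable across
    the matrix, as in real crosses, so between-sample normalization sees
    no systematic parent effect.
    """
    hi = base * 2 ** (effect_log2fc / 2)
    lo = base * 2 ** (-effect_log2fc / 2)
    step = 2 ** (effect_log2fc / 2)
    if label == "conserved":
        return base, base, base
    if label == "additive":
        triple = (hi, (hi + lo) / 2, lo)
    elif label == "ELD-P1-high":
        return hi, hi, lo
    elif label == "ELD-P1-low":
        return lo, lo, hi
    elif label == "ELD-P2-high":
        return lo, hi, hi
    elif label == "ELD-P2-low":
        return hi, lo, lo
    elif label == "transgressive-up":
        triple = (hi, hi * step, lo)
    elif label == "transgressive-down":
        triple = (hi, lo / step, lo)
    else:
        raise ConfigError(f"unknown pattern label {label!r}")
    if flip:
        return triple[2], triple[1], triple[0]
    return triple


def _allocate_classes(cfg: TriadSimConfig) -> list[str]:
    """Deterministic largest-remainder allocation of features to classes."""
    labels = [lab for lab in PATTERN_LABELS if cfg.class_proportions.get(lab, 0) > 0]
    exact = {lab: cfg.class_proportions[lab] * cfg.n_features for lab in labels}
    counts = {lab: int(np.floor(exact[lab])) for lab in labels}
    short = cfg.n_features - sum(counts.values())
    by_remainder = sorted(labels, key=lambda lab: exact[lab] - counts[lab], reverse=True)
    for lab in by_remainder[:short]:
        counts[lab] += 1
    out: list[str] = []
    for lab in labels:
        out.extend([lab] * counts[lab])
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with Var = mu + alpha mu^2; alpha = 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_triad_counts(cfg: TriadSimConfig) -> tuple[TriadCountMatrix, pd.DataFrame]:
    """Simulate a triad count matrix plus its truth table.

    Counts are NB(sf_j * mu_g, alpha) per feature and sample.  The truth
    table has one row per feature: feature_id, planted_class, mu_P1,
    mu_F1, mu_P2 (shared across stages).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    classes = _allocate_classes(cfg)
    lo10, hi10 = cfg.base_mean_log_range
    bases = 10 ** rng.uniform(lo10, hi10, size=cfg.n_features)
    feature_ids = [f"feat{i + 1:05d}" for i in range(cfg.n_features)]

    flips = rng.random(cfg.n_features) < 0.5
    means = np.array(
        [
            _planted_means(lab, base, cfg.effect_log2fc, flip)
            for lab, base, flip in zip(classes, bases, flips)
        ]
    )  # columns: P1, F1, P2
    genotype_means = {"P1": means[:, 0], "F1": means[:, 1], "P2": means[:, 2]}

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for stage in cfg.stages:
        for genotype in ("P1", "F1", "P2"):
            for rep in range(1, cfg.n_reps + 1):
                name = f"{genotype}_{stage}_r{rep}"
                sf = 1.0
                if cfg.library_size_factors is not None:
                    sf = float(cfg.library_size_factors.get(name, 1.0))
                    if sf <= 0:
                        raise ConfigError(f"non-positive size factor for sample {name!r}")
                columns[name] = _nb_draw(rng, sf * genotype_means[genotype], cfg.dispersion)
                meta_rows.append(
                    {"sample": name, "genotype": genotype, "stage": stage, "replicate": rep}
                )

    counts = pd.DataFrame(columns, index=feature_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "planted_class": classes,
            "mu_P1": means[:, 0],
            "mu_F1": means[:, 1],
            "mu_P2": means[:, 2],
        }
    )
    return TriadCountMatrix(counts=counts, sample_meta=meta), truth


DEFAULT_TRAITS = ("GW", "PH", "SLW", "LN", "LL", "LW")


def gen_phenotypes(
    traits: list[str] | tuple[str, ...] = DEFAULT_TRAITS,
    n_plants: int = 5,
    planted_mph: dict[str, float] | float = 90.0,
    planted_bph: dict[str, float] | float | None = None,
    noise_cv: float = 0.1,
    seed: int = 0,
    base_value: float = 100.0,
    stage: str = "S",
) -> PhenotypeTable:
    """Simulate plant-level phenotypes with planted MPH/BPH percentages.

    The better parent is fixed at ``base_value`` and the other parent and
    hybrid means are solved so the population MPH and BPH exactly equal
    the planted percentages before noise.  BPH defaults to 60% of MPH
    (a typical spread for biomass traits) and must not exceed MPH.
    Noise is gamma-distributed around each mean with coefficient of
    variation ``noise_cv`` (0 gives exact means).
    """
    if n_plants < 2:
        raise ConfigError("n_plants must be >= 2")
    if noise_cv < 0:
        raise ConfigError("noise_cv must be >= 0")
    mph_map = planted_mph if isinstance(planted_mph, dict) else {t: float(planted_mph) for t in traits}
    if planted_bph is None:
        bph_map = {t: 0.6 * mph_map[t] for t in traits}
    elif isinstance(planted_bph, dict):
        bph_map = planted_bph
    else:
        bph_map = {t: float(planted_bph) for t in traits}

    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        mph, bph = mph_map[trait], bph_map[trait]
        if bph > mph:
            raise ConfigError(f"planted BPH ({bph}) exceeds planted MPH ({mph}) for {trait!r}")
        # better parent at base_value; solve the weaker parent from the
        # MPH/BPH ratio: BP/MP = (1 + MPH/100) / (1 + BPH/100)
        m1 = base_value
        m2 = 2 * base_value * (1 + bph / 100.0) / (1 + mph / 100.0) - base_value
        if m2 <= 0:
            raise ConfigError(
                f"planted MPH/BPH pair ({mph}, {bph}) for {trait!r} implies a "
                "non-positive weaker parent"
            )
        f1 = base_value * (1 + bph / 100.0)
        for genotype, mu in (("P1", m1), ("F1", f1), ("P2", m2)):
            if noise_cv == 0:
                values = np.full(n_plants, mu)
            else:
                shape = 1.0 / noise_cv**2
                values = rng.gamma(shape, mu / shape, size=n_plants)
            for i, v in enumerate(values, start=1):
                rows.append(
                    {
                        "plant_id": f"{genotype}_{trait}_{i}",
                        "genotype": genotype,
                        "trait": trait,
                        "value": float(v),
                        "stage": stage,
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


@dataclass
class DegradomeSimConfig:
    """Configuration for the degradome simulator.

    ``planted_sites`` rows are (mirna_id, transcript_id, cleavage_position,
    tag_count); when None, one perfect-complement site per miRNA is placed
    on its own transcript at a random valid position with ``default_tag_count``
    tags.  ``background_tag_rate`` is the Poisson mean of background tags
    per transcript position.
    """

    n_transcripts: int = 20
    transcript_length_range: tuple[int, int] = (300, 800)
    n_mirnas: int = 10
    mirna_length: int = 21
    planted_sites: list[tuple[str, str, int, int]] | None = None
    default_tag_count: int = 10
    background_tag_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1 or self.n_mirnas < 1:
            raise ConfigError("need at least one transcript and one miRNA")
        if self.mirna_length < 12:
            raise ConfigError("mirna_length must be >= 12 (cleavage site at position 10)")
        if self.transcript_length_range[0] < self.mirna_length:
            raise ConfigError("transcripts must be at least one miRNA long")
        if self.background_tag_rate < 0:
            raise ConfigError("background_tag_rate must be >= 0")


def gen_degradome(
    cfg: DegradomeSimConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, DegradomeProfile], pd.DataFrame]:
    """Simulate miRNAs, transcripts and degradome profiles.

    Each planted site's transcript window is overwritten with the reverse
    complement of its miRNA (a perfect-complement, score-0 duplex) and its
    cleavage position receives ``tag_count`` extra tags on top of the
    Poisson background.  Returns (mirnas, transcripts, profiles,
    planted-site table with columns mirna_id, transcript_id,
    cleavage_position, tag_count, target_start).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.mirna_length
    alphabet = np.array(list("ACGT"))

    def random_seq(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length))

    mirnas = {f"mir{i + 1:03d}": random_seq(L).replace("T", "U") for i in range(cfg.n_mirnas)}
    lo, hi = cfg.transcript_length_range
    transcripts = {
        f"tx{i + 1:03d}": random_seq(int(rng.integers(lo, hi + 1)))
        for i in range(cfg.n_transcripts)
    }

    sites = cfg.planted_sites
    if sites is None:
        sites = []
        tx_ids = list(transcripts)
        for i, mid in enumerate(mirnas):
            tid = tx_ids[i % len(tx_ids)]
            tx_len = len(transcripts[tid])
            # cleavage sits at window start + (L - 10); keep the window inside
            start = int(rng.integers(1, tx_len - L + 2))
            sites.append((mid, tid, start + (L - 10), cfg.default_tag_count))

    planted_rows = []
    for mid, tid, cleavage, tag_count in sites:
        if mid not in mirnas:
            raise ConfigError(f"planted site names unknown miRNA {mid!r}")
        if tid not in transcripts:
            raise ConfigError(f"planted site names unknown transcript {tid!r}")
        if tag_count < 1:
            raise ConfigError(f"tag_count must be >= 1 for site {mid!r}/{tid!r}")
        start = cleavage - (L - 10)
        tx = transcripts[tid]
        if start < 1 or start + L - 1 > len(tx):
            raise ConfigError(
                f"planted site {mid!r}/{tid!r}: cleavage {cleavage} puts the "
                f"target window outside the transcript (length {len(tx)})"
            )
        window = reverse_complement(mirnas[mid])
        transcripts[tid] = tx[: start - 1] + window + tx[start - 1 + L :]
        planted_rows.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "cleavage_position": cleavage,
                "tag_count": tag_count,
                "target_start": start,
            }
        )

    profiles = {}
    for tid, seq in transcripts.items():
        counts = rng.poisson(cfg.background_tag_rate, size=len(seq)).astype(np.int64)
        profiles[tid] = DegradomeProfile(tid, counts)
    for row in planted_rows:
        profiles[row["transcript_id"]].counts[row["cleavage_position"] - 1] += row["tag_count"]

    return mirnas, transcripts, profiles, pd.DataFrame(planted_rows)
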