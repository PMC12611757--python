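"""CRISPRi growth-screen scoring against non-targeting controls.

Raw guide counts → CPM → QC filters (abundance, guide specificity, minimum
guides per element) → per-guide fitness ratios against the NTC reference →
Z scores → element-level averages and hit calls.

The Z reference population is the NTC guides' log2 ratios by default, which
keeps the null centred even when many elements carry true effects; an
all-guide reference and a raw-ratio mode are available as config switches
for reconciliation with alternative conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigError, DataError, parse_sample, sample_columns

__all__ = [
    "FitnessConfig",
    "cpm_normalize",
    "qc_filter",
    "guide_fitness",
    "element_scores",
    "score_screen",
]

META_COLUMNS = ["guide_id", "element", "is_ntc", "specificity"]


@dataclass
class FitnessConfig:
    """Screen-scoring parameters.

    ``cpm_min=20`` (guides must reach 20 CPM in every sample),
    ``specificity_min=0.2`` (CRISPRi specificity-score cut-off; NTCs are
    exempt), ``min_guides_per_element=2``; an element is a negative hit
    when its mean guide Z falls below ``z_neg`` (default −1).
    """

    cpm_min: float = 20.0
    specificity_min: float = 0.2
    min_guides_per_element: int = 2
    z_neg: float = -1.0
    z_pos: float = 1.0
    ntc_summary: str = "median"
    zscore_population: str = "ntc"  # "ntc" | "all"
    log_ratios: bool = True

    def __post_init__(self) -> None:
        if self.cpm_min < 0:
            raise ConfigError("cpm_min must be non-negative")
        if self.min_guides_per_element < 1:
            raise ConfigError("min_guides_per_element must be >= 1")
        if self.z_neg >= self.z_pos:
            raise ConfigError("z_neg must be below z_pos")
        if self.ntc_summary not in ("median", "mean"):
            raise ConfigError("ntc_summary must be 'median' or 'mean'")
        if self.zscore_population not in ("ntc", "all"):
            raise ConfigError("zscore_population must be 'ntc' or 'all'")


def cpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample column; each sample sums to 1e6."""
    cols = sample_columns(table)
    if not cols:
        raise DataError("no sample columns to normalize")
    out = table.copy()
    for c in cols:
        total = table[c].sum()
        if total <= 0:
            raise DataError(f"sample {c!r} has zero total count")
        out[c] = table[c] * 1e6 / total
    return out


def qc_filter(cpm: pd.DataFrame, cfg: FitnessConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply guide- and element-level QC.

    Keeps a guide iff its CPM is at least ``cfg.cpm_min`` in every sample
    and (it is an NTC or its specificity exceeds ``cfg.specificity_min``);
    then drops targeting elements left with fewer than
    ``cfg.min_guides_per_element`` guides. Returns the filtered table and an
    exclusion report (guide_id, reason) listing every removal.
    """
    cols = sample_columns(cpm)
    excl = []
    low_cpm = ~(cpm[cols] >= cfg.cpm_min).all(axis=1)
    low_spec = (~cpm["is_ntc"]) & ~(cpm["specificity"] > cfg.specificity_min)
    for r in cpm[low_cpm].itertuples():
        excl.append((r.guide_id, "low_abundance"))
    for r in cpm[low_spec & ~low_cpm].itertuples():
        excl.append((r.guide_id, "low_specificity"))
    kept = cpm[~(low_cpm | low_spec)].copy()
    if not kept["is_ntc"].any():
        raise DataError("all NTC guides excluded by QC; no reference population")
    sizes = kept[~kept["is_ntc"]].groupby("element")["guide_id"].size()
    thin = set(sizes[sizes < cfg.min_guides_per_element].index)
    for r in kept[kept["element"].isin(thin)].itertuples():
        excl.append((r.guide_id, "too_few_guides"))
    kept = kept[~kept["element"].isin(thin)].reset_index(drop=True)
    report = pd.DataFrame(excl, columns=["guide_id", "reason"])
    return kept, report


def _replicate_means(filtered: pd.DataFrame) -> tuple[pd.DataFrame, list[float]]:
    cols = sample_columns(filtered)
    days = sorted({parse_sample(c)[0] for c in cols})
    means = filtered[META_COLUMNS].copy()
    for day in days:
        day_cols = [c for c in cols if parse_sample(c)[0] == day]
        means[f"d{day:g}"] = filtered[day_cols].mean(axis=1)
    return means, days


def guide_fitness(
    filtered: pd.DataFrame, timepoint: float, cfg: FitnessConfig | None = None
) -> pd.DataFrame:
    """Per-guide fitness at one timepoint.

    Replicate CPMs are averaged per guide; ``ratio`` is guide CPM over the
    NTC summary statistic at that timepoint; ``z`` standardizes log2(ratio)
    (or the raw ratio with ``log_ratios=False``) against the reference
    population (NTC guides by default), whose Z mean is 0 by construction.
    """
    cfg = cfg or FitnessConfig()
    means, days = _replicate_means(filtered)
    if timepoint not in days:
        raise DataError(f"timepoint {timepoint} not present (have {days})")
    col = f"d{timepoint:g}"
    ntc = means.loc[means["is_ntc"], col]
    if len(ntc) < 2:
        raise DataError("need at least 2 NTC guides")
    ref = ntc.median() if cfg.ntc_summary == "median" else ntc.mean()
    out = means[META_COLUMNS].copy()
    out["timepoint"] = timepoint
    out["cpm"] = means[col]
    out["ratio"] = means[col] / ref
    score = np.log2(out["ratio"]) if cfg.log_ratios else out["ratio"]
    pop = score[out["is_ntc"]] if cfg.zscore_population == "ntc" else score
    sd = pop.std(ddof=1)
    if sd == 0:
        raise DataError("reference population has zero spread; Z undefined")
    out["log2_ratio" if cfg.log_ratios else "raw_ratio"] = score
    out["z"] = (score - pop.mean()) / sd
    return out


def element_scores(guide_z: pd.DataFrame, cfg: FitnessConfig | None = None) -> pd.DataFrame:
    """Element-level mean guide Z and hit class per timepoint.

    Hit classes: ``negative`` (mean Z < z_neg, candidate viability hit),
    ``positive`` (mean Z > z_pos), else ``none``. NTC guides are excluded.
    """
    cfg = cfg or FitnessConfig()
    sub = guide_z[~guide_z["is_ntc"]]
    g = (
        sub.groupby(["element", "timepoint"], as_index=False)
        .agg(mean_z=("z", "mean"), n_guides=("guide_id", "size"))
    )
    g["hit_class"] = np.select(
        [g["mean_z"] < cfg.z_neg, g["mean_z"] > cfg.z_pos], ["negative", "positive"], "none"
    )
    return g


def score_screen(
    raw: pd.DataFrame, cfg: FitnessConfig | None = None
) -> dict:
    """Full pipeline: CPM → QC → per-guide Z at every timepoint → element
    scores. Returns dict with ``guides`` (long per-timepoint table),
    ``elements``, ``exclusions``."""
    cfg = cfg or FitnessConfig()
    cpm = cpm_normalize(raw)
    kept, report = qc_filter(cpm, cfg)
    _, days = _replicate_means(kept)
    guides = pd.concat(
        [guide_fitness(kept, day, cfg) for day in days], ignore_index=True
    )
    elements = element_scores(guides, cfg)
    return {"guides": guides, "elements": elements, "exclusions": report}
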