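"""3D spatial statistics for labelled FISH/ORCA spots, cell by cell.

The experimental question is whether ecDNA-borne loci cluster in the
nucleus. Three complementary quantifications are provided:

* shortest cross-locus distances per reference spot, compared with a
  matched random-points-in-a-sphere null via a two-tailed Wilcoxon
  rank-sum test (normal approximation, tie- and continuity-corrected);
* a shell-corrected Ripley's-K-style statistic: the observed fraction of
  cross pair distances in each radial shell, divided by the fraction a
  uniform-in-volume pair-distance distribution would put there
  (``((r+dr)^3 - r^3)/cutoff^3``). K > 1 in a shell means clustering at
  that scale, ~1 randomness, < 1 dispersion;
* the per-cell copy-number (spot-count) Pearson correlation between loci.

No edge correction is applied to K; the complete-spatial-randomness
calibration is therefore run at cutoffs small relative to the nucleus
radius, where the residual edge bias stays inside the test tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ConfigError, DataError
from .synthetic_data import component_rng, uniform_in_sphere

__all__ = [
    "NullConfig",
    "RipleyConfig",
    "DistanceSummary",
    "pairwise_distances",
    "shortest_cross_distances",
    "sphere_null",
    "compare_obs_exp",
    "ripley_k",
    "copy_correlation",
    "spot_summary",
]


@dataclass
class NullConfig:
    """Random-points-in-a-sphere null: ``sphere_radius`` defaults to the
    4-µm average cell radius; per-cell, per-locus point counts are matched
    exactly to the observed table."""

    sphere_radius: float = 4.0
    n_sims: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ConfigError("sphere_radius must be positive")
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")


@dataclass
class RipleyConfig:
    """Radial shell grid for the shell-corrected K statistic.

    Defaults follow the 0.01:0.01:2 µm grid with a 2-µm cutoff;
    ``report_grid`` (lo, hi, step) optionally re-bins the output onto a
    coarser display grid (e.g. 0.01–0.5 µm in 0.02-µm steps).
    """

    r_start: float = 0.01
    r_step: float = 0.01
    r_stop: float = 2.0
    cutoff: float = 2.0
    report_grid: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.r_step <= 0:
            raise ConfigError("r_step must be positive")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        if self.r_stop > self.cutoff:
            raise ConfigError("r_stop must not exceed cutoff")

    def edges(self) -> np.ndarray:
        if self.report_grid is not None:
            lo, hi, step = self.report_grid
            e = np.arange(lo, hi + step / 2, step)
        else:
            e = np.arange(self.r_start, self.r_stop + self.r_step / 2, self.r_step)
            if e[-1] < self.cutoff - 1e-12:
                e = np.append(e, self.cutoff)
        if e[0] > 0:
            e = np.insert(e, 0, 0.0)
        return e


@dataclass
class DistanceSummary:
    observed: np.ndarray
    null: np.ndarray
    median_observed: float
    median_null: float
    statistic: float  # Mann-Whitney U of observed vs null
    pvalue: float
    fraction_within_threshold: float
    threshold_um: float = 0.3


def _check_loci(spots: pd.DataFrame, *loci: str) -> None:
    known = set(spots["locus"].unique())
    if "loci" in spots.attrs:
        known |= set(spots.attrs["loci"])
    unknown = [l for l in loci if l not in known]
    if unknown:
        raise DataError(f"unknown locus label(s): {unknown}")


def _coords(spots: pd.DataFrame, locus: str) -> np.ndarray:
    sub = spots[spots["locus"] == locus]
    return sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def pairwise_distances(
    spots: pd.DataFrame, locus_a: str, locus_b: str, cell_id: str | None = None
) -> np.ndarray:
    """All A×B Euclidean distances (µm) within one cell.

    For ``locus_a == locus_b`` the matrix is square with the diagonal
    (self-pairs) set to NaN. With no spot of either locus the matrix is
    empty along that axis.
    """
    _check_loci(spots, locus_a, locus_b)
    if cell_id is not None:
        spots = spots[spots["cell_id"] == cell_id]
    a = _coords(spots, locus_a)
    b = _coords(spots, locus_b)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    if locus_a == locus_b and len(a):
        np.fill_diagonal(d, np.nan)
    return d


def shortest_cross_distances(
    spots: pd.DataFrame, reference: str, target: str
) -> pd.DataFrame:
    """One minimum distance per reference spot, per cell.

    Each reference-locus centroid is paired with its nearest target-locus
    centroid in the same cell. In same-locus mode the spot itself is
    excluded, so cells with fewer than two spots contribute nothing;
    in cross mode cells with no target spot contribute nothing.
    """
    _check_loci(spots, reference, target)
    rows = []
    for cell, sub in spots.groupby("cell_id", sort=True):
        d = pairwise_distances(sub, reference, target)
        if d.shape[0] == 0 or d.shape[1] < (2 if reference == target else 1):
            continue
        mins = np.nanmin(d, axis=1)
        rows.extend((cell, float(v)) for v in mins)
    return pd.DataFrame(rows, columns=["cell_id", "distance_um"])


def sphere_null(spots: pd.DataFrame, loci, cfg: NullConfig) -> pd.DataFrame:
    """Matched random null: uniform points in a sphere, per cell and locus.

    Per null replicate (column ``sim``), every cell receives uniform random
    points in a sphere of ``cfg.sphere_radius`` with per-locus counts equal
    to that cell's observed counts, so density is controlled exactly. Cell
    order does not affect the draws for a given cell (stream keyed per
    replicate, cells processed in sorted order).
    """
    rng = component_rng(cfg.seed, "sphere_null")
    counts = (
        spots[spots["locus"].isin(list(loci))]
        .groupby(["cell_id", "locus"], sort=True)
        .size()
    )
    rows = []
    for sim in range(cfg.n_sims):
        for (cell, locus), n in counts.items():
            pts = uniform_in_sphere(rng, int(n), cfg.sphere_radius)
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell,
                        "locus": locus,
                        "x_um": pts[:, 0],
                        "y_um": pts[:, 1],
                        "z_um": pts[:, 2],
                        "sim": sim,
                    }
                )
            )
    if not rows:
        out = pd.DataFrame(columns=["cell_id", "locus", "x_um", "y_um", "z_um", "sim"])
    else:
        out = pd.concat(rows, ignore_index=True)
    out.attrs["loci"] = list(loci)
    return out


def compare_obs_exp(
    observed, null, threshold_um: float = 0.3
) -> DistanceSummary:
    """Observed vs expected distance comparison.

    Two-tailed Wilcoxon rank-sum test in its normal approximation with tie
    correction and continuity correction; ``fraction_within_threshold`` is
    the share of *observed* distances at or below the regulatory-range
    threshold (default 0.3 µm = 300 nm).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0:
        raise DataError("observed distance list is empty")
    if null.size == 0:
        raise DataError("null distance list is empty")
    res = sps.mannwhitneyu(
        observed, null, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return DistanceSummary(
        observed=observed,
        null=null,
        median_observed=float(np.median(observed)),
        median_null=float(np.median(null)),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        fraction_within_threshold=float((observed <= threshold_um).mean()),
        threshold_um=threshold_um,
    )


def _cell_pair_distances(sub: pd.DataFrame, reference: str, target: str) -> np.ndarray:
    d = pairwise_distances(sub, reference, target)
    if d.size == 0:
        return np.empty(0)
    if reference == target:
        iu = np.triu_indices(d.shape[0], k=1)
        return d[iu]
    return d.ravel()


def ripley_k(
    spots: pd.DataFrame, reference: str, target: str, cfg: RipleyConfig
) -> pd.DataFrame:
    """Shell-corrected K per radial shell, averaged across cells.

    Per cell, over cross pair distances d ≤ cutoff:
    ``p_obs_i = #{d in [r_i, r_i+dr)} / #{d <= cutoff}`` and
    ``p_unif_i = ((r_i+dr)^3 - r_i^3) / cutoff^3``; ``K_i = p_obs_i / p_unif_i``.
    Cells without a qualifying pair are skipped; cells are weighted equally.
    Under uniform-in-volume pair distances every shell has expectation 1.

    Returns a DataFrame (r_lo, r_hi, mean_K, sem, n_cells).
    """
    _check_loci(spots, reference, target)
    edges = cfg.edges()
    p_unif = (edges[1:] ** 3 - edges[:-1] ** 3) / cfg.cutoff**3
    ks = []
    for _, sub in spots.groupby("cell_id", sort=True):
        d = _cell_pair_distances(sub, reference, target)
        d = d[d <= cfg.cutoff]
        if d.size == 0:
            continue
        hist, _ = np.histogram(d, bins=edges)
        # distances beyond the last edge (possible when r_stop < cutoff with
        # a report grid) are outside the partition but still in the denominator
        p_obs = hist / d.size
        with np.errstate(divide="ignore", invalid="ignore"):
            ks.append(np.where(p_unif > 0, p_obs / p_unif, np.nan))
    if not ks:
        return pd.DataFrame(columns=["r_lo", "r_hi", "mean_K", "sem", "n_cells"])
    arr = np.vstack(ks)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(arr.shape[1], np.nan)
    return pd.DataFrame(
        {"r_lo": edges[:-1], "r_hi": edges[1:], "mean_K": mean, "sem": sem, "n_cells": n}
    )


def copy_correlation(
    spots: pd.DataFrame, locus_a: str, locus_b: str, cell_ids=None
) -> float:
    """Pearson correlation of per-cell spot counts between two loci.

    ``cell_ids`` optionally supplies the full cell roster (cells absent from
    the table count 0 for both loci); by default the roster is the set of
    cells present in the table.
    """
    _check_loci(spots, locus_a, locus_b)
    if cell_ids is None:
        cell_ids = sorted(spots["cell_id"].unique())
    if len(cell_ids) < 3:
        raise DataError("copy_correlation requires at least 3 cells")
    counts = spots.groupby(["cell_id", "locus"]).size()
    a = np.array([counts.get((c, locus_a), 0) for c in cell_ids], dtype=float)
    b = np.array([counts.get((c, locus_b), 0) for c in cell_ids], dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise DataError("undefined correlation: zero variance in spot counts")
    r, _ = sps.pearsonr(a, b)
    return float(r)


def spot_summary(spots: pd.DataFrame, loci=None) -> dict:
    """Headline per-table numbers: analysed cell count and mean copies per
    locus — the quantities reported alongside the distance statistics."""
    if loci is None:
        loci = sorted(spots["locus"].unique())
    n_cells = spots.attrs.get("n_cells", spots["cell_id"].nunique())
    counts = spots.groupby(["cell_id", "locus"]).size().unstack(fill_value=0)
    out = {"n_cells": int(n_cells)}
    for locus in loci:
        col = counts[locus] if locus in counts else pd.Series(dtype=float)
        # cells with zero spots of this locus still count toward the mean
        total = col.sum()
        out[f"mean_copies_{locus}"] = float(total / n_cells) if n_cells else float("nan")
    return out
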