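"""Discovery and annotation of ecDNA-interacting elements (EIEs).

An EIE is a small (1-kb) genomic element physically inserted on ecDNA
molecules. Because the ecDNA is present at high copy number and each copy
carries the element next to a different part of the amplicon, the element's
bin contacts the *entire* megabase-scale amplified region in a binned
contact map — a trans "stripe". This module calls such stripes
automatically, scores the repeat-class content of candidate elements
against the genome-wide expectation, and counts long-read evidence that an
element co-amplifies with the ecDNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError

__all__ = [
    "ContactMatrix",
    "stripe_bin_stats",
    "call_trans_stripes",
    "overlap_fractions",
    "genome_class_fraction",
    "ecdna_support_counts",
    "merge_intervals",
    "repeat_class",
]

DEFAULT_CLASSES = ("LINE", "SINE", "LTR")


# ---------------------------------------------------------------------------
# Interval primitives (0-based half-open throughout)

def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent intervals; returns sorted disjoint arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def _covered_bp(start: int, end: int, m_starts: np.ndarray, m_ends: np.ndarray) -> int:
    """bp of [start, end) covered by merged disjoint intervals."""
    if len(m_starts) == 0:
        return 0
    lo = np.maximum(m_starts, start)
    hi = np.minimum(m_ends, end)
    return int(np.maximum(hi - lo, 0).sum())


def repeat_class(name: str) -> str:
    """Repeat class from the annotation label prefix before '/'
    (RepeatMasker convention: 'LINE/L1' → 'LINE'); unknown prefixes → 'other'."""
    cls = str(name).split("/", 1)[0]
    return cls if cls in DEFAULT_CLASSES else "other"


# ---------------------------------------------------------------------------
# Contact matrix

@dataclass
class ContactMatrix:
    """Sparse symmetric binned contact counts.

    ``pairs`` holds one row per stored bin pair (chrom1, start1, chrom2,
    start2, count); storage order and orientation are immaterial — pairs are
    canonicalized on construction and duplicate mirror entries must agree.
    """

    bin_size: int
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        need = ["chrom1", "start1", "chrom2", "start2", "count"]
        df = df[need]
        if (df["count"] < 0).any():
            raise DataError("negative contact counts")
        for c in ("start1", "start2"):
            if (df[c] % self.bin_size).any():
                raise DataError(f"{c} not multiples of bin_size={self.bin_size}")
        c1, s1 = df["chrom1"].to_numpy(), df["start1"].to_numpy()
        c2, s2 = df["chrom2"].to_numpy(), df["start2"].to_numpy()
        flip = (c2 < c1) | ((c2 == c1) & (s2 < s1))
        df["chrom1"], df["chrom2"] = np.where(flip, c2, c1), np.where(flip, c1, c2)
        df["start1"], df["start2"] = np.where(flip, s2, s1), np.where(flip, s1, s2)
        key = ["chrom1", "start1", "chrom2", "start2"]
        g = df.groupby(key, as_index=False)["count"].agg(["min", "max", "first"])
        if (g["min"] != g["max"]).any():
            raise DataError("conflicting counts for mirrored bin pairs")
        g["count"] = g["first"]
        self.pairs = (
            g[key + ["count"]].sort_values(key, kind="stable").reset_index(drop=True)
        )

    def bins(self) -> pd.DataFrame:
        a = self.pairs[["chrom1", "start1"]].rename(
            columns={"chrom1": "chrom", "start1": "start"}
        )
        b = self.pairs[["chrom2", "start2"]].rename(
            columns={"chrom2": "chrom", "start2": "start"}
        )
        return pd.concat([a, b]).drop_duplicates().sort_values(["chrom", "start"]).reset_index(drop=True)


def _amplicon_bins(amplicon, bin_size: int) -> list[tuple[str, int]]:
    out = []
    for chrom, s, e in amplicon:
        if e <= s:
            raise DataError(f"empty amplicon interval {chrom}:{s}-{e}")
        out.extend((chrom, b) for b in range(s - s % bin_size, e, bin_size))
    return sorted(set(out))


def stripe_bin_stats(cm: ContactMatrix, amplicon, min_contact: int = 1) -> pd.DataFrame:
    """Per-trans-bin stripe scores against an amplicon.

    For every trans bin b (on a chromosome carrying no amplicon bin):

    * ``coverage_fraction`` — share of amplicon bins a with
      ``counts[a, b] >= min_contact``;
    * ``enrichment`` — (mean amplicon contact of b + 1) divided by (the
      median mean-amplicon-contact over contact-bearing bins of b's
      chromosome + 1). Zero-contact bins are excluded from the median so
      scores do not depend on whether empty bins are stored.
    """
    if min_contact < 1:
        raise DataError("min_contact must be >= 1")
    amplicon = list(amplicon)
    if not amplicon:
        raise DataError("empty amplicon")
    bs = cm.bin_size
    amp_bins = _amplicon_bins(amplicon, bs)
    amp_set = set(amp_bins)
    amp_chroms = {c for c, _ in amp_bins}
    n_amp = len(amp_bins)

    cm_bins = {(r.chrom, r.start) for r in cm.bins().itertuples()}
    missing = amp_set - cm_bins
    if missing:
        raise DataError(f"{len(missing)} amplicon bins absent from the contact matrix")

    p = cm.pairs
    m1 = pd.Series([t in amp_set for t in zip(p["chrom1"], p["start1"])], index=p.index)
    m2 = pd.Series([t in amp_set for t in zip(p["chrom2"], p["start2"])], index=p.index)

    # orient as (amplicon side, partner side); keep trans partners only
    part = []
    for mask, pc, ps in ((m1 & ~m2, "chrom2", "start2"), (m2 & ~m1, "chrom1", "start1")):
        sub = p[mask]
        part.append(
            pd.DataFrame(
                {"chrom": sub[pc].to_numpy(), "start": sub[ps].to_numpy(), "count": sub["count"].to_numpy()}
            )
        )
    part = pd.concat(part, ignore_index=True)
    part = part[~part["chrom"].isin(amp_chroms)]

    if len(part) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "mean_contact", "coverage_fraction", "enrichment"]
        )

    grp = part.groupby(["chrom", "start"])["count"]
    stats = grp.agg(total="sum", covered=lambda s: int((s >= min_contact).sum())).reset_index()
    stats["mean_contact"] = stats["total"] / n_amp
    stats["coverage_fraction"] = stats["covered"] / n_amp
    med = stats.groupby("chrom")["mean_contact"].median().rename("background")
    stats = stats.join(med, on="chrom")
    stats["enrichment"] = (stats["mean_contact"] + 1.0) / (stats["background"] + 1.0)
    return stats[["chrom", "start", "mean_contact", "coverage_fraction", "enrichment"]]


def call_trans_stripes(
    cm: ContactMatrix,
    amplicon,
    min_contact: int = 1,
    min_coverage_fraction: float = 0.5,
    min_enrichment: float = 3.0,
) -> pd.DataFrame:
    """Call trans stripe anchors against an amplicon.

    Bins are scored with :func:`stripe_bin_stats`; bins passing both the
    coverage and enrichment thresholds are emitted, with runs of adjacent
    passing bins merged into one record anchored at the maximal-coverage
    bin (ties broken toward the lower coordinate).

    Threshold defaults are deliberately permissive and calibrated on
    planted synthetic maps; all three are exposed on the command line.
    """
    if not 0 < min_coverage_fraction <= 1 or min_enrichment < 0:
        raise DataError("invalid stripe-caller thresholds")
    bs = cm.bin_size
    stats = stripe_bin_stats(cm, amplicon, min_contact=min_contact)
    if len(stats) == 0:
        return _empty_stripe_table(bs)
    passing = stats[
        (stats["coverage_fraction"] >= min_coverage_fraction)
        & (stats["enrichment"] >= min_enrichment)
    ].sort_values(["chrom", "start"], kind="stable")

    records = []
    for chrom, sub in passing.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        breaks = np.flatnonzero(np.diff(starts) != bs)
        bounds = np.concatenate([[0], breaks + 1, [len(starts)]])
        for i in range(len(bounds) - 1):
            run = sub.iloc[bounds[i] : bounds[i + 1]]
            anchor = run.loc[run["coverage_fraction"].idxmax()]  # idxmax: first max → lower coord
            records.append(
                {
                    "chrom": chrom,
                    "start": int(anchor["start"]),
                    "end": int(anchor["start"]) + bs,
                    "coverage_fraction": float(anchor["coverage_fraction"]),
                    "enrichment": float(anchor["enrichment"]),
                    "run_start": int(run["start"].min()),
                    "run_end": int(run["start"].max()) + bs,
                    "n_bins": len(run),
                }
            )
    if not records:
        return _empty_stripe_table(bs)
    out = pd.DataFrame(records).sort_values(["chrom", "start"]).reset_index(drop=True)
    out.attrs["bin_size"] = bs
    return out


def _empty_stripe_table(bin_size: int) -> pd.DataFrame:
    out = pd.DataFrame(
        columns=[
            "chrom", "start", "end", "coverage_fraction", "enrichment",
            "run_start", "run_end", "n_bins",
        ]
    )
    out.attrs["bin_size"] = bin_size
    return out


# ---------------------------------------------------------------------------
# Repeat-class overlap

def overlap_fractions(
    eies: pd.DataFrame, rep: pd.DataFrame, classes=DEFAULT_CLASSES
) -> pd.DataFrame:
    """Per-interval repeat-class overlap fractions.

    For each query interval and class, the fraction of its bases covered by
    the union of that class's annotations (same-class overlaps merged first,
    so no base counts twice). Elements are fixed-length (1 kb in the
    discovery pipeline), so fractions are directly comparable without length
    normalization.
    """
    rep = rep.copy()
    rep["cls"] = rep["name"].map(repeat_class)
    merged: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, cls), sub in rep.groupby(["chrom", "cls"]):
        merged[(chrom, cls)] = merge_intervals(sub["start"], sub["end"])
    rows = []
    for r in eies.itertuples():
        length = r.end - r.start
        if length <= 0:
            raise DataError(f"zero-length interval {r.chrom}:{r.start}-{r.end}")
        row = {"chrom": r.chrom, "start": r.start, "end": r.end}
        for cls in classes:
            ms, me = merged.get((r.chrom, cls), (np.array([]), np.array([])))
            row[cls] = _covered_bp(r.start, r.end, ms, me) / length
        rows.append(row)
    return pd.DataFrame(rows)


def genome_class_fraction(
    rep: pd.DataFrame, chrom_lengths: dict[str, int], classes=DEFAULT_CLASSES
) -> dict[str, float]:
    """Fraction of the genome covered by each repeat class (merged bp / total bp)."""
    total = sum(chrom_lengths.values())
    rep = rep.copy()
    rep["cls"] = rep["name"].map(repeat_class)
    for r in rep.itertuples():
        if r.chrom not in chrom_lengths:
            raise DataError(f"annotation on unknown chromosome {r.chrom}")
        if r.end > chrom_lengths[r.chrom] or r.start < 0:
            raise DataError(f"interval {r.chrom}:{r.start}-{r.end} beyond chromosome end")
    out = {}
    for cls in classes:
        covered = 0
        sub = rep[rep["cls"] == cls]
        for chrom, s in sub.groupby("chrom"):
            ms, me = merge_intervals(s["start"], s["end"])
            covered += int((me - ms).sum())
        out[cls] = covered / total
    return out


# ---------------------------------------------------------------------------
# Long-read support

def _overlaps_any(chrom, start, end, intervals) -> bool:
    return any(c == chrom and start < e and s < end for c, s, e in intervals)


def ecdna_support_counts(
    reads: pd.DataFrame,
    eies: pd.DataFrame,
    ecdna: pd.DataFrame,
    coverage_baseline: float = 12.1,
) -> pd.DataFrame:
    """Count reads linking each EIE to the ecDNA amplicon.

    A read supports an EIE iff at least one of its alignment blocks overlaps
    the EIE (≥1 bp) and at least one block overlaps any ecDNA cycle
    interval. Counts are distinct read ids, reported raw and as
    log10(1 + x); ``above_baseline`` flags elements whose raw count exceeds
    ``coverage_baseline`` (the genome-wide average read coverage), the
    heuristic separating ecDNA-amplified elements from purely chromosomal
    copies.
    """
    ec = [(r.chrom, r.start, r.end) for r in ecdna.itertuples()]
    on_ecdna: set = set()
    by_read: dict = {}
    for r in reads.itertuples():
        by_read.setdefault(r.read_id, []).append((r.chrom, r.start, r.end))
        if _overlaps_any(r.chrom, r.start, r.end, ec):
            on_ecdna.add(r.read_id)
    rows = []
    for e in eies.itertuples():
        supp = {
            rid
            for rid, blocks in by_read.items()
            if rid in on_ecdna
            and _overlaps_any(e.chrom, e.start, e.end, blocks)
        }
        raw = len(supp)
        rows.append(
            {
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "raw_count": raw,
                "log10_count": float(np.log10(1 + raw)),
                "above_baseline": raw > coverage_baseline,
            }
        )
    return pd.DataFrame(rows)
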