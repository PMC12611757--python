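"""Tiling FISH/ORCA probe design with composition and homology filters.

40-mer candidates are tiled across each target region, filtered on GC
content (20–80%), nearest-neighbour melting temperature (65–90 °C),
genome uniqueness (no shared 17-mer with other genomic regions, both
strands) and repeat homology (no shared 14-mer with a repeat-consensus
library), then appended with a 20-mer readout barcode per target region.

Checking all k-mers of length exactly k implements the "k or longer" rule:
any longer shared substring necessarily contains a shared k-mer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .io import ConfigError, DataError

__all__ = [
    "ProbeConfig",
    "KmerIndex",
    "tile_candidates",
    "gc_and_tm",
    "homology_filters",
    "assemble_library",
    "design_probes",
    "select_nonoverlapping",
    "melting_temperature",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ProbeConfig:
    """Probe constraints; defaults are the 40-mer ORCA design rules.

    Tm model: unified nearest-neighbour thermodynamics (Allawi & SantaLucia
    parameter set) at 50 mM Na+ and 250 nM oligo, pinned here so runs are
    reproducible; the wide 65–90 °C band makes pass/fail largely insensitive
    to the exact parameter choice.
    """

    probe_len: int = 40
    gc_min: float = 0.20
    gc_max: float = 0.80
    tm_min: float = 65.0
    tm_max: float = 90.0
    unique_k: int = 17
    repeat_k: int = 14
    barcode_len: int = 20
    tiling_step: int = 1
    tm_model: str = "nn_unified_Na50mM_250nM"

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ConfigError("need 0 <= gc_min < gc_max <= 1")
        if self.unique_k > self.probe_len or self.repeat_k > self.probe_len:
            raise ConfigError("k-mer sizes must not exceed probe_len")
        if min(self.probe_len, self.unique_k, self.repeat_k, self.barcode_len, self.tiling_step) < 1:
            raise ConfigError("lengths and step must be positive")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def melting_temperature(seq: str, cfg: ProbeConfig | None = None) -> float:
    """Nearest-neighbour Tm (°C), unified parameters, 50 mM Na+, 250 nM oligo."""
    return float(
        _mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=50, dnac1=250, dnac2=0, saltcorr=5)
    )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for base, val in zip(b"ACGT", range(4)):
        code[arr == base] = val
    return code


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all ACGT-only k-mers of ``seq`` (forward strand)."""
    code = _encode(seq)
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    v = code[:n].copy()
    ok = code[:n] >= 0
    for i in range(1, k):
        v = v * 4 + code[i : i + n]
        ok &= code[i : i + n] >= 0
    return v[ok]


class KmerIndex:
    """Sorted-array membership index over the k-mers of a sequence set.

    Both strands are indexed. ``exclude`` masks a genomic footprint
    (chrom, start, end): any window overlapping it contributes no k-mers,
    so a target region is not counted as its own off-target site.
    """

    def __init__(self, seqs: dict[str, str], k: int, exclude: tuple[str, int, int] | None = None):
        if k < 1 or k > 31:
            raise ConfigError("k must be in 1..31")
        self.k = k
        codes = []
        for name, seq in seqs.items():
            if exclude is not None and name == exclude[0]:
                s, e = exclude[1], exclude[2]
                # blank out the footprint; N-containing windows are skipped,
                # so windows straddling the boundary drop out too
                seq = seq[:s] + "N" * max(0, min(e, len(seq)) - s) + seq[e:]
            for strand_seq in (seq, reverse_complement(seq)):
                codes.append(_kmer_codes(strand_seq, k))
        self._codes = np.unique(np.concatenate(codes)) if codes else np.empty(0, dtype=np.int64)

    def __contains__(self, kmer: str) -> bool:
        c = _kmer_codes(kmer, self.k)
        return bool(len(c)) and self.contains(c).any()

    def contains(self, codes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._codes, codes)
        idx = np.clip(idx, 0, max(len(self._codes) - 1, 0))
        if len(self._codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        return self._codes[idx] == codes

    def any_hit(self, seq: str) -> bool:
        c = _kmer_codes(seq, self.k)
        return bool(self.contains(c).any()) if len(c) else False


def _add_flag(df: pd.DataFrame, mask, label: str) -> None:
    df.loc[mask & (df["flags"] != ""), "flags"] += ";" + label
    df.loc[mask & (df["flags"] == ""), "flags"] = label


def tile_candidates(region_seq: str, cfg: ProbeConfig, region: str = "region") -> pd.DataFrame:
    """All probe-length windows at ``tiling_step`` offsets across a region."""
    L = len(region_seq)
    if L < cfg.probe_len:
        raise DataError(f"region {region!r} shorter ({L}) than probe_len {cfg.probe_len}")
    seq = region_seq.upper()
    offsets = range(0, L - cfg.probe_len + 1, cfg.tiling_step)
    return pd.DataFrame(
        {
            "region": region,
            "offset": list(offsets),
            "sequence": [seq[o : o + cfg.probe_len] for o in offsets],
            "flags": "",
        }
    )


def gc_and_tm(candidates: pd.DataFrame, cfg: ProbeConfig) -> pd.DataFrame:
    """GC fraction and nearest-neighbour Tm with out-of-band flags.

    Sequences containing IUPAC ambiguity codes are flagged ``ambiguous``
    (Tm undefined) rather than raising.
    """
    out = candidates.copy()
    gc, tm = [], []
    for seq in out["sequence"]:
        if set(seq) - set("ACGT"):
            gc.append(np.nan)
            tm.append(np.nan)
            continue
        gc.append((seq.count("G") + seq.count("C")) / len(seq))
        tm.append(melting_temperature(seq, cfg))
    out["gc"] = gc
    out["tm"] = tm
    ambiguous = out["gc"].isna()
    _add_flag(out, ambiguous, "ambiguous")
    _add_flag(out, ~ambiguous & ((out["gc"] < cfg.gc_min) | (out["gc"] > cfg.gc_max)), "gc")
    _add_flag(out, ~ambiguous & ((out["tm"] < cfg.tm_min) | (out["tm"] > cfg.tm_max)), "tm")
    return out


def homology_filters(
    candidates: pd.DataFrame,
    genome_index: KmerIndex | None,
    repeat_index: KmerIndex | None,
    cfg: ProbeConfig,
) -> pd.DataFrame:
    """Flag candidates sharing a ``unique_k``-mer with the genome outside
    their own region (``non_unique``) or a ``repeat_k``-mer with the repeat
    library (``repeat_hit``)."""
    if genome_index is None and repeat_index is None:
        raise DataError("homology filtering requires at least one k-mer index")
    if genome_index is not None and genome_index.k != cfg.unique_k:
        raise DataError("genome index k does not match cfg.unique_k")
    if repeat_index is not None and repeat_index.k != cfg.repeat_k:
        raise DataError("repeat index k does not match cfg.repeat_k")
    out = candidates.copy()
    if genome_index is not None:
        hit = out["sequence"].map(genome_index.any_hit)
        _add_flag(out, hit, "non_unique")
    if repeat_index is not None:
        hit = out["sequence"].map(repeat_index.any_hit)
        _add_flag(out, hit, "repeat_hit")
    return out


def assemble_library(
    candidates: pd.DataFrame, barcodes: dict[str, str], cfg: ProbeConfig
) -> pd.DataFrame:
    """Append each region's readout barcode to its passing candidates.

    Probe = barcode + targeting sequence. Barcodes must be pairwise
    distinct and of ``barcode_len``.
    """
    if len(set(barcodes.values())) != len(barcodes):
        raise DataError("duplicate barcodes across regions")
    for region, bc in barcodes.items():
        if len(bc) != cfg.barcode_len:
            raise DataError(f"barcode for {region!r} is not {cfg.barcode_len} nt")
    passing = candidates[candidates["flags"] == ""]
    if len(passing) == 0:
        warnings.warn("no passing candidates; probe library is empty", stacklevel=2)
    rows = []
    for r in passing.itertuples():
        if r.region not in barcodes:
            raise DataError(f"no barcode supplied for region {r.region!r}")
        bc = barcodes[r.region]
        rows.append(
            {
                "region": r.region,
                "offset": r.offset,
                "barcode": bc,
                "targeting_seq": r.sequence,
                "probe_seq": bc + r.sequence,
            }
        )
    return pd.DataFrame(rows, columns=["region", "offset", "barcode", "targeting_seq", "probe_seq"])


def select_nonoverlapping(candidates: pd.DataFrame, cfg: ProbeConfig) -> pd.DataFrame:
    """Optional greedy leftmost-first non-overlapping subset per region."""
    keep = []
    for _, sub in candidates.sort_values(["region", "offset"]).groupby("region"):
        last_end = -1
        for r in sub.itertuples():
            if r.offset >= last_end:
                keep.append(r.Index)
                last_end = r.offset + cfg.probe_len
    return candidates.loc[keep]


def design_probes(
    genome: dict[str, str],
    regions: pd.DataFrame,
    repeat_lib: dict[str, str] | None,
    barcodes: dict[str, str],
    cfg: ProbeConfig | None = None,
) -> dict:
    """End-to-end design over BED-style ``regions`` (chrom, start, end, name).

    Returns ``candidates`` (all windows with flags) and ``library``
    (assembled barcode+targeting probes).
    """
    cfg = cfg or ProbeConfig()
    repeat_index = KmerIndex(repeat_lib, cfg.repeat_k) if repeat_lib else None
    all_cands = []
    for r in regions.itertuples():
        name = getattr(r, "name", None) or f"{r.chrom}:{r.start}-{r.end}"
        seq = genome[r.chrom][r.start : r.end]
        cand = tile_candidates(seq, cfg, region=name)
        cand = gc_and_tm(cand, cfg)
        gidx = KmerIndex(genome, cfg.unique_k, exclude=(r.chrom, r.start, r.end))
        cand = homology_filters(cand, gidx, repeat_index, cfg)
        all_cands.append(cand)
    candidates = pd.concat(all_cands, ignore_index=True)
    library = assemble_library(candidates, barcodes, cfg)
    return {"candidates": candidates, "library": library}
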