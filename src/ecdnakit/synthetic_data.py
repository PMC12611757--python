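"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators emulate the three experimental arms:

* :func:`simulate_nuclei` — multiplexed-FISH spot tables: nuclei modelled as
  4-µm spheres containing a Poisson number of ecDNA molecules that gather in
  a small number of hubs; each labelled locus is detected on each ecDNA with
  a fixed probability and scattered around it. A hub-free CSR mode
  (``hub_rate=None``) places every ecDNA i.i.d. uniform in the sphere, which
  makes complete spatial randomness exact and is the calibration condition
  for the spatial statistics.
* :func:`simulate_guide_screen` — NTC-anchored guide-count matrices with
  planted per-element log2 growth effects, negative-binomial counting noise
  and log-normal baseline abundance heterogeneity.
* :func:`simulate_genome_and_contacts` — a toy genome with non-overlapping
  repeat-class intervals placed to hit target genome fractions, a binned
  contact map with a cis amplicon block and trans stripes at planted
  ecDNA-interacting-element (EIE) sites, and a long-read alignment-block
  table with a configurable fraction of reads linking an EIE to the ecDNA.

Randomness: one root seed per config; each generator derives an independent
numpy PCG64 stream via ``SeedSequence(seed, spawn_key=(crc32(name),))`` so
adding a component never perturbs the draws of another. Fixed seed gives
byte-identical output across platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, SPOT_COLUMNS

__all__ = [
    "NucleusSimConfig",
    "ScreenSimConfig",
    "GenomeSimConfig",
    "component_rng",
    "uniform_in_sphere",
    "simulate_nuclei",
    "simulate_guide_screen",
    "simulate_genome_and_contacts",
]


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, platform-stable stream for one named component."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Exactly uniform points in a ball by rejection from the bounding cube.

    Rejected draws are resampled (never projected), so the CSR property is
    exact.
    """
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 3))
        keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def _gaussian_in_sphere(
    rng: np.random.Generator, centres: np.ndarray, sigma: float, radius: float
) -> np.ndarray:
    """Centres + isotropic Gaussian offsets, resampling any point that lands
    outside the sphere (centres must lie inside)."""
    if sigma == 0 or len(centres) == 0:
        return centres.copy()
    pts = centres + rng.normal(0.0, sigma, size=centres.shape)
    bad = np.einsum("ij,ij->i", pts, pts) > radius**2
    while bad.any():
        pts[bad] = centres[bad] + rng.normal(0.0, sigma, size=(bad.sum(), 3))
        bad_idx = np.flatnonzero(bad)
        still = np.einsum("ij,ij->i", pts[bad_idx], pts[bad_idx]) > radius**2
        bad = np.zeros(len(pts), dtype=bool)
        bad[bad_idx[still]] = True
    return pts


# ---------------------------------------------------------------------------
# Nuclei / FISH spots

@dataclass
class NucleusSimConfig:
    """Parameters of the spherical-nucleus ecDNA hub model.

    ``nucleus_radius`` (µm) defaults to the 4-µm average cell radius used for
    the random-point null. ``mean_ecdna`` defaults to 29, the mean copy
    number observed for the amplified oncogene locus. ``hub_rate=None``
    disables hub structure entirely (pure CSR placement of ecDNAs).
    """

    n_cells: int
    nucleus_radius: float = 4.0
    loci: tuple[str, ...] = ("MYC", "PVT1", "EIE14")
    mean_ecdna: float = 29.0
    hub_rate: float | None = 3.0
    hub_sigma: float = 0.1
    locus_sigma: float = 0.05
    detect_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if self.nucleus_radius <= 0:
            raise ConfigError("nucleus_radius must be positive")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ConfigError("detect_prob must lie in [0, 1]")
        if (self.hub_rate is not None and self.hub_rate < 0) or self.hub_sigma < 0:
            raise ConfigError("hub_rate and hub_sigma must be non-negative")
        if self.locus_sigma < 0:
            raise ConfigError("locus_sigma must be non-negative")
        if self.mean_ecdna < 0:
            raise ConfigError("mean_ecdna must be non-negative")


def simulate_nuclei(config: NucleusSimConfig) -> pd.DataFrame:
    """Simulate per-cell 3D spot tables.

    Per cell: ecDNA count ~ Poisson(``mean_ecdna``); hub count
    ~ 1 + Poisson(``hub_rate``) with hub centres uniform in the sphere; each
    ecDNA joins a uniformly chosen hub at hub centre + N(0, ``hub_sigma``²I);
    each locus is present on each ecDNA with probability ``detect_prob`` at
    ecDNA position + N(0, ``locus_sigma``²I). All placements are confined to
    the sphere by resampling.

    Returns
    -------
    DataFrame with columns cell_id, locus, x_um, y_um, z_um; the configured
    cell count is recorded in ``df.attrs["n_cells"]`` (cells with no detected
    spot have no rows).
    """
    rng = component_rng(config.seed, "nuclei")
    R = config.nucleus_radius
    rows: list[pd.DataFrame] = []
    for cell in range(config.n_cells):
        n_ec = rng.poisson(config.mean_ecdna)
        if config.hub_rate is None:
            ec_pos = uniform_in_sphere(rng, n_ec, R)
        else:
            n_hub = 1 + rng.poisson(config.hub_rate)
            hubs = uniform_in_sphere(rng, n_hub, R)
            assign = rng.integers(0, n_hub, size=n_ec)
            ec_pos = _gaussian_in_sphere(rng, hubs[assign], config.hub_sigma, R)
        for locus in config.loci:
            if n_ec == 0:
                continue
            present = rng.random(n_ec) < config.detect_prob
            pts = _gaussian_in_sphere(rng, ec_pos[present], config.locus_sigma, R)
            if len(pts) == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": f"cell{cell:05d}",
                        "locus": locus,
                        "x_um": pts[:, 0],
                        "y_um": pts[:, 1],
                        "z_um": pts[:, 2],
                    }
                )
            )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=SPOT_COLUMNS)
    df.attrs["n_cells"] = config.n_cells
    df.attrs["loci"] = list(config.loci)
    return df


# ---------------------------------------------------------------------------
# CRISPRi screen

@dataclass
class ScreenSimConfig:
    """Pooled CRISPRi growth-screen generator.

    Defaults mirror the screen design: 4–6 guides per element (5 here),
    125 non-targeting controls, timepoints 0/3/14/30 days. ``effects``
    plants explicit per-element log2 growth effects per day and overrides
    the Normal(effect_mean, effect_sd) draw. ``baseline_sd`` is the log2 s.d.
    of per-guide baseline abundance (library composition heterogeneity).
    """

    n_elements: int = 36
    guides_per_element: int = 5
    n_ntc: int = 125
    effect_mean: float = 0.0
    effect_sd: float = 0.0
    effects: tuple[float, ...] | None = None
    timepoints: tuple[float, ...] = (0.0, 3.0, 14.0, 30.0)
    depth: float = 1_000_000.0
    dispersion: float = 0.01
    replicates: int = 2
    baseline_sd: float = 0.25
    specificity_beta: tuple[float, float] = (8.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_elements", "guides_per_element", "n_ntc", "replicates"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigError("timepoints must be strictly increasing")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.effects is not None and len(self.effects) != self.n_elements:
            raise ConfigError("effects must have one entry per element")


def _nb_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # gamma-Poisson mixture: var = mu + dispersion * mu^2
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam)


def simulate_guide_screen(config: ScreenSimConfig) -> pd.DataFrame:
    """Simulate a guide × sample count table.

    Expected abundance of guide g at day t is proportional to
    ``w_g * 2**(effect_e * t)`` with NTC effect 0, where ``w_g`` is a
    log-normal baseline weight; counts are negative-binomial with the given
    overdispersion, scaled so each sample totals ~``depth``.
    """
    rng = component_rng(config.seed, "screen")
    n_t = config.n_elements * config.guides_per_element
    n = n_t + config.n_ntc
    elements = [
        f"EIE{e + 1:03d}" for e in range(config.n_elements) for _ in range(config.guides_per_element)
    ] + ["NTC"] * config.n_ntc
    is_ntc = np.array([e == "NTC" for e in elements])
    guide_ids = [
        f"{el}_g{i % config.guides_per_element + 1}" if el != "NTC" else f"NTC_g{i - n_t + 1}"
        for i, el in enumerate(elements)
    ]
    if config.effects is not None:
        eff_elem = np.asarray(config.effects, dtype=float)
    else:
        eff_elem = rng.normal(config.effect_mean, config.effect_sd, size=config.n_elements)
    effect = np.concatenate(
        [np.repeat(eff_elem, config.guides_per_element), np.zeros(config.n_ntc)]
    )
    baseline = 2.0 ** rng.normal(0.0, config.baseline_sd, size=n)
    a, b = config.specificity_beta
    specificity = rng.beta(a, b, size=n)

    out = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "element": elements,
            "is_ntc": is_ntc,
            "specificity": np.round(specificity, 4),
        }
    )
    for t in config.timepoints:
        frac = baseline * 2.0 ** (effect * t)
        frac = frac / frac.sum()
        for r in range(1, config.replicates + 1):
            mu = config.depth * frac
            col = f"d{t:g}_r{r}"
            out[col] = _nb_counts(rng, mu, config.dispersion)
    out.attrs["effects"] = {f"EIE{e + 1:03d}": float(eff_elem[e]) for e in range(config.n_elements)}
    return out


# ---------------------------------------------------------------------------
# Toy genome, repeats, contact map, read blocks

@dataclass
class GenomeSimConfig:
    """Toy genome with planted repeat classes, amplicon and EIE stripes.

    The contact map is restricted to amplicon-anchored pairs (amplicon×all
    bins), which is the part of the matrix the trans-stripe caller reads:
    Poisson(``background_contact_rate``) per amplicon–trans bin pair,
    Poisson(``stripe_contact_rate``) where the trans bin is a planted EIE,
    and Poisson(``cis_contact_rate``) inside the amplicon block.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrA": 400_000, "chrB": 1_000_000}
    )
    repeat_density: dict[str, float] = field(
        default_factory=lambda: {"LINE": 0.20, "SINE": 0.13, "LTR": 0.08}
    )
    eie_sites: tuple[tuple[str, int, int], ...] = (
        ("chrB", 100_000, 101_000),
        ("chrB", 300_000, 301_000),
        ("chrB", 500_000, 501_000),
        ("chrB", 700_000, 701_000),
        ("chrB", 900_000, 901_000),
    )
    amplicon: tuple[tuple[str, int, int], ...] = (("chrA", 100_000, 300_000),)
    stripe_contact_rate: float = 20.0
    background_contact_rate: float = 1.0
    cis_contact_rate: float = 50.0
    bin_size: int = 1000
    n_reads_per_eie: int = 30
    read_support_fraction: float = 0.6
    read_length: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")
        for rate in (self.stripe_contact_rate, self.background_contact_rate, self.cis_contact_rate):
            if rate < 0:
                raise ConfigError("contact rates must be non-negative")
        for chrom, length in self.chrom_lengths.items():
            if length % self.bin_size:
                raise ConfigError(f"length of {chrom} not a multiple of bin_size")
        for chrom, s, e in list(self.eie_sites) + list(self.amplicon):
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"interval on unknown chromosome {chrom}")
            if not (0 <= s < e <= self.chrom_lengths[chrom]):
                raise ConfigError(f"interval {chrom}:{s}-{e} outside chromosome")
        amp_chroms = {c for c, _, _ in self.amplicon}
        for chrom, s, e in self.eie_sites:
            for ac, a_s, a_e in self.amplicon:
                if chrom == ac and s < a_e and a_s < e:
                    raise ConfigError(f"eie site {chrom}:{s}-{e} overlaps the amplicon")
        if not 0.0 <= self.read_support_fraction <= 1.0:
            raise ConfigError("read_support_fraction must lie in [0, 1]")
        self._amp_chroms = amp_chroms


def _place_repeats(rng, chrom_lengths, repeat_density) -> pd.DataFrame:
    """Scan each chromosome left to right, alternating exponential gaps with
    repeat intervals assigned to the class furthest below its target density.
    Classes never overlap; each class stops once its target is reached, so the
    realized per-class genome fraction lands within one interval of target."""
    classes = list(repeat_density)
    total = sum(chrom_lengths.values())
    target = {c: repeat_density[c] * total for c in classes}
    covered = {c: 0 for c in classes}
    rho = sum(repeat_density.values())
    len_mean = 350.0
    mean_gap = max(1.0, (1.0 - rho) * len_mean / max(rho, 1e-9) * 0.7)
    recs = []
    for chrom, L in chrom_lengths.items():
        pos = 0
        while pos < L:
            deficits = {c: target[c] - covered[c] for c in classes}
            if max(deficits.values()) <= 0:
                break
            pos += 1 + int(rng.exponential(mean_gap))
            cls = max(classes, key=lambda c: deficits[c] / max(target[c], 1.0))
            length = 50 + int(rng.gamma(2.0, (len_mean - 50) / 2.0))
            end = min(pos + length, L)
            if end <= pos:
                break
            sub = ["L1", "L2", "Alu", "MIR", "ERVL", "ERV1"][rng.integers(0, 6)]
            recs.append((chrom, pos, end, f"{cls}/{sub}"))
            covered[cls] += end - pos
            pos = end
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])


def simulate_genome_and_contacts(config: GenomeSimConfig) -> dict:
    """Generate the toy-genome bundle.

    Returns a dict with keys ``genome`` (chrom → sequence), ``repeats``
    (BED-style DataFrame, class in ``name``), ``contacts``
    (:class:`~ecdnakit.eie_discovery.ContactMatrix`), ``reads`` (alignment
    blocks), ``ecdna`` (interval DataFrame; the amplicon doubles as the
    reconstructed ecDNA cycle) and ``eie_truth`` (planted sites).
    """
    from .eie_discovery import ContactMatrix

    rng = component_rng(config.seed, "genome")
    bs = config.bin_size

    genome = {
        chrom: "".join(
            np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=length)]
        )
        for chrom, length in config.chrom_lengths.items()
    }
    repeats = _place_repeats(rng, config.chrom_lengths, config.repeat_density)

    amp_bins = [
        (c, s) for c, a_s, a_e in config.amplicon for s in range(a_s, a_e, bs)
    ]
    eie_bins = {(c, s - s % bs) for c, s, _ in config.eie_sites}
    trans_bins = [
        (chrom, s)
        for chrom, L in config.chrom_lengths.items()
        if chrom not in config._amp_chroms
        for s in range(0, L, bs)
    ]

    c1, s1, c2, s2 = [], [], [], []
    rates = []
    for ac, a_start in amp_bins:
        for tc, t_start in trans_bins:
            c1.append(ac); s1.append(a_start); c2.append(tc); s2.append(t_start)
            rates.append(
                config.stripe_contact_rate
                if (tc, t_start) in eie_bins
                else config.background_contact_rate
            )
    # cis amplicon block (upper triangle only; the matrix is symmetric)
    for i, (ac, a_start) in enumerate(amp_bins):
        for bc, b_start in amp_bins[i:]:
            c1.append(ac); s1.append(a_start); c2.append(bc); s2.append(b_start)
            rates.append(config.cis_contact_rate)
    counts = rng.poisson(np.array(rates, dtype=float))
    pairs = pd.DataFrame(
        {"chrom1": c1, "start1": s1, "chrom2": c2, "start2": s2, "count": counts}
    )
    pairs = pairs[pairs["count"] > 0].reset_index(drop=True)
    contacts = ContactMatrix(bin_size=bs, pairs=pairs)

    reads = _simulate_reads(rng, config)
    ecdna = pd.DataFrame(list(config.amplicon), columns=["chrom", "start", "end"])
    eie_truth = pd.DataFrame(list(config.eie_sites), columns=["chrom", "start", "end"])
    eie_truth["name"] = [f"EIE{i + 1}" for i in range(len(eie_truth))]
    return {
        "genome": genome,
        "repeats": repeats,
        "contacts": contacts,
        "reads": reads,
        "ecdna": ecdna,
        "eie_truth": eie_truth,
    }


def _simulate_reads(rng, config: GenomeSimConfig) -> pd.DataFrame:
    rows = []
    rid = 0
    amp = list(config.amplicon)
    for chrom, s, e in config.eie_sites:
        for _ in range(config.n_reads_per_eie):
            rid += 1
            name = f"read{rid:06d}"
            lo = max(0, s - rng.integers(0, config.read_length // 4))
            hi = min(config.chrom_lengths[chrom], e + int(rng.integers(0, config.read_length // 4)))
            rows.append((name, chrom, int(lo), int(hi)))
            if rng.random() < config.read_support_fraction:
                ac, a_s, a_e = amp[rng.integers(0, len(amp))]
                b_s = int(rng.integers(a_s, a_e - 1))
                b_e = min(a_e, b_s + 1 + int(rng.integers(1, config.read_length)))
                rows.append((name, ac, b_s, b_e))
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end"])
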