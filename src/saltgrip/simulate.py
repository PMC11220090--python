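"""Synthetic data generator for the whole pipeline.

The generator emulates the statistical structure that the downstream analyses
assume: a latent per-motif retention value r in [0, 1] drives salt-dependent
occupancy loss through a logistic law, a transient-binding term models
crosslink accumulation in X-ChIP (compressing the retention spectrum),
auxiliary-motif presence is logit-coupled to retention, zinc depletion (TPA)
shifts the effective stringency threshold, and contact maps carry loops and
boundaries whose perturbation stability depends on anchor retention.

Occupied motifs emit short protected fragments (~30-40 bp) spanning a fixed
footprint; everything else is uniform background.  All randomness flows from
``SimConfig.seed`` plus a per-condition stream tag, so every ``simulate_*``
call is deterministic under a fixed configuration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ContactMatrix, FragmentSet, SyntheticTruth

# Planted consensus sequences.  The core motif (C-motif) stands in for a
# zinc-finger TF's canonical recognition sequence; U-/D-motifs are the
# upstream/downstream auxiliary motifs.  Exact instances are written into the
# random genome so PWM scanning can rediscover them.
C_MOTIF = "CCACCAGGGGGCGC"
U_MOTIF = "CTAGGTGCA"
D_MOTIF = "GGAGGCAGA"

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Lengths are bp; rates and slopes are unitless.  salt_levels are the
    logistic stringency thresholds theta_c, one per salt condition, strictly
    increasing (they play the role of 75/150/225 mM NaCl).
    """

    genome_length: int = 400_000
    n_chroms: int = 2
    n_motifs: int = 2000
    min_spacing: int = 300
    footprint_len: int = 35
    frag_len_mean: float = 35.0
    frag_len_sd: float = 3.0
    background_frag_mean: float = 80.0
    background_frag_sd: float = 25.0
    depth: int = 150_000
    frags_per_site: float = 80.0
    salt_levels: tuple[float, ...] = (0.2, 0.5, 0.8)
    logistic_slope: float = 10.0
    crosslink_gain: float = 1.0
    transient_rate: float = 2.0
    aux_logit_slope: float = 4.0
    tpa_slope: float = 0.3
    contact_resolution: int = 2000
    contact_intensity: float = 100.0
    loop_count: int = 60
    loop_strength: float = 3.0
    boundary_count: int = 24
    insulation_depth: float = 2.0
    insulation_range: int = 8
    r_crit: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.salt_levels) < 1 or any(
            b <= a for a, b in zip(self.salt_levels, self.salt_levels[1:])
        ):
            raise ValueError("salt_levels must be strictly increasing")
        for name in (
            "genome_length", "n_chroms", "n_motifs", "min_spacing",
            "footprint_len", "frag_len_mean", "frag_len_sd",
            "background_frag_mean", "background_frag_sd", "frags_per_site",
            "contact_resolution", "contact_intensity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth < 0 or self.loop_count < 0 or self.boundary_count < 0:
            raise ValueError("counts must be >= 0")
        if self.footprint_len >= self.genome_length:
            raise ValueError("footprint_len must be smaller than genome_length")
        if self.transient_rate <= 0:
            raise ValueError("transient_rate must be positive")

    @property
    def salt_labels(self) -> tuple[str, ...]:
        if len(self.salt_levels) == 3:
            return ("75mM", "150mM", "225mM")
        return tuple(f"salt{i + 1}" for i in range(len(self.salt_levels)))

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chroms))

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}

    def conditions(self) -> tuple[str, ...]:
        return self.salt_labels + ("xchip", "dmso", "tpa")


def _rng(config: SimConfig, *tags: str) -> np.random.Generator:
    ints = [config.seed & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# truth + genome


def _place_motifs(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    """Place motifs >= min_spacing apart, uniform given the spacing constraint."""
    w = len(C_MOTIF)
    margin = 40  # room for auxiliary motifs and footprints at chrom edges
    usable = config.genome_length - 2 * margin - w
    per_chrom = np.full(config.n_chroms, config.n_motifs // config.n_chroms)
    per_chrom[: config.n_motifs % config.n_chroms] += 1
    rows = []
    for chrom, n in zip(config.chrom_names, per_chrom):
        slack = usable - (n - 1) * config.min_spacing if n else usable
        if n and slack < 0:
            raise ValueError(
                f"cannot place {n} motifs with min_spacing={config.min_spacing} "
                f"on a {config.genome_length} bp chromosome"
            )
        u = np.sort(rng.random(n) * slack)
        starts = margin + (u + np.arange(n) * config.min_spacing).astype(int)
        strands = rng.choice(["+", "-"], size=n)
        for s, st in zip(starts, strands):
            rows.append((chrom, int(s), int(s) + w, st))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    frame.insert(0, "motif_id", [f"m{i:05d}" for i in range(len(frame))])
    return frame


def simulate_truth(
    config: SimConfig,
) -> tuple[pd.DataFrame, SyntheticTruth, dict[str, str]]:
    """Draw the latent truth, place motifs, and emit a genome sequence.

    Returns (catalog, truth, genome).  The catalog has one row per motif with
    coordinates, strand, and planted auxiliary flags; retention r is
    Uniform(0,1) (a continuum, not clusters), the transient-binding rate t is
    Exponential(1/transient_rate), and P(has_U) = sigmoid(aux_logit_slope*(r-0.5)).
    Exact C-motif instances (plus a U-motif 5-6 bp upstream where has_U, and a
    D-motif 5-6 bp downstream where has_D) are written into the genome at the
    motif coordinates, reverse-complemented on the minus strand.
    """
    rng = _rng(config, "truth")
    catalog = _place_motifs(rng, config)
    n = len(catalog)
    r = rng.random(n)
    t = rng.exponential(scale=1.0 / config.transient_rate, size=n)
    has_u = rng.random(n) < _sigmoid(config.aux_logit_slope * (r - 0.5))
    # D-motif presence couples to retention only weakly (half the U slope)
    has_d = rng.random(n) < _sigmoid(0.5 * config.aux_logit_slope * (r - 0.5))
    u_gap = rng.integers(5, 7, size=n)  # 5 or 6 bp upstream
    d_gap = rng.integers(5, 7, size=n)

    genome = {}
    base_arrays = {
        chrom: rng.integers(0, 4, size=config.genome_length)
        for chrom in config.chrom_names
    }
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)

    def plant(arr: np.ndarray, pos: int, seq: str) -> None:
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        arr[pos : pos + len(seq)] = codes

    char_arrays = {
        chrom: alphabet[base_arrays[chrom]].copy() for chrom in config.chrom_names
    }
    for row, (ru, gu, rd, gd) in zip(
        catalog.itertuples(index=False), zip(has_u, u_gap, has_d, d_gap)
    ):
        arr = char_arrays[row.chrom]
        if row.strand == "+":
            plant(arr, row.start, C_MOTIF)
            if ru:
                plant(arr, row.start - gu - len(U_MOTIF), U_MOTIF)
            if rd:
                plant(arr, row.end + gd, D_MOTIF)
        else:
            plant(arr, row.start, revcomp(C_MOTIF))
            if ru:  # upstream on - strand = higher genomic coordinate
                plant(arr, row.end + gu, revcomp(U_MOTIF))
            if rd:
                plant(arr, row.start - gd - len(D_MOTIF), revcomp(D_MOTIF))
    for chrom, arr in char_arrays.items():
        genome[chrom] = arr.tobytes().decode()

    catalog = catalog.assign(has_U=has_u, has_D=has_d, u_gap=u_gap, d_gap=d_gap)
    motifs = pd.DataFrame(
        {
            "motif_id": catalog["motif_id"],
            "retention": r,
            "transient": t,
            "has_U": has_u,
            "has_D": has_d,
        }
    )
    truth = SyntheticTruth(motifs=motifs)
    truth.boundaries, truth.loops = _plan_structure(rng, catalog, motifs, config)
    return catalog, truth, genome


def _plan_structure(
    rng: np.random.Generator,
    catalog: pd.DataFrame,
    motifs: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign loop anchors and boundaries on the first chromosome."""
    res = config.contact_resolution
    nbins = config.genome_length // res
    chrom = config.chrom_names[0]
    on_chrom = catalog[catalog["chrom"] == chrom].reset_index(drop=True)
    motif_bins = ((on_chrom["start"] + on_chrom["end"]) // 2 // res).to_numpy()
    ret = motifs.set_index("motif_id")["retention"]

    # boundaries: half anchored to a motif (their stability tracks that
    # motif's retention under TPA), half unanchored controls whose depth is
    # perturbation-independent
    n_with = config.boundary_count // 2
    n_without = config.boundary_count - n_with
    idx = rng.choice(len(on_chrom), size=min(n_with, len(on_chrom)), replace=False)
    b_rows = []
    used: set[int] = set()
    for i in idx:
        b = int(motif_bins[i])
        if b in used or not (5 <= b < nbins - 5):
            continue
        used.add(b)
        mid = on_chrom.loc[i, "motif_id"]
        b_rows.append((b, mid, float(ret[mid]), config.insulation_depth))
    free_bins = np.array(
        [
            b
            for b in range(5, nbins - 5)
            if all(abs(b - u) > 2 for u in used)
        ]
    )
    ctrl = rng.choice(free_bins, size=min(n_without, len(free_bins)), replace=False)
    for b in ctrl:
        b = int(b)
        used.add(b)
        b_rows.append((b, "", np.nan, config.insulation_depth))
    boundaries = pd.DataFrame(
        b_rows, columns=["bin", "anchor_motif", "anchor_retention", "depth"]
    ).sort_values("bin").reset_index(drop=True)

    # loops: anchor bin at a motif, partner bin at a fixed-range separation
    n_loops = min(config.loop_count, len(on_chrom))
    pick = rng.choice(len(on_chrom), size=n_loops, replace=False)
    # loop separations scale with the matrix so small genomes still get loops
    sep_lo = max(4, min(12, nbins // 6))
    sep_hi = max(sep_lo + 2, min(60, nbins // 2))
    l_rows = []
    for i in pick:
        bi = int(motif_bins[i])
        sep = int(rng.integers(sep_lo, sep_hi))
        bj = bi + sep if bi + sep < nbins - 4 else bi - sep
        if bj < 4:
            continue
        lo, hi = (bi, bj) if bi < bj else (bj, bi)
        mid = on_chrom.loc[i, "motif_id"]
        l_rows.append((lo, hi, mid, float(ret[mid]), config.loop_strength))
    loops = pd.DataFrame(
        l_rows, columns=["bin_i", "bin_j", "anchor_motif", "anchor_retention", "strength"]
    ).sort_values(["bin_i", "bin_j"]).reset_index(drop=True)
    return boundaries, loops


# ---------------------------------------------------------------------------
# fragment libraries


def occupancy_probability(
    truth: SyntheticTruth, condition: str, config: SimConfig
) -> np.ndarray:
    """Per-motif occupancy probability under one perturbation condition.

    Salt condition c: p = sigmoid(a * (r - theta_c)).
    X-ChIP: p = clip(r + beta * t, 0, 1) — transient binding accumulates.
    DMSO: lowest-salt baseline threshold.  TPA: threshold shifted by tpa_slope.
    """
    r = truth.motifs["retention"].to_numpy()
    a = config.logistic_slope
    labels = config.salt_labels
    if condition in labels:
        theta = config.salt_levels[labels.index(condition)]
        return _sigmoid(a * (r - theta))
    if condition == "xchip":
        t = truth.motifs["transient"].to_numpy()
        return np.clip(r + config.crosslink_gain * t, 0.0, 1.0)
    if condition == "dmso":
        return _sigmoid(a * (r - config.salt_levels[0]))
    if condition == "tpa":
        theta = config.salt_levels[0] + config.tpa_slope
        return _sigmoid(a * (r - theta))
    raise ValueError(
        f"unknown condition {condition!r}; expected one of "
        f"{labels + ('xchip', 'dmso', 'tpa')}"
    )


def simulate_fragment_library(
    truth: SyntheticTruth,
    catalog: pd.DataFrame,
    condition: str,
    config: SimConfig,
) -> FragmentSet:
    """Simulate one sequencing library of footprint + background fragments.

    Each occupied motif emits ~Poisson(frags_per_site) protected fragments
    spanning its footprint, with lengths ~Normal(frag_len_mean, frag_len_sd)
    clipped to [footprint_len-10, footprint_len+25] and both ends jittered
    +/-1 bp; the remaining depth is uniform background.  Total fragments =
    depth (footprint fragments are subsampled in the unlikely event they
    exceed it).
    """
    p = occupancy_probability(truth, condition, config)
    rng = _rng(config, "library", condition)
    n = len(catalog)
    # a library pools many cells, so the footprint fragment count at a site is
    # Poisson with mean (fragments per fully occupied site) x (occupancy prob)
    counts = rng.poisson(config.frags_per_site * p)
    total_fp = int(counts.sum())
    if total_fp > config.depth:
        # keep a uniform subsample so the library size stays at depth
        keep = rng.random(total_fp) < config.depth / total_fp
    else:
        keep = None

    centers = ((catalog["start"] + catalog["end"]) // 2).to_numpy()
    chrom_codes = catalog["chrom"].to_numpy()
    rep = np.repeat(np.arange(n), counts)
    m = len(rep)
    lo = config.footprint_len - 10
    hi = config.footprint_len + 25
    lengths = np.clip(
        np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=m)),
        lo, hi,
    ).astype(int)
    fs = centers[rep] - config.footprint_len // 2  # footprint left edge
    # overhang places the fragment around the footprint: fragments longer than
    # the footprint overhang it uniformly; shorter ones sit inside it
    span = lengths - config.footprint_len
    u = rng.random(m)
    overhang = np.sign(span) * np.floor(u * (np.abs(span) + 1)).astype(int)
    jit_l = rng.integers(-1, 2, size=m)
    jit_r = rng.integers(-1, 2, size=m)
    starts = fs - overhang + jit_l
    ends = starts + lengths + jit_r
    ends = np.maximum(ends, starts + 1)
    frames = [
        pd.DataFrame({"chrom": chrom_codes[rep], "start": starts, "end": ends})
    ]
    if keep is not None:
        frames[0] = frames[0][keep]

    n_bg = max(config.depth - len(frames[0]), 0)
    if n_bg:
        chroms = rng.choice(config.chrom_names, size=n_bg)
        bg_len = np.clip(
            np.rint(
                rng.normal(
                    config.background_frag_mean, config.background_frag_sd, size=n_bg
                )
            ),
            20, 400,
        ).astype(int)
        bg_start = (rng.random(n_bg) * (config.genome_length - bg_len)).astype(int)
        frames.append(
            pd.DataFrame({"chrom": chroms, "start": bg_start, "end": bg_start + bg_len})
        )
    frame = pd.concat(frames, ignore_index=True)
    frame["start"] = frame["start"].clip(lower=0)
    frame["end"] = np.minimum(frame["end"], config.genome_length)
    frame = frame.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )
    return FragmentSet(frame, condition=condition)


# ---------------------------------------------------------------------------
# contact maps


def tpa_attenuation(retention: np.ndarray | float, r_crit: float) -> np.ndarray:
    """Scaling factor min(1, r / r_crit): saturated anchors keep full strength,
    low-retention anchors weaken proportionally."""
    return np.minimum(1.0, np.asarray(retention, dtype=float) / r_crit)


def expected_contacts(
    truth: SyntheticTruth, condition: str, config: SimConfig
) -> np.ndarray:
    """Expected (Poisson-mean) contact matrix before noise."""
    if condition not in ("dmso", "tpa"):
        raise ValueError(f"contact condition must be 'dmso' or 'tpa', got {condition!r}")
    if config.contact_resolution <= 0:
        raise ValueError("contact_resolution must be positive")
    nbins = config.genome_length // config.contact_resolution
    d = np.abs(np.subtract.outer(np.arange(nbins), np.arange(nbins)))
    expected = config.contact_intensity / (d + 1.0)

    for row in truth.loops.itertuples(index=False):
        s = row.strength
        if condition == "tpa":
            s = s * float(tpa_attenuation(row.anchor_retention, config.r_crit))
        # loop factor over a 3x3 pixel neighborhood of the anchor pair
        i0, i1 = max(row.bin_i - 1, 0), min(row.bin_i + 2, nbins)
        j0, j1 = max(row.bin_j - 1, 0), min(row.bin_j + 2, nbins)
        expected[i0:i1, j0:j1] *= 1.0 + s
        expected[j0:j1, i0:i1] *= 1.0 + s

    atten = np.ones((nbins, nbins))
    idx = np.arange(nbins)
    for row in truth.boundaries.itertuples(index=False):
        depth = row.depth
        if condition == "tpa" and row.anchor_motif:
            depth = depth * float(
                tpa_attenuation(row.anchor_retention, config.r_crit)
            )
        crossing = np.logical_and.outer(idx < row.bin, idx >= row.bin)
        # insulation is local: only contacts within insulation_range of the
        # boundary are attenuated, so distant loops are unaffected
        local = np.abs(np.subtract.outer(idx, idx)) <= config.insulation_range
        sel = (crossing | crossing.T) & local
        atten[sel] *= 1.0 + depth
    return expected / atten


def simulate_contact_maps(
    truth: SyntheticTruth, condition: str, config: SimConfig
) -> ContactMatrix:
    """Poisson-sample a symmetric contact matrix for the first chromosome.

    Background decays as (|i-j|+1)^-1; planted loops multiply expected counts
    by (1+strength) over a 3x3 neighborhood; boundaries divide all crossing
    contacts by (1+depth).  Under TPA both effects are attenuated by
    min(1, r_anchor / r_crit).
    """
    expected = expected_contacts(truth, condition, config)
    rng = _rng(config, "contacts", condition)
    upper = rng.poisson(np.triu(expected))
    counts = np.triu(upper) + np.triu(upper, 1).T
    return ContactMatrix(
        chrom=config.chrom_names[0],
        resolution=config.contact_resolution,
        matrix=counts.astype(float),
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: same study conditions, different random stream."""
    return replace(config, seed=int(seed))
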