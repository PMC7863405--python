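"""Fragment-level simulator for spike-in anchored accessibility experiments.

The generator emulates a three-arm design (solvent control plus two
treatment timepoints, ``t8`` and ``t18``) on a small multi-chromosome host
genome.  Regions of distinct archetypes (promoters, enhancers, CTCF sites,
heterochromatin) are placed on the host contigs; treatment multiplies each
region's fragment rate by an archetype-specific fold at each timepoint.

Two spike-in contigs mirror the double spike-in design:

* ``lambda`` is added before transposition, so its yield carries the same
  per-sample technical (transposition-efficiency) factor as the host counts;
* ``phiX`` is added after transposition but before amplification, so it does
  NOT carry that factor.

A PCR-style duplication process then emits exact duplicate fragments across
all contigs (everything is amplified), giving duplicate- and spike-based QC
something real to measure.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic_io import ChromSizes, GenomicInterval
from .window_counting import CountMatrix

LAMBDA_LENGTH = 48_502  # NC_001416.1
PHIX_LENGTH = 5_386

CONDITIONS = ("solvent", "t8", "t18")


@dataclass(frozen=True)
class RegionArchetype:
    """Fragment-rate behaviour of a region class.

    ``base_rate`` is expected fragments per bp per unit depth in solvent;
    ``effect_8h``/``effect_18h`` are multiplicative folds vs solvent.
    """

    kind: str
    base_rate: float
    effect_8h: float = 1.0
    effect_18h: float = 1.0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.effect_8h <= 0 or self.effect_18h <= 0:
            raise ValueError("effect folds must be > 0")

    def fold(self, condition: str) -> float:
        return {"solvent": 1.0, "t8": self.effect_8h, "t18": self.effect_18h}[condition]


@dataclass(frozen=True)
class PlacedRegion:
    interval: GenomicInterval
    archetype: RegionArchetype


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: str
    depth: float
    technical_factor: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.depth <= 0 or self.technical_factor <= 0:
            raise ValueError("depth and technical_factor must be > 0")


@dataclass
class SimulationConfig:
    """Full description of one simulated experiment."""

    chrom_lengths: dict[str, int]
    regions: list[PlacedRegion]
    samples: list[SampleSpec]
    background_rate: float = 2.5e-7
    lambda_mass_fraction: float = 0.02
    phiX_mass_fraction: float = 0.005
    fragment_mean: float = 120.0
    fragment_sd: float = 40.0
    fragment_min: int = 30
    fragment_max: int = 500
    duplication_rate: float = 0.10
    technical_mode: str = "enrichment"  # or "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.duplication_rate < 1):
            raise ValueError("duplication_rate must be in [0, 1)")
        for frac in (self.lambda_mass_fraction, self.phiX_mass_fraction):
            if not (0 < frac < 1):
                raise ValueError("spike mass fractions must be in (0, 1)")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids")
        if self.technical_mode not in ("enrichment", "global"):
            raise ValueError("technical_mode must be 'enrichment' or 'global'")
        for region in self.regions:
            iv = region.interval
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"region on unknown contig {iv.chrom!r}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(
                    f"region {iv.chrom}:{iv.start}-{iv.end} extends past contig end"
                )

    def chrom_sizes(self) -> ChromSizes:
        sizes = dict(self.chrom_lengths)
        sizes["lambda"] = LAMBDA_LENGTH
        sizes["phiX"] = PHIX_LENGTH
        return ChromSizes(sizes=sizes, spike_contigs=frozenset({"lambda", "phiX"}))


@dataclass
class GroundTruth:
    """Planted truth exported with every simulated experiment.

    ``regions`` has one row per placed region with its archetype and true
    folds plus the 1.5-fold direction class; ``samples`` carries the hidden
    per-sample technical factor and realized fragment totals.
    """

    regions: pd.DataFrame
    samples: pd.DataFrame


def direction_class(effect_8h: float, effect_18h: float, fold: float = 1.5) -> str:
    """Trend class implied by the true folds at the given linear threshold."""
    if effect_18h >= fold and effect_8h >= 1.0:
        return "up"
    if effect_18h <= 1.0 / fold and effect_8h <= 1.0:
        return "down"
    return "none"


def default_config(
    n_replicates: int = 3,
    depth: float = 40_000.0,
    technical_sd: float = 0.0,
    seed: int = 0,
    duplication_rate: float = 0.10,
) -> SimulationConfig:
    """The study-condition default: 1 Mb host genome, 3 conditions.

    Archetypes: promoters that gain accessibility (2-fold at 8 h, 4-fold at
    18 h), null promoters/enhancers, CTCF sites that lose accessibility
    (trending to 1.5-fold down at 18 h), and quiescent heterochromatin.
    ``technical_sd`` > 0 draws per-sample lognormal transposition-efficiency
    factors (host + lambda only).
    """
    chrom_lengths = {"chr1": 800_000, "chr2": 600_000, "chr3": 600_000}
    arch = {
        "promoter_gain": RegionArchetype("promoter", 6e-6, 2.0, 4.0),
        "promoter_loss": RegionArchetype("promoter", 6e-6, 0.8, 0.3),
        "promoter_null": RegionArchetype("promoter", 6e-6, 1.0, 1.0),
        "enhancer_null": RegionArchetype("enhancer", 3e-6, 1.0, 1.0),
        "ctcf_loss": RegionArchetype("ctcf_site", 5e-6, 0.85, 1.0 / 1.5),
        "hetero": RegionArchetype("heterochromatin", 5e-8, 1.0, 1.0),
    }
    widths = {
        "promoter_gain": 1_000,
        "promoter_loss": 1_000,
        "promoter_null": 2_000,
        "enhancer_null": 1_000,
        "ctcf_loss": 600,
        "hetero": 5_000,
    }
    # Regular interleaved placement, cycled over chroms.  Gains and losses
    # are mass-balanced so the total host library barely shifts between
    # conditions (few genome-wide changes, as in the emulated biology).
    plan = [
        "promoter_gain",
        "promoter_loss",
        "promoter_null",
        "promoter_loss",
        "enhancer_null",
        "promoter_loss",
        "promoter_null",
        "ctcf_loss",
        "promoter_loss",
        "enhancer_null",
        "promoter_null",
        "hetero",
    ]
    regions: list[PlacedRegion] = []
    for chrom, length in chrom_lengths.items():
        pos = 5_000
        i = 0
        while pos + 6_000 < length - 5_000:
            name = plan[i % len(plan)]
            w = widths[name]
            regions.append(PlacedRegion(GenomicInterval(chrom, pos, pos + w), arch[name]))
            pos += w + 20_000  # wide spacing: ~half the library is background
            i += 1
    rng = np.random.default_rng(seed)
    samples: list[SampleSpec] = []
    for cond in CONDITIONS:
        for r in range(n_replicates):
            tf = float(np.exp(rng.normal(0.0, technical_sd))) if technical_sd > 0 else 1.0
            samples.append(SampleSpec(f"{cond}_rep{r + 1}", cond, depth, tf))
    return SimulationConfig(
        chrom_lengths=chrom_lengths,
        regions=regions,
        samples=samples,
        duplication_rate=duplication_rate,
        seed=seed,
    )


def null_config(
    n_replicates: int = 3,
    depth: float = 40_000.0,
    confounded_factor: float = 1.6,
    technical_sd: float = 0.1,
    seed: int = 0,
) -> SimulationConfig:
    """A no-effect experiment with a condition-confounded technical factor.

    All region folds are 1 (true null everywhere), but treated samples carry
    a ``confounded_factor``-times larger transposition-efficiency factor
    (times lognormal noise).  Because the factor multiplies host and lambda
    counts alike, lambda-based factors can rescue the type-I error of the
    downstream test; without them the confound masquerades as signal.
    """
    cfg = default_config(n_replicates=n_replicates, depth=depth, seed=seed)
    null_regions = [
        PlacedRegion(
            r.interval,
            RegionArchetype(r.archetype.kind, r.archetype.base_rate, 1.0, 1.0),
        )
        for r in cfg.regions
    ]
    rng = np.random.default_rng(seed)
    samples = []
    for spec in cfg.samples:
        base = 1.0 if spec.condition == "solvent" else confounded_factor
        tf = float(base * np.exp(rng.normal(0.0, technical_sd)))
        samples.append(SampleSpec(spec.sample_id, spec.condition, spec.depth, tf))
    return SimulationConfig(
        chrom_lengths=cfg.chrom_lengths,
        regions=null_regions,
        samples=samples,
        duplication_rate=cfg.duplication_rate,
        seed=seed,
    )


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Truncated-normal fragment lengths by rejection with a clip fallback."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(8):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(np.round(out), lo, hi).astype(np.int64)


def _emit_fragments(
    rng: np.random.Generator,
    chrom: str,
    contig_len: int,
    n: int,
    region_start: int,
    region_end: int,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragments with uniform midpoints in [region_start, region_end)."""
    mids = rng.integers(region_start, region_end, size=n)
    lengths = _truncated_normal_lengths(
        rng, n, cfg.fragment_mean, cfg.fragment_sd, cfg.fragment_min, cfg.fragment_max
    )
    starts = np.clip(mids - lengths // 2, 0, contig_len - 1)
    ends = np.clip(starts + lengths, 1, contig_len)
    starts = np.minimum(starts, ends - 1)
    return starts, ends


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate fragments per sample plus the planted ground truth.

    Per sample, region counts are Poisson with mean
    ``base_rate * width * depth * technical_factor * fold(condition)``;
    lambda follows ``lambda_mass_fraction * depth * technical_factor`` and
    phiX ``phiX_mass_fraction * depth`` (no technical factor).  A
    ``duplication_rate`` fraction of emitted fragments are exact duplicates.

    In the default ``technical_mode='enrichment'``, the technical factor
    models transposition efficiency: it scales open-chromatin yields
    (promoter/enhancer/CTCF regions, and lambda, which is naked DNA) but not
    closed-chromatin fragments (background and heterochromatin) — i.e. it
    moves the signal-to-background enrichment, as efficiency variation does
    in real libraries.  ``technical_mode='global'`` scales every host
    fragment instead (a pure depth-like multiplier).
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.chrom_sizes()

    # Complement ("background") intervals per chrom, outside placed regions.
    complement: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in config.chrom_lengths.items():
        placed = sorted(
            (r.interval.start, r.interval.end)
            for r in config.regions
            if r.interval.chrom == chrom
        )
        gaps = []
        prev = 0
        for s, e in placed:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            gaps.append((prev, length))
        complement[chrom] = gaps

    fragments: dict[str, pd.DataFrame] = {}
    realized: list[int] = []
    for spec in config.samples:
        chroms_l: list[np.ndarray] = []
        starts_l: list[np.ndarray] = []
        ends_l: list[np.ndarray] = []
        open_scale = spec.depth * spec.technical_factor
        closed_scale = (
            open_scale if config.technical_mode == "global" else spec.depth
        )
        for region in config.regions:
            iv = region.interval
            scale = (
                closed_scale
                if region.archetype.kind == "heterochromatin"
                else open_scale
            )
            mean = region.archetype.base_rate * len(iv) * scale * region.archetype.fold(
                spec.condition
            )
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            s, e = _emit_fragments(
                rng, iv.chrom, config.chrom_lengths[iv.chrom], n, iv.start, iv.end, config
            )
            chroms_l.append(np.repeat(iv.chrom, n))
            starts_l.append(s)
            ends_l.append(e)
        for chrom, gaps in complement.items():
            if not gaps:
                continue
            lens = np.array([e - s for s, e in gaps], dtype=float)
            total = lens.sum()
            n = int(rng.poisson(config.background_rate * total * closed_scale))
            if n == 0:
                continue
            which = rng.choice(len(gaps), size=n, p=lens / total)
            s_all = np.empty(n, dtype=np.int64)
            e_all = np.empty(n, dtype=np.int64)
            for gi in np.unique(which):
                sel = which == gi
                s, e = _emit_fragments(
                    rng, chrom, config.chrom_lengths[chrom], int(sel.sum()),
                    gaps[gi][0], gaps[gi][1], config,
                )
                s_all[sel] = s
                e_all[sel] = e
            chroms_l.append(np.repeat(chrom, n))
            starts_l.append(s_all)
            ends_l.append(e_all)
        # lambda: pre-transposition spike, carries the technical factor.
        n_lambda = int(rng.poisson(config.lambda_mass_fraction * spec.depth * spec.technical_factor))
        if n_lambda:
            s, e = _emit_fragments(rng, "lambda", LAMBDA_LENGTH, n_lambda, 0, LAMBDA_LENGTH, config)
            chroms_l.append(np.repeat("lambda", n_lambda))
            starts_l.append(s)
            ends_l.append(e)
        # phiX: post-transposition spike, no technical factor.
        n_phix = int(rng.poisson(config.phiX_mass_fraction * spec.depth))
        if n_phix:
            s, e = _emit_fragments(rng, "phiX", PHIX_LENGTH, n_phix, 0, PHIX_LENGTH, config)
            chroms_l.append(np.repeat("phiX", n_phix))
            starts_l.append(s)
            ends_l.append(e)

        chrom_arr = np.concatenate(chroms_l) if chroms_l else np.array([], dtype=object)
        start_arr = np.concatenate(starts_l) if starts_l else np.array([], dtype=np.int64)
        end_arr = np.concatenate(ends_l) if ends_l else np.array([], dtype=np.int64)
        n_unique = len(chrom_arr)
        d = config.duplication_rate
        if d > 0 and n_unique > 0:
            n_dup = int(np.floor(n_unique * d / (1.0 - d)))
            if n_dup:
                idx = rng.integers(0, n_unique, size=n_dup)
                chrom_arr = np.concatenate([chrom_arr, chrom_arr[idx]])
                start_arr = np.concatenate([start_arr, start_arr[idx]])
                end_arr = np.concatenate([end_arr, end_arr[idx]])
        df = pd.DataFrame({"chrom": chrom_arr, "start": start_arr, "end": end_arr})
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        fragments[spec.sample_id] = df
        realized.append(len(df))

    regions_df = pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in config.regions],
            "start": [r.interval.start for r in config.regions],
            "end": [r.interval.end for r in config.regions],
            "kind": [r.archetype.kind for r in config.regions],
            "effect_8h": [r.archetype.effect_8h for r in config.regions],
            "effect_18h": [r.archetype.effect_18h for r in config.regions],
            "direction_1p5": [
                direction_class(r.archetype.effect_8h, r.archetype.effect_18h)
                for r in config.regions
            ],
        }
    )
    samples_df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in config.samples],
            "condition": [s.condition for s in config.samples],
            "depth": [s.depth for s in config.samples],
            "technical_factor": [s.technical_factor for s in config.samples],
            "realized_fragments": realized,
        }
    )
    _ = sizes  # chrom sizes validated above
    return fragments, GroundTruth(regions=regions_df, samples=samples_df)


def simulate_null_matrix(
    n_windows: int,
    n_samples: int,
    nb_mean: float = 50.0,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    width: int = 150,
    step: int = 50,
) -> CountMatrix:
    """I.i.d. negative-binomial counts with no condition effect.

    Counts follow mean ``nb_mean`` and variance ``nb_mean + phi*nb_mean^2``
    (gamma-Poisson mixture); ``nb_dispersion == 0`` is the Poisson limit.
    Rows are laid out as an overlapping sliding-window grid on one synthetic
    contig so clustering behaves as it would on real retained windows.
    """
    if nb_mean <= 0:
        raise ValueError("nb_mean must be > 0")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (n_windows, n_samples)
    if nb_dispersion == 0:
        counts = rng.poisson(nb_mean, size=shape)
    else:
        lam = rng.gamma(1.0 / nb_dispersion, nb_mean * nb_dispersion, size=shape)
        counts = rng.poisson(lam)
    ks = np.arange(n_windows)
    samples = [f"s{j + 1}" for j in range(n_samples)]
    return CountMatrix(
        chroms=np.repeat("chrN", n_windows).astype(object),
        starts=ks * step,
        ends=ks * step + width,
        samples=samples,
        counts=counts.astype(np.int64),
        is_spike=np.zeros(n_windows, dtype=bool),
    )


def simulate_compartment_bins(
    n_bins: int = 50,
    n_samples: int = 8,
    block_membership: np.ndarray | None = None,
    swap_fraction: float = 0.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.3,
    bin_width: int = 100_000,
    chromosome: str = "chr1",
    seed: int = 0,
):
    """Binned abundance with a planted two-block (A/B) covariance structure.

    Bins carry a loading of +1 (open block) or -1 (closed block); each
    sample draws a shared factor so same-block bins co-vary and opposite
    blocks anti-covary.  ``swap_fraction`` flips that fraction of bin
    memberships (deterministically, every ``1/swap_fraction``-th bin) to
    emulate compartment switching between groups.  Returns a
    :class:`~spikewin.compartments.BinMatrix` plus the membership vector.
    """
    from .compartments import BinMatrix

    rng = np.random.default_rng(seed)
    if block_membership is None:
        membership = np.where(np.arange(n_bins) < n_bins // 2, 1.0, -1.0)
    else:
        membership = np.asarray(block_membership, dtype=float).copy()
        n_bins = len(membership)
    if swap_fraction > 0:
        n_swap = int(round(swap_fraction * n_bins))
        if n_swap:
            idx = np.linspace(0, n_bins - 1, n_swap).astype(int)
            membership[idx] *= -1.0
    factors = rng.normal(1.0, 1.0, size=n_samples)  # mean 1: open bins richer
    abundance = (
        5.0
        + amplitude * membership[:, None] * factors[None, :]
        + rng.normal(0.0, noise_sd, size=(n_bins, n_samples))
    )
    samples = [f"g{seed}_s{j + 1}" for j in range(n_samples)]
    bm = BinMatrix(
        bin_width=bin_width,
        chroms=np.repeat(chromosome, n_bins).astype(object),
        starts=np.arange(n_bins) * bin_width,
        samples=samples,
        abundance=abundance,
    )
    return bm, membership


def write_experiment(
    fragments: Mapping[str, pd.DataFrame],
    truth: GroundTruth,
    config: SimulationConfig,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write per-sample fragment BEDs, chrom.sizes and the truth tables."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    sizes = config.chrom_sizes()
    cs_path = out / "chrom.sizes"
    with open(cs_path, "w") as fh:
        for name, length in sizes.sizes.items():
            fh.write(f"{name}\t{length}\n")
    paths["chrom_sizes"] = cs_path

    for sid, df in fragments.items():
        p = out / f"{sid}.fragments.bed"
        df.to_csv(p, sep="\t", header=False, index=False)
        paths[sid] = p

    tr = out / "truth_regions.tsv"
    truth.regions.to_csv(tr, sep="\t", index=False)
    paths["truth_regions"] = tr
    ts = out / "truth_samples.tsv"
    truth.samples.to_csv(ts, sep="\t", index=False)
    paths["truth_samples"] = ts
    return paths
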