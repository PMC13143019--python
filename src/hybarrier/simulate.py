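"""Forward-time simulation of a hybrid swarm with planted incompatibilities.

The generator produces every input the detection pipeline consumes, with
known ground truth: two parental diploid reference panels (mostly
alternatively fixed alleles), a population of haploid hybrid males evolved
forward in time with recombination and viability selection against planted
two-locus ancestry combinations, a long-term barrier-window table whose
effective migration rates can depend on planted incompatibility degree,
random gene/repeat annotation tracks with configurable enrichment inside
planted regions, and centromere positions.

The demographic model is deliberately simple: discrete non-overlapping
generations, random union of gametes, viability selection on diploid
parents, and haploid males produced by meiosis (hymenopteran males develop
from unfertilized eggs, so each sampled male is a single maternal gamete).
An incompatibility acts in cis: a haplotype carrying the incompatible
two-locus ancestry combination takes a (1 - s) viability penalty, applied
multiplicatively to a diploid's two haplotypes and to each sampled haploid
male. Unrecombined parental haplotypes never carry a recombinant
combination, so the incompatibility first appears through recombination
and selectively removes one recombinant class — the signature the
downstream scan detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, IntervalSet, merge

__all__ = [
    "SimConfig",
    "BdmiPair",
    "hub_bdmi",
    "ParentalPanels",
    "HybridPopulation",
    "SimulationError",
    "ConfigError",
    "simulate_parental_panels",
    "simulate_hybrid_population",
    "plant_barrier_table",
    "emit_annotations",
    "simulate_dataset",
    "planted_regions",
]

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """A SimConfig field violates its invariant."""


class SimulationError(RuntimeError):
    """The forward simulation could not proceed (e.g. population extinct)."""


@dataclass(frozen=True)
class BdmiPair:
    """One planted pairwise incompatibility.

    Loci are addressed as (chromosome index, site index on that chromosome).
    ``combo`` is the incompatible ordered ancestry combination at
    (locus_a, locus_b); ``s`` is the selection coefficient against a
    haplotype carrying that combination. ``anchor_a``/``anchor_b`` are the
    frequencies at which the balancing term holds the combo-contributing
    ancestry at each locus (0.5 = maximally polymorphic; a hub's partner
    loci are typically anchored lower, since a locus incompatible with a
    highly polymorphic partner could not itself stay common).
    """

    locus_a: tuple[int, int]
    locus_b: tuple[int, int]
    combo: tuple[int, int] = (0, 1)
    s: float = 0.5
    anchor_a: float = 0.5
    anchor_b: float = 0.5


def hub_bdmi(
    focal: tuple[int, int],
    partners: Sequence[tuple[int, int]],
    combo: tuple[int, int] = (0, 1),
    s: float = 0.5,
    focal_anchor: float = 0.5,
    partner_anchor: float = 0.5,
) -> list[BdmiPair]:
    """Encode a hub locus as independent pairwise interactions sharing it."""
    return [
        BdmiPair(focal, p, combo, s, anchor_a=focal_anchor, anchor_b=partner_anchor)
        for p in partners
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the empirical setting the pipeline targets: 286 sampled
    haploid males, 10 diploid reference individuals per parental species,
    a genome-wide map length of 33.3 cM per chromosome (about one crossover
    per chromosome per meiosis), and parental panels in which most sites are
    alternatively fixed between the species.
    """

    n_chromosomes: int = 12
    chrom_length_bp: int = 2_000_000
    n_parental_per_species: int = 10
    n_hybrid_males: int = 286
    n_sites: int = 120  # per chromosome
    prop_fixed_diff: float = 0.8
    admixture_p0: float = 0.5
    generations: int = 25
    map_length_cM: float = 33.3
    bdmi_spec: tuple[BdmiPair, ...] = ()
    hub_degree: int = 0
    missing_rate: float = 0.0
    pop_size: int = 5000  # diploid individuals per generation
    # genome-wide ancestry sorting (directional selection toward one species,
    # sparing the neighborhoods where incompatibilities keep both ancestries
    # segregating), emulating the strongly sorted hybrid swarms the pipeline
    # targets; 0 disables
    sorting_strength: float = 0.7  # standardized selection gradient per gen
    sorting_burnin: int = 5  # neutral generations before sorting applies
    sorting_target: int = 1  # base ancestry favored by sorting
    sorting_exclusion_bp: int = 400_000  # radius spared around planted loci
    # fraction of s exposed in the transmitting (breeding) pool; sampled
    # haploid males always express the full s (haploid expression)
    transmission_selection: float = 0.1
    # restoring force toward each planted locus's anchor frequency,
    # emulating the maintenance of polymorphism at segregating
    # incompatibility regions (spatial structure / influx in the real
    # population; see methods)
    planted_balancing: float = 0.8
    # restrict the sorting trait to these regions ((chrom index, start bp,
    # end bp) triples); None = whole genome minus planted-locus exclusions.
    # Lets an experiment plant fully sorted windows on an otherwise
    # segregating background (the ancestry-sorting contrast).
    sorting_regions: tuple[tuple[int, int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_parental_per_species": self.n_parental_per_species,
            "n_hybrid_males": self.n_hybrid_males,
            "n_sites": self.n_sites,
            "pop_size": self.pop_size,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        for name in ("prop_fixed_diff", "admixture_p0", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.generations < 0:
            raise ConfigError(f"generations must be >= 0, got {self.generations}")
        if self.map_length_cM < 0:
            raise ConfigError(f"map_length_cM must be >= 0, got {self.map_length_cM}")
        if self.sorting_strength < 0:
            raise ConfigError("sorting_strength must be >= 0")
        if not 0.0 <= self.transmission_selection <= 1.0:
            raise ConfigError("transmission_selection must lie in [0, 1]")
        if self.sorting_target not in (0, 1):
            raise ConfigError("sorting_target must be 0 or 1")
        object.__setattr__(self, "bdmi_spec", tuple(self.bdmi_spec))
        if self.sorting_regions is not None:
            object.__setattr__(
                self, "sorting_regions", tuple(tuple(r) for r in self.sorting_regions)
            )
        for pair in self.bdmi_spec:
            if not 0.0 <= pair.s <= 1.0:
                raise ConfigError(f"selection coefficient must lie in [0, 1], got {pair.s}")
            for c, i in (pair.locus_a, pair.locus_b):
                if not (0 <= c < self.n_chromosomes and 0 <= i < self.n_sites):
                    raise ConfigError(
                        f"bdmi_spec locus (chrom {c}, site {i}) outside the simulated genome"
                    )
            if pair.combo[0] not in (0, 1) or pair.combo[1] not in (0, 1):
                raise ConfigError(f"combo must be binary ancestries, got {pair.combo}")
            for anchor in (pair.anchor_a, pair.anchor_b):
                if not 0.0 < anchor <= 0.5:
                    raise ConfigError(f"anchor frequencies must lie in (0, 0.5], got {anchor}")

    # -- genome geometry ---------------------------------------------------
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def site_positions(self) -> np.ndarray:
        """0-based bp positions of the site grid on one chromosome."""
        step = self.chrom_length_bp / (self.n_sites + 1)
        return (np.arange(1, self.n_sites + 1) * step).astype(np.int64)

    def flat_index(self, locus: tuple[int, int]) -> int:
        return locus[0] * self.n_sites + locus[1]

    def layout(self, rng: np.random.Generator | None = None) -> GenomeLayout:
        """Genome layout; centromeres are placed when an RNG is supplied."""
        lengths = {c: self.chrom_length_bp for c in self.chrom_names()}
        cents: dict[str, tuple[int, int]] = {}
        if rng is not None:
            width = max(1, int(0.05 * self.chrom_length_bp))
            for c in self.chrom_names():
                s = int(rng.integers(0, self.chrom_length_bp - width))
                cents[c] = (s, s + width)
        return GenomeLayout(lengths, centromeres=cents)


@dataclass(frozen=True)
class ParentalPanels:
    """Diploid reference genotypes for the two parental species.

    ``sites`` records, per site, the true ALT-allele frequency in each
    species (p0, p1) and whether the site is alternatively fixed.
    Genotypes are ALT-allele dosages in {0, 1, 2}.
    """

    sites: pd.DataFrame  # chrom, pos (0-based), ref, alt, p0, p1, fixed
    genotypes0: np.ndarray  # (n_parental, n_total_sites) dosage
    genotypes1: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class HybridPopulation:
    """Sampled haploid males with full ancestry truth."""

    ancestry: np.ndarray  # (n_males, n_total_sites) in {0, 1}
    genotypes: np.ndarray  # ALT dosage in {0, 1}; -1 = missing
    sample_ids: list[str]
    mean_ancestry: float


def simulate_parental_panels(cfg: SimConfig, rng: np.random.Generator | None = None) -> ParentalPanels:
    """Draw per-site species allele frequencies and diploid panel genotypes.

    A fraction ``prop_fixed_diff`` of sites (exact count per chromosome) are
    alternatively fixed (|p1 − p0| = 1); the remainder get a frequency
    difference uniform on [0, 0.9], so only fixed sites can reach the usual
    0.95 ancestry-informativeness threshold.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    names = cfg.chrom_names()
    pos = cfg.site_positions()
    n_fixed = int(round(cfg.prop_fixed_diff * cfg.n_sites))

    rows = []
    for chrom in names:
        fixed = np.zeros(cfg.n_sites, dtype=bool)
        fixed[rng.choice(cfg.n_sites, size=n_fixed, replace=False)] = True
        # orientation: which species carries the ALT allele
        flip = rng.random(cfg.n_sites) < 0.5
        diff = np.where(fixed, 1.0, rng.uniform(0.0, 0.9, cfg.n_sites))
        base = rng.uniform(0.0, 1.0 - diff)
        p_lo, p_hi = base, base + diff
        p0 = np.where(flip, p_hi, p_lo)
        p1 = np.where(flip, p_lo, p_hi)
        for j in range(cfg.n_sites):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                (chrom, int(pos[j]), _BASES[ref], _BASES[alt],
                 float(p0[j]), float(p1[j]), bool(fixed[j]))
            )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "p0", "p1", "fixed"])

    n = cfg.n_parental_per_species
    g0 = rng.binomial(2, sites["p0"].to_numpy()[None, :], size=(n, len(sites)))
    g1 = rng.binomial(2, sites["p1"].to_numpy()[None, :], size=(n, len(sites)))
    return ParentalPanels(sites, g0.astype(np.int8), g1.astype(np.int8))


def _meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete per (hap_a, hap_b) row pair.

    Crossover count per chromosome ~ Poisson(map_length_cM / 100), positions
    uniform on the chromosome; the gamete follows one parental haplotype and
    switches at each crossover.
    """
    n_g = hap_a.shape[0]
    pos = cfg.site_positions().astype(float)
    lam = cfg.map_length_cM / 100.0
    out = np.empty_like(hap_a)
    for c in range(cfg.n_chromosomes):
        sl = slice(c * cfg.n_sites, (c + 1) * cfg.n_sites)
        k = rng.poisson(lam, n_g)
        kmax = int(k.max()) if n_g else 0
        if kmax == 0:
            crossings = np.zeros((n_g, len(pos)), dtype=np.int64)
        else:
            x = rng.uniform(0.0, cfg.chrom_length_bp, (n_g, kmax))
            x[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            crossings = (x[:, :, None] < pos[None, None, :]).sum(axis=1)
        start = rng.integers(0, 2, n_g)
        use_a = (crossings + start[:, None]) % 2 == 0
        out[:, sl] = np.where(use_a, hap_a[:, sl], hap_b[:, sl])
    return out


def _hap_fitness(hap: np.ndarray, cfg: SimConfig, s_scale: float = 1.0) -> np.ndarray:
    """Viability factor of each haplotype's own two-locus ancestry.

    The incompatible combination only acts in cis: a haplotype carrying it
    takes a (1 - s_scale * s) penalty per planted pair. Unrecombined
    parental haplotypes never carry a recombinant combination, so the
    incompatibility first arises through recombination, matching the
    recombinant-deficit signature the scan detects.
    """
    w = np.ones(hap.shape[0])
    for pair in cfg.bdmi_spec:
        ia, ib = cfg.flat_index(pair.locus_a), cfg.flat_index(pair.locus_b)
        aa, ab = pair.combo
        hit = (hap[:, ia] == aa) & (hap[:, ib] == ab)
        w *= np.where(hit, 1.0 - s_scale * pair.s, 1.0)
    return w


def sorting_targets(cfg: SimConfig) -> np.ndarray:
    """Favored ancestry per chromosome for the sorting gradient.

    Chromosomes without planted loci sort toward ``sorting_target``. A
    chromosome carrying a planted locus sorts toward the ancestry OPPOSITE
    the one that locus contributes to its incompatible combination, so the
    combination stays locally rare — a segregating incompatibility whose
    incompatible combination were common would have purged itself long
    before sampling.
    """
    targets = np.full(cfg.n_chromosomes, cfg.sorting_target, dtype=np.int8)
    for pair in cfg.bdmi_spec:
        for (c, _), anc in zip((pair.locus_a, pair.locus_b), pair.combo):
            targets[c] = 1 - anc
    return targets


def sorting_site_mask(cfg: SimConfig) -> np.ndarray:
    """Sites contributing to the ancestry-sorting trait.

    All sites except those within ``sorting_exclusion_bp`` of a planted
    incompatibility locus: the incompatibility itself is what keeps both
    ancestries segregating there, so sorting selection spares the
    neighborhood.
    """
    n_tot = cfg.n_chromosomes * cfg.n_sites
    pos = cfg.site_positions()
    if cfg.sorting_regions is not None:
        mask = np.zeros(n_tot, dtype=bool)
        for c, start, end in cfg.sorting_regions:
            inside = (pos >= start) & (pos < end)
            mask[c * cfg.n_sites : (c + 1) * cfg.n_sites][inside] = True
        return mask
    mask = np.ones(n_tot, dtype=bool)
    for pair in cfg.bdmi_spec:
        for c, i in (pair.locus_a, pair.locus_b):
            near = np.abs(pos - pos[i]) <= cfg.sorting_exclusion_bp
            mask[c * cfg.n_sites : (c + 1) * cfg.n_sites][near] = False
    return mask


def _breeding_weights(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cfg: SimConfig,
    sort_mask: np.ndarray,
    sorting_on: bool,
) -> np.ndarray:
    """Relative parental weights: sorting gradient x transmitted BDMI penalty.

    Sorting is a standardized (per-generation z-scored) exponential gradient
    on the individual's mean ancestry over the sorting sites — soft
    selection, so its intensity stays constant as variance erodes.
    """
    w = np.ones(hap_a.shape[0])
    if sorting_on and cfg.sorting_strength > 0 and sort_mask.any():
        target_site = np.repeat(sorting_targets(cfg), cfg.n_sites)[sort_mask]
        trait = 0.5 * (
            (hap_a[:, sort_mask] == target_site).mean(axis=1)
            + (hap_b[:, sort_mask] == target_site).mean(axis=1)
        )
        sd = trait.std()
        if sd > 1e-12:
            w = np.exp(cfg.sorting_strength * (trait - trait.mean()) / sd)
    ts = cfg.transmission_selection
    if ts > 0 and cfg.bdmi_spec:
        w = w * _hap_fitness(hap_a, cfg, ts) * _hap_fitness(hap_b, cfg, ts)
    if cfg.planted_balancing > 0 and cfg.bdmi_spec:
        # frequency-dependent restoring force toward each locus's anchor
        # frequency for its combo-contributing ancestry
        lw = np.zeros(hap_a.shape[0])
        seen: set[tuple[int, int]] = set()
        for pair in cfg.bdmi_spec:
            for (c, i), anc, anchor in zip(
                (pair.locus_a, pair.locus_b), pair.combo, (pair.anchor_a, pair.anchor_b)
            ):
                if (c, i) in seen:
                    continue
                seen.add((c, i))
                flat = cfg.flat_index((c, i))
                f = 0.5 * ((hap_a[:, flat] == anc).mean() + (hap_b[:, flat] == anc).mean())
                pull = 2.0 * cfg.planted_balancing * (anchor - f)
                lw += pull * 0.5 * ((hap_a[:, flat] == anc) + (hap_b[:, flat] == anc))
        w = w * np.exp(lw)
    return w


def simulate_hybrid_population(
    cfg: SimConfig,
    panels: ParentalPanels,
    rng: np.random.Generator | None = None,
) -> HybridPopulation:
    """Evolve the hybrid swarm forward and sample haploid males.

    Founding haplotypes are pure species-1 with probability ``admixture_p0``.
    Each generation, parents are drawn proportional to their breeding weight
    (the sorting gradient times the transmitted share of the incompatibility
    penalty) and diploids are formed by random union of their gametes.
    Sampled males are gametes of the final generation's weighted parents,
    viability-filtered at the full selection coefficient (haploid males
    express incompatibilities directly); with ``generations=0`` the
    founders' pure haplotypes are sampled directly (no meiosis yet).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n_tot = cfg.n_chromosomes * cfg.n_sites
    n_pop = cfg.pop_size
    sort_mask = sorting_site_mask(cfg)

    founder_anc = (rng.random(2 * n_pop) < cfg.admixture_p0).astype(np.int8)
    hap_a = np.repeat(founder_anc[:n_pop, None], n_tot, axis=1)
    hap_b = np.repeat(founder_anc[n_pop:, None], n_tot, axis=1)

    def weighted_parents(size: int, gen: int) -> np.ndarray:
        w = _breeding_weights(hap_a, hap_b, cfg, sort_mask, gen >= cfg.sorting_burnin)
        tot = w.sum()
        if tot <= 0:
            raise SimulationError(
                f"population extinct at generation {gen}: every diploid carries "
                "a lethal combination; lower s or the number of planted pairs"
            )
        return rng.choice(n_pop, size=size, p=w / tot)

    if cfg.generations == 0:
        pool = np.concatenate([hap_a, hap_b], axis=0)
        pick = rng.choice(pool.shape[0], size=cfg.n_hybrid_males, replace=True)
        males = pool[pick]
    else:
        for gen in range(cfg.generations):
            mothers = weighted_parents(n_pop, gen)
            fathers = weighted_parents(n_pop, gen)
            hap_a, hap_b = (
                _meiosis(hap_a[mothers], hap_b[mothers], cfg, rng),
                _meiosis(hap_a[fathers], hap_b[fathers], cfg, rng),
            )
        # haploid males express incompatibilities at full strength: keep
        # resampling viability-filtered gametes until the sample is complete
        males_parts: list[np.ndarray] = []
        n_left = cfg.n_hybrid_males
        for _ in range(200):
            if n_left <= 0:
                break
            mothers = weighted_parents(n_left, cfg.generations)
            cand = _meiosis(hap_a[mothers], hap_b[mothers], cfg, rng)
            ok = rng.random(n_left) < _hap_fitness(cand, cfg)
            males_parts.append(cand[ok])
            n_left -= int(ok.sum())
        if n_left > 0:
            raise SimulationError(
                "could not sample enough viable haploid males; lower s or the number of planted pairs"
            )
        males = np.concatenate(males_parts, axis=0)

    p0 = panels.sites["p0"].to_numpy()
    p1 = panels.sites["p1"].to_numpy()
    p_alt = np.where(males == 1, p1[None, :], p0[None, :])
    geno = (rng.random(males.shape) < p_alt).astype(np.int8)
    if cfg.missing_rate > 0:
        geno[rng.random(males.shape) < cfg.missing_rate] = -1

    ids = [f"male_{i + 1:03d}" for i in range(cfg.n_hybrid_males)]
    return HybridPopulation(males, geno, ids, float(males.mean()))


def planted_regions(cfg: SimConfig, pad_bp: int = 25_000) -> IntervalSet:
    """Merged genomic regions around the planted incompatibility loci."""
    names = cfg.chrom_names()
    pos = cfg.site_positions()
    rows = []
    loci = {pair.locus_a for pair in cfg.bdmi_spec} | {pair.locus_b for pair in cfg.bdmi_spec}
    for c, i in sorted(loci):
        p = int(pos[i])
        rows.append((names[c], max(0, p - pad_bp), min(cfg.chrom_length_bp, p + pad_bp)))
    return merge(IntervalSet.from_records(rows))


def truth_degrees(cfg: SimConfig) -> dict[tuple[int, int], int]:
    """Pairwise-interaction count per planted locus."""
    deg: dict[tuple[int, int], int] = {}
    for pair in cfg.bdmi_spec:
        for loc in (pair.locus_a, pair.locus_b):
            deg[loc] = deg.get(loc, 0) + 1
    return deg


def plant_barrier_table(
    cfg: SimConfig,
    relation: Callable[[int], float],
    window_bp: int = 50_000,
    noise_sd: float = 0.0,
    background_me: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tile the genome into barrier-scan windows with planted signal.

    Windows overlapping a planted incompatibility locus are barrier calls
    (delta_b0 > 0, fpr_pass) with m_e = relation(total planted degree in the
    window) + Gaussian noise; all other windows get the background m_e and
    delta_b0 <= 0. ``relation`` must be non-increasing in degree.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    degs = truth_degrees(cfg)
    observed = sorted({d for d in degs.values()})
    for lo, hi in zip(observed, observed[1:]):
        if relation(hi) > relation(lo):
            raise ConfigError("relation(degree) must be non-increasing in degree")
    pos = cfg.site_positions()
    rows = []
    for ci, chrom in enumerate(cfg.chrom_names()):
        for start in range(0, cfg.chrom_length_bp, window_bp):
            end = min(start + window_bp, cfg.chrom_length_bp)
            deg = sum(
                d for (c, i), d in degs.items()
                if c == ci and start <= pos[i] < end
            )
            if deg > 0:
                me = max(0.0, relation(deg) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
                rows.append((chrom, start, end, float(rng.uniform(0.5, 5.0)), me, True))
            else:
                rows.append((chrom, start, end, float(-rng.uniform(0.0, 5.0)), background_me, False))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "delta_b0", "m_e", "fpr_pass"]
    )


def emit_annotations(
    cfg: SimConfig,
    layout: GenomeLayout,
    enrichment: dict[str, float] | None = None,
    n_features: int = 60,
    feature_bp: int = 4_000,
    pad_bp: int = 25_000,
    rng: np.random.Generator | None = None,
) -> dict[str, IntervalSet]:
    """Place random annotation features with configurable planted enrichment.

    ``enrichment`` maps a class label to the odds multiplier of landing
    inside the planted incompatibility regions relative to a
    length-proportional draw (1 = no enrichment; ``inf`` = always inside).
    Classes default to a gene track (with CDS sub-features, so introns are
    derivable) and three repeat classes. Features within a class do not
    overlap.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    classes = ["gene", "LTR/Copia", "DNA/hAT", "snRNA"]
    enrichment = dict(enrichment or {})
    planted = planted_regions(cfg, pad_bp=pad_bp)
    genome_bp = layout.total_length()
    if n_features * feature_bp > 0.5 * genome_bp:
        raise ConfigError(
            f"requested {n_features * feature_bp} annotation bp per class exceeds "
            f"half the genome ({genome_bp} bp)"
        )
    f_in = planted.total_bp() / genome_bp
    chroms = list(layout.chrom_lengths)
    weights = np.array([layout.chrom_lengths[c] for c in chroms], float)
    weights /= weights.sum()

    def _inside_prob(odds: float) -> float:
        if np.isinf(odds):
            return 1.0
        return odds * f_in / (odds * f_in + (1.0 - f_in)) if f_in > 0 else 0.0

    def _draw_feature(odds: float) -> tuple[str, int, int]:
        if f_in > 0 and rng.random() < _inside_prob(odds):
            row = planted.df.iloc[int(rng.integers(0, len(planted.df)))]
            lo = int(row.start)
            hi = max(lo + 1, int(row.end) - feature_bp)
            s = int(rng.integers(lo, hi))
            return (row.chrom, s, min(s + feature_bp, layout.chrom_lengths[row.chrom]))
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        s = int(rng.integers(0, layout.chrom_lengths[c] - feature_bp))
        return (c, s, s + feature_bp)

    out: dict[str, IntervalSet] = {}
    for label in classes:
        odds = enrichment.get(label, 1.0)
        placed: list[tuple[str, int, int]] = []
        attempts = 0
        while len(placed) < n_features and attempts < 50 * n_features:
            attempts += 1
            cand = _draw_feature(odds)
            if all(not (cand[0] == p[0] and cand[1] < p[2] and p[1] < cand[2]) for p in placed):
                placed.append(cand)
        out[label] = IntervalSet.from_records(sorted(placed)).sorted()

    # CDS sub-intervals inside each gene (1-3 per gene), so introns exist
    cds_rows = []
    for r in out["gene"].df.itertuples(index=False):
        n_cds = int(rng.integers(1, 4))
        length = r.end - r.start
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_cds, replace=False))
        for k in range(n_cds):
            cds_rows.append((r.chrom, int(r.start + cuts[2 * k]), int(r.start + cuts[2 * k + 1])))
    out["CDS"] = IntervalSet.from_records(cds_rows).sorted()
    return out


@dataclass(frozen=True)
class SimOutput:
    """All file paths plus ground truth for one simulated dataset."""

    parental_vcf: str
    hybrid_vcf: str
    barrier_table: str
    gff: str
    repeats_bed: str
    centromeres_bed: str
    chrom_lengths: str
    truth_bdmis: tuple[BdmiPair, ...]
    truth_barriers: pd.DataFrame
    layout: GenomeLayout
    panels: ParentalPanels
    population: HybridPopulation


def simulate_dataset(
    cfg: SimConfig,
    outdir,
    relation: Callable[[int], float] | None = None,
    enrichment: dict[str, float] | None = None,
    n_diploid_females: int = 0,
) -> SimOutput:
    """Run the full generator and write every pipeline input to ``outdir``.

    ``n_diploid_females`` optionally appends diploid individuals to the
    hybrid VCF (un-flagged diploids emulate the mislabeled females the
    haploid QC step must catch).
    """
    from pathlib import Path

    from . import vcfio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    panels = simulate_parental_panels(cfg, rng)
    pop = simulate_hybrid_population(cfg, panels, rng)
    layout = cfg.layout(rng)
    relation = relation or (lambda d: 1.0 / (1.0 + d))
    barriers = plant_barrier_table(cfg, relation, rng=rng)
    annot = emit_annotations(cfg, layout, enrichment, rng=rng)

    parental_vcf = str(outdir / "parental.vcf")
    hybrid_vcf = str(outdir / "hybrid.vcf")
    vcfio.write_parental_vcf(parental_vcf, panels, cfg)
    female_geno = None
    female_ids: list[str] = []
    if n_diploid_females > 0:
        # diploid females = two random male-like gametes -> het where they differ
        idx = rng.integers(0, pop.genotypes.shape[0], (n_diploid_females, 2))
        a = np.where(pop.genotypes[idx[:, 0]] < 0, 0, pop.genotypes[idx[:, 0]])
        b = np.where(pop.genotypes[idx[:, 1]] < 0, 0, pop.genotypes[idx[:, 1]])
        female_geno = a + b
        female_ids = [f"female_{i + 1:03d}" for i in range(n_diploid_females)]
    vcfio.write_hybrid_vcf(hybrid_vcf, pop, panels, female_geno, female_ids)

    barrier_path = str(outdir / "barriers.tsv")
    barriers.to_csv(barrier_path, sep="\t", index=False)

    gff_path = str(outdir / "annotations.gff3")
    vcfio.write_gff(gff_path, annot["gene"], annot["CDS"])
    rep_path = str(outdir / "repeats.bed")
    rep_rows, rep_labels = [], []
    for label in ("LTR/Copia", "DNA/hAT", "snRNA"):
        for r in annot[label].df.itertuples(index=False):
            rep_rows.append((r.chrom, r.start, r.end))
            rep_labels.append(label)
    IntervalSet.from_records(rep_rows, labels=rep_labels).write_bed(rep_path)

    cent_path = str(outdir / "centromeres.bed")
    IntervalSet.from_records(
        [(c, s, e) for c, (s, e) in layout.centromeres.items()]
    ).write_bed(cent_path)

    len_path = str(outdir / "chrom_lengths.tsv")
    with open(len_path, "w") as fh:
        for c, L in layout.chrom_lengths.items():
            fh.write(f"{c}\t{L}\n")

    return SimOutput(
        parental_vcf, hybrid_vcf, barrier_path, gff_path, rep_path, cent_path,
        len_path, cfg.bdmi_spec, barriers, layout, panels, pop,
    )
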