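"""Ancestry-informative markers and polarized ancestry calls.

An AIM is a biallelic SNP whose allele frequencies differ between the two
parental reference panels by at least a threshold (0.95 by default), so a
hybrid's allele at the site tags which species the surrounding haplotype
descends from. Hybrid genotype calls are converted to parental ancestry:
0 for the species-0-like allele, 1 for the species-1-like allele, missing
for anything else (no call, heterozygous in a haploid, third allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "AimPanel",
    "AncestryMatrix",
    "InputError",
    "identify_aims",
    "flag_diploid_males",
    "polarize",
]

log = logging.getLogger(__name__)

MISSING = np.int8(-1)


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class AimPanel:
    """Ancestry-informative marker records, ordered by genome position.

    ``df`` columns: chrom, pos (0-based), allele0, allele1, freq_diff.
    ``allele0``/``allele1`` are the bases tagging species 0 / species 1.
    """

    df: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        d = self.df
        if (d["freq_diff"] < self.threshold - 1e-12).any():
            raise InputError("AIM record below the frequency-difference threshold")
        if (d["allele0"] == d["allele1"]).any():
            raise InputError("AIM with identical species alleles")
        for _, sub in d.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise InputError("AIM positions must increase within chromosome")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# positions: 0-based\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, threshold: float = 0.95) -> "AimPanel":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df.reset_index(drop=True), threshold)


@dataclass(frozen=True)
class AncestryMatrix:
    """Samples × AIMs ancestry calls; -1 encodes missing.

    Column order follows the AIM panel (genome order).
    """

    samples: list[str]
    sites: pd.DataFrame  # chrom, pos (0-based) per retained AIM
    data: np.ndarray  # int8 (n_samples, n_sites) in {0, 1, -1}

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.samples), len(self.sites)):
            raise InputError("ancestry matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def hybrid_index(self) -> np.ndarray:
        """Per-sample mean ancestry over non-missing AIMs."""
        mask = self.data >= 0
        with np.errstate(invalid="ignore"):
            return np.where(
                mask.sum(1) > 0, (self.data * mask).sum(1) / mask.sum(1), np.nan
            )

    def to_tsv(self, path) -> None:
        cols = [f"{c}:{p}" for c, p in zip(self.sites["chrom"], self.sites["pos"])]
        df = pd.DataFrame(
            np.where(self.data < 0, np.nan, self.data), index=self.samples, columns=cols
        )
        with open(path, "w") as fh:
            fh.write("# ancestry calls: 0/1/NA; positions 0-based\n")
            df.to_csv(fh, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "AncestryMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        chrom = [c.rsplit(":", 1)[0] for c in df.columns]
        pos = [int(c.rsplit(":", 1)[1]) for c in df.columns]
        data = df.to_numpy(dtype=float)
        out = np.where(np.isnan(data), MISSING, data).astype(np.int8)
        return cls(list(df.index), pd.DataFrame({"chrom": chrom, "pos": pos}), out)


def _group_freqs(variant, idx: np.ndarray) -> tuple[float, int]:
    """ALT-allele frequency over non-missing alleles in a sample subset."""
    gts = variant.genotype.array()[idx]  # rows: allele indices + phased flag
    alleles = gts[:, :-1].ravel()
    called = alleles[alleles >= 0]
    if called.size == 0:
        return np.nan, 0
    return float(np.mean(called == 1)), int(called.size)


def identify_aims(
    parental_vcf: str,
    species0_samples: Sequence[str],
    species1_samples: Sequence[str],
    threshold: float = 0.95,
    max_missing: float = 0.4,
) -> AimPanel:
    """Ascertain AIMs from the two parental panels.

    Keeps biallelic SNPs where the between-species ALT-frequency difference
    (complete-case per site) reaches ``threshold`` and neither panel exceeds
    ``max_missing`` missing alleles. Sites with more than two alleles are
    skipped and counted.
    """
    vcf = VCF(parental_vcf)
    all_samples = vcf.samples
    if not species0_samples or not species1_samples:
        raise InputError("each species panel needs at least one sample")
    for s in list(species0_samples) + list(species1_samples):
        if s not in all_samples:
            raise InputError(f"panel sample {s!r} absent from VCF")
    idx0 = np.array([all_samples.index(s) for s in species0_samples])
    idx1 = np.array([all_samples.index(s) for s in species1_samples])

    rows = []
    n_multi = n_lowdiff = n_missing = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.ALT[0] == "<NON_REF>":
            n_multi += 1
            continue
        p0, n0 = _group_freqs(v, idx0)
        p1, n1 = _group_freqs(v, idx1)
        full0, full1 = 2 * len(idx0), 2 * len(idx1)
        if n0 == 0 or n1 == 0 or (full0 - n0) / full0 > max_missing or (full1 - n1) / full1 > max_missing:
            n_missing += 1
            continue
        diff = abs(p1 - p0)
        if diff < threshold:
            n_lowdiff += 1
            continue
        # the allele at higher frequency in each species tags that species
        a0 = v.ALT[0] if p0 > 0.5 else v.REF
        a1 = v.ALT[0] if p1 > 0.5 else v.REF
        rows.append((v.CHROM, v.POS - 1, a0, a1, diff))
    if not rows and n_multi + n_lowdiff + n_missing == 0:
        raise InputError(f"no variant records in {parental_vcf}")
    log.info(
        "identify_aims: kept %d; skipped %d multiallelic, %d low-diff, %d high-missing",
        len(rows), n_multi, n_lowdiff, n_missing,
    )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "allele0", "allele1", "freq_diff"])
    return AimPanel(df.reset_index(drop=True), threshold)


def flag_diploid_males(
    hybrid_vcf: str,
    male_ids: Sequence[str],
    threshold: int | None = None,
    female_ids: Sequence[str] | None = None,
    het_fraction_cutoff: float = 0.05,
) -> tuple[pd.Series, list[str]]:
    """Count heterozygous calls per listed male and flag likely diploids.

    A truly haploid male yields no heterozygous genotype calls, so an excess
    marks a mislabeled diploid. The cutoff is, in order of precedence: the
    explicit ``threshold`` count; the midpoint between the male and female
    median counts when ``female_ids`` is given; else ``het_fraction_cutoff``
    of the number of records. Returns (counts per male, flagged ids).
    """
    male_ids = list(male_ids)
    if not male_ids:
        return pd.Series(dtype=int), []
    vcf = VCF(hybrid_vcf)
    samples = vcf.samples
    wanted = male_ids + list(female_ids or [])
    for s in wanted:
        if s not in samples:
            raise InputError(f"sample {s!r} absent from VCF")
    idx = np.array([samples.index(s) for s in wanted])
    het = np.zeros(len(wanted), dtype=int)
    n_records = 0
    for v in vcf:
        n_records += 1
        g = v.genotype.array()[idx]
        a, b = g[:, 0], g[:, 1] if g.shape[1] > 2 else g[:, 0]
        het += ((a >= 0) & (b >= 0) & (a != b)).astype(int)
    counts = pd.Series(het[: len(male_ids)], index=male_ids)
    if threshold is None:
        if female_ids:
            fem = pd.Series(het[len(male_ids):], index=list(female_ids))
            threshold = 0.5 * (counts.median() + fem.median())
        else:
            threshold = het_fraction_cutoff * n_records
    flagged = [s for s in male_ids if counts[s] > threshold]
    log.info("flag_diploid_males: %d of %d flagged (cutoff %.1f)", len(flagged), len(male_ids), threshold)
    return counts, flagged


def polarize(
    hybrid_vcf: str,
    panel: AimPanel,
    haploid_ids: Sequence[str],
    max_missing: float = 0.4,
) -> AncestryMatrix:
    """Convert hybrid genotype calls at AIM sites to ancestry {0, 1, missing}.

    A homozygous or haploid call matching allele0 maps to 0, matching
    allele1 maps to 1; heterozygous calls, no-calls, and third alleles are
    missing. AIMs missing from the VCF are dropped; AIMs whose post-
    conversion missingness exceeds ``max_missing`` are dropped and counted.
    """
    haploid_ids = list(haploid_ids)
    vcf = VCF(hybrid_vcf)
    samples = vcf.samples
    for s in haploid_ids:
        if s not in samples:
            raise InputError(f"sample {s!r} absent from VCF")
    idx = np.array([samples.index(s) for s in haploid_ids])
    lookup = {
        (r.chrom, r.pos): (r.allele0, r.allele1)
        for r in panel.df.itertuples(index=False)
    }
    found: dict[tuple[str, int], np.ndarray] = {}
    for v in vcf:
        key = (v.CHROM, v.POS - 1)
        pair = lookup.get(key)
        if pair is None:
            continue
        a0, a1 = pair
        alleles = [v.REF] + list(v.ALT)
        g = v.genotype.array()[idx]
        a, b = g[:, 0], g[:, 1] if g.shape[1] > 2 else g[:, 0]
        col = np.full(len(idx), MISSING)
        ok = (a >= 0) & ((b < 0) | (b == a))  # haploid call or homozygous diploid
        called = np.where(a >= 0, a, 0)
        base = np.array(alleles, dtype=object)[np.minimum(called, len(alleles) - 1)]
        col[ok & (base == a0)] = 0
        col[ok & (base == a1)] = 1
        found[key] = col

    keep_cols, keep_rows = [], []
    n_absent = n_toomissing = 0
    for r in panel.df.itertuples(index=False):
        key = (r.chrom, r.pos)
        col = found.get(key)
        if col is None:
            n_absent += 1
            continue
        if np.mean(col == MISSING) > max_missing:
            n_toomissing += 1
            continue
        keep_cols.append(col)
        keep_rows.append((r.chrom, r.pos))
    log.info(
        "polarize: kept %d AIMs; %d absent from VCF, %d over missingness cap",
        len(keep_cols), n_absent, n_toomissing,
    )
    data = (
        np.stack(keep_cols, axis=1).astype(np.int8)
        if keep_cols
        else np.empty((len(haploid_ids), 0), dtype=np.int8)
    )
    sites = pd.DataFrame(keep_rows, columns=["chrom", "pos"])
    return AncestryMatrix(haploid_ids, sites, data)
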