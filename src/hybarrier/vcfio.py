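"""VCF and GFF3 plumbing for the synthetic-data generator and the callers.

Reading goes through cyvcf2; writing emits plain uncompressed VCF 4.2 text
(single-allele genotypes for haploid males, unphased diploid genotypes for
the parental panels). Positions are 1-based in VCF and converted to the
package's 0-based convention on ingest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import IntervalSet

__all__ = [
    "write_parental_vcf",
    "write_hybrid_vcf",
    "write_gff",
    "read_gff_features",
]

_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _contig_lines(cfg) -> str:
    return "".join(
        f"##contig=<ID={c},length={cfg.chrom_length_bp}>\n" for c in cfg.chrom_names()
    )


_DIP = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_HAP = {0: "0", 1: "1", -1: "."}


def write_parental_vcf(path, panels, cfg) -> None:
    """Two parental panels in one VCF; sample names carry the species tag."""
    ids0 = [f"sp0_{i + 1:02d}" for i in range(panels.genotypes0.shape[0])]
    ids1 = [f"sp1_{i + 1:02d}" for i in range(panels.genotypes1.shape[0])]
    with open(path, "w") as fh:
        fh.write(_HEADER + _contig_lines(cfg))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids0 + ids1) + "\n")
        for j, site in enumerate(panels.sites.itertuples(index=False)):
            gts = [_DIP[int(g)] for g in panels.genotypes0[:, j]]
            gts += [_DIP[int(g)] for g in panels.genotypes1[:, j]]
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_hybrid_vcf(path, pop, panels, female_geno=None, female_ids=None) -> None:
    """Haploid male calls (plus optional diploid females) as VCF."""
    female_ids = female_ids or []
    with open(path, "w") as fh:
        fh.write(_HEADER)
        chrom_max = panels.sites.groupby("chrom", sort=False)["pos"].max()
        for c, p in chrom_max.items():
            fh.write(f"##contig=<ID={c},length={int(p) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(pop.sample_ids + female_ids) + "\n")
        for j, site in enumerate(panels.sites.itertuples(index=False)):
            gts = [_HAP[int(g)] for g in pop.genotypes[:, j]]
            if female_geno is not None:
                gts += [_DIP[int(g)] for g in female_geno[:, j]]
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_gff(path, genes: IntervalSet, cds: IntervalSet) -> None:
    """Genes with their contained CDS sub-features as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        cds_by_chrom = cds.by_chrom()
        gid = 0
        for g in genes.df.itertuples(index=False):
            gid += 1
            fh.write(
                f"{g.chrom}\thybarrier_sim\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID=gene{gid}\n"
            )
            sub = cds_by_chrom.get(g.chrom)
            if sub is None:
                continue
            hits = sub[(sub["start"] >= g.start) & (sub["end"] <= g.end)]
            for k, r in enumerate(hits.itertuples(index=False), 1):
                fh.write(
                    f"{r.chrom}\thybarrier_sim\tCDS\t{r.start + 1}\t{r.end}\t.\t+\t0\t"
                    f"ID=cds{gid}.{k};Parent=gene{gid}\n"
                )


def read_gff_features(path, feature_types=("gene", "CDS")) -> dict[str, IntervalSet]:
    """Extract feature intervals (converted to 0-based half-open) per type."""
    wanted = set(feature_types)
    rows: dict[str, list[tuple[str, int, int]]] = {t: [] for t in wanted}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in wanted:
                continue
            rows[parts[2]].append((parts[0], int(parts[3]) - 1, int(parts[4])))
    return {t: IntervalSet.from_records(sorted(r)).sorted() for t, r in rows.items()}


def read_repeat_bed(path) -> dict[str, IntervalSet]:
    """Repeat BED with the class/subfamily label in column 4, split by class."""
    ivs = IntervalSet.read_bed(path)
    out: dict[str, IntervalSet] = {}
    if ivs.is_empty():
        return out
    for label, sub in ivs.df.groupby("label"):
        out[str(label)] = IntervalSet(sub.reset_index(drop=True))
    return out


def read_chrom_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"], df["length"].astype(int)))
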