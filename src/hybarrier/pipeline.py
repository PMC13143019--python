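"""Configuration, the barrier-window table, and the end-to-end pipeline.

The long-term barrier table is the output of a demographically explicit
genome scan, consumed here as input: one row per genomic window with
delta_b0 (support for a zero-migration history relative to the genome-wide
background model; > 0 marks a potential barrier), m_e (the window's
effective migration rate), and an fpr_pass flag from the scan's
false-positive-rate calibration. A window is a barrier call when
delta_b0 > 0 and fpr_pass.

``run_pipeline`` chains the stages — simulate, AIM ascertainment,
polarization, the incompatibility scan, the network analysis, interval
overlap tests, and the sorting contrast — from one seeded configuration,
writing a manifest of every output so a rerun with the same configuration
reproduces all files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, network, scan, simulate, sorting, vcfio
from .intervals import (
    GenomeLayout,
    IntervalSet,
    centromere_distance_test,
    derive_introns,
    feature_enrichment,
    merge,
    overlap_bootstrap,
    subtract,
)

__all__ = [
    "BarrierWindowTable",
    "PipelineConfig",
    "read_barrier_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_BARRIER_COLS = ["chrom", "start", "end", "delta_b0", "m_e", "fpr_pass"]


@dataclass(frozen=True)
class BarrierWindowTable:
    """Validated barrier-scan window table plus derived barrier regions."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _BARRIER_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"barrier table missing column(s): {', '.join(missing)}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("barrier table contains an empty or inverted window")

    @property
    def calls(self) -> pd.DataFrame:
        """Rows that are barrier calls (delta_b0 > 0 and fpr_pass)."""
        return self.df[(self.df["delta_b0"] > 0) & self.df["fpr_pass"].astype(bool)]

    def barrier_bed(self) -> IntervalSet:
        """Merged barrier regions from the calling rows."""
        rows = [(r.chrom, int(r.start), int(r.end)) for r in self.calls.itertuples(index=False)]
        return merge(IntervalSet.from_records(rows))

    def nonbarrier_bed(self, layout: GenomeLayout) -> IntervalSet:
        """Genome complement of the barrier regions."""
        whole = IntervalSet.from_records(
            [(c, 0, L) for c, L in layout.chrom_lengths.items()]
        )
        return subtract(whole, self.barrier_bed())

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_barrier_table(path) -> BarrierWindowTable:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return BarrierWindowTable(df)


@dataclass
class PipelineConfig:
    """One reproducible end-to-end run.

    Thresholds default to the study's standard choices: AIM frequency
    difference 0.95, 20-AIM windows, base X(2) cutoff -0.005, 99th-
    percentile bootstrap criteria, 40% site-missingness cap.
    """

    outdir: str = "hybarrier_run"
    seed: int = 0
    reps: int = 1000
    aim_threshold: float = 0.95
    max_missing: float = 0.4
    window_size: int = scan.WINDOW_SIZE
    base_cutoff: float = scan.X2_BASE_CUTOFF
    percentile: float = 99.0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    stages: tuple[str, ...] = (
        "simulate", "aims", "polarize", "bdmi-scan", "network", "overlap", "dbar",
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_STAGE_ORDER = ["simulate", "aims", "polarize", "bdmi-scan", "network", "overlap", "dbar"]
_STAGE_DEPS = {
    "aims": ["simulate"],
    "polarize": ["aims"],
    "bdmi-scan": ["polarize"],
    "network": ["bdmi-scan"],
    "overlap": ["bdmi-scan"],
    "dbar": ["polarize"],
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    enabled = set(cfg.stages)
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, []):
            if dep not in enabled:
                raise ValueError(f"stage {stage!r} requires stage {dep!r} to be enabled")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {},
        "outputs": {},
        "counts": {},
    }
    rng_root = np.random.SeedSequence(cfg.seed)
    stage_seed = {
        s: int(np.random.default_rng(child).integers(2**31))
        for s, child in zip(_STAGE_ORDER, rng_root.spawn(len(_STAGE_ORDER)))
    }
    manifest["stage_seeds"] = stage_seed

    sim_out = panel = matrix = None
    stats = windows = pw = None
    callset = None

    if "simulate" in enabled:
        sim_cfg = simulate.SimConfig(**{"seed": stage_seed["simulate"], **cfg.sim})
        sim_out = simulate.simulate_dataset(sim_cfg, outdir / "sim")
        manifest["outputs"]["simulate"] = {
            "parental_vcf": sim_out.parental_vcf,
            "hybrid_vcf": sim_out.hybrid_vcf,
            "barrier_table": sim_out.barrier_table,
            "gff": sim_out.gff,
            "repeats_bed": sim_out.repeats_bed,
            "centromeres_bed": sim_out.centromeres_bed,
            "chrom_lengths": sim_out.chrom_lengths,
        }

    if "aims" in enabled:
        n_par = sim_out.panels.genotypes0.shape[0]
        sp0 = [f"sp0_{i + 1:02d}" for i in range(n_par)]
        sp1 = [f"sp1_{i + 1:02d}" for i in range(n_par)]
        panel = ancestry.identify_aims(
            sim_out.parental_vcf, sp0, sp1, cfg.aim_threshold, cfg.max_missing
        )
        path = outdir / "aims.tsv"
        panel.to_tsv(path)
        manifest["outputs"]["aims"] = str(path)
        manifest["counts"]["n_aims"] = len(panel)

    if "polarize" in enabled:
        ids = sim_out.population.sample_ids
        counts, flagged = ancestry.flag_diploid_males(sim_out.hybrid_vcf, ids)
        keep = [s for s in ids if s not in set(flagged)]
        matrix = ancestry.polarize(sim_out.hybrid_vcf, panel, keep, cfg.max_missing)
        path = outdir / "ancestry_matrix.tsv"
        matrix.to_tsv(path)
        manifest["outputs"]["polarize"] = str(path)
        manifest["counts"]["n_flagged_diploid"] = len(flagged)
        manifest["counts"]["n_haploid_samples"] = matrix.n_samples

    if "bdmi-scan" in enabled:
        rng = np.random.default_rng(stage_seed["bdmi-scan"])
        pw = scan.pairwise_stats(matrix)
        windows = scan.make_windows(matrix.sites, cfg.window_size)
        stats = scan.all_window_pair_stats(pw, windows, cfg.base_cutoff)
        _, frac_thresh = scan.bootstrap_fraction_null(
            pw.pool(), cfg.window_size**2, cfg.reps, rng, cfg.base_cutoff
        )
        _, count_thresh = scan.bootstrap_aim_position_null(
            pw, 2 * cfg.window_size, cfg.reps, rng, cfg.base_cutoff
        )
        path = outdir / "window_pairs.tsv"
        stats.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["bdmi-scan"] = {"window_pairs": str(path), "cutoffs": {}}
        manifest["counts"]["frac_threshold"] = frac_thresh
        manifest["counts"]["count_threshold"] = count_thresh
        calls_by_cutoff = {}
        for cutoff in scan.cutoff_grid():
            cs = scan.call_candidates(stats, windows, frac_thresh, count_thresh, cutoff)
            calls_by_cutoff[float(cutoff)] = cs
            if cs.n_pairs:
                bed = outdir / f"bdmi_regions_{cutoff:+.4f}.bed"
                cs.regions.write_bed(bed, header="merged candidate regions; score = degree")
                manifest["outputs"]["bdmi-scan"]["cutoffs"][f"{cutoff:+.4f}"] = {
                    "n_pairs": cs.n_pairs,
                    "regions_bed": str(bed),
                }
        callset = calls_by_cutoff[float(cfg.base_cutoff)]
        manifest["counts"]["n_candidate_pairs_base"] = callset.n_pairs

    if "network" in enabled:
        g = network.build_graph(callset, matrix)
        table = read_barrier_table(sim_out.barrier_table)
        res = network.degree_vs_me(
            g, table.calls, reps=cfg.reps, seed=stage_seed["network"]
        )
        out = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "degree_me_r": res.r,
            "degree_me_p_lower": res.p_lower,
        }
        if g.number_of_nodes() >= 2:
            boot = network.orr_bootstrap(g, reps=cfg.reps, seed=stage_seed["network"] + 1)
            out["orr_p"] = boot.params.p
            out["topology_p"] = boot.p_values
        path = outdir / "network.json"
        path.write_text(json.dumps(out, indent=2, default=float))
        manifest["outputs"]["network"] = str(path)

    if "overlap" in enabled:
        table = read_barrier_table(sim_out.barrier_table)
        barrier_bed = table.barrier_bed()
        bdmi_bed = callset.regions
        layout = sim_out.layout
        results = {}
        if not bdmi_bed.is_empty():
            ov = overlap_bootstrap(
                bdmi_bed, barrier_bed, layout, reps=cfg.reps, seed=stage_seed["overlap"]
            )
            results["bdmi_vs_barrier"] = {
                "observed_bp": ov.observed_bp,
                "p_upper": ov.p_upper,
                "p_lower": ov.p_lower,
                "direction": ov.direction,
            }
            if layout.centromeres:
                cent = centromere_distance_test(
                    bdmi_bed, layout, reps=min(cfg.reps, 200), seed=stage_seed["overlap"] + 1
                )
                results["centromere_distance_p"] = cent.p_value
        genes = vcfio.read_gff_features(sim_out.gff)
        introns = derive_introns(genes["gene"], genes["CDS"])
        classes = {"CDS": genes["CDS"], "intron": introns}
        classes.update(vcfio.read_repeat_bed(sim_out.repeats_bed))
        enr = feature_enrichment(
            barrier_bed, classes, layout, reps=cfg.reps, seed=stage_seed["overlap"] + 2
        )
        results["barrier_annotation"] = {
            k: None if v is None else {"observed_bp": v.observed_bp, "p": v.p, "direction": v.direction}
            for k, v in enr.items()
        }
        path = outdir / "overlap.json"
        path.write_text(json.dumps(results, indent=2, default=float))
        manifest["outputs"]["overlap"] = str(path)

    if "dbar" in enabled:
        table = read_barrier_table(sim_out.barrier_table)
        layout = sim_out.layout
        barrier_bed = table.barrier_bed()
        if not barrier_bed.is_empty():
            contrast = sorting.dbar_contrast(
                matrix, barrier_bed, table.nonbarrier_bed(layout), layout,
                reps=cfg.reps, seed=stage_seed["dbar"],
            )
            path = outdir / "dbar.tsv"
            contrast.per_window.to_csv(path, sep="\t", index=False)
            manifest["outputs"]["dbar"] = {
                "per_window": str(path),
                "mean_barrier": contrast.mean_barrier,
                "mean_nonbarrier": contrast.mean_nonbarrier,
                "p_lower": contrast.p_lower,
            }

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    log.info("pipeline complete: %s", manifest_path)
    return manifest
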