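"""Genomic interval algebra and circular-permutation statistics.

All coordinates are 0-based half-open (BED convention). The circularization
bootstrap rotates every feature on a chromosome by one shared random offset,
which preserves feature lengths and the within-chromosome spacing of features
while randomizing their position relative to a second, fixed track. Repeating
the rotation builds an empirical null distribution for any statistic of the
two tracks (total overlap in bp, distance to the centromere, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "OverlapTestResult",
    "merge",
    "intersect_bp",
    "subtract",
    "trim_to_extent",
    "circular_shift",
    "overlap_bootstrap",
    "derive_introns",
    "feature_enrichment",
    "centromere_distance_test",
    "chromosome_enrichment",
    "empirical_p",
]


class IntervalError(ValueError):
    """Raised for records violating coordinate invariants."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus optional centromeres and data extents.

    ``extents`` records, per chromosome, the innermost first/last covered
    position of the underlying SNP data; when set, shift-based null models
    treat the extent (not the full chromosome) as the circle circumference.
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    extents: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise IntervalError(f"chromosome {c} has non-positive length {L}")
        for name, table in (("centromere", self.centromeres), ("extent", self.extents)):
            for c, (s, e) in table.items():
                L = self.chrom_lengths.get(c)
                if L is None:
                    raise IntervalError(f"{name} on unknown chromosome {c}")
                if not (0 <= s < e <= L):
                    raise IntervalError(f"{name} [{s},{e}) outside chromosome {c} (len {L})")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def effective_span(self, chrom: str) -> tuple[int, int]:
        """[start, end) used as the circle for shift-based null models."""
        if chrom in self.extents:
            return self.extents[chrom]
        return (0, self.chrom_lengths[chrom])

    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))


_COLS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class IntervalSet:
    """A set of genomic intervals with optional labels and scores."""

    df: pd.DataFrame

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        labels: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
    ) -> "IntervalSet":
        recs = list(records)
        df = pd.DataFrame(recs, columns=_COLS) if recs else pd.DataFrame(columns=_COLS)
        df["start"] = df.get("start", pd.Series(dtype=int)).astype(np.int64)
        df["end"] = df.get("end", pd.Series(dtype=int)).astype(np.int64)
        if labels is not None:
            df["label"] = list(labels)
        if scores is not None:
            df["score"] = list(scores)
        return cls(df)

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                row = [parts[0], int(parts[1]), int(parts[2])]
                row.append(parts[3] if len(parts) > 3 else "")
                row.append(float(parts[4]) if len(parts) > 4 and parts[4] != "." else np.nan)
                rows.append(row)
        df = pd.DataFrame(rows, columns=_COLS + ["label", "score"])
        return cls(df)

    def write_bed(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write("# coordinates: 0-based half-open (BED)\n")
            for r in self.df.itertuples(index=False):
                cols = [r.chrom, str(int(r.start)), str(int(r.end))]
                if "label" in self.df.columns:
                    cols.append(str(getattr(r, "label", "")))
                if "score" in self.df.columns:
                    sc = getattr(r, "score", np.nan)
                    cols.append("." if pd.isna(sc) else f"{sc:g}")
                fh.write("\t".join(cols) + "\n")

    def __len__(self) -> int:
        return len(self.df)

    def is_empty(self) -> bool:
        return len(self.df) == 0

    def validate(self, layout: GenomeLayout) -> None:
        for r in self.df.itertuples(index=False):
            L = layout.chrom_lengths.get(r.chrom)
            if L is None:
                raise IntervalError(f"record on unknown chromosome {r.chrom}")
            if not (0 <= r.start < r.end <= L):
                raise IntervalError(
                    f"record {r.chrom}:{r.start}-{r.end} outside chromosome bounds (len {L})"
                )

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        )

    def total_bp(self) -> int:
        if self.is_empty():
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def by_chrom(self) -> Mapping[str, pd.DataFrame]:
        if self.is_empty():
            return {}
        return dict(tuple(self.df.groupby("chrom", sort=True)))

    def restrict(self, chroms: Iterable[str]) -> "IntervalSet":
        chroms = set(chroms)
        return IntervalSet(self.df[self.df["chrom"].isin(chroms)].reset_index(drop=True))


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals under strict-overlap semantics.

    Book-ended intervals (next start == previous end) stay separate.
    """
    if len(starts) == 0:
        return starts, ends
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] < out_e[-1]:  # strict overlap only
            if e[i] > out_e[-1]:
                out_e[-1] = e[i]
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge(a: IntervalSet, layout: GenomeLayout | None = None) -> IntervalSet:
    """Union of strictly overlapping records per chromosome.

    Total bp is conserved or reduced, never increased. ``layout`` triggers
    bounds validation when given.
    """
    if layout is not None:
        a.validate(layout)
    rows = []
    for chrom, sub in a.by_chrom().items():
        s, e = _merge_arrays(sub["start"].to_numpy(), sub["end"].to_numpy())
        rows.extend((chrom, int(x), int(y)) for x, y in zip(s, e))
    return IntervalSet.from_records(rows)


def intersect_bp(a: IntervalSet, b: IntervalSet) -> tuple[int, IntervalSet]:
    """Total overlap in bp between two merged interval sets, plus the pieces.

    Both inputs are expected merged (non-overlapping within chromosome);
    results are undefined otherwise.
    """
    total = 0
    rows: list[tuple[str, int, int]] = []
    bmap = b.by_chrom()
    for chrom, sub_a in a.by_chrom().items():
        sub_b = bmap.get(chrom)
        if sub_b is None:
            continue
        oa = np.argsort(sub_a["start"].to_numpy(), kind="stable")
        ob = np.argsort(sub_b["start"].to_numpy(), kind="stable")
        sa = sub_a["start"].to_numpy()[oa]
        ea = sub_a["end"].to_numpy()[oa]
        sb = sub_b["start"].to_numpy()[ob]
        eb = sub_b["end"].to_numpy()[ob]
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
                rows.append((chrom, int(lo), int(hi)))
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return total, IntervalSet.from_records(rows)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-base set difference a − b (both merged)."""
    rows: list[tuple[str, int, int]] = []
    bmap = b.by_chrom()
    for chrom, sub_a in a.by_chrom().items():
        sub_b = bmap.get(chrom)
        if sub_b is None:
            rows.extend((chrom, int(s), int(e)) for s, e in zip(sub_a["start"], sub_a["end"]))
            continue
        ob = np.argsort(sub_b["start"].to_numpy(), kind="stable")
        sb = sub_b["start"].to_numpy()[ob]
        eb = sub_b["end"].to_numpy()[ob]
        for s, e in zip(sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            cur = int(s)
            for bs, be in zip(sb, eb):
                if be <= cur:
                    continue
                if bs >= e:
                    break
                if bs > cur:
                    rows.append((chrom, cur, int(min(bs, e))))
                cur = max(cur, int(be))
                if cur >= e:
                    break
            if cur < e:
                rows.append((chrom, cur, int(e)))
    return IntervalSet.from_records(rows)


def trim_to_extent(a: IntervalSet, layout: GenomeLayout) -> IntervalSet:
    """Clip records to each chromosome's data extent; drop records outside.

    Downstream shift-based nulls then treat the extent as the effective
    chromosome length, so features cannot rotate into data-free territory.
    """
    rows, labels, scores = [], [], []
    has_label = "label" in a.df.columns
    has_score = "score" in a.df.columns
    n_dropped = 0
    for r in a.df.itertuples(index=False):
        es, ee = layout.effective_span(r.chrom)
        s, e = max(r.start, es), min(r.end, ee)
        if s >= e:
            n_dropped += 1
            continue
        rows.append((r.chrom, int(s), int(e)))
        if has_label:
            labels.append(r.label)
        if has_score:
            scores.append(r.score)
    out = IntervalSet.from_records(
        rows, labels=labels if has_label else None, scores=scores if has_score else None
    )
    return out


def circular_shift(
    a: IntervalSet, layout: GenomeLayout, offsets: Mapping[str, float]
) -> IntervalSet:
    """Rotate features around each chromosome by ``offsets[chrom]`` (fraction).

    The circle is the chromosome's effective span. A record spanning the wrap
    point splits into two records. Total bp is conserved.
    """
    rows: list[tuple[str, int, int]] = []
    for chrom, sub in a.by_chrom().items():
        es, ee = layout.effective_span(chrom)
        eff = ee - es
        frac = float(offsets.get(chrom, 0.0))
        shift = int(round(frac * eff))
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            length = int(e - s)
            ns = es + (int(s) - es + shift) % eff
            ne = ns + length
            if ne <= ee:
                rows.append((chrom, ns, ne))
            else:
                rows.append((chrom, ns, ee))
                rows.append((chrom, es, es + (ne - ee)))
    return IntervalSet.from_records(rows)


def empirical_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    """Lower/upper-tail empirical CDF p-values with a 1/reps floor."""
    null = np.asarray(null, dtype=float)
    reps = len(null)
    p_lower = max(float(np.mean(null <= observed)), 1.0 / reps)
    p_upper = max(float(np.mean(null >= observed)), 1.0 / reps)
    return min(p_lower, 1.0), min(p_upper, 1.0)


@dataclass(frozen=True)
class OverlapTestResult:
    """Observed overlap, its circular-shift null, and two one-sided p-values."""

    observed_bp: float
    null: np.ndarray
    p_lower: float
    p_upper: float
    direction: str  # "enriched" | "depleted"
    degenerate: bool = False

    @property
    def p(self) -> float:
        """The smaller one-sided p (direction is reported alongside)."""
        return self.p_lower if self.direction == "depleted" else self.p_upper


def overlap_bootstrap(
    a: IntervalSet,
    b: IntervalSet,
    layout: GenomeLayout,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    statistic: Callable[[IntervalSet], float] | None = None,
) -> OverlapTestResult:
    """Circularization bootstrap of the overlap between two tracks.

    Track ``a`` is rotated per chromosome by i.i.d. uniform fractional
    offsets each rep; track ``b`` stays fixed. ``statistic`` defaults to
    total intersection bp with ``b``.
    """
    import warnings

    if reps < 100:
        warnings.warn(f"reps={reps} < 100: empirical percentiles will be unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_m = merge(a)
    b_m = merge(b)
    if statistic is None:
        statistic = lambda s: intersect_bp(s, b_m)[0]  # noqa: E731
    observed = float(statistic(a_m))
    chroms = sorted(a_m.by_chrom())
    null = np.empty(reps)
    for i in range(reps):
        offs = {c: rng.random() for c in chroms}
        null[i] = statistic(circular_shift(a_m, layout, offs))
    p_lower, p_upper = empirical_p(null, observed)
    direction = "enriched" if observed >= float(np.median(null)) else "depleted"
    degenerate = bool(np.all(null == observed))
    return OverlapTestResult(observed, null, p_lower, p_upper, direction, degenerate)


def derive_introns(genes: IntervalSet, cds: IntervalSet) -> IntervalSet:
    """Intronic territory as gene bp minus CDS bp (genes assumed CDS+intron)."""
    return subtract(merge(genes), merge(cds))


def feature_enrichment(
    targets: IntervalSet,
    annotation_classes: Mapping[str, IntervalSet],
    layout: GenomeLayout,
    reps: int = 1000,
    seed: int = 0,
    intersect_with: IntervalSet | None = None,
) -> dict[str, OverlapTestResult | None]:
    """Circular-shift enrichment of ``targets`` in each annotation class.

    With ``intersect_with`` the test subject becomes targets ∩ intersect_with
    (e.g. persistent incompatibilities = long-term barriers ∩ BDMI regions).
    Returns None for a class when the subject is empty (test skipped).
    """
    subject = merge(targets)
    if intersect_with is not None:
        _, subject = intersect_bp(subject, merge(intersect_with))
    rng = np.random.default_rng(seed)
    out: dict[str, OverlapTestResult | None] = {}
    for label in annotation_classes:
        if subject.is_empty():
            out[label] = None
            continue
        out[label] = overlap_bootstrap(
            subject, annotation_classes[label], layout, reps=reps, seed=rng
        )
    return out


@dataclass(frozen=True)
class CentromereTestResult:
    observed_distances: np.ndarray
    null_distances: np.ndarray
    p_value: float
    n_excluded: int


def centromere_distance_test(
    features: IntervalSet,
    layout: GenomeLayout,
    reps: int = 1000,
    seed: int = 0,
) -> CentromereTestResult:
    """Are features closer to centromere centers than circularly expected?

    Distances are |feature center − centromere center| per feature, on
    chromosomes with a defined centromere (others excluded). The null pools
    the same distances over ``reps`` random rotations; significance is a
    one-sided rank-sum test (alternative: observed distances are smaller).
    """
    if not layout.centromeres:
        raise IntervalError("no chromosome has centromere data")
    rng = np.random.default_rng(seed)
    usable = features.restrict(layout.centromeres)
    n_excluded = len(features) - len(usable)
    if usable.is_empty():
        raise IntervalError("no feature lies on a chromosome with centromere data")
    cent_center = {
        c: 0.5 * (s + e) for c, (s, e) in layout.centromeres.items()
    }

    def distances(ivs: IntervalSet) -> np.ndarray:
        centers = 0.5 * (ivs.df["start"] + ivs.df["end"]).to_numpy()
        cc = ivs.df["chrom"].map(cent_center).to_numpy(dtype=float)
        return np.abs(centers - cc)

    obs = distances(usable)
    chroms = sorted(set(usable.df["chrom"]))
    pooled = []
    for _ in range(reps):
        offs = {c: rng.random() for c in chroms}
        pooled.append(distances(circular_shift(usable, layout, offs)))
    null = np.concatenate(pooled)
    stat = _scistats.mannwhitneyu(obs, null, alternative="less")
    return CentromereTestResult(obs, null, float(stat.pvalue), n_excluded)


def chromosome_enrichment(
    features: IntervalSet,
    chromosome: str,
    layout: GenomeLayout,
    reps: int = 1000,
    seed: int = 0,
    null: str = "label_permutation",
) -> OverlapTestResult:
    """Is feature bp disproportionately located on one chromosome?

    The default null reassigns each feature to a chromosome with probability
    proportional to chromosome length and a uniform position, keeping feature
    lengths; within-chromosome rotation (``null="rotation"``) is degenerate
    for this question (it cannot move bp between chromosomes) and is flagged.
    """
    if chromosome not in layout.chrom_lengths:
        raise IntervalError(f"unknown chromosome {chromosome}")
    rng = np.random.default_rng(seed)
    merged = merge(features)
    observed = float(merged.restrict([chromosome]).total_bp())
    lengths = merged.df["end"].to_numpy() - merged.df["start"].to_numpy() if not merged.is_empty() else np.array([], dtype=int)
    chroms = list(layout.chrom_lengths)
    weights = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    target_idx = chroms.index(chromosome)
    if null == "rotation":
        res = overlap_bootstrap(
            merged,
            IntervalSet.from_records([(chromosome, 0, layout.chrom_lengths[chromosome])]),
            layout,
            reps=reps,
            seed=rng,
        )
        return res
    null_vals = np.empty(reps)
    for i in range(reps):
        assign = rng.choice(len(chroms), size=len(lengths), p=weights)
        null_vals[i] = float(lengths[assign == target_idx].sum())
    p_lower, p_upper = empirical_p(null_vals, observed)
    direction = "enriched" if observed >= float(np.median(null_vals)) else "depleted"
    return OverlapTestResult(observed, null_vals, p_lower, p_upper, direction,
                             bool(np.all(null_vals == observed)))
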