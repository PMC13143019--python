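"""Two-locus ancestry statistics and the candidate-incompatibility scan.

A Bateson-Dobzhansky-Muller incompatibility (BDMI) removes one recombinant
two-locus ancestry class from a hybrid population. For ancestry classes
00/01/10/11 with frequencies g_ij (complete-case over individuals called at
both loci), the scan statistic is

    X(2) = g_r * g_R - g00 * g11,

where r is the rarer and R the commoner recombinant class (01/10). X(2) is
negative when the parental classes jointly exceed the recombinant product —
the footprint of selection against a recombinant combination — zero under
full symmetry, and invariant to relabeling 01 <-> 10 or 0 <-> 1. D' is the
standard normalized linkage disequilibrium of the two ancestry indicators.

Because a causal incompatibility distorts linked sites around it, calls are
made on window pairs (20 consecutive ancestry-informative markers per
window, 400 cross-window comparisons), with two genome-wide bootstrap null
distributions calibrating how much signal a window pair shows by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import AimPanel, AncestryMatrix
from .intervals import IntervalSet

__all__ = [
    "PairCounts",
    "PairStat",
    "AimWindow",
    "PairwiseStats",
    "BdmiCallSet",
    "X2_BASE_CUTOFF",
    "pair_counts",
    "pair_stat",
    "pairwise_stats",
    "make_windows",
    "window_pair_stats",
    "all_window_pair_stats",
    "bootstrap_fraction_null",
    "bootstrap_aim_position_null",
    "call_candidates",
    "cutoff_grid",
]

log = logging.getLogger(__name__)

X2_BASE_CUTOFF = -0.005
WINDOW_SIZE = 20


@dataclass(frozen=True)
class PairCounts:
    """Two-locus ancestry tabulation over complete-case individuals."""

    n00: int
    n01: int
    n10: int
    n11: int
    usable: bool = True

    @property
    def n_eff(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def g(self) -> np.ndarray:
        """(g00, g01, g10, g11)."""
        n = self.n_eff
        return np.array([self.n00, self.n01, self.n10, self.n11], dtype=float) / n


@dataclass(frozen=True)
class PairStat:
    x2: float
    d_prime: float
    ordering_ok: bool
    direction: str | None  # "01" or "10" when ordering_ok
    usable: bool = True


def pair_counts(matrix: AncestryMatrix, i: int, j: int, min_n: int | None = None) -> PairCounts:
    """Tabulate the four two-locus ancestry combinations at AIMs i and j.

    Only individuals non-missing at both AIMs are counted; the pair is
    unusable when fewer than ``min_n`` remain (default: half the samples).
    """
    if i == j:
        raise ValueError("pair_counts requires two distinct AIMs")
    if min_n is None:
        min_n = matrix.n_samples // 2
    a, b = matrix.data[:, i], matrix.data[:, j]
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n00 = int(np.sum((a == 0) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n11 = int(np.sum((a == 1) & (b == 1)))
    return PairCounts(n00, n01, n10, n11, usable=(n00 + n01 + n10 + n11) >= min_n)


def pair_stat(c: PairCounts) -> PairStat:
    """X(2) and D' from a two-locus tabulation.

    Pairs monomorphic at either locus in the complete-case subset are
    flagged unusable (both statistics undefined there).
    """
    if not c.usable or c.n_eff == 0:
        return PairStat(np.nan, np.nan, False, None, usable=False)
    g00, g01, g10, g11 = c.g
    p0, p1 = g00 + g01, g10 + g11  # ancestry 0/1 marginals at locus i
    q0, q1 = g00 + g10, g01 + g11  # at locus j
    if min(p0, p1, q0, q1) == 0.0:
        return PairStat(np.nan, np.nan, False, None, usable=False)
    r, big_r = (g01, g10) if g01 <= g10 else (g10, g01)
    x2 = r * big_r - g00 * g11
    ordering_ok = bool(r < g00 and r < g11 and big_r > g00 and big_r > g11)
    direction = None
    if ordering_ok:
        direction = "01" if g01 <= g10 else "10"
    d = g00 * g11 - g01 * g10
    d_max = min(p0 * q1, p1 * q0) if d > 0 else min(p0 * q0, p1 * q1)
    d_prime = d / d_max if d_max > 0 else 0.0
    return PairStat(float(x2), float(d_prime), ordering_ok, direction)


@dataclass(frozen=True)
class PairwiseStats:
    """All-pairs X(2)/D' matrices over the AIMs of an ancestry matrix.

    ``x2`` and ``d_prime`` are symmetric (n_aims, n_aims) with NaN on the
    diagonal and at unusable pairs; ``usable`` is the validity mask.
    """

    x2: np.ndarray
    d_prime: np.ndarray
    usable: np.ndarray
    min_n: int

    def pool(self) -> np.ndarray:
        """Genome-wide pool of usable X(2) values (upper triangle)."""
        iu = np.triu_indices(self.x2.shape[0], k=1)
        vals = self.x2[iu]
        return vals[self.usable[iu]]


def pairwise_stats(matrix: AncestryMatrix, min_n: int | None = None) -> PairwiseStats:
    """Vectorized all-pairs computation (matches pair_stat exactly)."""
    if min_n is None:
        min_n = matrix.n_samples // 2
    d = matrix.data
    A = (d == 1).astype(np.float64)
    B = (d == 0).astype(np.float64)
    n11 = A.T @ A
    n00 = B.T @ B
    n01 = B.T @ A  # ancestry 0 at locus i, 1 at locus j
    n10 = A.T @ B
    n_eff = n00 + n01 + n10 + n11
    with np.errstate(divide="ignore", invalid="ignore"):
        g00, g01, g10, g11 = (n / n_eff for n in (n00, n01, n10, n11))
        p0, p1 = g00 + g01, g10 + g11
        q0, q1 = g00 + g10, g01 + g11
        usable = (
            (n_eff >= min_n)
            & (p0 > 0) & (p1 > 0) & (q0 > 0) & (q1 > 0)
        )
        np.fill_diagonal(usable, False)
        r = np.minimum(g01, g10)
        big_r = np.maximum(g01, g10)
        x2 = r * big_r - g00 * g11
        dld = g00 * g11 - g01 * g10
        d_max = np.where(dld > 0, np.minimum(p0 * q1, p1 * q0), np.minimum(p0 * q0, p1 * q1))
        d_prime = np.where(d_max > 0, dld / d_max, 0.0)
    x2[~usable] = np.nan
    d_prime[~usable] = np.nan
    return PairwiseStats(x2, d_prime, usable, min_n)


@dataclass(frozen=True)
class AimWindow:
    """Exactly ``WINDOW_SIZE`` consecutive AIMs on one chromosome."""

    window_id: int
    chrom: str
    aim_indices: np.ndarray  # column indices into the AncestryMatrix
    start: int  # bp of first AIM
    end: int  # bp past the last AIM

    @property
    def size(self) -> int:
        return len(self.aim_indices)


def make_windows(
    panel_sites: pd.DataFrame, size: int = WINDOW_SIZE, step: int | None = None
) -> list[AimWindow]:
    """Windows of ``size`` consecutive AIMs per chromosome.

    With the default ``step = size`` the windows are disjoint blocks and the
    trailing remainder (< size AIMs) is dropped. A smaller step gives
    sliding (overlapping) windows, whose spans then merge into larger
    candidate regions downstream. ``panel_sites`` needs chrom/pos columns in
    genome order (an AimPanel's df or an AncestryMatrix's sites).
    """
    if step is None:
        step = size
    if not 1 <= step <= size:
        raise ValueError("step must lie in [1, size]")
    windows: list[AimWindow] = []
    n_dropped = 0
    wid = 0
    col = np.arange(len(panel_sites))
    for chrom, sub in panel_sites.groupby("chrom", sort=False):
        idx = col[panel_sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        starts = list(range(0, len(idx) - size + 1, step))
        covered = starts[-1] + size if starts else 0
        n_dropped += len(idx) - covered
        for k in starts:
            block = idx[k : k + size]
            windows.append(
                AimWindow(wid, str(chrom), block, int(pos[k]), int(pos[k + size - 1]) + 1)
            )
            wid += 1
    if n_dropped:
        log.info("make_windows: dropped %d trailing AIMs", n_dropped)
    return windows


def window_pair_stats(
    pw: PairwiseStats, wi: AimWindow, wj: AimWindow, base_cutoff: float = X2_BASE_CUTOFF
) -> dict | None:
    """Summaries of the size x size cross-window AIM comparisons.

    Means are over usable pairs; ``frac_below`` is the usable fraction with
    X(2) < base_cutoff; ``n_candidate_aims`` counts AIMs (of the 2*size)
    with at least one such comparison. Returns None when no pair is usable.
    """
    if wi.window_id == wj.window_id:
        raise ValueError("window_pair_stats requires two distinct windows")
    block_x2 = pw.x2[np.ix_(wi.aim_indices, wj.aim_indices)]
    block_dp = pw.d_prime[np.ix_(wi.aim_indices, wj.aim_indices)]
    ok = pw.usable[np.ix_(wi.aim_indices, wj.aim_indices)]
    n_ok = int(ok.sum())
    if n_ok == 0:
        return None
    below = ok & (block_x2 < base_cutoff)
    return {
        "window_i": wi.window_id,
        "window_j": wj.window_id,
        "n_comparisons": int(ok.size),
        "n_usable": n_ok,
        "mean_x2": float(np.nanmean(np.where(ok, block_x2, np.nan))),
        "mean_dprime": float(np.nanmean(np.where(ok, block_dp, np.nan))),
        "frac_below": float(below.sum() / n_ok),
        "n_candidate_aims": int(below.any(axis=1).sum() + below.any(axis=0).sum()),
        "interchromosomal": wi.chrom != wj.chrom,
    }


def all_window_pair_stats(
    pw: PairwiseStats, windows: list[AimWindow], base_cutoff: float = X2_BASE_CUTOFF
) -> pd.DataFrame:
    """Vectorized window-pair table over all unordered window pairs.

    Works for disjoint and sliding windows alike (the gather below does not
    assume the windows partition the AIM index).
    """
    if not windows:
        return pd.DataFrame()
    size = windows[0].size
    kept = np.concatenate([w.aim_indices for w in windows])
    nw = len(windows)
    X = pw.x2[np.ix_(kept, kept)].reshape(nw, size, nw, size)
    DP = pw.d_prime[np.ix_(kept, kept)].reshape(nw, size, nw, size)
    OK = pw.usable[np.ix_(kept, kept)].reshape(nw, size, nw, size)
    n_ok = OK.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        mean_x2 = np.nansum(np.where(OK, X, 0.0), axis=(1, 3)) / n_ok
        mean_dp = np.nansum(np.where(OK, DP, 0.0), axis=(1, 3)) / n_ok
    below = OK & (X < base_cutoff)
    frac = below.sum(axis=(1, 3)) / np.where(n_ok > 0, n_ok, 1)
    cand = below.any(axis=3).sum(axis=1) + below.any(axis=1).sum(axis=2)
    chroms = np.array([w.chrom for w in windows])
    rows = []
    skipped = 0
    for i in range(nw):
        for j in range(i + 1, nw):
            if n_ok[i, j] == 0:
                skipped += 1
                continue
            rows.append(
                (
                    i, j, size * size, int(n_ok[i, j]), float(mean_x2[i, j]),
                    float(mean_dp[i, j]), float(frac[i, j]), int(cand[i, j]),
                    chroms[i] != chroms[j],
                )
            )
    if skipped:
        log.info("all_window_pair_stats: skipped %d pairs with no usable comparison", skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "window_i", "window_j", "n_comparisons", "n_usable", "mean_x2",
            "mean_dprime", "frac_below", "n_candidate_aims", "interchromosomal",
        ],
    )


def bootstrap_fraction_null(
    pool: np.ndarray,
    n_draw: int = 400,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    base_cutoff: float = X2_BASE_CUTOFF,
) -> tuple[np.ndarray, float]:
    """Null for ``frac_below``: resample n_draw X(2) values from the genome-
    wide pool with replacement, per rep; returns (fractions, 99th pct)."""
    import warnings

    if len(pool) == 0:
        raise ValueError("empty X(2) pool")
    if reps < 100:
        warnings.warn(f"reps={reps} < 100: the 99th percentile will be unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(pool, size=(reps, n_draw), replace=True)
    fracs = (draws < base_cutoff).mean(axis=1)
    return fracs, float(np.percentile(fracs, 99))


def bootstrap_aim_position_null(
    pw: PairwiseStats,
    n_draw: int = 2 * WINDOW_SIZE,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    base_cutoff: float = X2_BASE_CUTOFF,
) -> tuple[np.ndarray, float]:
    """Null for ``n_candidate_aims``: per rep, draw ``n_draw`` AIMs genome-
    wide without replacement, split into two pseudo-windows of n_draw/2,
    and count AIMs with >= 1 cross comparison below the base cutoff."""
    n_aims = pw.x2.shape[0]
    if n_aims < n_draw:
        raise ValueError(f"need >= {n_draw} AIMs genome-wide, have {n_aims}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = n_draw // 2
    counts = np.empty(reps, dtype=int)
    for rix in range(reps):
        pick = rng.choice(n_aims, size=n_draw, replace=False)
        block = pw.x2[np.ix_(pick[:half], pick[half:])]
        ok = pw.usable[np.ix_(pick[:half], pick[half:])]
        below = ok & (block < base_cutoff)
        counts[rix] = int(below.any(axis=1).sum() + below.any(axis=0).sum())
    return counts, float(np.percentile(counts, 99))


def cutoff_grid() -> np.ndarray:
    """The mean-X(2) ceiling grid: -0.0600 to -0.0050 in steps of 0.0025."""
    return np.round(np.arange(-0.0600, -0.0050 + 1e-9, 0.0025), 4)


@dataclass(frozen=True)
class BdmiCallSet:
    """Candidate window pairs at one cutoff plus merged candidate regions."""

    cutoff: float
    pairs: pd.DataFrame  # candidate rows of the window-pair table
    regions: IntervalSet  # merged regions; score column = degree
    window_region: dict[int, int] = field(default_factory=dict)  # window id -> region row

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def interchromosomal_proportion(self) -> float:
        if self.pairs.empty:
            return float("nan")
        return float(self.pairs["interchromosomal"].mean())


def _merge_count(records: list[tuple[str, int, int, int]]) -> tuple[list, dict[int, int]]:
    """Merge window intervals, counting absorbed records (strict overlap).

    Input rows are (chrom, start, end, window_id); output rows are
    (chrom, start, end, count) plus a window-id -> region-row map.
    """
    out: list[list] = []
    wmap: dict[int, int] = {}
    for chrom, s, e, wid in sorted(records, key=lambda r: (r[0], r[1], r[2])):
        if out and out[-1][0] == chrom and s < out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
            out[-1][3] += 1
        else:
            out.append([chrom, s, e, 1])
        wmap[wid] = len(out) - 1
    return out, wmap


def call_candidates(
    stats: pd.DataFrame,
    windows: list[AimWindow],
    frac_thresh: float,
    count_thresh: float,
    cutoff: float = X2_BASE_CUTOFF,
) -> BdmiCallSet:
    """Candidate window pairs and merged candidate regions at one cutoff.

    A window pair is a candidate iff mean X(2) <= cutoff, its fraction of
    below-cutoff comparisons strictly exceeds ``frac_thresh`` (99th
    percentile of the resampled-fraction null), and its below-cutoff AIM
    count strictly exceeds ``count_thresh`` (99th percentile of the
    resampled-position null). Candidate windows become intervals (one record
    per candidate-pair membership) merged into regions; a region's degree is
    the number of records absorbed.
    """
    if stats.empty:
        return BdmiCallSet(cutoff, stats, IntervalSet.from_records([]))
    sel = (
        (stats["mean_x2"] <= cutoff)
        & (stats["frac_below"] > frac_thresh)
        & (stats["n_candidate_aims"] > count_thresh)
    )
    pairs = stats[sel].reset_index(drop=True)
    wlookup = {w.window_id: w for w in windows}
    records = []
    for r in pairs.itertuples(index=False):
        for wid in (r.window_i, r.window_j):
            w = wlookup[wid]
            records.append((w.chrom, w.start, w.end, wid))
    merged, wmap = _merge_count(records)
    regions = IntervalSet.from_records(
        [(c, s, e) for c, s, e, _ in merged], scores=[n for *_, n in merged]
    )
    return BdmiCallSet(cutoff, pairs, regions, wmap)
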