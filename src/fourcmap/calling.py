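"""Significant-interaction calling by permutation FDR on windowed counts.

For each analysed region, per-fragment read counts on the region's mappable
fragments are summed over sliding windows of w fragments (default 3).  The
null is generated by uniformly shuffling the multiset of per-fragment counts
across those fragments: a window sum T is accepted as a significance
threshold when the mean number of permuted windows reaching T, relative to
the number of observed windows reaching T, estimates an FDR below the cutoff
(default 0.01).  Candidate thresholds are restricted to the top fdr_prob
(default 0.05) tail of observed window sums — the "top fifth percentile of
interactions".  Runs of significant windows are merged into intervals, and
each interval is graded for robustness:

* category 1 — still significant with the highest-count member fragment
  zeroed out;
* category 2 — significant when that fragment is replaced by the mean of
  its two flanking fragments;
* category 3 — significant only with all fragments included.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .quantify import FragmentCounts
from .restriction import FragmentMap

DEFAULT_WINDOW = 3
DEFAULT_ITERATIONS = 1000
DEFAULT_FDR = 0.01
DEFAULT_FDR_PROB = 0.05


@dataclass(frozen=True)
class CallerParams:
    window: int = DEFAULT_WINDOW
    iterations: int = DEFAULT_ITERATIONS
    fdr: float = DEFAULT_FDR
    fdr_prob: float = DEFAULT_FDR_PROB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0,1)")
        if not (0 < self.fdr_prob <= 1):
            raise ValueError("fdr_prob must be in (0,1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class Region:
    """A calling region: a whole chromosome or a sub-interval of one."""

    label: str
    chrom: str
    start: int | None = None  # None = whole chrom
    end: int | None = None


@dataclass
class SignificantInterval:
    chrom: str
    start: int
    end: int
    member_fragments: list[int]  # global fragment indices on chrom
    peak_stat: float
    category: int  # 1 | 2 | 3
    threshold: float
    region: str = ""
    bait: str = ""
    library: str = ""

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class FdrRow:
    threshold: float
    n_observed: int
    mean_permuted: float
    fdr_hat: float


@dataclass
class CallResult:
    intervals: list["SignificantInterval"]
    threshold: float | None
    fdr_table: list[FdrRow]
    seed: int


def window_sums(counts: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of w consecutive entries (step 1)."""
    if len(counts) < w:
        raise ValueError(f"need >= {w} mappable fragments, got {len(counts)}")
    cs = np.concatenate(([0.0], np.cumsum(counts, dtype=float)))
    return cs[w:] - cs[:-w]


def candidate_thresholds(obs: np.ndarray, fdr_prob: float) -> list[float]:
    """Distinct observed window sums in the top fdr_prob tail.

    The floor is the m-th largest observed sum with m = max(1,
    floor(fdr_prob * n_windows)); candidates are the distinct observed
    values at or above it, ascending.
    """
    n = len(obs)
    m = max(1, math.floor(fdr_prob * n))
    floor_val = np.sort(obs)[::-1][m - 1]
    return sorted(set(float(v) for v in obs if v >= floor_val))


def permutation_threshold(
    counts: np.ndarray, params: CallerParams, rng: np.random.Generator
) -> tuple[float | None, list[FdrRow]]:
    """Smallest candidate threshold with estimated FDR below params.fdr.

    For each candidate T, FDR^(T) = (mean over permutations of the number
    of permuted window sums >= T) / (number of observed window sums >= T).
    Each permutation uniformly shuffles the per-fragment count multiset;
    the permutation stream is fully reproducible from ``rng``.  Returns
    (None, table) when no candidate qualifies ("no significant
    interactions") — e.g. for permutation-invariant all-equal counts.
    """
    w = params.window
    obs = window_sums(counts, w)
    cands = np.array(candidate_thresholds(obs, params.fdr_prob))
    # total permuted exceedances per candidate, accumulated exactly as ints
    totals = np.zeros(len(cands), dtype=np.int64)
    for _ in range(params.iterations):
        perm = rng.permutation(counts)
        ws = np.sort(window_sums(perm, w))
        # count of ws >= T for each candidate
        totals += len(ws) - np.searchsorted(ws, cands, side="left")
    table: list[FdrRow] = []
    threshold: float | None = None
    for T, total in zip(cands, totals):
        n_obs = int(np.sum(obs >= T))
        mean_perm = total / params.iterations
        fdr_hat = mean_perm / n_obs
        table.append(FdrRow(float(T), n_obs, mean_perm, fdr_hat))
        if threshold is None and fdr_hat < params.fdr:
            threshold = float(T)
    return threshold, table


def call_significant(
    counts: np.ndarray, threshold: float, w: int
) -> list[tuple[int, int, float]]:
    """Merge significant windows into runs.

    Returns (first member local index, last member local index inclusive,
    peak window sum) per merged run; windows whose fragment ranges overlap
    or touch are merged.
    """
    obs = window_sums(counts, w)
    sig = np.flatnonzero(obs >= threshold)
    runs: list[tuple[int, int, float]] = []
    for i in sig:
        i = int(i)
        if runs and i <= runs[-1][1] + 1:  # window ranges overlap or touch
            first, last_end, peak = runs[-1]
            runs[-1] = (first, i + w - 1, max(peak, float(obs[i])))
        else:
            runs.append((i, i + w - 1, float(obs[i])))
    return runs


def classify_category(
    counts: np.ndarray, first: int, last: int, threshold: float, w: int
) -> int:
    """Robustness category of the interval spanning local fragments
    [first, last] (inclusive), called at ``threshold``.

    The highest-count member fragment m (lowest index on ties) is zeroed
    (category 1 test) or replaced by the mean of its flanking fragments in
    mappable-index space (category 2 test); the interval keeps its category
    if any member window — a window whose start lies in [first, last-w+1] —
    still reaches the threshold.
    """
    members = np.arange(first, last + 1)
    m = int(members[np.argmax(counts[members])])

    def member_windows_reach(x: np.ndarray) -> bool:
        ws = window_sums(x, w)
        starts = range(first, last - w + 2)
        return any(ws[s] >= threshold for s in starts)

    zeroed = counts.astype(float).copy()
    zeroed[m] = 0.0
    if member_windows_reach(zeroed):
        return 1

    flanks = [j for j in (m - 1, m + 1) if 0 <= j < len(counts)]
    averaged = counts.astype(float).copy()
    averaged[m] = float(np.mean([counts[j] for j in flanks])) if flanks else 0.0
    if member_windows_reach(averaged):
        return 2
    return 3


def _region_seed(base_seed: int, bait: str, label: str) -> int:
    """Stable per-(bait, region) RNG seed below 2**31."""
    return (base_seed * 1_000_003 + zlib.crc32(f"{bait}:{label}".encode())) % (2**31)


def call_region(
    counts: FragmentCounts,
    fragmap: FragmentMap,
    region: Region,
    params: CallerParams,
    exclude_fragments: set[int] | None = None,
) -> CallResult:
    """Run the threshold → call → classify chain for one region.

    Only mappable fragments inside the region enter the analysis;
    ``exclude_fragments`` (typically the bait fragment and its uncut
    neighbours, already zeroed upstream) are dropped from the vector
    entirely so they cannot dilute the null.
    """
    chrom = region.chrom
    frags = fragmap.fragments[chrom]
    lo = region.start if region.start is not None else 0
    hi = region.end if region.end is not None else fragmap.chrom_length(chrom)
    excl = exclude_fragments or set()
    sel = [
        f.index
        for f in frags
        if f.mappable and f.start < hi and f.end > lo and f.index not in excl
    ]
    vec = counts.counts[chrom][sel].astype(float)
    seed = _region_seed(params.seed, counts.bait, region.label)
    rng = np.random.default_rng(seed)
    threshold, table = permutation_threshold(vec, params, rng)
    intervals: list[SignificantInterval] = []
    if threshold is not None:
        for first, last, peak in call_significant(vec, threshold, params.window):
            cat = classify_category(vec, first, last, threshold, params.window)
            members = [sel[i] for i in range(first, last + 1)]
            intervals.append(
                SignificantInterval(
                    chrom=chrom,
                    start=frags[members[0]].start,
                    end=frags[members[-1]].end,
                    member_fragments=members,
                    peak_stat=peak,
                    category=cat,
                    threshold=threshold,
                    region=region.label,
                    bait=counts.bait,
                    library=counts.library,
                )
            )
    return CallResult(intervals, threshold, table, seed)


def call_bait(
    counts: FragmentCounts,
    fragmap: FragmentMap,
    bait,
    regions: list[Region],
    params: CallerParams,
) -> dict[str, CallResult]:
    """Call significant interactions independently per configured region.

    The bait fragment and its two index-adjacent neighbours are excluded
    from every region (their counts were zeroed by the upstream filters;
    exclusion guards against misconfiguration).
    """
    labels = [r.label for r in regions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels")
    bf = bait.bait_fragment
    excl = {bf.index - 1, bf.index, bf.index + 1}
    out: dict[str, CallResult] = {}
    for region in regions:
        ex = excl if region.chrom == bf.chrom else set()
        out[region.label] = call_region(counts, fragmap, region, params, ex)
    return out


def write_bed9(intervals: list[SignificantInterval], path, red: set[int] | None = None) -> None:
    """BED9 of called intervals: name = category, score = peak scaled to
    0-1000, itemRgb red for replicate-reproducible category-1 calls (set
    downstream), orange otherwise."""
    peak_max = max((iv.peak_stat for iv in intervals), default=1.0) or 1.0
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            colour = "255,0,0" if red and i in red else "255,165,0"
            score = int(round(1000 * iv.peak_stat / peak_max))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcat{iv.category}\t{score}\t.\t"
                f"{iv.start}\t{iv.end}\t{colour}\n"
            )
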