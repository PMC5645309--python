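"""Contact-profile smoothing and read-distance summaries.

The displayed 4C profile is the RPM-normalised windowed sum over nine
successive restriction fragments; the cumulative-distance curve shows what
fraction of a chromosome's reads lie within a given distance of the bait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demux import BaitSpec
from .quantify import FragmentCounts
from .restriction import FragmentMap

DEFAULT_WINDOW = 9  # successive fragments per smoothing window


def rpm_normalize(counts: FragmentCounts) -> FragmentCounts:
    """Scale counts to reads-per-million of the library's retained total.

    Each fragment count becomes count * 1e6 / total retained reads, so the
    values sum to 1e6 when every retained read sits on the map.  The
    denominator is the post-filter retained total (stored in the filter
    report when filters ran, otherwise the on-map sum), which keeps
    replicate profiles comparable after blacklist differences.
    """
    total = counts.filter_report.get("retained", counts.total())
    if total <= 0:
        raise ValueError("cannot RPM-normalise a library with zero retained reads")
    out = counts.copy()
    out.counts = {c: arr.astype(float) * 1e6 / total for c, arr in counts.counts.items()}
    return out


@dataclass
class SmoothedProfile:
    bait: str
    window: int
    values: dict[str, np.ndarray]  # RPM units, per fragment

    def to_bedgraph(self, fragmap: FragmentMap, path) -> None:
        with open(path, "w") as fh:
            for chrom, frags in fragmap.fragments.items():
                arr = self.values[chrom]
                for f in frags:
                    if arr[f.index]:
                        fh.write(f"{chrom}\t{f.start}\t{f.end}\t{arr[f.index]:.6g}\n")


def running_window_sum(
    norm: FragmentCounts, k: int = DEFAULT_WINDOW, mean: bool = False
) -> SmoothedProfile:
    """Windowed sum (optionally mean) over k successive fragments.

    The window is centred on each fragment and truncated at chromosome
    edges; with ``mean=True`` each value is divided by the number of
    fragments actually in the window.  k=1 is the identity.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("window size must be odd and >= 1")
    half = (k - 1) // 2
    values = {}
    for chrom, arr in norm.counts.items():
        n = len(arr)
        cs = np.concatenate(([0.0], np.cumsum(arr, dtype=float)))
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        sums = cs[hi] - cs[lo]
        values[chrom] = sums / (hi - lo) if mean else sums
    return SmoothedProfile(norm.bait, k, values)


@dataclass
class CumulativeCurve:
    """Cumulative fraction of a chromosome's reads along the coordinate.

    Points are (fragment midpoint, cumulative % of chrom reads), monotone
    non-decreasing from ~0 to 100; ``bait_position`` marks the viewpoint.
    """

    bait: str
    chrom: str
    positions: np.ndarray   # fragment midpoints, bp
    cumulative_pct: np.ndarray
    bait_position: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# bait={self.bait}\tchrom={self.chrom}\tbait_pos={self.bait_position}\n")
            fh.write("position\tcumulative_pct\n")
            for p, c in zip(self.positions, self.cumulative_pct):
                fh.write(f"{p:.1f}\t{c:.6f}\n")


def cumulative_distance_curve(
    counts: FragmentCounts, bait: BaitSpec, fragmap: FragmentMap, chrom: str
) -> CumulativeCurve:
    """Cumulative read percentage along one chromosome.

    Fragments are taken in genomic order; the curve value at a fragment
    midpoint is the percentage of the chromosome's reads at or before that
    fragment, ending at exactly 100%.
    """
    arr = counts.counts[chrom].astype(float)
    total = arr.sum()
    if total <= 0:
        raise ValueError(f"no reads on {chrom}")
    mids = np.array([f.midpoint for f in fragmap.fragments[chrom]])
    cum = np.cumsum(arr) / total * 100.0
    return CumulativeCurve(counts.bait, chrom, mids, cum, bait.bait_fragment.midpoint)


def plot_profile(profile: SmoothedProfile, fragmap: FragmentMap, chrom: str, ax=None):
    """Minimal unstyled profile plot (midpoint vs smoothed RPM)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mids = [f.midpoint for f in fragmap.fragments[chrom]]
    ax.plot(mids, profile.values[chrom], lw=0.8)
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel(f"RPM ({profile.window}-fragment sum)")
    ax.set_title(profile.bait)
    return ax
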