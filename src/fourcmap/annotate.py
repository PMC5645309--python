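"""Results-level annotation of called interactions.

Covers replicate reproducibility (with the red/orange colour classes),
domain inside/outside counts, gene-body and promoter overlap, transcription
factor co-binding clusters, enhancer-candidate calling, TSS-distance
naming, and the cohesin-without-CTCF status used to flag candidate
CTCF-independent enhancer loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import SignificantInterval

DEFAULT_MIN_TFS = 6      # distinct TFs co-bound at one location
DEFAULT_MAX_DIST = 2000  # bp between a cluster and a supporting interaction
DEFAULT_PROMOTER_EXT = 2000  # bp upstream of the TSS counted as promoter


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    name: str = ""


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    strand: str  # '+' | '-'
    tx_start: int  # 0-based
    tx_end: int

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True)
class DomainInterval:
    chrom: str
    start: int
    end: int
    label: str = "domain"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("domain start must be < end")


@dataclass
class ReproducibleInterval:
    """Intersection of a rep1 and a rep2 call, with the colour class."""

    chrom: str
    start: int
    end: int
    colour: str  # 'red' | 'orange'
    rep1: SignificantInterval
    rep2: SignificantInterval
    bait: str = ""
    region: str = ""


@dataclass
class TFCluster:
    chrom: str
    start: int
    end: int
    tfs: frozenset[str]

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)


@dataclass
class EnhancerCandidate:
    cluster: TFCluster
    supports: list[tuple[str, ReproducibleInterval]]  # (bait, interval)
    distance: int  # bp, min gap to any supporting interval (0 = overlap)
    name: str = ""
    rad21_no_ctcf: bool = False
    cne_overlap: bool = False


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between two half-open intervals; 0 when they overlap or touch."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def intersect_replicates(
    calls_rep1: list[SignificantInterval],
    calls_rep2: list[SignificantInterval],
    bait: str = "",
    region: str = "",
) -> list[ReproducibleInterval]:
    """Keep interactions found in both replicates.

    Category-3 (single-fragment-driven) calls are discarded first; a rep1
    and a rep2 interval that overlap by >= 1 bp yield one output spanning
    their intersection.  Colour: red iff both parents are category 1 —
    the most robust reproducible interactions — else orange.
    """
    out: list[ReproducibleInterval] = []
    r1 = [iv for iv in calls_rep1 if iv.category in (1, 2)]
    r2 = [iv for iv in calls_rep2 if iv.category in (1, 2)]
    for a in r1:
        for b in r2:
            if a.chrom != b.chrom:
                continue
            if _overlap(a.start, a.end, b.start, b.end) >= 1:
                colour = "red" if a.category == 1 and b.category == 1 else "orange"
                out.append(
                    ReproducibleInterval(
                        a.chrom,
                        max(a.start, b.start),
                        min(a.end, b.end),
                        colour,
                        a,
                        b,
                        bait=bait,
                        region=region,
                    )
                )
    return out


def count_domain(intervals, domain: DomainInterval) -> tuple[int, int]:
    """(inside, outside) counts by interval midpoint; sums to len(intervals)."""
    inside = sum(
        1
        for iv in intervals
        if iv.chrom == domain.chrom and domain.start <= (iv.start + iv.end) / 2 < domain.end
    )
    return inside, len(list(intervals)) - inside


def promoter_window(gene: GeneModel, ext: int = DEFAULT_PROMOTER_EXT) -> tuple[int, int]:
    """Half-open span of the ext-bp promoter 5' of the TSS, on the gene's strand."""
    if gene.strand == "+":
        return max(0, gene.tx_start - ext), gene.tx_start
    return gene.tx_end, gene.tx_end + ext


def gene_overlap(
    intervals, genes: list[GeneModel], promoter_ext: int = DEFAULT_PROMOTER_EXT
) -> list[tuple[object, GeneModel]]:
    """All (interval, gene) hits where the interval overlaps the gene body
    or its promoter window (``promoter_ext`` bp upstream of the TSS)."""
    hits = []
    for iv in intervals:
        for g in genes:
            if iv.chrom != g.chrom:
                continue
            p_start, p_end = promoter_window(g, promoter_ext)
            body = _overlap(iv.start, iv.end, g.tx_start, g.tx_end) >= 1
            prom = _overlap(iv.start, iv.end, p_start, p_end) >= 1
            if body or prom:
                hits.append((iv, g))
    return hits


def find_tf_clusters(
    peak_tracks: dict[str, list[Peak]], min_tfs: int = DEFAULT_MIN_TFS
) -> list[TFCluster]:
    """Locations co-bound by >= min_tfs distinct TFs.

    Coverage by distinct-TF multiplicity is computed with a sweep line over
    the union of peaks; maximal runs with multiplicity >= min_tfs are the
    cluster cores, each extended to the union span of its contributing
    peaks.  Six TFs overlapping only pairwise in a chain never reach a
    multiplicity of six and yield no cluster.
    """
    if len(peak_tracks) != len(set(peak_tracks)):
        raise ValueError("duplicate TF track names")
    # sweep per chromosome; a TF contributes multiplicity 1 where >=1 of its
    # peaks covers the position (overlapping peaks of one TF do not stack)
    chroms = {p.chrom for peaks in peak_tracks.values() for p in peaks}
    clusters: list[TFCluster] = []
    for chrom in sorted(chroms):
        events: list[tuple[int, int]] = []  # (pos, +1/-1)
        for tf, peaks in peak_tracks.items():
            ivs = sorted((p.start, p.end) for p in peaks if p.chrom == chrom)
            # merge the TF's own peaks so it counts once per position
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                events.append((s, +1))
                events.append((e, -1))
        events.sort()
        depth, core_start = 0, None
        cores: list[tuple[int, int]] = []
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < min_tfs <= depth:
                core_start = pos
            elif prev >= min_tfs > depth:
                cores.append((core_start, pos))
                core_start = None
        for c_start, c_end in cores:
            members: set[str] = set()
            span_start, span_end = c_start, c_end
            for tf, peaks in peak_tracks.items():
                for p in peaks:
                    if p.chrom == chrom and _overlap(p.start, p.end, c_start, c_end) >= 1:
                        members.add(tf)
                        span_start = min(span_start, p.start)
                        span_end = max(span_end, p.end)
            clusters.append(TFCluster(chrom, span_start, span_end, frozenset(members)))
    return clusters


def call_enhancer_candidates(
    clusters: list[TFCluster],
    intervals_per_bait: dict[str, list[ReproducibleInterval]],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[EnhancerCandidate]:
    """TF clusters with a reproducible interaction at or within max_dist bp.

    One candidate per qualifying cluster; every supporting (bait, interval)
    pair within range is recorded, so per-bait connectivity stays
    queryable.  The distance is the span-to-span gap (0 on overlap).
    """
    out: list[EnhancerCandidate] = []
    for cluster in clusters:
        supports = []
        best = None
        for bait, ivs in intervals_per_bait.items():
            for iv in ivs:
                if iv.chrom != cluster.chrom:
                    continue
                gap = _gap(cluster.start, cluster.end, iv.start, iv.end)
                if gap <= max_dist:
                    supports.append((bait, iv))
                    best = gap if best is None else min(best, gap)
        if supports:
            out.append(EnhancerCandidate(cluster, supports, best))
    return out


def name_by_tss_distance(candidate: EnhancerCandidate, tss: int, strand: str) -> str:
    """Signed-kb label relative to the TSS in transcription direction.

    Positive = downstream of the TSS; the distance is taken from the
    cluster midpoint and rounded to the nearest kb.
    """
    mid = (candidate.cluster.start + candidate.cluster.end) / 2
    dist = mid - tss if strand == "+" else tss - mid
    kb = int(round(abs(dist) / 1000))
    sign = "+" if dist >= 0 else "-"
    return f"{sign}{kb}"


def cohesin_ctcf_status(
    candidate: EnhancerCandidate, rad21: list[Peak], ctcf: list[Peak]
) -> bool:
    """True iff cohesin (Rad21) binds the cluster span with no CTCF peak there."""
    c = candidate.cluster
    has_rad21 = any(
        p.chrom == c.chrom and _overlap(p.start, p.end, c.start, c.end) >= 1 for p in rad21
    )
    has_ctcf = any(
        p.chrom == c.chrom and _overlap(p.start, p.end, c.start, c.end) >= 1 for p in ctcf
    )
    return has_rad21 and not has_ctcf


def cne_status(candidate: EnhancerCandidate, cnes: list[Peak]) -> bool:
    c = candidate.cluster
    return any(
        p.chrom == c.chrom and _overlap(p.start, p.end, c.start, c.end) >= 1 for p in cnes
    )


def annotate_candidates(
    candidates: list[EnhancerCandidate],
    tss: int,
    strand: str,
    rad21: list[Peak],
    ctcf: list[Peak],
    cnes: list[Peak] | None = None,
) -> list[EnhancerCandidate]:
    """Fill in name, cohesin/CTCF and CNE status for each candidate."""
    for cand in candidates:
        cand.name = name_by_tss_distance(cand, tss, strand)
        cand.rad21_no_ctcf = cohesin_ctcf_status(cand, rad21, ctcf)
        if cnes is not None:
            cand.cne_overlap = cne_status(cand, cnes)
    return candidates


# ---------------------------------------------------------------------------
# plain-text I/O

def read_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return peaks


def read_gene_models(path) -> list[GeneModel]:
    """Minimal gene-model TSV: name, chrom, strand, txStart, txEnd."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("name\t"):
                continue
            name, chrom, strand, s, e = line.rstrip("\n").split("\t")[:5]
            genes.append(GeneModel(name, chrom, strand, int(s), int(e)))
    return genes


def write_reproducible_bed9(intervals: list[ReproducibleInterval], path) -> None:
    colours = {"red": "255,0,0", "orange": "255,165,0"}
    peak_max = max(
        (max(iv.rep1.peak_stat, iv.rep2.peak_stat) for iv in intervals), default=1.0
    ) or 1.0
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(round(1000 * max(iv.rep1.peak_stat, iv.rep2.peak_stat) / peak_max))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.bait}:{iv.colour}\t{score}\t.\t"
                f"{iv.start}\t{iv.end}\t{colours[iv.colour]}\n"
            )


def write_candidates_tsv(candidates: list[EnhancerCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\tn_tfs\tsupports\tdistance\trad21_no_ctcf\tcne_overlap\n")
        for c in candidates:
            supports = ",".join(sorted({bait for bait, _ in c.supports}))
            fh.write(
                f"{c.name}\t{c.cluster.chrom}\t{c.cluster.start}\t{c.cluster.end}\t"
                f"{c.cluster.n_tfs}\t{supports}\t{c.distance}\t"
                f"{int(c.rad21_no_ctcf)}\t{int(c.cne_overlap)}\n"
            )
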