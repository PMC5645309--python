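"""Synthetic 4C-seq scenarios with known planted ground truth.

Generates toy genomes carrying primary-enzyme sites at a controlled
density, annotation tracks (a two-promoter gene, TF/cohesin/CTCF/CNE
peaks with planted co-binding clusters), and seeded paired-end read
libraries: two replicates with distance-decay contacts plus planted
high-contact enhancer fragments, and one sparse non-ligated control.

The contact model is a truncated power law on fragment midpoints,

    w_j = eps + gamma_j * beta^{cross(j)} * (1 + |mid_j - mid_bait|/s)^(-alpha)

for cis fragments, where gamma_j > 1 on planted enhancer fragments,
cross(j) = 1 outside the domain containing the bait (contacts across the
domain boundary are attenuated by beta), plus a small uniform weight on
trans fragments.  Planted enhancers are runs of three consecutive
fragments: real interactions span multiple restriction fragments, and a
single spiked fragment carries no multi-fragment support for the caller's
robustness categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import DomainInterval, GeneModel, Peak
from .demux import BaitSpec, ReadPair
from .restriction import (
    BFAI,
    DPNII,
    Enzyme,
    FragmentMap,
    digest_sequence,
    flag_mappability,
    reverse_complement,
)

TF_NAMES = [
    "Fli1", "Erg", "Gata2", "Lyl1", "Lmo2", "Meis1", "Pu1",
    "Runx1", "Scl", "Gfi1b", "Mtgr1", "Ldb1", "Cbfb",
]  # thirteen haematopoietic progenitor TFs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ContactModel:
    decay_scale: float = 50_000.0   # bp; power-law scale of cis decay
    decay_exponent: float = 1.0     # alpha > 0
    background: float = 0.02        # eps, flat cis weight per fragment
    boundary_attenuation: float = 0.3  # beta in (0,1]
    trans_weight: float = 0.005     # flat weight per trans fragment
    planted: dict[int, float] = field(default_factory=dict)  # frag index -> gamma
    domain: DomainInterval | None = None

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if not (0 < self.boundary_attenuation <= 1):
            raise ValueError("boundary_attenuation must be in (0,1]")


@dataclass
class LibrarySpec:
    n_reads: int = 200_000
    p_self: float = 0.2    # self-ligated fraction
    p_uncut: float = 0.05  # uncut fraction
    read_len: int = 75
    seed: int = 0
    is_control: bool = False
    control_sparsity: float = 0.01  # fraction of fragments a control touches

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.p_self + self.p_uncut >= 1:
            raise ValueError("p_self + p_uncut must be < 1")


@dataclass
class GroundTruth:
    planted_fragments: dict[str, list[int]]  # bait -> fragment indices (bait chrom)
    tf_clusters: list[tuple[str, int, int, int]]  # (chrom, start, end, n_tfs)
    domain: DomainInterval


@dataclass
class ToyData:
    genome: dict[str, str]
    fragmap: FragmentMap
    genes: list[GeneModel]
    peak_tracks: dict[str, list[Peak]]  # per-TF
    rad21: list[Peak]
    ctcf: list[Peak]
    cnes: list[Peak]
    domain: DomainInterval
    truth: GroundTruth | None = None


def _scrub_motif(seq: np.ndarray, motif: bytes) -> None:
    """Destroy every occurrence of motif in-place (replace its last base)."""
    m = motif.decode()
    repl = ord("A") if m[-1] != "A" else ord("C")
    s = seq.tobytes().decode()
    while True:
        hits = []
        i = s.find(m)
        while i != -1:
            hits.append(i)
            i = s.find(m, i + 1)
        if not hits:
            return
        for h in hits:
            seq[h + len(m) - 1] = repl
        s = seq.tobytes().decode()


def random_chromosome(length: int, site_density: float, rng: np.random.Generator,
                      motif: str = "GATC") -> str:
    """Random DNA with motif occurrences as a controlled point process.

    The motif is planted at 4-bp-aligned slots, each independently with
    probability 4 * site_density, on an otherwise motif-free random
    background, so the number of sites is Binomial(length/4, 4*site_density)
    with mean length * site_density.
    """
    if not (0 < site_density * len(motif) < 1):
        raise ValueError(f"infeasible site_density {site_density}")
    seq = rng.integers(0, 4, size=length).astype(np.uint8)
    seq = _BASES[seq]
    _scrub_motif(seq, motif.encode())
    k = len(motif)
    n_slots = length // k - 1
    slots = (1 + np.flatnonzero(rng.random(n_slots) < site_density * k)) * k
    mb = np.frombuffer(motif.encode(), dtype=np.uint8)
    for s in slots:
        seq[s : s + k] = mb
    return seq.tobytes().decode()


def make_toy_genome(
    n_chrom: int = 2,
    chrom_len: int = 500_000,
    site_density: float = 1 / 250,
    seed: int = 0,
    mappability_read_len: int = 36,
    enzyme: Enzyme = DPNII,
) -> ToyData:
    """Deterministic toy genome + fragment map + annotation tracks.

    Chromosome 1 carries the full scenario: a domain spanning the central
    2/5 of the chromosome, a bait near its centre, five planted enhancer
    loci inside the domain (each a 3-fragment run, decorated with a 6-TF
    co-binding cluster, a Rad21 peak and no CTCF), a 5-TF decoy cluster
    next to a planted locus, and a distant 6-TF decoy outside the domain.
    A short duplicated block makes a couple of fragments unmappable so the
    mappability path is exercised.  Further chromosomes provide trans
    background.  Byte-identical output for a fixed seed.
    """
    if chrom_len * site_density < 200:
        raise ValueError("chrom_len too small: need >= 200 expected fragments")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for c in range(n_chrom):
        length = chrom_len if c == 0 else max(chrom_len // 5, 50_000)
        genome[f"chr{c + 1}"] = random_chromosome(length, site_density, rng, enzyme.motif)

    # duplicated block -> non-unique fragment-start k-mers (unmappable)
    if n_chrom >= 2:
        src = genome["chr1"]
        block = src[10_000:10_150]
        dst = genome["chr2"]
        genome["chr2"] = dst[:5_000] + block + dst[5_000 + len(block):]

    fragmap = digest_sequence(genome, enzyme)
    fragmap = flag_mappability(fragmap, genome, mappability_read_len)

    chrom = "chr1"
    length = len(genome[chrom])
    domain = DomainInterval(chrom, int(length * 0.30), int(length * 0.70), "domain")
    centre = length // 2

    # two-promoter gene: P1 (active convention) upstream of P2
    p1_tss = centre + int(length * 0.01)
    p2_tss = p1_tss + int(length * 0.05)
    genes = [
        GeneModel("toygene-P1", chrom, "+", p1_tss, p2_tss + 20_000),
        GeneModel("toygene-P2", chrom, "+", p2_tss, p2_tss + 20_000),
    ]

    # planted enhancer loci: comparable contact distances either side of
    # the bait, all inside the domain
    offsets = [int(length * f) for f in (-0.14, -0.12, -0.10, 0.11, 0.13)]
    frags = fragmap.fragments[chrom]
    planted_runs: list[list[int]] = []
    for off in offsets:
        i = fragmap.locate(chrom, centre + off).index
        while not all(frags[j].mappable for j in (i - 1, i, i + 1)):
            i += 1
        planted_runs.append([i - 1, i, i + 1])

    def cluster_peaks(pos: int, n_tfs: int, jitter_rng) -> list[tuple[str, Peak]]:
        out = []
        for tf in TF_NAMES[:n_tfs]:
            j = int(jitter_rng.integers(-30, 31))
            out.append((tf, Peak(chrom, pos - 150 + j, pos + 150 + j, tf)))
        return out

    peak_tracks: dict[str, list[Peak]] = {tf: [] for tf in TF_NAMES}
    rad21: list[Peak] = []
    ctcf: list[Peak] = []
    cnes: list[Peak] = []
    truth_clusters: list[tuple[str, int, int, int]] = []

    for run in planted_runs:
        mid = int(frags[run[1]].midpoint)
        for tf, p in cluster_peaks(mid, 6, rng):
            peak_tracks[tf].append(p)
        rad21.append(Peak(chrom, mid - 120, mid + 120, "Rad21"))
        truth_clusters.append((chrom, mid - 180, mid + 180, 6))

    # 5-TF decoy adjacent to the first planted locus: close to a real
    # interaction but below the co-binding threshold
    decoy5_pos = int(frags[planted_runs[0][1]].midpoint) + 800
    for tf, p in cluster_peaks(decoy5_pos, 5, rng):
        peak_tracks[tf].append(p)
    truth_clusters.append((chrom, decoy5_pos - 180, decoy5_pos + 180, 5))

    # 6-TF decoy far outside the domain, > 2 kb from any interaction
    decoy6_pos = int(length * 0.06)
    for tf, p in cluster_peaks(decoy6_pos, 6, rng):
        peak_tracks[tf].append(p)
    rad21.append(Peak(chrom, decoy6_pos - 120, decoy6_pos + 120, "Rad21"))
    ctcf.append(Peak(chrom, decoy6_pos - 100, decoy6_pos + 100, "CTCF"))
    truth_clusters.append((chrom, decoy6_pos - 180, decoy6_pos + 180, 6))

    # cohesin/CTCF at the domain boundaries, as at real TAD borders
    for pos in (domain.start, domain.end):
        rad21.append(Peak(chrom, pos - 200, pos + 200, "Rad21"))
        ctcf.append(Peak(chrom, pos - 200, pos + 200, "CTCF"))

    # CNEs on two of the planted loci
    for run in planted_runs[:2]:
        mid = int(frags[run[1]].midpoint)
        cnes.append(Peak(chrom, mid - 100, mid + 100, "CNE"))

    truth = GroundTruth(
        planted_fragments={"P1": [i for run in planted_runs for i in run]},
        tf_clusters=truth_clusters,
        domain=domain,
    )
    return ToyData(genome, fragmap, genes, peak_tracks, rad21, ctcf, cnes, domain, truth)


def make_bait(
    data: ToyData,
    name: str = "P1",
    position: int | None = None,
    primer_len: int = 16,
    secondary: Enzyme = BFAI,
) -> BaitSpec:
    """Build a BaitSpec at a genomic position of the toy genome.

    The forward primer is the ``primer_len`` bp at the 3' end of the bait
    fragment plus the downstream digestion site; the reverse primer reads
    back from just inside the fragment's 5' boundary.
    """
    chrom = "chr1"
    if position is None:
        position = len(data.genome[chrom]) // 2
    frag = data.fragmap.locate(chrom, position)
    seq = data.genome[chrom]
    motif = data.fragmap.enzyme.motif
    k = len(motif)
    fwd = seq[frag.end - primer_len : frag.end] + seq[frag.end : frag.end + k]
    rev = reverse_complement(seq[frag.start + k : frag.start + k + primer_len])
    return BaitSpec(name, fwd, rev, frag, secondary, primary_motif=motif)


def contact_weights(
    fragmap: FragmentMap, bait: BaitSpec, model: ContactModel
) -> dict[str, np.ndarray]:
    """Per-fragment capture weights under the contact model.

    Cis fragments follow the truncated power law with planted boosts and
    boundary attenuation; trans fragments get the flat trans weight.  The
    bait fragment and first fragments of each chromosome (whose starts are
    not cut sites, so no ligation junction can begin there) get weight 0.
    """
    bf = bait.bait_fragment
    dom = model.domain
    weights: dict[str, np.ndarray] = {}
    for chrom in fragmap.chroms:
        frags = fragmap.fragments[chrom]
        n = len(frags)
        if chrom != bf.chrom:
            w = np.full(n, model.trans_weight)
        else:
            mids = np.array([f.midpoint for f in frags])
            decay = (1 + np.abs(mids - bf.midpoint) / model.decay_scale) ** (
                -model.decay_exponent
            )
            gamma = np.ones(n)
            for idx, g in model.planted.items():
                gamma[idx] = g
            cross = np.zeros(n, dtype=bool)
            if dom is not None:
                cross = ~((mids >= dom.start) & (mids < dom.end))
            atten = np.where(cross, model.boundary_attenuation, 1.0)
            w = model.background + gamma * atten * decay
            w[bf.index] = 0.0
        w[0] = 0.0  # chromosome start is not a cut site
        weights[chrom] = w
    return weights


def simulate_4c_library(
    genome: dict[str, str],
    fragmap: FragmentMap,
    bait: BaitSpec,
    model: ContactModel,
    spec: LibrarySpec,
) -> tuple[list[ReadPair], dict[str, np.ndarray]]:
    """Simulate one paired-end 4C library plus its true count table.

    Each read pair is, with probability p_self, a self-ligation (captured
    fragment = the bait fragment), with p_uncut an uncut product (the
    fragment 3'-adjacent to the bait), and otherwise a ligation capture
    drawn from the contact-model weights — or, for a control library, drawn
    uniformly from a sparse random subset of fragments (ligation omitted,
    so no contact signal).  The forward mate runs from the bait primer
    through the primary digestion site into the captured fragment; the
    reverse mate starts with the reverse primer.  Mate order is randomised.
    Deterministic for a fixed spec.seed; self + uncut + captured counts sum
    to n_reads exactly.
    """
    if model.domain is not None:
        bf = bait.bait_fragment
        if not (model.domain.start <= bf.midpoint < model.domain.end):
            raise ValueError("bait fragment must lie inside the model domain")
    rng = np.random.default_rng(spec.seed)
    bf = bait.bait_fragment
    n_self, n_uncut, n_cap = rng.multinomial(
        spec.n_reads, [spec.p_self, spec.p_uncut, 1 - spec.p_self - spec.p_uncut]
    )

    true_counts = {c: np.zeros(fragmap.n_fragments(c), dtype=np.int64) for c in fragmap.chroms}
    chrom_order = list(fragmap.chroms)

    if spec.is_control:
        # sparse uniform noise: a small random subset of fragments, never on
        # planted ground-truth fragments (which must stay recoverable)
        forbidden = {(bf.chrom, i) for i in model.planted}
        forbidden |= {(bf.chrom, i + d) for i in model.planted for d in (-1, 1)}
        pool = [
            (c, f.index)
            for c in chrom_order
            for f in fragmap.fragments[c]
            if f.index > 0 and (c, f.index) not in forbidden
        ]
        k = max(1, int(len(pool) * spec.control_sparsity))
        chosen = rng.choice(len(pool), size=k, replace=False)
        probs = np.zeros(len(pool))
        probs[chosen] = 1.0 / k
        draw = rng.multinomial(n_cap, probs)
        cap_per_frag = {}
        for (c, i), n in zip(pool, draw):
            if n:
                cap_per_frag[(c, i)] = int(n)
    else:
        weights = contact_weights(fragmap, bait, model)
        flat = np.concatenate([weights[c] for c in chrom_order])
        probs = flat / flat.sum()
        draw = rng.multinomial(n_cap, probs)
        cap_per_frag = {}
        pos = 0
        for c in chrom_order:
            n = fragmap.n_fragments(c)
            nz = np.flatnonzero(draw[pos : pos + n])
            for i in nz:
                cap_per_frag[(c, int(i))] = int(draw[pos + i])
            pos += n

    # assemble per-read capture list: self -> bait frag, uncut -> 3' neighbour
    capture_list: list[tuple[str, int]] = []
    capture_list += [(bf.chrom, bf.index)] * int(n_self)
    uncut_idx = min(bf.index + 1, fragmap.n_fragments(bf.chrom) - 1)
    capture_list += [(bf.chrom, uncut_idx)] * int(n_uncut)
    for key, n in sorted(cap_per_frag.items()):
        capture_list += [key] * n
    order = rng.permutation(len(capture_list))

    motif = fragmap.enzyme.motif
    k = len(motif)
    prefix = bait.fwd_primer[:-k]
    rev_primer = bait.rev_primer
    bait_seq = genome[bf.chrom]
    rev_tail = reverse_complement(
        bait_seq[max(0, bf.start - 40) : bf.start + k + len(rev_primer)]
    )
    qual_template = "I"
    pairs: list[ReadPair] = []
    swap = rng.random(len(order)) < 0.5
    for out_i, idx in enumerate(order):
        chrom, frag_i = capture_list[idx]
        f = fragmap.fragments[chrom][frag_i]
        cap_len = spec.read_len - len(prefix)
        cap = genome[chrom][f.start : f.start + cap_len]
        seq1 = prefix + cap
        seq2 = (rev_primer + rev_tail)[: spec.read_len]
        q1, q2 = qual_template * len(seq1), qual_template * len(seq2)
        rid = f"{bait.name}:{spec.seed}:{out_i}"
        if swap[out_i]:
            pairs.append(ReadPair(rid, seq2, q2, seq1, q1))
        else:
            pairs.append(ReadPair(rid, seq1, q1, seq2, q2))
        true_counts[chrom][frag_i] += 1
    return pairs, true_counts


# ---------------------------------------------------------------------------
# track output

def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tchrom\tdetail\n")
        for bait, idxs in truth.planted_fragments.items():
            fh.write(f"planted\t{truth.domain.chrom}\t{bait}:{','.join(map(str, idxs))}\n")
        for chrom, s, e, n in truth.tf_clusters:
            fh.write(f"tf_cluster\t{chrom}\t{s}-{e}:{n}\n")
        fh.write(f"domain\t{truth.domain.chrom}\t{truth.domain.start}-{truth.domain.end}\n")
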