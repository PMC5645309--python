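"""Read-to-fragment assignment and artefact filtering.

Trimmed captured-fragment reads are placed on the genome by unique exact
match (both strands), assigned to the primary-enzyme fragment containing
the 5'-most aligned base, and then cleaned with the three standard 4C
filters: self-ligated reads (the bait fragment itself), uncut reads (the
two fragments index-adjacent to the bait), and fragments carrying any
signal in the non-ligated control library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demux import BaitSpec, TrimmedRead
from .restriction import FragmentMap, reverse_complement


@dataclass
class FragmentCounts:
    """Per-fragment read counts for one bait/library.

    ``counts`` holds one int/float array per chromosome, index-aligned with
    the FragmentMap.  ``total_assigned`` is the number of reads placed on
    any fragment before filtering.
    """

    bait: str
    library: str  # rep1 | rep2 | control
    counts: dict[str, np.ndarray]
    total_assigned: int = 0
    n_unmapped: int = 0
    filter_report: dict[str, int] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def copy(self) -> "FragmentCounts":
        return FragmentCounts(
            self.bait,
            self.library,
            {c: arr.copy() for c, arr in self.counts.items()},
            self.total_assigned,
            self.n_unmapped,
            dict(self.filter_report),
        )

    @classmethod
    def zeros(cls, bait: str, library: str, fragmap: FragmentMap) -> "FragmentCounts":
        return cls(
            bait,
            library,
            {c: np.zeros(fragmap.n_fragments(c), dtype=np.int64) for c in fragmap.chroms},
        )

    def to_tsv(self, fragmap: FragmentMap, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tfrag_index\tcount\n")
            for chrom, frags in fragmap.fragments.items():
                arr = self.counts[chrom]
                for f in frags:
                    fh.write(f"{chrom}\t{f.start}\t{f.end}\t{f.index}\t{arr[f.index]}\n")

    def to_bedgraph(self, fragmap: FragmentMap, path) -> None:
        with open(path, "w") as fh:
            for chrom, frags in fragmap.fragments.items():
                arr = self.counts[chrom]
                for f in frags:
                    if arr[f.index]:
                        fh.write(f"{chrom}\t{f.start}\t{f.end}\t{arr[f.index]}\n")


class ExactAligner:
    """Unique exact-match placement of reads on a small genome.

    Seeds on the first ``seed_len`` bases through a hash index, verifies the
    full read, and reports a locus only when the read (or its reverse
    complement) occurs exactly once genome-wide.  The reported position is
    the leftmost genomic coordinate of the match; strand records which
    orientation matched.
    """

    def __init__(self, genome: dict[str, str], seed_len: int = 30):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_len = seed_len
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                self.index.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    def _occurrences(self, read: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, pos in self.index.get(read[: self.seed_len], ()):
            if self.genome[chrom].startswith(read, pos):
                hits.append((chrom, pos))
        return hits

    def align(self, read: str) -> tuple[str, int, str] | None:
        """Return (chrom, leftmost pos, strand) of the unique exact hit."""
        if len(read) < self.seed_len:
            raise ValueError(f"read shorter than seed length {self.seed_len}")
        fwd = self._occurrences(read)
        rev = self._occurrences(reverse_complement(read))
        if len(fwd) + len(rev) != 1:
            return None
        if fwd:
            chrom, pos = fwd[0]
            return chrom, pos, "+"
        chrom, pos = rev[0]
        return chrom, pos, "-"


def align_exact(read: str, genome: dict[str, str]) -> tuple[str, int, str] | None:
    """Brute-force unique exact match of one read (both strands).

    Convenience wrapper around a full scan; use ExactAligner for streams.
    """
    from .restriction import find_motif_positions

    fwd, rev = [], []
    rc = reverse_complement(read)
    for chrom, seq in genome.items():
        seq = seq.upper()
        fwd += [(chrom, p) for p in find_motif_positions(seq, read)]
        rev += [(chrom, p) for p in find_motif_positions(seq, rc)]
    if len(fwd) + len(rev) != 1:
        return None
    return (*fwd[0], "+") if fwd else (*rev[0], "-")


def align_reads(reads: list[TrimmedRead], aligner: ExactAligner):
    """Yield (read, locus-or-None) for a stream of trimmed reads."""
    for r in reads:
        yield r, aligner.align(r.seq)


def count_per_fragment(
    loci, fragmap: FragmentMap, bait: str = "", library: str = ""
) -> FragmentCounts:
    """Tally aligned loci per primary-enzyme fragment.

    Each locus is (chrom, leftmost pos, strand, read length); the counted
    base is the 5'-most aligned base of the read — the leftmost coordinate
    on the plus strand, the rightmost on the minus strand.  ``None`` loci
    (unmapped/multi-mapped reads) are tallied but not counted.
    """
    fc = FragmentCounts.zeros(bait, library, fragmap)
    starts = {c: fragmap.starts(c) for c in fragmap.chroms}
    for locus in loci:
        if locus is None:
            fc.n_unmapped += 1
            continue
        chrom, pos, strand, read_len = locus
        five_prime = pos if strand == "+" else pos + read_len - 1
        i = int(np.searchsorted(starts[chrom], five_prime, side="right")) - 1
        fc.counts[chrom][i] += 1
        fc.total_assigned += 1
    return fc


def apply_filters(
    counts: FragmentCounts, bait: BaitSpec, control: FragmentCounts
) -> FragmentCounts:
    """Zero self-ligated, uncut, and control-blacklisted fragments.

    Removes, in the 4C sense: (1) the bait fragment itself (self-ligation),
    (2) the two fragments immediately index-adjacent to the bait (uncut
    products), and (3) every fragment with >= 1 read in the non-ligated
    control library.  All other counts pass through unchanged; the filter
    report records reads removed per rule.  Idempotent, and the three rules
    commute.
    """
    for chrom in counts.counts:
        if chrom not in control.counts or len(control.counts[chrom]) != len(counts.counts[chrom]):
            raise ValueError("counts and control use different fragment maps")

    out = counts.copy()
    bf = bait.bait_fragment
    chrom_arr = out.counts[bf.chrom]

    removed_self = int(chrom_arr[bf.index])
    chrom_arr[bf.index] = 0

    removed_uncut = 0
    for j in (bf.index - 1, bf.index + 1):
        if 0 <= j < len(chrom_arr):
            removed_uncut += int(chrom_arr[j])
            chrom_arr[j] = 0

    removed_control = 0
    for chrom, arr in out.counts.items():
        hit = control.counts[chrom] >= 1
        removed_control += int(arr[hit].sum())
        arr[hit] = 0

    out.filter_report = {
        "self_ligated": removed_self,
        "uncut": removed_uncut,
        "control_blacklist": removed_control,
        "retained": int(out.total()),
    }
    return out
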