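"""Bait demultiplexing, orientation checking, trimming and length filtering.

4C-seq libraries multiplex several viewpoints (baits) in one sequencing run;
each read pair carries the bait's forward primer (which extends up to and
including the primary digestion site) on one mate and the reverse primer on
the other.  This stage assigns pairs to baits with zero mismatches, enforces
the forward/reverse orientation, strips the primer up to (but excluding) the
digestion-site motif, quality-trims the 3' end, and drops reads shorter than
the minimum mappable length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .restriction import Enzyme, Fragment

DEFAULT_QUAL_MIN = 20   # Phred floor for 3' trimming
DEFAULT_LEN_MIN = 30    # shortest read worth aligning, in bp


@dataclass(frozen=True)
class BaitSpec:
    """A 4C viewpoint.

    ``fwd_primer`` must end with the primary enzyme motif: demultiplexing
    matches the full primer, trimming removes it up to but excluding that
    motif so the retained read starts at the digestion site.
    """

    name: str
    fwd_primer: str
    rev_primer: str
    bait_fragment: Fragment
    secondary_enzyme: Enzyme
    primary_motif: str = "GATC"

    def __post_init__(self) -> None:
        if not self.fwd_primer.endswith(self.primary_motif):
            raise ValueError(
                f"bait {self.name!r}: fwd_primer must end with the primary "
                f"digestion motif {self.primary_motif}"
            )


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class TrimmedRead:
    id: str
    seq: str
    qual: str
    bait: str


def validate_baits(baits: list[BaitSpec]) -> None:
    """Reject bait sets whose forward primers are not mutually non-prefix."""
    names = [b.name for b in baits]
    if len(set(names)) != len(names):
        raise ValueError("duplicate bait names")
    for i, a in enumerate(baits):
        for b in baits[i + 1 :]:
            if a.fwd_primer == b.fwd_primer:
                raise ValueError(
                    f"baits {a.name!r} and {b.name!r} share a forward primer"
                )
            if a.fwd_primer.startswith(b.fwd_primer) or b.fwd_primer.startswith(a.fwd_primer):
                raise ValueError(
                    f"forward primers of {a.name!r} and {b.name!r} are nested; "
                    "assignment would be ambiguous"
                )


def assign_pair(pair: ReadPair, baits: list[BaitSpec]) -> tuple[str, ReadPair] | None:
    """Assign a pair to a bait, normalising mate order.

    A pair belongs to bait b iff one mate begins exactly with b.fwd_primer
    and the other begins exactly with b.rev_primer (0 mismatches).  The
    returned pair is re-oriented so mate 1 carries the forward primer.
    Anything else — including a forward hit for one bait and a reverse hit
    for another — is unassigned (None).
    """
    for b in baits:
        if pair.seq1.startswith(b.fwd_primer) and pair.seq2.startswith(b.rev_primer):
            return b.name, pair
        if pair.seq2.startswith(b.fwd_primer) and pair.seq1.startswith(b.rev_primer):
            swapped = ReadPair(pair.id, pair.seq2, pair.qual2, pair.seq1, pair.qual1)
            return b.name, swapped
    return None


def demultiplex(
    pairs, baits: list[BaitSpec]
) -> tuple[dict[str, list[ReadPair]], list[ReadPair], dict[str, int]]:
    """Partition read pairs by bait.

    Returns (per-bait pairs, unassigned pairs, tally).  Every input pair
    lands in exactly one output stream; the tally sums to the input count.
    """
    validate_baits(baits)
    by_bait: dict[str, list[ReadPair]] = {b.name: [] for b in baits}
    unassigned: list[ReadPair] = []
    tally = {b.name: 0 for b in baits}
    tally["unassigned"] = 0
    for pair in pairs:
        hit = assign_pair(pair, baits)
        if hit is None:
            unassigned.append(pair)
            tally["unassigned"] += 1
        else:
            name, oriented = hit
            by_bait[name].append(oriented)
            tally[name] += 1
    return by_bait, unassigned, tally


def trim_and_filter(
    pair: ReadPair,
    bait: BaitSpec,
    qual_min: int = DEFAULT_QUAL_MIN,
    len_min: int = DEFAULT_LEN_MIN,
    phred_offset: int = 33,
) -> TrimmedRead | None:
    """Trim a demultiplexed pair down to the captured-fragment read.

    The primer prefix is removed up to but excluding the digestion-site
    motif, so the retained read starts with the motif; 3' bases with
    Phred < qual_min are then trimmed (longest low-quality suffix), and
    reads shorter than len_min are rejected (None).  Only mate 1 — the
    mate carrying the captured-fragment sequence — survives; mate 2
    served demultiplexing only.  Trimming is idempotent.
    """
    keep_from = len(bait.fwd_primer) - len(bait.primary_motif)
    seq = pair.seq1[keep_from:]
    qual = pair.qual1[keep_from:]
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - phred_offset < qual_min:
        end -= 1
    seq, qual = seq[:end], qual[:end]
    if len(seq) < len_min:
        return None
    return TrimmedRead(pair.id, seq, qual, bait.name)


# ---------------------------------------------------------------------------
# FASTQ I/O

def read_paired_fastq(path1, path2):
    """Yield ReadPair from two synchronized FASTQ files."""
    with open(path1) as fh1, open(path2) as fh2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2), strict=True
        ):
            base1 = id1.split()[0].removesuffix("/1")
            base2 = id2.split()[0].removesuffix("/2")
            if base1 != base2:
                raise ValueError(f"mate id mismatch: {id1} vs {id2}")
            yield ReadPair(base1, s1, q1, s2, q2)


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_demux_report(tally: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("bait\tn_pairs\n")
        for name, n in tally.items():
            fh.write(f"{name}\t{n}\n")
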