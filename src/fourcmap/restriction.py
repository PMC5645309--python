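"""In-silico restriction digestion and fragment maps.

The whole pipeline counts reads on the fragments produced by the primary
(4-cutter, e.g. DpnII/GATC) digestion; this module builds that coordinate
system.  Coordinates are 0-based half-open throughout (BED convention).
Cut positions are placed at the start of each motif occurrence, so every
fragment other than the first begins with the recognition motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_DNA = set("ACGT")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme named by its recognition motif.

    The motif must be plain DNA (no ambiguity codes); cut offsets and
    overhangs are not modelled because fragment identity is all that
    downstream quantification needs.
    """

    name: str
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) < 1 or not set(self.motif) <= _DNA:
            raise ValueError(
                f"enzyme {self.name!r}: motif must be non-empty A/C/G/T, got {self.motif!r}"
            )


DPNII = Enzyme("DpnII", "GATC")
BFAI = Enzyme("BfaI", "CTAG")
MSEI = Enzyme("MseI", "TTAA")

ENZYMES = {e.name: e for e in (DPNII, BFAI, MSEI)}


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    index: int  # ordinal on chrom
    mappable: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment extent [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class FragmentMap:
    """Ordered restriction fragments per chromosome.

    Fragments tile each chromosome exactly: sorted, non-overlapping,
    covering [0, chrom_length).
    """

    enzyme: Enzyme
    fragments: dict[str, list[Fragment]] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.fragments)

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom])
        return sum(len(v) for v in self.fragments.values())

    def chrom_length(self, chrom: str) -> int:
        return self.fragments[chrom][-1].end

    def starts(self, chrom: str) -> np.ndarray:
        return np.array([f.start for f in self.fragments[chrom]], dtype=np.int64)

    def ends(self, chrom: str) -> np.ndarray:
        return np.array([f.end for f in self.fragments[chrom]], dtype=np.int64)

    def mappable_mask(self, chrom: str) -> np.ndarray:
        return np.array([f.mappable for f in self.fragments[chrom]], dtype=bool)

    def locate(self, chrom: str, pos: int) -> Fragment:
        """Return the unique fragment with start <= pos < end."""
        if chrom not in self.fragments:
            raise KeyError(f"unknown chrom {chrom!r}")
        frags = self.fragments[chrom]
        if not (0 <= pos < frags[-1].end):
            raise ValueError(f"position {pos} outside {chrom} [0,{frags[-1].end})")
        starts = self.starts(chrom)
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return frags[i]

    def to_bed(self, path, mappability: bool = False) -> None:
        """Write the map as BED: name = fragment index, score = 0.

        With ``mappability=True`` an extra 7th column (0/1) is appended.
        """
        with open(path, "w") as fh:
            for chrom, frags in self.fragments.items():
                for f in frags:
                    row = [chrom, str(f.start), str(f.end), str(f.index), "0", "."]
                    if mappability:
                        row.append("1" if f.mappable else "0")
                    fh.write("\t".join(row) + "\n")

    def with_mappability(self, mappable: dict[str, np.ndarray]) -> "FragmentMap":
        new = {}
        for chrom, frags in self.fragments.items():
            mask = mappable[chrom]
            new[chrom] = [replace(f, mappable=bool(mask[f.index])) for f in frags]
        return FragmentMap(self.enzyme, new)


def find_motif_positions(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of motif in seq."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def digest_sequence(genome: dict[str, str], enzyme: Enzyme) -> FragmentMap:
    """Digest a genome in silico.

    Cut positions are every occurrence start of the enzyme motif; the first
    fragment starts at 0 and the last ends at the chromosome length.  A
    contig without the motif yields a single fragment.  All fragments start
    out mappable.
    """
    fragmap = FragmentMap(enzyme)
    for chrom, seq in genome.items():
        if len(seq) == 0:
            raise ValueError(f"empty contig {chrom!r}")
        seq = seq.upper()
        cuts = find_motif_positions(seq, enzyme.motif)
        bounds = [0] + [c for c in cuts if c > 0] + [len(seq)]
        frags = [
            Fragment(chrom, s, e, idx)
            for idx, (s, e) in enumerate(zip(bounds[:-1], bounds[1:]))
        ]
        fragmap.fragments[chrom] = frags
    return fragmap


def flag_mappability(fragmap: FragmentMap, genome: dict[str, str], read_len: int) -> FragmentMap:
    """Flag fragments whose cut-site-adjacent k-mer is not genome-unique.

    A fragment is mappable iff the ``read_len``-bp sequence at its start
    (the end adjacent to a cut site, where 4C reads begin) occurs exactly
    once across both strands of the genome.  Fragments shorter than
    ``read_len`` are unmappable.  This is an intrinsic surrogate for an
    alignability track and needs no external data.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    # exhaustive k-mer occurrence count over both strands
    from collections import Counter

    counts: Counter[str] = Counter()
    for seq in genome.values():
        seq = seq.upper()
        for i in range(len(seq) - read_len + 1):
            counts[seq[i : i + read_len]] += 1
        rc = reverse_complement(seq)
        for i in range(len(rc) - read_len + 1):
            counts[rc[i : i + read_len]] += 1

    mappable: dict[str, np.ndarray] = {}
    for chrom, frags in fragmap.fragments.items():
        seq = genome[chrom].upper()
        mask = np.zeros(len(frags), dtype=bool)
        for f in frags:
            if f.length < read_len:
                continue
            kmer = seq[f.start : f.start + read_len]
            # counted once on + strand; palindromic k-mers double-count,
            # which correctly marks them ambiguous
            mask[f.index] = counts[kmer] == 1
        mappable[chrom] = mask
    return fragmap.with_mappability(mappable)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
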