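"""ORF prediction on circular dsDNA genomes.

The caller enumerates start->stop open reading frames of at least
``min_codons`` codons (stop excluded) on both strands, including frames that
cross the origin of a circular genome; overlap between accepted ORFs is then
minimized by a greedy longest-first filter with a small overlap tolerance, the
convention used for compact viral genomes whose genes rarely overlap by more
than a few codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome import CircularGenome, Feature, FeatureTable, revcomp


@dataclass
class OrfRecord:
    """A predicted or annotated coding feature.

    ``start``/``end`` are internal 0-based half-open plus-strand coordinates
    of the full CDS *including* the stop codon; for an origin-spanning ORF
    (``wrap=True``) ``end`` exceeds the genome length.  ``codons`` counts
    sense codons only (stop excluded) and equals ``len(translation)``.
    """

    orf_id: str
    start: int
    end: int
    strand: str
    codons: int
    translation: str
    wrap: bool = False

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"{self.orf_id}: span not a codon multiple")

    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSummary:
    length_bp: int
    gc_percent: float
    orf_count: int
    coding_percent: float


def _translate(nt: str, table: int = 1) -> str:
    return str(Seq(nt).translate(table=table))


def _orfs_one_strand(s: str, L: int, min_codons: int,
                     start_codons: frozenset, table: int) -> list[tuple[int, int]]:
    """Strand-local ORF intervals [start, end) including the stop codon.

    ``s`` is the (possibly doubled) strand sequence; returned starts are < L
    and spans are <= L.
    """
    n = len(s)
    out = []
    stops = set(CodonTable.unambiguous_dna_by_id[table].stop_codons)
    for frame in range(3):
        prev_stop_end = frame  # scan region starts here
        i = frame
        while i + 3 <= n:
            codon = s[i:i + 3]
            if codon in stops:
                # longest ORF ending at this stop = first start after last stop
                j = prev_stop_end
                while j + 3 <= i:
                    if s[j:j + 3] in start_codons:
                        if (i - j) // 3 >= min_codons and j < L and i + 3 - j <= L:
                            out.append((j, i + 3))
                        break
                    j += 3
                prev_stop_end = i + 3
            i += 3
    return out


def find_orfs(genome: CircularGenome, min_codons: int = 50,
              start_codons=frozenset({"ATG"}), table: int = 1) -> list[OrfRecord]:
    """Enumerate candidate ORFs of >= ``min_codons`` codons on both strands.

    Candidates sharing a stop codon are collapsed to the longest (most
    upstream ATG).  On circular genomes frames crossing the origin are
    scanned on the doubled sequence; an ORF may occupy at most the full
    genome length.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    start_codons = frozenset(start_codons)
    L = len(genome)
    seq = genome.seq
    records = []
    for strand in "+-":
        s1 = seq if strand == "+" else revcomp(seq)
        s = s1 + s1 if genome.is_circular else s1
        for j, e in _orfs_one_strand(s, L, min_codons, start_codons, table):
            if strand == "+":
                start, end = j, e
            else:
                start = (L - e) % L
                end = start + (e - j)
            aa = _translate(s[j:e - 3], table)
            records.append(OrfRecord("", start, end, strand,
                                     (e - j) // 3 - 1, aa, end > L))
    # candidates sharing a genomic stop codon collapse to the longest: on a
    # circle the doubled-sequence scan can see both a wrap ORF and its
    # shadow truncated at the origin cut
    by_stop: dict[tuple, OrfRecord] = {}
    for r in records:
        key = (r.strand, r.start % L if r.strand == "-" else (r.end - 3) % L)
        if key not in by_stop or r.codons > by_stop[key].codons:
            by_stop[key] = r
    records = sorted(by_stop.values(), key=lambda r: (r.start, r.end, r.strand))
    for k, r in enumerate(records, 1):
        r.orf_id = f"cand{k}"
    return records


def _circ_intervals(start: int, end: int, L: int) -> list[tuple[int, int]]:
    if end > L:
        return [(start, L), (0, end - L)]
    return [(start, end)]


def circular_overlap_bp(a: OrfRecord, b: OrfRecord, L: int) -> int:
    """Number of genome positions covered by both ORFs (strand-agnostic)."""
    total = 0
    for s1, e1 in _circ_intervals(a.start, a.end, L):
        for s2, e2 in _circ_intervals(b.start, b.end, L):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def resolve_overlaps(candidates: list[OrfRecord], genome_length: int,
                     max_overlap_bp: int = 30) -> list[OrfRecord]:
    """Greedy minimal-overlap selection.

    Candidates are taken in order of descending codon count (ties: smaller
    start, then + strand); one is rejected iff it overlaps an already
    accepted ORF by more than ``max_overlap_bp`` on either strand.  Accepted
    ORFs are renumbered ``orf1..orfN`` in genome order.
    """
    if max_overlap_bp < 0:
        raise ValueError("max_overlap_bp must be >= 0")
    ranked = sorted(candidates,
                    key=lambda r: (-r.codons, r.start, 0 if r.strand == "+" else 1))
    accepted: list[OrfRecord] = []
    for cand in ranked:
        if all(circular_overlap_bp(cand, a, genome_length) <= max_overlap_bp
               for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda r: (r.start, r.end, r.strand))
    out = []
    for k, r in enumerate(accepted, 1):
        out.append(replace(r, orf_id=f"orf{k}"))
    return out


def annotate(genome: CircularGenome, min_codons: int = 50,
             max_overlap_bp: int = 30, start_codons=frozenset({"ATG"}),
             table: int = 1) -> list[OrfRecord]:
    """find_orfs followed by resolve_overlaps."""
    return resolve_overlaps(find_orfs(genome, min_codons, start_codons, table),
                            len(genome), max_overlap_bp)


def orfs_to_table(genome: CircularGenome, orfs: list[OrfRecord]) -> FeatureTable:
    feats = [Feature(r.orf_id, r.start, r.end, r.strand, "CDS",
                     {"product": "hypothetical protein",
                      "translation": r.translation})
             for r in orfs]
    return FeatureTable(genome.id, len(genome), feats)


def orfs_from_table(genome: CircularGenome, table: FeatureTable,
                    genetic_code: int = 1) -> list[OrfRecord]:
    """Interpret the CDS features of an annotation as ORF records."""
    out = []
    L = len(genome)
    for f in table.of_kind("CDS"):
        nt = genome.subsequence(f.start % L, f.end, f.strand)
        aa = f.qualifiers.get("translation") or _translate(nt[:-3], genetic_code)
        aa = aa.rstrip("*")
        out.append(OrfRecord(f.feature_id, f.start, f.end, f.strand,
                             (f.end - f.start) // 3 - 1, aa, f.end > L))
    return out


def linearize_on(genome: CircularGenome, anchor_start: int,
                 anchor_strand: str = "+") -> CircularGenome:
    """Rotate (and, for a minus-strand anchor, reverse-complement) a circular
    genome so the anchor's start codon occupies the first three bases.

    ``anchor_start`` is the genome coordinate of the 5' base of the start
    codon *on the anchor's strand*: for ``+`` the position of the A of ATG;
    for ``-`` the highest coordinate of the codon on the plus strand (the
    base whose complement is that A).
    """
    if not genome.is_circular:
        raise ValueError("linearize_on requires a circular genome")
    L = len(genome)
    anchor_start %= L
    if anchor_strand == "+":
        s = genome.seq[anchor_start:] + genome.seq[:anchor_start]
    else:
        rc = revcomp(genome.seq)
        k = (L - 1 - anchor_start) % L
        s = rc[k:] + rc[:k]
    return CircularGenome(genome.id, s, "circular")


def rotate_feature(f: Feature, offset: int, L: int) -> Feature:
    """Re-map a feature after rotating the genome left by ``offset``."""
    start = (f.start - offset) % L
    end = start + f.length()
    return replace(f, start=start, end=end)


def summarize(genome: CircularGenome, table: FeatureTable) -> GenomeSummary:
    """Length, GC%, ORF count and coding density (union of CDS intervals,
    overlapping bases counted once)."""
    L = len(genome)
    covered = bytearray(L)
    cds = table.of_kind("CDS")
    for f in cds:
        for s, e in f.intervals(L):
            for i in range(s, e):
                covered[i] = 1
    coding = 100.0 * sum(covered) / L
    return GenomeSummary(L, round(genome.gc_percent(), 10), len(cds), coding)
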