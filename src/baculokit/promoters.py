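"""Promoter-element screening upstream of annotated ORFs.

Three element classes are screened in the upstream window of each ORF on its
coding strand, following the conventions used for baculovirus genomes:

* ``early_tata_cakt`` — a TATA box (``TATAW``) with a ``CAKT`` mRNA start-site
  motif beginning 25–35 nt downstream of it;
* ``lef_tata_like``  — the TATA-like element ``TAATWAA`` first described
  upstream of *lef* genes;
* ``late``           — the late-transcription initiator ``DTAAG``.

Hit positions are reported relative to the A of the initiation codon
(position 0), so upstream offsets are negative; a late element starting
within ``proximal_nt`` of the start codon sets ``proximal_late``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .genome import CircularGenome, revcomp
from .orfs import OrfRecord

PATTERNS = {
    "early_tata": "TATAW",
    "early_initiator": "CAKT",
    "lef_tata_like": "TAATWAA",
    "late": "DTAAG",
}

CLASSES = ("early_tata_cakt", "lef_tata_like", "late")


@dataclass(frozen=True)
class PromoterHit:
    promoter_class: str
    rel_start: int          # motif start relative to the start-codon A (negative)
    matched_text: str
    spacing_nt: int | None = None   # TATAW-start -> CAKT-start, early class only


@dataclass
class PromoterHits:
    orf_id: str
    hits: list[PromoterHit]
    proximal_late: bool


def iupac_match(pattern: str, window: str) -> list[int]:
    """All 0-based offsets where the IUPAC pattern matches, overlaps allowed.

    ``N`` in the *window* never matches (conservative scanning); ``N`` in the
    pattern matches any unambiguous base.
    """
    classes = []
    for c in pattern.upper():
        if c not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC letter {c!r} in pattern")
        classes.append(set(ambiguous_dna_values[c]))
    m, hits = len(classes), []
    w = window.upper()
    for i in range(len(w) - m + 1):
        if all(w[i + k] in classes[k] for k in range(m)):
            hits.append(i)
    return hits


def _upstream_window(genome: CircularGenome, orf: OrfRecord,
                     window_nt: int) -> str:
    """The ``window_nt`` bases 5' of the start codon, on the coding strand,
    written 5'->3' so that the last character abuts the start-codon A.

    On circular genomes the window wraps across the origin; on linear ones it
    is truncated at the sequence edge.
    """
    L = len(genome)
    if orf.strand == "+":
        s = orf.start % L
        if genome.is_circular:
            begin = (s - window_nt) % L
            return genome.subsequence(begin, begin + window_nt, "+")
        begin = max(0, s - window_nt)
        return genome.seq[begin:s]
    # minus strand: upstream lies at higher plus-strand coordinates
    if genome.is_circular:
        e = orf.end % L
        return genome.subsequence(e, e + window_nt, "-")
    return revcomp(genome.seq[orf.end:orf.end + window_nt])


def scan_orf(genome: CircularGenome, orf: OrfRecord, window_nt: int = 180,
             cakt_spacing: tuple[int, int] = (25, 35), proximal_nt: int = 15,
             spacing_anchor: str = "start") -> PromoterHits:
    """Screen one ORF's upstream window for the three element classes."""
    longest = max(len(p) for p in PATTERNS.values())
    if window_nt < longest:
        raise ValueError(f"window_nt must be >= {longest}")
    if spacing_anchor not in ("start", "end"):
        raise ValueError("spacing_anchor must be 'start' or 'end'")
    w = _upstream_window(genome, orf, window_nt)
    shift = len(w)  # == window_nt except truncated linear edges
    hits: list[PromoterHit] = []

    tata = iupac_match(PATTERNS["early_tata"], w)
    cakt = iupac_match(PATTERNS["early_initiator"], w)
    lo, hi = cakt_spacing
    for t in tata:
        anchor = t if spacing_anchor == "start" else t + len(PATTERNS["early_tata"])
        for c in cakt:
            if lo <= c - anchor <= hi:
                hits.append(PromoterHit("early_tata_cakt", t - shift,
                                        w[t:t + 5], c - anchor))
    for p in iupac_match(PATTERNS["lef_tata_like"], w):
        hits.append(PromoterHit("lef_tata_like", p - shift, w[p:p + 7]))
    late_hits = iupac_match(PATTERNS["late"], w)
    for p in late_hits:
        hits.append(PromoterHit("late", p - shift, w[p:p + 5]))

    proximal = any(p - shift >= -proximal_nt for p in late_hits)
    hits.sort(key=lambda h: (h.rel_start, h.promoter_class))
    return PromoterHits(orf.orf_id, hits, proximal)


def scan_promoters(genome: CircularGenome, orfs: list[OrfRecord],
                   window_nt: int = 180,
                   cakt_spacing: tuple[int, int] = (25, 35),
                   proximal_nt: int = 15,
                   spacing_anchor: str = "start") -> list[PromoterHits]:
    """Per-ORF promoter screen over the whole annotation."""
    return [scan_orf(genome, o, window_nt, cakt_spacing, proximal_nt,
                     spacing_anchor) for o in orfs]


def promoter_summary(all_hits: list[PromoterHits]) -> dict:
    """Per-class hit counts plus the mean late-element offset (the quantity
    usually quoted as 'on average -60 nt')."""
    counts = {c: 0 for c in CLASSES}
    late_offsets = []
    for ph in all_hits:
        for h in ph.hits:
            counts[h.promoter_class] += 1
            if h.promoter_class == "late":
                late_offsets.append(h.rel_start)
    mean_late = sum(late_offsets) / len(late_offsets) if late_offsets else None
    return {"class_counts": counts,
            "orfs_with_proximal_late": sum(1 for p in all_hits if p.proximal_late),
            "mean_late_offset_nt": mean_late}
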