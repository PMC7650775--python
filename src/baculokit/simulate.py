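"""Ground-truthed synthetic granulovirus-like genomes.

The generator emits a circular genome with a known layout — stop-free ORFs
with ATG starts on both strands, promoter motifs implanted at stated offsets
upstream of start codons, homologous-repeat (hr) loci built from long repeat
units in mixed orientations around a perfect palindromic core, and AT-rich
tandem direct repeats — together with an exact feature-level truth table, so
every analysis stage can be scored against known answers.  Sequence
divergence between genome pairs follows a two-parameter (Kimura-type)
substitution process with a chosen expected distance and
transition:transversion ratio.

All generation is driven by one mandatory seed and is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import CircularGenome, Feature, FeatureTable, revcomp
from .orfs import OrfRecord, _translate
from .promoters import iupac_match

STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PromoterPlan:
    """Per-class implant probabilities and offset conventions.

    Offsets are coding-strand positions of the motif start relative to the
    start-codon A at 0 (upstream negative).  The late-element range is
    centred near -60, the offset usually quoted as the average position of
    the baculovirus late initiator.
    """

    early_prob: float = 0.3
    early_tata_offset_range: tuple[int, int] = (-118, -80)
    cakt_spacing_range: tuple[int, int] = (25, 35)
    lef_prob: float = 0.3
    lef_offset_range: tuple[int, int] = (-75, -40)
    late_prob: float = 0.6
    late_offset_range: tuple[int, int] = (-110, -10)


@dataclass
class HrSpec:
    unit_length: int = 104
    n_units: int = 5
    n_reverse: int = 2
    core: str = "GTAAACGTTTAC"
    mutation_rate: float = 0.02
    gap_range: tuple[int, int] = (20, 40)

    def __post_init__(self):
        if self.core and self.core != revcomp(self.core):
            raise ValueError("hr core must be a perfect palindrome")
        if not 0 <= self.n_reverse <= self.n_units:
            raise ValueError("n_reverse out of range")


@dataclass
class DrSpec:
    unit: str = "AT"
    copies: int = 30


@dataclass
class GenomeSpec:
    length_bp: int
    n_orfs: int
    seed: int
    gc_percent: float = 37.18
    orf_codon_range: tuple[int, int] = (50, 300)
    strand_fraction_plus: float = 0.7
    promoter_plan: PromoterPlan = field(default_factory=PromoterPlan)
    hr_specs: list[HrSpec] = field(default_factory=list)
    dr_specs: list[DrSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory: no unseeded generation")


def maphgv_like_spec(seed: int, length_bp: int = 20_000,
                     n_orfs: int = 15) -> GenomeSpec:
    """The default study-like configuration: 37.18% GC background, one hr of
    five 104-bp units (two reverse) around the GTAAACGTTTAC core, one AT
    tandem dr."""
    return GenomeSpec(length_bp=length_bp, n_orfs=n_orfs, seed=seed,
                      hr_specs=[HrSpec()], dr_specs=[DrSpec("AT", 30)])


@dataclass
class PromoterTruth:
    orf_id: str
    promoter_class: str
    rel_start: int
    matched_text: str
    spacing_nt: int | None = None


@dataclass
class HrTruth:
    region_id: str
    span: tuple[int, int]
    units: list[tuple[int, int, str]]       # (start, end, orientation)
    consensus: str
    core: str
    core_span: tuple[int, int] | None
    mutations: list[tuple[int, int, str, str]]  # (unit_idx, offset, old, new)


@dataclass
class DrTruth:
    region_id: str
    span: tuple[int, int]
    unit: str
    copies: int


@dataclass
class GroundTruth:
    table: FeatureTable
    orfs: list[OrfRecord]
    promoters: list[PromoterTruth]
    hrs: list[HrTruth]
    drs: list[DrTruth]


# ---------------------------------------------------------------------------
# building blocks

def _background(rng, n: int, gc: float) -> str:
    p_gc = gc / 200.0
    p_at = (100.0 - gc) / 200.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return bytes(_BASES[idx]).decode()


def _random_codons(rng, n: int, gc: float) -> str:
    """Stop-free codons drawn base-wise at the background composition."""
    out = []
    while len(out) < n:
        c = _background(rng, 3, gc)
        if c not in STOPS:
            out.append(c)
    return "".join(out)


def _orf_block(rng, codons: int, gc: float) -> str:
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + _random_codons(rng, codons - 1, gc) + stop


def _instantiate(rng, pattern: str) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values
    return "".join(c if c in "ACGT" else
                   ambiguous_dna_values[c][rng.integers(0, len(ambiguous_dna_values[c]))]
                   for c in pattern)


_SCAN_PATTERNS = ("TATAW", "TAATWAA", "DTAAG")


def _clean_background(rng, n: int, gc: float, max_tries: int = 300) -> str:
    """Background rejected until free of the three promoter patterns (both
    given and read-through orientation is the caller's concern; the window is
    scanned as written)."""
    for _ in range(max_tries):
        s = _background(rng, n, gc)
        if all(not iupac_match(p, s) for p in _SCAN_PATTERNS):
            return s
    return s  # pragma: no cover - astronomically unlikely at n <= 200


# ---------------------------------------------------------------------------
# genome generation

_UPSTREAM_RESERVE = 130      # gap reserved 5' of each ORF for promoter implants
_BASE_GAP = 30


def generate_genome(spec: GenomeSpec) -> tuple[CircularGenome, GroundTruth]:
    """Emit a circular genome satisfying the spec plus its exact truth.

    Raises before any sequence is produced if the requested features cannot
    be packed into ``length_bp``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.orf_codon_range

    # plan block lengths first so packing is checked before any emission
    orf_codons = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_orfs)]
    orf_strands = ["+" if rng.random() < spec.strand_fraction_plus else "-"
                   for _ in range(spec.n_orfs)]
    blocks: list[tuple[str, int, object]] = []   # (kind, length, payload)
    for k, codons in enumerate(orf_codons):
        blocks.append(("orf", 3 * codons + 3, (codons, orf_strands[k])))
    for h in spec.hr_specs:
        gaps = [int(rng.integers(h.gap_range[0], h.gap_range[1] + 1))
                for _ in range(h.n_units - 1)]
        core_gap_extra = len(h.core) + 8 if h.core else 0
        length = h.n_units * h.unit_length + sum(gaps) + core_gap_extra
        blocks.append(("hr", length, (h, gaps)))
    for dspec in spec.dr_specs:
        blocks.append(("dr", len(dspec.unit) * dspec.copies, dspec))
    if not blocks:
        return (CircularGenome(f"synth-{spec.seed}",
                               _background(rng, spec.length_bp, spec.gc_percent)),
                GroundTruth(FeatureTable(f"synth-{spec.seed}", spec.length_bp),
                            [], [], [], []))

    order = list(rng.permutation(len(blocks)))

    def _is_orf(bi, strand):
        return blocks[bi][0] == "orf" and blocks[bi][2][1] == strand

    # each gap precedes the block in its slot; a plus ORF needs its promoter
    # window in the gap before it, a minus ORF in the gap after it
    n = len(order)
    gap_before = []
    for slot in range(n):
        g = _BASE_GAP
        if _is_orf(order[slot], "+"):
            g += _UPSTREAM_RESERVE
        if _is_orf(order[slot - 1], "-"):     # slot-1 wraps to the last block
            g += _UPSTREAM_RESERVE
        gap_before.append(g)

    needed = sum(ln for _, ln, _ in blocks) + sum(gap_before)
    if needed > spec.length_bp:
        raise ValueError(
            f"infeasible packing: features need {needed} bp, genome is "
            f"{spec.length_bp} bp")
    slack = spec.length_bp - needed
    extra = rng.multinomial(slack, np.full(n, 1.0 / n))

    chars = list("N" * spec.length_bp)
    features: list[Feature] = []
    orf_records: list[OrfRecord] = []
    promoter_truth: list[PromoterTruth] = []
    hr_truth: list[HrTruth] = []
    dr_truth: list[DrTruth] = []

    def put(pos: int, text: str):
        chars[pos:pos + len(text)] = list(text)

    cursor = 0
    for slot, bi in enumerate(order):
        kind, length, payload = blocks[bi]
        gap = gap_before[slot] + int(extra[slot])
        put(cursor, _background(rng, gap, spec.gc_percent))
        start = cursor + gap
        cursor = start + length

        if kind == "orf":
            codons, strand = payload
            coding = _orf_block(rng, codons, spec.gc_percent)
            put(start, coding if strand == "+" else revcomp(coding))
            orf_records.append(OrfRecord("", start, start + length, strand,
                                         codons, _translate(coding[:-3])))
        elif kind == "hr":
            hr_truth.append(_implant_hr(rng, chars, spec, payload, start,
                                        length))
        else:
            text = payload.unit * payload.copies
            put(start, text)
            dr_truth.append(DrTruth("", (start, start + length), payload.unit,
                                    payload.copies))
    # trailing slack stays background
    tail = spec.length_bp - cursor
    if tail > 0:
        put(cursor, _background(rng, tail, spec.gc_percent))

    # second pass: promoter implants after every block is laid down, so a
    # minus-strand ORF's window (in the following gap) is never overwritten
    for rec in orf_records:
        promoter_truth.extend(
            _implant_promoters(rng, chars, spec, rec, spec.length_bp))

    genome = CircularGenome(f"synth-{spec.seed}", "".join(chars))

    orf_records.sort(key=lambda r: r.start)
    for k, rec in enumerate(orf_records, 1):
        rec.orf_id = f"orf{k}"
    by_pos = {(r.start, r.strand): r.orf_id for r in orf_records}
    for p in promoter_truth:
        p.orf_id = by_pos[p.orf_id]        # placeholder was (start, strand)

    for k, h in enumerate(hr_truth, 1):
        h.region_id = f"hr{k}"
    for k, dtr in enumerate(dr_truth, 1):
        dtr.region_id = f"dr{k}"

    for rec in orf_records:
        features.append(Feature(rec.orf_id, rec.start, rec.end, rec.strand,
                                "CDS", {"translation": rec.translation}))
    for p in promoter_truth:
        anchor = next(r for r in orf_records if r.orf_id == p.orf_id)
        m = len(p.matched_text)
        if anchor.strand == "+":
            s = (anchor.start + p.rel_start) % spec.length_bp
        else:
            s = (anchor.end - p.rel_start - m) % spec.length_bp
        features.append(Feature(f"{p.orf_id}_{p.promoter_class}", s, s + m,
                                anchor.strand, "promoter",
                                {"promoter_class": p.promoter_class,
                                 "orf_id": p.orf_id,
                                 "rel_start": str(p.rel_start)}))
    for h in hr_truth:
        features.append(Feature(h.region_id, h.span[0], h.span[1], "+",
                                "repeat_region",
                                {"rpt_type": "hr", "n_units": str(len(h.units)),
                                 "unit_length": str(len(h.consensus))}))
    for dtr in dr_truth:
        features.append(Feature(dtr.region_id, dtr.span[0], dtr.span[1], "+",
                                "repeat_region",
                                {"rpt_type": "dr", "unit": dtr.unit}))

    table = FeatureTable(genome.id, len(genome),
                         sorted(features, key=lambda f: (f.start, f.end)))
    truth = GroundTruth(table, orf_records, promoter_truth, hr_truth, dr_truth)
    return genome, truth


def _implant_promoters(rng, chars, spec: GenomeSpec, rec: OrfRecord,
                       L: int) -> list:
    """Write planned motifs into the upstream window of one ORF; returns
    truth rows whose orf_id field temporarily holds (start, strand)."""
    plan = spec.promoter_plan
    window = _UPSTREAM_RESERVE
    # clean the upstream window of accidental motifs first (coding strand)
    clean = _clean_background(rng, window, spec.gc_percent)
    occupied: list[tuple[int, int]] = []
    rows = []

    def write(o: int, text: str):
        """Write motif text at coding offset o (motif start, upstream
        negative), modulo the genome length."""
        if rec.strand == "+":
            g = rec.start + o
            out = text
        else:
            g = rec.end - o - len(text)
            out = revcomp(text)
        for k2, ch in enumerate(out):
            chars[(g + k2) % L] = ch

    # lay the cleaned background under the window, then close the reading
    # frame just 5' of the start codon so the implanted ATG is the most
    # upstream start for its stop (the ORF caller keeps the longest)
    write(-window, clean)
    write(-3, "TAA")
    occupied.append((-3, 0))

    def try_place(lo_off: int, hi_off: int, m: int) -> int | None:
        for _ in range(60):
            o = int(rng.integers(lo_off, hi_off + 1))
            if o + m > 0 or o < -window:
                continue
            if all(o + m <= s or o >= e for s, e in occupied):
                occupied.append((o, o + m))
                return o
        return None

    key = (rec.start, rec.strand)
    if rng.random() < plan.early_prob:
        spacing = int(rng.integers(plan.cakt_spacing_range[0],
                                   plan.cakt_spacing_range[1] + 1))
        t = try_place(*plan.early_tata_offset_range, 5)
        if t is not None and all(t + spacing + 4 <= s or t + spacing >= e
                                 for s, e in occupied):
            tata = _instantiate(rng, "TATAW")
            cakt = _instantiate(rng, "CAKT")
            write(t, tata)
            write(t + spacing, cakt)
            occupied.append((t + spacing, t + spacing + 4))
            rows.append(PromoterTruth(key, "early_tata_cakt", t, tata, spacing))
    if rng.random() < plan.lef_prob:
        o = try_place(*plan.lef_offset_range, 7)
        if o is not None:
            text = _instantiate(rng, "TAATWAA")
            write(o, text)
            rows.append(PromoterTruth(key, "lef_tata_like", o, text))
    if rng.random() < plan.late_prob:
        o = try_place(*plan.late_offset_range, 5)
        if o is not None:
            text = _instantiate(rng, "DTAAG")
            write(o, text)
            rows.append(PromoterTruth(key, "late", o, text))
    return rows


def _implant_hr(rng, chars, spec: GenomeSpec, payload, start: int,
                length: int) -> HrTruth:
    h, gaps = payload
    consensus = _background(rng, h.unit_length, spec.gc_percent)
    orientations = ["+"] * (h.n_units - h.n_reverse) + ["-"] * h.n_reverse
    core_after = h.n_units - h.n_reverse - 1 if h.n_reverse else None

    pos = start
    units = []
    mutations = []
    core_span = None
    for k, orient in enumerate(orientations):
        unit = list(consensus)
        for j in range(h.unit_length):
            if rng.random() < h.mutation_rate:
                old = unit[j]
                alt = "ACGT".replace(old, "")
                new = alt[rng.integers(0, 3)]
                unit[j] = new
                mutations.append((k, j, old, new))
        text = "".join(unit)
        chars[pos:pos + h.unit_length] = list(
            text if orient == "+" else revcomp(text))
        units.append((pos, pos + h.unit_length, orient))
        pos += h.unit_length
        if k < h.n_units - 1:
            gap = gaps[k]
            if h.core and k == core_after:
                pad = 4
                left = _clean_core_flank(rng, pad, spec.gc_percent)
                right = _clean_core_flank(rng, gap + 4, spec.gc_percent)
                # neighbours must not extend the implanted palindrome
                while revcomp(left[-1]) == right[0]:
                    right = _clean_core_flank(rng, gap + 4, spec.gc_percent)
                gseq = left + h.core + right
                core_span = (pos + pad, pos + pad + len(h.core))
                chars[pos:pos + len(gseq)] = list(gseq)
                pos += len(gseq)
            else:
                gseq = _background(rng, gap, spec.gc_percent)
                chars[pos:pos + gap] = list(gseq)
                pos += gap
    return HrTruth("", (start, start + length), units, consensus,
                   h.core, core_span, mutations)


def _clean_core_flank(rng, n: int, gc: float, max_tries: int = 200) -> str:
    """Flank free of palindromes >= 8 bp so the implanted core stays the
    unique longest palindrome in its gap."""
    from .repeats import find_palindromes
    for _ in range(max_tries):
        s = _background(rng, n, gc)
        if not find_palindromes(s, min_len=8, max_mismatch=0):
            return s
    return s  # pragma: no cover


# ---------------------------------------------------------------------------
# divergence

_IDX = {65: 0, 67: 1, 71: 2, 84: 3}          # A C G T byte -> index
_TS_PARTNER = np.array([2, 3, 0, 1])          # A<->G, C<->T
_TV1 = np.array([1, 0, 1, 0])                 # A->C, C->A, G->C, T->A
_TV2 = np.array([3, 2, 3, 2])                 # A->T, C->G, G->T, T->G


def k2p_event_probs(d_true: float, kappa: float) -> tuple[float, float]:
    """Expected observed transition (P) and transversion (Q) proportions at
    divergence ``d_true`` with transition:transversion ratio ``kappa``."""
    b = d_true / (2.0 * (kappa + 1.0))
    a = d_true * kappa / (kappa + 1.0)
    Q = 0.5 - 0.5 * np.exp(-4.0 * b)
    P = 0.25 + 0.25 * np.exp(-4.0 * b) - 0.5 * np.exp(-2.0 * (a + b))
    return float(P), float(Q)


def diverge(seq: str, d_true: float, kappa: float, seed: int) -> str:
    """Substitute sites so the expected K2P distance of the pair is
    ``d_true`` with expected transition:transversion count ratio ``kappa``.

    No indels; non-ACGT characters are left unchanged; deterministic under
    the seed.
    """
    if not 0.0 <= d_true < 0.75:
        raise ValueError("d_true must be in [0, 0.75)")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if d_true == 0.0:
        return seq
    rng = np.random.default_rng(seed)
    P, Q = k2p_event_probs(d_true, kappa)
    x = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.full(x.size, -1, dtype=np.int64)
    for byte, k in _IDX.items():
        idx[x == byte] = k
    valid = idx >= 0
    u = rng.random(x.size)
    pick = rng.random(x.size) < 0.5
    out_idx = idx.copy()
    ts = valid & (u < P)
    tv = valid & (u >= P) & (u < P + Q)
    out_idx[ts] = _TS_PARTNER[idx[ts]]
    out_idx[tv & pick] = _TV1[idx[tv & pick]]
    out_idx[tv & ~pick] = _TV2[idx[tv & ~pick]]
    x[valid] = _BASES[out_idx[valid]]
    return bytes(x).decode()


@dataclass
class DivergedPair:
    genome: CircularGenome
    orfs: list[OrfRecord]
    homolog_pairs: list[tuple[str, str]]
    d_true: float
    kappa: float


def diverge_genome_pair(genome: CircularGenome, truth: GroundTruth,
                        d_true: float, kappa: float, seed: int,
                        block_plan: list[tuple[int, int, bool]] | None = None
                        ) -> DivergedPair:
    """Diverge a generated genome coherently (ORFs stay open: start and stop
    codons are preserved and substitutions creating in-frame stops revert),
    optionally rearranging labelled ORF blocks; homolog truth is the identity
    mapping composed with the rearrangement.

    ``block_plan`` lists contiguous ORF-index blocks (start_idx, end_idx
    inclusive, invert) in their *new* order; it must cover all ORFs exactly
    once.
    """
    L = len(genome)
    seq_b = list(diverge(genome.seq, d_true, kappa, seed))

    for rec in truth.orfs:
        coding_old = genome.subsequence(rec.start % L, rec.end, rec.strand)
        coding_new = _read(seq_b, rec, L)
        fixed = list(coding_new)
        fixed[:3] = coding_old[:3]
        fixed[-3:] = coding_old[-3:]
        for c in range(3, len(fixed) - 3, 3):
            if "".join(fixed[c:c + 3]) in STOPS:
                fixed[c:c + 3] = coding_old[c:c + 3]
        _write(seq_b, rec, L, "".join(fixed))

    orfs_sorted = sorted(truth.orfs, key=lambda r: r.start)
    if block_plan is None:
        block_plan = [(0, len(orfs_sorted) - 1, False)]
    covered = sorted(i for s, e, _ in block_plan for i in range(s, e + 1))
    if covered != list(range(len(orfs_sorted))):
        raise ValueError("block plan must cover every ORF index exactly once")

    # cut the genome midway through intergenic gaps
    cuts = [0]
    for i in range(1, len(orfs_sorted)):
        cuts.append((orfs_sorted[i - 1].end + orfs_sorted[i].start) // 2)
    cuts.append(L)

    s_b = "".join(seq_b)
    new_seq_parts = []
    new_orfs: list[OrfRecord] = []
    pairs: list[tuple[str, str]] = []
    offset = 0
    for s_idx, e_idx, invert in block_plan:
        seg = s_b[cuts[s_idx]:cuts[e_idx + 1]]
        m = len(seg)
        block = orfs_sorted[s_idx:e_idx + 1]
        if invert:
            seg = revcomp(seg)
            block = block[::-1]
        for rec in block:
            if invert:
                ns = offset + (cuts[e_idx + 1] - rec.end)
                strand = "-" if rec.strand == "+" else "+"
            else:
                ns = offset + (rec.start - cuts[s_idx])
                strand = rec.strand
            new_orfs.append(replace(rec, start=ns, end=ns + rec.length(),
                                    strand=strand))
            pairs.append((rec.orf_id, ""))
        new_seq_parts.append(seg)
        offset += m
    genome_b = CircularGenome(genome.id + "-div", "".join(new_seq_parts))

    order = sorted(range(len(new_orfs)), key=lambda t: new_orfs[t].start)
    renamed = []
    for rank, t in enumerate(order, 1):
        rec = new_orfs[t]
        coding = genome_b.subsequence(rec.start % len(genome_b), rec.end,
                                      rec.strand)
        rec = replace(rec, orf_id=f"orf{rank}",
                      translation=_translate(coding[:-3]))
        renamed.append((t, rec))
    final = [rec for _, rec in sorted(renamed, key=lambda x: x[0])]
    pairs = [(pairs[t][0], final[t].orf_id) for t in range(len(final))]
    final_sorted = sorted(final, key=lambda r: r.start)
    return DivergedPair(genome_b, final_sorted, sorted(pairs), d_true, kappa)


def _read(chars: list[str], rec: OrfRecord, L: int) -> str:
    s = "".join(chars[i % L] for i in range(rec.start, rec.end))
    return s if rec.strand == "+" else revcomp(s)


def _write(chars: list[str], rec: OrfRecord, L: int, coding: str) -> None:
    text = coding if rec.strand == "+" else revcomp(coding)
    for k, i in enumerate(range(rec.start, rec.end)):
        chars[i % L] = text[k]
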