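"""Repeat discovery: direct repeats (drs), homologous repeat regions (hrs),
and palindromic cores.

Two kinds of repeat loci are distinguished the way they are in granulovirus
genome descriptions: *drs* are AT-rich tandem arrays in intergenic regions
(adjacent copies of one unit), while *hrs* are sets of longer, highly similar
units that may be dispersed and may occur in both orientations, often with a
perfect palindromic core between opposite-orientation neighbours (the
signature of a cruciform-forming replication origin / enhancer element).

The hr finder is seed-and-extend: exact k-mer seeds (k=12) in both
orientations, ungapped x-drop extension scored +1/−1, unit clustering by
interval overlap, and a majority-vote consensus per region.  Gapped extension
adds nothing for the substitution-dominated divergence of hr units and would
cost an alignment engine, so matches are extended without indels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genome import CircularGenome, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class RepeatUnit:
    start: int
    end: int
    orientation: str            # '+' or '-'
    identity_to_consensus: float = 1.0
    seq: str = ""               # orientation-normalized sequence

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("unit end must exceed start")


@dataclass
class RepeatRegion:
    region_id: str
    kind: str                   # 'hr' or 'dr'
    span: tuple[int, int]
    units: list[RepeatUnit]
    consensus: str
    unit_length: int
    palindrome_core: str | None = None
    at_percent: float = 0.0
    overlaps_cds: bool = False

    def __post_init__(self):
        if self.kind == "hr" and len(self.units) < 2:
            raise ValueError("an hr requires at least two units")
        if self.palindrome_core is not None:
            if self.palindrome_core != revcomp(self.palindrome_core):
                raise ValueError("palindrome core must equal its own reverse "
                                 "complement")


# ---------------------------------------------------------------------------
# palindromes

def find_palindromes(seq: str, min_len: int = 6,
                     max_mismatch: int = 0) -> list[tuple[int, int, int]]:
    """All maximal even-length reverse-complement palindromes.

    Returns ``(start, length, mismatches)`` triples.  A span is maximal when
    it cannot be extended symmetrically about its centre; the outermost base
    pair of a reported span always matches (mismatch budget is interior
    only).  ``N`` never pairs.
    """
    if min_len % 2 != 0:
        raise ValueError("min_len must be even (biological palindromes pair "
                         "around a central axis)")
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    s = seq.upper()
    n = len(s)
    out = []
    for c in range(1, n):               # axis between c-1 and c
        l, r = c - 1, c
        mism = 0
        best = None                      # (l, r, mism) at last matching pair
        while l >= 0 and r < n:
            if _COMP.get(s[l]) == s[r] and s[r] in _COMP:
                best = (l, r, mism)
            else:
                mism += 1
                if mism > max_mismatch:
                    break
            l -= 1
            r += 1
        if best is not None:
            bl, br, bm = best
            length = br - bl + 1
            if length >= min_len:
                out.append((bl, length, bm))
    out.sort()
    return out


def longest_palindrome(seq: str, min_len: int = 8) -> str | None:
    hits = find_palindromes(seq, min_len=min_len, max_mismatch=0)
    if not hits:
        return None
    start, length, _ = max(hits, key=lambda h: (h[1], -h[0]))
    return seq[start:start + length]


# ---------------------------------------------------------------------------
# tandem direct repeats

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (first, last) index pairs of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _majority_consensus(seqs: list[str]) -> str:
    """Column-wise majority vote; ties break alphabetically; column length =
    modal sequence length."""
    lengths = sorted(len(s) for s in seqs)
    modal = max(set(lengths), key=lambda v: (lengths.count(v), -v))
    cols = []
    for j in range(modal):
        counts: dict[str, int] = defaultdict(int)
        for s in seqs:
            if j < len(s) and s[j] != "N":
                counts[s[j]] += 1
        cols.append(max(sorted(counts), key=lambda b: counts[b]) if counts
                    else "N")
    return "".join(cols)


def _hamming_identity(a: str, b: str) -> float:
    m = min(len(a), len(b))
    if m == 0:
        return 0.0
    same = sum(1 for x, y in zip(a[:m], b[:m]) if x == y)
    return same / max(len(a), len(b))


def _at_percent(s: str) -> float:
    acgt = sum(s.count(b) for b in "ACGT")
    return 100.0 * sum(s.count(b) for b in "AT") / acgt if acgt else 0.0


def find_tandem_repeats(genome: CircularGenome, min_unit: int = 10,
                        max_unit: int = 200, min_copies: float = 1.8,
                        min_identity: float = 0.8) -> list[RepeatRegion]:
    """Tandem-array discovery by per-lag self-comparison.

    For each candidate unit length ``d`` the sequence is compared with itself
    shifted by ``d``; windows of length ``d`` whose identity reaches
    ``min_identity`` mark adjacent repeat copies, and contiguous stretches of
    such windows are merged into arrays.  Overlapping calls at different unit
    lengths keep the higher score (copies x identity x unit length, ties to
    the smaller unit).  Arrays spanning the origin are not searched.
    """
    if not (0 < min_unit <= max_unit) or min_copies < 1 or not 0 < min_identity <= 1:
        raise ValueError("repeat-finder parameter out of range")
    s = genome.seq
    n = len(s)
    x = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates = []   # (score, d, start, end, copies, identity)
    for d in range(min_unit, min(max_unit, n // 2) + 1):
        m = (x[:-d] == x[d:]).astype(np.float64)
        cs = np.concatenate([[0.0], np.cumsum(m)])
        if cs.size <= d:
            continue
        ident = (cs[d:] - cs[:-d]) / d          # ident[i]: unit i vs unit i+d
        for a, b in _runs(ident >= min_identity):
            start, end = a, b + 2 * d
            copies = (end - start) / d
            if copies < min_copies:
                continue
            region_ident = float((cs[b + d] - cs[a]) / (b + d - a))
            score = copies * region_ident * d
            candidates.append((score, d, start, end, copies, region_ident))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[tuple] = []
    for cand in candidates:
        _, d, start, end, _, _ = cand
        if all(min(end, e2) - max(start, s2) <= 0 for _, _, s2, e2, _, _ in accepted):
            accepted.append(cand)

    regions = []
    for score, d, start, end, copies, region_ident in sorted(
            accepted, key=lambda c: c[2]):
        n_full = (end - start) // d
        copies_seqs = [s[start + t * d:start + (t + 1) * d] for t in range(n_full)]
        consensus = _majority_consensus(copies_seqs)
        units = [RepeatUnit(start + t * d, start + (t + 1) * d, "+",
                            _hamming_identity(copies_seqs[t], consensus),
                            copies_seqs[t])
                 for t in range(n_full)]
        span_seq = s[start:end]
        regions.append(RepeatRegion("", "dr", (start, end), units, consensus,
                                    len(consensus), None, _at_percent(span_seq)))
    for k, r in enumerate(regions, 1):
        r.region_id = f"dr{k}"
    return regions


# ---------------------------------------------------------------------------
# homologous repeat regions (hr)

_SEED_K = 12
_XDROP = 8
_MAX_KMER_OCC = 30


def _extend_ungapped(sa: str, sb: str, i: int, p: int, k: int
                     ) -> tuple[int, int, int, int]:
    """X-drop extension of an exact seed ``sa[i:i+k] == sb[p:p+k]``.

    Returns ``(i0, i1, p0, p1)`` of the trimmed maximal-scoring segment
    (match +1, mismatch -1).
    """
    # right
    score, best, best_t = 0, 0, -1
    t = 0
    while i + k + t < len(sa) and p + k + t < len(sb):
        score += 1 if sa[i + k + t] == sb[p + k + t] else -1
        if score > best:
            best, best_t = score, t
        if score < best - _XDROP:
            break
        t += 1
    right = best_t + 1
    # left
    score, best, best_t = 0, 0, -1
    t = 0
    while i - 1 - t >= 0 and p - 1 - t >= 0:
        score += 1 if sa[i - 1 - t] == sb[p - 1 - t] else -1
        if score > best:
            best, best_t = score, t
        if score < best - _XDROP:
            break
        t += 1
    left = best_t + 1
    return i - left, i + k + right, p - left, p + k + right


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Cluster intervals that overlap by more than half the shorter one;
    each cluster becomes its union."""
    if not intervals:
        return []
    parent = list(range(len(intervals)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    order = sorted(range(len(intervals)), key=lambda t: intervals[t])
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            a, b = order[ai], order[bi]
            (s1, e1), (s2, e2) = intervals[a], intervals[b]
            if s2 >= e1:
                break
            ov = min(e1, e2) - max(s1, s2)
            if ov > 0.5 * min(e1 - s1, e2 - s2):
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = defaultdict(list)
    for t in range(len(intervals)):
        groups[find(t)].append(t)
    merged = []
    for members in groups.values():
        ss = min(intervals[t][0] for t in members)
        ee = max(intervals[t][1] for t in members)
        merged.append((ss, ee))
    return sorted(merged)


def find_hrs(genome: CircularGenome, min_unit: int = 40, min_units: int = 2,
             min_identity: float = 0.7) -> list[RepeatRegion]:
    """Discover homologous-repeat regions.

    Units are clusters of >= ``min_units`` similar segments in either
    orientation; purely tandem same-orientation arrays are left to the dr
    finder.  Each region carries a majority-vote consensus over
    orientation-normalized units and, when opposite-orientation neighbours
    flank one, the longest perfect palindrome (>= 8 bp) in the gap between
    them.
    """
    s = genome.seq
    L = len(s)
    if L < min_unit * min_units:
        raise ValueError("genome shorter than min_unit * min_units")
    k = _SEED_K
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        w = s[i:i + k]
        if "N" not in w:
            pos[w].append(i)

    rc = revcomp(s)
    rc_pos: dict[str, list[int]] = defaultdict(list)
    for p in range(L - k + 1):
        w = rc[p:p + k]
        if "N" not in w:
            rc_pos[w].append(p)

    # seed pairs: (i, j, orientation); j is the genome start of the partner
    seeds: list[tuple[int, int, str]] = []
    for w, plist in pos.items():
        if len(plist) > _MAX_KMER_OCC:
            continue
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                if plist[b] - plist[a] >= min_unit:
                    seeds.append((plist[a], plist[b], "+"))
        rlist = rc_pos.get(w, [])
        if len(rlist) > _MAX_KMER_OCC:
            continue
        for p in rlist:
            j = L - p - k          # genome start of the reverse partner
            for i in plist:
                # i < j orders each reverse pair once; overlapping intervals
                # are self-palindromic matches, not repeat-unit pairs
                if i < j and j - i >= k:
                    seeds.append((i, p, "-"))

    # extended alignments; diag is p0 - i0 in the partner's coordinate space
    # (genome coords for '+', reverse-complement coords for '-')
    alignments = []   # (intervalA, intervalB, orientation, identity, diag)
    done: dict[tuple, int] = {}
    for i, j, orient in sorted(seeds, key=lambda t: (t[2], t[1] - t[0], t[0])):
        diag_key = (orient, j - i)
        if done.get(diag_key, -1) >= i + k:
            continue
        if orient == "+":
            i0, i1, p0, p1 = _extend_ungapped(s, s, i, j, k)
            b_iv = (p0, p1)
        else:
            i0, i1, p0, p1 = _extend_ungapped(s, rc, i, j, k)
            b_iv = (L - p1, L - p0)
        done[diag_key] = i1
        length = i1 - i0
        if length < min_unit:
            continue
        other = s[p0:p1] if orient == "+" else rc[p0:p1]
        ident = _hamming_identity(s[i0:i1], other)
        if ident < min_identity:
            continue
        if orient == "-" and min(i1, b_iv[1]) - max(i0, b_iv[0]) > 0:
            continue
        alignments.append(((i0, i1), b_iv, orient, ident, p0 - i0))

    if not alignments:
        return []

    intervals = []
    for a_iv, b_iv, _, _, _ in alignments:
        intervals.append(a_iv)
        intervals.append(b_iv)
    units_iv = _merge_intervals(intervals)

    def owner(iv):
        best, best_ov = None, 0
        for u_idx, (us, ue) in enumerate(units_iv):
            ov = min(ue, iv[1]) - max(us, iv[0])
            if ov > best_ov:
                best, best_ov = u_idx, ov
        return best

    # each alignment is an exact affine map between unit coordinate frames:
    # x -> x + d for a forward pair, x -> c - x for a reverse pair
    edges: list[tuple[int, int, tuple[int, int]]] = []
    for a_iv, b_iv, orient, _, diag in alignments:
        ua, ub = owner(a_iv), owner(b_iv)
        if ua is None or ub is None or ua == ub:
            continue
        if orient == "+":
            edges.append((ua, ub, (1, diag)))
        else:
            edges.append((ua, ub, (-1, L - 1 - diag)))

    adj: dict[int, list[tuple[int, tuple[int, int]]]] = defaultdict(list)
    for ua, ub, emap in edges:
        sign, off = emap
        adj[ua].append((ub, emap))
        # inverse of x -> sign*x + off is y -> sign*y - sign*off
        adj[ub].append((ua, (sign, -sign * off) if sign == 1 else emap))

    # connected components; map_of[u] sends reference-frame coords to unit u
    map_of: dict[int, tuple[int, int]] = {}
    components: list[list[int]] = []
    for u in range(len(units_iv)):
        if u in map_of or u not in adj:
            continue
        comp = [u]
        map_of[u] = (1, 0)
        queue = [u]
        while queue:
            cur = queue.pop(0)
            s_cur, o_cur = map_of[cur]
            for nxt, (s_e, o_e) in adj[cur]:
                if nxt not in map_of:
                    # compose: edge map after the current map
                    map_of[nxt] = (s_e * s_cur, s_e * o_cur + o_e)
                    comp.append(nxt)
                    queue.append(nxt)
        components.append(sorted(comp, key=lambda t: units_iv[t]))

    def project(mapping, x):
        sign, off = mapping
        return sign * x + off

    def inv_interval(mapping, iv):
        """Pre-image of a genome interval in reference-frame coordinates."""
        sign, off = mapping
        if sign == 1:
            return iv[0] - off, iv[1] - off
        return off - iv[1] + 1, off - iv[0] + 1

    regions = []
    for comp in components:
        if len(comp) < min_units:
            continue
        # trim unit boundaries to the majority-support span of the reference
        # frame: merged intervals overshoot into flanking sequence, so keep
        # the columns covered by more than half of the units
        pre = {u: inv_interval(map_of[u], units_iv[u]) for u in comp}
        lo = min(a for a, _ in pre.values())
        hi = max(b for _, b in pre.values())
        support = [0] * (hi - lo)
        for a, b in pre.values():
            for x in range(a - lo, b - lo):
                support[x] += 1
        need = len(comp) / 2
        best_run, run_start = None, None
        for x, v in enumerate(support + [0]):
            if v > need and run_start is None:
                run_start = x
            elif v <= need and run_start is not None:
                if best_run is None or x - run_start > best_run[1] - best_run[0]:
                    best_run = (run_start, x)
                run_start = None
        if best_run is None:
            continue
        xs, xe = best_run[0] + lo, best_run[1] + lo
        if xe - xs < min_unit:
            continue

        units = []
        for u in comp:
            sign, off = map_of[u]
            if sign == 1:
                us, ue = xs + off, xe + off
            else:
                us, ue = off - xe + 1, off - xs + 1
            # units abutting the sequence ends are clipped, with N padding
            # keeping their columns in register with the others
            us_c, ue_c = max(0, us), min(L, ue)
            if ue_c - us_c < min_unit:
                continue
            o = "+" if sign == 1 else "-"
            padded = ("N" * (us_c - us)) + s[us_c:ue_c] + ("N" * (ue - ue_c))
            units.append(RepeatUnit(us_c, ue_c, o, 1.0,
                                    padded if o == "+" else revcomp(padded)))
        if len(units) < min_units:
            continue
        units.sort(key=lambda u: u.start)
        # tandem same-orientation arrays belong to the dr finder
        gaps = [units[t + 1].start - units[t].end for t in range(len(units) - 1)]
        if all(u.orientation == units[0].orientation for u in units) and \
                gaps and max(gaps) < 10:
            continue
        consensus = _majority_consensus([u.seq for u in units])
        units = _trim_to_consensus_support(units, consensus)
        if len(units) < min_units or len(units[0].seq) < min_unit:
            continue
        consensus = _majority_consensus([u.seq for u in units])
        for u in units:
            u.identity_to_consensus = _hamming_identity(u.seq, consensus)
        units = [u for u in units if u.identity_to_consensus >= min_identity]
        if len(units) < min_units:
            continue
        consensus = _majority_consensus([u.seq for u in units])
        for u in units:
            u.identity_to_consensus = _hamming_identity(u.seq, consensus)

        core = None
        for t in range(len(units) - 1):
            if units[t].orientation != units[t + 1].orientation:
                gap_seq = s[units[t].end:units[t + 1].start]
                cand = longest_palindrome(gap_seq, min_len=8)
                if cand and (core is None or len(cand) > len(core)):
                    core = cand
        span = (units[0].start, units[-1].end)
        regions.append(RepeatRegion("", "hr", span, units, consensus,
                                    len(consensus), core,
                                    _at_percent(s[span[0]:span[1]])))
    regions.sort(key=lambda r: r.span)
    for t, r in enumerate(regions, 1):
        r.region_id = f"hr{t}"
    return regions


def _trim_to_consensus_support(units: list[RepeatUnit], consensus: str
                               ) -> list[RepeatUnit]:
    """Trim x-drop overshoot: drop leading/trailing columns whose smoothed
    agreement with the consensus falls below the level expected inside a
    genuine repeat unit."""
    n = len(units)
    width = min(len(consensus), min(len(u.seq) for u in units))
    agree = [sum(1 for u in units if u.seq[j] == consensus[j]) / n
             for j in range(width)]
    win = min(7, width)

    # random columns agree with a majority-vote consensus at ~0.45 even for
    # unrelated sequence, so the cut level sits well above that
    def smooth_ok(j):
        a = max(0, min(j - win // 2, width - win))
        return sum(agree[a:a + win]) / win >= 0.75

    j0 = 0
    while j0 < width and not smooth_ok(j0):
        j0 += 1
    j1 = width
    while j1 > j0 and not smooth_ok(j1 - 1):
        j1 -= 1
    if j1 - j0 < 1:
        return []
    out = []
    for u in units:
        hp = len(u.seq) - len(u.seq.lstrip("N"))   # leading pad columns
        if u.orientation == "+":
            ns, ne = u.start - hp + j0, u.start - hp + j1
        else:
            ns, ne = u.end + hp - j1, u.end + hp - j0
        ns, ne = max(0, ns), min(max(u.end, u.start + 1), ne)
        out.append(RepeatUnit(ns, ne, u.orientation, 1.0, u.seq[j0:j1]))
    return out


# ---------------------------------------------------------------------------
# alignment rendering

def render_unit_alignment(region: RepeatRegion) -> str:
    """Plain-text unit alignment in the style of a shaded repeat-unit figure.

    Orientation-normalized units are stacked over the consensus; columns where
    more than half the units agree with the consensus are marked ``*``.
    Genome coordinates (1-based, 5'->3' on the unit's strand) flank each row;
    reverse-strand units carry a ``(rev)`` tag.
    """
    if region.kind != "hr":
        raise ValueError("unit alignments are rendered for hr regions")
    if len(region.units) < 2:
        raise ValueError("need at least two units to render an alignment")
    width = max(len(u.seq) for u in region.units)
    names = [f"{region.region_id}{chr(ord('a') + t)}"
             for t in range(len(region.units))]
    name_w = max(len(n) for n in names) + 6
    lines = []
    for u, name in zip(region.units, names):
        left, right = (u.start + 1, u.end) if u.orientation == "+" \
            else (u.end, u.start + 1)
        tag = " (rev)" if u.orientation == "-" else ""
        lines.append(f"{(name + tag):<{name_w}}{left:>8}  "
                     f"{u.seq:<{width}}  {right}")
    cons = region.consensus.ljust(width)
    marks = []
    for j in range(width):
        agree = sum(1 for u in region.units
                    if j < len(u.seq) and j < len(region.consensus)
                    and u.seq[j] == region.consensus[j])
        marks.append("*" if agree > len(region.units) / 2 else " ")
    lines.append(f"{'consensus':<{name_w}}{'':>8}  {cons}")
    lines.append(f"{'':<{name_w}}{'':>8}  {''.join(marks)}")
    return "\n".join(lines) + "\n"


def parse_unit_alignment(text: str) -> list[tuple[str, int, int, str]]:
    """Recover ``(name, start, end, orientation)`` from a rendered block
    (internal coordinates)."""
    out = []
    for line in text.splitlines():
        parts = line.split()
        if not parts or parts[0] == "consensus" or not parts[0][0:2].isalpha():
            continue
        if parts[1] == "(rev)":
            name, left, right = parts[0], int(parts[2]), int(parts[4])
            orientation = "-"
        else:
            name, left, right = parts[0], int(parts[1]), int(parts[3])
            orientation = "+"
        if orientation == "+":
            start, end = left - 1, right
        else:
            start, end = right - 1, left
        out.append((name, start, end, orientation))
    return out
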