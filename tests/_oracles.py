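"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles, separately from the
package code paths it checks: different algorithms and different data
structures wherever feasible.
"""

from __future__ import annotations

import bisect
import re

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
         "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
         "H": "ACT", "V": "ACG", "N": "ACGT"}


def rc(s: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(s))


# ---------------------------------------------------------------------------
# ORFs: enumerate per frame via stop lists + bisect (different formulation
# from the package's single codon walk)

def orf_oracle(seq: str, min_codons: int) -> set[tuple[int, int, str]]:
    """All genome-coordinate (start, end, strand) ORFs of a circular genome,
    collapsed to the longest candidate per stop codon."""
    L = len(seq)
    stops = {"TAA", "TAG", "TGA"}
    raw = []
    for strand in "+-":
        s1 = seq if strand == "+" else rc(seq)
        s = s1 + s1
        for frame in range(3):
            stop_pos = [i for i in range(frame, len(s) - 2, 3)
                        if s[i:i + 3] in stops]
            starts = [i for i in range(frame, len(s) - 2, 3)
                      if s[i:i + 3] == "ATG"]
            for j in starts:
                k = bisect.bisect_left(stop_pos, j)
                if k == len(stop_pos):
                    continue
                i = stop_pos[k]
                if (i - j) // 3 < min_codons or j >= L or i + 3 - j > L:
                    continue
                raw.append((strand, j, i + 3))
    best: dict[tuple, tuple] = {}
    for strand, j, e in raw:
        if strand == "+":
            start, end = j, e
        else:
            start = (L - e) % L
            end = start + (e - j)
        key = (strand, start % L) if strand == "-" else (strand, (end - 3) % L)
        if key not in best or (end - start) > (best[key][1] - best[key][0]):
            best[key] = (start, end, strand)
    return set(best.values())


# ---------------------------------------------------------------------------
# IUPAC matching via regex with overlap lookahead

def iupac_regex_offsets(pattern: str, window: str) -> list[int]:
    rx = "(?=(" + "".join(f"[{IUPAC[c]}]" for c in pattern.upper()) + "))"
    return [m.start() for m in re.finditer(rx, window.upper())]


def promoter_oracle(window: str, cakt_spacing=(25, 35)):
    """All hits in one upstream window (offset relative to the start codon =
    offset - len(window))."""
    shift = len(window)
    hits = []
    tata = iupac_regex_offsets("TATAW", window)
    cakt = iupac_regex_offsets("CAKT", window)
    for t in tata:
        for c in cakt:
            if cakt_spacing[0] <= c - t <= cakt_spacing[1]:
                hits.append(("early_tata_cakt", t - shift, c - t))
    for p in iupac_regex_offsets("TAATWAA", window):
        hits.append(("lef_tata_like", p - shift, None))
    for p in iupac_regex_offsets("DTAAG", window):
        hits.append(("late", p - shift, None))
    return sorted(hits, key=lambda h: (h[1], h[0]))


# ---------------------------------------------------------------------------
# palindromes by checking every even substring

def palindrome_oracle(seq: str, min_len: int) -> set[tuple[int, int]]:
    """(start, length) of all maximal perfect reverse-complement palindromes,
    maximality meaning not symmetrically extendable."""
    s = seq.upper()
    n = len(s)

    def is_pal(a, b):          # [a, b)
        sub = s[a:b]
        return all(c in COMP for c in sub) and sub == rc(sub)

    out = set()
    for a in range(n):
        for b in range(a + min_len, n + 1, 2):
            if (b - a) % 2 == 0 and is_pal(a, b):
                if a > 0 and b < n and is_pal(a - 1, b + 1):
                    continue   # extendable
                out.add((a, b - a))
    return out


# ---------------------------------------------------------------------------
# collinearity via O(n^2) LIS over explicit rotations/reflection

def lis_quadratic(vals: list[int]) -> int:
    n = len(vals)
    best = [1] * n
    for i in range(n):
        for j in range(i):
            if vals[j] < vals[i]:
                best[i] = max(best[i], best[j] + 1)
    return max(best) if best else 0


def collinearity_oracle(pairs, n_a, n_b, allow_reflection=True) -> float:
    if not pairs:
        return 0.0
    variants = [pairs]
    if allow_reflection:
        variants.append([(ia, n_b - 1 - ib) for ia, ib in pairs])
    best = 0
    for var in variants:
        for ra in range(n_a):
            ordered = sorted(((ia - ra) % n_a, ib) for ia, ib in var)
            seq = [ib for _, ib in ordered]
            for rb in range(n_b):
                best = max(best, lis_quadratic([(v - rb) % n_b for v in seq]))
    return best / len(pairs)


# ---------------------------------------------------------------------------
# affine-gap protein alignment score by Gotoh three-matrix DP

def gotoh_score(a: str, b: str, matrix, open_gap=-11, extend=-1,
                local=False) -> float:
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_gap + (i - 1) * extend
        if local:
            M[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = open_gap + (j - 1) * extend
        if local:
            M[0][j] = 0.0
    best_local = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + sub
            if local:
                M[i][j] = max(M[i][j], 0.0)
            X[i][j] = max(M[i - 1][j] + open_gap, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_gap, Y[i][j - 1] + extend)
            best_local = max(best_local, M[i][j])
    if local:
        return best_local
    return max(M[n][m], X[n][m], Y[n][m])
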