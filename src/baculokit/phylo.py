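"""Kimura two-parameter distances, species demarcation, and neighbor joining.

The K2P distance corrects separately for transitions (proportion P) and
transversions (proportion Q) observed over the sites compared:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites holding a gap or an ambiguity code in either sequence of a pair are
excluded from that pair only (pairwise deletion), and rates are uniform
across sites (no gamma correction).  The demarcation rule follows baculovirus
taxonomy practice: two isolates whose granulin/polyhedrin, lef-8 and lef-9
distances all exceed 0.05 substitutions/site are distinct species; the rule
is applied strictly in that direction only, so mixed evidence is
*inconclusive* rather than forced to a call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}
_UNAMBIG = set("ACGT")


class SaturationError(ValueError):
    """Raised when a saturated (undefined) distance blocks an operation."""


@dataclass
class AlignedPair:
    """Site counts for one pair of rows from an alignment."""

    a: str
    b: str
    n_compared: int
    P: float                    # transition proportion
    Q: float                    # transversion proportion

    @classmethod
    def from_strings(cls, a: str, b: str) -> "AlignedPair":
        if len(a) != len(b):
            raise ValueError(f"aligned rows differ in length: {len(a)} vs {len(b)}")
        a, b = a.upper(), b.upper()
        n = ts = tv = 0
        for x, y in zip(a, b):
            if x not in _UNAMBIG or y not in _UNAMBIG:
                continue            # pairwise deletion: gaps and ambiguity codes
            n += 1
            if x != y:
                if frozenset((x, y)) in TRANSITION_PAIRS:
                    ts += 1
                else:
                    tv += 1
        P = ts / n if n else 0.0
        Q = tv / n if n else 0.0
        return cls(a, b, n, P, Q)


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form K2P distance; NaN marks saturation (undefined)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(pair: AlignedPair) -> float:
    """K2P distance for an aligned pair under pairwise deletion."""
    if pair.n_compared == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    return k2p_from_pq(pair.P, pair.Q)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray               # symmetric; NaN marks undefined entries

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    def has_undefined(self) -> bool:
        return bool(np.isnan(self.d).any())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                cells = ["NA" if math.isnan(v) else f"{v:.6f}" for v in row]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        labels = lines[0].split("\t")[1:]
        rows = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            rows.append([math.nan if c == "NA" else float(c) for c in cells[1:]])
        return cls(labels, np.array(rows))


def pairwise_distances(rows: dict[str, str] | list[tuple[str, str]]
                       ) -> DistanceMatrix:
    """All-pairs K2P distances from one multiple alignment."""
    items = list(rows.items()) if isinstance(rows, dict) else list(rows)
    if len(items) < 2:
        raise ValueError("need at least two aligned sequences")
    length = len(items[0][1])
    for lab, seq in items:
        if len(seq) != length:
            raise ValueError(f"row {lab!r} has length {len(seq)}, expected {length}")
    labels = [lab for lab, _ in items]
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(
                AlignedPair.from_strings(items[i][1], items[j][1]))
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# species demarcation

@dataclass
class DemarcationVerdict:
    distances: dict[str, float]
    threshold: float
    verdict: str                # same_species | distinct_species | inconclusive


def demarcate(distances: dict[str, float], threshold: float = 0.05
              ) -> DemarcationVerdict:
    """Apply the per-gene distance rule.

    ``distinct_species`` iff every supplied gene distance exceeds the
    threshold; ``same_species`` iff every one is at or below it; anything
    mixed — or any undefined (NaN) distance — is ``inconclusive``.
    """
    if not distances:
        raise ValueError("at least one gene distance is required")
    vals = list(distances.values())
    if any(math.isnan(v) for v in vals):
        verdict = "inconclusive"
    elif all(v > threshold for v in vals):
        verdict = "distinct_species"
    elif all(v <= threshold for v in vals):
        verdict = "same_species"
    else:
        verdict = "inconclusive"
    return DemarcationVerdict(dict(distances), threshold, verdict)


# ---------------------------------------------------------------------------
# neighbor joining

def _nj_merge_order(matrix: DistanceMatrix):
    """Run NJ agglomeration; yields newick + the bipartitions created.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch, preserving the joined pair's distance.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if matrix.has_undefined():
        raise SaturationError(
            "distance matrix has undefined (saturated) entries; exclude the "
            "saturated taxa and rerun")
    d = {(i, j): float(matrix.d[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    newick = {i: lab for i, lab in enumerate(labels)}
    members = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    splits: list[frozenset] = []
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * d[(i, j)] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = d[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.6f},{newick[j]}:{lj:.6f})"
        members[u] = members[i] | members[j]
        splits.append(members[u])
        for k in active:
            if k in (i, j):
                continue
            d[(u, k)] = d[(k, u)] = 0.5 * (d[(i, k)] + d[(j, k)] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    la, lb, lc = (max(0.0, v) for v in (la, lb, lc))
    tree = f"({newick[a]}:{la:.6f},{newick[b]}:{lb:.6f},{newick[c]}:{lc:.6f});"
    return tree, splits


def nj_tree(matrix: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree serialized as Newick."""
    tree, _ = _nj_merge_order(matrix)
    return tree


def nj_splits(matrix: DistanceMatrix) -> set[frozenset]:
    """Non-trivial bipartitions of the NJ tree, each given as the member set
    of the clade created at a join (canonicalized against the full set)."""
    tree, splits = _nj_merge_order(matrix)
    full = frozenset(matrix.labels)
    canon = set()
    for s in splits:
        if 1 < len(s) < len(full) - 1:
            other = full - s
            canon.add(min(s, other, key=lambda x: (len(x), tuple(sorted(x)))))
    return canon


def bootstrap_support(rows: dict[str, str], n_replicates: int = 100,
                      seed: int = 0) -> dict[frozenset, int]:
    """Site-resampling bootstrap counts on NJ bipartitions (optional extra;
    NaN-producing replicates are skipped)."""
    rng = np.random.default_rng(seed)
    labels = list(rows)
    length = len(rows[labels[0]])
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        res = {lab: "".join(rows[lab][c] for c in cols) for lab in labels}
        mat = pairwise_distances(res)
        if mat.has_undefined():
            continue
        for split in nj_splits(mat):
            counts[split] = counts.get(split, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# alignment concatenation

def concat_alignments(alignments: list[tuple[str, dict[str, str]]],
                      order: list[str] | None = None
                      ) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    """Row-wise concatenation of per-gene alignments in a reference gene
    order, with per-gene column offsets recorded."""
    if not alignments:
        raise ValueError("no alignments supplied")
    blocks = dict(alignments)
    names = order if order is not None else [nm for nm, _ in alignments]
    missing_names = [nm for nm in names if nm not in blocks]
    if missing_names:
        raise ValueError(f"alignments missing for genes: {missing_names}")
    taxa = sorted(blocks[names[0]])
    for nm in names:
        absent = sorted(set(taxa) ^ set(blocks[nm]))
        if absent:
            raise ValueError(f"gene {nm}: taxa mismatch, absentees {absent}")
    out = {t: [] for t in taxa}
    offsets = {}
    pos = 0
    for nm in names:
        block = blocks[nm]
        width = len(block[taxa[0]])
        for t in taxa:
            if len(block[t]) != width:
                raise ValueError(f"gene {nm}: ragged alignment row {t}")
            out[t].append(block[t])
        offsets[nm] = (pos, pos + width)
        pos += width
    return {t: "".join(parts) for t, parts in out.items()}, offsets
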