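"""Gene-content classification, homolog mapping and gene parity plots.

Annotated ORFs are classified against a reference panel of named baculovirus
genes (core genes conserved in all baculoviruses, lepidopteran-baculovirus
conserved genes, other known baculovirus genes); ORFs without a panel hit at
the identity/coverage thresholds are *unique*.  Homologs between two genomes
are reciprocal best hits under local protein alignment, and gene order is
compared with a parity plot whose collinearity score is the longest common
monotone chain of homolog indices, maximized over circular rotations of
either genome and optional reflection.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .genome import CircularGenome, revcomp
from .orfs import OrfRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

PANEL_CLASSES = ("core", "lepidopteran_conserved", "other", "unique")


# ---------------------------------------------------------------------------
# protein alignment

def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_proteins(a: str, b: str, mode: str = "local"
                   ) -> tuple[float, float, tuple | None]:
    """Affine-gap protein alignment (BLOSUM62, open -11 / extend -1).

    Returns ``(score, identity, spans)`` where identity is computed over
    aligned residue-residue columns (gaps excluded) and ``spans`` is
    ``((a_start, a_end), (b_start, b_end))`` of the aligned region, or
    ``None`` when nothing aligns.
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name}: invalid residue(s) {sorted(bad)}")
    a, b = a.upper(), b.upper()
    aln = _aligner(mode).align(a, b)
    best = aln[0]
    blocks_a, blocks_b = best.aligned
    matches = cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        cols += ae - as_
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    identity = matches / cols if cols else 0.0
    if cols:
        spans = ((int(blocks_a[0][0]), int(blocks_a[-1][1])),
                 (int(blocks_b[0][0]), int(blocks_b[-1][1])))
    else:
        spans = None
    return float(best.score), identity, spans


# ---------------------------------------------------------------------------
# reference panel

@dataclass
class PanelEntry:
    gene_name: str
    gene_class: str
    category: str = ""
    orf_id: str = ""
    alias: str = ""
    sequences: list[str] = field(default_factory=list)


@dataclass
class ReferencePanel:
    entries: list[PanelEntry]

    def __post_init__(self):
        names = [e.gene_name for e in self.entries]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate panel gene names: {dup}")
        for e in self.entries:
            if e.gene_class not in PANEL_CLASSES:
                raise ValueError(f"{e.gene_name}: unknown class {e.gene_class!r}")

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in PANEL_CLASSES}
        for e in self.entries:
            out[e.gene_class] += 1
        return out

    def searchable(self) -> list[PanelEntry]:
        """Entries usable as homology-search targets (have representative
        sequences and a non-unique class)."""
        return [e for e in self.entries
                if e.sequences and e.gene_class != "unique"]


def load_reference_panel(tsv_path=None, fasta: dict[str, str] | None = None
                         ) -> ReferencePanel:
    """Load the gene panel (default: the packaged granulovirus gene-content
    table) and optionally attach representative protein sequences keyed by
    gene name."""
    if tsv_path is None:
        source = resources.files("baculokit.data").joinpath("table1_panel.tsv")
        text = source.read_text()
    else:
        with open(tsv_path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    entries = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        entries.append(PanelEntry(row["gene_name"], row["gene_class"],
                                  row.get("category", ""), row.get("orf_id", ""),
                                  row.get("alias", "") or ""))
    panel = ReferencePanel(entries)
    if fasta:
        by_name = {e.gene_name: e for e in panel.entries}
        for name, seq in fasta.items():
            if name in by_name:
                by_name[name].sequences.append(seq.upper().rstrip("*"))
    return panel


# ---------------------------------------------------------------------------
# classification

@dataclass
class ClassificationRow:
    orf_id: str
    gene_name: str | None
    gene_class: str
    best_score: float
    best_identity: float


@dataclass
class ClassificationResult:
    rows: list[ClassificationRow]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in PANEL_CLASSES}
        for r in self.rows:
            out[r.gene_class] += 1
        return out


def _coverage(spans, len_a: int, len_b: int) -> float:
    if spans is None:
        return 0.0
    (as_, ae), (bs, be) = spans
    return max((ae - as_) / len_a, (be - bs) / len_b)


#: raw-score floor below which a local hit is treated as noise; random or
#: shuffled sequences of these lengths score < ~50 under BLOSUM62 while
#: remote homologs (25-30% identity over >=100 aa) score well above 100
MIN_ALIGN_SCORE = 60.0


def classify_orfs(orfs: list[OrfRecord], panel: ReferencePanel,
                  min_identity: float = 0.25, min_coverage: float = 0.5,
                  min_score: float = MIN_ALIGN_SCORE) -> ClassificationResult:
    """Assign each ORF to its best panel gene meeting the identity, coverage
    and score thresholds (ties: higher identity, then panel order);
    unassigned ORFs are unique."""
    targets = panel.searchable()
    rows = []
    for orf in orfs:
        best = None   # (score, identity, entry)
        for entry in targets:
            for rep in entry.sequences:
                score, ident, spans = align_proteins(orf.translation, rep,
                                                     "local")
                if score < min_score or ident < min_identity:
                    continue
                if _coverage(spans, len(orf.translation), len(rep)) < min_coverage:
                    continue
                if best is None or (score, ident) > (best[0], best[1]):
                    best = (score, ident, entry)
        if best is None:
            rows.append(ClassificationRow(orf.orf_id, None, "unique", 0.0, 0.0))
        else:
            score, ident, entry = best
            rows.append(ClassificationRow(orf.orf_id, entry.gene_name,
                                          entry.gene_class, score, ident))
    return ClassificationResult(rows)


# ---------------------------------------------------------------------------
# homolog mapping

def map_homologs(orfs_a: list[OrfRecord], orfs_b: list[OrfRecord],
                 min_identity: float = 0.25, min_coverage: float = 0.5,
                 min_score: float = MIN_ALIGN_SCORE) -> list[tuple[str, str]]:
    """One-to-one reciprocal-best-hit pairs under local protein alignment."""
    score: dict[tuple[int, int], tuple[float, float, float]] = {}
    for i, oa in enumerate(orfs_a):
        for j, ob in enumerate(orfs_b):
            sc, ident, spans = align_proteins(oa.translation, ob.translation,
                                              "local")
            cov = _coverage(spans, len(oa.translation), len(ob.translation))
            score[(i, j)] = (sc, ident, cov)

    def best_of(i, axis):
        cands = [(score[(i, j)][0], -j, j) for j in range(len(orfs_b))] \
            if axis == 0 else \
            [(score[(j, i)][0], -j, j) for j in range(len(orfs_a))]
        return max(cands)[2] if cands else None

    pairs = []
    for i in range(len(orfs_a)):
        j = best_of(i, 0)
        if j is None:
            continue
        sc, ident, cov = score[(i, j)]
        if sc < min_score or ident < min_identity or cov < min_coverage:
            continue
        if best_of(j, 1) == i:
            pairs.append((orfs_a[i].orf_id, orfs_b[j].orf_id))
    return pairs


# ---------------------------------------------------------------------------
# parity plots

@dataclass
class ParityData:
    pairs: list[tuple[int, int]]     # ordinal gene indices (a, b)
    n_a: int
    n_b: int
    collinearity: float


def _lis_length(values: list[int]) -> int:
    tails: list[int] = []
    for v in values:
        k = bisect.bisect_left(tails, v)
        if k == len(tails):
            tails.append(v)
        else:
            tails[k] = v
    return len(tails)


def _best_chain(pairs: list[tuple[int, int]], n_a: int, n_b: int) -> int:
    best = 0
    rot_as = sorted({ia for ia, _ in pairs})
    rot_bs = sorted({ib for _, ib in pairs})
    for ra in rot_as:
        ordered = sorted(((ia - ra) % n_a, ib) for ia, ib in pairs)
        seq = [ib for _, ib in ordered]
        for rb in rot_bs:
            best = max(best, _lis_length([(v - rb) % n_b for v in seq]))
    return best


def parity_plot(orfs_a: list[OrfRecord], orfs_b: list[OrfRecord],
                homologs: list[tuple[str, str]],
                allow_reflection: bool = True) -> ParityData:
    """Ordinal homolog index pairs plus a collinearity score in [0, 1].

    Collinearity is the longest monotone chain of pairs divided by the number
    of pairs, maximized over circular rotations of either gene order and
    (optionally) reflection of genome B.
    """
    index_a = {o.orf_id: k for k, o in enumerate(orfs_a)}
    index_b = {o.orf_id: k for k, o in enumerate(orfs_b)}
    pairs = []
    for ida, idb in homologs:
        if ida not in index_a or idb not in index_b:
            raise ValueError(f"homolog pair ({ida}, {idb}) references unknown genes")
        pairs.append((index_a[ida], index_b[idb]))
    n_a, n_b = len(orfs_a), len(orfs_b)
    if not pairs:
        return ParityData([], n_a, n_b, 0.0)
    best = _best_chain(pairs, n_a, n_b)
    if allow_reflection:
        mirrored = [(ia, n_b - 1 - ib) for ia, ib in pairs]
        best = max(best, _best_chain(mirrored, n_a, n_b))
    return ParityData(sorted(pairs), n_a, n_b, best / len(pairs))


def save_parity_plot(data: ParityData, path, label_a: str = "genome A",
                     label_b: str = "genome B") -> None:
    """Scatter of homolog ordinal positions (the parity plot itself)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    if data.pairs:
        xs, ys = zip(*data.pairs)
        ax.scatter(xs, ys, s=12)
    ax.set_xlabel(f"ORF ordinal in {label_a}")
    ax.set_ylabel(f"ORF ordinal in {label_b}")
    ax.set_title(f"collinearity = {data.collinearity:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# whole-genome identity surrogate

def _canonical_kmers(genome: CircularGenome, k: int) -> set[str]:
    s = genome.seq + (genome.seq[:k - 1] if genome.is_circular else "")
    out = set()
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        if "N" in w:
            continue
        out.add(min(w, revcomp(w)))
    return out


def kmer_identity(a: CircularGenome, b: CircularGenome, k: int = 17) -> float:
    """Symmetrized shared-k-mer containment between two genomes.

    A fast, alignment-free stand-in for whole-genome identity: the mean of
    the two containment fractions of canonical (strand-collapsed) k-mer sets.
    Odd ``k >= 11`` avoids self-reverse-complement k-mers and near-certain
    random collisions.
    """
    if k % 2 == 0 or k < 11:
        raise ValueError("k must be odd and >= 11")
    if len(a) < k or len(b) < k:
        raise ValueError("genomes must be at least k long")
    ka, kb = _canonical_kmers(a, k), _canonical_kmers(b, k)
    inter = len(ka & kb)
    return 0.5 * (inter / len(ka) + inter / len(kb))
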