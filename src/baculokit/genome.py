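"""Circular-genome container and annotation I/O.

Coordinates are 0-based half-open internally and 1-based inclusive in files
(GenBank, GFF3).  A feature that spans the origin of a circular genome is held
as a single logical feature whose ``end`` exceeds the genome length (so
``start < end`` always holds after linearization); on disk it becomes a
``join`` of two spans (GenBank) or two CDS parts sharing one ``ID`` (GFF3).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: feature kinds given first-class treatment; anything else is kept as "other"
KNOWN_KINDS = {"CDS", "repeat_region", "promoter"}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A dsDNA genome sequence with explicit topology.

    Parameters
    ----------
    id : str
        Record label.
    seq : str
        Uppercase DNA over ``{A, C, G, T, N}``.
    topology : str
        ``"circular"`` (index arithmetic is modulo length, slices may cross
        the origin) or ``"linear"``.
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = next((i for i, c in enumerate(self.seq) if c not in _DNA), None)
        if bad is not None:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC character "
                f"{self.seq[bad]!r} at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        """Extract ``[start, end)``; on circular genomes ``end`` may exceed
        the length, in which case the slice wraps across the origin.

        For ``strand == "-"`` the reverse complement of the plus-strand slice
        is returned.
        """
        n = len(self.seq)
        if not 0 <= start < n:
            raise IndexError(f"start {start} outside genome of length {n}")
        if end < start:
            raise IndexError(f"end {end} < start {start}")
        if end > n:
            if not self.is_circular:
                raise ValueError("slice wraps origin but topology is linear")
            if end - start > n:
                raise IndexError(f"slice of length {end - start} exceeds genome")
            s = self.seq[start:] + self.seq[: end - n]
        else:
            s = self.seq[start:end]
        return s if strand == "+" else revcomp(s)

    def gc_percent(self) -> float:
        """GC percentage over unambiguous bases; N excluded from both the
        numerator and the denominator."""
        gc = sum(self.seq.count(b) for b in "GC")
        acgt = sum(self.seq.count(b) for b in "ACGT")
        return 100.0 * gc / acgt if acgt else 0.0


@dataclass
class Feature:
    """One annotated interval (internal coordinates).

    ``wrap`` marks an origin-spanning feature: ``start < L <= end`` with
    genome length ``L``; the occupied bases are ``start..L-1`` and
    ``0..end-L-1``.
    """

    feature_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.feature_id}: end {self.end} <= start {self.start}"
            )

    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Occupied base intervals modulo the genome length (1 or 2 pieces)."""
        if self.wraps(genome_length):
            return [(self.start, genome_length), (0, self.end - genome_length)]
        return [(self.start, self.end)]


@dataclass
class FeatureTable:
    genome_id: str
    genome_length: int
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        for f in self.features:
            if f.start >= self.genome_length or f.end > 2 * self.genome_length:
                raise FormatError(
                    f"feature {f.feature_id}: coordinates ({f.start},{f.end}) "
                    f"outside genome of length {self.genome_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def sorted(self) -> "FeatureTable":
        feats = sorted(self.features, key=lambda f: (f.start, f.end, f.strand))
        return FeatureTable(self.genome_id, self.genome_length, feats)


# ---------------------------------------------------------------------------
# coordinate conversion

def to_external(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> external 1-based inclusive."""
    return start + 1, end


def to_internal(first: int, last: int) -> tuple[int, int]:
    """External 1-based inclusive -> internal 0-based half-open."""
    return first - 1, last


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, topology: str = "circular") -> CircularGenome:
    """Read a single-record genome FASTA.

    Raises :class:`FormatError` on an empty file, more than one record, or
    characters outside ``{A,C,G,T,N}`` (case-insensitive), naming the record
    and offset.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(
            f"{path}: expected a single genome record, found {len(records)} "
            f"(first extras: {records[1].id})"
        )
    rec = records[0]
    return CircularGenome(rec.id, str(rec.seq).upper(), topology)


def read_fasta_many(path) -> dict[str, str]:
    """Read a multi-record FASTA (e.g. protein panels, alignments) as a
    label -> sequence mapping, uppercased."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(genome: CircularGenome, path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation I/O

def read_annotation(path, dialect: str, topology: str = "circular") -> FeatureTable:
    """Read a GenBank flat file or GFF3 into a :class:`FeatureTable`.

    Unknown feature kinds are kept with kind ``"other"`` and a logged
    warning.  Origin-spanning joins are reconstructed into single wrapped
    features.
    """
    if dialect == "genbank":
        return _read_genbank(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_annotation(table: FeatureTable, path, dialect: str,
                     genome: CircularGenome | None = None) -> None:
    """Write a :class:`FeatureTable`; the emitted file re-parses to an equal
    table.  The GenBank dialect requires the genome sequence."""
    if dialect == "gff3":
        _write_gff3(table, path)
    elif dialect == "genbank":
        if genome is None:
            raise ValueError("GenBank output requires the genome sequence")
        _write_genbank(table, path, genome)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


def _flatten_qualifiers(quals) -> dict:
    out = {}
    for k, v in quals.items():
        if isinstance(v, (list, tuple)):
            out[k] = v[0] if len(v) == 1 else list(v)
        else:
            out[k] = v
    return out


def _read_genbank(path) -> FeatureTable:
    rec = SeqIO.read(str(path), "genbank")
    length = len(rec.seq)
    feats = []
    counter = 0
    for f in rec.features:
        if f.type == "source":
            continue
        kind = f.type if f.type in KNOWN_KINDS else "other"
        if kind == "other":
            logger.warning("feature kind %r kept as 'other'", f.type)
        counter += 1
        quals = _flatten_qualifiers(f.qualifiers)
        fid = quals.pop("locus_tag", None) or quals.pop("ID", None) or f"f{counter}"
        loc = f.location
        strand = "-" if loc.strand == -1 else "+"
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
            # join across the origin: tail piece + head piece
            start, end = int(parts[1].start), length + int(parts[0].end)
        else:
            start, end = int(loc.start), int(loc.end)
        if end > length and start >= length:
            raise FormatError(
                f"feature {fid}: location outside genome of length {length}")
        feats.append(Feature(fid, start, end, strand, kind, quals))
    return FeatureTable(rec.id, length, feats)


_GFF_ESC = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09"}


def _gff_escape(s: str) -> str:
    s = s.replace("%", "%25")
    for c, e in _GFF_ESC.items():
        s = s.replace(c, e)
    return s


def _gff_unescape(s: str) -> str:
    return re.sub("%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), s)


def _read_gff3(path) -> FeatureTable:
    genome_id = None
    length = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, sid, first, last = line.split()
                genome_id, length = sid, int(last)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            rows.append((ln, cols))
    if genome_id is None:
        if not rows:
            raise FormatError(f"{path}: empty GFF3 with no sequence-region directive")
        genome_id = rows[0][1][0]
        length = max(int(c[4]) for _, c in rows)

    by_id: dict[str, list] = {}
    order: list[str] = []
    for ln, cols in rows:
        seqid, _src, kind, first, last, _score, strand, _phase, attrs = cols
        start, end = to_internal(int(first), int(last))
        if end > length or start < 0:
            raise FormatError(
                f"{path}:{ln}: coordinates {first}..{last} outside genome "
                f"of length {length}")
        qd = {}
        for item in attrs.split(";"):
            if not item:
                continue
            k, _, v = item.partition("=")
            qd[_gff_unescape(k)] = _gff_unescape(v)
        fid = qd.pop("ID", f"f{ln}")
        if kind not in KNOWN_KINDS:
            logger.warning("feature kind %r kept as 'other'", kind)
            qd.setdefault("original_kind", kind)
            kind = "other"
        if fid not in by_id:
            order.append(fid)
            by_id[fid] = []
        by_id[fid].append((start, end, strand, kind, qd))

    feats = []
    for fid in order:
        parts = sorted(by_id[fid])
        if len(parts) == 1:
            start, end, strand, kind, qd = parts[0]
        elif len(parts) == 2 and parts[0][0] == 0 and parts[1][1] == length:
            # two parts sharing an ID: wrapped feature (tail + head)
            head, tail = parts[0], parts[1]
            start, end = tail[0], length + head[1]
            strand, kind, qd = tail[2], tail[3], tail[4]
        else:
            raise FormatError(
                f"{path}: feature {fid} has {len(parts)} parts that do not "
                f"form an origin-spanning join")
        feats.append(Feature(fid, start, end, strand, kind, qd))
    return FeatureTable(genome_id, length, feats)


def _cds_phases(part_lengths: list[int]) -> list[int]:
    phases, carried = [], 0
    for n in part_lengths:
        phases.append((3 - carried % 3) % 3 if carried else 0)
        carried += n
    return phases


def _write_gff3(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {table.genome_id} 1 {table.genome_length}\n")
        for f in table.features:
            pieces = f.intervals(table.genome_length)
            # order pieces 5'->3' on the feature's strand for phase computation
            ordered = pieces if f.strand == "+" else pieces[::-1]
            phases = (_cds_phases([e - s for s, e in ordered])
                      if f.kind == "CDS" else ["."] * len(ordered))
            kind = f.qualifiers.get("original_kind", f.kind) \
                if f.kind == "other" else f.kind
            for (s, e), ph in zip(ordered, phases):
                first, last = to_external(s, e)
                attrs = [f"ID={_gff_escape(f.feature_id)}"]
                for k, v in f.qualifiers.items():
                    if k == "original_kind":
                        continue
                    vals = v if isinstance(v, list) else [v]
                    attrs.append(
                        f"{_gff_escape(k)}=" +
                        ",".join(_gff_escape(str(x)) for x in vals))
                fh.write("\t".join([
                    table.genome_id, "baculokit", kind, str(first), str(last),
                    ".", f.strand, str(ph), ";".join(attrs)]) + "\n")


def _write_genbank(table: FeatureTable, path, genome: CircularGenome) -> None:
    rec = SeqRecord(Seq(genome.seq), id=table.genome_id, name=table.genome_id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for f in table.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps(table.genome_length):
            tail = SimpleLocation(f.start, table.genome_length, strand)
            head = SimpleLocation(0, f.end - table.genome_length, strand)
            parts = [tail, head] if strand == 1 else [head, tail]
            loc = CompoundLocation(parts)
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals = {"locus_tag": [f.feature_id]}
        for k, v in f.qualifiers.items():
            if k == "original_kind":
                continue
            quals[k] = v if isinstance(v, list) else [v]
        kind = f.qualifiers.get("original_kind", f.kind) \
            if f.kind == "other" else f.kind
        rec.features.append(SeqFeature(loc, type=kind, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")
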