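"""Readers/writers and shared conventions.

All coordinates inside the package are 0-based half-open, BED style. SAM
input (1-based POS) is converted on read. The 5' end of a read is ``start``
on the plus strand and ``end - 1`` on the minus strand; the 3' end is the
opposite extremity.

Collapsed-read copy numbers are carried in the BED/SAM name field as a
``-<int>`` suffix (``seq12-34`` means 34 identical reads); absent suffix
means one copy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "AlignmentRecord",
    "RepeatCopy",
    "GenomeIndex",
    "LibraryStats",
    "read_alignments",
    "write_intervals",
    "write_alignments",
    "write_fasta",
    "normalize",
]

_COPIES_RE = re.compile(r"^(?P<stem>.*)-(?P<copies>\d+)$")
_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")


@dataclass
class AlignmentRecord:
    """One mapped occurrence of a small-RNA / RNA / DNA read.

    ``copies`` counts collapsed identical reads; ``n_loci`` is the number of
    genomic placements of the read (1 = uniquely mapped). ``gap`` holds the
    (donor, acceptor) coordinates of a spliced alignment's single intron, in
    reference coordinates; ungapped reads have ``gap = None``. A read whose
    sequence extends past its templated interval (3' tailing, stored as a
    soft clip) is flagged ``soft_clipped``.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    copies: int = 1
    n_loci: int = 1
    sequence: str | None = None
    mapq: int | None = None
    soft_clipped: bool = False
    gap: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty interval for read {self.read_id!r}: "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.copies < 1 or self.n_loci < 1:
            raise ValueError("copies and n_loci must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' nucleotide."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the read's 3' nucleotide."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def is_unique(self) -> bool:
        return self.n_loci == 1


@dataclass(frozen=True)
class RepeatCopy:
    """A transposon/repeat copy from a repeat annotation."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    divergence: float  # percent, in [0, 100]

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 100.0:
            raise ValueError(f"divergence must be in [0, 100], got {self.divergence}")


@dataclass
class GenomeIndex:
    """Contig lengths plus optional sequence, repeat and sex annotation."""

    lengths: dict[str, int]
    sequences: dict[str, str] | None = None
    repeats: list[RepeatCopy] = field(default_factory=list)
    sex_labels: dict[str, str] | None = None  # contig -> A / Z / W
    annotations: dict[str, list[tuple[str, int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rep in self.repeats:
            limit = self.lengths.get(rep.contig)
            if limit is None or rep.start < 0 or rep.end > limit:
                raise ValueError(f"repeat copy {rep} outside contig bounds")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        sequences = {name: str(fa[name][:]).upper() for name in fa.keys()}
        return cls(
            lengths={name: len(seq) for name, seq in sequences.items()},
            sequences=sequences,
        )

    def fetch(self, contig: str, start: int, end: int) -> str:
        if self.sequences is None:
            raise ValueError("genome has no sequence loaded")
        return self.sequences[contig][start:end]


@dataclass
class LibraryStats:
    """Sequencing-depth denominators for abundance normalization."""

    total_reads: float
    unique_mapped_reads: float
    cluster_mapped_reads: float = 0.0

    def __post_init__(self) -> None:
        if self.unique_mapped_reads > self.total_reads:
            raise ValueError("unique_mapped_reads cannot exceed total_reads")


def _parse_name(name: str) -> tuple[str, int]:
    """Split a collapsed-read name into (read id, copy count)."""
    m = _COPIES_RE.match(name)
    if m:
        return m.group("stem"), int(m.group("copies"))
    return name, 1


def _iter_bed6(path: Path) -> Iterator[AlignmentRecord]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            read_id, copies = _parse_name(name)
            # the score column doubles as MAPQ for DNA coverage reads
            mapq = int(score) if score not in (".", "") else None
            yield AlignmentRecord(
                read_id=read_id,
                contig=chrom,
                start=start_i,
                end=end_i,
                strand=strand,
                copies=copies,
                mapq=mapq,
            )


def _parse_sam_line(
    line: str, lineno: int
) -> AlignmentRecord | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError(f"line {lineno}: SAM record needs >= 6 columns")
    qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
    try:
        flag = int(flag_s)
        pos = int(pos_s)
        mapq = int(mapq_s)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer FLAG/POS/MAPQ") from exc
    if flag & 0x4 or rname == "*":
        return None  # unmapped
    strand = "-" if flag & 0x10 else "+"
    start = pos - 1  # SAM is 1-based

    span = 0
    gap: tuple[int, int] | None = None
    soft = False
    for count_s, op in _CIGAR_RE.findall(cigar):
        count = int(count_s)
        if op in ("M", "D"):
            span += count
        elif op == "N":
            if gap is not None:
                raise ValueError(f"line {lineno}: more than one gap in CIGAR")
            gap = (start + span, start + span + count)
            span += count
        elif op == "S":
            soft = True
        elif op == "I":
            pass
        else:
            raise ValueError(f"line {lineno}: unsupported CIGAR opcode {op!r}")
    if sum(len(c) + 1 for c, _ in _CIGAR_RE.findall(cigar)) != len(cigar):
        raise ValueError(f"line {lineno}: malformed CIGAR {cigar!r}")

    n_loci = 1
    explicit_nh = False
    sequence = None
    if len(fields) >= 10 and fields[9] != "*":
        sequence = fields[9]
    for tag in fields[11:]:
        if tag.startswith("NH:i:"):
            n_loci = int(tag[5:])
            explicit_nh = True
    read_id, copies = _parse_name(qname)
    rec = AlignmentRecord(
        read_id=read_id,
        contig=rname,
        start=start,
        end=start + span,
        strand=strand,
        copies=copies,
        n_loci=n_loci,
        sequence=sequence,
        mapq=mapq,
        soft_clipped=soft,
        gap=gap,
    )
    rec._explicit_nh = explicit_nh  # type: ignore[attr-defined]
    return rec


def read_alignments(path: str | Path, format: str = "bed6") -> list[AlignmentRecord]:
    """Read alignments from a BED6 or headerless-SAM file.

    For SAM input without NH multiplicity tags, ``n_loci`` is inferred by
    grouping records on ``read_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed6":
        return list(_iter_bed6(path))
    if format != "sam":
        raise ValueError(f"unknown format {format!r} (expected 'bed6' or 'sam')")

    records: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            rec = _parse_sam_line(line, lineno)
            if rec is not None:
                records.append(rec)
    # infer multiplicity for reads lacking an explicit NH tag
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.read_id] = counts.get(rec.read_id, 0) + 1
    for rec in records:
        if not getattr(rec, "_explicit_nh", False) and counts[rec.read_id] > 1:
            rec.n_loci = counts[rec.read_id]
    return records


def _as_bed_fields(item, index: int) -> tuple[str, int, int, str, int, str]:
    if isinstance(item, AlignmentRecord):
        name = f"{item.read_id}-{item.copies}"
        score = item.mapq if item.mapq is not None else 0
        return (item.contig, item.start, item.end, name, score, item.strand)
    contig = item.contig
    start = item.start
    end = item.end
    strand = getattr(item, "strand", ".")
    name = getattr(item, "name", None) or f"cluster_{index}"
    return (contig, start, end, name, 0, strand)


def write_intervals(
    records: Iterable, path: str | Path, genome: GenomeIndex | None = None
) -> None:
    """Write a named interval set as sorted BED6 with a '#' header line."""
    rows = [_as_bed_fields(item, i + 1) for i, item in enumerate(records)]
    if genome is not None:
        for contig, start, end, name, _, _ in rows:
            limit = genome.lengths.get(contig)
            if limit is None or start < 0 or end > limit:
                raise ValueError(
                    f"interval {contig}:{start}-{end} ({name}) outside contig bounds"
                )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[5]))
    with open(path, "w") as handle:
        handle.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_alignments(
    records: Iterable[AlignmentRecord], path: str | Path, format: str = "bed6"
) -> None:
    """Write alignment records as BED6 or a headerless SAM subset.

    SAM output preserves spliced gaps (N CIGAR) and soft-clipped 3'
    tails, which BED6 cannot represent; use it for RNA-seq junction
    reads and tailed small RNAs.
    """
    if format == "bed6":
        write_intervals(records, path)
        return
    if format != "sam":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as handle:
        for rec in records:
            flag = 16 if rec.strand == "-" else 0
            span = rec.end - rec.start
            if rec.gap is not None:
                donor, acceptor = rec.gap
                cigar = f"{donor - rec.start}M{acceptor - donor}N{rec.end - acceptor}M"
            elif rec.soft_clipped and rec.sequence is not None:
                clip = len(rec.sequence) - span
                cigar = f"{span}M{clip}S" if clip > 0 else f"{span}M"
            else:
                cigar = f"{span}M"
            seq = rec.sequence.replace("U", "T") if rec.sequence else "*"
            name = f"{rec.read_id}-{rec.copies}"
            mapq = rec.mapq if rec.mapq is not None else 255
            handle.write(
                "\t".join(
                    [
                        name,
                        str(flag),
                        rec.contig,
                        str(rec.start + 1),
                        str(mapq),
                        cigar,
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                        f"NH:i:{rec.n_loci}",
                    ]
                )
                + "\n"
            )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write contig sequences as FASTA (fixed line width)."""
    with open(path, "w") as handle:
        for name in sorted(sequences):
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def normalize(
    count: float,
    stats: LibraryStats,
    mode: str = "ppm_unique",
    length_nt: int | None = None,
) -> float:
    """Normalize a read count to ppm or rpkm.

    ``ppm_unique`` divides by uniquely mapped reads, ``ppm_total`` by total
    reads; ``rpkm`` additionally divides by the feature length in kb.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    if mode in ("ppm_unique", "rpkm"):
        denom = stats.unique_mapped_reads
    elif mode == "ppm_total":
        denom = stats.total_reads
    elif mode == "ppm_cluster":
        denom = stats.cluster_mapped_reads
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        raise ValueError(f"zero denominator for mode {mode!r}")
    ppm = count / denom * 1e6
    if mode != "rpkm":
        return ppm
    if length_nt is None or length_nt <= 0:
        raise ValueError("rpkm requires a positive length_nt")
    return ppm / (length_nt / 1000.0)
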