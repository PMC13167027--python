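"""Readers/writers for the formats the pipeline touches, and run configuration.

Coordinate convention: everything inside the package is **0-based,
half-open** (BED-style).  SAM's 1-based leftmost positions are converted
exactly once, here, at parse time; :class:`AlignmentRecord.pos0` is already
0-based.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("symprof")

GROUP_LUNA = "luna_dominant"
GROUP_LOTTI = "lotti_dominant"
GROUPS = (GROUP_LUNA, GROUP_LOTTI)

#: CIGAR operations that consume the reference.
REF_CONSUMING_OPS = frozenset("M=XDN")
#: CIGAR operations that add depth at consumed positions.
DEPTH_OPS = frozenset("M=X")

_CIGAR_OPS = "MIDNSHP=X"


class SymprofError(Exception):
    """Base class for package errors."""


class FormatError(SymprofError):
    """A file violated its format contract."""


class ParameterError(SymprofError):
    """An argument violated an operation's precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGenome:
    """A reference sequence (here: the symbiont MAG used for read mapping)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("reference id must be nonempty")
        if not self.sequence:
            raise FormatError(f"reference {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneInterval:
    """A gene interval on the reference, 0-based half-open."""

    gene_id: str
    ref_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped primary alignment.  ``pos0`` is 0-based (converted from SAM)."""

    read_id: str
    ref_id: str
    pos0: int
    cigar: tuple[tuple[int, str], ...]
    flags: int = 0
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise FormatError(f"read {self.read_id!r}: negative position")
        for length, op in self.cigar:
            if length < 1 or op not in _CIGAR_OPS:
                raise FormatError(f"read {self.read_id!r}: bad CIGAR op ({length}, {op})")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for n, op in self.cigar if op in REF_CONSUMING_OPS)

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ReferenceGenome]:
    """Read all records of a FASTA file.

    Sequences are uppercased; characters outside {A,C,G,T} are preserved but
    counted and reported in a warning.  An empty file yields an empty list.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), None)
    if first is not None and not first.startswith(">"):
        lineno = next(
            i for i, ln in enumerate(text.splitlines(), start=1) if ln.strip()
        )
        raise FormatError(f"{path}: line {lineno}: expected FASTA header, got {first!r}")

    genomes: list[ReferenceGenome] = []
    n_nonacgt = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        n_nonacgt += sum(1 for c in seq if c not in "ACGT")
        genomes.append(ReferenceGenome(id=rec.id, sequence=seq))
    if not genomes:
        logger.warning("read_fasta: %s contains no records", path)
    if n_nonacgt:
        logger.warning("read_fasta: %s: %d non-ACGT characters", path, n_nonacgt)
    return genomes


def write_fasta(genomes: Iterable[ReferenceGenome], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read a 3+ column BED file of gene intervals (0-based half-open).

    The name column becomes ``gene_id``; 3-column lines get ``gene_<n>``.
    Strand defaults to ``+`` when absent or ``.``.
    """
    path = Path(path)
    intervals: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            ref_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: empty or inverted interval [{start}, {end})"
                )
            gene_id = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"gene_{len(intervals) + 1}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                intervals.append(GeneInterval(gene_id, ref_id, start, end, strand))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.ref_id}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def read_sam(path: str | Path, mapq_min: int = 0) -> list[AlignmentRecord]:
    """Read mapped primary alignments from a SAM text file.

    Unmapped (0x4), secondary (0x100) and supplementary (0x800) records are
    dropped, as are mapped records with no CIGAR; drop counts are logged.
    Only primary mapped alignments contribute to depth downstream.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    dropped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "no_cigar": 0, "mapq": 0}
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped:
                    # htslib reflags CIGAR-less mapped records as unmapped but
                    # keeps their placement; surface those as the distinct case
                    if aln.cigartuples is None and aln.reference_id >= 0 and aln.reference_start >= 0:
                        dropped["no_cigar"] += 1
                        logger.warning(
                            "read_sam: %s: mapped record %s has CIGAR '*', skipped",
                            path, aln.query_name,
                        )
                    else:
                        dropped["unmapped"] += 1
                    continue
                if aln.is_secondary:
                    dropped["secondary"] += 1
                    continue
                if aln.is_supplementary:
                    dropped["supplementary"] += 1
                    continue
                if aln.cigartuples is None:
                    dropped["no_cigar"] += 1
                    logger.warning(
                        "read_sam: %s: mapped record %s has CIGAR '*', skipped",
                        path, aln.query_name,
                    )
                    continue
                if aln.mapping_quality < mapq_min:
                    dropped["mapq"] += 1
                    continue
                cigar = tuple((n, _CIGAR_OPS[op]) for op, n in aln.cigartuples)
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        ref_id=aln.reference_name or "*",
                        pos0=aln.reference_start,
                        cigar=cigar,
                        flags=aln.flag,
                        mapq=aln.mapping_quality,
                    )
                )
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: unparseable SAM: {exc}") from exc
    n_drop = sum(dropped.values())
    if n_drop:
        logger.info(
            "read_sam: %s: kept=%d dropped=%d (%s)", path, len(records), n_drop,
            " ".join(f"{k}={v}" for k, v in dropped.items() if v),
        )
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    references: Mapping[str, int],
    path: str | Path,
    sort_order: str = "coordinate",
) -> None:
    """Write alignments as SAM text (deterministic, byte-stable)."""
    with open(path, "w") as fh:
        fh.write(f"@HD\tVN:1.6\tSO:{sort_order}\n")
        for ref_id, length in references.items():
            fh.write(f"@SQ\tSN:{ref_id}\tLN:{length}\n")
        for rec in records:
            fh.write(
                f"{rec.read_id}\t{rec.flags}\t{rec.ref_id}\t{rec.pos0 + 1}\t"
                f"{rec.mapq}\t{rec.cigar_string}\t*\t0\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All printed analysis constants, with the study's values as defaults.

    * ``breadth_present`` / per-group depth thresholds: a gene is *present*
      when breadth >= 65% and mean depth >= 20x (luna-dominant) or >= 2x
      (lotti-dominant samples).
    * ``breadth_absent`` / ``depth_absent``: a gene is *absent* when breadth
      and depth fall below both cutoffs; everything else is *unknown*.
    * ``css_quantile`` / ``css_scale``: cumulative-sum-scaling parameters.
    * ``fdr_alpha``: BH-adjusted significance level for differential calls.
    * ``min_library_size``: amplicon samples below this total are excluded.
    * ``detection_min_count``: raw count at which an ASV counts as detected.
    """

    breadth_present: float = 0.65
    depth_present_luna: float = 20.0
    depth_present_lotti: float = 2.0
    breadth_absent: float = 0.10
    depth_absent: float = 1.0
    threshold_on_normalized_depth: bool = False
    mapq_min: int = 0
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    fdr_alpha: float = 0.05
    min_library_size: int = 1000
    detection_min_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("breadth_present", "breadth_absent", "css_quantile", "fdr_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1 and not (name == "breadth_absent" and v == 0):
                raise ParameterError(f"{name}={v} outside (0, 1)")
        if self.breadth_absent >= self.breadth_present:
            raise ParameterError("breadth_absent must be < breadth_present")
        if self.depth_absent >= min(self.depth_present_luna, self.depth_present_lotti):
            raise ParameterError("depth_absent must be < every presence depth threshold")
        if self.css_scale <= 0:
            raise ParameterError("css_scale must be positive")
        if self.min_library_size < 0 or self.detection_min_count < 1:
            raise ParameterError("invalid library-size / detection thresholds")

    @property
    def depth_present_by_group(self) -> dict[str, float]:
        return {GROUP_LUNA: self.depth_present_luna, GROUP_LOTTI: self.depth_present_lotti}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**data)
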