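"""Readers and writers for FASTA/FASTQ/SAM/VCF plus the toolkit's own formats.

Coordinates are 1-based and inclusive on the forward strand of the reference
everywhere (SAM convention).  Ground truth for a simulated read is carried in
two redundant places: encoded in the read name (SAM-safe, survives any mapper)
and in a tab-separated truth table; the table is authoritative on conflict.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO

from .exceptions import CodecError, FormatError, MissingTagError

logger = logging.getLogger(__name__)

#: Sentinel contig name carried by random (unmappable) reads.
RANDOM_CONTIG = "*"

# IUPAC ambiguity codes are collapsed to N; anything else is rejected.
_IUPAC_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")
_VALID_BASES = frozenset("ACGTN")

TRUTH_COLUMNS = [
    "read_id", "contig", "start", "end", "strand",
    "n_ins", "n_del", "n_sub", "is_random",
]


@dataclass(frozen=True)
class Contig:
    """A named reference sequence over the alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadTruth:
    """Exact per-read ground truth: origin and canonical edit counts.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of the
    reference bases actually covered by the read.  ``n_ins``/``n_del``/``n_sub``
    are canonical (post-compensation) counts of inserted, deleted and
    substituted bases.  Random reads carry sentinel coordinates and zero
    counts.
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    n_ins: int
    n_del: int
    n_sub: int
    is_random: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if min(self.n_ins, self.n_del, self.n_sub) < 0:
            raise ValueError("edit counts must be non-negative")
        if not self.is_random and self.start > self.end:
            raise ValueError(
                f"truth for {self.read_id}: start {self.start} > end {self.end}"
            )

    @property
    def read_length(self) -> int:
        """Length of the read implied by span and canonical counts."""
        if self.is_random:
            raise ValueError("random reads do not imply a length")
        return (self.end - self.start + 1) + self.n_ins - self.n_del

    @classmethod
    def random(cls, read_id: str) -> "ReadTruth":
        return cls(read_id, RANDOM_CONTIG, 0, 0, "+", 0, 0, 0, True)


@dataclass(frozen=True)
class AlignmentObservation:
    """One SAM hit reduced to the fields the correctness rule inspects."""

    read_id: str
    mapped: bool
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    clip_left: int = 0
    clip_right: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_sub: int = 0


@dataclass(frozen=True)
class VariantCall:
    """One allele of a VCF record with its supporting depth and frequency."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fraction: float

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def load_reference(path: str | Path) -> list[Contig]:
    """Load a FASTA reference as an ordered list of :class:`Contig`.

    Sequences are uppercased, line wraps joined and IUPAC ambiguity codes
    collapsed to ``N``.  Duplicate contig names, empty files and non-FASTA
    content raise :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head != ">":
        raise FormatError(f"{path}: not FASTA (first character {head!r})")
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: record with empty header")
        if name in seen:
            raise FormatError(f"{path}: duplicate contig name {name!r}")
        seen.add(name)
        seq = str(rec.seq).upper().translate(_IUPAC_TO_N)
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: contig {name!r} contains invalid characters {sorted(bad)}"
            )
        contigs.append(Contig(name, seq))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i:i + width] + "\n")


def write_fastq(
    records: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    """Write (name, sequence) pairs as 4-line FASTQ with constant quality."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Ground-truth read-name codec
# ---------------------------------------------------------------------------
#
# Layout (underscore-delimited, fixed field order):
#
#   <read_id>_<contig>_<start>_<end>_<F|R>_<n_ins>_<n_del>_<n_sub>_<0|1>
#
# ``read_id`` is an opaque token (typically ``r<serial>``) that may not contain
# underscores or whitespace.  Underscores inside contig names are escaped as
# ``%u`` (and ``%`` as ``%p``) so the encoded name always splits into exactly
# nine fields.

def _escape_contig(name: str) -> str:
    return name.replace("%", "%p").replace("_", "%u")


def _unescape_contig(name: str) -> str:
    return name.replace("%u", "_").replace("%p", "%")


def encode_truth_name(truth: ReadTruth) -> str:
    """Encode a :class:`ReadTruth` into a SAM-safe read name."""
    if re.search(r"[\s_]", truth.read_id):
        raise CodecError(
            f"read_id {truth.read_id!r} contains whitespace or underscore"
        )
    if re.search(r"\s", truth.contig):
        raise CodecError(f"contig {truth.contig!r} contains whitespace")
    strand = "F" if truth.strand == "+" else "R"
    return "_".join(
        [
            truth.read_id,
            _escape_contig(truth.contig),
            str(truth.start),
            str(truth.end),
            strand,
            str(truth.n_ins),
            str(truth.n_del),
            str(truth.n_sub),
            "1" if truth.is_random else "0",
        ]
    )


def decode_truth_name(name: str) -> ReadTruth:
    """Inverse of :func:`encode_truth_name`; raises :class:`CodecError`."""
    parts = name.split("_")
    if len(parts) != 9:
        raise CodecError(
            f"{name!r}: expected 9 underscore-delimited fields, got {len(parts)}"
        )
    read_id, contig_raw, start_s, end_s, strand_s, ins_s, del_s, sub_s, rand_s = parts
    if strand_s not in ("F", "R"):
        raise CodecError(f"{name!r}: strand field {strand_s!r} not in {{F,R}}")
    if rand_s not in ("0", "1"):
        raise CodecError(f"{name!r}: random flag {rand_s!r} not in {{0,1}}")
    ints = {}
    for field, value in (
        ("start", start_s), ("end", end_s),
        ("n_ins", ins_s), ("n_del", del_s), ("n_sub", sub_s),
    ):
        try:
            ints[field] = int(value)
        except ValueError:
            raise CodecError(f"{name!r}: field {field} is not an integer: {value!r}")
    try:
        return ReadTruth(
            read_id=read_id,
            contig=_unescape_contig(contig_raw),
            start=ints["start"],
            end=ints["end"],
            strand="+" if strand_s == "F" else "-",
            n_ins=ints["n_ins"],
            n_del=ints["n_del"],
            n_sub=ints["n_sub"],
            is_random=rand_s == "1",
        )
    except ValueError as exc:
        raise CodecError(f"{name!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Truth table TSV
# ---------------------------------------------------------------------------

def write_truth_table(truths: Iterable[ReadTruth], path: str | Path) -> None:
    rows = [
        (t.read_id, t.contig, t.start, t.end, t.strand,
         t.n_ins, t.n_del, t.n_sub, int(t.is_random))
        for t in truths
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[ReadTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: truth table lacks columns {sorted(missing)}")
    return [
        ReadTruth(
            read_id=row.read_id, contig=row.contig,
            start=int(row.start), end=int(row.end), strand=row.strand,
            n_ins=int(row.n_ins), n_del=int(row.n_del), n_sub=int(row.n_sub),
            is_random=bool(row.is_random),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _md_substitution_count(md: str) -> int:
    """Count mismatch letters in an MD tag (letters not part of a ^deletion)."""
    pos = 0
    n_sub = 0
    for m in _MD_RE.finditer(md):
        if m.start() != pos:
            raise FormatError(f"malformed MD tag {md!r}")
        pos = m.end()
        if m.group(3):
            n_sub += 1
    if pos != len(md):
        raise FormatError(f"malformed MD tag {md!r}")
    return n_sub


# pysam CIGAR op codes
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)
_REF_CONSUMING = {_OP_M, _OP_D, _OP_N, _OP_EQ, _OP_X}
_CLIP_OPS = {_OP_S, _OP_H}


def observation_from_record(rec: pysam.AlignedSegment) -> AlignmentObservation:
    """Reduce one SAM record to an :class:`AlignmentObservation`.

    Edit counts: insertions/deletions are the summed lengths of CIGAR I/D
    runs; substitutions come from the MD tag when present, else from =/X
    CIGAR operations, else NM − (inserted + deleted bases).  Hard and soft
    clips both count toward clip lengths — the bases are absent from the
    alignment either way.
    """
    name = rec.query_name or ""
    if rec.is_unmapped:
        return AlignmentObservation(read_id=name, mapped=False)
    cig = rec.cigartuples or []
    n_ins = sum(ln for op, ln in cig if op == _OP_I)
    n_del = sum(ln for op, ln in cig if op == _OP_D)
    ref_span = sum(ln for op, ln in cig if op in _REF_CONSUMING)
    clip_left = 0
    for op, ln in cig:
        if op in _CLIP_OPS:
            clip_left += ln
        else:
            break
    clip_right = 0
    for op, ln in reversed(cig):
        if op in _CLIP_OPS:
            clip_right += ln
        else:
            break
    if rec.has_tag("MD"):
        n_sub = _md_substitution_count(str(rec.get_tag("MD")))
    elif any(op == _OP_X for op, _ in cig):
        n_sub = sum(ln for op, ln in cig if op == _OP_X)
    elif rec.has_tag("NM"):
        n_sub = int(rec.get_tag("NM")) - n_ins - n_del
        if n_sub < 0:
            raise FormatError(
                f"record {name!r}: NM tag smaller than CIGAR indel bases"
            )
    else:
        raise MissingTagError(
            f"record {name!r} has neither MD nor NM tag; substitutions cannot "
            "be counted — regenerate the SAM with NM/MD (e.g. samtools calmd)"
        )
    start = rec.reference_start + 1
    return AlignmentObservation(
        read_id=name,
        mapped=True,
        contig=rec.reference_name or "",
        start=start,
        end=start + ref_span - 1,
        strand="-" if rec.is_reverse else "+",
        clip_left=clip_left,
        clip_right=clip_right,
        n_ins=n_ins,
        n_del=n_del,
        n_sub=n_sub,
    )


def canonical_read_id(name: str) -> str:
    """The bare read id used to join SAM hits with truth-table rows.

    Simulated reads carry the full truth codec in their name; the leading
    token is the read id the truth table indexes by.  Names that do not
    conform to the codec are used verbatim.
    """
    try:
        return decode_truth_name(name).read_id
    except CodecError:
        return name


def parse_sam(path: str | Path) -> dict[str, list[AlignmentObservation]]:
    """Parse a SAM file into observations grouped by read id.

    Primary, secondary and supplementary hits are all retained — correctness
    asks whether *any* reported hit satisfies the rule.  Codec-encoded read
    names are reduced to their bare read id so hits join against truth rows.
    """
    grouped: dict[str, list[AlignmentObservation]] = {}
    ids: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            obs = observation_from_record(rec)
            rid = ids.get(obs.read_id)
            if rid is None:
                rid = ids[obs.read_id] = canonical_read_id(obs.read_id)
            if rid != obs.read_id:
                obs = replace(obs, read_id=rid)
            grouped.setdefault(rid, []).append(obs)
    return grouped


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def load_and_filter_vcf(
    path: str | Path,
    min_depth: int = 10,
    min_fraction: float = 0.8,
) -> list[VariantCall]:
    """Load a VCF and keep alleles with depth ≥ ``min_depth`` and alternate
    fraction ≥ ``min_fraction`` (both bounds inclusive).

    Multi-allelic records are split into one :class:`VariantCall` per
    alternate allele.  Depth is taken from INFO/DP, then the first sample's
    FORMAT/DP, then the sum of FORMAT/AD.  Alternate counts come from INFO/AO
    (FreeBayes) or FORMAT/AD; records where neither is recoverable are
    excluded with a logged warning.
    """
    calls: list[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            depth = rec.info.get("DP")
            sample = rec.samples[0] if rec.samples else None
            ad = None
            if sample is not None:
                ad = sample.get("AD")
                if depth is None:
                    depth = sample.get("DP")
                if depth is None and ad is not None:
                    depth = sum(a for a in ad if a is not None)
            ao = rec.info.get("AO")
            if ao is not None and not isinstance(ao, tuple):
                ao = (ao,)
            for i, alt in enumerate(alts):
                if alt is None:
                    continue
                alt_count = None
                if ao is not None and i < len(ao):
                    alt_count = ao[i]
                elif ad is not None and i + 1 < len(ad):
                    alt_count = ad[i + 1]
                if depth is None or alt_count is None:
                    n_skipped += 1
                    logger.warning(
                        "VCF %s:%d alt %s: depth/alt-count fields missing; excluded",
                        rec.chrom, rec.pos, alt,
                    )
                    continue
                depth_i = int(depth)
                fraction = (alt_count / depth_i) if depth_i > 0 else 0.0
                if depth_i >= min_depth and fraction >= min_fraction:
                    calls.append(
                        VariantCall(
                            contig=rec.chrom,
                            position=int(rec.pos),
                            ref_allele=str(rec.ref),
                            alt_allele=str(alt),
                            depth=depth_i,
                            alt_fraction=min(fraction, 1.0),
                        )
                    )
    if n_skipped:
        logger.warning("%d VCF allele(s) excluded for missing fields", n_skipped)
    return calls
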