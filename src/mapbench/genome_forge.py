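"""Benchmark reference construction: mutated genomes and repeat genomes.

Two generators feed the evaluation side of the toolkit:

* :func:`mutate_genome` introduces an exact number of point mutations
  (substitutions and 1 bp indels by default) into a genome and emits a truth
  table, so that variant calls made against the mutated genome can be scored.
* :func:`build_repeat_genome` embeds near-identical copies of a master
  repeat in random background sequence, so that multi-mapping recovery can
  be measured with exact knowledge of every copy's interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import encode_bases
from .exceptions import ConfigurationError, FormatError
from .io_formats import Contig

_BASES = "ACGT"

MUTATION_KINDS = ("substitution", "insertion", "deletion")


@dataclass(frozen=True)
class MutationRecord:
    """One introduced mutation, anchored, in ORIGINAL-genome coordinates.

    Substitution: |ref| = |alt| = 1, ref != alt.  Insertion: alt = ref +
    inserted bases (the insertion sits immediately after ``position``).
    Deletion: ref = anchor + deleted bases, alt = anchor.
    """

    contig: str
    position: int
    kind: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in MUTATION_KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution must change the base")
        elif self.kind == "insertion":
            if len(self.alt_allele) <= len(self.ref_allele):
                raise ValueError("insertion must lengthen the allele")
        elif len(self.ref_allele) <= len(self.alt_allele):
            raise ValueError("deletion must shorten the allele")

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class RepeatMap:
    """Intervals (1-based inclusive) of all repeat copies in a genome."""

    intervals: tuple[tuple[int, int], ...]
    master_length: int
    divergence: float

    def __post_init__(self) -> None:
        spans = [e - s + 1 for s, e in self.intervals]
        if any(sp != self.master_length for sp in spans):
            raise ValueError("repeat intervals must all equal master_length")
        ordered = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError("repeat intervals must not overlap")

    @property
    def n_copies(self) -> int:
        return len(self.intervals)

    def containing(self, position: int) -> int | None:
        """Index of the copy whose interval contains ``position``, else None."""
        for i, (s, e) in enumerate(self.intervals):
            if s <= position <= e:
                return i
        return None


def random_sequence(length: int, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=length)
    return "".join(_BASES[c] for c in codes) if length < 1024 else \
        np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")


def random_contig(name: str, length: int, rng: np.random.Generator) -> Contig:
    """A contig of i.i.d. uniform bases — the synthetic stand-in for the
    bacterial genomes real benchmarks are built on."""
    return Contig(name, random_sequence(length, rng))


def _spaced_positions(
    n: int, low: int, high: int, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n sorted positions in [low, high] with pairwise gaps >= min_gap."""
    span = high - low + 1
    shrink = (n - 1) * (min_gap - 1)
    if span - shrink < n:
        raise ConfigurationError(
            f"cannot place {n} positions with gap >= {min_gap} in [{low}, {high}]"
        )
    base = np.sort(rng.choice(span - shrink, size=n, replace=False))
    return base + np.arange(n) * (min_gap - 1) + low


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = _BASES.replace(base, "") if base in _BASES else _BASES
    return choices[int(rng.integers(0, len(choices)))]


def mutate_genome(
    reference: Sequence[Contig],
    rate: float,
    rng: np.random.Generator,
    sub_fraction: float = 0.9,
    indel_length: int = 1,
) -> tuple[list[Contig], list[MutationRecord]]:
    """Introduce ``round(rate * length)`` mutations per contig.

    Positions are sampled without replacement, pairwise >= 2 bases apart so
    anchored edits never overlap.  Each mutation is a substitution with
    probability ``sub_fraction``, else an insertion or deletion
    (equiprobable) of ``indel_length`` bases.  Applying the returned records
    to the original genome reproduces the mutated genome exactly.
    """
    if not 0.0 <= rate < 0.5:
        raise ConfigurationError("mutation rate must lie in [0, 0.5)")
    if not 0.0 <= sub_fraction <= 1.0:
        raise ConfigurationError("sub_fraction must lie in [0, 1]")
    records: list[MutationRecord] = []
    for contig in reference:
        n_mut = int(round(rate * contig.length))
        if n_mut == 0:
            continue
        # positions in [1, L - indel_length] so deletion anchors stay in range
        positions = _spaced_positions(
            n_mut, 1, contig.length - indel_length, 1 + indel_length, rng
        )
        seq = contig.sequence
        for pos in positions:
            pos = int(pos)
            anchor = seq[pos - 1]
            if rng.random() < sub_fraction:
                records.append(
                    MutationRecord(
                        contig.name, pos, "substitution",
                        anchor, _other_base(anchor, rng),
                    )
                )
            elif rng.random() < 0.5:
                inserted = "".join(
                    _BASES[int(b)] for b in rng.integers(0, 4, size=indel_length)
                )
                records.append(
                    MutationRecord(
                        contig.name, pos, "insertion", anchor, anchor + inserted
                    )
                )
            else:
                records.append(
                    MutationRecord(
                        contig.name, pos, "deletion",
                        seq[pos - 1:pos + indel_length], anchor,
                    )
                )
    mutated = apply_mutations(reference, records)
    return mutated, records


def apply_mutations(
    reference: Sequence[Contig], records: Iterable[MutationRecord]
) -> list[Contig]:
    """Apply sorted, non-overlapping mutation records to a genome."""
    by_contig: dict[str, list[MutationRecord]] = {}
    for rec in records:
        by_contig.setdefault(rec.contig, []).append(rec)
    out: list[Contig] = []
    for contig in reference:
        muts = sorted(by_contig.get(contig.name, []), key=lambda r: r.position)
        pieces: list[str] = []
        cursor = 0  # 0-based position in the original sequence
        seq = contig.sequence
        for m in muts:
            i = m.position - 1
            if i < cursor:
                raise ValueError(
                    f"overlapping mutations near {contig.name}:{m.position}"
                )
            if seq[i:i + len(m.ref_allele)] != m.ref_allele:
                raise ValueError(
                    f"ref allele mismatch at {contig.name}:{m.position}: "
                    f"expected {m.ref_allele!r}, found "
                    f"{seq[i:i + len(m.ref_allele)]!r}"
                )
            pieces.append(seq[cursor:i])
            pieces.append(m.alt_allele)
            cursor = i + len(m.ref_allele)
        pieces.append(seq[cursor:])
        out.append(Contig(contig.name, "".join(pieces)))
    return out


def build_repeat_genome(
    total_length: int,
    n_copies: int,
    copy_length: int,
    divergence: float,
    rng: np.random.Generator,
    contig_name: str = "repeat_genome",
) -> tuple[Contig, RepeatMap]:
    """An artificial genome: random background plus diverged repeat copies.

    A master repeat of ``copy_length`` is drawn once; each copy is the master
    independently substituted at per-base rate ``divergence`` (substitutions
    only, keeping copies colinear), placed at evenly spaced, non-adjacent
    positions.  Default study conditions: 250,000 bp, five copies of 500 bp,
    3% divergence.
    """
    if n_copies * copy_length >= total_length:
        raise ConfigurationError("copies do not fit in total_length")
    segment = total_length // n_copies
    pad = (segment - copy_length) // 2
    if pad < 1:
        raise ConfigurationError(
            "copies would be adjacent; increase total_length or reduce copies"
        )
    background = np.array(list(random_sequence(total_length, rng)))
    master = random_sequence(copy_length, rng)
    intervals: list[tuple[int, int]] = []
    for k in range(n_copies):
        copy = list(master)
        hit = np.flatnonzero(rng.random(copy_length) < divergence)
        for i in hit:
            copy[i] = _other_base(copy[i], rng)
        start0 = k * segment + pad
        background[start0:start0 + copy_length] = copy
        intervals.append((start0 + 1, start0 + copy_length))
    contig = Contig(contig_name, "".join(background))
    return contig, RepeatMap(tuple(intervals), copy_length, divergence)


# ---------------------------------------------------------------------------
# TSV round trips
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ["contig", "position", "kind", "ref", "alt"]


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        (r.contig, r.position, r.kind, r.ref_allele, r.alt_allele) for r in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: mutation table lacks columns {sorted(missing)}")
    return [
        MutationRecord(r.contig, int(r.position), r.kind, r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]


def write_repeat_map(
    repeat_map: RepeatMap, path: str | Path, manifest_path: str | Path | None = None
) -> None:
    pd.DataFrame(repeat_map.intervals, columns=["start", "end"]).to_csv(
        path, sep="\t", index=False
    )
    if manifest_path is not None:
        Path(manifest_path).write_text(
            json.dumps(
                {
                    "master_length": repeat_map.master_length,
                    "divergence": repeat_map.divergence,
                },
                indent=2,
            )
            + "\n"
        )


def read_repeat_map(path: str | Path, divergence: float = 0.0) -> RepeatMap:
    df = pd.read_csv(path, sep="\t")
    if not {"start", "end"} <= set(df.columns):
        raise FormatError(f"{path}: repeat map lacks start/end columns")
    intervals = tuple(
        (int(r.start), int(r.end)) for r in df.itertuples(index=False)
    )
    master_length = intervals[0][1] - intervals[0][0] + 1
    return RepeatMap(intervals, master_length, divergence)
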