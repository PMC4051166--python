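"""Read simulation with controlled error rates, placement and exact truth.

The simulator emulates single-end reads from ion-semiconductor-style
platforms, whose error profile is dominated by short indels in homopolymer
runs: per-base insertion/deletion/substitution rates are independent dials,
read length is normally distributed, and a configurable fraction of reads is
pure random sequence (unmappable by construction, probing false-positive
mapping).  Every read carries exact ground truth — origin window, strand and
*canonical* edit counts after compensation — both in its name and in a truth
table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import canonical_alignment, encode_bases
from .exceptions import ConfigurationError
from .io_formats import (
    Contig,
    ReadTruth,
    encode_truth_name,
    write_fastq,
    write_truth_table,
)

logger = logging.getLogger(__name__)

MIN_READ_LENGTH = 20
PLACEMENT_MODES = ("uniform", "ramp3prime", "homopolymer")

#: The simulated-dataset grid: (ins, del, sub) per-base rates giving total
#: error rates 0..4% in 0.5% steps, indel-dominant as on the Ion Torrent
#: platform the design targets.
DATASET_GRID: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0),
    (0.0, 0.0, 0.005),
    (0.0, 0.0, 0.01),
    (0.005, 0.01, 0.0),
    (0.005, 0.01, 0.005),
    (0.005, 0.01, 0.01),
    (0.01, 0.02, 0.0),
    (0.01, 0.02, 0.005),
    (0.01, 0.02, 0.01),
)

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return _decode(_COMP[encode_bases(seq)][::-1])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults are the toolkit's reference conditions: 50,000 reads of mean
    length 200 with 10% length SD, 0.5% insertions / 1% deletions / 0.5%
    substitutions, and 5% random reads.
    """

    n_reads: int = 50_000
    mean_length: float = 200.0
    sd_fraction: float = 0.10
    ins_rate: float = 0.005
    del_rate: float = 0.01
    sub_rate: float = 0.005
    random_fraction: float = 0.05
    placement_mode: str = "uniform"
    seed: int = 1
    both_strands: bool = True
    quality_char: str = "I"

    def __post_init__(self) -> None:
        for name in ("ins_rate", "del_rate", "sub_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.ins_rate + self.del_rate + self.sub_rate > 1.0:
            raise ConfigurationError("ins_rate + del_rate + sub_rate must be <= 1")
        if not 0.0 <= self.random_fraction < 1.0:
            raise ConfigurationError("random_fraction must lie in [0, 1)")
        if self.mean_length < 1:
            raise ConfigurationError("mean_length must be >= 1")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        if self.placement_mode not in PLACEMENT_MODES:
            raise ConfigurationError(
                f"placement_mode must be one of {PLACEMENT_MODES}"
            )


@dataclass(frozen=True)
class RawEdit:
    """One injected edit, before canonicalization.

    ``read_offset`` is the 0-based offset in the emitted read for insertions
    and substitutions; for deletions it is the 0-based offset of the deleted
    base in the source window (``src_offset`` mirrors it for ins/sub).
    """

    kind: str  # "ins" | "del" | "sub"
    read_offset: int
    src_offset: int
    base: str


def sample_read_length(mean: float, sd_fraction: float, rng: np.random.Generator) -> int:
    """Draw a read length from Normal(mean, sd_fraction*mean), clamped >= 20."""
    if mean < 1:
        raise ConfigurationError("mean length must be >= 1")
    draw = rng.normal(mean, sd_fraction * mean)
    return max(MIN_READ_LENGTH, int(round(draw)))


def draw_origin(
    contigs: Sequence[Contig],
    read_ref_span: int,
    rng: np.random.Generator,
    max_n_fraction: float = 0.10,
    max_tries: int = 50,
) -> tuple[Contig, int, str]:
    """Sample a uniform origin window and strand.

    Start positions are uniform over all valid 1-based starts, contigs
    weighted by their number of valid starts; strand is uniform over {+,-}.
    Windows with more than ``max_n_fraction`` N bases are rejected and
    redrawn (bounded retries).
    """
    valid = np.array([c.length - read_ref_span + 1 for c in contigs], dtype=np.int64)
    usable = valid > 0
    if not usable.any():
        raise ConfigurationError(
            f"no contig is long enough for a {read_ref_span} bp window"
        )
    weights = np.where(usable, valid, 0).astype(float)
    weights /= weights.sum()
    worst_n = 0.0
    for _ in range(max_tries):
        ci = int(rng.choice(len(contigs), p=weights))
        contig = contigs[ci]
        start = int(rng.integers(1, valid[ci] + 1))
        window = contig.sequence[start - 1:start - 1 + read_ref_span]
        n_frac = window.count("N") / read_ref_span
        worst_n = max(worst_n, n_frac)
        if n_frac <= max_n_fraction:
            strand = "+" if rng.random() < 0.5 else "-"
            return contig, start, strand
    raise ConfigurationError(
        f"could not draw a window with <= {max_n_fraction:.0%} N in {max_tries} "
        f"tries (worst N-density seen: {worst_n:.0%})"
    )


def _placement_weights(codes: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position multipliers (indel_weights, sub_weights), each mean 1.

    uniform: constant.  ramp3prime: all rates ramp linearly from 0.5x at the
    read start to 1.5x at the end (3' degradation).  homopolymer: indel mass
    doubled inside runs of length >= 3, then renormalized so the expected
    genome-wide rate matches the configured one; substitutions untouched.
    """
    L = codes.shape[0]
    ones = np.ones(L)
    if mode == "uniform":
        return ones, ones
    if mode == "ramp3prime":
        ramp = np.linspace(0.5, 1.5, L) if L > 1 else ones.copy()
        ramp *= 1.0 / ramp.mean()
        return ramp, ramp
    # homopolymer
    w = np.ones(L)
    if L >= 3:
        boundaries = np.flatnonzero(np.diff(codes) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [L]))
        for s, e in zip(starts, ends):
            if e - s >= 3:
                w[s:e] = 2.0
    w /= w.mean()
    return w, ones


def inject_errors(
    source: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, list[RawEdit]]:
    """Inject per-base errors into ``source`` and return (read, edits).

    Each position independently receives a deletion w.p. ``del_rate`` or a
    substitution w.p. ``sub_rate`` (the substituted base is never the
    original); an insertion of a uniform base occurs before each position
    w.p. ``ins_rate``.  ``placement_mode`` reweights the per-position rates.
    """
    if not source:
        raise ValueError("source window is empty")
    codes = encode_bases(source)
    L = codes.shape[0]
    w_indel, w_sub = _placement_weights(codes, config.placement_mode)
    del_p = config.del_rate * w_indel
    sub_p = config.sub_rate * w_sub
    ins_p = config.ins_rate * w_indel
    if (del_p + sub_p).max() > 1.0 or ins_p.max() > 1.0:
        raise ConfigurationError(
            "per-position error probabilities exceed 1 after placement reweighting"
        )
    u = rng.random(L)
    del_mask = u < del_p
    sub_mask = (~del_mask) & (u < del_p + sub_p)
    ins_mask = rng.random(L) < ins_p

    out_codes = codes.copy()
    sub_idx = np.flatnonzero(sub_mask)
    if sub_idx.size:
        # uniform over the three non-original bases; N positions get any base
        shifts = rng.integers(1, 4, size=sub_idx.size)
        orig = out_codes[sub_idx]
        new = (orig + shifts) % 4
        n_pos = orig == 4
        if n_pos.any():
            new[n_pos] = rng.integers(0, 4, size=int(n_pos.sum()))
        out_codes[sub_idx] = new.astype(np.uint8)
    ins_codes = rng.integers(0, 4, size=int(ins_mask.sum())).astype(np.uint8)

    keep = ~del_mask
    counts = ins_mask.astype(np.int64) + keep.astype(np.int64)
    offsets = np.cumsum(counts) - counts  # emitted offset of each source slot
    read_codes = np.empty(int(counts.sum()), dtype=np.uint8)
    read_codes[offsets[ins_mask]] = ins_codes
    read_codes[(offsets + ins_mask)[keep]] = out_codes[keep]

    edits: list[RawEdit] = []
    ins_positions = np.flatnonzero(ins_mask)
    for k, i in enumerate(ins_positions):
        edits.append(RawEdit("ins", int(offsets[i]), int(i), _decode(ins_codes[k:k + 1])))
    for i in np.flatnonzero(del_mask):
        edits.append(RawEdit("del", int(offsets[i] + ins_mask[i]), int(i), source[i]))
    for i in sub_idx:
        edits.append(
            RawEdit("sub", int(offsets[i] + ins_mask[i]), int(i), _decode(out_codes[i:i + 1]))
        )
    edits.sort(key=lambda e: (e.src_offset, e.read_offset))
    return _decode(read_codes), edits


def canonicalize_truth(
    read: str, source_window: str, window_start: int
) -> tuple[int, int, int, int, int]:
    """Canonical (start, end, n_ins, n_del, n_sub) of ``read`` vs its window.

    Minimal-cost alignment under unit costs with free end gaps on the
    reference side; compensation can only reduce counts relative to the
    injected edits.  ``window_start`` is the 1-based reference coordinate of
    the window's first base.
    """
    j_start, j_end, n_ins, n_del, n_sub = canonical_alignment(read, source_window)
    if j_end <= j_start:
        raise ValueError("read does not align to any window base")
    return window_start + j_start, window_start + j_end - 1, n_ins, n_del, n_sub


def make_random_read(length: int, rng: np.random.Generator) -> str:
    """A read of i.i.d. uniform bases over {A,C,G,T}."""
    if length < 1:
        raise ValueError("random read length must be >= 1")
    return _decode(rng.integers(0, 4, size=length).astype(np.uint8))


def simulate_dataset(
    config: SimulationConfig,
    reference: Sequence[Contig],
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
    stats: dict | None = None,
) -> tuple[list[ReadTruth], list[str]]:
    """Simulate a full dataset; optionally write FASTQ / truth TSV / manifest.

    Returns ``(truths, sequences)`` in emission order.  Exactly
    ``round(random_fraction * n_reads)`` random reads are interleaved at
    seeded-random positions.  Reverse-strand reads are emitted as sequenced
    (reverse complement of the mutated window) with truth coordinates on the
    forward strand.  A fixed seed makes the run byte-reproducible.

    If a ``stats`` dict is passed it is filled with raw injected versus
    canonical edit counts, base totals and the compensation deficit, which
    is also logged.
    """
    rng = np.random.default_rng(config.seed)
    n_random = int(round(config.random_fraction * config.n_reads))
    random_idx = set(
        int(i) for i in rng.choice(config.n_reads, size=n_random, replace=False)
    )
    truths: list[ReadTruth] = []
    seqs: list[str] = []
    tally = {
        "raw_ins": 0, "raw_del": 0, "raw_sub": 0,
        "canonical_ins": 0, "canonical_del": 0, "canonical_sub": 0,
        "source_bases": 0, "emitted_bases": 0, "random_bases": 0,
    }
    for i in range(config.n_reads):
        read_id = f"r{i + 1}"
        length = sample_read_length(config.mean_length, config.sd_fraction, rng)
        if i in random_idx:
            seq = make_random_read(length, rng)
            seqs.append(seq)
            truths.append(ReadTruth.random(read_id))
            tally["random_bases"] += len(seq)
            continue
        contig, win_start, strand = draw_origin(reference, length, rng)
        if not config.both_strands:
            strand = "+"
        window = contig.sequence[win_start - 1:win_start - 1 + length]
        template = window if strand == "+" else reverse_complement(window)
        read, edits = inject_errors(template, config, rng)
        start, end, n_ins, n_del, n_sub = canonicalize_truth(read, template, 1)
        for e in edits:
            tally["raw_" + e.kind] += 1
        tally["canonical_ins"] += n_ins
        tally["canonical_del"] += n_del
        tally["canonical_sub"] += n_sub
        tally["source_bases"] += length
        tally["emitted_bases"] += len(read)
        if strand == "+":
            ref_start = win_start + (start - 1)
            ref_end = win_start + (end - 1)
        else:
            win_end = win_start + length - 1
            ref_start = win_end - (end - 1)
            ref_end = win_end - (start - 1)
        truths.append(
            ReadTruth(
                read_id=read_id, contig=contig.name,
                start=ref_start, end=ref_end, strand=strand,
                n_ins=n_ins, n_del=n_del, n_sub=n_sub, is_random=False,
            )
        )
        seqs.append(read)
    deficit = (
        tally["raw_ins"] + tally["raw_del"]
        - tally["canonical_ins"] - tally["canonical_del"]
    )
    tally["indel_compensation_deficit"] = deficit
    if tally["emitted_bases"] and deficit:
        logger.info(
            "compensation: canonical indel count is %d below the %d raw "
            "injected indels (%.4f%% of emitted bases)",
            deficit, tally["raw_ins"] + tally["raw_del"],
            100.0 * deficit / tally["emitted_bases"],
        )
    if stats is not None:
        stats.update(tally)
    if fastq_path is not None:
        write_fastq(
            ((encode_truth_name(t), s) for t, s in zip(truths, seqs)),
            fastq_path,
            quality_char=config.quality_char,
        )
    if truth_path is not None:
        write_truth_table(truths, truth_path)
    if manifest_path is not None:
        manifest = {
            "command": "simulate",
            "config": asdict(config),
            "outputs": {
                "fastq": str(fastq_path) if fastq_path else None,
                "truth": str(truth_path) if truth_path else None,
            },
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")
    return truths, seqs
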