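"""Small-RNA read quantification and isomiR classification.

Mature miRNAs appear in sequencing data as families of length and
sequence variants (isomiRs) produced during biogenesis: 3'-end trimming
or non-templated extension, 5'-end shifts, and internal substitutions
relative to the canonical mature sequence.  This module assigns each
read to its best mature reference by exhaustive ungapped alignment over
a bounded window of 5'/3' offsets, flags the read's isomiR classes, and
aggregates per-sample miRNA and isomiR count tables.

Alignment model: placing the read at 5' offset ``o5`` against a
reference fixes the 3' offset ``o3 = o5 + len(read) - len(ref)``.
Read bases overhanging the reference (extensions) are untemplated and
not scored; within the overlap, mismatches at the two terminal overlap
positions are treated as end-variation rather than internal
substitutions, so only internal mismatches count against
``max_mismatch`` and toward the polymorphic flag.  Candidates are ranked
by (internal mismatches, |o5| + |o3|, reference name); a tie between two
references on the first two keys marks the read ambiguous, and the read
is counted once under the lexicographic winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .expression_matrix import CountMatrix, InputError
from .synthetic_data import ALPHABET, MirnaReference

UNASSIGNED = "UNASSIGNED"

FLAG_ORDER = ("canonical", "trim3", "ext3", "shift5", "polymorphic")


@dataclass
class ReadAssignment:
    """Assignment of one read to a mature miRNA reference.

    offset5: read 5' start minus canonical start (positive = 5' trimming,
    negative = 5' extension).  offset3: read 3' end minus canonical end
    (positive = 3' extension, negative = 3' trimming).
    mismatch_positions are internal overlap positions (0-based on the
    overlap; termini excluded).
    """

    read_id: str
    mirna: str
    offset5: int = 0
    offset3: int = 0
    mismatch_positions: tuple[int, ...] = ()
    class_flags: frozenset[str] = frozenset()
    ambiguous: bool = False
    read_seq: str = ""
    sample: str | None = None

    @property
    def assigned(self) -> bool:
        return self.mirna != UNASSIGNED


# ---------------------------------------------------------------------------
# FASTQ input and pre-filters
# ---------------------------------------------------------------------------


def read_fastq(path_or_handle) -> list[tuple[str, str]]:
    """Parse a FASTQ file into (read_id, sequence) pairs."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path_or_handle, "fastq")
    ]


def trim_adapter(reads, adapter: str, k: int = 8):
    """Trim a known 3' adapter by exact leading-k-mer search.

    The adapter's first ``k`` bases are searched in the 3' half of each
    read; on a hit the read is truncated at the match start.  Reads
    without a hit pass through unchanged.
    """
    if len(adapter) < k:
        k = len(adapter)
    kmer = adapter[:k]
    out = []
    for rid, seq in reads:
        half = len(seq) // 2
        pos = seq.find(kmer, half)
        out.append((rid, seq[:pos] if pos != -1 else seq))
    return out


def filter_by_length(reads, min_len: int = 16, max_len: int = 28):
    """Keep reads with ``min_len <= length <= max_len``, order preserved."""
    if min_len > max_len:
        raise InputError("min_len must be <= max_len")
    return [(rid, seq) for rid, seq in reads if min_len <= len(seq) <= max_len]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _score_candidate(read: str, ref: str, o5: int):
    """Internal-mismatch count and positions for one (ref, o5) placement.

    Returns (internal_mismatches, o3, positions) or None when the
    placement has no overlap.
    """
    lq, lr = len(read), len(ref)
    o3 = o5 + lq - lr
    start = max(0, o5)  # overlap in reference coordinates
    end = min(lr - 1, o5 + lq - 1)
    if end < start:
        return None
    positions = []
    for p in range(start + 1, end):  # termini excluded
        if read[p - o5] != ref[p]:
            positions.append(p - start)
    return len(positions), o3, tuple(positions)


def classify_read(
    read: tuple[str, str] | str,
    refs: list[MirnaReference],
    max_mismatch: int = 2,
    max_offset: int = 3,
) -> ReadAssignment:
    """Assign one read to its best reference and set isomiR class flags.

    Flags: shift5 iff offset5 != 0; trim3 iff offset3 < 0; ext3 iff
    offset3 > 0; polymorphic iff >= 1 internal mismatch; canonical iff no
    other flag is set.  UNASSIGNED when no reference admits a placement
    with internal mismatches <= ``max_mismatch`` and both offsets within
    +/-``max_offset``.
    """
    if isinstance(read, str):
        rid, seq = "read", read
    else:
        rid, seq = read
    if not refs:
        raise InputError("reference set is empty")
    if not seq or any(b not in ALPHABET for b in seq):
        raise InputError(f"{rid}: read sequence must be nonempty over ACGT")

    # best candidate per reference, then a global rank over references
    per_ref = []  # (internal_mm, offset_sum, name, o5, o3, positions)
    for ref in refs:
        lq, lr = len(seq), len(ref.mature_seq)
        ref_best = None
        for o5 in range(-max_offset, max_offset + 1):
            o3 = o5 + lq - lr
            if abs(o3) > max_offset:
                continue
            scored = _score_candidate(seq, ref.mature_seq, o5)
            if scored is None:
                continue
            mm, o3, positions = scored
            if mm > max_mismatch:
                continue
            cand = (mm, abs(o5) + abs(o3), ref.name, o5, o3, positions)
            if ref_best is None or cand[:2] < ref_best[:2]:
                ref_best = cand
        if ref_best is not None:
            per_ref.append(ref_best)

    if not per_ref:
        return ReadAssignment(read_id=rid, mirna=UNASSIGNED, read_seq=seq)

    per_ref.sort(key=lambda c: c[:3])
    best = per_ref[0]
    tie = len(per_ref) > 1 and per_ref[1][:2] == best[:2]
    _, _, name, o5, o3, positions = best
    flags = set()
    if o5 != 0:
        flags.add("shift5")
    if o3 < 0:
        flags.add("trim3")
    if o3 > 0:
        flags.add("ext3")
    if positions:
        flags.add("polymorphic")
    if not flags:
        flags.add("canonical")
    return ReadAssignment(
        read_id=rid,
        mirna=name,
        offset5=o5,
        offset3=o3,
        mismatch_positions=positions,
        class_flags=frozenset(flags),
        ambiguous=tie,
        read_seq=seq,
    )


def classify_batch(
    reads, refs, max_mismatch: int = 2, max_offset: int = 3, sample: str | None = None
) -> list[ReadAssignment]:
    out = []
    for read in reads:
        a = classify_read(read, refs, max_mismatch=max_mismatch, max_offset=max_offset)
        a.sample = sample
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def quantify(assignments: list[ReadAssignment], sample_ids: list[str]):
    """Aggregate read assignments into count tables.

    Returns ``(mirna_counts, isomir_table)``: a :class:`CountMatrix` of
    assigned-read counts per miRNA per sample, and an isomiR table keyed
    by (mirna, variant sequence) with class flags, per-sample counts and
    each variant's fraction of its miRNA's total.  Ambiguous reads are
    counted once under their deterministic winner; unassigned reads are
    dropped.  isomiR counts sum to the miRNA counts per sample.
    """
    known = set(sample_ids)
    counts: dict[tuple[str, str], dict[str, int]] = {}
    flags: dict[tuple[str, str], frozenset] = {}
    for a in assignments:
        if a.sample not in known:
            raise InputError(f"unknown sample id: {a.sample!r}")
        if not a.assigned:
            continue
        key = (a.mirna, a.read_seq)
        counts.setdefault(key, {})[a.sample] = counts.get(key, {}).get(a.sample, 0) + 1
        flags.setdefault(key, a.class_flags)

    rows = []
    for (mirna, seq), per_sample in sorted(counts.items()):
        row = {
            "mirna": mirna,
            "variant_seq": seq,
            "class_flags": ",".join(f for f in FLAG_ORDER if f in flags[(mirna, seq)]),
        }
        for s in sample_ids:
            row[s] = per_sample.get(s, 0)
        rows.append(row)
    isomir = pd.DataFrame(
        rows, columns=["mirna", "variant_seq", "class_flags", *sample_ids]
    )

    if len(isomir):
        mirna_counts = isomir.groupby("mirna")[list(sample_ids)].sum()
        totals = isomir.groupby("mirna")[list(sample_ids)].transform("sum").sum(axis=1)
        isomir["fraction_of_mirna"] = isomir[list(sample_ids)].sum(axis=1) / totals
    else:
        mirna_counts = pd.DataFrame(
            np.empty((0, len(sample_ids)), dtype=np.int64), columns=sample_ids
        )
        isomir["fraction_of_mirna"] = pd.Series(dtype=float)
    return CountMatrix(mirna_counts.astype(np.int64)), isomir


def summarize_isomirs(
    isomir_table: pd.DataFrame,
    min_mean_count: float = 10.0,
    major_fraction: float = 0.10,
):
    """Prevalence-filter isomiRs and summarize class composition.

    Isoforms whose mean count across samples is below ``min_mean_count``
    are removed first.  Class fractions per sample are computed per flag
    independently on read counts — a read can carry several flags (for
    example trim3 + polymorphic), so fractions may sum above one.  The
    major-isoform list holds isoforms carrying more than
    ``major_fraction`` of their miRNA's filtered expression, canonical
    sequences included.
    """
    sample_cols = [
        c
        for c in isomir_table.columns
        if c not in ("mirna", "variant_seq", "class_flags", "fraction_of_mirna")
    ]
    if not len(isomir_table):
        empty = pd.DataFrame(0.0, index=sample_cols, columns=list(FLAG_ORDER))
        return empty, isomir_table.copy()
    kept = isomir_table[
        isomir_table[sample_cols].mean(axis=1) >= min_mean_count
    ].copy()

    class_fracs = pd.DataFrame(0.0, index=sample_cols, columns=list(FLAG_ORDER))
    if len(kept):
        totals = kept[sample_cols].sum(axis=0).astype(float)
        for flag in FLAG_ORDER:
            has = kept["class_flags"].str.split(",").apply(lambda fl: flag in fl)
            with np.errstate(invalid="ignore", divide="ignore"):
                class_fracs[flag] = (
                    kept.loc[has, sample_cols].sum(axis=0) / totals
                ).fillna(0.0)

        mirna_totals = kept.groupby("mirna")[sample_cols].transform("sum").sum(axis=1)
        kept["fraction_of_mirna"] = kept[sample_cols].sum(axis=1) / mirna_totals
        major = kept[kept["fraction_of_mirna"] > major_fraction].copy()
    else:
        major = kept
    return class_fracs, major


# ---------------------------------------------------------------------------
# Manifest-driven pipeline entry
# ---------------------------------------------------------------------------


def quantify_samples(
    fastq_by_sample: dict[str, object],
    refs: list[MirnaReference],
    max_mismatch: int = 2,
    max_offset: int = 3,
    min_len: int = 16,
    max_len: int = 28,
    adapter: str | None = None,
):
    """Full per-sample small-RNA quantification.

    ``fastq_by_sample`` maps sample id to a FASTQ path or handle.
    Applies adapter trimming (optional), the length filter, per-read
    classification and aggregation.  Returns the same pair as
    :func:`quantify`.
    """
    assignments: list[ReadAssignment] = []
    sample_ids = list(fastq_by_sample)
    for sample, src in fastq_by_sample.items():
        reads = read_fastq(src)
        if adapter:
            reads = trim_adapter(reads, adapter)
        reads = filter_by_length(reads, min_len, max_len)
        assignments.extend(
            classify_batch(
                reads, refs, max_mismatch=max_mismatch, max_offset=max_offset,
                sample=sample,
            )
        )
    return quantify(assignments, sample_ids)


def read_reference_fasta(path) -> list[MirnaReference]:
    return [
        MirnaReference(name=rec.id, mature_seq=str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(path, "fasta")
    ]
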