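"""Paired-read preprocessing for ITS amplicon libraries.

Raw MiSeq-style paired reads are merged into single amplicon sequences,
short fragments are dropped, primer stretches are stripped (assigning each
read to the ITS1 or ITS2 pool), and reads whose summed per-base error
probability exceeds a maximum expected-error budget are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FastqRead",
    "MergedRead",
    "MergeRejection",
    "DEFAULT_PRIMERS",
    "reverse_complement",
    "expected_errors",
    "merge_pairs",
    "length_filter",
    "strip_primers",
    "maxee_filter",
    "preprocess",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Primer pairs used to amplify each spacer: (forward, reverse) in PCR
#: orientation.  ITS1 is amplified with ITS5 / ITS-2RK, ITS2 with ITS3 / ITS4.
DEFAULT_PRIMERS: Mapping[str, tuple[str, str]] = {
    "ITS1": ("GGAAGTAAAAGTCGTAACAAGG", "CGTTCAAAGATTCGATGATTCAC"),
    "ITS2": ("GCATCGATGAAGAACGCAGC", "TCCTCCGCTTATTGATATGC"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expected_errors(qualities: Sequence[int]) -> float:
    """Expected number of base-call errors: E = sum_i 10^(-Q_i/10)."""
    q = np.asarray(qualities, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


@dataclass
class FastqRead:
    id: str
    sequence: str
    qualities: list[int]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


@dataclass
class MergedRead:
    id: str
    sequence: str
    qualities: list[int]
    sample_id: str = ""
    region_tag: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    @property
    def expected_errors(self) -> float:
        return expected_errors(self.qualities)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MergeRejection:
    id: str
    reason: str
    sample_id: str = ""


def merge_pairs(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 16,
    max_mismatch_frac: float = 0.25,
) -> MergedRead | MergeRejection:
    """Merge a read pair into one amplicon sequence.

    Mate 2 is reverse-complemented and slid along mate 1; among overlap
    lengths >= ``min_overlap`` the one minimizing the mismatch fraction wins
    (ties broken toward the longest overlap).  In the overlapped stretch the
    higher-quality base is taken; on agreement the consensus quality is
    Q1+Q2 capped at 45, on disagreement |Q1-Q2|.
    """
    if not r1.sequence or not r2.sequence:
        return MergeRejection(r1.id, "empty_mate", r1.sample_id)
    if min(len(r1.sequence), len(r2.sequence)) < min_overlap:
        return MergeRejection(r1.id, "shorter_than_min_overlap", r1.sample_id)

    fwd = r1.sequence
    fq = np.asarray(r1.qualities, dtype=np.int64)
    rev = reverse_complement(r2.sequence)
    rq = np.asarray(r2.qualities[::-1], dtype=np.int64)

    fa = np.frombuffer(fwd.encode(), dtype="S1")
    ra = np.frombuffer(rev.encode(), dtype="S1")

    best: tuple[float, int] | None = None  # (mismatch_frac, L)
    max_l = min(len(fwd), len(rev))
    for L in range(min_overlap, max_l + 1):
        mism = int(np.sum(fa[len(fwd) - L :] != ra[:L]))
        frac = mism / L
        if frac <= max_mismatch_frac and (
            best is None or frac < best[0] - 1e-12 or (abs(frac - best[0]) <= 1e-12 and L > best[1])
        ):
            best = (frac, L)
    if best is None:
        return MergeRejection(r1.id, "no_overlap", r1.sample_id)

    L = best[1]
    off = len(fwd) - L
    seq = list(fwd[:off])
    qual = list(fq[:off])
    for i in range(L):
        b1, q1 = fwd[off + i], int(fq[off + i])
        b2, q2 = rev[i], int(rq[i])
        if b1 == b2:
            seq.append(b1)
            qual.append(min(q1 + q2, 45))
        elif q1 >= q2:
            seq.append(b1)
            qual.append(abs(q1 - q2))
        else:
            seq.append(b2)
            qual.append(abs(q1 - q2))
    seq += list(rev[L:])
    qual += [int(q) for q in rq[L:]]
    return MergedRead(r1.id, "".join(seq), qual, r1.sample_id)


def length_filter(reads: Iterable[MergedRead], min_len: int = 120) -> list[MergedRead]:
    """Drop merged reads shorter than ``min_len`` (the boundary is kept)."""
    return [r for r in reads if len(r.sequence) >= min_len]


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def strip_primers(
    read: MergedRead,
    primer_set: Mapping[str, tuple[str, str]] = DEFAULT_PRIMERS,
    max_mismatch: int = 1,
) -> MergedRead:
    """Remove primer stretches and tag the read with its spacer region.

    A region is assigned only when the read starts with that region's
    forward primer AND ends with the reverse primer's reverse complement
    (each with at most ``max_mismatch`` mismatches); both are stripped.
    Requiring both primers keeps partially-stripped artifacts out of the
    clustering pools; reads failing the rule keep region_tag 'unknown'.
    """
    for region, (fwd, rev) in primer_set.items():
        rc = reverse_complement(rev)
        if len(read.sequence) < len(fwd) + len(rc):
            continue
        if (
            _mismatches(read.sequence[: len(fwd)], fwd) <= max_mismatch
            and _mismatches(read.sequence[len(read.sequence) - len(rc) :], rc) <= max_mismatch
        ):
            start = len(fwd)
            end = len(read.sequence) - len(rc)
            return replace(
                read,
                sequence=read.sequence[start:end],
                qualities=read.qualities[start:end],
                region_tag=region,
            )
    return replace(read, region_tag="unknown")


def maxee_filter(reads: Iterable[MergedRead], max_ee: float = 1.0) -> list[MergedRead]:
    """Keep reads whose expected error count is <= ``max_ee`` (strict > discards)."""
    return [r for r in reads if r.expected_errors <= max_ee]


def preprocess(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    min_overlap: int = 16,
    max_mismatch_frac: float = 0.25,
    min_len: int = 120,
    max_ee: float = 1.0,
    primer_set: Mapping[str, tuple[str, str]] = DEFAULT_PRIMERS,
) -> tuple[list[MergedRead], list[MergeRejection]]:
    """Full preprocessing chain: merge -> length filter -> primer strip -> maxEE."""
    merged: list[MergedRead] = []
    rejected: list[MergeRejection] = []
    for r1, r2 in pairs:
        res = merge_pairs(r1, r2, min_overlap, max_mismatch_frac)
        if isinstance(res, MergeRejection):
            rejected.append(res)
        else:
            merged.append(res)
    kept = []
    for r in length_filter(merged, min_len):
        kept.append(strip_primers(r, primer_set))
    out = []
    for r in kept:
        if r.expected_errors <= max_ee:
            out.append(r)
        else:
            rejected.append(MergeRejection(r.id, "maxee", r.sample_id))
    short = {r.id for r in merged} - {r.id for r in kept}
    for rid in sorted(short):
        rejected.append(MergeRejection(rid, "too_short"))
    return out, rejected
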