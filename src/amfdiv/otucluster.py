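"""Two-step OTU construction at a 97% identity radius.

Dereplicated amplicons are first mapped onto reference centroids
(closed-reference step, the MaarjAM-style pass that rescues reliable
singletons), and the leftovers are clustered de novo by an abundance-greedy
centroid pass with chimera screening; de novo clusters whose final abundance
is a single read are discarded ("residual singletons").  The two centroid
sets together define the OTU table.

Identity convention: end-to-end global alignment (match +1, mismatch -1,
gap open -2, gap extend -1); identity = matching columns / alignment
columns, terminal gaps counted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "DereplicatedSeq",
    "OtuRecord",
    "OtuTable",
    "dereplicate",
    "global_identity",
    "align_pair",
    "closed_ref_map",
    "denovo_cluster",
    "chimera_check",
    "build_otu_table",
    "two_step_cluster",
]


@dataclass
class DereplicatedSeq:
    sequence: str
    total_abundance: int
    per_sample_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.total_abundance != sum(self.per_sample_counts.values()):
            raise ValueError("total_abundance inconsistent with per-sample counts")
        if self.total_abundance < 1:
            raise ValueError("dereplicated sequence must have abundance >= 1")


@dataclass
class OtuRecord:
    otu_id: str
    centroid_sequence: str
    origin: str  # "reference" | "denovo"
    centroid_accession: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("reference", "denovo"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "reference" and not self.centroid_accession:
            raise ValueError("reference OTUs require a centroid accession")


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with the marker it was built from."""

    counts: pd.DataFrame
    marker: str = "ITS1"

    def to_tsv(self, path) -> None:
        self.counts.T.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path, marker: str = "ITS1") -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.T.astype(int), marker)


def dereplicate(reads: Iterable[tuple[str, str]]) -> list[DereplicatedSeq]:
    """Group identical sequences, keeping per-sample counts.

    ``reads`` yields (sample_id, sequence).  Output is sorted by abundance
    descending, ties broken by lexicographically smaller sequence.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample_id, seq in reads:
        counts[seq][sample_id] += 1
    out = [
        DereplicatedSeq(seq, sum(per.values()), dict(per))
        for seq, per in counts.items()
    ]
    out.sort(key=lambda d: (-d.total_abundance, d.sequence))
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner

_ALIGNER = _make_aligner()


def align_pair(a: str, b: str):
    """Optimal global alignment of two sequences (first optimum)."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    return _ALIGNER.align(a, b)[0]


def global_identity(a: str, b: str) -> float:
    """End-to-end identity fraction between two sequences in [0, 1]."""
    aln = align_pair(a, b)
    c = aln.counts()
    ncols = c.gaps + c.identities + c.mismatches
    return c.identities / ncols


def _kmer_set(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


class _KmerPrefilter:
    """Cheap shared-k-mer screen to skip hopeless alignments.

    At >= 97% identity two ~200 bp sequences share most of their 8-mers; a
    candidate sharing less than ``min_frac`` of the query's k-mers cannot
    plausibly reach the radius and is not aligned.
    """

    def __init__(self, sequences: Sequence[str], k: int = 8, min_frac: float = 0.3):
        self.k = k
        self.min_frac = min_frac
        self.sets = [_kmer_set(s, k) for s in sequences]

    def candidates(self, query: str) -> list[int]:
        qs = _kmer_set(query, self.k)
        if not qs:
            return list(range(len(self.sets)))
        need = self.min_frac * len(qs)
        return [i for i, s in enumerate(self.sets) if len(qs & s) >= need]


def closed_ref_map(
    dereps: Sequence[DereplicatedSeq],
    references: Sequence[tuple[str, str]],
    threshold: float = 0.97,
    prefilter: bool = True,
) -> tuple[list[tuple[int, str, float]], list[int]]:
    """Map dereplicated sequences onto reference centroids.

    ``references`` is a sequence of (accession, centroid_sequence).  Each
    derep is assigned to the highest-identity reference at >= ``threshold``;
    identity ties go to the centroid with the larger mapped abundance so far,
    then the lexicographically smallest accession.  Singletons are eligible.

    Returns (assignments, unmapped_indices) where assignments are
    (derep_index, accession, identity).
    """
    accs = [a for a, _ in references]
    seqs = [s for _, s in references]
    pf = _KmerPrefilter(seqs) if prefilter else None
    mapped_abundance: dict[str, int] = defaultdict(int)
    assignments: list[tuple[int, str, float]] = []
    unmapped: list[int] = []
    for i, d in enumerate(dereps):
        cand = pf.candidates(d.sequence) if pf is not None else range(len(seqs))
        hits: list[tuple[float, str]] = []
        for j in cand:
            ident = global_identity(d.sequence, seqs[j])
            if ident >= threshold:
                hits.append((ident, accs[j]))
        if not hits:
            unmapped.append(i)
            continue
        best_ident = max(h[0] for h in hits)
        tied = [a for idn, a in hits if abs(idn - best_ident) <= 1e-12]
        tied.sort(key=lambda a: (-mapped_abundance[a], a))
        acc = tied[0]
        mapped_abundance[acc] += d.total_abundance
        assignments.append((i, acc, best_ident))
    return assignments, unmapped


def _match_profile(query: str, parent: str) -> np.ndarray:
    """Per-query-position boolean: position aligned to an identical parent base."""
    aln = align_pair(query, parent)
    qg, pg = str(aln[0]), str(aln[1])
    prof = np.zeros(len(query), dtype=bool)
    qpos = 0
    for qc, pc in zip(qg, pg):
        if qc != "-":
            prof[qpos] = qc == pc
            qpos += 1
    return prof


def chimera_check(
    query: str,
    centroids: Sequence[str],
    radius: float = 0.97,
    model_identity: float = 0.99,
    max_parents: int = 8,
) -> bool:
    """Two-parent single-crossover chimera test against existing centroids.

    True iff some model taking a left prefix from one centroid and the right
    suffix from another (crossover scanned over every query position)
    explains >= ``model_identity`` of the query positions while the best
    single parent stays below ``radius``.  With fewer than two centroids the
    test is vacuously False.
    """
    if len(centroids) < 2 or not query:
        return False
    scored = []
    for c in centroids:
        prof = _match_profile(query, c)
        scored.append((prof.mean(), prof))
    scored.sort(key=lambda t: -t[0])
    if scored[0][0] >= radius:
        return False  # a single parent already explains the query
    top = scored[:max_parents]
    n = len(query)
    for _, p1 in top:
        cum1 = np.concatenate(([0], np.cumsum(p1)))
        for _, p2 in top:
            if p2 is p1:
                continue
            cum2 = np.concatenate(([0], np.cumsum(p2)))
            tot2 = cum2[-1]
            # matches(x) = prefix from parent1 up to x + suffix from parent2
            best = np.max(cum1 + (tot2 - cum2)) / n
            if best >= model_identity:
                return True
    return False


def denovo_cluster(
    dereps: Sequence[DereplicatedSeq],
    radius: float = 0.97,
    chimera_model_identity: float = 0.99,
) -> tuple[list[OtuRecord], list[tuple[int, str, float]], list[tuple[int, str]]]:
    """Abundance-greedy de novo centroid clustering (UPARSE-style).

    Dereps are visited in (abundance desc, sequence) order.  Each joins the
    highest-identity existing centroid at >= ``radius``; otherwise, if it
    looks like a two-parent chimera of existing centroids it is discarded;
    otherwise it founds a new centroid.  After the pass, centroids whose
    total abundance is 1 are dropped as residual singletons.

    Returns (otu_records, assignments (derep_index, otu_id, identity),
    discards (derep_index, reason)).
    """
    order = sorted(
        range(len(dereps)),
        key=lambda i: (-dereps[i].total_abundance, dereps[i].sequence),
    )
    centroid_seqs: list[str] = []
    centroid_ids: list[str] = []
    members: dict[str, list[tuple[int, float]]] = {}
    discards: list[tuple[int, str]] = []
    for i in order:
        seq = dereps[i].sequence
        best_j, best_ident = -1, -1.0
        for j, cseq in enumerate(centroid_seqs):
            ident = global_identity(seq, cseq)
            if ident > best_ident + 1e-12:
                best_j, best_ident = j, ident
        if best_j >= 0 and best_ident >= radius:
            members[centroid_ids[best_j]].append((i, best_ident))
        elif chimera_check(seq, centroid_seqs, radius, chimera_model_identity):
            discards.append((i, "chimera"))
        else:
            oid = f"DN{len(centroid_ids) + 1:04d}"
            centroid_seqs.append(seq)
            centroid_ids.append(oid)
            members[oid] = [(i, 1.0)]
    records: list[OtuRecord] = []
    assignments: list[tuple[int, str, float]] = []
    for oid, cseq in zip(centroid_ids, centroid_seqs):
        total = sum(dereps[i].total_abundance for i, _ in members[oid])
        if total <= 1:
            for i, _ in members[oid]:
                discards.append((i, "residual_singleton"))
            continue
        records.append(OtuRecord(oid, cseq, "denovo"))
        for i, ident in members[oid]:
            assignments.append((i, oid, ident))
    return records, assignments, discards


def build_otu_table(
    dereps: Sequence[DereplicatedSeq],
    assignments: Sequence[tuple[int, str]],
    samples: Sequence[str] | None = None,
    marker: str = "ITS1",
) -> OtuTable:
    """Sum read abundances per (sample, OTU); all-zero columns never appear."""
    tally: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    otu_order: list[str] = []
    for idx, otu_id, *_ in assignments:
        if otu_id not in tally:
            otu_order.append(otu_id)
        for sample, n in dereps[idx].per_sample_counts.items():
            tally[otu_id][sample] += n
    if samples is None:
        samples = sorted({s for per in tally.values() for s in per})
    df = pd.DataFrame(0, index=list(samples), columns=otu_order, dtype=int)
    for otu_id, per in tally.items():
        for sample, n in per.items():
            df.loc[sample, otu_id] = n
    df = df.loc[:, df.sum(axis=0) > 0]
    return OtuTable(df, marker)


def two_step_cluster(
    dereps: Sequence[DereplicatedSeq],
    references: Sequence[tuple[str, str]],
    threshold: float = 0.97,
    samples: Sequence[str] | None = None,
    marker: str = "ITS1",
):
    """Closed-reference mapping followed by de novo clustering of the rest.

    Returns (otu_records, otu_table, discards).  Reference OTUs are named
    ``REF_<accession>``; de novo OTUs get DNxxxx ids in founding order.
    """
    ref_assign, unmapped = closed_ref_map(dereps, references, threshold)
    ref_seq = dict(references)
    used = sorted({acc for _, acc, _ in ref_assign})
    records = [OtuRecord(f"REF_{acc}", ref_seq[acc], "reference", acc) for acc in used]
    assignments: list[tuple[int, str, float]] = [
        (i, f"REF_{acc}", ident) for i, acc, ident in ref_assign
    ]
    sub = [dereps[i] for i in unmapped]
    dn_records, dn_assign, dn_discards = denovo_cluster(sub, threshold)
    records.extend(dn_records)
    for local_i, oid, ident in dn_assign:
        assignments.append((unmapped[local_i], oid, ident))
    discards = [(unmapped[i], reason) for i, reason in dn_discards]
    table = build_otu_table(dereps, [(i, o) for i, o, _ in assignments], samples, marker)
    return records, table, discards
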