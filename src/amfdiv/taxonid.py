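"""Tree-based species and virtual-taxon assignment for OTU centroids.

OTUs are annotated against the reference database, binned by genus (inter-
genus ITS divergence is too high to align), rRNA coding flanks are trimmed
off, and each genus bin gets a neighbor-joining p-distance tree with
bootstrap supports over a center-star alignment.  Explicit clade rules then
formalize the identification workflow: an OTU in a supported clade with
references of a single species becomes a species call; supported reference-
free clades become species-level virtual taxa (VT); OTUs far from every
reference are excluded as higher-rank VTs.
"""

from __future__ import annotations

import hashlib
import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .otucluster import align_pair, global_identity
from .simcomm import SPACER_ANCHORS

__all__ = [
    "Annotation",
    "TaxonCall",
    "ClassifyThresholds",
    "annotate_best_hit",
    "trim_rrna",
    "p_distance",
    "p_distance_matrix",
    "precluster_alignment_free",
    "nj_tree",
    "bootstrap_support",
    "center_star_align",
    "diagnostic_sites",
    "classify_clades",
    "classify_genus_bin",
    "species_summary",
]


# ---------------------------------------------------------------------------
# annotation


@dataclass
class Annotation:
    otu_id: str
    accession: str | None
    lineage: tuple | None  # (phylum, class, order, family, genus, species)
    identity: float
    ambiguous: bool = False

    @property
    def genus(self) -> str | None:
        return self.lineage[4] if self.lineage else None


def annotate_best_hit(
    otu_id: str,
    centroid: str,
    references: Sequence[tuple[str, str]],
    taxonomy: Mapping[str, tuple],
    min_identity: float = 0.80,
) -> Annotation:
    """Best-global-identity lineage transfer down to genus.

    Below ``min_identity`` the OTU stays unclassified.  Equal-identity hits
    in different genera are flagged ambiguous and resolved toward the
    lexicographically smallest accession.
    """
    if not references:
        raise ValueError("empty reference database")
    best: list[tuple[float, str]] = []
    for acc, seq in references:
        ident = global_identity(centroid, seq)
        best.append((ident, acc))
    top = max(b[0] for b in best)
    if top < min_identity:
        return Annotation(otu_id, None, None, top)
    tied = sorted(acc for ident, acc in best if abs(ident - top) <= 1e-12)
    genera = {taxonomy[a][4] for a in tied}
    acc = tied[0]
    return Annotation(otu_id, acc, tuple(taxonomy[acc]), top, ambiguous=len(genera) > 1)


# ---------------------------------------------------------------------------
# rRNA trimming


def _find_anchor(seq: str, anchor: str, max_mismatch: int = 1) -> int:
    """Leftmost offset where ``anchor`` matches with <= max_mismatch, else -1."""
    la = len(anchor)
    for i in range(len(seq) - la + 1):
        mism = 0
        for a, b in zip(seq[i : i + la], anchor):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def trim_rrna(
    sequence: str,
    region: str | None = None,
    bounds: tuple[int, int] | None = None,
    anchors: Mapping[str, tuple[str, str]] = SPACER_ANCHORS,
    max_mismatch: int = 1,
) -> tuple[str, bool]:
    """Strip conserved rRNA flanks, returning (spacer, trimmed_flag).

    With explicit ``bounds`` the exact substring is returned.  Otherwise the
    conserved flank anchors for ``region`` are located (<= ``max_mismatch``
    mismatches each); if either anchor is missing the input is returned
    unchanged and flagged untrimmed.
    """
    if bounds is not None:
        s, e = bounds
        return sequence[s:e], True
    if region is None:
        raise ValueError("need region or explicit bounds")
    left, right = anchors[region]
    i = _find_anchor(sequence, left, max_mismatch)
    if i < 0:
        return sequence, False
    start = i + len(left)
    j = _find_anchor(sequence[start:], right, max_mismatch)
    if j < 0:
        return sequence, False
    return sequence[start : start + j], True


# ---------------------------------------------------------------------------
# distances


def p_distance(a: str, b: str, aligned: bool = False) -> float:
    """Proportion of differing sites under pairwise deletion of gap columns."""
    if aligned:
        ga, gb = a, b
    else:
        aln = align_pair(a, b)
        ga, gb = str(aln[0]), str(aln[1])
    comparable = 0
    diff = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable columns: p-distance undefined")
    return diff / comparable


def p_distance_matrix(alignment: Mapping[str, str], on_error: str = "raise") -> pd.DataFrame:
    """Pairwise p-distances over an existing multiple alignment."""
    labels = list(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            dist = p_distance(alignment[labels[i]], alignment[labels[j]], aligned=True)
        except ValueError:
            if on_error == "raise":
                raise
            dist = 1.0
        d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# alignment-free preclustering


def _kmer_profile(seq: str, k: int) -> dict[str, int]:
    prof: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - k + 1):
        prof[seq[i : i + k]] += 1
    return prof


def _cosine_distance(p: dict[str, int], q: dict[str, int]) -> float:
    keys = set(p) | set(q)
    if not keys:
        return 0.0
    dot = sum(p.get(x, 0) * q.get(x, 0) for x in keys)
    na = np.sqrt(sum(v * v for v in p.values()))
    nb = np.sqrt(sum(v * v for v in q.values()))
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - dot / (na * nb))


def precluster_alignment_free(
    sequences: Mapping[str, str],
    k: int = 6,
    cut_height: float = 0.15,
    min_shared_kmer_frac: float = 0.5,
) -> list[dict]:
    """Candidate alignable clusters from a k-mer-distance NJ tree.

    An NJ tree is built on cosine distances between k-mer count profiles and
    cut by removing internal edges longer than ``cut_height``; leaf
    components form the clusters.  A cluster is marked alignable when every
    member pair shares at least ``min_shared_kmer_frac`` of its k-mers.

    Returns a list of {"members": [...], "alignable": bool}.
    """
    labels = list(sequences)
    if len(labels) == 1:
        return [{"members": labels, "alignable": True}]
    profs = {l: _kmer_profile(sequences[l], k) for l in labels}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = _cosine_distance(profs[labels[i]], profs[labels[j]])
    if n == 2:
        comps = [labels] if d[0, 1] <= cut_height else [[labels[0]], [labels[1]]]
    else:
        tree = nj_tree(pd.DataFrame(d, index=labels, columns=labels))
        comps = _cut_tree(tree, cut_height)
    out = []
    for comp in comps:
        ok = True
        for a, b in itertools.combinations(comp, 2):
            sa = set(profs[a])
            sb = set(profs[b])
            if not sa or not sb:
                continue
            if len(sa & sb) / min(len(sa), len(sb)) < min_shared_kmer_frac:
                ok = False
                break
        out.append({"members": sorted(comp), "alignable": ok})
    out.sort(key=lambda c: c["members"][0])
    return out


def _cut_tree(tree: TreeNode, cut_height: float) -> list[list[str]]:
    """Leaf components after deleting internal edges longer than cut_height."""
    # union-find over leaves, connecting through surviving edges
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    node_rep: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_tip():
            parent.setdefault(node.name, node.name)
            node_rep[id(node)] = node.name
        else:
            reps = []
            for child in node.children:
                length = child.length or 0.0
                child_rep = node_rep[id(child)]
                cut = (not child.is_tip()) and length > cut_height
                if not cut:
                    reps.append(child_rep)
                else:
                    reps.append(None)
            live = [r for r in reps if r is not None]
            if live:
                base = live[0]
                for r in live[1:]:
                    union(base, r)
                node_rep[id(node)] = base
            else:
                # all children cut away; represent by first child's rep anyway
                node_rep[id(node)] = node_rep[id(node.children[0])]
    comps: dict[str, list[str]] = defaultdict(list)
    for leaf in tree.tips():
        comps[find(leaf.name)].append(leaf.name)
    return [sorted(c) for c in comps.values()]


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(distances: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Among pairs minimizing the Q criterion the lexicographically smallest
    pair (by the smallest leaf name each cluster contains) is joined.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  Returns an unrooted tree (trifurcating root).
    """
    labels = list(distances.index)
    n = len(labels)
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or list(distances.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    keys: list[str] = list(labels)  # canonical key = smallest contained leaf name
    D = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = []
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    ia, ib = active[a], active[b]
                    cands.append((tuple(sorted((keys[ia], keys[ib]))), a, b))
        cands.sort()
        _, a, b = cands[0]
        ia, ib = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[ia], nodes[ib]
        child_i.length = float(max(li, 0.0))
        child_j.length = float(max(lj, 0.0))
        new = TreeNode(children=[child_i, child_j])
        new_dists = 0.5 * (D[ia, active] + D[ib, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k_new = D.shape[0] - 1
        for pos, other in enumerate(active):
            D[k_new, other] = D[other, k_new] = new_dists[pos]
        D[k_new, k_new] = 0.0
        nodes.append(new)
        keys.append(min(keys[ia], keys[ib]))
        active = [x for x in active if x not in (ia, ib)] + [k_new]

    # final three-node join (closed form)
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = dab - la
    lc = dac - la
    lens = [la, lb, lc]
    for i in range(3):
        if lens[i] < 0:
            for j in range(3):
                if j != i:
                    lens[j] += lens[i] / 2
            lens[i] = 0.0
    for node, length in zip((nodes[a], nodes[b], nodes[c]), lens):
        node.length = float(max(length, 0.0))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.length = None
    return root


def _bipartitions(tree: TreeNode, leaf_names: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf names."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaf_names) - 2:
            continue
        other = leaf_names - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree over alignment p-distances with column-bootstrap supports.

    Resamples alignment columns with replacement; support of an internal
    edge is the percentage of replicate trees containing its bipartition.
    Each internal node of the returned tree carries a ``support`` attribute.
    """
    labels = list(alignment)
    length = len(next(iter(alignment.values())))
    if any(len(s) != length for s in alignment.values()):
        raise ValueError("alignment rows must have equal length")
    cols = np.array([list(alignment[l]) for l in labels])
    dmat = p_distance_matrix(alignment, on_error="max")
    tree = nj_tree(dmat)
    leafset = frozenset(labels)
    orig = _bipartitions(tree, leafset)
    hits = {bp: 0 for bp in orig}
    if n_reps > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_reps):
            idx = rng.integers(0, length, length)
            res = {l: "".join(cols[i][idx]) for i, l in enumerate(labels)}
            rep_d = p_distance_matrix(res, on_error="max")
            rep_bps = _bipartitions(nj_tree(rep_d), leafset)
            for bp in orig:
                if bp in rep_bps:
                    hits[bp] += 1
    supports = {
        bp: (100.0 * c / n_reps if n_reps > 0 else float("nan")) for bp, c in hits.items()
    }
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leafset - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.support = supports.get(canon, float("nan"))
        node.name = None if np.isnan(node.support) else f"{node.support:g}"
    return tree, supports


# ---------------------------------------------------------------------------
# center-star multiple alignment


def center_star_align(
    sequences: Mapping[str, str],
    center_label: str | None = None,
) -> dict[str, str]:
    """Progressive center-star multiple alignment.

    The center is the longest sequence (ties to the lexicographically
    smallest label) unless given.  Every sequence is pairwise-aligned to the
    center and merged by projecting onto center coordinates, padding
    insertions to their maximum width.  Deterministic; adequate at the
    intra-genus divergences it is used for.
    """
    labels = list(sequences)
    if not labels:
        return {}
    if len(labels) == 1:
        return {labels[0]: sequences[labels[0]]}
    if center_label is None:
        center_label = min(labels, key=lambda l: (-len(sequences[l]), l))
    center = sequences[center_label]
    lc = len(center)
    # per sequence: inserts[i] = chars inserted before center position i
    # (i == lc -> after the last center position); chars[i] = char aligned
    # to center position i ('-' if gapped)
    parsed: dict[str, tuple[list[str], list[str]]] = {}
    max_ins = [0] * (lc + 1)
    for l in labels:
        if l == center_label:
            continue
        aln = align_pair(center, sequences[l])
        cg, sg = str(aln[0]), str(aln[1])
        inserts = [""] * (lc + 1)
        chars = ["-"] * lc
        cpos = 0
        for cc, sc in zip(cg, sg):
            if cc == "-":
                inserts[cpos] += sc
            else:
                chars[cpos] = sc
                cpos += 1
        parsed[l] = (inserts, chars)
        for i in range(lc + 1):
            max_ins[i] = max(max_ins[i], len(inserts[i]))
    out: dict[str, str] = {}
    for l in labels:
        if l == center_label:
            inserts = [""] * (lc + 1)
            chars = list(center)
        else:
            inserts, chars = parsed[l]
        row = []
        for i in range(lc):
            row.append(inserts[i].ljust(max_ins[i], "-"))
            row.append(chars[i])
        row.append(inserts[lc].ljust(max_ins[lc], "-"))
        out[l] = "".join(row)
    return out


# ---------------------------------------------------------------------------
# diagnostic sites


def diagnostic_sites(
    alignment: Mapping[str, str],
    species_labels: Mapping[str, str],
) -> dict[str, list[int]]:
    """Species-specific fixed positions within a genus alignment.

    A column is diagnostic for species S when every reference of S carries
    the same non-gap state there and no reference of any other species
    carries that state.
    """
    refs = [l for l in alignment if l in species_labels]
    species = sorted(set(species_labels[l] for l in refs))
    if len(species) < 2:
        return {}
    length = len(next(iter(alignment.values())))
    out: dict[str, list[int]] = {s: [] for s in species}
    for pos in range(length):
        by_species: dict[str, set[str]] = defaultdict(set)
        for l in refs:
            by_species[species_labels[l]].add(alignment[l][pos])
        for s in species:
            states = by_species[s]
            if len(states) != 1:
                continue
            x = next(iter(states))
            if x == "-":
                continue
            others = set().union(*(by_species[t] for t in species if t != s))
            if x not in others and "-" not in others and others:
                out[s].append(pos)
    return out


# ---------------------------------------------------------------------------
# clade classification


@dataclass
class ClassifyThresholds:
    s_min: float = 70.0       # minimum bootstrap support for a clade (%)
    t_species: float = 0.03   # max p-distance to a conspecific reference
    t_genus: float = 0.15     # beyond this distance to every reference -> excluded


@dataclass
class TaxonCall:
    otu_id: str
    verdict: str  # "species" | "vt_species" | "excluded_vt_higher"
    label: str
    support: float
    nearest_ref_p_distance: float


def _vt_labels(genus: str, groups: list[list[str]], sequences: Mapping[str, str]) -> dict[str, str]:
    """Stable VT_<genus>_<k> labels ordered by each group's smallest member hash."""
    def group_key(grp: list[str]) -> str:
        return min(hashlib.sha1(sequences[m].encode()).hexdigest() for m in grp)

    ordered = sorted(groups, key=group_key)
    out = {}
    for k, grp in enumerate(ordered, start=1):
        for m in grp:
            out[m] = f"VT_{genus}_{k}"
    return out


def classify_clades(
    tree: TreeNode,
    supports: dict[frozenset, float],
    dmat: pd.DataFrame,
    otu_ids: Sequence[str],
    ref_species: Mapping[str, str],
    sequences: Mapping[str, str],
    genus: str,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    diagnostics: Mapping[str, list[int]] | None = None,
    alignment: Mapping[str, str] | None = None,
) -> list[TaxonCall]:
    """Apply the clade decision rules to every OTU in a genus bin.

    Rules, in order: (1) OTU inside a supported clade whose references all
    belong to one species, within t_species of the nearest such reference
    and not contradicting that species' diagnostic sites -> species call;
    (2) supported reference-free clade with >= 2 OTUs -> shared species-level
    VT; (3) OTU in no supported clade and farther than t_genus from every
    reference -> excluded higher-rank VT; (4) remaining OTUs pair up into VTs
    when within t_species of another unplaced OTU, else they are excluded.
    """
    leafset = frozenset(l.name for l in tree.tips())
    refs = [l for l in leafset if l in ref_species]
    otus = [o for o in otu_ids if o in leafset]

    # supported clades: both sides of every supported internal edge (the
    # tree is unrooted, so either side may be the biological clade)
    supported: list[frozenset] = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leafset - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        sup = supports.get(canon, float("nan"))
        if not np.isnan(sup) and sup >= thresholds.s_min:
            supported.extend((side, other))
    supported = sorted(set(supported), key=lambda s: (len(s), tuple(sorted(s))))

    calls: dict[str, TaxonCall] = {}
    vt_groups: dict[frozenset, list[str]] = defaultdict(list)
    unplaced: list[str] = []

    for otu in sorted(otus):
        nearest_ref = None
        nearest_d = float("inf")
        for ref in refs:
            dd = float(dmat.loc[otu, ref])
            if dd < nearest_d:
                nearest_ref, nearest_d = ref, dd
        containing = [c for c in supported if otu in c]
        clade_with_ref = None
        for c in containing:  # smallest first
            if any(r in c for r in refs):
                clade_with_ref = c
                break
        placed = False
        if clade_with_ref is not None:
            clade_species = {ref_species[r] for r in clade_with_ref if r in refs}
            if len(clade_species) == 1:
                sp = next(iter(clade_species))
                sp_refs = [r for r in clade_with_ref if r in refs]
                d_sp = min(float(dmat.loc[otu, r]) for r in sp_refs)
                ok_diag = True
                if diagnostics and alignment and sp in diagnostics and diagnostics[sp]:
                    ref0 = min(r for r in refs if ref_species[r] == sp)
                    agree = disagree = 0
                    for pos in diagnostics[sp]:
                        a = alignment[otu][pos]
                        if a == "-":
                            continue
                        if a == alignment[ref0][pos]:
                            agree += 1
                        else:
                            disagree += 1
                    ok_diag = disagree <= agree
                if d_sp <= thresholds.t_species and ok_diag:
                    sup = _clade_support(clade_with_ref, leafset, supports)
                    calls[otu] = TaxonCall(otu, "species", sp, sup, d_sp)
                    placed = True
        if not placed and containing:
            # smallest supported clade containing the OTU and no reference,
            # expanded to the largest such clade for stable VT grouping
            ref_free = [c for c in containing if not any(r in c for r in refs)]
            if ref_free and sum(1 for x in ref_free[-1] if x in otus) >= 2:
                vt_groups[ref_free[-1]].append(otu)
                placed = True
        if not placed:
            unplaced.append(otu)

    # rule 2 labels
    groups = [sorted(v) for v in vt_groups.values() if len(v) >= 1]
    # rule 4: pair unplaced OTUs that sit within t_species of each other
    still: list[str] = []
    for otu in unplaced:
        nearest_d = min(
            (float(dmat.loc[otu, r]) for r in refs), default=float("inf")
        )
        if nearest_d > thresholds.t_genus:
            calls[otu] = TaxonCall(
                otu, "excluded_vt_higher", f"VTX_{genus}", float("nan"),
                nearest_d if refs else float("nan"),
            )
        else:
            still.append(otu)
    # connected components among remaining unplaced at t_species
    comp: dict[str, str] = {s: s for s in still}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for a, b in itertools.combinations(still, 2):
        if float(dmat.loc[a, b]) <= thresholds.t_species:
            ra, rb = find(a), find(b)
            if ra != rb:
                comp[rb] = ra
    by_root: dict[str, list[str]] = defaultdict(list)
    for s in still:
        by_root[find(s)].append(s)
    for members in by_root.values():
        if len(members) >= 2:
            groups.append(sorted(members))
        else:
            otu = members[0]
            nearest_d = min((float(dmat.loc[otu, r]) for r in refs), default=float("inf"))
            calls[otu] = TaxonCall(
                otu, "excluded_vt_higher", f"VTX_{genus}", float("nan"), nearest_d
            )
    labels = _vt_labels(genus, groups, sequences)
    for grp in groups:
        for otu in grp:
            nearest_d = min((float(dmat.loc[otu, r]) for r in refs), default=float("nan"))
            calls[otu] = TaxonCall(otu, "vt_species", labels[otu], float("nan"), nearest_d)
    return [calls[o] for o in sorted(otus)]


def _clade_support(side: frozenset, leafset: frozenset, supports: dict) -> float:
    other = leafset - side
    canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
    return supports.get(canon, float("nan"))


def classify_genus_bin(
    genus: str,
    otu_spacers: Mapping[str, str],
    ref_spacers: Mapping[str, str],
    ref_species: Mapping[str, str],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[list[TaxonCall], TreeNode]:
    """Align a genus bin, build its bootstrap NJ tree, and call every OTU."""
    sequences = {**otu_spacers, **ref_spacers}
    if len(sequences) < 3 or not ref_spacers:
        # too small for a tree: fall back to nearest-reference distances
        calls = []
        for otu in sorted(otu_spacers):
            if ref_spacers:
                dists = {r: p_distance(otu_spacers[otu], s) for r, s in ref_spacers.items()}
                r0 = min(dists, key=lambda r: (dists[r], r))
                if dists[r0] <= thresholds.t_species:
                    calls.append(TaxonCall(otu, "species", ref_species[r0], float("nan"), dists[r0]))
                    continue
                nearest = dists[r0]
            else:
                nearest = float("inf")
            if nearest > thresholds.t_genus:
                calls.append(TaxonCall(otu, "excluded_vt_higher", f"VTX_{genus}", float("nan"), nearest))
            else:
                calls.append(TaxonCall(otu, "vt_species", f"VT_{genus}_1", float("nan"), nearest))
        return calls, None
    center = min(ref_spacers, key=lambda l: (-len(ref_spacers[l]), l)) if ref_spacers else None
    alignment = center_star_align(sequences, center_label=center)
    tree, supports = bootstrap_support(alignment, n_reps=n_boot, seed=seed)
    dmat = p_distance_matrix(alignment, on_error="max")
    diags = diagnostic_sites(alignment, ref_species)
    calls = classify_clades(
        tree, supports, dmat, list(otu_spacers), ref_species, sequences,
        genus, thresholds, diags, alignment,
    )
    return calls, tree


# ---------------------------------------------------------------------------
# biotope summary


def species_summary(
    calls: Sequence[TaxonCall],
    otu_table,
    biotopes: Mapping[str, str],
) -> dict:
    """Per-biotope OTU/species/VT counts, Venn regions, and endemics.

    Excluded higher-rank VTs never enter species-level counts.  A species is
    present in a biotope when any OTU called to it has reads in one of that
    biotope's samples.
    """
    counts = otu_table.counts if hasattr(otu_table, "counts") else otu_table
    call_by_otu = {c.otu_id: c for c in calls}
    biotope_list = sorted(set(biotopes.values()))
    presence: dict[str, set[str]] = defaultdict(set)  # taxon label -> biotopes
    otus_per_biotope: dict[str, set[str]] = defaultdict(set)
    for otu in counts.columns:
        call = call_by_otu.get(otu)
        for sample in counts.index:
            if counts.loc[sample, otu] > 0:
                b = biotopes.get(sample)
                if b is None:
                    continue
                otus_per_biotope[b].add(otu)
                if call is not None and call.verdict in ("species", "vt_species"):
                    presence[call.label].add(b)
    per_biotope = {}
    for b in biotope_list:
        sp = {l for l, bs in presence.items() if b in bs and not l.startswith("VT_")}
        vt = {l for l, bs in presence.items() if b in bs and l.startswith("VT_")}
        per_biotope[b] = {
            "n_otus": len(otus_per_biotope[b]),
            "n_species": len(sp),
            "n_vt_species": len(vt),
        }
    venn: dict[tuple[str, ...], int] = {}
    for rset in _powerset(biotope_list):
        if not rset:
            continue
        venn[rset] = sum(
            1 for l, bs in presence.items() if bs == set(rset)
        )
    endemics = {
        b: sorted(l for l, bs in presence.items() if bs == {b} and not l.startswith("VT_"))
        for b in biotope_list
    }
    return {"per_biotope": per_biotope, "venn": venn, "endemics": endemics}


def _powerset(items: Sequence[str]):
    for r in range(1, len(items) + 1):
        for combo in itertools.combinations(items, r):
            yield combo
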