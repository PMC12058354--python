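"""Greedy similarity clustering of amplicon reads and consensus building.

Reads are shuffled with a fixed seed, processed in batches, and assigned
greedily to the first-member seed of the best-matching existing cluster at
``within_sim`` identity (default 97%).  Per-cluster consensus sequences are
built by majority vote over members aligned to the cluster medoid, and
clusters whose consensi match at ``merge_sim`` identity (default 98%) are
merged by single linkage.

Identity is global (Needleman-Wunsch) percent identity: matches divided by
alignment columns, gaps counting as columns, with scoring match +1,
mismatch -1, gap -2 and no free end gaps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align

from .io import Read

__all__ = [
    "Cluster",
    "ClusterParams",
    "pairwise_identity",
    "cluster_batch",
    "build_consensus",
    "merge_clusters",
    "cluster_reads",
    "write_cluster_fasta",
    "write_membership_tsv",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class ClusterParams:
    """Clustering parameters: batch size 1000, 97% within-cluster identity,
    98% consensus-merge identity."""

    batch_size: int = 1000
    within_sim: float = 0.97
    merge_sim: float = 0.98
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.within_sim <= self.merge_sim <= 1):
            raise ValueError("require 0 < within_sim <= merge_sim <= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass
class Cluster:
    id: int
    member_ids: tuple[str, ...]
    consensus: str

    @property
    def size(self) -> int:
        return len(self.member_ids)


def pairwise_identity(a: str, b: str) -> float:
    """Global percent identity between two nucleotide sequences.

    Identity = matches / alignment columns * 100 over the optimal global
    alignment (match +1, mismatch -1, gap -2).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    if b < a:  # canonical order: ties among co-optimal alignments are
        a, b = b, a  # resolved identically regardless of argument order
    aln = _ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length * 100.0


def _identity_upper_bound(a: str, b: str) -> float:
    """Cheap upper bound on global percent identity via unit-cost edit
    distance: any alignment has >= d non-match columns and <= len(a)+len(b)
    columns, so identity <= 1 - d/(la+lb)."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return (1.0 - d / (len(a) + len(b))) * 100.0


def _align_to_ref(ref: str, seq: str) -> tuple[str, str]:
    aln = _ALIGNER.align(ref, seq)[0]
    return str(aln[0]), str(aln[1])


def _medoid(seqs: Sequence[str], max_exact: int = 200) -> int:
    """Index of the member minimising summed alignment distance to all
    members (brute force up to ``max_exact`` members, seeded sampling
    beyond that)."""
    n = len(seqs)
    if n == 1:
        return 0
    if n <= max_exact:
        others = range(n)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 100.0 - pairwise_identity(seqs[i], seqs[j])
                dist[i, j] = dist[j, i] = d
        return int(np.argmin(dist.sum(axis=1)))
    rng = np.random.default_rng(0)
    sample = rng.choice(n, size=max_exact, replace=False)
    totals = np.zeros(n)
    for i in range(n):
        totals[i] = sum(
            100.0 - pairwise_identity(seqs[i], seqs[j]) for j in sample if j != i
        )
    return int(np.argmin(totals))


_BASES = ("A", "C", "G", "T", "N")


def build_consensus(members: Sequence[str]) -> str:
    """Column-wise majority consensus of cluster members.

    Members are globally aligned to the medoid member; each medoid column
    takes the plurality base (gap-plurality columns are deleted, base ties
    broken lexicographically A<C<G<T).  Insertions relative to the medoid
    are kept when more than half of the members carry the same inserted
    segment at the same position, so a deletion error in the medoid itself
    is outvoted.
    """
    if len(members) == 0:
        raise ValueError("cannot build a consensus from an empty cluster")
    if len(members) == 1:
        return members[0]
    m = _medoid(members)
    ref = members[m]
    n = len(members)
    L = len(ref)
    column_votes: list[Counter] = [Counter() for _ in range(L)]
    insert_votes: list[Counter] = [Counter() for _ in range(L + 1)]
    for seq in members:
        if seq == ref:
            for j, base in enumerate(ref):
                column_votes[j][base] += 1
            continue
        gref, gseq = _align_to_ref(ref, seq)
        j = 0
        pending = ""
        for rc, sc in zip(gref, gseq):
            if rc == "-":
                pending += sc
            else:
                if pending:
                    insert_votes[j][pending] += 1
                    pending = ""
                column_votes[j][sc] += 1
                j += 1
        if pending:
            insert_votes[L][pending] += 1
    out: list[str] = []
    for j in range(L + 1):
        if insert_votes[j]:
            seg, count = min(
                insert_votes[j].items(), key=lambda kv: (-kv[1], kv[0])
            )
            if count > n / 2:
                out.append(seg)
        if j < L:
            votes = column_votes[j]
            best_base = min(
                ((b, votes[b]) for b in _BASES if votes[b] > 0),
                key=lambda kv: (-kv[1], kv[0]),
                default=(None, 0),
            )
            if best_base[0] is not None and votes["-"] <= best_base[1]:
                out.append(best_base[0])
    consensus = "".join(out)
    if not consensus:
        raise ValueError("consensus collapsed to the empty sequence")
    return consensus


def cluster_batch(reads: Sequence[Read], params: ClusterParams | None = None) -> list[Cluster]:
    """Greedy seeded clustering of filtered reads.

    Reads are shuffled with ``params.seed`` and processed in batches of
    ``batch_size``; each read joins the best existing cluster whose seed
    (first member) it matches at >= ``within_sim`` identity, else founds a
    new cluster.  Every read is assigned to exactly one cluster; the
    result is deterministic given the seed.  Consensus sequences are built
    for all clusters before returning.
    """
    params = params or ClusterParams()
    if not reads:
        return []
    rng = np.random.default_rng(params.seed)
    order = rng.permutation(len(reads))
    threshold = params.within_sim * 100.0
    seed_seqs: list[str] = []
    memberships: list[list[int]] = []
    for start in range(0, len(order), params.batch_size):
        for idx in order[start : start + params.batch_size]:
            seq = reads[idx].sequence
            best_c, best_id = -1, -1.0
            for c, sseq in enumerate(seed_seqs):
                if _identity_upper_bound(seq, sseq) < threshold:
                    continue
                ident = pairwise_identity(seq, sseq)
                if ident >= threshold and ident > best_id:
                    best_c, best_id = c, ident
            if best_c >= 0:
                memberships[best_c].append(idx)
            else:
                seed_seqs.append(seq)
                memberships.append([idx])
    clusters = []
    for c, idxs in enumerate(memberships):
        seqs = [reads[i].sequence for i in idxs]
        clusters.append(
            Cluster(
                id=c,
                member_ids=tuple(reads[i].id for i in idxs),
                consensus=build_consensus(seqs),
            )
        )
    return clusters


def merge_clusters(
    clusters: Sequence[Cluster],
    params: ClusterParams | None = None,
    reads: Mapping[str, str] | None = None,
) -> list[Cluster]:
    """Single-linkage merge of clusters whose consensi match at
    ``merge_sim`` identity.

    ``reads`` (read_id -> sequence) lets the merged consensus be rebuilt
    from all members; without it the rebuild uses the input consensi
    weighted by cluster size.  Merging is transitive (single linkage), so
    the post-merge consensi of distinct clusters may still exceed the
    threshold against each other; the guarantee applies to the pre-rebuild
    consensi.
    """
    params = params or ClusterParams()
    if not clusters:
        return []
    threshold = params.merge_sim * 100.0
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            a, b = clusters[i].consensus, clusters[j].consensus
            if _identity_upper_bound(a, b) < threshold:
                continue
            if pairwise_identity(a, b) >= threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[Cluster] = []
    for new_id, idxs in enumerate(sorted(groups.values(), key=lambda g: g[0])):
        if len(idxs) == 1:
            c = clusters[idxs[0]]
            merged.append(Cluster(new_id, c.member_ids, c.consensus))
            continue
        member_ids = tuple(rid for i in idxs for rid in clusters[i].member_ids)
        if reads is not None:
            seqs = [reads[rid] for rid in member_ids]
        else:
            seqs = [clusters[i].consensus for i in idxs for _ in clusters[i].member_ids]
        merged.append(Cluster(new_id, member_ids, build_consensus(seqs)))
    return merged


def cluster_reads(
    reads: Sequence[Read], params: ClusterParams | None = None
) -> list[Cluster]:
    """Full sorting stage: greedy batch clustering, consensus-level
    merging, then a rescue pass.

    The greedy pass compares reads to seed reads, which carry their own
    errors, so a read in the error tail can land just outside the
    ``within_sim`` radius of its true cluster and found a singleton.  The
    rescue pass re-compares each singleton against the denoised consensi
    of the multi-member clusters and absorbs it where it meets
    ``within_sim``; reads too error-laden even for that remain singleton
    clusters (exportable or not via a minimum-cluster-size filter).
    """
    params = params or ClusterParams()
    seq_of = {r.id: r.sequence for r in reads}
    clusters = cluster_batch(reads, params)
    for _ in range(5):  # alternate until the partition stabilises
        n_before = len(clusters)
        clusters = merge_clusters(clusters, params, reads=seq_of)
        clusters, n_rescued = _rescue_singletons(clusters, params, seq_of)
        if len(clusters) == n_before and n_rescued == 0:
            break
    return clusters


def _rescue_singletons(
    clusters: list[Cluster],
    params: ClusterParams,
    seq_of: Mapping[str, str],
) -> tuple[list[Cluster], int]:
    threshold = params.within_sim * 100.0
    multi = [c for c in clusters if c.size > 1]
    if not multi:
        return list(clusters), 0
    absorbed: dict[int, list[str]] = {}
    leftovers: list[Cluster] = []
    for c in clusters:
        if c.size > 1:
            continue
        seq = seq_of[c.member_ids[0]]
        best_i, best_id = -1, -1.0
        for i, target in enumerate(multi):
            if _identity_upper_bound(seq, target.consensus) < threshold:
                continue
            ident = pairwise_identity(seq, target.consensus)
            if ident >= threshold and ident > best_id:
                best_i, best_id = i, ident
        if best_i >= 0:
            absorbed.setdefault(best_i, []).append(c.member_ids[0])
        else:
            leftovers.append(c)
    out: list[Cluster] = []
    for i, c in enumerate(multi):
        member_ids = c.member_ids + tuple(absorbed.get(i, ()))
        consensus = (
            build_consensus([seq_of[rid] for rid in member_ids])
            if i in absorbed
            else c.consensus
        )
        out.append(Cluster(len(out), member_ids, consensus))
    for c in leftovers:
        out.append(Cluster(len(out), c.member_ids, c.consensus))
    return out, sum(len(v) for v in absorbed.values())


def write_cluster_fasta(
    clusters: Iterable[Cluster],
    path,
    sample_of_read: Mapping[str, str] | None = None,
) -> None:
    """FASTA of consensus sequences; headers carry id, size and sample
    composition."""
    with open(path, "w") as fh:
        for c in clusters:
            comp = ""
            if sample_of_read:
                counts = Counter(sample_of_read.get(r, "?") for r in c.member_ids)
                comp = ";samples=" + ",".join(
                    f"{s}:{n}" for s, n in sorted(counts.items())
                )
            fh.write(f">cluster_{c.id};size={c.size}{comp}\n{c.consensus}\n")


def write_membership_tsv(clusters: Iterable[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcluster_id\n")
        for c in clusters:
            for rid in c.member_ids:
                fh.write(f"{rid}\t{c.id}\n")
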