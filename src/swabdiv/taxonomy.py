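"""Taxonomic assignment of consensus sequences from similarity-search hits.

Hits (BLAST tabular, outfmt 6) are filtered on e-value, identity, coverage
and a top-N cap; assignments take the lowest common ancestor (LCA) of the
tied-top-bitscore hits and are then truncated by rank-specific identity
thresholds: species >= 98%, genus >= 96%, family >= 90%.  Ranks above
family survive whenever the 80% search floor was met, which is how
order-level detections arise.  Non-target lineages (outside Hexapoda,
which here includes Collembola) are excluded before the community table is
built.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster import pairwise_identity

__all__ = [
    "RANKS",
    "Lineage",
    "HitRecord",
    "RankThresholds",
    "TaxonAssignment",
    "CommunityMatrix",
    "parse_lineage_fasta",
    "parse_lineage_tsv",
    "parse_hits",
    "filter_hits",
    "lca",
    "assign_taxonomy",
    "assign_all",
    "exclude_nontarget",
    "tabulate_community",
    "rank_of",
    "naive_search",
]

RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: labels whose presence at any rank places a lineage inside Hexapoda;
#: Collembola (springtails) are retained as hexapods even though they are
#: no longer classified as insects.
HEXAPOD_LABELS = frozenset(
    {"Hexapoda", "Insecta", "Collembola", "Entognatha", "Diplura", "Protura"}
)


@dataclass(frozen=True)
class Lineage:
    """Ranked lineage phylum..species; absent ranks are None and must form
    a suffix (no gaps: a species cannot be present without its genus)."""

    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        seen_absent = False
        for name in self.labels_with_none():
            if name is None:
                seen_absent = True
            elif seen_absent:
                raise ValueError(
                    f"lineage has a gap below an absent rank: {self}"
                )

    def labels_with_none(self) -> tuple[str | None, ...]:
        return (self.phylum, self.class_, self.order, self.family, self.genus, self.species)

    def labels(self) -> tuple[str, ...]:
        return tuple(x for x in self.labels_with_none() if x is not None)

    def deepest_rank(self) -> str | None:
        labels = self.labels_with_none()
        for rank, label in zip(reversed(RANKS), reversed(labels)):
            if label is not None:
                return rank
        return None

    def truncated_to(self, rank: str | None) -> "Lineage":
        """Lineage cut to ``rank`` (inclusive); ``None`` empties it."""
        if rank is None:
            return Lineage()
        depth = RANKS.index(rank) + 1
        labels = list(self.labels_with_none())
        return Lineage(*(labels[i] if i < depth else None for i in range(6)))

    def label(self) -> str:
        """Display name: the deepest present label, or 'unassigned'."""
        labs = self.labels()
        return labs[-1] if labs else "unassigned"

    @staticmethod
    def from_labels(labels: Sequence[str | None]) -> "Lineage":
        labels = list(labels) + [None] * (6 - len(labels))
        return Lineage(*labels[:6])


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    lineage: Lineage
    identity: float
    coverage: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError(f"identity/coverage out of [0,100] for {self.query_id}")
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class RankThresholds:
    """Minimum top-hit identity required to keep each rank of the LCA."""

    species_min: float = 98.0
    genus_min: float = 96.0
    family_min: float = 90.0

    def __post_init__(self) -> None:
        if not (self.species_min >= self.genus_min >= self.family_min):
            raise ValueError("require species_min >= genus_min >= family_min")


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    lineage: Lineage
    assigned_rank: str  # species | genus | family | order | higher | unassigned
    top_identity: float
    n_tied_top_hits: int


@dataclass
class CommunityMatrix:
    """Sample x taxon read-count table plus per-sample metadata.

    ``counts`` is indexed by sample_id with one column per collapsed
    taxon; ``metadata`` (habitat, replicate, time_of_day) shares the
    index.  ``lineages`` maps taxon label -> Lineage.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    lineages: dict[str, Lineage] = field(default_factory=dict)

    def presence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)

    def incidence(self, habitat_of: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Taxon x habitat incidence frequencies (number of samples in the
        habitat where the taxon occurs)."""
        pres = self.presence()
        habitats = (
            pd.Series(habitat_of)
            if habitat_of is not None
            else self.metadata["habitat"]
        )
        return pres.groupby(habitats.loc[pres.index]).sum().T

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# lineage references

_TAXID_SUFFIX = re.compile(r"_\d+$")


def _parse_lineage_tokens(tokens: Sequence[str]) -> Lineage:
    """Tokens in root;(super)kingdom;phylum;...;species order, each
    optionally carrying a MIDORI-style numeric taxid suffix."""
    cleaned = [_TAXID_SUFFIX.sub("", t.strip()) for t in tokens if t.strip()]
    while cleaned and cleaned[0] in {"root", "Root", "Eukaryota", "Metazoa"}:
        cleaned.pop(0)
    if len(cleaned) > 6:
        raise ValueError(f"cannot map {len(cleaned)} lineage tokens onto 6 ranks: {cleaned}")
    return Lineage.from_labels(cleaned)


def parse_lineage_fasta(path: str | Path) -> dict[str, Lineage]:
    """Lineage map from a reference FASTA with MIDORI2-style headers:
    ``>id root_1;Eukaryota_2759;Phylum_x;Class_x;Order_x;Family_x;Genus_x;Genus species_x``.
    """
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(">"):
                continue
            header = line[1:].strip()
            if "###" in header:  # MIDORI2 uses id###lineage
                sid, lintxt = header.split("###", 1)
            else:
                parts = header.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"header without lineage: {header!r}")
                sid, lintxt = parts
            out[sid.strip()] = _parse_lineage_tokens(lintxt.split(";"))
    return out


def parse_lineage_tsv(path: str | Path) -> dict[str, Lineage]:
    """Two-column TSV: subject_id <tab> semicolon-joined lineage."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "lineage"], dtype=str)
    return {
        row.id: _parse_lineage_tokens(str(row.lineage).split(";"))
        for row in df.itertuples()
    }


# ---------------------------------------------------------------------------
# hit parsing and filtering

_OUTFMT6 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def parse_hits(
    path: str | Path,
    lineage_map: Mapping[str, Lineage],
    query_lengths: Mapping[str, int] | None = None,
) -> tuple[list[HitRecord], list[str]]:
    """Parse BLAST outfmt-6 hits (12 columns, or 13 with qcovs appended).

    Without a qcovs column, query coverage is computed as
    (qend - qstart + 1) / query length, which then requires
    ``query_lengths``.  Subject ids missing from ``lineage_map`` are
    returned in the second element, never silently dropped.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return [], []
    if df.shape[1] == 13:
        df.columns = _OUTFMT6 + ["qcovs"]
    elif df.shape[1] == 12:
        df.columns = _OUTFMT6
        if query_lengths is None:
            raise ValueError(
                "12-column hits file has no qcovs; query_lengths is required "
                "to compute query coverage"
            )
        df["qcovs"] = [
            (row.qend - row.qstart + 1) / query_lengths[row.qseqid] * 100.0
            for row in df.itertuples()
        ]
    else:
        raise ValueError(
            f"{path}: expected 12 or 13 tab-separated columns, got {df.shape[1]}"
        )
    hits: list[HitRecord] = []
    unresolved: list[str] = []
    for row in df.itertuples():
        lineage = lineage_map.get(str(row.sseqid))
        if lineage is None:
            unresolved.append(str(row.sseqid))
            continue
        hits.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                lineage=lineage,
                identity=float(row.pident),
                coverage=float(row.qcovs),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
        )
    return hits, unresolved


def filter_hits(
    hits: Iterable[HitRecord],
    max_e: float = 1e-3,
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    top_n: int = 20,
) -> dict[str, list[HitRecord]]:
    """Per-query hit filtering: e-value <= 1e-3, identity and coverage
    >= 80%, then the top 20 hits by bitscore (ties at the cutoff are all
    retained).  Queries whose hits all fail map to an empty list."""
    grouped: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    out: dict[str, list[HitRecord]] = {}
    for query, qhits in grouped.items():
        passing = [
            h
            for h in qhits
            if h.evalue <= max_e
            and h.identity >= min_identity
            and h.coverage >= min_coverage
        ]
        passing.sort(key=lambda h: (-h.bitscore, h.subject_id))
        if len(passing) > top_n:
            cutoff = passing[top_n - 1].bitscore
            passing = [h for h in passing if h.bitscore >= cutoff]
        out[query] = passing
    return out


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Longest common rank-prefix of the input lineages."""
    if not lineages:
        raise ValueError("lca of no lineages")
    common: list[str] = []
    for labels in zip(*(lin.labels_with_none() for lin in lineages)):
        if labels[0] is not None and all(x == labels[0] for x in labels):
            common.append(labels[0])
        else:
            break
    return Lineage.from_labels(common)


def _rank_bucket(rank: str | None) -> str:
    if rank in ("species", "genus", "family", "order"):
        return rank
    if rank is None:
        return "unassigned"
    return "higher"


def assign_taxonomy(
    hits: Sequence[HitRecord],
    thresholds: RankThresholds | None = None,
    query_id: str | None = None,
) -> TaxonAssignment:
    """Assign one query from its filtered hits.

    The candidate lineage is the LCA of the hits tied at maximal bitscore;
    the identity compared against the rank thresholds is the maximum
    identity among those tied hits.  Species/genus/family are stripped
    when the identity falls below their thresholds; coarser ranks are
    retained as they already met the 80% search floor.
    """
    thresholds = thresholds or RankThresholds()
    if not hits:
        return TaxonAssignment(query_id or "", Lineage(), "unassigned", 0.0, 0)
    top_score = max(h.bitscore for h in hits)
    top = [h for h in hits if h.bitscore == top_score]
    candidate = lca([h.lineage for h in top])
    top_identity = max(h.identity for h in top)
    if top_identity >= thresholds.species_min:
        allowed = "species"
    elif top_identity >= thresholds.genus_min:
        allowed = "genus"
    elif top_identity >= thresholds.family_min:
        allowed = "family"
    else:
        allowed = "order"  # deepest rank allowed above the family threshold
    depth = min(
        RANKS.index(allowed),
        RANKS.index(candidate.deepest_rank()) if candidate.deepest_rank() else -1,
    )
    assigned = candidate.truncated_to(RANKS[depth] if depth >= 0 else None)
    return TaxonAssignment(
        query_id=hits[0].query_id,
        lineage=assigned,
        assigned_rank=_rank_bucket(assigned.deepest_rank()),
        top_identity=top_identity,
        n_tied_top_hits=len(top),
    )


def assign_all(
    filtered: Mapping[str, Sequence[HitRecord]],
    thresholds: RankThresholds | None = None,
) -> list[TaxonAssignment]:
    return [
        assign_taxonomy(qhits, thresholds, query_id=query)
        for query, qhits in sorted(filtered.items())
    ]


def exclude_nontarget(
    assignments: Iterable[TaxonAssignment],
    target_labels: frozenset[str] | set[str] = HEXAPOD_LABELS,
) -> tuple[list[TaxonAssignment], list[tuple[TaxonAssignment, str]]]:
    """Split assignments into hexapods and excluded records.

    A lineage is kept when any of its labels belongs to the target clade.
    Assignments with no resolved ranks at all (e.g. resolvable only to
    Metazoa) are excluded as ``too_general``; resolved non-hexapods
    (human, roe deer, ...) as ``nontarget``.
    """
    kept: list[TaxonAssignment] = []
    excluded: list[tuple[TaxonAssignment, str]] = []
    for a in assignments:
        labels = a.lineage.labels()
        if not labels:
            excluded.append((a, "too_general"))
        elif any(lbl in target_labels for lbl in labels):
            kept.append(a)
        else:
            excluded.append((a, "nontarget"))
    return kept, excluded


def tabulate_community(
    assignments: Iterable[TaxonAssignment],
    read_counts: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> CommunityMatrix:
    """Collapse assignments with identical lineages and tabulate reads.

    ``read_counts`` has columns query_id, sample_id, reads (per-sample
    read totals for each consensus).  Distinct queries assigned the same
    lineage become one taxon whose cell values are summed reads.
    """
    taxon_of: dict[str, str] = {}
    lineage_of: dict[str, Lineage] = {}
    for a in assignments:
        if a.assigned_rank == "unassigned":
            continue
        label = a.lineage.label()
        taxon_of[a.query_id] = label
        lineage_of[label] = a.lineage
    df = read_counts.copy()
    df["taxon"] = df["query_id"].map(taxon_of)
    df = df.dropna(subset=["taxon"])
    counts = (
        df.pivot_table(
            index="sample_id", columns="taxon", values="reads", aggfunc="sum", fill_value=0
        )
        .astype(int)
        .sort_index()
    )
    counts.columns.name = None
    if metadata is None:
        metadata = pd.DataFrame(index=counts.index)
    else:
        metadata = metadata.reindex(counts.index)
    return CommunityMatrix(counts=counts, metadata=metadata, lineages=lineage_of)


def rank_of(item: TaxonAssignment | Lineage) -> str:
    """Deepest present rank of an assignment or lineage."""
    lineage = item.lineage if isinstance(item, TaxonAssignment) else item
    return _rank_bucket(lineage.deepest_rank())


def naive_search(
    queries: Mapping[str, str],
    reference: Mapping[str, str],
    lineage_map: Mapping[str, Lineage],
    min_identity: float = 80.0,
) -> list[HitRecord]:
    """Exhaustive global-alignment search used as a transparent stand-in
    for an external similarity-search run on toy references.

    Every query is aligned against every reference sequence; the percent
    identity doubles as the score (so bitscore ties coincide with identity
    ties), coverage is 100 (global alignment) and the e-value 0.
    """
    hits: list[HitRecord] = []
    for qid, qseq in queries.items():
        for sid, sseq in reference.items():
            ident = pairwise_identity(qseq, sseq)
            if ident < min_identity:
                continue
            hits.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    lineage=lineage_map[sid],
                    identity=round(ident, 3),
                    coverage=100.0,
                    evalue=0.0,
                    bitscore=round(ident, 3),
                )
            )
    return hits
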