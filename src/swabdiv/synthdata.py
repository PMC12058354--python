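"""Synthetic inputs with known ground truth, plus the packaged published
incidence table.

The generators emulate the study's data shapes: a lineage-annotated 16S
reference (MIDORI2-style headers), ~215 bp nanopore-like amplicon reads
drawn from known per-sample communities, and habitat-structured
site-by-taxon matrices with a grassland > shrubs > forest richness
gradient and high between-habitat turnover.  Everything is
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster import pairwise_identity
from .io import Read
from .taxonomy import Lineage

__all__ = [
    "SimSpec",
    "GroundTruth",
    "Table2Fixture",
    "make_reference",
    "simulate_reads",
    "simulate_community_matrix",
    "load_table2_fixture",
    "HABITATS",
]

HABITATS = ("grassland", "shrubs", "forest")

_BASES = np.array(list("ACGT"))

_FIXTURE_NAME = "table2_hexapoda.tsv"
_FIXTURE_SHA256 = "629d1bc2b5c9d15e5e1f62c437f6a05a4ff979be5a6a0ccbd1e807757358ace6"


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic study.

    Defaults mirror the field design: three habitats sampled with 6/6/5
    replicates, ~215 bp amplicons, and per-base error rates totalling
    ~2% — representative of quality-filtered nanopore amplicon reads.
    Divergence dials for the reference tree guarantee the identity bands
    the rank thresholds act on: congeneric species within 2%, families
    more than 10% apart.
    """

    # reference tree shape
    n_orders: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    n_nontarget: int = 0  # extra mammal references to exercise exclusion
    amplicon_len: int = 215
    # per-base read error rates
    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.005
    low_quality_fraction: float = 0.1
    reads_per_taxon: int = 20
    # community structure
    n_samples: tuple[int, int, int] = (6, 6, 5)
    mean_richness: tuple[float, float, float] = (14.0, 8.0, 7.0)
    pool_sizes: tuple[int, int, int] = (48, 32, 21)
    pool_overlap: float = 0.15
    n_taxa: int = 76
    seed: int = 1

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0 <= r <= 0.2):
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.amplicon_len < 50:
            raise ValueError("amplicon_len must be >= 50")
        if not (0 <= self.pool_overlap <= 1):
            raise ValueError("pool_overlap must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually emitted, for end-to-end checks."""

    read_source: dict[str, tuple[str, str]]  # read_id -> (taxon_id, sample_id)
    communities: dict[str, Counter]  # sample_id -> taxon_id -> reads
    low_quality_reads: set[str]

    def total_reads(self) -> int:
        return sum(sum(c.values()) for c in self.communities.values())


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_substitutions(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Apply exactly n_sub substitutions at distinct positions."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=min(n_sub, len(arr)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def make_reference(
    spec: SimSpec | None = None, max_tries: int = 20
) -> tuple[list[tuple[str, str]], dict[str, Lineage], dict[str, str]]:
    """Build a lineage-annotated reference: one sequence per species.

    Family ancestors are mutated heavily from an order root, genus
    ancestors moderately from their family, species lightly from their
    genus, then the identity bands are verified with true global
    alignments and the whole tree rejection-sampled until they hold:
    within-genus identity >= 98%, between-family identity <= 90%.

    Returns (FASTA records as (header, sequence), subject_id -> Lineage,
    subject_id -> sequence).
    """
    spec = spec or SimSpec()
    L = spec.amplicon_len
    n_sub_family = max(int(0.15 * L), 1)
    n_sub_genus = max(int(0.04 * L), 1)
    n_sub_species = max(int(0.004 * L), 1)
    for attempt in range(max_tries):
        rng = np.random.default_rng(spec.seed + 7919 * attempt)
        records: list[tuple[str, str]] = []
        lineages: dict[str, Lineage] = {}
        seqs: dict[str, str] = {}
        family_ancestors: list[str] = []
        genus_groups: list[list[str]] = []
        k = 0
        for o in range(spec.n_orders):
            order_root = _random_seq(rng, L)
            order_name = f"Synthorder{o + 1}"
            for f in range(spec.families_per_order):
                fam_seq = _mutate_substitutions(rng, order_root, n_sub_family)
                family_ancestors.append(fam_seq)
                fam_name = f"Synthfam{o + 1}{chr(97 + f)}idae"
                for g in range(spec.genera_per_family):
                    gen_seq = _mutate_substitutions(rng, fam_seq, n_sub_genus)
                    gen_name = f"Synthgenus{o + 1}{chr(97 + f)}{g + 1}"
                    group: list[str] = []
                    for s in range(spec.species_per_genus):
                        sp_seq = _mutate_substitutions(rng, gen_seq, n_sub_species)
                        sp_name = f"{gen_name} sp{s + 1}"
                        k += 1
                        sid = f"SYN{k:04d}"
                        lineage = Lineage(
                            "Arthropoda", "Insecta", order_name, fam_name, gen_name, sp_name
                        )
                        header = (
                            f"{sid} root_1;Eukaryota_2759;Arthropoda_6656;Insecta_50557;"
                            f"{order_name}_{100 + o};{fam_name}_{200 + f};"
                            f"{gen_name}_{300 + g};{sp_name}_{400 + k}"
                        )
                        records.append((header, sp_seq))
                        lineages[sid] = lineage
                        seqs[sid] = sp_seq
                        group.append(sid)
                    genus_groups.append(group)
        for m in range(spec.n_nontarget):
            k += 1
            sid = f"SYN{k:04d}"
            seq = _random_seq(rng, L)
            name = f"Synthmammal sp{m + 1}"
            header = (
                f"{sid} root_1;Eukaryota_2759;Chordata_7711;Mammalia_40674;"
                f"Synthprimates_9443;Synthhominidae_9604;Synthmammal_9605;{name}_{500 + m}"
            )
            records.append((header, seq))
            lineages[sid] = Lineage(
                "Chordata", "Mammalia", "Synthprimates", "Synthhominidae", "Synthmammal", name
            )
            seqs[sid] = seq
        ok = all(
            pairwise_identity(seqs[a], seqs[b]) >= 98.0
            for group in genus_groups
            for i, a in enumerate(group)
            for b in group[i + 1 :]
        ) and all(
            pairwise_identity(fa, fb) <= 90.0
            for i, fa in enumerate(family_ancestors)
            for fb in family_ancestors[i + 1 :]
        )
        if ok:
            return records, lineages, seqs
    raise ValueError(
        "could not satisfy the divergence bands for the requested tree shape"
    )


def _mutate_read(rng: np.random.Generator, template: str, spec: SimSpec) -> str:
    out: list[str] = []
    for base in template:
        if rng.random() < spec.del_rate:
            pass  # deletion
        elif rng.random() < spec.sub_rate:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
        else:
            out.append(base)
        if rng.random() < spec.ins_rate:
            out.append(_BASES[rng.integers(4)])
    if not out:
        out.append(template[0])
    return "".join(out)


def simulate_reads(
    reference: Mapping[str, str],
    spec: SimSpec | None = None,
    communities: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[list[Read], GroundTruth]:
    """Draw nanopore-like reads from designated taxa.

    ``communities`` maps sample_id -> taxon_id -> read count; by default a
    single sample containing every reference taxon at
    ``spec.reads_per_taxon`` reads.  A ``low_quality_fraction`` of reads
    receives per-base qualities whose error-domain mean falls below the
    Q12 intake filter; all others sit safely above it.  Ground truth
    records every read's source taxon and sample.
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(spec.seed + 1)
    if communities is None:
        communities = {"sample1": {t: spec.reads_per_taxon for t in reference}}
    for sample, comm in communities.items():
        unknown = set(comm) - set(reference)
        if unknown:
            raise ValueError(f"sample {sample!r} references unknown taxa: {sorted(unknown)}")
    reads: list[Read] = []
    source: dict[str, tuple[str, str]] = {}
    emitted: dict[str, Counter] = {}
    low_quality: set[str] = set()
    i = 0
    for sample in sorted(communities):
        emitted[sample] = Counter()
        for taxon in sorted(communities[sample]):
            template = reference[taxon]
            for _ in range(int(communities[sample][taxon])):
                i += 1
                rid = f"read{i:06d}"
                seq = _mutate_read(rng, template, spec)
                is_low = rng.random() < spec.low_quality_fraction
                if is_low:
                    quals = rng.integers(2, 9, size=len(seq))
                    low_quality.add(rid)
                else:
                    quals = rng.integers(16, 31, size=len(seq))
                reads.append(Read(rid, seq, tuple(int(q) for q in quals), sample))
                source[rid] = (taxon, sample)
                emitted[sample][taxon] += 1
    return reads, GroundTruth(source, emitted, low_quality)


def simulate_community_matrix(
    spec: SimSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site x taxon read-count matrix with habitat-structured richness and
    turnover.

    Each habitat owns a taxon pool; a ``pool_overlap`` fraction of each
    pool is drawn from a shared core (overlap 1 makes all pools
    identical, 0 makes them disjoint).  Per-sample richness is Poisson
    around the habitat mean, and read counts are lognormal.  Metadata
    carries habitat, replicate (1-3), location (two per habitat) and
    time_of_day, mirroring the field design.

    Returns (counts indexed by sample, metadata sharing the index).
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(spec.seed + 2)
    taxa = [f"taxon{i + 1:03d}" for i in range(spec.n_taxa)]
    n_core = int(round(spec.pool_overlap * min(spec.pool_sizes)))
    core = list(rng.choice(spec.n_taxa, size=n_core, replace=False))
    remaining = [i for i in range(spec.n_taxa) if i not in set(core)]
    rng.shuffle(remaining)
    pools: dict[str, list[int]] = {}
    cursor = 0
    for habitat, size in zip(HABITATS, spec.pool_sizes):
        own = size - n_core
        if spec.pool_overlap >= 1.0:
            pools[habitat] = list(range(spec.n_taxa))[:size]
            continue
        take = remaining[cursor : cursor + own]
        if len(take) < own:  # wrap: exclusive taxa exhausted, reuse others
            take = take + remaining[: own - len(take)]
        cursor += own
        pools[habitat] = core + take
    rows = []
    meta_rows = []
    counts = {}
    s = 0
    for habitat, n_samp, mean_rich in zip(HABITATS, spec.n_samples, spec.mean_richness):
        pool = pools[habitat]
        for j in range(n_samp):
            s += 1
            sample = f"{habitat[:5]}_{j + 1}"
            rich = int(np.clip(rng.poisson(mean_rich), 1, len(pool)))
            chosen = rng.choice(pool, size=rich, replace=False)
            row = np.zeros(spec.n_taxa, dtype=int)
            row[chosen] = np.maximum(
                1, np.round(rng.lognormal(mean=4.0, sigma=1.5, size=rich))
            ).astype(int)
            counts[sample] = row
            meta_rows.append(
                {
                    "sample_id": sample,
                    "habitat": habitat,
                    "replicate": (j % 3) + 1,
                    "location": f"{habitat[:5]}_loc{(j // 3) + 1}",
                    "time_of_day": f"{9 + (s % 8)}:00",
                }
            )
    counts_df = pd.DataFrame.from_dict(counts, orient="index", columns=taxa)
    counts_df.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts_df, meta


@dataclass
class Table2Fixture:
    """The published taxon x habitat incidence/read table.

    76 hexapod taxa over 6 grassland, 6 shrub and 5 forest samples; the
    ``nb_*`` columns are incidence frequencies (number of samples in the
    habitat where the taxon was detected), the ``reads_*`` columns summed
    read counts.
    """

    table: pd.DataFrame
    samples_per_habitat: dict[str, int] = field(
        default_factory=lambda: {"grassland": 6, "shrubs": 6, "forest": 5}
    )

    def incidence(self, habitat: str) -> np.ndarray:
        return self.table[f"nb_{habitat}"].to_numpy(int)

    def reads(self, habitat: str) -> np.ndarray:
        return self.table[f"reads_{habitat}"].to_numpy(int)

    def n_samples(self, habitat: str) -> int:
        return self.samples_per_habitat[habitat]

    def richness(self, habitat: str) -> int:
        return int((self.incidence(habitat) > 0).sum())

    def rank_counts(self) -> dict[str, int]:
        return self.table["rank"].value_counts().to_dict()


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged incidence table, verifying its checksum."""
    data = (
        resources.files("swabdiv.data").joinpath(_FIXTURE_NAME).read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"fixture checksum mismatch: expected {_FIXTURE_SHA256}, got {digest}"
        )
    from io import StringIO

    df = pd.read_csv(StringIO(data.decode()), sep="\t")
    if len(df) != 76:
        raise ValueError(f"fixture must contain 76 taxa, found {len(df)}")
    return Table2Fixture(table=df)
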