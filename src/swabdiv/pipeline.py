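"""End-to-end orchestration: filter -> cluster -> assign -> tabulate ->
diversity, driven by a single flat configuration.

Every run embeds its resolved configuration in the JSON report so a run
is reproducible from the report alone; all stochastic stages derive from
one seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import cluster as clustermod
from . import ecodiv, io, taxonomy

logger = logging.getLogger("swabdiv")

__all__ = ["RunConfig", "run", "diversity_report", "habitat_accumulation"]


@dataclass
class RunConfig:
    """Flat run configuration; the defaults are the study's parameters."""

    # read filters
    min_mean_q: float = 12.0
    min_len: int = 115
    max_len: int = 315
    # clustering
    batch_size: int = 1000
    within_sim: float = 0.97
    merge_sim: float = 0.98
    min_cluster_size: int = 1
    # hit filtering / rank thresholds
    max_e: float = 1e-3
    min_identity: float = 80.0
    min_coverage: float = 80.0
    top_n: int = 20
    species_min: float = 98.0
    genus_min: float = 96.0
    family_min: float = 90.0
    # diversity layer
    alpha: float = 0.05
    target_power: float = 0.8
    effect_size: float = 0.75
    n_groups: int = 3
    n_permutations: int = 999
    seed: int = 1
    # stage toggles
    stages: tuple[str, ...] = ("filter", "cluster", "assign", "tabulate", "diversity")
    # paths (empty string = unset)
    manifest: str = ""
    reference_fasta: str = ""
    hits: str = ""
    out_dir: str = "swabdiv_out"

    def __post_init__(self) -> None:
        io.FilterSpec(self.min_mean_q, self.min_len, self.max_len)  # validates
        clustermod.ClusterParams(self.batch_size, self.within_sim, self.merge_sim, self.seed)
        taxonomy.RankThresholds(self.species_min, self.genus_min, self.family_min)
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` configuration file."""
        values: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (x.strip() for x in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key == "stages":
                values[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
            else:
                ftype = fields[key].type
                if ftype in ("int", int):
                    values[key] = int(raw)
                elif ftype in ("float", float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        return cls(**values)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def habitat_accumulation(
    incidence: Mapping[str, np.ndarray] | Mapping[str, list],
    n_samples: Mapping[str, int],
) -> dict[str, dict[str, Any]]:
    """Per habitat: exact rarefaction curve, all three accumulation-model
    fits, and the AIC-selected best fit."""
    out: dict[str, dict[str, Any]] = {}
    for habitat, y in incidence.items():
        T = int(n_samples[habitat])
        curve = ecodiv.rarefaction_curve(np.asarray(y, dtype=int), T)
        fits = [
            ecodiv.fit_accumulation(np.arange(1, T + 1), curve, model)
            for model in ecodiv.ACCUMULATION_MODELS
        ]
        best = ecodiv.select_best_model(fits)
        out[habitat] = {
            "n_samples": T,
            "richness": float(curve[-1]),
            "rarefaction": [round(float(v), 6) for v in curve],
            "fits": {
                f.model: {
                    "params": {k: round(v, 6) for k, v in f.params.items()},
                    "aic": round(f.aic, 6),
                    "rss": round(f.rss, 9),
                    "converged": f.converged,
                }
                for f in fits
            },
            "best_model": best.model,
            "asymptote": round(best.asymptote, 6),
        }
    return out


def diversity_report(
    community: taxonomy.CommunityMatrix, config: RunConfig
) -> dict[str, Any]:
    """The statistical layer on a community matrix with habitat metadata."""
    counts = community.counts
    meta = community.metadata
    report: dict[str, Any] = {}

    report["power_analysis"] = {
        "k": config.n_groups,
        "f": config.effect_size,
        "alpha": config.alpha,
        "target_power": config.target_power,
        "n_per_group": ecodiv.anova_power_n(
            config.n_groups, config.effect_size, config.alpha, config.target_power
        ),
    }

    pres = community.presence()
    report["per_sample"] = {
        sample: {
            "richness": int(ecodiv.hill_number(counts.loc[sample], 0)),
            "evenness_q1": round(ecodiv.hill_number(counts.loc[sample], 1), 6),
        }
        for sample in counts.index
        if counts.loc[sample].sum() > 0
    }

    if "habitat" in meta.columns and meta["habitat"].notna().any():
        habitats = meta["habitat"]
        incid = community.incidence()
        n_samples = habitats.value_counts().to_dict()
        report["accumulation"] = habitat_accumulation(
            {h: incid[h].to_numpy() for h in incid.columns},
            n_samples,
        )

    jac, jtu, jnes = ecodiv.beta_pair_matrices(pres)
    tri = np.triu_indices(len(jac), k=1)
    report["beta_diversity"] = {
        "mean_beta_jac": round(float(jac.to_numpy()[tri].mean()), 6),
        "mean_beta_jtu": round(float(jtu.to_numpy()[tri].mean()), 6),
        "mean_beta_jnes": round(float(jnes.to_numpy()[tri].mean()), 6),
    }

    terms = [
        t
        for t in ("habitat", "replicate", "time_of_day")
        if t in meta.columns and meta[t].nunique() >= 2 and len(meta) > meta[t].nunique() + 1
    ]
    if terms:
        for name, dm in (("beta_jac", jac), ("beta_jtu", jtu)):
            res = ecodiv.permanova(
                dm, meta, terms=terms, n_perm=config.n_permutations, seed=config.seed
            )
            report.setdefault("permanova", {})[name] = {
                term: {
                    "r2": round(res.r2[term], 6),
                    "pseudo_f": round(res.pseudo_f[term], 6),
                    "p": round(res.p[term], 6),
                }
                for term in res.terms
            } | {"residual_r2": round(res.residual_r2, 6)}
            ord_res = ecodiv.pcoa(dm)
            report.setdefault("pcoa", {})[name] = {
                "proportion_explained": [
                    round(float(v), 6) for v in ord_res.proportion_explained[:4]
                ],
                "n_negative_eigenvalues": int(len(ord_res.negative_eigenvalues)),
            }
    return report


def _stage_filter(config: RunConfig, out: Path) -> tuple[list[io.Read], pd.DataFrame, dict]:
    manifest = io.read_manifest(config.manifest)
    spec = io.FilterSpec(config.min_mean_q, config.min_len, config.max_len)
    kept_all: list[io.Read] = []
    rejected_all: list[tuple[io.Read, str]] = []
    n_in = 0
    base = Path(config.manifest).parent
    for row in manifest.itertuples():
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        reads = io.read_fastq(fpath, sample_id=row.sample_id)
        n_in += len(reads)
        kept, rejected = io.filter_reads(reads, spec)
        kept_all.extend(kept)
        rejected_all.extend(rejected)
    io.write_fastq(kept_all, out / "filtered.fastq")
    io.write_rejection_report(rejected_all, out / "rejected.tsv")
    reasons = pd.Series([r for _, r in rejected_all]).value_counts().to_dict()
    stats = {
        "reads_in": n_in,
        "reads_kept": len(kept_all),
        "reads_rejected": len(rejected_all),
        "rejection_reasons": {k: int(v) for k, v in reasons.items()},
    }
    meta = manifest.set_index("sample_id")
    return kept_all, meta, stats


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write a JSON report.

    Stage outputs land in ``config.out_dir``; the report records the read
    count surviving every stage, the cluster count, taxa by rank, and the
    diversity results.  Identical config + seed gives a byte-identical
    report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.to_dict(), "stages": {}}
    reads: list[io.Read] = []
    meta: pd.DataFrame | None = None
    clusters: list[clustermod.Cluster] = []
    community: taxonomy.CommunityMatrix | None = None

    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        if stage == "filter":
            reads, meta, stats = _stage_filter(config, out)
            report["stages"]["filter"] = stats
        elif stage == "cluster":
            params = clustermod.ClusterParams(
                config.batch_size, config.within_sim, config.merge_sim, config.seed
            )
            clusters = clustermod.cluster_reads(reads, params)
            clusters = [c for c in clusters if c.size >= config.min_cluster_size]
            sample_of = {r.id: r.sample_id for r in reads}
            clustermod.write_cluster_fasta(clusters, out / "consensus.fasta", sample_of)
            clustermod.write_membership_tsv(clusters, out / "membership.tsv")
            report["stages"]["cluster"] = {
                "reads_in": len(reads),
                "n_clusters": len(clusters),
                "reads_clustered": sum(c.size for c in clusters),
            }
        elif stage == "assign":
            lineage_map, assignments, stats = _stage_assign(config, clusters)
            report["stages"]["assign"] = stats
            report["_assignments"] = assignments
        elif stage == "tabulate":
            assignments = report.pop("_assignments", [])
            sample_of = {r.id: r.sample_id for r in reads}
            rows = []
            for c in clusters:
                per_sample = pd.Series(
                    [sample_of[rid] for rid in c.member_ids]
                ).value_counts()
                for sample, n in per_sample.items():
                    rows.append(
                        {"query_id": f"cluster_{c.id}", "sample_id": sample, "reads": int(n)}
                    )
            read_counts = pd.DataFrame(rows, columns=["query_id", "sample_id", "reads"])
            community = taxonomy.tabulate_community(assignments, read_counts, meta)
            community.to_tsv(out / "community_matrix.tsv")
            rank_tally = pd.Series(
                [taxonomy.rank_of(lin) for lin in community.lineages.values()]
            ).value_counts().to_dict()
            report["stages"]["tabulate"] = {
                "n_taxa": community.counts.shape[1],
                "n_samples": community.counts.shape[0],
                "taxa_by_rank": {k: int(v) for k, v in rank_tally.items()},
            }
        elif stage == "diversity":
            if community is None:
                raise ValueError("diversity stage requires a tabulated community")
            report["stages"]["diversity"] = diversity_report(community, config)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)

    report.pop("_assignments", None)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _stage_assign(config: RunConfig, clusters) -> tuple[dict, list, dict]:
    if not config.reference_fasta and not config.hits:
        raise ValueError("assign stage needs reference_fasta (naive search) or hits")
    consensus = {f"cluster_{c.id}": c.consensus for c in clusters}
    if config.hits:
        lineage_map = taxonomy.parse_lineage_fasta(config.reference_fasta)
        hits, unresolved = taxonomy.parse_hits(
            config.hits, lineage_map, query_lengths={q: len(s) for q, s in consensus.items()}
        )
    else:
        lineage_map = taxonomy.parse_lineage_fasta(config.reference_fasta)
        ref_seqs = _reference_seqs(config.reference_fasta)
        hits = taxonomy.naive_search(consensus, ref_seqs, lineage_map, config.min_identity)
        unresolved = []
    filtered = taxonomy.filter_hits(
        hits, config.max_e, config.min_identity, config.min_coverage, config.top_n
    )
    thresholds = taxonomy.RankThresholds(
        config.species_min, config.genus_min, config.family_min
    )
    assignments = taxonomy.assign_all(filtered, thresholds)
    kept, excluded = taxonomy.exclude_nontarget(assignments)
    stats = {
        "queries_with_hits": len([a for a in assignments if a.assigned_rank != "unassigned"]),
        "queries_total": len(consensus),
        "unresolved_subjects": len(unresolved),
        "assignments_kept": len(kept),
        "assignments_excluded": len(excluded),
    }
    return lineage_map, kept, stats


def _reference_seqs(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    sid = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if sid is not None:
                    seqs[sid] = "".join(chunks)
                sid = line[1:].split(None, 1)[0].split("###", 1)[0]
                chunks = []
            else:
                chunks.append(line.strip())
    if sid is not None:
        seqs[sid] = "".join(chunks)
    return seqs
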