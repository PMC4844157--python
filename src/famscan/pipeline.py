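"""End-to-end orchestration: simulate -> ingest -> align -> classify ->
homology -> phylo -> express -> report.

Each stage is a pure function of (on-disk inputs, config, seed): it reads
the outputs of upstream stages from the working directory, writes its own
outputs with a provenance header (version, seed, thresholds), and raises
:class:`PipelineError` naming the missing stage when run out of order.
Re-running with the same config and seed reproduces every output file
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, align, domains, homology, phylo, seqio
from .expression import ReadSet, fold_changes, quantify, responses_table, specificity_summary
from .synthetic_data import SimConfig, simulate

log = logging.getLogger("famscan")


class PipelineError(RuntimeError):
    """A stage was run without its upstream inputs, or a stage failed."""


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the workflow in one serializable object."""

    seed: int = 7
    out_dir: str = "famscan_out"
    cluster_identity_min: float = 90.0
    duplication_identity_min: float = 80.0
    evalue_max: float = 1e-10
    td_window_bp: int = 5_000_000
    fold_pseudocount: float = 0.1
    bootstrap_reps: int = 1000
    kmer_k: int = 5
    kmer_min_shared: int = 25
    prefilter: bool = True
    multimap: str = "fractional"
    top_n: int = 10
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        for name in ("cluster_identity_min", "duplication_identity_min",
                     "evalue_max", "td_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.sim.seed = self.seed

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def provenance(self) -> list[str]:
        return [
            f"famscan {__version__}",
            f"seed={self.seed}",
            f"cluster_identity_min={self.cluster_identity_min} "
            f"duplication_identity_min={self.duplication_identity_min} "
            f"evalue_max={self.evalue_max} td_window_bp={self.td_window_bp}",
        ]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing input {path.name!r}: run the {stage!r} stage first"
        )
    return path


FAMILY_PREFIX = {"L_LRK": "L-LRK", "B_LRK": "B-LRK", "C_LRK": "C-LRK"}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, root: Path) -> None:
    log.info("simulate: seed=%d n_families=%d", cfg.seed, cfg.sim.n_families)
    simulate(cfg.sim, out_dir=root / "sim")


def _load_genome(root: Path, stage_hint: str = "simulate") -> seqio.GenomeSet:
    sim = root / "sim"
    gff = _require(sim / "speciesA.gff3", stage_hint)
    cds = seqio.read_fasta(_require(sim / "speciesA.cds.fa", stage_hint))
    prot = seqio.read_fasta(_require(sim / "speciesA.protein.fa", stage_hint))
    return seqio.read_gff3(gff, cds, prot, species_label="speciesA")


def stage_ingest(cfg: PipelineConfig, root: Path) -> None:
    genome = _load_genome(root)
    out = root / "ingest"
    seqio.write_tsv_tables(
        {"genes": seqio.gene_table(genome)}, out, cfg.provenance()
    )
    log.info("ingest: %d gene models", len(genome))


def stage_allvsall(cfg: PipelineConfig, root: Path) -> None:
    sim = root / "sim"
    prot_a = seqio.read_fasta(_require(sim / "speciesA.protein.fa", "simulate"))
    prot_b = seqio.read_fasta(_require(sim / "speciesB.protein.fa", "simulate"))
    hits_self = align.all_vs_all(
        prot_a, k=cfg.kmer_k, min_shared=cfg.kmer_min_shared, prefilter=cfg.prefilter
    )
    hits_ab = align.search(
        prot_a, prot_b, k=cfg.kmer_k, min_shared=cfg.kmer_min_shared,
        prefilter=cfg.prefilter,
    )
    hits_ba = align.search(
        prot_b, prot_a, k=cfg.kmer_k, min_shared=cfg.kmer_min_shared,
        prefilter=cfg.prefilter,
    )
    seqio.write_tsv_tables(
        {"hits_self": hits_self, "hits_ab": hits_ab, "hits_ba": hits_ba},
        root / "align",
        cfg.provenance(),
    )
    log.info("allvsall: %d within-species pairs", len(hits_self))


def stage_classify(cfg: PipelineConfig, root: Path) -> None:
    sim = root / "sim"
    prot = seqio.read_fasta(_require(sim / "speciesA.protein.fa", "simulate"))
    models = domains.load_packaged_models()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assignments = domains.classify_proteins(prot, models)
    fam_rows = []
    hit_rows = []
    mw_rows = []
    for gid, a in assignments.items():
        fam_rows.append(
            {"gene_id": gid, "family": a.family, "ambiguous": int(a.ambiguous)}
        )
        for h in a.evidence:
            hit_rows.append(
                {"gene_id": gid, "domain_id": h.domain_id, "start": h.start,
                 "end": h.end, "score": h.score}
            )
        try:
            mw, pi = domains.compute_mw_pi(prot[gid])
            mw_rows.append({"gene_id": gid, "mw_da": round(mw, 2), "pi": round(pi, 2)})
        except ValueError:
            mw_rows.append({"gene_id": gid, "mw_da": float("nan"), "pi": float("nan")})
    stats = domains.domain_length_stats(assignments.values())
    seqio.write_tsv_tables(
        {
            "families": pd.DataFrame(fam_rows),
            "domain_hits": pd.DataFrame(hit_rows),
            "domain_stats": stats,
            "mw_pi": pd.DataFrame(mw_rows),
        },
        root / "classify",
        cfg.provenance(),
    )
    n = sum(1 for a in assignments.values() if a.family != "none")
    log.info("classify: %d LRK genes of %d proteins", n, len(prot))


def _load_families(root: Path) -> pd.DataFrame:
    return seqio.read_tsv_table(_require(root / "classify" / "families.tsv", "classify"))


def stage_homology(cfg: PipelineConfig, root: Path) -> None:
    hits = seqio.read_tsv_table(_require(root / "align" / "hits_self.tsv", "allvsall"))
    hits_ab = seqio.read_tsv_table(_require(root / "align" / "hits_ab.tsv", "allvsall"))
    hits_ba = seqio.read_tsv_table(_require(root / "align" / "hits_ba.tsv", "allvsall"))
    families = _load_families(root)
    genome = _load_genome(root)
    prot = genome.proteins()

    all_clusters = []
    for fam in ("L_LRK", "B_LRK", "C_LRK"):
        fam_genes = families.loc[families["family"] == fam, "gene_id"].tolist()
        if not fam_genes:
            continue
        clusters = homology.cluster_homologs(
            hits, fam_genes, identity_min=cfg.cluster_identity_min,
            evalue_max=cfg.evalue_max, family=fam,
        )
        clusters = homology.assign_nomenclature(clusters, FAMILY_PREFIX[fam], prot)
        all_clusters.extend(clusters)

    lrk_ids = set(families.loc[families["family"] != "none", "gene_id"])
    lrk_hits = hits[hits["query"].isin(lrk_ids) & hits["subject"].isin(lrk_ids)]
    events = homology.find_duplications(
        genome, lrk_hits, identity_min=cfg.duplication_identity_min,
        evalue_max=cfg.evalue_max, window_bp=cfg.td_window_bp,
    )
    pairs = homology.find_orthologs(hits_ab, hits_ba, evalue_max=cfg.evalue_max)
    seqio.write_tsv_tables(
        {
            "clusters": homology.clusters_table(all_clusters),
            "duplications": homology.duplications_table(events),
            "orthologs": homology.orthologs_table(pairs),
        },
        root / "homology",
        cfg.provenance(),
    )
    log.info(
        "homology: %d clusters, %d duplication events, %d ortholog pairs",
        len(all_clusters), len(events), len(pairs),
    )


def stage_phylo(cfg: PipelineConfig, root: Path) -> None:
    families = _load_families(root)
    prot = seqio.read_fasta(_require(root / "sim" / "speciesA.protein.fa", "simulate"))
    out = root / "phylo"
    out.mkdir(parents=True, exist_ok=True)
    for fam in ("L_LRK", "B_LRK", "C_LRK"):
        fam_genes = families.loc[families["family"] == fam, "gene_id"].tolist()
        if len(fam_genes) < 3:
            continue
        seqs = {g: prot[g] for g in fam_genes}
        msa = phylo.center_star_msa(seqs)
        tree, _ = phylo.bootstrap(msa, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
        msa.to_fasta(out / f"{fam}.msa.fa")
        phylo.write_newick(tree, out / f"{fam}.tree.nwk")
        log.info("phylo: %s tree over %d taxa (%d reps)", fam, len(fam_genes),
                 cfg.bootstrap_reps)


def _read_fastq_reads(path: Path) -> list[str]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [seq for _, seq, _ in FastqGeneralIterator(fh)]


def load_read_sets(reads_dir: Path, samples_tsv: Path) -> list[ReadSet]:
    """Rebuild ReadSets from a reads directory plus sample sheet."""
    meta = pd.read_csv(samples_tsv, sep="\t")
    read_sets = []
    for row in meta.itertuples(index=False):
        fq = reads_dir / f"{row.sample_id}.fq"
        _require(fq, "simulate")
        read_sets.append(
            ReadSet(
                sample_id=row.sample_id,
                organ=str(row.organ) if not pd.isna(row.organ) else "",
                stage=str(row.stage) if not pd.isna(row.stage) else "",
                stress=str(row.stress) if not pd.isna(row.stress) else "",
                timepoint=str(row.timepoint) if not pd.isna(row.timepoint) else "",
                replicate=int(row.replicate),
                reads=_read_fastq_reads(fq),
                library_total=int(row.library_total) or None,
            )
        )
    return read_sets


def _contrasts_from_samples(meta: pd.DataFrame) -> dict[str, tuple[list[str], list[str]]]:
    """Pair stress samples with their mock control at the same timepoint."""
    contrasts = {}
    stress_rows = meta[(meta["stress"] != "") & ~meta["stress"].isna()]
    for (stress, tp), grp in stress_rows.groupby(["stress", "timepoint"]):
        if stress == "mock":
            continue
        controls = stress_rows[
            (stress_rows["stress"] == "mock") & (stress_rows["timepoint"] == tp)
        ]["sample_id"].tolist()
        if not controls:
            continue
        contrasts[f"{stress}_{tp}"] = (sorted(grp["sample_id"]), sorted(controls))
    return dict(sorted(contrasts.items()))


def stage_express(cfg: PipelineConfig, root: Path) -> None:
    sim = root / "sim"
    families = _load_families(root)
    cds = seqio.read_fasta(_require(sim / "speciesA.cds.fa", "simulate"))
    lrk_ids = families.loc[families["family"] != "none", "gene_id"].tolist()
    transcripts = {g: cds[g] for g in lrk_ids}
    read_sets = load_read_sets(sim / "reads", _require(sim / "samples.tsv", "simulate"))
    mat = quantify(read_sets, transcripts, multimap=cfg.multimap)

    responses = []
    for label, contrast in _contrasts_from_samples(mat.samples).items():
        responses.extend(
            fold_changes(mat, contrast, pseudocount=cfg.fold_pseudocount, label=label)
        )
    genome = _load_genome(root)
    spec = specificity_summary(mat, top_n=cfg.top_n, genome=genome)

    rpkm_out = mat.rpkm.rename_axis("gene_id").reset_index()
    counts_out = mat.counts.rename_axis("gene_id").reset_index()
    log2_out = np.log2(mat.rpkm + 1.0).rename_axis("gene_id").reset_index()
    seqio.write_tsv_tables(
        {
            "rpkm_matrix": rpkm_out,
            "counts": counts_out,
            "log2_matrix": log2_out,
            "fold_changes": responses_table(responses),
            "top_genes": spec["top_genes"],
            "top_gene_placement": spec["top_gene_placement"],
        },
        root / "express",
        cfg.provenance(),
    )
    log.info("express: %d genes x %d samples", *mat.rpkm.shape)


def stage_report(cfg: PipelineConfig, root: Path) -> None:
    families = _load_families(root)
    genes = seqio.read_tsv_table(_require(root / "ingest" / "genes.tsv", "ingest"))
    clusters = seqio.read_tsv_table(_require(root / "homology" / "clusters.tsv", "homology"))
    dups = seqio.read_tsv_table(_require(root / "homology" / "duplications.tsv", "homology"))
    orthos = seqio.read_tsv_table(_require(root / "homology" / "orthologs.tsv", "homology"))
    fcs = seqio.read_tsv_table(_require(root / "express" / "fold_changes.tsv", "express"))

    merged = genes.merge(families, on="gene_id")
    lrk = merged[merged["family"] != "none"]
    fam_counts = lrk.groupby("family").size().rename("n_genes").reset_index()
    subg = (
        lrk.groupby(["family", "sub_genome"]).size().rename("n_genes").reset_index()
    )
    cluster_sizes = clusters.groupby(["family", "cluster_id"]).size()
    cl_rows = []
    for fam in sorted(set(clusters["family"])):
        sizes = cluster_sizes[fam]
        cl_rows.append(
            {"family": fam, "n_clusters": len(sizes),
             "n_multi_member": int((sizes >= 2).sum()),
             "n_singletons": int((sizes == 1).sum())}
        )
    dup_counts = dups.groupby("category").size().rename("n_events").reset_index()
    affected = (
        fcs[fcs["direction"] != "unaffected"]
        .groupby(["contrast", "direction"]).size().rename("n_genes").reset_index()
    )

    summary_rows = [
        {"metric": "n_gene_models", "value": len(genes)},
        {"metric": "n_lrk_genes", "value": len(lrk)},
    ]
    for r in fam_counts.itertuples(index=False):
        summary_rows.append({"metric": f"n_{r.family}", "value": r.n_genes})
    for r in cl_rows:
        summary_rows.append(
            {"metric": f"n_clusters_{r['family']}", "value": r["n_clusters"]}
        )
    for r in dup_counts.itertuples(index=False):
        summary_rows.append({"metric": f"n_dup_{r.category}", "value": r.n_events})
    summary_rows.append({"metric": "n_ortholog_pairs", "value": len(orthos)})

    out = root / "report"
    seqio.write_tsv_tables(
        {
            "summary": pd.DataFrame(summary_rows),
            "family_subgenome_distribution": subg,
            "cluster_summary": pd.DataFrame(cl_rows),
            "stress_affected": affected,
        },
        out,
        cfg.provenance(),
    )
    with open(out / "summary.txt", "w") as fh:
        for line in cfg.provenance():
            fh.write(f"# {line}\n")
        fh.write("Gene-family survey summary\n")
        fh.write("==========================\n")
        for row in summary_rows:
            fh.write(f"{row['metric']}: {row['value']}\n")
    log.info("report: written to %s", out)


STAGES = [
    ("simulate", stage_simulate),
    ("ingest", stage_ingest),
    ("allvsall", stage_allvsall),
    ("classify", stage_classify),
    ("homology", stage_homology),
    ("phylo", stage_phylo),
    ("express", stage_express),
    ("report", stage_report),
]


def run_all(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage in order into ``out_dir`` (default from config)."""
    root = Path(out_dir or cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        log.info("=== stage %s ===", name)
        fn(cfg, root)
    return root
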