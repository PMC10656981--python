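"""Pipeline driver: digest -> build-db -> quantify -> diversity -> biomarker.

A :class:`RunConfig` collects every input path, parameter, and seed;
:func:`run_pipeline` executes the five stages, writes all stage outputs
under ``outdir``, and produces a machine-readable ``report.json`` with
the configuration, per-stage outputs, and content hashes, so a rerun
with the same configuration is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biomarker import ensemble_importance, indval, lefse_lite, roc_auc
from .ecology import (AbundanceStudy, BETA_METRICS, alpha_diversity_table,
                      beta_distance, permanova, venn_counts)
from .enzymes import EnzymeSpec, extract_tags, get_enzyme
from .io import (iter_genome_files, read_fasta, read_metadata, read_reads,
                 write_table)
from .markers import build_database, read_taxonomy, save_database
from .quantify import profile_sample, profiles_to_matrices

logger = logging.getLogger(__name__)

STAGES = ("digest", "build-db", "quantify", "diversity", "biomarker")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    genomes: str  # directory or FASTA file
    taxonomy: str | None
    reads: dict[str, str]  # sample id -> reads file
    metadata: str | None
    outdir: str
    enzyme: str = "BcgI"
    g_threshold: float = 5.0
    denominator_mode: str = "database"
    n_perm: int = 999
    n_trees: int = 500
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on the configured inputs; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enzyme: EnzymeSpec = get_enzyme(config.enzyme)
    report: dict = {
        "package": "twobradm",
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], **extra) -> None:
        report["stages"].append({
            "stage": stage,
            "outputs": {p.name: _md5(p) for p in outputs},
            **extra,
        })

    # ---- digest -------------------------------------------------------
    stage = "digest"
    try:
        tags_by_genome = {}
        rows = []
        for path in iter_genome_files(config.genomes):
            gid = path.name
            for suffix in (".gz", ".fa", ".fasta", ".fna"):
                gid = gid.removesuffix(suffix)
            tags = extract_tags(read_fasta(path), enzyme, genome_id=gid)
            tags_by_genome[gid] = tags
            rows.extend((t.sequence, t.genome_id, t.contig, t.start, t.strand)
                        for t in tags)
        tag_table = pd.DataFrame(
            rows, columns=["canonical_sequence", "genome_id", "contig",
                           "start", "strand"])
        tags_path = outdir / "tags.tsv"
        write_table(tag_table, tags_path, index=False)
        record(stage, [tags_path], n_genomes=len(tags_by_genome),
               n_tags=len(tag_table))
    except Exception as e:
        raise PipelineError(f"stage {stage} failed: {e}") from e

    # ---- build-db -----------------------------------------------------
    stage = "build-db"
    try:
        if not config.taxonomy:
            raise ValueError("no taxonomy file configured")
        taxonomy = read_taxonomy(config.taxonomy)
        db = build_database(tags_by_genome, taxonomy, enzyme)
        db_path = outdir / "marker_db.tsv"
        save_database(db, db_path)
        record(stage, [db_path], n_markers=len(db),
               n_species=len(db.species_marker_count))
    except Exception as e:
        raise PipelineError(f"stage {stage} failed: {e}") from e

    # ---- quantify -----------------------------------------------------
    stage = "quantify"
    try:
        if not config.reads:
            raise ValueError("no read files configured")
        profiles = []
        for sample_id, reads_path in sorted(config.reads.items()):
            reads = read_reads(reads_path)
            profiles.append(profile_sample(
                reads, db, sample_id=sample_id, threshold=config.g_threshold,
                denominator_mode=config.denominator_mode))
        profile_rows = []
        for p in profiles:
            df = p.to_frame()
            df.insert(0, "sample", p.sample_id)
            profile_rows.append(df)
        profiles_path = outdir / "profiles.tsv"
        write_table(pd.concat(profile_rows, ignore_index=True), profiles_path,
                    index=False)
        abundance, counts = profiles_to_matrices(profiles)
        ab_path = outdir / "abundance_matrix.tsv"
        ct_path = outdir / "count_matrix.tsv"
        write_table(abundance, ab_path)
        write_table(counts, ct_path)
        record(stage, [profiles_path, ab_path, ct_path], n_samples=len(profiles))
    except Exception as e:
        raise PipelineError(f"stage {stage} failed: {e}") from e

    # ---- diversity ----------------------------------------------------
    stage = "diversity"
    try:
        if not config.metadata:
            raise ValueError("no metadata file configured")
        groups = read_metadata(config.metadata)
        kingdom = pd.Series({taxonomy[g].species: taxonomy[g].kingdom
                             for g in taxonomy})
        study = AbundanceStudy(matrix=abundance, counts=counts, groups=groups,
                               kingdom=kingdom)
        outputs = []
        alpha = alpha_diversity_table(study)
        alpha_path = outdir / "alpha_diversity.tsv"
        write_table(alpha, alpha_path)
        outputs.append(alpha_path)
        perm_rows = []
        for metric in BETA_METRICS:
            dm = beta_distance(study, metric)
            dm_path = outdir / f"distance_{metric}.tsv"
            write_table(dm.to_data_frame(), dm_path)
            outputs.append(dm_path)
            if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
                res = permanova(dm, groups, n_perm=config.n_perm,
                                seed=config.seed)
                perm_rows.append((metric, res.pseudo_f, res.p_value,
                                  res.n_permutations))
        if perm_rows:
            perm_path = outdir / "permanova.tsv"
            write_table(pd.DataFrame(
                perm_rows, columns=["metric", "pseudo_F", "p_value", "n_perm"]),
                perm_path, index=False)
            outputs.append(perm_path)
        if groups.nunique() == 2:
            vc = venn_counts(study)
            venn_path = outdir / "venn_counts.tsv"
            write_table(pd.DataFrame(
                [(vc.group_a, vc.group_b, vc.shared, vc.unique_a, vc.unique_b)],
                columns=["group_a", "group_b", "shared", "unique_a", "unique_b"]),
                venn_path, index=False)
            outputs.append(venn_path)
        record(stage, outputs)
    except Exception as e:
        raise PipelineError(f"stage {stage} failed: {e}") from e

    # ---- biomarker ----------------------------------------------------
    stage = "biomarker"
    try:
        outputs = []
        iv = indval(study, n_perm=config.n_perm, seed=config.seed)
        iv_path = outdir / "indval.tsv"
        write_table(pd.DataFrame(
            [(r.species, r.group, r.A, r.B, r.indval, r.p) for r in iv],
            columns=["species", "group", "A", "B", "indval", "p"]),
            iv_path, index=False)
        outputs.append(iv_path)
        ef = lefse_lite(study)
        ef_path = outdir / "effect_sizes.tsv"
        write_table(pd.DataFrame(
            [(r.species, r.kw_p, r.enriched_group, r.lda_like_score) for r in ef],
            columns=["species", "kw_p", "enriched_group", "lda_like_score"]),
            ef_path, index=False)
        outputs.append(ef_path)
        imp = ensemble_importance(study, n_trees=config.n_trees, seed=config.seed)
        imp_path = outdir / "importance.tsv"
        write_table(pd.DataFrame(
            [(r.species, r.mean_decrease_gini, r.mean_decrease_accuracy)
             for r in imp],
            columns=["species", "mean_decrease_gini", "mean_decrease_accuracy"]),
            imp_path, index=False)
        outputs.append(imp_path)
        top = imp[0].species
        labels = study.group_labels()
        auc, curve = roc_auc(study.matrix.loc[top].to_numpy(),
                             study.groups.to_numpy(), positive=labels[0])
        roc_path = outdir / "roc_top_species.tsv"
        write_table(curve, roc_path, index=False)
        outputs.append(roc_path)
        record(stage, outputs, top_species=top, auc=auc)
    except Exception as e:
        raise PipelineError(f"stage {stage} failed: {e}") from e

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d stages, report at %s",
                len(report["stages"]), report_path)
    return report
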