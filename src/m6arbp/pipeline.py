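"""End-to-end orchestration: consensus -> overlap -> enrichment -> classifier
-> association, driven by a YAML config, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, classifier, consensus, enrichment, io
from .core import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genes: str
    samples: str
    sites: str
    expression: str | None = None
    expression_transcript: str | None = None
    ppi: str | None = None
    effectors: list[str] = field(default_factory=list)
    bin_size: int = 200
    min_replicate_frac: float = 0.6
    min_studies: int = 3
    n_perm: int = 1000
    min_ratio: float = 1.3
    max_fdr: float = 0.05
    pseudo: bool = False
    classifier: classifier.ClassifierConfig = field(
        default_factory=classifier.ClassifierConfig
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        clf = classifier.ClassifierConfig(**raw.pop("classifier", {}))
        cfg = cls(classifier=clf, **raw)
        cfg.base_dir = Path(path).parent
        return cfg

    base_dir: Path = Path(".")

    def _resolve(self, p: str | None) -> Path | None:
        if p is None:
            return None
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q

    def validate(self) -> None:
        if self.bin_size < 1:
            raise ParameterError("bin_size must be >= 1")
        if not 0.0 < self.min_replicate_frac <= 1.0:
            raise ParameterError("min_replicate_frac must be in (0, 1]")
        if self.min_studies < 1:
            raise ParameterError("min_studies must be >= 1")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if not 0.0 <= self.max_fdr <= 1.0:
            raise ParameterError("max_fdr must be in [0, 1]")
        for attr in ("genes", "samples", "sites", "expression",
                     "expression_transcript", "ppi"):
            p = self._resolve(getattr(self, attr))
            if getattr(self, attr) is not None and not Path(p).exists():
                raise InputError(f"{attr} file not found: {p}")
        n_studies = pd.read_csv(self._resolve(self.samples), sep="\t")["study_id"].nunique()
        if self.min_studies > n_studies:
            raise ParameterError(
                f"min_studies={self.min_studies} exceeds available studies ({n_studies})"
            )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        return False


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory.

    Writes: regions.bed, consensus_summary.tsv, enrichment.tsv, enriched.tsv,
    co_overlap.tsv, classifier_runs.tsv, importance.tsv, roc_grid.tsv,
    similarity.tsv, dendrogram.nwk, correlation/*.tsv (if expression given),
    and manifest.json recording parameters, seed and input checksums.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _StageTimer("consensus"):
        genes = io.read_genes_bed12(cfg._resolve(cfg.genes))
        bins = consensus.bin_transcriptome(genes, bin_size=cfg.bin_size)
        pcm = io.read_peak_calls(cfg._resolve(cfg.samples), bins)
        regions = consensus.call_consensus(
            pcm, min_replicate_frac=cfg.min_replicate_frac, min_studies=cfg.min_studies
        )
        io.write_regions_bed(regions, outdir / "regions.bed")
        consensus.consensus_summary(
            pcm, cfg.min_replicate_frac, cfg.min_studies
        ).to_csv(outdir / "consensus_summary.tsv", sep="\t", index=False)
        if not regions:
            raise InputError("consensus produced no reproducible regions")

    with _StageTimer("overlap"):
        sites = io.read_sites_bed(cfg._resolve(cfg.sites))
        pool = enrichment.build_control_pool(bins, regions)
        bm_m6a = enrichment.overlap_matrix(regions, sites)
        bm_pool = enrichment.overlap_matrix(pool.regions, sites)

    with _StageTimer("enrichment"):
        results = enrichment.enrichment_test(
            bm_m6a, bm_pool, pool, n_perm=cfg.n_perm, seed=cfg.seed, pseudo=cfg.pseudo
        )
        enrichment.results_to_frame(results).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        enriched = enrichment.filter_enriched(
            results, min_ratio=cfg.min_ratio, max_fdr=cfg.max_fdr
        )
        enrichment.results_to_frame(enriched).to_csv(
            outdir / "enriched.tsv", sep="\t", index=False
        )
        enrichment.co_overlap_table(bm_m6a, [r.rbp for r in enriched]).to_csv(
            outdir / "co_overlap.tsv", sep="\t", index=False
        )

    with _StageTimer("classifier"):
        clf_cfg = cfg.classifier
        if clf_cfg.seed == 0 and cfg.seed != 0:
            clf_cfg.seed = cfg.seed
        runs = classifier.run_control_sets(bm_m6a, bm_pool, pool, clf_cfg)
        pd.DataFrame(
            [
                {
                    "control_set_id": r.control_set_id, "tp": r.tp, "tn": r.tn,
                    "fp": r.fp, "fn": r.fn, "accuracy": r.accuracy,
                    "cv_accuracy": r.cv_accuracy, "auroc": r.auroc,
                }
                for r in runs
            ]
        ).to_csv(outdir / "classifier_runs.tsv", sep="\t", index=False)
        summary = classifier.aggregate_runs(runs)
        summary.mean_importance.rename("mean_importance").to_csv(
            outdir / "importance.tsv", sep="\t"
        )
        summary.roc_grid.to_csv(outdir / "roc_grid.tsv", sep="\t", index=False)

    with _StageTimer("association"):
        sim = association.cosine_matrix(bm_m6a)
        sim.to_csv(outdir / "similarity.tsv", sep="\t")
        usable = sim.index[~sim.isna().all(axis=1)]
        meta: dict = {}
        if len(usable) >= 2:
            order, _, newick = association.cluster_order(sim.loc[usable, usable])
            (outdir / "dendrogram.nwk").write_text(newick + "\n")
            meta["leaf_order"] = order
            meta["linkage"] = "average"
            meta["distance"] = "1 - cosine"
        if cfg.expression is not None and cfg.effectors:
            _correlate_stage(cfg, [r.rbp for r in enriched], list(bm_m6a.rbps), outdir)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "bin_size": cfg.bin_size,
            "min_replicate_frac": cfg.min_replicate_frac,
            "min_studies": cfg.min_studies,
            "n_perm": cfg.n_perm,
            "min_ratio": cfg.min_ratio,
            "max_fdr": cfg.max_fdr,
            "pseudo": cfg.pseudo,
            "classifier": {
                "n_control_sets": cfg.classifier.n_control_sets,
                "train_frac": cfg.classifier.train_frac,
                "cv_folds": cfg.classifier.cv_folds,
                "mtry": cfg.classifier.mtry,
                "n_trees": cfg.classifier.n_trees,
                "seed": cfg.classifier.seed,
            },
        },
        "inputs": {
            attr: {"path": str(cfg._resolve(getattr(cfg, attr))),
                   "sha256_16": _checksum(cfg._resolve(getattr(cfg, attr)))}
            for attr in ("genes", "samples", "sites", "expression",
                         "expression_transcript", "ppi")
            if getattr(cfg, attr) is not None
        },
        "counts": {
            "n_bins": len(bins),
            "n_regions": len(regions),
            "n_pool": len(pool.regions),
            "n_rbps": len(bm_m6a.rbps),
            "n_enriched": len(enriched),
        },
        "association_meta": meta,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def _correlate_stage(
    cfg: RunConfig, enriched_rbps: list[str], all_rbps: list[str], outdir: Path
) -> None:
    expr = io.read_expression_tsv(cfg._resolve(cfg.expression), level="protein")
    others = [r for r in all_rbps if r not in enriched_rbps]
    rows = []
    for eff in cfg.effectors:
        if eff not in list(expr.entities):
            logger.warning("effector %s absent from expression table; skipped", eff)
            continue
        grp_a = [r for r in enriched_rbps if r != eff]
        grp_b = [r for r in others if r != eff]
        rho_a = association.spearman_to_effector(expr, eff, grp_a)
        rho_b = association.spearman_to_effector(expr, eff, grp_b)
        rho_a.rename("rho").to_frame().assign(group="associated").to_csv(
            outdir / f"rho_{eff}_associated.tsv", sep="\t"
        )
        rho_b.rename("rho").to_frame().assign(group="other").to_csv(
            outdir / f"rho_{eff}_other.tsv", sep="\t"
        )
        try:
            cmp = association.compare_groups(
                rho_a.to_numpy(), rho_b.to_numpy(), "a_greater", effector=eff
            )
            rows.append(
                {
                    "effector": eff, "level": expr.level, "n_a": cmp.n_a, "n_b": cmp.n_b,
                    "p_value": cmp.p_value, "method": cmp.method,
                }
            )
        except ParameterError as exc:
            logger.warning("effector %s: comparison skipped (%s)", eff, exc)
    pd.DataFrame(rows).to_csv(outdir / "correlation_comparison.tsv", sep="\t", index=False)
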