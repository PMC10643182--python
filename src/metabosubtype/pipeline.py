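"""End-to-end discovery pipeline: simulate -> normalize -> screen -> subtype
-> train -> report, as one reproducible config-driven run.

A single global seed deterministically derives one seed per stage
(``stage_seed``), so re-running the same config reproduces every artifact
byte for byte.  Each stage writes its outputs under the run directory and
the run closes with a manifest (parameters, stage seeds, artifact
checksums); a stage failure aborts with the stage name while keeping the
artifacts already written.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_norm import (ClinicalTable, log_transform,
                      median_of_ratios_normalize, read_clinical,
                      read_expression, write_expression, write_json,
                      zscore_genes)
from .screen import (VirtualCohortParams, prognostic_risk_score,
                     run_virtual_cohorts, select_signature)
from .simulate import SyntheticConfig, generate_cohort, write_cohort
from .subtypes import cluster_subtypes, label_by_survival, train_classifier
from .survival_stats import cohort_characteristics, km_estimate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "screen", "subtype", "train", "report")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Everything a discovery run needs; one global seed drives all stages."""

    outdir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    expression_path: Path | None = None
    clinical_path: Path | None = None
    screen: VirtualCohortParams = field(default_factory=VirtualCohortParams)
    k: int = 2
    silhouette_range: tuple[int, int] = (2, 6)
    classifier: dict = field(default_factory=dict)  # kwargs of train_classifier
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.synthetic is None and (self.expression_path is None
                                       or self.clinical_path is None):
            raise ValueError("config needs either a synthetic block or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "depth_range" in syn:
                syn["depth_range"] = tuple(syn["depth_range"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "screen" in kwargs and kwargs["screen"] is not None:
            kwargs["screen"] = VirtualCohortParams(**kwargs["screen"])
        if "silhouette_range" in kwargs:
            kwargs["silhouette_range"] = tuple(kwargs["silhouette_range"])
        for key in ("expression_path", "clinical_path"):
            if kwargs.get(key):
                kwargs[key] = Path(kwargs[key])
        kwargs["outdir"] = Path(kwargs["outdir"])
        return cls(**kwargs)


def run_discovery(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        if config.synthetic is not None:
            syn = SyntheticConfig(**{**config.synthetic.to_dict(),
                                     "depth_range": config.synthetic.depth_range,
                                     "seed": seeds["simulate"]})
            expr, clin, truth = generate_cohort(syn)
            paths = write_cohort(out, expr, clin, truth, syn)
            artifacts.update(paths)
        else:
            expr = read_expression(config.expression_path, mode="counts")
            clin = read_clinical(config.clinical_path).aligned_to(expr)
            artifacts["expression"] = Path(config.expression_path)
            artifacts["clinical"] = Path(config.clinical_path)

        stage = "normalize"
        normalized, size_factors = median_of_ratios_normalize(expr)
        logged = log_transform(normalized, base=config.log_base)
        z = zscore_genes(logged)
        size_factors.to_csv(out / "size_factors.tsv", sep="\t")
        write_expression(z, out / "zscores.tsv")
        artifacts["size_factors"] = out / "size_factors.tsv"
        artifacts["zscores"] = out / "zscores.tsv"

        stage = "screen"
        params = VirtualCohortParams(**{**config.screen.to_dict(), "seed": seeds["screen"]})
        ranking = run_virtual_cohorts(z, clin, params)
        ranking.table.to_csv(out / "ranking.tsv", sep="\t")
        signature = select_signature(ranking)
        write_json(signature.to_dict(), out / "signature.json")
        (out / "signature_genes.txt").write_text("\n".join(signature.gene_ids) + "\n")
        risk = prognostic_risk_score(signature, z)
        risk.to_csv(out / "risk_score.tsv", sep="\t")
        artifacts.update({"ranking": out / "ranking.tsv",
                          "signature": out / "signature.json",
                          "signature_genes": out / "signature_genes.txt",
                          "risk_score": out / "risk_score.tsv"})

        stage = "subtype"
        if not signature.gene_ids:
            raise ValueError("empty signature: no genes passed selection")
        z_sig = z.restrict_genes(signature.gene_ids)
        assignment = cluster_subtypes(z_sig, k=config.k, seed=seeds["subtype"],
                                      silhouette_range=config.silhouette_range)
        labeled = label_by_survival(assignment, clin)
        labeled.labels.to_frame().to_csv(out / "subtypes.tsv", sep="\t")
        pd.Series(labeled.silhouette, name="silhouette").rename_axis("k") \
            .to_csv(out / "silhouette.tsv", sep="\t")
        artifacts.update({"subtypes": out / "subtypes.tsv",
                          "silhouette": out / "silhouette.tsv"})

        stage = "train"
        model = train_classifier(z_sig, labeled.labels, seed=seeds["train"],
                                 **config.classifier)
        write_json(model.to_dict(), out / "model.json")
        artifacts["model"] = out / "model.json"

        stage = "report"
        table = cohort_characteristics(labeled.labels, clin)
        table.to_csv(out / "characteristics.tsv", sep="\t", index=False)
        km_frames = []
        for gname in sorted(labeled.labels.unique()):
            sub = ClinicalTable(clin.data.loc[labeled.labels == gname].copy())
            f = km_estimate(sub).as_frame()
            f.insert(0, "subtype", gname)
            km_frames.append(f)
        pd.concat(km_frames, ignore_index=True).to_csv(out / "km_curves.tsv",
                                                       sep="\t", index=False)
        summary = {
            "n_samples": expr.n_samples, "n_genes": expr.n_genes,
            "signature_size": len(signature),
            "subtype_counts": labeled.labels.value_counts().to_dict(),
            "logrank_p": labeled.logrank.p if labeled.logrank else None,
            "cv_accuracy_mean": model.cv_accuracy_mean,
            "cv_accuracy_sd": model.cv_accuracy_sd,
        }
        write_json(summary, out / "summary.json")
        artifacts.update({"characteristics": out / "characteristics.tsv",
                          "km_curves": out / "km_curves.tsv",
                          "summary": out / "summary.json"})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "screen_params": config.screen.to_dict(),
        "k": config.k,
        "classifier": config.classifier,
        "synthetic": config.synthetic.to_dict() if config.synthetic else None,
        "artifacts": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                      for k, p in sorted(artifacts.items())},
    }
    write_json(manifest, out / "manifest.json")
    return manifest
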