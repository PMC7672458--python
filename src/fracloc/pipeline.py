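"""End-to-end synthetic experiment: generate -> features -> localization ->
strata -> imaging, from one flat config, with a reproducibility manifest.

Every stage writes deterministic TSV outputs into the run directory; the
manifest records package version, seed, a hash of the canonical config, and
the completed stages, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Any

import pandas as pd

from . import __version__
from .annotation import gene_metrics_table, write_gtf
from .imaging import brightest_speckle_pearson, classify_spots, detect_spots, segment_speckles
from .localization import LocalizationModel, intronic_read_fraction
from .simdata import (
    CONDITIONS,
    EffectModel,
    SpeckleImageParams,
    default_templates,
    make_toy_annotation,
    simulate_cell_image,
    simulate_fracseq_counts,
)
from .strata import feature_correlations, group_compare, length_bin_analysis, length_controlled_exon_analysis

log = logging.getLogger("fracloc.pipeline")

STAGES = ("simdata", "annofeat", "locstats", "strata", "imgquant")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; see docs/methods.md for parameter roles."""

    seed: int = 0
    outdir: str = "fracloc_run"
    replicates: int = 3
    fpkm_min: float = 1.0
    prior_count: float = 4.0
    kd_conditions: tuple[str, ...] = ("KD_A", "KD_D")
    effect: dict[str, Any] = field(default_factory=dict)    # EffectModel overrides
    template_counts: dict[str, int] = field(default_factory=dict)
    n_images: int = 4
    image: dict[str, Any] = field(default_factory=dict)     # SpeckleImageParams overrides

    def validate(self) -> None:
        if self.replicates < 2:
            raise PipelineError("replicates must be >= 2")
        if self.fpkm_min <= 0 or self.prior_count <= 0:
            raise PipelineError("thresholds must be positive")
        for kd in self.kd_conditions:
            if kd not in CONDITIONS:
                raise PipelineError(f"unknown knockdown condition {kd!r}; choose from {CONDITIONS[1:]}")
        if not self.kd_conditions:
            raise PipelineError("at least one knockdown condition is required")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.kd_conditions, list):
            cfg.kd_conditions = tuple(cfg.kd_conditions)
        return cfg

    def canonical_hash(self) -> str:
        params = asdict(self)
        params.pop("outdir")  # a path, not an analysis parameter
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _templates_for(config: PipelineConfig):
    templates = default_templates()
    if config.template_counts:
        by_name = {tpl.name: (tpl, n) for tpl, n in templates}
        for name, n in config.template_counts.items():
            if name not in by_name:
                raise PipelineError(f"unknown template {name!r}")
            by_name[name] = (by_name[name][0], int(n))
        templates = list(by_name.values())
    return templates


def _tsv(df: pd.DataFrame, path: str, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label=index_label,
              index=index_label is not None)


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages; returns the run directory path.

    Any stage failure aborts with the failing stage named; outputs of
    completed stages are left in place.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "fracloc",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.canonical_hash(),
        "stages": [],
    }
    stage = "simdata"
    try:
        t0 = time.perf_counter()
        log.info("stage simdata: generating annotation and counts")
        annotation = make_toy_annotation(_templates_for(config), seed=config.seed)
        write_gtf(annotation, os.path.join(outdir, "annotation.gtf"))
        conditions = ("control",) + tuple(config.kd_conditions)
        effect = EffectModel(**config.effect)
        experiment = simulate_fracseq_counts(
            annotation, effect, replicates=config.replicates,
            seed=config.seed + 1, conditions=conditions,
        )
        _tsv(experiment.counts, os.path.join(outdir, "counts.tsv"), index_label="gene_id")
        _tsv(experiment.design, os.path.join(outdir, "design.tsv"), index_label="sample")
        _tsv(experiment.intronic_counts, os.path.join(outdir, "intronic_counts.tsv"),
             index_label="gene_id")
        _tsv(experiment.truth, os.path.join(outdir, "truth.tsv"), index_label="gene_id")
        manifest["stages"].append({"name": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "annofeat"
        t0 = time.perf_counter()
        log.info("stage annofeat: computing gene metrics")
        metrics = gene_metrics_table(annotation)
        _tsv(metrics, os.path.join(outdir, "gene_metrics.tsv"), index_label="gene_id")
        manifest["stages"].append({"name": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "locstats"
        t0 = time.perf_counter()
        log.info("stage locstats: localization deltas")
        model = LocalizationModel(
            experiment,
            exonic_lengths=metrics["exonic_length"],
            chromosomes=metrics["chromosome"],
            prior_count=config.prior_count,
            fpkm_min=config.fpkm_min,
        )
        results = {}
        for kd in config.kd_conditions:
            res = model.fit(contrast=("nuclear", "cytoplasmic"), kd_condition=kd)
            res.to_tsv(os.path.join(outdir, f"localization_NC_{kd}.tsv"))
            results[kd] = res
        intron_frac = pd.DataFrame(
            {
                cond: intronic_read_fraction(experiment, "cytoplasmic", cond)
                for cond in conditions
            }
        )
        _tsv(intron_frac, os.path.join(outdir, "cytoplasmic_intronic_fraction.tsv"),
             index_label="sample")
        manifest["stages"].append({"name": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "strata"
        t0 = time.perf_counter()
        log.info("stage strata: stratified reports")
        primary = results[config.kd_conditions[0]]
        strata_dir = os.path.join(outdir, "strata")
        feature_correlations(primary.table, metrics).to_csv(
            os.path.join(outdir, "feature_correlations.tsv"), sep="\t",
            float_format="%.6g", index=False,
        )
        classes = metrics["exon_class"].reindex(primary.table.index)
        group_compare(primary.table, classes).to_tsv(os.path.join(strata_dir, "exon_class"))
        length_bin_analysis(primary.table, metrics).to_tsv(os.path.join(strata_dir, "length_bins"))
        length_controlled_exon_analysis(primary.table, metrics).to_tsv(
            os.path.join(strata_dir, "exon_windows")
        )
        manifest["stages"].append({"name": stage, "seconds": round(time.perf_counter() - t0, 3)})

        stage = "imgquant"
        t0 = time.perf_counter()
        log.info("stage imgquant: synthetic image quantification")
        img_params = SpeckleImageParams(**{"n_nuclear_spots": 20, "n_cyto_spots": 30, **config.image})
        rows = []
        for i in range(config.n_images):
            img = simulate_cell_image(img_params, seed=config.seed + 100 + i)
            seg = segment_speckles(img.sc35, img.nucleus_mask)
            pear = brightest_speckle_pearson(img.rna, img.sc35, seg.speckle_mask)
            spots = detect_spots(img.rna)
            counts = classify_spots(spots, img.nucleus_mask, img.cell_mask)
            rows.append(
                {
                    "cell": i,
                    "speckle_area_fraction": seg.area_fraction,
                    "mean_pearson": pear.mean_pearson,
                    "n_nuclear_spots": counts.n_nuclear,
                    "n_cytoplasmic_spots": counts.n_cytoplasmic,
                }
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "image_quantification.tsv"), sep="\t",
            float_format="%.6g", index=False,
        )
        manifest["stages"].append({"name": stage, "seconds": round(time.perf_counter() - t0, 3)})
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        stable = dict(manifest)
        stable["stages"] = [{"name": s["name"]} for s in manifest["stages"]]
        json.dump(stable, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(outdir, "pipeline.log"), "w") as fh:
        for s in manifest["stages"]:
            fh.write(f"{s['name']}\tcompleted\t{s['seconds']}s\n")
    return outdir
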