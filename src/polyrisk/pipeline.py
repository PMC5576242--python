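"""Config-driven end-to-end pipeline.

Wires the stages together — simulate (or load) genotypes -> QC ->
relatedness pruning -> ancestry adjustment -> cross-validated training and
evaluation — and stamps every artifact with the seed, a config hash and the
package version so any number in the output directory is reproducible from
the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._rng import spawn_seed
from .datasets import align_phenotypes
from .evaluation import Scenario, run_benchmark
from .qc import QcThresholds, apply_sample_filters, apply_snp_filters, prune_related
from .simulate import SimulationConfig, simulate_dataset
from .structure import adjust_phenotype, compute_grm, effective_marker_count, reference_pca
from . import io as pio

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``simulate`` (a :class:`SimulationConfig`) or the three genotype
    paths plus ``phenotype_path`` must be given.  ``adjust_k > 0`` adds an
    ``adjusted`` phenotype column (residual on the top projected
    eigenvectors of the study sample's own PCA) and evaluates both scales.
    """

    out_dir: str = "polyrisk_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    bed_path: str | None = None
    bim_path: str | None = None
    fam_path: str | None = None
    phenotype_path: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    prune_relatedness: bool = True
    adjust_k: int = 0
    methods: tuple[str, ...] = ("gprs", "gblup")
    n_folds: int = 5
    method_params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("bed_path", "bim_path", "fam_path", "phenotype_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        for m in self.methods:
            if m not in ("gprs", "en", "gblup", "bayesr"):
                raise ValueError(f"unknown method '{m}'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "qc" in raw:
            raw["qc"] = QcThresholds(**raw["qc"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest written to out_dir."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # ------------------------------------------------------------------ data
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=spawn_seed(config.seed, "simulate"))
            dataset, pheno, _model = simulate_dataset(sim)
            pio.write_plink_binary(dataset, out / "cohort")
            pio.write_phenotypes(pheno, out / "cohort.pheno.tsv")
            pio.write_snp_metadata(dataset, out / "cohort.snps.tsv")
        else:
            dataset = pio.read_plink_binary(config.bed_path, config.bim_path, config.fam_path)
            pheno = pio.read_phenotypes(config.phenotype_path)
        manifest["stages"]["data"] = {"n_samples": dataset.n_samples, "n_snps": dataset.n_snps}
    except Exception as err:
        raise RuntimeError(f"stage 'data' failed: {err}") from err

    # -------------------------------------------------------------------- qc
    try:
        dataset, snp_report = apply_snp_filters(dataset, config.qc)
        dataset, sample_report = apply_sample_filters(dataset, config.qc)
        (out / "qc_report.tsv").write_text(snp_report.to_text() + sample_report.to_text())
        grm = compute_grm(dataset)
        me = effective_marker_count(grm) if dataset.n_samples >= 10 else None
        if config.prune_relatedness:
            keep = prune_related(grm, config.qc.relatedness_cutoff,
                                 spawn_seed(config.seed, "prune"))
            dataset = dataset.subset_samples(keep)
        pheno = pheno[pheno["iid"].isin(dataset.sample_ids)]
        pheno = align_phenotypes(dataset, pheno)
        manifest["stages"]["qc"] = {
            "snp_removed": snp_report.removed,
            "sample_removed": sample_report.removed,
            "n_samples": dataset.n_samples,
            "n_snps": dataset.n_snps,
            "effective_markers": me,
        }
    except Exception as err:
        raise RuntimeError(f"stage 'qc' failed: {err}") from err

    # ------------------------------------------------------------- adjustment
    scales = ["status"]
    try:
        if config.adjust_k > 0:
            proj = reference_pca(dataset, k=config.adjust_k)
            coords = proj.scores
            pheno = pheno.copy()
            pheno["adjusted"] = adjust_phenotype(
                pheno["status"].to_numpy(dtype=float), coords, k=config.adjust_k
            )
            scales.append("adjusted")
            manifest["stages"]["adjust"] = {"k": config.adjust_k}
    except Exception as err:
        raise RuntimeError(f"stage 'adjust' failed: {err}") from err

    # -------------------------------------------------------------- evaluate
    try:
        scenarios = [Scenario(name=f"all-{s}", pheno_scale=s) for s in scales]
        reports = run_benchmark(
            dataset, pheno, methods=list(config.methods), scenarios=scenarios,
            n_folds=config.n_folds, seed=spawn_seed(config.seed, "evaluate"),
            method_params=config.method_params,
        )
        rows = []
        for r in reports:
            rows.append(
                {
                    "scenario": r.scenario,
                    "method": r.method,
                    "pheno_scale": r.pheno_scale,
                    "mean_auc": r.mean_auc,
                    "fold_aucs": r.fold_aucs,
                    "calibration": r.calibration,
                }
            )
            if r.decile_table is not None:
                r.decile_table.to_csv(
                    out / f"deciles_{r.scenario}_{r.method}.tsv", sep="\t", index=False
                )
        manifest["stages"]["evaluate"] = rows
    except Exception as err:
        raise RuntimeError(f"stage 'evaluate' failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
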