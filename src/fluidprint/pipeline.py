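"""End-to-end pipeline driver: simulate/load -> bucket -> classify (MCCV)
-> screen -> QEA -> baseline, with provenance logging.

Every stochastic stage derives its own substream from the run seed, so
changing the iteration count of one stage never perturbs another. Each
stage writes its outputs as soon as it completes; a failure leaves earlier
outputs intact and raises a :class:`StageError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .baseline import summarize_baseline
from .binning import BinningConfig, build_bucket_table, default_config
from .classify import mccv, sensitivity_specificity
from .enrichment import run_qea, venn_overlap  # noqa: F401  (venn re-exported for drivers)
from .library import default_library
from .screen import screen_bins, significant_fraction
from .synthetic import generate_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


_CONFIG_KEYS = {
    "biofluid", "spectra_manifest", "metabolite_table", "design", "binning",
    "classifier", "screen_alpha", "qea", "seed", "output_dir",
}
_CLASSIFIER_KEYS = {"n_iterations", "test_fraction", "variance_threshold", "alpha", "rule", "k"}
_QEA_KEYS = {"gmt", "contrast", "min_set_size", "n_permutations", "significance_alpha"}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    biofluid: str
    seed: int
    output_dir: str
    spectra_manifest: str | None = None
    metabolite_table: str | None = None
    design: str | None = None  # YAML cohort design; simulated when given
    binning: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    screen_alpha: float = 0.05
    qea: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.classifier) - _CLASSIFIER_KEYS
        if unknown:
            raise ValueError(f"unknown classifier keys: {sorted(unknown)}")
        unknown = set(self.qea) - _QEA_KEYS
        if unknown:
            raise ValueError(f"unknown qea keys: {sorted(unknown)}")
        if self.design is None and self.spectra_manifest is None:
            raise ValueError("either a cohort design or a spectra manifest is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _substream(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"seed": config.seed, "stages": {}, "inputs": {}, "defaults": {}}

    def log_stage(name: str, **info):
        provenance["stages"][name] = info
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    # --- inputs ------------------------------------------------------------
    stage = "inputs"
    try:
        if config.design is not None:
            design = fio.design_from_yaml(config.design)
            provenance["inputs"]["design"] = _sha256(Path(config.design))
            spectra, metadata, met_table = generate_cohort(design, default_library())
            provenance["defaults"]["simulate_seed"] = design.seed
        else:
            spectra, metadata = fio.read_spectra(config.spectra_manifest)
            provenance["inputs"]["spectra_manifest"] = _sha256(Path(config.spectra_manifest))
            met_table = None
            if config.metabolite_table:
                met_table = fio.read_metabolite_table(config.metabolite_table, config.biofluid)
                provenance["inputs"]["metabolite_table"] = _sha256(Path(config.metabolite_table))
        labels = [m.class_label for m in metadata]
        log_stage(stage, n_samples=len(spectra))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- bucketing ---------------------------------------------------------
    stage = "bucketing"
    try:
        bin_cfg = default_config(config.biofluid)
        for key, value in config.binning.items():
            if not hasattr(bin_cfg, key):
                raise ValueError(f"unknown binning override {key!r}")
            setattr(bin_cfg, key, tuple(value) if isinstance(value, list) else value)
        bin_cfg = BinningConfig(**{k: getattr(bin_cfg, k) for k in bin_cfg.__dataclass_fields__})
        table = build_bucket_table(spectra, bin_cfg)
        fio.write_bucket_table(table, out / "bucket_table.csv")
        log_stage(stage, n_bins=int(table.bin_centers_ppm.size), config=str(bin_cfg))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- classification ----------------------------------------------------
    stage = "classification"
    try:
        cls_cfg = {
            "n_iterations": 500, "test_fraction": 0.2, "variance_threshold": 0.95,
            "alpha": 0.05, "rule": "nearest_center", "k": 5,
        }
        cls_cfg.update(config.classifier)
        provenance["defaults"]["classifier"] = cls_cfg
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm, records = mccv(table, labels, seed=_substream(config.seed, "mccv"), **cls_cfg)
        pd.DataFrame(cm.counts, index=cm.class_labels, columns=cm.class_labels).to_csv(
            out / "confusion_counts.csv"
        )
        pd.DataFrame(cm.proportions, index=cm.class_labels, columns=cm.class_labels).to_csv(
            out / "confusion_proportions.csv"
        )
        pd.DataFrame(records).to_csv(out / "mccv_iterations.csv", index=False)
        metrics = {"diagonal": dict(zip(cm.class_labels, cm.diagonal().tolist()))}
        if "HEALTHY" in cm.class_labels and len(cm.class_labels) > 1:
            sens, spec = sensitivity_specificity(
                cm, [c for c in cm.class_labels if c != "HEALTHY"]
            )
            metrics["sensitivity"] = sens
            metrics["specificity"] = spec
        (out / "classification_metrics.json").write_text(json.dumps(metrics, indent=2))
        log_stage(stage, **metrics)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- univariate screen ---------------------------------------------------
    stage = "screen"
    try:
        results = screen_bins(table, labels, alpha=config.screen_alpha)
        rows = []
        for r in results:
            row = {"bin_center": r.bin_center_ppm, "H": r.H, "p": r.p_value,
                   "significant": r.significant}
            for g, (med, p5, p95) in r.per_group.items():
                row.update({f"{g}_median": med, f"{g}_p5": p5, f"{g}_p95": p95})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "screen.tsv", sep="\t", index=False)
        log_stage(stage, significant_fraction=significant_fraction(results))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- enrichment ----------------------------------------------------------
    stage = "enrichment"
    try:
        if met_table is None:
            log_stage(stage, skipped="no metabolite table available")
        else:
            qea_cfg = {"contrast": ("G12.0", "G12.1"), "min_set_size": 2,
                       "n_permutations": 1999, "significance_alpha": 0.05}
            qea_cfg.update(config.qea)
            library = (
                fio.read_gmt(qea_cfg["gmt"]) if qea_cfg.get("gmt")
                else fio.bundled_pathway_library()
            )
            provenance["defaults"]["qea"] = {k: v for k, v in qea_cfg.items() if k != "gmt"}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                qea = run_qea(
                    met_table, labels, library, config.biofluid,
                    contrast=tuple(qea_cfg["contrast"]),
                    min_set_size=qea_cfg["min_set_size"],
                    n_permutations=qea_cfg["n_permutations"],
                    seed=_substream(config.seed, "qea"),
                )
            pd.DataFrame(
                [
                    {"pathway": r.pathway_name, "n_members": r.n_members_measured,
                     "Q": r.Q, "p": r.p_value, "enrichment_ratio": r.enrichment_ratio,
                     "members": ";".join(r.member_names)}
                    for r in qea
                ]
            ).to_csv(out / "qea.tsv", sep="\t", index=False)
            log_stage(stage, n_sets=len(qea), top=qea[0].pathway_name)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- baseline ------------------------------------------------------------
    stage = "baseline"
    try:
        meta_df = pd.DataFrame(
            [
                {"sample_id": m.sample_id, "class_label": m.class_label,
                 "age_years": m.age_years, "sex": m.sex}
                for m in metadata
            ]
        )
        summaries = summarize_baseline(meta_df, ["age_years", "sex"], "class_label")
        payload = [
            {"variable": s.variable, "kind": s.kind, "groups": s.groups,
             "test_used": s.test_used, "statistic": s.statistic, "p_value": s.p_value}
            for s in summaries
        ]
        (out / "baseline.json").write_text(json.dumps(payload, indent=2, default=float))
        log_stage(stage, n_variables=len(summaries))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    return out
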