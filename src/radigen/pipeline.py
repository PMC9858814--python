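"""End-to-end orchestration: simulate -> maps -> features -> enrich ->
associate -> predict, with YAML configuration and a reproducible manifest.

The stage order fixes a documented preprocessing convention: kinetic maps
are computed on the native co-registered grid, each image is then remapped
to the within-mask mean ± 3 SD window, resampled to 1 mm isotropic, and only
then fed to feature extraction.  ``maps.normalize_before_maps`` switches to
remapping the raw timepoint volumes before map computation instead.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so stages are individually reproducible and independent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from radigen import io
from radigen._utils import derive_seed
from radigen.association import (
    qualitative_associations,
    quantitative_associations,
    summarize,
)
from radigen.dce_maps import DceSeries, compute_maps, normalize_volume, resample_isotropic
from radigen.enrichment import gsva_scores
from radigen.features import FeatureCatalog, extract_all
from radigen.prediction import (
    REDUCED_GRID,
    PreprocessPlan,
    RfGrid,
    train_and_evaluate,
)
from radigen.synthetic import (
    ExpressionConfig,
    PhantomConfig,
    cohort_manifest,
    plant_cohort,
)

# configuration schema: section -> allowed keys (None = any scalar)
_SCHEMA: dict[str, dict] = {
    "seed": None,
    "out_dir": None,
    "stages": {
        "simulate": None, "maps": None, "features": None,
        "enrich": None, "associate": None, "predict": None,
    },
    "paths": {"volumes_dir": None, "masks_dir": None, "counts": None, "gmt": None},
    "simulate": {
        "n_patients": None, "grid_shape": None, "spacing_mm": None,
        "tumor_radius_range": None, "lobulation": None,
        "washin_rate_range": None, "washout_range": None,
        "texture_heterogeneity_range": None, "noise_sd": None,
        "n_genes": None, "n_sets": None, "set_size_range": None,
        "nb_dispersion": None, "effect_size": None, "planted_pairs": None,
    },
    "maps": {"normalize_before_maps": None, "resample": None, "out_range": None},
    "features": {"n_bins": None},
    "associate": {"n_perm": None, "threshold": None, "regime": None},
    "predict": {"pathways": None, "plan": None, "grid": None},
}

_PLAN_KEYS = {"zscore", "oversample_bins", "top15_only", "sample_weights", "tune_hyperparams"}


def validate_config(config: dict) -> dict:
    """Reject unknown keys before any stage runs; fill stage defaults."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key, value in config.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key '{key}'")
        allowed = _SCHEMA[key]
        if isinstance(allowed, dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            for sub in value:
                if sub not in allowed:
                    raise ValueError(f"unknown config key '{key}.{sub}'")
    plan = config.get("predict", {}).get("plan", {})
    for sub in plan:
        if sub not in _PLAN_KEYS:
            raise ValueError(f"unknown config key 'predict.plan.{sub}'")
    out = {
        "seed": int(config.get("seed", 0)),
        "out_dir": config.get("out_dir", "."),
        "stages": {
            name: bool(config.get("stages", {}).get(name, True))
            for name in _SCHEMA["stages"]
        },
        "paths": dict(config.get("paths", {})),
        "simulate": dict(config.get("simulate", {})),
        "maps": {
            "normalize_before_maps": False, "resample": True,
            "out_range": [0.0, 100.0], **config.get("maps", {}),
        },
        "features": {"n_bins": 32, **config.get("features", {})},
        "associate": {
            "n_perm": 200, "threshold": 0.05, "regime": "pval",
            **config.get("associate", {}),
        },
        "predict": {
            "pathways": config.get("predict", {}).get("pathways", []),
            "plan": {k: bool(plan.get(k, False)) for k in _PLAN_KEYS},
            "grid": config.get("predict", {}).get("grid", "reduced"),
        },
    }
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Executes the configured stages and records a run manifest."""

    def __init__(self, config: dict):
        self.config = validate_config(config)
        self.out_dir = Path(self.config["out_dir"])
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.seed = self.config["seed"]
        self.manifest: dict = {
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest(),
            "seed": self.seed,
            "stages": {},
            "warnings": [],
        }

    # ------------------------------------------------------------------ util
    def _record(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            str(p.relative_to(self.out_dir)): _sha256(p) for p in sorted(outputs)
        }

    def _patient_ids(self) -> list[str]:
        vol_dir = Path(self.config["paths"]["volumes_dir"])
        return sorted({p.name.split("_")[0] for p in vol_dir.glob("*_pre.nii.gz")})

    # ---------------------------------------------------------------- stages
    def simulate(self) -> None:
        cfg = self.config["simulate"]
        phantom_kwargs = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.items()
            if k in PhantomConfig.__dataclass_fields__
        }
        expr_kwargs = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.items()
            if k in ExpressionConfig.__dataclass_fields__
        }
        phantom_cfg = PhantomConfig(seed=derive_seed(self.seed, "phantom"), **phantom_kwargs)
        expr_cfg = ExpressionConfig(seed=derive_seed(self.seed, "expression"), **expr_kwargs)
        planted = [tuple(p) for p in cfg.get("planted_pairs") or []]
        series_list, masks, counts, sets, truth = plant_cohort(phantom_cfg, expr_cfg, planted)

        vol_dir = self.out_dir / "volumes"
        mask_dir = self.out_dir / "masks"
        vol_dir.mkdir(exist_ok=True)
        mask_dir.mkdir(exist_ok=True)
        outputs = []
        for series, mask in zip(series_list, masks):
            pid = series.patient_id
            for label, vol in series.volumes.items():
                p = vol_dir / f"{pid}_{label}.nii.gz"
                io.write_volume(p, vol, series.spacing_mm)
                outputs.append(p)
            p = mask_dir / f"{pid}_mask.nii.gz"
            io.write_volume(p, mask, series.spacing_mm)
            outputs.append(p)
        counts_path = self.out_dir / "counts.tsv"
        gmt_path = self.out_dir / "sets.gmt"
        io.write_counts(counts_path, counts)
        io.write_gmt(gmt_path, sets)
        outputs += [counts_path, gmt_path]

        manifest_path = self.out_dir / "cohort_manifest.json"
        # paths recorded relative to the output dir so reruns are byte-identical
        manifest_path.write_text(
            cohort_manifest(
                phantom_cfg, expr_cfg, truth,
                paths={
                    "volumes_dir": "volumes", "masks_dir": "masks",
                    "counts": "counts.tsv", "gmt": "sets.gmt",
                },
            )
        )
        outputs.append(manifest_path)
        self.config["paths"].update(
            volumes_dir=str(vol_dir), masks_dir=str(mask_dir),
            counts=str(counts_path), gmt=str(gmt_path),
        )
        self._record("simulate", outputs)

    def maps(self) -> None:
        cfg = self.config["maps"]
        vol_dir = Path(self.config["paths"]["volumes_dir"])
        mask_dir = Path(self.config["paths"]["masks_dir"])
        maps_dir = self.out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        outputs = []
        for pid in self._patient_ids():
            series = io.read_dce_series(
                {t: vol_dir / f"{pid}_{t}.nii.gz" for t in ("pre", "early", "middle", "late")},
                patient_id=pid,
            )
            mask, _ = io.read_mask(mask_dir / f"{pid}_mask.nii.gz")
            if cfg["normalize_before_maps"]:
                remapped = {
                    t: normalize_volume(v, mask, tuple(cfg["out_range"]))[0]
                    for t, v in series.volumes.items()
                }
                series = DceSeries(remapped, series.spacing_mm, pid)
            map_set = compute_maps(series, mask)
            sidecar = dict(map_set.meta)
            images = {}
            for label, image in map_set.images.items():
                remapped, params = normalize_volume(image, mask, tuple(cfg["out_range"]))
                sidecar[f"remap_{label}"] = params
                images[label] = remapped
            if cfg["resample"]:
                images = {
                    label: resample_isotropic(img, series.spacing_mm)
                    for label, img in images.items()
                }
                mask_out = resample_isotropic(mask, series.spacing_mm, is_mask=True)
                invalid = resample_isotropic(
                    map_set.invalid_voxel_mask, series.spacing_mm, is_mask=True
                )
            else:
                mask_out, invalid = mask, map_set.invalid_voxel_mask
            for label, img in images.items():
                p = maps_dir / f"{pid}_{label}.nii.gz"
                io.write_volume(p, img)
                outputs.append(p)
            for name, arr in (("procmask", mask_out), ("invalid", invalid)):
                p = maps_dir / f"{pid}_{name}.nii.gz"
                io.write_volume(p, arr)
                outputs.append(p)
            p = maps_dir / f"{pid}_sidecar.json"
            io.write_json(p, sidecar)
            outputs.append(p)
        self._record("maps", outputs)

    def features(self) -> None:
        from radigen.dce_maps import ParametricMapSet

        maps_dir = self.out_dir / "maps"
        catalog = FeatureCatalog()
        rows = {}
        for pid in self._patient_ids():
            images = {
                label: io.read_volume(maps_dir / f"{pid}_{label}.nii.gz")[0]
                for label in ("pre", "PE_early", "SER_middle", "SER_late")
            }
            mask = io.read_volume(maps_dir / f"{pid}_procmask.nii.gz")[0] > 0.5
            invalid = io.read_volume(maps_dir / f"{pid}_invalid.nii.gz")[0] > 0.5
            map_set = ParametricMapSet(
                pre=images["pre"], pe_early=images["PE_early"],
                ser_middle=images["SER_middle"], ser_late=images["SER_late"],
                invalid_voxel_mask=invalid,
            )
            rows[pid] = extract_all(
                map_set, mask, n_bins=self.config["features"]["n_bins"], catalog=catalog
            )
        table = pd.DataFrame(rows).T
        table.index.name = "patient_id"
        feat_path = self.out_dir / "features.tsv"
        io.write_tsv(feat_path, table)
        cat_path = self.out_dir / "feature_categories.json"
        io.write_json(cat_path, catalog.categories().to_dict("index"))
        self._record("features", [feat_path, cat_path])

    def enrich(self) -> None:
        counts = io.read_counts(self.config["paths"]["counts"])
        sets = io.read_gmt(self.config["paths"]["gmt"])
        es = gsva_scores(counts, sets)
        es_path = self.out_dir / "es_matrix.tsv"
        io.write_tsv(es_path, es, index_label="pathway")
        self._record("enrich", [es_path])

    def associate(self) -> None:
        cfg = self.config["associate"]
        features = pd.read_csv(self.out_dir / "features.tsv", sep="\t", index_col=0)
        counts = io.read_counts(self.config["paths"]["counts"])
        sets = io.read_gmt(self.config["paths"]["gmt"])
        es = pd.read_csv(self.out_dir / "es_matrix.tsv", sep="\t", index_col=0)
        qual = qualitative_associations(
            features, counts, sets,
            n_perm=cfg["n_perm"], seed=derive_seed(self.seed, "associate"),
            threshold=cfg["threshold"], regime=cfg["regime"],
        )
        quant = quantitative_associations(features, es, threshold=cfg["threshold"])
        qual_path = self.out_dir / "associations_qualitative.tsv"
        quant_path = self.out_dir / "associations_quantitative.tsv"
        io.write_tsv(qual_path, qual.qualitative.reset_index())
        io.write_tsv(quant_path, quant.quantitative.reset_index())
        flags = (
            qual.qualitative["significant"].unstack("pathway").fillna(False).astype(bool)
        )
        summary = summarize(flags, FeatureCatalog())
        summary_path = self.out_dir / "association_summary.json"
        io.write_json(
            summary_path, {"regime": cfg["regime"], "threshold": cfg["threshold"],
                           **summary.as_dict()}
        )
        self._record("associate", [qual_path, quant_path, summary_path])

    def predict(self) -> None:
        cfg = self.config["predict"]
        features = pd.read_csv(self.out_dir / "features.tsv", sep="\t", index_col=0)
        es = pd.read_csv(self.out_dir / "es_matrix.tsv", sep="\t", index_col=0)
        plan = PreprocessPlan(**cfg["plan"])
        grid = REDUCED_GRID if cfg["grid"] == "reduced" else RfGrid()
        pathways = cfg["pathways"] or list(es.index[:1])
        reports = {}
        for pathway in pathways:
            report = train_and_evaluate(
                features, es.loc[pathway, features.index], plan=plan, grid=grid,
                seed=derive_seed(self.seed, f"predict:{pathway}"), pathway=pathway,
            )
            reports[pathway] = report.as_dict()
        path = self.out_dir / "prediction_reports.json"
        io.write_json(path, {"schema_version": 1, "reports": reports})
        self._record("predict", [path])

    # ------------------------------------------------------------------- run
    def run(self) -> dict:
        order = ("simulate", "maps", "features", "enrich", "associate", "predict")
        for stage in order:
            if self.config["stages"][stage]:
                getattr(self, stage)()
        manifest_path = self.out_dir / "run_manifest.json"
        io.write_json(manifest_path, self.manifest)
        return self.manifest


def run_pipeline(config: dict) -> dict:
    """Validate the config, execute the enabled stages, return the manifest."""
    return PipelineRun(config).run()
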