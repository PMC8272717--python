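"""Pipeline orchestration and report tables.

Ties the stages together over an artifacts directory and emits the
report tables: per-parameter mean (±SD); median ICC per ROI/group,
cluster-corrected threshold counts, and the condition-ranking summary.
Every artifact carries a provenance JSON (config hash, package version,
seed) so each table cell is traceable to one upstream run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .bold_models import PARAMETERS, ParameterMaps, estimate_all_parameters
from .cluster import estimate_acf, icc_to_p, simulate_cluster_null, extract_clusters
from .ranking import ConditionGrid, rank_analysis
from .reliability import (
    RELIABILITY_THRESHOLDS,
    ICCMap,
    impute_covariates,
    roi_summary,
    semipartial_reliability,
    voxelwise_icc,
)

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "voxelwise_semipartial",
    "reliability_table",
    "threshold_count_table",
    "provenance",
    "run_command",
]

#: Covariate columns used in the adjusted (semi-partial) analyses.
COVARIATE_COLUMNS = [
    "bdi_pre",
    "bdi_post",
    "state_anxiety",
    "trait_anxiety",
    "rumination",
    "sleepiness",
    "scanner",
]


@dataclass
class RunConfig:
    output_dir: str = "relmap_out"
    seed: int = 0
    group: str = "all"  # "all" | "patients"
    parameters: tuple[str, ...] = PARAMETERS
    windsorize: bool = True
    thresholds: tuple[float, ...] = RELIABILITY_THRESHOLDS
    preproc_style: str = "standard"
    cluster_alpha: float = 0.05
    cluster_iter: int = 2000
    connectivity: int = 6
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.parameters, list):
            cfg.parameters = tuple(cfg.parameters)
        if isinstance(cfg.thresholds, list):
            cfg.thresholds = tuple(cfg.thresholds)
        sorted_thr = tuple(sorted(cfg.thresholds))
        if sorted_thr != tuple(cfg.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(getattr(self, k)) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance(config: RunConfig, command: str, extra: dict | None = None) -> dict:
    info = {
        "command": command,
        "config_hash": config.digest(),
        "seed": config.seed,
        "relmap_version": _version,
    }
    if extra:
        info.update(extra)
    return info


def voxelwise_semipartial(
    maps: ParameterMaps, parameter: str, covariates: pd.DataFrame
) -> np.ndarray:
    """Per-voxel semi-partial correlation of session-1 with session-2
    values given the covariates. Returns a 3-D sr map (NaN outside the
    mask or where the regression is undefined)."""
    vals = maps.get(parameter)  # (n_sub, 2, grid)
    mask = maps.mask
    out = np.full(mask.shape, np.nan)
    C = covariates.to_numpy(dtype=float)
    flat = vals.reshape(vals.shape[0], vals.shape[1], -1)
    for v in np.flatnonzero(mask.ravel()):
        pre, post = flat[:, 0, v], flat[:, 1, v]
        ok = np.isfinite(pre) & np.isfinite(post)
        if ok.sum() <= C.shape[1] + 3:
            continue
        try:
            res = semipartial_reliability(pre[ok], post[ok], C[ok])
        except ValueError:
            continue
        out.ravel()[v] = res.sr
    return out


def reliability_table(
    icc_maps: dict[str, ICCMap],
    roi_masks: dict[str, np.ndarray] | None = None,
    group_label: str = "all",
) -> pd.DataFrame:
    """Mean (±SD); median voxelwise ICC per parameter and ROI."""
    rows = []
    rois = roi_masks or {"whole_mask": None}
    for param, icc_map in icc_maps.items():
        for roi, roi_mask in rois.items():
            s = roi_summary(icc_map, roi_mask)
            rows.append(
                {
                    "group": group_label,
                    "parameter": param,
                    "roi": roi,
                    "mean_icc": round(s.mean, 4),
                    "sd_icc": round(s.sd, 4),
                    "median_icc": round(s.median, 4),
                    "n_voxels": s.n_voxels,
                    "formatted": f"{s.mean:.2f} (±{s.sd:.2f}); {s.median:.2f}",
                }
            )
    return pd.DataFrame(rows)


def threshold_count_table(
    icc_maps: dict[str, ICCMap],
    min_cluster_sizes: dict[float, int],
    thresholds: tuple[float, ...] = RELIABILITY_THRESHOLDS,
    connectivity: int = 6,
    group_label: str = "all",
) -> pd.DataFrame:
    """Cluster-corrected voxel counts above each reliability threshold,
    per parameter."""
    rows = []
    for param, icc_map in icc_maps.items():
        row: dict = {"group": group_label, "parameter": param}
        for t in thresholds:
            table = extract_clusters(
                icc_map.icc, theta=t, min_size=min_cluster_sizes[t],
                connectivity=connectivity,
            )
            row[f"n_voxels@{t}"] = table.surviving_voxels()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Command runner


def _subset_group(dataset, covariates: pd.DataFrame, group: str):
    if group == "all":
        return dataset, covariates
    if group != "patients":
        raise ValueError(f"unknown group filter {group!r}")
    sel = covariates["group"].to_numpy() == 1
    import copy

    ds = copy.copy(dataset)
    ds.data = dataset.data[sel]
    ds.subjects = [s for s, keep in zip(dataset.subjects, sel) if keep]
    ds.covariates = covariates.loc[sel].reset_index(drop=True)
    return ds, ds.covariates


def run_command(config: RunConfig, command: str) -> Path:
    """Run one pipeline stage; artifacts land under ``config.output_dir``.

    Stages must be run in order (simulate -> [preprocess] -> fit ->
    reliability -> rank / cluster -> report); a missing upstream
    artifact raises an error naming the stage to run first.
    """
    from .preprocessing import PreprocSpec, run_preprocessing
    from .synthetic import SimulationConfig, VoxelDataset, simulate_dataset
    from . import synthetic

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _need(path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing artifact {path}; run `relmap {producer}` first"
            )
        return path

    if command == "simulate":
        sim_kwargs = dict(config.simulation)
        design = sim_kwargs.pop("design_kind", "event_related")
        sim_kwargs.setdefault("seed", config.seed)
        if design == "block":
            cfg = synthetic.block_config(**sim_kwargs)
        else:
            cfg = synthetic.event_related_config(**sim_kwargs)
        dataset, truth = simulate_dataset(cfg)
        dataset.save(out / "data")
        (out / "data" / "ground_truth.json").write_text(
            json.dumps(
                {
                    "true_icc_per_class": {
                        k: (None if np.isnan(v) else v)
                        for k, v in truth.true_icc_per_class.items()
                    }
                },
                indent=2,
            )
        )
        target = out / "data"
    elif command == "preprocess":
        ds = VoxelDataset.load(_need(out / "data", "simulate"))
        spec = PreprocSpec(style=config.preproc_style)
        vox = float(abs(ds.affine[0, 0]))
        for i in range(ds.data.shape[0]):
            for j in range(ds.data.shape[1]):
                ds.data[i, j] = run_preprocessing(ds.data[i, j], spec, vox)
        ds.save(out / "preproc")
        target = out / "preproc"
    elif command == "fit":
        src = out / "preproc" if (out / "preproc").exists() else _need(out / "data", "simulate")
        ds = VoxelDataset.load(src)
        maps = estimate_all_parameters(ds, parameters=config.parameters)
        maps.save(out / "maps")
        if ds.covariates is not None:
            ds.covariates.to_csv(out / "maps" / "covariates.tsv", sep="\t", index=False)
        target = out / "maps"
    elif command == "reliability":
        maps = ParameterMaps.load(_need(out / "maps", "fit"))
        cov_path = out / "maps" / "covariates.tsv"
        covariates = pd.read_csv(cov_path, sep="\t") if cov_path.exists() else None
        if config.group == "patients":
            if covariates is None:
                raise ValueError("group filter requires a covariate table")
            sel = covariates["group"].to_numpy() == 1
            maps.values = maps.values[sel]
            covariates = covariates.loc[sel].reset_index(drop=True)
        import nibabel as nib

        (out / "reliability").mkdir(exist_ok=True)
        icc_rows = []
        for param in maps.parameters:
            m = voxelwise_icc(maps.get(param), maps.mask, windsorize=config.windsorize)
            nib.save(
                nib.Nifti1Image(m.icc, maps.metadata.get("affine", np.eye(4))),
                out / "reliability" / f"icc_{param}.nii.gz",
            )
            if covariates is not None:
                cov_cols = [c for c in COVARIATE_COLUMNS if c in covariates.columns]
                cov_imp, _ = impute_covariates(covariates[cov_cols])
                sr = voxelwise_semipartial(maps, param, cov_imp)
                nib.save(
                    nib.Nifti1Image(sr, maps.metadata.get("affine", np.eye(4))),
                    out / "reliability" / f"sr_{param}.nii.gz",
                )
            icc_rows.append((param, m))
        table = reliability_table(dict(icc_rows), group_label=config.group)
        table.to_csv(out / "reliability" / "roi_summary.tsv", sep="\t", index=False)
        (out / "reliability" / "provenance.json").write_text(
            json.dumps(provenance(config, command, {"n_subjects": int(maps.values.shape[0])}))
        )
        target = out / "reliability"
    elif command == "rank":
        import nibabel as nib

        rel = _need(out / "reliability", "reliability")
        values, names = [], []
        for param in config.parameters:
            icc = np.asarray(nib.load(rel / f"icc_{param}.nii.gz").dataobj)
            values.append(icc.ravel())
            names.append(f"{param}/no_cov")
            sr_path = rel / f"sr_{param}.nii.gz"
            if sr_path.exists():
                sr = np.asarray(nib.load(sr_path).dataobj)
                values.append(np.abs(sr).ravel())
                names.append(f"{param}/cov")
        grid = ConditionGrid(np.vstack(values), names)
        result = rank_analysis(grid)
        (out / "rank").mkdir(exist_ok=True)
        result.to_frame().to_csv(out / "rank" / "mean_ranks.tsv", sep="\t", index=False)
        (out / "rank" / "omnibus.json").write_text(
            json.dumps(
                {
                    "kruskal_wallis_h": result.kw_h,
                    "kruskal_wallis_p": result.kw_p,
                    "ks_stat": result.ks_stat,
                    "ks_p": result.ks_p,
                    **provenance(config, command),
                }
            )
        )
        target = out / "rank"
    elif command == "cluster":
        import nibabel as nib

        maps = ParameterMaps.load(_need(out / "maps", "fit"))
        n_sub = maps.values.shape[0]
        vox = float(abs(maps.metadata.get("affine", np.eye(4))[0, 0])) or 1.0
        # Residual smoothness proxy: across-subject demeaned parameter maps.
        param0 = maps.parameters[0]
        vols = maps.get(param0).reshape(-1, *maps.mask.shape)
        vols = vols - np.nanmean(vols, axis=0, keepdims=True)
        vols = np.nan_to_num(vols)
        acf = estimate_acf(vols, maps.mask, vox)
        sizes = {}
        for t in config.thresholds:
            p_thr = icc_to_p(t, n_sub)
            sizes[float(t)] = simulate_cluster_null(
                acf,
                maps.mask,
                p_thr,
                vox,
                n_iter=config.cluster_iter,
                alpha=config.cluster_alpha,
                connectivity=config.connectivity,
                seed=config.seed,
                null="icc",
                n_subjects=n_sub,
            )
        (out / "cluster").mkdir(exist_ok=True)
        (out / "cluster" / "min_cluster_sizes.json").write_text(
            json.dumps(
                {
                    "acf": {"a": acf.a, "b": acf.b, "c": acf.c},
                    "min_sizes": {str(k): v for k, v in sizes.items()},
                    **provenance(config, command),
                }
            )
        )
        target = out / "cluster"
    elif command == "nfsignal":
        from .nf import BlockDesign, average_blocks, feedback_signal, nf_reliability, summarize_visit

        ds = VoxelDataset.load(_need(out / "data", "simulate"))
        if ds.design_kind != "block":
            raise ValueError("nfsignal requires a block-design dataset")
        design = BlockDesign.from_events(ds.events, ds.tr)
        summaries = {0: [], 1: []}
        for i, sub in enumerate(ds.subjects):
            for j in (0, 1):
                roi = ds.data[i, j][ds.mask].mean(axis=0)
                tc = average_blocks(feedback_signal(roi, design))
                g = summarize_visit(tc, "gamma", ds.tr)
                summaries[j].append(
                    {
                        "subject": sub,
                        "mean": summarize_visit(tc, "mean"),
                        "onset_delay": g.onset_delay,
                        "rise_decay": g.rise_decay,
                        "height": g.height,
                    }
                )
        v1 = pd.DataFrame(summaries[0]).set_index("subject")
        v2 = pd.DataFrame(summaries[1]).set_index("subject")
        res = nf_reliability(v1, v2)
        (out / "nfsignal").mkdir(exist_ok=True)
        pd.DataFrame(
            [{"parameter": k, "icc": v} for k, v in res.icc.items()]
        ).to_csv(out / "nfsignal" / "nf_reliability.tsv", sep="\t", index=False)
        (out / "nfsignal" / "provenance.json").write_text(
            json.dumps(provenance(config, command, {"n_subjects": res.n_subjects}))
        )
        target = out / "nfsignal"
    elif command == "report":
        import nibabel as nib

        rel = _need(out / "reliability", "reliability")
        sizes_path = out / "cluster" / "min_cluster_sizes.json"
        icc_maps = {}
        for param in config.parameters:
            icc = np.asarray(nib.load(rel / f"icc_{param}.nii.gz").dataobj)
            icc_maps[param] = ICCMap(icc=icc, mask=np.isfinite(icc), n_subjects=0)
        (out / "report").mkdir(exist_ok=True)
        reliability_table(icc_maps, group_label=config.group).to_csv(
            out / "report" / "table_reliability.tsv", sep="\t", index=False
        )
        if sizes_path.exists():
            sizes = {
                float(k): int(v)
                for k, v in json.loads(sizes_path.read_text())["min_sizes"].items()
            }
            threshold_count_table(
                icc_maps, sizes, config.thresholds, config.connectivity, config.group
            ).to_csv(out / "report" / "table_threshold_counts.tsv", sep="\t", index=False)
        (out / "report" / "provenance.json").write_text(
            json.dumps(provenance(config, command))
        )
        target = out / "report"
    else:
        raise ValueError(f"unknown command {command!r}")
    log.info("%s complete: %s", command, target)
    return target
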