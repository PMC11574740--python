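"""End-to-end orchestration: generate -> score -> features -> stats -> classify.

Each stage writes its artifacts plus a small manifest carrying a hash of the
configuration it ran under (chained with its upstream stage's hash).  A rerun
with an identical configuration is a no-op for completed stages; corrupting
or changing anything re-runs exactly that stage and its descendants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import fmri_features as ff
from . import group_stats as gs
from . import io as pio
from . import lesion_vae as lv
from . import synthetic_cohort as sc

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_run_config", "io_roundtrip"]

logger = logging.getLogger(__name__)

STAGES = ("cohort", "lesions", "features", "stats", "classify")

io_roundtrip = pio.io_roundtrip  # re-exported: part of this module's surface


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    cohort: sc.CohortConfig = field(default_factory=sc.CohortConfig)
    vae_arch: lv.VAEArchitecture = field(default_factory=lv.VAEArchitecture)
    vae_train: lv.TrainConfig = field(default_factory=lv.TrainConfig)
    n_train_subjects: int = 16  # extra lesion-light subjects for VAE training
    ocsvm_nu: float = 0.1
    nperm: int = 1000
    q: float = 0.05
    cv: cls.CVConfig = field(default_factory=cls.CVConfig)
    n_null: int = 0  # 0 disables the permutation-null stage output
    learning_curve_grid: tuple[int, ...] = ()
    stages: tuple[str, ...] = STAGES
    seed: int = 0


def _config_hash(obj, upstream: str = "") -> str:
    def canon(o):
        if dataclasses.is_dataclass(o):
            return {k: canon(v) for k, v in sorted(dataclasses.asdict(o).items())}
        if isinstance(o, dict):
            return {str(k): canon(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [canon(v) for v in o]
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    payload = json.dumps([canon(obj), upstream], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        pio.save_json({"stages": self.stages, "summaries": self.summaries}, path)


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a single YAML document.

    Top-level keys mirror the RunConfig fields; nested mappings populate the
    per-stage dataclasses.  Tuple-keyed tables (connectivity shifts) are
    written as 'ROI A|ROI B' keys.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return build_run_config(raw)


def build_run_config(raw: dict) -> RunConfig:
    raw = dict(raw)

    def tup(x):
        return tuple(x) if isinstance(x, list) else x

    cohort_kw = dict(raw.pop("cohort", {}))
    for key in ("grid_shape", "alff_band"):
        if key in cohort_kw:
            cohort_kw[key] = tup(cohort_kw[key])
    if "lesion_prevalence" in cohort_kw:
        cohort_kw["lesion_prevalence"] = {
            k: tuple(v) for k, v in cohort_kw["lesion_prevalence"].items()
        }
    if "connectivity_shift" in cohort_kw:
        cohort_kw["connectivity_shift"] = {
            tuple(k.split("|")): tuple(v)
            for k, v in cohort_kw["connectivity_shift"].items()
        }
    arch_kw = {k: tup(v) for k, v in dict(raw.pop("vae_arch", {})).items()}
    train_kw = dict(raw.pop("vae_train", {}))
    cv_kw = {k: tup(v) for k, v in dict(raw.pop("cv", {})).items()}
    for key in ("stages", "learning_curve_grid"):
        if key in raw:
            raw[key] = tup(raw[key])
    return RunConfig(
        cohort=sc.CohortConfig(**cohort_kw),
        vae_arch=lv.VAEArchitecture(**arch_kw),
        vae_train=lv.TrainConfig(**train_kw),
        cv=cls.CVConfig(**cv_kw),
        **raw,
    )


def cohort_feature_table(
    config: sc.CohortConfig,
    parcellation: sc.Parcellation | None = None,
) -> cls.FeatureTable:
    """In-memory cohort -> 135-column feature table, streaming one subject
    at a time.

    Lesion volumes are counted from the generator's ground-truth masks, so
    this isolates the feature/classification stages from the VAE scoring
    stage (which has its own evaluation path).
    """
    parc = parcellation or sc.generate_parcellation(config.grid_shape)
    les_cols, conn_cols, alff_cols = cls.feature_columns(parc.roi_names)
    les, conn, alff, labels = {}, {}, {}, {}
    for subj in sc.iter_subjects(config, parc):
        les[subj.subject_id] = lv.roi_lesion_volumes(subj.true_lesion_mask, parc)
        ts = subj.ts.astype(np.float64)
        roi_ts = ff.roi_mean_timeseries(ts, parc)
        conn[subj.subject_id] = ff.connectivity(roi_ts, parc.roi_names).z_vector
        alff[subj.subject_id] = ff.lobe_alff(ts, parc, config)
        labels[subj.subject_id] = subj.group
    return cls.assemble_features(
        pd.DataFrame.from_dict(les, orient="index", columns=les_cols),
        pd.DataFrame.from_dict(conn, orient="index", columns=conn_cols),
        pd.DataFrame.from_dict(alff, orient="index", columns=alff_cols),
        pd.Series(labels),
        roi_names=parc.roi_names,
    )


__all__.append("cohort_feature_table")


class _StageRunner:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report = RunReport()
        self.hashes: dict[str, str] = {}
        self.dirty = False  # once a stage re-runs, its descendants must too

    def _manifest_path(self, stage: str) -> Path:
        return self.out / f"{stage}.manifest.json"

    def run_stage(self, stage: str, stage_cfg, upstream: str, fn) -> str:
        h = _config_hash(stage_cfg, upstream)
        man_path = self._manifest_path(stage)
        if man_path.exists() and not self.dirty:
            try:
                man = pio.load_json(man_path)
            except (json.JSONDecodeError, OSError):
                man = {}
            if man.get("hash") == h and all(
                (self.out / p).exists() for p in man.get("outputs", [])
            ):
                self.report.stages[stage] = {"status": "cached", "hash": h}
                self.report.summaries.update(man.get("summaries", {}))
                return h
        self.dirty = True
        t0 = time.time()
        outputs, summaries = fn()
        pio.save_json(
            {"stage": stage, "hash": h, "outputs": outputs, "summaries": summaries},
            man_path,
        )
        self.report.stages[stage] = {
            "status": "ran",
            "hash": h,
            "seconds": round(time.time() - t0, 2),
        }
        self.report.summaries.update(summaries)
        return h


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; see module docstring for caching."""
    r = _StageRunner(config)
    out = r.out
    upstream = ""
    for stage in STAGES:
        if stage not in config.stages:
            continue
        fn = {
            "cohort": lambda: _stage_cohort(config, out),
            "lesions": lambda: _stage_lesions(config, out),
            "features": lambda: _stage_features(config, out),
            "stats": lambda: _stage_stats(config, out),
            "classify": lambda: _stage_classify(config, out),
        }[stage]
        cfg_slice = {
            "cohort": config.cohort,
            "lesions": (config.vae_arch, config.vae_train, config.n_train_subjects,
                        config.ocsvm_nu),
            "features": config.cohort.alff_band,
            "stats": (config.nperm, config.q, config.seed),
            "classify": (config.cv, config.n_null, config.learning_curve_grid),
        }[stage]
        upstream = r.run_stage(stage, cfg_slice, upstream, fn)
    r.report.to_json(out / "report.json")
    return r.report


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream artifact: {path}"
        )
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_cohort(config: RunConfig, out: Path):
    d = out / "cohort"
    d.mkdir(exist_ok=True)
    parc = sc.generate_parcellation(config.cohort.grid_shape)
    pio.save_volume(parc.label_volume, d / "parcellation.nii")
    pio.save_table(
        pd.DataFrame(parc.roi_table, columns=["id", "name"]),
        d / "roi_names.tsv",
        index=False,
    )
    rows = []
    outputs = ["cohort/parcellation.nii", "cohort/roi_names.tsv", "cohort/labels.csv"]
    for subj in sc.iter_subjects(config.cohort, parc):
        pio.save_volume(subj.anat, d / f"{subj.subject_id}_anat.nii")
        pio.save_volume(subj.ts.astype(np.float32), d / f"{subj.subject_id}_ts.nii")
        pio.save_volume(subj.true_lesion_mask, d / f"{subj.subject_id}_truemask.nii")
        rows.append({"subject_id": subj.subject_id, "group": subj.group})
        outputs += [f"cohort/{subj.subject_id}_{k}.nii" for k in ("anat", "ts", "truemask")]
    labels = pd.DataFrame(rows)
    pio.save_table(labels, d / "labels.csv", index=False)
    return outputs, {"n_subjects": len(rows)}


def _load_labels(out: Path, stage: str) -> pd.DataFrame:
    path = _require(out / "cohort" / "labels.csv", stage)
    return pd.read_csv(path)


def _load_parcellation(out: Path, stage: str) -> sc.Parcellation:
    vol = pio.load_volume(_require(out / "cohort" / "parcellation.nii", stage))
    names = pd.read_csv(out / "cohort" / "roi_names.tsv", sep="\t")
    return sc.Parcellation(
        label_volume=np.asarray(vol, dtype=np.int16),
        roi_table=tuple(zip(names["id"].astype(int), names["name"])),
    )


def _stage_lesions(config: RunConfig, out: Path):
    d = out / "lesions"
    d.mkdir(exist_ok=True)
    labels = _load_labels(out, "lesions")
    parc = _load_parcellation(out, "lesions")

    # training set: extra lesion-light subjects from an independent seed stream
    train_cfg = replace(
        config.cohort,
        n_per_group=max(config.n_train_subjects, 2),
        seed=config.cohort.seed + 1,
    )
    train_parc = sc.generate_parcellation(train_cfg.grid_shape)
    reference = sc.generate_anatomy(train_cfg, (train_cfg.seed, 0))
    train_vols = []
    for subj in sc.iter_subjects(train_cfg, train_parc):
        if subj.group != sc.NONPTE:
            continue
        train_vols.append(
            lv.histogram_match(subj.anat, reference, mask=parc.brain_mask,
                               reference_mask=parc.brain_mask)
        )
    slices = lv.extract_brain_slices(train_vols, config.vae_arch.input_size)
    model = lv.train_vae(slices, config.vae_arch, config.vae_train)
    lv.save_model(model, d / "vae_model.npz")

    score_maps = []
    outputs = ["lesions/vae_model.npz", "lesions/lesion_volumes.csv"]
    for sid in labels["subject_id"]:
        anat = pio.load_volume(_require(out / "cohort" / f"{sid}_anat.nii", "lesions"))
        matched = lv.histogram_match(np.asarray(anat, dtype=np.float64), reference,
                                     mask=parc.brain_mask,
                                     reference_mask=parc.brain_mask)
        smap = lv.lesion_score_map(model, matched)
        score_maps.append(smap.astype(np.float32))
        pio.save_volume(smap.astype(np.float32), d / f"{sid}_score.nii")
        outputs.append(f"lesions/{sid}_score.nii")
    score_maps = np.stack(score_maps)
    masks = lv.binarize_lesions(score_maps, nu=config.ocsvm_nu,
                                brain_mask=parc.brain_mask)
    vols = {}
    for i, sid in enumerate(labels["subject_id"]):
        pio.save_volume(masks[i], d / f"{sid}_mask.nii")
        outputs.append(f"lesions/{sid}_mask.nii")
        vols[sid] = lv.roi_lesion_volumes(masks[i], parc)
    les_cols, _, _ = cls.feature_columns(parc.roi_names)
    df = pd.DataFrame.from_dict(vols, orient="index", columns=les_cols)
    df.index.name = "subject_id"
    pio.save_table(df, d / "lesion_volumes.csv")
    return outputs, {
        "vae_final_loss": model.final_loss,
        "mean_lesion_volume": float(df.to_numpy().sum(axis=1).mean()),
    }


def _stage_features(config: RunConfig, out: Path):
    d = out / "features"
    d.mkdir(exist_ok=True)
    labels = _load_labels(out, "features")
    parc = _load_parcellation(out, "features")
    _, conn_cols, alff_cols = cls.feature_columns(parc.roi_names)
    conn_rows, alff_rows = {}, {}
    for sid in labels["subject_id"]:
        ts = np.asarray(
            pio.load_volume(_require(out / "cohort" / f"{sid}_ts.nii", "features")),
            dtype=np.float64,
        )
        roi_ts = ff.roi_mean_timeseries(ts, parc)
        conn_rows[sid] = ff.connectivity(roi_ts, parc.roi_names).z_vector
        alff_rows[sid] = ff.lobe_alff(ts, parc, config.cohort)
    conn = pd.DataFrame.from_dict(conn_rows, orient="index", columns=conn_cols)
    alff = pd.DataFrame.from_dict(alff_rows, orient="index", columns=alff_cols)
    conn.index.name = alff.index.name = "subject_id"
    pio.save_table(conn, d / "connectivity.csv")
    pio.save_table(alff, d / "alff.csv")
    return ["features/connectivity.csv", "features/alff.csv"], {
        "n_connectivity_features": conn.shape[1],
        "n_alff_features": alff.shape[1],
    }


def _stage_stats(config: RunConfig, out: Path):
    d = out / "stats"
    d.mkdir(exist_ok=True)
    labels = _load_labels(out, "stats")
    parc = _load_parcellation(out, "stats")
    inb = parc.brain_mask
    maps = {g: [] for g in (sc.PTE, sc.NONPTE)}
    for sid, group in zip(labels["subject_id"], labels["group"]):
        smap = np.asarray(
            pio.load_volume(_require(out / "lesions" / f"{sid}_score.nii", "stats")),
            dtype=np.float64,
        )
        maps[group].append(smap[inb])
    stat = gs.permutation_f_test(
        np.stack(maps[sc.PTE]),
        np.stack(maps[sc.NONPTE]),
        nperm=config.nperm,
        seed=config.seed,
        q=config.q,
    )
    fvol = np.zeros(inb.shape, dtype=np.float32)
    pvol = np.ones(inb.shape, dtype=np.float32)
    mvol = np.zeros(inb.shape, dtype=np.uint8)
    fvol[inb] = np.nan_to_num(stat.F, posinf=np.finfo(np.float32).max)
    pvol[inb] = stat.p_raw
    mvol[inb] = stat.p_fdr_mask
    pio.save_volume(fvol, d / "lesion_F.nii")
    pio.save_volume(pvol, d / "lesion_p.nii")
    pio.save_volume(mvol, d / "lesion_sig_fdr.nii")
    pio.save_orthoslices(fvol, d / "lesion_F.png", title="lesion-score variance F")

    lesions = pio.load_table(_require(out / "lesions" / "lesion_volumes.csv", "stats"))
    alff = pio.load_table(_require(out / "features" / "alff.csv", "stats"))
    feats = lesions.join(alff)
    lab = labels.set_index("subject_id").loc[feats.index, "group"]
    table = gs.region_tests(
        feats, lab.to_numpy(), parc.roi_names, nperm=config.nperm, seed=config.seed,
        q=config.q,
    )
    pio.save_table(table, d / "region_tests.tsv", index=False)
    return (
        ["stats/lesion_F.nii", "stats/lesion_p.nii", "stats/lesion_sig_fdr.nii",
         "stats/region_tests.tsv", "stats/lesion_F.png"],
        {
            "n_sig_voxels_fdr": int(stat.p_fdr_mask.sum()),
            "sig_rois_lesion": table.loc[table.sig_lesion, "roi"].tolist(),
            "sig_rois_alff": table.loc[table.sig_alff, "roi"].tolist(),
        },
    )


def _stage_classify(config: RunConfig, out: Path):
    d = out / "classify"
    d.mkdir(exist_ok=True)
    labels = _load_labels(out, "classify")
    parc = _load_parcellation(out, "classify")
    lesions = pio.load_table(_require(out / "lesions" / "lesion_volumes.csv", "classify"))
    conn = pio.load_table(_require(out / "features" / "connectivity.csv", "classify"))
    alff = pio.load_table(_require(out / "features" / "alff.csv", "classify"))
    lab = labels.set_index("subject_id")["group"]
    table = cls.assemble_features(lesions, conn, alff, lab, roi_names=parc.roi_names)

    result = cls.nested_cv_auc(table, config.cv)
    summaries = {"auc_mean": result.mean, "auc_sd": result.sd}
    results_json = {
        "method": config.cv.method,
        "auc_mean": result.mean,
        "auc_sd": result.sd,
        "n_repeats": config.cv.n_repeats,
    }
    outputs = ["classify/results.json"]

    if config.n_null > 0:
        null = cls.permutation_auc_null(table, config.cv, n_null=config.n_null,
                                        observed=result)
        pd.DataFrame({"null_auc": null.null_auc_samples}).to_csv(
            d / "null_auc.tsv", sep="\t", index=False
        )
        results_json["null_auc_mean"] = float(null.null_auc_samples.mean())
        results_json["ranksum_p_vs_null"] = null.ranksum_p
        outputs.append("classify/null_auc.tsv")
        _plot_null(null, result, d / "null_auc.png")
        outputs.append("classify/null_auc.png")

    if config.cv.method in ("svm", "ksvm"):
        imp, roi_imp = cls.svm_feature_importance(table, config.cv, parc.roi_names)
        imp.rename("importance").to_frame().to_csv(d / "importance.tsv", sep="\t")
        roi_map = np.zeros(parc.label_volume.shape, dtype=np.float32)
        for (roi_id, name) in parc.roi_table:
            roi_map[parc.label_volume == roi_id] = roi_imp[name]
        pio.save_volume(roi_map, d / "importance_roi.nii")
        summaries["top_roi_importance"] = str(roi_imp.idxmax())
        outputs += ["classify/importance.tsv", "classify/importance_roi.nii"]

    if config.learning_curve_grid:
        curve = cls.learning_curve(table, config.cv, config.learning_curve_grid)
        pd.DataFrame(
            {"n": curve.n_values, "mean_auc": curve.mean_auc, "sd_auc": curve.sd_auc}
        ).to_csv(d / "learning_curve.tsv", sep="\t", index=False)
        _plot_curve(curve, d / "learning_curve.png")
        outputs += ["classify/learning_curve.tsv", "classify/learning_curve.png"]
        if curve.n_values.size >= 3:
            ext = cls.extrapolate_auc(curve, min(6, curve.n_values.size), 100)
            results_json["extrapolated_auc_n100"] = ext.predicted_auc

    pio.save_json(results_json, d / "results.json")
    summaries.update({k: v for k, v in results_json.items() if k != "method"})
    return outputs, summaries


def _plot_null(null: cls.NullAUC, result: cls.CVResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(null.kde_grid, null.kde_density, label="null (permuted labels)")
    ax.axvline(result.mean, color="r", label=f"observed mean {result.mean:.2f}")
    ax.set_xlabel("AUC")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_curve(curve: cls.LearningCurve, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(curve.n_values, curve.mean_auc, yerr=curve.sd_auc, marker="o")
    ax.set_xlabel("subjects")
    ax.set_ylabel("mean AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
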