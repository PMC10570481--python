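"""End-to-end orchestration: simulate -> extract -> cluster -> dtci ->
classify -> stats, with one master seed, cached stage artifacts, and a
checksummed run manifest.

Each stage writes its outputs under the run directory and records them in
``manifest.json`` with SHA-256 checksums and the seeds it derived from the
master seed.  A stage (or a single K within the cluster stage) is skipped
on re-run when its artifacts exist and its configuration hash is unchanged,
so interrupted runs resume and deleting one artifact rebuilds only that
artifact.  Two runs with the same configuration and master seed produce
bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._common import FEATURES, derive_seed, logger
from . import classify as _classify
from . import clustering as _clustering
from . import profiles as _profiles
from . import stats as _stats
from . import synthetic as _synthetic
from .features import (
    normalize_features,
    pool_voxels,
    read_subject,
    save_normalization_record,
)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline"]

STAGES = ("simulate", "extract", "cluster", "dtci", "classify", "stats")
GROUPINGS = ("who_grade", "mib1")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "dtci-run"
    input_dir: str | None = None  # existing cohort; None -> simulate
    seed: int = 0
    # simulation
    n_low: int = 19
    n_high: int = 8
    n_archetypes: int = 6
    separation: float = 0.5
    noise: float = 0.05
    shift_magnitude: float = _synthetic.DEFAULT_SHIFT_MAGNITUDE
    concentration: float = _synthetic.DEFAULT_CONCENTRATION
    brain_factor: float = _synthetic.DEFAULT_BRAIN_FACTOR
    roi_size_range: tuple[int, int] | None = None
    # clustering
    som_rows: int = 20
    som_cols: int = 20
    som_epochs: int = 50
    k_sweep: tuple[int, ...] = (4, 6, 8, 10, 12, 16, 20)
    scope: str = "brain"  # SOM training / DTcI scope
    weighted_nodes: bool = True
    # profiles / classification
    epsilon: float = 1e-3
    n_rep: int = 100
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    reseed_clustering: bool = True
    nested_cv: bool = False
    mib1_threshold_percent: float = 5.0
    n_boot: int = 2000
    dtci_volumes_for_k: tuple[int, ...] | None = None  # None -> profiles only

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_sweep"] = list(self.k_sweep)
        if self.roi_size_range is not None:
            d["roi_size_range"] = list(self.roi_size_range)
        if self.dtci_volumes_for_k is not None:
            d["dtci_volumes_for_k"] = list(self.dtci_volumes_for_k)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**doc)
        for name in ("k_sweep", "roi_size_range", "dtci_volumes_for_k"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violated constraints (empty = valid)."""
    v: list[str] = []
    if not config.k_sweep:
        v.append("k_sweep must be non-empty")
    if any(k < 2 for k in config.k_sweep):
        v.append("every K in k_sweep must be >= 2")
    if config.mib1_threshold_percent <= 0:
        v.append("mib1_threshold_percent must be positive")
    if config.scope not in ("brain", "roi"):
        v.append("scope must be 'brain' or 'roi'")
    if config.n_rep < 2:
        v.append("n_rep must be >= 2")
    if config.epsilon <= 0:
        v.append("epsilon must be positive")
    if config.som_rows < 2 or config.som_cols < 2:
        v.append("SOM grid must be at least 2x2")
    if config.separation < 0:
        v.append("separation must be non-negative")
    if config.input_dir is None and (config.n_low < 2 or config.n_high < 2):
        v.append("need at least 2 subjects per group")
    return v


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def artifact_checksums(self) -> dict[str, str]:
        out = {}
        for stage in self.stages.values():
            out.update(stage.get("artifacts", {}))
        return out

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        doc = json.loads(path.read_text())
        return cls(config=doc["config"], version=doc["version"], stages=doc["stages"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _stage_hash(config: RunConfig, stage: str) -> str:
    relevant = {
        "simulate": ("input_dir", "seed", "n_low", "n_high", "n_archetypes",
                     "separation", "noise", "shift_magnitude", "concentration",
                     "brain_factor", "roi_size_range"),
        "extract": ("scope",),
        "cluster": ("som_rows", "som_cols", "som_epochs", "scope",
                    "weighted_nodes", "seed"),
        "dtci": ("k_sweep", "epsilon", "dtci_volumes_for_k"),
        "classify": ("k_sweep", "epsilon", "n_rep", "svm_kernel", "svm_c",
                     "reseed_clustering", "nested_cv", "mib1_threshold_percent",
                     "seed"),
        "stats": ("k_sweep", "n_boot", "seed"),
    }[stage]
    doc = {k: getattr(config, k) for k in relevant}
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=list).encode()
    ).hexdigest()[:16]


class _Run:
    """Mutable state threaded through the pipeline stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        from . import __version__

        mpath = self.out / "manifest.json"
        if mpath.exists():
            self.manifest = RunManifest.load(mpath)
            if self.manifest.config != config.to_dict():
                logger.info("configuration changed; stale stages will be rebuilt")
        else:
            self.manifest = RunManifest(config=config.to_dict(), version=__version__)
        self.manifest.config = config.to_dict()
        self.subjects = None  # list[(ParameterMaps, TumorROI)] normalized
        self.cohort = None
        self.grid = None
        self.partitions: dict[int, _clustering.ClassPartition] = {}
        self.node_weights = None
        self.train_pool = None
        self.roi_pool = None
        self.roi_node_counts = None
        self.roi_subject_ids = None
        self.cv_results: dict = {}

    # -- caching helpers ----------------------------------------------------
    def stage_cached(self, stage: str, artifacts: list[Path]) -> bool:
        rec = self.manifest.stages.get(stage)
        if rec is None or rec.get("hash") != _stage_hash(self.config, stage):
            return False
        known = rec.get("artifacts", {})
        for p in artifacts:
            key = str(p.relative_to(self.out))
            if key not in known or not p.exists():
                return False
        return True

    def record_stage(self, stage: str, artifacts: list[Path], seeds: dict,
                     elapsed: float) -> None:
        self.manifest.stages[stage] = {
            "hash": _stage_hash(self.config, stage),
            "artifacts": {
                str(p.relative_to(self.out)): _sha256(p) for p in sorted(artifacts)
            },
            "seeds": seeds,
            "elapsed_s": round(elapsed, 3),
        }
        self.manifest.save(self.out / "manifest.json")


def run_pipeline(config: RunConfig, last_stage: str = "stats") -> RunManifest:
    """Execute the pipeline through ``last_stage`` and return the manifest."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    run = _Run(config)
    for stage in STAGES[: STAGES.index(last_stage) + 1]:
        t0 = time.perf_counter()
        globals()[f"_stage_{stage}"](run)
        logger.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
    return run.manifest


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    data_dir = run.out / "data"
    if cfg.input_dir is not None:
        return  # real/previously written cohort supplied
    cohort_path = data_dir / "cohort.csv"
    if run.stage_cached("simulate", [cohort_path, data_dir / "truth.json"]):
        return
    t0 = time.perf_counter()
    sim_seed = derive_seed(cfg.seed, "simulate")
    palette = _synthetic.make_archetype_palette(
        cfg.n_archetypes, cfg.separation, derive_seed(sim_seed, "palette"), cfg.noise
    )
    w_low = _synthetic.default_group_weights(palette)
    shift = _synthetic.necrosis_shift(w_low, palette, cfg.shift_magnitude)
    subjects, cohort, truth = _synthetic.simulate_cohort(
        n_per_group=(cfg.n_low, cfg.n_high),
        group_weight_shift=shift,
        palette=palette,
        seed=sim_seed,
        concentration=cfg.concentration,
        brain_factor=cfg.brain_factor,
        roi_size_range=cfg.roi_size_range,
    )
    _synthetic.write_cohort(subjects, cohort, truth, data_dir)
    artifacts = sorted(data_dir.glob("*.nii")) + [cohort_path, data_dir / "truth.json"]
    run.record_stage("simulate", artifacts, {"simulate": sim_seed},
                     time.perf_counter() - t0)


def _data_dir(run: _Run) -> Path:
    return Path(run.config.input_dir) if run.config.input_dir else run.out / "data"


def _load_subjects(run: _Run) -> None:
    if run.subjects is not None:
        return
    data = _data_dir(run)
    cohort = pd.read_csv(data / "cohort.csv")
    _stats.validate_cohort(cohort, run.config.mib1_threshold_percent)
    subjects = []
    for sid in cohort.subject_id:
        maps, roi = read_subject(data, sid)
        subjects.append((normalize_features(maps), roi))
    run.subjects = subjects
    run.cohort = cohort


def _stage_extract(run: _Run) -> None:
    work = run.out / "work"
    work.mkdir(exist_ok=True)
    norm_path = work / "normalization.json"
    t0 = time.perf_counter()
    _load_subjects(run)
    run.train_pool = pool_voxels(run.subjects, scope=run.config.scope)
    run.roi_pool = (
        run.train_pool
        if run.config.scope == "roi"
        else pool_voxels(run.subjects, scope="roi")
    )
    save_normalization_record([m for m, _ in run.subjects], norm_path)
    counts = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m, _ in run.subjects],
            "n_brain_voxels": [int(m.brain_mask.sum()) for m, _ in run.subjects],
            "n_roi_voxels": [r.n_voxels for _, r in run.subjects],
        }
    )
    counts_path = work / "voxel_counts.csv"
    counts.to_csv(counts_path, index=False)
    run.record_stage("extract", [norm_path, counts_path], {}, time.perf_counter() - t0)


def _stage_cluster(run: _Run) -> None:
    """Train (or reload) the SOM, then partition it for every K in the sweep.

    Caching is per artifact: with an unchanged stage configuration an
    existing codebook is reloaded instead of retrained, and only missing
    partition files are recomputed — deleting one ``partition_k*.json``
    rebuilds exactly that K.
    """
    cfg = run.config
    work = run.out / "work"
    t0 = time.perf_counter()
    fresh = _stage_hash(cfg, "cluster") == run.manifest.stages.get(
        "cluster", {}
    ).get("hash")
    som_seed = derive_seed(cfg.seed, "som")
    codebook_path = work / "som_codebook.csv"
    if fresh and codebook_path.exists():
        codebook = pd.read_csv(codebook_path).to_numpy(dtype=float)
        run.grid = _clustering.SOMGrid(
            rows=cfg.som_rows, cols=cfg.som_cols, codebook=codebook,
            seed=som_seed, epochs=cfg.som_epochs,
        )
    else:
        run.grid = _clustering.train_som(
            run.train_pool, rows=cfg.som_rows, cols=cfg.som_cols,
            epochs=cfg.som_epochs, seed=som_seed,
        )
        pd.DataFrame(run.grid.codebook, columns=list(FEATURES)).to_csv(
            codebook_path, index=False, float_format="%.17g"
        )
    run.node_weights = (
        _clustering.node_voxel_counts(run.grid, run.train_pool.X)
        if cfg.weighted_nodes
        else None
    )
    run.roi_node_counts, run.roi_subject_ids = _profiles.node_count_matrix(
        run.grid, run.roi_pool
    )
    artifacts = [codebook_path]
    seeds = {"som": som_seed}
    for K in cfg.k_sweep:
        km_seed = derive_seed(cfg.seed, "km", K)
        part_path = work / f"partition_k{K}.json"
        planes_path = work / f"component_planes_k{K}.csv"
        if fresh and part_path.exists() and planes_path.exists():
            doc = json.loads(part_path.read_text())
            part = _clustering.ClassPartition(
                K=K,
                node_to_class=np.asarray(doc["node_to_class"]),
                class_centroids=np.asarray(doc["class_centroids"]),
                seed=doc["seed"],
                wcss=doc["wcss"],
                ordering=doc["ordering"],
            )
        else:
            part = _clustering.cluster_protoclusters(
                run.grid, K, seed=km_seed, node_weights=run.node_weights
            )
            part_path.write_text(
                json.dumps(
                    {
                        "K": K,
                        "seed": km_seed,
                        "wcss": part.wcss,
                        "ordering": part.ordering,
                        "node_to_class": part.node_to_class.tolist(),
                        "class_centroids": part.class_centroids.tolist(),
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            planes = _clustering.export_component_planes(run.grid, part)
            rows = []
            for f, plane in planes.planes.items():
                for r in range(plane.shape[0]):
                    for c in range(plane.shape[1]):
                        rows.append({"feature": f, "row": r, "col": c,
                                     "value": plane[r, c],
                                     "class": int(planes.class_map[r, c])})
            pd.DataFrame(rows).to_csv(planes_path, index=False,
                                      float_format="%.17g")
        run.partitions[K] = part
        artifacts += [part_path, planes_path]
        seeds[f"km_k{K}"] = km_seed
    run.record_stage("cluster", artifacts, seeds, time.perf_counter() - t0)


def _log_ratio_features(run: _Run, partition) -> np.ndarray:
    counts = _profiles.class_counts_from_nodes(run.roi_node_counts, partition)
    profs = _profiles.profiles_from_counts(
        counts, run.roi_subject_ids, partition.K, epsilon=run.config.epsilon
    )
    return np.stack([p.log_ratios for p in profs])


def _stage_dtci(run: _Run) -> None:
    cfg = run.config
    work = run.out / "work"
    t0 = time.perf_counter()
    artifacts = []
    for K in cfg.k_sweep:
        part = run.partitions[K]
        counts = _profiles.class_counts_from_nodes(run.roi_node_counts, part)
        profs = _profiles.profiles_from_counts(
            counts, run.roi_subject_ids, K, epsilon=cfg.epsilon
        )
        ppath = work / f"profiles_k{K}.csv"
        _profiles.profiles_to_frame(profs).to_csv(
            ppath, index=False, float_format="%.17g"
        )
        artifacts.append(ppath)
        if cfg.dtci_volumes_for_k and K in cfg.dtci_volumes_for_k:
            import nibabel as nib

            vol_dir = run.out / "dtci_volumes"
            vol_dir.mkdir(exist_ok=True)
            for maps, roi in run.subjects:
                dtci = _profiles.build_dtci(maps, run.grid, part, scope=cfg.scope,
                                            roi=roi)
                vpath = vol_dir / f"{maps.subject_id}_dtci_k{K}.nii"
                nib.save(
                    nib.Nifti1Image(dtci.labels.astype(np.int16), maps.affine),
                    vpath,
                )
                artifacts.append(vpath)
    run.record_stage("dtci", artifacts, {}, time.perf_counter() - t0)


def _labels_for(run: _Run, grouping: str) -> np.ndarray:
    cohort = run.cohort.set_index("subject_id").loc[run.roi_subject_ids]
    if grouping == "who_grade":
        return (cohort.grade_group == "high").to_numpy().astype(int)
    if grouping == "mib1":
        return (
            cohort.mib1_li_percent >= run.config.mib1_threshold_percent
        ).to_numpy().astype(int)
    raise ValueError(f"unknown grouping {grouping!r}")


def _nested_repeat_loocv(run: _Run, K: int, grouping: str, labels) -> _classify.CVResult:
    """Leakage-free mode: re-partition the SOM from training-fold node
    weights inside every LOOCV fold."""
    cfg = run.config
    n = len(labels)
    rows = []
    for rep in range(cfg.n_rep):
        seed = derive_seed(cfg.seed, grouping, K, "nested-rep", rep)
        decisions = np.empty(n)
        preds = np.empty(n, dtype=int)
        for i in range(n):
            tr = np.arange(n) != i
            w = run.roi_node_counts[tr].sum(axis=0).astype(float)
            part = _clustering.cluster_protoclusters(
                run.grid, K, seed=derive_seed(seed, "fold", i), node_weights=w
            )
            F = _log_ratio_features(run, part)
            from sklearn.preprocessing import StandardScaler
            from sklearn.svm import SVC

            scaler = StandardScaler().fit(F[tr])
            clf = SVC(kernel=cfg.svm_kernel, C=cfg.svm_c)
            clf.fit(scaler.transform(F[tr]), labels[tr])
            decisions[i] = clf.decision_function(scaler.transform(F[i : i + 1]))[0]
            preds[i] = clf.predict(scaler.transform(F[i : i + 1]))[0]
        tp = int(((preds == 1) & (labels == 1)).sum())
        tn = int(((preds == 0) & (labels == 0)).sum())
        rows.append(
            {
                "repetition": rep, "seed": seed,
                "auc": _classify.auc_mann_whitney(decisions, labels),
                "sensitivity": tp / (labels == 1).sum(),
                "specificity": tn / (labels == 0).sum(),
                "accuracy": (tp + tn) / n,
                "decisions": decisions, "predictions": preds,
            }
        )
    return _classify.CVResult(K=K, grouping=grouping, records=pd.DataFrame(rows))


def _stage_classify(run: _Run) -> None:
    cfg = run.config
    res_dir = run.out / "results"
    res_dir.mkdir(exist_ok=True)
    t0 = time.perf_counter()
    artifacts = []
    run.cv_results = {}
    for grouping in GROUPINGS:
        labels = _labels_for(run, grouping)
        results: dict[int, _classify.CVResult] = {}
        if cfg.nested_cv:
            for K in cfg.k_sweep:
                results[K] = _nested_repeat_loocv(run, K, grouping, labels)
            table = pd.concat(
                [
                    r.records.assign(K=K)[["K", "repetition", *_classify.METRICS]]
                    for K, r in results.items()
                ],
                ignore_index=True,
            )
        else:
            builders = {}
            for K in cfg.k_sweep:
                part = run.partitions[K]
                if cfg.reseed_clustering:
                    builders[K] = (
                        lambda seed, K=K: _log_ratio_features(
                            run,
                            _clustering.cluster_protoclusters(
                                run.grid, K, seed=seed,
                                node_weights=run.node_weights,
                            ),
                        )
                    )
                else:
                    builders[K] = _log_ratio_features(run, part)
            results, table = _classify.sweep_k(
                builders, labels, grouping=grouping, n_rep=cfg.n_rep,
                master_seed=cfg.seed, C=cfg.svm_c, kernel=cfg.svm_kernel,
            )
        run.cv_results[grouping] = results
        table_path = res_dir / f"metrics_{grouping}.csv"
        table.to_csv(table_path, index=False, float_format="%.10g")
        summary = {
            str(K): res.summary for K, res in sorted(results.items())
        }
        best_k = max(results, key=lambda K: results[K].summary["auc"]["mean"])
        summary["best_K"] = best_k
        sum_path = res_dir / f"summary_{grouping}.json"
        sum_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        # ROC of the best K from per-subject mean decision values across reps
        best = results[best_k]
        dec = np.mean(np.stack(best.records["decisions"].to_list()), axis=0)
        roc = _classify.roc_with_ci(dec, labels, method="delong")
        roc_path = res_dir / f"roc_{grouping}_k{best_k}.csv"
        pd.DataFrame(
            {"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}
        ).to_csv(roc_path, index=False, float_format="%.10g")
        artifacts += [table_path, sum_path, roc_path]
    run.record_stage("classify", artifacts, {}, time.perf_counter() - t0)


def _stage_stats(run: _Run) -> None:
    cfg = run.config
    res_dir = run.out / "results"
    t0 = time.perf_counter()
    artifacts = []
    intensity_cache: dict[int, pd.DataFrame] = {}
    for grouping in GROUPINGS:
        table = pd.read_csv(res_dir / f"metrics_{grouping}.csv")
        if len(cfg.k_sweep) >= 2:
            anova, tukey = _stats.anova_tukey(table, value="auc", group="K")
            doc = {
                "anova": dataclasses.asdict(anova),
                "tukey": tukey.table.to_dict(orient="records"),
            }
            apath = res_dir / f"anova_{grouping}.json"
            apath.write_text(json.dumps(doc, indent=1, sort_keys=True, default=float))
            artifacts.append(apath)
        best_k = json.loads(
            (res_dir / f"summary_{grouping}.json").read_text()
        )["best_K"]
        labels = _labels_for(run, grouping)
        F = _log_ratio_features(run, run.partitions[best_k])
        comp = _stats.per_class_group_comparison(
            F, labels, seed=derive_seed(cfg.seed, "wmw", grouping)
        )
        cpath = res_dir / f"log_ratio_tests_{grouping}_k{best_k}.csv"
        comp.to_csv(cpath, index=False, float_format="%.10g")
        artifacts.append(cpath)
        # per-class six-feature intensity profiles over tumor voxels
        # (grouping-independent; cached per distinct best K)
        if best_k not in intensity_cache:
            part = run.partitions[best_k]
            voxel_classes = _clustering.assign_voxel_classes(
                run.grid, part, run.roi_pool.X
            )
            profs = _profiles.class_intensity_profiles(
                run.roi_pool.X, voxel_classes, best_k, n_boot=cfg.n_boot,
                seed=derive_seed(cfg.seed, "boot", best_k),
            )
            intensity_cache[best_k] = _profiles.intensity_profiles_to_frame(profs)
        rpath = res_dir / f"class_intensity_k{best_k}.csv"
        intensity_cache[best_k].to_csv(rpath, index=False, float_format="%.10g")
        artifacts.append(rpath)
    run.record_stage("stats", artifacts, {}, time.perf_counter() - t0)
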