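"""End-to-end driver: population -> alignment -> correspondence -> shape
models -> cut planes -> morphometrics -> statistics -> classification.

The pipeline either generates a synthetic population or loads a directory of
meshes with a manifest CSV (columns: id, gender, side, file).  Every stage
is deterministic for a fixed configuration and seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import align, classify, correspond, pdm, sections, stats
from .mesh import read_mesh, require_pipeline_mesh
from .synthetic import LabeledMesh, PopulationConfig, sample_population

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "load_manifest_population"]

log = logging.getLogger("radshape")


@dataclass
class PipelineConfig:
    """Configuration of a full run; every knob that affects output lives here."""

    population: PopulationConfig | None = None  # generate if set
    input_dir: str | None = None  # else load meshes + manifest.csv
    reference_id: str | None = None  # ICP reference; default first specimen
    n_landmarks: int = 2000
    gpa_scaling: bool = False
    variance_threshold: float = 0.95
    n_trees: int = 50
    n_iterations: int = 100
    classifier_seed: int = 0
    template_seed: int = 0
    feature_source: str = "coefficients"
    run_classification: bool = True
    run_icp: bool = True  # skip for data already in the standardized frame
    icp_max_iter: int = 60
    icp_sample: int = 2000  # source points participating in ICP
    # template-projection guard; None -> 30% of the reference bbox diagonal
    # (mirror-image specimens legitimately project ~2x the styloid offset)
    guard_distance: float | None = None
    mean_mesh_analysis: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.population is None and self.input_dir is None:
            raise ValueError("configure either a synthetic population or an input_dir")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultBundle:
    """Everything a run produces, reproducible from config + seeds."""

    config: PipelineConfig
    models: dict[str, pdm.PDMResults]
    mode_counts: pd.DataFrame
    records: list[classify.SpecimenRecord]
    morphometrics: pd.DataFrame
    descriptives: pd.DataFrame
    tests: dict
    classification: dict[str, classify.AccuracySummary]
    mean_shape_morphometrics: dict[str, sections.Morphometrics] | None
    config_hash: str = ""
    run_log: list[str] = None


def load_manifest_population(input_dir: str) -> list[LabeledMesh]:
    """Load meshes listed in ``<input_dir>/manifest.csv`` (id, gender, side, file)."""
    root = Path(input_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        mesh = read_mesh(str(root / row["file"]))
        out.append(LabeledMesh(
            mesh=mesh, gender=str(row["gender"]), side=str(row["side"]),
            truth_landmarks={}, truth_params=None, specimen_id=str(row["id"]),
        ))
    return out


def _stage(name: str, t0: float, timings: list[str]) -> float:
    t1 = time.time()
    line = f"stage {name:<16s} {t1 - t0:6.2f} s"
    log.info("%s", line)
    timings.append(line)
    return t1


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full workflow; see the module docstring for the stages."""
    timings: list[str] = []
    t0 = time.time()
    if config.population is not None:
        specimens = sample_population(config.population)
    else:
        specimens = load_manifest_population(config.input_dir)
    if not specimens:
        raise RuntimeError("stage load: no specimens")
    t0 = _stage("load/generate", t0, timings)

    for spec in specimens:
        try:
            require_pipeline_mesh(spec.mesh, name=spec.specimen_id)
        except ValueError as exc:
            raise RuntimeError(f"stage validate, specimen {spec.specimen_id}: {exc}") from exc
    t0 = _stage("validate", t0, timings)

    ids = [s.specimen_id for s in specimens]
    ref_idx = 0 if config.reference_id is None else ids.index(config.reference_id)
    reference = specimens[ref_idx]

    transforms: dict[str, align.RigidTransform] = {}
    registered: dict[str, trimesh.Trimesh] = {}
    for spec in specimens:
        if spec is reference or not config.run_icp:
            xf = align.RigidTransform.identity()
        else:
            init = align.principal_axes_init(spec.mesh.vertices, reference.mesh.vertices)
            xf, rms, _ = align.rigid_icp(
                spec.mesh, reference.mesh, init=init,
                max_iter=config.icp_max_iter, sample=config.icp_sample,
            )
            log.debug("ICP %s: rms %.4f mm", spec.specimen_id, rms)
        transforms[spec.specimen_id] = xf
        registered[spec.specimen_id] = trimesh.Trimesh(
            xf.apply(spec.mesh.vertices), spec.mesh.faces, process=False
        )
    t0 = _stage("register", t0, timings)

    n_landmarks = min(config.n_landmarks, len(reference.mesh.vertices))
    template = correspond.farthest_point_template(
        reference.mesh, n=n_landmarks, seed=config.template_seed
    )
    guard = config.guard_distance
    if guard is None:
        guard = 0.3 * float(np.linalg.norm(reference.mesh.extents))
    shapes = [
        correspond.correspond_to_template(
            template, registered[s.specimen_id], specimen_id=s.specimen_id,
            guard_distance=guard,
        )
        for s in specimens
    ]
    t0 = _stage("correspond", t0, timings)

    aligned, gpa_mean, _ = align.generalized_procrustes(
        [s.points for s in shapes], allow_scaling=config.gpa_scaling
    )
    aligned_shapes = [
        correspond.CorrespondedShape(a, specimen_id=i) for a, i in zip(aligned, ids)
    ]
    t0 = _stage("procrustes", t0, timings)

    groups = {
        "overall": ids,
        "female": [i for s, i in zip(specimens, ids) if s.gender == "F"],
        "male": [i for s, i in zip(specimens, ids) if s.gender == "M"],
        "left": [i for s, i in zip(specimens, ids) if s.side == "L"],
        "right": [i for s, i in zip(specimens, ids) if s.side == "R"],
    }
    models: dict[str, pdm.PDMResults] = {}
    mode_rows = []
    for name, members in groups.items():
        subset = [a for a, i in zip(aligned_shapes, ids) if i in set(members)]
        if len(subset) < 2:
            continue
        models[name] = pdm.build_pdm(subset, ids=list(members))
        mode_rows.append({
            "model": name,
            "n_specimens": len(subset),
            "num_modes": models[name].num_modes(config.variance_threshold),
            "first_mode_fraction": float(models[name].explained_variance_ratio[0])
            if len(models[name].eigenvalues) else float("nan"),
        })
    mode_counts = pd.DataFrame(mode_rows)
    t0 = _stage("shape models", t0, timings)

    records: list[classify.SpecimenRecord] = []
    overall = models["overall"]
    for spec, shape in zip(specimens, aligned_shapes):
        mesh_std = registered[spec.specimen_id]
        try:
            landmarks = sections.detect_landmarks(mesh_std)
            morpho = sections.specimen_morphometrics(mesh_std, landmarks)
        except ValueError as exc:
            raise RuntimeError(
                f"stage cutplanes, specimen {spec.specimen_id}: {exc}"
            ) from exc
        records.append(classify.SpecimenRecord(
            specimen_id=spec.specimen_id, gender=spec.gender, side=spec.side,
            coefficients=overall.project(shape), morphometrics=morpho,
        ))
    morpho_frame = stats.records_to_frame(records)
    t0 = _stage("cut planes", t0, timings)

    descriptives = stats.group_descriptives(morpho_frame, by=("plane", "gender", "side"))
    tests: dict = {"gender": {}, "side": {}, "anova": {}}
    for param in stats.PARAMETERS:
        tests["gender"][param] = stats.compare_gender_side(morpho_frame, param, "gender")
        tests["side"][param] = stats.compare_gender_side(morpho_frame, param, "side")
        tests["anova"][param] = stats.compare_planes_anova(morpho_frame, param)
    t0 = _stage("statistics", t0, timings)

    classification: dict[str, classify.AccuracySummary] = {}
    if config.run_classification:
        common = dict(
            n_trees=config.n_trees, n_iterations=config.n_iterations,
            seed=config.classifier_seed, feature_source=config.feature_source,
        )
        classification["side"] = classify.loocv_random_forest(records, "side", **common)
        classification["gender"] = classify.loocv_random_forest(records, "gender", **common)
        classification["stepwise"] = classify.stepwise_side_then_gender(records, **common)
        t0 = _stage("classification", t0, timings)

    mean_morpho = None
    if config.mean_mesh_analysis:
        mean_mesh = _mean_shape_mesh(reference, registered, ids, guard)
        try:
            mean_morpho = sections.specimen_morphometrics(mean_mesh)
        except ValueError as exc:  # pragma: no cover - degenerate mean
            log.warning("mean-shape morphometrics failed: %s", exc)
        t0 = _stage("mean shape", t0, timings)

    bundle = ResultBundle(
        config=config, models=models, mode_counts=mode_counts, records=records,
        morphometrics=morpho_frame, descriptives=descriptives, tests=tests,
        classification=classification, mean_shape_morphometrics=mean_morpho,
        config_hash=config.config_hash(), run_log=timings,
    )
    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _mean_shape_mesh(reference, registered: dict, ids: list[str],
                     guard: float) -> trimesh.Trimesh:
    """Mean surface via dense (vertex-level) correspondence to the reference."""
    ref_mesh = reference.mesh
    template = correspond.CorrespondedShape(np.asarray(ref_mesh.vertices), "reference")
    acc = np.zeros_like(template.points)
    for i in ids:
        shape = correspond.correspond_to_template(
            template, registered[i], specimen_id=i, guard_distance=guard
        )
        acc += shape.points
    return trimesh.Trimesh(acc / len(ids), ref_mesh.faces, process=False)


def _write_bundle(bundle: ResultBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": bundle.config_hash}
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"config hash {bundle.config_hash}\n")
        fh.write("\n".join(bundle.run_log or []) + "\n")
    bundle.morphometrics.to_csv(outdir / "morphometrics.csv", index=False)
    bundle.descriptives.to_csv(outdir / "descriptives.csv")
    bundle.mode_counts.to_csv(outdir / "mode_counts.csv", index=False)
    for name, model in bundle.models.items():
        model.save(outdir / f"model_{name}.npz")
    coeffs = pd.DataFrame(
        [r.coefficients for r in bundle.records],
        index=[r.specimen_id for r in bundle.records],
    )
    coeffs.to_csv(outdir / "coefficients.csv")
    test_json: dict = {"bonferroni_alpha": stats.BONFERRONI_ALPHA, **meta}
    for family, results in bundle.tests.items():
        test_json[family] = {}
        for param, res in results.items():
            if isinstance(res, stats.TTestResult):
                test_json[family][param] = {
                    "t": res.statistic, "df": res.df, "p": res.pvalue,
                    "significant": bool(res.significant), "direction": res.direction,
                }
            else:
                test_json[family][param] = {
                    "F": res["F"], "p": res["p"],
                    "posthoc": res["posthoc"].to_dict(orient="records"),
                }
    with open(outdir / "tests.json", "w") as fh:
        json.dump(test_json, fh, indent=2)
    if bundle.classification:
        cls_json = {**meta}
        rows = []
        for label, summary in bundle.classification.items():
            cls_json[label] = {
                "median_accuracy": summary.median_accuracy,
                "n_iterations": summary.n_iterations,
                "seed": summary.seed,
                "confusion": {f"{a}->{b}": c for (a, b), c in summary.confusion.items()},
            }
            rows.extend(
                {"label": label, "iteration": i, "accuracy": a}
                for i, a in enumerate(summary.accuracies)
            )
        with open(outdir / "classification.json", "w") as fh:
            json.dump(cls_json, fh, indent=2)
        pd.DataFrame(rows).to_csv(outdir / "classification_iterations.csv", index=False)
    if bundle.mean_shape_morphometrics is not None:
        with open(outdir / "mean_shape_morphometrics.json", "w") as fh:
            json.dump(
                {k: m.as_dict() for k, m in bundle.mean_shape_morphometrics.items()},
                fh, indent=2,
            )
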