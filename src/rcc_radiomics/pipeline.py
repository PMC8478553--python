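"""End-to-end pipeline: generate -> extract -> ICC -> select -> fit -> evaluate.

Every stage writes re-loadable artifacts into the run directory; a rerun
with the same configuration reproduces them bit-exactly.  Each random
stage draws its seed from a named substream of the global seed, so
stages can be rerun individually from cached upstream files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_clinical_table, generate_cohort, read_cohort, write_cohort
from .features import (
    PHASES,
    ExtractionConfig,
    combine_phase_matrices,
    extract_feature_matrix,
)
from .icc import filter_features
from .metrics import confusion_matrix, delong_test, per_class_metrics
from .models import (
    CLASS_ORDER,
    build_binary_task,
    fit_traditional,
    repeated_binary_cv,
    repeated_stratified_cv,
)
from .selection import SelectionConfig, run_stability_selection

PHASE_MODELS = ("NCP", "CMP", "NP", "EP", "ALL-P")
BINARY_TASKS = ("ccRCC", "pRCC", "cRCC")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    icc_threshold: float = 0.80
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv_repeats: int = 50
    cv_folds: int = 5
    phases: tuple[str, ...] = PHASE_MODELS
    run_binary_tasks: bool = True
    run_traditional: bool = True
    seed: int = 0

    def __post_init__(self):
        # the global seed drives every stage through named substreams
        self.cohort.seed = self._stage_seed("cohort")
        self.selection.seed = self._stage_seed("selection")

    def _stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = list(self.phases)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            for tup in ("shape", "spacing", "radius_frac"):
                if tup in c:
                    c[tup] = tuple(c[tup])
            d["cohort"] = CohortConfig(**c)
        if "extraction" in d:
            d["extraction"] = ExtractionConfig(**d["extraction"])
        if "selection" in d:
            s = dict(d["selection"])
            if "alphas" in s:
                s["alphas"] = tuple(s["alphas"])
            d["selection"] = SelectionConfig(**s)
        if "phases" in d:
            d["phases"] = tuple(d["phases"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _model_seed(cfg: RunConfig, *parts) -> int:
    h = hashlib.sha256((":".join(map(str, (cfg.seed,) + parts))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: RunConfig, outdir: Path):
    cohort_dir = outdir / "cohort"
    if (cohort_dir / "manifest.json").exists():
        return read_cohort(cohort_dir)
    cohort = generate_cohort(cfg.cohort)
    write_cohort(cohort, cohort_dir)
    return cohort


def stage_extract(cfg: RunConfig, outdir: Path, cohort):
    feat_dir = outdir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    matrices = {}
    for rater in (1, 2):
        paths = {ph: feat_dir / f"features_r{rater}_{ph}.csv" for ph in PHASES}
        if all(p.exists() for p in paths.values()):
            matrices[rater] = {
                ph: pd.read_csv(p, index_col=0) for ph, p in paths.items()
            }
            continue
        matrices[rater] = extract_feature_matrix(cohort, rater=rater, config=cfg.extraction)
        for ph, df in matrices[rater].items():
            df.to_csv(paths[ph])
    (feat_dir / "extraction_settings.json").write_text(
        json.dumps(cfg.extraction.to_dict(), indent=2)
    )
    return matrices


def stage_icc(cfg: RunConfig, outdir: Path, matrices):
    icc_dir = outdir / "icc"
    icc_dir.mkdir(parents=True, exist_ok=True)
    retained = {}
    for ph in PHASES:
        path = icc_dir / f"icc_{ph}.csv"
        if path.exists():
            table = pd.read_csv(path, index_col=0)
            retained[ph] = table.index[table["retained"]].tolist()
            continue
        names, result = filter_features(
            matrices[1][ph], matrices[2][ph], threshold=cfg.icc_threshold
        )
        result.table.to_csv(path)
        retained[ph] = names
    return retained


def _model_matrices(cfg: RunConfig, matrices, retained) -> dict[str, pd.DataFrame]:
    """Rater-1 design matrix per phase model, ICC filter applied.

    ALL-P concatenates the per-phase ICC-retained features with phase
    prefixes (each phase keeps its own retained set).
    """
    out = {}
    per_phase = {ph: matrices[1][ph][retained[ph]] for ph in PHASES}
    for ph in cfg.phases:
        if ph == "ALL-P":
            full = combine_phase_matrices(matrices[1])
            cols = [f"{p}_{c}" for p in PHASES for c in retained[p]]
            out[ph] = full[cols]
        else:
            out[ph] = per_phase[ph]
    return out


def stage_select(cfg: RunConfig, outdir: Path, design, labels):
    sel_dir = outdir / "selection"
    sel_dir.mkdir(parents=True, exist_ok=True)
    selections = {}
    for name, X in design.items():
        path = sel_dir / f"selection_{name}.csv"
        scfg = dataclasses.replace(cfg.selection, seed=_model_seed(cfg, "select", name))
        if path.exists():
            rep = pd.read_csv(path, index_col=0)
            selections[name] = rep.index[rep["selected"]].tolist()
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_stability_selection(X, labels, scfg)
        result.report().to_csv(path)
        selected = result.selected
        if not selected:
            # fall back to the most frequently nonzero features over all
            # fits so downstream models stay defined; logged in report
            warnings.warn(f"{name}: empty selection; using all ICC-retained features")
            selected = list(X.columns)
        selections[name] = selected
    (sel_dir / "selection_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg.selection), indent=2, default=str)
    )
    return selections


def stage_evaluate(cfg: RunConfig, outdir: Path, design, selections, labels, clinical):
    model_dir = outdir / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"multiclass": {}, "binary": {}}
    classes = tuple(c for c in CLASS_ORDER if c in set(labels))

    for name in cfg.phases:
        X = design[name][selections[name]]
        preds, accs = repeated_stratified_cv(
            X, labels, k=cfg.cv_folds, repeats=cfg.cv_repeats,
            seed=_model_seed(cfg, "cv", name), classes=classes,
        )
        accs.to_csv(model_dir / f"cv_accuracy_{name}.csv", index=False)
        vote = (
            preds.groupby("subject")["predicted"]
            .agg(lambda s: s.value_counts().idxmax())
            .reindex(design[name].index)
        )
        cm = confusion_matrix(vote.to_numpy(), labels, classes=classes)
        cm.to_csv(model_dir / f"confusion_{name}.csv")
        mt = per_class_metrics(cm, classes=classes)
        mt.to_csv(model_dir / f"metrics_{name}.csv")
        report["multiclass"][name] = {
            "mean_cv_accuracy": float(accs["accuracy"].mean()),
            "n_selected_features": int(X.shape[1]),
        }

    if cfg.run_binary_tasks:
        mean_scores: dict[tuple[str, str], np.ndarray] = {}
        for pos in BINARY_TASKS:
            if pos not in set(labels):
                continue
            y01 = build_binary_task(labels, pos)
            for name in cfg.phases:
                Xb = design[name]
                scfg = dataclasses.replace(
                    cfg.selection, seed=_model_seed(cfg, "select", name, pos)
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sel = run_stability_selection(Xb, y01, scfg)
                cols = sel.selected or selections[name]
                ms, recs = repeated_binary_cv(
                    Xb[cols], y01, k=cfg.cv_folds, repeats=cfg.cv_repeats,
                    seed=_model_seed(cfg, "bincv", name, pos),
                )
                recs.to_csv(model_dir / f"binary_{pos}_{name}.csv", index=False)
                mean_scores[(pos, name)] = ms
                report["binary"][f"{pos}|{name}"] = {
                    "mean_auc": float(recs["auc"].mean()),
                    "mean_accuracy": float(recs["accuracy"].mean()),
                }
        # paired DeLong comparisons against the ALL-P model
        comparisons = []
        for pos in BINARY_TASKS:
            if ("ALL-P" not in cfg.phases) or (pos, "ALL-P") not in mean_scores:
                continue
            y01 = build_binary_task(labels, pos)
            for name in cfg.phases:
                if name == "ALL-P" or (pos, name) not in mean_scores:
                    continue
                rc = delong_test(mean_scores[(pos, "ALL-P")], mean_scores[(pos, name)], y01)
                comparisons.append(
                    {"task": pos, "model": name, "auc_allp": rc.auc_a,
                     "auc_model": rc.auc_b, "z": rc.z, "p_unadjusted": rc.p}
                )
        if comparisons:
            pd.DataFrame(comparisons).to_csv(model_dir / "delong_vs_allp.csv", index=False)

    if cfg.run_traditional and clinical is not None:
        try:
            from .models import clinical_design_matrix

            trad = fit_traditional(clinical, labels, classes=classes)
            design_t = clinical_design_matrix(clinical, trad.screened)
            preds, accs = repeated_stratified_cv(
                design_t, labels, k=cfg.cv_folds, repeats=cfg.cv_repeats,
                seed=_model_seed(cfg, "cv", "traditional"), classes=classes,
            )
            trad.screen_table.to_csv(model_dir / "traditional_screen.csv")
            accs.to_csv(model_dir / "cv_accuracy_traditional.csv", index=False)
            vote = (
                preds.groupby("subject")["predicted"]
                .agg(lambda s: s.value_counts().idxmax())
                .reindex(clinical.index)
            )
            cm = confusion_matrix(vote.to_numpy(), labels, classes=classes)
            cm.to_csv(model_dir / "confusion_traditional.csv")
            per_class_metrics(cm, classes=classes).to_csv(model_dir / "metrics_traditional.csv")
            report["traditional"] = {
                "screened_variables": trad.screened,
                "mean_cv_accuracy": float(accs["accuracy"].mean()),
            }
        except ValueError as e:
            report["traditional"] = {"status": f"skipped: {e}"}
    return report


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "versions": {
            "rcc_radiomics": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "valid": False,
    }
    stage = "generate"
    try:
        cohort = stage_generate(cfg, outdir)
        manifest["stages"]["generate"] = {"n_subjects": len(cohort)}
        stage = "extract"
        matrices = stage_extract(cfg, outdir, cohort)
        manifest["stages"]["extract"] = {
            ph: list(matrices[1][ph].shape) for ph in PHASES
        }
        stage = "icc"
        retained = stage_icc(cfg, outdir, matrices)
        manifest["stages"]["icc"] = {ph: len(retained[ph]) for ph in PHASES}
        stage = "select"
        design = _model_matrices(cfg, matrices, retained)
        labels = np.asarray([s.subtype for s in cohort])
        selections = stage_select(cfg, outdir, design, labels)
        manifest["stages"]["select"] = {m: len(v) for m, v in selections.items()}
        stage = "evaluate"
        clinical_table = pd.read_csv(outdir / "cohort" / "clinical.csv", index_col=0)
        clinical = clinical_table.drop(columns=["subtype"])
        report = stage_evaluate(cfg, outdir, design, selections, labels, clinical)
        manifest["stages"]["evaluate"] = report
        manifest["valid"] = True
    except Exception as e:
        manifest["error"] = {"stage": stage, "message": str(e)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(f"stage {stage!r} failed: {e}") from e
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
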