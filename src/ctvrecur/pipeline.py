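"""End-to-end orchestration: simulate -> extract -> map -> train -> survival.

One YAML config (``RunConfig``) drives a full reproducible run; every stage
seed derives from the master seed, and all numeric outputs are written with
deterministic formatting so an identical config reproduces byte-identical
artifacts.  Each output file carries the hash of the resolved config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import features as feat
from . import model as mdl
from . import phantoms as ph
from . import recurrence as rc
from . import survival as sv
from .mask_model import PatientRecord, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "render_report", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    master_seed: int = 17
    n_patients: int = 180
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    grid_spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    effect: dict = field(default_factory=dict)          # EffectSpec overrides
    gross_disease: str = "union"
    min_overlap_voxels: int = 1
    correlation_threshold: float = 0.95
    folds: int = 5
    rfe_step: int = 1
    rfe_n_estimators: int = 100
    train_fraction: float = 0.8
    model_grid: dict = field(default_factory=lambda: {
        "max_depth": [3, 5, 7, None], "n_estimators": [100, 200, 500],
    })
    survival_horizon_months: float = 36.0
    survival_group_by: str = "tumor_diameter_cm:5"
    out_dir: str = "run"

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError(
                f"correlation_threshold must be in (0, 1], got {self.correlation_threshold}"
            )
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.rfe_step < 1:
            raise ValueError("rfe_step must be >= 1")
        if self.survival_horizon_months < 0:
            raise ValueError("survival_horizon_months must be >= 0")
        field_name, _sep, thr = self.survival_group_by.partition(":")
        if not _sep:
            raise ValueError("survival_group_by must look like 'field:threshold'")
        float(thr)  # raises if malformed
        if field_name not in {f.name for f in dataclasses.fields(PatientRecord)}:
            raise ValueError(f"unknown grouping covariate {field_name!r}")
        ph.EffectSpec(**self.effect)  # raises on bad effect overrides

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["grid_spacing"] = list(self.grid_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "grid_spacing" in d:
            d["grid_spacing"] = tuple(d["grid_spacing"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        """Digest of the scientific configuration (output path excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(obj: dict, path: Path, config_hash: str) -> None:
    obj = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _csv_dump(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def _grouped_samples(records: list[PatientRecord], group_by: str
                     ) -> tuple[list[sv.SurvivalSample], list[sv.SurvivalSample]]:
    field_name, _, thr = group_by.partition(":")
    thr = float(thr)
    lo, hi = [], []
    for r in records:
        g = int(float(getattr(r, field_name)) >= thr)
        s = sv.SurvivalSample(r.followup_months, r.relapse, group=g)
        (hi if g else lo).append(s)
    return lo, hi


def run_all(config: RunConfig, cohort: Optional[ph.Cohort] = None) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes features.csv, tally.csv, report.json, roc.csv, survival.json,
    km.csv, truth.json, the resolved config, and a structured log.  Any
    stage failure leaves partial outputs plus a FAILED marker naming the
    stage.  A pre-generated cohort can be injected (used by the CLI when
    chaining stages); otherwise one is simulated from the config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    with open(out / "config.yaml", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ctvrecur")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "simulate"
    try:
        logger.info("run start config_hash=%s", chash)
        if cohort is None:
            grid = VoxelGrid(shape=config.grid_shape, spacing=config.grid_spacing)
            cohort = ph.generate_cohort(
                config.n_patients,
                effect=ph.EffectSpec(**config.effect),
                atlas_spec=ph.AtlasSpec.default(grid),
                seed=config.master_seed,
                gross_disease=config.gross_disease,
            )
        _json_dump(cohort.truth.to_dict(), out / "truth.json", chash)
        logger.info("simulate: %d patients", len(cohort))

        stage = "extract"
        if (
            cohort.features is not None
            and config.gross_disease == "union"
            and config.min_overlap_voxels == 1
        ):
            table = cohort.features
        else:
            table = feat.feature_table(
                cohort, config.gross_disease, config.min_overlap_voxels
            )
        _csv_dump(table, out / "features.csv", chash, index=True)
        logger.info("extract: matrix %dx%d", len(table), table.shape[1] - 1)

        stage = "map-recurrence"
        events = []
        for ss, rec in cohort:
            if ss.has_recurrence:
                events.extend(
                    rc.classify_recurrence(
                        ss, rec.id, config.gross_disease, config.min_overlap_voxels
                    )
                )
        tallies, total = rc.tally_by_station(events)
        _csv_dump(rc.tally_frame(tallies, total), out / "tally.csv", chash)
        logger.info("map-recurrence: %d events from %d patients",
                    total, sum(1 for ss, _ in cohort if ss.has_recurrence))

        stage = "train"
        report, _model, _scaler = mdl.screen_and_train(
            table,
            fraction=config.train_fraction,
            correlation_threshold=config.correlation_threshold,
            folds=config.folds,
            rfe_step=config.rfe_step,
            grid=config.model_grid,
            seed=config.master_seed,
            rfe_n_estimators=config.rfe_n_estimators,
        )
        _json_dump(report.to_dict(), out / "report.json", chash)
        roc = pd.DataFrame(report.roc_points, columns=["fpr", "tpr", "threshold"])
        _csv_dump(roc, out / "roc.csv", chash)
        logger.info("train: validation AUC %.3f with %d features",
                    report.metrics_validation["auc"], len(report.screening.selected))

        stage = "survival"
        records = [rec for _ss, rec in cohort]
        lo, hi = _grouped_samples(records, config.survival_group_by)
        km_lo = sv.kaplan_meier(lo)
        km_hi = sv.kaplan_meier(hi)
        chi2, p_lr = sv.log_rank(lo, hi)
        surv: dict = {
            "group_by": config.survival_group_by,
            "horizon_months": config.survival_horizon_months,
            "n_below": len(lo), "n_above": len(hi),
            "events_below": int(sum(s.event for s in lo)),
            "events_above": int(sum(s.event for s in hi)),
            "lc_below": sv.lc_rate_at(km_lo, config.survival_horizon_months),
            "lc_above": sv.lc_rate_at(km_hi, config.survival_horizon_months),
            "log_rank_chi2": chi2, "log_rank_p": p_lr,
        }
        try:
            cox = sv.cox_univariate_binary(
                [sv.SurvivalSample(s.time_months, s.event, g)
                 for g, grp in ((0, lo), (1, hi)) for s in grp]
            )
            surv["cox"] = dataclasses.asdict(cox)
        except (RuntimeError, ValueError) as exc:
            surv["cox"] = {"error": str(exc)}
        a = sum(1 - s.event for s in lo); b = sum(s.event for s in lo)
        c = sum(1 - s.event for s in hi); d = sum(s.event for s in hi)
        try:
            ct = sv.contingency_2x2(a, b, c, d)
            surv["contingency"] = dataclasses.asdict(ct)
        except ValueError as exc:
            surv["contingency"] = {"error": str(exc)}
        _json_dump(surv, out / "survival.json", chash)
        km_rows = []
        for name, km in (("below", km_lo), ("above", km_hi)):
            for t, s in zip(km.times, km.survival):
                km_rows.append({"group": name, "time_months": t, "survival": s})
        _csv_dump(pd.DataFrame(km_rows), out / "km.csv", chash)
        logger.info("survival: LC@%g %.3f vs %.3f, log-rank p=%.4f",
                    config.survival_horizon_months, surv["lc_below"],
                    surv["lc_above"], p_lr)
        return out
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.exception("stage %s failed", stage)
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_REQUIRED = ["features.csv", "tally.csv", "report.json", "survival.json", "roc.csv"]


def render_report(run_dir: str | Path) -> str:
    """Render a completed run as a markdown summary (also written to
    summary.md): the 16-row station tally with a Total row, the
    train/validation metric grid, and the Kaplan–Meier contrast."""
    run_dir = Path(run_dir)
    missing = [f for f in _REQUIRED if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing: {', '.join(missing)}")
    tally = pd.read_csv(run_dir / "tally.csv", comment="#")
    report = json.loads((run_dir / "report.json").read_text())
    surv = json.loads((run_dir / "survival.json").read_text())

    lines = ["# Run summary", ""]
    lines.append("## Station recurrence tally")
    lines.append("")
    cols = ["station", "n_events", "mean_actual_over_idea",
            "min_actual_over_idea", "max_actual_over_idea",
            "n_gtv_affected", "n_ctv_minus_gtv"]
    hdr = ["Area", "Number of regional recurrence",
           "Actual/idea coverage (mean)", "Actual/idea coverage (min)",
           "Actual/idea coverage (max)", "GTV affected area",
           "CTV-GTV recurrence cases"]
    lines.append("| " + " | ".join(hdr) + " |")
    lines.append("|" + "---|" * len(hdr))
    for _, row in tally.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append("–" if pd.isna(v) else (str(int(v)) if c.startswith("n_") else str(v)))
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    lines.append("## Model metrics")
    lines.append("")
    lines.append("| Metric | Training set | Validation set |")
    lines.append("|---|---|---|")
    for m in ("accuracy", "auc", "precision", "recall", "f1"):
        lines.append(
            f"| {m} | {report['metrics_train'][m]:.3f} "
            f"| {report['metrics_validation'][m]:.3f} |"
        )
    lines.append("")
    lines.append(f"Selected features ({len(report['screening']['selected'])}): "
                 + ", ".join(report['screening']['selected']))
    lines.append("")
    lines.append("## Local control")
    lines.append("")
    lines.append(f"Grouping: {surv['group_by']} — "
                 f"n={surv['n_below']}/{surv['n_above']} (below/above)")
    lines.append(f"LC at {surv['horizon_months']:g} months: "
                 f"{surv['lc_below']:.3f} vs {surv['lc_above']:.3f}; "
                 f"log-rank p={surv['log_rank_p']:.4f}")
    if "error" not in surv.get("cox", {}):
        cox = surv["cox"]
        lines.append(f"Cox HR {cox['hr']:.3f} "
                     f"(95% CI {cox['ci_low']:.3f}-{cox['ci_high']:.3f}, "
                     f"p={cox['p_value']:.4f})")
    text = "\n".join(lines) + "\n"
    (run_dir / "summary.md").write_text(text)
    return text
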