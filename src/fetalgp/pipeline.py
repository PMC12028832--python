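"""End-to-end pipeline: cohort -> assessment -> descriptives -> models -> ranking.

``run_pipeline`` executes the full analysis on a supplied or freshly simulated
cohort and writes a reproducible report bundle::

    table1.tsv   descriptive between-group comparisons
    table2.tsv   univariable logistic screen (OR, 95% CI, p, AIC, AUC, DR)
    table3.tsv   multivariable models anchored on MCA PI MoM (models 1-4)
    table4.tsv   multivariable models anchored on CPR MoM (models 5-8)
    table5.tsv   all models ranked ascending by AIC (2-unit rule flagged)
    roc/*.tsv    one (threshold, fpr, tpr) export per fitted model
    tables.json  machine-readable mirror of tables 2-5
    run_metadata.json  seed, config hash, curve provenance, version, flags

Every TSV carries the run's seed and config hash in a leading comment line;
identical config + seed produces a byte-identical bundle.  A stage failure
aborts with the stage name and removes partial outputs.  The pipeline never
mutates the cohort: assessment columns live in a separate table joined by
subject_id.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort, CohortSpec, default_cohort_spec, generate_group_conditional
from .curves import CurveSet
from .evaluation import compare_groups, comparisons_to_frame, dr_at_fpr
from .io import read_cohort
from .metrics import ASSESSMENT_COLUMNS, assess_cohort
from .regression import LogisticFit, fit_logistic, predefined_models, rank_models_by_aic, univariable_screen

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "config_hash"]

#: Descriptive-table variable lists (assessment columns joined in).
TABLE1_CONTINUOUS = (
    "maternal_age",
    "maternal_weight_kg",
    "maternal_height_cm",
    "bmi",
    "ga3t_weeks",
    "ga_delivery_weeks",
    "efw20_g",
    "efw20_mom",
    "ua_pi_mom",
    "mca_pi_mom",
    "cpr_mom",
    "efw3t_g",
    "efwc_local",
    "efwc_ig",
    "exfw3t_g",
    "pct_exfw3t",
    "interval_days",
    "birthweight_g",
)
TABLE1_CATEGORICAL = ("nulliparity", "smoking", "male_sex", "induction", "neonatal_ward")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; the seed is mandatory."""

    seed: int
    out_dir: str | Path = "fetalgp_report"
    cohort_path: str | Path | None = None  # if None, simulate from cohort_spec
    cohort_spec: CohortSpec | None = None
    curves: CurveSet | None = None
    interpolated_dr: bool = False
    fisher_exact: bool = False
    enforce_ga_windows: bool = False

    def resolved_curves(self) -> CurveSet:
        return self.curves if self.curves is not None else CurveSet.default()

    def to_jsonable(self) -> dict:
        spec = self.cohort_spec if self.cohort_spec is not None else default_cohort_spec()
        return {
            "seed": int(self.seed),
            "cohort_path": str(self.cohort_path) if self.cohort_path is not None else None,
            "cohort_spec": None if self.cohort_path is not None else spec.to_jsonable(),
            "curves": self.resolved_curves().provenance,
            "flags": {
                "interpolated_dr": self.interpolated_dr,
                "fisher_exact": self.fisher_exact,
                "enforce_ga_windows": self.enforce_ga_windows,
            },
        }


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _fit_frame(fits: list[LogisticFit], interpolated_dr: bool = False) -> pd.DataFrame:
    """Long-format table: one row per term plus an intercept row per model."""
    rows = []
    for f in fits:
        lo, hi = f.roc.auc_ci95 if f.roc is not None else (float("nan"), float("nan"))
        if f.roc is None:
            dr5 = dr10 = float("nan")
        elif interpolated_dr:
            dr5 = dr_at_fpr(f.roc, 0.05, interpolate=True)
            dr10 = dr_at_fpr(f.roc, 0.10, interpolate=True)
        else:
            dr5, dr10 = f.roc.dr_at_fpr5, f.roc.dr_at_fpr10
        shared = {
            "loglik": f.loglik,
            "aic": f.aic,
            "n": f.n,
            "n_events": f.n_events,
            "n_dropped": f.n_dropped,
            "converged": f.converged,
            "p_model": f.p_model,
            "auc": f.auc,
            "auc_ci_low": lo,
            "auc_ci_high": hi,
            "dr_fpr5": dr5,
            "dr_fpr10": dr10,
        }
        for term in f.model.predictors:
            rows.append(
                {
                    "model": f.model.name,
                    "term": term,
                    "estimate": f.beta[term],
                    "or": f.or_[term],
                    "ci_low": f.ci95[term][0],
                    "ci_high": f.ci95[term][1],
                    "p": f.p_wald[term],
                    **shared,
                }
            )
        rows.append(
            {
                "model": f.model.name,
                "term": "(intercept)",
                "estimate": f.intercept,
                "or": float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "p": float("nan"),
                **shared,
            }
        )
    return pd.DataFrame(rows)


def _slug(name: str) -> str:
    keep = [c.lower() if c.isalnum() else "_" for c in name]
    out = "".join(keep)
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages and write the report bundle; returns output paths."""
    out = Path(config.out_dir)
    roc_dir = out / "roc"
    roc_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"# seed={config.seed} config={chash} fetalgp={__version__}\n"
    written: list[Path] = []
    paths: dict[str, Path] = {}
    curves = config.resolved_curves()

    def write_tsv(df: pd.DataFrame, path: Path, footer: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
            if footer:
                fh.write(footer)
        written.append(path)

    stage = "cohort"
    try:
        if config.cohort_path is not None:
            cohort, read_report = read_cohort(config.cohort_path)
            io_meta = {
                "n_accepted": read_report.n_accepted,
                "n_rejected": read_report.n_rejected,
                "warnings": read_report.warnings,
            }
        else:
            spec = config.cohort_spec if config.cohort_spec is not None else default_cohort_spec()
            cohort = generate_group_conditional(spec, curves=curves, seed=config.seed)
            io_meta = {"n_accepted": cohort.n, "n_rejected": 0, "warnings": []}
        if cohort.n == 0:
            raise ValueError("no valid cohort rows")

        stage = "assess"
        assessment = assess_cohort(cohort.data, curves, enforce_windows=config.enforce_ga_windows)
        assessment.insert(0, "subject_id", cohort.data["subject_id"].to_numpy())
        write_tsv(assessment, out / "assessment.tsv")
        paths["assessment"] = out / "assessment.tsv"
        merged = cohort.data.join(assessment.drop(columns="subject_id"))

        stage = "describe"
        continuous = [c for c in TABLE1_CONTINUOUS if c in merged.columns]
        categorical = [c for c in TABLE1_CATEGORICAL if c in merged.columns]
        table1 = comparisons_to_frame(
            compare_groups(merged, continuous, categorical, fisher=config.fisher_exact)
        )
        write_tsv(table1, out / "table1.tsv")
        paths["table1"] = out / "table1.tsv"

        stage = "univariable"
        multivariable, univariable = predefined_models()
        uv_specs = [m for m in univariable if m.predictors[0] in merged.columns]
        uv_fits, uv_errors = univariable_screen(merged, uv_specs)
        table2 = _fit_frame(uv_fits, interpolated_dr=config.interpolated_dr)
        write_tsv(
            table2,
            out / "table2.tsv",
            footer="# note: no multiple-testing correction applied in the univariable screen\n",
        )
        paths["table2"] = out / "table2.tsv"

        stage = "multivariable"
        mv_fits = [fit_logistic(merged, m) for m in multivariable]
        table3 = _fit_frame(mv_fits[:4], interpolated_dr=config.interpolated_dr)
        table4 = _fit_frame(mv_fits[4:], interpolated_dr=config.interpolated_dr)
        write_tsv(table3, out / "table3.tsv")
        write_tsv(table4, out / "table4.tsv")
        paths["table3"] = out / "table3.tsv"
        paths["table4"] = out / "table4.tsv"

        stage = "rank"
        table5 = rank_models_by_aic(uv_fits + mv_fits)
        write_tsv(table5, out / "table5.tsv")
        paths["table5"] = out / "table5.tsv"

        stage = "roc_export"
        for f in uv_fits + mv_fits:
            if f.roc is None:
                continue
            curve = pd.DataFrame(f.roc.curve_points, columns=["threshold", "fpr", "tpr"])
            p = roc_dir / f"{_slug(f.model.name)}.tsv"
            write_tsv(curve, p)
            paths[f"roc/{p.stem}"] = p

        stage = "tables_json"
        tables_json = out / "tables.json"
        with open(tables_json, "w") as fh:
            json.dump(
                {
                    "table2": table2.to_dict(orient="records"),
                    "table3": table3.to_dict(orient="records"),
                    "table4": table4.to_dict(orient="records"),
                    "table5": table5.to_dict(orient="records"),
                    "univariable_errors": uv_errors,
                },
                fh,
                indent=1,
                sort_keys=True,
                allow_nan=True,
            )
            fh.write("\n")
        written.append(tables_json)
        paths["tables_json"] = tables_json

        stage = "metadata"
        meta_path = out / "run_metadata.json"
        with open(meta_path, "w") as fh:
            json.dump(
                {
                    "seed": int(config.seed),
                    "config_hash": chash,
                    "version": __version__,
                    "config": config.to_jsonable(),
                    "cohort": {
                        "n": cohort.n,
                        "n_events": cohort.n_events,
                        **io_meta,
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        written.append(meta_path)
        paths["metadata"] = meta_path
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return paths
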