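"""End-to-end pipeline: cohort -> screening -> partition -> regressions ->
boundaries -> discriminant -> one-dimensional criteria -> metrics report.

Every stage's output is serialised (JSON/CSV) into an output directory;
figure rendering is best-effort and the geometry JSON is the canonical
artifact.  Deterministic under the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .boundaries import (
    METHODS,
    GridSpec,
    extract_boundary,
    probability_grid,
    train_classifier,
)
from .cohort import filter_coagulation_failure, read_cohort_csv, write_cohort_csv
from .discriminant import (
    discriminant_plane_line,
    fdp_criterion,
    fit_alpha_on_beta,
    fit_discriminant,
)
from .metrics import REPORT_COLUMNS, ConfusionMatrix, auc, class_mean_class_entropy, confusion_metrics, evaluate_all
from .partition import derive_partition
from .projection import fit_anchor_regressions, reduce_to_plane
from .reference import GATE_FBG_FAILURE
from .screening import screen_factors
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``input_csv`` (an existing cohort file) or ``generator``
    (synthetic conditions) supplies the cohort.  Thresholds default to the
    reference study's: fibrinogen gate 170 mg/dL, relatedness 0.49,
    collinearity ceiling 0.64.
    """

    output_dir: str | Path = "coagplane-out"
    input_csv: Optional[str | Path] = None
    generator: Optional[GeneratorConfig] = None
    gate_threshold: float = GATE_FBG_FAILURE
    relate_threshold: float = 0.49
    collinearity_ceiling: float = 0.64
    grid: GridSpec = field(default_factory=GridSpec)
    methods: tuple[str, ...] = METHODS
    seed: int = 0
    figures: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.relate_threshold <= 1) or not (0 < self.collinearity_ceiling <= 1):
            raise ValueError("fractional thresholds must lie in (0, 1]")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods: {bad}")


def _screening_table(results) -> pd.DataFrame:
    rows: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for r in results:
        if r.factor not in rows:
            rows[r.factor] = {}
            order.append(r.factor)
        rows[r.factor][f"{r.method}_p"] = r.p_value
        rows[r.factor][f"{r.method}_statistic"] = r.statistic
    return pd.DataFrame.from_dict(rows, orient="index").loc[order]


def _maybe_figures(outdir, cohort, fields, boundaries, line):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        for method, fld in fields.items():
            fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(10, 4))
            extent = (fld.grid.alpha_min, fld.grid.alpha_max, fld.grid.beta_min, fld.grid.beta_max)
            ax0.imshow(
                (fld.values.T > 0.5), origin="lower", extent=extent, aspect="auto",
                cmap="gray_r",
            )
            colors = np.where(cohort.labels, "black", "red")
            ax0.scatter(cohort.df["fbg"], cohort.df["fdp"], c=colors, s=18)
            ax0.set(xlabel="fibrinogen (mg/dL)", ylabel="FDP (mg/dL)", title=method)
            im = ax1.contourf(
                fld.grid.alpha, fld.grid.beta, fld.values.T, levels=np.linspace(0, 1, 11),
                cmap="Greys",
            )
            fig.colorbar(im, ax=ax1, label="p(hematuria)")
            ax1.set(xlabel="fibrinogen (mg/dL)", ylabel="FDP (mg/dL)")
            fig.tight_layout()
            fig.savefig(figdir / f"boundary_{method}.png", dpi=110)
            plt.close(fig)
        if line is not None:
            fig, ax = plt.subplots(figsize=(5, 4))
            xs = np.array([0.0, 170.0])
            ax.plot(xs, [line.fdp_at(x) for x in xs], "k-")
            ax.scatter(cohort.df["fbg"], cohort.df["fdp"],
                       c=np.where(cohort.labels, "black", "red"), s=18)
            ax.set(xlabel="fibrinogen (mg/dL)", ylabel="FDP (mg/dL)",
                   title="discriminant boundary")
            fig.tight_layout()
            fig.savefig(figdir / "discriminant_line.png", dpi=110)
            plt.close(fig)
    except Exception as exc:  # rendering is best-effort only
        logger.warning("figure rendering skipped: %s", exc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and serialise all artifacts; returns a summary dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
    else:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        cohort = generate_cohort(gen)
        write_cohort_csv(cohort, outdir / "cohort.csv")
    logger.info("stage cohort: %d records enrolled", len(cohort))

    gated = filter_coagulation_failure(cohort, config.gate_threshold)
    n_pos = gated.n_hematuria
    logger.info(
        "stage gate: %d records below %g mg/dL (%d hematuria / %d non)",
        len(gated), config.gate_threshold, n_pos, len(gated) - n_pos,
    )

    screening = screen_factors(gated)
    _screening_table(screening).to_csv(outdir / "table1.csv")

    partition = derive_partition(
        gated,
        relate_threshold=config.relate_threshold,
        ceiling=config.collinearity_ceiling,
    )
    (outdir / "partition.json").write_text(json.dumps(partition.to_dict(), indent=2))
    logger.info("stage partition: feature vector %s", partition.feature_order)

    bundle = fit_anchor_regressions(gated, partition)
    (outdir / "bundle.json").write_text(json.dumps(bundle.to_dict(), indent=2))

    bdir = outdir / "boundaries"
    bdir.mkdir(exist_ok=True)
    classifiers, fields, geometries = {}, {}, {}
    for method in config.methods:
        clf = train_classifier(gated, partition, method, seed=config.seed)
        plane = reduce_to_plane(clf, bundle)
        fld = probability_grid(plane, config.grid)
        geom = extract_boundary(fld, level=0.5)
        classifiers[method], fields[method], geometries[method] = clf, fld, geom
        (bdir / f"{method}.json").write_text(json.dumps(geom.to_dict(), indent=2))
        logger.info("stage boundary[%s]: crude region '%s'", method, geom.crude_region.text)

    disc = fit_discriminant(gated, partition)
    line = discriminant_plane_line(disc, bundle)
    (outdir / "discriminant.json").write_text(json.dumps({
        "constant": disc.constant,
        "coefficients": disc.coefficients,
        "eta_squared": disc.eta_squared,
        "error_probability_pct": disc.error_probability_pct,
        "plane_line": {"a": line.a, "b": line.b, "c": line.c,
                        "endpoints": line.endpoints()},
    }, indent=2))

    report = evaluate_all(classifiers, gated, partition)
    report.to_csv(outdir / "table3.csv")

    reg = fit_alpha_on_beta(gated)
    y = gated.labels
    crit_rows = {}
    for method in config.methods:
        plane = reduce_to_plane(classifiers[method], bundle)
        crit = fdp_criterion(plane, reg, interval=(config.grid.beta_min, config.grid.beta_max),
                             method=method)
        if crit is None:
            crit_rows[method] = {"fdp_criterion": np.nan,
                                 **{c: np.nan for c in REPORT_COLUMNS}}
            continue
        pred = gated.df["fdp"].to_numpy(float) > crit.threshold
        row = confusion_metrics(ConfusionMatrix.from_labels(y, pred))
        row["auc"] = auc(y, gated.df["fdp"].to_numpy(float))
        p_pos = np.clip((gated.df["fdp"].to_numpy(float) > crit.threshold).astype(float), 0.02, 0.98)
        row["cmce"] = class_mean_class_entropy(y, np.column_stack([1 - p_pos, p_pos]))
        crit_rows[method] = {"fdp_criterion": crit.threshold, **{c: row.get(c) for c in REPORT_COLUMNS}}
    pd.DataFrame.from_dict(crit_rows, orient="index").to_csv(outdir / "table4.csv")

    if config.figures:
        _maybe_figures(outdir, gated, fields, geometries, line)

    return {
        "output_dir": str(outdir),
        "n_enrolled": len(cohort),
        "n_gated": len(gated),
        "n_hematuria": n_pos,
        "feature_order": list(partition.feature_order),
        "crude_regions": {m: geometries[m].crude_region.text for m in config.methods},
        "fdp_criteria": {m: crit_rows[m]["fdp_criterion"] for m in config.methods},
        "discriminant_endpoints": line.endpoints(),
    }
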