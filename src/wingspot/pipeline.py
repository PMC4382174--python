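"""End-to-end orchestration of the automated wing-spot readout.

``run_pipeline`` drives the four stages over a batch of focus stacks --
segmentation, discard masking, hair classification, and dose-response
statistics -- and writes every artifact (hair tables, wing scores, a
Table-1-style statistics table, a JSON run report) so that each number in
the statistics output is recomputable from the emitted per-wing CSV alone.

Stacks are referenced by a dose map: each entry names a wing, compound,
dose, and either a TIFF path or a generator seed (synthetic stacks).  A
stage failure on one stack is recorded and the remaining wings continue.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as wio
from .classify import ClassificationParams, MwhGrouping, classify_hairs
from .discard import DiscardMask, DiscardParams, apply_discard, build_discard_mask, maxima_projection, structure_density
from .segmentation import SegmentationParams, hairs_to_frame, segment_stack
from .stack import FocusStack, read_stack
from .stats import DoseResponse, compute_wing_scores, dose_dependency_test, fit_sigmoid
from .synthetic import StackParams, generate_wing_stack

logger = logging.getLogger("wingspot")

__all__ = ["StackEntry", "RunConfig", "RunReport", "run_pipeline", "validate_config",
           "analyze_stack", "run_stats"]


@dataclass
class StackEntry:
    """One focus stack in the batch: a file or a synthetic seed."""

    wing_id: str
    compound: str = "test"
    dose_mM: float = 0.0
    measure: str = "auto"
    path: str | None = None
    seed: int | None = None                  # synthetic generation
    stack_params: StackParams | None = None  # overrides for synthetic stacks


@dataclass
class RunConfig:
    output_dir: str = "wingspot_out"
    stacks: list[StackEntry] = field(default_factory=list)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    discard: DiscardParams = field(default_factory=DiscardParams)
    use_discard_mask: bool = True
    score_column: str = "score_cells"        # headline score
    enforced_top_factor: float = 1.1         # top = max per-dose mean x factor
    make_plots: bool = True
    seed: int = 0


@dataclass
class RunReport:
    n_stacks: int = 0
    n_stacks_failed: int = 0
    n_hairs_detected: int = 0
    n_hairs_discarded: dict = field(default_factory=dict)   # reason -> count
    n_mwh_hairs: int = 0
    n_cells: int = 0
    n_spots: int = 0
    per_wing: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    elapsed_s: float = 0.0
    parameters: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def validate_config(config: RunConfig) -> list[str]:
    """Collect all configuration violations; an empty list means valid."""
    issues: list[str] = []
    try:
        config.segmentation.validate()
    except ValueError as e:
        issues.append(f"segmentation: {e}")
    try:
        config.classification.validate()
    except ValueError as e:
        issues.append(f"classification: {e}")
    for thr in (config.discard.low_threshold, config.discard.high_threshold):
        if not 0 <= thr <= 1:
            issues.append(f"discard: threshold {thr} outside [0, 1]")
    if config.discard.low_threshold >= config.discard.high_threshold:
        issues.append("discard: low threshold must be below high threshold")
    wing_dose: dict[str, float] = {}
    for entry in config.stacks:
        if entry.dose_mM < 0:
            issues.append(f"stack {entry.wing_id}: negative dose {entry.dose_mM}")
        if entry.path is None and entry.seed is None:
            issues.append(f"stack {entry.wing_id}: neither path nor seed given")
        if entry.path is not None and not os.path.exists(entry.path):
            issues.append(f"stack {entry.wing_id}: missing file {entry.path}")
        prev = wing_dose.setdefault(entry.wing_id, entry.dose_mM)
        if prev != entry.dose_mM:
            issues.append(f"wing {entry.wing_id} mapped to two doses ({prev}, {entry.dose_mM})")
    return issues


def analyze_stack(
    stack: FocusStack,
    seg_params: SegmentationParams | None = None,
    cls_params: ClassificationParams | None = None,
    discard_params: DiscardParams | None = None,
    use_discard_mask: bool = True,
):
    """Segment, mask, and classify one focus stack.

    Returns ``(hair_frame, grouping, discard_mask, analyzed_area_um2)``.
    """
    seg_params = seg_params or SegmentationParams()
    cls_params = cls_params or ClassificationParams()
    discard_params = discard_params or DiscardParams()

    hairs, labels, filtered = segment_stack(stack, seg_params)
    vz, vy, vx = stack.voxel_size_um
    # discard analysis runs on the raw stack's projection: the top-hat would
    # flatten exactly the wide bright structures (vein bands) it must find
    proj = maxima_projection(stack.data)
    from .segmentation import estimate_background

    proj_bg, proj_sd = estimate_background(proj)
    thr = proj_bg + seg_params.stop_sd_multiple * proj_sd
    if use_discard_mask:
        density = structure_density(proj, thr, discard_params.density_sigma_um, vx)
        dmask = build_discard_mask(density, proj, vx, discard_params)
        hairs = apply_discard(hairs, dmask, labels)
    else:
        dmask = DiscardMask(
            mask=np.zeros(proj.shape, dtype=bool),
            provenance=np.zeros(proj.shape, dtype=np.uint8),
        )
    analyzed_area = float((~dmask.mask).sum()) * vx * vy
    frame = hairs_to_frame(hairs)
    if len(frame) >= 2:
        frame, grouping = classify_hairs(frame, cls_params)
    else:
        frame["side"] = ""
        frame["phenotype"] = ""
        frame["cell_id"] = -1
        frame["spot_id"] = -1
        grouping = MwhGrouping(0, 0, 0)
    return frame, grouping, dmask, analyzed_area


def run_stats(
    wing_scores: pd.DataFrame,
    score_column: str = "score_cells",
    enforced_top_factor: float = 1.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dose-dependency test and constrained sigmoid fit per compound.

    ``wing_scores`` needs columns compound, measure, dose_mM and the chosen
    score column.  Returns a Table-1-style frame: one row per compound and
    measure type with the trend sign, its one-sided P, and (for genotoxic
    compounds with enough doses) EC50, slope, and their 95% CIs.
    """
    rows = []
    for (compound, measure), grp in wing_scores.groupby(["compound", "measure"]):
        drc = DoseResponse.from_table(grp, compound=compound, measure=measure,
                                      score_col=score_column)
        try:
            slope_lin, p_one, verdict = dose_dependency_test(drc, alpha=alpha)
        except ValueError as e:
            rows.append(dict(compound=compound, measure=measure, error=str(e)))
            continue
        row = dict(
            compound=compound, measure=measure,
            trend_sign="+" if verdict == "genotoxic" else "-",
            trend_p=p_one,
        )
        if verdict == "genotoxic" and len(drc.doses) >= 4:
            top = float(drc.means.max()) * enforced_top_factor
            try:
                fit = fit_sigmoid(drc, top=top)
                row.update(
                    ec50_mM=fit.ec50_mM, ec50_lo=fit.ci_ec50[0], ec50_hi=fit.ci_ec50[1],
                    slope=fit.slope, slope_lo=fit.ci_slope[0], slope_hi=fit.ci_slope[1],
                    bottom=fit.bottom, top=fit.top, extrapolated=fit.extrapolated,
                )
            except Exception as e:  # fit failure must not kill the batch
                row["fit_error"] = str(e)
        rows.append(row)
    return pd.DataFrame(rows)


def _plot_drc(wing_scores, stats_frame, score_column, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (compound, measure), grp in wing_scores.groupby(["compound", "measure"]):
        drc = DoseResponse.from_table(grp, compound=compound, measure=measure,
                                      score_col=score_column)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.plot(drc.doses, drc.means, "o", color="tab:green", label="mean wing score")
        sel = stats_frame[
            (stats_frame["compound"] == compound) & (stats_frame["measure"] == measure)
        ]
        if len(sel) and "ec50_mM" in sel.columns and not pd.isna(sel.iloc[0].get("ec50_mM")):
            row = sel.iloc[0]
            drc2 = DoseResponse.from_table(grp, compound=compound, score_col=score_column)
            fit = fit_sigmoid(drc2, top=float(row["top"]))
            xs = np.linspace(0, drc.doses.max() * 1.05, 200)
            ax.plot(xs, fit.predict(xs), "-", color="tab:blue", label="sigmoid fit")
            lo, hi = fit.envelope(xs)
            ax.plot(xs, lo, "--", color="tab:blue", lw=0.8)
            ax.plot(xs, hi, "--", color="tab:blue", lw=0.8, label="95% envelope")
        ax.set_xlabel("dose (mM)")
        ax.set_ylabel(score_column)
        ax.set_title(f"{compound} ({measure})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"drc_{compound}_{measure}.png"), dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full batch and write all artifacts under ``output_dir``."""
    t0 = time.time()
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config:\n" + "\n".join(issues))
    os.makedirs(config.output_dir, exist_ok=True)
    report = RunReport(parameters=dict(
        segmentation=dataclasses.asdict(config.segmentation),
        classification=dataclasses.asdict(config.classification),
        discard=dataclasses.asdict(config.discard),
        use_discard_mask=config.use_discard_mask,
        score_column=config.score_column,
        enforced_top_factor=config.enforced_top_factor,
        seed=config.seed,
    ))

    per_wing: dict[str, dict] = {}
    for i, entry in enumerate(config.stacks):
        try:
            if entry.path is not None:
                stack = read_stack(entry.path)
            else:
                sp = entry.stack_params or StackParams()
                sp = dataclasses.replace(sp, seed=entry.seed)
                stack, _truth = generate_wing_stack(sp)
            frame, grouping, _dmask, area = analyze_stack(
                stack, config.segmentation, config.classification,
                config.discard, config.use_discard_mask,
            )
            frame.insert(0, "stack_index", i)
            wio.write_frame_csv(
                os.path.join(config.output_dir, f"hairs_{entry.wing_id}_{i:03d}.csv"),
                frame,
            )
            report.n_stacks += 1
            report.n_hairs_detected += len(frame)
            for reason, cnt in frame.loc[frame["discarded"], "discard_reason"].value_counts().items():
                report.n_hairs_discarded[reason] = report.n_hairs_discarded.get(reason, 0) + int(cnt)
            w = per_wing.setdefault(entry.wing_id, dict(
                compound=entry.compound, measure=entry.measure, dose_mM=entry.dose_mM,
                n_hairs=0, n_mwh=0, n_cells=0, n_spots=0, area_um2=0.0, n_stacks=0,
            ))
            w["n_hairs"] += int((~frame["discarded"]).sum())
            w["n_mwh"] += grouping.n_mwh_hairs
            w["n_cells"] += grouping.n_cells
            w["n_spots"] += grouping.n_spots
            w["area_um2"] += area
            w["n_stacks"] += 1
            report.n_mwh_hairs += grouping.n_mwh_hairs
            report.n_cells += grouping.n_cells
            report.n_spots += grouping.n_spots
        except Exception as e:
            report.n_stacks_failed += 1
            report.failures.append(dict(stack_index=i, wing_id=entry.wing_id,
                                        stage="stack-analysis", error=str(e)))
            logger.warning("stack %d (wing %s) failed: %s", i, entry.wing_id, e)

    score_rows = []
    for wing_id, w in sorted(per_wing.items()):
        ws = compute_wing_scores(
            MwhGrouping(w["n_mwh"], w["n_cells"], w["n_spots"]),
            analyzed_area_um2=w["area_um2"], wing_id=wing_id,
            dose_mM=w["dose_mM"], n_hairs_analyzed=w["n_hairs"],
        )
        score_rows.append(dict(
            wing_id=wing_id, compound=w["compound"], measure=w["measure"],
            dose_mM=w["dose_mM"], n_stacks=w["n_stacks"], n_hairs=ws.n_hairs,
            analyzed_area_um2=ws.analyzed_area_um2,
            score_hairs_per_mm2=ws.score_hairs_per_mm2,
            score_cells=ws.score_cells, score_spots=ws.score_spots,
            score_dichotomous=ws.score_dichotomous,
        ))
    wing_scores = pd.DataFrame(score_rows, columns=[
        "wing_id", "compound", "measure", "dose_mM", "n_stacks", "n_hairs",
        "analyzed_area_um2", "score_hairs_per_mm2", "score_cells",
        "score_spots", "score_dichotomous",
    ])
    wio.write_frame_csv(os.path.join(config.output_dir, "wing_scores.csv"), wing_scores)
    report.per_wing = {r["wing_id"]: r for r in score_rows}

    stats_frame = pd.DataFrame()
    if len(wing_scores):
        try:
            stats_frame = run_stats(
                wing_scores, config.score_column, config.enforced_top_factor
            )
        except Exception as e:
            report.failures.append(dict(stage="stats", error=str(e)))
    wio.write_frame_csv(os.path.join(config.output_dir, "genotoxicity_stats.csv"), stats_frame)
    if config.make_plots and len(stats_frame):
        try:
            _plot_drc(wing_scores, stats_frame, config.score_column, config.output_dir)
        except Exception as e:
            report.warnings.append(f"plotting failed: {e}")

    report.elapsed_s = time.time() - t0
    wio.write_json(os.path.join(config.output_dir, "run_report.json"),
                   dataclasses.asdict(report))
    return report
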