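"""End-to-end evaluation pipeline: score a cohort, build the
characteristics table (thresholds 2/3/4 across age strata), estimate
ROC/AUC per stratum and reporter with DeLong CIs, compare curves
(paired parent-vs-child, unpaired teen-vs-preteen and by pubertal
stage), and summarize reporter agreement with medians and Wilcoxon
signed-rank p-values. Outputs are plain JSON/CSV with the run
configuration and package version embedded."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SubjectRecord, classify_osa, filter_complete, smr_group
from .diagnostics import summaries_to_frame, summary_table
from .nonparam import median_iqr, wilcoxon_signed_rank
from .reference import ReferenceSet, load_reference_set
from .roc import auc_ci_delong, compare_auc_paired, compare_auc_unpaired
from .scoring import score_cohort

__all__ = ["RunConfig", "PipelineError", "run_full_evaluation"]

logger = logging.getLogger("stopbang")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Knobs for one full evaluation run."""

    reporter: str = "parent"
    variant: str = "stop_bang"
    score_thresholds: tuple[int, ...] = (2, 3, 4)
    ahi_threshold: float = 1.5
    bmi_cut: float = 95.0
    prevalence: float | None = None
    ci_method: str = "wilson"
    reference_dir: str | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not all(1 <= t <= 8 for t in self.score_thresholds):
            raise ValueError(f"score thresholds must be in [1, 8]: {self.score_thresholds}")
        if self.ahi_threshold <= 0:
            raise ValueError("AHI threshold must be > 0")


def _auc_record(scores, labels) -> dict:
    est = auc_ci_delong(scores, labels)
    return {
        "auc": est.auc,
        "variance": est.variance,
        "ci": list(est.ci),
        "n_pos": est.n_pos,
        "n_neg": est.n_neg,
        "ci_truncated": est.ci_truncated,
    }


def run_full_evaluation(
    records: list[SubjectRecord],
    config: RunConfig,
    refs: ReferenceSet | None = None,
) -> dict:
    """Run the whole analysis sequence on a cohort and return the report
    bundle as one JSON-serializable dict. When ``config.out_dir`` is set,
    writes report.json plus scores.csv and characteristics.csv there."""
    try:
        refs = refs or load_reference_set(config.reference_dir)
    except Exception as exc:
        raise PipelineError("reference", str(exc)) from exc

    try:
        kept, dropped = filter_complete(records, config.reporter)
        if not kept:
            raise ValueError("no complete records")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    logger.info("kept %d records, dropped %d", len(kept), len(dropped))

    try:
        frames = {
            reporter: score_cohort(
                kept, refs, reporter=reporter, variant=config.variant, bmi_cut=config.bmi_cut
            )
            for reporter in ("parent", "child")
        }
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    main = frames[config.reporter]
    labels = np.array(
        [classify_osa(a, config.ahi_threshold).is_osa for a in main["ahi"]]
    )
    ages = main["age"].to_numpy()
    prevalence = (
        float(labels.mean()) if config.prevalence is None else config.prevalence
    )

    try:
        summaries = summary_table(
            main["total"].to_numpy(),
            labels,
            ages=ages,
            thresholds=config.score_thresholds,
            prevalence=prevalence,
            ci_method=config.ci_method,
        )
    except Exception as exc:
        raise PipelineError("characteristics", str(exc)) from exc

    strata_masks = {
        "all": np.ones_like(labels, dtype=bool),
        "teen": ages >= 13.0,
        "preteen": ages < 13.0,
    }
    auc_records: dict[str, dict] = {}
    comparisons: dict[str, dict] = {}
    try:
        for reporter, frame in frames.items():
            totals = frame["total"].to_numpy()
            for stratum, mask in strata_masks.items():
                if labels[mask].all() or not labels[mask].any():
                    continue
                auc_records[f"{reporter}_{stratum}"] = _auc_record(totals[mask], labels[mask])
        parent_totals = frames["parent"]["total"].to_numpy()
        child_totals = frames["child"]["total"].to_numpy()
        for stratum, mask in strata_masks.items():
            if labels[mask].sum() >= 2 and (~labels[mask]).sum() >= 2:
                z, p = compare_auc_paired(
                    parent_totals[mask], child_totals[mask], labels[mask]
                )
                comparisons[f"parent_vs_child_{stratum}"] = {"z": z, "p": p, "paired": True}
        if "parent_teen" in auc_records and "parent_preteen" in auc_records:
            teen = auc_ci_delong(parent_totals[strata_masks["teen"]], labels[strata_masks["teen"]])
            pre = auc_ci_delong(parent_totals[strata_masks["preteen"]], labels[strata_masks["preteen"]])
            z, p = compare_auc_unpaired(teen, pre)
            comparisons["teen_vs_preteen_parent"] = {"z": z, "p": p, "paired": False}
        smr = main["smr"].to_numpy()
        groups = np.array([smr_group(None if np.isnan(float(s)) else int(s)) for s in smr])
        high, low = groups == "high", groups == "low"
        if (
            labels[high].sum() >= 2 and (~labels[high]).sum() >= 2
            and labels[low].sum() >= 2 and (~labels[low]).sum() >= 2
        ):
            est_high = auc_ci_delong(parent_totals[high], labels[high])
            est_low = auc_ci_delong(parent_totals[low], labels[low])
            auc_records["parent_smr_high"] = _auc_record(parent_totals[high], labels[high])
            auc_records["parent_smr_low"] = _auc_record(parent_totals[low], labels[low])
            z, p = compare_auc_unpaired(est_high, est_low)
            comparisons["smr_high_vs_low_parent"] = {"z": z, "p": p, "paired": False}
    except Exception as exc:
        raise PipelineError("roc", str(exc)) from exc

    try:
        reporter_rows = []
        for stratum, mask in strata_masks.items():
            if not mask.any():
                continue
            diffs = parent_totals[mask] - child_totals[mask]
            test = wilcoxon_signed_rank(diffs)
            p_med = median_iqr(parent_totals[mask])
            c_med = median_iqr(child_totals[mask])
            reporter_rows.append(
                {
                    "stratum": stratum,
                    "n": int(mask.sum()),
                    "parent_median_iqr": list(p_med),
                    "child_median_iqr": list(c_med),
                    "wilcoxon_p": test.p_value,
                    "method_notes": test.method_notes,
                }
            )
    except Exception as exc:
        raise PipelineError("reporter-comparison", str(exc)) from exc

    config_dict = asdict(config)
    config_dict.pop("out_dir")  # where the report lands is not part of the analysis
    report = {
        "package_version": __version__,
        "config": config_dict,
        "n_records": len(records),
        "n_complete": len(kept),
        "n_dropped": len(dropped),
        "prevalence": prevalence,
        "characteristics": json.loads(
            summaries_to_frame(summaries).to_json(orient="records")
        ),
        "auc": auc_records,
        "auc_comparisons": comparisons,
        "reporter_comparison": reporter_rows,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        score_cols = ["subject_id", "reporter", "variant"] + [
            c for c in frames["parent"].columns
            if c not in ("subject_id", "reporter", "variant", "age", "smr", "ahi")
        ]
        both = pd.concat(
            [frames["parent"][score_cols], frames["child"][score_cols]],
            ignore_index=True,
        )
        both.to_csv(out / "scores.csv", index=False)
        summaries_to_frame(summaries).to_csv(out / "characteristics.csv", index=False)
    return report
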