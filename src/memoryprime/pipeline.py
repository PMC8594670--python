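"""End-to-end orchestration: simulate or read -> normalize -> differential
expression -> memory classification -> summary.

Outputs per run (when an output directory is given): ratios.tsv, one
contrast table per comparison, class_a.tsv, class_b_labels.tsv, venn.tsv,
and summary.json (schema_version 1) with class sizes, label percentages,
the inversion Fisher table/p, orientation breakdowns and — in synthetic
mode — a confusion matrix of predicted memory labels against the planted
truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, memory, normalize, synthio
from .synthio import CONTRASTS, ConfigurationError, SimConfig

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ARABIDOPSIS_CONTRASTS = ("ww_wf", "ww_bw", "bw_bf", "wf_bf", "ww_bf")
APPLE_CONTRASTS = ("ww_bw", "bw_bf", "ww_bf")
VENN_CONTRASTS = ("ww_wf", "ww_bw", "bw_bf", "wf_bf")

#: planted class -> the memory label it should receive when recovered
TRUTH_TO_LABEL = {
    "deprimed": "deprimed",
    "persistent_primed": "primed",
    "transgressive": "transgressive",
}


@dataclass
class PipelineConfig:
    """Everything one run needs; synthetic mode when `sim` is set."""

    sim: SimConfig | None = None
    intensity_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    alpha: float = 0.05
    span: float | None = 0.3
    lowess_iterations: int = 3
    multiple_testing: str = "none"  # or "bh"
    contrasts: tuple[str, ...] = ARABIDOPSIS_CONTRASTS
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        bad = set(self.contrasts) - set(CONTRASTS)
        if bad:
            raise ConfigurationError(f"unknown contrasts: {sorted(bad)}")
        if self.multiple_testing not in ("none", "bh"):
            raise ConfigurationError(
                f"multiple_testing must be 'none' or 'bh', got {self.multiple_testing!r}"
            )
        if self.sim is None and not (
            self.intensity_path and self.design_path and self.annotation_path
        ):
            raise ConfigurationError(
                "either a SimConfig or intensity/design/annotation paths are required"
            )


def _contrast_bundle(
    ratios: pd.DataFrame, contrasts: tuple[str, ...], alpha: float, multiple_testing: str
) -> memory.ContrastBundle:
    tables = {}
    for cid in contrasts:
        sub = ratios[ratios["contrast_id"] == cid]
        if sub.empty:
            raise ConfigurationError(f"no ratio rows for contrast {cid!r}")
        table = diffexpr.analyze_contrast(sub, alpha=alpha)
        if multiple_testing == "bh":
            table = table.assign(p=diffexpr.benjamini_hochberg(table["p"].to_numpy()))
            table["is_de"] = table["p"] < alpha
        tables[cid] = table
    return memory.ContrastBundle(tables=tables, alpha=alpha)


def _confusion_matrix(
    truth: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Planted memory class (rows) vs. recovered label (columns).

    Rows cover the three Class-B-relevant planted classes; `missed` counts
    transcripts never recovered into Class B.
    """
    cols = list(memory.LABELS) + ["missed"]
    rows = {}
    planted = truth.set_index("transcript_id")["memory_class"]
    for cls, expected_label in TRUTH_TO_LABEL.items():
        ids = planted.index[planted == cls]
        row = {c: 0 for c in cols}
        for t in ids:
            if t in labels.index:
                row[labels.loc[t, "label"]] += 1
            else:
                row["missed"] += 1
        rows[cls] = row
    out = pd.DataFrame.from_dict(rows, orient="index")[cols]
    out.index.name = "planted_class"
    return out


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the summary dictionary."""
    config.validate()
    stage = "input"
    try:
        if config.sim is not None:
            sim = dataclasses.replace(
                config.sim, seed=config.seed, contrasts=tuple(config.contrasts)
            )
            arrays, annotation, truth = synthio.simulate_experiment(sim)
        else:
            arrays = synthio.read_arrayset(config.intensity_path, config.design_path)
            annotation = synthio.read_annotation(config.annotation_path)
            truth = None

        stage = "normalize"
        ratios = normalize.replicate_ratios(
            arrays, annotation, span=config.span, iterations=config.lowess_iterations
        )

        stage = "diffexpr"
        bundle = _contrast_bundle(
            ratios, tuple(config.contrasts), config.alpha, config.multiple_testing
        )

        stage = "memory"
        summary: dict = {
            "schema_version": SCHEMA_VERSION,
            "alpha": config.alpha,
            "seed": config.seed,
            "contrasts": list(config.contrasts),
            "n_transcripts": int(
                annotation["transcript_id"].nunique()
            ),
            "det_counts": {
                cid: len(bundle.det(cid)) for cid in config.contrasts
            },
        }

        outputs: dict[str, pd.DataFrame] = {"ratios": ratios}

        if set(VENN_CONTRASTS) <= set(config.contrasts):
            venn = memory.venn_counts(
                {cid: set(bundle.det(cid)) for cid in VENN_CONTRASTS}
            )
            venn_df = pd.DataFrame(
                {
                    "region": ["+".join(sorted(k)) for k in venn],
                    "count": list(venn.values()),
                }
            ).sort_values("region", ignore_index=True)
            outputs["venn"] = venn_df
            summary["venn"] = dict(zip(venn_df["region"], map(int, venn_df["count"])))

        has_class_a = {"ww_bw", "ww_wf"} <= set(config.contrasts)
        if has_class_a:
            ca = memory.class_a(bundle)
            outputs["class_a"] = ca.reset_index()
            summary["class_a"] = {
                "size": len(ca),
                "transgressive_pct": (
                    100.0 * float(ca["transgressive"].mean()) if len(ca) else float("nan")
                ),
                "orientation_breakdown": orientation_records(ca, annotation),
            }

        cb = memory.class_b(bundle)
        labels = memory.classify_memory(cb, bundle)
        outputs["class_b_labels"] = labels.reset_index()
        table, odds, fisher_p = (
            memory.inversion_fisher_test(cb) if len(cb) else (np.zeros((2, 2), int), float("nan"), float("nan"))
        )
        summary["class_b"] = {
            "size": len(cb),
            "label_counts": {
                label: int((labels["label"] == label).sum()) for label in memory.LABELS
            },
            "label_percentages": memory.label_percentages(labels),
            "fisher_table": np.asarray(table).tolist(),
            "fisher_odds_ratio": None if not np.isfinite(odds) else float(odds),
            "fisher_p": fisher_p,
            "orientation_breakdown": orientation_records(labels, annotation),
        }

        if truth is not None:
            confusion = _confusion_matrix(truth, labels)
            outputs["confusion"] = confusion.reset_index()
            summary["confusion_matrix"] = {
                cls: {col: int(v) for col, v in row.items()}
                for cls, row in confusion.to_dict(orient="index").items()
            }
            outputs["truth"] = truth
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in outputs.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        for cid, table in bundle.tables.items():
            table.reset_index().to_csv(out / f"contrast_{cid}.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        logger.info("wrote %d tables to %s", len(outputs), out)
    return summary


def orientation_records(table: pd.DataFrame, annotation: pd.DataFrame) -> dict:
    """orientation_breakdown as a plain JSON-serializable dict."""
    if table.empty:
        return {}
    bd = memory.orientation_breakdown(table, annotation)
    return {
        subcat: {col: float(v) for col, v in row.items()}
        for subcat, row in bd.to_dict(orient="index").items()
    }


def apple_mode(config: PipelineConfig) -> dict:
    """Three-contrast variant (ww_bw, bw_bf, ww_bf): Class B only.

    The apple design lacks the ww_wf comparison, so Class A cannot be
    formed; requesting it is an explicit error.
    """
    extra = set(config.contrasts) - set(APPLE_CONTRASTS)
    if "ww_wf" in extra:
        raise ConfigurationError(
            "Class A requires the ww_wf contrast, which the three-contrast "
            "apple design does not include"
        )
    cfg = PipelineConfig(**{**config.__dict__, "contrasts": APPLE_CONTRASTS})
    return run_full_pipeline(cfg)
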