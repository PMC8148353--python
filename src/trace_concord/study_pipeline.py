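"""Orchestration of the full tracing-agreement study.

For every image the three tracing pairs (rater vs rater and each rater
vs ground truth) are scored both with the raw tracings and with the
rater tracings replaced by their best-fit ellipses, producing the
before/after comparison that is the point of the analysis.  Aggregates
are unweighted means of per-image values within each stratum (dataset
or retinal condition) — i.e. distributions of per-image metrics, never
pooled pixels.

Ground truth is never refit by default; the ellipse repair targets the
raters' stroke artifacts, and the reference should stay fixed.  A flag
exists for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import agreement_metrics as am
from .ellipse_fit import refit_tracing
from .errors import FitError, InputError, MetricError
from .trace_io import ImageRecord, TraceMask, polyline_to_mask

__all__ = [
    "PAIRS",
    "AnalysisOptions",
    "StudyReport",
    "analyze_pair",
    "run_study",
    "summarize",
    "to_markdown",
]

#: The three comparisons, in reporting order.  For the rater-vs-rater
#: pair the boundary-distance reference is the first label (od1).
PAIRS = (("od1", "od2"), ("od1", "ground_truth"), ("od2", "ground_truth"))

_PAIR_LABEL = {
    ("od1", "od2"): "od1-od2",
    ("od1", "ground_truth"): "od1-gt",
    ("od2", "ground_truth"): "od2-gt",
}

METRIC_COLUMNS = ("dice", "kappa_region", "kappa_border", "mu_d")


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable knobs of the analysis.

    ``bbox_scope`` chooses whether the kappa bounding box surrounds just
    the two tracings compared ("pair", the default, self-contained per
    comparison) or every tracing of the image ("all").
    """

    apply_ellipse_fit: bool = False
    bbox_scope: Literal["pair", "all"] = "pair"
    border_tolerance: float = 2.0
    angle_set: str | Sequence[float] = "uniform30"
    bbox_margin: int = 0
    refit_ground_truth: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.border_tolerance < 0:
            raise InputError("border_tolerance must be >= 0")
        if self.bbox_margin < 0:
            raise InputError("bbox_margin must be >= 0")
        if self.bbox_scope not in ("pair", "all"):
            raise InputError("bbox_scope must be 'pair' or 'all'")

    @property
    def angles(self) -> tuple[float, ...]:
        if isinstance(self.angle_set, str):
            if self.angle_set == "uniform30":
                return am.ANGLES_UNIFORM30
            if self.angle_set in ("paper-literal", "paper"):
                return am.ANGLES_PAPER_LITERAL
            raise InputError(f"unknown angle set {self.angle_set!r}")
        return tuple(float(a) for a in self.angle_set)


@dataclass
class StudyReport:
    """Per-image rows plus stratified aggregate tables."""

    per_image: pd.DataFrame
    by_dataset: pd.DataFrame
    by_condition: pd.DataFrame
    options: dict = field(default_factory=dict)


def _as_mask(tracing, shape) -> TraceMask:
    if isinstance(tracing, TraceMask):
        return tracing
    return polyline_to_mask(tracing, shape)


def _prepare_masks(
    record: ImageRecord,
    options: AnalysisOptions,
    raw_cache: dict[str, TraceMask] | None = None,
) -> tuple[dict[str, TraceMask], list[str]]:
    """Raster (and optionally ellipse-refit) every tracing of a record."""
    masks: dict[str, TraceMask] = {}
    flags: list[str] = []
    for label, tracing in record.tracings.items():
        refit_this = options.apply_ellipse_fit and (
            label != "ground_truth" or options.refit_ground_truth
        )
        if refit_this:
            try:
                masks[label] = refit_tracing(tracing, record.shape)
                continue
            except (FitError, InputError):
                flags.append(f"fit-fallback:{label}")
        if raw_cache is not None:
            if label not in raw_cache:
                raw_cache[label] = _as_mask(tracing, record.shape)
            masks[label] = raw_cache[label]
        else:
            masks[label] = _as_mask(tracing, record.shape)
    return masks, flags


def _pair_result(
    masks: dict[str, TraceMask],
    label_a: str,
    label_b: str,
    options: AnalysisOptions,
    extra_flags: Sequence[str] = (),
    band_cache: dict[str, TraceMask] | None = None,
) -> am.AgreementResult:
    a, b = masks[label_a], masks[label_b]
    flags = list(extra_flags)
    if a.is_empty or b.is_empty:
        return am.AgreementResult(
            dice=float("nan"),
            region=None,
            border=None,
            radial=None,
            flags=tuple(flags + ["empty-tracing"]),
        )
    if options.bbox_scope == "all":
        bbox = am.union_bounding_box(masks.values(), margin=options.bbox_margin)
    else:
        bbox = am.union_bounding_box([a, b], margin=options.bbox_margin)
    d = am.dice(a, b)
    region = am.region_kappa(a, b, bbox)
    if band_cache is None:
        band_cache = {}
    for label in (label_a, label_b):
        if label not in band_cache:
            band_cache[label] = am.border_band(masks[label], options.border_tolerance)
    border = am.region_kappa(band_cache[label_a], band_cache[label_b], bbox)
    # boundary distance: reference is ground truth when present in the
    # pair, otherwise the first-listed rater (recorded as a flag)
    if label_b == "ground_truth":
        ref, test = b, a
    elif label_a == "ground_truth":
        ref, test = a, b
    else:
        ref, test = a, b
        flags.append(f"mu-d-reference:{label_a}")
    try:
        radial = am.average_boundary_distance(ref, test, angles=options.angles)
        if radial.n_valid < len(radial.angles):
            flags.append(f"excluded-angles:{len(radial.angles) - radial.n_valid}")
        if radial.n_valid * 2 < len(radial.angles):
            flags.append("mu-d-majority-undefined")
    except MetricError:
        radial = None
        flags.append("mu-d-undefined")
    return am.AgreementResult(dice=d, region=region, border=border, radial=radial, flags=tuple(flags))


def analyze_pair(
    record: ImageRecord, rater_a: str, rater_b: str, options: AnalysisOptions
) -> am.AgreementResult:
    """Score one tracing pair of one image under the given options."""
    for label in (rater_a, rater_b):
        if label not in record.tracings:
            raise InputError(f"record {record.image_id} has no tracing {label!r}")
    masks, flags = _prepare_masks(record, options)
    return _pair_result(masks, rater_a, rater_b, options, extra_flags=flags)


def _result_row(
    record: ImageRecord, pair: tuple[str, str], fitted: bool, res: am.AgreementResult
) -> dict:
    return {
        "image_id": record.image_id,
        "dataset": record.dataset,
        "condition": record.condition,
        "pair": _PAIR_LABEL.get(pair, f"{pair[0]}-{pair[1]}"),
        "fitted": fitted,
        "dice": res.dice,
        "kappa_region": res.region.kappa if res.region else float("nan"),
        "kappa_border": res.border.kappa if res.border else float("nan"),
        "mu_d": res.radial.mu_d if res.radial else float("nan"),
        "n_valid_angles": res.radial.n_valid if res.radial else 0,
        "flags": ";".join(res.flags),
    }


def run_study(
    records: Sequence[ImageRecord], options: AnalysisOptions = AnalysisOptions()
) -> StudyReport:
    """Score all pairs of all records, raw and ellipse-fitted.

    Every image contributes the three pairs twice (``fitted`` False and
    True).  Aggregates are unweighted per-image means grouped by
    (pair, dataset, fitted) and (pair, condition, fitted), with
    interpretation bands attached to the aggregate kappas.
    """
    if not records:
        raise InputError("run_study needs at least one record")
    rows = []
    for record in records:
        raw_cache: dict[str, TraceMask] = {}
        for fitted in (False, True):
            opts = dataclasses.replace(options, apply_ellipse_fit=fitted)
            masks, prep_flags = _prepare_masks(record, opts, raw_cache=raw_cache)
            band_cache: dict[str, TraceMask] = {}
            for pair in PAIRS:
                if pair[0] not in masks or pair[1] not in masks:
                    raise InputError(
                        f"record {record.image_id} is missing tracing "
                        f"{pair[0] if pair[0] not in masks else pair[1]!r}"
                    )
                res = _pair_result(
                    masks, pair[0], pair[1], opts, extra_flags=prep_flags, band_cache=band_cache
                )
                rows.append(_result_row(record, pair, fitted, res))
    per_image = pd.DataFrame(rows)
    usable = per_image[~per_image[list(METRIC_COLUMNS)].isna().all(axis=1)]
    if usable.empty:
        raise MetricError("every row of the study is flagged/unusable")

    def _agg(by: str) -> pd.DataFrame:
        g = (
            per_image.groupby(["pair", by, "fitted"], as_index=False)[list(METRIC_COLUMNS)]
            .mean()
            .sort_values(["pair", by, "fitted"], ignore_index=True)
        )
        g["n_images"] = (
            per_image.groupby(["pair", by, "fitted"])
            .size()
            .reindex(pd.MultiIndex.from_frame(g[["pair", by, "fitted"]]))
            .to_numpy()
        )
        g["kappa_region_band"] = g["kappa_region"].map(am.interpret_kappa)
        g["kappa_border_band"] = g["kappa_border"].map(am.interpret_kappa)
        return g

    return StudyReport(
        per_image=per_image,
        by_dataset=_agg("dataset"),
        by_condition=_agg("condition"),
        options={
            **dataclasses.asdict(options),
            "angle_set": list(AnalysisOptions.angles.fget(options)),
            "mu_d_reference_for_rater_pair": "od1",
        },
    )


def to_markdown(report: StudyReport) -> str:
    """Aggregate tables as markdown: rows = pairs, columns = metric x
    stratum, one block before and one after ellipse fitting."""
    if report.by_dataset.empty:
        raise InputError("report has no aggregates")
    lines: list[str] = []
    for strat_name, table in (("dataset", report.by_dataset), ("condition", report.by_condition)):
        strata = sorted(table[strat_name].unique())
        for fitted, title in ((False, "Before ellipse fitting"), (True, "After ellipse fitting")):
            lines.append(f"### {title} — by {strat_name}")
            lines.append("")
            header = ["pair"] + [f"{m} ({s})" for m in METRIC_COLUMNS for s in strata]
            lines.append("| " + " | ".join(header) + " |")
            lines.append("|" + "---|" * len(header))
            sub = table[table["fitted"] == fitted]
            for pair in ("od1-od2", "od1-gt", "od2-gt"):
                row = [pair]
                for m in METRIC_COLUMNS:
                    for s in strata:
                        cell = sub[(sub["pair"] == pair) & (sub[strat_name] == s)]
                        row.append("-" if cell.empty else f"{cell[m].iloc[0]:.3f}")
                lines.append("| " + " | ".join(row) + " |")
            lines.append("")
    return "\n".join(lines)


def summarize(
    report: StudyReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "json", "markdown"),
) -> dict[str, Path]:
    """Serialize a report; returns the written paths keyed by artifact."""
    if report.per_image.empty:
        raise InputError("cannot summarize an empty report")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: dict[str, Path] = {}
    if "csv" in formats:
        for name, df in (
            ("per_image", report.per_image),
            ("aggregate_by_dataset", report.by_dataset),
            ("aggregate_by_condition", report.by_condition),
        ):
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            written[name + "_csv"] = p
    if "json" in formats:
        p = out_dir / "report.json"
        payload = {
            "options": report.options,
            "by_dataset": report.by_dataset.to_dict(orient="records"),
            "by_condition": report.by_condition.to_dict(orient="records"),
        }
        p.write_text(json.dumps(payload, indent=2, default=float))
        written["json"] = p
    if "markdown" in formats or "md" in formats:
        p = out_dir / "summary.md"
        p.write_text(to_markdown(report))
        written["markdown"] = p
    return written
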