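"""End-to-end per-field analysis and cohort comparison.

For every field: prefilter -> maximum z-projection -> segmentation
(trained classifier or auto-threshold) -> density and interganglionic-area
census -> skeletonization -> junction/branch census -> orientation and
coherency.  Field rows aggregate to subject means (the subject is the
default statistical unit) and groups are compared metric-by-metric with
Welch's t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as nm
from . import skeleton as sk
from .orientation import orientation_and_coherency
from .preprocess import ImageStack, prefilter, z_project_max
from .segment import PixelClassifier, auto_threshold, binarize_prob, classify
from .simulate import CohortRecord
from .stats import significance_stars, welch_t

__all__ = ["AnalysisConfig", "analyze_field", "analyze_cohort", "compare_groups",
           "run_cohort_pipeline"]

log = logging.getLogger(__name__)

#: metrics compared between groups, in reporting order
DEFAULT_METRICS = (
    "density_percent",
    "n_junctions",
    "n_triple",
    "n_quadruple",
    "n_branches",
    "total_branch_length_px",
    "mean_branch_length_px",
    "mean_orientation_deg",
    "coherency",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-field analysis chain."""

    prefilter_method: str = "median_then_gaussian"
    median_radius: int = 2
    gaussian_sigma: float = 1.0
    segmenter: str = "otsu"  # "otsu" | "classifier"
    prob_threshold: float = 0.5
    junction_merge_px: float = 3.0
    spur_min_px: float = 4.0
    min_component_px: float = 12.0
    compute_orientation: bool = True
    gradient_sigma: float = 1.0
    window_sigma: float = 4.0
    bin_scheme: nm.AreaBinScheme = field(default_factory=nm.AreaBinScheme)
    unit: str = "subject"  # statistical unit: "subject" | "field"

    def __post_init__(self):
        if self.segmenter not in ("otsu", "classifier"):
            raise ValueError("segmenter must be 'otsu' or 'classifier'")
        if self.unit not in ("subject", "field"):
            raise ValueError("unit must be 'subject' or 'field'")


def segment_field(
    image: np.ndarray, config: AnalysisConfig, classifier: PixelClassifier | None
) -> np.ndarray:
    if config.segmenter == "classifier":
        if classifier is None:
            raise ValueError("config requests a classifier but none was given")
        return binarize_prob(classify(image, classifier), config.prob_threshold)
    return auto_threshold(image)


def analyze_field(
    stack: ImageStack,
    config: AnalysisConfig = AnalysisConfig(),
    classifier: PixelClassifier | None = None,
) -> dict:
    """Compute the full per-field metric row from a raw z-stack."""
    filtered = prefilter(
        stack,
        method=config.prefilter_method,
        median_radius=config.median_radius,
        gaussian_sigma=config.gaussian_sigma,
    )
    proj = z_project_max(filtered)
    mask = segment_field(proj, config, classifier)

    row: dict = {"density_percent": nm.network_density(mask)}
    areas = nm.interganglionic_areas(mask)
    counts = nm.bin_areas(areas, config.bin_scheme)
    for label, c in zip(config.bin_scheme.labels, counts):
        row[f"areas_{label}"] = int(c)

    skel = sk.skeletonize_2d(mask)
    graph = sk.build_graph(skel, check=False)
    graph = sk.contract_short_branches(graph, config.junction_merge_px)
    graph = sk.prune_spurs(graph, config.spur_min_px)
    graph = sk.drop_small_components(graph, config.min_component_px)
    census = sk.junction_census(graph)
    branches = sk.branch_stats(graph)
    row.update(
        n_junctions=census.total,
        n_triple=census.n_triple,
        n_quadruple=census.n_quadruple,
        n_higher=census.n_higher,
        n_branches=branches.n_branches,
        total_branch_length_px=branches.total_length_px,
        mean_branch_length_px=branches.mean_length_px,
    )

    if config.compute_orientation:
        ori = orientation_and_coherency(
            proj, gradient_sigma=config.gradient_sigma, window_sigma=config.window_sigma
        )
        row.update(
            mean_orientation_deg=ori.mean_orientation_deg,
            raw_arithmetic_mean_deg=ori.raw_arithmetic_mean_deg,
            coherency=ori.coherency,
            coherency_percent=ori.coherency_percent,
        )
    return row


def analyze_cohort(
    records: list[CohortRecord],
    config: AnalysisConfig = AnalysisConfig(),
    classifier: PixelClassifier | None = None,
) -> pd.DataFrame:
    """Per-field metric table for a cohort; failed fields are logged and
    skipped (their count is attached to ``DataFrame.attrs['n_failed']``)."""
    rows = []
    n_failed = 0
    for rec in records:
        try:
            row = analyze_field(rec.stack, config, classifier)
        except Exception:  # noqa: BLE001 - a bad field must not kill the run
            log.exception(
                "field failed: group=%s subject=%s field=%s",
                rec.group, rec.subject, rec.fieldnum,
            )
            n_failed += 1
            continue
        row.update(group=rec.group, subject=rec.subject, fieldnum=rec.fieldnum)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    if n_failed:
        log.warning("%d field(s) failed and were excluded", n_failed)
    return df


def compare_groups(
    per_field: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    unit: str = "subject",
) -> pd.DataFrame:
    """Welch comparison of two groups for each metric.

    With ``unit='subject'`` fields are first averaged per subject
    (conservative default for a several-fields-per-animal design); with
    ``unit='field'`` every field is treated as an observation.
    """
    groups = sorted(per_field["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    if unit == "subject":
        data = per_field.groupby(["group", "subject"], sort=True)[list(metrics)].mean()
        data = data.reset_index()
    elif unit == "field":
        data = per_field
    else:
        raise ValueError("unit must be 'subject' or 'field'")
    rows = []
    for m in metrics:
        a = data.loc[data["group"] == groups[0], m].dropna().to_numpy()
        b = data.loc[data["group"] == groups[1], m].dropna().to_numpy()
        res = welch_t(a, b)
        rows.append(
            {
                "metric": m,
                "unit": unit,
                f"mean_{groups[0]}": a.mean(),
                f"sem_{groups[0]}": a.std(ddof=1) / np.sqrt(len(a)),
                f"mean_{groups[1]}": b.mean(),
                f"sem_{groups[1]}": b.std(ddof=1) / np.sqrt(len(b)),
                "n_a": len(a),
                "n_b": len(b),
                "welch_t": res.t,
                "welch_df": res.df,
                "p": res.p,
                "stars": significance_stars(res.p),
            }
        )
    return pd.DataFrame(rows)


def run_cohort_pipeline(
    records: list[CohortRecord],
    config: AnalysisConfig = AnalysisConfig(),
    classifier: PixelClassifier | None = None,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full cohort run: per-field table, per-unit table, group comparison."""
    per_field = analyze_cohort(records, config, classifier)
    avail = tuple(m for m in metrics if m in per_field.columns)
    per_subject = (
        per_field.groupby(["group", "subject"], sort=True)[list(avail)]
        .mean()
        .reset_index()
    )
    summary = compare_groups(per_field, avail, unit=config.unit)
    return per_field, per_subject, summary
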