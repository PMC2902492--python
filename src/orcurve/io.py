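"""Data ingestion, curve serialization, and report rendering.

Input is any delimited table (CSV/TSV) with a header, or a SAS transport
(XPT) file; the loader applies the case-defining outcome rule, the optional
minimum-age inclusion filter, and the drop-missing policy, logging the count
excluded at each step.  Outputs are tidy delimited tables that re-ingest
bit-identically, plus SVG plots.  No file payload contains timestamps, so
every output is deterministic given inputs and configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curve_scan import CutoffGrid, ORCurve, explicit_grid
from .effects import AnalyticSample
from .selectors import StrategyResult, strategy_table

__all__ = [
    "LoadConfig",
    "load_table",
    "load_frame",
    "write_sample",
    "curve_to_frame",
    "curve_from_frame",
    "write_curve",
    "read_curve",
    "render_report",
]

logger = logging.getLogger(__name__)

_CURVE_COLUMNS = [
    "cutoff", "a", "b", "c", "d", "or", "ci_low", "ci_high",
    "se_log_or", "estimable", "correction_applied",
]


@dataclass(frozen=True)
class LoadConfig:
    """Column mapping and filter rules for building an analytic sample.

    ``outcome_threshold``: None when the outcome column is already binary
    (values in {0, 1}); otherwise the outcome is continuous and a record is a
    case exactly when its value is at or above the threshold (e.g. total
    cholesterol >= 200 mg/dl).  ``min_age`` keeps records with
    ``age >= min_age`` (requires ``age_column``).  Records missing the
    exposure or outcome are always dropped, with the count logged.
    """

    exposure_column: str
    outcome_column: str
    outcome_threshold: float | None = None
    stratum_column: str | None = None
    age_column: str | None = None
    min_age: float | None = None

    def __post_init__(self) -> None:
        if self.outcome_threshold is not None and not math.isfinite(
            self.outcome_threshold
        ):
            raise ValueError("outcome_threshold must be finite")
        if self.min_age is not None and self.age_column is None:
            raise ValueError("min_age filter requires age_column")


def _read_any(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xpt":
        return pd.read_sas(path, format="xport")
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, comment="#",
                       float_precision="round_trip")


def load_frame(frame: pd.DataFrame, config: LoadConfig) -> AnalyticSample:
    """Build an :class:`AnalyticSample` from an in-memory table."""
    needed = [config.exposure_column, config.outcome_column]
    for col in (config.stratum_column, config.age_column):
        if col is not None:
            needed.append(col)
    missing_cols = [c for c in needed if c not in frame.columns]
    if missing_cols:
        raise KeyError(f"missing column(s): {', '.join(missing_cols)}")

    df = frame.loc[:, needed].copy()
    n0 = len(df)
    for col in (config.exposure_column, config.outcome_column):
        df[col] = pd.to_numeric(df[col], errors="raise")

    if config.min_age is not None:
        ages = pd.to_numeric(df[config.age_column], errors="raise")
        keep = ages >= config.min_age
        dropped = int((~keep | ages.isna()).sum())
        if dropped:
            logger.info(
                "excluded %d record(s) below age %g or missing age",
                dropped, config.min_age,
            )
        df = df[keep.fillna(False)]

    core = [config.exposure_column, config.outcome_column]
    before = len(df)
    df = df.dropna(subset=core)
    if before - len(df):
        logger.info(
            "excluded %d record(s) missing exposure or outcome", before - len(df)
        )
    if df.empty:
        raise ValueError(f"no records remain after filters (started with {n0})")

    outcome = df[config.outcome_column].to_numpy(dtype=float)
    if config.outcome_threshold is None:
        if not np.isin(outcome, (0.0, 1.0)).all():
            raise ValueError(
                "outcome column is not binary; give outcome_threshold to "
                "define cases from a continuous outcome"
            )
        case = outcome.astype(np.int8)
    else:
        case = (outcome >= config.outcome_threshold).astype(np.int8)

    return AnalyticSample(
        exposure=df[config.exposure_column].to_numpy(dtype=float),
        case=case,
        stratum=(df[config.stratum_column].to_numpy()
                 if config.stratum_column else None),
        age=(pd.to_numeric(df[config.age_column]).to_numpy(dtype=float)
             if config.age_column else None),
    )


def load_table(path: str | Path, config: LoadConfig) -> AnalyticSample:
    """Read a delimited or XPT file and apply the load config.

    Lines starting with ``#`` in delimited files are treated as comments
    (the sample writer records its provenance that way).
    """
    return load_frame(_read_any(path), config)


def write_sample(
    sample: AnalyticSample,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a sample as CSV; ``header_comment`` lines are prefixed with #."""
    path = Path(path)
    cols = {"exposure": sample.exposure, "case": sample.case}
    if sample.stratum is not None:
        cols["stratum"] = sample.stratum
    if sample.age is not None:
        cols["age"] = sample.age
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def curve_to_frame(curve: ORCurve) -> pd.DataFrame:
    """Tidy one-row-per-cutoff representation of an OR curve."""
    return pd.DataFrame({
        "cutoff": curve.cutoffs,
        "a": curve.a, "b": curve.b, "c": curve.c, "d": curve.d,
        "or": curve.or_value,
        "ci_low": curve.ci_low, "ci_high": curve.ci_high,
        "se_log_or": curve.se_log_or,
        "estimable": curve.estimable.astype(bool),
        "correction_applied": curve.correction_applied.astype(bool),
    })


def curve_from_frame(frame: pd.DataFrame, sample_n: int | None = None) -> ORCurve:
    """Rebuild an :class:`ORCurve` from its tidy representation."""
    missing = [c for c in _CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise KeyError(f"curve table missing column(s): {', '.join(missing)}")
    cells = [frame[k].to_numpy(dtype=np.int64) for k in "abcd"]
    if sample_n is None:
        sample_n = int(sum(x[0] for x in cells))
    or_value = frame["or"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        log_or = np.log(or_value)
    return ORCurve(
        grid=explicit_grid(frame["cutoff"].to_numpy(dtype=float)),
        a=cells[0], b=cells[1], c=cells[2], d=cells[3],
        or_value=or_value, log_or=log_or,
        se_log_or=frame["se_log_or"].to_numpy(dtype=float),
        ci_low=frame["ci_low"].to_numpy(dtype=float),
        ci_high=frame["ci_high"].to_numpy(dtype=float),
        estimable=frame["estimable"].to_numpy(dtype=bool),
        correction_applied=frame["correction_applied"].to_numpy(dtype=bool),
        sample_n=sample_n,
    )


def write_curve(curve: ORCurve, path: str | Path) -> None:
    # %.17g round-trips every float64 bit-exactly
    curve_to_frame(curve).to_csv(path, index=False, float_format="%.17g")


def read_curve(path: str | Path, sample_n: int | None = None) -> ORCurve:
    frame = pd.read_csv(path, float_precision="round_trip")
    return curve_from_frame(frame, sample_n=sample_n)


def _plot_or_curve(curve: ORCurve, path: Path, window=None) -> dict:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    est = curve.estimable.astype(bool)
    x = curve.cutoffs
    masked = ~est & ~curve.correction_applied.astype(bool)
    ax.fill_between(x, curve.ci_low, curve.ci_high, where=est,
                    alpha=0.25, color="tab:blue", label="pointwise 95% CI")
    ax.plot(x[est], curve.or_value[est], color="tab:blue", lw=1.2,
            label="OR")
    corrected = curve.correction_applied.astype(bool)
    if corrected.any():
        ax.plot(x[corrected], curve.or_value[corrected], ".",
                color="tab:orange", ms=3, label="continuity-corrected")
    if window is not None:
        ax.axvspan(window[0], window[1], color="0.9", zorder=0)
    ax.axhline(1.0, color="0.4", lw=0.8, ls="--")
    ax.set_xlabel("cutoff (exposure units)")
    ax.set_ylabel("odds ratio")
    ax.set_yscale("log")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    masked_spans = _runs(x, masked)
    return {"path": str(path), "masked_spans": masked_spans}


def _runs(x: np.ndarray, flag: np.ndarray) -> list[tuple[float, float]]:
    spans, start = [], None
    for xi, fi in zip(x, flag):
        if fi and start is None:
            start = float(xi)
        elif not fi and start is not None:
            spans.append((start, prev))
            start = None
        prev = float(xi)
    if start is not None:
        spans.append((start, prev))
    return spans


def _plot_roc(roc: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(roc["fpr"], roc["sensitivity"], color="tab:blue", lw=1.2)
    ax.plot([0, 1], [0, 1], color="0.4", lw=0.8, ls="--")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_auc(auc: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(auc["cutoff"], auc["auc"], color="tab:blue", lw=1.2)
    ax.set_xlabel("cutoff (exposure units)")
    ax.set_ylabel("AUC of the dichotomized classifier")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_report(
    outdir: str | Path,
    curve: ORCurve | None = None,
    strategies: Sequence[StrategyResult] | None = None,
    roc: pd.DataFrame | None = None,
    auc: pd.DataFrame | None = None,
    fmt: str = "svg",
) -> dict:
    """Write whichever result artifacts were supplied into ``outdir``.

    Emits: the OR-curve plot (CI band, corrected points marked, non-estimable
    spans masked and listed in the returned metadata), the curve's tidy CSV,
    the ROC and AUC-by-cutoff plots with their CSVs, and the strategy
    comparison table.  Returns a dict of written paths plus plot metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("svg", "png"):
        raise ValueError("plot format must be 'svg' or 'png'")
    written: dict = {}
    if curve is not None:
        written["or_curve_plot"] = _plot_or_curve(
            curve, outdir / f"or_curve.{fmt}", window=None
        )
        write_curve(curve, outdir / "or_curve.csv")
        written["or_curve_csv"] = str(outdir / "or_curve.csv")
    if roc is not None:
        _plot_roc(roc, outdir / f"roc.{fmt}")
        roc.to_csv(outdir / "roc.csv", index=False)
        written["roc_plot"] = str(outdir / f"roc.{fmt}")
        written["roc_csv"] = str(outdir / "roc.csv")
    if auc is not None:
        _plot_auc(auc, outdir / f"auc_by_cutoff.{fmt}")
        auc.to_csv(outdir / "auc_by_cutoff.csv", index=False)
        written["auc_plot"] = str(outdir / f"auc_by_cutoff.{fmt}")
        written["auc_csv"] = str(outdir / "auc_by_cutoff.csv")
    if strategies is not None:
        table = strategy_table(list(strategies))
        table.to_csv(outdir / "strategies.csv", index=False)
        written["strategies_csv"] = str(outdir / "strategies.csv")
    return written
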