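"""Analysis of colicin potency and cross-induction assays.

Covers the two standard bench readouts and their joint analysis:

* **Spot-titer assay** — a colicin extract is serially diluted and spotted on
  a lawn of a sensitive indicator strain; the titer is the inverse of the
  greatest dilution that still clears an inhibition zone.
* **Reporter (luminescence) assay** — a *lux* reporter fused to a colicin
  promoter is challenged with a colicin extract and light emission (RLU) is
  monitored hourly; induction is summarized as the response ratio, induced
  RLU over the non-induced control, with ratios above 2 called as induction.
* **Potency-induction correlation** — the Pearson correlation between each
  colicin's titer and the mean response it triggers across reporter strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "ResponseTable",
    "ReporterTimeseries",
    "InductionCalls",
    "compute_titer",
    "response_ratio",
    "induction_matrix",
    "potency_induction_correlation",
]


@dataclass
class DilutionSeries:
    """Ordered dilution factors with per-spot inhibition flags.

    Factors are in (0, 1], strictly decreasing (e.g. two-fold steps
    1, 1/2, 1/4, ...); ``inhibited[k]`` records whether the spot of dilution
    ``factors[k]`` produced a clear inhibition zone.
    """

    factors: np.ndarray
    inhibited: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.inhibited = np.asarray(self.inhibited, dtype=bool)
        if self.factors.size == 0:
            raise ValueError("at least one dilution must be tested")
        if self.factors.shape != self.inhibited.shape:
            raise ValueError("factors and inhibition flags must align")
        if np.any(self.factors <= 0) or np.any(self.factors > 1):
            raise ValueError("dilution factors must lie in (0, 1]")
        if np.any(np.diff(self.factors) >= 0):
            raise ValueError("dilution factors must be strictly decreasing")


@dataclass
class ResponseTable:
    """Colicin x reporter response-ratio matrix.

    Rows are reporter strains, columns are inducing extracts; ``data`` holds
    the response ratios (RLU/RLU0), ``sd`` their dispersion if known.  The
    toxin-free extract column and the promoterless reporter row are named so
    analyses can exclude them.
    """

    data: pd.DataFrame
    sd: pd.DataFrame | None = None
    control_column: str | None = None
    promoterless_row: str | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float) <= 0).any():
            raise ValueError("response ratios must be positive")

    def assay_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != self.control_column]

    def reporter_rows(self) -> list[str]:
        return [r for r in self.data.index if r != self.promoterless_row]


@dataclass
class ReporterTimeseries:
    """Hourly RLU of induced wells and the non-induced control.

    ``induced`` and ``control`` are (n_replicates, n_times) arrays (a 1D
    array is treated as a single replicate) over the same hourly grid.
    """

    hours: np.ndarray
    induced: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        self.induced = np.atleast_2d(np.asarray(self.induced, dtype=float))
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        if self.induced.shape[1] != self.hours.size or self.control.shape[1] != self.hours.size:
            raise ValueError("induced/control lengths must match the hour grid")
        if (self.induced < 0).any() or (self.control < 0).any():
            raise ValueError("RLU values must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return self.induced.shape[0]


def compute_titer(series: DilutionSeries) -> float:
    """Titer = inverse of the greatest dilution still producing inhibition.

    "Greatest dilution" means the most dilute spot (smallest factor) whose
    inhibition flag is set.  Returns 0 when no dilution inhibits.  A
    non-monotone pattern (a clear zone reappearing after disappearing) is
    physically suspect and triggers a warning, but the greatest-dilution rule
    is still applied.
    """
    flags = series.inhibited
    if not flags.any():
        return 0.0
    # factors are strictly decreasing, so the "greatest dilution" with
    # inhibition is the last flagged entry
    last_true = int(np.flatnonzero(flags)[-1])
    if not flags[: last_true + 1].all():
        warnings.warn(
            "non-monotone inhibition pattern: clear zone reappears after "
            "disappearing; applying the greatest-dilution rule anyway",
            stacklevel=2,
        )
    return 1.0 / float(series.factors[last_true])


def response_ratio(
    ts: ReporterTimeseries,
    summary: Literal["max_over_time", "per_time"] = "max_over_time",
) -> float | np.ndarray:
    """Induced/control luminescence ratio.

    Replicates are averaged first; the ratio is computed per hour.  The
    ``max_over_time`` summary collapses the hourly ratios to their maximum
    (peak induction, robust to onset lag); ``per_time`` returns the full
    hourly ratio vector.
    """
    induced = ts.induced.mean(axis=0)
    control = ts.control.mean(axis=0)
    if (control <= 0).any():
        raise ValueError("control RLU must be positive at every compared time")
    ratios = induced / control
    if summary == "per_time":
        return ratios
    if summary == "max_over_time":
        return float(ratios.max())
    raise ValueError("summary must be 'max_over_time' or 'per_time'")


@dataclass
class InductionCalls:
    """Boolean induction calls and per-extract induced-reporter counts."""

    calls: pd.DataFrame
    counts: pd.Series
    threshold: float
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = int(self.counts.sum())


def induction_matrix(table: ResponseTable, threshold: float = 2.0) -> InductionCalls:
    """Call induction wherever the response ratio exceeds ``threshold``.

    The per-extract counts cover only genuine assay cells: the toxin-free
    control column and the promoterless reporter row are excluded.  Raising
    the threshold can only remove calls, never add them.
    """
    if threshold <= 1:
        raise ValueError("induction threshold must exceed 1")
    calls = table.data > threshold
    if table.control_column is None or table.control_column not in table.data.columns:
        warnings.warn(
            "no toxin-free control column declared; counting over all columns",
            stacklevel=2,
        )
    cols = table.assay_columns()
    rows = table.reporter_rows()
    counts = calls.loc[rows, cols].sum(axis=0)
    return InductionCalls(calls=calls, counts=counts, threshold=threshold)


def mean_response(table: ResponseTable) -> pd.Series:
    """Mean response ratio per extract across real reporter rows."""
    return table.data.loc[table.reporter_rows(), table.assay_columns()].mean(axis=0)


def potency_induction_correlation(
    titers: Mapping[str, float],
    table: ResponseTable,
    scale: Literal["log10", "linear"] = "log10",
) -> float:
    """Pearson correlation between colicin potency and mean induced response.

    ``titers`` maps extract names (matching the table's assay columns) to
    spot titers.  Each extract's induction strength is the mean response
    ratio across the non-promoterless reporter rows; both axes are optionally
    log10-scaled before correlating (the default, since titers span orders of
    magnitude).  Requires at least three extracts present in both inputs and
    nonzero variance on both axes.
    """
    means = mean_response(table)
    common = [c for c in means.index if c in titers]
    if len(common) < 3:
        raise ValueError("need >= 3 extracts with both a titer and responses")
    x = np.array([float(titers[c]) for c in common])
    y = means.loc[common].to_numpy(dtype=float)
    if scale == "log10":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 scale requires positive titers and responses")
        x, y = np.log10(x), np.log10(y)
    elif scale != "linear":
        raise ValueError("scale must be 'log10' or 'linear'")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance on one axis")
    r, _ = stats.pearsonr(x, y)
    return float(r)
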