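"""Fixed-width dose binning of per-ear observations.

Each observation is one inner ear's dose exposure (its mean or maximum dose
in Gy) together with a binary toxicity outcome.  Observations are grouped
into half-open dose intervals of fixed width (5 Gy by default) and the
per-bin toxicity incidence — events over totals — is the quantity the CDLR
sigmoid is fitted to, with the bin totals serving as fit weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EarObservation",
    "DoseBin",
    "BinnedSeries",
    "bin_observations",
    "incidence_table",
    "series_from_table",
    "read_cohort_csv",
    "write_cohort_csv",
]

SIDES = ("left", "right")
METRICS = ("mean", "max")

COHORT_COLUMNS = ["patient_id", "side", "metric", "dose_gy", "event"]
TABLE_COLUMNS = ["lower_gy", "upper_gy", "dose_rep_gy", "n_total", "n_events", "incidence"]


@dataclass(frozen=True)
class EarObservation:
    """One ear's dose exposure and binary toxicity outcome.

    ``metric`` records whether ``dose`` is the mean or the maximum dose the
    ear received; both ears of a patient appear as separate observations.
    """

    patient_id: str
    side: str  # "left" | "right"
    metric: str  # "mean" | "max"
    dose: float  # Gy
    event: int  # 0 | 1

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if not (math.isfinite(self.dose) and self.dose > 0):
            raise ValueError(f"dose must be finite and > 0 Gy, got {self.dose}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class DoseBin:
    """A half-open dose interval [lower, upper) with its toxicity tally."""

    lower: float  # Gy
    upper: float  # Gy
    n_total: int
    n_events: int
    incidence: float  # n_events / n_total
    dose_rep: float  # representative dose plotted/fitted for this bin, Gy


@dataclass(frozen=True)
class BinnedSeries:
    """Ordered, non-overlapping dose bins for one dose metric."""

    metric: str
    bin_width: float
    bins: tuple  # tuple[DoseBin, ...], ascending by lower edge

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def n_observations(self) -> int:
        return sum(b.n_total for b in self.bins)


def bin_observations(
    obs: Iterable[EarObservation],
    metric: str,
    bin_width: float = 5.0,
    anchor: float = 0.0,
    dose_rep_mode: str = "midpoint",
) -> BinnedSeries:
    """Group observations of one dose metric into fixed-width dose bins.

    Every observation whose ``metric`` matches is assigned to exactly one
    half-open interval ``[anchor + k*width, anchor + (k+1)*width)``.  Bins
    that receive no observations are not materialised — they would carry zero
    weight in the fit.

    Parameters
    ----------
    dose_rep_mode : {"midpoint", "member_mean"}
        Representative dose of a bin: the interval midpoint (default) or the
        mean of the member doses.

    Returns
    -------
    BinnedSeries
        Bins in ascending dose order; empty input yields zero bins.
    """
    if not (bin_width > 0):
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if dose_rep_mode not in ("midpoint", "member_mean"):
        raise ValueError(f"unknown dose_rep_mode {dose_rep_mode!r}")

    groups: dict[int, list[EarObservation]] = {}
    for o in obs:
        if o.metric != metric:
            continue
        k = math.floor((o.dose - anchor) / bin_width)
        groups.setdefault(k, []).append(o)

    bins = []
    for k in sorted(groups):
        members = groups[k]
        lower = anchor + k * bin_width
        n_total = len(members)
        n_events = sum(o.event for o in members)
        if dose_rep_mode == "midpoint":
            dose_rep = lower + bin_width / 2.0
        else:
            dose_rep = sum(o.dose for o in members) / n_total
        bins.append(
            DoseBin(
                lower=lower,
                upper=lower + bin_width,
                n_total=n_total,
                n_events=n_events,
                incidence=n_events / n_total,
                dose_rep=dose_rep,
            )
        )
    return BinnedSeries(metric=metric, bin_width=bin_width, bins=tuple(bins))


def incidence_table(series: BinnedSeries) -> pd.DataFrame:
    """One row per bin: edges, representative dose, counts, incidence."""
    return pd.DataFrame(
        [
            {
                "lower_gy": b.lower,
                "upper_gy": b.upper,
                "dose_rep_gy": b.dose_rep,
                "n_total": b.n_total,
                "n_events": b.n_events,
                "incidence": b.incidence,
            }
            for b in series.bins
        ],
        columns=TABLE_COLUMNS,
    )


def series_from_table(df: pd.DataFrame, metric: str, bin_width: float) -> BinnedSeries:
    """Rebuild a :class:`BinnedSeries` from its :func:`incidence_table` form.

    The incidence is recomputed from the counts rather than trusting the
    serialized column, so the round trip is exact at full double precision.
    """
    bins = tuple(
        DoseBin(
            lower=float(r.lower_gy),
            upper=float(r.upper_gy),
            n_total=int(r.n_total),
            n_events=int(r.n_events),
            incidence=int(r.n_events) / int(r.n_total),
            dose_rep=float(r.dose_rep_gy),
        )
        for r in df.itertuples(index=False)
    )
    return BinnedSeries(metric=metric, bin_width=bin_width, bins=bins)


def _observations_from_frame(df: pd.DataFrame, source: str) -> list:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        import warnings

        warnings.warn(f"{source}: ignoring unknown column(s) {extra}", stacklevel=3)

    obs, bad = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        # +2: header line plus 1-based line numbering
        line = i + 2
        try:
            obs.append(
                EarObservation(
                    patient_id=str(row.patient_id),
                    side=str(row.side),
                    metric=str(row.metric),
                    dose=float(row.dose_gy),
                    event=int(row.event),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(f"line {line}: {exc}")
    if bad:
        raise ValueError(f"{source}: {len(bad)} unparseable row(s):\n" + "\n".join(bad))
    return obs


def read_cohort_csv(path) -> list:
    """Read a per-ear cohort CSV (patient_id, side, metric, dose_gy, event).

    Strict: missing required columns or unparseable rows raise ``ValueError``
    naming the offending lines; unknown columns only warn.
    """
    df = pd.read_csv(path, dtype=str)
    return _observations_from_frame(df, str(path))


def write_cohort_csv(obs: Sequence[EarObservation], path) -> None:
    """Write observations in the cohort CSV schema (full double precision)."""
    pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "side": o.side,
                "metric": o.metric,
                "dose_gy": repr(o.dose),
                "event": o.event,
            }
            for o in obs
        ],
        columns=COHORT_COLUMNS,
    ).to_csv(path, index=False)
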