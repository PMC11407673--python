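"""Detection-history construction from raw camera-trap records.

Raw inputs are a record table (station_id, timestamp) and a deployment table
(station_id, start, end, survey). Deployments are first stacked so each
camera x calendar-year combination becomes its own sampling site, then each
site's active window is cut into consecutive fixed-length occasions (15 days
by default), truncated at 120 days to respect the closure assumption. The
result is a sites x occasions binary matrix plus a parallel effort matrix of
active days per occasion; an occasion with zero effort is missing (NaN), not
a non-detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["station_id", "timestamp"]
DEPLOYMENT_COLUMNS = ["station_id", "start", "end", "survey"]


class OverlapError(ValueError):
    """Two deployments overlap within the same station-year."""


@dataclass
class DetectionHistory:
    """Stacked sites x occasions detection and effort matrices.

    ``y`` holds 0/1 with NaN for missing occasions; ``effort`` holds the
    number of active camera-days in each occasion (0 exactly where ``y`` is
    missing). ``site_frame`` carries one row of site metadata
    (station_id, year, survey) per matrix row, in matrix order.
    """

    site_index: list[tuple[str, int]]
    y: np.ndarray
    effort: np.ndarray
    occasion_length_days: int = 15
    site_frame: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.y.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing (effort > 0) cells."""
        return self.effort > 0

    def validate(self) -> None:
        if self.y.shape != self.effort.shape:
            raise ValueError("y and effort shapes differ")
        miss = np.isnan(self.y)
        if not np.array_equal(miss, self.effort == 0):
            raise ValueError("missingness pattern of y must match effort == 0")
        if not np.isin(self.y[~miss], [0.0, 1.0]).all():
            raise ValueError("y entries must be 0, 1 or NaN")
        if self.n_sites and np.any((~miss).sum(axis=1) == 0):
            raise ValueError("every site needs at least one non-missing occasion")

    def subset(self, idx: np.ndarray) -> "DetectionHistory":
        return DetectionHistory(
            site_index=[self.site_index[i] for i in np.atleast_1d(idx)],
            y=self.y[idx].copy(),
            effort=self.effort[idx].copy(),
            occasion_length_days=self.occasion_length_days,
            site_frame=None
            if self.site_frame is None
            else self.site_frame.iloc[np.atleast_1d(idx)].reset_index(drop=True),
        )


def filter_independent_records(
    records: pd.DataFrame, interval_minutes: float = 30.0
) -> pd.DataFrame:
    """Collapse bursts of photos into independent detection events.

    Within each station (independence is per-station), records are walked in
    time order and a record is dropped when it falls strictly less than
    ``interval_minutes`` after the previously *retained* record. Exact
    duplicate rows are removed first; ``interval_minutes=0`` therefore keeps
    every distinct record.
    """
    if interval_minutes < 0:
        raise ValueError("independence interval must be non-negative")
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"], format="mixed")
    rec = rec.drop_duplicates(subset=RECORD_COLUMNS).sort_values(
        RECORD_COLUMNS, kind="stable"
    )
    keep_frames = []
    delta = pd.Timedelta(minutes=interval_minutes)
    for _, grp in rec.groupby("station_id", sort=True):
        ts = grp["timestamp"].to_numpy()
        keep = np.zeros(len(grp), dtype=bool)
        last = None
        for i, t in enumerate(ts):
            if last is None or (t - last) >= delta:
                keep[i] = True
                last = t
        keep_frames.append(grp[keep])
    if not keep_frames:
        return rec.reset_index(drop=True)
    return pd.concat(keep_frames).reset_index(drop=True)


def stack_site_years(deployments: pd.DataFrame) -> pd.DataFrame:
    """Split deployments at calendar-year boundaries into stacked site-years.

    Each output row is one (station_id, year) sampling site. A deployment
    spanning New Year is cut into one piece per calendar year. Overlapping
    deployments within the same station-year raise :class:`OverlapError`.
    """
    rows = []
    for _, row in deployments.iterrows():
        start = pd.Timestamp(row["start"])
        end = pd.Timestamp(row["end"])
        if start > end:
            raise ValueError(
                f"deployment for {row['station_id']} has start after end"
            )
        cur = start
        while cur <= end:
            year_end = pd.Timestamp(year=cur.year, month=12, day=31)
            piece_end = min(end, year_end)
            out = {c: row[c] for c in deployments.columns if c not in ("start", "end")}
            out.update(start=cur, end=piece_end, year=cur.year)
            rows.append(out)
            cur = piece_end + pd.Timedelta(days=1)
    if not rows:
        out = deployments.iloc[0:0].copy()
        out["year"] = pd.Series(dtype=int)
        return out
    stacked = pd.DataFrame(rows)
    for (sid, year), grp in stacked.groupby(["station_id", "year"]):
        if len(grp) > 1:
            g = grp.sort_values("start")
            if (g["start"].iloc[1:].to_numpy() <= g["end"].iloc[:-1].to_numpy()).any():
                raise OverlapError(
                    f"overlapping deployments for station {sid} in {year}"
                )
    return stacked.sort_values(["station_id", "year", "start"]).reset_index(drop=True)


def build_detection_history(
    records: pd.DataFrame,
    deployments: pd.DataFrame,
    occasion_length: int = 15,
    max_days: int = 120,
) -> DetectionHistory:
    """Bin independent records into a sites x occasions detection matrix.

    ``deployments`` must already be stacked (have a ``year`` column and one
    row per station-year); occasions are anchored at each site's own
    deployment start and truncated at ``min(end, start + max_days - 1)``.
    All rows share ``K = max_days // occasion_length`` columns, with trailing
    never-active occasions marked missing.

    Records that fall outside every deployment interval of their station are
    dropped with a warning; zero-length sites cannot occur because a stacked
    deployment always spans at least one day.
    """
    if occasion_length < 1 or max_days < occasion_length:
        raise ValueError("need occasion_length >= 1 and max_days >= occasion_length")
    if "year" not in deployments.columns:
        raise ValueError("deployments must be stacked first (missing 'year' column)")
    dep = deployments.copy()
    dep["start"] = pd.to_datetime(dep["start"])
    dep["end"] = pd.to_datetime(dep["end"])
    dep = dep.sort_values(["station_id", "year"]).reset_index(drop=True)
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])

    K = max_days // occasion_length
    n = len(dep)
    y = np.full((n, K), np.nan)
    effort = np.zeros((n, K))
    site_index: list[tuple[str, int]] = []
    used = np.zeros(len(rec), dtype=bool)

    rec_by_station = {sid: grp for sid, grp in rec.groupby("station_id")}
    for i, row in dep.iterrows():
        sid, year = row["station_id"], int(row["year"])
        site_index.append((sid, year))
        start, dep_end = row["start"].normalize(), row["end"].normalize()
        win_end = min(dep_end, start + pd.Timedelta(days=max_days - 1))
        grp = rec_by_station.get(sid)
        if grp is not None:
            days = (grp["timestamp"].dt.normalize() - start).dt.days.to_numpy()
            in_dep = (days >= 0) & (grp["timestamp"].dt.normalize() <= dep_end)
            used[grp.index[in_dep]] = True
        for t in range(K):
            occ_start = start + pd.Timedelta(days=t * occasion_length)
            occ_end = min(
                occ_start + pd.Timedelta(days=occasion_length - 1), win_end
            )
            active = (occ_end - occ_start).days + 1
            if occ_start > win_end or active <= 0:
                break
            effort[i, t] = active
            y[i, t] = 0.0
            if grp is not None:
                dnorm = grp["timestamp"].dt.normalize()
                hit = (dnorm >= occ_start) & (dnorm <= occ_end)
                if hit.any():
                    y[i, t] = 1.0

    n_orphan = int((~used).sum())
    if n_orphan:
        warnings.warn(
            f"{n_orphan} record(s) fall outside every deployment interval of "
            "their station and were dropped",
            stacklevel=2,
        )
    meta_cols = [c for c in ("station_id", "year", "survey") if c in dep.columns]
    hist = DetectionHistory(
        site_index=site_index,
        y=y,
        effort=effort,
        occasion_length_days=occasion_length,
        site_frame=dep[meta_cols].reset_index(drop=True),
    )
    hist.validate()
    return hist


def summarize_effort(history: DetectionHistory) -> dict:
    """Totals the field crew cares about: trap-nights, effort moments, events."""
    obs = history.observed
    eff = history.effort[obs]
    detections = history.y[obs]
    return {
        "n_sites": history.n_sites,
        "total_trap_nights": float(history.effort.sum()),
        "mean_effort_per_occasion": float(eff.mean()) if eff.size else 0.0,
        "sd_effort_per_occasion": float(eff.std(ddof=1)) if eff.size > 1 else 0.0,
        "n_detection_events": int(np.nansum(detections)) if detections.size else 0,
        "naive_occupancy": float(np.mean(np.nansum(history.y, axis=1) > 0))
        if history.n_sites
        else 0.0,
    }
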