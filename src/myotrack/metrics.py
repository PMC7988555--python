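"""Per-muscle, per-session summary statistics over matched masks.

One :class:`MuscleSummaryRecord` is produced per subject x muscle x side x
time-point, with the quantities of the cohort tables:

* FF (%), T2 (ms), MD (10^-3 mm^2/s), FA: means over in-mask voxels of the
  native-space parameter maps (masks are transferred to the T2/DWI grids by
  nearest-neighbour lookup; maps are never resampled);
* CSA (cm^2): mean cross-sectional area = in-mask voxel count x in-plane
  voxel area / number of slices the muscle occupies;
* cCSA (cm^2): contractile area, each voxel discounted by its fat fraction
  (``sum (1 - FF_voxel) * area / n_slices``), so cCSA/CSA equals one minus
  the area-weighted mean FF by construction;
* SNR: median over the mask of the PCA noise-derived SNR map.

The module also aggregates records into per-muscle tables (printed-table
layout: cross-sectional FF mean +- SD, CSA/cCSA column totals) and
summarises the fat-fraction distribution (fixed 2%-FF bins, KDE mode count,
low-infiltration flags at the 30% threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import MUSCLE_GROUPS, MuscleLabelMap, ScalarVolume, resample_labels_to_grid

__all__ = [
    "MuscleSummaryRecord",
    "summarize_muscle",
    "summarize_session",
    "aggregate_table",
    "ff_distribution",
    "load_reference_muscle_table",
]

LOW_FF_THRESHOLD_PCT = 30.0


@dataclass
class MuscleSummaryRecord:
    subject: object
    time_point: str
    muscle: str
    side: str
    n_voxels: int
    FF: float    # %
    CSA: float   # cm^2
    cCSA: float  # cm^2
    T2: float    # ms
    MD: float    # 10^-3 mm^2/s
    FA: float
    SNR: float

    def __post_init__(self):
        if self.cCSA > self.CSA + 1e-9:
            raise ValueError("contractile CSA cannot exceed CSA")
        if not (0 <= self.FF <= 100 or np.isnan(self.FF)):
            raise ValueError("FF out of range")


def _masked_mean(vol: ScalarVolume | None, mask: np.ndarray) -> float:
    if vol is None:
        return float("nan")
    vals = vol.values[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def summarize_muscle(
    maps: dict,
    matched_labels: MuscleLabelMap,
    label: int,
    subject,
    time_point: str,
) -> MuscleSummaryRecord | None:
    """Summarise one muscle over its matched mask.

    ``maps`` holds native-space ScalarVolumes under the keys ``ff`` (fraction),
    ``t2`` (ms), ``md`` (mm^2/s), ``fa``, ``snr``; each may live on its own
    grid -- the Dixon-grid mask is transferred to it by nearest neighbour.
    Returns ``None`` (record omitted) if the mask is empty on the Dixon grid
    or after transfer to every map grid.
    """
    from .phantom import parse_label_name  # local import to avoid cycle

    name = matched_labels.label_names[label]
    muscle, side = parse_label_name(name)
    mask = matched_labels.labels == label
    n_vox = int(mask.sum())
    if n_vox == 0:
        return None
    geom = matched_labels.geometry
    vx, vy, _ = geom.voxel_size
    area_cm2 = (vx * vy) / 100.0
    n_slices = int(np.unique(np.argwhere(mask)[:, 2]).size)
    csa = n_vox * area_cm2 / n_slices

    ff_vol = maps.get("ff")
    if ff_vol is not None:
        ff_vals = ff_vol.values[mask]
        good = np.isfinite(ff_vals)
        ff_mean = float(ff_vals[good].mean()) if good.any() else np.nan
        ccsa = float(((1.0 - ff_vals[good]).sum()) * area_cm2 / n_slices) if good.any() else np.nan
    else:
        ff_mean, ccsa = np.nan, np.nan

    def other_grid_mean(key):
        vol = maps.get(key)
        if vol is None:
            return np.nan
        if vol.geometry.allclose(geom):
            m = mask
        else:
            m = resample_labels_to_grid(matched_labels, vol.geometry).labels == label
        if not m.any():
            return np.nan
        return _masked_mean(vol, m)

    t2 = other_grid_mean("t2")
    md = other_grid_mean("md")
    fa = other_grid_mean("fa")
    snr_vol = maps.get("snr")
    if snr_vol is not None:
        if snr_vol.geometry.allclose(geom):
            m = mask
        else:
            m = resample_labels_to_grid(matched_labels, snr_vol.geometry).labels == label
        vals = snr_vol.values[m]
        vals = vals[np.isfinite(vals)]
        snr = float(np.median(vals)) if vals.size else np.nan
    else:
        snr = np.nan

    return MuscleSummaryRecord(
        subject=subject, time_point=time_point, muscle=muscle, side=side,
        n_voxels=n_vox,
        FF=100.0 * ff_mean if np.isfinite(ff_mean) else np.nan,
        CSA=csa,
        cCSA=min(ccsa, csa) if np.isfinite(ccsa) else np.nan,
        T2=t2,
        MD=md * 1e3 if np.isfinite(md) else np.nan,
        FA=fa,
        SNR=snr,
    )


def summarize_session(maps: dict, matched_labels: MuscleLabelMap, subject, time_point: str):
    """Records for every retained muscle of one subject/session."""
    records = []
    present = set(np.unique(matched_labels.labels)) - {0}
    for label in sorted(present):
        rec = summarize_muscle(maps, matched_labels, int(label), subject, time_point)
        if rec is not None:
            records.append(rec)
    return records


def aggregate_table(records, group_by: str = "muscle") -> pd.DataFrame:
    """Cross-sectional aggregates in the printed-table layout.

    ``group_by="muscle"``: one row per muscle (sides pooled) and a
    ``Total`` row -- FF as mean +- SD across measurements, CSA and cCSA as
    column totals, n as measurement count.  ``group_by="muscle_group"``:
    per functional group FF means.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(r) for r in records])
    if records.empty:
        raise ValueError("no records to aggregate")
    df = records.copy()
    if group_by == "muscle_group":
        df["muscle_group"] = df["muscle"].map(MUSCLE_GROUPS)
        out = (
            df.groupby(["muscle_group", "time_point"])
            .agg(FF_mean=("FF", "mean"), FF_sd=("FF", "std"), n=("FF", "size"))
            .reset_index()
        )
        return out
    rows = []
    for (muscle, t), grp in df.groupby(["muscle", "time_point"]):
        rows.append(dict(muscle=muscle, time_point=t,
                         FF_mean=grp.FF.mean(), FF_sd=grp.FF.std(),
                         CSA_total=grp.CSA.sum(), cCSA_total=grp.cCSA.sum(),
                         n=len(grp)))
    out = pd.DataFrame(rows)
    totals = []
    for t, grp in df.groupby("time_point"):
        totals.append(dict(muscle="Total", time_point=t,
                           FF_mean=grp.FF.mean(), FF_sd=grp.FF.std(),
                           CSA_total=grp.CSA.sum(), cCSA_total=grp.cCSA.sum(),
                           n=len(grp)))
    return pd.concat([out, pd.DataFrame(totals)], ignore_index=True)


def ff_distribution(
    ff_percent,
    per_muscle: pd.DataFrame | None = None,
    bin_width: float = 2.0,
    kde_bandwidth: float = 2.0,
    threshold: float = LOW_FF_THRESHOLD_PCT,
) -> dict:
    """Histogram and modality summary of fat-fraction values (%).

    Returns a dict with fixed-width histogram (``bin_edges``, ``counts``),
    the KDE mode locations/count (Gaussian kernel, ``kde_bandwidth`` %FF),
    and -- when ``per_muscle`` records with columns ``muscle``/``FF`` are
    given -- the muscles whose mean FF sits at or below ``threshold``.
    """
    vals = np.asarray(ff_percent, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least two values")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    if vals.std() < 1e-9:
        modes = [float(vals.mean())]
    else:
        grid = np.arange(0.0, 100.0, 0.25)
        dens = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / kde_bandwidth) ** 2).mean(axis=1)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(dens, prominence=0.02 * dens.max())
        modes = [float(grid[p]) for p in peaks]
        if not modes:
            modes = [float(grid[np.argmax(dens)])]
    low_ff = []
    if per_muscle is not None:
        means = per_muscle.groupby("muscle")["FF"].mean()
        low_ff = sorted(means[means <= threshold].index.tolist())
    below = modes and any(m < threshold for m in modes) and any(m > threshold for m in modes)
    return {
        "bin_edges": edges,
        "counts": counts,
        "modes": modes,
        "n_modes": len(modes),
        "modes_split_at_threshold": bool(below),
        "low_ff_muscles": low_ff,
    }


def load_reference_muscle_table() -> pd.DataFrame:
    """The published per-muscle FF/CSA/cCSA table (both time-points).

    Shipped as a CSV fixture; used for aggregate-arithmetic checks."""
    with resources.files("myotrack.fixtures").joinpath("muscle_table.csv").open() as fh:
        return pd.read_csv(fh)
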