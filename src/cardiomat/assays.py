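"""Calcium transient feature extraction and plate-assay reductions.

Fluorescence traces are normalized to ΔF/F0, transients are located by peak
prominence, and per-transient kinetics (amplitude, FWHM, rise and decay
times) are measured with sub-sample accuracy by linear interpolation of the
level crossings. qPCR Ct tables reduce via the comparative cycle-threshold
(ΔΔCT) method against a housekeeping gene and reference group; ATP plate
tables reduce to luminescence/absorbance ratios normalized to a control
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TransientFeatures",
    "normalize_trace",
    "extract_transients",
    "summarize_group",
    "ddct_relative_expression",
    "atp_normalize",
]


@dataclass
class TransientFeatures:
    """Averaged kinetic features of the transients in one trace.

    Durations are in seconds, ``peak_amplitude`` in ΔF/F0 units; the kinetic
    fields are NaN when ``n_transients`` is 0.
    """

    peak_amplitude: float
    fwhm: float
    rise_time: float
    decay_time: float
    n_transients: int

    def as_dict(self) -> dict[str, float]:
        return {
            "peak_amplitude": self.peak_amplitude,
            "fwhm": self.fwhm,
            "rise_time": self.rise_time,
            "decay_time": self.decay_time,
            "n_transients": self.n_transients,
        }


def _check_trace(time: np.ndarray, intensity: np.ndarray) -> float:
    if time.ndim != 1 or intensity.ndim != 1 or len(time) != len(intensity):
        raise ValueError("time and intensity must be 1-D vectors of equal length")
    if len(time) < 3:
        raise ValueError("trace too short")
    dt = np.diff(time)
    if (dt <= 0).any():
        raise ValueError("time must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("time must be uniformly spaced")
    if not np.isfinite(intensity).all():
        raise ValueError("intensity contains non-finite values")
    return float(dt[0])


def normalize_trace(
    time: np.ndarray,
    intensity: np.ndarray,
    baseline_quantile: float = 0.05,
    detrend: bool = True,
) -> tuple[np.ndarray, float]:
    """Convert a raw fluorescence trace to ΔF/F0.

    F0 is the ``baseline_quantile`` quantile of the intensity after an
    optional linear detrend; the output is ``(F − F0) / F0``.

    The drift slope is estimated from a line through per-window baseline
    quantiles (8 windows) rather than ordinary least squares on the raw
    trace, which the transients themselves would bias; the correction is
    anchored at the trace start, where the baseline is least contaminated
    by accumulated drift. F0 itself is read off a lightly smoothed copy of
    the trace (9-sample moving average) so that a low quantile of flat
    baseline is not pulled down by per-sample noise. Returns ``(dff, f0)``.
    """
    time = np.asarray(time, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    _check_trace(time, intensity)
    if not 0.0 < baseline_quantile < 0.5:
        raise ValueError("baseline_quantile must be in (0, 0.5)")

    f = intensity
    if detrend and len(time) >= 16:
        n_win = 8
        edges = np.linspace(0, len(time), n_win + 1, dtype=int)
        tq, fq = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            tq.append(time[lo:hi].mean())
            fq.append(np.quantile(intensity[lo:hi], baseline_quantile))
        slope, _ = np.polyfit(tq, fq, 1)
        f = intensity - slope * (time - time[0])
    w = min(9, len(f))
    smooth = np.convolve(f, np.ones(w) / w, mode="valid")
    f0 = float(np.quantile(smooth, baseline_quantile))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:.4g} is non-positive; not a physical fluorescence level")
    return (f - f0) / f0, f0


def _interp_crossing(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where y crosses `level` between i and i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t[i])
    return float(t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i]))


def _crossing_before(t: np.ndarray, y: np.ndarray, start: int, stop: int, level: float) -> float | None:
    """Last upward crossing of `level` in [start, stop] scanning backwards from stop."""
    for i in range(stop - 1, start - 1, -1):
        if y[i] <= level <= y[i + 1] or y[i] < level < y[i + 1]:
            return _interp_crossing(t, y, i, level)
    return None


def _crossing_after(t: np.ndarray, y: np.ndarray, start: int, stop: int, level: float) -> float | None:
    """First downward crossing of `level` in [start, stop] scanning forward from start."""
    for i in range(start, stop):
        if y[i] >= level >= y[i + 1] or y[i] > level > y[i + 1]:
            return _interp_crossing(t, y, i, level)
    return None


def extract_transients(
    time: np.ndarray,
    dff: np.ndarray,
    min_prominence: float = 0.2,
    min_separation: float = 0.3,
    rise_bounds: tuple[float, float] = (0.10, 0.90),
    decay_bounds: tuple[float, float] = (0.90, 0.10),
    baseline_window: float = 0.2,
) -> TransientFeatures:
    """Measure transient kinetics on a ΔF/F0 trace.

    Peaks are located by prominence with a minimum separation. Per
    transient, the local baseline is the median of a ``baseline_window``-s
    window ending at the pre-peak minimum; amplitude = peak − baseline; the
    FWHM is the time between the two half-amplitude crossings and the
    rise/decay times the durations between the fractional-amplitude levels
    (defaults 10→90% up, 90→10% down), all by linear interpolation.
    Transients whose crossings run off the trace edge are skipped with a
    warning. Features are averaged over the retained transients.
    """
    time = np.asarray(time, dtype=float)
    dff = np.asarray(dff, dtype=float)
    dt = _check_trace(time, dff)
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")

    distance = max(int(round(min_separation / dt)), 1)
    peaks, _ = find_peaks(dff, prominence=min_prominence, distance=distance)
    if len(peaks) == 0:
        return TransientFeatures(np.nan, np.nan, np.nan, np.nan, 0)

    amps, fwhms, rises, decays = [], [], [], []
    n_skipped = 0
    bounds = [0, *((peaks[:-1] + peaks[1:]) // 2).tolist(), len(dff) - 1]
    for k, p in enumerate(peaks):
        left, right = bounds[k], bounds[k + 1]
        seg = dff[left : p + 1]
        i_min = left + int(np.argmin(seg))
        w = max(int(round(baseline_window / dt)), 1)
        base = float(np.median(dff[max(i_min - w, left) : i_min + 1]))
        amp = float(dff[p] - base)
        if amp <= 0:
            n_skipped += 1
            continue

        def level(frac: float) -> float:
            return base + frac * amp

        half_up = _crossing_before(time, dff, left, p, level(0.5))
        half_down = _crossing_after(time, dff, p, right, level(0.5))
        r_lo = _crossing_before(time, dff, left, p, level(rise_bounds[0]))
        r_hi = _crossing_before(time, dff, left, p, level(rise_bounds[1]))
        d_hi = _crossing_after(time, dff, p, right, level(decay_bounds[0]))
        d_lo = _crossing_after(time, dff, p, right, level(decay_bounds[1]))
        if None in (half_up, half_down, r_lo, r_hi, d_hi, d_lo):
            n_skipped += 1
            continue
        amps.append(amp)
        fwhms.append(half_down - half_up)
        rises.append(r_hi - r_lo)
        decays.append(d_lo - d_hi)

    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} transient(s) truncated at the trace edge or without full crossings",
            stacklevel=2,
        )
    if not amps:
        return TransientFeatures(np.nan, np.nan, np.nan, np.nan, 0)
    return TransientFeatures(
        float(np.mean(amps)),
        float(np.mean(fwhms)),
        float(np.mean(rises)),
        float(np.mean(decays)),
        len(amps),
    )


def summarize_group(
    features: pd.DataFrame,
    cells_per_video: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random per-video cell subsampling, then video and condition summaries.

    ``features`` is a table with one row per cell and columns
    ``condition, video_id, cell_id`` plus numeric feature columns. Per video,
    exactly ``cells_per_video`` cells are sampled without replacement using
    ``seed`` (all cells when fewer are present); video means are then
    averaged per condition with the standard error of the mean. Returns
    ``(per_video, per_condition)``.
    """
    required = {"condition", "video_id", "cell_id"}
    if not required <= set(features.columns):
        raise ValueError(f"features table must have columns {sorted(required)}")
    if features.empty:
        raise ValueError("no features to summarize")
    value_cols = [
        c for c in features.columns if c not in required and pd.api.types.is_numeric_dtype(features[c])
    ]
    rng = np.random.default_rng(seed)
    sampled = []
    for _, grp in features.sort_values(["condition", "video_id", "cell_id"]).groupby("video_id", sort=True):
        if len(grp) > cells_per_video:
            idx = rng.choice(len(grp), size=cells_per_video, replace=False)
            grp = grp.iloc[np.sort(idx)]
        sampled.append(grp)
    sub = pd.concat(sampled, ignore_index=True)

    per_video = sub.groupby(["condition", "video_id"])[value_cols].mean().reset_index()
    g = per_video.groupby("condition")[value_cols]
    per_condition = g.mean()
    sem = g.sem(ddof=1)
    per_condition = per_condition.join(sem, rsuffix="_sem")
    per_condition["n_videos"] = g.size()
    return per_video, per_condition.reset_index()


def ddct_relative_expression(
    ct: pd.DataFrame,
    design: pd.DataFrame,
    housekeeping_gene: str,
    reference_group: str,
) -> pd.DataFrame:
    """Relative expression by the comparative cycle-threshold (ΔΔCT) method.

    ``ct`` is a gene × sample matrix of Ct values; ``design`` maps samples
    to groups (column ``group``). Per sample, ΔCt = Ct_gene − Ct_housekeeping;
    ΔΔCt subtracts the mean ΔCt of the reference group; relative expression
    is 2^(−ΔΔCt), so the reference-group geometric mean is 1.
    """
    if housekeeping_gene not in ct.index:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} missing from Ct table")
    if ct.loc[housekeeping_gene].isna().any():
        bad = ct.columns[ct.loc[housekeeping_gene].isna()][0]
        raise ValueError(f"housekeeping Ct missing in sample {bad!r}")
    groups = design.loc[ct.columns, "group"]
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} absent from design")
    if not np.isfinite(ct.to_numpy(dtype=float)).all():
        raise ValueError("Ct table contains non-finite values")

    dct = ct.sub(ct.loc[housekeeping_gene], axis=1)
    ref_cols = groups.index[groups == reference_group]
    ddct = dct.sub(dct[ref_cols].mean(axis=1), axis=0)
    rel = 2.0 ** (-ddct)
    return rel.drop(index=housekeeping_gene)


def atp_normalize(plate: pd.DataFrame, control_group: str = "mCherry") -> pd.DataFrame:
    """Per-group ATP levels from a luminescence/absorbance plate table.

    ``plate`` has columns ``group, luminescence, absorbance_595`` (one row
    per well). Each well's ratio is luminescence/absorbance; group values
    are mean ratios normalized so the control group equals 1.
    """
    required = {"group", "luminescence", "absorbance_595"}
    if not required <= set(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    if (plate["absorbance_595"] <= 0).any():
        i = plate.index[plate["absorbance_595"] <= 0][0]
        raise ValueError(f"well {i}: absorbance must be positive")
    if control_group not in set(plate["group"]):
        raise ValueError(f"control group {control_group!r} absent from plate")

    ratios = plate["luminescence"] / plate["absorbance_595"]
    grouped = ratios.groupby(plate["group"])
    means = grouped.mean()
    ctrl = means[control_group]
    out = pd.DataFrame(
        {
            "normalized_atp": means / ctrl,
            "sem": grouped.sem(ddof=1) / ctrl,
            "n_wells": grouped.size(),
        }
    )
    out.index.name = "group"
    return out
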