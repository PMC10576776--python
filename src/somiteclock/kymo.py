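"""Oscillation-amplitude extraction along the determination front of a kymograph.

A kymograph is a time (rows) x space (columns) intensity matrix built by
sampling a fluorescence time-lapse along a line of interest (LOI) running
through the presomitic mesoderm (PSM), posterior end at column 0.  The
segmentation clock produces posterior-to-anterior kinematic waves; the wave
amplitude at the determination front (mid-PSM) is what instructs somite
boundary formation.  This module extracts per-cycle trough-to-peak
amplitudes at the front, maps each wave to the somite boundary it
determines, normalizes amplitudes within an experiment, and compares
intact- versus defected-boundary amplitude groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import mannwhitneyu
from skimage.measure import profile_line

__all__ = [
    "Kymograph",
    "AnalysisConfig",
    "FrontProfile",
    "build_kymograph",
    "locate_front",
    "extract_front_profile",
    "smooth_resample",
    "detect_waves",
    "assign_boundaries",
    "attach_phenotypes",
    "normalize_amplitudes",
    "compare_amplitude_groups",
]

#: Clock-period windows (in frames) used at each imaging temperature.
DEFAULT_WINDOW_FRAMES = {"21.5C": 12, "26C": 7}

#: The first wave crossing the front at the 7-somite stage determines the
#: 11th somite boundary, so wave k determines boundary k + 10.
FIRST_BOUNDARY = 11


@dataclass
class Kymograph:
    """Time x space intensity matrix with acquisition metadata.

    Rows are frames, columns are positions along the LOI with the posterior
    (tail-bud) end at column 0.  ``seven_somite_frame`` is the frame index at
    which the embryo reaches the 7-somite stage; wave counting starts there.
    """

    data: np.ndarray
    frame_interval_min: float
    px_size_um: float
    seven_somite_frame: int
    temperature_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph must be a 2-D (frames x space) matrix")
        if not 0 <= self.seven_somite_frame < self.data.shape[0]:
            raise ValueError(
                f"seven_somite_frame {self.seven_somite_frame} outside the "
                f"{self.data.shape[0]}-frame range"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_px(self) -> int:
        return self.data.shape[1]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the amplitude-extraction pipeline.

    ``window_frames`` is the approximate clock period in (pre-resampling)
    frames; when None it is resolved from the kymograph's temperature label
    via :data:`DEFAULT_WINDOW_FRAMES` (12 frames at 21.5 degC, 7 at 26 degC,
    5-min frame interval).  ``front_fraction`` places the determination front
    as a fraction of PSM length from the posterior end (0.5 = mid-PSM).
    """

    front_fraction: float = 0.5
    window_frames: int | None = None
    sg_window: int = 9
    sg_order: int = 2
    resample_factor: int = 10
    n_waves: int = 15
    profile_width_px: int = 4
    loi_width_px: int = 15

    def __post_init__(self) -> None:
        if not 0.0 < self.front_fraction < 1.0:
            raise ValueError("front_fraction must lie in (0, 1)")
        if self.window_frames is not None and self.window_frames < 3:
            raise ValueError("window_frames must be >= 3")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and exceed sg_order")
        if self.resample_factor < 1:
            raise ValueError("resample_factor must be >= 1")

    def resolve_window(self, temperature_label: str) -> int:
        if self.window_frames is not None:
            return self.window_frames
        try:
            return DEFAULT_WINDOW_FRAMES[temperature_label]
        except KeyError:
            raise ValueError(
                f"no default window for temperature {temperature_label!r}; "
                "set window_frames explicitly"
            ) from None


@dataclass
class FrontProfile:
    """Raw and smoothed/resampled intensity along the front trajectory.

    ``resampled`` holds the Savitzky-Golay-smoothed series linearly
    interpolated onto a uniform grid of ``factor`` x len(raw) samples.
    ``sample_of_frame`` maps a (possibly fractional) frame index onto the
    resampled grid.
    """

    raw: np.ndarray
    smoothed: np.ndarray
    resampled: np.ndarray
    factor: int

    def sample_of_frame(self, frame: float) -> float:
        n = len(self.raw)
        if n < 2:
            return 0.0
        return frame * (len(self.resampled) - 1) / (n - 1)


def build_kymograph(
    stack: np.ndarray,
    loi: np.ndarray,
    width_px: int = 15,
    *,
    frame_interval_min: float = 5.0,
    px_size_um: float = 2.6,
    seven_somite_frame: int = 0,
    temperature_label: str = "",
) -> Kymograph:
    """Build a posterior-aligned kymograph from a time-lapse stack and an LOI.

    ``loi`` is an (n_points, 2) polyline of (row, col) vertices, posterior
    vertex first; each kymograph row is the mean intensity across the
    ``width_px``-wide band perpendicular to the polyline, sampled at unit
    arc-length steps.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    loi = np.atleast_2d(np.asarray(loi, dtype=float))
    if loi.shape[0] < 2 or loi.shape[1] != 2:
        raise ValueError("loi must be a polyline of >= 2 (row, col) points")
    h, w = stack.shape[1:]
    if (loi[:, 0] < 0).any() or (loi[:, 0] > h - 1).any() or (
        loi[:, 1] < 0
    ).any() or (loi[:, 1] > w - 1).any():
        bad = np.where(
            (loi[:, 0] < 0) | (loi[:, 0] > h - 1) | (loi[:, 1] < 0) | (loi[:, 1] > w - 1)
        )[0][0]
        raise ValueError(f"LOI vertex {bad} exits the image (all frames affected)")

    rows = []
    for t in range(stack.shape[0]):
        segs = []
        for i in range(loi.shape[0] - 1):
            prof = profile_line(
                stack[t], loi[i], loi[i + 1], linewidth=width_px,
                mode="reflect", reduce_func=np.mean,
            )
            if i > 0:  # segment endpoints are shared with the previous segment
                prof = prof[1:]
            segs.append(prof)
        rows.append(np.concatenate(segs))
    return Kymograph(
        np.asarray(rows),
        frame_interval_min=frame_interval_min,
        px_size_um=px_size_um,
        seven_somite_frame=seven_somite_frame,
        temperature_label=temperature_label,
    )


def locate_front(
    kymo: Kymograph, psm_extent_px: float | np.ndarray, front_fraction: float
) -> np.ndarray:
    """Determination-front trajectory: ``front_fraction`` of the PSM length
    from the posterior edge (column 0), one fractional-pixel position per
    frame.

    ``psm_extent_px`` is the PSM length per frame in pixels (scalar or
    per-frame array); it is an input, not segmented from the image.
    """
    if not 0.0 < front_fraction < 1.0:
        raise ValueError("front_fraction must lie in (0, 1)")
    extent = np.broadcast_to(
        np.asarray(psm_extent_px, dtype=float), (kymo.n_frames,)
    )
    if (extent <= 0).any():
        raise ValueError("psm_extent_px must be positive for every frame")
    traj = front_fraction * extent
    if (traj > kymo.n_px - 1).any():
        raise ValueError("front trajectory exceeds the kymograph's spatial extent")
    return traj


def extract_front_profile(
    kymo: Kymograph, trajectory: np.ndarray, width_px: int = 4
) -> np.ndarray:
    """Mean intensity over a ``width_px``-column band at the front, per frame.

    The band is centered on the round-half-up pixel of the (fractional)
    front position; for even widths the extra column falls on the anterior
    side, i.e. columns c - (w-1)//2 .. c + w//2 inclusive.  Bands that would
    leave the matrix are clamped to the edge with a warning.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape != (kymo.n_frames,):
        raise ValueError("trajectory must hold one position per frame")
    centers = np.floor(traj + 0.5).astype(int)
    lo = centers - (width_px - 1) // 2
    hi = lo + width_px  # exclusive
    if (lo < 0).any() or (hi > kymo.n_px).any():
        warnings.warn(
            "front band clipped at the kymograph edge; clamping", stacklevel=2
        )
        shift = np.clip(lo, None, 0)
        lo = lo - shift
        hi = hi - shift
        over = np.clip(hi - kymo.n_px, 0, None)
        lo, hi = lo - over, hi - over
        lo = np.clip(lo, 0, None)
    out = np.empty(kymo.n_frames)
    for t in range(kymo.n_frames):
        out[t] = kymo.data[t, lo[t]:hi[t]].mean()
    return out


def smooth_resample(
    series: np.ndarray, window: int = 9, order: int = 2, factor: int = 10
) -> FrontProfile:
    """Savitzky-Golay smoothing followed by ``factor`` x linear resampling.

    The smoothed series is linearly interpolated onto a uniform grid of
    ``factor * len(series)`` samples spanning the same frame interval.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and exceed the polynomial order")
    if len(series) <= window:
        raise ValueError("series must be longer than the smoothing window")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    smoothed = savgol_filter(series, window_length=window, polyorder=order)
    n = len(series)
    grid = np.linspace(0.0, n - 1, factor * n)
    resampled = np.interp(grid, np.arange(n), smoothed)
    return FrontProfile(raw=series, smoothed=smoothed, resampled=resampled, factor=factor)


def _window_extrema(y: np.ndarray, s0: int, s1: int) -> tuple[float | None, float | None]:
    """Largest interior local max and smallest interior local min in y[s0:s1].

    A local extremum must be strictly greater/less than both neighbours on
    the resampled grid; the window-edge samples themselves never qualify.
    """
    peak = trough = None
    lo = max(s0 + 1, 1)
    hi = min(s1 - 1, len(y) - 1)
    if hi <= lo:
        return None, None
    seg = y[lo:hi]
    left = y[lo - 1:hi - 1]
    right = y[lo + 1:hi + 1]
    maxima = seg[(seg > left) & (seg > right)]
    minima = seg[(seg < left) & (seg < right)]
    if maxima.size:
        peak = float(maxima.max())
    if minima.size:
        trough = float(minima.min())
    return peak, trough


def detect_waves(
    profile: FrontProfile,
    window_frames: int,
    n_waves: int = 15,
    start_frame: int = 0,
) -> pd.DataFrame:
    """Windowed trough-to-peak amplitudes of consecutive clock waves.

    The resampled profile is partitioned, starting at ``start_frame`` (the
    7-somite stage), into ``n_waves`` contiguous windows of ``window_frames``
    frames (the approximate clock period).  Within each window the peak is
    the largest interior local maximum and the trough the smallest interior
    local minimum; amplitude = peak - trough.  If either extremum is absent
    (e.g. the window is monotone) the amplitude is set to zero.

    Returns a DataFrame with columns wave_index (1-based), trough, peak,
    amplitude; trough/peak are NaN where the zero rule fired.
    """
    if window_frames < 3:
        raise ValueError("window_frames must be >= 3")
    y = profile.resampled
    edges_f = start_frame + window_frames * np.arange(n_waves + 1)
    edges_s = np.round([profile.sample_of_frame(f) for f in edges_f]).astype(int)
    n_full = int(np.searchsorted(edges_s, len(y), side="right")) - 1
    if n_full < n_waves:
        warnings.warn(
            f"profile holds only {max(n_full, 0)} of {n_waves} full windows; "
            "truncating", stacklevel=2,
        )
        n_waves = max(n_full, 0)
    records = []
    for k in range(n_waves):
        peak, trough = _window_extrema(y, edges_s[k], edges_s[k + 1])
        if peak is None or trough is None:
            amp, peak_v, trough_v = 0.0, np.nan, np.nan
        else:
            amp, peak_v, trough_v = max(peak - trough, 0.0), peak, trough
        records.append(
            {"wave_index": k + 1, "trough": trough_v, "peak": peak_v, "amplitude": amp}
        )
    return pd.DataFrame(records, columns=["wave_index", "trough", "peak", "amplitude"])


def assign_boundaries(waves: pd.DataFrame) -> pd.DataFrame:
    """Map wave k to the somite boundary it determines: boundary k + 10.

    The first wave crossing the front at the 7-somite stage determines the
    11th boundary.
    """
    out = waves.copy()
    out["boundary_index"] = out["wave_index"].astype(int) + FIRST_BOUNDARY - 1
    return out


def attach_phenotypes(
    waves: pd.DataFrame,
    boundary_table: pd.DataFrame,
    experiment_id: str,
    side: str | None = None,
) -> pd.DataFrame:
    """Pair each wave with the scored phenotype of its boundary.

    ``boundary_table`` rows are matched on embryo_id == experiment_id (and
    side, when given); boundaries without a score get phenotype NaN
    ('unknown').
    """
    mask = boundary_table["embryo_id"].astype(str) == str(experiment_id)
    if side is not None:
        mask &= boundary_table["side"] == side
    pheno = boundary_table.loc[mask, ["boundary_index", "phenotype"]]
    out = waves.merge(pheno, on="boundary_index", how="left")
    out["experiment_id"] = experiment_id
    return out


def normalize_amplitudes(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize each amplitude to the mean intact-boundary amplitude of its
    experiment.

    After normalization the mean of intact-boundary values is exactly 1
    within every experiment.  Experiments without any intact boundary cannot
    be normalized; their rows get NaN and a warning is emitted.
    """
    out = records.copy()
    out["normalized_amplitude"] = np.nan
    for exp, grp in out.groupby("experiment_id"):
        intact = grp.loc[grp["phenotype"] == 0, "amplitude"]
        if intact.empty:
            warnings.warn(
                f"experiment {exp!r} has no intact boundary; unnormalizable",
                stacklevel=2,
            )
            continue
        out.loc[grp.index, "normalized_amplitude"] = grp["amplitude"] / intact.mean()
    return out


def compare_amplitude_groups(records: pd.DataFrame) -> dict:
    """Compare normalized amplitudes preceding intact vs defected boundaries.

    Reports both group medians, the percent by which the defected median
    falls below the intact one, and the two-sided Mann-Whitney U p-value.
    """
    vals = records.dropna(subset=["normalized_amplitude"])
    intact = vals.loc[vals["phenotype"] == 0, "normalized_amplitude"].to_numpy()
    defected = vals.loc[vals["phenotype"] == 1, "normalized_amplitude"].to_numpy()
    for name, grp in (("intact", intact), ("defected", defected)):
        if grp.size == 0:
            raise ValueError(f"the {name} amplitude group is empty")
    med_i, med_d = float(np.median(intact)), float(np.median(defected))
    stat, p = mannwhitneyu(intact, defected, alternative="two-sided")
    return {
        "n_intact": int(intact.size),
        "n_defected": int(defected.size),
        "intact_median": med_i,
        "defected_median": med_d,
        "percent_less": 100.0 * (1.0 - med_d / med_i),
        "mannwhitney_U": float(stat),
        "p_value": float(p),
    }
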