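"""Drift correction, quality filtering, and blink merging.

The stage order mirrors a standard STORM pipeline: fiducial beads are found as
1x1 um histogram bins whose localization count is close to the number of camera
frames; each bead's per-frame track is smoothed with a Gaussian-weighted local
cubic fit; the per-bead trajectories (each re-zeroed at its start) are averaged
into one drift trajectory and subtracted. Quality filters then discard poorly
fit localizations, and repeated blinks of one fluorophore are merged across
frames by nearest-neighbor linking with a short dark-gap tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

REQUIRED_COLUMNS = ["frame", "x_nm", "y_nm", "precision_nm", "sigma_nm", "loglike", "photons"]


class FovRejectedError(RuntimeError):
    """The whole field of view must be discarded (e.g. no usable fiducials)."""


@dataclass
class FilterParams:
    """Quality-filter and merge settings.

    All threshold comparisons are strict: a localization is discarded only if
    its value exceeds the threshold, so values exactly at the boundary are
    retained. Defaults: precision > 30 nm, log-likelihood-ratio score > 250, and
    fitted PSF width > 175 nm are discarded; blinks are merged within a 30 nm
    radius tolerating one dark frame.
    """

    max_precision_nm: float = 30.0
    max_loglike: float = 250.0
    max_sigma_nm: float = 175.0
    merge_radius_nm: float = 30.0
    gap_frames: int = 1

    def __post_init__(self) -> None:
        if min(self.max_precision_nm, self.max_loglike, self.max_sigma_nm) <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.merge_radius_nm < 0:
            raise ValueError("merge_radius_nm must be >= 0")
        if self.gap_frames < 0:
            raise ValueError("gap_frames must be >= 0")


@dataclass
class FiducialTrack:
    """Per-frame positions of one candidate fiducial bead."""

    bin_origin_nm: tuple[float, float]
    member_indices: np.ndarray
    frames: np.ndarray  # unique, ascending
    x_nm: np.ndarray  # per frame in ``frames`` (within-frame duplicates averaged)
    y_nm: np.ndarray

    @property
    def n_frames_covered(self) -> int:
        return len(self.frames)


@dataclass
class DriftSpline:
    """Smoothed x(t), y(t) for one fiducial track."""

    spline_x: CubicSpline
    spline_y: CubicSpline
    frame_range: tuple[int, int]

    def __call__(self, frames: np.ndarray) -> np.ndarray:
        f = np.clip(np.asarray(frames, float), *self.frame_range)
        return np.column_stack([self.spline_x(f), self.spline_y(f)])


@dataclass
class DriftTrajectory:
    """Per-frame lateral offset (frame i+1 -> row i), averaged over fiducials."""

    dxy_nm: np.ndarray  # (frames_total, 2)
    n_fiducials_used: int

    def __post_init__(self) -> None:
        if self.n_fiducials_used < 1:
            raise ValueError("n_fiducials_used must be >= 1")
        if not np.all(np.isfinite(self.dxy_nm)):
            raise ValueError("drift trajectory must be finite")

    @property
    def frames_total(self) -> int:
        return len(self.dxy_nm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(1, self.frames_total + 1),
                "dx_nm": self.dxy_nm[:, 0],
                "dy_nm": self.dxy_nm[:, 1],
            }
        )


def validate_table(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"localization table is missing column {col!r}")


# ---------------------------------------------------------------------------
# fiducials and drift


def find_fiducials(
    table: pd.DataFrame,
    frames_total: int,
    bin_size_um: float = 1.0,
    min_fraction: float = 0.8,
    max_fraction: float = 1.5,
) -> list[FiducialTrack]:
    """Locate always-on beads as dense bins of a coarse 2D histogram.

    A bin of side ``bin_size_um`` qualifies when its localizations cover nearly
    every camera frame -- the signature of a bead that never blinks off: at
    least ``min_fraction * frames_total`` *distinct* frames must be present,
    and the total count must not exceed ``max_fraction * frames_total`` (a bin
    holding far more than one localization per frame contains blinking emitters
    on top of the bead and would corrupt the track). A blinking cluster may
    accumulate many localizations, but never covers almost all frames.
    """
    validate_table(table)
    b = bin_size_um * 1000.0
    ix = np.floor(table["x_nm"].to_numpy() / b).astype(np.int64)
    iy = np.floor(table["y_nm"].to_numpy() / b).astype(np.int64)
    pairs = np.column_stack([ix, iy])
    uniq, inverse, counts = np.unique(pairs, axis=0, return_inverse=True, return_counts=True)
    frames_arr = table["frame"].to_numpy()
    tracks: list[FiducialTrack] = []
    lo = min_fraction * frames_total
    hi = max_fraction * frames_total
    # distinct frames <= count, so bins below lo in raw count can be skipped
    for k in np.flatnonzero((counts >= lo) & (counts <= hi)):
        idx = np.flatnonzero(inverse == k)
        if len(np.unique(frames_arr[idx])) < lo:
            continue
        sub = table.iloc[idx]
        grouped = sub.groupby("frame", sort=True)[["x_nm", "y_nm"]].mean()
        tracks.append(
            FiducialTrack(
                bin_origin_nm=(float(uniq[k, 0] * b), float(uniq[k, 1] * b)),
                member_indices=idx,
                frames=grouped.index.to_numpy(),
                x_nm=grouped["x_nm"].to_numpy(),
                y_nm=grouped["y_nm"].to_numpy(),
            )
        )
    return tracks


def scaled_smoothing(frames_total: int) -> tuple[float, int]:
    """(weight_sigma_frames, window_frames) adapted to the acquisition length.

    The reference scale (sigma 200 frames, window 800) suits 20,000-frame
    acquisitions; shorter stacks compress the drift's features proportionally,
    so the smoother shrinks with them (sigma clamped to [20, 200] frames).
    """
    sigma = float(np.clip(200.0 * frames_total / 20_000.0, 20.0, 200.0))
    return sigma, int(4 * sigma)


def fit_drift_spline(
    track: FiducialTrack,
    weight_sigma_frames: float = 200.0,
    window_frames: int = 800,
    knot_spacing: int = 50,
) -> DriftSpline:
    """Smooth one fiducial track into continuous x(t), y(t).

    Gaussian-weighted local cubic regression (weight std ``weight_sigma_frames``,
    truncated at ``window_frames``) is evaluated on a regular grid of knots and
    interpolated with a cubic spline. Local-polynomial smoothing reproduces
    polynomial trajectories exactly, including at the track ends, while
    suppressing the per-frame localization jitter.
    """
    span = track.frames[-1] - track.frames[0] + 1
    if span < 2 * window_frames:
        raise ValueError(
            f"track covers only {span} frames; need >= {2 * window_frames} "
            f"for window_frames={window_frames}"
        )
    t = track.frames.astype(float)
    knots = np.arange(track.frames[0], track.frames[-1], knot_spacing, dtype=float)
    knots = np.append(knots, float(track.frames[-1]))
    half = window_frames / 2.0
    fx = np.empty(len(knots))
    fy = np.empty(len(knots))
    for j, t0 in enumerate(knots):
        sel = np.abs(t - t0) <= half
        tt = (t[sel] - t0) / weight_sigma_frames
        w = np.exp(-0.5 * tt**2)
        # weighted cubic polynomial fit; value at the knot is the intercept
        basis = np.vander(tt, 4, increasing=True)
        aw = basis * w[:, None]
        coef_x, *_ = np.linalg.lstsq(aw, track.x_nm[sel] * w, rcond=None)
        coef_y, *_ = np.linalg.lstsq(aw, track.y_nm[sel] * w, rcond=None)
        fx[j] = coef_x[0]
        fy[j] = coef_y[0]
    return DriftSpline(
        spline_x=CubicSpline(knots, fx),
        spline_y=CubicSpline(knots, fy),
        frame_range=(int(track.frames[0]), int(track.frames[-1])),
    )


def build_drift(
    tracks: list[FiducialTrack],
    frames_total: int,
    weight_sigma_frames: float = 200.0,
    window_frames: int = 800,
) -> DriftTrajectory:
    """Average per-fiducial smoothed trajectories into one drift trajectory.

    Each track is re-zeroed to its own smoothed position at its first frame so
    absolute bead positions cancel and only the common motion remains. FOVs with
    no usable fiducial are rejected outright.
    """
    if not tracks:
        raise FovRejectedError("FOV contains no good fiducials; discarding it")
    frames = np.arange(1, frames_total + 1, dtype=float)
    acc = np.zeros((frames_total, 2))
    for track in tracks:
        spline = fit_drift_spline(track, weight_sigma_frames, window_frames)
        vals = spline(frames)
        vals = vals - spline(np.array([float(track.frames[0])]))
        acc += vals
    return DriftTrajectory(dxy_nm=acc / len(tracks), n_fiducials_used=len(tracks))


def apply_drift(table: pd.DataFrame, trajectory: DriftTrajectory) -> pd.DataFrame:
    """Subtract the per-frame drift offset from every localization."""
    validate_table(table)
    frames = table["frame"].to_numpy()
    if len(frames) and (frames.min() < 1 or frames.max() > trajectory.frames_total):
        raise ValueError(
            f"table frames span [{frames.min()}, {frames.max()}] but the drift "
            f"trajectory covers [1, {trajectory.frames_total}]"
        )
    out = table.copy()
    shift = trajectory.dxy_nm[frames - 1]
    out["x_nm"] = out["x_nm"].to_numpy() - shift[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy() - shift[:, 1]
    return out


# ---------------------------------------------------------------------------
# filtering


def filter_localizations(
    table: pd.DataFrame, params: FilterParams | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Discard poorly fit localizations; return the survivors and a tally.

    Rejection rules (strict inequalities, boundary values retained):
    precision > ``max_precision_nm``; log-likelihood-ratio score >
    ``max_loglike``; fitted PSF width > ``max_sigma_nm`` (keeps only
    localizations from a thin in-focus axial slab in 2D imaging). A localization
    violating several rules is tallied under each.
    """
    params = params or FilterParams()
    validate_table(table)
    bad_prec = table["precision_nm"].to_numpy() > params.max_precision_nm
    bad_ll = table["loglike"].to_numpy() > params.max_loglike
    bad_sig = table["sigma_nm"].to_numpy() > params.max_sigma_nm
    keep = ~(bad_prec | bad_ll | bad_sig)
    tally = {
        "precision": int(bad_prec.sum()),
        "loglike": int(bad_ll.sum()),
        "sigma": int(bad_sig.sum()),
        "rejected_total": int((~keep).sum()),
        "retained": int(keep.sum()),
    }
    return table.loc[keep].reset_index(drop=True), tally


# ---------------------------------------------------------------------------
# blink merging


def merge_localizations(
    table: pd.DataFrame, radius_nm: float = 30.0, gap_frames: int = 1
) -> pd.DataFrame:
    """Collapse repeated blinks of one fluorophore into single localizations.

    Localizations are linked frame-to-frame by nearest-neighbor association
    within ``radius_nm``, tolerating up to ``gap_frames`` consecutive dark
    frames inside a track (Crocker-Grier-style linking). Each track collapses to
    one record: inverse-variance (precision-weighted) mean position, photons
    summed, combined precision = sqrt(1 / sum(1/prec_i^2)), frame = first frame
    of the track. Ties (two tracks equidistant from a new localization) go to
    the older track, and localizations are processed in table order, so the
    result is deterministic. ``radius_nm = 0`` returns the input unlinked.
    """
    if radius_nm < 0 or gap_frames < 0:
        raise ValueError("radius_nm and gap_frames must be >= 0")
    validate_table(table)
    df = table.sort_values("frame", kind="stable").reset_index(drop=True)
    n = len(df)
    track_of = np.full(n, -1, dtype=np.int64)
    if radius_nm == 0 or n == 0:
        track_of = np.arange(n)
    else:
        frames = df["frame"].to_numpy()
        xy = df[["x_nm", "y_nm"]].to_numpy()
        # open tracks: id -> (last position, last frame)
        open_ids: list[int] = []
        open_pos: list[np.ndarray] = []
        open_frame: list[int] = []
        n_tracks = 0
        uniq_frames, frame_start = np.unique(frames, return_index=True)
        frame_start = np.append(frame_start, n)
        for fi, f in enumerate(uniq_frames):
            # expire tracks whose last frame is too old to bridge the gap
            alive = [k for k in range(len(open_ids)) if f - open_frame[k] <= gap_frames + 1]
            open_ids = [open_ids[k] for k in alive]
            open_pos = [open_pos[k] for k in alive]
            open_frame = [open_frame[k] for k in alive]
            rows = range(frame_start[fi], frame_start[fi + 1])
            eligible = [k for k in range(len(open_ids)) if open_frame[k] < f]
            claimed: set[int] = set()
            tree = cKDTree(np.asarray([open_pos[k] for k in eligible])) if eligible else None
            for row in rows:
                best = -1
                if tree is not None:
                    hits = tree.query_ball_point(xy[row], radius_nm)
                    best_d = np.inf
                    for hit in hits:
                        k = eligible[hit]
                        if k in claimed:
                            continue
                        d = float(np.hypot(*(xy[row] - open_pos[k])))
                        tid = open_ids[k]
                        if d < best_d - 1e-12 or (
                            abs(d - best_d) <= 1e-12 and (best < 0 or tid < open_ids[best])
                        ):
                            best_d, best = d, k
                if best >= 0:
                    claimed.add(best)
                    track_of[row] = open_ids[best]
                    open_pos[best] = xy[row]
                    # last frame updated after the whole frame is processed via claimed
                else:
                    track_of[row] = n_tracks
                    open_ids.append(n_tracks)
                    open_pos.append(xy[row])
                    open_frame.append(int(f))
                    claimed.add(len(open_ids) - 1)
                    n_tracks += 1
            for k in claimed:
                open_frame[k] = int(f)

    df = df.assign(_track=track_of)
    eps = 1e-6
    prec = np.maximum(df["precision_nm"].to_numpy(), eps)
    df = df.assign(_w=1.0 / prec**2)
    df["_wx"] = df["_w"] * df["x_nm"]
    df["_wy"] = df["_w"] * df["y_nm"]
    g = df.groupby("_track", sort=True)
    agg = g.agg(
        frame=("frame", "first"),
        _wsum=("_w", "sum"),
        _wx=("_wx", "sum"),
        _wy=("_wy", "sum"),
        photons=("photons", "sum"),
        sigma_nm=("sigma_nm", "mean"),
        loglike=("loglike", "mean"),
        n_merged=("frame", "size"),
        _first_row=("frame", lambda s: s.index[0]),
    )
    agg["x_nm"] = agg["_wx"] / agg["_wsum"]
    agg["y_nm"] = agg["_wy"] / agg["_wsum"]
    raw_prec = df["precision_nm"].to_numpy()
    zero_prec = g.apply(lambda s: bool(np.all(raw_prec[s.index] <= eps)), include_groups=False)
    agg["precision_nm"] = np.where(zero_prec, 0.0, np.sqrt(1.0 / agg["_wsum"]))
    for extra in ("true_cluster_id", "true_x_nm", "true_y_nm"):
        if extra in df.columns:
            agg[extra] = g[extra].first()
    agg = agg.sort_values(["frame", "_first_row"], kind="stable")
    cols = ["frame", "x_nm", "y_nm", "precision_nm", "sigma_nm", "loglike", "photons", "n_merged"]
    cols += [c for c in ("true_cluster_id", "true_x_nm", "true_y_nm") if c in agg.columns]
    return agg[cols].reset_index(drop=True)
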