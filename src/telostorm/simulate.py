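"""Ground-truthed synthetic STORM datasets.

Emulates the acquisitions the downstream pipeline was designed for: fields of
view containing telomere-like clusters of blinking emitters, always-on fiducial
beads, a smooth lateral stage drift, per-localization precision near 10 nm, and
two wide-field reference channels (the telomere probe and a DDR marker that
overlaps a chosen subset of clusters).

Conventions
-----------
* All positions are 2D, in nanometres, origin at the lower-left corner of the
  field of view; frames are 1-based.
* All randomness flows from one explicit integer seed; per-stage substreams are
  derived deterministically with :class:`numpy.random.SeedSequence`.
* In localization tables, ``true_cluster_id >= 0`` marks a cluster emitter and
  ``true_cluster_id = -(k + 1)`` marks fiducial bead ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

LOCALIZATION_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "precision_nm",
    "sigma_nm",
    "loglike",
    "photons",
]

ClusterShape = Literal["gaussian", "anisotropic-gaussian", "disk"]


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass
class EmitterField:
    """Geometry of one simulated field of view.

    ``cluster_rg_nm`` is the *target* radius of gyration of each cluster's
    emitter distribution: for a uniform disk of radius R, Rg = R/sqrt(2); for an
    isotropic 2D Gaussian with per-axis sigma, Rg = sigma*sqrt(2).
    """

    cluster_centers: np.ndarray  # (n, 2) nm
    cluster_rg_nm: np.ndarray  # (n,) nm
    field_size_nm: tuple[float, float] = (40_000.0, 40_000.0)
    shape: ClusterShape = "anisotropic-gaussian"
    axis_ratio_range: tuple[float, float] = (1.0, 2.5)
    emitters_per_cluster: int = 60
    fiducial_positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=float)
    )
    ddr_positive_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.cluster_centers = np.atleast_2d(np.asarray(self.cluster_centers, float))
        self.cluster_rg_nm = np.atleast_1d(np.asarray(self.cluster_rg_nm, float))
        self.fiducial_positions = np.asarray(self.fiducial_positions, float).reshape(-1, 2)
        self.ddr_positive_indices = frozenset(self.ddr_positive_indices)
        self.validate()

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_centers)

    def validate(self) -> None:
        w, h = self.field_size_nm
        if w <= 0 or h <= 0:
            raise ValueError("field_size_nm must be positive")
        if len(self.cluster_rg_nm) != self.n_clusters:
            raise ValueError("cluster_rg_nm must have one entry per cluster")
        if np.any(self.cluster_rg_nm <= 0):
            raise ValueError("target Rg must be > 0 for every cluster")
        if self.emitters_per_cluster < 1:
            raise ValueError("emitters_per_cluster must be >= 1")
        for pts, what in [(self.cluster_centers, "cluster"), (self.fiducial_positions, "fiducial")]:
            if len(pts) and (
                np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w)
                or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h)
            ):
                raise ValueError(f"{what} positions must lie inside field_size_nm")
        bad = self.ddr_positive_indices - set(range(self.n_clusters))
        if bad:
            raise ValueError(f"ddr_positive_indices not valid cluster indices: {sorted(bad)}")


@dataclass
class BlinkModel:
    """Fluorophore on/off kinetics.

    Off times are drawn from a two-component geometric mixture: a short
    pronounced component near the origin plus a long tail, the qualitative shape
    seen for Alexa 647 under STORM buffers. ``survival_prob_per_frame`` is the
    per-on-frame probability of *not* photobleaching, so the expected total
    on-time of an emitter is 1/(1-p) frames (infinite at p=1).
    """

    mean_on_frames: float = 2.0
    off_time_mixture: tuple[float, float, float] = (2.0, 200.0, 0.8)
    survival_prob_per_frame: float = 0.9
    frames_total: int = 20_000

    def __post_init__(self) -> None:
        short, long_, w = self.off_time_mixture
        if self.mean_on_frames < 1:
            raise ValueError("mean_on_frames must be >= 1")
        if short < 1 or long_ < 1:
            raise ValueError("off-time component means must be >= 1 frame")
        if not 0.0 <= w <= 1.0:
            raise ValueError("short-component weight must be in [0, 1]")
        if not 0.0 < self.survival_prob_per_frame <= 1.0:
            raise ValueError("survival_prob_per_frame must be in (0, 1]")
        if self.frames_total < 1:
            raise ValueError("frames_total must be >= 1")

    def off_time_pmf(self, k: np.ndarray) -> np.ndarray:
        """P(off duration = k frames), k >= 1, under the geometric mixture."""
        k = np.asarray(k)
        short, long_, w = self.off_time_mixture
        ps, pl = 1.0 / short, 1.0 / long_
        return w * ps * (1 - ps) ** (k - 1) + (1 - w) * pl * (1 - pl) ** (k - 1)

    def sample_off_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        short, long_, w = self.off_time_mixture
        pick_short = rng.random(n) < w
        out = np.empty(n, dtype=np.int64)
        out[pick_short] = rng.geometric(1.0 / short, pick_short.sum())
        out[~pick_short] = rng.geometric(1.0 / long_, (~pick_short).sum())
        return out


@dataclass
class DriftModel:
    """Lateral stage-drift trajectory over the acquisition.

    ``linear`` ramps the x offset from 0 to ``magnitude_nm``; ``smooth-random``
    produces an independent smooth random walk per axis, rescaled so the largest
    absolute excursion equals ``magnitude_nm``. Frame 1 always has zero offset.
    """

    kind: Literal["none", "linear", "smooth-random"] = "smooth-random"
    magnitude_nm: float = 150.0
    seed: int = 0

    def trajectory(self, frames_total: int) -> np.ndarray:
        """Per-frame (dx_nm, dy_nm), shape (frames_total, 2)."""
        if frames_total < 1:
            raise ValueError("frames_total must be >= 1")
        t = np.arange(frames_total, dtype=float)
        out = np.zeros((frames_total, 2))
        if self.kind == "none" or frames_total == 1:
            return out
        if self.kind == "linear":
            out[:, 0] = self.magnitude_nm * t / (frames_total - 1)
            return out
        if self.kind != "smooth-random":
            raise ValueError(f"unknown drift kind: {self.kind!r}")
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xD21F]))
        from scipy.ndimage import gaussian_filter1d

        sigma = max(frames_total / 20.0, 2.0)
        for ax in range(2):
            walk = np.cumsum(rng.standard_normal(frames_total))
            walk = gaussian_filter1d(walk, sigma, mode="nearest")
            walk -= walk[0]
            peak = np.max(np.abs(walk))
            if peak > 0:
                walk *= self.magnitude_nm / peak
            out[:, ax] = walk
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    emitter_positions: np.ndarray  # (n_emitters, 2) nm
    emitter_cluster_id: np.ndarray  # (n_emitters,)
    cluster_centers: np.ndarray
    cluster_rg_target_nm: np.ndarray
    cluster_rg_realized_nm: np.ndarray
    fiducial_positions: np.ndarray
    ddr_positive_indices: frozenset[int]
    drift_trajectory: np.ndarray | None = None  # (frames, 2)
    channel_offset_nm: tuple[float, float] = (0.0, 0.0)


@dataclass
class WideFieldImage:
    """Diffraction-limited reference image covering the field of view."""

    pixels: np.ndarray  # (rows, cols), row ~ y, col ~ x
    pixel_size_nm: float
    channel: Literal["probe", "ddr"] = "probe"
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("intensities must be nonnegative")


# ---------------------------------------------------------------------------
# emitter placement


def _rg_stats(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((points - c) ** 2, axis=1))))


def place_clusters(config: EmitterField, seed: int) -> tuple[np.ndarray, GroundTruth]:
    """Draw emitter positions for every cluster of ``config``.

    Each cluster's emitters are drawn from the configured shape model with the
    target Rg, then recentred on the cluster center (so a single-emitter cluster
    sits exactly at its center and the realized centroid is exact).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1]))
    w, h = config.field_size_nm
    n = config.emitters_per_cluster
    all_pts: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    realized = np.zeros(config.n_clusters)
    for i in range(config.n_clusters):
        rg = config.cluster_rg_nm[i]
        if config.shape == "disk":
            radius = rg * math.sqrt(2.0)
            r = radius * np.sqrt(rng.random(n))
            theta = rng.random(n) * 2 * np.pi
            pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        else:
            if config.shape == "gaussian":
                sa = sb = rg / math.sqrt(2.0)
                angle = 0.0
            elif config.shape == "anisotropic-gaussian":
                lo, hi = config.axis_ratio_range
                ratio = rng.uniform(lo, hi)
                sb = rg / math.sqrt(1.0 + ratio**2)
                sa = ratio * sb
                angle = rng.uniform(0, np.pi)
            else:
                raise ValueError(f"unknown cluster shape: {config.shape!r}")
            raw = rng.standard_normal((n, 2)) * [sa, sb]
            c, s = math.cos(angle), math.sin(angle)
            pts = raw @ np.array([[c, s], [-s, c]])
        if n > 1:
            pts = pts - pts.mean(axis=0)
        else:
            pts = np.zeros((1, 2))
        pts = pts + config.cluster_centers[i]
        if (
            np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > w)
            or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > h)
        ):
            raise ValueError(
                f"cluster {i}: emitters spill outside the field "
                f"(target Rg {rg:.1f} nm too large for its position)"
            )
        realized[i] = _rg_stats(pts) if n > 1 else 0.0
        all_pts.append(pts)
        ids.append(np.full(n, i, dtype=np.int64))
    emitters = np.vstack(all_pts) if all_pts else np.empty((0, 2))
    truth = GroundTruth(
        emitter_positions=emitters,
        emitter_cluster_id=np.concatenate(ids) if ids else np.empty(0, np.int64),
        cluster_centers=config.cluster_centers.copy(),
        cluster_rg_target_nm=config.cluster_rg_nm.copy(),
        cluster_rg_realized_nm=realized,
        fiducial_positions=config.fiducial_positions.copy(),
        ddr_positive_indices=config.ddr_positive_indices,
    )
    return emitters, truth


# ---------------------------------------------------------------------------
# localization simulation


def _blink_on_frames(blink: BlinkModel, rng: np.random.Generator) -> np.ndarray:
    """1-based frame indices during which one emitter is on."""
    frames = []
    # random initial dark delay desynchronizes emitters across the acquisition
    t = int(rng.integers(0, max(1, int(blink.frames_total * 0.9))))
    if blink.survival_prob_per_frame < 1.0:
        budget = int(rng.geometric(1.0 - blink.survival_prob_per_frame))
    else:
        budget = blink.frames_total
    while t < blink.frames_total and budget > 0:
        dur = int(rng.geometric(1.0 / blink.mean_on_frames))
        dur = min(dur, budget, blink.frames_total - t)
        frames.extend(range(t + 1, t + dur + 1))
        budget -= dur
        t += dur
        t += int(blink.sample_off_times(1, rng)[0])
    return np.asarray(frames, dtype=np.int64)


def simulate_localizations(
    truth: GroundTruth,
    blink: BlinkModel,
    drift: DriftModel,
    precision_mean_nm: float = 10.0,
    precision_shape: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Turn emitters + fiducials into a per-frame localization table.

    Each on-frame of each emitter yields one localization: the true position
    plus the drift offset of that frame plus isotropic Gaussian error whose
    per-axis standard deviation is that localization's ``precision_nm``, drawn
    from a gamma distribution (mean ``precision_mean_nm``, shape
    ``precision_shape``; right-skewed, strictly positive). Fiducials emit
    exactly one localization every frame. Quality columns (PSF width,
    log-likelihood-ratio score, photons) are drawn from typical in-focus
    distributions so the downstream filters have realistic inputs.
    """
    if precision_mean_nm < 0:
        raise ValueError("precision_mean_nm must be >= 0")
    frames_total = blink.frames_total
    traj = drift.trajectory(frames_total)
    ss = np.random.SeedSequence([int(seed), 0x10C])
    rng_blink, rng_noise, rng_quality = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    frame_chunks: list[np.ndarray] = []
    pos_chunks: list[np.ndarray] = []
    src_chunks: list[np.ndarray] = []
    for i in range(len(truth.emitter_positions)):
        on = _blink_on_frames(blink, rng_blink)
        if len(on) == 0:
            continue
        frame_chunks.append(on)
        pos_chunks.append(np.repeat(truth.emitter_positions[i : i + 1], len(on), axis=0))
        src_chunks.append(np.full(len(on), truth.emitter_cluster_id[i], np.int64))
    for k in range(len(truth.fiducial_positions)):
        on = np.arange(1, frames_total + 1, dtype=np.int64)
        frame_chunks.append(on)
        pos_chunks.append(np.repeat(truth.fiducial_positions[k : k + 1], frames_total, axis=0))
        src_chunks.append(np.full(frames_total, -(k + 1), np.int64))

    if frame_chunks:
        frame = np.concatenate(frame_chunks)
        true_pos = np.vstack(pos_chunks)
        source = np.concatenate(src_chunks)
    else:
        frame = np.empty(0, np.int64)
        true_pos = np.empty((0, 2))
        source = np.empty(0, np.int64)
    m = len(frame)

    if precision_mean_nm == 0:
        precision = np.zeros(m)
        noise = np.zeros((m, 2))
    else:
        scale = precision_mean_nm / precision_shape
        precision = rng_noise.gamma(precision_shape, scale, m)
        noise = rng_noise.standard_normal((m, 2)) * precision[:, None]
    xy = true_pos + traj[frame - 1] + noise

    sigma = np.clip(rng_quality.normal(150.0, 10.0, m), 50.0, None)
    loglike = rng_quality.chisquare(45, m)
    photons = rng_quality.lognormal(np.log(3000.0), 0.5, m)

    table = pd.DataFrame(
        {
            "frame": frame,
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "precision_nm": precision,
            "sigma_nm": sigma,
            "loglike": loglike,
            "photons": photons,
            "true_x_nm": true_pos[:, 0],
            "true_y_nm": true_pos[:, 1],
            "true_cluster_id": source,
        }
    )
    table = table.sort_values("frame", kind="stable").reset_index(drop=True)
    out_truth = GroundTruth(**{**truth.__dict__, "drift_trajectory": traj})
    return table, out_truth


# ---------------------------------------------------------------------------
# wide-field rendering


def render_widefield(
    centers: np.ndarray,
    weights: Sequence[float] | np.ndarray,
    field_size_nm: tuple[float, float],
    pixel_size_nm: float = 108.0,
    psf_sigma_nm: float = 130.0,
    channel: Literal["probe", "ddr"] = "probe",
    background: float = 100.0,
    peak_scale: float = 20.0,
    shift_nm: tuple[float, float] = (0.0, 0.0),
    poisson: bool = True,
    seed: int = 0,
) -> WideFieldImage:
    """Render a diffraction-limited image of Gaussian spots.

    The expected image is ``background + peak_scale * weight_i`` Gaussians of
    width ``psf_sigma_nm`` at each center (intensity proportional to emitter
    count), optionally Poisson-sampled. ``shift_nm`` displaces the rendered
    content relative to the localization coordinate frame, emulating the small
    channel offset the registration stage must recover.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    w, h = field_size_nm
    ncol = int(math.ceil(w / pixel_size_nm))
    nrow = int(math.ceil(h / pixel_size_nm))
    img = np.full((nrow, ncol), float(background))
    centers = np.asarray(centers, float).reshape(-1, 2)
    weights = np.asarray(weights, float).reshape(-1)
    half = int(math.ceil(4 * psf_sigma_nm / pixel_size_nm))
    for (cx, cy), wt in zip(centers, weights):
        cx += shift_nm[0]
        cy += shift_nm[1]
        pc = int(cx / pixel_size_nm)
        pr = int(cy / pixel_size_nm)
        c0, c1 = max(0, pc - half), min(ncol, pc + half + 1)
        r0, r1 = max(0, pr - half), min(nrow, pr + half + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * pixel_size_nm
        ys = (np.arange(r0, r1) + 0.5) * pixel_size_nm
        gx = np.exp(-0.5 * ((xs - cx) / psf_sigma_nm) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / psf_sigma_nm) ** 2)
        img[r0:r1, c0:c1] += peak_scale * wt * np.outer(gy, gx)
    if poisson:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1F]))
        img = rng.poisson(img).astype(float)
    return WideFieldImage(pixels=img, pixel_size_nm=pixel_size_nm, channel=channel)


def render_frames(
    table: pd.DataFrame,
    field_size_nm: tuple[float, float],
    frames_total: int,
    pixel_size_nm: float = 108.0,
    psf_sigma_nm: float = 150.0,
    photons_per_loc: float = 5000.0,
    background: float = 10.0,
    poisson: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Paint a raw STORM frame stack from a localization table.

    Every row of ``table`` becomes one Gaussian spot of ``photons_per_loc``
    photons in its frame (positions taken from ``true_x_nm/true_y_nm`` when
    present, else ``x_nm/y_nm``). Used to exercise the raw-frame localization
    stage on data with known ground truth.
    """
    w, h = field_size_nm
    ncol = int(math.ceil(w / pixel_size_nm))
    nrow = int(math.ceil(h / pixel_size_nm))
    stack = np.full((frames_total, nrow, ncol), float(background))
    xcol = "true_x_nm" if "true_x_nm" in table else "x_nm"
    ycol = "true_y_nm" if "true_y_nm" in table else "y_nm"
    sig_px = psf_sigma_nm / pixel_size_nm
    half = int(math.ceil(4 * sig_px))
    norm = photons_per_loc / (2 * np.pi * sig_px**2)
    for frame, x, y in zip(table["frame"], table[xcol], table[ycol]):
        f = int(frame) - 1
        if not 0 <= f < frames_total:
            continue
        # pixel i covers [i*p, (i+1)*p); its center sits at (i+0.5)*p
        px = x / pixel_size_nm - 0.5
        py = y / pixel_size_nm - 0.5
        c0, c1 = max(0, int(px) - half), min(ncol, int(px) + half + 1)
        r0, r1 = max(0, int(py) - half), min(nrow, int(py) + half + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        gx = np.exp(-0.5 * ((np.arange(c0, c1) - px) / sig_px) ** 2)
        gy = np.exp(-0.5 * ((np.arange(r0, r1) - py) / sig_px) ** 2)
        stack[f, r0:r1, c0:c1] += norm * np.outer(gy, gx)
    if poisson:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF7A]))
        stack = rng.poisson(stack).astype(float)
    return stack


# ---------------------------------------------------------------------------
# whole-FOV convenience


@dataclass
class FovSpec:
    """One simulated field of view: geometry plus acquisition settings.

    Defaults describe a scaled-down acquisition of a HeLa-S-like condition:
    clusters with target Rg drawn around 68 nm, ~10 nm mean localization
    precision, smooth 150-nm drift, and four fiducial beads.
    """

    n_clusters: int = 60
    field_size_nm: tuple[float, float] = (40_000.0, 40_000.0)
    rg_mean_nm: float = 68.0
    rg_sd_nm: float = 15.0
    emitters_per_cluster: int = 60
    shape: ClusterShape = "anisotropic-gaussian"
    n_fiducials: int = 4
    ddr_fraction: float = 0.0
    precision_mean_nm: float = 10.0
    blink: BlinkModel = field(
        default_factory=lambda: BlinkModel(
            mean_on_frames=2.0,
            off_time_mixture=(2.0, 200.0, 0.8),
            survival_prob_per_frame=0.875,
            frames_total=2_000,
        )
    )
    drift_kind: Literal["none", "linear", "smooth-random"] = "smooth-random"
    drift_magnitude_nm: float = 150.0
    channel_offset_nm: tuple[float, float] = (50.0, 50.0)
    widefield_pixel_nm: float = 108.0


def _grid_positions(n: int, field: tuple[float, float], margin: float, jitter: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid layout keeping spots well separated and off the edges."""
    w, h = field
    side = int(math.ceil(math.sqrt(n)))
    xs = np.linspace(margin, w - margin, side)
    ys = np.linspace(margin, h - margin, side)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    return np.clip(pts, margin / 2, [w - margin / 2, h - margin / 2])


def simulate_fov(spec: FovSpec, seed: int) -> dict:
    """Generate one complete FOV: localization table, truth, wide-field images.

    Fiducials are placed near the centers of distinct 1x1 um grid cells so a
    drifting bead stays inside its histogram bin, mirroring how beads are picked
    out of the rendered 2D histogram downstream.
    """
    ss = np.random.SeedSequence([int(seed), 0xF0F])
    rng_layout, rng_wf1, rng_wf2, s_place, s_loc = ss.spawn(5)
    rng = np.random.default_rng(rng_layout)

    centers = _grid_positions(
        spec.n_clusters, spec.field_size_nm, margin=2_500.0, jitter=800.0, rng=rng
    )
    rg = np.clip(
        rng.normal(spec.rg_mean_nm, spec.rg_sd_nm, spec.n_clusters),
        max(20.0, spec.rg_mean_nm - 3 * spec.rg_sd_nm),
        spec.rg_mean_nm + 3 * spec.rg_sd_nm,
    )
    # fiducials: random distinct 1-um bins, near the bin center, and clear of
    # telomere clusters so each bead track is an uncontaminated drift readout
    w, h = spec.field_size_nm
    nx, ny = int(w // 1000), int(h // 1000)
    perm = rng.permutation(nx * ny) if spec.n_fiducials > 0 else []
    fid_rows = []
    for cell in perm:
        cx = (cell % nx) * 1000.0 + 500.0
        cy = (cell // nx) * 1000.0 + 500.0
        if len(centers) and np.min(np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)) < 1500.0:
            continue
        fid_rows.append([cx + rng.uniform(-150, 150), cy + rng.uniform(-150, 150)])
        if len(fid_rows) == spec.n_fiducials:
            break
    fid = np.asarray(fid_rows, dtype=float).reshape(-1, 2)
    n_ddr = int(round(spec.ddr_fraction * spec.n_clusters))
    ddr_idx = frozenset(rng.choice(spec.n_clusters, size=n_ddr, replace=False).tolist())

    field_cfg = EmitterField(
        cluster_centers=centers,
        cluster_rg_nm=rg,
        field_size_nm=spec.field_size_nm,
        shape=spec.shape,
        emitters_per_cluster=spec.emitters_per_cluster,
        fiducial_positions=fid,
        ddr_positive_indices=ddr_idx,
    )
    _, truth = place_clusters(field_cfg, seed=int(s_place.generate_state(1)[0] % 2**31))
    drift = DriftModel(
        kind=spec.drift_kind,
        magnitude_nm=spec.drift_magnitude_nm,
        seed=int(seed) % 2**31,
    )
    table, truth = simulate_localizations(
        truth,
        spec.blink,
        drift,
        precision_mean_nm=spec.precision_mean_nm,
        seed=int(s_loc.generate_state(1)[0] % 2**31),
    )
    truth.channel_offset_nm = spec.channel_offset_nm

    # gold beads are bright in the wide-field reference too; rendering them
    # anchors the cross-correlation just as in a real acquisition
    probe_centers = np.vstack([centers, fid]) if len(fid) else centers
    weights = np.concatenate(
        [
            np.full(spec.n_clusters, float(spec.emitters_per_cluster)),
            np.full(len(fid), 4.0 * spec.emitters_per_cluster),
        ]
    )
    probe = render_widefield(
        probe_centers,
        weights,
        spec.field_size_nm,
        pixel_size_nm=spec.widefield_pixel_nm,
        psf_sigma_nm=130.0,
        channel="probe",
        shift_nm=spec.channel_offset_nm,
        seed=int(rng_wf1.generate_state(1)[0] % 2**31),
    )
    ddr_centers = centers[sorted(ddr_idx)] if n_ddr else np.empty((0, 2))
    ddr = render_widefield(
        ddr_centers,
        np.full(len(ddr_centers), float(spec.emitters_per_cluster)),
        spec.field_size_nm,
        pixel_size_nm=spec.widefield_pixel_nm,
        psf_sigma_nm=250.0,
        channel="ddr",
        peak_scale=40.0,
        shift_nm=spec.channel_offset_nm,
        seed=int(rng_wf2.generate_state(1)[0] % 2**31),
    )
    return {
        "table": table,
        "truth": truth,
        "probe_widefield": probe,
        "ddr_widefield": ddr,
        "frames_total": spec.blink.frames_total,
    }
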