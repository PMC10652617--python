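"""Scripted cone-assay scenes with exact ground truth.

Every pipeline stage is testable without real footage: a scene scripts five
dark discs (mosquito-sized, soft-edged) over a brighter, slowly drifting
background with optional Gaussian sensor noise, renders it to a standard
540 x 960 @ 30 fps video, and emits per-0.1-s-sample ground truth (position,
moving flag, cone region for every mosquito) from which the behavioural
metrics can be recomputed independently of the detector.

A mosquito counts as *moving* at a sample when its scripted centroid moved
more than 1 px since the previous sample — the same physics a
background-subtraction detector responds to.  Scenes are fully
seed-deterministic.

The presets mimic the behavioural phenotypes seen in real assays: untreated
nets provoke crawling along the net surface (high proportion of activity in
the lower cone), treated nets disperse activity throughout the cone, and
strongly resting strains sit still for much of the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import RegionGeometry
from .metrics import (
    ACCLIMATISATION,
    CONE_OCCUPANCY,
    EPOCH_LENGTH,
    N_EPOCHS,
    SAMPLE_INTERVAL,
)
from .video import STANDARD_FPS, VideoAsset, open_writer, sample_indices

#: scripted displacement (px) between consecutive samples above which a
#: mosquito counts as moving
MOVING_THRESHOLD_PX = 1.0
#: soft-edge width of rendered discs (px)
DISC_EDGE_PX = 2.0


class SceneSpecError(ValueError):
    """A scene specification is internally inconsistent or out of frame."""


@dataclass(frozen=True)
class TrajectorySpec:
    """Piecewise-linear scripted path of one mosquito.

    ``waypoints`` is a time-sorted sequence of (t, x, y); position is
    interpolated linearly between waypoints and clamped outside their span.
    ``resting_intervals`` documents (t_start, t_end) windows in which the
    path holds still; they must be consistent with the waypoints.
    """

    mosquito_id: str
    waypoints: tuple[tuple[float, float, float], ...]
    resting_intervals: tuple[tuple[float, float], ...] = ()
    blob_diameter: float = 9.0
    blob_intensity: float = 30.0

    def __post_init__(self) -> None:
        wps = tuple((float(t), float(x), float(y)) for t, x, y in self.waypoints)
        if len(wps) < 1:
            raise SceneSpecError("trajectory needs at least one waypoint")
        ts = [w[0] for w in wps]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise SceneSpecError("waypoints must be time-sorted")
        rests = tuple((float(a), float(b)) for a, b in self.resting_intervals)
        for a, b in rests:
            if b <= a:
                raise SceneSpecError("resting interval must have t_end > t_start")
        for (_, e1), (s2, _) in zip(rests, rests[1:]):
            if s2 < e1:
                raise SceneSpecError("resting intervals must not overlap")
        object.__setattr__(self, "waypoints", wps)
        object.__setattr__(self, "resting_intervals", rests)

    def position(self, t: float | np.ndarray) -> np.ndarray:
        """Interpolated (x, y) position(s) at time(s) ``t``."""
        ts = np.array([w[0] for w in self.waypoints])
        xs = np.array([w[1] for w in self.waypoints])
        ys = np.array([w[2] for w in self.waypoints])
        return np.stack([np.interp(t, ts, xs), np.interp(t, ts, ys)], axis=-1)

    def is_resting(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.resting_intervals)


@dataclass(frozen=True)
class SyntheticScene:
    """Full specification of a renderable scene."""

    trajectories: tuple[TrajectorySpec, ...]
    duration: float = 180.0
    fps: float = STANDARD_FPS
    background_intensity: float = 200.0
    background_drift: float = 0.1  # intensity units per second
    noise_sd: float = 5.0
    seed: int = 0
    geometry: RegionGeometry = field(default_factory=RegionGeometry.default)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SceneSpecError("noise_sd must be non-negative")
        if self.duration <= 0 or self.fps <= 0:
            raise SceneSpecError("duration and fps must be positive")

    @property
    def n_mosquitoes(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "fps": self.fps,
            "background_intensity": self.background_intensity,
            "background_drift": self.background_drift,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "geometry": self.geometry.to_dict(),
            "trajectories": [
                {
                    "mosquito_id": tr.mosquito_id,
                    "waypoints": [list(w) for w in tr.waypoints],
                    "resting_intervals": [list(r) for r in tr.resting_intervals],
                    "blob_diameter": tr.blob_diameter,
                    "blob_intensity": tr.blob_intensity,
                }
                for tr in self.trajectories
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScene":
        trajectories = tuple(
            TrajectorySpec(
                mosquito_id=tr["mosquito_id"],
                waypoints=tuple(tuple(w) for w in tr["waypoints"]),
                resting_intervals=tuple(tuple(r) for r in tr.get("resting_intervals", [])),
                blob_diameter=tr.get("blob_diameter", 9.0),
                blob_intensity=tr.get("blob_intensity", 30.0),
            )
            for tr in d["trajectories"]
        )
        return cls(
            trajectories=trajectories,
            duration=d.get("duration", 180.0),
            fps=d.get("fps", STANDARD_FPS),
            background_intensity=d.get("background_intensity", 200.0),
            background_drift=d.get("background_drift", 0.1),
            noise_sd=d.get("noise_sd", 5.0),
            seed=d.get("seed", 0),
            geometry=RegionGeometry.from_dict(d["geometry"])
            if "geometry" in d
            else RegionGeometry.default(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticScene":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample truth records for a rendered scene.

    ``table`` has one row per (sample, mosquito): columns ``sample`` (index),
    ``t`` (s), ``mosquito_id``, ``x``, ``y`` (px), ``moving`` (bool),
    ``region`` (upper/lower).  All derived quantities (per-epoch regional
    counts, resting-frame count, proportions) are recomputed from these rows.
    """

    table: pd.DataFrame
    occupancy: int = CONE_OCCUPANCY

    def n_moving(self) -> pd.Series:
        """Number of moving mosquitoes per sample."""
        return self.table.groupby("sample")["moving"].sum().astype(int)

    def resting_frame_count(self) -> int:
        """Samples (first excluded) in which no mosquito moved."""
        n = self.n_moving()
        return int((n.iloc[1:] == 0).sum())

    def epoch_regional_counts(
        self,
        *,
        interval: float = SAMPLE_INTERVAL,
        start: float = ACCLIMATISATION,
        epoch_length: float = EPOCH_LENGTH,
        n_epochs: int = N_EPOCHS,
    ) -> pd.DataFrame:
        """True per-epoch activity counts (moving mosquitoes per region)."""
        per_epoch = int(round(epoch_length / interval))
        start_slot = int(round(start / interval))
        df = self.table[self.table["moving"]].copy()
        df["epoch"] = (df["sample"] - start_slot) // per_epoch + 1
        df = df[(df["epoch"] >= 1) & (df["epoch"] <= n_epochs)]
        counts = (
            df.groupby(["epoch", "region"]).size().unstack(fill_value=0)
            .reindex(range(1, n_epochs + 1), fill_value=0)
        )
        for col in ("upper", "lower"):
            if col not in counts:
                counts[col] = 0
        counts["total"] = counts["upper"] + counts["lower"]
        return counts[["upper", "lower", "total"]]

    def total_activity(self) -> int:
        return int(self.epoch_regional_counts()["total"].sum())

    def prop_lower(self) -> float:
        counts = self.epoch_regional_counts()
        total = counts["total"].sum()
        return float(counts["lower"].sum() / total) if total else float("nan")

    def resting_seconds(self) -> float:
        return self.resting_frame_count() * SAMPLE_INTERVAL

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# rendering


def _draw_disc(frame: np.ndarray, x: float, y: float, diameter: float,
               intensity: float) -> None:
    """Alpha-blend a soft-edged dark disc into ``frame`` (float32, in place)."""
    r = diameter / 2.0
    half = DISC_EDGE_PX / 2.0
    pad = int(np.ceil(r + half)) + 1
    h, w = frame.shape
    x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
    y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - x, yy - y)
    alpha = np.clip((r + half - dist) / DISC_EDGE_PX, 0.0, 1.0)
    patch = frame[y0:y1, x0:x1]
    patch -= alpha * (patch - intensity)


def _validate_in_frame(scene: SyntheticScene) -> None:
    w, h = scene.geometry.frame_dims
    for tr in scene.trajectories:
        margin = tr.blob_diameter / 2.0 + DISC_EDGE_PX / 2.0
        pts = np.array([(x, y) for _, x, y in tr.waypoints])
        if (
            pts[:, 0].min() < margin or pts[:, 0].max() > w - 1 - margin
            or pts[:, 1].min() < margin or pts[:, 1].max() > h - 1 - margin
        ):
            raise SceneSpecError(
                f"trajectory {tr.mosquito_id!r} leaves the frame"
            )
        for a, b in tr.resting_intervals:
            grid = np.linspace(a, min(b, scene.duration), 25)
            pos = tr.position(grid)
            if np.hypot(*(pos.max(axis=0) - pos.min(axis=0))) > 1e-6:
                raise SceneSpecError(
                    f"trajectory {tr.mosquito_id!r} moves during a resting interval"
                )


def ground_truth_for(scene: SyntheticScene,
                     interval: float = SAMPLE_INTERVAL) -> GroundTruth:
    """Exact per-sample truth for a scene (no rendering required)."""
    indices = sample_indices(scene.n_frames, scene.fps, interval)
    times = np.array(indices) / scene.fps
    rows = []
    for tr in scene.trajectories:
        pos = tr.position(times)
        disp = np.hypot(*np.diff(pos, axis=0).T)
        moving = np.concatenate([[False], disp > MOVING_THRESHOLD_PX])
        for k, (t, (x, y), m) in enumerate(zip(times, pos, moving)):
            rows.append((k, round(t, 3), tr.mosquito_id, float(x), float(y),
                         bool(m), scene.geometry.region_of(y)))
    table = pd.DataFrame(
        rows, columns=["sample", "t", "mosquito_id", "x", "y", "moving", "region"]
    ).sort_values(["sample", "mosquito_id"], ignore_index=True)
    return GroundTruth(table, occupancy=max(CONE_OCCUPANCY, scene.n_mosquitoes))


def generate_scene(
    scene: SyntheticScene, out_path: str | Path
) -> tuple[VideoAsset, GroundTruth]:
    """Render a scene to a video file and return its asset plus ground truth.

    Rendering is deterministic for a fixed spec and seed: identical inputs
    produce byte-identical files.
    """
    _validate_in_frame(scene)
    w, h = scene.geometry.frame_dims
    rng = np.random.default_rng(scene.seed)
    n_frames = scene.n_frames
    times = np.arange(n_frames) / scene.fps
    positions = [tr.position(times) for tr in scene.trajectories]
    with open_writer(out_path, scene.fps) as writer:
        for i in range(n_frames):
            base = scene.background_intensity + scene.background_drift * times[i]
            frame = np.full((h, w), base, dtype=np.float32)
            for tr, pos in zip(scene.trajectories, positions):
                _draw_disc(frame, pos[i, 0], pos[i, 1], tr.blob_diameter,
                           tr.blob_intensity)
            if scene.noise_sd > 0:
                frame += rng.standard_normal((h, w), dtype=np.float32) * scene.noise_sd
            writer.append(np.clip(frame, 0, 255).round().astype(np.uint8))
    asset = VideoAsset(Path(out_path), w, h, scene.fps, n_frames)
    return asset, ground_truth_for(scene)


# ---------------------------------------------------------------------------
# preset scenes


def _rect_loop_waypoints(
    cx: float, cy: float, half_w: float, half_h: float,
    speed: float, duration: float, s0: float = 0.0, t0: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Waypoints tracing a rectangular loop at constant speed from ``t0``.

    Corners are emitted as explicit waypoints so segments stay linear; the
    90-degree turns keep per-sample displacement above the moving threshold
    (a straight reversal could momentarily cancel displacement).
    """
    corners = np.array([
        (cx - half_w, cy - half_h), (cx + half_w, cy - half_h),
        (cx + half_w, cy + half_h), (cx - half_w, cy + half_h),
    ])
    seg_len = np.array([2 * half_w, 2 * half_h, 2 * half_w, 2 * half_h], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    perimeter = cum[-1]

    def pos_at(s: float) -> tuple[float, float]:
        s = s % perimeter
        seg = int(np.searchsorted(cum, s, side="right")) - 1
        seg = min(seg, 3)
        frac = (s - cum[seg]) / seg_len[seg]
        a = corners[seg]
        b = corners[(seg + 1) % 4]
        return (a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1]))

    wps = [(t0, *pos_at(s0))]
    # times at which the path crosses each corner (segments are unequal, so
    # corner arc-lengths are the cumulative boundaries, not quarter-points)
    s_end = s0 + speed * (duration - t0)
    crossings = sorted(
        c + m * perimeter
        for m in range(int(s0 // perimeter), int(s_end // perimeter) + 2)
        for c in cum[1:]
        if s0 < c + m * perimeter < s_end
    )
    for s in crossings:
        t = t0 + (s - s0) / speed
        if t > t0 + 1e-9 and t < duration - 1e-9:
            wps.append((t, *pos_at(s)))
    wps.append((duration, *pos_at(s_end)))
    return wps


def _hold(pos: tuple[float, float], t0: float, t1: float):
    return [(t0, *pos), (t1, *pos)]


_CRAWL_LANES = [660.0, 710.0, 760.0, 810.0, 855.0]
_DISPERSED_CELLS = [  # (cy, region): three upper cells, two lower
    (220.0, "upper"), (330.0, "upper"), (430.0, "upper"),
    (600.0, "lower"), (730.0, "lower"),
]


def _crawler(duration: float) -> tuple[TrajectorySpec, ...]:
    """Five mosquitoes crawling along the net surface (lower cone)."""
    out = []
    for i, lane in enumerate(_CRAWL_LANES):
        speed = 35.0 + 5.0 * i
        wps = _rect_loop_waypoints(270.0, lane, 130.0, 6.0, speed, duration,
                                   s0=i * 97.0)
        out.append(TrajectorySpec(f"crawler_{i}", tuple(wps)))
    return tuple(out)


def _dispersed(duration: float) -> tuple[TrajectorySpec, ...]:
    """Five mosquitoes in continuous flight dispersed through the cone."""
    out = []
    for i, (cy, _) in enumerate(_DISPERSED_CELLS):
        speed = 40.0 + 6.0 * i
        wps = _rect_loop_waypoints(270.0, cy, 120.0, 20.0, speed, duration,
                                   s0=i * 83.0)
        out.append(TrajectorySpec(f"dispersed_{i}", tuple(wps)))
    return tuple(out)


def _high_rest(duration: float) -> tuple[TrajectorySpec, ...]:
    """Five mosquitoes active early, then settling for the rest of the test."""
    stop_t = min(55.0, duration / 3.0)
    out = []
    for i, (cy, _) in enumerate(_DISPERSED_CELLS):
        speed = 40.0 + 6.0 * i
        wps = _rect_loop_waypoints(270.0, cy, 120.0, 20.0, speed, stop_t,
                                   s0=i * 83.0)
        last = wps[-1]
        wps.append((duration, last[1], last[2]))
        out.append(
            TrajectorySpec(f"rester_{i}", tuple(wps),
                           resting_intervals=((stop_t, duration),))
        )
    return tuple(out)


def _mixed(duration: float) -> tuple[TrajectorySpec, ...]:
    """Two net-surface crawlers, two dispersed flyers, one early rester."""
    crawl = _crawler(duration)[:2]
    disp = _dispersed(duration)[:2]
    rest = _high_rest(duration)[4:]
    return crawl + disp + rest


def preset_scenes(
    *, duration: float = 180.0, noise_sd: float = 5.0, seed: int = 0
) -> dict[str, SyntheticScene]:
    """Catalogue of named scenes with documented ground-truth expectations.

    ``crawler``   — all activity at the net surface: true prop_lower = 1.0.
    ``dispersed`` — continuous flight, 3 upper / 2 lower: prop_lower = 0.4.
    ``high_rest`` — everyone settles after the first third: resting > 90 s
    at the standard duration.
    ``mixed``     — two crawlers, two flyers, one rester.
    """
    builders = {
        "crawler": _crawler,
        "dispersed": _dispersed,
        "high_rest": _high_rest,
        "mixed": _mixed,
    }
    return {
        name: SyntheticScene(
            trajectories=build(duration), duration=duration,
            noise_sd=noise_sd, seed=seed,
        )
        for name, build in builders.items()
    }


# ---------------------------------------------------------------------------
# synthetic life-history records


def synthetic_life_history(
    assay_ids: list[str], *, seed: int = 0, per_assay: int = CONE_OCCUPANCY,
    treatment: str = "UT", strain: str = "KS",
) -> pd.DataFrame:
    """Plausible post-exposure monitoring records for testing the merge.

    Feeding, blood meal size (haematin proxy), wing length and longevity are
    drawn from ranges typical of untreated-net assays; mosquitoes that do not
    feed at 1 h get a second opportunity at 24 h, so ``fed_24h`` is recorded
    only for those with ``fed_1h`` false.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for assay in assay_ids:
        for i in range(per_assay):
            fed_1h = bool(rng.random() < 0.9)
            fed_24h = bool(rng.random() < 0.5) if not fed_1h else False
            fed = fed_1h or fed_24h
            haematin = round(float(max(0.5, rng.normal(12.5, 7.6))), 2) if fed else None
            death_day = int(max(0, round(rng.normal(12.0, 4.0))))
            rows.append(
                {
                    "mosquito_id": f"{assay}_m{i + 1}",
                    "assay_id": assay,
                    "strain": strain,
                    "treatment": treatment,
                    "fed_1h": fed_1h,
                    "fed_24h": fed_24h,
                    "haematin": haematin,
                    "wing_length": round(float(rng.normal(3.0, 0.2)), 2),
                    "death_day": death_day,
                    "dead_24h": death_day < 1,
                }
            )
    return pd.DataFrame(rows)
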