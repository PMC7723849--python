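"""Kymograph construction and organelle transport kinetics.

A kymograph resamples a time-lapse movie along an axon path: rows are
arc-length stations (one pixel of arc length apart), columns are frames,
and each sample is the maximum over a short line orthogonal to the path.
The position axis is oriented so that increasing position is anterograde
(toward the declared growth-cone end).

Kinetics follow the kymograph-tool conventions:

* per-interval velocity v_i = Δposition / Δtime, classified anterograde
  (v ≥ v_min), retrograde (v ≤ −v_min) or pausing, with the minimum-speed
  threshold inclusive (default 0.02 μm/s);
* an organelle is anterograde/retrograde by the sign of its net
  displacement when its net speed reaches v_min, otherwise stationary;
* Vma = anterograde distance / time, Vmr = |retrograde distance| / time,
  with "time" taken as time spent moving in that direction (the total
  recording time is selectable via ``time_base="total"``);
* pausing time is the per-organelle pausing fraction averaged within each
  axon, then across axons;
* linear flow rate Q = Vma · n_anterograde + Vmr · n_retrograde.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from . import simgen
from .errors import ConfigurationError, InputError

__all__ = [
    "TimeLapseMovie",
    "AxonPath",
    "Kymograph",
    "Track",
    "TrackKinetics",
    "build_kymograph",
    "extract_tracks_auto",
    "classify_track",
    "classify_organelle",
    "kinetics",
    "tracks_from_truth",
    "recover_preset",
    "V_MIN_DEFAULT",
]

#: Minimum speed (μm/s) counted as movement, per the reference analysis.
V_MIN_DEFAULT = 0.02


@dataclass
class TimeLapseMovie:
    """(time, y, x) stack with physical calibration."""

    stack: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[0] < 2:
            raise InputError("movie must be a 3D stack with at least 2 frames")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise InputError("frame_interval_s and pixel_size_um must be positive")


@dataclass
class AxonPath:
    """Segmented line along the axon.

    ``polyline`` is an ordered array of (x, y) pixel vertices.
    ``distal_end`` declares which end points toward the growth cone:
    ``"last"`` (default) or ``"first"``.
    """

    polyline: np.ndarray
    distal_end: str = "last"
    linewidth_px: int = 3

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2:
            raise InputError("path needs at least two vertices")
        if self.distal_end not in ("first", "last"):
            raise InputError("distal_end must be 'first' or 'last'")
        if self.linewidth_px < 1 or self.linewidth_px % 2 == 0:
            raise InputError("linewidth_px must be an odd positive integer")
        seg = np.diff(self.polyline, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if self._seg_len.sum() <= 0:
            raise InputError("path has zero length")

    @property
    def length_px(self) -> float:
        return float(self._seg_len.sum())

    def sample(self, spacing_px: float = 1.0):
        """Equally spaced points and unit tangents along the path.

        Points run from the proximal end toward the distal (growth-cone)
        end, so arc length increases anterogradely.
        """
        pts = self.polyline if self.distal_end == "last" else self.polyline[::-1]
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        stations = np.arange(0.0, cum[-1] + spacing_px / 2, spacing_px)
        xs = np.interp(stations, cum, pts[:, 0])
        ys = np.interp(stations, cum, pts[:, 1])
        # tangent per station from the owning segment
        idx = np.clip(np.searchsorted(cum, stations, side="right") - 1, 0, len(seg) - 1)
        tx = seg[idx, 0] / seg_len[idx]
        ty = seg[idx, 1] / seg_len[idx]
        return np.column_stack([xs, ys]), np.column_stack([tx, ty])


@dataclass
class Kymograph:
    """Position-along-path × time intensity array."""

    array: np.ndarray
    position_step_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 2:
            raise InputError("kymograph must be 2D (position × time)")

    @property
    def n_positions(self) -> int:
        return self.array.shape[0]

    @property
    def n_frames(self) -> int:
        return self.array.shape[1]


@dataclass
class Track:
    """One organelle trajectory as ordered (frame, position_um) samples."""

    organelle_id: str
    frames: np.ndarray
    positions_um: np.ndarray
    source: str = "manual"
    axon_id: str = "axon0"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.shape != self.positions_um.shape:
            raise InputError("frames and positions must have equal length")
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise InputError("frame indices must be strictly increasing")
        if self.source not in ("manual", "auto"):
            raise InputError("source must be 'manual' or 'auto'")

    def reversed(self, path_length_um: float | None = None) -> "Track":
        """The same trajectory under the opposite path orientation.

        Kinetics depend only on position differences, so the origin is
        arbitrary: with ``path_length_um`` the positions are mapped to
        ``L - p`` (staying in ``[0, L]``); without it they are negated,
        which flips orientation exactly in floating point.
        """
        if path_length_um is None:
            positions = -self.positions_um
        else:
            positions = path_length_um - self.positions_um
        return Track(
            organelle_id=self.organelle_id,
            frames=self.frames.copy(),
            positions_um=positions,
            source=self.source,
            axon_id=self.axon_id,
            low_confidence=self.low_confidence,
        )


@dataclass
class TrackKinetics:
    """Transport kinetics for a set of tracks."""

    Vma_um_s: float
    Vmr_um_s: float
    n_anterograde: int
    n_retrograde: int
    n_stationary: int
    pausing_fraction: float
    Q_um_s: float
    v_min_um_s: float = V_MIN_DEFAULT
    flags: list = field(default_factory=list)

    @property
    def n_organelles(self) -> int:
        return self.n_anterograde + self.n_retrograde + self.n_stationary

    @property
    def moving_fraction(self) -> float:
        n = self.n_organelles
        return (self.n_anterograde + self.n_retrograde) / n if n else 0.0


# ---------------------------------------------------------------------------
# kymograph construction


def build_kymograph(movie: TimeLapseMovie, path: AxonPath) -> Kymograph:
    """Resample the movie along the path into a position × time array.

    At each arc-length station the intensity is the maximum over
    ``linewidth_px`` bilinear samples taken orthogonally to the path.
    """
    points, tangents = path.sample(spacing_px=1.0)
    h, w = movie.stack.shape[1:]
    if (
        points[:, 0].min() < -0.5
        or points[:, 0].max() > w - 0.5
        or points[:, 1].min() < -0.5
        or points[:, 1].max() > h - 0.5
    ):
        raise InputError("axon path extends outside the movie frame")

    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    half = (path.linewidth_px - 1) // 2
    offsets = np.arange(-half, half + 1)
    # sample grid: (n_offsets, n_stations)
    xs = points[None, :, 0] + offsets[:, None] * normals[None, :, 0].squeeze(0)
    ys = points[None, :, 1] + offsets[:, None] * normals[None, :, 1].squeeze(0)

    n_frames = movie.stack.shape[0]
    kymo = np.empty((points.shape[0], n_frames))
    coords = [ys.ravel(), xs.ravel()]
    for t in range(n_frames):
        vals = map_coordinates(movie.stack[t], coords, order=1, mode="nearest")
        kymo[:, t] = vals.reshape(offsets.size, -1).max(axis=0)
    return Kymograph(
        array=kymo,
        position_step_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# automatic track extraction (the reference workflow draws tracks manually;
# this automatic mode exists to close the loop against synthetic truth)


def _frame_peaks(column: np.ndarray, threshold: float, min_separation_px: int = 2):
    """Local maxima above threshold with centre-of-mass subpixel refinement."""
    n = column.size
    if n < 3:
        return np.array([])
    is_peak = (
        (column[1:-1] >= column[:-2])
        & (column[1:-1] > column[2:])
        & (column[1:-1] > threshold)
    )
    idx = np.flatnonzero(is_peak) + 1
    if idx.size == 0:
        return np.array([])
    # enforce minimum separation, keeping the brighter peak
    keep = []
    for i in idx[np.argsort(column[idx])[::-1]]:
        if all(abs(i - j) >= min_separation_px for j in keep):
            keep.append(i)
    keep = np.sort(np.array(keep))
    # parabolic/CoM refinement over a 3-px window
    refined = []
    for i in keep:
        lo, hi = max(i - 1, 0), min(i + 2, n)
        window = column[lo:hi]
        pos = np.arange(lo, hi)
        refined.append(float((window * pos).sum() / window.sum()))
    return np.array(refined)


class _ActiveTrack:
    __slots__ = ("frames", "positions", "misses", "low_confidence")

    def __init__(self, frame, pos):
        self.frames = [frame]
        self.positions = [pos]
        self.misses = 0
        self.low_confidence = False

    def predict(self):
        if len(self.positions) >= 3:
            v = (self.positions[-1] - self.positions[-3]) / (
                self.frames[-1] - self.frames[-3]
            )
        else:
            v = 0.0
        gap = self.misses + 1
        return self.positions[-1] + v * gap


def extract_tracks_auto(
    kymograph: Kymograph,
    intensity_threshold: float,
    max_speed_um_s: float = 2.0,
    min_track_frames: int = 5,
    max_gap_frames: int = 2,
    axon_id: str = "axon0",
) -> list[Track]:
    """Peak detection per frame + nearest-neighbour linking across frames.

    Peaks are matched to velocity-extrapolated track positions greedily by
    distance, gated at ``max_speed_um_s × frame_interval``. Tracks may
    survive up to ``max_gap_frames`` missed detections; tracks shorter
    than ``min_track_frames`` are discarded. Matches where two tracks
    competed for one peak are flagged low-confidence.
    """
    step = kymograph.position_step_um
    dt = kymograph.frame_interval_s
    gate_um = max_speed_um_s * dt * (1 + max_gap_frames)

    active: list[_ActiveTrack] = []
    finished: list[_ActiveTrack] = []
    for t in range(kymograph.n_frames):
        peaks_um = _frame_peaks(kymograph.array[:, t], intensity_threshold) * step
        assigned_peaks: set[int] = set()
        assigned_tracks: set[int] = set()
        if active and peaks_um.size:
            preds = np.array([tr.predict() for tr in active])
            cost = np.abs(preds[:, None] - peaks_um[None, :])
            pairs = sorted(
                (
                    (cost[i, j], i, j)
                    for i in range(len(active))
                    for j in range(peaks_um.size)
                    if cost[i, j] <= gate_um
                ),
            )
            candidates_per_peak = np.zeros(peaks_um.size, dtype=int)
            for _, _, j in pairs:
                candidates_per_peak[j] += 1
            for c, i, j in pairs:
                if i in assigned_tracks or j in assigned_peaks:
                    continue
                active[i].frames.append(t)
                active[i].positions.append(float(peaks_um[j]))
                active[i].misses = 0
                if candidates_per_peak[j] > 1:
                    active[i].low_confidence = True
                assigned_tracks.add(i)
                assigned_peaks.add(j)
        survivors = []
        for i, tr in enumerate(active):
            if i in assigned_tracks:
                survivors.append(tr)
            else:
                tr.misses += 1
                if tr.misses > max_gap_frames:
                    finished.append(tr)
                else:
                    survivors.append(tr)
        active = survivors
        for j, p in enumerate(peaks_um):
            if j not in assigned_peaks:
                active.append(_ActiveTrack(t, float(p)))
    finished.extend(active)

    tracks = []
    k = 0
    for tr in finished:
        if len(tr.frames) < min_track_frames:
            continue
        tracks.append(
            Track(
                organelle_id=f"auto{k}",
                frames=np.array(tr.frames),
                positions_um=np.array(tr.positions),
                source="auto",
                axon_id=axon_id,
                low_confidence=tr.low_confidence,
            )
        )
        k += 1
    return tracks


# ---------------------------------------------------------------------------
# classification and kinetics


def classify_track(
    track: Track, v_min_um_s: float = V_MIN_DEFAULT, frame_interval_s: float = 1.0
):
    """Per-interval motion states and the organelle's direction class.

    Returns ``(states, organelle_class)`` where states are
    'anterograde' / 'retrograde' / 'pausing' per inter-sample interval and
    the class is by net displacement ('anterograde', 'retrograde' or
    'stationary'). Threshold comparisons are inclusive.
    """
    if track.frames.size < 2:
        raise InputError("a track needs at least two samples to classify")
    dts = np.diff(track.frames) * frame_interval_s
    v = np.diff(track.positions_um) / dts
    states = np.where(
        v >= v_min_um_s, "anterograde", np.where(v <= -v_min_um_s, "retrograde", "pausing")
    )
    return list(states), classify_organelle(track, v_min_um_s, frame_interval_s)


def classify_organelle(
    track: Track, v_min_um_s: float = V_MIN_DEFAULT, frame_interval_s: float = 1.0
) -> str:
    net = track.positions_um[-1] - track.positions_um[0]
    duration = (track.frames[-1] - track.frames[0]) * frame_interval_s
    if duration <= 0 or abs(net) / duration < v_min_um_s:
        return "stationary"
    return "anterograde" if net > 0 else "retrograde"


def kinetics(
    tracks: Sequence[Track],
    v_min_um_s: float = V_MIN_DEFAULT,
    frame_interval_s: float = 1.0,
    time_base: str = "segment",
) -> TrackKinetics:
    """Transport kinetics pooled over tracks.

    ``time_base="segment"`` (default) divides directional distance by the
    time spent moving in that direction; ``"total"`` divides by the total
    recording time of the contributing organelles.
    """
    if len(tracks) == 0:
        raise InputError("at least one track is required")
    if time_base not in ("segment", "total"):
        raise ConfigurationError("time_base must be 'segment' or 'total'")

    antero_dist = antero_time = 0.0
    retro_dist = retro_time = 0.0
    total_time_antero = total_time_retro = 0.0
    n_a = n_r = n_s = 0
    pausing_by_axon: dict = {}
    flags: list = []

    for track in tracks:
        states, cls = classify_track(track, v_min_um_s, frame_interval_s)
        dts = np.diff(track.frames) * frame_interval_s
        dxs = np.diff(track.positions_um)
        duration = float(dts.sum())
        st = np.array(states)
        a = st == "anterograde"
        r = st == "retrograde"
        p = st == "pausing"
        antero_dist += float(dxs[a].sum())
        antero_time += float(dts[a].sum())
        retro_dist += float(-dxs[r].sum())
        retro_time += float(dts[r].sum())
        if cls == "anterograde":
            n_a += 1
            total_time_antero += duration
        elif cls == "retrograde":
            n_r += 1
            total_time_retro += duration
        else:
            n_s += 1
        pausing_by_axon.setdefault(track.axon_id, []).append(
            float(dts[p].sum()) / duration if duration > 0 else 1.0
        )

    if time_base == "segment":
        vma = antero_dist / antero_time if antero_time > 0 else 0.0
        vmr = retro_dist / retro_time if retro_time > 0 else 0.0
    else:
        vma = antero_dist / total_time_antero if total_time_antero > 0 else 0.0
        vmr = retro_dist / total_time_retro if total_time_retro > 0 else 0.0
    if antero_time == 0:
        flags.append("no anterograde intervals: Vma = 0 by convention")
    if retro_time == 0:
        flags.append("no retrograde intervals: Vmr = 0 by convention")

    per_axon = [float(np.mean(fr)) for fr in pausing_by_axon.values()]
    pausing = float(np.mean(per_axon))

    return TrackKinetics(
        Vma_um_s=vma,
        Vmr_um_s=vmr,
        n_anterograde=n_a,
        n_retrograde=n_r,
        n_stationary=n_s,
        pausing_fraction=pausing,
        Q_um_s=vma * n_a + vmr * n_r,
        v_min_um_s=v_min_um_s,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# synthetic-truth integration


def tracks_from_truth(truth: simgen.SyntheticGroundTruth, axon_id="axon0") -> list[Track]:
    """Exact per-organelle tracks from a movie generator's ground truth."""
    pos = truth.data["positions_um"]
    frames = np.arange(pos.shape[1])
    return [
        Track(
            organelle_id=f"true{i}",
            frames=frames,
            positions_um=pos[i],
            source="manual",
            axon_id=axon_id,
        )
        for i in range(pos.shape[0])
    ]


def recover_preset(
    preset_name: str,
    n_organelles: int = 50,
    seed: int = 0,
    n_frames: int | None = None,
    v_min_um_s: float = V_MIN_DEFAULT,
    axon_length_um: float | None = None,
    max_gap_frames: int = 15,
):
    """End-to-end parameter recovery on a named transport regime.

    Simulates a movie, builds the kymograph, extracts tracks automatically
    and computes kinetics. Returns ``(estimated, truth_kinetics, truth)``
    where ``truth_kinetics`` applies the same kinetics computation to the
    generator's exact trajectories.

    When ``axon_length_um`` is not given, the field of view is scaled with
    the organelle count to hold the linear density at the reference
    regime's ~15 organelles per 120 μm of axon, so large-n recovery runs
    do not become unrealistically crowded.
    """
    if axon_length_um is None:
        axon_length_um = max(120.0, 7.2 * n_organelles)
    overrides: dict = {
        "n_organelles": n_organelles,
        "seed": seed,
        "axon_length_um": axon_length_um,
    }
    if n_frames is not None:
        overrides["n_frames"] = n_frames
    config = simgen.preset(preset_name, **overrides)
    movie_arr, truth = simgen.simulate_organelle_movie(config)
    movie = TimeLapseMovie(
        stack=movie_arr,
        frame_interval_s=config.frame_interval_s,
        pixel_size_um=config.pixel_size_um,
    )
    cy = (movie_arr.shape[1] - 1) / 2.0
    path = AxonPath(
        polyline=np.array([[0.0, cy], [movie_arr.shape[2] - 1.0, cy]]),
        distal_end="last",
        linewidth_px=3,
    )
    kymo = build_kymograph(movie, path)
    tracks = extract_tracks_auto(
        kymo,
        intensity_threshold=0.3 * config.punctum_intensity,
        max_gap_frames=max_gap_frames,
    )
    estimated = (
        kinetics(tracks, v_min_um_s, config.frame_interval_s) if tracks else None
    )
    truth_kin = kinetics(
        tracks_from_truth(truth), v_min_um_s, config.frame_interval_s
    )
    return estimated, truth_kin, truth
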