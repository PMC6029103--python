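"""Track records -> attachment count series and event logs.

The upstream microscopy pipeline delivers per-cell, per-frame positions.
This module (a) classifies each frame of each track as surface-attached or
mobile from a displacement criterion, (b) aggregates classifications into
the N_b(t) / N_s(t) count series the kinetics module fits, (c) audits the
attach/detach event balance that justifies dropping the detachment term
from the rate model, and (d) rebuilds genealogical forests from
parent-linked tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import StructuralError
from .lineage import LineageForest, LineageNode
from .simulate import CellTrack

DEFAULT_WINDOW = 5        # frames (15 s at the 3-s default interval)
DEFAULT_THRESHOLD = 1.0   # um


@dataclass
class AttachmentSeries:
    """Bulk/surface counts over the frame grid, with N conserved."""

    times: np.ndarray
    n_bulk: np.ndarray
    n_surface: np.ndarray
    n_total: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_bulk = np.asarray(self.n_bulk)
        self.n_surface = np.asarray(self.n_surface)
        if not (len(self.times) == len(self.n_bulk) == len(self.n_surface)):
            raise StructuralError("series arrays differ in length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise StructuralError("times must be strictly increasing")
        if np.any(self.n_bulk < 0) or np.any(self.n_surface < 0):
            raise StructuralError("counts must be nonnegative")
        if np.any(self.n_bulk + self.n_surface != self.n_total):
            raise StructuralError("conservation violated: n_bulk + n_surface != n_total")

    @property
    def fraction_bulk(self) -> np.ndarray:
        """N_b(t)/N, the quantity the exponential mixture model describes."""
        return self.n_bulk / self.n_total

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FluxSummary:
    """Attach/detach event balance used to audit the no-detachment model."""

    n_attach_events: int
    n_detach_events: int

    @property
    def ratio(self) -> float:
        return self.n_attach_events / max(self.n_detach_events, 1)

    @property
    def detachment_negligible(self) -> bool:
        """True when net attachment dominates (ratio >= 10)."""
        return self.ratio >= 10.0


def _window_diameter(xy: np.ndarray, window: int) -> np.ndarray:
    """Max pairwise displacement within each trailing window.

    Returns an array of length ``len(xy) - window + 1``; entry j covers
    frames [j, j + window).
    """
    n = len(xy)
    m = n - window + 1
    diam = np.zeros(m)
    for a in range(window):
        for b in range(a + 1, window):
            d = np.linalg.norm(xy[b : b + m] - xy[a : a + m], axis=1)
            np.maximum(diam, d, out=diam)
    return diam


def classify_attached(
    track: CellTrack,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    backdate: bool = True,
) -> np.ndarray:
    """Classify each frame of *track* as attached (True) or mobile (False).

    A window of ``window`` consecutive frames certifies attachment when its
    maximum pairwise displacement is below ``threshold``.  With
    ``backdate=True`` (default) every frame inside any certifying window is
    marked attached, so the detected attach time coincides with the first
    stationary frame; with ``backdate=False`` only the last frame of a
    certifying window is marked (a trailing-window rule), which lags the
    true attach time by window - 1 frames.  Tracks shorter than the window
    are classified whole by their total displacement.
    """
    if window < 2:
        raise StructuralError("window must be >= 2 frames")
    n = len(track)
    if n < window:
        diam = _window_diameter(track.xy, n)[0] if n > 1 else 0.0
        return np.full(n, diam < threshold)
    diam = _window_diameter(track.xy, window)
    cert = diam < threshold  # cert[j] certifies frames [j, j+window)
    out = np.zeros(n, dtype=bool)
    if backdate:
        for off in range(window):
            out[off : off + len(cert)] |= cert
    else:
        out[window - 1 :] = cert
        out[: window - 1] = cert[0]  # inherit the first decided state
    return out


def classify_tracks(
    tracks: Sequence[CellTrack],
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    backdate: bool = True,
) -> List[np.ndarray]:
    """Vectorised :func:`classify_attached` over tracks sharing one grid."""
    if not tracks:
        raise StructuralError("empty track set")
    lengths = {len(t) for t in tracks}
    if len(lengths) > 1 or min(lengths) < window:
        return [classify_attached(t, window, threshold, backdate) for t in tracks]
    xy = np.stack([t.xy for t in tracks])  # (n_cells, n_frames, 2)
    n_cells, n_frames, _ = xy.shape
    m = n_frames - window + 1
    diam = np.zeros((n_cells, m))
    for a in range(window):
        for b in range(a + 1, window):
            d = np.linalg.norm(xy[:, b : b + m] - xy[:, a : a + m], axis=2)
            np.maximum(diam, d, out=diam)
    cert = diam < threshold
    out = np.zeros((n_cells, n_frames), dtype=bool)
    if backdate:
        for off in range(window):
            out[:, off : off + m] |= cert
    else:
        out[:, window - 1 :] = cert
        out[:, : window - 1] = cert[:, [0]]
    return list(out)


def _common_grid(tracks: Sequence[CellTrack]) -> np.ndarray:
    if not tracks:
        raise StructuralError("empty track set")
    t0 = tracks[0].times
    for t in tracks[1:]:
        if len(t.times) != len(t0) or not np.allclose(t.times, t0):
            raise StructuralError("tracks do not share a common frame grid")
    return t0


def count_series(
    tracks: Sequence[CellTrack],
    attached: Optional[Sequence[np.ndarray]] = None,
) -> AttachmentSeries:
    """Aggregate per-frame attached states into an :class:`AttachmentSeries`.

    ``attached`` supplies classifications (e.g. from :func:`classify_tracks`);
    when omitted, the tracks' own ``attached`` flags (generator bookkeeping)
    are counted.  All tracks must share the frame grid.
    """
    times = _common_grid(tracks)
    if attached is None:
        attached = [t.attached for t in tracks]
    if len(attached) != len(tracks):
        raise StructuralError("one attached array per track required")
    mat = np.stack([np.asarray(a, dtype=bool) for a in attached])
    if mat.shape[1] != len(times):
        raise StructuralError("attached arrays do not match the frame grid")
    n_surface = mat.sum(axis=0)
    n_total = len(tracks)
    return AttachmentSeries(times, n_total - n_surface, n_surface, n_total)


def flux_check(
    tracks: Sequence[CellTrack],
    attached: Optional[Sequence[np.ndarray]] = None,
) -> FluxSummary:
    """Count attach (False->True) and detach (True->False) transitions.

    A ratio below 10 means detachment is not negligible for this dataset
    and the no-detachment mixture model is questionable; a warning is
    emitted in that case.
    """
    if attached is None:
        attached = [t.attached for t in tracks]
    n_att = n_det = 0
    for a in attached:
        a = np.asarray(a, dtype=bool)
        if len(a) < 2:
            continue
        d = np.diff(a.astype(np.int8))
        n_att += int(np.sum(d == 1))
        n_det += int(np.sum(d == -1))
    summary = FluxSummary(n_att, n_det)
    if not summary.detachment_negligible:
        warnings.warn(
            f"attach/detach event ratio {summary.ratio:.2f} < 10: the "
            "no-detachment simplification may not hold for this dataset",
            stacklevel=2,
        )
    return summary


def extract_division_events(
    tracks: Sequence[CellTrack],
    censor_window: float = 9.0,
) -> Tuple[LineageForest, List[str]]:
    """Rebuild a genealogical forest from parent-linked tracks.

    Daughter outcome rules: a daughter that later divides "stays"; a
    daughter whose attached record contains a detach transition ending
    detached "leaves"; otherwise it "stays" if observed at least
    ``censor_window`` seconds beyond its birth and is "censored" if not.
    Daughters whose parent track is missing or not temporally adjacent are
    returned as orphans (second element), never silently dropped.
    """
    by_id = {t.cell_id: t for t in tracks}
    if len(by_id) != len(tracks):
        raise StructuralError("duplicate cell ids in track set")
    children: Dict[str, List[str]] = {tid: [] for tid in by_id}
    orphans: List[str] = []
    dt = None
    for t in tracks:
        if len(t.times) > 1:
            dt = float(t.times[1] - t.times[0])
            break
    adjacency = 2.0 * dt if dt is not None else float("inf")

    for t in tracks:
        if t.parent_id is None:
            continue
        parent = by_id.get(t.parent_id)
        if parent is None or t.times[0] - parent.times[-1] > adjacency or (
            t.times[0] < parent.times[0]
        ):
            orphans.append(t.cell_id)
        else:
            children[t.parent_id].append(t.cell_id)

    orphan_set = set(orphans)
    nodes: Dict[str, LineageNode] = {}
    for tid, t in by_id.items():
        kids = children[tid]
        t_birth = float(t.times[0])
        t_division = None
        if kids:
            t_division = min(float(by_id[k].times[0]) for k in kids)
            if t_division <= t_birth:
                t_division = t_birth + (dt or 1.0) / 2.0
        a = np.asarray(t.attached, dtype=bool)
        has_detach = len(a) >= 2 and np.any(np.diff(a.astype(np.int8)) == -1)
        if t_division is not None:
            fate = "stay"
        elif (has_detach and not a[-1]) or (len(a) == 1 and not a[0]):
            fate = "leave"
        elif float(t.times[-1]) - t_birth >= censor_window:
            fate = "stay"
        else:
            fate = "censored"
        # orphaned daughters become roots of their own (partial) trees
        parent = None if tid in orphan_set else t.parent_id
        nodes[tid] = LineageNode(tid, parent, t_birth, t_division, fate)

    return LineageForest(nodes), orphans
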