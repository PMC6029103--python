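"""Seeded synthetic-data generators.

These generators produce every input the analysis pipeline consumes, with
the statistical structure the downstream estimators assume:

* per-cell attachment tracks realised from a mixture of exponentially
  distributed attachment waiting times (one rate per phenotype), optionally
  with rare detachment;
* two-channel single-cell fluorescence in which an inverted reporter
  (intensity decreasing with expression) and a direct stain (increasing)
  are coupled through a Gaussian copula calibrated to a target Pearson
  correlation;
* genealogical trees whose divisions draw postdivision fates
  (both-stay / one-stays / both-leave) from stated probabilities;
* biofilm thickness maps calibrated to a target roughness coefficient.

All randomness in a call flows from one integer seed through a single
``numpy.random.Generator`` stream, so identical configurations reproduce
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .lineage import LineageForest, LineageNode


# --------------------------------------------------------------------------
# attachment tracks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeMix:
    """Generative truth for a k-phenotype attachment mixture.

    ``fractions[i]`` is the number fraction of phenotype i, ``attach_rates[i]``
    its attachment rate alpha_i (1/s) and ``detach_rates[i]`` its detachment
    rate beta_i (1/s, zero by default — detachment is negligible in the
    no-growth attachment assay the generator emulates).  Components are
    ordered fastest first.
    """

    fractions: Tuple[float, ...]
    attach_rates: Tuple[float, ...]
    detach_rates: Tuple[float, ...] = ()

    def __post_init__(self):
        f = tuple(float(x) for x in self.fractions)
        a = tuple(float(x) for x in self.attach_rates)
        b = tuple(float(x) for x in self.detach_rates) or (0.0,) * len(a)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "attach_rates", a)
        object.__setattr__(self, "detach_rates", b)
        if not (len(f) == len(a) == len(b)) or len(f) == 0:
            raise ParameterError("fractions/attach_rates/detach_rates lengths differ")
        if abs(sum(f) - 1.0) > 1e-12:
            raise ParameterError(f"fractions must sum to 1, got {sum(f)!r}")
        if any(x < 0 or x > 1 for x in f):
            raise ParameterError("fractions must lie in [0, 1]")
        if any(x < 0 for x in a) or any(x < 0 for x in b):
            raise ParameterError("rates must be nonnegative")
        if any(a[i] <= a[i + 1] for i in range(len(a) - 1)):
            raise ParameterError("attach_rates must be strictly decreasing (fastest first)")

    @property
    def k(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class SimConfig:
    """Imaging/geometry configuration for an attachment movie.

    Defaults mirror a typical single-field time-lapse assay: one frame every
    3 s over a 165 um x 139 um field of view for about an hour.
    """

    n_cells: int
    duration: float = 3600.0
    frame_interval: float = 3.0
    seed: int = 0
    jitter_attached: float = 0.05   # um, positional noise of attached cells
    diffusion_bulk: float = 0.5     # um^2/s, mobile-cell displacement scale
    field: Tuple[float, float] = (165.0, 139.0)  # um

    def __post_init__(self):
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ParameterError("duration and frame_interval must be positive")
        if self.jitter_attached < 0 or self.diffusion_bulk < 0:
            raise ParameterError("noise scales must be nonnegative")
        if self.field[0] <= 0 or self.field[1] <= 0:
            raise ParameterError("field dimensions must be positive")

    @property
    def times(self) -> np.ndarray:
        n_frames = int(math.floor(self.duration / self.frame_interval)) + 1
        return np.arange(n_frames) * self.frame_interval


@dataclass
class CellTrack:
    """Per-frame record of one cell: position, attachment state, lineage link."""

    cell_id: str
    phenotype: int
    times: np.ndarray
    xy: np.ndarray
    attached: np.ndarray
    parent_id: Optional[str] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.attached = np.asarray(self.attached, dtype=bool)
        if not (len(self.times) == len(self.xy) == len(self.attached)):
            raise ParameterError(f"track {self.cell_id}: per-frame arrays differ in length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ParameterError(f"track {self.cell_id}: frame times must be uniform and increasing")

    def __len__(self) -> int:
        return len(self.times)


def _reflect(x: np.ndarray, width: float) -> np.ndarray:
    """Fold an unbounded walk into [0, width] by reflection at the walls."""
    period = 2.0 * width
    w = np.mod(x, period)
    return np.where(w > width, period - w, w)


def simulate_attachment(mix: PhenotypeMix, cfg: SimConfig) -> List[CellTrack]:
    """Realise per-cell attachment tracks from a phenotype mixture.

    Each cell is assigned a phenotype by its number fraction and draws an
    exponential attachment waiting time at that phenotype's rate
    (event-driven; discretised to the frame grid afterwards, which avoids
    the per-frame Bernoulli bias of time-stepped schemes).  With nonzero
    detachment rates, attached cells detach at rate beta_i and re-enter the
    bulk pool.  Mobile cells perform a reflected random walk with diffusion
    coefficient ``cfg.diffusion_bulk``; attached cells sit at their landing
    position plus Gaussian jitter ``cfg.jitter_attached``.

    A phenotype with zero attachment rate simply never attaches.
    """
    rng = np.random.default_rng(cfg.seed)
    times = cfg.times
    n, n_frames = cfg.n_cells, len(times)
    dt = cfg.frame_interval

    phen = rng.choice(mix.k, size=n, p=mix.fractions)
    alphas = np.asarray(mix.attach_rates)[phen]
    betas = np.asarray(mix.detach_rates)[phen]

    if np.all(betas == 0.0):
        attached = _attached_grid_no_detach(rng, alphas, times)
    else:
        attached = _attached_grid_with_detach(rng, alphas, betas, times)

    xy = _positions(rng, attached, cfg)

    ids = [f"c{i:05d}" for i in range(n)]
    return [
        CellTrack(ids[i], int(phen[i]), times, xy[i], attached[i])
        for i in range(n)
    ]


def _attached_grid_no_detach(rng, alphas, times):
    scale = np.full_like(alphas, np.inf, dtype=float)
    pos = alphas > 0
    scale[pos] = 1.0 / alphas[pos]
    waits = np.where(pos, rng.exponential(scale=np.where(pos, scale, 1.0)), np.inf)
    return times[None, :] >= waits[:, None]


def _attached_grid_with_detach(rng, alphas, betas, times):
    """Per-cell alternating exponential attach/detach waits on [0, T].

    Attached stretches are marked when their end is drawn, so a stretch
    running past the movie end is covered by its (unobserved) detach time.
    """
    n, n_frames = len(alphas), len(times)
    horizon = times[-1]
    attached = np.zeros((n, n_frames), dtype=bool)
    for i in range(n):
        t, on = 0.0, False
        state = np.zeros(n_frames, dtype=bool)
        while t <= horizon:
            rate = betas[i] if on else alphas[i]
            if rate <= 0:
                if on:  # attached with no detachment: attached forever
                    state[times >= t] = True
                break
            t_next = t + rng.exponential(1.0 / rate)
            if on:
                state[(times >= t) & (times < t_next)] = True
            t, on = t_next, not on
        attached[i] = state
    return attached


def _positions(rng, attached, cfg):
    """Random-walk positions while mobile, frozen + jitter while attached."""
    n, n_frames = attached.shape
    dt = cfg.frame_interval
    step_sd = math.sqrt(2.0 * cfg.diffusion_bulk * dt)
    x0 = rng.uniform(low=(0.0, 0.0), high=cfg.field, size=(n, 2))
    steps = rng.normal(0.0, step_sd, size=(n, n_frames, 2))
    steps[:, 0, :] = 0.0
    # the step into frame f is suppressed only when the cell was already
    # attached at frame f-1; a cell attaching during (f-1, f] still walks
    # before landing, so its landing position differs from frame f-1
    mobile_into = ~attached[:, :-1]
    steps[:, 1:, :] *= mobile_into[:, :, None]
    path = x0[:, None, :] + np.cumsum(steps, axis=1)
    # re-freeze: while attached the position must not drift even if the cell
    # later detaches and resumes walking — cumsum already handles that because
    # zeroed steps contribute nothing during attached stretches.
    jitter = rng.normal(0.0, cfg.jitter_attached, size=(n, n_frames, 2))
    path = path + jitter * attached[:, :, None]
    path[:, :, 0] = _reflect(path[:, :, 0], cfg.field[0])
    path[:, :, 1] = _reflect(path[:, :, 1], cfg.field[1])
    return path


# --------------------------------------------------------------------------
# two-channel fluorescence
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelMap:
    """Monotone log-linear transfer from latent expression to one channel.

    The channel intensity is ``scale * exp(direction * gain * logsd * Z)``
    times multiplicative log-normal noise ``exp(noise_sd * W)``, where Z is
    the channel's standard-normal copula coordinate.  ``direction=+1`` gives
    an increasing readout (a direct stain), ``direction=-1`` a decreasing
    one (an inverted reporter).
    """

    direction: int
    scale: float = 1.0
    gain: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ParameterError("direction must be +1 or -1")
        if self.scale <= 0 or self.gain <= 0:
            raise ParameterError("scale and gain must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


def _default_channel_maps(latent_logsd: float, mean_au: float = 312.0) -> Dict[str, ChannelMap]:
    """Channels whose marginals are log-normal with the given arithmetic mean."""
    gain, noise = 1.0, 0.1
    var = (gain * latent_logsd) ** 2 + noise**2
    scale = mean_au / math.exp(var / 2.0)
    return {
        "egfp": ChannelMap(direction=-1, scale=scale, gain=gain, noise_sd=noise),
        "lectin": ChannelMap(direction=+1, scale=scale, gain=gain, noise_sd=noise),
    }


@dataclass
class FluorGenConfig:
    """Configuration of the bivariate inverted-reporter/stain generator.

    The latent expression is log-normal (single-cell intensity histograms
    are unimodal and right-skewed; log-normal is the conventional stand-in
    when no family is known).  ``target_pearson`` is the desired sample
    Pearson correlation between the two channels after transfer and noise;
    ``None`` couples both channels to the same latent draw (perfect copula).

    Defaults reproduce an inverted-reporter channel with arithmetic mean
    ~3.12e2 a.u. and CV ~0.99, the scale of typical background-subtracted
    single-cell measurements.
    """

    n_cells: int
    latent_logmean: float = 5.407   # ln a.u.; exp(mu + sigma^2/2) ~ 312 a.u.
    latent_logsd: float = 0.82
    channel_maps: Optional[Dict[str, ChannelMap]] = None
    target_pearson: Optional[float] = -0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.latent_logsd <= 0:
            raise ParameterError("latent_logsd must be positive")
        if self.target_pearson is not None and not (-1.0 < self.target_pearson < 1.0):
            raise ParameterError("target_pearson must lie strictly inside (-1, 1)")
        if self.channel_maps is None:
            self.channel_maps = _default_channel_maps(self.latent_logsd)
        if set(self.channel_maps) != {"egfp", "lectin"}:
            raise ParameterError("channel_maps must define exactly 'egfp' and 'lectin'")


def _lognormal_pair_pearson(a1: float, b1: float, a2: float, b2: float, rho: float) -> float:
    """Pearson correlation of (exp(a1 Z1 + b1 W1), exp(a2 Z2 + b2 W2)),
    corr(Z1, Z2) = rho, all other coordinates independent standard normal."""
    num = math.exp(a1 * a2 * rho) - 1.0
    den = math.sqrt((math.exp(a1**2 + b1**2) - 1.0) * (math.exp(a2**2 + b2**2) - 1.0))
    return num / den


def calibrate_copula_rho(cfg: FluorGenConfig) -> float:
    """Latent-normal correlation that yields ``cfg.target_pearson`` between
    the two channels after log-normal transfer and multiplicative noise.

    The bivariate log-normal correlation has a closed form, so the copula
    correlation is obtained by moment inversion rather than search.  Raises
    :class:`ParameterError` when the target is outside the attainable range
    for the configured channel maps (log-normal marginals bound how negative
    the Pearson correlation can be).
    """
    if cfg.target_pearson is None:
        return 1.0
    me, ml = cfg.channel_maps["egfp"], cfg.channel_maps["lectin"]
    a_e = me.direction * me.gain * cfg.latent_logsd
    a_l = ml.direction * ml.gain * cfg.latent_logsd
    den = math.sqrt(
        (math.exp(a_e**2 + me.noise_sd**2) - 1.0)
        * (math.exp(a_l**2 + ml.noise_sd**2) - 1.0)
    )
    arg = 1.0 + cfg.target_pearson * den
    if arg <= 0.0:
        raise ParameterError(
            f"target Pearson {cfg.target_pearson} unattainable for these channel maps"
        )
    rho = math.log(arg) / (a_e * a_l)
    if not -1.0 <= rho <= 1.0:
        raise ParameterError(
            f"target Pearson {cfg.target_pearson} requires copula correlation "
            f"{rho:.3f} outside [-1, 1]; weaken the noise or the target"
        )
    return rho


def simulate_fluorescence(cfg: FluorGenConfig, population: str = "bulk"):
    """Draw a per-cell two-channel fluorescence table.

    Returns a :class:`attachkin.hetero.FluorTable` whose ``meta`` records the
    calibrated copula correlation and, for n >= 1000, the realised sample
    Pearson correlation (``calibration_checked``); for smaller samples the
    check is skipped and flagged.
    """
    from scipy.optimize import brentq

    from .hetero import FluorTable  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    rho_pop = calibrate_copula_rho(cfg)  # also rejects unattainable targets

    z_l = rng.standard_normal(cfg.n_cells)
    z_ind = rng.standard_normal(cfg.n_cells)
    noise = {
        name: m.noise_sd * rng.standard_normal(cfg.n_cells) if m.noise_sd > 0 else 0.0
        for name, m in cfg.channel_maps.items()
    }

    def channel(name: str, z: np.ndarray) -> np.ndarray:
        m = cfg.channel_maps[name]
        return m.scale * np.exp(m.direction * m.gain * cfg.latent_logsd * z + noise[name])

    def realise(rho: float):
        z_e = rho * z_l + math.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
        return channel("egfp", z_e), channel("lectin", z_l)

    # With heavy-tailed marginals the sample Pearson scatters around the
    # population value, so the copula correlation is refined by a
    # one-dimensional search until the *realised* sample correlation of this
    # draw hits the target; the closed-form population value seeds the
    # search and serves as fallback for tiny samples.
    rho = rho_pop
    if cfg.target_pearson is not None and cfg.n_cells >= 10:

        def gap(r: float) -> float:
            e, l = realise(r)
            return float(np.corrcoef(e, l)[0, 1]) - cfg.target_pearson

        lo, hi = -1.0 + 1e-9, 1.0 - 1e-9
        try:
            if gap(lo) * gap(hi) < 0:
                rho = brentq(gap, lo, hi, xtol=1e-10)
        except ValueError:  # pragma: no cover - no sign change: keep fallback
            rho = rho_pop

    egfp, lectin = realise(rho)
    latent = np.exp(cfg.latent_logmean + cfg.latent_logsd * z_l)

    data = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(cfg.n_cells)],
            "population": population,
            "egfp_au": egfp,
            "lectin_au": lectin,
            "latent_au": latent,
        }
    )
    meta: dict = {
        "copula_rho": rho,
        "copula_rho_population": rho_pop,
        "target_pearson": cfg.target_pearson,
    }
    if cfg.n_cells >= 1000:
        meta["calibration_checked"] = True
        meta["realized_pearson"] = float(np.corrcoef(egfp, lectin)[0, 1])
    else:
        meta["calibration_checked"] = False
        meta["flag"] = "n < 1000: calibration check skipped"
    return FluorTable(data, meta=meta)


# --------------------------------------------------------------------------
# lineage trees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageGenConfig:
    """Configuration of the genealogical-tree generator.

    Founders divide at exponentially distributed intervals (the interval
    distribution is a modelling choice; only its mean is constrained by the
    data the generator emulates).  At each division an independent fate is
    drawn from ``fate_probs = (p_both_stay, p_one_stays, p_both_leave)``:
    "leave" daughters detach and terminate, "stay" daughters continue
    dividing until ``duration``.  Daughters observed for less than
    ``censor_window`` seconds before the movie ends are censored.
    """

    n_founders: int
    fate_probs: Tuple[float, float, float]
    mean_division_interval: float
    duration: float
    seed: int = 0
    censor_window: float = 9.0  # s; 3 frames at the default 3-s interval

    def __post_init__(self):
        if self.n_founders < 1:
            raise ParameterError("n_founders must be >= 1")
        p = tuple(float(x) for x in self.fate_probs)
        object.__setattr__(self, "fate_probs", p)
        if len(p) != 3 or any(x < 0 for x in p):
            raise ParameterError("fate_probs must be three nonnegative numbers")
        if abs(sum(p) - 1.0) > 1e-12:
            raise ParameterError(f"fate_probs must sum to 1, got {sum(p)!r}")
        if self.mean_division_interval <= 0 or self.duration <= 0:
            raise ParameterError("mean_division_interval and duration must be positive")
        if self.censor_window < 0:
            raise ParameterError("censor_window must be nonnegative")


def simulate_lineage(cfg: LineageGenConfig) -> LineageForest:
    """Grow a forest of division trees with drawn postdivision fates.

    A duration shorter than every drawn division interval yields a valid
    forest with zero divisions; downstream estimators must handle
    ``n_div == 0``.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes: Dict[str, LineageNode] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"n{counter:06d}"

    # queue of attached cells still eligible to divide: (id, t_birth)
    queue: List[Tuple[str, float]] = []
    for _ in range(cfg.n_founders):
        nid = new_id()
        nodes[nid] = LineageNode(nid, None, 0.0)
        queue.append((nid, 0.0))

    while queue:
        nid, t0 = queue.pop()
        t_div = t0 + rng.exponential(cfg.mean_division_interval)
        if t_div > cfg.duration:
            # never divides within the movie: stay if observed long enough
            nodes[nid].fate = (
                "stay" if cfg.duration - t0 >= cfg.censor_window else "censored"
            )
            continue
        nodes[nid].t_division = t_div
        nodes[nid].fate = "stay"
        category = rng.choice(3, p=cfg.fate_probs)
        if category == 0:
            daughter_fates = ["stay", "stay"]
        elif category == 2:
            daughter_fates = ["leave", "leave"]
        else:
            daughter_fates = ["stay", "leave"]
            rng.shuffle(daughter_fates)
        for f in daughter_fates:
            did = new_id()
            if f == "leave":
                nodes[did] = LineageNode(did, nid, t_div, fate="leave")
            else:
                nodes[did] = LineageNode(did, nid, t_div, fate="stay")
                queue.append((did, t_div))
    forest = LineageForest(nodes)
    return forest


def forest_to_tracks(
    forest: LineageForest,
    duration: float,
    frame_interval: float = 3.0,
    field: Tuple[float, float] = (165.0, 139.0),
    jitter: float = 0.05,
    seed: int = 0,
) -> List[CellTrack]:
    """Render a lineage forest as per-frame surface tracks.

    Every node becomes a short track on the global frame grid: attached at a
    fixed (jittered) position from birth until it divides, detaches or the
    movie ends.  "Leave" nodes get one final detached frame so that the
    detach transition is present in the record.  This is the inverse of
    :func:`attachkin.tracks.extract_division_events` up to frame rounding.
    """
    rng = np.random.default_rng(seed)
    tracks: List[CellTrack] = []
    grid = np.arange(int(math.floor(duration / frame_interval)) + 1) * frame_interval
    anchors: Dict[str, np.ndarray] = {}
    for nid, node in forest.nodes.items():
        if node.parent is None:
            anchors[nid] = rng.uniform((0.0, 0.0), field)
    # children inherit the mother's anchor plus a small offset
    for nid, node in sorted(forest.nodes.items()):
        if node.parent is not None:
            anchors[nid] = anchors[node.parent] + rng.normal(0.0, 1.0, size=2)

    for nid, node in sorted(forest.nodes.items()):
        if node.t_division is not None:
            t_end = node.t_division
        elif node.fate == "leave":
            t_end = min(node.t_birth + frame_interval, duration)
        else:
            t_end = duration
        sel = (grid >= node.t_birth) & (grid <= t_end + 1e-9)
        times = grid[sel]
        if len(times) == 0:
            idx = int(np.searchsorted(grid, node.t_birth))
            idx = min(idx, len(grid) - 1)
            times = grid[idx : idx + 1]
        attached = np.ones(len(times), dtype=bool)
        if node.fate == "leave":
            attached[-1] = False
        xy = anchors[nid][None, :] + rng.normal(0.0, jitter, size=(len(times), 2))
        tracks.append(
            CellTrack(nid, 0, times, xy, attached, parent_id=node.parent)
        )
    return tracks


# --------------------------------------------------------------------------
# biofilm thickness maps
# --------------------------------------------------------------------------

def simulate_heightmap(
    mean_thickness: float,
    roughness_target: float,
    grid: Tuple[int, int] = (64, 64),
    seed: int = 0,
    correlation_length: float = 4.0,
):
    """Generate a smooth positive thickness grid with calibrated summaries.

    The grid is the exponential of a Gaussian random field (white noise
    smoothed over ``correlation_length`` pixels) — positive by construction
    and right-skewed, like real local-thickness maps.  The exponent scale is
    calibrated by a one-dimensional root search so that the roughness
    coefficient mean(|L - mean|)/mean of the realised grid equals
    ``roughness_target`` (to root-solver precision) and the grid mean equals
    ``mean_thickness`` exactly.  Targets beyond the construction's reachable
    roughness (~1.9) raise :class:`ParameterError`.
    """
    from scipy.ndimage import gaussian_filter
    from scipy.optimize import brentq

    from .biofilm import HeightMap

    if mean_thickness <= 0:
        raise ParameterError("mean_thickness must be positive")
    if roughness_target < 0:
        raise ParameterError("roughness_target must be nonnegative")
    rng = np.random.default_rng(seed)
    if roughness_target == 0.0:
        return HeightMap(np.full(grid, float(mean_thickness)))
    f = gaussian_filter(rng.standard_normal(grid), sigma=correlation_length)
    f = (f - f.mean()) / f.std()

    def realised_roughness(c: float) -> float:
        g = np.exp(c * f)
        g *= mean_thickness / g.mean()
        return float(np.mean(np.abs(g - mean_thickness)) / mean_thickness)

    c_hi = 12.0
    if roughness_target > realised_roughness(c_hi):
        raise ParameterError(
            f"roughness_target {roughness_target} exceeds the reachable "
            f"roughness {realised_roughness(c_hi):.3f} of this construction"
        )
    c = brentq(lambda c: realised_roughness(c) - roughness_target, 1e-9, c_hi, xtol=1e-12)
    values = np.exp(c * f)
    values *= mean_thickness / values.mean()
    return HeightMap(values)
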