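"""Synthetic two-photon odor-response data with full ground truth.

Emulates the structure of awake-anesthetized piriform-cortex imaging
experiments: 30 s odor trials (8 s baseline, 2 s odor, 20 s post) at ~15 Hz,
4 trials per stimulus, with either a 13-odorant panel at a single dilution or
a 3 odorants x 3 log-spaced dilutions concentration series.  Cells fall into
functional categories with known proportions:

``null``
    no stimulus-locked modulation (pure trial noise);
``identity_only``
    odorant-selective response whose per-odorant mean is identical across
    concentrations (the concentration-invariant subpopulation);
``concentration_modulated``
    responds only at dilutions at or above a per-cell recruitment threshold;
``mixed``
    response pattern redrawn independently per odorant-dilution pair
    (identity x concentration interaction);
``suppressed``
    negative-going transients whose magnitude ramps with concentration.

Calcium dynamics use an instant-rise exponential kernel exp(-t/tau) with
tau = 2 s (GCaMP6s-like).  Each responsive cell-stimulus pair fires one
onset-locked event per trial with probability ``p_respond``; its amplitude is
drawn once per cell-stimulus and jittered per trial.  Movies add an annular
("donut", nuclear-excluded) radial intensity profile per cell, a smooth
correlated neuropil background, a slow sinusoidal drift and white pixel
noise.  Every random draw flows from a single seed through fixed-purpose
``numpy`` child generators, so the category/mean structure is shared between
the table, trace and movie generators for the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import Movie, ResponseTable, TrialLayout, TrialTensor


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without mask overlap."""


def concentration_series() -> list[tuple[str, float]]:
    """3 odorants x 3 ten-fold dilutions (1:10,000, 1:1,000, 1:100 vol/vol)."""
    odors = ["acetophenone", "ethyl_acetate", "hexanone"]
    dilutions = [1e-4, 1e-3, 1e-2]
    return [(o, d) for o in odors for d in dilutions]


def odor_panel(n_odorants: int = 13, dilution: float = 1e-4
               ) -> list[tuple[str, float]]:
    """A monomolecular odorant panel at a single dilution."""
    return [(f"odor_{i:02d}", dilution) for i in range(n_odorants)]


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment (defaults = study conditions)."""

    field_size: tuple[int, int] = (64, 64)          # rows, cols (pixels)
    pixel_size: float = 1.36                        # um / pixel
    frame_rate: float = 15.0                        # Hz
    n_cells: int = 300
    cell_radius: float = 5.0                        # um
    trial_layout: TrialLayout = field(default_factory=TrialLayout)
    n_trials_per_stimulus: int = 4
    stimulus_set: list[tuple[str, float]] = field(
        default_factory=concentration_series)
    fraction_activated: float = 0.20
    fraction_suppressed: float = 0.11
    fraction_invariant: float = 0.10
    fraction_mixed: float = 0.05
    response_amplitude_mean: float = 1.0            # dF/F peak
    response_amplitude_sd: float = 0.3
    trial_noise_sd: float = 0.2                     # dF/F units (scalar responses)
    trace_noise_sd: float = 0.05                    # dF/F units (per frame)
    p_respond: float = 0.75                         # per-trial event probability
    amplitude_jitter: float = 0.15                  # per-trial relative jitter
    kernel_tau: float = 2.0                         # s
    neuropil_amplitude: float = 0.1                 # dF/F units
    drift_period: float = 300.0                     # s
    drift_amplitude: float = 0.05
    pixel_noise_sd: float = 0.03
    spontaneous_rate_hz: float = 0.05               # background events (movies)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.fraction_activated, self.fraction_suppressed,
                 self.fraction_invariant, self.fraction_mixed)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.fraction_activated + self.fraction_suppressed > 1 + 1e-12:
            raise ConfigurationError(
                "fraction_activated + fraction_suppressed must be <= 1")
        if self.fraction_invariant + self.fraction_mixed > \
                self.fraction_activated + 1e-12:
            raise ConfigurationError(
                "invariant + mixed fractions cannot exceed fraction_activated")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if not self.stimulus_set:
            raise ConfigurationError("stimulus_set must be non-empty")
        if self.kernel_tau <= 0:
            raise ConfigurationError("kernel_tau must be positive")

    @property
    def odorants(self) -> list[str]:
        seen: dict[str, None] = {}
        for o, _ in self.stimulus_set:
            seen.setdefault(o)
        return list(seen)

    @property
    def dilutions(self) -> list[float]:
        return sorted({d for _, d in self.stimulus_set})

    def frames_per_trial(self) -> int:
        return self.trial_layout.n_frames(self.frame_rate)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    category: np.ndarray                       # (n_cells,) strings
    true_response_means: np.ndarray            # (n_cells, n_stimuli)
    stimuli: list[tuple[str, float]]
    preferred_odorant: np.ndarray              # (n_cells,) strings ('' = none)
    event_times: np.ndarray | None = None      # (cells, stim, trials), s; NaN
    cell_masks: list[tuple[np.ndarray, np.ndarray]] | None = None
    centers: np.ndarray | None = None          # (n_cells, 2) row, col (px)
    profiles: list[np.ndarray] | None = None   # per-cell pixel amplitudes

    @property
    def n_cells(self) -> int:
        return len(self.category)


# --------------------------------------------------------------------------
# category / mean-structure machinery (shared by all generators)
# --------------------------------------------------------------------------

def _child_rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    names = ("structure", "table", "traces", "movie")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _assign_categories(rng: np.random.Generator, config: SimConfig
                       ) -> np.ndarray:
    n = config.n_cells
    n_inv = int(round(config.fraction_invariant * n))
    n_mix = int(round(config.fraction_mixed * n))
    n_act = int(round(config.fraction_activated * n))
    n_sup = int(round(config.fraction_suppressed * n))
    n_cm = n_act - n_inv - n_mix
    if n_cm < 0 or n_act + n_sup > n:
        raise ConfigurationError("category counts inconsistent with n_cells")
    cats = (["identity_only"] * n_inv + ["mixed"] * n_mix +
            ["concentration_modulated"] * n_cm + ["suppressed"] * n_sup)
    cats += ["null"] * (n - len(cats))
    cats = np.array(cats, dtype=object)
    rng.shuffle(cats)
    return cats


def _draw_amplitude(rng: np.random.Generator, config: SimConfig) -> float:
    a = rng.normal(config.response_amplitude_mean, config.response_amplitude_sd)
    return max(a, 0.2 * config.response_amplitude_mean)


def _draw_tuning(rng: np.random.Generator, config: SimConfig,
                 odorants: list[str]) -> tuple[np.ndarray, str]:
    """Sparse per-odorant amplitudes with one clear preferred odorant."""
    amp = _draw_amplitude(rng, config)
    a = np.zeros(len(odorants))
    pref = rng.integers(len(odorants))
    a[pref] = amp
    for j in range(len(odorants)):
        if j != pref and rng.random() < 0.3:
            a[j] = amp * rng.uniform(0.2, 0.8)
    return a, odorants[pref]


def _true_means(rng: np.random.Generator, config: SimConfig,
                categories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell expected response for every stimulus in stimulus_set order."""
    odorants = config.odorants
    dilutions = config.dilutions
    odor_idx = {o: i for i, o in enumerate(odorants)}
    dil_idx = {d: i for i, d in enumerate(dilutions)}
    n_dil = len(dilutions)
    means = np.zeros((config.n_cells, len(config.stimulus_set)))
    preferred = np.full(config.n_cells, "", dtype=object)

    for c, cat in enumerate(categories):
        if cat == "null":
            continue
        grid = np.zeros((len(odorants), n_dil))
        if cat == "identity_only":
            a, pref = _draw_tuning(rng, config, odorants)
            grid[:] = a[:, None]                      # constant across dilution
        elif cat == "concentration_modulated":
            a, pref = _draw_tuning(rng, config, odorants)
            thr = rng.integers(1, n_dil) if n_dil > 1 else 0
            grid[:, thr:] = a[:, None]                # recruited above threshold
        elif cat == "mixed":
            amp = _draw_amplitude(rng, config)
            hit = rng.random(grid.shape) < 0.4
            grid = hit * amp * rng.uniform(0.3, 1.0, grid.shape)
            if not grid.any():
                grid[rng.integers(len(odorants)), rng.integers(n_dil)] = amp
            pref = odorants[int(np.argmax(grid.max(axis=1)))]
        elif cat == "suppressed":
            # suppression is odor-unspecific and deepens with concentration
            amp = _draw_amplitude(rng, config)
            ramp = np.linspace(0.3, 1.0, n_dil)
            grid = np.broadcast_to(-0.6 * amp * ramp[None, :],
                                   grid.shape).copy()
            pref = ""
        else:  # pragma: no cover - unknown label guard
            raise ConfigurationError(f"unknown category {cat!r}")
        preferred[c] = pref
        for s, (o, d) in enumerate(config.stimulus_set):
            means[c, s] = grid[odor_idx[o], dil_idx[d]]
    return means, preferred


def _structure(config: SimConfig, rngs: dict[str, np.random.Generator]
               ) -> GroundTruth:
    cats = _assign_categories(rngs["structure"], config)
    means, preferred = _true_means(rngs["structure"], config, cats)
    return GroundTruth(category=cats, true_response_means=means,
                       stimuli=list(config.stimulus_set),
                       preferred_odorant=preferred)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_response_dataset(config: SimConfig
                              ) -> tuple[ResponseTable, GroundTruth]:
    """Per-trial scalar responses: true mean + i.i.d. Gaussian trial noise."""
    rngs = _child_rngs(config)
    gt = _structure(config, rngs)
    n_trials = config.n_trials_per_stimulus
    shape = (config.n_cells, len(config.stimulus_set), n_trials)
    responses = gt.true_response_means[:, :, None] + np.zeros(shape)
    if config.trial_noise_sd > 0:
        responses = responses + rngs["table"].normal(
            0.0, config.trial_noise_sd, shape)
    table = ResponseTable.from_array(responses, config.stimulus_set)
    return table, gt


def _exp_kernel(config: SimConfig, n_frames: int) -> np.ndarray:
    t = np.arange(n_frames) / config.frame_rate
    return np.exp(-t / config.kernel_tau)


def _event_trains(config: SimConfig, gt: GroundTruth,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Onset-locked per-trial event amplitudes and times.

    Returns (amps, times), both (n_cells, n_stimuli, n_trials); amp 0 and
    time NaN where no event fired.
    """
    n_trials = config.n_trials_per_stimulus
    shape = (config.n_cells, len(config.stimulus_set), n_trials)
    fires = rng.random(shape) < config.p_respond
    fires &= (gt.true_response_means != 0)[:, :, None]
    jitter = 1.0 + rng.normal(0.0, config.amplitude_jitter, shape)
    amps = np.where(fires, gt.true_response_means[:, :, None] * jitter, 0.0)
    times = np.where(fires, config.trial_layout.pre_s, np.nan)
    return amps, times


def generate_trial_traces(config: SimConfig
                          ) -> tuple[TrialTensor, GroundTruth]:
    """Per-cell dF/F traces, one transient per responsive trial at odor onset."""
    rngs = _child_rngs(config)
    gt = _structure(config, rngs)
    n_frames = config.frames_per_trial()
    onset = config.trial_layout.onset_frame(config.frame_rate)
    kernel = _exp_kernel(config, n_frames - onset)
    amps, times = _event_trains(config, gt, rngs["traces"])
    traces = np.zeros(amps.shape + (n_frames,))
    traces[:, :, :, onset:] = amps[..., None] * kernel
    if config.trace_noise_sd > 0:
        traces += rngs["traces"].normal(0.0, config.trace_noise_sd,
                                        traces.shape)
    gt.event_times = times
    tensor = TrialTensor(data=traces, stimuli=list(config.stimulus_set),
                         frame_rate=config.frame_rate,
                         layout=config.trial_layout)
    return tensor, gt


def _place_cells(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers; (n_cells, 2) row/col."""
    rows, cols = config.field_size
    r_px = config.cell_radius / config.pixel_size
    margin = r_px + 1
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise PlacementError("field too small for the requested cell radius")
    centers: list[np.ndarray] = []
    min_sep2 = (2 * r_px + 1.0) ** 2
    attempts = 0
    max_attempts = 500 * config.n_cells
    while len(centers) < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {config.n_cells} non-overlapping cells "
                f"in a {rows}x{cols} field")
        c = np.array([rng.uniform(margin, rows - margin),
                      rng.uniform(margin, cols - margin)])
        if all(((c - p) ** 2).sum() >= min_sep2 for p in centers):
            centers.append(c)
    return np.array(centers)


def _donut_profile(center: np.ndarray, r_px: float, shape: tuple[int, int]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel indices and annular amplitude profile for one cell.

    The profile peaks at ~0.55 R, is dimmer in the (nucleus-like) center and
    falls off toward the membrane edge (point-spread blur), so per-pixel
    signal amplitudes inside a mask are genuinely non-uniform and border
    pixels carry the least signal.
    """
    r0, c0 = center
    rr = np.arange(int(np.floor(r0 - r_px)), int(np.ceil(r0 + r_px)) + 1)
    cc = np.arange(int(np.floor(c0 - r_px)), int(np.ceil(c0 + r_px)) + 1)
    rr = rr[(rr >= 0) & (rr < shape[0])]
    cc = cc[(cc >= 0) & (cc < shape[1])]
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    dist = np.hypot(grid_r - r0, grid_c - c0)
    inside = dist <= r_px
    prof = 0.1 + 0.9 * np.exp(-((dist - 0.55 * r_px) ** 2)
                              / (2 * (0.22 * r_px) ** 2))
    return grid_r[inside], grid_c[inside], prof[inside]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_px: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    f = gaussian_filter(rng.normal(size=shape), sigma_px)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return 0.5 + f          # positive, spatially smooth, O(1)


def _slow_signal(rng: np.random.Generator, n_frames: int, frame_rate: float
                 ) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d
    s = gaussian_filter1d(rng.normal(size=n_frames), 5.0 * frame_rate)
    sd = s.std()
    return s / sd if sd > 0 else s


def generate_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Simulated recording: planted cells + neuropil + drift + pixel noise.

    The movie concatenates all trials (stimulus-major order) of the config's
    stimulus set.  Cells additionally fire spontaneous (stimulus-unlocked)
    events at ``spontaneous_rate_hz`` so that even unresponsive cells carry
    enough activity to be segmentable, as real neurons do.
    """
    rngs = _child_rngs(config)
    gt = _structure(config, rngs)
    rng = rngs["movie"]

    n_frames_trial = config.frames_per_trial()
    n_stim = len(config.stimulus_set)
    n_trials = config.n_trials_per_stimulus
    n_frames = n_frames_trial * n_stim * n_trials
    rows, cols = config.field_size
    r_px = config.cell_radius / config.pixel_size

    centers = _place_cells(config, rng)
    onset = config.trial_layout.onset_frame(config.frame_rate)
    kernel = _exp_kernel(config, n_frames_trial - onset)
    amps, times = _event_trains(config, gt, rngs["traces"])
    gt.event_times = times

    # per-cell dF/F time course over the whole session
    dff = np.zeros((config.n_cells, n_frames))
    for s in range(n_stim):
        for tr in range(n_trials):
            start = (s * n_trials + tr) * n_frames_trial + onset
            seg = dff[:, start:start + kernel.size]
            seg += amps[:, s, tr, None] * kernel
    # spontaneous events, one long kernel per event
    spont_kernel = _exp_kernel(config, int(10 * config.kernel_tau
                                           * config.frame_rate))
    p_frame = config.spontaneous_rate_hz / config.frame_rate
    if p_frame > 0:
        for c in range(config.n_cells):
            ev = np.flatnonzero(rng.random(n_frames) < p_frame)
            for t0 in ev:
                a = 0.5 * _draw_amplitude(rng, config)
                stop = min(n_frames, t0 + spont_kernel.size)
                dff[c, t0:stop] += a * spont_kernel[:stop - t0]

    baseline = rng.uniform(0.7, 1.3, config.n_cells)
    elevated = np.where(gt.category == "suppressed", 1.5, 1.0)
    cell_f = (baseline * elevated)[:, None] * (1.0 + dff)

    movie = np.full((n_frames, rows, cols), 0.2)     # background level
    masks, profiles = [], []
    for c in range(config.n_cells):
        rr, cc, prof = _donut_profile(centers[c], r_px, (rows, cols))
        masks.append((rr, cc))
        profiles.append(prof)
        movie[:, rr, cc] += prof[None, :] * cell_f[c][:, None]

    if config.neuropil_amplitude > 0:
        npf = _smooth_field(rng, (rows, cols), sigma_px=8.0)
        slow = _slow_signal(rng, n_frames, config.frame_rate)
        movie += config.neuropil_amplitude * slow[:, None, None] * npf
    if config.drift_amplitude > 0:
        t = np.arange(n_frames) / config.frame_rate
        movie += config.drift_amplitude * np.sin(
            2 * np.pi * t / config.drift_period)[:, None, None]
    if config.pixel_noise_sd > 0:
        movie += rng.normal(0.0, config.pixel_noise_sd, movie.shape)
    np.clip(movie, 0.0, None, out=movie)

    gt.cell_masks = masks
    gt.centers = centers
    gt.profiles = profiles
    return (Movie(data=movie, frame_rate=config.frame_rate,
                  pixel_size=config.pixel_size), gt)


# --------------------------------------------------------------------------
# ground-truth serialization (masks as run-length-encoded pixel lists)
# --------------------------------------------------------------------------

def _rle_encode(rr: np.ndarray, cc: np.ndarray, n_cols: int) -> list[list[int]]:
    flat = np.sort(rr.astype(int) * n_cols + cc.astype(int))
    runs: list[list[int]] = []
    for v in flat:
        if runs and v == runs[-1][0] + runs[-1][1]:
            runs[-1][1] += 1
        else:
            runs.append([int(v), 1])
    return runs


def _rle_decode(runs: list[list[int]], n_cols: int
                ) -> tuple[np.ndarray, np.ndarray]:
    flat = np.concatenate([np.arange(s, s + l) for s, l in runs]) \
        if runs else np.array([], dtype=int)
    return flat // n_cols, flat % n_cols


def write_ground_truth(gt: GroundTruth, path: str | Path,
                       field_size: tuple[int, int] | None = None) -> None:
    obj: dict = {
        "category": list(gt.category),
        "true_response_means": gt.true_response_means.tolist(),
        "stimuli": [[o, d] for o, d in gt.stimuli],
        "preferred_odorant": list(gt.preferred_odorant),
    }
    if gt.event_times is not None:
        obj["event_times"] = np.where(np.isnan(gt.event_times), None,
                                      gt.event_times).tolist()
    if gt.cell_masks is not None:
        if field_size is None:
            raise ValueError("field_size required to RLE-encode masks")
        obj["field_size"] = list(field_size)
        obj["cell_masks_rle"] = [_rle_encode(rr, cc, field_size[1])
                                 for rr, cc in gt.cell_masks]
        obj["centers"] = gt.centers.tolist()
    Path(path).write_text(json.dumps(obj))


def read_ground_truth(path: str | Path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    gt = GroundTruth(
        category=np.array(obj["category"], dtype=object),
        true_response_means=np.array(obj["true_response_means"]),
        stimuli=[(o, float(d)) for o, d in obj["stimuli"]],
        preferred_odorant=np.array(obj["preferred_odorant"], dtype=object),
    )
    if "event_times" in obj:
        gt.event_times = np.array(
            [[[np.nan if v is None else v for v in tr] for tr in s]
             for s in obj["event_times"]], dtype=float)
    if "cell_masks_rle" in obj:
        n_cols = obj["field_size"][1]
        gt.cell_masks = [_rle_decode(r, n_cols) for r in obj["cell_masks_rle"]]
        gt.centers = np.array(obj["centers"])
    return gt
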