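"""Fluorescence trace extraction, dF/F, deconvolution and response detection.

Converts a registered movie plus a segmentation into per-trial traces:

1. rigid sub-pixel motion correction by Fourier cross-correlation;
2. weighted pixel averaging inside each ROI;
3. neuropil correction F_true = F_measured - r * F_neuropil (r = 0.5), with
   the neuropil signal averaged over a 20 um disk around the cell center
   excluding all ROI pixels;
4. dF/F against F0 = median fluorescence of seconds 4-8 of the pre-stimulus
   baseline of each trial;
5. linear deconvolution r(t) = f'(t) + f(t)/tau (tau = 2 s, GCaMP6s),
   low-pass filtered with a zero-phase four-pole Butterworth at 2.5 Hz;
6. run-length response detection: a trial is called activated (suppressed)
   if dF/F stays above +2 SD (below -2 SD) of its baseline for at least 21
   (19) consecutive frames starting within the 4 s after odor onset.

The detection thresholds were originally calibrated by ROC analysis against
blank (no-stimulus) trials; ``calibrate_threshold_roc`` reproduces that
procedure on labeled synthetic data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps
from skimage.registration import phase_cross_correlation

from .core import Movie, TrialLayout, TrialTensor
from .segmentation import RegionSet


@dataclass
class DetectionParams:
    """Run-length response-detection parameters.

    Run lengths (21 frames activation / 19 suppression) were calibrated at
    the reference 15 Hz acquisition rate and are rescaled proportionally for
    other frame rates.
    """

    threshold_multiplier: float = 2.0       # baseline-SD units
    run_activation: int = 21                # frames at reference_rate
    run_suppression: int = 19
    response_window: float = 4.0            # s after odor onset
    reference_rate: float = 15.0            # Hz

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if min(self.run_activation, self.run_suppression) < 1:
            raise ValueError("run lengths must be >= 1")

    def runs_at_rate(self, frame_rate: float) -> tuple[int, int]:
        scale = frame_rate / self.reference_rate
        return (max(1, int(round(self.run_activation * scale))),
                max(1, int(round(self.run_suppression * scale))))


# --------------------------------------------------------------------------
# motion correction
# --------------------------------------------------------------------------

def register_frames(movie: Movie, upsample_factor: int = 10,
                    n_reference_frames: int = 100
                    ) -> tuple[Movie, np.ndarray]:
    """Sub-pixel rigid registration against the mean of the first frames."""
    if movie.n_frames < 2:
        raise ValueError("need at least two frames to register")
    ref = movie.data[:min(n_reference_frames, movie.n_frames)].mean(axis=0)
    registered = np.empty_like(movie.data, dtype=float)
    shifts = np.zeros((movie.n_frames, 2))
    for i, frame in enumerate(movie.data):
        if not frame.any():
            warnings.warn(f"frame {i} is all zero; zero shift assumed",
                          stacklevel=2)
            registered[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None)
        shifts[i] = shift
        registered[i] = np.real(np.fft.ifft2(
            ndimage.fourier_shift(np.fft.fft2(frame), shift)))
    return (Movie(data=registered, frame_rate=movie.frame_rate,
                  pixel_size=movie.pixel_size), shifts)


# --------------------------------------------------------------------------
# trace extraction and neuropil correction
# --------------------------------------------------------------------------

def extract_traces(movie: Movie, regions: RegionSet) -> np.ndarray:
    """Weighted in-ROI pixel averages, (n_regions, n_frames).

    F(t) = sum_i w_i x_i(t) / sum_i w_i; uniform weights reduce to the plain
    mean over region pixels.
    """
    t = movie.n_frames
    out = np.empty((len(regions.pixels), t))
    for k, rid in enumerate(regions.region_ids):
        rr, cc = regions.pixels[rid]
        w = regions.weights.get(rid)
        if w is None:
            w = np.full(len(rr), 1.0 / len(rr))
        total = w.sum()
        if total == 0:
            raise ValueError(f"region {rid} has all-zero weights")
        out[k] = movie.data[:, rr, cc] @ (w / total)
    return out


def neuropil_correct(traces: np.ndarray, movie: Movie, regions: RegionSet,
                     radius_um: float = 20.0, r: float = 0.5) -> np.ndarray:
    """Subtract r x (local neuropil signal) from each region's trace."""
    if r == 0:
        return traces.copy()
    rows, cols = movie.shape[1:]
    roi = regions.labels > 0
    grid_r, grid_c = np.mgrid[0:rows, 0:cols]
    radius_px = radius_um / movie.pixel_size
    corrected = traces.copy()
    for k, rid in enumerate(regions.region_ids):
        rr, cc = regions.pixels[rid]
        center = (rr.mean(), cc.mean())
        disk = (np.hypot(grid_r - center[0], grid_c - center[1])
                <= radius_px) & ~roi
        if not disk.any():
            warnings.warn(f"region {rid}: neuropil disk empty, "
                          "correction skipped", stacklevel=2)
            continue
        f_np = movie.data[:, disk].mean(axis=1)
        corrected[k] = traces[k] - r * f_np
    return corrected


# --------------------------------------------------------------------------
# dF/F and deconvolution
# --------------------------------------------------------------------------

def compute_dff(trace: np.ndarray, frame_rate: float,
                layout: TrialLayout = TrialLayout(),
                f0_window: tuple[float, float] = (4.0, 8.0)
                ) -> np.ndarray:
    """Per-trial dF/F; F0 = median fluorescence of seconds 4-8 of baseline.

    ``trace`` may be any array whose last axis is the within-trial frame
    axis.  Trials whose F0 is non-positive are marked invalid (all-NaN).
    """
    if layout.pre_s < f0_window[1]:
        raise ValueError("pre-stimulus period shorter than the F0 window")
    lo = int(round(f0_window[0] * frame_rate))
    hi = int(round(f0_window[1] * frame_rate))
    f0 = np.median(trace[..., lo:hi], axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (trace - f0) / f0
    dff = np.where(f0 > 0, dff, np.nan)
    return dff


def deconvolve(dff: np.ndarray, tau: float, frame_rate: float,
               cutoff_hz: float = 2.5, order: int = 4,
               lowpass: bool = True) -> np.ndarray:
    """Linear deconvolution r(t) = f'(t) + f(t)/tau of the calcium signal.

    The derivative is the causal first difference scaled by the frame rate
    (an event raising f at frame n peaks in r at frame n); with
    ``lowpass=True`` the result is filtered forward-backward with a
    four-pole Butterworth at ``cutoff_hz`` so the response window is not
    delayed.  Exact left-inverse of exp(-t/tau) kernel convolution up to
    O(1/frame_rate) discretization error.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    f = np.asarray(dff, dtype=float)
    diff = np.diff(f, axis=-1, prepend=f[..., :1]) * frame_rate
    rate = diff + f / tau
    if lowpass:
        if frame_rate <= 2 * cutoff_hz:
            raise ValueError("frame_rate must exceed twice the filter cutoff")
        sos = sps.butter(order, cutoff_hz, fs=frame_rate, output="sos")
        rate = sps.sosfiltfilt(sos, rate, axis=-1)
    return rate


def convolve_events(event_frames: np.ndarray, amplitudes: np.ndarray,
                    n_frames: int, tau: float, frame_rate: float
                    ) -> np.ndarray:
    """Forward model: impulse train convolved with the exp(-t/tau) kernel."""
    f = np.zeros(n_frames)
    kernel = np.exp(-np.arange(n_frames) / (tau * frame_rate))
    for t0, a in zip(event_frames, amplitudes):
        f[t0:] += a * kernel[:n_frames - t0]
    return f


# --------------------------------------------------------------------------
# response detection
# --------------------------------------------------------------------------

def _has_run(above: np.ndarray, start_lo: int, start_hi: int,
             min_run: int, region_end: int) -> bool:
    """Is there a run of >= min_run True values starting in [start_lo,
    start_hi) and contained in [start_lo, region_end)?"""
    n = len(above)
    region_end = min(region_end, n)
    run_start = None
    for i in range(start_lo, region_end):
        if above[i]:
            if run_start is None:
                run_start = i
        else:
            run_start = None
        if run_start is not None and run_start < start_hi \
                and i - run_start + 1 >= min_run:
            return True
    return False


def detect_responses(dff: np.ndarray, frame_rate: float,
                     params: DetectionParams = DetectionParams(),
                     layout: TrialLayout = TrialLayout()) -> str:
    """Classify one trial's dF/F trace as 'act', 'sup' or 'none'.

    The baseline SD is taken over the full pre-stimulus period of the same
    trial; a response must stay beyond +/- k*SD for the configured number of
    consecutive frames, in a run starting within the response window and
    wholly inside [onset, onset + window + run].
    """
    onset = layout.onset_frame(frame_rate)
    window = int(round(params.response_window * frame_rate))
    run_act, run_sup = params.runs_at_rate(frame_rate)
    if window < max(run_act, run_sup):
        raise ValueError("response window shorter than the required run")
    if np.isnan(dff).all():
        return "none"
    sd = float(np.nanstd(dff[:onset]))
    thr = params.threshold_multiplier * sd
    trace = np.nan_to_num(dff, nan=0.0)
    if _has_run(trace > thr, onset, onset + window, run_act,
                onset + window + run_act):
        return "act"
    if _has_run(trace < -thr, onset, onset + window, run_sup,
                onset + window + run_sup):
        return "sup"
    return "none"


def detect_responses_tensor(tensor: TrialTensor,
                            params: DetectionParams = DetectionParams()
                            ) -> np.ndarray:
    """Per cell-stimulus-trial flags over a whole trial tensor."""
    n_cells, n_stim, n_trials, _ = tensor.data.shape
    flags = np.empty((n_cells, n_stim, n_trials), dtype=object)
    for c in range(n_cells):
        for s in range(n_stim):
            for t in range(n_trials):
                flags[c, s, t] = detect_responses(
                    tensor.data[c, s, t], tensor.frame_rate, params,
                    tensor.layout)
    return flags


# --------------------------------------------------------------------------
# ROC calibration of the detection threshold
# --------------------------------------------------------------------------

def calibrate_threshold_roc(trials: np.ndarray, labels: np.ndarray,
                            frame_rate: float,
                            k_grid: np.ndarray | list[float] = (1.0, 1.5, 2.0,
                                                                2.5, 3.0),
                            run_grid: np.ndarray | list[int] = (11, 16, 21,
                                                                26, 31),
                            layout: TrialLayout = TrialLayout()
                            ) -> dict:
    """Grid-search (threshold multiplier, run length) maximizing Youden's J.

    ``trials`` is (n_trials, n_frames) dF/F; ``labels`` marks planted
    responses (True) versus blank no-stimulus trials (False), the latter
    providing the false-positive rate.  Returns the chosen grid point with
    its sensitivity/specificity/accuracy/J.
    """
    labels = np.asarray(labels, dtype=bool)
    if not (~labels).any():
        raise ValueError("ROC calibration needs blank (negative) trials")
    best = None
    for k in k_grid:
        for run in run_grid:
            p = DetectionParams(threshold_multiplier=float(k),
                                run_activation=int(run),
                                run_suppression=int(run),
                                reference_rate=frame_rate)
            calls = np.array([detect_responses(tr, frame_rate, p, layout)
                              == "act" for tr in trials])
            tpr = calls[labels].mean() if labels.any() else 0.0
            fpr = calls[~labels].mean()
            j = tpr - fpr
            acc = (calls == labels).mean()
            cand = {"k": float(k), "run": int(run), "tpr": float(tpr),
                    "fpr": float(fpr), "youden_j": float(j),
                    "accuracy": float(acc)}
            if best is None or j > best["youden_j"]:
                best = cand
    return best
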