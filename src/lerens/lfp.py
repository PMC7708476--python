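"""LFP featurization and event detection.

Interictal epileptiform discharges (IEDs) are detected semi-supervisedly:
the LFP is segmented into snippets aligned to imaging frames, each snippet
is represented by its FFT magnitude spectrum (phase-invariant, so an event
is detected regardless of where it falls within the frame), and an online
kernelized perceptron (Gaussian RBF, σ = 1 on per-bin standardized
features) is trained from a small set of labeled frames, optionally refined
over interactive correction rounds.  Sharp-wave ripples (SPW-Rs) are
detected from ripple-band (100–225 Hz) Gabor-wavelet power exceeding
median + 12·MAD, gated to immobility epochs lasting at least 3 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .session import Session

__all__ = [
    "SpectrumMatrix",
    "EventSet",
    "PerceptronModel",
    "frame_spectra",
    "one_over_f_correct",
    "perceptron_fit",
    "refine_interactive",
    "detect_ieds",
    "ied_rate",
    "detect_spwr",
    "save_events",
    "load_events",
]

logger = logging.getLogger(__name__)


@dataclass
class SpectrumMatrix:
    """Per-frame magnitude spectra of the LFP (frames × frequency bins)."""

    values: np.ndarray
    freqs: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("magnitude spectra must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency bins must be strictly increasing")


@dataclass
class EventSet:
    """Detected LFP events on the imaging-frame clock."""

    frames: np.ndarray          # sorted unique event frame indices
    kind: str                   # "IED" or "SPWR"
    peak_samples: np.ndarray | None = None  # per-event LFP-clock peak

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if self.frames.size and np.any(np.diff(np.sort(self.frames)) == 0):
            raise ValueError("event frames must be unique")
        self.frames = np.sort(self.frames)

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class PerceptronModel:
    """Online kernelized perceptron over standardized frame spectra."""

    support: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    coef: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma: float = 1.0
    feat_mean: np.ndarray | None = None
    feat_sd: np.ndarray | None = None
    labeled: dict | None = None   # frame -> bool, as trained
    passes: int = 5

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_sd

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Kernel score; > 0 is the positive (event) class."""
        Xs = self._standardize(np.atleast_2d(X))
        if self.support.size == 0:
            return np.zeros(Xs.shape[0])
        d2 = (
            (Xs ** 2).sum(axis=1)[:, None]
            + (self.support ** 2).sum(axis=1)[None, :]
            - 2.0 * Xs @ self.support.T
        )
        kmat = np.exp(-np.maximum(d2, 0.0) / (2.0 * self.sigma ** 2))
        return kmat @ self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties (score exactly 0) resolve to the negative class
        return self.decision_function(X) > 0


def frame_spectra(session: Session, drop_dc: bool = True) -> SpectrumMatrix:
    """FFT magnitude spectrum of the LFP snippet owned by each frame.

    Snippets are rectangular-windowed; the DC bin is dropped by default so
    downstream 1/f correction is well defined.  All frames must map to
    equal-length snippets (true for uniformly rendered/aligned sessions).
    """
    bounds = session.frame_bounds
    if bounds[-1] > session.lfp.size:
        raise ValueError("frame alignment exceeds the LFP extent")
    lengths = np.diff(bounds)
    if lengths.min() < 2:
        raise ValueError("frame windows must contain at least 2 LFP samples")
    if np.any(lengths != lengths[0]):
        raise ValueError("frame windows must be equal length")
    w = int(lengths[0])
    snippets = session.lfp[bounds[0]: bounds[-1]].reshape(-1, w)
    mag = np.abs(np.fft.rfft(snippets, axis=1))
    freqs = np.fft.rfftfreq(w, d=1.0 / session.lfp_rate)
    if drop_dc:
        mag, freqs = mag[:, 1:], freqs[1:]
    return SpectrumMatrix(values=mag, freqs=freqs,
                          frame_indices=np.arange(session.n_frames))


def one_over_f_correct(spec: SpectrumMatrix) -> SpectrumMatrix:
    """Whiten a 1/f background: multiply each bin by its frequency."""
    if spec.freqs[0] == 0:
        raise ValueError("DC bin must be dropped before 1/f correction")
    return SpectrumMatrix(
        values=spec.values * spec.freqs[None, :],
        freqs=spec.freqs.copy(),
        frame_indices=spec.frame_indices,
    )


def _as_label_arrays(labels) -> tuple[np.ndarray, np.ndarray]:
    """Normalize partial labels (dict frame->bool or pair of arrays)."""
    if isinstance(labels, dict):
        idx = np.asarray(sorted(labels), dtype=np.int64)
        y = np.asarray([bool(labels[i]) for i in idx])
    else:
        idx, y = labels
        idx = np.asarray(idx, dtype=np.int64)
        y = np.asarray(y, dtype=bool)
    return idx, y


def perceptron_fit(
    spectra: SpectrumMatrix,
    labels,
    passes: int = 5,
    sigma: float = 1.0,
) -> PerceptronModel:
    """Train the online kernelized perceptron on partially labeled frames.

    Features are z-scored per frequency bin across all frames before kernel
    evaluation.  Training visits the labeled examples in frame order for a
    fixed number of passes; each misclassified example is added as a
    support vector with coefficient ±1.  Deterministic given input order.
    """
    idx, y = _as_label_arrays(labels)
    if idx.size == 0 or y.all() or not y.any():
        raise ValueError("need at least one labeled example of each class")
    if idx.min() < 0 or idx.max() >= spec_len(spectra):
        raise IndexError("label frame index out of range")

    mean = spectra.values.mean(axis=0)
    sd = spectra.values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    model = PerceptronModel(sigma=sigma, feat_mean=mean, feat_sd=sd,
                            labeled=dict(zip(idx.tolist(), y.tolist())),
                            passes=passes)
    X = model._standardize(spectra.values[idx])
    sv: list[np.ndarray] = []
    coef: list[float] = []
    for _ in range(passes):
        mistakes = 0
        for xi, yi in zip(X, y):
            if sv:
                S = np.asarray(sv)
                d2 = ((S - xi) ** 2).sum(axis=1)
                score = float(np.exp(-d2 / (2 * sigma ** 2)) @ np.asarray(coef))
            else:
                score = 0.0
            pred = score > 0
            if pred != yi:
                sv.append(xi)
                coef.append(1.0 if yi else -1.0)
                mistakes += 1
        if mistakes == 0:
            break
    model.support = np.asarray(sv) if sv else np.empty((0, X.shape[1]))
    model.coef = np.asarray(coef)
    return model


def spec_len(spectra: SpectrumMatrix) -> int:
    return spectra.values.shape[0]


def refine_interactive(
    model: PerceptronModel,
    spectra: SpectrumMatrix,
    corrections,
) -> PerceptronModel:
    """Re-fit with human label corrections merged in.

    ``corrections`` maps frame → label (or is a (frames, labels) pair);
    duplicate contradictory corrections are an error.  With no corrections
    the model is re-fit on the same labels and predictions are unchanged.
    """
    if isinstance(corrections, dict):
        corr_idx = np.asarray(sorted(corrections), dtype=np.int64)
        corr_y = np.asarray([bool(corrections[i]) for i in corr_idx])
    else:
        corr_idx, corr_y = corrections
        corr_idx = np.asarray(corr_idx, dtype=np.int64)
        corr_y = np.asarray(corr_y, dtype=bool)
        uniq, first = np.unique(corr_idx, return_index=True)
        if uniq.size != corr_idx.size:
            for f in uniq:
                vals = set(corr_y[corr_idx == f].tolist())
                if len(vals) > 1:
                    raise ValueError(f"contradictory corrections for frame {f}")
            corr_idx, corr_y = uniq, corr_y[first]
    if corr_idx.size and (corr_idx.min() < 0 or corr_idx.max() >= spec_len(spectra)):
        raise IndexError("correction frame index out of range")
    merged = dict(model.labeled or {})
    merged.update(dict(zip(corr_idx.tolist(), corr_y.tolist())))
    return perceptron_fit(spectra, merged, passes=model.passes, sigma=model.sigma)


def detect_ieds(
    session: Session,
    seed_labels,
    passes: int = 5,
    sigma: float = 1.0,
    refine_rounds: int = 0,
    oracle=None,
) -> EventSet:
    """Detect IED events with the semi-supervised spectral classifier.

    Runs of consecutive IED-positive frames are merged into one event at
    the frame of maximal broadband (20–500 Hz) power.  If ``oracle`` is
    given (callable frame → bool, standing in for the human annotator),
    ``refine_rounds`` rounds of feedback flip mislabeled positives.
    """
    spectra = frame_spectra(session)
    model = perceptron_fit(spectra, seed_labels, passes=passes, sigma=sigma)
    positive = model.predict(spectra.values)
    for _ in range(refine_rounds):
        if oracle is None:
            break
        flagged = np.flatnonzero(positive)
        wrong = {int(f): bool(oracle(int(f))) for f in flagged
                 if bool(oracle(int(f))) != bool(positive[f])}
        if not wrong:
            break
        model = refine_interactive(model, spectra, wrong)
        positive = model.predict(spectra.values)

    band = (spectra.freqs >= 20) & (spectra.freqs <= 500)
    power = (spectra.values[:, band] ** 2).sum(axis=1)
    frames = _merge_runs(positive, power)
    return EventSet(frames=frames, kind="IED")


def _merge_runs(positive: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Collapse runs of positive frames to the max-power frame of each run."""
    frames = []
    in_run, start = False, 0
    padded = np.concatenate([positive, [False]])
    for i, flag in enumerate(padded):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            in_run = False
            run = np.arange(start, i)
            frames.append(run[np.argmax(power[run])])
    return np.asarray(frames, dtype=np.int64)


def ied_rate(events: EventSet, duration: float) -> tuple[float, int]:
    """IED rate (events/s) and session count."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(events) / duration, len(events)


def ripple_band_power(
    lfp: np.ndarray,
    lfp_rate: float,
    f_lo: float = 100.0,
    f_hi: float = 225.0,
    step: float = 25.0,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Ripple-band Gabor (complex Morlet) wavelet power envelope.

    A filter bank of Gabor atoms at centers f_lo..f_hi (inclusive, ``step``
    spacing) is convolved with the LFP; the per-sample power is the maximum
    squared magnitude across centers.
    """
    if lfp_rate < 2 * f_hi:
        raise ValueError("LFP rate must be at least twice the top ripple band")
    centers = np.arange(f_lo, f_hi + step / 2, step)
    power = np.zeros(lfp.size)
    for fc in centers:
        s = n_cycles / (2 * np.pi * fc)
        t_half = np.arange(0, 4 * s, 1.0 / lfp_rate)
        t = np.concatenate([-t_half[:0:-1], t_half])
        atom = np.exp(2j * np.pi * fc * t) * np.exp(-(t ** 2) / (2 * s ** 2))
        atom /= np.abs(atom).sum()
        env = np.abs(sps.fftconvolve(lfp, atom, mode="same")) ** 2
        power = np.maximum(power, env)
    return power


def immobility_epochs(
    speed: np.ndarray,
    frame_rate: float,
    speed_cutoff: float = 1.0,
    min_duration: float = 3.0,
) -> list[tuple[int, int]]:
    """Frame intervals [start, stop) with speed < cutoff lasting ≥ min_duration."""
    immobile = np.concatenate([speed < speed_cutoff, [False]])
    epochs, in_run, start = [], False, 0
    min_frames = int(np.ceil(min_duration * frame_rate))
    for i, flag in enumerate(immobile):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            in_run = False
            if i - start >= min_frames:
                epochs.append((start, i))
    return epochs


def detect_spwr(
    session: Session,
    mad_factor: float = 12.0,
    speed_cutoff: float = 1.0,
    min_immobility: float = 3.0,
    min_duration: float = 0.02,
) -> EventSet:
    """Detect sharp-wave ripples by thresholded ripple-band power.

    Candidate events are contiguous regions where ripple-band Gabor power
    strictly exceeds median + ``mad_factor``·MAD of the session and lasts
    at least ``min_duration`` seconds (a genuine ripple sustains several
    cycles; isolated single-sample crossings of a heavy-tailed power
    envelope are noise).  Each event is reported at its within-event power
    peak and retained only when the peak falls inside an immobility epoch
    lasting at least ``min_immobility`` s.
    """
    if session.speed is None or session.speed.size != session.n_frames:
        raise ValueError("a locomotion trace is required for SPW-R detection")
    power = ripple_band_power(session.lfp, session.lfp_rate)
    med = np.median(power)
    mad = np.median(np.abs(power - med))
    thresh = med + mad_factor * mad
    min_samples = max(int(round(min_duration * session.lfp_rate)), 1)

    above = np.concatenate([power > thresh, [False]])
    peaks = []
    in_run, start = False, 0
    for i, flag in enumerate(above):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            in_run = False
            if i - start >= min_samples:
                run = slice(start, i)
                peaks.append(start + int(np.argmax(power[run])))

    epochs = immobility_epochs(session.speed, session.frame_rate,
                               speed_cutoff, min_immobility)
    samples_per_frame = session.lfp_rate / session.frame_rate
    kept_frames, kept_peaks = [], []
    for pk in peaks:
        frame = int(pk // samples_per_frame)
        frame = min(frame, session.n_frames - 1)
        if any(a <= frame < b for a, b in epochs):
            if not kept_frames or frame != kept_frames[-1]:
                kept_frames.append(frame)
                kept_peaks.append(pk)
    return EventSet(frames=np.asarray(kept_frames, dtype=np.int64),
                    kind="SPWR",
                    peak_samples=np.asarray(kept_peaks, dtype=np.int64))


def save_events(events: EventSet, path: str | Path) -> None:
    """Write an EventSet as a BED-like TSV (frame_start, frame_end, kind, peak)."""
    path = Path(path)
    peaks = (events.peak_samples if events.peak_samples is not None
             else np.full(len(events), -1))
    with path.open("w") as f:
        f.write("frame_start\tframe_end\tkind\tpeak_sample\n")
        for fr, pk in zip(events.frames, peaks):
            f.write(f"{fr}\t{fr + 1}\t{events.kind}\t{pk}\n")


def load_events(path: str | Path) -> EventSet:
    rows = Path(path).read_text().strip().splitlines()[1:]
    frames, peaks, kinds = [], [], []
    for row in rows:
        a, _, kind, pk = row.split("\t")
        frames.append(int(a))
        peaks.append(int(pk))
        kinds.append(kind)
    kind = kinds[0] if kinds else "IED"
    peaks_arr = np.asarray(peaks, dtype=np.int64)
    return EventSet(frames=np.asarray(frames, dtype=np.int64), kind=kind,
                    peak_samples=peaks_arr if np.any(peaks_arr >= 0) else None)
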