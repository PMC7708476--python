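"""Synthetic session generator with planted latent-ensemble structure.

The generator implements the latent ensemble recruitment (LER) generative
process and renders the result as realistic recording signals so that every
downstream analysis stage can be validated against a known ground truth:

1. Once per network, each ensemble's cell-association vector σ_k (a
   probability vector over the N cells) is drawn from a Dirichlet with
   sparsity-controlling concentration β.  By default the population is
   partitioned into disjoint lineage-pure ensembles — a configurable
   fraction of the K ensembles tile the adult-born granule cells (abGCs,
   ~11% of the population) and the remainder tile the mature granule cells
   (mGCs) — mirroring the low pairwise ensemble overlap seen in vivo.
2. Per event i, an ensemble-recruitment vector θ_i (probability vector over
   the K ensembles) is drawn from a Dirichlet(α); small α makes each event
   recruit a sparse mix of ensembles.
3. Per (event, cell), a recruitment indicator z_ij ~ Bernoulli(p_ij) with
   p_ij = g·Σ_k θ_ik σ_kj clipped to [0, 1].  Because σ rows are simplexes
   over cells, the raw Σ_k θ_ik σ_kj averages 1/N; the gain g =
   recruitment_fraction·N restores a realistic per-event recruitment size
   while preserving the relative recruitment structure.  For each recruited
   cell the source ensemble ζ_ij is drawn with probability
   θ_ik σ_kj / Σ_k θ_ik σ_kj.  The observed responsiveness Δ_ij is then
   drawn from N(μ_on, σ_on²) when z_ij = 1 and N(μ_off, σ_off²) otherwise.

Rendering turns the latent draws into signals: ΔF/F traces are per-cell
event-impulse trains scaled by Δ and convolved with a GCaMP6f-like
double-exponential kernel plus Gaussian noise; the LFP is 1/f (pink) noise
with a biphasic ~50 ms transient (derivative of a Gaussian, deflection
half-widths ~10 ms) at each event frame.  Sharp-wave-ripple-like bursts can
be injected on top with :func:`inject_ripples`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .session import Session, ABGC, MGC

__all__ = [
    "LERParams",
    "SessionConfig",
    "GroundTruth",
    "sample_ler",
    "render_session",
    "inject_ripples",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass
class LERParams:
    """Hyperparameters of the LER generative process.

    Defaults are the package's reference study conditions; they are chosen
    to emulate a 10–30 min dentate gyrus recording in an epileptic animal
    (see docs/methods.md).
    """

    K: int = 6                  # number of latent ensembles
    N: int = 200                # cells
    M: int = 2000               # events
    alpha: float = 0.3          # Dirichlet concentration for θ (event over ensembles)
    beta: float = 1.0           # Dirichlet concentration for σ (ensemble over cells)
    mu_on: float = 1.0          # recruited responsiveness mean (ΔF/F)
    sigma_on: float = 0.25
    mu_off: float = 0.0         # non-recruited responsiveness mean
    sigma_off: float = 0.1
    recruitment_fraction: float = 0.1   # expected fraction of cells recruited/event
    abgc_fraction: float = 0.11         # lineage composition of the population
    abgc_ensemble_fraction: float = 0.25  # fraction of ensembles that are abGC-pure
    structure: str = "lineage"  # "lineage" (disjoint lineage-pure pools) or "dirichlet"

    def validate(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError("K must be an integer >= 1")
        if self.K > self.N:
            raise ValueError(f"K={self.K} exceeds cell count N={self.N}")
        for name in ("alpha", "beta", "sigma_on", "sigma_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("mu_on", "mu_off", "recruitment_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.abgc_fraction <= 1.0:
            raise ValueError("abgc_fraction must lie in [0, 1]")
        if not 0.0 < self.recruitment_fraction <= 1.0:
            raise ValueError("recruitment_fraction must lie in (0, 1]")
        if self.structure not in {"lineage", "dirichlet"}:
            raise ValueError("structure must be 'lineage' or 'dirichlet'")

    @property
    def n_abgc_ensembles(self) -> int:
        if self.structure != "lineage" or self.abgc_fraction == 0:
            return 0
        return max(1, round(self.abgc_ensemble_fraction * self.K)) if self.K > 1 else 0


@dataclass
class SessionConfig:
    """Signal-rendering parameters.

    ``duration`` defaults to just covering the last event plus a margin.
    The LFP rate of 1250 Hz matches common downsampled hippocampal
    recordings and comfortably resolves the 100–225 Hz ripple band.
    """

    frame_rate: float = 15.0        # Hz, imaging
    lfp_rate: float = 1250.0        # Hz
    duration: float | None = None   # s; None → derived from event frames
    kernel_rise: float = 0.05       # s, calcium indicator rise time constant
    kernel_decay: float = 0.5       # s, decay time constant
    kernel: str = "double_exp"      # or "box" (window-matched box response)
    noise_sd: float = 0.05          # ΔF/F trace noise
    ied_amplitude: float = 8.0      # transient peak, units of LFP noise SD
    ied_width: float = 10.0         # ms, deflection half-width scale
    pink_exponent: float = 1.0      # LFP background power ∝ 1/f^exponent
    seed: int = 0

    def validate(self, max_event_frame: int | None = None) -> None:
        if self.kernel_rise <= 0 or self.kernel_decay <= 0:
            raise ValueError("calcium kernel time constants must be > 0")
        if self.frame_rate <= 0 or self.lfp_rate <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.kernel not in {"double_exp", "box"}:
            raise ValueError("kernel must be 'double_exp' or 'box'")
        if (
            max_event_frame is not None
            and self.duration is not None
            and self.duration * self.frame_rate <= max_event_frame
        ):
            raise ValueError("duration too short for the planted event frames")


@dataclass
class GroundTruth:
    """Latent variables planted by :func:`sample_ler`."""

    sigma_star: np.ndarray       # (K, N) ensemble-over-cell probability vectors
    theta_star: np.ndarray       # (M, K) event-over-ensemble probability vectors
    z_star: np.ndarray           # (M, N) binary recruitment indicators
    zeta_star: np.ndarray        # (M, N) source ensemble, -1 where z_star == 0
    delta: np.ndarray            # (N, M) responsiveness emissions (ΔF/F)
    labels: np.ndarray           # (N,) lineage labels
    event_frames: np.ndarray     # (M,) frame index of each event
    params: LERParams = field(default=None)  # type: ignore[assignment]

    @property
    def abgc_pure_ensembles(self) -> np.ndarray:
        """Indices of planted ensembles whose mass sits on abGC cells only."""
        abgc = np.asarray([lab == ABGC for lab in self.labels])
        mass = self.sigma_star[:, abgc].sum(axis=1)
        return np.flatnonzero(mass > 0.999)


def sample_ler(
    params: LERParams,
    seed: int,
    n_frames: int | None = None,
) -> GroundTruth:
    """Draw one realization of the LER generative process.

    ``n_frames`` sets the span over which the M event frames are placed
    (uniformly at random, distinct, with an edge margin); the default of
    13 frames per event yields ≈1.15 events/s at the 15 Hz default frame
    rate, in the empirically observed interictal-discharge range.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    K, N, M = params.K, params.N, params.M

    # lineage labels: fixed count, shuffled positions
    n_abgc = round(params.abgc_fraction * N)
    labels = np.asarray([ABGC] * n_abgc + [MGC] * (N - n_abgc), dtype=object)
    rng.shuffle(labels)
    abgc_idx = np.flatnonzero([lab == ABGC for lab in labels])
    mgc_idx = np.flatnonzero([lab == MGC for lab in labels])

    # ensemble-over-cell vectors
    sigma = np.zeros((K, N))
    if params.structure == "lineage" and params.n_abgc_ensembles > 0 and len(abgc_idx):
        n_a = min(params.n_abgc_ensembles, K - 1) if K > 1 else 0
        pools = _partition(abgc_idx, n_a, rng) + _partition(mgc_idx, K - n_a, rng)
        for k, pool in enumerate(pools):
            sigma[k, pool] = rng.dirichlet(np.full(len(pool), params.beta))
    else:
        sigma = rng.dirichlet(np.full(N, params.beta), size=K)

    theta = rng.dirichlet(np.full(K, params.alpha), size=M) if K > 1 \
        else np.ones((M, 1))

    # recruitment probabilities with documented gain
    gain = params.recruitment_fraction * N
    contrib = theta[:, :, None] * sigma[None, :, :]     # (M, K, N)
    p_raw = contrib.sum(axis=1)                          # (M, N)
    p = np.clip(gain * p_raw, 0.0, 1.0)
    z = (rng.random((M, N)) < p).astype(np.int8)

    # source ensemble for recruited pairs: k ∝ θ_ik σ_kj
    zeta = np.full((M, N), -1, dtype=np.int32)
    rec_i, rec_j = np.nonzero(z)
    if rec_i.size:
        w = contrib[rec_i, :, rec_j]                     # (n_rec, K)
        tot = w.sum(axis=1, keepdims=True)
        w = np.where(tot > 0, w / np.where(tot == 0, 1, tot), 1.0 / K)
        cum = np.cumsum(w, axis=1)
        u = rng.random(rec_i.size)
        zeta[rec_i, rec_j] = (u[:, None] < cum).argmax(axis=1)

    # responsiveness emissions, cells × events
    on = rng.normal(params.mu_on, params.sigma_on, size=(M, N))
    off = rng.normal(params.mu_off, params.sigma_off, size=(M, N))
    delta = np.where(z == 1, on, off).T

    if n_frames is None:
        n_frames = 13 * M + 100
    margin = 50  # frames kept clear at each edge for responsiveness windows
    if n_frames - 2 * margin < M:
        raise ValueError("n_frames too small to place M distinct event frames")
    event_frames = np.sort(
        rng.choice(np.arange(margin, n_frames - margin), size=M, replace=False)
    )

    return GroundTruth(
        sigma_star=sigma,
        theta_star=theta,
        z_star=z,
        zeta_star=zeta,
        delta=delta,
        labels=labels,
        event_frames=event_frames,
        params=params,
    )


def _partition(idx: np.ndarray, n_parts: int, rng: np.random.Generator) -> list:
    """Split an index set into n_parts near-equal random disjoint pools."""
    if n_parts <= 0:
        return []
    idx = rng.permutation(idx)
    return [np.sort(part) for part in np.array_split(idx, n_parts)]


def calcium_kernel(cfg: SessionConfig) -> np.ndarray:
    """Max-normalized indicator impulse response on the imaging clock."""
    if cfg.kernel == "box":
        # box spanning one 3-s responsiveness window: measured post-minus-pre
        # mean equals the planted amplitude exactly
        return np.ones(int(round(3.0 * cfg.frame_rate)))
    t = np.arange(0, 6 * cfg.kernel_decay, 1.0 / cfg.frame_rate)
    k = (1 - np.exp(-t / cfg.kernel_rise)) * np.exp(-t / cfg.kernel_decay)
    m = k.max()
    return k / m if m > 0 else k


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^exponent, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def ied_waveform(cfg: SessionConfig) -> np.ndarray:
    """Biphasic interictal-discharge transient: derivative of a Gaussian.

    The deflection scale (``ied_width`` ms) puts the positive and negative
    lobes ~2·width apart inside an event lasting roughly 5·width.
    """
    s = cfg.ied_width / 1000.0
    t = np.arange(-3 * s, 3 * s, 1.0 / cfg.lfp_rate)
    w = -t / s * np.exp(-(t ** 2) / (2 * s ** 2))
    peak = np.abs(w).max()
    return cfg.ied_amplitude * w / peak if peak > 0 else w


def render_session(gt: GroundTruth, cfg: SessionConfig) -> Session:
    """Render latent draws into a full recording session."""
    cfg.validate(max_event_frame=int(gt.event_frames.max(initial=0)))
    rng = np.random.default_rng(cfg.seed)
    N = gt.delta.shape[0]
    M = gt.event_frames.size

    if cfg.duration is None:
        n_frames = int(gt.event_frames.max(initial=0)) + 50 + 1
    else:
        n_frames = int(round(cfg.duration * cfg.frame_rate))
    if M and gt.event_frames.max() >= n_frames:
        raise ValueError("event frames do not fit within the session duration")

    # ΔF/F: impulse train scaled by planted responsiveness, convolved
    kern = calcium_kernel(cfg)
    impulses = np.zeros((N, n_frames))
    impulses[:, gt.event_frames] = gt.delta[:, :M]
    clean = signal.fftconvolve(impulses, kern[None, :], axes=1)[:, :n_frames] \
        if N else impulses
    dff = clean + (rng.standard_normal((N, n_frames)) * cfg.noise_sd
                   if cfg.noise_sd > 0 else 0.0)

    # LFP: pink background + IED transients at event frames
    samples_per_frame = int(round(cfg.lfp_rate / cfg.frame_rate))
    n_lfp = samples_per_frame * n_frames
    lfp = pink_noise(n_lfp, cfg.pink_exponent, rng)
    wave = ied_waveform(cfg)
    for ev in gt.event_frames:
        start = ev * samples_per_frame + (samples_per_frame - wave.size) // 2
        start = max(start, 0)
        stop = min(start + wave.size, n_lfp)
        lfp[start:stop] += wave[: stop - start]

    frame_bounds = np.arange(n_frames + 1, dtype=np.int64) * samples_per_frame
    return Session(
        dff=dff,
        lfp=lfp,
        frame_bounds=frame_bounds,
        labels=gt.labels.copy(),
        speed=np.zeros(n_frames),
        frame_rate=cfg.frame_rate,
        lfp_rate=cfg.lfp_rate,
        seed=cfg.seed,
        meta={"event_frames": gt.event_frames.copy()},
    )


def inject_ripples(
    session: Session,
    times: np.ndarray | list,
    ripple_freq: float = 150.0,
    n_cycles: int = 8,
    amplitude: float = 5.0,
) -> Session:
    """Add Gaussian-windowed ripple-band bursts to the LFP.

    Each burst is a sinusoid at ``ripple_freq`` under a Gaussian envelope
    spanning ~``n_cycles`` cycles; the locomotion trace is zeroed for ±2 s
    around each burst so the immobility criterion (≥3 s) is satisfiable.
    Returns a new session; the input is not modified.
    """
    if not 100.0 <= ripple_freq <= 225.0:
        raise ValueError("ripple_freq must lie within the 100-225 Hz band")
    if ripple_freq >= session.lfp_rate / 2:
        raise ValueError("ripple_freq exceeds the LFP Nyquist frequency")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    dur = session.n_frames / session.frame_rate
    if np.any(times < 0) or np.any(times > dur):
        raise ValueError("ripple times must lie within the session duration")

    lfp = session.lfp.copy()
    speed = session.speed.copy()
    sd = n_cycles / ripple_freq / 4.0   # envelope SD: burst ≈ n_cycles cycles
    t_half = np.arange(0, 4 * sd, 1.0 / session.lfp_rate)
    t = np.concatenate([-t_half[:0:-1], t_half])
    burst = amplitude * np.cos(2 * np.pi * ripple_freq * t) * \
        np.exp(-(t ** 2) / (2 * sd ** 2))
    for t0 in times:
        center = int(round(t0 * session.lfp_rate))
        start = center - burst.size // 2
        s0, s1 = max(start, 0), min(start + burst.size, lfp.size)
        lfp[s0:s1] += burst[s0 - start: s1 - start]
        f0 = int((t0 - 2.0) * session.frame_rate)
        f1 = int((t0 + 2.0) * session.frame_rate) + 1
        speed[max(f0, 0): min(f1, speed.size)] = 0.0

    return Session(
        dff=session.dff,
        lfp=lfp,
        frame_bounds=session.frame_bounds,
        labels=session.labels,
        speed=speed,
        frame_rate=session.frame_rate,
        lfp_rate=session.lfp_rate,
        seed=session.seed,
        meta=dict(session.meta),
    )


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write ground truth as a JSON meta file plus CSV matrices."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "sigma_star.csv", gt.sigma_star, delimiter=",")
    np.savetxt(path / "theta_star.csv", gt.theta_star, delimiter=",")
    np.savetxt(path / "z_star.csv", gt.z_star, delimiter=",", fmt="%d")
    np.savetxt(path / "zeta_star.csv", gt.zeta_star, delimiter=",", fmt="%d")
    np.savetxt(path / "delta.csv", gt.delta, delimiter=",")
    meta = {
        "labels": [str(x) for x in gt.labels],
        "event_frames": gt.event_frames.tolist(),
        "params": asdict(gt.params) if gt.params is not None else None,
    }
    (path / "ground_truth.json").write_text(json.dumps(meta, indent=2))


def load_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    meta = json.loads((path / "ground_truth.json").read_text())
    params = LERParams(**meta["params"]) if meta["params"] else None
    return GroundTruth(
        sigma_star=np.atleast_2d(np.loadtxt(path / "sigma_star.csv", delimiter=",")),
        theta_star=np.atleast_2d(np.loadtxt(path / "theta_star.csv", delimiter=",")),
        z_star=np.atleast_2d(np.loadtxt(path / "z_star.csv", delimiter=",")).astype(np.int8),
        zeta_star=np.atleast_2d(np.loadtxt(path / "zeta_star.csv", delimiter=",")).astype(np.int32),
        delta=np.atleast_2d(np.loadtxt(path / "delta.csv", delimiter=",")),
        labels=np.asarray(meta["labels"], dtype=object),
        event_frames=np.asarray(meta["event_frames"], dtype=np.int64),
        params=params,  # type: ignore[arg-type]
    )
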