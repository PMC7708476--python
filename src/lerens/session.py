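"""Recording session container and on-disk formats.

A :class:`Session` bundles everything one imaging+electrophysiology
recording provides: a ΔF/F matrix (cells × frames), a single-channel LFP
trace, the frame→LFP alignment, per-cell lineage labels (adult-born vs
mature granule cells), and a locomotion speed trace.  All downstream
analyses consume this container, whether it came from the synthetic
generator or from user data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Session", "load_session", "save_session"]

ABGC = "abGC"
MGC = "mGC"


@dataclass
class Session:
    """One recording session.

    Parameters
    ----------
    dff : ndarray, shape (n_cells, n_frames)
        ΔF/F traces per cell.
    lfp : ndarray, shape (n_samples,)
        Single-channel LFP.
    frame_bounds : ndarray, shape (n_frames + 1,)
        LFP sample boundaries; frame ``i`` owns samples
        ``lfp[frame_bounds[i]:frame_bounds[i + 1]]``.
    labels : ndarray of str, shape (n_cells,)
        Lineage label per cell, ``"abGC"`` or ``"mGC"``.
    speed : ndarray, shape (n_frames,)
        Locomotion speed (cm/s) per imaging frame.
    frame_rate, lfp_rate : float
        Sampling rates in Hz.
    """

    dff: np.ndarray
    lfp: np.ndarray
    frame_bounds: np.ndarray
    labels: np.ndarray
    speed: np.ndarray
    frame_rate: float
    lfp_rate: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.frame_bounds = np.asarray(self.frame_bounds, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D (cells × frames)")
        if self.frame_bounds.size != self.n_frames + 1:
            raise ValueError(
                f"frame_bounds must have n_frames+1={self.n_frames + 1} "
                f"entries, got {self.frame_bounds.size}"
            )
        if self.frame_bounds[-1] > self.lfp.size:
            raise ValueError("frame alignment extends past the LFP trace")
        if self.labels.size != self.n_cells:
            raise ValueError("one lineage label per cell required")
        if self.speed.size != self.n_frames:
            raise ValueError("speed trace must have one sample per frame")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (imaging clock)."""
        return self.n_frames / self.frame_rate

    def is_abgc(self) -> np.ndarray:
        return np.asarray([lab == ABGC for lab in self.labels], dtype=bool)

    def frame_window(self, frame: int) -> np.ndarray:
        """The LFP snippet aligned to one imaging frame."""
        return self.lfp[self.frame_bounds[frame]:self.frame_bounds[frame + 1]]


def save_session(session: Session, path: str | Path) -> None:
    """Write a session to HDF5 (``.h5``) or to a CSV/JSON directory."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("dff", data=session.dff)
            f.create_dataset("lfp", data=session.lfp)
            f.create_dataset("frame_to_lfp", data=session.frame_bounds)
            f.create_dataset(
                "labels",
                data=np.asarray([str(x) for x in session.labels], dtype="S8"),
            )
            f.create_dataset("speed", data=session.speed)
            f.attrs["frame_rate"] = session.frame_rate
            f.attrs["lfp_rate"] = session.lfp_rate
            if session.seed is not None:
                f.attrs["seed"] = session.seed
    else:
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "traces.csv", session.dff, delimiter=",")
        np.savetxt(path / "lfp.csv", session.lfp, delimiter=",")
        np.savetxt(path / "frame_to_lfp.csv", session.frame_bounds,
                   delimiter=",", fmt="%d")
        np.savetxt(path / "speed.csv", session.speed, delimiter=",")
        meta = {
            "frame_rate": session.frame_rate,
            "lfp_rate": session.lfp_rate,
            "seed": session.seed,
            "labels": [str(x) for x in session.labels],
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_session(path: str | Path) -> Session:
    """Read a session written by :func:`save_session`."""
    path = Path(path)
    if path.is_file():
        with h5py.File(path, "r") as f:
            return Session(
                dff=f["dff"][()],
                lfp=f["lfp"][()],
                frame_bounds=f["frame_to_lfp"][()],
                labels=np.asarray([x.decode() for x in f["labels"][()]],
                                  dtype=object),
                speed=f["speed"][()],
                frame_rate=float(f.attrs["frame_rate"]),
                lfp_rate=float(f.attrs["lfp_rate"]),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )
    meta = json.loads((path / "meta.json").read_text())
    return Session(
        dff=np.atleast_2d(np.loadtxt(path / "traces.csv", delimiter=",")),
        lfp=np.loadtxt(path / "lfp.csv", delimiter=","),
        frame_bounds=np.loadtxt(path / "frame_to_lfp.csv",
                                delimiter=",").astype(np.int64),
        labels=np.asarray(meta["labels"], dtype=object),
        speed=np.loadtxt(path / "speed.csv", delimiter=","),
        frame_rate=float(meta["frame_rate"]),
        lfp_rate=float(meta["lfp_rate"]),
        seed=meta.get("seed"),
    )
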