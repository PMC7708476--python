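"""End-to-end analysis pipeline with manifest-based reproducibility.

Stages: simulate (or load a session) → detect IEDs → event responsiveness →
bootstrap activation → lineage classification → LER fit + ensemble
statistics → inverse decoding → population synchrony → summary report.
One global seed deterministically derives independent per-stage seeds via
``numpy.random.SeedSequence(global_seed).spawn``, so heavy stages (LER
restarts, 100-split cross-validation) are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .session import Session, load_session, save_session
from .synthetic import LERParams, SessionConfig, sample_ler, render_session
from .lfp import detect_ieds, ied_rate, frame_spectra, save_events
from .responsiveness import event_responsiveness, bootstrap_activation
from .celltype import cross_validate, fit_lineage_classifier, informative_events
from .ler import fit_ler, membership, ensemble_overlap, dominance_test
from .decoding import (
    most_active_ensemble,
    decode_from_spectrum,
    population_synchrony,
)
from .lfp import SpectrumMatrix

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "session_path": None,        # load instead of simulating when set
    "simulate": {
        "params": {},            # LERParams overrides
        "session": {},           # SessionConfig overrides
    },
    "detect": {"n_seed_labels": 30, "passes": 5, "labels_path": None},
    "respond": {"window": 3.0, "n_boot": 10000, "alpha": 0.05},
    "classify": {"enabled": True, "penalty": "l2", "n_splits": 25},
    "ler": {"K": 6, "restarts": 10, "max_iter": 30, "n_shuffle": 10000},
    "decode": {"n_estimators": 100, "n_splits": 10},
}

_STAGE_NAMES = ["simulate", "detect", "respond", "classify", "ler",
                "decode", "synchrony", "report"]


def _merged(cfg: dict) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            for k2, v2 in val.items():
                if isinstance(v2, dict) and isinstance(out[key].get(k2), dict):
                    out[key][k2].update(v2)
                else:
                    out[key][k2] = v2
        else:
            out[key] = val
    return out


def validate_config(cfg: dict) -> list[str]:
    """Cross-stage consistency checks; returns a list of error strings."""
    errors: list[str] = []
    cfg = _merged(cfg)
    try:
        params = LERParams(**cfg["simulate"]["params"])
        params.validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"simulate.params: {exc}")
        params = None
    try:
        scfg = SessionConfig(**cfg["simulate"]["session"])
        scfg.validate()
    except (TypeError, ValueError) as exc:
        errors.append(f"simulate.session: {exc}")
        scfg = None
    if params is not None and cfg["ler"]["K"] > params.N:
        errors.append(f"ler.K: K={cfg['ler']['K']} exceeds N={params.N}")
    if cfg["respond"]["window"] <= 0:
        errors.append("respond.window: must be positive")
    if not 0 < cfg["respond"]["alpha"] < 1:
        errors.append("respond.alpha: must lie in (0, 1)")
    if scfg is not None and params is not None and scfg.duration is not None:
        if scfg.duration * scfg.frame_rate < 13 * params.M:
            errors.append("simulate.session.duration: too short for M events")
    if cfg["session_path"] is not None:
        if not Path(cfg["session_path"]).exists():
            errors.append(f"session_path: {cfg['session_path']} does not exist")
        if cfg["detect"]["labels_path"] is None:
            errors.append(
                "detect.labels_path: seed IED annotations (CSV frame,is_ied) "
                "are required when analysing a user-supplied session"
            )
    if cfg["detect"]["n_seed_labels"] < 2:
        errors.append("detect.n_seed_labels: need at least 2")
    return errors


def _stage_seeds(global_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGE_NAMES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGE_NAMES, children)}


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Run all stages and write outputs + manifest under ``out_dir``.

    Returns the summary report dict.  A stage failure raises after writing
    a FAILED marker naming the stage; outputs of completed stages remain.
    """
    cfg = _merged(cfg)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest: dict = {"version": __version__, "seed": cfg["seed"],
                      "stage_seeds": seeds, "config": cfg, "stages": {}}
    timings: dict = {}
    report: dict = {}
    stage = "simulate"
    try:
        t0 = time.time()
        gt = None
        if cfg["session_path"]:
            session = load_session(cfg["session_path"])
        else:
            params = LERParams(**cfg["simulate"]["params"])
            scfg = SessionConfig(**{"seed": seeds["simulate"],
                                    **cfg["simulate"]["session"]})
            gt = sample_ler(params, seed=seeds["simulate"])
            session = render_session(gt, scfg)
            save_session(session, out / "session.h5")
        timings["simulate"] = round(time.time() - t0, 2)
        manifest["stages"]["simulate"] = {
            "dff_hash": _hash_array(session.dff),
            "lfp_hash": _hash_array(session.lfp),
        }

        stage = "detect"
        t0 = time.time()
        if gt is not None:
            seed_labels = _seed_labels_from_truth(
                gt, session, cfg["detect"]["n_seed_labels"], seeds["detect"])
        else:
            rows = np.loadtxt(cfg["detect"]["labels_path"], delimiter=",",
                              skiprows=1, ndmin=2)
            seed_labels = (rows[:, 0].astype(int), rows[:, 1].astype(bool))
        events = detect_ieds(session, seed_labels,
                             passes=cfg["detect"]["passes"])
        save_events(events, out / "ied_events.tsv")
        rate, count = ied_rate(events, session.duration)
        report["ied_rate_per_s"] = round(rate, 4)
        report["ied_count"] = count
        timings["detect"] = round(time.time() - t0, 2)
        manifest["stages"]["detect"] = {"n_events": count}

        stage = "respond"
        t0 = time.time()
        rcfg = cfg["respond"]
        R = event_responsiveness(session, events, window=rcfg["window"])
        A = bootstrap_activation(session, events, window=rcfg["window"],
                                 n_boot=rcfg["n_boot"], alpha=rcfg["alpha"],
                                 exclude=events.frames, seed=seeds["respond"])
        np.savetxt(out / "responsiveness.csv", R.delta, delimiter=",")
        np.savetxt(out / "activation.csv", A.zprime, delimiter=",", fmt="%d")
        report["activation_rate"] = float(A.zprime.mean())
        timings["respond"] = round(time.time() - t0, 2)
        manifest["stages"]["respond"] = {"z_hash": _hash_array(A.zprime)}

        stage = "classify"
        if cfg["classify"]["enabled"]:
            t0 = time.time()
            cv = cross_validate(R, session.labels,
                                penalty=cfg["classify"]["penalty"],
                                n_splits=cfg["classify"]["n_splits"],
                                seed=seeds["classify"])
            res = fit_lineage_classifier(R, session.labels,
                                         penalty=cfg["classify"]["penalty"],
                                         seed=seeds["classify"])
            ie = informative_events(res)
            np.savetxt(out / "event_weights.csv", res.weights, delimiter=",")
            np.savetxt(out / "cell_scores.csv", res.scores, delimiter=",")
            report["lineage_accuracy_mean"] = round(cv["mean"], 4)
            report["lineage_accuracy_sd"] = round(cv["sd"], 4)
            report["n_pro_mgc_events"] = int(ie.pro_mgc.size)
            report["n_anti_mgc_events"] = int(ie.anti_mgc.size)
            timings["classify"] = round(time.time() - t0, 2)
            manifest["stages"]["classify"] = {"done": True}

        stage = "ler"
        t0 = time.time()
        lcfg = cfg["ler"]
        fit = fit_ler(A, K=lcfg["K"], seed=seeds["ler"],
                      restarts=lcfg["restarts"], max_iter=lcfg["max_iter"])
        summ = membership(fit)
        ensemble_overlap(fit, summ)
        summ = dominance_test(summ, session.labels,
                              n_shuffle=lcfg["n_shuffle"], seed=seeds["ler"])
        np.savetxt(out / "sigma.csv", fit.sigma, delimiter=",")
        np.savetxt(out / "theta.csv", fit.theta, delimiter=",")
        dom = np.asarray(summ.dominance)
        report["abgc_dominated_fraction"] = float(np.mean(dom == "abGC-dominated"))
        report["mgc_dominated_fraction"] = float(np.mean(dom == "mGC-dominated"))
        report["median_ensemble_overlap"] = float(np.median(
            summ.overlap[np.triu_indices(fit.K, k=1)]))
        timings["ler"] = round(time.time() - t0, 2)
        manifest["stages"]["ler"] = {"elbo": fit.elbo}

        stage = "decode"
        t0 = time.time()
        spectra = frame_spectra(session)
        kept = A.event_frames if A.event_frames is not None else events.frames
        kept = kept[fit.event_index] if fit.event_index is not None else kept
        event_spectra = SpectrumMatrix(values=spectra.values[kept],
                                       freqs=spectra.freqs,
                                       frame_indices=kept)
        targets = most_active_ensemble(fit)
        dec = decode_from_spectrum(event_spectra, targets,
                                   n_estimators=cfg["decode"]["n_estimators"],
                                   n_splits=cfg["decode"]["n_splits"],
                                   seed=seeds["decode"])
        report["decode_accuracy"] = round(float(dec.accuracies.mean()), 4)
        report["decode_chance_empirical"] = round(dec.chance_empirical, 4)
        report["decode_p_value"] = dec.p_value
        timings["decode"] = round(time.time() - t0, 2)
        manifest["stages"]["decode"] = {"done": True}

        stage = "synchrony"
        t0 = time.time()
        sync = population_synchrony(A, session.labels)
        report["synchrony_tau"] = (None if np.isnan(sync.tau)
                                   else round(sync.tau, 4))
        timings["synchrony"] = round(time.time() - t0, 2)
        manifest["stages"]["synchrony"] = {"done": True}

        stage = "report"
        (out / "summary.json").write_text(json.dumps(report, indent=2))
        (out / "summary.txt").write_text(_human_report(report))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        (out / "timings.json").write_text(json.dumps(timings, indent=2))
        for name, sec in timings.items():
            logger.info("stage %s: %.2f s", name, sec)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return report


def _seed_labels_from_truth(gt, session: Session, n_labels: int, seed: int):
    """Label a few frames from ground truth, mimicking the human annotator."""
    rng = np.random.default_rng(seed)
    n_pos = max(n_labels // 2, 1)
    pos = rng.choice(gt.event_frames, size=min(n_pos, gt.event_frames.size),
                     replace=False)
    non_event = np.setdiff1d(np.arange(session.n_frames), gt.event_frames)
    neg = rng.choice(non_event, size=n_labels - pos.size, replace=False)
    idx = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    order = np.argsort(idx)
    return idx[order], y[order]


def _human_report(report: dict) -> str:
    lines = ["lerens pipeline summary", "=" * 30]
    for key, val in report.items():
        lines.append(f"{key:32s} {val}")
    return "\n".join(lines) + "\n"
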