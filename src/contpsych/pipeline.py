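"""End-to-end pipeline: simulate -> (de-adapt) -> analyze -> bin -> fit."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import yaml

from .adaptation import optimize_q, de_adapt
from .agent import SessionRecord, simulate_session, simulate_training
from .analysis import FinalSeries, finalize
from .config import RunConfig
from .series import write_columns
from .stats import bin_series, compare_fits, fit_model
from .training import SpringFit, fit_training_session
from .walks import gen_blob_walk, gen_session_walk

log = logging.getLogger("contpsych")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) for the pipeline stages."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole study on synthetic data and return all artifacts.

    Stages: training simulation and spring fit; session walk generation and
    session simulation; optional adaptation correction; inverse analysis to
    (x*, y*); binning and induced-motion model fits on raw and final data;
    raw-vs-final comparison.  With ``outdir`` set, all series and fits are
    written as delimited text / YAML.
    """
    s_blob, s_train, s_session = derive_seeds(cfg.seed, 3)
    p = cfg.params

    blob = gen_blob_walk(
        step_deg=cfg.blob_step_deg,
        step_period=cfg.blob_step_period,
        duration=cfg.training_duration,
        dt=cfg.walk.dt,
        seed=s_blob,
    )
    training = simulate_training(blob, p, seed=s_train)
    spring = fit_training_session(
        blob, training.y, step_period=cfg.blob_step_period, discard=cfg.discard
    )
    log.info(
        "training fit: b=%.4f c=%.4f delta_t=%.3f s sigma2=%.3f deg2 (%d steps)",
        spring.b, spring.c, spring.delta_t, spring.sigma_omega2_hat, spring.n_steps,
    )

    walk_cfg = dataclasses.replace(cfg.walk, seed=cfg.walk.seed + s_session % 10_000)
    walk = gen_session_walk(walk_cfg)
    session = simulate_session(walk, p, seed=s_session)
    log.info(
        "session: %d samples, walk seed %s after %s tries, %d perception clips",
        walk.n, walk.meta.get("seed"), walk.meta.get("n_tried"), session.y.meta["n_clipped"],
    )

    qfit = None
    analyzed = session
    if cfg.deadapt:
        x_post = session.x.discard_initial(cfg.discard)
        y_post = session.y.discard_initial(cfg.discard)
        qfit = optimize_q(
            x_post, y_post,
            target_intercept=cfg.target_intercept,
            speed=p.speed,
            bounds=cfg.q_bounds,
        )
        y_corr = de_adapt(session.y, qfit.q, speed=p.speed)
        analyzed = SessionRecord(x=session.x, y=y_corr, params=p, seed=session.seed)
        log.info("adaptation: q=%.3g intercept=%.2f deg", qfit.q, qfit.achieved_intercept)

    final = finalize(
        analyzed, p, spring, discard=cfg.discard, percept_step_sd=cfg.percept_step_sd
    )
    log.info(
        "lags: sense=%.3f s action=%.3f s residual=%.3f s (k_x=%.3g, k_y=%.3g)",
        final.lag_sense, final.lag_action, final.lag_residual, final.k_x, final.k_y,
    )

    x_raw = session.x.discard_initial(cfg.discard)
    y_raw = session.y.discard_initial(cfg.discard)
    lo, hi = cfg.walk.range_lo, cfg.walk.range_hi
    raw_fit = fit_model(x_raw, y_raw, n_bins=cfg.n_bins, lo=lo, hi=hi)
    final_fit = fit_model(final.x_star, final.y_star, n_bins=cfg.n_bins, lo=lo, hi=hi)
    raw_bins = bin_series(x_raw, y_raw, n_bins=cfg.n_bins, lo=lo, hi=hi)
    final_bins = bin_series(final.x_star, final.y_star, n_bins=cfg.n_bins, lo=lo, hi=hi)
    comparison = compare_fits(raw_fit, final_fit, raw_bins, final_bins)
    log.info(
        "fits: raw beta=%.3f r2=%.3f | final beta=%.3f r2=%.3f | dAIC=%.1f",
        raw_fit.beta, raw_fit.r2, final_fit.beta, final_fit.r2, comparison.d_aic,
    )

    result = {
        "config": cfg,
        "blob": blob,
        "training": training,
        "spring": spring,
        "walk": walk,
        "session": session,
        "qfit": qfit,
        "final": final,
        "raw_fit": raw_fit,
        "final_fit": final_fit,
        "raw_bins": raw_bins,
        "final_bins": final_bins,
        "comparison": comparison,
    }
    if outdir is not None:
        write_artifacts(result, Path(outdir), cfg.out_prefix)
    return result


def write_artifacts(result: dict, outdir: Path, prefix: str) -> None:
    """Write every pipeline artifact as text under ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = result["config"]
    cfg.to_yaml(outdir / f"{prefix}_config.yaml")

    tr: SessionRecord = result["training"]
    write_columns(
        outdir / f"{prefix}_training.csv", tr.x.times, blob=tr.x.values, y=tr.y.values
    )
    sess: SessionRecord = result["session"]
    write_columns(
        outdir / f"{prefix}_session.csv", sess.x.times, x=sess.x.values, y=sess.y.values
    )
    fin: FinalSeries = result["final"]
    write_columns(
        outdir / f"{prefix}_final.csv",
        fin.x_star.times,
        x_star=fin.x_star.values,
        y_star=fin.y_star.values,
        y_tilde=fin.y_tilde_hat.values,
    )

    spring: SpringFit = result["spring"]
    report = {
        "spring": dataclasses.asdict(spring),
        "raw_fit": dataclasses.asdict(result["raw_fit"]),
        "final_fit": dataclasses.asdict(result["final_fit"]),
        "comparison": dataclasses.asdict(result["comparison"]),
        "lags": {
            "sense": fin.lag_sense,
            "action": fin.lag_action,
            "residual": fin.lag_residual,
        },
        "gains": {"k_x": fin.k_x, "k_y": fin.k_y},
        "seed": cfg.seed,
    }
    if result["qfit"] is not None:
        report["adaptation"] = dataclasses.asdict(result["qfit"])
    (outdir / f"{prefix}_report.yaml").write_text(
        yaml.safe_dump(_plain(report), sort_keys=False)
    )


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
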