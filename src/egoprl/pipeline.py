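"""Stage functions behind the command-line pipeline.

Each stage is a pure function of its input files plus configuration:
generate -> fit -> features -> analyze (plus the standalone recover stage).
All artifacts are flat CSV/JSON for inspectability; a manifest records the
configuration hash, seed and package version so identical inputs yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .egonet import ASBWeights, compute_features, parse_network_files
from .hgf import HGFParams, fit_hgf, parameter_recovery
from .prl_task import (
    ScheduleConfig,
    TaskSession,
    build_schedule,
    lose_stay_rate,
    win_switch_rate,
)
from .stats_pipeline import analyze_cohort, build_cohort_table
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage could not run (typically a missing prior stage)."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage '{stage}' requires missing input {path}")
    return path


def stage_generate(config: CohortConfig, outdir: Path) -> Dict[str, Path]:
    data = generate_cohort(config)
    paths = write_cohort(data, outdir)
    logger.info("generated cohort of %d egos -> %s", config.n_egos, outdir)
    return paths


def read_sessions(path: Path) -> List[TaskSession]:
    df = pd.read_csv(path, dtype={"ego_id": str})
    sessions = []
    for ego_id, grp in df.groupby("ego_id", sort=False):
        grp = grp.sort_values("trial")
        trials = grp["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise StageError(f"non-contiguous trial indices for ego {ego_id}")
        sessions.append(TaskSession(ego_id=ego_id, frame=str(grp["frame"].iloc[0]),
                                    choices=grp["choice"].to_numpy(),
                                    outcomes=grp["outcome"].to_numpy()))
    return sessions


def stage_fit(sessions_path: Path, outdir: Path, seed: int,
              halves=("first", "second"), free=("mu3_0", "omega2"),
              n_starts: int = 4) -> Path:
    """Fit the HGF per ego and half; write fits.csv + optimizer sidecar."""
    sessions = read_sessions(_require(sessions_path, "fit"))
    rows, diag = [], []
    rng = np.random.default_rng(seed)
    for sess in sessions:
        for half in halves:
            fit = fit_hgf(sess, half=half, free=tuple(free), n_starts=n_starts,
                          seed=int(rng.integers(2**31 - 1)))
            rows.append({"ego_id": sess.ego_id, "half": half,
                         "mu3_0": fit.params.mu3_0, "omega2": fit.params.omega2,
                         "neg_log_joint": fit.neg_log_joint,
                         "converged": fit.converged})
            diag.append({"ego_id": sess.ego_id, "half": half,
                         "n_starts_ok": fit.n_starts_ok,
                         "n_trials": fit.n_trials})
    outdir.mkdir(parents=True, exist_ok=True)
    fits_path = outdir / "fits.csv"
    pd.DataFrame(rows).to_csv(fits_path, index=False)
    (outdir / "fits_diagnostics.json").write_text(json.dumps(diag, indent=1))
    logger.info("fit %d sessions x %d halves", len(sessions), len(halves))
    return fits_path


def stage_behavior(sessions_path: Path, outdir: Path) -> Path:
    sessions = read_sessions(_require(sessions_path, "behavior"))
    rows = [{"ego_id": s.ego_id, "frame": s.frame,
             "win_switch": win_switch_rate(s), "lose_stay": lose_stay_rate(s)}
            for s in sessions]
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "behavior.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def stage_features(edges_path: Path, alters_path: Path, cohort_path: Path,
                   outdir: Path, weights: ASBWeights = ASBWeights()) -> Path:
    """Compute the seven network features per ego; write features.csv."""
    result = parse_network_files(_require(edges_path, "features"),
                                 _require(alters_path, "features"))
    cohort = pd.read_csv(_require(cohort_path, "features"), dtype={"ego_id": str})
    gen_cols = [f"gen{i}" for i in range(1, 6)]
    ego_items = {r.ego_id: [getattr(r, c) for c in gen_cols]
                 for r in cohort.itertuples(index=False)}
    rows = []
    for net in result.networks:
        if net.ego_id not in ego_items:
            raise StageError(f"network ego {net.ego_id} missing from cohort table")
        f = compute_features(net, ego_items[net.ego_id], weights)
        rows.append({"ego_id": net.ego_id, **asdict(f)})
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "features.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    if result.excluded:
        (outdir / "excluded_egos.json").write_text(json.dumps(result.excluded, indent=1))
    logger.info("features for %d egos (%d excluded)", len(rows), len(result.excluded))
    return path


def stage_analyze(cohort_path: Path, features_path: Path, fits_path: Path,
                  behavior_path: Path, outdir: Path, seed: int = 0) -> Path:
    cohort = pd.read_csv(_require(cohort_path, "analyze"), dtype={"ego_id": str})
    features = pd.read_csv(_require(features_path, "analyze"), dtype={"ego_id": str})
    fits = pd.read_csv(_require(fits_path, "analyze"), dtype={"ego_id": str})
    behavior = pd.read_csv(_require(behavior_path, "analyze"), dtype={"ego_id": str})
    table = build_cohort_table(cohort, features, fits, behavior)
    results = analyze_cohort(table, seed=seed)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "cohort_table.csv", index=False)
    path = outdir / "analysis_results.json"
    path.write_text(json.dumps(results, indent=1, default=float))
    return path


def stage_recover(outdir: Path, seed: int, n_sets: int = 20, n_iter: int = 10,
                  schedule_config: Optional[ScheduleConfig] = None) -> Path:
    """Simulate/refit parameter recovery; write recovery.csv."""
    rng = np.random.default_rng(seed)
    schedule = build_schedule(schedule_config or ScheduleConfig())
    sets = [HGFParams(mu3_0=float(-3.0 + 0.75 * rng.standard_normal()),
                      omega2=float(-0.5 + 0.5 * rng.standard_normal()))
            for _ in range(n_sets)]
    table = parameter_recovery(sets, schedule, n_iter=n_iter, rng=rng)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "recovery.csv"
    table.to_csv(path, index=False)
    (outdir / "recovery_summary.json").write_text(
        json.dumps(table.attrs["recovery_r"], indent=1))
    return path


def replicate_directions(seed: int, n_egos: int = 400,
                         n_starts: int = 4) -> Dict[str, object]:
    """Generate a cohort at study-default conditions and test the headline
    directional effects.

    Returns the five sign checks — high-paranoia group higher in fitted
    mu3_0 and win-switch, lower in lose-stay; positive Spearman
    paranoia-mu3_0; negative size x belief coefficient in the reduced
    psychopathology model — plus the underlying statistics.  The fitted
    mu3_0 is the first-half MAP estimate, as consumed downstream.
    """
    from .stats_pipeline import fit_reduced_model_psych, spearman

    config = CohortConfig(n_egos=n_egos, seed=seed)
    data = generate_cohort(config)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for ego, feat, sess in zip(data.egos, data.features, data.sessions):
        fit = fit_hgf(sess, half="first", n_starts=n_starts,
                      seed=int(rng.integers(2**31 - 1)))
        rows.append({"ego_id": ego.ego_id, "group": ego.paranoia_group,
                     "rgpts_total": ego.rgpts_total, "bai": ego.bai,
                     "bdi": ego.bdi, "mu30": fit.params.mu3_0,
                     "win_switch": win_switch_rate(sess),
                     "lose_stay": lose_stay_rate(sess),
                     "size": feat.size, "strong_ties": feat.strong_ties,
                     "kinship": feat.kinship, "asb": feat.asb})
    df = pd.DataFrame(rows)
    from .stats_pipeline import psychopathology_composite

    df["psychopathology"] = psychopathology_composite(df["bai"], df["bdi"],
                                                      df["rgpts_total"])

    def z(col: str) -> np.ndarray:
        v = df[col].to_numpy(dtype=float)
        return (v - v.mean()) / v.std()

    df["SIZE"], df["TIES"] = z("size"), z("strong_ties")
    df["KIN"], df["BELIEF"] = z("kinship"), z("asb")
    hi, lo = df[df["group"] == "high"], df[df["group"] == "low"]
    rho = spearman(df["rgpts_total"], df["mu30"]).statistic
    beta = fit_reduced_model_psych(df).coef(("SIZE", "BELIEF"))
    return {
        "mu30_higher_in_high_paranoia": bool(hi["mu30"].mean() > lo["mu30"].mean()),
        "win_switch_higher_in_high_paranoia": bool(
            hi["win_switch"].mean() > lo["win_switch"].mean()),
        "lose_stay_lower_in_high_paranoia": bool(
            hi["lose_stay"].mean() < lo["lose_stay"].mean()),
        "rho_paranoia_mu30_positive": bool(rho > 0),
        "size_belief_interaction_negative": bool(beta < 0),
        "rho_paranoia_mu30": float(rho),
        "beta_size_belief": float(beta),
        "n_high": int(len(hi)), "n_low": int(len(lo)),
    }


def config_hash(config: CohortConfig, seed: int) -> str:
    blob = json.dumps({"config": repr(config), "seed": seed,
                       "version": __version__}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: CohortConfig, outdir: Path, seed: int,
                 fit_kwargs: Optional[dict] = None) -> Path:
    """Run generate -> fit -> behavior -> features -> analyze; write manifest.

    All stage seeds derive deterministically from ``seed``; identical
    config+seed produce identical manifests.
    """
    outdir = Path(outdir)
    ss = np.random.SeedSequence(seed)
    s_gen, s_fit, s_an = (int(s.generate_state(1)[0] % (2**31 - 1))
                          for s in ss.spawn(3))
    config = CohortConfig(**{**_config_dict(config), "seed": s_gen})
    stage = "generate"
    try:
        paths = stage_generate(config, outdir)
        stage = "fit"
        fits = stage_fit(paths["sessions"], outdir, seed=s_fit,
                         **(fit_kwargs or {}))
        stage = "behavior"
        behavior = stage_behavior(paths["sessions"], outdir)
        stage = "features"
        feats = stage_features(paths["edges"], paths["alters"], paths["cohort"],
                               outdir, config.asb_weights)
        stage = "analyze"
        stage_analyze(paths["cohort"], feats, fits, behavior, outdir, seed=s_an)
    except Exception:
        logger.error("pipeline failed in stage '%s'", stage)
        raise
    manifest = {"seed": seed, "config_hash": config_hash(config, seed),
                "version": __version__,
                "stages": ["generate", "fit", "behavior", "features", "analyze"]}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["task_config"] = config.task_config
    d["asb_weights"] = config.asb_weights
    return d
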