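"""Experiment orchestration: sample -> simulate -> fit -> analyze.

Every stage persists its outputs as delimited text under the experiment
directory and is skipped on re-run when those outputs already exist, so a
partially completed experiment resumes where it stopped.  Seeding is
hierarchical (master seed -> per-stage -> per-network -> per-trial), which
makes the whole artifact bundle reproducible bit-for-bit from the
configuration alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .ddm import WienerDiffusionModel
from .ensemble import (
    ControlEnsembleAnalysis, FeatureMatrices, regression_influence,
)
from .network import VARIABLE_WEIGHT_NAMES, WeightConfig
from .protocol import (
    RATE_FEATURE_COLUMNS, DecisionCircuit, NoDecidedTrialsError,
    compute_rate_features, trials_frame,
)
from .sampling import default_bounds, latin_hypercube

logger = logging.getLogger("cbgt.experiment")


class SchemaError(ValueError):
    """A persisted table does not match its expected schema."""


def write_table(df: pd.DataFrame, path) -> None:
    """Write a delimited table preserving >= 15 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path, expected_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if expected_columns is not None:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _stage_seeds(master_seed: int) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(master_seed)
    names = ["sample", "simulate", "fit", "analyze"]
    return dict(zip(names, root.spawn(len(names))))


def run_sample(config: ExperimentConfig, out: Path) -> pd.DataFrame:
    design_path = out / "design.tsv"
    if design_path.exists():
        logger.info("sample: reusing %s", design_path)
        return read_table(design_path, VARIABLE_WEIGHT_NAMES)
    ss = _stage_seeds(config.master_seed)["sample"]
    bounds, names = default_bounds()
    design = latin_hypercube(bounds, config.n_networks, seed=_seed_int(ss),
                             names=names)
    write_table(design.to_frame(), design_path)
    write_table(pd.DataFrame({"name": names, "lower": bounds[:, 0],
                              "upper": bounds[:, 1]}), out / "bounds.tsv")
    return design.to_frame()


def run_simulate(config: ExperimentConfig, out: Path,
                 design: pd.DataFrame) -> pd.DataFrame:
    """Run one session per sampled network; returns the R feature table."""
    beh_dir = out / "behavior"
    feat_path = out / "features.tsv"
    if feat_path.exists():
        logger.info("simulate: reusing %s", feat_path)
        return read_table(feat_path)
    ss = _stage_seeds(config.master_seed)["simulate"]
    net_seeds = ss.spawn(len(design))
    rows = []
    for i, (_, w_row) in enumerate(design.iterrows()):
        net_path = beh_dir / f"net_{i:04d}.tsv"
        conn_ss, sess_ss = net_seeds[i].spawn(2)
        if not net_path.exists():
            t0 = time.perf_counter()
            weights = WeightConfig.from_vector(
                w_row[list(VARIABLE_WEIGHT_NAMES)].to_numpy())
            circuit = DecisionCircuit(weights=weights,
                                      connectivity_seed=_seed_int(conn_ss))
            summary, trials = circuit.run_session(
                config.protocol, n_trials=config.n_trials,
                seed=_seed_int(sess_ss))
            write_table(trials_frame(trials), net_path)
            logger.info("simulate: network %d/%d in %.1f s (p_A=%.2f, rt=%.1f ms)",
                        i + 1, len(design), time.perf_counter() - t0,
                        summary.p_A, summary.rt_mean)
        df = read_table(net_path, ["trial", "choice", "rt_ms"])
        row = {"network": i}
        decided = df[df["choice"].isin(["A", "B"])]
        if len(decided) == 0:
            row["excluded"] = True
            row.update({c: np.nan for c in RATE_FEATURE_COLUMNS})
        else:
            row["excluded"] = False
            feats = _features_from_frame(df)
            row.update(dict(zip(RATE_FEATURE_COLUMNS, feats)))
            row["p_A"] = float((decided["choice"] == "A").mean())
            row["rt_mean"] = float(decided["rt_ms"].mean())
            row["n_decided"] = int(len(decided))
        rows.append(row)
    features = pd.DataFrame(rows)
    write_table(features, feat_path)
    return features


def _features_from_frame(df: pd.DataFrame) -> np.ndarray:
    """Rate features (channel sums/differences) from a persisted trial table."""
    decided = df[df["choice"].isin(["A", "B"])]
    if len(decided) == 0:
        raise NoDecidedTrialsError("no decided trials")
    feats = []
    regions = [c.rsplit("_sum", 1)[0] for c in RATE_FEATURE_COLUMNS if c.endswith("_sum")]
    for r in regions:
        feats.append((decided[f"rate_{r}_A"] + decided[f"rate_{r}_B"]).mean())
    for r in regions:
        feats.append((decided[f"rate_{r}_A"] - decided[f"rate_{r}_B"]).mean())
    feats.append(decided["rate_CxI"].mean())
    feats.append(decided["rate_FSI"].mean())
    return np.array(feats)


def run_fit(config: ExperimentConfig, out: Path, design: pd.DataFrame) -> pd.DataFrame:
    fits_path = out / "fits.tsv"
    if fits_path.exists():
        logger.info("fit: reusing %s", fits_path)
        return read_table(fits_path, ["network", "a", "nu", "t", "z"])
    ss = _stage_seeds(config.master_seed)["fit"]
    fit_seeds = ss.spawn(len(design))
    rows = []
    for i in range(len(design)):
        df = read_table(out / "behavior" / f"net_{i:04d}.tsv")
        decided = df[df["choice"].isin(["A", "B"])]
        row = {"network": i}
        if len(decided) < 2:
            row.update({"a": np.nan, "nu": np.nan, "t": np.nan, "z": np.nan,
                        "log_likelihood": np.nan, "converged": False,
                        "excluded": True})
        else:
            model = WienerDiffusionModel.from_dataframe(df)
            res = model.fit(n_starts=config.ddm_n_starts,
                            seed=_seed_int(fit_seeds[i]))
            p = res.params
            row.update({"a": p.a, "nu": p.nu, "t": p.t, "z": p.z,
                        "log_likelihood": res.log_likelihood,
                        "converged": res.converged, "excluded": False})
        rows.append(row)
    fits = pd.DataFrame(rows)
    write_table(fits, fits_path)
    return fits


def run_analyze(config: ExperimentConfig, out: Path, design: pd.DataFrame,
                features: pd.DataFrame, fits: pd.DataFrame):
    """CCA / clustering stage; writes CV scores, loadings and cluster labels."""
    ss = _stage_seeds(config.master_seed)["analyze"]
    keep = (~features["excluded"].astype(bool)) & (~fits["excluded"].astype(bool))
    excluded = [{"network": int(i)} for i in features.loc[~keep, "network"]]
    W = design.loc[keep.to_numpy(), list(VARIABLE_WEIGHT_NAMES)].to_numpy()
    R = features.loc[keep, list(RATE_FEATURE_COLUMNS)].to_numpy()
    P = fits.loc[keep, ["a", "nu", "t", "z"]].to_numpy()
    data = FeatureMatrices(W=W, R=R, P=P,
                           network_ids=features.loc[keep, "network"].to_numpy(),
                           excluded=excluded)
    analysis = ControlEnsembleAnalysis(
        data, w_names=VARIABLE_WEIGHT_NAMES, r_names=RATE_FEATURE_COLUMNS)
    n = data.n
    folds = config.cv_folds
    if n % folds != 0:
        # contiguous-block CV needs equal folds: trim the tail remainder
        n_keep = (n // folds) * folds
        data = FeatureMatrices(W=data.W[:n_keep], R=data.R[:n_keep],
                               P=data.P[:n_keep],
                               network_ids=data.network_ids[:n_keep],
                               excluded=data.excluded)
        analysis = ControlEnsembleAnalysis(
            data, w_names=VARIABLE_WEIGHT_NAMES, r_names=RATE_FEATURE_COLUMNS)
    results = analysis.fit(n_folds=folds, seed=_seed_int(ss),
                           sensitivity_runs=config.sensitivity_runs,
                           sensitivity_step=config.sensitivity_step,
                           k_grid=config.kmeans_k_grid)
    write_table(results.cv_wr.drop(columns=["scores"]), out / "cv_scores_WR.tsv")
    write_table(results.cv_rp.drop(columns=["scores"]), out / "cv_scores_RP.tsv")
    for tag, (lx, ly) in (("WR", results.loadings_wr), ("RP", results.loadings_rp)):
        write_table(lx.to_frame().reset_index(names="variable"),
                    out / f"loadings_{tag}_X.tsv")
        write_table(ly.to_frame().reset_index(names="variable"),
                    out / f"loadings_{tag}_Y.tsv")
    labels = results.clustering[results.selected_K].labels
    write_table(pd.DataFrame({"network": data.network_ids, "cluster": labels}),
                out / "clusters.tsv")
    influence = regression_influence(
        W, R, weight_names=VARIABLE_WEIGHT_NAMES, rate_names=RATE_FEATURE_COLUMNS)
    write_table(influence, out / "regression_influence.tsv")
    return results


def run_experiment(config: ExperimentConfig):
    """Execute all stages; resumable from persisted intermediates."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "master_seed": config.master_seed,
        "n_networks": config.n_networks,
        "n_trials": config.n_trials,
        "stages": [],
    }
    manifest_path = out / "manifest.json"
    config.to_yaml(out / "config.yaml")
    results = {}
    try:
        for name, fn, args in (
            ("sample", run_sample, ()),
            ("simulate", run_simulate, ("design",)),
            ("fit", run_fit, ("design",)),
            ("analyze", run_analyze, ("design", "features", "fits")),
        ):
            t0 = time.perf_counter()
            results[{"sample": "design", "simulate": "features",
                     "fit": "fits", "analyze": "analysis"}[name]] = fn(
                config, out, *[results[a] for a in args])
            manifest["stages"].append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 2)})
    except Exception as exc:
        manifest["incomplete"] = True
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return results
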