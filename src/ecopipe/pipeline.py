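"""End-to-end orchestration: landscape -> ES layers -> pair matrix ->
BBN drivers -> boosted-tree/Shapley thresholds.

``run_pipeline`` executes the stages in order on a seeded synthetic
landscape, persists every intermediate artifact as plain text (ASCII
grids, CSV tables, JSON reports) and returns a :class:`RunReport`.  All
stage outputs are pure functions of (config, seed): rerunning with the
same configuration reproduces the result files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bbn
from .es import ES_NAMES, compute_all_es
from .gbdt import TrainConfig, evaluate_classifier, fit_gbdt, make_pair_labels, predict_proba
from .io import config_hash, default_biophysical, default_carbon_pools, write_ascii_grid
from .landscape import FACTOR_NAMES, GeneratorConfig, generate_landscape
from .pairs import pairwise_relationship_matrix
from .shapley import exact_shap
from .thresholds import bin_and_smooth, detect_thresholds

log = logging.getLogger("ecopipe")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "select_key_factors"]

# Default factor -> ES parent structure for the two-layer network: each ES
# node's parents are the factors its production model and the regional
# sensitivity pattern tie it to, trimmed to four for tractable CPTs.
DEFAULT_PARENTS = {
    "N": ("landuse", "pre", "r", "k"),
    "P": ("landuse", "pre", "r", "k"),
    "HQ": ("landuse", "k", "ndvi", "pop"),
    "SDR": ("pre", "k", "r", "slope"),
    "CS": ("ndvi", "k", "pop", "tem"),
    "WY": ("r", "pre", "tem"),
    "FS": ("pop", "slope", "ndvi", "landuse"),
}

STAGES = ("generate", "es", "pairs", "bbn", "thresholds")


@dataclass
class RunConfig:
    seed: int = 0
    nrows: int = 64
    ncols: int = 64
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    n_states: int = 3
    cpt_alpha: float = 1.0
    alpha: float = 0.05            # FDR significance level for pairs
    split: float = 0.7             # train fraction for network validation
    percentile: float = 95.0
    n_boot: int = 10_000
    max_scenarios: int = 24
    top_k_factors: int = 4         # per-ES VR screening depth
    n_threshold_pairs: int = 3     # pairs taken to the threshold stage
    gbdt_sample: int = 2000        # cells used to train the classifier
    shap_sample: int = 800         # cells explained
    shap_background: int = 50
    n_bins: int = 20
    loess_frac: float = 0.5
    gbdt: dict = field(default_factory=dict)  # TrainConfig overrides
    fs_total: float = 6.5e7
    write_rasters: bool = False
    out_dir: str | None = None

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(nrows=self.nrows, ncols=self.ncols, **self.generator)

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(**{"n_estimators": 100, "max_depth": 3,
                              "learning_rate": 0.1, **self.gbdt, "seed": seed})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: RunConfig
    provenance: dict
    pair_results: list = field(default_factory=list)
    accuracy: dict = field(default_factory=dict)
    vr_table: pd.DataFrame | None = None
    key_factors: dict = field(default_factory=dict)
    driver_result: object = None
    thresholds: dict = field(default_factory=dict)  # (pair, driver) -> ThresholdSet
    stage_seconds: dict = field(default_factory=dict)


def select_key_factors(vr_table: pd.DataFrame, top_k: int = 4) -> dict:
    """Rank factors by variance reduction per ES; the union over ESs is the
    candidate driver set.  Ties order deterministically by factor name."""
    if vr_table is None or len(vr_table) == 0:
        raise ValueError("empty VR table")
    per_es = {}
    for es, sub in vr_table.groupby("es"):
        ranked = sub.sort_values(["vr", "factor"], ascending=[False, True])
        per_es[es] = list(ranked["factor"].head(top_k))
    union = sorted({f for fs in per_es.values() for f in fs})
    return {"per_es": per_es, "union": union}


def _pair_frame(pair_results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "es_a": pr.pair[0],
                "es_b": pr.pair[1],
                "r": pr.r,
                "n": pr.n,
                "p_raw": pr.p_raw,
                "p_fdr": pr.p_fdr,
                "ci_low": pr.ci95[0],
                "ci_high": pr.ci95[1],
                "relation": pr.relation,
                "strength": pr.strength,
            }
            for pr in pair_results
        ]
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig, stages=STAGES) -> RunReport:
    """Execute the requested pipeline stages in order (earlier stages are
    always run since later ones consume their outputs)."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    last = max(STAGES.index(s) for s in stages)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in config.to_dict().items()
              if k not in ("out_dir", "write_rasters")}
    provenance = {"config_hash": config_hash(hashed), "seed": config.seed}
    report = RunReport(config=config, provenance=provenance)
    t0 = time.perf_counter()

    def tick(stage):
        nonlocal t0
        now = time.perf_counter()
        report.stage_seconds[stage] = now - t0
        log.info("stage %-11s %6.2fs", stage, now - t0)
        t0 = now

    # -- generate ----------------------------------------------------
    grid, _ = generate_landscape(config.generator_config(), seed=config.seed)
    if out and config.write_rasters:
        for name in grid.LAYERS:
            write_ascii_grid(out / f"{name}.asc", grid.layer(name),
                             cellsize=grid.cellsize, mask=grid.mask)
    tick("generate")
    if last < 1:
        return report

    # -- es ----------------------------------------------------------
    layers = compute_all_es(grid, default_carbon_pools(), default_biophysical(),
                            fs_total=config.fs_total)
    if out:
        _write_csv(pd.DataFrame([L.summary(grid.mask) for L in layers.values()]),
                   out / "es_summary.csv")
        if config.write_rasters:
            for name, L in layers.items():
                write_ascii_grid(out / f"es_{name}.asc", L.grid,
                                 cellsize=grid.cellsize, mask=grid.mask)
    tick("es")
    if last < 2:
        return report

    # -- pairs -------------------------------------------------------
    es_grids = {name: L.grid for name, L in layers.items()}
    report.pair_results = pairwise_relationship_matrix(
        es_grids, mask=grid.mask, alpha=config.alpha
    )
    if out:
        _write_csv(_pair_frame(report.pair_results), out / "pairs.csv")
    tick("pairs")
    if last < 3:
        return report

    # -- bbn ---------------------------------------------------------
    factors = grid.factor_table()
    nodes, data = {}, {}
    for col in factors.columns:
        if col == "landuse":
            cats = sorted(np.unique(factors[col]))
            node, idx = bbn.discretize_categorical(factors[col].to_numpy(), col, cats)
        else:
            node, idx = bbn.discretize_equal_frequency(
                factors[col].to_numpy(), config.n_states, col
            )
        nodes[col], data[col] = node, idx
    for name in ES_NAMES:
        v = es_grids[name][grid.mask]
        node, idx = bbn.discretize_equal_frequency(v, config.n_states, name)
        nodes[name], data[name] = node, idx
    data = pd.DataFrame(data)
    parents = {f: () for f in factors.columns}
    parents.update(DEFAULT_PARENTS)

    report.accuracy = {}
    evaluation = bbn.evaluate_network(
        nodes, parents, data, target_nodes=list(ES_NAMES),
        split=config.split, seed=config.seed + 1, alpha=config.cpt_alpha,
    )
    report.accuracy = {
        "overall": evaluation["overall_accuracy"],
        "per_target": {k: v["accuracy"] for k, v in evaluation["per_target"].items()},
    }
    net = bbn.learn_cpts(data, nodes, parents, alpha=config.cpt_alpha)

    vr_rows = []
    for es in ES_NAMES:
        for f in FACTOR_NAMES:
            vr_rows.append({"es": es, "factor": f,
                            "vr": bbn.variance_reduction(net, es, f)})
    report.vr_table = pd.DataFrame(vr_rows)
    report.key_factors = select_key_factors(report.vr_table, config.top_k_factors)

    scenarios = bbn.scenarios_from_pairs(report.pair_results)[: config.max_scenarios]
    deltas = (
        pd.concat([bbn.run_scenario(net, sc) for sc in scenarios], ignore_index=True)
        if scenarios
        else pd.DataFrame(columns=["scenario", "scenario_type", "node", "state",
                                   "prior", "posterior", "delta"])
    )
    factor_deltas = deltas[deltas["node"].isin(FACTOR_NAMES)].reset_index(drop=True)
    if len(factor_deltas) >= 20:
        report.driver_result = bbn.identify_drivers(
            factor_deltas,
            percentile=config.percentile,
            n_boot=config.n_boot,
            seed=config.seed + 2,
            factor_nodes=list(FACTOR_NAMES),
        )
    if out:
        _write_csv(report.vr_table, out / "vr.csv")
        _write_csv(deltas, out / "deltas.csv")
        with open(out / "network.json", "w") as fh:
            fh.write(net.to_json())
        payload = {
            "accuracy": report.accuracy,
            "key_factors": report.key_factors,
            "n_scenarios": len(scenarios),
        }
        if report.driver_result is not None:
            payload["drivers"] = report.driver_result.drivers
            payload["threshold"] = report.driver_result.threshold
            payload["ci95"] = list(report.driver_result.ci95)
        with open(out / "drivers.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    tick("bbn")
    if last < 4:
        return report

    # -- thresholds --------------------------------------------------
    shap_features = report.key_factors["union"][:6]
    feature_matrix = factors[shap_features].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed + 3)
    significant = [pr for pr in report.pair_results if pr.relation != "non-significant"]
    significant.sort(key=lambda pr: (-abs(pr.r), pr.pair))
    rows_curve = []
    n_processed = 0
    for pr in significant:
        if n_processed >= config.n_threshold_pairs:
            break
        a, b = pr.pair
        labels, keep, _ = make_pair_labels(es_grids[a], es_grids[b], grid.mask)
        Xk = feature_matrix[keep]
        n_avail = len(labels)
        take = min(config.gbdt_sample, n_avail)
        sel = rng.choice(n_avail, size=take, replace=False)
        Xs, ys = Xk[sel], labels[sel]
        if len(np.unique(ys)) < 2:
            log.warning("pair %s-%s has single-class labels; skipped", a, b)
            continue
        n_processed += 1
        model = fit_gbdt(Xs, ys, config.train_config(seed=config.seed + 4))
        scores = evaluate_classifier(ys, predict_proba(model, Xs))
        explain = rng.choice(len(Xs), size=min(config.shap_sample, len(Xs)), replace=False)
        bg = Xs[rng.choice(len(Xs), size=min(config.shap_background, len(Xs)),
                           replace=False)]
        phi = exact_shap(model, Xs[explain], bg)
        # the pair's key driver: largest mean absolute attribution
        order = np.argsort(-np.abs(phi).mean(axis=0))
        j = int(order[0])
        driver = shap_features[j]
        curve = bin_and_smooth(Xs[explain, j], phi[:, j],
                               n_bins=config.n_bins, loess_frac=config.loess_frac)
        if len(curve.feature_mean) < 3:  # near-categorical driver: no curve
            log.warning("pair %s-%s driver %s has <3 bins; no threshold search",
                        a, b, driver)
            from .thresholds import ThresholdSet
            ts = ThresholdSet()
        else:
            ts = detect_thresholds(curve)
        report.thresholds[(pr.pair, driver)] = ts
        for xc, direction in ts.crossings:
            rows_curve.append({"es_a": a, "es_b": b, "driver": driver,
                               "kind": "crossing", "lo": xc, "hi": xc,
                               "direction": direction,
                               "train_auc": scores["auc"]})
        for lo, hi in ts.intervals:
            rows_curve.append({"es_a": a, "es_b": b, "driver": driver,
                               "kind": "interval", "lo": lo, "hi": hi,
                               "direction": "", "train_auc": scores["auc"]})
        if out:
            _write_csv(
                pd.DataFrame({
                    "feature_mean": curve.feature_mean,
                    "shap_mean": curve.shap_mean,
                    "ci_halfwidth": curve.ci_halfwidth,
                    "count": curve.count,
                    "smoothed": curve.smoothed,
                }),
                out / f"curve_{a}_{b}_{driver}.csv",
            )
    if out:
        _write_csv(pd.DataFrame(rows_curve,
                                columns=["es_a", "es_b", "driver", "kind", "lo",
                                         "hi", "direction", "train_auc"]),
                   out / "thresholds.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "provenance": provenance,
                    "accuracy": report.accuracy,
                    "n_pairs": len(report.pair_results),
                    "key_factors": report.key_factors,
                    "drivers": report.driver_result.drivers
                    if report.driver_result
                    else None,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
    tick("thresholds")
    return report
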