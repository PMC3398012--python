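"""End-to-end orchestration of the descriptor-connectivity workflow.

The five framework components run in order: curation (or synthetic
study generation), descriptor-matrix preparation (constant-column
removal, class balancing), PLS-DA/VIP selection per endpoint with a
permutation test, the classifier bake-off plus CFS check, the
small-data-set robustness score, and finally the integrative stage
(intersection, third-endpoint evaluation with the common descriptors,
ANOVA, connectivity-map export).

Every threshold of the workflow is a named config key with its
conventional default (label thresholds 80/70/-4, VIP cutoff 1, model
permutation alpha 0.01, ANOVA alpha 0.05, robustness 1000 x 100
resamples, significance at score >= 5).  The global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence`` so each stage is
independently reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfs as cfs_mod
from . import connectivity as conn_mod
from .curation import LabelledDataset, balance_dataset
from .descriptors import DescriptorMatrix, remove_constant_descriptors
from .mlbench import classifier_bakeoff, cross_validate, default_classifiers, \
    per_descriptor_accuracy, RidgeLogistic
from .plsda import fit_plsda, permutation_test, select_vip, vip_scores
from .robustness import small_set_score
from .synthetic import gen_two_endpoint_study

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_full_pipeline", "PipelineError",
           "load_labelled_csv", "save_labelled_csv"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    return {
        "seed": 0,
        "mode": "simulate",
        "tier": "core",
        "simulate": {
            "n_per_endpoint": 300, "p": 198, "n_common": 47,
            "n_unique_a": 2, "n_unique_b": 3, "effect_sd": 1.5,
            "noise_sd": 0.5, "rho": 0.3,
        },
        "thresholds": {"bioavailability": 80.0, "hia": 70.0, "caco2": -4.0},
        "constant_tol": 1e-12,
        "vip_cutoff": 1.0,
        "plsda": {"max_components": 10},
        "permutation": {"n_perm": 999, "alpha": 0.01, "statistic": "q2"},
        "cv": {"repeats": 10, "folds": 10},
        "bakeoff": {"enabled": True, "rf_trees": 100},
        "cfs": {"stall_limit": 5},
        "robustness": {"n_sets": 1000, "set_size": 100},
        "anova_alpha": 0.05,
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _stage_seed(root_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), stage])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=str) + "\n")


def save_labelled_csv(d: LabelledDataset, path) -> None:
    frame = d.X.copy()
    frame["label"] = d.y
    frame.to_csv(path, index_label="molecule_id")


def load_labelled_csv(path, endpoint: str = "endpoint") -> LabelledDataset:
    frame = pd.read_csv(path, index_col="molecule_id")
    if "label" not in frame.columns:
        raise ValueError(f"{path}: no 'label' column")
    y = frame.pop("label").to_numpy(dtype=int)
    return LabelledDataset(frame, y, endpoint)


def _prepare_endpoint(d: LabelledDataset, config: dict,
                      seed: int) -> tuple[LabelledDataset, list[str]]:
    matrix = DescriptorMatrix(values=d.X,
                              families={c: "synthetic" for c in d.X.columns},
                              tiers={c: "core" for c in d.X.columns})
    cleaned, removed = remove_constant_descriptors(matrix,
                                                   config["constant_tol"])
    balanced = balance_dataset(
        LabelledDataset(cleaned.values, d.y, d.endpoint, d.provenance), seed)
    return balanced, removed


def _select_stage(d: LabelledDataset, config: dict, seed: int) -> dict:
    model = fit_plsda(d.X, d.y, A_max=config["plsda"]["max_components"])
    perm = permutation_test(d.X, d.y,
                            n_perm=config["permutation"]["n_perm"],
                            seed=seed,
                            statistic=config["permutation"]["statistic"],
                            A_max=config["plsda"]["max_components"])
    selected = select_vip(model, config["vip_cutoff"])
    if not selected:
        raise PipelineError(
            "select", f"empty selection: no descriptor reached "
            f"VIP >= {config['vip_cutoff']} for endpoint {d.endpoint}")
    vip = vip_scores(model)
    return {
        "endpoint": d.endpoint,
        "n_components": int(model.n_components_),
        "r2y": float(model.r2y_),
        "q2": float(model.q2_),
        "p_value": float(perm["p_value"]),
        "significant": bool(perm["p_value"] <= config["permutation"]["alpha"]),
        "selected": selected,
        "vip": {str(k): float(v) for k, v in vip.items()},
        "model": model,
    }


def run_full_pipeline(config: dict | None = None,
                      out_dir: str | Path | None = None,
                      datasets: dict[str, LabelledDataset] | None = None,
                      truth: dict | None = None) -> dict:
    """Run the full workflow; returns a results dict and writes reports.

    ``datasets`` maps ``{"hia": ..., "caco2": ..., "bioavailability": ...}``
    and overrides the configured input mode (used by the CSV path of the
    CLI); otherwise the synthetic two-endpoint study is generated.
    """
    config = _merge(default_config(), config or {})
    seed = int(config["seed"])
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": copy.deepcopy(config)}

    # -- stage 1: inputs ----------------------------------------------------
    if datasets is None:
        if config["mode"] != "simulate":
            raise PipelineError("inputs", "mode 'csv' needs datasets=...")
        study = gen_two_endpoint_study(seed=_stage_seed(seed, 0),
                                       **config["simulate"])
        datasets = study.datasets
        truth = {"common": study.common, "unique_a": study.unique_a,
                 "unique_b": study.unique_b}
        results["truth"] = truth
    for key in ("hia", "caco2", "bioavailability"):
        if key not in datasets:
            raise PipelineError("inputs", f"missing endpoint data set {key!r}")

    # -- stage 2: prepare + select per endpoint -----------------------------
    selections: dict[str, dict] = {}
    for i, endpoint in enumerate(("hia", "caco2")):
        balanced, removed = _prepare_endpoint(datasets[endpoint], config,
                                              _stage_seed(seed, 10 + i))
        try:
            sel = _select_stage(balanced, config, _stage_seed(seed, 20 + i))
        except ValueError as exc:
            raise PipelineError("select", f"{endpoint}: {exc}") from exc
        sel["removed_constant"] = removed
        sel["n_balanced"] = balanced.n
        selections[endpoint] = sel
        if out is not None:
            payload = {k: v for k, v in sel.items() if k != "model"}
            _write_json(out / f"vip_{endpoint}.json", payload)

    # -- stage 3: bake-off on the HIA-like endpoint -------------------------
    cvcfg = config["cv"]
    if config["bakeoff"]["enabled"]:
        hia_sel = datasets["hia"].subset_descriptors(
            selections["hia"]["selected"])
        ranked = classifier_bakeoff(
            hia_sel,
            classifiers=default_classifiers(
                _stage_seed(seed, 30), rf_trees=config["bakeoff"]["rf_trees"]),
            seed=_stage_seed(seed, 31),
            repeats=cvcfg["repeats"], folds=cvcfg["folds"])
        results["bakeoff"] = [
            {"classifier": r.classifier,
             "mean_accuracy": r.mean_accuracy,
             "mean_precision": r.mean_precision} for r in ranked]
        if out is not None:
            pd.DataFrame(results["bakeoff"]).to_csv(
                out / "bakeoff.csv", index=False)

    # -- stage 4: intersection ----------------------------------------------
    common, unique_a, unique_b = conn_mod.intersect_descriptors(
        selections["hia"]["selected"], selections["caco2"]["selected"])
    if not common:
        raise PipelineError("intersect", "empty common descriptor set")
    results["common"] = common
    results["unique_hia"] = unique_a
    results["unique_caco2"] = unique_b

    # -- stage 5: third-endpoint evaluation with the common set -------------
    joint = datasets["bioavailability"].subset_descriptors(common)
    eval_seed = _stage_seed(seed, 40)
    profile = per_descriptor_accuracy(joint, seed=eval_seed,
                                      repeats=cvcfg["repeats"],
                                      folds=cvcfg["folds"])
    results["joint_eval"] = profile

    # CFS check: does a reduced subset hold up?
    selector = cfs_mod.CFSSelector(
        stall_limit=config["cfs"]["stall_limit"]).fit(joint.X, joint.y)
    cfs_names = list(selector.subset_.names)
    cfs_eval = None
    if cfs_names:
        cfs_eval = cross_validate(
            RidgeLogistic(lam=1e-8), joint.subset_descriptors(cfs_names),
            repeats=cvcfg["repeats"], folds=cvcfg["folds"],
            seed=eval_seed, name="cfs_subset").mean_accuracy
    results["cfs"] = {"selected": cfs_names, "merit": selector.merit_,
                      "accuracy": cfs_eval,
                      "full_set_accuracy": profile["combined"]}

    # -- stage 6: robustness score ------------------------------------------
    rob = small_set_score(
        joint, reference_accuracy=profile["combined"],
        n_sets=config["robustness"]["n_sets"],
        set_size=config["robustness"]["set_size"],
        seed=_stage_seed(seed, 50))
    results["robustness"] = {
        "m": rob.m, "n": rob.n, "score": rob.score,
        "significant": rob.significant,
        "reference_accuracy": rob.reference_accuracy,
        "redraws": rob.redraws,
    }

    # -- stage 7: ANOVA + connectivity map ----------------------------------
    anova = conn_mod.anova_table(joint, alpha=config["anova_alpha"])
    results["anova_significant"] = int(anova["significant"].sum())
    graph = conn_mod.build_connectivity_map(
        common, unique_a, unique_b,
        per_descriptor_accuracy=profile["individual"])
    results["connectivity_nodes"] = graph.number_of_nodes()

    if out is not None:
        _write_json(out / "intersection.json", {
            "common": common, "unique_hia": unique_a,
            "unique_caco2": unique_b})
        _write_json(out / "joint_eval.json", profile)
        _write_json(out / "cfs.json", results["cfs"])
        _write_json(out / "robustness.json", results["robustness"])
        if rob.accuracies is not None:
            pd.DataFrame({"accuracy": rob.accuracies}).to_csv(
                out / "robustness_histogram.csv", index=False)
        anova.to_csv(out / "anova.csv", index_label="descriptor")
        conn_mod.export_connectivity(graph, out)
        if truth is not None:
            _write_json(out / "truth.json", truth)
        manifest = {k: v for k, v in results.items()
                    if k in ("common", "unique_hia", "unique_caco2",
                             "robustness", "anova_significant",
                             "connectivity_nodes")}
        _write_json(out / "manifest.json", manifest)
    return results
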