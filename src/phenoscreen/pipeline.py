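"""Experiment driver: simulation -> preprocessing -> CV grid ->
attribution -> inference, as one reproducible run.

``run_experiment`` takes a single config mapping (YAML/JSON-friendly) and
writes the standard outputs: ``fold_aucs.csv``, ``predictions_<test>.csv``,
``auc_comparisons.csv``, ``effects.csv``, ``linkage.json``, an attribution
overlay gallery, and ``run_metadata.json`` capturing every seed and flag.
One master seed expands deterministically into per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io as psio, synthetic
from .attribution import integrated_gradients
from .classification import (ClassifierConfig, FieldDataset,
                             enumerate_channel_combinations,
                             run_cv_grid, train_classifier, _crops_for_records)
from .preprocessing import BIII, DAPI

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "layout": {
        "experiments": ["EXP1"],
        "cell_lines": ["CTRL1", "CTRL2", "CTRL3", "MUT1", "MUT2"],
        "conditions": ["control", "heat"],
        "wells_per_combo": 1,
    },
    "field_size": 540,
    "fields_per_well": None,       # None: sample uniformly in [10, 12]
    "n_z": None,                   # None: sample uniformly in [3, 5]
    "tests": ["isALS", "isHEAT"],
    "n_subsets": 5,
    "k_folds": 10,
    "split_level": "image",
    "tile_size": 270,
    "input_size": 224,
    "backbone": "scratch_small_cnn",
    "learning_rate": 0.001,
    "batch_size": 32,
    "epochs": 10,
    "attribution_steps": 50,
    "n_attribution_images": 4,
}


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master & 0x7FFFFFFF)
    names = ["simulate", "cv", "attribution"]
    return {n: int(np.random.default_rng(c).integers(0, 2 ** 31 - 1))
            for n, c in zip(names, ss.spawn(len(names)))}


def run_experiment(config: dict | None = None, seed: int = 0, out_dir="results") -> dict:
    """Run the full pipeline on synthetic data (or a manifest if the config
    names one) and persist all result tables.  Returns the result bundle in
    memory as well."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seeds = _stage_seeds(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if cfg.get("manifest"):
            manifest = psio.read_manifest(cfg["manifest"])
            dataset = psio.load_fields(manifest, root=Path(cfg["manifest"]).parent)
        else:
            layout = synthetic.PlateLayout(
                experiments=tuple(cfg["layout"]["experiments"]),
                cell_lines=tuple(cfg["layout"]["cell_lines"]),
                conditions=tuple(cfg["layout"]["conditions"]),
                wells_per_combo=cfg["layout"].get("wells_per_combo", 1))
            fields, manifest = synthetic.generate_plate(
                layout, seed=seeds["simulate"],
                size=(cfg["field_size"], cfg["field_size"]),
                fields_per_well=cfg["fields_per_well"], n_z=cfg["n_z"])
            dataset = FieldDataset.from_plate(fields)

        stage = "cv_grid"
        clf_config = ClassifierConfig(
            backbone=cfg["backbone"], learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"], epochs=cfg["epochs"], seed=seeds["cv"])
        rbps = sorted(dataset.markers - {DAPI, BIII})
        combos = enumerate_channel_combinations(rbps)
        fold_aucs, crop_preds = run_cv_grid(
            dataset, tests=cfg["tests"], combinations=combos,
            n_subsets=cfg["n_subsets"], k=cfg["k_folds"], config=clf_config,
            input_size=cfg["input_size"], tile_size=cfg["tile_size"],
            split_level=cfg["split_level"], return_predictions=True)

        stage = "aggregate"
        meta = {r.culture: r for r in dataset.records}
        tables = {"fold_aucs": fold_aucs}
        per_test_cultures = {}
        for test in cfg["tests"]:
            sub = crop_preds[crop_preds["test"] == test]
            if sub.empty:
                continue
            rows = []
            for combo_name, cg in sub.groupby("combination"):
                cg = cg.assign(crop=np.arange(len(cg)).astype(str))
                pt = (cg.groupby(["image", "culture"])["p"].mean().reset_index()
                        .groupby("culture")["p"].agg(["mean", "size"]).reset_index())
                for _, r in pt.iterrows():
                    rec = meta[r["culture"]]
                    rows.append({"culture": r["culture"], "cell_line": rec.cell_line,
                                 "experiment": rec.experiment,
                                 "condition": rec.condition, "marker": combo_name,
                                 "n_images": int(r["size"]),
                                 "probability": float(r["mean"])})
            per_test_cultures[test] = pd.DataFrame(rows)
            tables[f"predictions_{test}"] = per_test_cultures[test]

        stage = "inference"
        comp_rows = []
        for test, tg in fold_aucs.groupby("test"):
            by_combo = {c: g["auc"].to_numpy() for c, g in tg.groupby("combination")}
            for a in by_combo:
                for b in by_combo:
                    if a < b:
                        res = inference.mann_whitney_one_sided(by_combo[a], by_combo[b])
                        comp_rows.append({"test": test, "combination_a": a,
                                          "combination_b": b, "u": res.u, "p": res.p,
                                          "neg_log10_p": -np.log10(max(res.p, 1e-300))})
        tables["auc_comparisons"] = pd.DataFrame(
            comp_rows, columns=psio.RESULT_SCHEMAS["auc_comparisons"])

        effect_rows = []
        for test, preds in per_test_cultures.items():
            controls = preds[preds["condition"] == "control"]
            for cond in sorted(set(preds["condition"]) - {"control"}):
                for combo_name, _ in preds.groupby("marker"):
                    sub = preds[(preds["marker"] == combo_name)
                                & (preds["condition"].isin(["control", cond]))]
                    if sub["condition"].nunique() < 2:
                        continue
                    try:
                        est = inference.fit_random_intercept_lmm(
                            sub.rename(columns={"probability": "prediction"}))
                    except Exception as exc:  # degenerate cells are reported, not fatal
                        logger.warning("LMM failed for (%s, %s, %s): %s",
                                       test, cond, combo_name, exc)
                        continue
                    effect_rows.append({"condition": cond,
                                        "classifier": f"{test}|{combo_name}",
                                        "beta": est.beta_hat, "se": est.se,
                                        "chi2": est.chi2, "p": est.p})
        effects = pd.DataFrame(effect_rows, columns=psio.RESULT_SCHEMAS["effects"])
        tables["effects"] = effects

        linkage_info = None
        if not effects.empty:
            mat = effects.pivot_table(index="condition", columns="classifier",
                                      values="beta")
            mat = mat.dropna(axis=1)
            if mat.shape[0] >= 2 and mat.shape[1] >= 1:
                clustering = inference.ward_cluster(mat)
                linkage_info = {"labels": clustering.labels,
                                "leaf_order": clustering.leaf_order,
                                "linkage": clustering.linkage.tolist()}
                (out / "linkage.json").write_text(json.dumps(linkage_info, indent=2))

        stage = "attribution"
        gallery = []
        if cfg["n_attribution_images"] > 0 and not crop_preds.empty:
            rng = np.random.default_rng(seeds["attribution"])
            test = cfg["tests"][0]
            combo = combos[0]
            records, labels = dataset.select_for_test(test)
            usable = [i for i, r in enumerate(records)
                      if set(combo.members) <= set(r.channels)]
            if len(usable) >= 2 and np.unique(labels[usable]).size == 2:
                recs = [records[i] for i in usable]
                crops, _ = _crops_for_records(recs, combo,
                                              cfg["input_size"], cfg["tile_size"])
                crop_labels = np.repeat(labels[usable], len(crops) // len(recs))
                clf = train_classifier(
                    crops, crop_labels,
                    ClassifierConfig(backbone=cfg["backbone"], epochs=2,
                                     seed=seeds["attribution"]), combo=combo)
                # attribute the highest-scoring positive-class crops
                p = clf.predict_proba(crops)
                top = np.argsort(p)[::-1][:cfg["n_attribution_images"]]
                for i in top:
                    amap = integrated_gradients(clf, crops[i],
                                                steps=cfg["attribution_steps"])
                    gallery.append({"crop": int(i), "p": float(p[i]),
                                    "completeness_error": amap.completeness_error})

        stage = "write"
        written = psio.write_results(tables, out)
        psio.write_run_metadata(cfg, {"master": seed, **seeds}, out,
                                extra={"attribution_gallery": gallery})
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise

    return {"tables": tables, "written": written, "linkage": linkage_info,
            "seeds": seeds}
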