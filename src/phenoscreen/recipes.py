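"""Fixed desk-scale study designs used by the validation suite and the
reproduction script.

Each recipe wires the synthetic generator, the CV engine and the
statistics layer into one named experiment with a frozen design
(layout, phenotype contrast, network size, fold scheme); only the seed
varies.  Problem sizes are chosen so a full recipe runs in minutes on one
CPU core: 540-px fields tiled into four 270-px crops resized to 64 px,
50 fields per class, and a ~15k-parameter scratch CNN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as sy
from .classification import (ClassifierConfig, FieldDataset, _crops_for_records,
                             apply_classifier, run_cv_grid, train_classifier)
from .inference import fit_random_intercept_lmm, mann_whitney_one_sided, ward_cluster
from .preprocessing import BIII, DAPI, ChannelCombination

#: Phenotype contrasts confined to a single cellular compartment.
NUCLEAR_ONLY = {"control": {},
                "mutant": {"nuclear_irregularity": 0.14, "nuclear_radius_px": -5.0}}
NEURITE_ONLY = {"control": {},
                "mutant": {"neurite_fragmentation": 0.45, "neurite_density": -18.0}}

_FIELD = 540
_TILE = 270
_INPUT = 64
_NZ = 3


def marker_relevance_study(phenotype: str, seed: int = 0, k: int = 10,
                           epochs: int = 4) -> dict[str, np.ndarray]:
    """Single-compartment phenotype vs the DAPI-only and BIII-only
    classifiers: k-fold CV AUC distributions for each marker.

    ``phenotype`` is 'nuclear' (irregular, shrunken nuclei; only the DAPI
    channel is informative) or 'neurite' (fragmented, sparser neurites;
    only the BIII channel is informative).  200 crops per class.
    """
    effects = {"nuclear": NUCLEAR_ONLY, "neurite": NEURITE_ONLY}[phenotype]
    layout = sy.PlateLayout(
        cell_lines=("CTRL1", "CTRL2", "CTRL3", "CTRL4", "CTRL5"),
        conditions=("control", "mutant"))
    fields, _ = sy.generate_plate(layout, sy.PhenotypeConfig(effects=effects),
                                  seed=seed, size=(_FIELD, _FIELD),
                                  fields_per_well=10, n_z=_NZ)
    dataset = FieldDataset.from_plate(fields)
    config = ClassifierConfig(seed=seed, epochs=epochs)
    combos = [ChannelCombination((DAPI,)), ChannelCombination((BIII,))]
    table = run_cv_grid(dataset, tests=["isALS"], combinations=combos,
                        n_subsets=1, k=k, config=config,
                        input_size=_INPUT, tile_size=_TILE)
    return {c.name: table[table["combination"] == c.name]["auc"].to_numpy()
            for c in combos}


def transfer_study(seed: int = 0, epochs: int = 6) -> dict:
    """Cross-condition phenotype transfer.

    Trains mutant-vs-control classifiers on the DAPI and BIII channels,
    scores every culture from the control / mutant / heat / osmotic
    conditions, estimates each condition's mixed-model effect size on each
    classifier's per-culture predictions, and Ward-clusters the resulting
    condition-by-classifier effect profiles.
    """
    layout = sy.PlateLayout(
        experiments=("EXP1", "EXP2"),
        cell_lines=("CTRL1", "CTRL2", "CTRL3"),
        conditions=("control", "mutant", "heat", "osmotic"))
    fields, _ = sy.generate_plate(layout, seed=seed, size=(_FIELD, _FIELD),
                                  fields_per_well=6, n_z=_NZ)
    dataset = FieldDataset.from_plate(fields)
    records, labels = dataset.select_for_test("isALS")

    condition_means: dict[str, dict[str, float]] = {}
    betas: dict[str, dict[str, float]] = {}
    for marker in (DAPI, BIII):
        combo = ChannelCombination((marker,))
        crops, _ = _crops_for_records(records, combo, _INPUT, _TILE)
        crop_labels = np.repeat(labels, len(crops) // len(records))
        clf = train_classifier(crops, crop_labels,
                               ClassifierConfig(seed=seed + 1, epochs=epochs),
                               combo=combo, tile_size=_TILE)
        cultures = apply_classifier(clf, dataset).cultures
        condition_means[marker] = dict(cultures.groupby("condition")["p"].mean())
        col = {}
        for cond in ("mutant", "heat", "osmotic"):
            sub = (cultures[cultures["condition"].isin(["control", cond])]
                   .rename(columns={"p": "prediction"}))
            col[cond] = fit_random_intercept_lmm(sub).beta_hat
        betas[marker] = col

    effect_matrix = pd.DataFrame(betas)  # rows = conditions, cols = classifiers
    clustering = ward_cluster(effect_matrix)
    return {"condition_means": condition_means, "effect_matrix": effect_matrix,
            "clustering": clustering}


def auc_points_demo(seed: int = 0, n_subsets: int = 5, k: int = 10) -> pd.DataFrame:
    """One (test, combination) grid cell at full fold count on a small
    plate with a fast linear scorer: yields the canonical
    n_subsets x k AUC rows."""
    layout = sy.PlateLayout(cell_lines=("CTRL1", "CTRL2"),
                            conditions=("control", "heat"))
    fields, _ = sy.generate_plate(layout, seed=seed, size=(256, 256),
                                  fields_per_well=6, n_z=3)
    dataset = FieldDataset.from_plate(fields)
    config = ClassifierConfig(backbone="linear", epochs=1, seed=seed)
    return run_cv_grid(dataset, tests=["isHEAT"],
                       combinations=[ChannelCombination((DAPI,))],
                       n_subsets=n_subsets, k=k, config=config,
                       input_size=32, tile_size=128)
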