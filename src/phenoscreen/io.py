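"""Manifest handling and results serialization.

A manifest is a CSV with one row per stored image plane and the nine
columns ``experiment, plate, well, cell_line, condition, marker, field,
z, path``.  A culture is identified by (experiment, plate, well); each
well carries exactly one RBP marker alongside DAPI and BIII.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import FieldDataset, FieldRecord
from .preprocessing import BIII, DAPI

MANIFEST_COLUMNS = ["experiment", "plate", "well", "cell_line", "condition",
                    "marker", "field", "z", "path"]

RESULT_SCHEMAS = {
    "fold_aucs": ["test", "combination", "subset", "fold", "auc"],
    "predictions": ["culture", "cell_line", "experiment", "condition",
                    "marker", "n_images", "probability"],
    "effects": ["condition", "classifier", "beta", "se", "chi2", "p"],
    "auc_comparisons": ["test", "combination_a", "combination_b", "u", "p",
                        "neg_log10_p"],
}


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a manifest CSV.

    Checks: all nine columns present; referenced files exist; one RBP
    marker per well; z-planes contiguous from 0 within each
    (well, marker, field).  Errors cite offending row numbers (0-based
    data rows).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    if check_paths:
        bad = [i for i, p in enumerate(df["path"])
               if not (Path(p) if Path(p).is_absolute() else path.parent / p).exists()]
        if bad:
            raise ValueError(f"manifest rows {bad[:10]} reference nonexistent files")
    for well, grp in df.groupby(["experiment", "plate", "well"]):
        rbps = sorted(set(grp["marker"]) - {DAPI, BIII})
        if len(rbps) > 1:
            rows = grp.index[grp["marker"].isin(rbps)].tolist()
            raise ValueError(f"well {well} has multiple RBP markers {rbps} "
                             f"(rows {rows[:10]})")
    for key, grp in df.groupby(["experiment", "plate", "well", "marker", "field"]):
        zs = np.sort(grp["z"].to_numpy())
        if not np.array_equal(zs, np.arange(len(zs))):
            raise ValueError(f"z-planes not contiguous from 0 for {key} "
                             f"(rows {grp.index.tolist()[:10]})")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_fields(manifest: pd.DataFrame, root=None) -> FieldDataset:
    """Read the TIFF planes behind a manifest into a `FieldDataset`."""
    import tifffile
    records = []
    for (exp, plate, well, fidx), grp in manifest.groupby(
            ["experiment", "plate", "well", "field"]):
        channels = {}
        for marker, mg in grp.groupby("marker"):
            planes = []
            for _, row in mg.sort_values("z").iterrows():
                p = Path(row["path"])
                if root is not None and not p.is_absolute():
                    p = Path(root) / p
                planes.append(tifffile.imread(p))
            channels[marker] = np.stack(planes)
        first = grp.iloc[0]
        culture = f"{exp}|{plate}|{well}"
        records.append(FieldRecord(
            channels=channels, image_id=f"{culture}|f{fidx}", culture=culture,
            condition=first["condition"], cell_line=first["cell_line"],
            experiment=first["experiment"]))
    return FieldDataset(records)


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write result tables as CSV with fixed column order; keys must match
    a known schema name (a trailing ``_<suffix>`` is allowed, e.g.
    ``predictions_isALS``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        base = next((s for s in RESULT_SCHEMAS if name == s or name.startswith(s + "_")),
                    None)
        if base is None:
            raise ValueError(f"unknown result table {name!r}; "
                             f"known schemas: {sorted(RESULT_SCHEMAS)}")
        cols = RESULT_SCHEMAS[base]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} missing column(s) {missing}")
        path = out / f"{name}.csv"
        df[cols].to_csv(path, index=False)
        written[name] = str(path)
    return written


def write_run_metadata(config: dict, seeds: dict, out_dir, extra: dict | None = None) -> str:
    """Persist everything needed to reconstruct a run."""
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config, "seeds": seeds, "version": __version__}
    if extra:
        meta.update(extra)
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, default=str))
    return str(path)
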