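"""Seeded synthetic fluorescence microscopy of motor-neuron cultures.

Emulates the structure of a high-content imaging screen of iPSC-derived
motor neurons: three stained channels per field (DAPI marking nuclei,
beta-III-tubulin marking somata and the neurite network, and one
RNA-binding-protein stain split between nucleus and cytoplasm), acquired
as 16-bit z-stacks of 3-5 planes, 10-12 fields per well, with wells laid
out over experiments x cell lines x stress conditions.

Phenotypes are carried by a small parameter vector (`PhenotypeParams`):
nuclear size and boundary irregularity, neurite width/density/
fragmentation, and the nuclear-to-cytoplasmic intensity ratio of the RBP
stain.  Condition effects are additive shifts on that vector declared in
one table (`CONDITION_EFFECTS`), with multiplicative cell-line and
experiment random effects on top — the same hierarchical structure the
downstream mixed-effects analysis assumes.  Every field comes with
ground-truth masks so that image statistics can be verified directly.

Geometry model
--------------
* Nuclei: ellipses (mild axis ratio) whose angular radius is perturbed by
  the first six Fourier modes with amplitudes proportional to
  ``nuclear_irregularity``.
* Neurites: branching random walks (bounded heading noise, branch
  probability 0.1 per step) rendered as Gaussian tubes of width
  ``neurite_width_px``; fragmentation deletes whole walk chunks.
* z-stacks: plane k is the in-focus render blurred with
  sigma = sigma0 * |k - focus|, so the maximum-intensity projection
  approximately recovers the in-focus image.
* Intensities: scaled so the 99.9th percentile sits near 20,000 of the
  65,535-count range; Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, binary_dilation
from skimage.draw import polygon as draw_polygon, line as draw_line

__all__ = [
    "PhenotypeParams", "CultureSpec", "FieldStack", "GroundTruth",
    "PhenotypeConfig", "CONDITION_EFFECTS", "PlateLayout",
    "apply_condition", "render_field", "generate_plate", "write_plate",
    "simulate_prediction_table",
    "nucleus_boundary_radial_std", "skeleton_length", "measured_nc_ratio",
]

_PARAM_FIELDS = ("nuclear_radius_px", "nuclear_irregularity", "neurite_width_px",
                 "neurite_fragmentation", "neurite_density", "rbp_nc_ratio",
                 "noise_sd", "soma_radius_px", "cell_density")


@dataclass(frozen=True)
class PhenotypeParams:
    """Parameter vector controlling one culture's rendered phenotype.

    Units: pixels for sizes, probability for fragmentation, expected
    neurite trees per field for density, dimensionless ratio for the
    RBP nuclear/cytoplasmic intensity, 16-bit counts for read noise.
    """

    nuclear_radius_px: float = 14.0
    nuclear_irregularity: float = 0.06
    neurite_width_px: float = 1.5
    neurite_fragmentation: float = 0.0
    neurite_density: float = 30.0
    cell_density: float = 12.0
    soma_radius_px: float = 22.0
    rbp_nc_ratio: float = 3.0
    noise_sd: float = 120.0

    def __post_init__(self) -> None:
        for name in _PARAM_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rbp_nc_ratio <= 0:
            raise ValueError("rbp_nc_ratio must be > 0")
        if not 0.0 <= self.neurite_fragmentation <= 1.0:
            raise ValueError("neurite_fragmentation must be in [0, 1]")

    def shifted(self, deltas: Mapping[str, float], scale: float = 1.0) -> "PhenotypeParams":
        """Apply additive shifts (optionally attenuated), clipping into the
        valid domain rather than erroring at the boundary."""
        vals = dataclasses.asdict(self)
        for name, d in deltas.items():
            if name not in vals:
                raise KeyError(f"unknown phenotype parameter {name!r}")
            vals[name] += scale * d
        vals["neurite_fragmentation"] = float(np.clip(vals["neurite_fragmentation"], 0.0, 1.0))
        vals["rbp_nc_ratio"] = max(vals["rbp_nc_ratio"], 1e-3)
        for name in _PARAM_FIELDS:
            vals[name] = max(vals[name], 0.0)
        return PhenotypeParams(**vals)


#: Additive condition effects on PhenotypeParams — the single source of
#: truth for what each condition does to the rendered phenotype.  "mutant"
#: (the VCP-ALS genotype) shrinks and deforms nuclei and fragments/thins
#: the neurite network; "heat" shifts the same parameters in the same
#: direction at 3/4 the magnitude; "oxidative" relocalizes the RBP stain
#: toward the cytoplasm; "osmotic" swells nuclei and somata — an axis
#: distinct from the mutant phenotype.
CONDITION_EFFECTS: dict[str, dict[str, float]] = {
    "control": {},
    "mutant": {"nuclear_irregularity": 0.10, "nuclear_radius_px": -3.0,
               "neurite_fragmentation": 0.35, "neurite_density": -12.0},
    "heat": {"nuclear_irregularity": 0.075, "nuclear_radius_px": -2.25,
             "neurite_fragmentation": 0.26, "neurite_density": -9.0},
    "oxidative": {"rbp_nc_ratio": -1.2},
    "osmotic": {"nuclear_radius_px": 4.0, "soma_radius_px": 6.0},
}


@dataclass(frozen=True)
class PhenotypeConfig:
    """Baseline phenotype, condition-effect table and random-effect scales."""

    base: PhenotypeParams = field(default_factory=PhenotypeParams)
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: CONDITION_EFFECTS)
    line_jitter: float = 0.03      # multiplicative SD of cell-line random effect
    experiment_jitter: float = 0.02  # multiplicative SD of experiment random effect
    recovery_halflife_h: float = 1.0  # condition shift halves per this many hours
    rbp_marker: str = "FUS"


@dataclass(frozen=True)
class CultureSpec:
    """One culture (well) to render: condition, identifiers and the fully
    resolved phenotype.  Same spec + seed => bit-identical output."""

    condition: str
    cell_line_id: str
    experiment_id: str
    phenotype: PhenotypeParams
    seed: int
    recovery_h: float = 0.0


@dataclass
class FieldStack:
    """One field of view: per-marker 16-bit z-stacks plus metadata."""

    channels: dict[str, np.ndarray]  # marker -> (n_z, H, W) uint16
    n_z: int
    metadata: dict

    def __post_init__(self) -> None:
        shapes = {m: ch.shape for m, ch in self.channels.items()}
        for m, sh in shapes.items():
            if sh[0] != self.n_z:
                raise ValueError(f"channel {m} has {sh[0]} planes, expected {self.n_z}")
        if not 1 <= self.n_z:
            raise ValueError("n_z must be >= 1")


@dataclass
class GroundTruth:
    """Masks aligned with the rendered channels, for property checks."""

    nucleus_mask: np.ndarray
    neurite_skeleton: np.ndarray
    soma_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    params_used: PhenotypeParams


def _is_mutant_line(cell_line_id: str) -> bool:
    return cell_line_id.upper().startswith("MUT")


def apply_condition(config: PhenotypeConfig, condition: str, cell_line_id: str,
                    experiment_id: str, master_seed: int,
                    recovery_h: float = 0.0) -> PhenotypeParams:
    """Resolve the phenotype of one culture: baseline + condition shift
    (+ mutant-genotype shift for MUT* lines), attenuated by recovery time,
    with deterministic cell-line and experiment multiplicative jitter."""
    if condition not in config.effects:
        raise ValueError(f"unknown condition label {condition!r}; "
                         f"known: {sorted(config.effects)}")
    scale = 0.5 ** (recovery_h / config.recovery_halflife_h)
    params = config.base.shifted(config.effects[condition], scale=scale)
    if _is_mutant_line(cell_line_id) and condition != "mutant":
        params = params.shifted(config.effects.get("mutant", {}))

    vals = dataclasses.asdict(params)
    for kind, ident, sd in (("line", cell_line_id, config.line_jitter),
                            ("experiment", experiment_id, config.experiment_jitter)):
        if sd <= 0:
            continue
        digest = zlib.crc32(f"{kind}:{ident}".encode())
        ss = np.random.SeedSequence([master_seed & 0x7FFFFFFF, digest])
        rng = np.random.default_rng(ss)
        factors = 1.0 + rng.normal(0.0, sd, size=len(_PARAM_FIELDS))
        for name, f in zip(_PARAM_FIELDS, factors):
            if name != "noise_sd":
                vals[name] = max(vals[name] * f, 0.0)
    vals["neurite_fragmentation"] = float(np.clip(vals["neurite_fragmentation"], 0.0, 1.0))
    vals["rbp_nc_ratio"] = max(vals["rbp_nc_ratio"], 1e-3)
    return PhenotypeParams(**vals)


# --------------------------------------------------------------------------
# field rendering

def _nucleus_polygon(rng: np.random.Generator, center: np.ndarray,
                     params: PhenotypeParams, n_theta: int = 180) -> np.ndarray:
    """Vertices (y, x) of one radially perturbed elliptical nucleus."""
    r = max(rng.normal(params.nuclear_radius_px, 0.1 * params.nuclear_radius_px), 4.0)
    axis_ratio = rng.uniform(1.0, 1.1)
    phi = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    a, b = r * np.sqrt(axis_ratio), r / np.sqrt(axis_ratio)
    # angular radius of the rotated ellipse
    ct, st = np.cos(theta - phi), np.sin(theta - phi)
    radius = a * b / np.sqrt((b * ct) ** 2 + (a * st) ** 2)
    if params.nuclear_irregularity > 0:
        amp = params.nuclear_irregularity / np.sqrt(6)
        for k in range(1, 7):
            radius += r * rng.normal(0.0, amp) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    radius = np.clip(radius, 2.0, None)
    return np.stack([center[0] + radius * np.sin(theta),
                     center[1] + radius * np.cos(theta)], axis=1)


def _grow_tree(rng: np.random.Generator, origin: np.ndarray, heading: float,
               shape: tuple[int, int], max_steps: int = 120,
               step_px: float = 2.5, total_budget: int = 400) -> list[list[tuple]]:
    """Branching random walk; returns a list of polylines (lists of (y,x)).

    Branch probability 0.1 per step with a hard cap on total steps per
    tree so branching stays subcritical.
    """
    polylines = []
    stack = [(origin.copy(), heading, max_steps)]
    spent = 0
    while stack and spent < total_budget:
        pos, ang, budget = stack.pop()
        pts = [tuple(pos)]
        for _ in range(budget):
            if spent >= total_budget:
                break
            spent += 1
            ang += np.clip(rng.normal(0.0, 0.15), -0.5, 0.5)
            pos = pos + step_px * np.array([np.sin(ang), np.cos(ang)])
            if not (0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1]):
                break
            pts.append(tuple(pos))
            if rng.random() < 0.1 and budget > 20:
                stack.append((pos.copy(), ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.9),
                              budget // 2))
        if len(pts) > 1:
            polylines.append(pts)
    return polylines


def _chunks(seq: Sequence, size: int) -> Iterable[Sequence]:
    for i in range(0, len(seq), size):
        yield seq[i:i + size]


def render_field(spec: CultureSpec, size: tuple[int, int] = (1080, 1080),
                 n_z: int = 4) -> tuple[FieldStack, GroundTruth]:
    """Render one field of view for a culture.

    Returns the three-channel 16-bit z-stack (DAPI, BIII and the RBP
    marker named in the metadata) plus ground-truth masks.
    """
    h, w = size
    if h < 256 or w < 256:
        raise ValueError(f"field size must be at least 256x256, got {size}")
    if not 1 <= n_z <= 8:
        raise ValueError(f"n_z out of range: {n_z}")
    p = spec.phenotype
    ss = np.random.SeedSequence(spec.seed & 0x7FFFFFFF)
    rng_layout, rng_shape, rng_walk, rng_frag, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(5))

    n_cells = max(1, rng_layout.poisson(p.cell_density))
    margin = 1.8 * p.nuclear_radius_px + 4
    centers = []
    for _ in range(n_cells):
        for _attempt in range(40):  # rejection sampling for separation
            c = rng_layout.uniform([margin, margin], [h - margin, w - margin])
            if all(np.hypot(*(c - o)) > 3.2 * p.nuclear_radius_px for o in centers):
                centers.append(c)
                break

    nucleus = np.zeros((h, w), bool)
    soma = np.zeros((h, w), bool)
    dapi_soft = np.zeros((h, w))
    for c in centers:
        poly = _nucleus_polygon(rng_shape, c, p)
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=(h, w))
        brightness = rng_shape.uniform(0.8, 1.2)
        nucleus[rr, cc] = True
        dapi_soft[rr, cc] = np.maximum(dapi_soft[rr, cc], brightness)
        # soma size is decoupled from the nucleus so nuclear phenotype
        # shifts do not leak into the BIII channel
        rel = poly - c
        mean_r = np.hypot(rel[:, 0], rel[:, 1]).mean()
        theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        soma_r = max(p.soma_radius_px, mean_r + 3.0)
        soma_poly = np.stack([c[0] + soma_r * np.sin(theta),
                              c[1] + soma_r * np.cos(theta)], axis=1)
        rr, cc = draw_polygon(soma_poly[:, 0], soma_poly[:, 1], shape=(h, w))
        soma[rr, cc] = True

    # neurite trees are drawn independently of the cell count (each rooted
    # at some soma) so neurite_density shifts leave the DAPI channel alone
    skeleton = np.zeros((h, w), bool)
    n_trees = max(1, rng_walk.poisson(p.neurite_density))
    for _ in range(n_trees):
        c = centers[rng_walk.integers(len(centers))]
        polylines = _grow_tree(rng_walk, c, rng_walk.uniform(0, 2 * np.pi), (h, w))
        for pts in polylines:
            # fragmentation deletes whole chunks of the walk
            for chunk in _chunks(pts, 10):
                if p.neurite_fragmentation > 0 and rng_frag.random() < p.neurite_fragmentation:
                    continue
                for (y0, x0), (y1, x1) in zip(chunk[:-1], chunk[1:]):
                    rr, cc = draw_line(int(round(y0)), int(round(x0)),
                                       int(round(y1)), int(round(x1)))
                    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                    skeleton[rr[ok], cc[ok]] = True

    blur = 0.6  # slight optical softening of the structural channels
    background = 0.03  # autofluorescence floor, fraction of peak signal
    nuc_soft = gaussian_filter(dapi_soft, blur)
    tube = gaussian_filter(skeleton.astype(float), max(p.neurite_width_px, 0.3))
    if tube.max() > 0:
        tube = tube / tube.max()
    soma_soft = gaussian_filter(soma.astype(float), blur)
    nuc_dilated = binary_dilation(nucleus, iterations=2)
    cytoplasm_mask = ((soma | (tube > 0.35)) & ~nuc_dilated)

    # RBP is rendered piecewise-constant on the masks so the rendered
    # nuclear/cytoplasmic mean-intensity ratio equals rbp_nc_ratio exactly
    # (up to noise); optical softening there comes only from the z-model.
    clean = {
        "DAPI": background + 1.0 * nuc_soft,
        "BIII": background + 0.85 * np.maximum(soma_soft, tube),
        "RBP": (background + 1.0 * nucleus
                + (1.0 / p.rbp_nc_ratio) * cytoplasm_mask.astype(float)),
    }
    for marker, img in clean.items():
        hi = np.percentile(img, 99.9)
        clean[marker] = img * (20000.0 / hi) if hi > 0 else img

    focus = n_z // 2
    sigma0 = 1.5
    channels: dict[str, np.ndarray] = {}
    for marker, img in clean.items():
        stack = np.empty((n_z, h, w), dtype=np.uint16)
        for k in range(n_z):
            s = sigma0 * abs(k - focus)
            plane = gaussian_filter(img, s) if s > 0 else img
            noisy = rng_noise.poisson(np.clip(plane, 0, None)).astype(float)
            if p.noise_sd > 0:
                noisy += rng_noise.normal(0.0, p.noise_sd, size=plane.shape)
            stack[k] = np.clip(noisy, 0, 65535).astype(np.uint16)
        channels[marker] = stack

    meta = {"condition": spec.condition, "cell_line": spec.cell_line_id,
            "experiment": spec.experiment_id, "seed": spec.seed}
    fs = FieldStack(channels=channels, n_z=n_z, metadata=meta)
    gt = GroundTruth(nucleus_mask=nucleus, neurite_skeleton=skeleton,
                     soma_mask=soma, cytoplasm_mask=cytoplasm_mask, params_used=p)
    return fs, gt


# --------------------------------------------------------------------------
# measurement helpers (oracles on ground truth)

def nucleus_boundary_radial_std(nucleus_mask: np.ndarray) -> float:
    """Mean per-nucleus std of boundary distance from the nucleus centroid."""
    from scipy.ndimage import label as nd_label
    from skimage.measure import find_contours
    labels, n = nd_label(nucleus_mask)
    stds = []
    for i in range(1, n + 1):
        m = labels == i
        if m.sum() < 30:
            continue
        ys, xs = np.nonzero(m)
        cy, cx = ys.mean(), xs.mean()
        contours = find_contours(m.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        d = np.hypot(contour[:, 0] - cy, contour[:, 1] - cx)
        stds.append(d.std())
    return float(np.mean(stds)) if stds else 0.0


def skeleton_length(gt: GroundTruth) -> int:
    """Total neurite skeleton length in pixels."""
    return int(gt.neurite_skeleton.sum())


def measured_nc_ratio(fs: FieldStack, gt: GroundTruth, marker: str = "RBP") -> float:
    """Nuclear / cytoplasmic mean intensity of a channel's in-focus plane,
    measured on the ground-truth masks after background subtraction."""
    plane = fs.channels[marker][fs.n_z // 2].astype(float)
    bg_mask = ~(gt.nucleus_mask | gt.soma_mask | (gt.cytoplasm_mask))
    bg = np.median(plane[bg_mask]) if bg_mask.any() else 0.0
    nuc = plane[gt.nucleus_mask].mean() - bg
    cyto = plane[gt.cytoplasm_mask].mean() - bg
    return float(nuc / cyto)


# --------------------------------------------------------------------------
# plate generation

@dataclass(frozen=True)
class PlateLayout:
    """Factorial layout: every experiment x cell line x condition gets
    ``wells_per_combo`` wells on one plate."""

    experiments: tuple[str, ...] = ("EXP1",)
    cell_lines: tuple[str, ...] = ("CTRL1", "CTRL2", "CTRL3")
    conditions: tuple[str, ...] = ("control", "heat")
    wells_per_combo: int = 1
    plate: str = "P1"

    def __post_init__(self) -> None:
        for name in ("experiments", "cell_lines", "conditions"):
            if len(getattr(self, name)) < 1:
                raise ValueError(f"layout requires at least one entry in {name}")
        if self.wells_per_combo < 1:
            raise ValueError("wells_per_combo must be >= 1")


def generate_plate(layout: PlateLayout, config: PhenotypeConfig | None = None,
                   seed: int = 0, size: tuple[int, int] = (1080, 1080),
                   fields_per_well: int | None = None,
                   n_z: int | None = None,
                   ) -> tuple[list[tuple[FieldStack, GroundTruth]], pd.DataFrame]:
    """Render a full plate and build its manifest.

    Fields per well are sampled uniformly in [10, 12] and z-planes in
    [3, 5] unless fixed.  The manifest has one row per (field, marker,
    z-plane) with the standard nine columns; the ``path`` column holds the
    file name ``write_plate`` would use.
    """
    config = config or PhenotypeConfig()
    for cond in layout.conditions:
        if cond not in config.effects:
            raise ValueError(f"unknown condition label {cond!r}; "
                             f"known: {sorted(config.effects)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xA11CE]))
    fields: list[tuple[FieldStack, GroundTruth]] = []
    rows = []
    well_counter = 0
    for exp in layout.experiments:
        for line in layout.cell_lines:
            for cond in layout.conditions:
                for _ in range(layout.wells_per_combo):
                    well_counter += 1
                    well = f"W{well_counter:03d}"
                    params = apply_condition(config, cond, line, exp, seed)
                    n_fields = fields_per_well or int(rng.integers(10, 13))
                    for f_idx in range(n_fields):
                        nz = n_z or int(rng.integers(3, 6))
                        culture_seed = int(rng.integers(0, 2 ** 31 - 1))
                        spec = CultureSpec(condition=cond, cell_line_id=line,
                                           experiment_id=exp, phenotype=params,
                                           seed=culture_seed)
                        fs, gt = render_field(spec, size=size, n_z=nz)
                        fs.metadata.update({"well": well, "field": f_idx,
                                            "plate": layout.plate,
                                            "rbp_marker": config.rbp_marker})
                        fields.append((fs, gt))
                        for marker in fs.channels:
                            out_name = config.rbp_marker if marker == "RBP" else marker
                            for z in range(nz):
                                rows.append({
                                    "experiment": exp, "plate": layout.plate,
                                    "well": well, "cell_line": line,
                                    "condition": cond, "marker": out_name,
                                    "field": f_idx, "z": z,
                                    "path": f"{exp}_{well}_{out_name}_{f_idx}_z{z}.tif",
                                })
    manifest = pd.DataFrame(rows, columns=["experiment", "plate", "well", "cell_line",
                                           "condition", "marker", "field", "z", "path"])
    return fields, manifest


def write_plate(fields: list[tuple[FieldStack, GroundTruth]], manifest: pd.DataFrame,
                out_dir) -> pd.DataFrame:
    """Write one 16-bit grayscale TIFF per (marker, plane) plus manifest.csv;
    returns the manifest with absolute paths."""
    import tifffile
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    by_key = {}
    for fs, _gt in fields:
        md = fs.metadata
        by_key[(md["experiment"], md["well"], md["field"])] = fs
    paths = []
    for _, row in manifest.iterrows():
        fs = by_key[(row["experiment"], row["well"], row["field"])]
        marker = "RBP" if row["marker"] == fs.metadata.get("rbp_marker") else row["marker"]
        path = out / row["path"]
        if not path.exists():
            tifffile.imwrite(path, fs.channels[marker][row["z"]])
        paths.append(str(path))
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# --------------------------------------------------------------------------
# prediction-table simulator (the mixed-model testbed)

def simulate_prediction_table(beta0: float, beta1: float, sd_line: float,
                              sd_exp: float, sd_resid: float,
                              n_lines: int = 7, n_experiments: int = 3,
                              n_cultures: int = 10, seed: int = 0,
                              clip: bool = False) -> pd.DataFrame:
    """Per-culture classifier predictions from the generative model

        y = beta0 + beta1 * condition + u_line + u_exp + eps,

    with Gaussian random intercepts (SDs ``sd_line``, ``sd_exp``) and
    residual SD ``sd_resid``.  ``n_cultures`` cultures per (line,
    experiment, condition) cell, condition coded 0/1.  Values are clipped
    to [0, 1] only when ``clip`` is set (off by default so the generative
    model stays exactly linear-Gaussian).
    """
    for name, sd in (("sd_line", sd_line), ("sd_exp", sd_exp), ("sd_resid", sd_resid)):
        if sd < 0:
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5EED]))
    u_line = rng.normal(0, sd_line, size=n_lines)
    u_exp = rng.normal(0, sd_exp, size=n_experiments)
    rows = []
    culture = 0
    for i in range(n_lines):
        for j in range(n_experiments):
            for cond in (0, 1):
                eps = rng.normal(0, sd_resid, size=n_cultures)
                y = beta0 + beta1 * cond + u_line[i] + u_exp[j] + eps
                if clip:
                    y = np.clip(y, 0.0, 1.0)
                for v in y:
                    culture += 1
                    rows.append({"culture": f"C{culture:05d}",
                                 "cell_line": f"L{i + 1}",
                                 "experiment": f"E{j + 1}",
                                 "condition": cond, "prediction": float(v)})
    return pd.DataFrame(rows)
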