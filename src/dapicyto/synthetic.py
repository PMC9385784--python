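"""Synthetic DAPI scenes and per-nucleus intensity tables with known ground truth.

Every downstream stage of the package (segmentation, calibration, the
peak-class estimator, the size-content correlation) is exercised against
scenes produced here.  A scene is a mixture of nucleus populations
(:class:`ComponentSpec`), each characterised by a mean DNA content in
picograms and a coefficient of variation, plus a population of internal
standard nuclei of constant DNA content (chicken erythrocytes, 2.4 pg by
default).  Fluorescence intensity is linear in DNA content through an
explicit arbitrary-units gain, so calibration against the standard is a real
operation rather than an identity.

Nucleus area is coupled to DNA content through ``size_scale * pg**exponent``;
populations listed in ``decoupled_labels`` instead draw their area from the
size distribution of a 1C-sized nucleus regardless of their DNA content,
mimicking the male-gametophyte anomaly in which nuclei as small as zoospore
nuclei carry about 2.6x the DNA.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "SyntheticSceneSpec",
    "GroundTruth",
    "StagePreset",
    "ValidationError",
    "PlacementError",
    "gen_intensity_table",
    "render_scene",
    "suggest_shape",
    "stage_presets",
]

TABLE_COLUMNS = ["id", "label", "true_pg", "intensity", "area", "is_standard"]


class ValidationError(ValueError):
    """A generator spec violates one of its invariants."""


class PlacementError(RuntimeError):
    """Non-overlapping nucleus placement failed within the retry budget."""


@dataclass(frozen=True)
class ComponentSpec:
    """One nucleus population of a stage.

    Parameters
    ----------
    label:
        Population name, e.g. ``"zoospores_released"``.
    mean_pg:
        Mean DNA content in picograms (> 0).
    cv:
        Coefficient of variation of the per-nucleus DNA content (>= 0).
    n:
        Number of nuclei to draw (>= 0).
    weight:
        Mixture fraction when several components make up one stage.
    size_scale:
        Stage-specific multiplier on the area-DNA coupling; lets tissues with
        large vacuolated cells carry larger nuclei than their DNA content
        alone predicts.
    """

    label: str
    mean_pg: float
    cv: float
    n: int
    weight: float = 1.0
    size_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.mean_pg > 0:
            raise ValidationError(f"component {self.label!r}: mean_pg must be > 0")
        if self.cv < 0:
            raise ValidationError(f"component {self.label!r}: cv must be >= 0")
        if self.n < 0:
            raise ValidationError(f"component {self.label!r}: n must be >= 0")
        if not 0 <= self.weight <= 1:
            raise ValidationError(f"component {self.label!r}: weight must be in [0, 1]")
        if not self.size_scale > 0:
            raise ValidationError(f"component {self.label!r}: size_scale must be > 0")


@dataclass
class SyntheticSceneSpec:
    """Full description of a synthetic scene; seed fully determines output."""

    components: list[ComponentSpec] = field(default_factory=list)
    image_shape: tuple[int, int] = (1024, 1024)
    n_standard: int = 50
    standard_pg: float = 2.4
    standard_cv: float = 0.02
    gain: float = 5000.0
    measurement_cv: float = 0.0
    coupling_exponent: float = 2.0 / 3.0
    decoupled_labels: tuple[str, ...] = ()
    decoupled_size_pg: float = 0.76
    area_per_pg: float = 240.0
    area_cv: float = 0.05
    background_level: float = 100.0
    background_gradient: tuple[float, float] = (0.005, 0.005)
    noise_sd: float = 2.0
    min_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_standard < 0:
            raise ValidationError("n_standard must be >= 0")
        if not self.standard_pg > 0:
            raise ValidationError("standard_pg must be > 0")
        if self.standard_cv < 0 or self.standard_cv > 0.03:
            raise ValidationError("standard_cv must be in [0, 0.03]")
        if not self.gain > 0:
            raise ValidationError("gain must be > 0")
        if self.measurement_cv < 0:
            raise ValidationError("measurement_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        self.components = list(self.components)
        self.decoupled_labels = tuple(self.decoupled_labels)

    # -- (de)serialisation -------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSceneSpec":
        d = json.loads(text)
        d["components"] = [ComponentSpec(**c) for c in d.get("components", [])]
        d["image_shape"] = tuple(d.get("image_shape", (1024, 1024)))
        d["background_gradient"] = tuple(d.get("background_gradient", (0.0, 0.0)))
        d["decoupled_labels"] = tuple(d.get("decoupled_labels", ()))
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-nucleus truth and a label mask aligned to the rendered image.

    ``table`` carries one row per nucleus (id, label, true_pg, intensity =
    true integrated signal above background, area = realised mask pixels,
    is_standard, row, col).  ``mask`` holds the nucleus id at each pixel
    (0 = background).
    """

    table: pd.DataFrame
    mask: np.ndarray
    spec: SyntheticSceneSpec

    @property
    def standard_mask(self) -> np.ndarray:
        """Boolean mask of pixels belonging to standard nuclei."""
        ids = self.table.loc[self.table["is_standard"], "id"].to_numpy()
        return np.isin(self.mask, ids)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, float(mean))
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def _is_decoupled(label: str, decoupled: tuple[str, ...]) -> bool:
    stem = label.split(":")[0]
    return label in decoupled or stem in decoupled


def _sample_nuclei(spec: SyntheticSceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-nucleus table (shared by table and image routes)."""
    rows: list[pd.DataFrame] = []
    for comp in spec.components:
        if comp.n == 0:
            continue
        true_pg = _lognormal(rng, comp.mean_pg, comp.cv, comp.n)
        intensity = spec.gain * true_pg * _lognormal(rng, 1.0, spec.measurement_cv, comp.n)
        if _is_decoupled(comp.label, spec.decoupled_labels):
            size_pg = _lognormal(rng, spec.decoupled_size_pg, comp.cv, comp.n)
        else:
            size_pg = true_pg
        area = (
            spec.area_per_pg
            * comp.size_scale
            * np.power(size_pg, spec.coupling_exponent)
            * _lognormal(rng, 1.0, spec.area_cv, comp.n)
        )
        rows.append(
            pd.DataFrame(
                {
                    "label": comp.label,
                    "true_pg": true_pg,
                    "intensity": intensity,
                    "area": area,
                    "is_standard": False,
                }
            )
        )
    if spec.n_standard > 0:
        n = spec.n_standard
        intensity = spec.gain * spec.standard_pg * _lognormal(rng, 1.0, spec.standard_cv, n)
        area = (
            spec.area_per_pg
            * np.power(spec.standard_pg, spec.coupling_exponent)
            * _lognormal(rng, 1.0, spec.area_cv, n)
        )
        rows.append(
            pd.DataFrame(
                {
                    "label": "standard",
                    "true_pg": float(spec.standard_pg),
                    "intensity": intensity,
                    "area": area,
                    "is_standard": True,
                }
            )
        )
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(
            {"label": [], "true_pg": [], "intensity": [], "area": [], "is_standard": []}
        )
    table.insert(0, "id", np.arange(1, len(table) + 1, dtype=int))
    table["is_standard"] = table["is_standard"].astype(bool)
    return table[TABLE_COLUMNS]


def gen_intensity_table(spec: SyntheticSceneSpec) -> pd.DataFrame:
    """Generate the per-nucleus intensity table for a scene spec.

    Returns a DataFrame with columns ``id, label, true_pg, intensity, area,
    is_standard``.  Intensity is ``gain * true_pg`` perturbed by
    multiplicative lognormal noise of coefficient ``measurement_cv`` (exact
    when both the component cv and measurement_cv are zero); standard
    entries are drawn around ``standard_pg`` with cv <= 0.03.
    """
    rng = np.random.default_rng(spec.seed)
    return _sample_nuclei(spec, rng)


def _background(spec: SyntheticSceneSpec, rng: np.random.Generator | None) -> np.ndarray:
    h, w = spec.image_shape
    gr, gc = spec.background_gradient
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    bg = spec.background_level + gr * rows + gc * cols
    bg = np.broadcast_to(bg, (h, w)).copy()
    if rng is not None and spec.noise_sd > 0:
        bg += rng.normal(0.0, spec.noise_sd, (h, w))
    return bg


def background_model(spec: SyntheticSceneSpec) -> np.ndarray:
    """The noise-free background plane of a scene (level + gradient)."""
    return _background(spec, None)


def suggest_shape(spec: SyntheticSceneSpec, fill: float = 0.12, minimum: int = 256) -> tuple[int, int]:
    """Square image shape large enough to place the scene at a packing ``fill``.

    Uses the expected per-nucleus footprint (bounding circle + separation);
    the default 12% fill keeps rejection-sampling placement cheap.
    """
    budget = 0.0
    sep = spec.min_separation
    for comp in spec.components:
        if _is_decoupled(comp.label, spec.decoupled_labels):
            pg = spec.decoupled_size_pg
        else:
            pg = comp.mean_pg
        area = spec.area_per_pg * comp.size_scale * pg ** spec.coupling_exponent
        r = math.sqrt(area / math.pi) * 1.15  # ellipticity head-room
        budget += comp.n * math.pi * (r + sep) ** 2
    if spec.n_standard > 0:
        area = spec.area_per_pg * spec.standard_pg ** spec.coupling_exponent
        r = math.sqrt(area / math.pi) * 1.15
        budget += spec.n_standard * math.pi * (r + sep) ** 2
    side = int(math.ceil(math.sqrt(budget / fill))) if budget > 0 else minimum
    side = max(side, minimum)
    return (side, side)


def _place(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: np.ndarray,
    sep: float,
    max_retries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample non-overlapping centres; big nuclei first."""
    h, w = shape
    n = len(radii)
    order = np.argsort(-radii, kind="stable")
    centers = np.empty((n, 2))
    placed_r = np.empty(n)
    for k, idx in enumerate(order):
        r = radii[idx]
        border = r + 8.0
        if h - 2 * border <= 0 or w - 2 * border <= 0:
            raise PlacementError(
                "image too small for the largest nucleus; increase image_shape"
            )
        for _ in range(max_retries):
            cr = rng.uniform(border, h - border)
            cc = rng.uniform(border, w - border)
            if k == 0:
                break
            d2 = (centers[:k, 0] - cr) ** 2 + (centers[:k, 1] - cc) ** 2
            if np.all(d2 >= (placed_r[:k] + r + sep) ** 2):
                break
        else:
            raise PlacementError(
                f"could not place nucleus {k + 1}/{n} after {max_retries} retries; "
                "use a larger image or fewer nuclei"
            )
        centers[k] = (cr, cc)
        placed_r[k] = r
    out = np.empty((n, 2))
    out[order] = centers
    return out


def render_scene(
    spec: SyntheticSceneSpec,
    positions: np.ndarray | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene into a float image plus ground truth.

    Each nucleus is drawn as a smooth elliptical blob (raised-cosine radial
    profile, zero at the mask rim) scaled so that its integrated signal above
    background equals its ground-truth intensity exactly.  The background is
    ``level + linear gradient + N(0, noise_sd)`` pixel noise.

    ``positions`` optionally fixes the (row, col) centres (one per nucleus,
    table order); explicit positions may overlap, in which case later nuclei
    overwrite earlier ones in the label mask.
    """
    rng = np.random.default_rng(spec.seed)
    table = _sample_nuclei(spec, rng)
    h, w = spec.image_shape
    n = len(table)

    radii = np.sqrt(table["area"].to_numpy() / math.pi) if n else np.empty(0)
    # per-nucleus ellipse shape
    squish = rng.uniform(0.85, 1.0, n) if n else np.empty(0)
    angles = rng.uniform(0.0, math.pi, n) if n else np.empty(0)
    bounding = radii / np.sqrt(squish) if n else radii

    if n:
        if positions is not None:
            centers = np.asarray(positions, dtype=float)
            if centers.shape != (n, 2):
                raise ValidationError(
                    f"positions must have shape ({n}, 2), got {centers.shape}"
                )
        else:
            centers = _place(rng, (h, w), bounding, spec.min_separation)
    else:
        centers = np.empty((0, 2))

    image = _background(spec, rng)
    mask = np.zeros((h, w), dtype=np.int32)
    realised_area = np.zeros(n, dtype=int)

    intensities = table["intensity"].to_numpy()
    for i in range(n):
        a = radii[i] / math.sqrt(squish[i])  # semi-major
        b = radii[i] * math.sqrt(squish[i])  # semi-minor
        cr, cc = centers[i]
        th = angles[i]
        rad = int(math.ceil(a)) + 1
        r0, r1 = max(0, int(cr) - rad), min(h, int(cr) + rad + 1)
        c0, c1 = max(0, int(cc) - rad), min(w, int(cc) + rad + 1)
        yy = np.arange(r0, r1, dtype=float)[:, None] - cr
        xx = np.arange(c0, c1, dtype=float)[None, :] - cc
        u = yy * math.cos(th) + xx * math.sin(th)
        v = -yy * math.sin(th) + xx * math.cos(th)
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        inside = rho < 1.0
        if not inside.any():
            continue
        profile = np.zeros_like(rho)
        profile[inside] = np.cos(math.pi * rho[inside] / 2.0) ** 2
        total = profile.sum()
        if total > 0:
            profile *= intensities[i] / total
        image[r0:r1, c0:c1] += profile
        patch = mask[r0:r1, c0:c1]
        patch[inside] = int(table["id"].iloc[i])
        realised_area[i] = int(inside.sum())

    gt_table = table.copy()
    gt_table["area"] = realised_area
    gt_table["row"] = centers[:, 0] if n else np.empty(0)
    gt_table["col"] = centers[:, 1] if n else np.empty(0)
    return image, GroundTruth(table=gt_table, mask=mask, spec=spec)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StagePreset:
    """A life-cycle stage preset: mixture components plus main-stage summary."""

    label: str
    components: tuple[ComponentSpec, ...]
    mean_pg: float
    sd_pg: float
    cv: float
    n_total: int
    decoupled: bool = False
    n_sources: int | None = None

    def __iter__(self):
        return iter(self.components)


# (label, mean pg, sd pg, n nuclei, n sources, size_scale, decoupled,
#  minor components as (multiple of main mean, flag)):
# size scales follow the published relative-nucleus-size column so that the
# generator reproduces the observed size ladder across stages.
_STAGE_TABLE = [
    ("zoospores_released", 0.76, 0.07, 387, 3, 1.00, False, [(2, "+")]),
    ("zoospores_unreleased", 0.79, 0.05, 64, 1, 1.00, False, []),
    ("male_gametophytes", 2.01, 0.22, 1464, 6, 1.00, True, [(2, "+")]),
    ("female_gametophytes", 2.27, 0.56, 946, 5, 0.92, False, [(2, "++"), (4, "+")]),
    ("sporophytes_embryonic", 1.64, 0.21, 408, 25, 1.29, False, [(2, "+")]),
    ("meristoderm", 1.51, 0.16, 905, 7, 1.86, False, []),
    ("cortex_medulla", 2.40, 0.41, 629, 7, 2.50, False, [(2, "++"), (4, "++:0.06"), (8, "++:0.04")]),
]


def stage_presets(
    plus_fraction: float = 0.02,
    plus_plus_fraction: float = 0.10,
) -> dict[str, StagePreset]:
    """Presets for the seven measured life-cycle stages/tissues.

    Each preset's main component carries the published per-stage mean +/- SD
    and nucleus count; stages in which minor higher-ploidy subpopulations
    were seen gain extra components at ``plus_fraction`` ("+") or
    ``plus_plus_fraction`` ("++") of the nuclei, at 2x/4x/8x the main mean.
    The true abundances behind the flags are not published; the fractions are
    explicit configuration, not inferred fact.
    """
    out: dict[str, StagePreset] = {}
    for label, mean, sd, n_total, n_sources, size_scale, decoupled, minors in _STAGE_TABLE:
        cv = sd / mean
        fracs: list[tuple[int, float]] = []
        for multiple, flag in minors:
            if ":" in flag:
                base, frac_s = flag.split(":")
                frac = float(frac_s)
            else:
                base = flag
                frac = plus_fraction if base == "+" else plus_plus_fraction
                if base == "++" and flag == "++":
                    frac = plus_plus_fraction
            fracs.append((multiple, frac))
        minor_total = sum(f for _, f in fracs)
        if minor_total >= 1:
            raise ValidationError(f"stage {label!r}: minor fractions must sum below 1")
        comps: list[ComponentSpec] = []
        n_minor_sum = 0
        for multiple, frac in fracs:
            n_minor = max(1, round(n_total * frac))
            n_minor_sum += n_minor
            comps.append(
                ComponentSpec(
                    label=f"{label}:{multiple}x",
                    mean_pg=mean * multiple,
                    cv=cv,
                    n=n_minor,
                    weight=frac,
                    size_scale=size_scale,
                )
            )
        main = ComponentSpec(
            label=label,
            mean_pg=mean,
            cv=cv,
            n=n_total - n_minor_sum,
            weight=1.0 - minor_total,
            size_scale=size_scale,
        )
        out[label] = StagePreset(
            label=label,
            components=(main, *comps),
            mean_pg=mean,
            sd_pg=sd,
            cv=cv,
            n_total=n_total,
            decoupled=decoupled,
            n_sources=n_sources,
        )
    return out
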