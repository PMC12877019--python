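"""Synthetic multi-slide mIF cohorts with known ground truth.

Emulates the statistical structure of a 12-patient melanoma cohort so that
every pipeline stage is testable without patient data:

* **Spatial point patterns** — background stroma as a homogeneous Poisson
  process, tumor nests as a Thomas cluster process (Poisson parents with
  Gaussian-dispersed offspring), immune cells as sparse Poisson processes,
  plus small "immune aggregates" (CD8-moderate patches present on every
  slide) so immune-rich tiles exist in both response classes.
* **Marker co-expression** — every cell carries one latent type; the 8
  binary markers are independent Bernoulli draws with per-type
  probabilities. The stromal type has all probabilities 0, so stromal
  cells are marker-negative by construction.
* **Responder effects** — responder slides receive planted TIL-like niches
  (disks of dense CD8/PD-L1/LAG-3-high T cells mixed with PD-L1/iNOS-high
  tumor cells; background processes are thinned inside the disk) and
  cohort-level marker-probability shifts (elevated iNOS/PD-L1
  co-positivity). Effect presets: ``null`` (no difference), ``weak``,
  ``strong``.

Ground truth records each cell's latent type and whether it lies inside a
planted niche disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cells import CellTable
from .panel import LYMPHOID_PANEL, MarkerPanel

MAX_CELLS_PER_SLIDE = 10_000_000

STROMA = "stroma"

#: Per-latent-type Bernoulli marker probabilities, lymphoid panel.
DEFAULT_MARKER_PROBS: dict[str, dict[str, float]] = {
    STROMA: {},
    "tumor": {"SOX10": 0.95, "iNOS": 0.25, "PD-L1": 0.03, "nNOS": 0.05},
    "t_helper": {"CD3": 0.95, "CD8": 0.03, "PD-L1": 0.05, "LAG-3": 0.02},
    "t_cytotoxic": {"CD3": 0.90, "CD8": 0.90, "PD-L1": 0.08, "LAG-3": 0.05, "iNOS": 0.08},
    "b_cell": {"CD20": 0.90, "CD3": 0.08},
    "niche_t": {"CD3": 0.90, "CD8": 0.90, "PD-L1": 0.50, "LAG-3": 0.50, "iNOS": 0.50},
    "niche_tumor": {"SOX10": 0.90, "PD-L1": 0.60, "iNOS": 0.60},
}

#: Responder-slide marker-probability shifts at full ("strong") effect.
DEFAULT_RESPONDER_SHIFTS: dict[tuple[str, str], float] = {
    ("t_cytotoxic", "iNOS"): +0.32,
    ("tumor", "iNOS"): +0.20,
    ("tumor", "PD-L1"): +0.09,
}

#: Effect presets scale (niche count multiplier, marker-shift multiplier).
PRESETS: dict[str, tuple[float, float]] = {
    "null": (0.0, 0.0),
    "weak": (1 / 3, 0.5),
    "strong": (1.0, 1.0),
}


@dataclass
class SyntheticConfig:
    """Cohort generator configuration; defaults are the study conditions."""

    n_responders: int = 4
    n_nonresponders: int = 8
    extent_um: tuple[float, float] = (3000.0, 3000.0)
    # background and tumor processes (intensities in cells/mm^2)
    stroma_per_mm2: float = 600.0
    tumor_parents_per_mm2: float = 2.5
    tumor_offspring_mean: float = 60.0
    tumor_sigma_um: float = 40.0
    immune_per_mm2: dict[str, float] = field(
        default_factory=lambda: {"t_helper": 80.0, "t_cytotoxic": 10.0, "b_cell": 30.0}
    )
    # CD8-moderate immune aggregates, present on every slide
    aggregates_per_slide: int = 2
    aggregate_radius_um: float = 200.0
    aggregate_cells_per_mm2: float = 400.0
    aggregate_composition: dict[str, float] = field(
        default_factory=lambda: {"t_cytotoxic": 0.5, "t_helper": 0.5}
    )
    # planted TIL-like niches on responder slides
    niches_per_responder: int = 3
    niche_radius_um: float = 250.0
    niche_cells_per_mm2: float = 1200.0
    niche_composition: dict[str, float] = field(
        default_factory=lambda: {"niche_t": 0.6, "niche_tumor": 0.4}
    )
    niche_background_keep: float = 0.3  # background thinning inside niches
    marker_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKER_PROBS.items()}
    )
    responder_shifts: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONDER_SHIFTS)
    )
    effect_preset: str = "strong"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_preset not in PRESETS:
            raise ValueError(f"unknown preset {self.effect_preset!r}")
        for p in self._all_probs():
            if not 0.0 <= p <= 1.0:
                raise ValueError("marker probabilities must lie in [0, 1]")
        if min(self.extent_um) <= 1000.0:
            raise ValueError("slide extent must exceed the 1 mm tile size")

    def _all_probs(self):
        for row in self.marker_probs.values():
            yield from row.values()

    @property
    def niche_count(self) -> int:
        scale, _ = PRESETS[self.effect_preset]
        return int(round(self.niches_per_responder * scale))

    @property
    def shift_scale(self) -> float:
        return PRESETS[self.effect_preset][1]

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["responder_shifts"] = sorted(
            (t, m, v) for (t, m), v in self.responder_shifts.items()
        )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(effect_preset="null", seed=seed, **overrides)


def weak_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(effect_preset="weak", seed=seed, **overrides)


def strong_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(effect_preset="strong", seed=seed, **overrides)


def cd8_confined_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Responder signal confined to CD8-rich tiles: niches only, no
    cohort-wide marker shifts. Used to probe the immune-high filter."""
    cfg = SyntheticConfig(effect_preset="strong", seed=seed, **overrides)
    cfg.responder_shifts = {k: 0.0 for k in cfg.responder_shifts}
    return cfg


def load_preset(path: str | Path) -> SyntheticConfig:
    """Load a generator configuration from YAML (ships in ``presets/``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "responder_shifts" in raw:
        raw["responder_shifts"] = {
            (t, m): float(v) for t, m, v in raw["responder_shifts"]
        }
    if "extent_um" in raw:
        raw["extent_um"] = tuple(raw["extent_um"])
    return SyntheticConfig(**raw)


def _disk_centers(
    rng: np.random.Generator,
    n: int,
    extent: tuple[float, float],
    radius: float,
    max_tries: int = 1000,
) -> np.ndarray:
    """Disk centres at least ``radius`` from every border, non-overlapping."""
    w, h = extent
    if n == 0:
        return np.zeros((0, 2))
    if w <= 2 * radius or h <= 2 * radius:
        raise ValueError("slide too small for the requested disk radius")
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        c = rng.uniform([radius, radius], [w - radius, h - radius])
        if all(np.linalg.norm(c - p) >= 2 * radius for p in centers):
            centers.append(c)
        if len(centers) == n:
            break
    else:
        raise RuntimeError("could not place non-overlapping disks")
    return np.array(centers)


def _poisson_uniform(
    rng: np.random.Generator, intensity_per_mm2: float, extent: tuple[float, float]
) -> np.ndarray:
    area_mm2 = extent[0] * extent[1] / 1e6
    n = rng.poisson(intensity_per_mm2 * area_mm2)
    return rng.uniform([0, 0], list(extent), size=(n, 2))


def _uniform_in_disks(
    rng: np.random.Generator, centers: np.ndarray, radius: float, n_per_disk: np.ndarray
) -> np.ndarray:
    pts = []
    for c, n in zip(centers, n_per_disk):
        r = radius * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0, 2 * np.pi, size=n)
        pts.append(c + np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    return np.vstack(pts) if pts else np.zeros((0, 2))


def _in_any_disk(xy: np.ndarray, centers: np.ndarray, radius: float) -> np.ndarray:
    if len(centers) == 0 or len(xy) == 0:
        return np.zeros(len(xy), dtype=bool)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= radius**2).any(axis=1)


def sample_point_pattern(
    config: SyntheticConfig, is_responder: bool, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One slide's point pattern: ``(xy, latent_types, in_niche)``.

    Stroma/immune are homogeneous Poisson; tumor nests follow a Thomas
    process; aggregates and (responder-only) niches add cells inside
    planted disks, with background thinned inside niche disks.
    """
    rng = np.random.default_rng(seed)
    extent = config.extent_um
    area_mm2 = extent[0] * extent[1] / 1e6
    expected = (
        config.stroma_per_mm2
        + config.tumor_parents_per_mm2 * config.tumor_offspring_mean
        + sum(config.immune_per_mm2.values())
    ) * area_mm2
    if expected > MAX_CELLS_PER_SLIDE:
        raise ValueError(f"configuration implies ~{expected:.2e} cells per slide")

    niche_centers = _disk_centers(
        rng,
        config.niche_count if is_responder else 0,
        extent,
        config.niche_radius_um,
    )

    def thin(xy: np.ndarray) -> np.ndarray:
        if len(niche_centers) == 0:
            return xy
        inside = _in_any_disk(xy, niche_centers, config.niche_radius_um)
        keep = ~inside | (rng.uniform(size=len(xy)) < config.niche_background_keep)
        return xy[keep]

    points: list[np.ndarray] = []
    types: list[np.ndarray] = []

    xy = thin(_poisson_uniform(rng, config.stroma_per_mm2, extent))
    points.append(xy)
    types.append(np.full(len(xy), STROMA, dtype=object))

    # Thomas process: Poisson parents, Poisson offspring, Gaussian dispersion
    parents = _poisson_uniform(rng, config.tumor_parents_per_mm2, extent)
    n_off = rng.poisson(config.tumor_offspring_mean, size=len(parents))
    if n_off.sum():
        off = np.repeat(parents, n_off, axis=0) + rng.normal(
            scale=config.tumor_sigma_um, size=(int(n_off.sum()), 2)
        )
        inside = (off >= 0).all(axis=1) & (off < np.array(extent)).all(axis=1)
        off = thin(off[inside])
        points.append(off)
        types.append(np.full(len(off), "tumor", dtype=object))

    for latent, intensity in config.immune_per_mm2.items():
        xy = thin(_poisson_uniform(rng, intensity, extent))
        points.append(xy)
        types.append(np.full(len(xy), latent, dtype=object))

    disk_specs = [
        (
            config.aggregates_per_slide,
            config.aggregate_radius_um,
            config.aggregate_cells_per_mm2,
            config.aggregate_composition,
        )
    ]
    if len(niche_centers):
        disk_specs.append(
            (
                len(niche_centers),
                config.niche_radius_um,
                config.niche_cells_per_mm2,
                config.niche_composition,
            )
        )
    for i, (count, radius, density, composition) in enumerate(disk_specs):
        if count == 0:
            continue
        centers = (
            niche_centers
            if i == 1
            else _disk_centers(rng, count, extent, radius)
        )
        disk_area_mm2 = np.pi * radius**2 / 1e6
        n_per = rng.poisson(density * disk_area_mm2, size=len(centers))
        xy = _uniform_in_disks(rng, centers, radius, n_per)
        comp_types = list(composition)
        comp_p = np.array([composition[t] for t in comp_types], dtype=float)
        comp_p /= comp_p.sum()
        drawn = rng.choice(comp_types, size=len(xy), p=comp_p)
        points.append(xy)
        types.append(drawn.astype(object))

    xy_all = np.vstack(points)
    type_all = np.concatenate(types)
    in_niche = _in_any_disk(xy_all, niche_centers, config.niche_radius_um)
    order = np.lexsort((xy_all[:, 1], xy_all[:, 0]))
    return xy_all[order], type_all[order], in_niche[order]


def assign_markers(
    latent_types: np.ndarray,
    config: SyntheticConfig,
    is_responder: bool,
    seed: int,
    panel: MarkerPanel = LYMPHOID_PANEL,
) -> np.ndarray:
    """Draw the (n_cells, 8) positivity matrix from per-type Bernoulli rows."""
    rng = np.random.default_rng(seed)
    probs = {t: dict(row) for t, row in config.marker_probs.items()}
    missing = set(np.unique(latent_types)) - set(probs)
    if missing:
        raise ValueError(f"no marker-probability row for latent types {sorted(missing)}")
    if is_responder and config.shift_scale:
        for (latent, marker), delta in config.responder_shifts.items():
            row = probs[latent]
            row[marker] = float(
                np.clip(row.get(marker, 0.0) + config.shift_scale * delta, 0, 1)
            )
    p_matrix = np.array(
        [[probs[t].get(m, 0.0) for m in panel.markers] for t in latent_types]
    )
    return rng.uniform(size=p_matrix.shape) < p_matrix


def generate_cohort(
    config: SyntheticConfig, panel: MarkerPanel = LYMPHOID_PANEL
) -> tuple[list[CellTable], pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort: ``(cell_tables, metadata, ground_truth)``.

    Slide ids are ``R1..`` (responders) and ``N1..`` (non-responders).
    Ground truth has one row per cell: slide_id, cell_id, latent_type,
    in_niche. Fully deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    n_slides = config.n_responders + config.n_nonresponders
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_slides)]

    tables: list[CellTable] = []
    truth_frames = []
    slide_num = 0
    for is_responder, count, prefix in (
        (True, config.n_responders, "R"),
        (False, config.n_nonresponders, "N"),
    ):
        for i in range(count):
            slide_id = f"{prefix}{i + 1}"
            pattern_seed = child_seeds[2 * slide_num]
            marker_seed = child_seeds[2 * slide_num + 1]
            slide_num += 1
            xy, latent, in_niche = sample_point_pattern(config, is_responder, pattern_seed)
            pos = assign_markers(latent, config, is_responder, marker_seed, panel)
            cell_ids = [f"{slide_id}-{j}" for j in range(len(xy))]
            df = pd.DataFrame({"cell_id": cell_ids, "x": xy[:, 0], "y": xy[:, 1]})
            for m_i, marker in enumerate(panel.markers):
                df[marker] = pos[:, m_i]
            tables.append(
                CellTable(
                    panel=panel,
                    slide_id=slide_id,
                    cells=df,
                    response="responder" if is_responder else "non-responder",
                    sample_type="resection",
                )
            )
            truth_frames.append(
                pd.DataFrame(
                    {
                        "slide_id": slide_id,
                        "cell_id": cell_ids,
                        "latent_type": latent,
                        "in_niche": in_niche,
                    }
                )
            )

    metadata = pd.DataFrame(
        {
            "slide_id": [t.slide_id for t in tables],
            "response": [t.response for t in tables],
            "sample_type": [t.sample_type for t in tables],
            "n_cells": [t.n_cells for t in tables],
        }
    )
    metadata.attrs["config_hash"] = config.config_hash()
    ground_truth = pd.concat(truth_frames, ignore_index=True)
    return tables, metadata, ground_truth
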