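"""Synthetic tissue cohorts with controllable spatial signal.

Generates cohorts of multiplexed-imaging-like tissue samples: multiple
images per patient, a few hundred to a few thousand cells per image in a
square field, discrete cell types with an immune/non-immune binarization,
per-type marker profiles, and a class label that is encoded through exactly
one chosen signal channel:

``composition``
    classes differ in their immune-cell fraction.
``density``
    classes differ in the point-process intensity (cells per unit area).
``arrangement``
    classes share composition, density and marker laws; one class places its
    immune cells inside a small number of Gaussian aggregates (a compact
    lymphoid-structure analogue), the other by uniform thinning. Both
    classes share one uniform point pattern, so spatial arrangement of the
    immune label is the only signal.
``interaction``
    one class enriches a source cell type in the immediate vicinity of a
    target cell type (e.g. fibroblasts around tumor cells); type
    composition is matched across classes.
``ordinal_grade``
    a latent severity in [0, 1] drives three ordinal grade labels (tertile
    thresholds), interpolates the channel parameters linearly, and drives
    right-censored survival (exponential event times with a log-linear rate
    in severity, independent uniform censoring).

At ``strength = 0`` every channel degenerates to identical class-conditional
generative laws.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tissuegraph")

DEFAULT_TYPE_MENU = ("tumor", "fibroblast", "macrophage", "T cell", "B cell", "stroma")
DEFAULT_IMMUNE_TYPES = ("macrophage", "T cell", "B cell")
# conditional proportions within the immune / non-immune compartments
_IMMUNE_SPLIT = {"macrophage": 0.4, "T cell": 0.4, "B cell": 0.2}
_NONIMMUNE_SPLIT = {"tumor": 0.5, "fibroblast": 0.3, "stroma": 0.2}

REQUIRED_COLUMNS = ("image_id", "patient_id", "x", "y", "cell_type")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PanelSpec:
    """A marker panel: per-type mean log-intensity profiles plus noise."""

    marker_names: tuple
    means: dict            # cell type -> vector of per-marker means
    dispersions: dict      # cell type -> positive scalar sd
    background_sd: float = 0.1

    def __post_init__(self):
        for t, d in self.dispersions.items():
            if d < 0:
                raise ValueError(f"dispersion for type {t!r} must be >= 0")
        for t, m in self.means.items():
            if len(m) != len(self.marker_names):
                raise ValueError(f"mean vector for type {t!r} has wrong length")

    @classmethod
    def default(cls, type_menu=DEFAULT_TYPE_MENU, n_markers: int = 12,
                dispersion: float = 0.3, background_sd: float = 0.1):
        """Archetypal panel: each type highly expresses two dedicated markers."""
        names = tuple(f"marker_{i:02d}" for i in range(n_markers))
        means = {}
        for i, t in enumerate(type_menu):
            m = np.full(n_markers, 0.5)
            hi = [(2 * i) % n_markers, (2 * i + 1) % n_markers]
            m[hi] = 3.0
            means[t] = m
        disps = {t: dispersion for t in type_menu}
        return cls(names, means, disps, background_sd)


@dataclass
class SignalConfig:
    """Which channel encodes the class label, and how strongly."""

    channel: str = "arrangement"
    strength: float = 1.0
    aggregate_sd: float = 60.0
    aggregate_count: int = 3
    aggregate_background: float = 0.25  # uniform mixture weight inside the aggregated class
    interaction_pair: tuple = ("fibroblast", "tumor")
    immune_fraction: dict = field(default_factory=dict)   # class -> fraction
    intensity: dict = field(default_factory=dict)         # class -> mean cells per image
    base_immune_fraction: float = 0.3

    _CHANNELS = ("composition", "density", "arrangement", "interaction", "ordinal_grade")

    def __post_init__(self):
        if self.channel not in self._CHANNELS:
            raise ValueError(f"unknown signal channel {self.channel!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.aggregate_sd <= 0:
            raise ValueError("aggregate_sd must be positive")
        if self.aggregate_count < 1:
            raise ValueError("aggregate_count must be a positive integer")
        for c, f in self.immune_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"immune fraction for class {c!r} outside [0, 1]")
        for c, lam in self.intensity.items():
            if lam <= 0:
                raise ValueError(f"intensity for class {c!r} must be positive")


@dataclass
class TissueSample:
    """One image: coordinates, cell types, markers, label and metadata."""

    image_id: str
    patient_id: str
    coords: np.ndarray          # (n, 2)
    cell_type: np.ndarray       # (n,) strings
    immune_flag: np.ndarray     # (n,) bool
    markers: np.ndarray         # (n, m)
    label: str
    severity: float | None = None          # latent, simulation-only
    survival_time: float | None = None
    event: int | None = None
    in_aggregate: np.ndarray | None = None  # simulation-only ground truth
    extras: pd.DataFrame | None = None      # tolerated unknown columns

    @property
    def n_cells(self) -> int:
        return len(self.coords)


@dataclass
class Cohort:
    samples: list
    field_size: float
    type_immune_map: dict
    class_names: tuple
    marker_names: tuple

    def __post_init__(self):
        for s in self.samples:
            if s.label not in self.class_names:
                raise ValueError(f"label {s.label!r} not in class names")

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def patients(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.samples])

    def __len__(self):
        return len(self.samples)


@dataclass
class SimConfig:
    """Full description of a simulated cohort."""

    n_patients: int = 40
    images_per_patient: int = 4
    cells_per_image: int = 800
    class_names: tuple = ("aggregated", "diffuse")
    class_balance: tuple | None = None       # patient-level class probabilities
    signal: SignalConfig = field(default_factory=SignalConfig)
    panel: PanelSpec | None = None
    field_size: float = 1000.0
    type_menu: tuple = DEFAULT_TYPE_MENU
    immune_types: tuple = DEFAULT_IMMUNE_TYPES
    patient_effect_sd: float = 0.05          # within-patient severity jitter (ordinal channel)
    survival_a: float = 0.1                  # baseline event rate
    survival_b: float = 3.0                  # log-linear severity effect on the rate
    censor_upper: float = 15.0               # uniform censoring upper bound (~30% censoring)

    def validate(self):
        if self.n_patients < 1 or self.images_per_patient < 1:
            raise ValueError("need at least one patient and one image per patient")
        if self.cells_per_image < 0:
            raise ValueError("cells_per_image must be nonnegative")
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")
        if self.class_balance is not None:
            if len(self.class_balance) != len(self.class_names):
                raise ValueError("class_balance length must match class_names")
            if abs(sum(self.class_balance) - 1.0) > 1e-9:
                raise ValueError("class_balance must sum to 1")
        if self.signal.channel == "ordinal_grade" and len(self.class_names) != 3:
            raise ValueError("ordinal_grade channel requires exactly 3 class names")
        for c in self.signal.immune_fraction:
            if c not in self.class_names:
                raise ValueError(f"immune_fraction given for unknown class {c!r}")
        for c in self.signal.intensity:
            if c not in self.class_names:
                raise ValueError(f"intensity given for unknown class {c!r}")
        unknown = set(self.immune_types) - set(self.type_menu)
        if unknown:
            raise ValueError(f"immune types not in menu: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# point patterns


def sample_point_pattern(field, n, process="uniform", seed=0, sd=None, n_parents=None):
    """Draw ``n`` points in a rectangular field.

    ``field`` is (width, height) or a scalar side length. ``process`` is
    ``"uniform"`` or ``"clustered"``; clustered points scatter around
    uniformly placed parent centers with Gaussian spread ``sd`` and are
    resampled until they land inside the field.
    """
    if np.isscalar(field):
        field = (float(field), float(field))
    w, h = field
    if w <= 0 or h <= 0:
        raise ValueError("field must have positive area")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 2))
    if process == "uniform":
        return rng.uniform((0, 0), (w, h), size=(n, 2))
    if process == "clustered":
        if sd is None or sd <= 0:
            raise ValueError("clustered mode requires sd > 0")
        k = n_parents or 5
        parents = rng.uniform((0, 0), (w, h), size=(k, 2))
        assign = rng.integers(0, k, size=n)
        pts = parents[assign] + rng.normal(0, sd, size=(n, 2))
        bad = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        while bad.any():
            pts[bad] = parents[assign[bad]] + rng.normal(0, sd, size=(bad.sum(), 2))
            bad = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        return pts
    raise ValueError(f"unknown process {process!r}")


# ---------------------------------------------------------------------------
# type / label assignment


def _split_types(rng, n, immune_mask, immune_types, nonimmune_types):
    """Assign concrete cell types given an immune/non-immune partition."""
    types = np.empty(n, dtype=object)
    imm_p = np.array([_IMMUNE_SPLIT.get(t, 1.0) for t in immune_types], dtype=float)
    imm_p /= imm_p.sum()
    non_p = np.array([_NONIMMUNE_SPLIT.get(t, 1.0) for t in nonimmune_types], dtype=float)
    non_p /= non_p.sum()
    n_imm = int(immune_mask.sum())
    if n_imm:
        types[immune_mask] = rng.choice(immune_types, size=n_imm, p=imm_p)
    if n - n_imm:
        types[~immune_mask] = rng.choice(nonimmune_types, size=n - n_imm, p=non_p)
    return types


def assign_labels_and_types(coords, class_label, signal: SignalConfig,
                            type_menu=DEFAULT_TYPE_MENU,
                            immune_types=DEFAULT_IMMUNE_TYPES,
                            class_names=("aggregated", "diffuse"),
                            field_size=1000.0, seed=0, severity=None):
    """Assign cell types and immune flags implementing one signal channel.

    Returns ``(cell_type, immune_flag, in_aggregate)``. ``severity`` is only
    used by the ``ordinal_grade`` channel, which interpolates the composition
    and arrangement parameters linearly in the latent severity.
    """
    rng = np.random.default_rng(seed)
    n = len(coords)
    nonimmune_types = tuple(t for t in type_menu if t not in immune_types)
    in_agg = np.zeros(n, dtype=bool)
    if class_label not in class_names:
        raise ValueError(f"class {class_label!r} not in class names")

    base_f = signal.base_immune_fraction
    channel = signal.channel

    if channel == "composition":
        target = signal.immune_fraction.get(class_label, base_f)
        f = (1 - signal.strength) * base_f + signal.strength * target
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"shifted immune fraction {f} outside [0, 1]")
        immune = rng.random(n) < f
        types = _split_types(rng, n, immune, immune_types, nonimmune_types)
        return types, immune, in_agg

    if channel == "density":
        # class signal is carried upstream by per-class intensity; types iid
        immune = rng.random(n) < base_f
        types = _split_types(rng, n, immune, immune_types, nonimmune_types)
        return types, immune, in_agg

    if channel in ("arrangement", "ordinal_grade"):
        if channel == "ordinal_grade":
            if severity is None:
                raise ValueError("ordinal_grade channel requires a severity value")
            strength = signal.strength * float(severity)
            aggregated = True
        else:
            strength = signal.strength
            aggregated = class_label == class_names[0]
        n_imm = int(round(base_f * n))
        n_imm = min(max(n_imm, 0), n)
        immune = np.zeros(n, dtype=bool)
        if n_imm and n:
            if aggregated and strength > 0:
                centers = rng.uniform(0, field_size, size=(signal.aggregate_count, 2))
                d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
                kern = np.exp(-d2 / (2 * signal.aggregate_sd ** 2)).sum(axis=1)
                bg = signal.aggregate_background
                w_agg = (1 - bg) * kern / max(kern.sum(), 1e-300) + bg / n
                w = (1 - strength) / n + strength * w_agg
                w /= w.sum()
                chosen = rng.choice(n, size=n_imm, replace=False, p=w)
                near = np.sqrt(d2.min(axis=1)) < 2 * signal.aggregate_sd
                immune[chosen] = True
                in_agg = immune & near
            else:
                chosen = rng.choice(n, size=n_imm, replace=False)
                immune[chosen] = True
        types = _split_types(rng, n, immune, immune_types, nonimmune_types)
        return types, immune, in_agg

    if channel == "interaction":
        immune = rng.random(n) < base_f
        types = _split_types(rng, n, immune, immune_types, nonimmune_types)
        source, target = signal.interaction_pair
        candidates = np.flatnonzero(types != target)
        m = int(round(signal.strength * len(candidates)))
        if m > 0:
            tgt_idx = np.flatnonzero(types == target)
            if class_label == class_names[0] and len(tgt_idx):
                from scipy.spatial import cKDTree
                tree = cKDTree(coords[tgt_idx])
                dist, _ = tree.query(coords[candidates])
                chosen = candidates[np.argsort(dist, kind="stable")[:m]]
            else:
                chosen = rng.choice(candidates, size=m, replace=False)
            types[chosen] = source
            immune[chosen] = source in immune_types
        return types, immune, in_agg

    raise ValueError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------------
# markers


def sample_markers(cell_types, panel: PanelSpec, seed=0):
    """Per-cell marker vectors: type mean + per-type noise + background, clamped at 0."""
    rng = np.random.default_rng(seed)
    cell_types = np.asarray(cell_types, dtype=object)
    m = len(panel.marker_names)
    out = np.zeros((len(cell_types), m))
    unknown = set(cell_types) - set(panel.means)
    if unknown:
        raise ValueError(f"cell types missing from panel: {sorted(map(str, unknown))}")
    for t in sorted(set(cell_types), key=str):
        idx = np.flatnonzero(cell_types == t)
        noise = rng.normal(0.0, panel.dispersions[t], size=(len(idx), m))
        out[idx] = np.asarray(panel.means[t]) + noise
    if panel.background_sd > 0:
        out += rng.normal(0.0, panel.background_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(config: SimConfig, seed=0) -> Cohort:
    """Generate a full cohort; reproducible given ``(config, seed)``."""
    config.validate()
    panel = config.panel or PanelSpec.default(config.type_menu)
    rng = np.random.default_rng(seed)
    sig = config.signal
    class_names = tuple(config.class_names)
    balance = config.class_balance or (1.0 / len(class_names),) * len(class_names)

    ordinal = sig.channel == "ordinal_grade"
    if not ordinal:
        # exact patient quota per class (shuffled), mirroring the fixed
        # composition of real cohorts and avoiding degenerate folds
        quota = np.floor(np.asarray(balance) * config.n_patients).astype(int)
        while quota.sum() < config.n_patients:
            quota[int(np.argmax(np.asarray(balance) * config.n_patients - quota))] += 1
        assignment = np.repeat(np.arange(len(class_names)), quota)
        assignment = assignment[rng.permutation(config.n_patients)]
    samples = []
    for p in range(config.n_patients):
        pid = f"patient_{p:03d}"
        if ordinal:
            sev_p = rng.uniform()
        else:
            patient_class = class_names[assignment[p]]
            sev_p = None
        # survival (populated only for the ordinal channel)
        if ordinal:
            rate = config.survival_a * np.exp(config.survival_b * sev_p)
            t_event = rng.exponential(1.0 / rate)
            if config.censor_upper > 0:
                t_cens = rng.uniform(0.0, config.censor_upper)
            else:
                t_cens = np.inf
            surv_t = float(min(t_event, t_cens))
            event = int(t_event <= t_cens)
        for k in range(config.images_per_patient):
            iid = f"img_{p:03d}_{k}"
            if ordinal:
                sev = float(np.clip(sev_p + rng.normal(0, config.patient_effect_sd), 0, 1))
                label = class_names[min(int(sev * 3), 2)]
            else:
                sev = None
                label = patient_class
            if sig.channel == "density":
                area = config.field_size ** 2
                lams = {c: (sig.intensity[c] * area if c in sig.intensity
                            else float(config.cells_per_image))
                        for c in class_names}
                base = float(np.mean(list(lams.values())))
                lam = (1 - sig.strength) * base + sig.strength * lams[label]
            else:
                lam = config.cells_per_image
            n = int(rng.poisson(lam))
            coords = rng.uniform(0, config.field_size, size=(n, 2))
            types, immune, in_agg = assign_labels_and_types(
                coords, label, sig, config.type_menu, config.immune_types,
                class_names, config.field_size,
                seed=rng.integers(0, 2 ** 31), severity=sev,
            )
            markers = sample_markers(types, panel, seed=rng.integers(0, 2 ** 31))
            samples.append(TissueSample(
                image_id=iid, patient_id=pid, coords=coords,
                cell_type=types, immune_flag=immune, markers=markers,
                label=label, severity=sev,
                survival_time=surv_t if ordinal else None,
                event=event if ordinal else None,
                in_aggregate=in_agg,
            ))
    immune_map = {t: (t in config.immune_types) for t in config.type_menu}
    return Cohort(samples, config.field_size, immune_map, class_names, panel.marker_names)


# ---------------------------------------------------------------------------
# persistence: columnar cell table + structured metadata sidecar


def write_cohort(cohort: Cohort, path):
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = []
    meta_samples = []
    for s in cohort.samples:
        df = pd.DataFrame({
            "image_id": s.image_id,
            "patient_id": s.patient_id,
            "x": s.coords[:, 0],
            "y": s.coords[:, 1],
            "cell_type": s.cell_type.astype(str),
            "in_aggregate": (s.in_aggregate if s.in_aggregate is not None
                             else np.zeros(s.n_cells, dtype=bool)).astype(int),
        })
        for j, m in enumerate(cohort.marker_names):
            df[m] = s.markers[:, j]
        frames.append(df)
        meta_samples.append({
            "image_id": s.image_id, "patient_id": s.patient_id, "label": s.label,
            "severity": s.severity, "survival_time": s.survival_time, "event": s.event,
        })
    pd.concat(frames, ignore_index=True).to_csv(path / "cells.csv", index=False,
                                                float_format="%.17g")
    meta = {
        "field_size": cohort.field_size,
        "class_names": list(cohort.class_names),
        "type_immune_map": cohort.type_immune_map,
        "marker_names": list(cohort.marker_names),
        "samples": meta_samples,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def read_cohort(path) -> Cohort:
    path = Path(path)
    cells = pd.read_csv(path / "cells.csv", float_precision="round_trip")
    meta = json.loads((path / "metadata.json").read_text())
    marker_names = tuple(meta["marker_names"])
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    missing_markers = [m for m in marker_names if m not in cells.columns]
    if missing_markers:
        raise ValueError(f"cell table missing required columns: {missing_markers}")
    known = set(REQUIRED_COLUMNS) | set(marker_names) | {"in_aggregate"}
    extra = [c for c in cells.columns if c not in known]
    if extra:
        logger.warning("cell table has unknown columns (preserved): %s", extra)
        warnings.warn(f"cell table has unknown columns (preserved): {extra}")
    samples = []
    by_image = {m["image_id"]: m for m in meta["samples"]}
    for iid, g in cells.groupby("image_id", sort=False):
        m = by_image[iid]
        types = g["cell_type"].to_numpy(dtype=object)
        immune = np.array([meta["type_immune_map"].get(str(t), False) for t in types])
        samples.append(TissueSample(
            image_id=iid, patient_id=m["patient_id"],
            coords=g[["x", "y"]].to_numpy(),
            cell_type=types, immune_flag=immune,
            markers=g[list(marker_names)].to_numpy(),
            label=m["label"], severity=m.get("severity"),
            survival_time=m.get("survival_time"), event=m.get("event"),
            in_aggregate=(g["in_aggregate"].to_numpy().astype(bool)
                          if "in_aggregate" in g.columns else None),
            extras=g[extra].reset_index(drop=True) if extra else None,
        ))
    return Cohort(samples, meta["field_size"], meta["type_immune_map"],
                  tuple(meta["class_names"]), marker_names)
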