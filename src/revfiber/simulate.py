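"""Synthetic dystrophic-muscle cohorts with clonal revertant expansion.

A muscle is modeled as a fixed 2D fiber tessellation extruded along its
longitudinal axis.  Reversion starts in a Poisson number of founder
fibers at birth, each carrying a dystrophin-positive segment of limited
longitudinal extent; over successive degeneration/regeneration cycles
every revertant fiber can annex adjacent negative fibers (clonal
expansion) while new founders keep appearing (de-novo reversion).
Transverse sections sampled ~120 um apart then see a fiber as revertant
exactly when its positive segment overlaps the slice, which reproduces
the dependence between nearby sections of the same muscle.

Rates are expressed per mm^2 of cross-section so simulated densities do
not depend on the tessellation size chosen for speed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .core import (
    AGE_GROUPS,
    MUSCLES,
    FiberRecord,
    SectionGraph,
    StudyKey,
    ValidationError,
)
from .quantify import SIZE_CLASSES, classify_cluster_size

DEFAULT_CYCLES_PER_GROUP: Mapping[int, int] = {1: 1, 2: 5, 3: 6, 4: 7}


@dataclass(frozen=True)
class SimConfig:
    """All rates and geometry parameters of the cohort generator.

    ``founder_rate`` and ``denovo_rate`` are expected counts per mm^2 of
    cross-sectional tissue area (founders at birth, respectively new
    founders per regeneration cycle).  ``heart_mode`` suppresses clonal
    expansion and shortens positive segments.
    """

    n_fibers: int = 400
    muscle_length_um: float = 2000.0
    mean_csa_um2: float = 2000.0
    csa_sigma: float = 0.35
    founder_rate: float = 6.0
    expansion_prob: float = 0.30
    cycles_per_group: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_CYCLES_PER_GROUP)
    )
    denovo_rate: float = 0.8
    extent_range_um: tuple[float, float] = (100.0, 300.0)
    extent_tail_max_um: float = 900.0
    extent_tail_prob: float = 0.05
    section_spacing_um: float = 120.0
    section_thickness_um: float = 9.0
    sections_range: tuple[int, int] = (10, 12)
    heart_mode: bool = False
    mouse_sd: float = 0.6
    muscle_sd: float = 0.20
    annex_jitter_um: float = 25.0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValidationError("n_fibers must be >= 1")
        for name in ("founder_rate", "denovo_rate", "mouse_sd", "muscle_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.expansion_prob <= 1.0):
            raise ValidationError("expansion_prob must be in [0, 1]")
        lo, hi = self.extent_range_um
        if not (100.0 <= lo <= hi <= self.extent_tail_max_um <= 900.0):
            raise ValidationError("extent support must lie within [100, 900] um")
        if not (self.section_spacing_um > self.section_thickness_um):
            raise ValidationError("section spacing must exceed section thickness")
        if any(g not in self.cycles_per_group for g in AGE_GROUPS):
            raise ValidationError(f"cycles_per_group must cover groups {AGE_GROUPS}")


@dataclass(frozen=True)
class MuscleProfile:
    """Per-muscle scaling of reversion rates."""

    founder_scale: float
    denovo_scale: float
    heart: bool = False


#: Default per-muscle rate scalings: diaphragm/pectoralis low, TA/soleus
#: high, heart lowest with expansion suppressed.
MUSCLE_PROFILES: Mapping[str, MuscleProfile] = {
    "TA": MuscleProfile(1.20, 1.20),
    "EDL": MuscleProfile(1.15, 1.15),
    "SOL": MuscleProfile(1.25, 1.25),
    "GC": MuscleProfile(1.00, 1.00),
    "PL": MuscleProfile(1.15, 1.15),
    "Q": MuscleProfile(0.95, 0.95),
    "TRIC": MuscleProfile(0.95, 0.95),
    "PT": MuscleProfile(0.60, 0.60),
    "D": MuscleProfile(0.55, 0.55),
    "IC": MuscleProfile(0.90, 0.90),
    "H": MuscleProfile(0.20, 1.80, heart=True),
}


@dataclass(frozen=True)
class Tessellation:
    """A planar fiber packing: centroids, areas and the adjacency graph."""

    centroids: np.ndarray  # (n, 2) um
    csa: np.ndarray  # (n,) um^2
    edges: tuple[tuple[int, int], ...]  # 1-based fiber-id pairs
    neighbors: tuple[tuple[int, ...], ...]  # 0-based index adjacency

    @property
    def n_fibers(self) -> int:
        return len(self.csa)

    @property
    def area_mm2(self) -> float:
        return float(self.csa.sum()) / 1e6


def make_tessellation(
    n_fibers: int,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    mean_csa_um2: float = 2000.0,
    csa_sigma: float = 0.35,
) -> Tessellation:
    """Seeded random fiber packing with a Delaunay adjacency graph.

    Fiber ids are 1..n.  Centroids are uniform in a square sized so the
    total fiber area matches ``n_fibers * mean_csa_um2``; areas are
    log-normal with the requested mean.
    """
    if n_fibers < 1:
        raise ValidationError("n_fibers must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    side = np.sqrt(n_fibers * mean_csa_um2)
    centroids = rng.uniform(0.0, side, size=(n_fibers, 2))
    csa = rng.lognormal(
        mean=np.log(mean_csa_um2) - csa_sigma**2 / 2, sigma=csa_sigma, size=n_fibers
    )
    edge_set: set[tuple[int, int]] = set()
    if n_fibers == 2:
        edge_set.add((0, 1))
    elif n_fibers >= 3:
        tri = Delaunay(centroids)
        for simplex in tri.simplices:
            for i in range(3):
                a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
                edge_set.add((a, b) if a < b else (b, a))
    neighbors: list[list[int]] = [[] for _ in range(n_fibers)]
    for a, b in edge_set:
        neighbors[a].append(b)
        neighbors[b].append(a)
    return Tessellation(
        centroids=centroids,
        csa=csa,
        edges=tuple(sorted((a + 1, b + 1) for a, b in edge_set)),
        neighbors=tuple(tuple(sorted(n)) for n in neighbors),
    )


@dataclass
class ReversionState:
    """Clone membership and longitudinal extent per fiber (0-based arrays)."""

    clone_id: np.ndarray  # int, -1 = not revertant
    z_lo: np.ndarray  # um
    z_hi: np.ndarray  # um
    n_clones: int = 0

    def revertant_indices(self) -> np.ndarray:
        return np.nonzero(self.clone_id >= 0)[0]


@dataclass(frozen=True)
class MuscleSim:
    """One simulated muscle: geometry plus realized reversion state."""

    tessellation: Tessellation
    state: ReversionState
    config: SimConfig


def _draw_extent(rng: np.random.Generator, config: SimConfig) -> float:
    lo, hi = config.extent_range_um
    if config.heart_mode:
        # Shortened positive segments, no heavy tail.
        return float(rng.uniform(lo, (lo + hi) / 2))
    if rng.random() < config.extent_tail_prob:
        return float(rng.uniform(hi, config.extent_tail_max_um))
    return float(rng.uniform(lo, hi))


def simulate_reversion(
    tess: Tessellation,
    config: SimConfig,
    age_group: int,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    rate_multiplier: float = 1.0,
) -> MuscleSim:
    """Run founder reversion + clonal expansion for one muscle.

    Founders appear Poisson(founder_rate * area * multiplier) at birth.
    Each elapsed regeneration cycle, every non-revertant fiber adjacent to
    k revertant fibers is annexed with probability 1 - (1-p_exp)^k (one
    independent chance per revertant neighbor) and inherits a jittered
    copy of the source clone's extent interval; Poisson de-novo founders
    are added per cycle.  ``heart_mode`` forces p_exp = 0.
    """
    if age_group not in AGE_GROUPS:
        raise ValidationError(f"age_group must be one of {AGE_GROUPS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = tess.n_fibers
    length = config.muscle_length_um
    state = ReversionState(
        clone_id=np.full(n, -1, dtype=np.int64),
        z_lo=np.zeros(n),
        z_hi=np.zeros(n),
    )
    area = tess.area_mm2
    p_exp = 0.0 if config.heart_mode else config.expansion_prob
    jitter = config.annex_jitter_um

    def add_founders(expected: float) -> None:
        count = rng.poisson(expected)
        for _ in range(count):
            negatives = np.nonzero(state.clone_id < 0)[0]
            if negatives.size == 0:
                return
            fiber = int(negatives[rng.integers(negatives.size)])
            extent = _draw_extent(rng, config)
            center = rng.uniform(0.0, length)
            state.clone_id[fiber] = state.n_clones
            state.z_lo[fiber] = max(0.0, center - extent / 2)
            state.z_hi[fiber] = min(length, center + extent / 2)
            state.n_clones += 1

    add_founders(config.founder_rate * area * rate_multiplier)
    cycles = int(config.cycles_per_group[age_group])
    for _ in range(cycles):
        if p_exp > 0.0:
            rev_idx = state.revertant_indices()  # snapshot: synchronous update
            sources: dict[int, list[int]] = {}
            for r in rev_idx:
                for nb in tess.neighbors[r]:
                    if state.clone_id[nb] < 0:
                        sources.setdefault(nb, []).append(int(r))
            for fiber in sorted(sources):
                srcs = sources[fiber]
                if rng.random() >= 1.0 - (1.0 - p_exp) ** len(srcs):
                    continue
                src = srcs[int(rng.integers(len(srcs)))]
                lo = state.z_lo[src] + rng.uniform(-jitter, jitter)
                hi = state.z_hi[src] + rng.uniform(-jitter, jitter)
                if hi - lo < jitter:  # keep a minimal positive segment
                    mid = (lo + hi) / 2
                    lo, hi = mid - jitter / 2, mid + jitter / 2
                state.clone_id[fiber] = state.clone_id[src]
                state.z_lo[fiber] = max(0.0, lo)
                state.z_hi[fiber] = min(length, hi)
        add_founders(config.denovo_rate * area * rate_multiplier)
    return MuscleSim(tessellation=tess, state=state, config=config)


def _components(visible: Sequence[int], neighbors: Sequence[Sequence[int]]) -> list[list[int]]:
    """Union-find over the visible revertant fibers (simulator ground truth)."""
    parent = {v: v for v in visible}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    vis = set(visible)
    for v in visible:
        for nb in neighbors[v]:
            if nb in vis:
                ra, rb = find(v), find(nb)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for v in visible:
        comps.setdefault(find(v), []).append(v)
    return list(comps.values())


@dataclass(frozen=True)
class SectionSample:
    """Realized sections of one muscle plus the generator's ground truth."""

    sections: tuple[SectionGraph, ...]
    ground_truth: pd.DataFrame  # per-section cluster-size histogram


def sample_sections(
    sim: MuscleSim,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    section_prefix: str = "s",
) -> SectionSample:
    """Cut 10-12 transverse sections ~120 um apart through a muscle.

    A fiber is revertant in a section iff its positive segment overlaps
    the slice's z-interval.  The ground-truth frame carries the
    generator's own per-section cluster-size histogram, computed with an
    internal union-find independent of the quantification pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    config = sim.config
    tess = sim.tessellation
    state = sim.state
    s_lo, s_hi = config.sections_range
    n_sections = int(rng.integers(s_lo, s_hi + 1))
    span = (n_sections - 1) * config.section_spacing_um + config.section_thickness_um
    if span > config.muscle_length_um:
        raise ValidationError(
            f"{n_sections} sections spanning {span} um do not fit in a "
            f"{config.muscle_length_um} um muscle"
        )
    z0 = rng.uniform(0.0, config.muscle_length_um - span)
    base_records = tuple(
        FiberRecord(
            fiber_id=i + 1,
            centroid_xy=(float(tess.centroids[i, 0]), float(tess.centroids[i, 1])),
            csa=float(tess.csa[i]),
            revertant=False,
            stain_fraction=0.0,
        )
        for i in range(tess.n_fibers)
    )
    area = tess.area_mm2
    rev_idx = state.revertant_indices()
    sections: list[SectionGraph] = []
    gt_rows: list[dict] = []
    for s in range(n_sections):
        z = z0 + s * config.section_spacing_um
        z_top = z + config.section_thickness_um
        visible = [
            int(i) for i in rev_idx if state.z_lo[i] <= z_top and state.z_hi[i] >= z
        ]
        records = list(base_records)
        for i in visible:
            records[i] = replace(base_records[i], revertant=True, stain_fraction=1.0)
        section_id = f"{section_prefix}{s:02d}"
        sections.append(
            SectionGraph(
                section_id=section_id,
                fibers=tuple(records),
                edges=tess.edges,
                section_area_mm2=area,
                z_position=z,
            )
        )
        sizes = [len(c) for c in _components(visible, tess.neighbors)]
        counts = {f"n_{cls}": 0 for cls in SIZE_CLASSES}
        for size in sizes:
            counts[f"n_{classify_cluster_size(size)}"] += 1
        gt_rows.append(
            {
                "section_id": section_id,
                "n_rf": len(visible),
                "max_cluster_size": max(sizes, default=0),
                **counts,
            }
        )
    return SectionSample(sections=tuple(sections), ground_truth=pd.DataFrame(gt_rows))


def default_design(
    n_mice: int = 10,
    groups: Sequence[int] = AGE_GROUPS,
    muscles: Sequence[str] = MUSCLES,
) -> pd.DataFrame:
    """Crossed cohort design: every muscle of every mouse in every group."""
    rows = [
        {"mouse_id": f"g{g}m{m:02d}", "age_group": g, "muscle": muscle}
        for g in groups
        for m in range(1, n_mice + 1)
        for muscle in muscles
    ]
    return pd.DataFrame(rows)


def _mouse_multiplier(rng: np.random.Generator, sd: float) -> float:
    # Log-normal with unit mean.
    return float(np.exp(rng.normal(0.0, sd) - sd**2 / 2)) if sd > 0 else 1.0


def iter_cohort(
    config: Optional[SimConfig] = None,
    *,
    design: Optional[pd.DataFrame] = None,
    n_mice: int = 10,
    groups: Sequence[int] = AGE_GROUPS,
    muscles: Sequence[str] = MUSCLES,
    master_seed: int = 0,
    profiles: Mapping[str, MuscleProfile] = MUSCLE_PROFILES,
) -> Iterator[tuple[StudyKey, SectionSample]]:
    """Yield one :class:`SectionSample` per (mouse, muscle), deterministically.

    Seeds are content-addressed from ``(master_seed, group, mouse, muscle)``
    so results do not depend on iteration order.  A log-normal per-mouse
    multiplier (shared across that mouse's muscles) plus a smaller
    per-muscle jitter scale the reversion rates, producing the strong
    inter-individual variability the analysis expects.
    """
    if config is None:
        config = SimConfig()
    if design is None:
        design = default_design(n_mice, groups, muscles)
    required = {"mouse_id", "age_group", "muscle"}
    if not required <= set(design.columns):
        raise ValidationError(f"design needs columns {sorted(required)}")
    per_mouse = design[["mouse_id", "age_group"]].drop_duplicates()
    dup = per_mouse["mouse_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate mouse ids across groups: {sorted(per_mouse['mouse_id'][dup])}"
        )
    mouse_order = {m: i for i, m in enumerate(per_mouse["mouse_id"])}
    muscle_order = {m: i for i, m in enumerate(MUSCLES)}
    for row in design.itertuples(index=False):
        key = StudyKey(mouse_id=row.mouse_id, age_group=int(row.age_group), muscle=row.muscle)
        profile = profiles.get(key.muscle, MuscleProfile(1.0, 1.0))
        cfg = replace(
            config,
            heart_mode=profile.heart,
            founder_rate=config.founder_rate * profile.founder_scale,
            denovo_rate=config.denovo_rate * profile.denovo_scale,
        )
        mouse_rng = np.random.default_rng(
            np.random.SeedSequence((master_seed, 1, mouse_order[key.mouse_id]))
        )
        mult_mouse = _mouse_multiplier(mouse_rng, config.mouse_sd)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (master_seed, 2, mouse_order[key.mouse_id], muscle_order[key.muscle])
            )
        )
        mult = mult_mouse * _mouse_multiplier(rng, config.muscle_sd)
        tess = make_tessellation(
            cfg.n_fibers, rng=rng, mean_csa_um2=cfg.mean_csa_um2, csa_sigma=cfg.csa_sigma
        )
        sim = simulate_reversion(tess, cfg, key.age_group, rng=rng, rate_multiplier=mult)
        prefix = f"{key.mouse_id}_{key.muscle}_s"
        yield key, sample_sections(sim, rng=rng, section_prefix=prefix)


@dataclass(frozen=True)
class CohortTables:
    """Pipeline-ready cohort: fiber, edge, design and ground-truth tables."""

    fibers: pd.DataFrame
    edges: pd.DataFrame
    design: pd.DataFrame
    ground_truth: pd.DataFrame


def generate_cohort(
    config: Optional[SimConfig] = None,
    *,
    design: Optional[pd.DataFrame] = None,
    n_mice: int = 10,
    groups: Sequence[int] = AGE_GROUPS,
    muscles: Sequence[str] = MUSCLES,
    master_seed: int = 0,
    profiles: Mapping[str, MuscleProfile] = MUSCLE_PROFILES,
) -> CohortTables:
    """Materialize a full synthetic cohort as the CSV-ready tables the
    quantification CLI consumes.  Deterministic given ``master_seed``."""
    fiber_rows: list[dict] = []
    edge_rows: list[dict] = []
    design_rows: list[dict] = []
    gt_frames: list[pd.DataFrame] = []
    for key, sample in iter_cohort(
        config,
        design=design,
        n_mice=n_mice,
        groups=groups,
        muscles=muscles,
        master_seed=master_seed,
        profiles=profiles,
    ):
        for graph in sample.sections:
            for f in graph.fibers:
                fiber_rows.append(
                    {
                        "section_id": graph.section_id,
                        "fiber_id": f.fiber_id,
                        "x_um": round(f.centroid_xy[0], 3),
                        "y_um": round(f.centroid_xy[1], 3),
                        "csa_um2": round(f.csa, 3),
                        "stain_fraction": f.stain_fraction,
                        "revertant": int(f.revertant),
                    }
                )
            for a, b in graph.edges:
                edge_rows.append({"section_id": graph.section_id, "fiber_a": a, "fiber_b": b})
            design_rows.append(
                {
                    "mouse_id": key.mouse_id,
                    "age_group": key.age_group,
                    "muscle": key.muscle,
                    "section_id": graph.section_id,
                    "section_area_mm2": round(graph.section_area_mm2, 6),
                    "z_position_um": round(graph.z_position, 3),
                }
            )
        gt = sample.ground_truth.copy()
        gt.insert(0, "muscle", key.muscle)
        gt.insert(0, "age_group", key.age_group)
        gt.insert(0, "mouse_id", key.mouse_id)
        gt_frames.append(gt)
    return CohortTables(
        fibers=pd.DataFrame(fiber_rows),
        edges=pd.DataFrame(edge_rows),
        design=pd.DataFrame(design_rows),
        ground_truth=pd.concat(gt_frames, ignore_index=True)
        if gt_frames
        else pd.DataFrame(),
    )


def config_to_dict(config: SimConfig) -> dict:
    """JSON-ready representation of a :class:`SimConfig`."""
    d = dataclasses.asdict(config)
    d["cycles_per_group"] = {str(k): v for k, v in config.cycles_per_group.items()}
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    kwargs = dict(d)
    if "cycles_per_group" in kwargs:
        kwargs["cycles_per_group"] = {int(k): int(v) for k, v in kwargs["cycles_per_group"].items()}
    for key in ("extent_range_um", "sections_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)
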