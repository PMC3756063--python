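"""Domain types, positivity calling, and fiber adjacency-graph construction.

A *section* is one transverse slice of a muscle.  Fibers in a section are
represented as :class:`FiberRecord` objects; the physical contact relation
between fibers is an undirected graph held in :class:`SectionGraph`.
Graphs can be built from an explicit edge list or from a 2D integer label
map (:func:`graph_from_labelmap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

#: Canonical muscle codes: tibialis anterior, extensor digitorum longus,
#: soleus, gastrocnemius, plantaris, quadriceps, triceps, pectoralis,
#: diaphragm, intercostal, heart.
MUSCLES: tuple[str, ...] = ("TA", "EDL", "SOL", "GC", "PL", "Q", "TRIC", "PT", "D", "IC", "H")

#: Muscles other than the heart.
SKELETAL_MUSCLES: tuple[str, ...] = tuple(m for m in MUSCLES if m != "H")

#: The seven limb (locomotor) muscles.
LIMB_MUSCLES: tuple[str, ...] = ("TA", "EDL", "SOL", "GC", "PL", "Q", "TRIC")

AGE_GROUPS: tuple[int, ...] = (1, 2, 3, 4)

#: Default leniency on the full-circumference positivity rule; a rasterized
#: membrane rarely yields a stain fraction of exactly 1.0.
DEFAULT_TOLERANCE: float = 0.01


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def call_revertant(stain_fraction: float, tolerance: float = DEFAULT_TOLERANCE) -> bool:
    """Decide whether a fiber counts as revertant.

    A fiber is revertant only when its whole membrane circumference is
    dystrophin-positive, i.e. ``stain_fraction >= 1 - tolerance``.

    Parameters
    ----------
    stain_fraction
        Fraction of the membrane circumference that stains positive, in [0, 1].
    tolerance
        Allowed shortfall from a complete circumference, in [0, 0.05].
    """
    if not np.isfinite(stain_fraction) or not (0.0 <= stain_fraction <= 1.0):
        raise ValidationError(f"stain_fraction must be in [0, 1], got {stain_fraction!r}")
    if not (0.0 <= tolerance <= 0.05):
        raise ValidationError(f"tolerance must be in [0, 0.05], got {tolerance!r}")
    return bool(stain_fraction >= 1.0 - tolerance)


@dataclass(frozen=True)
class FiberRecord:
    """One muscle fiber in one section.

    Attributes
    ----------
    fiber_id
        Integer label, unique within the section, >= 1.
    centroid_xy
        Fiber centroid in micrometers, ``(x, y)``.
    csa
        Cross-sectional area in square micrometers, > 0.
    revertant
        Whether the fiber is counted as dystrophin-positive.
    stain_fraction
        Optional fraction of the membrane circumference stained, in [0, 1].
    """

    fiber_id: int
    centroid_xy: tuple[float, float]
    csa: float
    revertant: bool
    stain_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.fiber_id) != self.fiber_id or self.fiber_id < 1:
            raise ValidationError(f"fiber_id must be an integer >= 1, got {self.fiber_id!r}")
        if not (self.csa > 0):
            raise ValidationError(f"csa must be > 0, got {self.csa!r}")
        if self.stain_fraction is not None and not (0.0 <= self.stain_fraction <= 1.0):
            raise ValidationError(
                f"stain_fraction must be in [0, 1], got {self.stain_fraction!r}"
            )

    @classmethod
    def from_stain(
        cls,
        fiber_id: int,
        centroid_xy: tuple[float, float],
        csa: float,
        stain_fraction: float,
        tolerance: float = DEFAULT_TOLERANCE,
    ) -> "FiberRecord":
        """Build a record whose revertant call follows the positivity rule."""
        return cls(
            fiber_id=fiber_id,
            centroid_xy=centroid_xy,
            csa=csa,
            revertant=call_revertant(stain_fraction, tolerance),
            stain_fraction=stain_fraction,
        )


def _normalize_edge(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


@dataclass
class SectionGraph:
    """Fibers of one section plus their adjacency relation.

    Edges are unordered fiber-id pairs; the section area is in mm^2 and
    ``z_position`` locates the slice along the muscle axis in micrometers.
    """

    section_id: str
    fibers: tuple[FiberRecord, ...]
    edges: tuple[tuple[int, int], ...]
    section_area_mm2: float
    z_position: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.fibers, tuple):
            self.fibers = tuple(self.fibers)
        # skip re-normalizing an already-normalized (possibly shared) edge tuple
        if not (isinstance(self.edges, tuple) and (not self.edges or type(self.edges[0]) is tuple)):
            self.edges = tuple((int(a), int(b)) for a, b in self.edges)

    @property
    def fiber_map(self) -> dict[int, FiberRecord]:
        return {f.fiber_id: f for f in self.fibers}

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    def revertant_ids(self) -> frozenset[int]:
        return frozenset(f.fiber_id for f in self.fibers if f.revertant)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(f.fiber_id for f in self.fibers)
        g.add_edges_from(self.edges)
        return g

    def neighbors(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {f.fiber_id: set() for f in self.fibers}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def validate_section(graph: SectionGraph) -> list[str]:
    """Return a list of invariant violations; empty iff the graph is valid."""
    problems: list[str] = []
    seen_ids: set[int] = set()
    for f in graph.fibers:
        if f.fiber_id in seen_ids:
            problems.append(f"duplicate fiber_id {f.fiber_id}")
        seen_ids.add(f.fiber_id)
    seen_edges: set[tuple[int, int]] = set()
    for a, b in graph.edges:
        if a == b:
            problems.append(f"self-edge on fiber {a}")
            continue
        key = _normalize_edge(a, b)
        if key in seen_edges:
            problems.append(f"duplicate edge {key}")
        seen_edges.add(key)
        for endpoint in key:
            if endpoint not in seen_ids:
                problems.append(f"edge {key} references absent fiber {endpoint}")
    if not (graph.section_area_mm2 > 0):
        problems.append(f"section_area_mm2 must be > 0, got {graph.section_area_mm2!r}")
    return problems


@dataclass(frozen=True)
class StudyKey:
    """Identifies one muscle of one animal within the study design."""

    mouse_id: str
    age_group: int
    muscle: str

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")
        if self.muscle not in MUSCLES:
            raise ValidationError(f"muscle must be one of {MUSCLES}, got {self.muscle!r}")


def graph_from_labelmap(
    label_map: np.ndarray,
    pixel_size_um: float,
    connectivity: int = 4,
    *,
    min_shared_boundary: int = 1,
    stain_fraction: Optional[Mapping[int, float]] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    section_id: str = "section",
    z_position: float = 0.0,
    section_area_mm2: Optional[float] = None,
) -> SectionGraph:
    """Build a :class:`SectionGraph` from a 2D integer label map.

    Label 0 is background and never mediates adjacency.  Two labels are
    adjacent when they touch in at least ``min_shared_boundary`` pixel
    contacts under the chosen connectivity (4 = edge-sharing only, 8 adds
    diagonal corner contacts).

    Fiber areas are pixel counts scaled by ``pixel_size_um**2``; centroids
    are mean 0-based pixel indices scaled to micrometers (x = column,
    y = row).  Unless ``section_area_mm2`` is given, the section area is the
    tissue-mask area (all nonzero pixels), which excludes interstitium.

    ``stain_fraction`` optionally maps labels to membrane stain fractions;
    labels absent from the mapping are treated as fully negative.
    """
    lab = np.asarray(label_map)
    if lab.ndim != 2:
        raise ValidationError(f"label map must be 2D, got shape {lab.shape}")
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValidationError(f"label map must have an integer dtype, got {lab.dtype}")
    if lab.size and lab.min() < 0:
        raise ValidationError("label map must be non-negative (0 = background)")
    if not (pixel_size_um > 0):
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um!r}")
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity!r}")
    if min_shared_boundary < 1:
        raise ValidationError("min_shared_boundary must be >= 1")

    ys, xs = np.nonzero(lab)
    vals = lab[ys, xs]
    px_area = pixel_size_um**2

    fibers: list[FiberRecord] = []
    if vals.size:
        counts = np.bincount(vals)
        sx = np.bincount(vals, weights=xs, minlength=counts.size)
        sy = np.bincount(vals, weights=ys, minlength=counts.size)
        for label in np.nonzero(counts)[0]:
            n_px = int(counts[label])
            cx = sx[label] / n_px * pixel_size_um
            cy = sy[label] / n_px * pixel_size_um
            sf = float(stain_fraction.get(int(label), 0.0)) if stain_fraction is not None else 0.0
            fibers.append(
                FiberRecord(
                    fiber_id=int(label),
                    centroid_xy=(cx, cy),
                    csa=n_px * px_area,
                    revertant=call_revertant(sf, tolerance),
                    stain_fraction=sf if stain_fraction is not None else None,
                )
            )

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    contact_counts = _count_contacts(lab, offsets)
    edges = tuple(sorted(p for p, c in contact_counts.items() if c >= min_shared_boundary))

    area = vals.size * px_area / 1e6 if section_area_mm2 is None else float(section_area_mm2)
    return SectionGraph(
        section_id=section_id,
        fibers=tuple(fibers),
        edges=edges,
        section_area_mm2=area,
        z_position=z_position,
    )


def _count_contacts(
    lab: np.ndarray, offsets: Sequence[tuple[int, int]]
) -> dict[tuple[int, int], int]:
    """Count pixel contacts between distinct nonzero labels for each offset."""
    counts: dict[tuple[int, int], int] = {}
    h, w = lab.shape
    for dy, dx in offsets:
        ys = slice(0, h - dy)
        ys2 = slice(dy, h)
        if dx >= 0:
            xs, xs2 = slice(0, w - dx), slice(dx, w)
        else:
            xs, xs2 = slice(-dx, w), slice(0, w + dx)
        a = lab[ys, xs].ravel()
        b = lab[ys2, xs2].ravel()
        mask = (a > 0) & (b > 0) & (a != b)
        if not mask.any():
            continue
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        pairs, n = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (p, q), c in zip(pairs, n):
            key = (int(p), int(q))
            counts[key] = counts.get(key, 0) + int(c)
    return counts
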