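"""Per-section revertant-fiber statistics.

Clusters are connected components of the adjacency subgraph induced by
revertant fibers.  Cluster sizes fall into five classes::

    1       singleton
    2-4     small
    5-8     medium
    9-17    large
    >= 18   very_large

A singleton is *isolated* when every other revertant fiber in the section
is separated from it by at least ``min_separation`` intervening negative
fibers (graph distance >= min_separation + 1 on the full fiber graph).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import SectionGraph, StudyKey, ValidationError

SIZE_CLASSES: tuple[str, ...] = ("singleton", "small", "medium", "large", "very_large")

#: Default number of intervening negative fibers required for isolation.
DEFAULT_MIN_SEPARATION: int = 2

#: Traits emitted per section, in long-format order.
TRAIT_NAMES: tuple[str, ...] = (
    "n_rf",
    "rf_per_mm2",
    "pct_clustered",
    "n_isolated",
    "n_singleton",
    "n_small",
    "n_medium",
    "n_large",
    "n_very_large",
    "max_cluster_size",
)


def classify_cluster_size(size: int) -> str:
    """Map a cluster cardinality to its size class."""
    if size < 1:
        raise ValidationError(f"cluster size must be >= 1, got {size!r}")
    if size == 1:
        return "singleton"
    if size <= 4:
        return "small"
    if size <= 8:
        return "medium"
    if size <= 17:
        return "large"
    return "very_large"


@dataclass(frozen=True)
class ClusterSet:
    """Connected components of revertant fibers within one section."""

    clusters: tuple[frozenset[int], ...]
    size_classes: tuple[str, ...]
    isolated_ids: frozenset[int]

    @property
    def n_rf(self) -> int:
        return sum(len(c) for c in self.clusters)

    def singleton_ids(self) -> frozenset[int]:
        return frozenset(next(iter(c)) for c in self.clusters if len(c) == 1)


def count_isolated(graph: SectionGraph, min_separation: int = DEFAULT_MIN_SEPARATION) -> frozenset[int]:
    """Return ids of isolated revertant fibers.

    A revertant fiber is isolated iff the shortest path on the full fiber
    graph from it to every other revertant fiber is at least
    ``min_separation + 1`` edges long (equivalently: at least
    ``min_separation`` negative fibers lie on every shortest path to the
    nearest revertant).  A section with a single revertant fiber yields
    that fiber as isolated.
    """
    if min_separation < 1:
        raise ValidationError(f"min_separation must be >= 1, got {min_separation!r}")
    revertant = graph.revertant_ids()
    if not revertant:
        return frozenset()
    adj = graph.neighbors()
    isolated: set[int] = set()
    for src in revertant:
        # BFS limited to depth min_separation: any other revertant reached
        # within that radius disqualifies the source.
        seen = {src}
        frontier = deque([(src, 0)])
        near_rf = False
        while frontier:
            node, dist = frontier.popleft()
            if dist == min_separation:
                continue
            for nxt in adj[node]:
                if nxt in seen:
                    continue
                seen.add(nxt)
                if nxt in revertant:
                    near_rf = True
                    frontier.clear()
                    break
                frontier.append((nxt, dist + 1))
        if not near_rf:
            isolated.add(src)
    return frozenset(isolated)


def find_clusters(graph: SectionGraph, min_separation: int = DEFAULT_MIN_SEPARATION) -> ClusterSet:
    """Group adjacent revertant fibers into clusters.

    Returns the connected components of the subgraph induced by revertant
    fibers, each labeled with its size class, together with the ids of
    isolated singletons.
    """
    revertant = graph.revertant_ids()
    if not revertant:
        return ClusterSet(clusters=(), size_classes=(), isolated_ids=frozenset())
    # Breadth-first search over the revertant-induced subgraph; adjacency is
    # rebuilt from the edge list so only revertant-revertant contacts count.
    adj: dict[int, list[int]] = {r: [] for r in revertant}
    for a, b in graph.edges:
        if a in adj and b in adj:
            adj[a].append(b)
            adj[b].append(a)
    components: list[frozenset[int]] = []
    unseen = set(revertant)
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = deque([start])
        while frontier:
            node = frontier.popleft()
            for nxt in adj[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    unseen.discard(nxt)
                    frontier.append(nxt)
        components.append(frozenset(comp))
    clusters = tuple(sorted(components, key=sorted))
    classes = tuple(classify_cluster_size(len(c)) for c in clusters)
    return ClusterSet(
        clusters=clusters,
        size_classes=classes,
        isolated_ids=count_isolated(graph, min_separation),
    )


@dataclass(frozen=True)
class SectionTraits:
    """All per-section summary statistics."""

    n_rf: int
    rf_per_mm2: float
    pct_clustered: float
    n_isolated: int
    cluster_size_counts: Mapping[str, int]
    max_cluster_size: int

    def as_dict(self) -> dict[str, float]:
        d = {
            "n_rf": float(self.n_rf),
            "rf_per_mm2": self.rf_per_mm2,
            "pct_clustered": self.pct_clustered,
            "n_isolated": float(self.n_isolated),
            "max_cluster_size": float(self.max_cluster_size),
        }
        for cls in SIZE_CLASSES:
            d[f"n_{cls}"] = float(self.cluster_size_counts.get(cls, 0))
        return d


def section_traits(
    graph: SectionGraph, min_separation: int = DEFAULT_MIN_SEPARATION
) -> SectionTraits:
    """Compute every :class:`SectionTraits` field for one section.

    ``pct_clustered`` is the percentage of revertant fibers lying in
    clusters of size >= 2, defined as 0 for sections with no revertant
    fiber.
    """
    if not (graph.section_area_mm2 > 0):
        raise ValidationError(
            f"section {graph.section_id!r}: section_area_mm2 must be > 0, "
            f"got {graph.section_area_mm2!r}"
        )
    cs = find_clusters(graph, min_separation)
    n_rf = cs.n_rf
    n_clustered_fibers = sum(len(c) for c in cs.clusters if len(c) >= 2)
    counts = {cls: 0 for cls in SIZE_CLASSES}
    for name in cs.size_classes:
        counts[name] += 1
    return SectionTraits(
        n_rf=n_rf,
        rf_per_mm2=n_rf / graph.section_area_mm2,
        pct_clustered=100.0 * n_clustered_fibers / n_rf if n_rf else 0.0,
        n_isolated=len(cs.isolated_ids),
        cluster_size_counts=counts,
        max_cluster_size=max((len(c) for c in cs.clusters), default=0),
    )


def traits_to_frame(
    records: Iterable[tuple[StudyKey, str, SectionTraits]],
    empty_section_policy: str = "zero",
) -> pd.DataFrame:
    """Flatten per-section traits into a long-format table.

    Columns: mouse_id, age_group, muscle, section_id, trait, value.
    With ``empty_section_policy='drop'`` the pct_clustered rows of
    zero-revertant sections are omitted instead of recorded as 0.
    """
    if empty_section_policy not in ("zero", "drop"):
        raise ValidationError(
            f"empty_section_policy must be 'zero' or 'drop', got {empty_section_policy!r}"
        )
    rows = []
    for key, section_id, traits in records:
        for trait, value in traits.as_dict().items():
            if (
                empty_section_policy == "drop"
                and trait == "pct_clustered"
                and traits.n_rf == 0
            ):
                continue
            rows.append(
                {
                    "mouse_id": key.mouse_id,
                    "age_group": key.age_group,
                    "muscle": key.muscle,
                    "section_id": section_id,
                    "trait": trait,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["mouse_id", "age_group", "muscle", "section_id", "trait", "value"])


@dataclass(frozen=True)
class AggregateTables:
    """Aggregations of a long-format trait table.

    per_mouse
        Mean trait value over the sections of each (mouse, muscle).
    per_group
        Mean, sd (ddof=1) and n over mice for each (muscle, age_group, trait).
    grand
        Per (muscle, trait): the unweighted mean of the four group means and
        the pooled mean over all per-mouse values.
    """

    per_mouse: pd.DataFrame
    per_group: pd.DataFrame
    grand: pd.DataFrame


def aggregate_traits(table: pd.DataFrame) -> AggregateTables:
    """Aggregate a long-format trait table mouse-, group- and study-wide.

    Sections average within each (mouse, muscle); group summaries average
    over mice.  Empty groups are simply absent from the output.
    """
    required = {"mouse_id", "age_group", "muscle", "trait", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"trait table is missing columns: {sorted(missing)}")
    per_mouse = (
        table.groupby(["muscle", "age_group", "mouse_id", "trait"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    per_group = (
        per_mouse.groupby(["muscle", "age_group", "trait"], as_index=False)["mean"]
        .agg(mean="mean", sd="std", n="count")
    )
    grand = (
        per_group.groupby(["muscle", "trait"], as_index=False)["mean"]
        .mean()
        .rename(columns={"mean": "mean_of_group_means"})
    )
    pooled = (
        per_mouse.groupby(["muscle", "trait"], as_index=False)["mean"]
        .mean()
        .rename(columns={"mean": "pooled_mean"})
    )
    grand = grand.merge(pooled, on=["muscle", "trait"])
    return AggregateTables(per_mouse=per_mouse, per_group=per_group, grand=grand)


def grand_mean_of_group_means(group_means: Sequence[float]) -> float:
    """Unweighted mean of per-group means (study-wide density summary)."""
    if len(group_means) == 0:
        raise ValidationError("need at least one group mean")
    return float(sum(group_means)) / len(group_means)
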