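"""Label fusion across candidate segmentations.

Several stages of the pipeline produce a labeling of the same image — the
semantic segmenter's probability map, the detector's instance masks, the
watershed labeling.  This module reconciles them two ways:

* **pixel level** — :func:`fuse_probmaps` takes a convex combination of
  class-probability maps;
* **instance level** — :func:`vote_instances` chains corresponding instances
  across sources by mask IoU and keeps those supported by enough sources,
  with the consensus mask built from per-pixel coverage counts.

:func:`resolve_overlaps` turns a set of possibly-overlapping candidate masks
into a partition: uncontested pixels keep their candidate, contested pixels
go to the highest-scoring claimant, ties to the claimant with the nearest
centroid, and any remaining tie to the lower instance id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imgio import InstanceLabelMap

__all__ = [
    "FusionConfig",
    "fuse_probmaps",
    "mask_iou",
    "match_instances",
    "vote_instances",
    "resolve_overlaps",
]


@dataclass(frozen=True)
class FusionConfig:
    source_weights: tuple[float, ...] | None = None  # None -> equal weights
    vote_min: int | None = None  # None -> strict majority of sources
    match_iou: float = 0.5

    def __post_init__(self) -> None:
        if self.source_weights is not None:
            w = np.asarray(self.source_weights, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("need non-negative weights with a positive sum")
        if self.vote_min is not None and self.vote_min < 1:
            raise ValueError("vote_min must be >= 1")
        if not (0.0 <= self.match_iou <= 1.0):
            raise ValueError("match_iou must lie in [0, 1]")


def fuse_probmaps(maps: Sequence[np.ndarray], weights: Sequence[float] | None = None) -> np.ndarray:
    """Per-pixel convex combination of probability maps (weights normalised
    to sum to 1)."""
    if len(maps) == 0:
        raise ValueError("need at least one probability map")
    shape = np.asarray(maps[0]).shape
    if any(np.asarray(m).shape != shape for m in maps):
        raise ValueError("probability maps must share a shape")
    if weights is None:
        weights = [1.0] * len(maps)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (len(maps),):
        raise ValueError("one weight per map required")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("need non-negative weights with a positive sum")
    w = w / w.sum()
    out = np.zeros(shape, dtype=np.float64)
    for wi, m in zip(w, maps):
        out += wi * np.asarray(m, dtype=np.float64)
    return out


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (0 when both empty)."""
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def match_instances(
    map_a: InstanceLabelMap,
    map_b: InstanceLabelMap,
    match_iou: float = 0.5,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one instance matching by descending mask IoU.

    Pairs with IoU below ``match_iou`` are rejected; IoU ties break by
    (lower id in A, lower id in B).  Returns
    ``(matches, unmatched_a, unmatched_b)``.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("label maps must share a shape")
    ids_a = [int(i) for i in map_a.ids()]
    ids_b = [int(i) for i in map_b.ids()]
    cands: list[tuple[float, int, int]] = []
    for ia in ids_a:
        ma = map_a.mask(ia)
        for ib in ids_b:
            v = mask_iou(ma, map_b.mask(ib))
            if v >= match_iou and v > 0:
                cands.append((v, ia, ib))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _v, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        matches.append((ia, ib))
        used_a.add(ia)
        used_b.add(ib)
    unmatched_a = [i for i in ids_a if i not in used_a]
    unmatched_b = [i for i in ids_b if i not in used_b]
    return matches, unmatched_a, unmatched_b


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def vote_instances(
    maps: Sequence[InstanceLabelMap], config: FusionConfig | None = None
) -> InstanceLabelMap:
    """Instance-level voting across sources.

    Corresponding instances are chained across all source pairs via
    :func:`match_instances` (union-find on (source, id) nodes).  Groups seen
    in at least ``vote_min`` distinct sources survive; a surviving group's
    consensus mask is the set of pixels covered by at least ``vote_min`` of
    its member masks.  Consensus instances are renumbered 1..n by descending
    consensus area (ties by the group's smallest (source, id) node).
    """
    if len(maps) == 0:
        raise ValueError("need at least one label map")
    config = config or FusionConfig()
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("label maps must share a shape")
    vote_min = config.vote_min if config.vote_min is not None else len(maps) // 2 + 1

    uf = _UnionFind()
    for s, m in enumerate(maps):
        for i in m.ids():
            uf.find((s, int(i)))
    for sa in range(len(maps)):
        for sb in range(sa + 1, len(maps)):
            pairs, _, _ = match_instances(maps[sa], maps[sb], config.match_iou)
            for ia, ib in pairs:
                uf.union((sa, ia), (sb, ib))

    groups: dict = {}
    for node in list(uf.parent):
        groups.setdefault(uf.find(node), []).append(node)

    consensus: list[tuple[int, tuple, np.ndarray]] = []
    for root, nodes in groups.items():
        sources = {s for s, _ in nodes}
        if len(sources) < vote_min:
            continue
        coverage = np.zeros(shape, dtype=np.int64)
        for s, i in nodes:
            coverage += maps[s].mask(i)
        mask = coverage >= vote_min
        area = int(mask.sum())
        if area > 0:
            consensus.append((area, min(nodes), mask))
    consensus.sort(key=lambda t: (-t[0], t[1]))
    out = np.zeros(shape, dtype=np.int64)
    for new_id, (_area, _node, mask) in enumerate(consensus, start=1):
        out[mask & (out == 0)] = new_id
    return InstanceLabelMap(out)


def resolve_overlaps(
    candidates: Sequence[tuple[int, np.ndarray, float]],
    fused_probs: np.ndarray | None = None,
) -> InstanceLabelMap:
    """Partition pixels among possibly-overlapping scored candidate masks.

    A pixel claimed by one candidate keeps it; a contested pixel goes to the
    highest-scoring claimant, score ties to the claimant with the nearest
    mask centroid, and any remaining tie to the lower instance id.
    ``fused_probs`` is accepted for interface compatibility with the fusion
    stage and is not consulted by the assignment rule.
    """
    if not candidates:
        return InstanceLabelMap(np.zeros((1, 1), dtype=np.int64))
    shape = np.asarray(candidates[0][1]).shape
    for _i, m, s in candidates:
        if np.asarray(m).shape != shape:
            raise ValueError("candidate masks must share a shape")
        if not np.isfinite(s):
            raise ValueError("candidate scores must be finite")

    out = np.zeros(shape, dtype=np.int64)
    claims = np.zeros(shape, dtype=np.int64)
    for _i, m, _s in candidates:
        claims += np.asarray(m, dtype=bool)
    # uncontested pixels
    for inst_id, m, _s in candidates:
        sole = np.asarray(m, dtype=bool) & (claims == 1)
        out[sole] = inst_id
    contested = np.argwhere(claims > 1)
    if contested.size:
        centroids = []
        for _i, m, _s in candidates:
            rr, cc = np.nonzero(m)
            centroids.append((rr.mean(), cc.mean()) if rr.size else (np.inf, np.inf))
        for r, c in contested:
            best_key = None
            best_id = 0
            for (inst_id, m, score), (cr, cc_) in zip(candidates, centroids):
                if not m[r, c]:
                    continue
                d2 = (r - cr) ** 2 + (c - cc_) ** 2
                key = (-score, d2, inst_id)
                if best_key is None or key < best_key:
                    best_key, best_id = key, inst_id
            out[r, c] = best_id
    return InstanceLabelMap(out)
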