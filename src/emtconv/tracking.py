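"""Frame-to-frame linking, lineage reconstruction and migration.

Linking is greedy mutual-nearest-neighbour on centroid distance within a
gate, mirroring the closest-cell logic of manual live-cell tracing; a
cell that vanishes while two unmatched cells appear nearby is recorded
as a division. Migration per hour is the Euclidean distance between a
cell's centroids on hour n and hour n+1; a cell with no identity link
("untraceable") gets the distance to the globally closest cell on hour
n+1, flagged as imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .morphology import CellObservation

DEATH = "death"
UNTRACEABLE = "untraceable"


@dataclass
class FrameLink:
    """Assignment between two consecutive frames."""

    frame: int                                  # index of the earlier frame
    links: list[tuple[int, int]] = field(default_factory=list)
    divisions: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    disappearances: list[tuple[int, str]] = field(default_factory=list)
    appearances: list[int] = field(default_factory=list)

    def validate(self) -> None:
        targets = [b for _, b in self.links]
        for _, (ca, cb) in self.divisions:
            targets += [ca, cb]
        if len(targets) != len(set(targets)):
            raise ValueError(f"frame {self.frame}: a target id is linked twice")


def _centroids(obs: Sequence[CellObservation]) -> np.ndarray:
    if not obs:
        return np.empty((0, 2))
    return np.array([o.centroid for o in obs], dtype=float)


def link_frames(
    obs_n: Sequence[CellObservation],
    obs_n1: Sequence[CellObservation],
    gate: float = 50.0,
    division_radius: Optional[float] = None,
) -> FrameLink:
    """Link cells of frame n to frame n+1.

    Identity links are mutual nearest neighbours within ``gate`` pixels,
    assigned greedily in order of increasing distance (ties broken by
    lower source then target label). Afterwards an unmatched source cell
    with at least two unmatched cells within ``division_radius`` (default
    2× the mean major-axis length of frame-n cells) is recorded as a
    division to the two nearest. A remaining unmatched target within the
    division radius of a source whose identity link is equally short is
    rescued as that source's second daughter (daughters are adjacent, so
    one of them often captures the identity link). Remaining unmatched
    sources disappear and unmatched targets appear. Deterministic in the
    input sets.
    """
    if gate < 0:
        raise ValueError("gate must be non-negative")
    obs_n = sorted(obs_n, key=lambda o: o.label)
    obs_n1 = sorted(obs_n1, key=lambda o: o.label)
    frame = obs_n[0].frame if obs_n else 0
    out = FrameLink(frame=frame)
    if not obs_n or not obs_n1:
        out.disappearances = [(o.label, DEATH) for o in obs_n]
        out.appearances = [o.label for o in obs_n1]
        return out

    A = _centroids(obs_n)
    B = _centroids(obs_n1)
    D = np.hypot(A[:, None, 0] - B[None, :, 0], A[:, None, 1] - B[None, :, 1])

    # candidate mutual nearest neighbours within the gate
    nn_of_a = D.argmin(axis=1)
    nn_of_b = D.argmin(axis=0)
    cands = [
        (D[i, j], obs_n[i].label, obs_n1[j].label, i, j)
        for i, j in enumerate(nn_of_a)
        if nn_of_b[j] == i and D[i, j] <= gate
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    for d, la, lb, i, j in cands:
        if i in used_a or j in used_b:
            continue
        out.links.append((la, lb))
        used_a.add(i)
        used_b.add(j)

    # iterate: after removing matched cells, new mutual pairs may emerge
    changed = True
    while changed:
        changed = False
        free_a = [i for i in range(len(obs_n)) if i not in used_a]
        free_b = [j for j in range(len(obs_n1)) if j not in used_b]
        if not free_a or not free_b:
            break
        sub = D[np.ix_(free_a, free_b)]
        nn_a = sub.argmin(axis=1)
        nn_b = sub.argmin(axis=0)
        pairs = [
            (sub[x, y], obs_n[free_a[x]].label, obs_n1[free_b[y]].label,
             free_a[x], free_b[y])
            for x, y in enumerate(nn_a)
            if nn_b[y] == x and sub[x, y] <= gate
        ]
        pairs.sort()
        for d, la, lb, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            out.links.append((la, lb))
            used_a.add(i)
            used_b.add(j)
            changed = True

    if division_radius is None:
        division_radius = 2.0 * float(np.mean([o.length for o in obs_n]))

    for i in range(len(obs_n)):
        if i in used_a:
            continue
        free_b = [j for j in range(len(obs_n1)) if j not in used_b]
        near = sorted(
            ((D[i, j], obs_n1[j].label, j) for j in free_b if D[i, j] <= division_radius)
        )
        if len(near) >= 2:
            (da, la, ja), (db, lb, jb) = near[0], near[1]
            ca, cb = sorted((la, lb))
            out.divisions.append((obs_n[i].label, (ca, cb)))
            used_a.add(i)
            used_b.add(ja)
            used_b.add(jb)

    # second-chance linking just beyond the gate: a cell whose step
    # exceeded the gate is re-linked to its mutual nearest unmatched
    # neighbour instead of being split into a disappearance plus an
    # appearance
    ext = min(2.0 * gate, division_radius) if gate > 0 else division_radius
    changed = True
    while changed:
        changed = False
        free_a = [i for i in range(len(obs_n)) if i not in used_a]
        free_b = [j for j in range(len(obs_n1)) if j not in used_b]
        if not free_a or not free_b:
            break
        sub = D[np.ix_(free_a, free_b)]
        nn_a = sub.argmin(axis=1)
        nn_b = sub.argmin(axis=0)
        pairs = sorted(
            (sub[x, y], obs_n[free_a[x]].label, obs_n1[free_b[y]].label,
             free_a[x], free_b[y])
            for x, y in enumerate(nn_a)
            if nn_b[y] == x and sub[x, y] <= ext
        )
        for d, la, lb, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            out.links.append((la, lb))
            used_a.add(i)
            used_b.add(j)
            changed = True

    # division rescue: a remaining unmatched target near a linked source
    # is the second daughter of a division whose first daughter captured
    # the identity link. The true parent sits near the midpoint of its
    # daughters, so the best candidate is the source whose two distances
    # are most nearly equal.
    link_of_i = {
        next(i for i, o in enumerate(obs_n) if o.label == la): (la, lb)
        for la, lb in out.links
    }
    idx_of_label_b = {o.label: j for j, o in enumerate(obs_n1)}
    for j in sorted(
        (j for j in range(len(obs_n1)) if j not in used_b),
        key=lambda j: obs_n1[j].label,
    ):
        candidates = []
        for i in link_of_i:
            d1 = D[i, j]
            if d1 > division_radius:
                continue
            la, lb = link_of_i[i]
            d2 = D[i, idx_of_label_b[lb]]
            if d2 > division_radius:
                continue
            candidates.append((abs(d1 - d2), obs_n[i].label, i))
        if candidates:
            _, la, i = min(candidates)
            la_, lb = link_of_i[i]
            out.links.remove((la, lb))
            ca, cb = sorted((lb, obs_n1[j].label))
            out.divisions.append((la, (ca, cb)))
            used_b.add(j)
            del link_of_i[i]

    for i in range(len(obs_n)):
        if i not in used_a:
            out.disappearances.append((obs_n[i].label, DEATH))
    for j in range(len(obs_n1)):
        if j not in used_b:
            out.appearances.append(obs_n1[j].label)

    out.links.sort()
    out.divisions.sort()
    out.validate()
    return out


def brute_force_link(
    obs_n: Sequence[CellObservation],
    obs_n1: Sequence[CellObservation],
    gate: float = 50.0,
) -> list[tuple[int, int]]:
    """Globally optimal (minimum total distance) one-to-one assignment
    within the gate, by the Hungarian algorithm. Test oracle for small
    frames; not used in the pipeline."""
    from scipy.optimize import linear_sum_assignment

    if not obs_n or not obs_n1:
        return []
    A = _centroids(sorted(obs_n, key=lambda o: o.label))
    B = _centroids(sorted(obs_n1, key=lambda o: o.label))
    la = [o.label for o in sorted(obs_n, key=lambda o: o.label)]
    lb = [o.label for o in sorted(obs_n1, key=lambda o: o.label)]
    D = np.hypot(A[:, None, 0] - B[None, :, 0], A[:, None, 1] - B[None, :, 1])
    big = 1e9
    C = np.where(D <= gate, D, big)
    ri, ci = linear_sum_assignment(C)
    return sorted((la[i], lb[j]) for i, j in zip(ri, ci) if C[i, j] < big)


@dataclass
class MigrationRecord:
    cell: int
    frame: int
    distance: float
    imputed: bool


def migration_distance(
    obs_n: Sequence[CellObservation],
    obs_n1: Sequence[CellObservation],
    link: FrameLink,
    cell_label: int,
) -> Optional[MigrationRecord]:
    """Distance the cell moved between hour n and hour n+1.

    Returns None when frame n+1 has no observations at all (last frame:
    explicitly absent, not zero). If the cell has no identity link, the
    distance to the globally closest cell on hour n+1 is used and
    flagged as imputed.
    """
    by_label_n = {o.label: o for o in obs_n}
    by_label_n1 = {o.label: o for o in obs_n1}
    if cell_label not in by_label_n:
        raise KeyError(f"cell {cell_label} not present in frame n")
    if not obs_n1:
        return None
    src = np.array(by_label_n[cell_label].centroid)
    linked = dict(link.links).get(cell_label)
    if linked is not None:
        dst = np.array(by_label_n1[linked].centroid)
        return MigrationRecord(cell_label, link.frame, float(np.hypot(*(dst - src))), False)
    dists = [float(np.hypot(*(np.array(o.centroid) - src))) for o in obs_n1]
    return MigrationRecord(cell_label, link.frame, min(dists), True)


@dataclass
class TrackNode:
    """One track: a cell identity over a span of frames."""

    node_id: int
    parent: Optional[int]
    first_frame: int
    last_frame: int
    labels: list[tuple[int, int]]            # (frame, per-frame label)
    classes: list[Optional[str]] = field(default_factory=list)
    children: list[int] = field(default_factory=list)
    end_reason: Optional[str] = None         # death / untraceable / division / end


@dataclass
class LineageForest:
    """Per-cell tracks with parent/daughter links."""

    nodes: dict[int, TrackNode]

    @property
    def roots(self) -> list[int]:
        return sorted(n.node_id for n in self.nodes.values() if n.parent is None)

    def leaves_at(self, frame: int) -> list[int]:
        return sorted(
            n.node_id for n in self.nodes.values()
            if n.first_frame <= frame <= n.last_frame
        )

    def label_at(self, node_id: int, frame: int) -> int:
        node = self.nodes[node_id]
        for f, lab in node.labels:
            if f == frame:
                return lab
        raise KeyError(f"node {node_id} has no observation at frame {frame}")

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path


def build_lineages(
    frame_links: Sequence[FrameLink],
    observations: Sequence[Sequence[CellObservation]],
) -> LineageForest:
    """Assemble consecutive frame links into a lineage forest.

    Identity links extend tracks; divisions close the parent track and
    open two child tracks; appearances open root tracks. Every
    observation belongs to exactly one node. Inconsistent links (an id
    linked twice) raise with the offending frame named.
    """
    nodes: dict[int, TrackNode] = {}
    next_node = 1
    active: dict[int, int] = {}    # current frame label -> node id

    def open_node(parent: Optional[int], frame: int, label: int,
                  cls: Optional[str]) -> int:
        nonlocal next_node
        nid = next_node
        next_node += 1
        nodes[nid] = TrackNode(nid, parent, frame, frame, [(frame, label)], [cls])
        if parent is not None:
            nodes[parent].children.append(nid)
        return nid

    if observations:
        for o in observations[0]:
            active[o.label] = open_node(None, 0, o.label, o.assigned_class)

    for t, link in enumerate(frame_links):
        link.validate()
        cls_n1 = {o.label: o.assigned_class for o in observations[t + 1]}
        new_active: dict[int, int] = {}
        for la, lb in link.links:
            if la not in active:
                raise ValueError(f"frame {t}: link source {la} not in an active track")
            nid = active[la]
            node = nodes[nid]
            node.last_frame = t + 1
            node.labels.append((t + 1, lb))
            node.classes.append(cls_n1.get(lb))
            new_active[lb] = nid
        for la, (ca, cb) in link.divisions:
            if la not in active:
                raise ValueError(f"frame {t}: division parent {la} not active")
            pid = active[la]
            nodes[pid].end_reason = "division"
            for child in (ca, cb):
                new_active[child] = open_node(pid, t + 1, child, cls_n1.get(child))
        for la, reason in link.disappearances:
            if la in active:
                nodes[active[la]].end_reason = reason
        for lb in link.appearances:
            new_active[lb] = open_node(None, t + 1, lb, cls_n1.get(lb))
        active = new_active

    for nid in active.values():
        if nodes[nid].end_reason is None:
            nodes[nid].end_reason = "end"
    return LineageForest(nodes)


def track_movie(
    observations: Sequence[Sequence[CellObservation]],
    gate: float = 50.0,
    division_radius: Optional[float] = None,
) -> tuple[list[FrameLink], LineageForest]:
    """Convenience: link all consecutive frames and build the forest."""
    links = [
        link_frames(observations[t], observations[t + 1], gate, division_radius)
        for t in range(len(observations) - 1)
    ]
    return links, build_lineages(links, observations)
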