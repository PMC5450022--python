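"""Population and lineage kinetics.

Covers the growth, composition and conversion readouts of a live-cell
conversion experiment: doubling time from the log₂ count increase over
a 24-h interval, per-day class time courses, detection of conversion
events on classified lineage forests with a high-/low-mitosis split,
the contribution of each mode to the final converted population, and
the k×k-field sampling protocol used to pick cells for manual tracing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .morphology import CellObservation, NEURON_LIKE, UNCLASSIFIED, CLASSES
from .tracking import FrameLink, LineageForest

HIGH_MITOSIS = "high-mitosis"
LOW_MITOSIS = "low-mitosis"


def doubling_time(n_t: float, n_t24: float) -> Optional[float]:
    """Doubling time in hours from counts 24 h apart.

    Td = 24 / log₂(N(t+24) / N(t)); undefined (None) when the count did
    not increase.
    """
    if n_t <= 0:
        raise ValueError("N_t must be positive")
    if n_t24 <= n_t:
        return None
    return 24.0 / math.log2(n_t24 / n_t)


def growth_table(counts: Sequence[float], frames_per_day: int = 24) -> pd.DataFrame:
    """Doubling time at every start hour with a full 24-h lookahead."""
    rows = []
    for t in range(len(counts) - frames_per_day):
        n_t, n_t24 = counts[t], counts[t + frames_per_day]
        td = doubling_time(n_t, n_t24) if n_t > 0 else None
        rows.append((t, n_t, n_t24, td))
    return pd.DataFrame(rows, columns=["t", "N_t", "N_t24", "Td"])


def _alive_with_class(forest: LineageForest, frame: int) -> list[tuple[int, Optional[str]]]:
    out = []
    for nid in forest.leaves_at(frame):
        node = forest.nodes[nid]
        idx = frame - node.first_frame
        out.append((nid, node.classes[idx] if idx < len(node.classes) else None))
    return out


def class_time_course(
    forest: LineageForest, n_frames: int, frames_per_day: int = 24
) -> pd.DataFrame:
    """Per-day class composition.

    Day d covers frames [24d, 24(d+1)); the census is taken at the last
    frame of each day that the movie reaches. Percentages are of all
    surviving cells at that frame and sum to 100 across the four
    classes.
    """
    rows = []
    day = 0
    while day * frames_per_day < n_frames:
        frame = min((day + 1) * frames_per_day - 1, n_frames - 1)
        alive = _alive_with_class(forest, frame)
        counts = {c: 0 for c in CLASSES}
        for _, cls in alive:
            counts[cls if cls in counts else UNCLASSIFIED] += 1
        total = len(alive)
        for cls in CLASSES:
            rows.append(
                (day, frame, cls, counts[cls],
                 100.0 * counts[cls] / total if total else float("nan"),
                 total == 0)
            )
        day += 1
    return pd.DataFrame(
        rows, columns=["day", "census_frame", "cls", "count", "percent", "empty"]
    )


@dataclass
class ConversionEvent:
    """A lineage branch switching stably into the target class."""

    node_id: int
    lineage_root: int
    frame: int                 # conversion frame (hours)
    mode: str                  # high-mitosis / low-mitosis
    divisions_before: int      # division edges from root to conversion
    divisions_recent: int      # divisions within the preceding 24 h
    descendants_final: int     # final-frame target-class descendants


def detect_conversions(
    forest: LineageForest,
    n_frames: int,
    target: str = NEURON_LIKE,
    persistence: int = 3,
    mitosis_threshold: int = 1,
    recent_window: int = 24,
) -> list[ConversionEvent]:
    """Find stable class switches into ``target`` on a classified forest.

    A conversion is the first frame, along any root-to-leaf path, where
    the class becomes ``target`` and stays so for at least
    ``persistence`` observed frames (a run cut short only by the end of
    the movie still counts). The event is attributed to the track node
    where the run starts, so a conversion followed by divisions is one
    event per converted branch, not one per leaf. Mode is high-mitosis
    when at least ``mitosis_threshold`` divisions occurred within the
    ``recent_window`` hours preceding the conversion, else low-mitosis.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    final = n_frames - 1
    events: dict[tuple[int, int], ConversionEvent] = {}

    leaf_ids = [nid for nid, n in forest.nodes.items() if not n.children]
    for leaf in leaf_ids:
        path = list(reversed(forest.path_to_root(leaf)))   # root ... leaf
        seq: list[tuple[int, Optional[str], int]] = []     # (frame, class, node)
        for nid in path:
            node = forest.nodes[nid]
            for k, (f, _) in enumerate(node.labels):
                seq.append((f, node.classes[k], nid))
        # find the first qualifying run of the target class
        i = 0
        while i < len(seq):
            if seq[i][1] == target and (i == 0 or seq[i - 1][1] != target):
                run = 0
                j = i
                while j < len(seq) and seq[j][1] == target:
                    run += 1
                    j += 1
                reaches_end = j == len(seq)
                if run >= persistence or (reaches_end and run >= 1):
                    frame, _, nid = seq[i]
                    key = (nid, frame)
                    if key not in events:
                        # divisions on the path root -> conversion node;
                        # each non-root node starts at a division
                        conv_path = list(reversed(forest.path_to_root(nid)))
                        div_frames = [
                            forest.nodes[m].first_frame
                            for m in conv_path
                            if forest.nodes[m].parent is not None
                        ]
                        recent = sum(
                            1 for f in div_frames if frame - recent_window < f <= frame
                        )
                        mode = HIGH_MITOSIS if recent >= mitosis_threshold else LOW_MITOSIS
                        events[key] = ConversionEvent(
                            node_id=nid,
                            lineage_root=conv_path[0],
                            frame=frame,
                            mode=mode,
                            divisions_before=len(div_frames),
                            divisions_recent=recent,
                            descendants_final=0,
                        )
                    break
                i = j
            else:
                i += 1

    # final-frame descendant census per event
    for ev in events.values():
        ev.descendants_final = len(_final_target_descendants(forest, ev.node_id, final, target))
    return sorted(events.values(), key=lambda e: (e.frame, e.node_id))


def _final_target_descendants(
    forest: LineageForest, node_id: int, final: int, target: str
) -> set[int]:
    out: set[int] = set()
    stack = [node_id]
    while stack:
        nid = stack.pop()
        node = forest.nodes[nid]
        if node.first_frame <= final <= node.last_frame:
            idx = final - node.first_frame
            if idx < len(node.classes) and node.classes[idx] == target:
                out.add(nid)
        stack.extend(node.children)
    return out


def mitosis_contribution_summary(
    events: Sequence[ConversionEvent],
    forest: LineageForest,
    n_frames: int,
    target: str = NEURON_LIKE,
) -> pd.DataFrame:
    """Per-mode census: converting founders, mean emergence time, and
    percent of final-frame target cells descending from each mode's
    founders. When every final target cell descends from a detected
    event, the two contributions sum to 100."""
    final = n_frames - 1
    final_target = {
        nid for nid, node in forest.nodes.items()
        if node.first_frame <= final <= node.last_frame
        and node.classes[final - node.first_frame] == target
    }
    rows = []
    for mode in (HIGH_MITOSIS, LOW_MITOSIS):
        mode_events = [e for e in events if e.mode == mode]
        desc: set[int] = set()
        for e in mode_events:
            desc |= _final_target_descendants(forest, e.node_id, final, target)
        contribution = (
            100.0 * len(desc & final_target) / len(final_target)
            if final_target else float("nan")
        )
        emergence = (
            float(np.mean([e.frame for e in mode_events])) if mode_events else float("nan")
        )
        rows.append((mode, len(mode_events), emergence, contribution))
    df = pd.DataFrame(
        rows, columns=["mode", "n_founders", "mean_emergence_h", "contribution_pct"]
    )
    df.attrs["empty"] = len(events) == 0
    df.attrs["n_final_target"] = len(final_target)
    return df


def estimate_division_prob(
    links: Sequence["FrameLink"],
    observations: Sequence[Sequence[CellObservation]],
) -> dict[str, tuple[float, int]]:
    """Per-class per-frame division probability from tracked data.

    For each class c: number of detected divisions whose parent was of
    class c, over the number of cell-frames of class c that had a next
    frame (the exposures). Returns class → (p̂, exposures)."""
    exposures: dict[str, int] = {}
    divisions: dict[str, int] = {}
    for t, link in enumerate(links):
        cls_of = {o.label: o.assigned_class for o in observations[t]}
        for o in observations[t]:
            c = o.assigned_class or UNCLASSIFIED
            exposures[c] = exposures.get(c, 0) + 1
        for parent, _ in link.divisions:
            c = cls_of.get(parent) or UNCLASSIFIED
            divisions[c] = divisions.get(c, 0) + 1
    return {
        c: (divisions.get(c, 0) / n if n else float("nan"), n)
        for c, n in sorted(exposures.items())
    }


def estimate_motion_sd(
    links: Sequence["FrameLink"],
    observations: Sequence[Sequence[CellObservation]],
) -> dict[str, tuple[float, int]]:
    """Per-class per-axis displacement SD from identity links (the
    Gaussian step SD of the random-walk motion model). Returns
    class → (sd, n_steps); both axes are pooled."""
    steps: dict[str, list[float]] = {}
    for t, link in enumerate(links):
        src = {o.label: o for o in observations[t]}
        dst = {o.label: o for o in observations[t + 1]}
        for la, lb in link.links:
            o, p = src[la], dst[lb]
            c = o.assigned_class or UNCLASSIFIED
            steps.setdefault(c, []).append(p.centroid[0] - o.centroid[0])
            steps[c].append(p.centroid[1] - o.centroid[1])
    return {
        c: (float(np.std(v, ddof=1)), len(v) // 2)
        for c, v in sorted(steps.items())
    }


def grid_sample(
    observations: Sequence[CellObservation],
    bounds: tuple[float, float],
    k: int = 5,
) -> list[int]:
    """Random-selection protocol: divide the picture into k×k equal
    fields and pick, per field, the cell whose centroid is closest to
    the field's middle (ties broken by lower label). Fields without any
    cell contribute nothing. Returns at most k² labels, sorted."""
    if k < 1:
        raise ValueError("k must be >= 1")
    h, w = bounds
    chosen: list[int] = []
    for gi in range(k):
        for gj in range(k):
            r0, r1 = gi * h / k, (gi + 1) * h / k
            c0, c1 = gj * w / k, (gj + 1) * w / k
            center = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
            best: Optional[tuple[float, int]] = None
            for o in observations:
                r, c = o.centroid
                if r0 <= r < r1 and c0 <= c < c1:
                    d = math.hypot(r - center[0], c - center[1])
                    if best is None or (d, o.label) < best:
                        best = (d, o.label)
            if best is not None:
                chosen.append(best[1])
    return sorted(set(chosen))
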