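"""Synthetic time-lapse movies of a fibroblast-to-neuron conversion.

The generator emulates a 60-min-interval live-cell acquisition over a
field of cells drawn from three morphological archetypes — MEF-like
(large, flat, low nucleus-to-cytosol ratio), neuron-like (elongated,
length-to-width ratio over 5, with neurite outgrowths) and shrunken
(small, nearly spherical, high nucleus-to-cytosol ratio). Cells move as
an isotropic Gaussian random walk with reflecting boundaries, divide and
die with per-archetype per-frame probabilities, and convert to the
neuron-like archetype according to a schedule, either *with-mitosis*
(the conversion happens at a forced division and both daughters are
neuron-like) or *without-mitosis* (an in-place archetype switch).

Frames are integer label images (each cell one 8-connected region,
pixel value = the cell's global id) with an aligned nucleus label
stack, so tracking and feature logic can be tested independently of
segmentation. Full ground truth (lineage, events, displacement,
final-frame marker identity) is returned alongside.

All randomness flows from a single integer seed; identical configs give
bit-identical movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, cos, pi, sin, sqrt
from typing import Optional

import numpy as np
import pandas as pd

from .. import morphology

MODE_WITH_MITOSIS = "with-mitosis"
MODE_WITHOUT_MITOSIS = "without-mitosis"


class OvercrowdingError(RuntimeError):
    """Raised when a cell cannot be placed without overlap."""

    def __init__(self, frame: int, cell_id: int):
        self.frame = frame
        self.cell_id = cell_id
        super().__init__(
            f"frame {frame}: cell {cell_id} cannot be placed without overlap "
            f"(field too crowded)"
        )


@dataclass(frozen=True)
class ArchetypeShape:
    """Shape-parameter distributions for one archetype.

    Areas are pixel² (no physical scale is assumed); the length-to-width
    target is the aspect ratio of the rendered ellipse body; the nucleus
    fraction is nucleus area / total cell area.
    """

    area_mean: float
    area_sd: float
    lw_mean: float
    lw_sd: float
    nucleus_frac_mean: float
    nucleus_frac_sd: float
    n_neurites: tuple[int, int] = (0, 0)     # inclusive range of rendered rays
    neurite_len: tuple[float, float] = (8.0, 16.0)


DEFAULT_SHAPES: dict[str, ArchetypeShape] = {
    morphology.MEF_LIKE: ArchetypeShape(
        area_mean=1500.0, area_sd=150.0,
        lw_mean=2.5, lw_sd=0.35,
        nucleus_frac_mean=0.060, nucleus_frac_sd=0.008,
    ),
    morphology.NEURON_LIKE: ArchetypeShape(
        area_mean=360.0, area_sd=40.0,
        lw_mean=7.5, lw_sd=0.7,
        nucleus_frac_mean=0.15, nucleus_frac_sd=0.02,
        n_neurites=(2, 4),
    ),
    morphology.SHRUNKEN: ArchetypeShape(
        area_mean=140.0, area_sd=18.0,
        lw_mean=1.12, lw_sd=0.06,
        nucleus_frac_mean=0.30, nucleus_frac_sd=0.04,
    ),
}


@dataclass(frozen=True)
class ConversionRule:
    """Schedule one wave of conversions: a fraction of the initial
    lineages converts to ``target`` in ``frame_window`` (inclusive),
    either at a forced division (with-mitosis) or in place."""

    fraction: float
    mode: str
    frame_window: tuple[int, int]
    target: str = morphology.NEURON_LIKE

    def __post_init__(self) -> None:
        if self.mode not in (MODE_WITH_MITOSIS, MODE_WITHOUT_MITOSIS):
            raise ValueError(f"unknown conversion mode {self.mode!r}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0,1]")


@dataclass
class MovieConfig:
    """Configuration of one synthetic movie (frames 60 min apart)."""

    n_frames: int = 36
    field_size: tuple[int, int] = (1400, 1400)
    n_initial_cells: int = 60
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {
            morphology.MEF_LIKE: 1.0,
            morphology.NEURON_LIKE: 0.0,
            morphology.SHRUNKEN: 0.0,
        }
    )
    motion_step_sd: dict[str, float] = field(
        default_factory=lambda: {
            morphology.MEF_LIKE: 3.0,
            morphology.NEURON_LIKE: 1.5,
            morphology.SHRUNKEN: 1.0,
        }
    )
    division_prob: dict[str, float] = field(
        default_factory=lambda: {
            morphology.MEF_LIKE: 0.065,
            morphology.NEURON_LIKE: 0.008,
            morphology.SHRUNKEN: 0.0,
        }
    )
    apoptosis_prob: dict[str, float] = field(
        default_factory=lambda: {
            morphology.MEF_LIKE: 0.001,
            morphology.NEURON_LIKE: 0.001,
            morphology.SHRUNKEN: 0.01,
        }
    )
    conversion_schedule: list[ConversionRule] = field(
        default_factory=lambda: [
            ConversionRule(0.10, MODE_WITH_MITOSIS, (12, 20)),
            ConversionRule(0.45, MODE_WITH_MITOSIS, (16, 28)),
            ConversionRule(0.10, MODE_WITHOUT_MITOSIS, (24, 33)),
            ConversionRule(0.12, MODE_WITHOUT_MITOSIS, (26, 34), target=morphology.SHRUNKEN),
        ]
    )
    shape_params: dict[str, ArchetypeShape] = field(
        default_factory=lambda: dict(DEFAULT_SHAPES)
    )
    enforce_shape_contract: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix fractions must sum to 1, got {total}")
        for name, probs in (("division_prob", self.division_prob),
                            ("apoptosis_prob", self.apoptosis_prob)):
            for k, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{k}]={p} not in [0,1]")
        total_conv = sum(r.fraction for r in self.conversion_schedule)
        if total_conv > 1.0 + 1e-9:
            raise ValueError("conversion_schedule fractions exceed 1")
        # a crude capacity check: initial cells must plausibly fit
        h, w = self.field_size
        max_area = max(s.area_mean + 4 * s.area_sd for s in self.shape_params.values())
        if self.n_initial_cells * 4 * max_area > h * w:
            raise ValueError("field_size too small for n_initial_cells without overlap")


# ---------------------------------------------------------------- rendering

def _ellipse_mask(area: float, lw: float, theta: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse with the given pixel area and
    aspect ratio, tightly cropped."""
    b = sqrt(area / (pi * lw))
    a = lw * b
    ext = int(ceil(max(a, b))) + 2
    rr, cc = np.mgrid[-ext:ext + 1, -ext:ext + 1]
    u = rr * cos(theta) + cc * sin(theta)
    v = -rr * sin(theta) + cc * cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _crop(mask: np.ndarray) -> np.ndarray:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    return mask[r0:r1 + 1, c0:c1 + 1]


def _nucleus_from_soma(soma: np.ndarray, frac: float, theta: float, lw: float) -> np.ndarray:
    """Nucleus = the frac-quantile core of the soma ellipse (the pixels
    with smallest normalized elliptical radius), giving an exact pixel
    count and hence an exact nucleus-to-cytosol ratio."""
    coords = np.argwhere(soma)
    center = coords.mean(axis=0)
    d = coords.astype(float) - center
    u = d[:, 0] * cos(theta) + d[:, 1] * sin(theta)
    v = -d[:, 0] * sin(theta) + d[:, 1] * cos(theta)
    rho = (u / lw) ** 2 + v**2    # elliptical radius, same aspect as soma
    k = max(1, int(round(frac * len(coords))))
    order = np.argsort(rho, kind="stable")[:k]
    nuc = np.zeros_like(soma)
    nuc[tuple(coords[order].T)] = True
    return nuc


class ShapeContractError(RuntimeError):
    """Raised when shape parameters cannot produce a mask satisfying the
    archetype's measured-feature contract."""


def _satisfies_contract(archetype: str, cell: np.ndarray, nuc: np.ndarray) -> bool:
    f = morphology.shape_features(cell, nuc)
    nc = f.nucleus_to_cytosol
    if archetype == morphology.NEURON_LIKE:
        return f.length_to_width > 5.0 and f.neurite_count >= 2
    if archetype == morphology.SHRUNKEN:
        return f.length_to_width < 1.5 and nc is not None and nc > 0.2
    if archetype == morphology.MEF_LIKE:
        return nc is not None and nc < 0.1
    raise ValueError(f"unknown archetype {archetype!r}")


def render_archetype(
    archetype: str,
    params: ArchetypeShape,
    rng: np.random.Generator,
    *,
    check: bool = True,
    max_tries: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cell: (cell mask, nucleus mask), tightly cropped.

    The body is an ellipse; neuron-like cells additionally get 2–4 thin
    rays (neurites) leaving the soma near its poles. When ``check`` is
    true the rendered mask is measured with the morphology module and
    parameters are redrawn until the archetype's rule contract holds;
    if it cannot be met a :class:`ShapeContractError` is raised rather
    than silently emitting an off-contract mask.
    """
    if archetype not in DEFAULT_SHAPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    last = None
    for _ in range(max_tries if check else 1):
        area = max(25.0, rng.normal(params.area_mean, params.area_sd))
        lw = max(1.0, rng.normal(params.lw_mean, params.lw_sd))
        frac = float(np.clip(rng.normal(params.nucleus_frac_mean, params.nucleus_frac_sd),
                             0.01, 0.6))
        theta = rng.uniform(0, pi)
        soma = _ellipse_mask(area, lw, theta)
        cell = soma.copy()
        lo, hi = params.n_neurites
        n_rays = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        if n_rays:
            b = sqrt(area / (pi * lw))
            a = lw * b
            pad = int(ceil(a + params.neurite_len[1])) + 4
            cell = np.pad(cell, pad)
            center = np.array(cell.shape) / 2.0
            for i in range(n_rays):
                # rays leave near the poles of the major axis so the
                # elongation contract survives
                pole = theta if i % 2 == 0 else theta + pi
                ang = pole + rng.uniform(-0.35, 0.35)
                length = rng.uniform(*params.neurite_len)
                width = int(rng.integers(1, 3))
                cell = _draw_ray(cell, center, 0.8 * a, pole, ang, length, width)
        cell = _crop(cell)
        soma_c = _ellipse_mask(area, lw, theta)
        # re-derive nucleus on the cropped frame: nucleus pixels are the
        # soma core, located by elliptical radius inside the cell mask
        nuc = _nucleus_from_cell(cell, frac, theta, lw)
        if not check or _satisfies_contract(archetype, cell, nuc):
            return cell, nuc
        last = (cell, nuc)
    raise ShapeContractError(
        f"could not render {archetype} satisfying its rule contract "
        f"after {max_tries} draws (params {params})"
    )


def _nucleus_from_cell(cell: np.ndarray, frac: float, theta: float, lw: float) -> np.ndarray:
    coords = np.argwhere(cell)
    center = coords.mean(axis=0)
    d = coords.astype(float) - center
    u = d[:, 0] * cos(theta) + d[:, 1] * sin(theta)
    v = -d[:, 0] * sin(theta) + d[:, 1] * cos(theta)
    rho = (u / lw) ** 2 + v**2
    k = max(1, int(round(frac * len(coords))))
    order = np.argsort(rho, kind="stable")[:k]
    nuc = np.zeros_like(cell)
    nuc[tuple(coords[order].T)] = True
    return nuc


def _draw_ray(cell: np.ndarray, center: np.ndarray, anchor_r: float,
              pole: float, ang: float, length: float, width: int) -> np.ndarray:
    """Stamp a ray: anchored inside the soma at radius ``anchor_r``
    along the ``pole`` direction, then extending ``length`` px along
    ``ang``. The canvas must already be padded to hold it."""
    h, w = cell.shape
    p0 = center + np.array([cos(pole), sin(pole)]) * anchor_r
    dr, dc = cos(ang), sin(ang)
    for s in np.arange(0.0, length + 0.25, 0.5):
        r = int(round(p0[0] + dr * s))
        c = int(round(p0[1] + dc * s))
        r0, r1 = max(0, r - width // 2), min(h, r + (width + 1) // 2)
        c0, c1 = max(0, c - width // 2), min(w, c + (width + 1) // 2)
        cell[r0:r1, c0:c1] = True
    return cell


def _reflect(x: float, lo: float, hi: float) -> float:
    """Mirror a coordinate back into [lo, hi]."""
    if hi <= lo:
        return lo
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    return lo + (y if y <= span else 2.0 * span - y)


# ---------------------------------------------------------------- simulation

@dataclass
class _Cell:
    cell_id: int
    lineage: int
    parent: Optional[int]
    archetype: str
    pos: np.ndarray            # float (row, col) of mask center
    mask: np.ndarray
    nucleus: np.ndarray
    birth_frame: int
    fate: Optional[ConversionRule] = None
    conv_frame: Optional[int] = None


@dataclass
class SyntheticTruth:
    """Generator-side ground truth.

    ``cells``: one row per cell per frame (frame, cell_id, lineage,
    parent, archetype, row, col, displacement). ``divisions``: (frame,
    parent, child_a, child_b). ``deaths``: (frame, cell_id).
    ``conversions``: (frame, cell_id, lineage, mode, target).
    ``marker_positive``: ids of final-frame cells whose archetype is
    neuron-like — the stand-in for TuJ (β-III-tubulin) positivity.
    """

    cells: pd.DataFrame
    divisions: pd.DataFrame
    deaths: pd.DataFrame
    conversions: pd.DataFrame
    marker_positive: set[int]

    def validate(self, n_frames: int) -> None:
        c = self.cells
        if not self.divisions.empty and (self.divisions["frame"] < 1).any():
            raise AssertionError("division in frame 0")
        for t in range(1, n_frames):
            prev = set(c.loc[c.frame == t - 1, "cell_id"])
            born = c.loc[(c.frame == t) & ~c.cell_id.isin(prev) & c.parent.notna()]
            parents = set(born["parent"].astype(int))
            if not parents <= prev:
                raise AssertionError(f"frame {t}: parent not present in frame {t-1}")


def generate_movie(
    config: MovieConfig,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Simulate a movie.

    Returns ``(labels, nuclei, truth)`` where ``labels`` and ``nuclei``
    are uint16 stacks of shape (n_frames, H, W); pixel values are global
    cell ids (0 = background). Identical config and seed give
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size

    cells: list[_Cell] = []
    next_id = 1

    def new_cell(archetype: str, lineage: int, parent: Optional[int],
                 pos: np.ndarray, frame: int, fate=None, conv_frame=None) -> _Cell:
        nonlocal next_id
        mask, nuc = render_archetype(
            archetype, config.shape_params[archetype], rng,
            check=config.enforce_shape_contract or archetype == morphology.NEURON_LIKE,
        )
        c = _Cell(next_id, lineage, parent, archetype, pos.astype(float),
                  mask, nuc, frame, fate, conv_frame)
        next_id += 1
        return c

    # --- initial placement: rejection-sample positions with separation
    mix_names = sorted(config.archetype_mix)
    mix_p = np.array([config.archetype_mix[k] for k in mix_names])
    counts = rng.multinomial(config.n_initial_cells, mix_p)
    archetypes: list[str] = []
    for name, k in zip(mix_names, counts):
        archetypes += [name] * int(k)

    max_r = max(
        sqrt((s.area_mean + 3 * s.area_sd) * max(s.lw_mean + 2 * s.lw_sd, 1) / pi)
        + (s.neurite_len[1] if s.n_neurites[1] else 0)
        for s in config.shape_params.values()
    )
    margin = max_r + 2
    placed: list[np.ndarray] = []
    min_sep = 1.6 * max_r
    for i, arch in enumerate(archetypes):
        ok = False
        for _ in range(400):
            pos = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(np.hypot(*(pos - q)) >= min_sep for q in placed):
                ok = True
                break
        if not ok:
            raise OvercrowdingError(0, i + 1)
        placed.append(pos)
        cells.append(new_cell(arch, lineage=i + 1, parent=None, pos=pos, frame=0))

    # --- assign conversion fates to initial lineages
    lineage_ids = [c.lineage for c in cells]
    perm = rng.permutation(len(lineage_ids))
    cursor = 0
    fate_of: dict[int, tuple[ConversionRule, int]] = {}
    for rule in config.conversion_schedule:
        k = int(round(rule.fraction * len(lineage_ids)))
        f0, f1 = rule.frame_window
        f1 = min(f1, config.n_frames - 1)
        if f0 > f1:
            # window lies beyond the movie: the wave never happens
            cursor += k
            continue
        for j in perm[cursor:cursor + k]:
            conv_frame = int(rng.integers(f0, f1 + 1))
            fate_of[lineage_ids[j]] = (rule, conv_frame)
        cursor += k
    for c in cells:
        if c.lineage in fate_of:
            c.fate, c.conv_frame = fate_of[c.lineage]

    labels = np.zeros((config.n_frames, h, w), dtype=np.uint16)
    nuclei = np.zeros((config.n_frames, h, w), dtype=np.uint16)

    rows_cells: list[tuple] = []
    rows_div: list[tuple] = []
    rows_death: list[tuple] = []
    rows_conv: list[tuple] = []
    prev_pos: dict[int, np.ndarray] = {}

    def stamp(frame: int, cell: _Cell) -> None:
        # place at the desired position; on overlap, nudge by the
        # smallest displacement that frees the mask (deterministic
        # spiral search) so collisions perturb the motion minimally
        mh, mw = cell.mask.shape

        def fits(r0: int, c0: int) -> bool:
            if not (0 <= r0 <= h - mh and 0 <= c0 <= w - mw):
                return False
            return not (labels[frame, r0:r0 + mh, c0:c0 + mw][cell.mask] != 0).any()

        base_r = int(np.clip(round(cell.pos[0] - mh / 2), 0, h - mh))
        base_c = int(np.clip(round(cell.pos[1] - mw / 2), 0, w - mw))
        placed_at = None
        if fits(base_r, base_c):
            placed_at = (base_r, base_c)
        else:
            for radius in range(1, 320):
                n_dirs = max(8, 2 * radius)
                for k in range(n_dirs):
                    ang = 2 * pi * k / n_dirs
                    r0 = int(np.clip(base_r + round(radius * cos(ang)), 0, h - mh))
                    c0 = int(np.clip(base_c + round(radius * sin(ang)), 0, w - mw))
                    if fits(r0, c0):
                        placed_at = (r0, c0)
                        break
                if placed_at:
                    break
        if placed_at is None:
            raise OvercrowdingError(frame, cell.cell_id)
        r0, c0 = placed_at
        labels[frame, r0:r0 + mh, c0:c0 + mw][cell.mask] = cell.cell_id
        nuclei[frame, r0:r0 + mh, c0:c0 + mw][cell.nucleus] = cell.cell_id
        cell.pos = np.array([r0 + mh / 2, c0 + mw / 2])

    for t in range(config.n_frames):
        if t > 0:
            survivors: list[_Cell] = []
            newborn: list[_Cell] = []
            for cell in cells:
                # apoptosis
                if rng.random() < config.apoptosis_prob[cell.archetype]:
                    rows_death.append((t, cell.cell_id))
                    continue
                forced_division = (
                    cell.fate is not None
                    and cell.conv_frame == t
                    and cell.fate.mode == MODE_WITH_MITOSIS
                )
                divides = forced_division or (
                    rng.random() < config.division_prob[cell.archetype]
                )
                if cell.fate is not None and cell.conv_frame == t and not forced_division:
                    # in-place conversion (without mitosis)
                    target = cell.fate.target
                    rows_conv.append((t, cell.cell_id, cell.lineage,
                                      MODE_WITHOUT_MITOSIS, target))
                    m, n = render_archetype(
                        target, config.shape_params[target], rng,
                        check=config.enforce_shape_contract
                        or target == morphology.NEURON_LIKE,
                    )
                    cell.archetype, cell.mask, cell.nucleus = target, m, n
                    cell.fate = None
                if divides:
                    target = (cell.fate.target if forced_division else cell.archetype)
                    off_ang = rng.uniform(0, 2 * pi)
                    direction = np.array([cos(off_ang), sin(off_ang)])
                    kids = []
                    for sgn in (+1, -1):
                        kid = new_cell(target, cell.lineage, cell.cell_id,
                                       cell.pos, t)
                        # adjacent but non-overlapping: offset by a bit
                        # over half the daughter's bounding-box diagonal
                        r_off = 0.55 * float(np.hypot(*kid.mask.shape))
                        kid.pos = cell.pos + sgn * direction * r_off
                        if forced_division:
                            rows_conv.append((t, kid.cell_id, cell.lineage,
                                              MODE_WITH_MITOSIS, target))
                        elif cell.fate is not None:
                            # the whole lineage carries the fate: both
                            # daughters inherit it
                            kid.fate, kid.conv_frame = cell.fate, cell.conv_frame
                        kids.append(kid)
                    rows_div.append((t, cell.cell_id, kids[0].cell_id, kids[1].cell_id))
                    newborn.extend(kids)
                else:
                    # Gaussian random-walk step, reflecting boundaries
                    step = rng.normal(0, config.motion_step_sd[cell.archetype], 2)
                    pos = cell.pos + step
                    pos[0] = _reflect(pos[0], margin, h - margin)
                    pos[1] = _reflect(pos[1], margin, w - margin)
                    cell.pos = pos
                    survivors.append(cell)
            cells = survivors + newborn

        order = sorted(cells, key=lambda c: c.cell_id)
        for cell in order:
            stamp(t, cell)
        for cell in order:
            disp = (
                float(np.hypot(*(cell.pos - prev_pos[cell.cell_id])))
                if cell.cell_id in prev_pos
                else np.nan
            )
            rows_cells.append((t, cell.cell_id, cell.lineage, cell.parent,
                               cell.archetype, cell.pos[0], cell.pos[1], disp))
        prev_pos = {c.cell_id: c.pos.copy() for c in cells}

    cells_df = pd.DataFrame(
        rows_cells,
        columns=["frame", "cell_id", "lineage", "parent", "archetype",
                 "row", "col", "displacement"],
    )
    truth = SyntheticTruth(
        cells=cells_df,
        divisions=pd.DataFrame(rows_div, columns=["frame", "parent", "child_a", "child_b"]),
        deaths=pd.DataFrame(rows_death, columns=["frame", "cell_id"]),
        conversions=pd.DataFrame(
            rows_conv, columns=["frame", "cell_id", "lineage", "mode", "target"]
        ),
        marker_positive=set(
            cells_df.loc[
                (cells_df.frame == config.n_frames - 1)
                & (cells_df.archetype == morphology.NEURON_LIKE),
                "cell_id",
            ]
        ),
    )
    return labels, nuclei, truth


def to_grayscale(labels: np.ndarray) -> np.ndarray:
    """Optional 8-bit render: foreground 200, background 20 (flat
    light-field-like contrast)."""
    return np.where(labels > 0, 200, 20).astype(np.uint8)
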