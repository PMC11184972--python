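"""Phosphene-like stimulus set, decoding tasks, and presentation schedule.

Visual neuroprostheses elicit solid bright blobs (phosphenes) on a dark
background; the experimental proxy used here is a set of gray squares and
rectangles flashed on a 5x5 grid covering the visual field.  This module
defines that grid, the 60-stimulus registry, the ten decoding tasks built
from it (location, size, and mixed-feature discriminations), and the
two-session presentation schedule (30 sub-sessions of 50 presentations,
750 ms stimulus, 1.0-1.25 s jittered inter-stimulus interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

Cell = tuple[int, int]

STIMULUS_DURATION_S = 0.75
ISI_RANGE_S = (1.0, 1.25)


@dataclass(frozen=True)
class GridSpec:
    """Screen grid on which stimuli are drawn.

    The stimulus region is divided into ``n_rows x n_cols`` equally sized
    cells; row 0 is at the top of the screen (superior visual field).
    Lengths are in cm.
    """

    n_rows: int = 5
    n_cols: int = 5
    screen_w: float = 166.0
    screen_h: float = 93.0
    viewing_distance: float = 40.0
    #: (x0, y0, width, height) of the stimulus region in screen coordinates
    stimulus_region: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        region = self.stimulus_region
        if region is None:
            object.__setattr__(
                self, "stimulus_region", (0.0, 0.0, self.screen_w, self.screen_h)
            )
        else:
            x0, y0, w, h = region
            if x0 < 0 or y0 < 0 or x0 + w > self.screen_w or y0 + h > self.screen_h:
                raise ValueError("stimulus_region does not fit inside the screen")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) of the grid center in cell coordinates."""
        return ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)


@dataclass(frozen=True)
class Stimulus:
    """One gray-on-black stimulus: a set of lit grid cells at a luminance."""

    id: str
    lit_cells: frozenset[Cell]
    gray_level: float = 0.5
    orientation: str = "none"  # "vertical" | "horizontal" | "none"

    def __post_init__(self) -> None:
        if not self.lit_cells:
            raise ValueError(f"stimulus {self.id!r} has no lit cells")
        if not 0.0 <= self.gray_level <= 1.0:
            raise ValueError(f"gray_level {self.gray_level} outside [0, 1]")
        if self.orientation not in ("vertical", "horizontal", "none"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def area(self) -> int:
        """Number of lit cells (proxy for stimulus size and luminosity)."""
        return len(self.lit_cells)

    @property
    def centroid(self) -> tuple[float, float]:
        """Mean (row, col) of lit cells, fractional."""
        rows = [r for r, _ in self.lit_cells]
        cols = [c for _, c in self.lit_cells]
        return (float(np.mean(rows)), float(np.mean(cols)))

    def validate_on(self, grid: GridSpec) -> None:
        for r, c in self.lit_cells:
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ValueError(f"stimulus {self.id!r} cell {(r, c)} outside grid")


class StimulusRegistry:
    """Ordered collection of stimuli with unique ids and lookup by id."""

    def __init__(self, stimuli: Sequence[Stimulus], grid: GridSpec | None = None):
        self.grid = grid if grid is not None else GridSpec()
        self.stimuli: list[Stimulus] = list(stimuli)
        self._by_id = {s.id: s for s in self.stimuli}
        if len(self._by_id) != len(self.stimuli):
            seen: set[str] = set()
            dups = [s.id for s in self.stimuli if s.id in seen or seen.add(s.id)]
            raise ValueError(f"duplicate stimulus ids: {sorted(set(dups))}")
        for s in self.stimuli:
            s.validate_on(self.grid)
        # Two stimuli with the same lit-cell set and gray level are
        # physically indistinguishable; treat that as a registry error.
        shapes: dict[tuple[frozenset[Cell], float], str] = {}
        dup_shapes = []
        for s in self.stimuli:
            key = (s.lit_cells, s.gray_level)
            if key in shapes:
                dup_shapes.append((shapes[key], s.id))
            else:
                shapes[key] = s.id
        if dup_shapes:
            raise ValueError(f"duplicate lit-cell sets: {dup_shapes}")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def __getitem__(self, stimulus_id: str) -> Stimulus:
        return self._by_id[stimulus_id]

    def __contains__(self, stimulus_id: str) -> bool:
        return stimulus_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.stimuli]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stimuli:
            r, c = s.centroid
            rows.append(
                dict(
                    id=s.id,
                    area=s.area,
                    centroid_row=r,
                    centroid_col=c,
                    gray_level=s.gray_level,
                    orientation=s.orientation,
                    lit_cells=";".join(f"{rr},{cc}" for rr, cc in sorted(s.lit_cells)),
                )
            )
        return pd.DataFrame(rows)

    def to_yaml(self, path) -> None:
        payload = [
            dict(
                id=s.id,
                lit_cells=[list(c) for c in sorted(s.lit_cells)],
                gray_level=s.gray_level,
                orientation=s.orientation,
            )
            for s in self.stimuli
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, grid: GridSpec | None = None) -> "StimulusRegistry":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        stimuli = [
            Stimulus(
                id=item["id"],
                lit_cells=frozenset(tuple(c) for c in item["lit_cells"]),
                gray_level=item.get("gray_level", 0.5),
                orientation=item.get("orientation", "none"),
            )
            for item in payload
        ]
        return cls(stimuli, grid=grid)


@dataclass
class DecodingTask:
    """A named partition of stimulus ids into M mutually exclusive classes."""

    name: str
    classes: dict[str, frozenset[str]]
    balanced: bool = True

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError(f"task {self.name!r} needs at least 2 classes")
        seen: set[str] = set()
        for label, members in self.classes.items():
            overlap = seen & members
            if overlap:
                raise ValueError(
                    f"task {self.name!r}: stimuli {sorted(overlap)} appear in "
                    f"multiple classes"
                )
            seen |= members

    @property
    def M(self) -> int:
        return len(self.classes)

    @property
    def class_labels(self) -> list[str]:
        return list(self.classes.keys())

    @property
    def stimulus_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.classes.values():
            out |= members
        return frozenset(out)

    def assign(self, stimulus_id: str) -> Optional[str]:
        for label, members in self.classes.items():
            if stimulus_id in members:
                return label
        return None


# ---------------------------------------------------------------------------
# Default registry construction
# ---------------------------------------------------------------------------

DEFAULT_FAMILIES = (
    "single_blocks",
    "vertical_bars_5",
    "horizontal_bars_5",
    "vertical_bars_3",
    "horizontal_bars_3",
    "blocks_2x2",
    "blocks_3x3",
    "rings_center",
)


def _block(anchor_r: int, anchor_c: int, size: int) -> frozenset[Cell]:
    return frozenset(
        (anchor_r + i, anchor_c + j) for i in range(size) for j in range(size)
    )


def _family_stimuli(family: str, grid: GridSpec) -> list[Stimulus]:
    nr, nc = grid.n_rows, grid.n_cols
    cr, cc = int((nr - 1) // 2), int((nc - 1) // 2)
    out: list[Stimulus] = []
    if family == "single_blocks":
        for r in range(nr):
            for c in range(nc):
                out.append(Stimulus(f"block1_r{r}c{c}", frozenset({(r, c)})))
    elif family == "vertical_bars_5":
        for c in range(nc):
            cells = frozenset((r, c) for r in range(nr))
            out.append(Stimulus(f"vbar5_c{c}", cells, orientation="vertical"))
    elif family == "horizontal_bars_5":
        for r in range(nr):
            cells = frozenset((r, c) for c in range(nc))
            out.append(Stimulus(f"hbar5_r{r}", cells, orientation="horizontal"))
    elif family == "vertical_bars_3":
        for c in range(nc):
            cells = frozenset((cr + d, c) for d in (-1, 0, 1))
            out.append(Stimulus(f"vbar3_c{c}", cells, orientation="vertical"))
    elif family == "horizontal_bars_3":
        for r in range(nr):
            cells = frozenset((r, cc + d) for d in (-1, 0, 1))
            out.append(Stimulus(f"hbar3_r{r}", cells, orientation="horizontal"))
    elif family == "blocks_2x2":
        anchors = {
            "tl": (0, 0),
            "tr": (0, nc - 2),
            "bl": (nr - 2, 0),
            "br": (nr - 2, nc - 2),
            "center": (cr - 1, cc - 1),
        }
        for tag, (r, c) in anchors.items():
            out.append(Stimulus(f"block4_{tag}", _block(r, c, 2)))
    elif family == "blocks_3x3":
        anchors = {
            "tl": (0, 0),
            "tr": (0, nc - 3),
            "bl": (nr - 3, 0),
            "br": (nr - 3, nc - 3),
            "center": (cr - 1, cc - 1),
        }
        for tag, (r, c) in anchors.items():
            out.append(Stimulus(f"block9_{tag}", _block(r, c, 3)))
    elif family == "rings_center":
        border = frozenset(
            (r, c)
            for r in range(nr)
            for c in range(nc)
            if r in (0, nr - 1) or c in (0, nc - 1)
        )
        corners = frozenset({(0, 0), (0, nc - 1), (nr - 1, 0), (nr - 1, nc - 1)})
        edges = border - corners
        middle_ring = frozenset(
            (cr + dr, cc + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        cross = frozenset({(cr, cc), (cr - 1, cc), (cr + 1, cc), (cr, cc - 1), (cr, cc + 1)})
        out += [
            Stimulus("ring16_outer", border),
            Stimulus("ring12_edges", edges),
            Stimulus("ring4_corners", corners),
            Stimulus("ring8_middle", middle_ring),
            Stimulus("cross5_center", cross),
        ]
    else:
        raise ValueError(f"unknown stimulus family {family!r}")
    return out


def build_stimulus_registry(
    grid: GridSpec | None = None,
    families: Iterable[str] = DEFAULT_FAMILIES,
    gray_level: float = 0.5,
) -> StimulusRegistry:
    """Build the stimulus registry from named families.

    The default configuration yields exactly 60 stimuli: 25 single blocks,
    5+5 full-span bars, 5+5 centered three-cell bars, 5 two-by-two and 5
    three-by-three blocks (four corners plus center), and 5 ring/center
    stimuli.  Duplicate lit-cell sets at the same gray level are rejected.
    """
    grid = grid if grid is not None else GridSpec()
    stimuli: list[Stimulus] = []
    for family in families:
        for s in _family_stimuli(family, grid):
            if gray_level != 0.5:
                s = Stimulus(s.id, s.lit_cells, gray_level, s.orientation)
            stimuli.append(s)
    return StimulusRegistry(stimuli, grid=grid)


# ---------------------------------------------------------------------------
# Task registry
# ---------------------------------------------------------------------------

#: Classes are balanced when the largest class holds at most 1.5x the
#: stimuli of the smallest; larger imbalance triggers the Monte Carlo
#: resampling scheme downstream.
BALANCE_RATIO = 1.5


def _balanced(classes: Mapping[str, frozenset[str]]) -> bool:
    sizes = [len(v) for v in classes.values()]
    return max(sizes) <= BALANCE_RATIO * min(sizes)


def _make_task(name: str, classes: dict[str, set[str]]) -> DecodingTask:
    frozen = {k: frozenset(v) for k, v in classes.items()}
    for label, members in frozen.items():
        if not members:
            raise ValueError(f"task {name!r}: class {label!r} is empty — registry "
                             f"is missing a required stimulus family")
    return DecodingTask(name=name, classes=frozen, balanced=_balanced(frozen))


def build_task_registry(registry: StimulusRegistry) -> list[DecodingTask]:
    """Construct the ten decoding tasks over the default registry.

    Location tasks: left-vs-right, superior-vs-inferior, vertical-bars (five
    column levels), horizontal-bars (five row levels), corners,
    outer-vs-middle.  Size tasks: bars (1 block / 3-cell bar / 5-cell bar),
    blocks (1 / 4 / 9 cells), luminosities (five lit-area levels).  Mixed:
    outer-vs-center (large peripheral vs small central stimuli).
    """
    grid = registry.grid
    cr, cc = grid.center
    by_id = {s.id: s for s in registry}

    def centroid(sid: str) -> tuple[float, float]:
        return by_id[sid].centroid

    ids = set(registry.ids)

    left = {sid for sid in ids if centroid(sid)[1] < cc - 1e-9}
    right = {sid for sid in ids if centroid(sid)[1] > cc + 1e-9}
    superior = {sid for sid in ids if centroid(sid)[0] < cr - 1e-9}
    inferior = {sid for sid in ids if centroid(sid)[0] > cr + 1e-9}

    vbars = {
        f"col{c}": {f"vbar5_c{c}", f"vbar3_c{c}"} & ids for c in range(grid.n_cols)
    }
    hbars = {
        f"row{r}": {f"hbar5_r{r}", f"hbar3_r{r}"} & ids for r in range(grid.n_rows)
    }

    corner_tags = {"tl", "tr", "bl", "br"}
    corner_singles = {
        "tl": f"block1_r0c0",
        "tr": f"block1_r0c{grid.n_cols - 1}",
        "bl": f"block1_r{grid.n_rows - 1}c0",
        "br": f"block1_r{grid.n_rows - 1}c{grid.n_cols - 1}",
    }
    corners = {
        tag: ({f"block4_{tag}", f"block9_{tag}", corner_singles[tag]} & ids)
        for tag in corner_tags
    }

    # Ring distance: Chebyshev distance of the centroid from the grid center,
    # in cell units. Outer >= 1.5 (border band), middle <= 0.5 (central band).
    def ring_dist(sid: str) -> float:
        r, c = centroid(sid)
        return max(abs(r - cr), abs(c - cc))

    outer = {sid for sid in ids if ring_dist(sid) >= 1.5}
    middle = {sid for sid in ids if ring_dist(sid) <= 0.5}

    singles = {sid for sid in ids if sid.startswith("block1_")}
    bars3 = {sid for sid in ids if sid.startswith(("vbar3_", "hbar3_"))}
    bars5 = {sid for sid in ids if sid.startswith(("vbar5_", "hbar5_"))}
    blocks4 = {sid for sid in ids if sid.startswith("block4_")}
    blocks9 = {sid for sid in ids if sid.startswith("block9_")}

    areas = sorted({by_id[sid].area for sid in ids})
    lum_levels = [a for a in areas if a in (1, 3, 4, 5, 9)][:5]
    luminosities = {
        f"area{a}": {sid for sid in ids if by_id[sid].area == a} for a in lum_levels
    }

    outer_large = {"ring16_outer", "ring12_edges", "ring4_corners"} & ids
    center_small = {
        "cross5_center", "ring8_middle", f"block1_r{int(cr)}c{int(cc)}"
    } & ids

    tasks = [
        _make_task("left_vs_right", {"left": left, "right": right}),
        _make_task("superior_vs_inferior", {"superior": superior, "inferior": inferior}),
        _make_task("vertical_bars", vbars),
        _make_task("horizontal_bars", hbars),
        _make_task("corners", corners),
        _make_task("outer_vs_middle", {"outer": outer, "middle": middle}),
        _make_task("bars", {"1-block": singles, "3-bars": bars3, "5-bars": bars5}),
        _make_task("blocks", {"1-block": singles, "4-blocks": blocks4, "9-blocks": blocks9}),
        _make_task("luminosities", luminosities),
        _make_task("outer_vs_center", {"outer": outer_large, "center": center_small}),
    ]
    return tasks


def assign_class(task: DecodingTask, stimulus_id: str, registry: StimulusRegistry) -> Optional[str]:
    """Class label of a stimulus under a task, or None if excluded."""
    if stimulus_id not in registry:
        raise KeyError(f"unknown stimulus id {stimulus_id!r}")
    return task.assign(stimulus_id)


def tasks_to_yaml(tasks: Sequence[DecodingTask], path) -> None:
    payload = [
        dict(
            name=t.name,
            balanced=bool(t.balanced),
            classes={k: sorted(v) for k, v in t.classes.items()},
        )
        for t in tasks
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_stimulus(
    stimulus: Stimulus, grid: GridSpec | None = None, resolution: int = 50
) -> np.ndarray:
    """Render a stimulus as a luminance image, ``resolution`` pixels per cell.

    Lit cells take the stimulus gray level, the rest of the grid is black, so
    mean luminance equals ``area * gray_level / n_cells``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    grid = grid if grid is not None else GridSpec()
    stimulus.validate_on(grid)
    img = np.zeros((grid.n_rows * resolution, grid.n_cols * resolution))
    for r, c in stimulus.lit_cells:
        img[r * resolution : (r + 1) * resolution, c * resolution : (c + 1) * resolution] = (
            stimulus.gray_level
        )
    return img


# ---------------------------------------------------------------------------
# Presentation schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledEvent:
    onset: float  # seconds from session start
    stimulus_id: str
    session: int
    subsession: int


@dataclass
class EventSchedule:
    """Presentation schedule: onsets within each session's own clock."""

    events: list[ScheduledEvent]
    stimulus_duration: float = STIMULUS_DURATION_S
    isi_range: tuple[float, float] = ISI_RANGE_S

    def __post_init__(self) -> None:
        for session in self.sessions:
            onsets = [e.onset for e in self.session_events(session)]
            if any(b - a < self.stimulus_duration + self.isi_range[0] - 1e-9
                   for a, b in zip(onsets, onsets[1:])):
                raise ValueError("onset gaps violate stimulus duration + minimum ISI")

    @property
    def sessions(self) -> list[int]:
        return sorted({e.session for e in self.events})

    def session_events(self, session: int) -> list[ScheduledEvent]:
        return [e for e in self.events if e.session == session]

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                onset=[e.onset for e in self.events],
                duration=[self.stimulus_duration] * len(self.events),
                stimulus_id=[e.stimulus_id for e in self.events],
                session=[e.session for e in self.events],
                subsession=[e.subsession for e in self.events],
            )
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventSchedule":
        df = pd.read_csv(path, sep="\t")
        events = [
            ScheduledEvent(
                onset=float(row.onset),
                stimulus_id=str(row.stimulus_id),
                session=int(row.session),
                subsession=int(row.subsession),
            )
            for row in df.itertuples()
        ]
        return cls(events=events)


@dataclass(frozen=True)
class ScheduleDesign:
    """Design parameters for the presentation schedule."""

    n_sessions: int = 2
    n_subsessions: int = 30
    presentations_per_subsession: int = 50
    repetitions_per_stimulus: int = 25  # per session
    stimulus_duration: float = STIMULUS_DURATION_S
    isi_range: tuple[float, float] = ISI_RANGE_S
    lead_in: float = 2.0  # seconds of recording before the first onset


def generate_schedule(
    registry: StimulusRegistry,
    design: ScheduleDesign | None = None,
    seed: int = 0,
) -> EventSchedule:
    """Randomized presentation schedule for both sessions.

    Per session every stimulus appears exactly ``repetitions_per_stimulus``
    times in a seed-shuffled order, chopped into sub-sessions; consecutive
    onsets are separated by the stimulus duration plus a uniform ISI.
    """
    design = design if design is not None else ScheduleDesign()
    n_stim = len(registry)
    per_session = n_stim * design.repetitions_per_stimulus
    if per_session != design.n_subsessions * design.presentations_per_subsession:
        raise ValueError(
            f"{n_stim} stimuli x {design.repetitions_per_stimulus} repetitions "
            f"cannot be divided into {design.n_subsessions} sub-sessions of "
            f"{design.presentations_per_subsession}"
        )
    rng = np.random.default_rng(seed)
    events: list[ScheduledEvent] = []
    for session in range(design.n_sessions):
        order = np.repeat(np.arange(n_stim), design.repetitions_per_stimulus)
        rng.shuffle(order)
        gaps = design.stimulus_duration + rng.uniform(
            design.isi_range[0], design.isi_range[1], size=per_session - 1
        )
        onsets = design.lead_in + np.concatenate([[0.0], np.cumsum(gaps)])
        for k, (stim_idx, onset) in enumerate(zip(order, onsets)):
            events.append(
                ScheduledEvent(
                    onset=float(onset),
                    stimulus_id=registry.stimuli[int(stim_idx)].id,
                    session=session,
                    subsession=k // design.presentations_per_subsession,
                )
            )
    return EventSchedule(
        events=events,
        stimulus_duration=design.stimulus_duration,
        isi_range=design.isi_range,
    )
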