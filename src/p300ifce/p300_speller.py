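"""The 3x3 row/column speller paradigm and the seed-pixel dataset.

Nine targets are laid out on a 3x3 grid (seven active objects O1..O7 plus
two reserved cells O8/O9 for future seeds).  One repetition flashes each of
the 3 rows and 3 columns once in random order; a flash is presented for
200 ms with a 300 ms onset-to-onset interval, so a repetition spans
6 x 300 ms = 1.8 s and covers every target exactly twice (its row and its
column).  Attending a target elicits a P300 deflection on the two flashes
that cover it; the classified target indexes a dataset mapping each object
to its seed pixel and fuzzy extraction parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fuzzy_engine import FuzzyParams

__all__ = [
    "FLASH_DURATION_MS",
    "ONSET_SPACING_MS",
    "REPETITION_MS",
    "SpellerLayout",
    "StimulusEvent",
    "RepetitionSchedule",
    "SeedDatasetEntry",
    "UnknownTargetError",
    "build_schedule",
    "flashes_covering_target",
    "default_dataset",
    "lookup_params",
    "save_dataset",
    "load_dataset",
    "save_schedule",
    "load_schedule",
]

FLASH_DURATION_MS = 200
ONSET_SPACING_MS = 300  # interstimulus interval, read as onset-to-onset
REPETITION_MS = 6 * ONSET_SPACING_MS  # 1.8 s per repetition


class UnknownTargetError(KeyError):
    """Target or object identifier not present in the layout/dataset."""


@dataclass(frozen=True)
class SpellerLayout:
    """Row-major 3x3 target grid: O1..O7 active, O8/O9 reserved."""

    grid: tuple[tuple[str, ...], ...] = (
        ("O1", "O2", "O3"),
        ("O4", "O5", "O6"),
        ("O7", "O8", "O9"),
    )

    def __post_init__(self) -> None:
        cells = [c for row in self.grid for c in row]
        if len(self.grid) != 3 or any(len(r) != 3 for r in self.grid):
            raise ValueError("layout must be a 3x3 grid")
        if len(set(cells)) != 9:
            raise ValueError("layout cells must be unique")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(c for row in self.grid for c in row)

    def position(self, target_id: str) -> tuple[int, int]:
        for i, row in enumerate(self.grid):
            for j, cell in enumerate(row):
                if cell == target_id:
                    return i, j
        raise UnknownTargetError(target_id)

    def target_at(self, row: int, col: int) -> str:
        return self.grid[row][col]


@dataclass(frozen=True)
class StimulusEvent:
    """One row or column flash within a repetition."""

    kind: str  # "row" | "col"
    index: int  # 0..2
    onset_ms: int  # from repetition start; multiple of the onset spacing
    duration_ms: int = FLASH_DURATION_MS

    def __post_init__(self) -> None:
        if self.kind not in ("row", "col"):
            raise ValueError(f"kind must be 'row' or 'col', got {self.kind!r}")
        if not 0 <= self.index <= 2:
            raise ValueError(f"index must be 0..2, got {self.index}")
        if self.onset_ms % ONSET_SPACING_MS != 0:
            raise ValueError("onset must be a multiple of the onset spacing")

    def covers(self, position: tuple[int, int]) -> bool:
        row, col = position
        return (self.kind == "row" and self.index == row) or (
            self.kind == "col" and self.index == col
        )


@dataclass(frozen=True)
class RepetitionSchedule:
    """Six stimulus events: each row and column exactly once, random order."""

    events: tuple[StimulusEvent, ...]
    rng_seed: int

    def __post_init__(self) -> None:
        keys = sorted((e.kind, e.index) for e in self.events)
        expected = sorted([("row", i) for i in range(3)] + [("col", i) for i in range(3)])
        if keys != expected:
            raise ValueError("a repetition must flash each of the 3 rows and 3 columns once")


def build_schedule(n_repetitions: int, rng_seed: int) -> list[RepetitionSchedule]:
    """Seeded random flash order for ``n_repetitions`` repetitions.

    Onsets are ``0, 300, ..., 1500`` ms within each repetition; a full
    session of n repetitions spans exactly ``n * 1.8`` s.
    """
    if n_repetitions < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(rng_seed)
    stimuli = [("row", 0), ("row", 1), ("row", 2), ("col", 0), ("col", 1), ("col", 2)]
    schedules = []
    for _ in range(n_repetitions):
        order = rng.permutation(6)
        events = tuple(
            StimulusEvent(kind=stimuli[k][0], index=stimuli[k][1], onset_ms=j * ONSET_SPACING_MS)
            for j, k in enumerate(order)
        )
        schedules.append(RepetitionSchedule(events=events, rng_seed=rng_seed))
    return schedules


def flashes_covering_target(schedule, target_id: str, layout: SpellerLayout | None = None):
    """Events whose row or column contains ``target_id``, in onset order.

    ``schedule`` may be a single :class:`RepetitionSchedule` or a list of
    them (events then come back in repetition order).
    """
    layout = layout or SpellerLayout()
    pos = layout.position(target_id)  # raises UnknownTargetError
    reps = [schedule] if isinstance(schedule, RepetitionSchedule) else list(schedule)
    out = []
    for rep in reps:
        out.extend(sorted((e for e in rep.events if e.covers(pos)), key=lambda e: e.onset_ms))
    return out


# ---------------------------------------------------------------------------
# seed-pixel dataset

@dataclass(frozen=True)
class SeedDatasetEntry:
    """One object's seed pixel and fuzzy extraction parameters."""

    object_id: str
    seed: tuple[int, int, int]
    params: FuzzyParams


#: Published seed-pixel dataset for the seven trained objects.  The gate
#: threshold r and the gap threshold are experience-set defaults (see
#: FuzzyParams); the remaining columns are the trained per-object values.
_DATASET_ROWS = (
    ("O1", (186, 69, 34), 0.2, 0.3, 0.2, 0.5),
    ("O2", (104, 140, 53), 0.2, 0.3, 0.2, 0.5),
    ("O3", (130, 100, 142), 0.1, 0.2, 0.3, 0.6),
    ("O4", (141, 47, 48), 0.1, 0.4, 0.3, 0.6),
    ("O5", (87, 133, 166), 0.1, 0.3, 0.3, 0.6),
    ("O6", (134, 147, 181), 0.15, 0.25, 0.8, 0.5),
    ("O7", (176, 134, 36), 0.2, 0.3, 0.4, 0.4),
)


def default_dataset(r: float = 1000.0, gap_threshold: int = 3) -> dict[str, SeedDatasetEntry]:
    """The built-in seven-object dataset keyed by object id."""
    return {
        oid: SeedDatasetEntry(
            object_id=oid,
            seed=seed,
            params=FuzzyParams(
                alpha1=a1, alpha2=a2, rho_m=rho_m, sigma=sigma, r=r, gap_threshold=gap_threshold
            ),
        )
        for oid, seed, a1, a2, rho_m, sigma in _DATASET_ROWS
    }


def lookup_params(dataset: dict[str, SeedDatasetEntry], object_id: str) -> SeedDatasetEntry:
    """Entry for ``object_id``; reserved/unknown ids raise UnknownTargetError."""
    try:
        return dataset[object_id]
    except KeyError:
        raise UnknownTargetError(object_id) from None


def save_dataset(path, dataset: dict[str, SeedDatasetEntry]) -> None:
    rows = [
        {
            "object": e.object_id,
            "R": e.seed[0],
            "G": e.seed[1],
            "B": e.seed[2],
            "alpha1": e.params.alpha1,
            "alpha2": e.params.alpha2,
            "rho_m": e.params.rho_m,
            "sigma": e.params.sigma,
            "r": e.params.r,
            "gap_threshold": e.params.gap_threshold,
        }
        for e in dataset.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_dataset(path) -> dict[str, SeedDatasetEntry]:
    df = pd.read_csv(path)
    out = {}
    for rec in df.to_dict("records"):
        params = FuzzyParams(
            alpha1=float(rec["alpha1"]),
            alpha2=float(rec["alpha2"]),
            rho_m=float(rec["rho_m"]),
            sigma=float(rec["sigma"]),
            r=float(rec["r"]),
            gap_threshold=int(rec["gap_threshold"]),
        )
        oid = str(rec["object"])
        out[oid] = SeedDatasetEntry(
            object_id=oid, seed=(int(rec["R"]), int(rec["G"]), int(rec["B"])), params=params
        )
    return out


def save_schedule(path, schedules: list[RepetitionSchedule]) -> None:
    """Export as a delimited event log: repetition, onset_ms, kind, index."""
    rows = [
        {"repetition": i, "onset_ms": e.onset_ms, "kind": e.kind, "index": e.index}
        for i, rep in enumerate(schedules)
        for e in rep.events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_schedule(path) -> list[RepetitionSchedule]:
    df = pd.read_csv(path, sep="\t")
    schedules = []
    for _, grp in df.groupby("repetition", sort=True):
        events = tuple(
            StimulusEvent(kind=str(r["kind"]), index=int(r["index"]), onset_ms=int(r["onset_ms"]))
            for r in grp.sort_values("onset_ms").to_dict("records")
        )
        schedules.append(RepetitionSchedule(events=events, rng_seed=-1))
    return schedules
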