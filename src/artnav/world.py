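"""The map the agents navigate: extent, start/goal points and a landmark field.

Defaults follow the study conditions: a 200 x 130 unit map carrying 6,500
uniformly scattered landmarks (density 0.25 per square unit), with start
and goal on the horizontal midline, symmetric about the map centre and
104 units apart: start = (48, 65), goal = (152, 65).

Landmark placement is seeded and regenerable, so a world serialises to a
small JSON document (dimensions + seed) rather than a coordinate dump.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["World", "SpatialIndex", "build_world", "nearest_landmark"]


class SpatialIndex:
    """Uniform-grid bin of landmark IDs for nearest-neighbour queries.

    Cell size equals the query radius, so a 3x3 cell neighbourhood is
    guaranteed to contain every landmark within ``radius`` of a query
    point.  Results are identical to an exhaustive scan (property-tested).
    """

    def __init__(self, points: np.ndarray, cell: float) -> None:
        self.points = np.asarray(points, dtype=float)
        self.cell = float(cell)
        self._cells: dict[tuple[int, int], np.ndarray] = {}
        self._hood: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if len(self.points):
            ix = np.floor(self.points[:, 0] / self.cell).astype(np.int64)
            iy = np.floor(self.points[:, 1] / self.cell).astype(np.int64)
            order = np.lexsort((np.arange(len(ix)), iy, ix))
            for idx in order:
                self._cells.setdefault((int(ix[idx]), int(iy[idx])), []).append(idx)  # type: ignore[union-attr]
            self._cells = {k: np.asarray(v, dtype=np.int64) for k, v in self._cells.items()}

    def _neighbourhood(self, key: tuple[int, int]):
        hood = self._hood.get(key)
        if hood is None:
            ids = [
                self._cells[(key[0] + dx, key[1] + dy)]
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                if (key[0] + dx, key[1] + dy) in self._cells
            ]
            cand = np.sort(np.concatenate(ids)) if ids else np.empty(0, dtype=np.int64)
            hood = (cand, self.points[cand, 0].copy(), self.points[cand, 1].copy())
            self._hood[key] = hood
        return hood

    def nearest_within(self, x: float, y: float, radius: float) -> int | None:
        """ID of the closest point within ``radius`` (ties -> lowest ID)."""
        if radius > self.cell:
            raise ValueError("query radius exceeds index cell size")
        key = (int(math.floor(x / self.cell)), int(math.floor(y / self.cell)))
        cand, px, py = self._neighbourhood(key)
        if not len(cand):
            return None
        d2 = (px - x) ** 2 + (py - y) ** 2
        best = int(np.argmin(d2))  # candidates sorted by ID -> ties break low
        if d2[best] <= radius * radius:
            return int(cand[best])
        return None

    def all_within(self, x: float, y: float, radius: float) -> list[int]:
        """IDs of all points within ``radius``, ordered by distance
        (ties -> lowest ID)."""
        if radius > self.cell:
            raise ValueError("query radius exceeds index cell size")
        key = (int(math.floor(x / self.cell)), int(math.floor(y / self.cell)))
        cand, px, py = self._neighbourhood(key)
        if not len(cand):
            return []
        d2 = (px - x) ** 2 + (py - y) ** 2
        inside = d2 <= radius * radius
        sel = cand[inside]
        order = np.argsort(d2[inside], kind="stable")
        return [int(i) for i in sel[order]]


@dataclass(frozen=True)
class World:
    """Map geometry plus the seeded landmark field."""

    width: float
    height: float
    start: tuple[float, float]
    goal: tuple[float, float]
    landmark_seed: int
    n_landmarks: int
    placement: str = "uniform"
    landmarks: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore[assignment]
    index: SpatialIndex = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    @property
    def start_goal_distance(self) -> float:
        return math.dist(self.start, self.goal)

    def to_json(self) -> str:
        return json.dumps(
            {
                "width": self.width,
                "height": self.height,
                "start": list(self.start),
                "goal": list(self.goal),
                "landmark_seed": self.landmark_seed,
                "n_landmarks": self.n_landmarks,
                "placement": self.placement,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "World":
        d = json.loads(doc)
        return build_world(
            landmark_seed=d["landmark_seed"],
            n_landmarks=d["n_landmarks"],
            width=d["width"],
            height=d["height"],
            start=tuple(d["start"]),
            goal=tuple(d["goal"]),
            placement=d.get("placement", "uniform"),
        )


def _place_landmarks(
    rng: np.random.Generator, n: int, width: float, height: float, placement: str
) -> np.ndarray:
    if placement == "uniform":
        return rng.uniform((0.0, 0.0), (width, height), size=(n, 2))
    if placement == "grid":
        # regular grid option for sensitivity checks: near-square cells
        if n == 0:
            return np.empty((0, 2))
        nx = max(1, int(round(math.sqrt(n * width / height))))
        ny = max(1, int(math.ceil(n / nx)))
        xs = (np.arange(nx) + 0.5) * (width / nx)
        ys = (np.arange(ny) + 0.5) * (height / ny)
        pts = np.array([(x, y) for y in ys for x in xs])
        return pts[:n]
    raise ValueError(f"unknown landmark placement {placement!r}")


def build_world(
    landmark_seed: int = 0,
    n_landmarks: int = 6500,
    width: float = 200.0,
    height: float = 130.0,
    start: tuple[float, float] | None = None,
    goal: tuple[float, float] | None = None,
    separation: float = 104.0,
    placement: str = "uniform",
    index_cell: float = 10.0,
) -> World:
    """Construct a world with a seeded landmark field.

    By default start and goal sit on the horizontal midline, symmetric
    about the map centre and ``separation`` units apart.
    """
    if width <= 0 or height <= 0:
        raise ValueError("map dimensions must be positive")
    if n_landmarks < 0:
        raise ValueError("n_landmarks must be >= 0")
    if start is None:
        start = ((width - separation) / 2.0, height / 2.0)
    if goal is None:
        goal = ((width + separation) / 2.0, height / 2.0)
    rng = np.random.default_rng(landmark_seed)
    pts = _place_landmarks(rng, n_landmarks, width, height, placement)
    return World(
        width=float(width),
        height=float(height),
        start=(float(start[0]), float(start[1])),
        goal=(float(goal[0]), float(goal[1])),
        landmark_seed=int(landmark_seed),
        n_landmarks=int(n_landmarks),
        placement=placement,
        landmarks=pts,
        index=SpatialIndex(pts, cell=index_cell),
    )


def nearest_landmark(world: World, p: tuple[float, float], radius: float) -> int | None:
    """ID of the closest landmark within ``radius`` of ``p``, else ``None``.

    Ties are broken towards the lowest landmark ID.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return world.index.nearest_within(float(p[0]), float(p[1]), float(radius))
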