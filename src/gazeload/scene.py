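"""Phone-booth scene geometry and ray casting.

The virtual scene is a narrow booth (interior a little over 1 m across) whose
front wall carries a glowing target sphere at 1.5 m height, with three
distraction posters between 1.2 and 1.4 m.  The booth entrance (behind the
standing position) and the space above it are open, so rays leaving through
them hit nothing.  Coordinates: right-handed, y-up, metres; the standing
position is the origin on the floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Height of the standing eye position used by the simulator (m).
EYE_HEIGHT = 1.60

#: Labels of the three distraction posters.
POSTER_LABELS = ("poster_left", "poster_right", "poster_front")

TARGET_LABEL = "target_sphere"


@dataclass(frozen=True)
class RectSurface:
    """A finite rectangle: center, two orthonormal in-plane axes, half-extents."""

    label: str
    center: np.ndarray
    u: np.ndarray  # in-plane unit axis
    v: np.ndarray  # in-plane unit axis, orthogonal to u
    half_u: float
    half_v: float

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Ray parameters t (NaN where no hit) for (n,3) origins/dirs."""
        n = self.normal
        denom = dirs @ n
        rel = self.center - origins
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (rel @ n) / denom
            p = origins + t[:, None] * dirs
            d = p - self.center
            inside = (np.abs(d @ self.u) <= self.half_u) & (
                np.abs(d @ self.v) <= self.half_v
            )
            ok = (np.abs(denom) > 1e-12) & (t > 1e-9) & inside
        return np.where(ok, t, np.nan)


@dataclass(frozen=True)
class SphereSurface:
    """A sphere; rays report the nearest front intersection."""

    label: str
    center: np.ndarray
    radius: float

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        rel = origins - self.center
        b = np.einsum("ij,ij->i", rel, dirs)
        c = np.einsum("ij,ij->i", rel, rel) - self.radius**2
        disc = b * b - c
        with np.errstate(invalid="ignore"):
            sq = np.sqrt(disc)
        t1 = -b - sq
        t2 = -b + sq
        t = np.where(t1 > 1e-9, t1, t2)
        ok = (disc >= 0) & (t > 1e-9)
        return np.where(ok, t, np.nan)


@dataclass(frozen=True)
class SceneModel:
    """Named surfaces of the booth scene."""

    surfaces: tuple

    def labels(self) -> list[str]:
        return [s.label for s in self.surfaces]

    def cast_rays(
        self, origins: np.ndarray, dirs: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Nearest positive-distance hits for a batch of rays.

        Returns ``(points, labels)``: an (n, 3) array with NaN rows where no
        surface is hit, and an object array of labels ('' for misses).
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-length ray direction")
        dirs = dirs / norms[:, None]
        n = len(origins)
        best_t = np.full(n, np.inf)
        best_idx = np.full(n, -1, dtype=int)
        for i, surf in enumerate(self.surfaces):
            t = surf.intersect(origins, dirs)
            better = np.nan_to_num(t, nan=np.inf) < best_t
            best_t = np.where(better, t, best_t)
            best_idx = np.where(better, i, best_idx)
        with np.errstate(invalid="ignore"):
            points = origins + best_t[:, None] * dirs
        points[best_idx < 0] = np.nan
        labels = np.array(
            ["" if i < 0 else self.surfaces[i].label for i in best_idx], dtype=object
        )
        return points, labels


def cast_ray(
    scene: SceneModel, origin: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, str] | None:
    """Nearest intersection of a single ray with the scene, or ``None``."""
    points, labels = scene.cast_rays(origin, direction)
    if labels[0] == "":
        return None
    return points[0], str(labels[0])


def _rect(label, center, u, v, half_u, half_v) -> RectSurface:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return RectSurface(
        label,
        np.asarray(center, dtype=float),
        u / np.linalg.norm(u),
        v / np.linalg.norm(v),
        float(half_u),
        float(half_v),
    )


def build_scene() -> SceneModel:
    """The fixed booth scene.

    Interior 1.1 m across, walls 2.2 m high on three sides (the rear entrance
    side, height 1.95 m, is open), target sphere (r = 5 cm) on the front wall
    at 1.5 m height, and three posters (25 x 20 cm) at 1.2-1.4 m height.
    Posters sit 1 mm proud of their wall so they win the nearest-hit test.
    """
    half = 0.55
    wall_h = 2.2
    surfaces = [
        # front wall (z = +half), facing the user at -z
        _rect("wall_front", (0, wall_h / 2, half), (1, 0, 0), (0, 1, 0), half, wall_h / 2),
        _rect("wall_left", (-half, wall_h / 2, 0), (0, 0, 1), (0, 1, 0), half, wall_h / 2),
        _rect("wall_right", (half, wall_h / 2, 0), (0, 0, 1), (0, 1, 0), half, wall_h / 2),
        _rect("floor", (0, 0.0, 0), (1, 0, 0), (0, 0, 1), half, half),
        SphereSurface(TARGET_LABEL, np.array([0.0, 1.5, 0.49]), 0.05),
        _rect("poster_left", (-half + 0.001, 1.30, 0.15), (0, 0, 1), (0, 1, 0), 0.125, 0.10),
        _rect("poster_right", (half - 0.001, 1.30, 0.15), (0, 0, 1), (0, 1, 0), 0.125, 0.10),
        _rect("poster_front", (0.30, 1.30, half - 0.001), (1, 0, 0), (0, 1, 0), 0.125, 0.10),
    ]
    labels = [s.label for s in surfaces]
    assert len(labels) == len(set(labels)), "surface labels must be unique"
    return SceneModel(surfaces=tuple(surfaces))
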