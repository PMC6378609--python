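"""Catheter and chamber geometry.

Electrode layouts for panoramic (basket) and regional (PentaRay-style)
mapping catheters, their neighbor graphs, an idealized atrial surface on
which activation sources live, and the 1 cm center-to-center rule used to
decide whether two mapped sites are the same site.

All coordinates are millimetres in a right-handed frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Electrode",
    "ElectrodeArray",
    "AtrialSurface",
    "SitePair",
    "make_basket_array",
    "make_pentaray_array",
    "neighbor_graph",
    "correlate_sites",
]

#: center-to-center distance (mm) under which two sites are the same site
SITE_CORRELATION_MM = 10.0


@dataclass(frozen=True)
class Electrode:
    """One electrode: id, spline index, position along the spline, xyz (mm)."""

    electrode_id: str
    spline: int
    index: int
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass
class ElectrodeArray:
    """A multi-electrode catheter: electrodes plus a symmetric neighbor graph.

    ``array_kind`` is one of ``basket`` (8 splines x 8 electrodes),
    ``pentaray`` (5 splines x 4 electrodes) or ``custom``.
    """

    array_kind: str
    electrodes: list[Electrode]
    adjacency: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- access -----------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [e.electrode_id for e in self.electrodes]

    def positions(self) -> dict[str, np.ndarray]:
        return {e.electrode_id: e.position for e in self.electrodes}

    def position_of(self, electrode_id: str) -> np.ndarray:
        for e in self.electrodes:
            if e.electrode_id == electrode_id:
                return e.position
        raise KeyError(electrode_id)

    def __len__(self) -> int:
        return len(self.electrodes)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        pos = np.array([e.position for e in self.electrodes])
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        # pairwise distances strictly positive
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.any(d2 <= 0):
            raise ValueError("two electrodes share a position")
        idset = set(ids)
        for a, nbrs in self.adjacency.items():
            if a not in idset:
                raise ValueError(f"adjacency references unknown electrode {a!r}")
            if a in nbrs:
                raise ValueError(f"self-edge on {a!r}")
            for b in nbrs:
                if b not in idset:
                    raise ValueError(f"adjacency references unknown electrode {b!r}")
                if a not in self.adjacency.get(b, frozenset()):
                    raise ValueError(f"asymmetric edge {a!r}->{b!r}")
        if self.array_kind == "basket" and len(ids) != 64:
            raise ValueError("basket arrays have 8 splines x 8 electrodes = 64")
        if self.array_kind == "pentaray" and len(ids) != 20:
            raise ValueError("pentaray arrays have 5 splines x 4 electrodes = 20")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        edges = sorted(
            [sorted((a, b)) for a, nbrs in self.adjacency.items() for b in nbrs if a < b]
        )
        doc = {
            "array_kind": self.array_kind,
            "electrodes": [
                {
                    "id": e.electrode_id,
                    "spline": e.spline,
                    "index": e.index,
                    "xyz": [float(x) for x in e.position],
                }
                for e in self.electrodes
            ],
            "adjacency": edges,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ElectrodeArray":
        doc = json.loads(text)
        electrodes = [
            Electrode(d["id"], int(d["spline"]), int(d["index"]), np.array(d["xyz"]))
            for d in doc["electrodes"]
        ]
        adj: dict[str, set[str]] = {e.electrode_id: set() for e in electrodes}
        for a, b in doc["adjacency"]:
            adj[a].add(b)
            adj[b].add(a)
        return cls(
            array_kind=doc["array_kind"],
            electrodes=electrodes,
            adjacency={k: frozenset(v) for k, v in adj.items()},
        )


def _freeze(adj: Mapping[str, set[str]]) -> dict[str, frozenset[str]]:
    return {k: frozenset(v) for k, v in adj.items()}


def make_basket_array(
    radius_mm: float = 25.0,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    n_splines: int = 8,
    electrodes_per_spline: int = 8,
) -> ElectrodeArray:
    """Spherical basket catheter: ``n_splines`` meridians between two poles.

    Electrodes sit at colatitudes ``pi*(k+1)/(electrodes_per_spline+1)`` so no
    electrode sits exactly on a pole. Adjacency links along-spline neighbors
    and the same-rank electrode on each circumferentially adjacent spline, so
    interior electrodes have degree 4 and spline-end electrodes degree 3.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if n_splines < 3 or electrodes_per_spline < 2:
        raise ValueError("need >=3 splines and >=2 electrodes per spline")
    center = np.asarray(center, dtype=float).reshape(3)
    letters = [chr(ord("A") + j) for j in range(n_splines)]
    electrodes: list[Electrode] = []
    for j in range(n_splines):
        phi = 2.0 * np.pi * j / n_splines
        for k in range(electrodes_per_spline):
            theta = np.pi * (k + 1) / (electrodes_per_spline + 1)
            xyz = center + radius_mm * np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
            electrodes.append(Electrode(f"{letters[j]}{k + 1}", j, k, xyz))

    adj: dict[str, set[str]] = {e.electrode_id: set() for e in electrodes}

    def eid(j: int, k: int) -> str:
        return f"{letters[j % n_splines]}{k + 1}"

    for j in range(n_splines):
        for k in range(electrodes_per_spline):
            if k + 1 < electrodes_per_spline:  # along spline
                adj[eid(j, k)].add(eid(j, k + 1))
                adj[eid(j, k + 1)].add(eid(j, k))
            adj[eid(j, k)].add(eid(j + 1, k))  # same rank, next spline
            adj[eid(j + 1, k)].add(eid(j, k))

    kind = "basket" if (n_splines, electrodes_per_spline) == (8, 8) else "custom"
    return ElectrodeArray(kind, electrodes, _freeze(adj))


#: consecutive along-spline electrode gaps of the regional catheter (mm)
PENTARAY_GAPS_MM = (2.0, 6.0, 2.0)
#: radial distance of the innermost electrode from the hub (mm)
PENTARAY_INNER_MM = 4.0


def make_pentaray_array(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    orientation: np.ndarray | None = None,
) -> ElectrodeArray:
    """Five-spline planar star with 2-6-2 mm electrode spacing per spline.

    ``orientation`` is a 3x3 rotation matrix mapping the canonical frame
    (splines in the xy-plane) into world coordinates; identity by default.
    Adjacency links along-spline neighbors only.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    if orientation is None:
        orientation = np.eye(3)
    R = np.asarray(orientation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0.5:
        raise ValueError("degenerate orientation: need a proper 3x3 rotation matrix")

    radii = PENTARAY_INNER_MM + np.concatenate([[0.0], np.cumsum(PENTARAY_GAPS_MM)])
    electrodes: list[Electrode] = []
    adj: dict[str, set[str]] = {}
    for j in range(5):
        phi = 2.0 * np.pi * j / 5.0
        u = R @ np.array([np.cos(phi), np.sin(phi), 0.0])
        for k, r in enumerate(radii):
            electrodes.append(Electrode(f"P{j + 1}-{k + 1}", j, k, center + r * u))
    for e in electrodes:
        adj[e.electrode_id] = set()
    for j in range(5):
        for k in range(3):
            a, b = f"P{j + 1}-{k + 1}", f"P{j + 1}-{k + 2}"
            adj[a].add(b)
            adj[b].add(a)
    return ElectrodeArray("pentaray", electrodes, _freeze(adj))


def neighbor_graph(
    array: ElectrodeArray, mode: str = "structural", radius_mm: float | None = None
) -> dict[str, frozenset[str]]:
    """Electrode neighborhoods: catheter wiring or a metric ball.

    ``structural`` returns the array's built-in adjacency; ``metric`` links
    every pair of electrodes within ``radius_mm`` of each other.
    """
    if mode == "structural":
        return dict(array.adjacency)
    if mode == "metric":
        if radius_mm is None or radius_mm <= 0:
            raise ValueError("metric mode requires radius_mm > 0")
        ids = array.ids
        pos = np.array([e.position for e in array.electrodes])
        d = np.sqrt(np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1))
        adj: dict[str, set[str]] = {i: set() for i in ids}
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                if d[a, b] <= radius_mm:
                    adj[ids[a]].add(ids[b])
                    adj[ids[b]].add(ids[a])
        return _freeze(adj)
    raise ValueError(f"unknown neighbor mode {mode!r}")


def correlate_sites(
    a: Sequence[float], b: Sequence[float], threshold_mm: float = SITE_CORRELATION_MM
) -> tuple[bool, float]:
    """Do two sites correlate (< ``threshold_mm`` center to center, strict)?

    Returns ``(correlated, distance_mm)``.
    """
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("site coordinates must be finite")
    d = float(np.linalg.norm(a - b))
    return d < threshold_mm, d


@dataclass(frozen=True)
class SitePair:
    """Two mapped sites and their center-to-center distance (mm)."""

    site_a: np.ndarray
    site_b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_a", np.asarray(self.site_a, float).reshape(3))
        object.__setattr__(self, "site_b", np.asarray(self.site_b, float).reshape(3))

    @property
    def center_to_center(self) -> float:
        return float(np.linalg.norm(self.site_a - self.site_b))

    def correlated(self, threshold_mm: float = SITE_CORRELATION_MM) -> bool:
        return self.center_to_center < threshold_mm


_THOMSEN_P = 1.6075  # exponent of the Thomsen ellipsoid-area approximation


@dataclass(frozen=True)
class AtrialSurface:
    """Closed convex chamber wall: an ellipsoid with semi-axes in mm.

    Activation sources live on this surface and mapping electrodes sit on or
    near it. The default is the spherical special case a basket catheter
    conforms to. Geodesic distances on a sphere are exact great-circle
    lengths; on a general ellipsoid they are computed from a finely sampled
    surface polyline (central spherical interpolation projected back onto the
    ellipsoid), accurate to well below 0.1 mm at chamber scale.
    """

    semi_axes: tuple[float, float, float] = (25.0, 25.0, 25.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    @property
    def _axes(self) -> np.ndarray:
        return np.asarray(self.semi_axes, dtype=float)

    @property
    def _c(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def is_sphere(self) -> bool:
        a, b, c = self.semi_axes
        return np.isclose(a, b) and np.isclose(b, c)

    @property
    def diameter_mm(self) -> float:
        return 2.0 * float(max(self.semi_axes))

    def area_cm2(self) -> float:
        """Surface area in cm^2 (exact for spheres, Thomsen otherwise)."""
        a, b, c = self.semi_axes
        if self.is_sphere:
            return float(4.0 * np.pi * a * a) / 100.0
        p = _THOMSEN_P
        s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return float(4.0 * np.pi * s ** (1.0 / p)) / 100.0

    def project(self, points: np.ndarray) -> np.ndarray:
        """Central projection of points onto the surface (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self._c
        scale = np.sqrt(np.sum((rel / self._axes) ** 2, axis=-1, keepdims=True))
        if np.any(scale == 0):
            raise ValueError("cannot project the chamber center onto the surface")
        out = self._c + rel / scale
        return out[0] if np.asarray(points).ndim == 1 else out

    def surface_residual(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance (mm) of points from the surface."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - self._c) / self._axes
        f = np.sum(rel**2, axis=-1) - 1.0
        grad = 2.0 * rel / self._axes  # gradient of the implicit function, 1/mm
        res = f / np.maximum(np.linalg.norm(grad, axis=-1), 1e-12)
        return res[0] if np.asarray(points).ndim == 1 else res

    def geodesic_mm(self, p: Sequence[float], q: Sequence[float], n: int = 512) -> float:
        """Surface (geodesic) distance between two points, mm.

        Both points are first projected onto the surface.
        """
        p = self.project(np.asarray(p, dtype=float))
        q = self.project(np.asarray(q, dtype=float))
        u = (p - self._c) / self._axes
        v = (q - self._c) / self._axes
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
        omega = float(np.arccos(dot))
        if self.is_sphere:
            return float(self.semi_axes[0] * omega)
        if omega < 1e-12:
            return 0.0
        if np.pi - omega < 1e-9:  # antipodal: pick any orthogonal waypoint
            w = np.zeros(3)
            w[np.argmin(np.abs(u))] = 1.0
            w -= u * np.dot(u, w)
            w /= np.linalg.norm(w)
            mid = self._c + self._axes * w
            return self.geodesic_mm(p, mid, n) + self.geodesic_mm(mid, q, n)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        so = np.sin(omega)
        path = (np.sin((1.0 - t) * omega) * u + np.sin(t * omega) * v) / so
        pts = self._c + path * self._axes  # exactly on the ellipsoid
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
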