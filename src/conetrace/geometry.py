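"""Cone geometry for the WHO cone bioassay arena.

The cone is modelled by its projected silhouette: a convex polygon with the
apex up and the net edge along the base.  Image coordinates are used
throughout the package: ``x`` grows rightward, ``y`` grows *downward*, so the
apex has the smallest ``y`` and the net edge the largest.  ``midline_y``
splits the silhouette into the upper and lower half regions used for
spatial activity assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConeGeometry:
    """Projected cone silhouette inside a video frame.

    Parameters
    ----------
    frame_width, frame_height
        Frame size in pixels.
    cone_outline
        ``(n, 2)`` array of ``(x, y)`` vertices of a convex polygon, apex up.
    net_edge
        ``((x1, y), (x2, y))`` horizontal segment along the cone base where
        the net swatch sits.
    midline_y
        Horizontal line splitting the cone into top and bottom regions;
        strictly between apex and base.
    """

    frame_width: int
    frame_height: int
    cone_outline: np.ndarray
    net_edge: tuple[tuple[float, float], tuple[float, float]]
    midline_y: float
    # cached inward edge normals for the convex point-in-polygon test
    _edge_data: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        outline = np.asarray(self.cone_outline, dtype=float)
        if outline.ndim != 2 or outline.shape[1] != 2 or len(outline) < 3:
            raise ValueError("cone_outline must be an (n, 2) polygon, n >= 3")
        object.__setattr__(self, "cone_outline", outline)
        (x1, y1), (x2, y2) = self.net_edge
        if y1 != y2:
            raise ValueError("net_edge must be horizontal")
        apex_y = outline[:, 1].min()
        base_y = outline[:, 1].max()
        if not np.isclose(y1, base_y):
            raise ValueError("net_edge must lie on the lower boundary of the cone")
        if not (apex_y < self.midline_y < base_y):
            raise ValueError("midline_y must lie strictly between apex and base")
        if outline[:, 0].min() < 0 or outline[:, 0].max() > self.frame_width:
            raise ValueError("cone outline exceeds frame width")
        if outline[:, 1].min() < 0 or outline[:, 1].max() > self.frame_height:
            raise ValueError("cone outline exceeds frame height")
        # signed-area orientation; store edges so that "inside" is cross >= 0
        a = outline
        b = np.roll(outline, -1, axis=0)
        area2 = np.sum(a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1])
        if area2 < 0:  # clockwise in image coords -> flip
            a, b = b, a
        object.__setattr__(self, "_edge_data", np.hstack([a, b - a]))

    # -- queries ---------------------------------------------------------

    @property
    def apex_y(self) -> float:
        return float(self.cone_outline[:, 1].min())

    @property
    def base_y(self) -> float:
        return float(self.net_edge[0][1])

    @property
    def net_x_range(self) -> tuple[float, float]:
        (x1, _), (x2, _) = self.net_edge
        return (min(x1, x2), max(x1, x2))

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Vectorised convex point-in-polygon test.

        ``margin > 0`` shrinks the admissible region away from the walls.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        e = self._edge_data
        ax, ay, dx, dy = e[:, 0], e[:, 1], e[:, 2], e[:, 3]
        norm = np.hypot(dx, dy)
        # cross((d), (p - a)) / |d| = signed distance to the edge line
        px = pts[:, 0][:, None] - ax[None, :]
        py = pts[:, 1][:, None] - ay[None, :]
        cross = (dx[None, :] * py - dy[None, :] * px) / norm[None, :]
        inside = np.all(cross >= margin, axis=1)
        return inside if points.ndim > 1 else inside[0]

    def mask(self) -> np.ndarray:
        """Boolean (H, W) raster of the cone interior."""
        yy, xx = np.mgrid[0 : self.frame_height, 0 : self.frame_width]
        pts = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        return self.contains(pts).reshape(self.frame_height, self.frame_width)

    # -- constructors ----------------------------------------------------

    @classmethod
    def default(
        cls,
        frame_width: int = 160,
        frame_height: int = 192,
        margin_frac: float = 0.08,
    ) -> "ConeGeometry":
        """Standard triangular silhouette: apex up, net edge on the base."""
        mx = margin_frac * frame_width
        my = margin_frac * frame_height
        apex = (frame_width / 2.0, my)
        base_y = frame_height - my
        left = (mx, base_y)
        right = (frame_width - mx, base_y)
        outline = np.array([apex, right, left])
        return cls(
            frame_width=frame_width,
            frame_height=frame_height,
            cone_outline=outline,
            net_edge=(left, right),
            midline_y=(apex[1] + base_y) / 2.0,
        )
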