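"""Workspace geometry of the sequential reaching task.

Four circular targets (1 cm diameter) are arranged around a central "via"
target.  Targets 1 and 4 sit 10 cm above/below the via target on the
y-axis; targets 2 and 3 sit 5 cm from the via target with 126 degrees
between them.  A trial is eight continuous point-to-point reaches that
start in the via target, alternate outward target / via target, and end
back in the via target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Visit order of the eight reaches: each entry is the target ending that
# segment.  Segment k runs from leaving the previous target to leaving
# (or, for the last, entering) this one.
DEFAULT_SEQUENCE: tuple[str, ...] = (
    "T1", "via", "T2", "via", "T3", "via", "T4", "via",
)


@dataclass(frozen=True)
class TargetLayout:
    """Positions (cm) of the via target and the four outer targets."""

    via: tuple[float, float]
    targets: tuple[tuple[float, float], ...]  # T1..T4
    target_diameter: float = 1.0
    start_box_side: float = 2.0
    prep_box_side: float = 2.0

    @property
    def target_radius(self) -> float:
        return self.target_diameter / 2.0

    def point(self, name: str) -> np.ndarray:
        """Centre of a named target ('via' or 'T1'..'T4')."""
        if name == "via":
            return np.asarray(self.via, dtype=float)
        if name.startswith("T"):
            idx = int(name[1:]) - 1
            if 0 <= idx < len(self.targets):
                return np.asarray(self.targets[idx], dtype=float)
        raise KeyError(f"unknown target name: {name!r}")

    def sequence_points(self, sequence: tuple[str, ...] = DEFAULT_SEQUENCE) -> np.ndarray:
        """(n+1, 2) polyline through the reach sequence, starting at via."""
        pts = [self.point("via")] + [self.point(n) for n in sequence]
        return np.vstack(pts)


def make_target_layout(outer_angle_deg: float = 126.0) -> TargetLayout:
    """Build the standard target layout with the via target at the origin.

    T1 = (0, 10), T4 = (0, -10); T2 and T3 lie on the 5 cm circle,
    symmetric about the +y axis with ``outer_angle_deg`` between them.
    """
    half = np.deg2rad(outer_angle_deg) / 2.0
    # angles measured from +y axis
    t2 = (-5.0 * np.sin(half), 5.0 * np.cos(half))
    t3 = (5.0 * np.sin(half), 5.0 * np.cos(half))
    return TargetLayout(
        via=(0.0, 0.0),
        targets=((0.0, 10.0), t2, t3, (0.0, -10.0)),
    )
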