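"""Neuron morphologies as trees of tapered cylindrical segments, with
standard 7-column SWC reading and writing.

A segment runs from a proximal to a distal 3D point (um) with proximal and
distal diameters; regions are ``soma``, ``dendrite`` or ``axon`` (SWC type
codes 1, 2, 3 map to soma, axon, dendrite).  Child segments must begin at
their parent's distal point, which is the representable subset of SWC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Segment", "Morphology", "read_swc", "write_swc"]

REGIONS = ("soma", "axon", "dendrite")
_SWC_TYPE = {"soma": 1, "axon": 2, "dendrite": 3}
_SWC_REGION = {1: "soma", 2: "axon", 3: "dendrite"}


@dataclass
class Segment:
    id: int
    parent: int  # -1 for the root segment
    p0: np.ndarray  # proximal xyz, um
    p1: np.ndarray  # distal xyz, um
    d0: float  # proximal diameter, um
    d1: float  # distal diameter, um
    region: str

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.p0 + self.p1)


@dataclass
class Morphology:
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("morphology has no segments")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        by_id = {s.id: s for s in self.segments}
        roots = [s for s in self.segments if s.parent == -1]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, got {len(roots)}")
        for s in self.segments:
            if s.region not in REGIONS:
                raise ValueError(f"unknown region {s.region!r}")
            if s.d0 <= 0 or s.d1 <= 0:
                raise ValueError(f"segment {s.id}: diameters must be positive")
            if s.length <= 0:
                raise ValueError(f"segment {s.id}: zero or negative length")
            if s.parent != -1 and s.parent not in by_id:
                raise ValueError(f"segment {s.id}: missing parent {s.parent}")
        # cycle check via walk to root
        for s in self.segments:
            seen = set()
            cur = s
            while cur.parent != -1:
                if cur.id in seen:
                    raise ValueError("cycle detected in morphology tree")
                seen.add(cur.id)
                cur = by_id[cur.parent]

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent == -1)

    def by_id(self, sid: int) -> Segment:
        return next(s for s in self.segments if s.id == sid)

    def children(self, sid: int) -> list[Segment]:
        return [s for s in self.segments if s.parent == sid]

    def region_segments(self, region: str) -> list[Segment]:
        return [s for s in self.segments if s.region == region]

    def topological_order(self) -> list[Segment]:
        """Segments ordered with every parent before its children."""
        order: list[Segment] = []
        stack = [self.root]
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(reversed(self.children(s.id)))
        return order

    def total_area(self) -> float:
        """Sum of lateral frustum areas, um^2."""
        return sum(frustum_area(s.length, s.d0 / 2, s.d1 / 2) for s in self.segments)


def frustum_area(length: float, r0: float, r1: float) -> float:
    """Lateral surface area of a conical frustum (slant-height form)."""
    slant = np.hypot(length, r1 - r0)
    return float(np.pi * (r0 + r1) * slant)


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write standard 7-column SWC.  The root segment contributes two nodes
    (proximal with parent -1, then distal); every other segment contributes
    its distal node attached to the parent segment's distal node.  Requires
    child segments to start at their parent's distal point."""
    morph.validate()
    lines = ["# id type x y z radius parent  (written by ionspike)"]
    node_of_segment: dict[int, int] = {}  # segment id -> SWC node id of distal point
    nid = 0
    for s in morph.topological_order():
        t = _SWC_TYPE[s.region]
        if s.parent == -1:
            nid += 1
            root_nid = nid
            lines.append(_swc_line(root_nid, t, s.p0, s.d0 / 2, -1))
            parent_nid = root_nid
        else:
            parent_seg = morph.by_id(s.parent)
            if not np.allclose(s.p0, parent_seg.p1):
                raise ValueError(
                    f"segment {s.id} does not start at parent's distal point; "
                    "not representable in SWC"
                )
            parent_nid = node_of_segment[s.parent]
            if not np.isclose(s.d0, parent_seg.d1):
                # diameter break: repeat the junction point with the child's
                # proximal radius (zero-length node pair, merged on read)
                nid += 1
                lines.append(_swc_line(nid, t, s.p0, s.d0 / 2, parent_nid))
                parent_nid = nid
        nid += 1
        lines.append(_swc_line(nid, t, s.p1, s.d1 / 2, parent_nid))
        node_of_segment[s.id] = nid
    Path(path).write_text("\n".join(lines) + "\n")


def _swc_line(nid, t, p, r, parent) -> str:
    return f"{nid} {t} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {r:.10g} {parent}"


def read_swc(path: str | Path) -> Morphology:
    """Read standard SWC; every non-root node becomes one segment from its
    parent node to itself, with region taken from its own type code."""
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {raw!r}")
        nid = int(parts[0])
        t = int(parts[1])
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        r = float(parts[5])
        parent = int(parts[6])
        if t not in _SWC_REGION:
            raise ValueError(f"unsupported SWC type code {t}")
        nodes[nid] = (t, xyz, r, parent)

    segments = []
    node_to_segment: dict[int, int] = {}
    sid = 0
    for nid in sorted(nodes):
        t, xyz, r, parent = nodes[nid]
        if parent == -1:
            continue
        if parent not in nodes:
            raise ValueError(f"SWC node {nid} references missing parent {parent}")
        pt, pxyz, pr, pparent = nodes[parent]
        parent_sid = node_to_segment.get(parent, -1)
        if np.linalg.norm(xyz - pxyz) < 1e-9:
            # zero-length node pair marking a diameter break: no segment;
            # children inherit this node's radius as their proximal radius
            node_to_segment[nid] = parent_sid
            continue
        segments.append(
            Segment(
                id=sid,
                parent=parent_sid,
                p0=pxyz,
                p1=xyz,
                d0=2 * pr,
                d1=2 * r,
                region=_SWC_REGION[t],
            )
        )
        node_to_segment[nid] = sid
        sid += 1
    return Morphology(segments)
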