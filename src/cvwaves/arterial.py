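"""Reduced distributed arterial tree with terminal Windkessel loads.

The tree is a rooted network of tapered elastic segments (linear wall
law: constant area compliance per unit length) whose leaves are loaded
by three-element Windkessels. Aggregate afterload descriptors — total
vascular resistance (TVR), arterial and terminal compliance (C_A, C_T),
total vascular compliance (TVC = C_A + C_T) and the aortic-root
characteristic impedance Zc — are computed by series/parallel reduction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ArterySegment",
    "TerminalWindkessel",
    "ArterialTree",
    "TreeAggregates",
    "tree_aggregates",
    "scale_tree",
    "MMHG",
    "RHO",
    "NU",
    "FRICTION_COEFF",
]

MMHG = 1333.22  # dyn/cm^2 per mmHg
RHO = 1.05      # blood density, g/mL
NU = 0.035 / RHO  # kinematic viscosity, cm^2/s (mu = 0.035 poise)
# Boundary-layer velocity-profile friction coefficient k: the momentum
# sink is -k*pi*nu*u per unit length (k = 22 for the standard profile).
FRICTION_COEFF = 22.0


class TopologyError(ValueError):
    """Raised when the segment graph is not a valid rooted tree."""


@dataclass(frozen=True)
class ArterySegment:
    """Tapered elastic segment.

    area_compliance is dA/dP per unit length, cm^2/mmHg (numerically
    equal to volume compliance per cm, mL/mmHg/cm), constant along the
    segment (linear elastic wall).
    """

    id: str
    name: str
    length: float                 # cm
    proximal_radius: float        # cm
    distal_radius: float          # cm
    area_compliance: float        # cm^2/mmHg per cm
    wall_friction_coefficient: float = FRICTION_COEFF
    n_grid_nodes: int = 5

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be positive")
        if self.proximal_radius <= 0 or self.distal_radius <= 0:
            raise ValueError(f"segment {self.id}: radii must be positive")
        if self.distal_radius > self.proximal_radius + 1e-12:
            raise ValueError(f"segment {self.id}: expansion not allowed")
        if self.area_compliance <= 0:
            raise ValueError(f"segment {self.id}: compliance must be positive")
        if self.n_grid_nodes < 3:
            raise ValueError(f"segment {self.id}: need >= 3 grid nodes")

    def radius_at(self, x: np.ndarray | float) -> np.ndarray | float:
        """Linearly tapered radius at position x (cm from proximal end)."""
        frac = np.asarray(x, dtype=float) / self.length
        r = self.proximal_radius + (self.distal_radius - self.proximal_radius) * frac
        return float(r) if np.ndim(x) == 0 else r

    def area_at(self, x: np.ndarray | float) -> np.ndarray | float:
        r = self.radius_at(x)
        return np.pi * r ** 2

    def volume_compliance(self) -> float:
        """Total segment compliance, mL/mmHg."""
        return self.area_compliance * self.length

    def poiseuille_resistance(self) -> float:
        """Viscous resistance, mmHg*s/mL, at the mean radius.

        Uses the same boundary-layer friction law as the 1D solver
        (sink -k*pi*nu*u), so that steady-state pressure drops and the
        TVR aggregate are mutually consistent.
        """
        r_mean = 0.5 * (self.proximal_radius + self.distal_radius)
        a_mean = np.pi * r_mean ** 2
        k = self.wall_friction_coefficient
        return k * np.pi * NU * RHO * self.length / (a_mean ** 2) / MMHG

    def char_impedance(self, x: float = 0.0) -> float:
        """Characteristic impedance sqrt(rho/(A*C')) at x, mmHg*s/mL."""
        A = self.area_at(x)
        return float(np.sqrt(RHO / (MMHG * A * self.area_compliance)))

    def wave_speed(self, x: float = 0.0) -> float:
        """Pulse wave speed c = sqrt(A/(rho*C')) at x, cm/s."""
        A = self.area_at(x)
        return float(np.sqrt(A * MMHG / (RHO * self.area_compliance)))


@dataclass(frozen=True)
class TerminalWindkessel:
    """Three-element Windkessel terminating a leaf segment."""

    R1: float           # proximal resistance, mmHg*s/mL
    R2: float           # distal resistance, mmHg*s/mL
    C: float            # compliance, mL/mmHg
    P_out: float = 5.0  # venous outflow pressure, mmHg

    def __post_init__(self) -> None:
        if self.R1 < 0 or self.R2 < 0:
            raise ValueError("Windkessel resistances must be non-negative")
        if self.C <= 0:
            raise ValueError("Windkessel compliance must be positive")


@dataclass
class TreeAggregates:
    """Aggregate afterload descriptors of a tree."""

    TVR: float      # mmHg*s/mL
    C_A: float      # mL/mmHg (segments)
    C_T: float      # mL/mmHg (terminals)
    TVC: float      # mL/mmHg = C_A + C_T
    Zc_root: float  # mmHg*s/mL


@dataclass
class ArterialTree:
    """Rooted tree of segments with Windkessel-loaded leaves.

    ``topology`` maps a segment id to the ordered ids of its children;
    leaves are absent or map to []. ``sites`` maps a measurement-site
    name to ``(segment_id, position_cm_from_proximal_end)``.
    """

    segments: dict[str, ArterySegment]
    topology: dict[str, list[str]]
    terminals: dict[str, TerminalWindkessel]
    sites: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        children = {c for cs in self.topology.values() for c in cs}
        roots = [s for s in self.segments if s not in children]
        if len(roots) != 1:
            raise TopologyError(f"expected a single root, found {roots}")
        return roots[0]

    def children(self, seg_id: str) -> list[str]:
        return list(self.topology.get(seg_id, []))

    def leaves(self) -> list[str]:
        return [s for s in self.segments if not self.topology.get(s)]

    def validate(self) -> None:
        for sid in self.topology:
            if sid not in self.segments:
                raise TopologyError(f"topology references unknown segment {sid}")
            for c in self.topology[sid]:
                if c not in self.segments:
                    raise TopologyError(f"unknown child segment {c}")
        root = self.root  # raises unless unique
        # reachability + acyclicity
        seen: set[str] = set()
        stack = [root]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise TopologyError(f"cycle through segment {sid}")
            seen.add(sid)
            stack.extend(self.children(sid))
        if seen != set(self.segments):
            raise TopologyError(
                f"disconnected segments: {sorted(set(self.segments) - seen)}"
            )
        for leaf in self.leaves():
            if leaf not in self.terminals:
                raise TopologyError(f"leaf {leaf} has no terminal Windkessel")
        for sid in self.terminals:
            if self.topology.get(sid):
                raise TopologyError(f"terminal attached to non-leaf {sid}")
        for name, (sid, pos) in self.sites.items():
            if sid not in self.segments:
                raise TopologyError(f"site {name} on unknown segment {sid}")
            if not (0.0 <= pos <= self.segments[sid].length + 1e-9):
                raise TopologyError(f"site {name} position {pos} outside segment")

    # -- JSON --------------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "segments": [
                {
                    "id": s.id,
                    "name": s.name,
                    "length": s.length,
                    "proximal_radius": s.proximal_radius,
                    "distal_radius": s.distal_radius,
                    "area_compliance": s.area_compliance,
                    "wall_friction_coefficient": s.wall_friction_coefficient,
                    "n_grid_nodes": s.n_grid_nodes,
                }
                for s in self.segments.values()
            ],
            "topology": self.topology,
            "terminals": {
                sid: {"R1": w.R1, "R2": w.R2, "C": w.C, "P_out": w.P_out}
                for sid, w in self.terminals.items()
            },
            "sites": {k: [sid, pos] for k, (sid, pos) in self.sites.items()},
        }
        text = json.dumps(obj, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ArterialTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        for key in ("segments", "topology", "terminals", "sites"):
            if key not in obj:
                raise ValueError(f"tree JSON missing key {key!r}")
        segments = {
            d["id"]: ArterySegment(**d) for d in obj["segments"]
        }
        terminals = {
            sid: TerminalWindkessel(**d) for sid, d in obj["terminals"].items()
        }
        sites = {k: (v[0], float(v[1])) for k, v in obj["sites"].items()}
        return cls(segments=segments, topology=dict(obj["topology"]),
                   terminals=terminals, sites=sites)


# -- aggregate afterload ----------------------------------------------------

def _subtree_resistance(tree: ArterialTree, sid: str) -> float:
    seg = tree.segments[sid]
    r = seg.poiseuille_resistance()
    kids = tree.children(sid)
    if not kids:
        wk = tree.terminals[sid]
        return r + wk.R1 + wk.R2
    inv = sum(1.0 / _subtree_resistance(tree, c) for c in kids)
    return r + 1.0 / inv


def tree_aggregates(tree: ArterialTree) -> TreeAggregates:
    """Series/parallel reduction to TVR, compliance sums and root Zc."""
    tree.validate()
    tvr = _subtree_resistance(tree, tree.root)
    c_a = sum(s.volume_compliance() for s in tree.segments.values())
    c_t = sum(w.C for w in tree.terminals.values())
    zc = tree.segments[tree.root].char_impedance(0.0)
    return TreeAggregates(TVR=tvr, C_A=c_a, C_T=c_t, TVC=c_a + c_t, Zc_root=zc)


def scale_tree(
    tree: ArterialTree,
    compliance_factor: float = 1.0,
    resistance_factor: float = 1.0,
) -> ArterialTree:
    """Scaled copy: compliances (segment and terminal) by one factor,
    terminal resistances by the other; geometry unchanged."""
    if compliance_factor <= 0 or resistance_factor <= 0:
        raise ValueError("scale factors must be positive")
    segments = {
        sid: replace(s, area_compliance=s.area_compliance * compliance_factor)
        for sid, s in tree.segments.items()
    }
    terminals = {
        sid: replace(
            w,
            R1=w.R1 * resistance_factor,
            R2=w.R2 * resistance_factor,
            C=w.C * compliance_factor,
        )
        for sid, w in tree.terminals.items()
    }
    return ArterialTree(
        segments=segments,
        topology={k: list(v) for k, v in tree.topology.items()},
        terminals=terminals,
        sites=dict(tree.sites),
    )
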