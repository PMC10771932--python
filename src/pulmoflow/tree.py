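"""Rooted airway-tree container.

An :class:`AirwayTree` is a rooted branching structure: nodes carry 3D
coordinates (mm) and branches connect a proximal node to a distal node,
carrying lobe label, generation (trachea = 1), Horsfield order (terminals
= 1), diameter and length in mm, and a flag marking whether the branch was
resolved on CT or grown by the volume-filling algorithm.  Topology is
strictly a tree: exactly one root, and every non-root branch starts at its
parent's distal node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Branch", "AirwayTree"]

CENTRAL = "central"


@dataclass
class Branch:
    id: int
    parent: int | None
    prox_node: int
    dist_node: int
    lobe: str  # one of the five lobes, or "central"
    generation: int
    order: int | None  # Horsfield order; None until assigned
    diameter_mm: float
    length_mm: float
    resolved: bool
    region: str | None = None  # optional anatomical label (e.g. "RB4", "BronInt")


@dataclass
class AirwayTree:
    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    branches: dict[int, Branch] = field(default_factory=dict)
    volume_state: str = "TLC"  # "TLC", "FRC" or "interpolated"

    # -- construction ----------------------------------------------------
    def add_node(self, node_id: int, xyz) -> int:
        self.nodes[node_id] = np.asarray(xyz, dtype=float)
        return node_id

    def add_branch(self, branch: Branch) -> Branch:
        if branch.id in self.branches:
            raise ValueError(f"duplicate branch id {branch.id}")
        self.branches[branch.id] = branch
        return branch

    def next_node_id(self) -> int:
        return max(self.nodes, default=-1) + 1

    def next_branch_id(self) -> int:
        return max(self.branches, default=-1) + 1

    # -- topology --------------------------------------------------------
    @property
    def root(self) -> Branch:
        roots = [b for b in self.branches.values() if b.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    def children(self, branch_id: int) -> list[Branch]:
        return [b for b in self.branches.values() if b.parent == branch_id]

    def child_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {bid: [] for bid in self.branches}
        for b in self.branches.values():
            if b.parent is not None:
                out[b.parent].append(b.id)
        return out

    def terminal_ids(self) -> list[int]:
        kids = self.child_map()
        return sorted(bid for bid, ch in kids.items() if not ch)

    def topological_order(self) -> list[int]:
        """Branch ids root-first, every parent before its children."""
        kids = self.child_map()
        order, stack = [], [self.root.id]
        while stack:
            bid = stack.pop()
            order.append(bid)
            stack.extend(sorted(kids[bid], reverse=True))
        return order

    def branch_vector(self, branch_id: int) -> np.ndarray:
        b = self.branches[branch_id]
        return self.nodes[b.dist_node] - self.nodes[b.prox_node]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise ValueError on the first failure."""
        root = self.root  # raises if not exactly one
        seen_dist: set[int] = set()
        for b in self.branches.values():
            if b.prox_node not in self.nodes or b.dist_node not in self.nodes:
                raise ValueError(f"branch {b.id} references missing node")
            if b.diameter_mm <= 0:
                raise ValueError(f"branch {b.id} has nonpositive diameter {b.diameter_mm}")
            if b.length_mm <= 0:
                raise ValueError(f"branch {b.id} has nonpositive length {b.length_mm}")
            if b.generation < 1:
                raise ValueError(f"branch {b.id} has generation {b.generation} < 1")
            if b.dist_node in seen_dist:
                raise ValueError(f"distal node {b.dist_node} shared by two branches")
            seen_dist.add(b.dist_node)
            if b.parent is not None:
                parent = self.branches.get(b.parent)
                if parent is None:
                    raise ValueError(f"branch {b.id} has missing parent {b.parent}")
                if b.prox_node != parent.dist_node:
                    raise ValueError(
                        f"branch {b.id} proximal node {b.prox_node} is not its "
                        f"parent's distal node {parent.dist_node}"
                    )
                if b.generation != parent.generation + 1:
                    raise ValueError(
                        f"branch {b.id} generation {b.generation} != parent + 1"
                    )
        order = self.topological_order()
        if len(order) != len(self.branches):
            raise ValueError("tree is not connected (unreachable branches exist)")
        kids = self.child_map()
        for bid in self.terminal_ids():
            if self.branches[bid].lobe == CENTRAL:
                raise ValueError(f"terminal branch {bid} lacks a lobe label")
        del root, kids

    # -- serialization ---------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [(nid, *xyz) for nid, xyz in sorted(self.nodes.items())],
            columns=["id", "x", "y", "z"],
        )
        branches = pd.DataFrame(
            [
                (
                    b.id,
                    -1 if b.parent is None else b.parent,
                    b.prox_node,
                    b.dist_node,
                    b.lobe,
                    b.generation,
                    -1 if b.order is None else b.order,
                    b.diameter_mm,
                    b.length_mm,
                    int(b.resolved),
                    "" if b.region is None else b.region,
                )
                for b in sorted(self.branches.values(), key=lambda b: b.id)
            ],
            columns=[
                "id", "parent", "prox_node", "dist_node", "lobe", "generation",
                "order", "diameter_mm", "length_mm", "resolved", "region",
            ],
        )
        return nodes, branches

    def write(self, directory, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes, branches = self.to_frames()
        nodes.to_csv(directory / f"{prefix}nodes.csv", index=False)
        branches.to_csv(directory / f"{prefix}branches.csv", index=False)
        meta = {"volume_state": self.volume_state, "n_nodes": len(self.nodes),
                "n_branches": len(self.branches)}
        (directory / f"{prefix}tree.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, branches: pd.DataFrame,
                    volume_state: str = "TLC") -> "AirwayTree":
        tree = cls(volume_state=volume_state)
        for row in nodes.itertuples():
            tree.add_node(int(row.id), (row.x, row.y, row.z))
        for row in branches.itertuples():
            region = getattr(row, "region", "")
            tree.add_branch(Branch(
                id=int(row.id),
                parent=None if int(row.parent) < 0 else int(row.parent),
                prox_node=int(row.prox_node),
                dist_node=int(row.dist_node),
                lobe=str(row.lobe),
                generation=int(row.generation),
                order=None if int(row.order) < 0 else int(row.order),
                diameter_mm=float(row.diameter_mm),
                length_mm=float(row.length_mm),
                resolved=bool(row.resolved),
                region=None if (isinstance(region, float) or region == "") else str(region),
            ))
        return tree

    @classmethod
    def read(cls, directory, prefix: str = "") -> "AirwayTree":
        directory = Path(directory)
        meta_path = directory / f"{prefix}tree.json"
        state = "TLC"
        if meta_path.exists():
            state = json.loads(meta_path.read_text()).get("volume_state", "TLC")
        return cls.from_frames(
            pd.read_csv(directory / f"{prefix}nodes.csv", float_precision="round_trip"),
            pd.read_csv(directory / f"{prefix}branches.csv", float_precision="round_trip"),
            volume_state=state,
        )

    def copy(self) -> "AirwayTree":
        out = AirwayTree(volume_state=self.volume_state)
        out.nodes = {nid: xyz.copy() for nid, xyz in self.nodes.items()}
        out.branches = {bid: replace(b) for bid, b in self.branches.items()}
        return out
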