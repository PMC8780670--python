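"""Directed cell-group communication networks from expressed ligand-receptor pairs.

An edge (sender, receiver) carries every database pair whose ligand is
expressed (detection fraction strictly above the threshold) in the sender
group and whose receptor is expressed in the receiver group, within one
condition. All ordered group pairs are evaluated, including self-loops
(communication within a group). Cross-condition diffs attribute each changed
pair to the side whose expression crossed the threshold: the motivating
biological pattern is a hub receptor (e.g. integrin-beta1) whose loss in one
receiver cell type silences many ligands at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .expression import GroupExpressionProfile
from .lr_database import LRDatabase

__all__ = [
    "CommunicationNetwork",
    "EdgeChange",
    "NetworkDiff",
    "build_network",
    "broadcast_summary",
    "diff_networks",
    "subnetwork",
]

Edge = tuple[str, str]
Pair = tuple[str, str]


@dataclass(frozen=True)
class CommunicationNetwork:
    """Per-condition directed multigraph over cell groups.

    ``edges`` maps (sender, receiver) to the sorted tuple of realized
    (ligand, receptor) pairs; edges with empty payload are not stored.
    """

    condition: str
    grouping: str
    groups: tuple[str, ...]
    edges: dict[Edge, tuple[Pair, ...]]

    @property
    def total_pairs(self) -> int:
        """Sum of payload sizes over all edges — the study's per-condition n."""
        return sum(len(p) for p in self.edges.values())

    def payload(self, sender: str, receiver: str) -> tuple[Pair, ...]:
        return self.edges.get((sender, receiver), ())

    def edge_counts(self) -> pd.DataFrame:
        """Dense sender x receiver table of payload sizes."""
        out = pd.DataFrame(0, index=list(self.groups), columns=list(self.groups))
        for (s, r), pairs in self.edges.items():
            out.at[s, r] = len(pairs)
        return out

    def to_edge_list(self) -> pd.DataFrame:
        """Long-format edge list: condition, sender, receiver, ligand, receptor."""
        rows = [
            (self.condition, s, r, lig, rec)
            for (s, r) in sorted(self.edges)
            for (lig, rec) in self.edges[(s, r)]
        ]
        return pd.DataFrame(rows, columns=["condition", "sender", "receiver", "ligand", "receptor"])

    def summary_json(self) -> str:
        counts = {f"{s}->{r}": len(p) for (s, r), p in sorted(self.edges.items())}
        bs = broadcast_summary(self)
        return json.dumps(
            {
                "condition": self.condition,
                "grouping": self.grouping,
                "total_pairs": self.total_pairs,
                "edge_counts": counts,
                "broadcast_summary": {
                    g: {"ligand_count": int(bs.at[g, "ligand_count"]),
                        "receptor_count": int(bs.at[g, "receptor_count"])}
                    for g in bs.index
                },
            },
            indent=2,
        )


def build_network(
    profile: GroupExpressionProfile,
    db: LRDatabase,
    condition: str,
    threshold: float = 0.20,
) -> CommunicationNetwork:
    """Build the communication network for one condition.

    The payload of edge (s, r) is every database pair (L, R) with
    ``fraction(L, s, condition) > threshold`` and
    ``fraction(R, r, condition) > threshold``.
    """
    if len(db) == 0:
        raise ValueError("ligand-receptor database is empty")
    groups = tuple(profile.groups(condition))
    expressed = {g: profile.expressed_genes(g, condition, threshold) for g in groups}
    pairs = sorted({p.key for p in db})
    edges: dict[Edge, tuple[Pair, ...]] = {}
    for s in groups:
        expr_s = expressed[s]
        realized_ligand = [(lig, rec) for (lig, rec) in pairs if lig in expr_s]
        for r in groups:
            expr_r = expressed[r]
            payload = tuple(p for p in realized_ligand if p[1] in expr_r)
            if payload:
                edges[(s, r)] = payload
    return CommunicationNetwork(condition=condition, grouping=profile.grouping, groups=groups, edges=edges)


def broadcast_summary(net: CommunicationNetwork, unit: str = "genes") -> pd.DataFrame:
    """Per-group counts of ligands broadcast and receptors received in realized pairs.

    ``unit="genes"`` (default) counts unique genes: a ligand appearing in many
    realized pairs counts once per sender. ``unit="pair_slots"`` counts
    pair occurrences instead, i.e. the number of realized pairs the group
    participates in on each side.
    """
    if unit not in ("genes", "pair_slots"):
        raise ValueError("unit must be 'genes' or 'pair_slots'")
    lig: dict[str, set[Pair] | set[str]] = {g: set() for g in net.groups}
    rec: dict[str, set[Pair] | set[str]] = {g: set() for g in net.groups}
    lig_n = {g: 0 for g in net.groups}
    rec_n = {g: 0 for g in net.groups}
    for (s, r), payload in net.edges.items():
        if unit == "genes":
            lig[s].update(L for (L, _) in payload)
            rec[r].update(R for (_, R) in payload)
        else:
            lig_n[s] += len(payload)
            rec_n[r] += len(payload)
    if unit == "genes":
        data = {g: (len(lig[g]), len(rec[g])) for g in net.groups}
    else:
        data = {g: (lig_n[g], rec_n[g]) for g in net.groups}
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["ligand_count", "receptor_count"]
    ).rename_axis(net.grouping)


@dataclass(frozen=True)
class EdgeChange:
    """One ligand-receptor pair that appears or disappears on a directed edge."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    direction: str  # "lost" (in A not B) | "gained" (in B not A)
    attribution: str  # "ligand_side" | "receptor_side" | "both_sides"


@dataclass
class NetworkDiff:
    """All per-edge pair changes between two same-grouping networks (A -> B)."""

    condition_a: str
    condition_b: str
    grouping: str
    changes: list[EdgeChange] = field(default_factory=list)

    def lost(self, sender: str | None = None, receiver: str | None = None) -> list[EdgeChange]:
        return self._select("lost", sender, receiver)

    def gained(self, sender: str | None = None, receiver: str | None = None) -> list[EdgeChange]:
        return self._select("gained", sender, receiver)

    def _select(self, direction: str, sender: str | None, receiver: str | None) -> list[EdgeChange]:
        return [
            c
            for c in self.changes
            if c.direction == direction
            and (sender is None or c.sender == sender)
            and (receiver is None or c.receiver == receiver)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.sender, c.receiver, c.ligand, c.receptor, c.direction, c.attribution)
                for c in self.changes
            ],
            columns=["sender", "receiver", "ligand", "receptor", "direction", "attribution"],
        )


def _attribute(
    lig_expressed_other: bool, rec_expressed_other: bool
) -> str:
    # For a lost pair: which side(s) fell below the threshold on the other
    # condition. Gains use the same rule with conditions swapped.
    if not lig_expressed_other and rec_expressed_other:
        return "ligand_side"
    if lig_expressed_other and not rec_expressed_other:
        return "receptor_side"
    return "both_sides"


def diff_networks(
    a: CommunicationNetwork,
    b: CommunicationNetwork,
    profile_a: GroupExpressionProfile,
    profile_b: GroupExpressionProfile,
    threshold: float = 0.20,
) -> NetworkDiff:
    """Pairwise diff of two networks with per-change attribution.

    A pair lost going A -> B is attributed ``ligand_side`` if the ligand's
    detection fraction fell to <= threshold in the sender under B while the
    receptor stayed expressed in the receiver, ``receptor_side`` for the
    converse, and ``both_sides`` if both fell. Gains are attributed
    mirror-symmetrically (which side rose under B).
    """
    if a.grouping != b.grouping:
        raise ValueError(f"grouping mismatch: {a.grouping!r} vs {b.grouping!r}")
    if set(a.groups) != set(b.groups):
        raise ValueError("the two networks cover different group sets")
    diff = NetworkDiff(condition_a=a.condition, condition_b=b.condition, grouping=a.grouping)
    all_edges = sorted(set(a.edges) | set(b.edges))
    for (s, r) in all_edges:
        pa = set(a.payload(s, r))
        pb = set(b.payload(s, r))
        for (lig, rec) in sorted(pa - pb):
            attr = _attribute(
                profile_b.fraction(lig, s, b.condition) > threshold,
                profile_b.fraction(rec, r, b.condition) > threshold,
            )
            diff.changes.append(EdgeChange(s, r, lig, rec, "lost", attr))
        for (lig, rec) in sorted(pb - pa):
            attr = _attribute(
                profile_a.fraction(lig, s, a.condition) > threshold,
                profile_a.fraction(rec, r, a.condition) > threshold,
            )
            diff.changes.append(EdgeChange(s, r, lig, rec, "gained", attr))
    return diff


def subnetwork(net: CommunicationNetwork, groups: Iterable[str]) -> CommunicationNetwork:
    """Restrict a network to edges whose sender and receiver both lie in ``groups``."""
    keep = tuple(g for g in net.groups if g in set(groups))
    unknown = set(groups) - set(net.groups)
    if unknown:
        raise KeyError(f"unknown groups {sorted(unknown)}")
    if not keep:
        raise ValueError("group subset must be non-empty")
    edges = {
        (s, r): payload
        for (s, r), payload in net.edges.items()
        if s in keep and r in keep
    }
    return CommunicationNetwork(
        condition=net.condition, grouping=net.grouping, groups=keep, edges=edges
    )
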