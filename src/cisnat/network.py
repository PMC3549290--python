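"""Sense-antisense networks: grouping cis-NAT pairs into connected components.

Most cis-NAT pairs are one-to-one (each member has exactly one antisense
partner).  When a transcript has several partners the pairs chain into a
many-to-many group; groups are typed by their strand-wise member counts
(one-to-two, one-to-three, two-to-two, ...) and one-to-two groups carry a
subtype naming the unordered combination of their two pairs' orientations.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .core import CisNatGroup, CisNatPair, ValidationError

_SPELLED = {1: "one", 2: "two", 3: "three", 4: "four"}


def _type_label(n_plus: int, n_minus: int) -> str:
    a, b = sorted((n_plus, n_minus))
    sa = _SPELLED.get(a, str(a))
    sb = _SPELLED.get(b, str(b))
    return f"{sa}-to-{sb}"


def build_groups(pairs: Iterable[CisNatPair]) -> list[CisNatGroup]:
    """Connected components of the transcript/pair graph.

    Vertices are transcripts, edges are pairs.  Components are returned in a
    deterministic order (sorted by smallest member id); two-vertex components
    are the one-to-one pairs.
    """
    graph = nx.Graph()
    strand_of: dict[str, str] = {}
    for p in pairs:
        graph.add_edge(p.plus_transcript, p.minus_transcript, pair=p)
        strand_of[p.plus_transcript] = "+"
        strand_of[p.minus_transcript] = "-"
    groups: list[CisNatGroup] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for idx, comp in enumerate(components, start=1):
        members = sorted(comp)
        comp_pairs = sorted(
            (graph.edges[u, v]["pair"] for u, v in graph.subgraph(comp).edges),
            key=lambda p: (p.plus_transcript, p.minus_transcript),
        )
        n_plus = sum(1 for m in members if strand_of[m] == "+")
        n_minus = len(members) - n_plus
        group = CisNatGroup(
            group_id=f"G{idx:04d}",
            transcripts=members,
            pairs=comp_pairs,
            n_plus=n_plus,
            n_minus=n_minus,
            group_type=_type_label(n_plus, n_minus),
        )
        if group.group_type == "one-to-two":
            group.subtype = subtype_one_to_two(group)
        groups.append(group)
    return groups


def classify_group(group: CisNatGroup) -> str:
    """Type label from strand-wise transcript counts (min-to-max)."""
    return _type_label(group.n_plus, group.n_minus)


def subtype_one_to_two(group: CisNatGroup) -> str:
    """Unordered orientation combination of a one-to-two group's two pairs."""
    if sorted((group.n_plus, group.n_minus)) != [1, 2] or len(group.pairs) != 2:
        raise ValidationError(
            f"group {group.group_id} is not one-to-two "
            f"({group.n_plus}+/{group.n_minus}-, {len(group.pairs)} pairs)"
        )
    rank = {o: i for i, o in enumerate(("enclosed", "convergent", "divergent"))}
    orientations = sorted((p.orientation for p in group.pairs), key=rank.__getitem__)
    return "+".join(orientations)


def split_one_to_one(
    groups: Iterable[CisNatGroup],
) -> tuple[list[CisNatGroup], list[CisNatGroup]]:
    """Separate one-to-one pairs from many-to-many groups."""
    ones, many = [], []
    for g in groups:
        (ones if g.group_type == "one-to-one" else many).append(g)
    return ones, many


def groups_to_table(groups: Iterable[CisNatGroup]):
    import pandas as pd

    rows = [
        {
            "group_id": g.group_id,
            "group_type": g.group_type,
            "subtype": g.subtype or "",
            "n_transcripts": len(g.transcripts),
            "n_pairs": len(g.pairs),
            "transcripts": ";".join(g.transcripts),
            "pairs": ";".join(p.pair_id for p in g.pairs),
        }
        for g in groups
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "group_type", "subtype",
            "n_transcripts", "n_pairs", "transcripts", "pairs",
        ],
    )
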