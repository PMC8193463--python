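"""Directed-triad (3-node graphlet) taxonomy.

A triple of nodes in a simple digraph induces one of 64 ordered edge
configurations; collapsing node permutations and discarding disconnected
cases leaves the 13 weakly connected directed-triad isomorphism classes of
the standard triad census. Each class is identified here by the minimum
6-bit edge code over the 6 node permutations, labelled with its
conventional census name (e.g. 030T is the feed-forward loop, 030C the
3-cycle).
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Set, Tuple

# bit k of a triple's code is set when the ordered pair _EDGE_BITS[k] is an edge
_EDGE_BITS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))

#: canonical (minimum) code -> standard triad census label, connected classes only
TRIAD_NAMES: Dict[int, str] = {
    5: "021D",
    6: "021C",
    7: "111U",
    10: "021U",
    11: "111D",
    15: "201",
    21: "030T",
    23: "120U",
    25: "030C",
    27: "120C",
    30: "120D",
    31: "210",
    63: "300",
}


def code_of(edges: FrozenSet[Tuple[int, int]]) -> int:
    """6-bit code of an ordered triple's edge set (pairs over {0,1,2})."""
    return sum(1 << k for k, pair in enumerate(_EDGE_BITS) if pair in edges)


def _edges_of(code: int) -> Set[Tuple[int, int]]:
    return {_EDGE_BITS[k] for k in range(6) if code >> k & 1}


def _is_connected(code: int) -> bool:
    edges = _edges_of(code)
    if not edges:
        return False
    adj = {i: set() for i in range(3)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        for v in adj[stack.pop()]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == 3


def _build_tables() -> Tuple[Tuple[int, ...], Tuple[bool, ...]]:
    canon = []
    connected = []
    for code in range(64):
        edges = _edges_of(code)
        best = min(
            code_of(frozenset((p[i], p[j]) for i, j in edges))
            for p in itertools.permutations(range(3))
        )
        canon.append(best)
        connected.append(_is_connected(code))
    return tuple(canon), tuple(connected)


#: code -> canonical class code / weak-connectivity flag, for all 64 configs
CANONICAL_CODE, IS_CONNECTED = _build_tables()

#: the 13 canonical class codes in ascending order
CONNECTED_CLASSES: Tuple[int, ...] = tuple(sorted(TRIAD_NAMES))


def classify(code: int) -> int:
    """Canonical class code of an ordered-triple configuration.

    Raises for disconnected configurations — only weakly connected triples
    count as graphlet instances.
    """
    if not IS_CONNECTED[code]:
        raise ValueError(f"triple configuration {code:#08b} is not weakly connected")
    return CANONICAL_CODE[code]


def class_name(class_code: int) -> str:
    return TRIAD_NAMES[class_code]
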