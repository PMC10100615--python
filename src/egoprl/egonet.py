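"""Ego-network survey parsing and the seven analysis features.

An ego (the surveyed participant) lists alters (members of their personal
network), flags each ego-alter tie as weak ("not especially close") or
strong ("especially close"), rates each alter-alter relationship as
stranger / weak / strong, assigns each alter a kinship category, and
attributes to each alter responses to the five general-conspiracy items
(1-5 scale).  From these we compute:

size, strong ties, density, degree centralization, Burt constraint,
kinship proportion, and the assumed-shared-belief score

    B = sum_j  w_j * (a_j / e)

where ``a_j`` is the mean belief the ego attributes to alter ``j``, ``e``
the ego's own mean belief, and ``w_j`` a tie-strength weight in (0, 1).
Larger B means the ego assumes a larger, closer circle of like-minded
contacts.  The similarity ratio is deliberately asymmetric and unbounded
above; B is a weighted *sum*, so it grows with network size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Alter",
    "EgoNetwork",
    "NetworkFeatures",
    "ASBWeights",
    "ParseResult",
    "NetworkDataError",
    "ALTER_CAP",
    "FAMILY_KINSHIP",
    "parse_network_files",
    "density",
    "degree_centralization",
    "burt_constraint",
    "kinship_proportion",
    "asb_score",
    "compute_features",
]

logger = logging.getLogger(__name__)

#: Alter-alter ties are only recorded among the first this-many listed alters.
ALTER_CAP = 15

EGO_ALTER_TIES = ("weak", "strong")
ALTER_ALTER_TIES = ("stranger", "weak", "strong")
KINSHIP_CATEGORIES = ("parent", "sibling", "spouse", "friend", "advisor", "coworker")
FAMILY_KINSHIP = frozenset({"parent", "sibling", "spouse"})


class NetworkDataError(ValueError):
    """Row-level survey data error (bad tie label, off-scale response...)."""


@dataclass(frozen=True)
class Alter:
    alter_id: str
    tie: str                       # ego-alter: weak | strong
    kinship: str
    items: Tuple[int, ...]         # five attributed general-conspiracy responses, 1..5

    def __post_init__(self) -> None:
        if self.tie not in EGO_ALTER_TIES:
            raise NetworkDataError(f"unknown ego-alter tie {self.tie!r}")
        if self.kinship not in KINSHIP_CATEGORIES:
            raise NetworkDataError(f"unknown kinship category {self.kinship!r}")
        for v in self.items:
            if not 1 <= v <= 5:
                raise NetworkDataError(f"attributed response {v} off the 1-5 scale")

    @property
    def item_mean(self) -> float:
        return float(np.mean(self.items))


@dataclass
class EgoNetwork:
    """One ego's reported network.

    ``alter_alter`` maps unordered alter-id pairs to a tie strength;
    'stranger' means the pair do not know each other (no edge for binary
    metrics).  Pairs are only defined among the first :data:`ALTER_CAP`
    listed alters.
    """

    ego_id: str
    alters: List[Alter]
    alter_alter: Dict[FrozenSet[str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.alter_id for a in self.alters]
        if len(set(ids)) != len(ids):
            raise NetworkDataError(f"duplicate alter names for ego {self.ego_id!r}")
        capped = set(ids[:ALTER_CAP])
        for pair, strength in self.alter_alter.items():
            if strength not in ALTER_ALTER_TIES:
                raise NetworkDataError(f"unknown alter-alter tie {strength!r}")
            if not pair <= capped:
                raise NetworkDataError(
                    f"alter-alter tie {sorted(pair)} outside the first {ALTER_CAP} alters"
                )

    @property
    def size(self) -> int:
        return len(self.alters)

    def alter_graph(self) -> nx.Graph:
        """Alters-only binary graph (weak and strong ties are edges)."""
        g = nx.Graph()
        g.add_nodes_from(a.alter_id for a in self.alters)
        for pair, strength in self.alter_alter.items():
            if strength != "stranger":
                g.add_edge(*sorted(pair))
        return g

    def ego_graph(self) -> nx.Graph:
        """Ego-inclusive binary graph; ego is adjacent to every alter."""
        g = self.alter_graph()
        g.add_node(self.ego_id)
        for a in self.alters:
            g.add_edge(self.ego_id, a.alter_id)
        return g


@dataclass
class NetworkFeatures:
    """The seven per-ego analysis features; NaN marks undefined values."""

    size: int
    strong_ties: int
    density: float
    centralization: float
    constraint: float
    kinship: float
    asb: float


@dataclass(frozen=True)
class ASBWeights:
    """Tie-strength weights for the assumed-shared-belief sum, each in (0, 1)."""

    strong: float = 0.75
    weak: float = 0.25

    def __post_init__(self) -> None:
        for w in (self.strong, self.weak):
            if not 0.0 < w < 1.0:
                raise ValueError("tie-strength weights must lie in (0, 1)")


@dataclass
class ParseResult:
    networks: List[EgoNetwork]
    excluded: Dict[str, str]       # ego_id -> reason
    n_edges_dropped: int = 0


def density(net: EgoNetwork) -> float:
    """Existing alter-alter ties over possible pairs; NaN for < 2 alters.

    Ego-alter ties exist by construction and are excluded; 'stranger'
    ratings are absent edges.
    """
    a = net.size
    if a < 2:
        return math.nan
    present = sum(1 for s in net.alter_alter.values() if s != "stranger")
    return present / (a * (a - 1) / 2)


def degree_centralization(net: EgoNetwork) -> float:
    """Freeman degree centralization of the ego-inclusive graph.

    ``sum(d_max - d_i) / ((n - 1)(n - 2))``: 1 for a star on the ego
    (no alter knows any other), 0 when all degrees are equal.  NaN for
    fewer than 3 nodes, where the index is undefined.
    """
    g = net.ego_graph()
    n = g.number_of_nodes()
    if n < 3:
        return math.nan
    degrees = np.array([d for _, d in g.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def burt_constraint(net: EgoNetwork) -> float:
    """Burt's structural-holes constraint of the ego in the ego-inclusive graph.

    ``C = sum_j (p_j + sum_q p_q p_qj)^2`` over the ego's contacts ``j``,
    with proportional tie allocations ``p`` on the binary graph.  The ego is
    most constrained (C high) when its contacts are few and interconnected;
    a dyad gives 1 and a star over k alters gives 1/k.  NaN with no alters.
    """
    if net.size == 0:
        return math.nan
    g = net.ego_graph()
    return float(nx.constraint(g, nodes=[net.ego_id])[net.ego_id])


def kinship_proportion(net: EgoNetwork) -> float:
    """Share of alters who are family (parent, sibling, spouse); NaN if empty."""
    if net.size == 0:
        return math.nan
    fam = sum(1 for a in net.alters if a.kinship in FAMILY_KINSHIP)
    return fam / net.size


def asb_score(
    net: EgoNetwork,
    ego_general_items: Sequence[float],
    weights: ASBWeights = ASBWeights(),
) -> float:
    """Assumed shared belief: tie-weighted sum of attributed/own belief ratios.

    ``sum_j w_j * (a_j / e)`` with ``a_j`` the mean response attributed to
    alter j, ``e`` the ego's own mean response (>= 1 on the 1-5 scale, so the
    ratio is well defined), and ``w_j`` the weight of the ego-alter tie.
    An empty network scores 0.
    """
    items = np.asarray(ego_general_items, dtype=float)
    if np.any(items < 1) or np.any(items > 5):
        raise NetworkDataError("ego general-conspiracy items must lie in 1..5")
    if net.size == 0:
        return 0.0
    e = float(items.mean())
    w = {"strong": weights.strong, "weak": weights.weak}
    return float(sum(w[a.tie] * (a.item_mean / e) for a in net.alters))


def compute_features(
    net: EgoNetwork,
    ego_general_items: Sequence[float],
    weights: ASBWeights = ASBWeights(),
) -> NetworkFeatures:
    """Assemble the seven analysis features for one ego."""
    return NetworkFeatures(
        size=net.size,
        strong_ties=sum(1 for a in net.alters if a.tie == "strong"),
        density=density(net),
        centralization=degree_centralization(net),
        constraint=burt_constraint(net),
        kinship=kinship_proportion(net),
        asb=asb_score(net, ego_general_items, weights),
    )


_ITEM_COLS = [f"attr_item{i}" for i in range(1, 6)]


def parse_network_files(edges_path, alters_path) -> ParseResult:
    """Read the survey CSVs into validated :class:`EgoNetwork` objects.

    ``alters_path`` holds one row per (ego, alter): ego_id, alter_id, tie,
    kinship and the five attributed responses; listing order defines the
    alter-cap window.  ``edges_path`` holds alter-alter rows: ego_id,
    node_a, node_b, strength.  Egos who listed the same alter name twice
    are excluded (their reported structure cannot be reconstructed), and
    alter-alter edges beyond the first :data:`ALTER_CAP` alters are dropped
    with a warning; both are tallied in the returned :class:`ParseResult`.
    """
    alters_df = pd.read_csv(alters_path, dtype={"ego_id": str, "alter_id": str})
    edges_df = pd.read_csv(edges_path, dtype={"ego_id": str, "node_a": str, "node_b": str})
    for col in ("ego_id", "alter_id", "tie", "kinship", *_ITEM_COLS):
        if col not in alters_df.columns:
            raise NetworkDataError(f"alters file missing column {col!r}")
    for col in ("ego_id", "node_a", "node_b", "strength"):
        if col not in edges_df.columns:
            raise NetworkDataError(f"edges file missing column {col!r}")

    excluded: Dict[str, str] = {}
    networks: List[EgoNetwork] = []
    n_dropped = 0
    edges_by_ego = dict(tuple(edges_df.groupby("ego_id", sort=False)))

    for ego_id, grp in alters_df.groupby("ego_id", sort=False):
        ids = grp["alter_id"].tolist()
        if len(set(ids)) != len(ids):
            excluded[ego_id] = "duplicate alter names"
            logger.warning("ego %s excluded: duplicate alter names", ego_id)
            continue
        try:
            alters = [
                Alter(
                    alter_id=row.alter_id,
                    tie=row.tie,
                    kinship=row.kinship,
                    items=tuple(int(getattr(row, c)) for c in _ITEM_COLS),
                )
                for row in grp.itertuples(index=False)
            ]
            capped = set(ids[:ALTER_CAP])
            alter_alter: Dict[FrozenSet[str], str] = {}
            for row in edges_by_ego.get(ego_id, pd.DataFrame(columns=edges_df.columns)).itertuples(index=False):
                pair = frozenset((row.node_a, row.node_b))
                if len(pair) != 2 or not pair <= set(ids):
                    raise NetworkDataError(
                        f"edge {sorted(pair)} references unknown alters for ego {ego_id}"
                    )
                if not pair <= capped:
                    n_dropped += 1
                    logger.warning(
                        "ego %s: dropping edge %s beyond the first %d alters",
                        ego_id, sorted(pair), ALTER_CAP,
                    )
                    continue
                alter_alter[pair] = row.strength
            networks.append(EgoNetwork(ego_id=ego_id, alters=alters, alter_alter=alter_alter))
        except NetworkDataError:
            raise
    return ParseResult(networks=networks, excluded=excluded, n_edges_dropped=n_dropped)
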