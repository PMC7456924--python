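"""LSU interaction-network hub analysis.

The network is an undirected simple graph over protein identifiers with two
designated node sets: the four LSU baits, and the LSU partners (direct LSU
interactors — "the LSU interactome").  For every other connected node the
hub statistic is the ratio of its neighbors inside the partner set
(degree.LSU) to its total neighbor count (degree.total); nodes most enriched
in partner interactions are selected as hubs and then ordered by their
absolute number of partner interactions (degree.LSU), mirroring how such
hubs are reported.

Bait nodes are excluded from hub candidacy and from degree.LSU counting:
they define the partner set rather than belong to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 9
#: Smallest partner-degree worth reporting as a hub.
DEFAULT_MIN_DEGREE_LSU = 10


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected simple graph with designated bait and partner node sets."""

    graph: nx.Graph = field(repr=False)
    baits: frozenset[str] = frozenset()
    partners: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.baits & self.partners
        if overlap:
            raise ValidationError(
                f"nodes cannot be both bait and partner: {sorted(overlap)}"
            )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        baits: Iterable[str] = (),
        partners: Iterable[str] | None = None,
    ) -> "InteractionNetwork":
        """Build from an edge iterable, dropping self-loops and duplicates.

        When ``partners`` is omitted it defaults to the direct neighbors of
        the baits (minus the baits themselves).
        """
        graph = nx.Graph()
        n_loops = 0
        for a, b in edges:
            if a == b:
                n_loops += 1
                continue
            graph.add_edge(a, b)
        if n_loops:
            logger.info("dropped %d self-loop edges", n_loops)
        baits = frozenset(baits)
        if partners is None:
            derived: set[str] = set()
            for bait in baits:
                if bait in graph:
                    derived.update(graph.neighbors(bait))
            partners = derived - baits
        return cls(graph=graph, baits=baits, partners=frozenset(partners))


def _read_node_set(path: str | Path) -> frozenset[str]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"node-set file not found: {path}")
    return frozenset(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )


def read_edge_list(
    path: str | Path,
    baits_path: str | Path | None = None,
    partners_path: str | Path | None = None,
) -> InteractionNetwork:
    """Read a TSV (two columns) or SIF (node type node [node...]) edge file.

    Duplicate edges and both-orientation listings collapse to one edge;
    self-loops are dropped with a logged count; a malformed row raises an
    error naming its line number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge list not found: {path}")
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 2:
            edges.append((tokens[0], tokens[1]))
        elif len(tokens) >= 3:
            # SIF: source, interaction type, one or more targets
            edges.extend((tokens[0], target) for target in tokens[2:])
        else:
            raise ValidationError(f"{path}: malformed edge row at line {lineno}")
    baits = _read_node_set(baits_path) if baits_path else frozenset()
    partners = _read_node_set(partners_path) if partners_path else None
    return InteractionNetwork.from_edges(edges, baits=baits, partners=partners)


def hub_scores(net: InteractionNetwork) -> pd.DataFrame:
    """degree.total, degree.LSU and their ratio per non-bait connected node.

    Isolated nodes are excluded (the ratio is undefined for them); output is
    sorted by node id, so the frame is independent of graph insertion order.
    """
    if net.n_nodes == 0:
        raise ValidationError("hub_scores requires a non-empty network")
    rows = []
    for node in net.graph.nodes:
        if node in net.baits:
            continue
        neighbors = set(net.graph.neighbors(node))
        degree_total = len(neighbors)
        if degree_total == 0:
            continue
        degree_lsu = len(neighbors & net.partners)
        rows.append(
            {
                "node": node,
                "degree_total": degree_total,
                "degree_lsu": degree_lsu,
                "ratio": degree_lsu / degree_total,
            }
        )
    return (
        pd.DataFrame.from_records(
            rows, columns=["node", "degree_total", "degree_lsu", "ratio"]
        )
        .sort_values("node")
        .reset_index(drop=True)
    )


def rank_hubs(
    scores: pd.DataFrame,
    k: int = DEFAULT_TOP_K,
    min_degree_lsu: int = DEFAULT_MIN_DEGREE_LSU,
    select_by: str = "ratio",
) -> pd.DataFrame:
    """Select the top-k hubs and order them for reporting.

    Nodes with degree.LSU below ``min_degree_lsu`` are filtered out, the
    top-k are selected by partner-interaction enrichment (``select_by =
    "ratio"``, the default) or by raw partner degree (``"degree_lsu"``), and
    the selection is then ordered by degree.LSU descending.  All ties break
    by node id, so the output is deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if select_by not in ("ratio", "degree_lsu"):
        raise ValidationError(f"select_by must be 'ratio' or 'degree_lsu', got {select_by!r}")
    eligible = scores.loc[scores["degree_lsu"] >= min_degree_lsu].copy()
    selected = eligible.sort_values(
        [select_by, "degree_lsu", "node"], ascending=[False, False, True]
    ).head(k)
    return selected.sort_values(
        ["degree_lsu", "node"], ascending=[False, True]
    ).reset_index(drop=True)


def hub_membership_counts(
    net: InteractionNetwork, hubs: Sequence[str]
) -> pd.DataFrame:
    """For each partner node, the number of selected hubs it touches."""
    unknown = set(hubs) - set(net.graph.nodes)
    if unknown:
        raise ValidationError(f"hub nodes not in network: {sorted(unknown)}")
    hub_set = set(hubs)
    rows = []
    for partner in sorted(net.partners):
        if partner not in net.graph:
            count = 0
        else:
            count = len(set(net.graph.neighbors(partner)) & hub_set)
        rows.append({"partner": partner, "n_hubs": count})
    return pd.DataFrame.from_records(rows, columns=["partner", "n_hubs"])


def export_network(
    net: InteractionNetwork,
    scores: pd.DataFrame,
    out_dir: str | Path,
    basename: str = "network",
) -> tuple[Path, Path]:
    """Write GraphML (with hub statistics as node attributes) and SIF files.

    Both formats load directly in Cytoscape; the SIF file uses the generic
    ``pp`` (protein-protein) interaction type.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graph = net.graph.copy()
    by_node = scores.set_index("node")
    for node in graph.nodes:
        graph.nodes[node]["is_bait"] = node in net.baits
        graph.nodes[node]["is_partner"] = node in net.partners
        if node in by_node.index:
            graph.nodes[node]["degree_total"] = int(by_node.at[node, "degree_total"])
            graph.nodes[node]["degree_lsu"] = int(by_node.at[node, "degree_lsu"])
            graph.nodes[node]["ratio"] = float(by_node.at[node, "ratio"])
    graphml_path = out_dir / f"{basename}.graphml"
    sif_path = out_dir / f"{basename}.sif"
    try:
        nx.write_graphml(graph, graphml_path)
        with sif_path.open("w") as fh:
            for a, b in sorted(map(sorted, graph.edges())):
                fh.write(f"{a}\tpp\t{b}\n")
    except OSError as exc:
        raise InputError(f"cannot write network export: {exc}") from exc
    return graphml_path, sif_path
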