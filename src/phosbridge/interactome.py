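"""Interactome assembly: bait-prey edges plus a literature PPI layer.

The experimental layer holds one edge per enriched prey of each bait,
carrying the prey's TNF-regulation class. A literature PPI (PSI-MITAB 2.5
or a 2-column edge list) is overlaid: experimental edges also present in
the literature are marked ``both`` (the dashed edges of an interactome
figure), and literature edges among any network nodes are kept as context.
Complexes among a bait's preys are read off as connected components of the
literature edges induced on the prey set.
"""

from __future__ import annotations

import csv
import logging
import re
from typing import Iterable, Mapping, Optional

import networkx as nx

from .types import EnrichmentCall, FormatError, Interaction, ValidationError

logger = logging.getLogger(__name__)


class PPINetwork:
    """Undirected PPI with annotated edges, backed by a networkx graph.

    Neighbor lookup is O(degree); edges are keyed by canonical (sorted)
    node pair so duplicates collapse.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> None:
        self.graph.add_node(node.upper())

    def add_interaction(self, inter: Interaction) -> None:
        a, b = inter.pair
        if self.graph.has_edge(a, b):
            data = self.graph.edges[a, b]
            if data["source"] != inter.source:
                data["source"] = "both"
            if inter.regulation is not None:
                data["regulation"] = inter.regulation
            if inter.bait is not None:
                data.setdefault("baits", set()).add(inter.bait)
        else:
            baits = {inter.bait} if inter.bait is not None else set()
            self.graph.add_edge(a, b, source=inter.source,
                                regulation=inter.regulation, baits=baits)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def edge_source(self, a: str, b: str) -> str:
        return self.graph.edges[a, b]["source"]

    def interactions(self) -> list[Interaction]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            baits = sorted(data.get("baits") or []) or [None]
            out.append(Interaction(a=a, b=b, source=data["source"],
                                   regulation=data.get("regulation"),
                                   bait=baits[0]))
        return sorted(out, key=lambda i: i.pair)

    def preys_of(self, bait: str) -> set[str]:
        """Nodes linked to ``bait`` by an edge from that bait's pull-down."""
        bait = bait.upper()
        preys = set()
        for nbr in self.graph.neighbors(bait):
            data = self.graph.edges[bait, nbr]
            if data["source"] in ("experimental", "both") and bait in (
                data.get("baits") or set()
            ):
                preys.add(nbr)
        return preys


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

_MITAB_SYMBOL = re.compile(r"(?:uniprotkb|entrez gene/locuslink|hgnc)?:?"
                           r"([A-Za-z0-9_.-]+)(?:\(gene name\))?$")


def _mitab_symbol(field: str) -> Optional[str]:
    """Best-effort gene symbol from a MITAB id/alias column.

    Prefers an alias tagged ``(gene name)``; otherwise takes the value of
    the first identifier. Returns None when nothing parseable is present.
    """
    for item in field.split("|"):
        item = item.strip()
        if item.endswith("(gene name)"):
            m = _MITAB_SYMBOL.match(item)
            if m:
                return m.group(1).upper()
    first = field.split("|")[0].strip()
    if not first or first == "-":
        return None
    m = _MITAB_SYMBOL.match(first)
    return m.group(1).upper() if m else None


def read_mitab(path) -> set[Interaction]:
    """Read literature interactions from a PSI-MITAB 2.5-style file.

    Uses columns 1-2 (unique ids) and 3-6 (alt ids / aliases) to recover a
    gene symbol per interactor; detection-method and score columns are
    ignored — pairs are binary evidence. Unparseable lines are skipped with
    a logged count; self-loops are dropped; duplicates collapse.
    """
    edges: set[Interaction] = set()
    n_skipped = 0
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                n_skipped += 1
                continue
            a = _best_symbol(cols, (0, 2, 4))
            b = _best_symbol(cols, (1, 3, 5))
            if a is None or b is None:
                n_skipped += 1
                continue
            if a == b:
                continue
            edges.add(Interaction(a=a, b=b, source="literature"))
    if n_skipped:
        logger.warning("%s: skipped %d unparseable MITAB lines", path, n_skipped)
    if not edges:
        raise FormatError(f"{path}: no interactions parsed")
    return edges


def _best_symbol(cols: list[str], indices: tuple[int, ...]) -> Optional[str]:
    # prefer an explicit gene-name alias in any of the candidate columns
    for idx in indices:
        if idx < len(cols) and "(gene name)" in cols[idx]:
            sym = _mitab_symbol(cols[idx])
            if sym:
                return sym
    for idx in indices:
        if idx < len(cols):
            sym = _mitab_symbol(cols[idx])
            if sym:
                return sym
    return None


def read_edge_list(path) -> set[Interaction]:
    """Read literature interactions from a 2-column TSV (header optional)."""
    edges: set[Interaction] = set()
    n_skipped = 0
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                n_skipped += 1
                continue
            a, b = cols[0].strip().upper(), cols[1].strip().upper()
            if line_no == 1 and {a, b} & {"A", "B", "SOURCE", "TARGET",
                                          "PROTEIN_A", "PROTEIN_B"}:
                continue  # header row
            if a == b:
                continue
            edges.add(Interaction(a=a, b=b, source="literature"))
    if n_skipped:
        logger.warning("%s: skipped %d malformed lines", path, n_skipped)
    if not edges:
        raise FormatError(f"{path}: no interactions parsed")
    return edges


# --------------------------------------------------------------------------
# Assembly and statistics
# --------------------------------------------------------------------------

def assemble_interactome(
    per_bait_calls: Mapping[str, list[EnrichmentCall]],
    literature: Iterable[Interaction] = (),
) -> PPINetwork:
    """Combine per-bait enrichment calls with the literature PPI layer.

    Each enriched call yields an experimental bait-prey edge carrying the
    call's regulation class; edges also present in the literature become
    ``both``. Literature edges between any pair of network nodes are added
    with ``source=literature``. Baits with zero enriched preys are kept as
    isolated nodes (with a warning).
    """
    literature = set(literature)
    lit_pairs = {i.pair for i in literature}

    net = PPINetwork()
    for bait in sorted(per_bait_calls):
        bait_sym = bait.upper()
        net.add_node(bait_sym)
        enriched = [c for c in per_bait_calls[bait] if c.enriched]
        if not enriched:
            logger.warning("bait %s has no enriched preys; kept isolated",
                           bait_sym)
            continue
        for call in sorted(enriched, key=lambda c: c.protein_id):
            prey = call.protein_id.upper()
            if prey == bait_sym:
                continue
            pair = tuple(sorted((bait_sym, prey)))
            source = "both" if pair in lit_pairs else "experimental"
            net.add_interaction(
                Interaction(a=bait_sym, b=prey, source=source,
                            regulation=call.regulation, bait=bait_sym)
            )
    for inter in sorted(literature, key=lambda i: i.pair):
        if net.graph.has_edge(*inter.pair):
            continue  # already marked both
        net.add_interaction(inter)
    return net


def literature_overlap_fraction(net: PPINetwork) -> float:
    """Fraction of identified (bait-prey) interactions with literature support:
    |both| / (|experimental| + |both|)."""
    n_exp = n_both = 0
    for _, _, data in net.graph.edges(data=True):
        if data["source"] == "experimental":
            n_exp += 1
        elif data["source"] == "both":
            n_both += 1
    if n_exp + n_both == 0:
        raise ValidationError("no bait-prey edges; overlap fraction undefined")
    return n_both / (n_exp + n_both)


def prey_complex_components(
    net: PPINetwork,
    bait: str,
    literature: Iterable[Interaction],
    include_experimental: bool = False,
) -> list[set[str]]:
    """Putative complexes among one bait's preys.

    Induces the literature edges (optionally also experimental edges of the
    assembled network) on the bait's prey set and returns connected
    components of size >= 2, sorted by size descending then by their
    lexicographically smallest member. Singleton preys are not complexes.
    """
    bait = bait.upper()
    if bait not in net.nodes:
        raise ValidationError(f"bait {bait} not in network")
    preys = net.preys_of(bait)
    sub = nx.Graph()
    sub.add_nodes_from(preys)
    for inter in literature:
        a, b = inter.pair
        if a in preys and b in preys:
            sub.add_edge(a, b)
    if include_experimental:
        for a, b, data in net.graph.subgraph(preys).edges(data=True):
            sub.add_edge(a, b)
    components = [set(c) for c in nx.connected_components(sub) if len(c) >= 2]
    return sorted(components, key=lambda c: (-len(c), min(c)))


def write_network_tsv(net: PPINetwork, path) -> None:
    """Write the annotated network as TSV (a, b, source, regulation, bait)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["a", "b", "source", "regulation", "bait"])
        for a, b in sorted(net.graph.edges):
            a, b = sorted((a, b))
            data = net.graph.edges[a, b]
            baits = ";".join(sorted(data.get("baits") or []))
            writer.writerow([a, b, data["source"],
                             data.get("regulation") or "", baits])


def write_network_graphml(net: PPINetwork, path) -> None:
    """Write the network as GraphML for external viewers."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for a, b in sorted(net.graph.edges):
        data = net.graph.edges[a, b]
        g.add_edge(a, b, source=data["source"],
                   regulation=data.get("regulation") or "",
                   baits=";".join(sorted(data.get("baits") or [])))
    nx.write_graphml(g, path)
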