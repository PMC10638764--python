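"""Genome-wide co-amplification graph.

Amplified regions are nodes, breakpoint pairs are weighted edges.
Connected components are co-amplified regions; simple cycles within a
component are candidate circular (ecDNA) structures. The "maximum
circle" of a component is the simple cycle whose member regions cover
the most genomic sequence, with ties broken by higher summed edge
support and then by lexicographic node ids. Pairs whose two breakpoints
fall in one region are single-region circularization candidates; they
are kept as node attributes (not edges) and reported as single-node
cycles of rank 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import networkx as nx

logger = logging.getLogger(__name__)

#: Components larger than this enumerate a fundamental cycle basis only.
MAX_ENUMERATION_NODES = 12


@dataclass
class Component:
    id: int
    nodes: List[int]
    score: int
    total_length: int
    cycles: List[List[int]] = field(default_factory=list)
    max_circle: Optional[List[int]] = None
    self_cycle_nodes: List[int] = field(default_factory=list)

    @property
    def has_cycle(self) -> bool:
        return bool(self.cycles) or bool(self.self_cycle_nodes)


def build_graph(regions, pairs) -> nx.Graph:
    """One node per retained region; one weighted edge per merged pair."""
    g = nx.Graph()
    for r in regions:
        g.add_node(
            r.id,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            length=r.length,
            mean_depth=r.mean_depth,
            self_support=0,
        )
    for p in pairs:
        if p.region_a_id is None or p.region_b_id is None:
            continue
        for rid in (p.region_a_id, p.region_b_id):
            if rid not in g:
                raise RuntimeError(
                    f"breakpoint pair references unknown region id {rid}; "
                    f"region assignment and graph build are out of sync"
                )
        if p.self_edge or p.region_a_id == p.region_b_id:
            g.nodes[p.region_a_id]["self_support"] += p.support
        elif g.has_edge(p.region_a_id, p.region_b_id):
            g.edges[p.region_a_id, p.region_b_id]["support"] += p.support
        else:
            g.add_edge(
                p.region_a_id, p.region_b_id, support=p.support, evidence=p.evidence
            )
    return g


def canonical_cycle(nodes) -> tuple:
    """Rotation/reflection-invariant form of a cycle's node sequence."""
    nodes = list(nodes)
    best = None
    for seq in (nodes, nodes[::-1]):
        for i in range(len(seq)):
            rot = tuple(seq[i:] + seq[:i])
            if best is None or rot < best:
                best = rot
    return best


def _cycle_metrics(g: nx.Graph, cycle) -> tuple:
    total_length = sum(g.nodes[n]["length"] for n in cycle)
    support = sum(
        g.edges[cycle[i], cycle[(i + 1) % len(cycle)]]["support"]
        for i in range(len(cycle))
    )
    return total_length, support


def find_components_and_cycles(g: nx.Graph) -> List[Component]:
    """Enumerate components, their simple cycles and the maximum circle."""
    components = []
    for ci, nodes in enumerate(
        sorted(nx.connected_components(g), key=lambda ns: min(ns)), start=1
    ):
        sub = g.subgraph(nodes)
        score = sum(d["support"] for _, _, d in sub.edges(data=True))
        score += sum(sub.nodes[n]["self_support"] for n in sub)
        if len(nodes) <= MAX_ENUMERATION_NODES:
            seen = {}
            for cyc in nx.simple_cycles(sub):
                if len(cyc) < 3:
                    continue
                seen[canonical_cycle(cyc)] = list(cyc)
            cycles = [list(c) for c in sorted(seen)]
        else:
            logger.warning(
                "component %d has %d nodes; reporting a cycle basis instead of "
                "all simple cycles",
                ci,
                len(nodes),
            )
            cycles = [
                list(canonical_cycle(c))
                for c in nx.cycle_basis(sub)
                if len(c) >= 3
            ]
        ranked = sorted(
            cycles,
            key=lambda c: (
                -_cycle_metrics(sub, c)[0],
                -_cycle_metrics(sub, c)[1],
                canonical_cycle(c),
            ),
        )
        components.append(
            Component(
                id=ci,
                nodes=sorted(nodes),
                score=score,
                total_length=sum(g.nodes[n]["length"] for n in nodes),
                cycles=ranked,
                max_circle=ranked[0] if ranked else None,
                self_cycle_nodes=sorted(
                    n for n in nodes if g.nodes[n]["self_support"] > 0
                ),
            )
        )
    return components


def export_graph(g: nx.Graph, components, out_dir, make_images: bool = True):
    """components.tsv, cycles.tsv, graph.graphml and per-component images.

    Text outputs are always written; image failures degrade to a
    warning (headless-safe via the Agg backend).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "components.tsv", "w") as fh:
        fh.write("component_id\tregion_ids\tscore\ttotal_length\thas_cycle\n")
        for c in components:
            fh.write(
                f"{c.id}\t{','.join(map(str, c.nodes))}\t{c.score}\t"
                f"{c.total_length}\t{str(c.has_cycle).lower()}\n"
            )

    with open(out_dir / "cycles.tsv", "w") as fh:
        fh.write("component_id\tcycle_rank\tregion_ids\tcycle_length\tcomponent_score\n")
        for c in components:
            for n in c.self_cycle_nodes:
                fh.write(f"{c.id}\t0\t{n}\t{g.nodes[n]['length']}\t{c.score}\n")
            for rank, cyc in enumerate(c.cycles, start=1):
                length = sum(g.nodes[n]["length"] for n in cyc)
                fh.write(
                    f"{c.id}\t{rank}\t{','.join(map(str, cyc))}\t{length}\t{c.score}\n"
                )

    nx.write_graphml(g, out_dir / "graph.graphml")

    if make_images and g.number_of_nodes():
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for c in components:
                sub = g.subgraph(c.nodes)
                fig, ax = plt.subplots(figsize=(6, 5))
                pos = nx.spring_layout(sub, seed=0)
                widths = [
                    1 + 4 * d["support"] / max(1, c.score)
                    for _, _, d in sub.edges(data=True)
                ]
                labels = {
                    n: f"{sub.nodes[n]['chrom']}:{sub.nodes[n]['start']}-{sub.nodes[n]['end']}"
                    for n in sub
                }
                nx.draw_networkx(
                    sub, pos, ax=ax, labels=labels, width=widths, node_size=600,
                    font_size=7, node_color="#ffb060",
                )
                ax.set_axis_off()
                fig.tight_layout()
                fig.savefig(out_dir / f"component_{c.id}.png", dpi=100)
                plt.close(fig)
        except Exception as exc:  # pragma: no cover - environment dependent
            warnings.warn(f"graph image rendering failed: {exc}")
    return out_dir
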