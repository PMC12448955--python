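"""Static renderings of the dashboard panels.

Each interactive panel of the original workflow maps to one plot function
emitting a PNG/SVG file: signalment bar charts, the proportion-by-frequency
stacked bars, the word-correlation network, the topic word cloud and the
findings histogram.  Layouts are deterministic (seeded force-directed
placement for the network) so re-runs with the same inputs reproduce the
figures structurally.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .explore import CorrelationEdge, TopicWordCloudSpec
from .signalment import CrossTab, FrequencyTable


def plot_frequency(table: FrequencyTable, path) -> None:
    levels = [lvl for lvl, _ in table.rows]
    counts = [c for _, c in table.rows]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(levels)), 4))
    ax.bar(range(len(levels)), counts, color="#4878a8")
    ax.set_xticks(range(len(levels)))
    ax.set_xticklabels(levels, rotation=45, ha="right")
    ax.set_ylabel("records")
    ax.set_title(table.variable)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cross_tab(ct: CrossTab, path) -> None:
    freq_levels = sorted({f for f, _, _, _ in ct.cells})
    prop_levels = sorted({p for _, p, _, _ in ct.cells})
    counts = {(f, p): c for f, p, c, _ in ct.cells}
    bottom = np.zeros(len(freq_levels))
    fig, ax = plt.subplots(figsize=(max(4, 0.7 * len(freq_levels)), 4))
    cmap = plt.get_cmap("tab10")
    for j, p in enumerate(prop_levels):
        heights = np.array([counts.get((f, p), 0) for f in freq_levels], dtype=float)
        ax.bar(range(len(freq_levels)), heights, bottom=bottom,
               label=p, color=cmap(j % 10))
        bottom += heights
    ax.set_xticks(range(len(freq_levels)))
    ax.set_xticklabels(freq_levels, rotation=45, ha="right")
    ax.set_ylabel("records")
    ax.set_title(f"{ct.freq_variable} by {ct.prop_variable}")
    ax.legend(title=ct.prop_variable, fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation_network(
    edges: list[CorrelationEdge], path, min_corr: float = 0.0, seed: int = 0
) -> None:
    """Force-directed network; edge darkness scales linearly with phi over
    [min_corr, 1]."""
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.term_a, e.term_b, phi=e.phi)
    fig, ax = plt.subplots(figsize=(8, 8))
    if graph.number_of_nodes():
        pos = nx.spring_layout(graph, seed=seed)
        span = max(1e-9, 1.0 - min_corr)
        shades = [
            str(0.8 * (1 - (d["phi"] - min_corr) / span))
            for _, _, d in graph.edges(data=True)
        ]
        nx.draw_networkx_edges(graph, pos, ax=ax, edge_color=shades)
        nx.draw_networkx_nodes(graph, pos, ax=ax, node_size=40, node_color="#4878a8")
        nx.draw_networkx_labels(graph, pos, ax=ax, font_size=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_word_cloud(spec: TopicWordCloudSpec, path, seed: int = 0) -> None:
    """Simple word-cloud rendering: jittered grid placement, font size by
    weight, one colour per topic."""
    rng = np.random.Generator(np.random.PCG64(seed))
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(8, 6))
    entries = []
    for topic, words in enumerate(spec.top_words):
        for word, weight in words:
            if spec.assigned_topic[word] == topic:
                entries.append((word, weight, topic))
    if entries:
        max_weight = max(w for _, w, _ in entries)
        cols = int(np.ceil(np.sqrt(len(entries))))
        for i, (word, weight, topic) in enumerate(entries):
            x = (i % cols + 0.5 + 0.2 * (rng.random() - 0.5)) / cols
            y = (i // cols + 0.5 + 0.2 * (rng.random() - 0.5)) / cols
            ax.text(x, 1 - y, word, color=cmap(topic % 10),
                    fontsize=8 + 20 * weight / max_weight,
                    ha="center", va="center")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_findings_histogram(histogram: list[tuple[str, int]], path) -> None:
    terms = [t for t, _ in histogram]
    counts = [c for _, c in histogram]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(terms)), 4))
    ax.bar(range(len(terms)), counts, color="#a84848")
    ax.set_xticks(range(len(terms)))
    ax.set_xticklabels(terms, rotation=45, ha="right")
    ax.set_ylabel("positive records")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
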