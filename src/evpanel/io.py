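"""Readers/writers for the small plain-text formats used around the pipeline.

Gene sets are one symbol per line (``#`` comments allowed) or GMT
(set name, description, then member genes, tab-separated).  Interaction
graphs are 2- or 3-column edge lists (geneA, geneB[, confidence score]).
Particle sizes are one diameter (nm) per line.  Protein lengths are
two-column TSV (gene, length in amino acids).
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np


def read_gene_set(path) -> set[str]:
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def read_edge_list(path, sep: str = "\t") -> nx.Graph:
    """Edge list TSV -> undirected graph; third column (if any) becomes the
    edge attribute ``score``.  Self-loops are dropped, duplicates collapsed."""
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: edge line needs >= 2 fields")
            u, v = fields[0], fields[1]
            if u == v:
                continue
            if len(fields) >= 3:
                graph.add_edge(u, v, score=float(fields[2]))
            else:
                graph.add_edge(u, v)
    return graph


def write_edge_list(graph: nx.Graph, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            if "score" in data:
                fh.write(sep.join([u, v, format(data["score"], ".6g")]) + "\n")
            else:
                fh.write(sep.join([u, v]) + "\n")


def read_sizes(path) -> np.ndarray:
    """One particle diameter (nm) per line; a non-numeric first line is
    treated as a header."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                if lineno == 1:
                    continue
                raise ValueError(f"{path}:{lineno}: not a diameter: {line!r}")
    return np.asarray(values, dtype=float)


def write_sizes(diameters, path) -> None:
    with open(path, "w") as fh:
        for d in np.asarray(diameters, dtype=float):
            fh.write(f"{d:.4f}\n")


def read_lengths(path, sep: str = "\t") -> dict[str, float]:
    lengths: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene{sep}length'")
            try:
                lengths[fields[0]] = float(fields[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise
    return lengths


def write_lengths(lengths: Mapping[str, float], path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for gene in sorted(lengths):
            fh.write(f"{gene}{sep}{lengths[gene]:g}\n")
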