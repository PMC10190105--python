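"""Streaming minimum-spanning-tree single-linkage clustering.

The all-pairs sketch-distance matrix is treated as a complete weighted
graph, but never held in memory: edges are streamed in blocks of ``t``
matrix rows, each logical worker keeps only the minimum spanning forest
of the edges it has seen, and the final MST is the spanning forest of the
union of the per-worker forests.  This is safe because an edge that is not
in the MST of any sub-graph containing it cannot be in the MST of the
whole graph, so discarded edges are never needed again.

Clusters are the connected components after removing MST edges heavier
than the distance threshold — exactly a single-linkage cut.  To avoid
chaining two genuine clusters through a low-quality "bridge" genome, each
vertex carries a local density (number of neighbours closer than the
threshold, counted during streaming); within each cluster, vertices with
density below ``min(Q1, 2)`` (Q1 = first quartile of member densities,
linear interpolation) are marked as noise and their MST edges cut.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .clustering import Clustering
from .distances import pairwise_distance
from .errors import ParameterError
from .sketching import MODE_RESEMBLANCE, Sketch, SketchParams

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_ROWS = 8


class Edge(NamedTuple):
    u: int
    v: int
    w: float


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def _kruskal(edges: list[Edge], n: int) -> list[Edge]:
    """Minimum spanning forest by Kruskal; ties broken by (w, u, v)."""
    uf = _UnionFind(n)
    kept = []
    for e in sorted(edges, key=lambda e: (e.w, e.u, e.v)):
        if uf.union(e.u, e.v):
            kept.append(e)
    return kept


@dataclass
class MSTState:
    """Spanning forest under construction plus per-vertex densities."""

    n: int
    block_rows: int = DEFAULT_BLOCK_ROWS
    workers: int = 1
    sub_msts: list = field(default_factory=list)
    densities: np.ndarray | None = None
    final_mst: list = field(default_factory=list)
    threshold: float = 0.0
    ids: list[str] = field(default_factory=list)
    lengths: list[int] = field(default_factory=list)
    params: SketchParams | None = None
    peak_edges: int = 0


def stream_blocks(
    sketches: list[Sketch],
    mode: str = MODE_RESEMBLANCE,
    threshold: float = 0.05,
    block_rows: int = DEFAULT_BLOCK_ROWS,
) -> Iterator[tuple[list[Edge], np.ndarray]]:
    """Stream all pairwise edges in blocks of ``block_rows`` matrix rows.

    Yields ``(edges, density_increments)`` per block; a row ``u`` holds the
    edges (u, v) for all v > u, so every pair appears exactly once.  The
    density increment counts, per vertex, neighbours at distance strictly
    below the threshold.
    """
    n = len(sketches)
    if n < 2:
        raise ParameterError("need at least two sketches to stream distances")
    for start in range(0, n - 1, block_rows):
        rows = range(start, min(start + block_rows, n - 1))
        edges: list[Edge] = []
        dens = np.zeros(n, dtype=np.int64)
        for u in rows:
            for v in range(u + 1, n):
                w = pairwise_distance(sketches[u], sketches[v], mode).distance
                edges.append(Edge(u, v, w))
                if w < threshold:
                    dens[u] += 1
                    dens[v] += 1
        yield edges, dens


def update_sub_mst(current: list[Edge], block: list[Edge], n: int) -> list[Edge]:
    """Minimum spanning forest of ``current ∪ block``.

    ``current`` must itself be a spanning forest; edges it discards are
    never part of the full-graph MST (edge-partition safety).
    """
    return _kruskal(list(current) + list(block), n)


def merge_final_mst(state: MSTState) -> list[Edge]:
    """Merge per-worker forests into the final MST."""
    all_edges: list[Edge] = []
    for sub in state.sub_msts:
        all_edges.extend(sub)
    state.final_mst = _kruskal(all_edges, state.n)
    return state.final_mst


def build_mst(
    sketches: list[Sketch],
    mode: str = MODE_RESEMBLANCE,
    threshold: float = 0.05,
    block_rows: int = DEFAULT_BLOCK_ROWS,
    workers: int = 1,
    params: SketchParams | None = None,
) -> MSTState:
    """Run the streaming MST construction over all sketch pairs.

    ``workers`` is a logical partition of blocks (round-robin); results are
    identical for any worker count.  ``peak_edges`` records the largest
    number of edges retained at any instant, for the linear-memory
    contract ``workers * (block_rows + 1) * n``.
    """
    n = len(sketches)
    state = MSTState(
        n=n,
        block_rows=block_rows,
        workers=workers,
        sub_msts=[[] for _ in range(workers)],
        densities=np.zeros(n, dtype=np.int64),
        threshold=threshold,
        ids=[s.genome_id for s in sketches],
        lengths=[s.genome_length for s in sketches],
        params=params,
    )
    for i, (block, dens) in enumerate(
        stream_blocks(sketches, mode, threshold, block_rows)
    ):
        held = len(block) + sum(len(s) for s in state.sub_msts)
        state.peak_edges = max(state.peak_edges, held)
        wi = i % workers
        state.sub_msts[wi] = update_sub_mst(state.sub_msts[wi], block, n)
        state.densities += dens
    merge_final_mst(state)
    return state


def _component_labels(n: int, edges: list[Edge]) -> list[int]:
    uf = _UnionFind(n)
    for e in edges:
        uf.union(e.u, e.v)
    remap: dict[int, int] = {}
    labels = []
    for v in range(n):
        root = uf.find(v)
        labels.append(remap.setdefault(root, len(remap)))
    return labels


def cut_mst(
    mst: list[Edge], threshold: float, n: int, ids: list[str] | None = None
) -> Clustering:
    """Single-linkage cut: drop MST edges with weight above the threshold.

    Connected components of the remaining forest are the clusters;
    equivalent to single-linkage agglomeration stopped at the threshold.
    """
    kept = [e for e in mst if e.w <= threshold]
    labels = _component_labels(n, kept)
    ids = ids if ids is not None else [str(i) for i in range(n)]
    return Clustering(dict(zip(ids, labels)))


def prune_noise(
    clusters: Clustering,
    densities: np.ndarray,
    mst: list[Edge],
    threshold: float,
) -> Clustering:
    """Cut MST edges incident to low-density (noise) vertices.

    Within each cluster, a member is noise when its density is below
    ``min(Q1, 2)`` where Q1 is the first quartile (linear interpolation) of
    that cluster's member densities.  Components are recomputed on the
    surviving edges, so noise vertices end as singletons.
    """
    ids = list(clusters.labels.keys())
    index = {gid: i for i, gid in enumerate(ids)}
    n = len(ids)
    by_cluster: dict[int, list[int]] = {}
    for gid, c in clusters.labels.items():
        by_cluster.setdefault(c, []).append(index[gid])
    noise = np.zeros(n, dtype=bool)
    for members in by_cluster.values():
        dens = np.asarray([densities[m] for m in members], dtype=float)
        cut = min(np.percentile(dens, 25), 2.0)
        for m, d in zip(members, dens):
            if d < cut:
                noise[m] = True
    kept = [
        e for e in mst
        if e.w <= threshold and not noise[e.u] and not noise[e.v]
    ]
    labels = _component_labels(n, kept)
    return Clustering(dict(zip(ids, labels)))


MST_FORMAT = "sketchclust-mst-v1"


def save_mst(state: MSTState, path: str) -> None:
    """Write the MST file: header, genome table, edge lines.

    Edge weights are printed at 6 significant digits.  The genome table
    carries the per-vertex density measured at the generation threshold,
    which noise pruning reuses when re-cutting.
    """
    p = state.params
    with open(path, "w") as fh:
        fh.write(f"#format\t{MST_FORMAT}\n")
        fh.write(f"#mode\t{p.mode if p else 'resemblance'}\n")
        fh.write(f"#k\t{p.k if p else ''}\n")
        if p and p.mode == MODE_RESEMBLANCE:
            fh.write(f"#S\t{p.sketch_size}\n")
        elif p:
            fh.write(f"#P\t{p.proportion!r}\n")
        fh.write(f"#hash_seed\t{p.hash_seed if p else ''}\n")
        fh.write(f"#threshold\t{state.threshold!r}\n")
        fh.write(f"#N\t{state.n}\n")
        for i, (gid, length) in enumerate(zip(state.ids, state.lengths)):
            fh.write(f"G\t{i}\t{gid}\t{length}\t{int(state.densities[i])}\n")
        for e in state.final_mst:
            fh.write(f"E\t{e.u}\t{e.v}\t{e.w:.6g}\n")


def load_mst(path: str) -> MSTState:
    header: dict[str, str] = {}
    ids: list[str] = []
    lengths: list[int] = []
    dens: list[int] = []
    edges: list[Edge] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                header[key] = val
            elif line.startswith("G\t"):
                _, _i, gid, length, d = line.split("\t")
                ids.append(gid)
                lengths.append(int(length))
                dens.append(int(d))
            elif line.startswith("E\t"):
                _, u, v, w = line.split("\t")
                edges.append(Edge(int(u), int(v), float(w)))
    if header.get("format") != MST_FORMAT:
        raise ParameterError(f"not a recognized MST file: {path}")
    mode = header["mode"]
    params = SketchParams(
        k=int(header["k"]),
        mode=mode,
        sketch_size=int(header["S"]) if "S" in header else None,
        proportion=float(header["P"]) if "P" in header else None,
        hash_seed=int(header["hash_seed"]),
        threshold=float(header["threshold"]),
    )
    n = int(header["N"])
    state = MSTState(
        n=n,
        densities=np.asarray(dens, dtype=np.int64),
        final_mst=edges,
        threshold=float(header["threshold"]),
        ids=ids,
        lengths=lengths,
        params=params,
    )
    return state


def clust_mst(
    sketches: list[Sketch] | None = None,
    params: SketchParams | None = None,
    threshold: float | None = None,
    block_rows: int = DEFAULT_BLOCK_ROWS,
    workers: int = 1,
    mst_state: MSTState | None = None,
    prune: bool = True,
) -> tuple[Clustering, MSTState]:
    """Full clust-mst pipeline, or a re-cut of a previously saved MST.

    With ``sketches``: streams distances, builds the MST and densities at
    ``threshold``, cuts and (optionally) noise-prunes.  With ``mst_state``
    (from :func:`load_mst`): skips sketching and re-cuts; if the requested
    threshold differs from the one the MST was generated at, stored
    densities are reused for pruning and a warning is logged, since exact
    densities at the new threshold would need the full distance matrix.
    """
    if mst_state is not None:
        if params is not None and mst_state.params is not None:
            sp = mst_state.params
            if (params.k, params.mode, params.sketch_size, params.proportion,
                    params.hash_seed) != (sp.k, sp.mode, sp.sketch_size,
                                          sp.proportion, sp.hash_seed):
                raise ParameterError(
                    "saved MST was built under different sketch parameters; "
                    "re-clustering is only valid when they match"
                )
        state = mst_state
        thr = state.threshold if threshold is None else threshold
        if threshold is not None and threshold != state.threshold:
            logger.warning(
                "re-cutting at threshold %g but densities were measured at %g; "
                "noise pruning reuses stored densities", threshold, state.threshold
            )
    else:
        if sketches is None or params is None:
            raise ParameterError("clust_mst needs sketches+params or a saved MST")
        thr = params.threshold if threshold is None else threshold
        state = build_mst(
            sketches,
            mode=params.mode,
            threshold=thr,
            block_rows=block_rows,
            workers=workers,
            params=params,
        )
    clusters = cut_mst(state.final_mst, thr, state.n, state.ids)
    if prune:
        clusters = prune_noise(clusters, state.densities, state.final_mst, thr)
    return clusters, state
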