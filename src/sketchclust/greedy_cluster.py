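"""Greedy incremental clustering against longest-genome representatives.

Genomes are processed in descending length order.  The first genome founds
a cluster and becomes its representative; each subsequent genome is
compared *only* against current representatives, joining the cluster of
the minimum-distance representative when that distance is within the
threshold and founding a new cluster otherwise.  Distances between
non-representative ("redundant") genomes are never computed.

The default distance is the containment-based AAF distance, which keeps
the estimate honest when a short genome is compared to a much longer
representative; a fixed-sketch resemblance mode is available for
comparison but over-estimates distances in that regime.
"""

from __future__ import annotations

from .clustering import Clustering
from .distances import pairwise_distance
from .errors import EmptyDatasetError
from .sketching import MODE_CONTAINMENT, Sketch


def sort_by_length(sketches: list[Sketch]) -> list[Sketch]:
    """Stable sort by genome length, descending; ties keep input order."""
    return sorted(sketches, key=lambda s: -s.genome_length)


def clust_greedy(
    sketches: list[Sketch],
    threshold: float,
    mode: str = MODE_CONTAINMENT,
) -> Clustering:
    """Greedy incremental clustering of ``sketches`` at ``threshold``.

    Ties between equally distant representatives go to the earliest-created
    cluster.  The returned clustering records per-cluster representatives
    and, in ``meta['distance_computations']``, how many pairwise distances
    were evaluated.
    """
    if not sketches:
        raise EmptyDatasetError("clust_greedy needs at least one sketch")
    ordered = sort_by_length(sketches)
    reps: list[Sketch] = []
    labels: dict[str, int] = {}
    representatives: dict[int, str] = {}
    n_dist = 0
    for sk in ordered:
        best_c = None
        best_d = None
        for ci, rep in enumerate(reps):
            d = pairwise_distance(sk, rep, mode).distance
            n_dist += 1
            if best_d is None or d < best_d:
                best_d, best_c = d, ci
        if best_d is not None and best_d <= threshold:
            labels[sk.genome_id] = best_c
        else:
            ci = len(reps)
            reps.append(sk)
            labels[sk.genome_id] = ci
            representatives[ci] = sk.genome_id
    return Clustering(
        labels, representatives, meta={"distance_computations": n_dist}
    )
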