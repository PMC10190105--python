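"""Sketch-based genome distances.

Resemblance: the Jaccard index of two genomes' k-mer sets is estimated
from fixed-size sketches with the merged bottom-s estimator, and converted
to the Mash distance ``D = -(1/k) ln(2J / (1 + J))``, which approximates
``1 - ANI`` under a Poisson model of point mutation.

Containment: for genomes of very different lengths, the containment
coefficient ``c`` of the smaller genome in the larger is estimated from
variable-size sketches as the fraction of the smaller sketch's hashes
found in the larger sketch, and converted to the distance
``d = -(1/k) ln c``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .sketching import MODE_CONTAINMENT, MODE_RESEMBLANCE, Sketch


@dataclass(frozen=True)
class PairDistance:
    id_a: str
    id_b: str
    similarity: float  # Jaccard estimate J or containment estimate c
    distance: float


def jaccard_fixed(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s Jaccard estimate from two fixed-size sketches.

    With nominal sketch size S, the s = min(S, |union|) smallest hashes of
    the union form the sampled universe U; the estimate is
    ``|U ∩ A ∩ B| / |U|``.
    """
    if a.kind != "fixed" or b.kind != "fixed":
        raise ParameterError("jaccard_fixed requires fixed-size sketches")
    if a.k != b.k:
        raise ParameterError(f"k mismatch: {a.k} vs {b.k}")
    if a.nominal != b.nominal:
        raise ParameterError("nominal sketch size mismatch")
    if a.size == 0 or b.size == 0:
        warnings.warn("empty sketch in Jaccard estimation; returning 0")
        return 0.0
    union = np.union1d(a.hashes, b.hashes)
    s = min(int(a.nominal), union.size)
    cutoff = union[s - 1]
    inter = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    shared = int(np.searchsorted(inter, cutoff, side="right"))
    return shared / s


def mash_distance(j: float, k: int) -> float:
    """Mash distance from a Jaccard estimate; J=0 clamps to distance 1."""
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / k)


def containment(small: Sketch, large: Sketch) -> float:
    """Containment estimate of the shorter genome in the longer.

    Both sketches must be variable-kind under the same proportion; the
    denominator is the sketch of the genome with the smaller length (ties
    broken by id), regardless of argument order.
    """
    if small.kind != "variable" or large.kind != "variable":
        raise ParameterError("containment requires variable-size sketches")
    if small.k != large.k:
        raise ParameterError(f"k mismatch: {small.k} vs {large.k}")
    if small.nominal != large.nominal:
        raise ParameterError("sampling proportion mismatch")
    if (small.genome_length, small.genome_id) > (large.genome_length, large.genome_id):
        small, large = large, small
    if small.size == 0:
        warnings.warn("empty sketch in containment estimation; returning 0")
        return 0.0
    inter = np.intersect1d(small.hashes, large.hashes, assume_unique=True)
    return inter.size / small.size


def aaf_distance(c: float, k: int) -> float:
    """AAF (containment) distance; c=0 clamps to distance 1."""
    if c <= 0.0:
        return 1.0
    if c >= 1.0:
        return 0.0
    return min(1.0, -math.log(c) / k)


def pairwise_distance(a: Sketch, b: Sketch, mode: str = MODE_RESEMBLANCE) -> PairDistance:
    """Dispatch to the mode-appropriate similarity estimate and distance."""
    if mode == MODE_RESEMBLANCE:
        j = jaccard_fixed(a, b)
        return PairDistance(a.genome_id, b.genome_id, j, mash_distance(j, a.k))
    if mode == MODE_CONTAINMENT:
        c = containment(a, b)
        return PairDistance(a.genome_id, b.genome_id, c, aaf_distance(c, a.k))
    raise ParameterError(f"unknown distance mode: {mode}")


def distance_matrix(sketches: list, mode: str = MODE_RESEMBLANCE) -> np.ndarray:
    """Dense symmetric distance matrix (small datasets / interoperability)."""
    n = len(sketches)
    mat = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            d = pairwise_distance(sketches[i], sketches[jx], mode).distance
            mat[i, jx] = mat[jx, i] = d
    return mat


def write_phylip(sketches: list, mode: str, path: str, triangular: bool = False) -> None:
    """PHYLIP square (or lower-triangular) distance matrix for downstream tools."""
    mat = distance_matrix(sketches, mode)
    with open(path, "w") as fh:
        fh.write(f"{len(sketches)}\n")
        for i, s in enumerate(sketches):
            row = mat[i, :i] if triangular else mat[i]
            vals = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{s.genome_id}\t{vals}\n" if vals else f"{s.genome_id}\n")
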