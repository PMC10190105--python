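"""MinHash sketching and automatic parameter selection.

A sketch is the *s* smallest distinct 64-bit hash values over a genome's
canonical k-mers (a bottom-s sketch).  Two sizing regimes exist:

* **fixed** (resemblance): every genome contributes ``S`` hashes (default
  1000), suitable for Jaccard/Mash distance between genomes of similar
  length;
* **variable** (containment): a genome of length ``L`` contributes
  ``round(L * P)`` hashes, with the sampling proportion ``P`` defaulting to
  ``1000 / L_a`` (average genome length), so the sketch density in hash
  space is comparable across genomes of very different lengths.

Parameter selection follows the collision/sensitivity trade-off: the
optimal k-mer size for the largest genome length ``L`` and random-match
probability ``q`` is ``ceil(log4(L * (1 - q) / q))`` with ``q = 1e-4``; a
warning size ``k_w`` uses ``q = 1e-3`` and user-chosen ``k < k_w`` is reset
to the optimal size.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _hashing
from .errors import EmptyDatasetError, ParameterError
from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

DEFAULT_SKETCH_SIZE = 1000
DEFAULT_HASH_SEED = 42
DEFAULT_THRESHOLD = 0.05
Q_OPTIMAL = 0.0001
Q_WARNING = 0.001

MODE_RESEMBLANCE = "resemblance"
MODE_CONTAINMENT = "containment"


@dataclass(frozen=True)
class SketchParams:
    """Resolved sketching parameters.

    Exactly one of ``sketch_size`` (fixed mode) or ``proportion``
    (variable mode) governs sizing, selected by ``mode``.
    """

    k: int
    mode: str = MODE_RESEMBLANCE
    sketch_size: int | None = DEFAULT_SKETCH_SIZE
    proportion: float | None = None
    hash_seed: int = DEFAULT_HASH_SEED
    threshold: float = DEFAULT_THRESHOLD

    @property
    def kind(self) -> str:
        return "fixed" if self.mode == MODE_RESEMBLANCE else "variable"


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of one genome.

    ``hashes`` is strictly increasing (distinct values, set semantics);
    ``nominal`` records S (fixed kind) or P (variable kind).
    """

    genome_id: str
    genome_length: int
    k: int
    hashes: np.ndarray
    kind: str
    nominal: float
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self):
        h = np.asarray(self.hashes, dtype=np.uint64)
        object.__setattr__(self, "hashes", h)

    @property
    def size(self) -> int:
        return int(self.hashes.size)


def hash_kmer(kmer: str, seed: int = DEFAULT_HASH_SEED) -> int:
    """Deterministic, uniform 64-bit hash of a canonical k-mer (k <= 32)."""
    return _hashing.hash_packed(_hashing.pack_kmer(kmer), seed)


def distinct_canonical_hashes(
    genome: GenomeRecord | str, k: int, seed: int = DEFAULT_HASH_SEED
) -> np.ndarray:
    """Sorted distinct hash values of all canonical k-mers of a genome.

    Contigs are processed independently so no k-mer spans a contig
    junction.  This is the full hash set that any bottom-s sketch truncates.
    """
    contigs = (genome,) if isinstance(genome, str) else genome.contigs
    parts = [_hashing.packed_canonical_windows(c, k) for c in contigs]
    packed = parts[0] if len(parts) == 1 else np.concatenate(parts)
    if packed.size == 0:
        return np.empty(0, dtype=np.uint64)
    return np.unique(_hashing.hash_packed_array(packed, seed))


def target_sketch_size(length: int, params: SketchParams) -> int:
    if params.mode == MODE_RESEMBLANCE:
        if params.sketch_size is None:
            raise ParameterError("resemblance mode requires a sketch size")
        return int(params.sketch_size)
    if params.proportion is None:
        raise ParameterError("containment mode requires a sampling proportion")
    return max(1, round(length * params.proportion))


def build_sketch(
    genome: GenomeRecord,
    params: SketchParams,
    hashes: np.ndarray | None = None,
) -> Sketch:
    """Bottom-s sketch of ``genome`` under resolved ``params``.

    ``hashes`` may supply the precomputed distinct hash set (as returned by
    :func:`distinct_canonical_hashes`) to amortize k-mer extraction when
    sketching the same genome under several sizings.
    """
    if hashes is None:
        if genome.length < params.k:
            warnings.warn(
                f"genome {genome.id} shorter than k={params.k}; empty sketch"
            )
            hashes = np.empty(0, dtype=np.uint64)
        else:
            hashes = distinct_canonical_hashes(genome, params.k, params.hash_seed)
    target = target_sketch_size(genome.length, params)
    nominal = params.sketch_size if params.mode == MODE_RESEMBLANCE else params.proportion
    return Sketch(
        genome_id=genome.id,
        genome_length=genome.length,
        k=params.k,
        # copy: a plain slice would keep the full distinct-hash array alive
        hashes=hashes[:target].copy(),
        kind=params.kind,
        nominal=float(nominal),
        hash_seed=params.hash_seed,
    )


def sketch_genomes(genomes: list[GenomeRecord], params: SketchParams) -> list:
    return [build_sketch(g, params) for g in genomes]


def optimal_kmer_size(length: int, q: float) -> int:
    """k-mer size at which a random k-mer match has probability about ``q``.

    ``k = ceil(log4(L * (1 - q) / q))`` for genome length ``L``.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if length < 1:
        raise ValueError("length must be >= 1")
    v = math.log(length * (1.0 - q) / q, 4)
    return max(1, math.ceil(v - 1e-9))


def resolve_params(
    genomes: list[GenomeRecord],
    k: int | None = None,
    mode: str = MODE_RESEMBLANCE,
    sketch_size: int | None = None,
    proportion: float | None = None,
    hash_seed: int = DEFAULT_HASH_SEED,
    threshold: float | None = None,
) -> SketchParams:
    """Scan the dataset and fill in unspecified sketching parameters.

    The largest genome length sets the optimal (q=1e-4) and warning
    (q=1e-3) k-mer sizes; a user ``k`` below the warning size is reset to
    the optimal size with a logged warning.  Fixed mode defaults to
    ``S = 1000``; variable mode defaults to ``P = 1000 / L_a``.
    """
    if not genomes:
        raise EmptyDatasetError("cannot resolve parameters for an empty genome list")
    if mode not in (MODE_RESEMBLANCE, MODE_CONTAINMENT):
        raise ParameterError(f"unknown mode: {mode}")
    lengths = [g.length for g in genomes]
    l_largest = max(lengths)
    l_average = sum(lengths) / len(lengths)
    k_o = optimal_kmer_size(l_largest, Q_OPTIMAL)
    k_w = optimal_kmer_size(l_largest, Q_WARNING)
    if k is None:
        k = k_o
    elif k < k_w:
        logger.warning(
            "k=%d is below the warning size k_w=%d; resetting to optimal k_o=%d",
            k, k_w, k_o,
        )
        k = k_o
    if mode == MODE_RESEMBLANCE:
        sketch_size = DEFAULT_SKETCH_SIZE if sketch_size is None else int(sketch_size)
        proportion = None
    else:
        proportion = 1000.0 / l_average if proportion is None else float(proportion)
        sketch_size = None
    params = SketchParams(
        k=k,
        mode=mode,
        sketch_size=sketch_size,
        proportion=proportion,
        hash_seed=hash_seed,
        threshold=DEFAULT_THRESHOLD if threshold is None else float(threshold),
    )
    logger.info(
        "resolved params: k=%d (k_o=%d, k_w=%d) mode=%s S=%s P=%s",
        k, k_o, k_w, mode, sketch_size, proportion,
    )
    return params


def max_threshold(params: SketchParams, min_length: int | None = None) -> float:
    """Largest distance threshold resolvable at the sketch granularity.

    Fixed mode: the smallest nonzero Jaccard step is ``J_m = 1/S`` and
    ``d_max = -(1/k) ln(2 J_m / (1 + J_m))``.  Variable mode: the smallest
    nonzero containment step for the shortest genome (length ``L_m``) is
    ``C_m = 1 / (L_m P)`` and ``d_max = -(1/k) ln C_m``.
    """
    if params.mode == MODE_RESEMBLANCE:
        j_m = 1.0 / params.sketch_size
        return -math.log(2 * j_m / (1 + j_m)) / params.k
    if min_length is None:
        raise ParameterError("containment-mode d_max needs the minimum genome length")
    s_min = min_length * params.proportion
    if s_min < 1:
        raise ParameterError(
            f"minimum genome length {min_length} times proportion "
            f"{params.proportion} is below one hash; no valid sketch"
        )
    c_m = 1.0 / s_min
    return -math.log(c_m) / params.k


def save_sketches(sketches: list, params: SketchParams, path: str) -> None:
    """Persist sketches as a JSON header line plus one TSV row per genome."""
    header = {
        "format": "sketchclust-sketches-v1",
        "k": params.k,
        "mode": params.mode,
        "sketch_size": params.sketch_size,
        "proportion": params.proportion,
        "hash_seed": params.hash_seed,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for s in sketches:
            hashes = ",".join(format(int(h), "x") for h in s.hashes)
            fh.write(f"{s.genome_id}\t{s.genome_length}\t{hashes}\n")


def load_sketches(path: str) -> tuple[list, SketchParams]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ParameterError(f"not a sketch file: {path}")
        header = json.loads(first[1:])
        if header.get("format") != "sketchclust-sketches-v1":
            raise ParameterError(f"unrecognized sketch file format in {path}")
        params = SketchParams(
            k=header["k"],
            mode=header["mode"],
            sketch_size=header["sketch_size"],
            proportion=header["proportion"],
            hash_seed=header["hash_seed"],
        )
        sketches = []
        for line in fh:
            gid, length, hashes = line.rstrip("\n").split("\t")
            arr = np.array(
                [int(h, 16) for h in hashes.split(",")] if hashes else [],
                dtype=np.uint64,
            )
            nominal = params.sketch_size if params.mode == MODE_RESEMBLANCE else params.proportion
            sketches.append(
                Sketch(gid, int(length), params.k, arr, params.kind,
                       float(nominal), params.hash_seed)
            )
    return sketches, params
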