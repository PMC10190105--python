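"""Synthetic genome generators for the three benchmark designs.

All generators draw from a :class:`numpy.random.Generator` and are fully
reproducible given its seed.

* :func:`make_mutation_panel` — mutate a random genome at rates 1-10% and
  record the Mash-distance estimate across a (k, S) grid, to chart how the
  estimator tracks the true mutation rate.
* :func:`make_containment_dataset` — clusters of prefix fragments cut to
  random proportions of mutually dissimilar seed genomes, the regime where
  containment distance shines and fixed-sketch resemblance fails.
* :func:`make_seed_mutant_dataset` — seed genomes plus mutants at rate
  0.045 per base, constructed so that every mutant is within distance
  0.05 of its own seed while mutant pairs from the same seed exceed 0.05
  and different seeds are near distance 1; single-linkage then recovers
  exactly the seed-of-origin classes while greedy clustering fragments
  them (insertions make mutants outgrow their seed, so the seed is rarely
  the longest genome of its class).

Mutation model: each base independently mutates with the given rate;
the event is substitution (to a different base), single-base deletion, or
single-base insertion (random base placed after the site) with equal
probability, so the expected length change is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import distances, sketching
from .errors import SketchClustError
from .genome_io import GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a synthetic dataset."""

    scheme: str  # mutation_panel | fragment_containment | seed_mutant
    n_seeds: int
    seed_length: int
    per_cluster: int
    mutation_rate: float = 0.0
    rng_seed: int = 0


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_genome(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T sequence; draws are mutually near-disjoint
    in k-mer space for k >= 12."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(
    seq: str, rate: float, rng: np.random.Generator, return_events: bool = False
):
    """Apply per-base mutations at the given rate.

    Each mutated site suffers exactly one event, chosen uniformly among
    substitution, deletion, and insertion-after-site.  With
    ``return_events`` the per-type event counts are returned alongside the
    sequence.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError("mutate expects an ACGT-only sequence")
    n = codes.size
    if rate == 0.0 or n == 0:
        if return_events:
            return seq, {"substitution": 0, "deletion": 0, "insertion": 0}
        return seq
    hit = rng.random(n) < rate
    etype = rng.integers(0, 3, size=n)
    sub = hit & (etype == 0)
    dele = hit & (etype == 1)
    ins = hit & (etype == 2)
    out_base = codes.copy()
    n_sub = int(sub.sum())
    if n_sub:
        out_base[sub] = (codes[sub] + rng.integers(1, 4, size=n_sub, dtype=np.uint8)) % 4
    keep = ~dele
    counts = keep.astype(np.int64) + ins
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    out[starts[keep]] = out_base[keep]
    n_ins = int(ins.sum())
    if n_ins:
        out[starts[ins] + 1] = rng.integers(0, 4, size=n_ins, dtype=np.uint8)
    result = _decode(out)
    if return_events:
        return result, {
            "substitution": n_sub,
            "deletion": int(dele.sum()),
            "insertion": n_ins,
        }
    return result


def make_mutation_panel(
    length: int = 100_000,
    rates: tuple = tuple(r / 100 for r in range(1, 11)),
    k_values: tuple = (16, 18, 21),
    sketch_sizes: tuple = (1000, 10_000),
    reps: int = 3,
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Mash-distance estimates across a (rate, k, S) grid.

    For each replicate and rate, one reference genome and one mutant are
    generated; both are sketched at every (k, S) combination (the distinct
    hash set per k is computed once and truncated per S).  Returns one
    record per (rep, rate, k, S) with the estimated distance.
    """
    rng = np.random.default_rng() if rng is None else rng
    out: list[dict] = []
    for rep in range(reps):
        for rate in rates:
            ref = random_genome(length, rng)
            mut = mutate(ref, rate, rng)
            for k in k_values:
                h_ref = sketching.distinct_canonical_hashes(ref, k)
                h_mut = sketching.distinct_canonical_hashes(mut, k)
                for s in sketch_sizes:
                    params = sketching.SketchParams(k=k, sketch_size=s)
                    a = sketching.build_sketch(
                        GenomeRecord("ref", (ref,)), params, hashes=h_ref
                    )
                    b = sketching.build_sketch(
                        GenomeRecord("mut", (mut,)), params, hashes=h_mut
                    )
                    j = distances.jaccard_fixed(a, b)
                    out.append(
                        {
                            "rep": rep,
                            "rate": rate,
                            "k": k,
                            "sketch_size": s,
                            "jaccard": j,
                            "distance": distances.mash_distance(j, k),
                        }
                    )
    return out


def panel_rmse(panel: list[dict]) -> dict[tuple, float]:
    """Root-mean-square error of the estimate vs the identity model
    (distance == mutation rate), per (k, sketch_size)."""
    acc: dict[tuple, list[float]] = {}
    for row in panel:
        acc.setdefault((row["k"], row["sketch_size"]), []).append(
            (row["distance"] - row["rate"]) ** 2
        )
    return {key: float(np.sqrt(np.mean(v))) for key, v in acc.items()}


def make_containment_dataset(
    n_seeds: int = 8,
    per_cluster: int = 50,
    seed_length: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Prefix-fragment clusters for containment-distance benchmarking.

    Each of ``n_seeds`` mutually dissimilar random seed genomes yields
    ``per_cluster`` genomes: prefixes cut to a uniform random proportion in
    (0, 1] of the seed length.  Every fragment's k-mer set is exactly
    contained in its seed's, so true containment similarity is 1 while
    inter-cluster similarity is near 0.  Truth label = seed of origin.
    """
    rng = np.random.default_rng() if rng is None else rng
    genomes: list[GenomeRecord] = []
    truth: dict[str, str] = {}
    for si in range(n_seeds):
        seed_seq = random_genome(seed_length, rng)
        cls = f"seed{si}"
        for fi in range(per_cluster):
            prop = 1.0 - rng.uniform(0.0, 1.0)  # uniform on (0, 1]
            cut = max(1, round(prop * seed_length))
            gid = f"seed{si}_frag{fi}"
            genomes.append(GenomeRecord(gid, (seed_seq[:cut],)))
            truth[gid] = cls
    return genomes, truth


def make_seed_mutant_dataset(
    n_seeds: int = 5,
    per_seed: int = 30,
    rate: float = 0.045,
    seed_length: int = 100_000,
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
    verify: bool = True,
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Seed genomes plus rate-0.045 mutants (default 5 + 150 = 155 genomes).

    When ``verify`` is set, the generator checks the intended distance
    structure with default resemblance sketches (S=1000, automatic k):
    every mutant within Mash distance 0.05 of its own seed (failing
    mutants are redrawn, up to ``max_retries`` each), every same-seed
    mutant pair above 0.05, and seed-seed distances near 1.  Estimator
    noise puts a few percent of mutant draws on the wrong side of 0.05,
    so redrawing enforces the stated structure rather than tuning it.
    """
    rng = np.random.default_rng() if rng is None else rng
    seeds = [random_genome(seed_length, rng) for _ in range(n_seeds)]
    params = sketching.SketchParams(k=sketching.optimal_kmer_size(seed_length, sketching.Q_OPTIMAL))
    seed_sketches = [
        sketching.build_sketch(GenomeRecord(f"seed{i}", (s,)), params)
        for i, s in enumerate(seeds)
    ]
    genomes: list[GenomeRecord] = []
    truth: dict[str, str] = {}
    for si, seed_seq in enumerate(seeds):
        gid = f"seed{si}"
        genomes.append(GenomeRecord(gid, (seed_seq,)))
        truth[gid] = f"seed{si}"
    if verify:
        for i in range(n_seeds):
            for j in range(i + 1, n_seeds):
                d = distances.pairwise_distance(seed_sketches[i], seed_sketches[j]).distance
                # At full (10 Mb) scale inter-seed distances clamp to 1.0; at
                # desk scale one or two chance-shared sketch hashes bound the
                # estimate near -ln(2/S)/k (~0.4), still far above any
                # clustering threshold.  Require an order of magnitude above
                # the 0.05 threshold.
                if d < 0.3:
                    raise SketchClustError(
                        f"random seeds {i},{j} unexpectedly similar (distance {d:.3f})"
                    )
    for si, seed_seq in enumerate(seeds):
        cluster_sketches = []
        for mi in range(per_seed):
            for attempt in range(max_retries + 1):
                mut = mutate(seed_seq, rate, rng)
                gid = f"seed{si}_mut{mi}"
                rec = GenomeRecord(gid, (mut,))
                sk = sketching.build_sketch(rec, params)
                if not verify:
                    break
                d_seed = distances.pairwise_distance(sk, seed_sketches[si]).distance
                if d_seed < 0.05 and all(
                    distances.pairwise_distance(sk, other).distance > 0.05
                    for other in cluster_sketches
                ):
                    break
            else:
                raise SketchClustError(
                    f"could not draw a structurally valid mutant for seed {si} "
                    f"after {max_retries} retries"
                )
            cluster_sketches.append(sk)
            genomes.append(rec)
            truth[gid] = f"seed{si}"
    return genomes, truth


def write_labels_tsv(truth: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#genome_id\tclass\n")
        for gid, cls in truth.items():
            fh.write(f"{gid}\t{cls}\n")
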