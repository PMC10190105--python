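"""Clustering-quality metrics and redundancy/impurity reporting.

For predicted clusters P and ground-truth classes G over N genomes:

* purity(P;G) = (1/N) * sum over p of max over g of |p ∩ g|
* MI(P;G)    = sum over (p,g) of (|p∩g|/N) * ln(N |p∩g| / (|p||g|))
* H(X)       = -sum over x of (|x|/N) * ln(|x|/N)
* NMI(P;G)   = MI / ((H(P) + H(G)) / 2)

Natural logarithms throughout (NMI is base-invariant); 0*ln(0) terms are
zero.  Coverage is the fraction of genomes sitting in clusters of size at
least two — purity is only meaningful when coverage is not tiny, since
all-singleton clusterings are trivially pure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .clustering import Clustering
from .errors import InputError


def _as_labels(part) -> dict[str, int | str]:
    if isinstance(part, Clustering):
        return part.labels
    return dict(part)


def _aligned(pred, truth) -> tuple[list, list]:
    p = _as_labels(pred)
    g = _as_labels(truth)
    if not p:
        raise InputError("empty partition")
    if set(p) != set(g):
        missing = set(p) ^ set(g)
        raise InputError(f"partitions cover different genomes, e.g. {sorted(missing)[:5]}")
    ids = sorted(p)
    return [p[i] for i in ids], [g[i] for i in ids]


def _contingency(pl: list, gl: list) -> dict[tuple, int]:
    table: dict[tuple, int] = {}
    for a, b in zip(pl, gl):
        table[(a, b)] = table.get((a, b), 0) + 1
    return table


def purity(pred, truth) -> float:
    """Fraction of genomes belonging to their cluster's dominant class."""
    pl, gl = _aligned(pred, truth)
    n = len(pl)
    table = _contingency(pl, gl)
    best: dict = {}
    for (p, _g), cnt in table.items():
        best[p] = max(best.get(p, 0), cnt)
    return sum(best.values()) / n


def _counts(labels: list) -> dict:
    c: dict = {}
    for x in labels:
        c[x] = c.get(x, 0) + 1
    return c


def entropy(labels: list) -> float:
    """Shannon entropy of a partition, in nats."""
    n = len(labels)
    return -sum(
        (cnt / n) * math.log(cnt / n) for cnt in _counts(labels).values()
    )


def mutual_information(pred, truth) -> float:
    pl, gl = _aligned(pred, truth)
    n = len(pl)
    pc = _counts(pl)
    gc = _counts(gl)
    mi = 0.0
    for (p, g), cnt in _contingency(pl, gl).items():
        mi += (cnt / n) * math.log(n * cnt / (pc[p] * gc[g]))
    return mi


def nmi(pred, truth) -> float:
    """Mutual information normalized by the average entropy, in [0, 1].

    Degenerate case (both partitions trivial, zero entropy): 1 when the
    partitions are identical up to relabeling, else 0.
    """
    pl, gl = _aligned(pred, truth)
    hp, hg = entropy(pl), entropy(gl)
    if hp == 0.0 and hg == 0.0:
        return 1.0 if len(set(zip(pl, gl))) == len(set(pl)) == len(set(gl)) else 0.0
    denom = (hp + hg) / 2.0
    if denom == 0.0:
        return 0.0
    return max(0.0, min(1.0, mutual_information(pred, truth) / denom))


def coverage(pred, n: int | None = None) -> float:
    """Fraction of genomes placed in clusters of size >= 2."""
    p = _as_labels(pred)
    total = n if n is not None else len(p)
    if total == 0:
        return 0.0
    sizes = _counts(list(p.values()))
    covered = sum(cnt for cnt in sizes.values() if cnt >= 2)
    return covered / total


@dataclass(frozen=True)
class ClusterImpurity:
    cluster: int | str
    size: int
    purity: float
    dominant_class: int | str
    dominant: tuple[str, ...]
    impurity: tuple[str, ...]


def impurity_report(
    pred, truth, lengths: dict[str, int] | None = None
) -> list[ClusterImpurity]:
    """Per-cluster dominant/impurity labelling for unpurified clusters.

    A cluster is unpurified when its purity is below 1; members of its
    most frequent class are dominant, the rest impurity genomes.  Class
    ties break by larger total genome length, then by label order.
    """
    p = _as_labels(pred)
    g = _as_labels(truth)
    members: dict = {}
    for gid, c in p.items():
        members.setdefault(c, []).append(gid)
    report = []
    for c in sorted(members, key=lambda c: (-len(members[c]), str(c))):
        ms = members[c]
        by_class: dict = {}
        for gid in ms:
            by_class.setdefault(g[gid], []).append(gid)

        def rank(cls):
            total_len = sum((lengths or {}).get(gid, 0) for gid in by_class[cls])
            return (-len(by_class[cls]), -total_len, str(cls))

        dom = min(by_class, key=rank)
        dominant = tuple(sorted(by_class[dom]))
        impure = tuple(sorted(gid for cls, gs in by_class.items() if cls != dom for gid in gs))
        report.append(
            ClusterImpurity(
                cluster=c,
                size=len(ms),
                purity=len(dominant) / len(ms),
                dominant_class=dom,
                dominant=dominant,
                impurity=impure,
            )
        )
    return report


def read_labels_tsv(path: str) -> dict[str, str]:
    """Two-column TSV of (genome_id, class label); '#' comments allowed."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"line {lineno} of {path}: expected two columns")
            labels[parts[0]] = parts[1]
    if not labels:
        raise InputError(f"no labels in {path}")
    return labels


def write_metrics_json(metrics: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_impurity_tsv(report: list[ClusterImpurity], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#cluster\tsize\tpurity\tdominant_class\tgenome\trole\n")
        for r in report:
            if r.purity >= 1.0:
                continue
            for gid in r.dominant:
                fh.write(f"{r.cluster}\t{r.size}\t{r.purity:.4f}\t{r.dominant_class}\t{gid}\tdominant\n")
            for gid in r.impurity:
                fh.write(f"{r.cluster}\t{r.size}\t{r.purity:.4f}\t{r.dominant_class}\t{gid}\timpurity\n")
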