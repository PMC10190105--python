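"""Cluster assignment container and the shared cluster-file format."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Clustering:
    """Assignment of every genome to exactly one cluster.

    ``labels`` maps genome id -> cluster index; ``representatives`` maps
    cluster index -> representative genome id (greedy mode only);
    ``meta`` carries run statistics (e.g. distance-computation counts).
    """

    labels: dict[str, int]
    representatives: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> list[list[str]]:
        """Member lists ordered by size descending (ties by first member)."""
        groups: dict[int, list[str]] = {}
        for gid, c in self.labels.items():
            groups.setdefault(c, []).append(gid)
        return sorted(groups.values(), key=lambda ms: (-len(ms), ms[0]))

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters()]


def write_clusters(
    clustering: Clustering,
    lengths: dict[str, int],
    path: str,
    header_lines: list[str] | None = None,
) -> None:
    """Write the cluster file: one block per cluster, size-descending.

    Lines are ``<cluster_index>\t<genome_id>\t<length>`` with a trailing
    ``*`` marker on representative genomes (greedy mode).
    """
    rep_ids = set(clustering.representatives.values())
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"#{line}\n")
        for idx, members in enumerate(clustering.clusters()):
            for gid in members:
                marker = "\t*" if gid in rep_ids else ""
                fh.write(f"{idx}\t{gid}\t{lengths.get(gid, 0)}{marker}\n")


def read_clusters(path: str) -> Clustering:
    labels: dict[str, int] = {}
    reps: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            idx, gid = int(parts[0]), parts[1]
            labels[gid] = idx
            if len(parts) > 3 and parts[3] == "*":
                reps[idx] = gid
    return Clustering(labels, reps)
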