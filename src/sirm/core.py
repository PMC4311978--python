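"""Domain types and file I/O for connectome parcellation.

The objects here mirror the generative story of the model: a set of named
brain regions, a partition of those regions into clusters, a latent binary
structural connectome per subject, and the observed tractography streamline
counts.  All matrices are square over the same region set; adjacency
matrices are symmetric with a zero diagonal (regions are not self-connected)
while streamline counts may be asymmetric (seeding from i toward j is a
different experiment than seeding from j toward i).

File formats are deliberately plain: delimited text with a header row and
row labels for matrices, two-column TSV for partitions, and newline-
delimited JSON for posterior sample chains.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sirm")

__all__ = [
    "RegionSet",
    "Partition",
    "Adjacency",
    "StreamlineData",
    "HyperParams",
    "Sample",
    "SampleChain",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "symmetrize",
    "save_chain",
    "load_chain",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSet:
    """Ordered collection of uniquely named brain regions (network nodes)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a region set needs at least two regions")
        if any(not lab for lab in self.labels):
            raise ValueError("region labels must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @classmethod
    def generic(cls, n: int, prefix: str = "region") -> "RegionSet":
        return cls(tuple(f"{prefix}{i:03d}" for i in range(n)))


def canonicalize_assignment(assignment: Sequence[int]) -> np.ndarray:
    """Relabel cluster ids to 0..K-1 in order of first appearance.

    Any relabelling of the same grouping canonicalizes to the same vector,
    which makes partitions comparable across samples.
    """
    out = np.empty(len(assignment), dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, a in enumerate(assignment):
        a = int(a)
        if a not in mapping:
            mapping[a] = len(mapping)
        out[i] = mapping[a]
    return out


@dataclass(frozen=True)
class Partition:
    """Assignment of N nodes to K non-empty clusters (the latent Z).

    The assignment is stored canonically: cluster ids are 0..K-1 ordered by
    the smallest member index, so two partitions are equal iff they group
    the nodes identically.
    """

    assignment: np.ndarray

    def __post_init__(self) -> None:
        arr = canonicalize_assignment(np.asarray(self.assignment))
        object.__setattr__(self, "assignment", arr)
        if arr.size == 0:
            raise ValueError("empty partition")

    def __len__(self) -> int:
        return int(self.assignment.size)

    @property
    def n(self) -> int:
        return len(self)

    @property
    def K(self) -> int:
        return int(self.assignment.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        """Cluster occupancies m_k, k = 0..K-1."""
        return np.bincount(self.assignment, minlength=self.K)

    def onehot(self) -> np.ndarray:
        """N x K indicator matrix Z with Z[n, k] = 1 iff node n is in cluster k."""
        z = np.zeros((self.n, self.K), dtype=np.int64)
        z[np.arange(self.n), self.assignment] = 1
        return z

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(self.assignment, other.assignment)

    def __hash__(self) -> int:
        return hash(self.assignment.tobytes())


@dataclass(frozen=True)
class Adjacency:
    """Symmetric binary N x N structural connectome with zero diagonal."""

    edges: np.ndarray
    regions: RegionSet | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.edges)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.uint8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-connections)")
        object.__setattr__(self, "edges", a)

    @property
    def n(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        return self.edges.sum(axis=1).astype(np.int64)


@dataclass(frozen=True)
class StreamlineData:
    """Observed N x N tractography streamline counts.

    Row i holds the counts of streamlines seeded in region i that terminated
    in each target region; row totals T_i are fixed by the tractography run.
    Asymmetry is allowed.  The diagonal is zero by construction; nonzero
    diagonals in input files are zeroed with a warning.
    """

    counts: np.ndarray
    regions: RegionSet | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.counts)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("streamline counts must be a square matrix")
        if not np.issubdtype(s.dtype, np.integer):
            if not np.all(s == np.floor(s)):
                raise ValueError("streamline counts must be integers")
            s = s.astype(np.int64)
        if np.any(s < 0):
            raise ValueError("streamline counts must be non-negative")
        s = s.astype(np.int64)
        if np.any(np.diag(s) != 0):
            logger.warning("nonzero diagonal in streamline counts; zeroing self-counts")
            s = s.copy()
            np.fill_diagonal(s, 0)
        object.__setattr__(self, "counts", s)

    @property
    def n(self) -> int:
        return int(self.counts.shape[0])

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class HyperParams:
    """Hyperparameters of the generative model.

    xi
        Chinese-restaurant-process concentration; larger values favour more
        clusters a priori.
    alpha, beta
        Beta prior on the cluster-to-cluster connection probabilities rho;
        alpha = beta = 1 is the uninformative default.
    delta_t, delta_f
        Dirichlet pseudo-counts of the streamline forward model for true and
        false connections.  A true connection must attract more streamline
        mass than a false one, so delta_t > delta_f is required.
    """

    xi: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    delta_t: float = 1.0
    delta_f: float = 0.05

    def __post_init__(self) -> None:
        for name in ("xi", "alpha", "beta", "delta_t", "delta_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.delta_t > self.delta_f:
            raise ValueError("delta_t must exceed delta_f")

    def to_dict(self) -> dict[str, float]:
        return {
            "xi": self.xi,
            "alpha": self.alpha,
            "beta": self.beta,
            "delta_t": self.delta_t,
            "delta_f": self.delta_f,
        }


@dataclass(frozen=True)
class Sample:
    """One retained posterior sample: (Z, {A^(m)}, joint log-posterior)."""

    partition: Partition
    adjacencies: tuple[Adjacency, ...]
    log_posterior: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_posterior):
            raise ValueError("sample log-posterior must be finite")
        for adj in self.adjacencies:
            if adj.n != self.partition.n:
                raise ValueError("sample adjacency size differs from partition size")


@dataclass
class SampleChain:
    """Ordered posterior samples plus the metadata needed to reproduce them."""

    samples: list[Sample]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples:
            n = self.samples[0].partition.n
            m = len(self.samples[0].adjacencies)
            for s in self.samples:
                if s.partition.n != n or len(s.adjacencies) != m:
                    raise ValueError("all samples must share N and subject count")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    @property
    def log_posteriors(self) -> np.ndarray:
        return np.array([s.log_posterior for s in self.samples])

    @property
    def cluster_counts(self) -> np.ndarray:
        return np.array([s.partition.K for s in self.samples])


# ---------------------------------------------------------------------------
# Matrix and partition I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_matrix(path: str | Path, kind: str = "counts") -> StreamlineData | Adjacency:
    """Read a labelled square matrix from delimited text (TSV or CSV).

    Parameters
    ----------
    path
        File with a header row of region labels and one labelled row per
        region.
    kind
        ``"counts"`` for streamline counts (non-negative integers, asymmetry
        allowed) or ``"binary"`` for an adjacency matrix (0/1, symmetric).
    """
    if kind not in ("counts", "binary"):
        raise ValueError("kind must be 'counts' or 'binary'")
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]})")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels")
    regions = RegionSet(tuple(rows))
    values = df.to_numpy()
    if kind == "binary":
        return Adjacency(values, regions=regions)
    return StreamlineData(values, regions=regions)


def write_matrix(
    matrix: StreamlineData | Adjacency | np.ndarray,
    path: str | Path,
    regions: RegionSet | None = None,
) -> None:
    """Write a square matrix as TSV with region labels on both axes."""
    if isinstance(matrix, StreamlineData):
        arr, regions = matrix.counts, regions or matrix.regions
    elif isinstance(matrix, Adjacency):
        arr, regions = matrix.edges, regions or matrix.regions
    else:
        arr = np.asarray(matrix)
    if regions is None:
        regions = RegionSet.generic(arr.shape[0])
    df = pd.DataFrame(arr, index=list(regions.labels), columns=list(regions.labels))
    df.to_csv(path, sep="\t")


def write_partition(partition: Partition, regions: RegionSet, path: str | Path) -> None:
    """Write a partition as two-column TSV (region label, cluster id)."""
    if partition.n != regions.n:
        raise ValueError("partition length does not match region count")
    with open(path, "w") as fh:
        fh.write("region\tcluster\n")
        for lab, k in zip(regions.labels, partition.assignment):
            fh.write(f"{lab}\t{int(k)}\n")


def read_partition(path: str | Path, regions: RegionSet | None = None) -> tuple[Partition, RegionSet]:
    """Read a two-column partition file; optionally reorder to match `regions`."""
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (region, cluster)")
    labels = [str(x) for x in df.iloc[:, 0]]
    assign = df.iloc[:, 1].to_numpy()
    file_regions = RegionSet(tuple(labels))
    if regions is not None:
        idx = file_regions.index
        try:
            order = [idx[lab] for lab in regions.labels]
        except KeyError as exc:
            raise ValueError(f"{path}: region label mismatch: {exc}") from exc
        assign = assign[order]
        file_regions = regions
    return Partition(assign), file_regions


def symmetrize(streamlines: StreamlineData) -> StreamlineData:
    """Return the symmetrized counts S' = S + S^T (total count doubles)."""
    return StreamlineData(streamlines.counts + streamlines.counts.T, regions=streamlines.regions)


# ---------------------------------------------------------------------------
# Chain serialization (NDJSON records + JSON metadata header)
# ---------------------------------------------------------------------------


def _edge_list(adj: Adjacency) -> list[list[int]]:
    iu = np.triu_indices(adj.n, k=1)
    present = adj.edges[iu] == 1
    return [[int(i), int(j)] for i, j in zip(iu[0][present], iu[1][present])]


def save_chain(chain: SampleChain, path: str | Path) -> None:
    """Serialize a chain: one JSON record per sample, plus a `.meta.json` header."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in chain.samples:
            rec = {
                "assignment": [int(a) for a in s.partition.assignment],
                "edges": [_edge_list(a) for a in s.adjacencies],
                "log_posterior": float(s.log_posterior),
            }
            fh.write(json.dumps(rec) + "\n")
    meta = dict(chain.meta)
    if chain.samples:
        meta.setdefault("n_regions", chain.samples[0].partition.n)
        meta.setdefault("n_subjects", len(chain.samples[0].adjacencies))
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_chain(path: str | Path) -> SampleChain:
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    samples: list[Sample] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            assign = np.array(rec["assignment"], dtype=np.int64)
            n = assign.size
            adjs = []
            for edges in rec["edges"]:
                a = np.zeros((n, n), dtype=np.uint8)
                for i, j in edges:
                    a[i, j] = a[j, i] = 1
                adjs.append(Adjacency(a))
            samples.append(Sample(Partition(assign), tuple(adjs), float(rec["log_posterior"])))
    return SampleChain(samples, meta=meta)
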