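"""Explicit random cross-feeding networks via a configuration model.

A cross-feeding network is a directed bipartite graph on N consumer
populations and M metabolites with two edge types: requirement edges
(metabolite -> consumer, "this consumer needs that metabolite") and
production edges (consumer -> metabolite, "this consumer secretes that
metabolite").

Generation follows a configuration-model construction: the number of edge
END points at each node (requirements per consumer, producers per
metabolite) is drawn from the target degree distribution; the edge START
points are partitioned over the source nodes by a multinomial with equal
cell probabilities, conditioned on the realised total link count, which
enforces stub balance exactly for any N, M; start and end stubs are then
paired by a seeded uniform shuffle.  Duplicate stub pairings are collapsed
to simple edges afterwards — the presence rules (all requirements / any
producer) are insensitive to edge multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrossFeedingNetwork",
    "generate_network",
    "wire_edges",
    "read_network",
    "write_network",
]


@dataclass(eq=False)
class CrossFeedingNetwork:
    """Directed bipartite cross-feeding network.

    ``req_edges`` holds (metabolite_id, consumer_id) rows; ``prod_edges``
    holds (consumer_id, metabolite_id) rows.  Both are deduplicated and
    lexicographically sorted.  ``supplied`` flags metabolites provided
    externally (present regardless of producers during percolation).
    Consumer and metabolite ids are 0-based and live in separate id spaces.
    """

    n_consumers: int
    n_metabolites: int
    req_edges: np.ndarray  # shape (E_r, 2): met -> cons
    prod_edges: np.ndarray  # shape (E_p, 2): cons -> met
    supplied: np.ndarray = field(default=None)  # bool, shape (M,)

    def __post_init__(self) -> None:
        if self.n_consumers < 0 or self.n_metabolites < 0:
            raise ValueError("node counts must be non-negative")
        self.req_edges = _canonical_edges(self.req_edges)
        self.prod_edges = _canonical_edges(self.prod_edges)
        if self.supplied is None:
            self.supplied = np.zeros(self.n_metabolites, dtype=bool)
        self.supplied = np.asarray(self.supplied, dtype=bool)
        if self.supplied.shape != (self.n_metabolites,):
            raise ValueError("supplied flags must have one entry per metabolite")
        self._validate_ids()

    def _validate_ids(self) -> None:
        for name, edges, src_n, dst_n in (
            ("requirement", self.req_edges, self.n_metabolites, self.n_consumers),
            ("production", self.prod_edges, self.n_consumers, self.n_metabolites),
        ):
            if len(edges) == 0:
                continue
            if edges[:, 0].min() < 0 or edges[:, 0].max() >= src_n:
                raise ValueError(f"{name} edge references invalid source id")
            if edges[:, 1].min() < 0 or edges[:, 1].max() >= dst_n:
                raise ValueError(f"{name} edge references invalid target id")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossFeedingNetwork):
            return NotImplemented
        return (
            self.n_consumers == other.n_consumers
            and self.n_metabolites == other.n_metabolites
            and np.array_equal(self.req_edges, other.req_edges)
            and np.array_equal(self.prod_edges, other.prod_edges)
            and np.array_equal(self.supplied, other.supplied)
        )

    # adjacency views used by the percolator
    def requirements_by_consumer(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_consumers)]
        for met, cons in self.req_edges:
            adj[cons].append(int(met))
        return adj

    def producers_by_metabolite(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_metabolites)]
        for cons, met in self.prod_edges:
            adj[met].append(int(cons))
        return adj


def _canonical_edges(edges) -> np.ndarray:
    arr = np.asarray(edges, dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("edges must be an (E, 2) array of id pairs")
    return np.unique(arr, axis=0)


def wire_edges(
    rng: np.random.Generator,
    n_source: int,
    end_degrees: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Configuration-model wiring for one edge type; may contain duplicates.

    ``end_degrees[i]`` is the sampled number of edges terminating at target
    node i.  Start stubs are partitioned over the ``n_source`` source nodes
    by an equal-probability multinomial conditioned on the realised total,
    then paired with the end stubs by a uniform shuffle.  Returns
    (source_ids, target_ids) of equal length sum(end_degrees).
    """
    end_degrees = np.asarray(end_degrees, dtype=np.int64)
    total = int(end_degrees.sum())
    start_counts = rng.multinomial(total, np.full(n_source, 1.0 / n_source))
    starts = np.repeat(np.arange(n_source, dtype=np.int64), start_counts)
    ends = np.repeat(np.arange(len(end_degrees), dtype=np.int64), end_degrees)
    rng.shuffle(starts)
    return starts, ends


def generate_network(
    N: int, M: int, z_c: float, z_m: float, seed: int
) -> CrossFeedingNetwork:
    """Random network with Poisson(z_c) requirements and Poisson(z_m) producers.

    Deterministic for a fixed (N, M, z_c, z_m, seed).  Zero-link edge types
    are valid (z = 0 gives an edgeless side).
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    if z_c < 0 or z_m < 0:
        raise ValueError("mean degrees must be >= 0")
    rng = np.random.default_rng(seed)
    req_deg = rng.poisson(z_c, N)  # requirement-edge end points sit at consumers
    met_src, cons_dst = wire_edges(rng, M, req_deg)
    prod_deg = rng.poisson(z_m, M)  # production-edge end points sit at metabolites
    cons_src, met_dst = wire_edges(rng, N, prod_deg)
    return CrossFeedingNetwork(
        n_consumers=N,
        n_metabolites=M,
        req_edges=np.column_stack([met_src, cons_dst]),
        prod_edges=np.column_stack([cons_src, met_dst]),
    )


def write_network(net: CrossFeedingNetwork, path) -> None:
    """Serialise to the documented TSV edge-list format."""
    with open(path, "w") as fh:
        fh.write(f"#consumers\t{net.n_consumers}\n")
        fh.write(f"#metabolites\t{net.n_metabolites}\n")
        for met in np.flatnonzero(net.supplied):
            fh.write(f"#supplied\t{met}\n")
        for met, cons in net.req_edges:
            fh.write(f"REQ\t{met}\t{cons}\n")
        for cons, met in net.prod_edges:
            fh.write(f"PROD\t{cons}\t{met}\n")


def read_network(path) -> CrossFeedingNetwork:
    """Parse the TSV edge-list format; hard error naming any malformed line."""
    n_cons = n_mets = None
    supplied_ids: list[int] = []
    req, prod = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                if fields[0] == "#consumers":
                    n_cons = int(fields[1])
                elif fields[0] == "#metabolites":
                    n_mets = int(fields[1])
                elif fields[0] == "#supplied":
                    supplied_ids.append(int(fields[1]))
                elif fields[0] == "REQ":
                    req.append((int(fields[1]), int(fields[2])))
                elif fields[0] == "PROD":
                    prod.append((int(fields[1]), int(fields[2])))
                else:
                    raise ValueError(f"unknown record type {fields[0]!r}")
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r} ({err})")
    if n_cons is None or n_mets is None:
        raise ValueError(f"{path}: missing #consumers/#metabolites header")
    supplied = np.zeros(n_mets, dtype=bool)
    for met in supplied_ids:
        if not 0 <= met < n_mets:
            raise ValueError(f"{path}: supplied flag references unknown metabolite {met}")
    supplied[supplied_ids] = True
    try:
        return CrossFeedingNetwork(
            n_consumers=n_cons,
            n_metabolites=n_mets,
            req_edges=np.array(req, dtype=np.int64).reshape(-1, 2),
            prod_edges=np.array(prod, dtype=np.int64).reshape(-1, 2),
            supplied=supplied,
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}")
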