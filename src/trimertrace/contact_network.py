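"""Residue contact networks and Fiedler-vector spectral bipartition.

A protein contact network (PCN) has one node per residue (its C-alpha) and an
edge wherever the C-alpha distance falls in a noncovalent band, 4-8 Angstrom
by default: the lower cutoff excludes covalently bonded backbone neighbours
(consecutive C-alphas sit near 3.8 A), the upper keeps only genuine contacts.
The graph Laplacian L = D - A is decomposed and the eigenvector of the
second-smallest eigenvalue (the Fiedler vector) splits the network in two by
the sign of its components. On a homotrimer with dynamic asymmetry this
bipartition pins two subunits in one cluster and the third alone — the 2:1
signature tracked frame by frame in :func:`cluster_trace`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from trimertrace.errors import ValidationError
from trimertrace.structure_io import Frame, StructureEnsemble

_ZERO_TOL = 1e-12  # |v2_i| below this times ||v2||_inf counts as zero
_DEGENERACY_TOL = 1e-10


@dataclass
class ContactNetwork:
    """Binary residue contact graph of one frame, with Laplacian views."""

    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    chain_ids: np.ndarray  # (n,) residue -> chain
    res_ids: np.ndarray  # (n,) residue -> author number
    cutoff_low: float = 4.0
    cutoff_high: float = 8.0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree_matrix - self.adjacency

    def n_components(self) -> int:
        n, _ = connected_components(self.adjacency, directed=False)
        return int(n)

    def interchain_edge_count(self, chain_x: str, chain_y: str) -> int:
        mx = self.chain_ids == chain_x
        my = self.chain_ids == chain_y
        return int(self.adjacency[np.ix_(mx, my)].sum())


@dataclass
class SpectralPartition:
    fiedler_vector: np.ndarray
    algebraic_connectivity: float
    labels: np.ndarray  # (n,) +1 / -1 by sign of the Fiedler components
    connected: bool


@dataclass
class ChainClustering:
    """Chain-level 2:1 result for one frame."""

    paired_chains: frozenset
    lone_chain: str
    purity: float  # fraction of residues matching their chain's majority label
    connected: bool
    low_confidence: bool = False
    disconnected_interface: bool = False


@dataclass
class ClusterTrace:
    clusterings: list  # per-frame ChainClustering
    lambda2: np.ndarray  # per-frame algebraic connectivity
    switch_events: list  # frame indices where paired_chains changes
    occupancy: dict  # pairing -> fraction of frames
    times_ns: np.ndarray

    def __len__(self):
        return len(self.clusterings)

    def paired_series(self) -> list:
        return [c.paired_chains for c in self.clusterings]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusterings):
            rows.append(
                {
                    "frame": i,
                    "time_ns": self.times_ns[i],
                    "paired_chains": "".join(sorted(c.paired_chains)),
                    "lone_chain": c.lone_chain,
                    "purity": c.purity,
                    "lambda2": self.lambda2[i],
                    "switch": i in self.switch_events,
                    "low_confidence": c.low_confidence,
                }
            )
        return pd.DataFrame(rows)


def build_contact_network(
    frame: Frame, cutoff_low: float = 4.0, cutoff_high: float = 8.0
) -> ContactNetwork:
    """Build the PCN of one frame from C-alpha distances.

    An edge joins residues i != j iff cutoff_low <= ||CA_i - CA_j|| <=
    cutoff_high; intra- and inter-chain pairs pass through the same band
    (covalent neighbours are excluded by the lower cutoff alone).
    """
    if cutoff_low >= cutoff_high:
        raise ValidationError(
            f"cutoff_low ({cutoff_low}) must be < cutoff_high ({cutoff_high})",
            field="cutoff_low",
        )
    if frame.n_residues < 2:
        raise ValidationError("frame must contain at least 2 residues", field="frame")
    d = squareform(pdist(frame.ca_coords))
    adjacency = ((d >= cutoff_low) & (d <= cutoff_high)).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return ContactNetwork(
        adjacency=adjacency,
        chain_ids=frame.chain_ids.copy(),
        res_ids=frame.res_ids.copy(),
        cutoff_low=cutoff_low,
        cutoff_high=cutoff_high,
    )


def _labels_from_vector(v: np.ndarray) -> np.ndarray:
    # components indistinguishable from zero join the positive class
    scale = np.max(np.abs(v))
    if scale == 0:
        return np.ones(len(v), dtype=int)
    labels = np.where(v >= -_ZERO_TOL * scale, 1, -1)
    return labels


def _orient(v: np.ndarray, chain_ids: np.ndarray) -> np.ndarray:
    """Fix the arbitrary eigenvector sign: first chain's mean component >= 0."""
    first = min(str(c) for c in chain_ids)
    mean = v[chain_ids == first].mean()
    if mean < 0 or (mean == 0 and v.sum() < 0):
        return -v
    return v


def fiedler_partition(network: ContactNetwork) -> SpectralPartition:
    """Spectral bipartition of the PCN by the Fiedler vector of L = D - A.

    The eigenvector of the second-smallest Laplacian eigenvalue is computed
    with a symmetric dense solver; nodes are two-coloured by the sign of its
    components. On a disconnected graph the algebraic connectivity is zero
    (within tolerance) and the partition separates components. Under
    eigenvalue degeneracy the eigenvector whose sign pattern gives the most
    balanced cut is chosen, then the lexicographically smallest labelling —
    a fixed deterministic rule.
    """
    n = network.n_nodes
    if n < 3:
        raise ValidationError("spectral partition needs at least 3 nodes", field="network")
    lap = network.laplacian.astype(float)
    eigenvalues, eigenvectors = eigh(lap)
    lam2 = float(eigenvalues[1])

    n_comp, comp_labels = connected_components(network.adjacency, directed=False)
    if n_comp > 1:
        # the zero eigenspace is degenerate and eigh returns an arbitrary
        # rotation of the component indicators; build the component-separating
        # vector deterministically instead (largest components balanced greedily)
        sizes = np.bincount(comp_labels)
        order = sorted(range(n_comp), key=lambda c: (-sizes[c], c))
        side, totals = {}, [0, 0]
        for c in order:
            s = 0 if totals[0] <= totals[1] else 1
            side[c] = s
            totals[s] += sizes[c]
        raw = np.array([1.0 if side[c] == 0 else -1.0 for c in comp_labels])
        v = raw - raw.mean()
        v = _orient(v / np.linalg.norm(v), network.chain_ids)
        return SpectralPartition(
            fiedler_vector=v,
            algebraic_connectivity=lam2,
            labels=_labels_from_vector(v),
            connected=False,
        )

    scale = max(1.0, float(eigenvalues[-1]))
    candidates = [
        i
        for i in range(1, n)
        if eigenvalues[i] - eigenvalues[1] < _DEGENERACY_TOL * scale
    ]
    best = None
    for i in candidates:
        v = _orient(eigenvectors[:, i], network.chain_ids)
        labels = _labels_from_vector(v)
        balance = abs(int(labels.sum()))
        key = (balance, tuple(labels))
        if best is None or key < best[0]:
            best = (key, v, labels)
    _, v2, labels = best

    return SpectralPartition(
        fiedler_vector=v2,
        algebraic_connectivity=lam2,
        labels=labels,
        connected=True,
    )


def assign_chain_clusters(
    partition: SpectralPartition, network: ContactNetwork
) -> ChainClustering:
    """Chain-level 2:1 assignment from a residue-level bipartition.

    Each chain takes the majority label of its residues; the two chains that
    share a majority label form the pair. If all three chains share one
    majority label there is no 2:1 spectral signal: the pairing falls back to
    the two chains with the most inter-chain contacts between them and the
    result is flagged low-confidence. With no inter-chain edges at all the
    pairing is arbitrary (lexicographic) and flagged disconnected.
    """
    chains = sorted(set(network.chain_ids))
    if len(chains) != 3:
        raise ValidationError(
            f"chain clustering is trimer-specific, got {len(chains)} chains",
            field="network",
        )
    majority = {}
    for c in chains:
        mask = network.chain_ids == c
        s = int(partition.labels[mask].sum())
        majority[c] = 1 if s >= 0 else -1
    matches = np.array(
        [partition.labels[i] == majority[c] for i, c in enumerate(network.chain_ids)]
    )
    purity = float(matches.mean())

    pairs = list(itertools.combinations(chains, 2))
    interchain = {
        frozenset(p): network.interchain_edge_count(*p) for p in pairs
    }
    no_interface = all(v == 0 for v in interchain.values())

    values = list(majority.values())
    if no_interface:
        paired = frozenset(pairs[0])
        low_confidence = True
    elif len(set(values)) == 1:
        # no 2:1 signal: most-connected pair, flagged
        paired = max(sorted(interchain), key=lambda p: interchain[p])
        low_confidence = True
    else:
        minority_label = 1 if values.count(1) == 1 else -1
        lone = next(c for c in chains if majority[c] == minority_label)
        paired = frozenset(c for c in chains if c != lone)
        low_confidence = False

    lone_chain = next(c for c in chains if c not in paired)
    return ChainClustering(
        paired_chains=paired,
        lone_chain=lone_chain,
        purity=purity,
        connected=partition.connected,
        low_confidence=low_confidence,
        disconnected_interface=no_interface,
    )


def cluster_frame(
    frame: Frame, cutoff_low: float = 4.0, cutoff_high: float = 8.0
) -> tuple[ChainClustering, SpectralPartition]:
    network = build_contact_network(frame, cutoff_low, cutoff_high)
    partition = fiedler_partition(network)
    return assign_chain_clusters(partition, network), partition


def cluster_trace(
    ensemble: StructureEnsemble, cutoff_low: float = 4.0, cutoff_high: float = 8.0
) -> ClusterTrace:
    """Per-frame 2:1 clustering over an ensemble, with switch events.

    A switch event is any frame whose paired chains differ from the previous
    frame's. The occupancy summary gives the fraction of frames spent in each
    pairing.
    """
    clusterings, lambda2 = [], []
    for frame in ensemble.frames:
        clustering, partition = cluster_frame(frame, cutoff_low, cutoff_high)
        clusterings.append(clustering)
        lambda2.append(partition.algebraic_connectivity)
    switches = [
        i
        for i in range(1, len(clusterings))
        if clusterings[i].paired_chains != clusterings[i - 1].paired_chains
    ]
    pairings = [c.paired_chains for c in clusterings]
    occupancy = {
        pair: pairings.count(pair) / len(pairings) for pair in sorted(set(pairings), key=sorted)
    }
    return ClusterTrace(
        clusterings=clusterings,
        lambda2=np.array(lambda2),
        switch_events=switches,
        occupancy=occupancy,
        times_ns=ensemble.times_ns(),
    )


def write_adjacency(network: ContactNetwork, path) -> None:
    """Sparse text export of the adjacency (1-based node indices)."""
    rows, cols = np.nonzero(np.triu(network.adjacency))
    with open(path, "w") as fh:
        fh.write(f"% PCN adjacency, {network.n_nodes} nodes, band "
                 f"[{network.cutoff_low}, {network.cutoff_high}] A\n")
        fh.write(f"{network.n_nodes} {network.n_nodes} {len(rows)}\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i + 1} {j + 1} 1\n")
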