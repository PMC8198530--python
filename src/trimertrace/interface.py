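"""Inter-chain contact maps, distance classes, contact typing and hotspots.

The contact map of a chain pair holds, for every residue of one chain against
every residue of the other, the minimum inter-residue distance — over
C-alphas only, or over all heavy atoms when atom records are available. The
map is classified into nested distance ranges (7, 10, 13, 16 Angstrom by
default, upper edges inclusive), contacts at the tightest range are typed
hydrophobic / hydrophilic / mixed, difference maps flag gained and lost
contacts between frames, and a sliding window ranks the sequence segments
richest in tight contacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from trimertrace.errors import ValidationError
from trimertrace.structure_io import Frame

logger = logging.getLogger(__name__)

DEFAULT_BINS = (7.0, 10.0, 13.0, 16.0)

#: Residues counted as hydrophobic when typing contacts: the aliphatic and
#: aromatic side chains plus GLY, CYS, PRO and TYR. A contact is hydrophobic
#: if both partners are in this set, hydrophilic if neither is, mixed else.
HYDROPHOBIC = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS", "GLY", "TYR"}
)
_STANDARD_AA = HYDROPHOBIC | {
    "ARG", "ASN", "ASP", "GLN", "GLU", "HIS", "LYS", "SER", "THR",
}


@dataclass
class ContactMap:
    """Minimum inter-residue distances between two chains of one frame."""

    chain_pair: tuple[str, str]
    distances: np.ndarray  # (n_x, n_y) Angstrom
    res_ids_x: np.ndarray
    res_ids_y: np.ndarray
    res_names_x: np.ndarray
    res_names_y: np.ndarray
    mode: str  # "ca_only" | "all_atom"
    bin_edges: tuple[float, ...] = DEFAULT_BINS

    def __post_init__(self):
        edges = tuple(self.bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("bin_edges must be strictly increasing", field="bin_edges")
        self.bin_edges = edges

    @property
    def shape(self):
        return self.distances.shape

    def transpose(self) -> "ContactMap":
        return ContactMap(
            chain_pair=(self.chain_pair[1], self.chain_pair[0]),
            distances=self.distances.T.copy(),
            res_ids_x=self.res_ids_y,
            res_ids_y=self.res_ids_x,
            res_names_x=self.res_names_y,
            res_names_y=self.res_names_x,
            mode=self.mode,
            bin_edges=self.bin_edges,
        )

    def to_long_frame(self) -> pd.DataFrame:
        classes = bin_contact_map(self)
        ii, jj = np.meshgrid(
            np.arange(len(self.res_ids_x)), np.arange(len(self.res_ids_y)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "res_i": self.res_ids_x[ii.ravel()],
                "res_j": self.res_ids_y[jj.ravel()],
                "distance_A": self.distances.ravel(),
                "distance_class": classes.ravel(),
                "type": [
                    _contact_type(a, b)
                    for a, b in zip(
                        self.res_names_x[ii.ravel()], self.res_names_y[jj.ravel()]
                    )
                ],
            }
        )


def interchain_distance_map(
    frame: Frame,
    chain_x: str,
    chain_y: str,
    mode: str = "ca_only",
    bin_edges: tuple[float, ...] = DEFAULT_BINS,
) -> ContactMap:
    """Minimum-distance map between two chains.

    ``ca_only`` measures C-alpha to C-alpha; ``all_atom`` takes the minimum
    over all heavy-atom pairs of the two residues and requires atom records
    on the frame.
    """
    for c in (chain_x, chain_y):
        if not frame.chain_mask(c).any():
            raise ValidationError(f"chain {c!r} not present in frame", field="chain")
    if mode not in ("ca_only", "all_atom"):
        raise ValidationError(f"unknown mode {mode!r}", field="mode")
    mx, my = frame.chain_mask(chain_x), frame.chain_mask(chain_y)

    if mode == "ca_only":
        d = cdist(frame.ca_coords[mx], frame.ca_coords[my])
    else:
        if not frame.has_atoms():
            raise ValidationError(
                "all_atom mode requires atom records on the frame", field="mode"
            )
        idx_x = np.flatnonzero(mx)
        idx_y = np.flatnonzero(my)
        pos_x = {r: k for k, r in enumerate(idx_x)}
        pos_y = {r: k for k, r in enumerate(idx_y)}
        in_x = np.isin(frame.atom_res_index, idx_x)
        in_y = np.isin(frame.atom_res_index, idx_y)
        ax, ay = frame.atom_coords[in_x], frame.atom_coords[in_y]
        rx = np.array([pos_x[r] for r in frame.atom_res_index[in_x]])
        ry = np.array([pos_y[r] for r in frame.atom_res_index[in_y]])
        all_d = cdist(ax, ay)
        d = np.full((len(idx_x), len(idx_y)), np.inf)
        np.minimum.at(d, (rx[:, None], ry[None, :]), all_d)

    return ContactMap(
        chain_pair=(chain_x, chain_y),
        distances=d,
        res_ids_x=frame.res_ids[mx],
        res_ids_y=frame.res_ids[my],
        res_names_x=frame.res_names[mx],
        res_names_y=frame.res_names[my],
        mode=mode,
        bin_edges=tuple(bin_edges),
    )


def bin_contact_map(cmap: ContactMap) -> np.ndarray:
    """Distance-class matrix: class k iff d <= edge_k (and > edge_{k-1}).

    With the default edges, class 1 means d <= 7 A, class 2 (7, 10], class 3
    (10, 13], class 4 (13, 16]; distances beyond the last edge are class 0
    (unclassified). Upper edges are inclusive.
    """
    edges = np.asarray(cmap.bin_edges)
    classes = np.searchsorted(edges, cmap.distances, side="left") + 1
    classes[cmap.distances > edges[-1]] = 0
    return classes.astype(int)


def _contact_type(name_a: str, name_b: str) -> str:
    a, b = str(name_a).upper(), str(name_b).upper()
    for nm in (a, b):
        if nm not in _STANDARD_AA:
            logger.warning("unknown residue name %s: counted as hydrophilic", nm)
    pa, pb = a in HYDROPHOBIC, b in HYDROPHOBIC
    if pa and pb:
        return "hydrophobic"
    if not pa and not pb:
        return "hydrophilic"
    return "mixed"


@dataclass
class ContactTypeSummary:
    hydrophobic: int
    hydrophilic: int
    mixed: int
    tight_bin: int

    @property
    def total(self) -> int:
        return self.hydrophobic + self.hydrophilic + self.mixed


def classify_contact_types(cmap: ContactMap, tight_bin: int = 1) -> ContactTypeSummary:
    """Count hydrophobic / hydrophilic / mixed contacts at the tightest classes."""
    classes = bin_contact_map(cmap)
    counts = {"hydrophobic": 0, "hydrophilic": 0, "mixed": 0}
    ii, jj = np.nonzero((classes >= 1) & (classes <= tight_bin))
    for i, j in zip(ii, jj):
        counts[_contact_type(cmap.res_names_x[i], cmap.res_names_y[j])] += 1
    return ContactTypeSummary(tight_bin=tight_bin, **counts)


@dataclass
class ContactDiff:
    gained: set  # residue-id pairs in contact in b but not a
    lost: set
    threshold_bin: int


def diff_contact_maps(map_a: ContactMap, map_b: ContactMap, threshold_bin: int = 1) -> ContactDiff:
    """Contacts gained and lost going from map_a to map_b.

    A pair is "in contact" when its distance class is <= threshold_bin.
    """
    if map_a.chain_pair != map_b.chain_pair or map_a.shape != map_b.shape:
        raise ValidationError(
            "maps must cover the same chain pair with identical dimensions",
            field="map_b",
        )
    in_a = (bin_contact_map(map_a) >= 1) & (bin_contact_map(map_a) <= threshold_bin)
    in_b = (bin_contact_map(map_b) >= 1) & (bin_contact_map(map_b) <= threshold_bin)

    def pairs(mask, cmap):
        ii, jj = np.nonzero(mask)
        return {
            (int(cmap.res_ids_x[i]), int(cmap.res_ids_y[j])) for i, j in zip(ii, jj)
        }

    return ContactDiff(
        gained=pairs(in_b & ~in_a, map_b),
        lost=pairs(in_a & ~in_b, map_a),
        threshold_bin=threshold_bin,
    )


@dataclass
class HotspotSegment:
    start_res: int
    end_res: int
    contact_count: int


def interface_hotspots(
    cmap: ContactMap, window: int = 10, tight_bin: int = 1, max_segments: int = 4
) -> list[HotspotSegment]:
    """Contiguous sequence windows of the first chain richest in tight contacts.

    Counts, per residue of chain X, its contacts at class <= tight_bin, sums
    them over a sliding window of ``window`` residues, and returns the
    highest-count non-overlapping windows (greedy, ties to the earlier
    segment). Windows with no contacts are not reported.
    """
    n = len(cmap.res_ids_x)
    if window < 1 or window > n:
        raise ValidationError(
            f"window must be in [1, {n}] for this chain", field="window"
        )
    classes = bin_contact_map(cmap)
    per_res = (((classes >= 1) & (classes <= tight_bin)).sum(axis=1)).astype(float)
    counts = np.convolve(per_res, np.ones(window), mode="valid")  # index = window start

    order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
    chosen: list[int] = []
    for start in order:
        if counts[start] <= 0 or len(chosen) >= max_segments:
            break
        if all(abs(start - s) >= window for s in chosen):
            chosen.append(start)
    return [
        HotspotSegment(
            start_res=int(cmap.res_ids_x[s]),
            end_res=int(cmap.res_ids_x[s + window - 1]),
            contact_count=int(counts[s]),
        )
        for s in sorted(chosen)
    ]
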