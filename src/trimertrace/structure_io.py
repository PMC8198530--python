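"""Multi-frame, multi-chain structure I/O and the ensemble data model.

Structures come and go as PDB: one MODEL per frame for multi-frame ensembles,
no MODEL records for single frames. Parsing is delegated to biotite; this
module layers the analysis contract on top — amino-acid residues only, one
mandatory C-alpha per residue, residues ordered by (chain, number, insertion
code), and strict congruence of the residue list across frames so every
downstream time series is index-aligned.

Coordinates are Angstroms throughout; frame times, when known, nanoseconds.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from trimertrace.errors import ValidationError

logger = logging.getLogger(__name__)

# PDB fixed-width coordinate field: %8.3f
_COORD_MIN, _COORD_MAX = -999.999, 9999.999


@dataclass
class Frame:
    """One time point of an ensemble.

    Residue-level arrays are index-aligned: element ``i`` of ``chain_ids``,
    ``res_ids``, ``res_names`` and row ``i`` of ``ca_coords`` describe the
    same residue. Optional all-atom arrays (heavy atoms, used by the all-atom
    contact-map mode) map each atom to its residue through ``atom_res_index``.
    """

    index: int
    chain_ids: np.ndarray  # (N,) str
    res_ids: np.ndarray  # (N,) int, author numbering
    res_names: np.ndarray  # (N,) 3-letter codes
    ca_coords: np.ndarray  # (N, 3) Angstrom
    time_ns: float | None = None
    atom_coords: np.ndarray | None = None  # (M, 3)
    atom_res_index: np.ndarray | None = None  # (M,) int into residue arrays
    atom_names: np.ndarray | None = None  # (M,) str

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return tuple(seen)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def has_atoms(self) -> bool:
        return self.atom_coords is not None

    def residue_key(self) -> list[tuple[str, int, str]]:
        """Identity of each residue, used for congruence checks."""
        return [
            (str(c), int(r), str(n))
            for c, r, n in zip(self.chain_ids, self.res_ids, self.res_names)
        ]


@dataclass
class StructureEnsemble:
    """Ordered frames of one multi-chain structure, congruent in residues."""

    frames: list[Frame]
    frame_interval_ns: float | None = None
    chain_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("ensemble must contain at least one frame", field="frames")
        if not self.chain_ids:
            self.chain_ids = self.frames[0].chains

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues

    def times_ns(self) -> np.ndarray:
        if self.frame_interval_ns is not None:
            return np.arange(self.n_frames) * self.frame_interval_ns
        return np.array(
            [f.time_ns if f.time_ns is not None else float(i) for i, f in enumerate(self.frames)]
        )

    def ca_trajectory(self) -> np.ndarray:
        """(n_frames, n_residues, 3) stacked C-alpha coordinates."""
        return np.stack([f.ca_coords for f in self.frames])


def _frame_from_atom_array(array, index: int, chain_filter=None) -> Frame:
    """Build a Frame from a biotite AtomArray (one model)."""
    keep = ~array.hetero
    keep &= np.array([bool(n.strip()) for n in array.res_name])
    if chain_filter is not None:
        chain_filter = set(chain_filter)
        keep &= np.isin(array.chain_id, list(chain_filter))
    array = array[keep]
    if array.array_length() == 0:
        raise ValidationError("no amino-acid ATOM records after filtering", field="source")

    ins = (
        array.ins_code
        if "ins_code" in array.get_annotation_categories()
        else np.full(array.array_length(), "", dtype="U1")
    )
    keys = list(zip(array.chain_id, array.res_id, ins))
    order = sorted(range(len(keys)), key=lambda i: (keys[i][0], int(keys[i][1]), keys[i][2]))

    chain_ids, res_ids, res_names, ca, atom_rows, atom_res = [], [], [], [], [], []
    atom_names = []
    current = None
    res_atoms: list[int] = []

    def flush(res_atoms):
        if not res_atoms:
            return
        names = array.atom_name[res_atoms]
        ca_idx = [k for k, nm in zip(res_atoms, names) if nm.strip() == "CA"]
        c, r, nm3 = (
            str(array.chain_id[res_atoms[0]]),
            int(array.res_id[res_atoms[0]]),
            str(array.res_name[res_atoms[0]]),
        )
        if not ca_idx:
            logger.warning(
                "dropping residue %s/%s %s: no C-alpha record", c, r, nm3
            )
            return
        res_index = len(res_ids)
        chain_ids.append(c)
        res_ids.append(r)
        res_names.append(nm3)
        ca.append(array.coord[ca_idx[0]])
        for k in res_atoms:
            element = str(array.element[k]).strip().upper()
            if element == "H":
                continue
            atom_rows.append(array.coord[k])
            atom_res.append(res_index)
            atom_names.append(str(array.atom_name[k]).strip())

    for i in order:
        key = keys[i]
        if key != current:
            flush(res_atoms)
            res_atoms = []
            current = key
        res_atoms.append(i)
    flush(res_atoms)

    if not res_ids:
        raise ValidationError("no residues with C-alpha atoms found", field="source")

    frame = Frame(
        index=index,
        chain_ids=np.array(chain_ids, dtype="U4"),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.array(res_names, dtype="U3"),
        ca_coords=np.array(ca, dtype=float),
    )
    # store the all-atom view only when it adds information beyond C-alphas
    if len(atom_rows) > frame.n_residues:
        frame.atom_coords = np.array(atom_rows, dtype=float)
        frame.atom_res_index = np.array(atom_res, dtype=int)
        frame.atom_names = np.array(atom_names, dtype="U6")
    return frame


def read_structure_ensemble(
    source, chain_filter=None, frame_interval_ns: float | None = None
) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a StructureEnsemble.

    ``source`` is a path or a text stream. HETATM records, waters and
    hydrogens are ignored; residues without a C-alpha are dropped with a
    warning; alternate locations are resolved to the highest occupancy.
    All MODELs must contain the identical residue list — the first mismatch
    aborts with an error naming the chain, residue and MODEL.
    """
    pdb = PDBFile.read(source)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValidationError("PDB source contains no coordinates", field="source")

    frames = []
    for m in range(1, n_models + 1):
        array = pdb.get_structure(model=m, altloc="occupancy")
        frames.append(_frame_from_atom_array(array, index=m - 1, chain_filter=chain_filter))

    ref = frames[0].residue_key()
    ref_set = set(ref)
    for f in frames[1:]:
        key = f.residue_key()
        if key != ref:
            key_set = set(key)
            missing = [k for k in ref if k not in key_set]
            extra = [k for k in key if k not in ref_set]
            where = (missing + extra)[0]
            raise ValidationError(
                f"MODEL {f.index + 1} is not congruent with MODEL 1: first mismatch at "
                f"chain {where[0]} residue {where[1]} ({where[2]}) in MODEL {f.index + 1}",
                field="source",
            )
    return StructureEnsemble(frames=frames, frame_interval_ns=frame_interval_ns)


def _atom_array_from_frame(frame: Frame):
    if frame.has_atoms():
        n = len(frame.atom_coords)
        arr = bst.AtomArray(n)
        arr.coord = np.asarray(frame.atom_coords, dtype=np.float32)
        arr.chain_id = frame.chain_ids[frame.atom_res_index]
        arr.res_id = frame.res_ids[frame.atom_res_index]
        arr.res_name = frame.res_names[frame.atom_res_index]
        arr.atom_name = frame.atom_names
        arr.element = np.array(
            [(nm.strip()[:1] if nm.strip() else "C") for nm in frame.atom_names], dtype="U2"
        )
    else:
        n = frame.n_residues
        arr = bst.AtomArray(n)
        arr.coord = np.asarray(frame.ca_coords, dtype=np.float32)
        arr.chain_id = frame.chain_ids
        arr.res_id = frame.res_ids
        arr.res_name = frame.res_names
        arr.atom_name = np.full(n, "CA", dtype="U4")
        arr.element = np.full(n, "C", dtype="U2")
    arr.hetero = np.zeros(arr.array_length(), dtype=bool)
    return arr


def write_structure_ensemble(ensemble: StructureEnsemble, sink) -> None:
    """Write an ensemble as PDB to a path or text stream.

    Single-frame ensembles are written without MODEL records; multi-frame
    ensembles with one MODEL/ENDMDL pair per frame. Coordinates round-trip at
    the PDB fixed-width precision (3 decimals); values outside the printable
    field range abort.
    """
    for f in ensemble.frames:
        coords = f.atom_coords if f.has_atoms() else f.ca_coords
        if np.any(coords < _COORD_MIN) or np.any(coords > _COORD_MAX):
            raise ValidationError(
                f"frame {f.index}: coordinates outside the PDB fixed-width range "
                f"[{_COORD_MIN}, {_COORD_MAX}] Angstrom",
                field="ensemble",
            )
    arrays = [_atom_array_from_frame(f) for f in ensemble.frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(bst.stack(arrays))
    pdb.write(sink)


def ensemble_to_string(ensemble: StructureEnsemble) -> str:
    buf = io.StringIO()
    write_structure_ensemble(ensemble, buf)
    return buf.getvalue()
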