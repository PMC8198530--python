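"""Geometric observables over structure ensembles.

Centre-of-mass distances per chain pair, gyration radius (absolute and
relative to the first frame), RMSD to a reference frame with optional
least-squares superposition, and mean-square displacement with the
Stokes-Einstein-ready diffusion coefficient from its linear fit.

Centres of mass are computed over C-alpha positions; by default each C-alpha
carries its residue's average mass, with a uniform weighting as the audited
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trimertrace.errors import ValidationError
from trimertrace.structure_io import Frame, StructureEnsemble

#: Average residue masses (Da), i.e. amino-acid masses less one water.
RESIDUE_MASSES = {
    "GLY": 57.0519, "ALA": 71.0788, "SER": 87.0782, "PRO": 97.1167,
    "VAL": 99.1326, "THR": 101.1051, "CYS": 103.1388, "LEU": 113.1594,
    "ILE": 113.1594, "ASN": 114.1038, "ASP": 115.0886, "GLN": 128.1307,
    "LYS": 128.1741, "GLU": 129.1155, "MET": 131.1926, "HIS": 137.1411,
    "PHE": 147.1766, "ARG": 156.1875, "TYR": 163.1760, "TRP": 186.2132,
}
_MEAN_RESIDUE_MASS = float(np.mean(list(RESIDUE_MASSES.values())))

WEIGHTINGS = ("residue_mass", "uniform_ca")


def _weights(res_names: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "uniform_ca":
        return np.ones(len(res_names))
    if weighting == "residue_mass":
        return np.array(
            [RESIDUE_MASSES.get(str(n).upper(), _MEAN_RESIDUE_MASS) for n in res_names]
        )
    raise ValidationError(f"unknown weighting {weighting!r}", field="weighting")


def center_of_mass(
    coords: np.ndarray, res_names: np.ndarray, weighting: str = "residue_mass"
) -> np.ndarray:
    """Weighted mean of C-alpha positions (Angstrom 3-vector)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValidationError("need at least one residue", field="coords")
    w = _weights(np.asarray(res_names), weighting)
    return np.average(coords, axis=0, weights=w)


def chain_center_of_mass(
    frame: Frame, chain_id: str, weighting: str = "residue_mass"
) -> np.ndarray:
    mask = frame.chain_mask(chain_id)
    if not mask.any():
        raise ValidationError(f"chain {chain_id!r} not in frame", field="chain_id")
    return center_of_mass(frame.ca_coords[mask], frame.res_names[mask], weighting)


@dataclass
class ComDistanceTrace:
    """Per-frame centre-of-mass distance for each chain pair."""

    pairs: list  # frozensets, sorted
    distances: np.ndarray  # (n_pairs, n_frames) Angstrom
    times_ns: np.ndarray
    weighting: str

    def series(self, chain_x: str, chain_y: str) -> np.ndarray:
        return self.distances[self.pairs.index(frozenset((chain_x, chain_y)))]

    def to_frame(self) -> pd.DataFrame:
        data = {"frame": np.arange(self.distances.shape[1]), "time_ns": self.times_ns}
        for pair, row in zip(self.pairs, self.distances):
            data["d_" + "".join(sorted(pair)) + "_A"] = row
        return pd.DataFrame(data)


def pairwise_com_distances(
    ensemble: StructureEnsemble, weighting: str = "residue_mass"
) -> ComDistanceTrace:
    """Distance between subunit centres of mass for every chain pair, per frame."""
    chains = sorted(ensemble.chain_ids)
    if len(chains) < 2:
        raise ValidationError("need at least two chains", field="ensemble")
    pairs = [
        frozenset((a, b)) for i, a in enumerate(chains) for b in chains[i + 1:]
    ]
    out = np.empty((len(pairs), ensemble.n_frames))
    for f, frame in enumerate(ensemble.frames):
        coms = {c: chain_center_of_mass(frame, c, weighting) for c in chains}
        for p, pair in enumerate(pairs):
            a, b = sorted(pair)
            out[p, f] = np.linalg.norm(coms[a] - coms[b])
    return ComDistanceTrace(
        pairs=pairs, distances=out, times_ns=ensemble.times_ns(), weighting=weighting
    )


@dataclass
class GyrationTrace:
    rg: np.ndarray  # (n_frames,) Angstrom
    relative: np.ndarray  # rg / rg[reference]
    reference_frame: int
    times_ns: np.ndarray
    degenerate: bool  # true if any frame collapsed to a point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.rg)),
                "time_ns": self.times_ns,
                "rg_A": self.rg,
                "rg_relative": self.relative,
            }
        )


def radius_of_gyration(
    coords: np.ndarray, res_names: np.ndarray, weighting: str = "residue_mass"
) -> float:
    """Rg = sqrt(sum w_i ||r_i - r_com||^2 / sum w_i)."""
    w = _weights(np.asarray(res_names), weighting)
    com = np.average(coords, axis=0, weights=w)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def gyration_trace(
    ensemble: StructureEnsemble, weighting: str = "residue_mass", reference_frame: int = 0
) -> GyrationTrace:
    """Per-frame Rg and the series relative to the reference frame's value."""
    if not (0 <= reference_frame < ensemble.n_frames):
        raise ValidationError("reference_frame out of range", field="reference_frame")
    rg = np.array(
        [radius_of_gyration(f.ca_coords, f.res_names, weighting) for f in ensemble.frames]
    )
    degenerate = bool(np.any(rg == 0))
    ref = rg[reference_frame]
    relative = rg / ref if ref > 0 else np.full_like(rg, np.nan)
    return GyrationTrace(
        rg=rg,
        relative=relative,
        reference_frame=reference_frame,
        times_ns=ensemble.times_ns(),
        degenerate=degenerate,
    )


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (no reflection) aligning centred ``mobile`` to
    centred ``target``, by the standard SVD construction."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def _rmsd(a: np.ndarray, b: np.ndarray, superpose: bool) -> float:
    if superpose:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        rot = kabsch_rotation(a, b)
        a = a @ rot.T
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class RmsdTrace:
    whole: np.ndarray  # (n_frames,) Angstrom
    per_chain: dict | None  # chain -> (n_frames,) array
    reference_frame: int
    superposed: bool
    times_ns: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {
            "frame": np.arange(len(self.whole)),
            "time_ns": self.times_ns,
            "rmsd_A": self.whole,
        }
        if self.per_chain:
            for c, series in self.per_chain.items():
                data[f"rmsd_{c}_A"] = series
        return pd.DataFrame(data)


def rmsd_trace(
    ensemble: StructureEnsemble,
    reference_frame: int = 0,
    per_chain: bool = False,
    superpose: bool = True,
) -> RmsdTrace:
    """C-alpha RMSD of every frame to a reference frame.

    With ``superpose`` each frame is first optimally superposed onto the
    reference (rotation + translation, reflections excluded); in per-chain
    mode each chain is superposed and scored independently.
    """
    if not (0 <= reference_frame < ensemble.n_frames):
        raise ValidationError("reference_frame out of range", field="reference_frame")
    ref = ensemble.frames[reference_frame]
    whole = np.array(
        [_rmsd(f.ca_coords, ref.ca_coords, superpose) for f in ensemble.frames]
    )
    chains_out = None
    if per_chain:
        chains_out = {}
        for c in ensemble.chain_ids:
            mask = ref.chain_mask(c)
            chains_out[c] = np.array(
                [
                    _rmsd(f.ca_coords[f.chain_mask(c)], ref.ca_coords[mask], superpose)
                    for f in ensemble.frames
                ]
            )
    return RmsdTrace(
        whole=whole,
        per_chain=chains_out,
        reference_frame=reference_frame,
        superposed=superpose,
        times_ns=ensemble.times_ns(),
    )


@dataclass
class MsdCurve:
    lag_ns: np.ndarray
    msd_a2: np.ndarray  # Angstrom^2, ensemble-averaged over particles
    slope_a2_per_ns: float  # least-squares line through the origin
    r_squared: float
    d_m2_per_s: float  # slope / 6, converted to SI
    linear: bool  # heuristic: r_squared >= 0.99 over the fit window

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ns": self.lag_ns, "msd_A2": self.msd_a2})


def msd_to_diffusion(
    series: np.ndarray,
    frame_interval_ns: float,
    lag_window: tuple[float, float] = (0.0, 1.0),
    sliding: bool = False,
) -> MsdCurve:
    """Diffusion coefficient from the mean-square displacement.

    ``series`` is one trajectory of 3-vectors, shape (F, 3), or a particle
    ensemble (P, F, 3); the MSD at lag t is the displacement from the origin
    frame, <(r(t) - r(0))^2>, averaged over particles. A least-squares line
    through the origin over ``lag_window`` (fractions of the maximum lag)
    gives the slope, and D = slope / 6 in the free-diffusion relation
    MSD = 6 D t, converted from A^2/ns to m^2/s. The fit's R^2 is reported
    and curves that are visibly non-linear (R^2 < 0.99) are flagged.

    ``sliding`` enables window-averaged MSD over all time origins for
    variance reduction; it is off by default so the curve is exactly the
    displacement-from-origin statistic.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError("series must be (F, 3) or (P, F, 3)", field="series")
    n_frames = arr.shape[1]
    if n_frames < 10:
        raise ValidationError("need at least 10 frames", field="series")
    if frame_interval_ns <= 0:
        raise ValidationError("frame_interval_ns must be positive", field="frame_interval_ns")

    if sliding:
        msd = np.zeros(n_frames)
        for lag in range(1, n_frames):
            disp = arr[:, lag:, :] - arr[:, :-lag, :]
            msd[lag] = np.mean(np.sum(disp**2, axis=2))
    else:
        disp = arr - arr[:, :1, :]
        msd = np.mean(np.sum(disp**2, axis=2), axis=0)
    lag_ns = np.arange(n_frames) * frame_interval_ns

    lo, hi = lag_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError("lag_window must satisfy 0 <= lo < hi <= 1", field="lag_window")
    max_lag = lag_ns[-1]
    sel = (lag_ns > lo * max_lag) & (lag_ns <= hi * max_lag) & (lag_ns > 0)
    t, y = lag_ns[sel], msd[sel]
    slope = float(np.sum(t * y) / np.sum(t * t))
    ss_res = float(np.sum((y - slope * t) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_a2_ns = slope / 6.0
    return MsdCurve(
        lag_ns=lag_ns,
        msd_a2=msd,
        slope_a2_per_ns=slope,
        r_squared=r2,
        d_m2_per_s=d_a2_ns * 1e-11,
        linear=r2 >= 0.99,
    )
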