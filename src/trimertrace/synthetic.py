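"""Synthetic trimer ensembles and DLS-style size distributions.

The generator is a geometry-only surrogate for a homotrimer trajectory: three
rigid copies of one subunit trace sit on a ring around the z axis, and planted
radial offsets make two subunits approach each other (``approach_delta``) or
one subunit drift away (``asymmetry_delta``), with optional per-frame drift
multipliers, scheduled switches of which pair is planted, and per-coordinate
thermal noise. The planted pairing is recorded per frame so downstream
cluster detection can be scored against ground truth. No force field, no
solvent — the point is a controllable, deterministic inter-subunit signal.

Subunit traces use realistic backbone spacing (consecutive C-alpha distance
3.8 Angstrom, inside the 3.6-4.0 band) so the 4 Angstrom lower cutoff of the
contact network excludes covalent neighbours exactly as it would on a real
chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trimertrace.errors import ValidationError
from trimertrace.hydro import SizeDistribution
from trimertrace.structure_io import Frame, StructureEnsemble

CHAIN_IDS = ("A", "B", "C")
SYMMETRIC = "symmetric"

_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

_STEP = 3.8  # consecutive C-alpha spacing, Angstrom
_CLASH = 3.6  # minimum non-adjacent self-distance during growth


@dataclass(frozen=True)
class TrimerGeometrySpec:
    """Parameters of a planted-asymmetry trimer ensemble.

    ``ring_radius`` is the distance from the trimer axis to each subunit
    centroid; if None it is derived from the subunit size so that in the
    symmetric state neighbouring subunits share a sparse contact fringe.
    ``approach_delta`` is added to the radial position of both chains of the
    planted pair (negative = the pair approaches); ``asymmetry_delta`` to the
    radial position of the remaining chain (positive = it distances).
    ``drift_schedule`` multiplies both deltas per frame; ``pair_schedule``
    re-plants the pair from given frames onward, e.g. ((0, ("A","C")),
    (50, ("A","B"))) switches the planted pair at frame 50.
    """

    n_residues_per_chain: int = 40
    subunit_template: str = "saw"  # "saw" (smoothed self-avoiding walk) | "helix"
    ring_radius: float | None = None
    asymmetry_delta: float = 0.0
    approach_delta: float = 0.0
    noise_sigma: float = 0.0
    n_frames: int = 1
    drift_schedule: tuple[float, ...] | None = None
    planted_pair: tuple[str, str] = ("A", "C")
    pair_schedule: tuple[tuple[int, tuple[str, str]], ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues_per_chain < 3:
            raise ValidationError(
                "n_residues_per_chain must be >= 3", field="n_residues_per_chain"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1", field="n_frames")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0", field="noise_sigma")
        if self.subunit_template not in ("saw", "helix"):
            raise ValidationError(
                f"unknown subunit_template {self.subunit_template!r}",
                field="subunit_template",
            )
        if self.ring_radius is not None and self.ring_radius <= 0:
            raise ValidationError("ring_radius must be positive", field="ring_radius")
        if self.drift_schedule is not None and len(self.drift_schedule) != self.n_frames:
            raise ValidationError(
                "drift_schedule must have one multiplier per frame",
                field="drift_schedule",
            )
        for pair in [self.planted_pair] + [
            p for _, p in (self.pair_schedule or ())
        ]:
            if len(set(pair)) != 2 or not set(pair) <= set(CHAIN_IDS):
                raise ValidationError(
                    f"chain pair must be two distinct chains of {CHAIN_IDS}, got {pair!r}",
                    field="planted_pair",
                )
        if self.pair_schedule is not None:
            starts = [s for s, _ in self.pair_schedule]
            if starts != sorted(starts) or (starts and starts[0] != 0):
                raise ValidationError(
                    "pair_schedule must start at frame 0 and be sorted by frame",
                    field="pair_schedule",
                )


@dataclass(frozen=True)
class GroundTruthLabels:
    """Per-frame planted pairing: a frozenset chain pair, or 'symmetric'."""

    labels: tuple

    def __post_init__(self):
        for lab in self.labels:
            if lab == SYMMETRIC:
                continue
            if not (isinstance(lab, frozenset) and lab <= set(CHAIN_IDS) and len(lab) == 2):
                raise ValidationError(f"invalid ground-truth label {lab!r}", field="labels")

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tplanted_pair\n")
            for i, lab in enumerate(self.labels):
                tag = SYMMETRIC if lab == SYMMETRIC else "".join(sorted(lab))
                fh.write(f"{i}\t{tag}\n")

    @classmethod
    def read(cls, path) -> "GroundTruthLabels":
        labels = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                tag = line.split("\t")[1].strip()
                labels.append(SYMMETRIC if tag == SYMMETRIC else frozenset(tag))
        return cls(tuple(labels))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _saw_template(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothed self-avoiding walk confined to a protein-density sphere.

    Steps of 3.8 Angstrom with persistent direction; proposals clashing with
    earlier points (< 3.6 Angstrom to any non-adjacent point) or leaving the
    confinement sphere are rejected, with single-step backtracking when stuck.
    The confinement radius 3.4 * n^(1/3) gives roughly globular packing.
    """
    confine = 3.4 * n ** (1.0 / 3.0)
    for _attempt in range(50):
        pts = np.zeros((n, 3))
        direction = _unit(rng.normal(size=3))
        i, tries, backtracks = 1, 0, 0
        failed = False
        while i < n:
            proposal = _unit(direction + 0.7 * rng.normal(size=3))
            p = pts[i - 1] + _STEP * proposal
            ok = np.linalg.norm(p) <= confine
            if ok and i >= 2:
                ok = np.min(np.linalg.norm(pts[: i - 1] - p, axis=1)) >= _CLASH
            if ok:
                pts[i] = p
                direction = proposal
                i += 1
                tries = 0
            else:
                tries += 1
                if tries > 60:
                    i = max(1, i - 1)
                    direction = _unit(rng.normal(size=3))
                    tries = 0
                    backtracks += 1
                    if backtracks > 40 * n:
                        failed = True
                        break
        if not failed:
            return pts - pts.mean(axis=0)
    raise RuntimeError("self-avoiding walk generation did not converge")


def _helix_template(n: int) -> np.ndarray:
    """Ideal alpha-helix-like trace: radius 2.3 A, 99.6 deg turn per residue.

    The rise per residue is chosen so consecutive C-alpha spacing is exactly
    3.8 A given the helical chord (~1.45 A, close to the canonical 1.5 A).
    """
    radius, turn = 2.3, np.deg2rad(99.6)
    chord = 2.0 * radius * np.sin(turn / 2.0)
    rise = np.sqrt(_STEP**2 - chord**2)
    t = np.arange(n)
    pts = np.stack(
        [radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t], axis=1
    )
    return pts - pts.mean(axis=0)


def _default_ring_radius(n: int) -> float:
    # symmetric centroid separation = 2*R_blob - 3 A: sparse fringe contacts
    r_blob = 3.4 * n ** (1.0 / 3.0)
    return (2.0 * r_blob - 3.0) / np.sqrt(3.0)


def _pair_for_frame(spec: TrimerGeometrySpec, frame: int) -> frozenset:
    pair = spec.planted_pair
    if spec.pair_schedule:
        for start, p in spec.pair_schedule:
            if frame >= start:
                pair = p
    return frozenset(pair)


def generate_trimer_ensemble(
    spec: TrimerGeometrySpec,
) -> tuple[StructureEnsemble, GroundTruthLabels]:
    """Generate a three-chain ensemble with planted 2:1 geometric asymmetry.

    Returns the ensemble (chains A, B, C; identical residue numbering and
    sequence across chains — a homotrimer) and the per-frame ground-truth
    pairing. Deterministic for a given spec and seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues_per_chain

    sequence = rng.choice(_AA3, size=n)
    if spec.subunit_template == "saw":
        template = _saw_template(n, rng)
    else:
        template = _helix_template(n)

    ring = spec.ring_radius if spec.ring_radius is not None else _default_ring_radius(n)
    angles = {c: np.deg2rad(90.0 + 120.0 * k) for k, c in enumerate(CHAIN_IDS)}
    schedule = (
        np.asarray(spec.drift_schedule, dtype=float)
        if spec.drift_schedule is not None
        else np.ones(spec.n_frames)
    )

    frames, labels = [], []
    for f in range(spec.n_frames):
        s = schedule[f]
        pair = _pair_for_frame(spec, f)
        planted = (
            SYMMETRIC
            if (spec.approach_delta * s == 0 and spec.asymmetry_delta * s == 0)
            else pair
        )
        labels.append(planted)

        chain_ids, res_ids, res_names, coords = [], [], [], []
        for c in CHAIN_IDS:
            a = angles[c]
            radial = np.array([np.cos(a), np.sin(a), 0.0])
            offset = spec.approach_delta * s if c in pair else spec.asymmetry_delta * s
            rot = np.array(
                [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
            )
            placed = template @ rot.T + (ring + offset) * radial
            coords.append(placed)
            chain_ids.extend([c] * n)
            res_ids.extend(range(1, n + 1))
            res_names.extend(sequence)
        xyz = np.concatenate(coords, axis=0)
        if spec.noise_sigma > 0:
            xyz = xyz + rng.normal(scale=spec.noise_sigma, size=xyz.shape)
        frames.append(
            Frame(
                index=f,
                chain_ids=np.array(chain_ids, dtype="U4"),
                res_ids=np.array(res_ids, dtype=int),
                res_names=np.array(res_names, dtype="U3"),
                ca_coords=xyz,
            )
        )
    ensemble = StructureEnsemble(frames=frames)
    return ensemble, GroundTruthLabels(tuple(labels))


def generate_dls_distribution(
    mean_diameter: float,
    sigma: float,
    n_bins: int = 50,
    bin_range: tuple[float, float] = (1.0, 20.0),
    shape: str = "gaussian",
    seed: int | None = None,
    second_mean: float | None = None,
    second_sigma: float | None = None,
    second_weight: float = 0.5,
    noise_frac: float = 0.0,
) -> SizeDistribution:
    """Synthetic DLS size histogram: diameter bins with percent frequencies.

    ``shape='gaussian'`` samples a Gaussian profile on the bin centres;
    ``shape='bimodal'`` adds a second mode (``second_mean/second_sigma``,
    mixed with ``second_weight``). ``noise_frac`` applies multiplicative
    measurement-like ripple (seeded). Frequencies are clipped at zero and
    normalized to sum to 100. In the sigma -> 0 limit all mass lands in the
    bin nearest the mean.
    """
    lo, hi = bin_range
    if not (lo < mean_diameter < hi):
        raise ValidationError(
            f"mean_diameter {mean_diameter} outside bin_range {bin_range}",
            field="mean_diameter",
        )
    if sigma <= 0:
        raise ValidationError("sigma must be positive", field="sigma")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1", field="n_bins")
    if shape not in ("gaussian", "bimodal"):
        raise ValidationError(f"unknown shape {shape!r}", field="shape")
    if shape == "bimodal" and (second_mean is None or second_sigma is None):
        raise ValidationError(
            "bimodal shape requires second_mean and second_sigma", field="second_mean"
        )

    centers = np.linspace(lo, hi, n_bins)
    width = centers[1] - centers[0] if n_bins > 1 else hi - lo

    def mode(mu, sd):
        if sd < width / 10.0:  # delta limit: everything in the nearest bin
            q = np.zeros(n_bins)
            q[int(np.argmin(np.abs(centers - mu)))] = 1.0
            return q
        return np.exp(-((centers - mu) ** 2) / (2.0 * sd**2))

    q = mode(mean_diameter, sigma)
    if shape == "bimodal":
        q1 = q / q.sum()
        q2 = mode(second_mean, second_sigma)
        q2 = q2 / q2.sum()
        q = (1.0 - second_weight) * q1 + second_weight * q2
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        q = np.clip(q * (1.0 + noise_frac * rng.normal(size=n_bins)), 0.0, None)
    q = q * (100.0 / q.sum())
    return SizeDistribution(centers, q)


def simulate_brownian(
    n_steps: int,
    dt_ns: float,
    d_m2_per_s: float,
    n_particles: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Free 3-D Brownian walks at a known diffusion coefficient.

    Returns positions in Angstrom of shape (n_particles, n_steps + 1, 3),
    starting at the origin. Per-axis increments are N(0, 2 D dt); D is
    converted from m^2/s to A^2/ns (1 A^2/ns = 1e-11 m^2/s).
    """
    if n_steps < 1 or dt_ns <= 0 or d_m2_per_s <= 0 or n_particles < 1:
        raise ValidationError("n_steps, dt_ns, d_m2_per_s, n_particles must be positive")
    d_a2_ns = d_m2_per_s / 1e-11
    rng = np.random.default_rng(seed)
    steps = rng.normal(
        scale=np.sqrt(2.0 * d_a2_ns * dt_ns), size=(n_particles, n_steps, 3)
    )
    paths = np.concatenate(
        [np.zeros((n_particles, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return paths
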