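"""End-to-end orchestration: ensemble in, traces/maps/report out.

``run_full_analysis`` composes the contact-network clustering, geometric
traces and interface maps over one ensemble, writes every stage's table as
delimited text under an output directory, and returns a self-describing
report (summary statistics plus a provenance block). All randomness flows
from a single root seed split per stage; identical inputs, config and seed
give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from trimertrace import __version__ as _version
from trimertrace import contact_network, geometry, interface
from trimertrace.errors import ValidationError
from trimertrace.structure_io import StructureEnsemble, read_structure_ensemble
from trimertrace.synthetic import (
    TrimerGeometrySpec,
    generate_dls_distribution,
    generate_trimer_ensemble,
)


@dataclass
class AnalysisConfig:
    cutoff_low: float = 4.0
    cutoff_high: float = 8.0
    contact_bins: tuple[float, ...] = interface.DEFAULT_BINS
    contact_mode: str = "ca_only"
    com_weighting: str = "residue_mass"
    superpose: bool = True
    msd_lag_window: tuple[float, float] = (0.0, 1.0)
    hotspot_window: int = 10
    seed: int = 0
    out_dir: str = "trimertrace_out"

    def validate(self) -> None:
        if self.cutoff_low >= self.cutoff_high:
            raise ValidationError(
                "cutoff_low must be < cutoff_high", field="cutoff_low"
            )
        edges = tuple(self.contact_bins)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError(
                "contact_bins must be strictly increasing", field="contact_bins"
            )
        if self.com_weighting not in geometry.WEIGHTINGS:
            raise ValidationError(
                f"com_weighting must be one of {geometry.WEIGHTINGS}",
                field="com_weighting",
            )
        if self.contact_mode not in ("ca_only", "all_atom"):
            raise ValidationError("unknown contact_mode", field="contact_mode")
        lo, hi = self.msd_lag_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError("invalid msd_lag_window", field="msd_lag_window")
        if self.hotspot_window < 1:
            raise ValidationError("hotspot_window must be >= 1", field="hotspot_window")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisReport:
    outputs: dict = field(default_factory=dict)  # stage -> file path
    summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "outputs": self.outputs,
                    "summary": self.summary,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
                default=str,
            )


def _stage(name: str, fn, frame_hint=None):
    try:
        return fn()
    except Exception as exc:  # annotate with the failing stage
        where = f" (frame {frame_hint})" if frame_hint is not None else ""
        raise RuntimeError(f"pipeline stage '{name}'{where} failed: {exc}") from exc


def run_full_analysis(source, config: AnalysisConfig) -> AnalysisReport:
    """Run clustering, geometry and interface analyses and write all outputs.

    ``source`` is a PDB path/stream or an already-built StructureEnsemble.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if isinstance(source, StructureEnsemble):
        ensemble = source
    else:
        ensemble = _stage("read", lambda: read_structure_ensemble(source))

    report = AnalysisReport()

    trace = _stage(
        "cluster",
        lambda: contact_network.cluster_trace(
            ensemble, config.cutoff_low, config.cutoff_high
        ),
    )
    path = out / "cluster_trace.tsv"
    trace.to_frame().to_csv(path, sep="\t", index=False)
    report.outputs["cluster_trace"] = str(path)

    com = _stage(
        "com_distances",
        lambda: geometry.pairwise_com_distances(ensemble, config.com_weighting),
    )
    path = out / "com_distances.tsv"
    com.to_frame().to_csv(path, sep="\t", index=False)
    report.outputs["com_distances"] = str(path)

    gyr = _stage("gyration", lambda: geometry.gyration_trace(ensemble, config.com_weighting))
    path = out / "gyration.tsv"
    gyr.to_frame().to_csv(path, sep="\t", index=False)
    report.outputs["gyration"] = str(path)

    rmsd = _stage(
        "rmsd",
        lambda: geometry.rmsd_trace(
            ensemble, per_chain=True, superpose=config.superpose
        ),
    )
    path = out / "rmsd.tsv"
    rmsd.to_frame().to_csv(path, sep="\t", index=False)
    report.outputs["rmsd"] = str(path)

    chains = sorted(ensemble.chain_ids)
    hotspots = {}
    first, last = ensemble.frames[0], ensemble.frames[-1]
    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            def maps():
                m0 = interface.interchain_distance_map(
                    first, a, b, config.contact_mode, config.contact_bins
                )
                m1 = interface.interchain_distance_map(
                    last, a, b, config.contact_mode, config.contact_bins
                )
                return m0, m1
            m0, m1 = _stage(f"contact_map_{a}{b}", maps)
            path = out / f"contact_map_{a}{b}_final.tsv"
            m1.to_long_frame().to_csv(path, sep="\t", index=False)
            report.outputs[f"contact_map_{a}{b}"] = str(path)
            diff = interface.diff_contact_maps(m0, m1)
            report.summary.setdefault("contacts_gained", {})[f"{a}{b}"] = len(diff.gained)
            report.summary.setdefault("contacts_lost", {})[f"{a}{b}"] = len(diff.lost)
            window = min(config.hotspot_window, m1.shape[0])
            hotspots[f"{a}{b}"] = [
                asdict(h) for h in interface.interface_hotspots(m1, window=window)
            ]
    report.summary["hotspots"] = hotspots

    tail = max(1, ensemble.n_frames // 4)
    report.summary["pairing_occupancy"] = {
        "".join(sorted(p)): frac for p, frac in trace.occupancy.items()
    }
    report.summary["switch_count"] = len(trace.switch_events)
    report.summary["switch_frames"] = trace.switch_events
    report.summary["mean_relative_rg_final_quarter"] = float(
        np.mean(gyr.relative[-tail:])
    )
    report.summary["mean_lambda2"] = float(np.mean(trace.lambda2))

    report.provenance = {
        "package_version": _version,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_frames": ensemble.n_frames,
        "n_residues": ensemble.n_residues,
        "chains": list(ensemble.chain_ids),
    }
    report.write(out / "report.json")
    report.outputs["report"] = str(out / "report.json")
    return report


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the canonical small test inputs: three ensembles + two DLS tables.

    Symmetric, planted-pair and switch-schedule trimer ensembles as
    multi-MODEL PDB with ground-truth sidecars, plus a unimodal and a bimodal
    size distribution. Returns a name -> path mapping.
    """
    from trimertrace.structure_io import write_structure_ensemble

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    bundle = {}

    specs = {
        "symmetric": TrimerGeometrySpec(
            n_frames=5, noise_sigma=0.3, seed=int(seeds[0])
        ),
        "planted_ac": TrimerGeometrySpec(
            n_frames=5,
            approach_delta=-6.0,
            noise_sigma=0.3,
            planted_pair=("A", "C"),
            seed=int(seeds[1]),
        ),
        "switch": TrimerGeometrySpec(
            n_frames=20,
            approach_delta=-6.0,
            noise_sigma=0.3,
            pair_schedule=((0, ("A", "C")), (10, ("A", "B"))),
            seed=int(seeds[2]),
        ),
    }
    for name, spec in specs.items():
        ensemble, truth = generate_trimer_ensemble(spec)
        pdb_path = out / f"{name}.pdb"
        write_structure_ensemble(ensemble, pdb_path)
        truth_path = out / f"{name}_truth.tsv"
        truth.write(truth_path)
        bundle[name] = str(pdb_path)
        bundle[f"{name}_truth"] = str(truth_path)

    mono = generate_dls_distribution(8.1, 0.9, seed=int(seeds[3]), noise_frac=0.03)
    mono_path = out / "dls_monodisperse.tsv"
    mono.write(mono_path)
    bundle["dls_monodisperse"] = str(mono_path)

    bimodal = generate_dls_distribution(
        8.0, 1.0, n_bins=80, bin_range=(1.0, 400.0), shape="bimodal",
        second_mean=200.0, second_sigma=30.0, seed=int(seeds[4]), noise_frac=0.03,
    )
    bi_path = out / "dls_bimodal.tsv"
    bimodal.write(bi_path)
    bundle["dls_bimodal"] = str(bi_path)
    return bundle
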