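#!/usr/bin/env python
"""Subunit 2:1 clustering over time on the synthetic trajectories.

Builds the per-frame contact network (4-8 A C-alpha band), takes the Fiedler
bipartition, assigns chains by residue majority, and reports pairing
occupancies and switch events against the generator's ground truth.
Writes per-frame traces under results/cluster/.
"""

import argparse
from pathlib import Path

import numpy as np

from trimertrace import contact_network as cn
from trimertrace.structure_io import read_structure_ensemble
from trimertrace.synthetic import GroundTruthLabels


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/cluster"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for name in ("symmetric", "planted_ac", "switch"):
        ensemble = read_structure_ensemble(args.data_dir / f"{name}.pdb")
        truth = GroundTruthLabels.read(args.data_dir / f"{name}_truth.tsv")
        trace = cn.cluster_trace(ensemble)
        trace.to_frame().to_csv(args.out_dir / f"{name}_trace.tsv", sep="\t", index=False)

        occ = {"".join(sorted(p)): round(f, 3) for p, f in trace.occupancy.items()}
        print(f"\n{name}: occupancy {occ}, switches at {trace.switch_events}")
        scored = [
            (c.paired_chains == truth[i])
            for i, c in enumerate(trace.clusterings)
            if truth[i] != "symmetric"
        ]
        if scored:
            print(f"  ground-truth recovery: {100 * np.mean(scored):.1f}% "
                  f"of {len(scored)} labelled frames")
        else:
            print("  no planted signal (symmetric null): occupancy should be "
                  "split between pairings rather than dominated by one")
        print(f"  mean algebraic connectivity lambda2 = {trace.lambda2.mean():.3f}")


if __name__ == "__main__":
    main()
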