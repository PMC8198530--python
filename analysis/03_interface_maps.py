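#!/usr/bin/env python
"""Inter-chain contact maps of the planted-pair trajectory.

For each chain pair: minimum-distance map at the first and last frame,
contacts per nested distance class (7/10/13/16 A), contact-type counts at
the tightest class, gained/lost contacts over the trajectory, and hotspot
segments. Long-format maps land under results/interface/.
"""

import argparse
from pathlib import Path

from trimertrace import interface
from trimertrace.structure_io import read_structure_ensemble


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/interface"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ensemble = read_structure_ensemble(args.data_dir / "planted_ac.pdb")
    first, last = ensemble.frames[0], ensemble.frames[-1]
    chains = sorted(ensemble.chain_ids)

    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            m0 = interface.interchain_distance_map(first, a, b)
            m1 = interface.interchain_distance_map(last, a, b)
            m1.to_long_frame().to_csv(
                args.out_dir / f"map_{a}{b}_final.tsv", sep="\t", index=False
            )
            classes = interface.bin_contact_map(m1)
            per_class = {k: int((classes == k).sum()) for k in (1, 2, 3, 4)}
            types = interface.classify_contact_types(m1)
            diff = interface.diff_contact_maps(m0, m1)
            hot = interface.interface_hotspots(m1, window=8)
            print(f"\npair {a}-{b}: contacts per class {per_class}")
            print(f"  tightest-class types: hydrophobic {types.hydrophobic}, "
                  f"hydrophilic {types.hydrophilic}, mixed {types.mixed}")
            print(f"  vs frame 0: gained {len(diff.gained)}, lost {len(diff.lost)}")
            if hot:
                spans = ", ".join(f"{h.start_res}-{h.end_res} ({h.contact_count})" for h in hot)
                print(f"  hotspot segments (residues of {a}): {spans}")

    print(
        "\nthe approaching pair should dominate the class-1 counts; the other "
        "two interfaces stay sparse."
    )


if __name__ == "__main__":
    main()
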