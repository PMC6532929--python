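#!/usr/bin/env python
"""Simulate the four strain/cell-cycle scenarios in both assay modes.

Writes, for each of wt-g1, wt-g2, sir2-g1 and sir2-term: an MNase-mode and a
ChEC-mode fragment BED plus truth sidecars, under results/sim/.  These files
feed the downstream analysis scripts; every later step can also regenerate
them on the fly, so this script exists mainly to make the inputs inspectable.
"""

import argparse
from pathlib import Path

import numpy as np

from rdnafoot.fragments import write_fragments_bed
from rdnafoot.regions import default_landmarks
from rdnafoot.simulate import (
    MODEL_PRESETS,
    simulate_chec_fragments,
    simulate_mnase_fragments,
    write_truth_tsv,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-fragments", type=int, default=50_000)
    ap.add_argument("--out-dir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    lm = default_landmarks()
    seeds = iter(
        int(c.generate_state(1)[0] % (2**31 - 1))
        for c in np.random.SeedSequence(args.seed).spawn(2 * len(MODEL_PRESETS))
    )
    for name, factory in MODEL_PRESETS.items():
        model = factory(lm)
        frags, truth = simulate_mnase_fragments(model, args.n_fragments, next(seeds))
        write_fragments_bed(frags, args.out_dir / f"{name}_mnase.bed")
        write_truth_tsv(truth, args.out_dir / f"{name}_mnase_truth.tsv")
        line = f"{name}: {len(frags)} MNase fragments"
        if model.effective_occupancies()["prerc"] > 0:
            cfrags, ctruth = simulate_chec_fragments(
                model, args.n_fragments, next(seeds)
            )
            write_fragments_bed(cfrags, args.out_dir / f"{name}_chec.bed")
            write_truth_tsv(ctruth, args.out_dir / f"{name}_chec_truth.tsv")
            line += f", {len(cfrags)} ChEC fragments"
        else:
            next(seeds)  # keep seed assignment stable across scenarios
            line += " (no ChEC: pre-RC absent in G2)"
        print(line)
    print(f"wrote fragment sets under {args.out_dir}")


if __name__ == "__main__":
    main()
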