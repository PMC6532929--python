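#!/usr/bin/env python
"""Build and render the 2D fragment matrices over the origin window.

For each simulated scenario this builds the position x fragment-length
matrix (span mode, 1 bp bins), normalizes it per million fragments, writes
it as TSV and renders the 2D plot with landmark overlays.  The G1 panels
show the 50-100 bp pre-RC band adjacent to the rARS; the G2 panels show the
nucleosome band in its place; the sir2-G1 panel additionally shows factor-
band signal right of the rARS.
"""

import argparse
from pathlib import Path

from rdnafoot.fragmatrix import build_matrix, normalize_matrix, write_matrix_tsv
from rdnafoot.fragments import read_fragments_bed
from rdnafoot.plotting import PlotSpec, render_2d
from rdnafoot.regions import default_landmarks
from rdnafoot.simulate import MODEL_PRESETS, NUCLEOSOME_SPACING


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/matrices"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    lm = default_landmarks()
    dyads = [lm.c_pro_start + NUCLEOSOME_SPACING * i for i in range(6)]
    for name in MODEL_PRESETS:
        bed = args.sim_dir / f"{name}_mnase.bed"
        if not bed.exists():
            raise SystemExit(f"{bed} missing; run 01_simulate_scenarios.py first")
        frags = read_fragments_bed(bed)
        matrix = normalize_matrix(build_matrix(frags, lm.analysis_window))
        write_matrix_tsv(matrix, args.out_dir / f"{name}_matrix.tsv")
        render_2d(
            normalize_matrix(matrix, "unit_max"), lm,
            PlotSpec(output=str(args.out_dir / f"{name}_matrix.png"), title=name),
            nucleosome_dyads=dyads,
        )
        print(f"{name}: matrix over {matrix.n_fragments} in-window fragments")
    print(f"wrote matrices and plots under {args.out_dir}")


if __name__ == "__main__":
    main()
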