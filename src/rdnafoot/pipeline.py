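"""End-to-end configurable run: simulate -> matrix -> quantify -> displace ->
sseq -> plot, with every report tab-separated and a self-describing JSON
manifest.  Reports are deterministic given (config, seeds)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .displacement import displacement_test
from .errors import ConfigurationError
from .fragmatrix import build_matrix, normalize_matrix, write_matrix_tsv
from .fragments import write_fragments_bed
from .occupancy import chec_abundance_change, compare_occupancy, reb1_normalized_occupancy
from .plotting import PlotSpec, render_2d
from .regions import default_landmarks, load_landmarks_file
from .simulate import (
    MODEL_PRESETS,
    expected_replication_index,
    simulate_chec_fragments,
    simulate_mnase_fragments,
    simulate_sseq_counts,
    write_truth_tsv,
)
from .sseq import replication_index

__all__ = ["default_config", "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "matrix", "quantify", "displace", "sseq", "plot")


def default_config() -> dict:
    """A full-locus run over all four preset scenarios with moderate depth."""
    return {
        "landmarks": "default",
        "seed": 1,
        "n_fragments": 20_000,
        "n_boot": 200,
        "scenarios": list(MODEL_PRESETS),
        "stages": list(DEFAULT_STAGES),
        "sseq": {
            "rdna_share_g1": 0.10,
            "replicated_fraction_rdna": 0.8,
            "replicated_fraction_genome": 0.5,
            "n_reads": 1_000_000,
        },
    }


def _stage(name, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages and write all reports under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lm_spec = config.get("landmarks", "default")
    if lm_spec == "default":
        lm = default_landmarks()
    else:
        if not Path(lm_spec).exists():
            raise ConfigurationError(f"landmark file not found: {lm_spec}")
        lm = load_landmarks_file(lm_spec)
    seed = int(config.get("seed", 1))
    n = int(config.get("n_fragments", 20_000))
    n_boot = int(config.get("n_boot", 200))
    scenarios = list(config.get("scenarios", list(MODEL_PRESETS)))
    stages = list(config.get("stages", DEFAULT_STAGES))
    unknown = set(scenarios) - set(MODEL_PRESETS)
    if unknown:
        raise ConfigurationError(f"unknown scenario(s): {sorted(unknown)}")

    ss = np.random.SeedSequence(seed)
    child_seeds = {
        (sc, mode): int(s.generate_state(1)[0] % (2**31 - 1))
        for (sc, mode), s in zip(
            [(sc, mode) for sc in scenarios for mode in ("mnase", "chec")],
            ss.spawn(2 * len(scenarios)),
        )
    }

    mnase = {}
    chec = {}
    if "simulate" in stages:
        for sc in scenarios:
            model = MODEL_PRESETS[sc](lm)
            frags, truth = _stage(
                "simulate", simulate_mnase_fragments, model, n, child_seeds[(sc, "mnase")]
            )
            mnase[sc] = frags
            write_fragments_bed(frags, out / f"{sc}_mnase.bed")
            write_truth_tsv(truth, out / f"{sc}_mnase_truth.tsv")
            cfrags, ctruth = _stage(
                "simulate", simulate_chec_fragments, model, n, child_seeds[(sc, "chec")]
            )
            chec[sc] = cfrags
            write_fragments_bed(cfrags, out / f"{sc}_chec.bed")
            write_truth_tsv(ctruth, out / f"{sc}_chec_truth.tsv")

    matrices = {}
    if "matrix" in stages:
        for sc, frags in mnase.items():
            m = _stage("matrix", build_matrix, frags, lm.analysis_window)
            matrices[sc] = m
            write_matrix_tsv(normalize_matrix(m), out / f"{sc}_matrix.tsv")

    if "quantify" in stages and {"wt-g1", "sir2-g1"} <= set(mnase):
        rows = []
        occs = {}
        for sc in ("wt-g1", "sir2-g1"):
            occ = _stage(
                "quantify", reb1_normalized_occupancy, mnase[sc], lm,
                n_boot=n_boot, seed=seed + 101,
            )
            occs[sc] = occ
            rows.append(
                {"target": f"{sc} Mcm2-7 / Reb1", "raw": occ.raw_signal,
                 "normalizer": occ.normalizer, "normalized": occ.normalized,
                 "ci_low": occ.ci_low, "ci_high": occ.ci_high, "percent_change": ""}
            )
        cmp_mnase = compare_occupancy(occs["wt-g1"], occs["sir2-g1"])
        rows.append(
            {"target": "sir2 vs WT (MNase, Reb1-normalized)", "raw": "",
             "normalizer": "", "normalized": "", "ci_low": cmp_mnase.ci_low,
             "ci_high": cmp_mnase.ci_high, "percent_change": cmp_mnase.percent_change}
        )
        cmp_chec = _stage(
            "quantify", chec_abundance_change, chec["wt-g1"], chec["sir2-g1"],
            lm.repeat_unit, seed=seed + 102,
        )
        rows.append(
            {"target": "sir2 vs WT (ChEC rDNA fraction)", "raw": "",
             "normalizer": "", "normalized": "", "ci_low": cmp_chec.ci_low,
             "ci_high": cmp_chec.ci_high, "percent_change": cmp_chec.percent_change}
        )
        pd.DataFrame(rows).to_csv(out / "occupancy.tsv", sep="\t", index=False)

    if "displace" in stages and {"wt-g1", "sir2-g1"} <= set(mnase):
        pairs = [("wt-g1", "sir2-g1")]
        if "sir2-term" in mnase:
            pairs.append(("sir2-g1", "sir2-term"))
        rows = []
        for ref, test in pairs:
            res = _stage(
                "displace", displacement_test, mnase[ref], mnase[test], lm,
                n_boot=n_boot, seed=seed + 103,
            )
            rows.append(
                {"reference": ref, "test": test,
                 "fraction_downstream_ref": res.fraction_downstream_ref,
                 "fraction_downstream_test": res.fraction_downstream_test,
                 "delta": res.delta, "com_shift_bp": res.com_shift,
                 "ci_low": res.ci_low, "ci_high": res.ci_high,
                 "p_value": res.p_value}
            )
        pd.DataFrame(rows).to_csv(out / "displacement.tsv", sep="\t", index=False)

    if "sseq" in stages:
        sq = config.get("sseq", default_config()["sseq"])
        counts = _stage(
            "sseq", simulate_sseq_counts, sq["rdna_share_g1"],
            sq["replicated_fraction_rdna"], sq["replicated_fraction_genome"],
            sq["n_reads"], sq["n_reads"], seed + 104,
        )
        ri = replication_index(counts)
        pd.DataFrame(
            [{"rdna_s": counts.rdna_s, "total_s": counts.total_s,
              "rdna_g1": counts.rdna_g1, "total_g1": counts.total_g1,
              "replication_index": ri.index, "ci_low": ri.ci_low,
              "ci_high": ri.ci_high,
              "expected_index": expected_replication_index(
                  sq["rdna_share_g1"], sq["replicated_fraction_rdna"],
                  sq["replicated_fraction_genome"])}]
        ).to_csv(out / "sseq.tsv", sep="\t", index=False)

    if "plot" in stages:
        for sc, m in matrices.items():
            _stage(
                "plot", render_2d, normalize_matrix(m, "unit_max"), lm,
                PlotSpec(output=str(out / f"{sc}_matrix.png"), title=sc),
            )

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config,
        "derived_seeds": {f"{sc}:{mode}": s for (sc, mode), s in child_seeds.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
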