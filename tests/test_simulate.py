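"""Synthetic generator: determinism, marginals, competition, preset scenarios."""

import dataclasses

import numpy as np
import pytest

from rdnafoot.errors import ModelError
from rdnafoot.fragments import Fragments
from rdnafoot.occupancy import chec_rdna_fraction
from rdnafoot.regions import GenomicInterval
from rdnafoot.simulate import (
    ChromatinModel,
    MODEL_PRESETS,
    ParticleSpec,
    SIR2_LOADING_FACTOR,
    sir2_g1_model,
    simulate_chec_fragments,
    simulate_mnase_fragments,
    simulate_sseq_counts,
    terminator_model,
    wt_g1_model,
    wt_g2_model,
)


class TestPresets:
    def test_g2_prerc_occupancy_is_zero(self, lm):
        model = wt_g2_model(lm)
        assert model.particle("prerc").occupancy == 0.0
        assert model.effective_occupancies()["prerc"] == 0.0

    def test_sir2_loading_factor_encodes_reduction(self, lm):
        assert sir2_g1_model(lm).loading_factor == pytest.approx(1 - 0.37)
        assert sir2_g1_model(lm).loading_factor == SIR2_LOADING_FACTOR

    def test_terminator_abolishes_push_but_keeps_sir2_loading(self, lm):
        model = terminator_model(lm)
        assert model.p_push == 0.0
        assert model.loading_factor == SIR2_LOADING_FACTOR

    def test_competition_scales_origin_nucleosome(self, lm):
        """Mutual exclusion: the origin nucleosome is bound only on repeat
        copies where the pre-RC is absent."""
        g1 = wt_g1_model(lm).effective_occupancies()
        g2 = wt_g2_model(lm).effective_occupancies()
        assert g1["nuc2"] == pytest.approx(0.3 * (1 - 0.9))
        assert g2["nuc2"] == pytest.approx(0.3)
        s2 = sir2_g1_model(lm).effective_occupancies()
        assert s2["prerc"] == pytest.approx(0.9 * SIR2_LOADING_FACTOR)
        assert s2["nuc2"] == pytest.approx(0.3 * (1 - 0.9 * SIR2_LOADING_FACTOR))

    def test_push_window_sits_in_downstream_region(self, lm):
        model = sir2_g1_model(lm)
        assert model.push_window.start >= lm.rars
        assert model.push_window.end <= lm.downstream_window.end


class TestModelValidation:
    def test_occupancy_outside_unit_interval_rejected(self):
        with pytest.raises(ModelError):
            ParticleSpec("p", 100, "factor", 60, 5, 1.5)

    def test_push_without_window_rejected(self, lm):
        with pytest.raises(ModelError):
            dataclasses.replace(wt_g1_model(lm), p_push=0.5, push_window=None)

    def test_unknown_competition_name_rejected(self, lm):
        with pytest.raises(ModelError):
            dataclasses.replace(wt_g1_model(lm), competition_pairs=(("nope", "prerc"),))


class TestMnaseSimulator:
    def test_same_seed_reproduces_output(self, lm):
        a, ta = simulate_mnase_fragments(wt_g1_model(lm), 5000, 42)
        b, tb = simulate_mnase_fragments(wt_g1_model(lm), 5000, 42)
        np.testing.assert_array_equal(a.starts, b.starts)
        np.testing.assert_array_equal(a.ends, b.ends)
        assert ta.per_fragment.equals(tb.per_fragment)
        c, _ = simulate_mnase_fragments(wt_g1_model(lm), 5000, 43)
        assert not np.array_equal(a.starts, c.starts)

    def test_degenerate_model_emits_exact_footprint(self, lm):
        center = lm.rars + 100
        model = ChromatinModel(
            landmarks=lm,
            particles=(ParticleSpec("solo", center, "nucleosome", 146.0, 0.0, 1.0),),
            background_rate=0.0,
            jitter_sd=0.0,
        )
        frags, truth = simulate_mnase_fragments(model, 200, 1)
        assert set(zip(frags.starts.tolist(), frags.ends.tolist())) == {
            (center - 73, center + 73)
        }
        assert (truth.per_fragment["source"] == "solo").all()

    def test_assignment_frequencies_match_effective_occupancies(self, wt_g1_sim, lm):
        frags, truth = wt_g1_sim
        n = len(frags)
        model = wt_g1_model(lm)
        eff = model.effective_occupancies()
        total = sum(eff.values())
        counts = truth.per_fragment["source"].value_counts()
        assert counts.get("background", 0) == pytest.approx(
            n * model.background_rate, abs=3 * np.sqrt(n * 0.05 * 0.95)
        )
        for name, occ in eff.items():
            p = (1 - model.background_rate) * occ / total
            sd = np.sqrt(n * p * (1 - p))
            assert counts.get(name, 0) == pytest.approx(n * p, abs=max(3 * sd, 1))

    def test_mutual_exclusion_in_truth_record(self, wt_g1_sim):
        """No simulated repeat instance yields both an origin-nucleosome and
        a pre-RC fragment; competition also depletes the origin nucleosome
        relative to its flanking neighbours."""
        _, truth = wt_g1_sim
        per = truth.per_fragment
        assert not (
            (per["source"] == "nuc2") & (per["displaced"])
        ).any()  # displaced fragments are always pre-RC
        assert set(per["source"].unique()) <= {
            "background", "reb1", "nuc1", "nuc2", "nuc3", "nuc4", "nuc5", "nuc6",
            "prerc",
        }
        n2 = (per["source"] == "nuc2").sum()
        n1 = (per["source"] == "nuc1").sum()
        assert n2 < 0.15 * n1  # eff 0.03 vs 0.9

    def test_displacement_latents_respect_p_push(self, sir2_g1_sim, lm):
        _, truth = sir2_g1_sim
        per = truth.per_fragment
        prerc = per[per["source"] == "prerc"]
        pushed = prerc["displaced"].mean()
        sd = np.sqrt(0.6 * 0.4 / len(prerc))
        assert pushed == pytest.approx(0.6, abs=3 * sd)
        win = sir2_g1_model(lm).push_window
        centers = prerc.loc[prerc["displaced"], "center"]
        assert ((centers >= win.start) & (centers < win.end)).all()


class TestChecSimulator:
    def test_same_seed_reproduces_output(self, lm):
        a, _ = simulate_chec_fragments(wt_g1_model(lm), 5000, 7)
        b, _ = simulate_chec_fragments(wt_g1_model(lm), 5000, 7)
        np.testing.assert_array_equal(a.starts, b.starts)
        assert a.chroms.tolist() == b.chroms.tolist()

    def test_rdna_fragments_overlap_tagged_footprint(self, lm):
        model = wt_g1_model(lm)
        frags, truth = simulate_chec_fragments(model, 20_000, 8)
        prerc = model.particle("prerc")
        in_rdna = frags.subset(np.asarray(truth.per_fragment["in_rdna"]))
        # each cut deviates from the particle edge by (L - mean)/2 + jitter
        edge_sd = np.sqrt((prerc.footprint_sd / 2) ** 2 + model.jitter_sd**2)
        pad = 6 * edge_sd + 1
        footprint = GenomicInterval(
            lm.chrom,
            int(prerc.center - prerc.footprint_mean / 2 - pad),
            int(prerc.center + prerc.footprint_mean / 2 + pad),
        )
        assert (in_rdna.starts >= footprint.start).all()
        assert (in_rdna.ends <= footprint.end).all()

    def test_share_recovered_and_cap_enforced(self, lm):
        model = wt_g1_model(lm)
        frags, truth = simulate_chec_fragments(model, 50_000, 9)
        assert frags.lengths.max() <= model.chec_max_length
        est = chec_rdna_fraction(frags, lm.repeat_unit)
        sd = np.sqrt(0.1 * 0.9 / len(frags))
        assert est == pytest.approx(model.rdna_share, abs=4 * sd)

    def test_untagged_model_rejected(self, lm):
        model = wt_g1_model(lm)
        untagged = dataclasses.replace(
            model,
            particles=tuple(dataclasses.replace(p, tagged=False) for p in model.particles),
        )
        with pytest.raises(ModelError):
            simulate_chec_fragments(untagged, 100, 1)


class TestSseqSimulator:
    def test_same_seed_reproduces_counts(self):
        a = simulate_sseq_counts(0.1, 0.8, 0.5, 10**5, 10**5, 3)
        b = simulate_sseq_counts(0.1, 0.8, 0.5, 10**5, 10**5, 3)
        assert a == b

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_sseq_counts(0.1, 1.4, 0.5, 100, 100, 1)
        with pytest.raises(ValueError):
            simulate_sseq_counts(0.0, 0.5, 0.5, 100, 100, 1)


@pytest.mark.parametrize("preset", sorted(MODEL_PRESETS))
def test_every_preset_simulates_both_modes(preset, lm):
    model = MODEL_PRESETS[preset](lm)
    mf, _ = simulate_mnase_fragments(model, 500, 2)
    assert len(mf) == 500
    if model.effective_occupancies()["prerc"] > 0:
        cf, _ = simulate_chec_fragments(model, 500, 2)
        assert len(cf) > 0
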