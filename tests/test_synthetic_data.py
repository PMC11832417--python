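"""Simulator ground truth: kinetics closed forms, fragmentation arithmetic,
reproducibility and monotonicity invariants."""

import numpy as np
import pandas as pd
import pytest

from qdaflux import synthetic_data as sd


@pytest.fixture()
def single_site():
    return sd.class_sites_table({"ORF": 1}, spacing=1000, chrom="c")


class TestSimulateStates:
    def test_zero_rate_zero_background_never_methylates(self, orf_sites):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.0}, f0=0.0)
        st = sd.simulate_states(orf_sites, kp, [0, 60, 240], 50, seed=1)
        assert not st.states.any()

    def test_nuclei_saturation_recovers_plateau(self, orf_sites):
        # p = 0.70 with c >> c0: the accessible fraction is the limit digest
        kp = sd.KineticsParams(mode="nuclei", plateau={"ORF": 0.70}, c0=0.8)
        st = sd.simulate_states(orf_sites, kp, [0.77, 5.6, 50.0], 2000, seed=2)
        frac = st.states[-1].mean()
        se = np.sqrt(0.7 * 0.3 / (2000 * len(orf_sites)))
        assert abs(frac - 0.70) < 3 * se

    def test_in_vivo_closed_form_instant_induction(self, orf_sites):
        # k = 0.01/min, t = 100 -> 1 - e^-1
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.01}, f0=0.0)
        st = sd.simulate_states(
            orf_sites, kp, [100.0], 2000, seed=3, induction=sd.INSTANT_INDUCTION
        )
        expected = 1 - np.exp(-1.0)
        se = np.sqrt(expected * (1 - expected) / (2000 * len(orf_sites)))
        assert abs(st.states[0].mean() - expected) < 3 * se

    def test_methylation_monotone_in_design_axis(self, orf_sites):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.01}, f0=0.05)
        st = sd.simulate_states(orf_sites, kp, [0, 30, 60, 120, 240], 200, seed=4)
        frac = st.states.mean(axis=(1, 2))
        assert np.all(np.diff(frac) >= 0)
        # within-cell monotonicity: once methylated, stays methylated
        assert not (st.states[:-1] & ~st.states[1:]).any()

    def test_unknown_class_rejected(self, orf_sites):
        kp = sd.KineticsParams(mode="in_vivo", rate={"NDR": 0.01})
        with pytest.raises(KeyError, match="ORF"):
            sd.simulate_states(orf_sites, kp, [10], 5, seed=1)

    def test_identical_seed_identical_states_and_cell_stability(self, orf_sites):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.01})
        a = sd.simulate_states(orf_sites, kp, [60], 50, seed=9)
        b = sd.simulate_states(orf_sites, kp, [60], 50, seed=9)
        assert np.array_equal(a.states, b.states)
        # growing n_cells never reshuffles earlier cells
        c = sd.simulate_states(orf_sites, kp, [60], 80, seed=9)
        assert np.array_equal(c.states[:, :50, :], a.states)

    def test_induced_fraction_tracks_half_time(self, orf_sites):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.1})
        ind = sd.InductionModel(half_time=80.0, sigma_cell=0.5)
        st = sd.simulate_states(orf_sites, kp, [80.0], 4000, seed=5, induction=ind)
        assert abs(st.induced_fraction(80.0) - 0.5) < 3 * np.sqrt(0.25 / 4000)


class TestGroundTruthTable:
    def test_counting(self, single_site):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.01})
        st = sd.simulate_states(single_site, kp, [60], 10, seed=1)
        st.states[0, :, 0] = [True] * 5 + [False] * 5
        table = sd.ground_truth_table(st)
        assert table["true_fraction"].tolist() == [0.5]

    def test_extremes(self, single_site):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.0}, f0=0.0)
        st = sd.simulate_states(single_site, kp, [60], 20, seed=1)
        assert sd.ground_truth_table(st)["true_fraction"].tolist() == [0.0]
        st.states[:] = True
        assert sd.ground_truth_table(st)["true_fraction"].tolist() == [1.0]


class TestFragmentize:
    @staticmethod
    def _states_single(methylated, start=3000, chrom_len=6000):
        sites = pd.DataFrame(
            {"chrom": ["c"], "start": [start], "motif": ["GATC"], "midpoint": [start + 2]}
        )
        states = np.full((1, 1, 1), bool(methylated))
        return (
            sd.MethylationStates(
                axis="time_min", design=np.array([60.0]), states=states,
                sites=sites, expected=states[:, 0].astype(float),
            ),
            {"c": chrom_len},
        )

    def test_no_methylation_no_sonication_full_length(self):
        st, cs = self._states_single(False)
        frag = sd.FragmentationParams(mean_length=1e12, terminal_loss_prob=0.0,
                                      **sd.NO_RECOVERY_LOSS)
        frags = sd.fragmentize(st, cs, frag, seed=1)
        assert frags[["start", "end"]].values.tolist() == [[0, 6000]]

    def test_blunt_cut_arithmetic_q0(self):
        st, cs = self._states_single(True, start=3000)
        frag = sd.FragmentationParams(mean_length=1e12, terminal_loss_prob=0.0,
                                      **sd.NO_RECOVERY_LOSS)
        frags = sd.fragmentize(st, cs, frag, seed=1).sort_values("start")
        # cut between A and T: left fragment's last base is the A (3001),
        # right fragment's first base is the T (3002)
        assert frags[["start", "end"]].values.tolist() == [[0, 3002], [3002, 6000]]

    def test_terminal_loss_arithmetic_q1(self):
        st, cs = self._states_single(True, start=3000)
        frag = sd.FragmentationParams(mean_length=1e12, terminal_loss_prob=1.0,
                                      **sd.NO_RECOVERY_LOSS)
        frags = sd.fragmentize(st, cs, frag, seed=1).sort_values("start")
        # left fragment now ends on the G (exclusive end 3001), right begins
        # on the C (3003)
        assert frags[["start", "end"]].values.tolist() == [[0, 3001], [3003, 6000]]

    def test_fragments_tile_molecule_exactly(self, orf_sites):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.01})
        st = sd.simulate_states(orf_sites, kp, [120], 1, seed=7,
                                induction=sd.INSTANT_INDUCTION)
        frag = sd.FragmentationParams(mean_length=300.0, terminal_loss_prob=0.0,
                                      **sd.NO_RECOVERY_LOSS)
        frags = sd.fragmentize(st, {"chrT": 6000}, frag, seed=8).sort_values("start")
        starts = frags["start"].to_numpy()
        ends = frags["end"].to_numpy()
        assert starts[0] == 0 and ends[-1] == 6000
        assert np.array_equal(starts[1:], ends[:-1])  # disjoint, gap-free

    def test_reproducible_and_bedpe_round_trip(self, orf_sites, tmp_path):
        kp = sd.KineticsParams(mode="in_vivo", rate={"ORF": 0.01})
        st = sd.simulate_states(orf_sites, kp, [120], 20, seed=7)
        frag = sd.FragmentationParams()
        a = sd.fragmentize(st, {"chrT": 6000}, frag, seed=5)
        b = sd.fragmentize(st, {"chrT": 6000}, frag, seed=5)
        pd.testing.assert_frame_equal(a, b)
        path = tmp_path / "frags.bedpe"
        sd.write_bedpe(a, path)
        from qdaflux import fragment_quant as fq

        back = fq.load_fragments(path)
        assert np.array_equal(back[["start", "end"]].values, a[["start", "end"]].values)


class TestLongreadEmission:
    @staticmethod
    def _cg_states(n_cells, frac, seed=0, n_sites=20):
        rng = np.random.default_rng(seed)
        starts = np.arange(100, 100 + 50 * n_sites, 50)
        seq = ["A"] * (200 + 50 * n_sites)
        for s in starts:
            seq[s], seq[s + 1] = "C", "G"
        sites = pd.DataFrame(
            {"chrom": "c", "start": starts, "motif": "CG", "midpoint": starts + 1,
             "region_class": "ORF"}
        )
        states = rng.random((1, n_cells, n_sites)) < frac
        st = sd.MethylationStates(
            axis="time_min", design=np.array([60.0]), states=states, sites=sites,
            expected=np.full((1, n_sites), frac),
        )
        return st, {"c": "".join(seq)}

    def test_all_methylated_all_positive_llr(self):
        st, seqs = self._cg_states(10, 1.1)
        calls = sd.emit_longread_calls(st, seqs, seed=1, error_rate=0.0)
        assert (calls["log_lik_ratio"] > 0).all()

    def test_proximal_sites_grouped(self):
        starts = np.array([100, 103])
        seq = list("A" * 300)
        for s in starts:
            seq[s], seq[s + 1] = "C", "G"
        sites = pd.DataFrame(
            {"chrom": "c", "start": starts, "motif": "CG", "midpoint": starts + 1}
        )
        st = sd.MethylationStates(
            axis="time_min", design=np.array([1.0]),
            states=np.ones((1, 3, 2), dtype=bool), sites=sites,
            expected=np.ones((1, 2)),
        )
        calls = sd.emit_longread_calls(st, {"c": "".join(seq)}, seed=1, group_gap=5)
        assert (calls["num_motifs"] == 2).all()
        assert len(calls) == 3  # one row per read
        assert calls["sequence"].str.upper().str.count("CG").eq(2).all()

    def test_non_cg_sites_rejected(self, orf_sites):
        st = sd.MethylationStates(
            axis="time_min", design=np.array([1.0]),
            states=np.zeros((1, 1, len(orf_sites)), dtype=bool),
            sites=orf_sites, expected=np.zeros((1, len(orf_sites))),
        )
        with pytest.raises(ValueError, match="CG"):
            sd.emit_longread_calls(st, {"chrT": "A" * 6000}, seed=1)


class TestPositionalAccessibility:
    def test_hard_occlusion_without_jitter(self):
        p = sd.positional_accessibility(
            np.array([0.0, 73.0, 74.0, 120.0]), np.array([0.0]),
            jitter_sd=0.0, p_linker=0.8, p_nucleosomal=0.1,
        )
        assert p.tolist() == [0.1, 0.1, 0.8, 0.8]

    def test_jitter_smooths_toward_mean_occupancy(self):
        x = np.arange(-300, 300).astype(float)
        sharp = sd.positional_accessibility(x, np.array([0.0]), jitter_sd=0.0)
        fuzzy = sd.positional_accessibility(x, np.array([0.0]), jitter_sd=40.0)
        assert fuzzy.max() - fuzzy.min() < sharp.max() - sharp.min()
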