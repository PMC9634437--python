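"""Generator contracts: determinism, planted truth, recovery, calibration."""

import numpy as np
import pandas as pd
import pytest

from translatekit import te_pipeline as tep
from translatekit.proteome_de import de_census, protein_de
from translatekit.synthetic_data import (
    ORFSpec,
    SimConfig,
    simulate_counts,
    simulate_proteome,
    simulate_splicing_events,
    simulate_transcripts,
)


class TestSimulateCounts:
    def test_null_config_has_no_shifts(self):
        cfg = SimConfig(n_genes=100, frac_mrna_te_down=0.0, frac_lnc_te_up=0.0, seed=1)
        _, _, truth = simulate_counts(cfg)
        assert (truth.true_log2_te_ratio == 0).all()
        assert not truth.is_te_shifted.any()

    def test_same_seed_identical_output(self):
        cfg = SimConfig(n_genes=120, seed=9)
        t1, p1, truth1 = simulate_counts(cfg)
        t2, p2, truth2 = simulate_counts(cfg)
        assert t1 == t2 and p1 == p2
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_differs(self):
        a, _, _ = simulate_counts(SimConfig(n_genes=120, seed=1))
        b, _, _ = simulate_counts(SimConfig(n_genes=120, seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_biotype_proportions_exact(self):
        _, _, truth = simulate_counts(SimConfig(n_genes=250, seed=0))
        counts = truth.biotype.value_counts()
        assert counts["protein_coding"] == 200
        assert counts["lincRNA"] == 30
        assert counts["processed_transcript"] == 20

    def test_low_dispersion_empirical_te_approaches_truth(self):
        # law-of-large-numbers check: Poisson counts, large means, many reps.
        # Only a few genes are shifted so the library composition (and hence
        # CPM of unshifted genes) stays nearly constant across conditions.
        cfg = SimConfig(
            n_genes=60, n_reps=20, nb_dispersion=0.0,
            baseline_log_mean=9.5, baseline_log_sd=0.2,
            frac_mrna_te_down=0.05, mrna_te_shift_log2=-1.0,
            frac_lnc_te_up=0.05, lnc_te_shift_log2=1.0, seed=5,
        )
        trans, poly, truth = simulate_counts(cfg)
        df = tep.run_te_pipeline(trans, poly, "CRPC", "ER")
        merged = df.merge(truth, on="gene_id")
        err = merged.log2_te_ratio - merged.true_log2_te_ratio
        assert np.abs(err).max() < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError, match="proportions"):
            SimConfig(biotype_proportions={"protein_coding": 0.5})


class TestSimulateProteome:
    def test_zero_noise_zero_shift_identical_groups(self):
        cfg = SimConfig(n_genes=50, frac_mrna_te_down=0.0, frac_lnc_te_up=0.0,
                        proteome_noise_sd=0.0, seed=2)
        _, _, truth = simulate_counts(cfg)
        table, groups = simulate_proteome(truth, cfg)
        means = {g: table[[c for c, gg in groups.items() if gg == g]].mean(axis=1)
                 for g in ("VCaP", "CRPC", "ER")}
        pd.testing.assert_series_equal(means["VCaP"], means["ER"], check_names=False)

    def test_noise_free_shift_gives_exact_fold_change(self):
        cfg = SimConfig(n_genes=50, proteome_noise_sd=0.0,
                        frac_mrna_te_down=0.5, mrna_te_shift_log2=1.0,
                        frac_lnc_te_up=0.0, seed=3)
        _, _, truth = simulate_counts(cfg)
        table, groups = simulate_proteome(truth, cfg)
        er = table[[c for c, g in groups.items() if g == "ER"]].mean(axis=1)
        crpc = table[[c for c, g in groups.items() if g == "CRPC"]].mean(axis=1)
        shifted = truth.set_index("gene_id").is_te_shifted
        np.testing.assert_allclose((er / crpc)[shifted.to_numpy()], 2.0)
        np.testing.assert_allclose((er / crpc)[~shifted.to_numpy()], 1.0)

    def test_power_to_recover_planted_two_fold_proteins(self):
        """With default noise, the DE rule recovers >= 80% of 2-fold shifts."""
        recovered = total = 0
        for seed in range(20):
            cfg = SimConfig(n_genes=100, frac_mrna_te_down=0.2,
                            mrna_te_shift_log2=1.0, frac_lnc_te_up=0.0, seed=seed)
            _, _, truth = simulate_counts(cfg)
            table, groups = simulate_proteome(truth, cfg)
            calls = {c.protein_id: c.status for c in protein_de(table, groups)}
            for _, row in truth[truth.is_te_shifted].iterrows():
                total += 1
                recovered += calls[row.gene_id] == "up"
        assert recovered / total >= 0.8


class TestSimulateSplicing:
    def test_pure_shared_same_mix(self):
        from translatekit.splicing_events import classify_direction, filter_events

        crpc, er, _ = simulate_splicing_events(50, {"shared_same": 1.0}, seed=1)
        out = classify_direction(filter_events(crpc), filter_events(er))
        assert {c.category for c in out} == {"shared_same"}

    def test_balanced_mix_recovered_within_tolerance(self):
        from collections import Counter
        from translatekit.splicing_events import classify_direction, filter_events

        mix = {"CRPC_only": 0.25, "ER_only": 0.25,
               "shared_same": 0.25, "shared_opposite": 0.25}
        crpc, er, _ = simulate_splicing_events(400, mix, seed=2)
        out = classify_direction(filter_events(crpc), filter_events(er))
        freq = Counter(c.category for c in out)
        for cat, target in mix.items():
            assert abs(freq[cat] / len(out) - target) <= 0.05

    def test_seed_determinism(self):
        a = simulate_splicing_events(30, {"shared_same": 1.0}, seed=5)
        b = simulate_splicing_events(30, {"shared_same": 1.0}, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_splicing_events(10, {"shared_same": 0.5}, seed=0)


class TestSimulateTranscripts:
    def test_planted_context_round_trip(self):
        from translatekit.orf_kozak import extract_kozak_context, splice_transcript

        genome, _, transcripts, planted = simulate_transcripts(
            6, ORFSpec(kozak_context="GAGAAGATGG"), seed=4
        )
        for _, row in planted.iterrows():
            t = next(x for x in transcripts if x.transcript_id == row.transcript_id)
            seq = splice_transcript(t, genome)
            assert extract_kozak_context(seq, row.start) == "GAGAAGAUGG"

    def test_orf_free_transcripts_have_no_atg(self):
        from translatekit.orf_kozak import find_orfs, splice_transcript

        genome, _, transcripts, planted = simulate_transcripts(5, None, seed=6)
        assert planted.empty
        for t in transcripts:
            seq = splice_transcript(t, genome)
            assert "ATG" not in seq
            assert find_orfs(seq, min_peptide_length=1) == []

    def test_planted_orf_structure(self):
        from translatekit.orf_kozak import splice_transcript, STOP_CODONS

        genome, _, transcripts, planted = simulate_transcripts(
            6, ORFSpec(peptide_length=15), seed=7
        )
        for _, row in planted.iterrows():
            t = next(x for x in transcripts if x.transcript_id == row.transcript_id)
            seq = splice_transcript(t, genome)
            assert seq[row.start : row.start + 3] == "ATG"
            assert seq[row.end - 3 : row.end] in STOP_CODONS
            assert len(row.peptide) == 15

    def test_bad_context_rejected(self):
        with pytest.raises(ValueError, match="ATG"):
            ORFSpec(kozak_context="GAGAAGAAGG")
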