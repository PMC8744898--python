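"""Synthetic-cohort generators: determinism, planted truth, graceful noise decay."""

import numpy as np
import pandas as pd
import pytest

from lincpep.expression_screen import find_exclusive_transcripts
from lincpep.orf_scan import find_orfs
from lincpep.polysome import polysome_enrichment, profiles_from_ct_table
from lincpep.synthetic import (
    SyntheticTruth,
    generate_cohort,
    generate_tracks_and_ct,
    generate_transcript_sequences,
    default_screen_bundle,
)


def normals_of(matrix):
    return matrix.samples_with_role("normal_tissue")


class TestGenerateCohort:
    def test_planted_exclusives_recovered_exactly_at_zero_leakage(self):
        matrix, _, truth = generate_cohort(n_transcripts=500, leakage=0.0, seed=5)
        calls = find_exclusive_transcripts(matrix, "tumor", normals_of(matrix))
        assert {c.transcript_id for c in calls} == set(truth.exclusive_ids)

    def test_all_transcripts_exclusive_in_degenerate_cohort(self):
        matrix, _, truth = generate_cohort(
            n_transcripts=12, n_exclusive=12, seed=5
        )
        calls = find_exclusive_transcripts(matrix, "tumor", normals_of(matrix))
        assert len(calls) == 12
        assert set(truth.exclusive_ids) == set(matrix.transcript_ids)

    def test_same_seed_reproduces_matrices(self):
        m1, r1, t1 = generate_cohort(seed=8)
        m2, r2, t2 = generate_cohort(seed=8)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(r1.values, r2.values)
        assert t1 == t2

    def test_different_seeds_differ(self):
        m1, _, _ = generate_cohort(seed=8)
        m2, _, _ = generate_cohort(seed=9)
        assert not m1.values.equals(m2.values)

    def test_leakage_breaks_exclusivity_but_not_precision(self):
        matrix, _, truth = generate_cohort(leakage=0.3, seed=5)
        calls = find_exclusive_transcripts(matrix, "tumor", normals_of(matrix))
        found = {c.transcript_id for c in calls}
        assert found <= set(truth.exclusive_ids)  # precision stays 1
        assert len(found) < len(truth.exclusive_ids)  # some leaked away

    def test_infeasible_truth_spec_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(n_exclusive=5, n_confirmed=9)

    def test_truth_nesting_validated(self):
        with pytest.raises(ValueError, match="nesting"):
            SyntheticTruth(
                exclusive_ids=("a",),
                confirmed_ids=("a",),
                orf_spec={"a": ((60, "strong"),)},
                exported_ids=("a", "b"),
                translated_ids=(),
                promoter_open_ids=(),
                seed=0,
            )


class TestGenerateTranscriptSequences:
    def test_planted_orfs_recovered_by_scanner(self):
        """A 52-aa weak + 68-aa strong request comes back exactly from find_orfs."""
        spec = {"tx1": ((52, "weak"), (68, "strong"))}
        records, models = generate_transcript_sequences(spec, seed=3)
        (tid, seq), = records
        orfs = find_orfs(seq, 50)
        assert sorted((o.length_aa, o.kozak) for o in orfs) == [
            (52, "weak"), (68, "strong"),
        ]
        assert models["tx1"].sequence == seq

    def test_no_orf_request_yields_no_qualifying_orf(self):
        records, _ = generate_transcript_sequences({"tx1": ()}, seed=3)
        assert find_orfs(records[0][1], 50) == []

    def test_same_seed_gives_identical_fasta(self):
        spec = {"a": ((60, "strong"),), "b": ()}
        r1, _ = generate_transcript_sequences(spec, seed=11)
        r2, _ = generate_transcript_sequences(spec, seed=11)
        assert r1 == r2

    def test_infeasible_length_raises(self):
        with pytest.raises(ValueError):
            generate_transcript_sequences(
                {"tx1": ((400, "strong"),)}, background_length=900, seed=0
            )

    def test_scanner_verified_over_many_transcripts(self):
        """Every generated sequence satisfies its own ORF request (50 transcripts)."""
        rng = np.random.default_rng(13)
        spec = {}
        for i in range(50):
            n = int(rng.integers(0, 3))
            spec[f"t{i}"] = tuple(
                (int(rng.integers(51, 80)), str(rng.choice(["strong", "adequate", "weak"])))
                for _ in range(n)
            )
        records, _ = generate_transcript_sequences(spec, seed=13)
        for tid, seq in records:
            found = sorted((o.length_aa, o.kozak) for o in find_orfs(seq, 50))
            assert found == sorted(spec[tid])


class TestGenerateTracksAndCt:
    def _bundle_parts(self, ct_noise_sd=0.0, seed=0):
        _, _, truth = generate_cohort(seed=seed)
        spec = {tid: truth.orf_spec.get(tid, ()) for tid in truth.confirmed_ids}
        _, models = generate_transcript_sequences(spec, seed=seed)
        tracks = generate_tracks_and_ct(
            truth, models, ct_noise_sd=ct_noise_sd, seed=seed
        )
        return truth, models, tracks

    def test_zero_noise_translated_mass_is_planted_mass(self):
        truth, _, tracks = self._bundle_parts()
        profiles = profiles_from_ct_table(tracks.ct_table)
        for tid in truth.translated_ids:
            score, translated = polysome_enrichment(profiles[tid])
            assert translated and abs(score - 0.75) < 1e-9

    def test_no_open_promoters_means_no_tumor_peaks(self):
        _, _, truth = generate_cohort(n_promoter_open=0, seed=2)
        spec = {tid: truth.orf_spec.get(tid, ()) for tid in truth.confirmed_ids}
        _, models = generate_transcript_sequences(spec, seed=2)
        tracks = generate_tracks_and_ct(truth, models, seed=2)
        assert tracks.tumor_dnase == []

    def test_seed_determinism(self):
        _, _, t1 = self._bundle_parts(ct_noise_sd=1.0, seed=4)
        _, _, t2 = self._bundle_parts(ct_noise_sd=1.0, seed=4)
        pd.testing.assert_frame_equal(t1.ct_table, t2.ct_table)
        assert t1.tumor_dnase == t2.tumor_dnase

    def test_translated_recall_degrades_gracefully_with_ct_noise(self):
        """Mean translated-call recall is monotone non-increasing over noise levels."""
        recalls = []
        for sd in (0.0, 2.0, 5.0):
            hits = total = 0
            for seed in range(10):
                truth, _, tracks = self._bundle_parts(ct_noise_sd=sd, seed=seed)
                profiles = profiles_from_ct_table(tracks.ct_table)
                for tid in truth.translated_ids:
                    total += 1
                    _, translated = polysome_enrichment(profiles[tid])
                    hits += translated
            recalls.append(hits / total)
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[2] < 1.0


class TestPaperMirrorBundle:
    def test_bundle_is_internally_consistent(self):
        bundle = default_screen_bundle(seed=1, n_transcripts=200)
        truth = bundle.truth
        sequences = dict(bundle.sequences)
        assert set(truth.confirmed_ids) <= set(sequences)
        for tid in truth.qualifying_orf_ids():
            found = sorted(
                (o.length_aa, o.kozak) for o in find_orfs(sequences[tid], 50)
            )
            assert found == sorted(truth.orf_spec[tid])
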