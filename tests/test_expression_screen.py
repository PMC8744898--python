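"""Exclusivity filter: worked example, brute-force oracle, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincpep.examples import hcc_expression_matrix
from lincpep.expression_screen import (
    ScreenThresholds,
    classify_expression,
    confirm_in_replicate,
    find_exclusive_transcripts,
)
from lincpep.io_formats import ExpressionMatrix, SampleInfo


def random_matrix(rng, n_transcripts, n_normals, zero_inflation=0.6, scale=5.0):
    """A sparse random FPKM matrix with one tumor and n normal samples."""
    shape = (n_transcripts, n_normals + 1)
    values = rng.gamma(1.0, scale, size=shape)
    values[rng.random(shape) < zero_inflation] = 0.0
    ids = [f"t{i:04d}" for i in range(n_transcripts)]
    cols = ["tumor"] + [f"n{j}" for j in range(n_normals)]
    meta = {"tumor": SampleInfo(role="tumor")}
    meta.update({c: SampleInfo(role="normal_tissue", tissue=c) for c in cols[1:]})
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols), meta)


class TestClassifyExpression:
    @pytest.mark.parametrize(
        "fpkm,expected",
        [(61.3, "on"), (0.0, "off"), (0.5, "ambiguous"), (1.0, "on")],
    )
    def test_default_thresholds(self, fpkm, expected):
        assert classify_expression(fpkm, ScreenThresholds()) == expected

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            classify_expression(-0.1, ScreenThresholds())

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScreenThresholds(tau_on=0.5, tau_off=0.5)
        with pytest.raises(ValueError):
            ScreenThresholds(tau_on=1.0, tau_off=-0.1)


class TestFindExclusive:
    def test_published_six_transcript_table(self):
        """The printed liver/HepG2 table yields six exclusive calls, largest first."""
        calls = find_exclusive_transcripts(
            hcc_expression_matrix(), "HepG2", ["liver"], ScreenThresholds(1.0, 0.0)
        )
        assert len(calls) == 6
        assert calls[0].transcript_id == "NONHSAT226968.1"
        assert [c.tumor_fpkm for c in calls] == [104.9, 61.3, 39.3, 30.5, 15.0, 13.7]
        assert all(c.status == "exclusive" for c in calls)
        assert all(c.max_normal_fpkm == 0.0 for c in calls)

    def test_all_zero_matrix_gives_empty_list(self):
        df = pd.DataFrame(
            np.zeros((10, 5)),
            index=[f"t{i}" for i in range(10)],
            columns=["tumor"] + [f"n{j}" for j in range(4)],
        )
        meta = {"tumor": SampleInfo(role="tumor")}
        meta.update({f"n{j}": SampleInfo(role="normal_tissue") for j in range(4)})
        matrix = ExpressionMatrix(df, meta)
        assert find_exclusive_transcripts(matrix, "tumor", [f"n{j}" for j in range(4)]) == []

    def test_matches_exhaustive_per_cell_rule(self):
        """Vectorized screen equals applying the on/off rule cell by cell."""
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng, 200, 17)
        thresholds = ScreenThresholds(1.0, 0.0)
        normals = [f"n{j}" for j in range(17)]
        calls = find_exclusive_transcripts(matrix, "tumor", normals, thresholds)

        expected = set()
        for tid in matrix.transcript_ids:
            tumor_state = classify_expression(matrix.value(tid, "tumor"), thresholds)
            normal_states = {
                classify_expression(matrix.value(tid, n), thresholds) for n in normals
            }
            if tumor_state == "on" and normal_states == {"off"}:
                expected.add(tid)
        assert {c.transcript_id for c in calls} == expected

    def test_ambiguous_normal_excludes(self):
        df = pd.DataFrame(
            {"tumor": [10.0], "n0": [0.5]}, index=["t0"]
        )
        meta = {"tumor": SampleInfo(role="tumor"), "n0": SampleInfo(role="normal_tissue")}
        matrix = ExpressionMatrix(df, meta)
        assert find_exclusive_transcripts(matrix, "tumor", ["n0"]) == []

    def test_errors(self):
        matrix = hcc_expression_matrix()
        with pytest.raises(KeyError):
            find_exclusive_transcripts(matrix, "nope", ["liver"])
        with pytest.raises(ValueError):
            find_exclusive_transcripts(matrix, "HepG2", [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tau_on=st.floats(0.5, 5.0),
        tau_off=st.floats(0.0, 0.4),
        d_on=st.floats(0.0, 3.0),
        d_off=st.floats(0.0, 0.3),
    )
    def test_monotone_in_thresholds(self, tau_on, tau_off, d_on, d_off):
        """Raising tau_on or lowering tau_off never adds an exclusive transcript."""
        rng = np.random.default_rng(11)
        matrix = random_matrix(rng, 100, 5)
        normals = [f"n{j}" for j in range(5)]
        loose = find_exclusive_transcripts(
            matrix, "tumor", normals, ScreenThresholds(tau_on, tau_off)
        )
        tight = find_exclusive_transcripts(
            matrix, "tumor", normals,
            ScreenThresholds(tau_on + d_on, max(0.0, tau_off - d_off)),
        )
        assert {c.transcript_id for c in tight} <= {c.transcript_id for c in loose}


class TestConfirmInReplicate:
    def _matrix_with_tumor(self, levels):
        df = pd.DataFrame({"tumor": list(levels.values())}, index=list(levels.keys()))
        return ExpressionMatrix(df, {"tumor": SampleInfo(role="tumor")})

    def test_keeps_only_replicate_expressed(self):
        """Twelve calls against a replicate expressing nine of them leaves nine."""
        rng = np.random.default_rng(3)
        ids = [f"t{i}" for i in range(12)]
        matrix = self._matrix_with_tumor({t: 10.0 for t in ids})
        calls = find_exclusive_transcripts(
            ExpressionMatrix(
                pd.concat([matrix.values, pd.Series(0.0, index=ids, name="n0")], axis=1),
                {**matrix.sample_meta, "n0": SampleInfo(role="normal_tissue")},
            ),
            "tumor",
            ["n0"],
        )
        assert len(calls) == 12
        replicate = self._matrix_with_tumor(
            {t: (20.0 if i < 9 else 0.0) for i, t in enumerate(ids)}
        )
        kept = confirm_in_replicate(calls, replicate, "tumor")
        assert {c.transcript_id for c in kept} == set(ids[:9])

    def test_empty_call_list(self):
        replicate = self._matrix_with_tumor({"t0": 5.0})
        assert confirm_in_replicate([], replicate, "tumor") == []

    def test_idempotent_on_same_matrix(self):
        matrix = hcc_expression_matrix()
        calls = find_exclusive_transcripts(matrix, "HepG2", ["liver"])
        assert confirm_in_replicate(calls, matrix, "HepG2") == calls

    def test_absent_transcripts_dropped(self):
        matrix = hcc_expression_matrix()
        calls = find_exclusive_transcripts(matrix, "HepG2", ["liver"])
        replicate = self._matrix_with_tumor({"NONHSAT226968.1": 9.0})
        kept = confirm_in_replicate(calls, replicate, "tumor")
        assert [c.transcript_id for c in kept] == ["NONHSAT226968.1"]
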