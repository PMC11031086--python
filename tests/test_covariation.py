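"""Mutual information against a brute-force joint-counting oracle, plus the
dual-threshold covariation calling rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from evoassay.evolution import CovariationCriteria, call_covariation, mutual_information
from evoassay.evolution.msa import MsaBundle
from evoassay.synthetic import make_covariation_fixture


def bundle(rows):
    rows = [list(r) for r in rows]
    return MsaBundle(
        ids=tuple(f"s{i}" for i in range(len(rows))),
        protein=np.array(rows, dtype="U1"),
    )


def brute_force_mi(col_a, col_b):
    """Independent oracle: dictionary joint counting, log2 plug-in MI."""
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a != "-" and b != "-"]
    n = len(pairs)
    joint: dict = {}
    pa: dict = {}
    pb: dict = {}
    for a, b in pairs:
        joint[(a, b)] = joint.get((a, b), 0) + 1
        pa[a] = pa.get(a, 0) + 1
        pb[b] = pb.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        mi += pab * math.log2(pab / ((pa[a] / n) * (pb[b] / n)))
    return mi


class TestMutualInformation:
    def test_coupled_four_states_two_bits(self):
        rows = ["AAK", "CCK", "DDK", "EEK"]
        df = mutual_information(bundle(rows), min_joint_coverage=0.0)
        pair = df.set_index(["pos_i", "pos_j"]).loc[(48, 49)]
        assert pair["mi_raw"] == pytest.approx(2.0)

    def test_identical_uniform_twenty_states(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rows = [a + a + "K" for a in aas]
        df = mutual_information(bundle(rows), min_joint_coverage=0.0)
        pair = df.set_index(["pos_i", "pos_j"]).loc[(48, 49)]
        assert pair["mi_raw"] == pytest.approx(math.log2(20))

    def test_independent_constant_column_zero(self):
        rows = ["AK", "CK", "DK", "EK"]
        rows = [r + "V" for r in rows]
        df = mutual_information(bundle(rows), min_joint_coverage=0.0)
        pair = df.set_index(["pos_i", "pos_j"]).loc[(48, 49)]
        assert pair["mi_raw"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(0)
        aas = np.array(list("ACDE"))
        rows = ["".join(r) for r in aas[rng.integers(0, 4, size=(8, 6))]]
        df = mutual_information(bundle(rows), min_joint_coverage=0.0)
        assert (df["mi_raw"].dropna() >= -1e-12).all()
        assert (df["pos_i"] < df["pos_j"]).all()  # each unordered pair once

    def test_matches_brute_force_oracle(self):
        # <= 10x10 alignments, exact agreement to 1e-12
        rng = np.random.default_rng(42)
        aas = np.array(list("ACDEFG-"))
        for trial in range(10):
            mat = aas[rng.integers(0, len(aas), size=(10, 10))]
            rows = ["".join(r) for r in mat]
            df = mutual_information(bundle(rows), min_joint_coverage=0.0)
            df = df.set_index(["pos_i", "pos_j"])
            for i, j in itertools.combinations(range(10), 2):
                expected = brute_force_mi(mat[:, i], mat[:, j])
                got = df.loc[(48 + i, 48 + j), "mi_raw"]
                if np.isnan(got):
                    # unscored: fewer than 2 jointly non-gap rows
                    n_joint = sum(
                        1 for a, b in zip(mat[:, i], mat[:, j])
                        if a != "-" and b != "-"
                    )
                    assert n_joint < 2
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_low_coverage_pair_unscored(self):
        rows = ["A-K", "C-K", "DAK", "ECK"]  # cols 0/1 share only 2 of 4 rows
        df = mutual_information(bundle(rows), min_joint_coverage=0.9)
        df = df.set_index(["pos_i", "pos_j"])
        assert np.isnan(df.loc[(48, 49), "mi_raw"])
        assert not np.isnan(df.loc[(48, 50), "mi_raw"])

    def test_apc_reduces_background(self):
        # identical columns vs independent ones: APC-corrected score of the
        # coupled pair stays dominant
        rng = np.random.default_rng(1)
        aas = np.array(list("ACDEFGHIKL"))
        base = aas[rng.integers(0, 10, size=20)]
        noise = aas[rng.integers(0, 10, size=(20, 3))]
        mat = np.column_stack([base, base, noise])
        df = mutual_information(bundle(["".join(r) for r in mat]))
        top = df.sort_values("mi_apc", ascending=False).iloc[0]
        assert (top["pos_i"], top["pos_j"]) == (48, 49)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(bundle(["AK", "CV"]))


def pair_df(records):
    return pd.DataFrame(records, columns=["pos_i", "pos_j", "mi_raw"])


class TestCallCovariation:
    def conservation(self, mapping, positions):
        return pd.Series({p: mapping.get(p, 0.0) for p in positions})

    def test_low_mi_rule_fires(self):
        pairs = pair_df([(1, 2, 4.5)])
        cons = pd.Series({1: -0.8, 2: -0.6})
        out = call_covariation(pairs, cons)
        assert out["covary_call"].iloc[0]
        assert out["rule_fired"].iloc[0] == "low_MI_rule"

    def test_low_mi_rule_requires_both_conserved(self):
        pairs = pair_df([(1, 2, 4.5)])
        cons = pd.Series({1: -0.8, 2: -0.4})
        out = call_covariation(pairs, cons)
        assert not out["covary_call"].iloc[0]

    def test_high_mi_rule_fires(self):
        pairs = pair_df([(1, 2, 8.5)])
        cons = pd.Series({1: -0.4, 2: -0.35})
        out = call_covariation(pairs, cons)
        assert out["covary_call"].iloc[0]
        assert out["rule_fired"].iloc[0] == "high_MI_rule"

    def test_boundary_mi_exactly_four_not_called(self):
        pairs = pair_df([(1, 2, 4.0)])
        cons = pd.Series({1: -0.9, 2: -0.9})
        out = call_covariation(pairs, cons)
        assert not out["covary_call"].iloc[0]

    def test_missing_conservation_unscored(self):
        pairs = pair_df([(1, 3, 9.0)])
        cons = pd.Series({1: -0.9, 2: -0.9})
        out = call_covariation(pairs, cons)
        assert not out["covary_call"].iloc[0]

    def test_fixture_calls_exactly_half_percent(self):
        sites, pairs = make_covariation_fixture()
        out = call_covariation(pairs, sites["conservation"])
        assert int(out["covary_call"].sum()) == 401
        assert out.attrs["called_fraction"] == pytest.approx(0.005)

    def test_fixture_background_never_called(self):
        sites, pairs = make_covariation_fixture()
        out = call_covariation(pairs, sites["conservation"])
        background = out[out["mi_raw"] == 0.1]
        assert not background["covary_call"].any()

    def test_cap_ranked_by_mi(self):
        # C(21,2) = 210 pairs -> cap ceil(1.05) = 2; highest-MI pairs kept
        positions = list(range(1, 22))
        records = [(1, 2, 5.0), (1, 3, 6.0), (2, 3, 7.0)]
        records += [(i, j, 0.0) for i, j in itertools.combinations(positions, 2)
                    if (i, j) not in {(1, 2), (1, 3), (2, 3)}]
        pairs = pair_df(records)
        cons = pd.Series({p: -1.0 for p in positions})
        out = call_covariation(pairs, cons).set_index(["pos_i", "pos_j"])
        assert out.loc[(2, 3), "covary_call"]
        assert out.loc[(1, 3), "covary_call"]
        assert not out.loc[(1, 2), "covary_call"]

    def test_cap_disabled(self):
        positions = list(range(1, 30))
        records = [(1, 2, 5.0), (1, 3, 6.0), (2, 3, 7.0)]
        records += [(i, j, 0.0) for i, j in itertools.combinations(positions, 2)
                    if (i, j) not in {(1, 2), (1, 3), (2, 3)}]
        pairs = pair_df(records)
        cons = pd.Series({p: -1.0 for p in positions})
        out = call_covariation(pairs, cons, apply_cap=False)
        assert int(out["covary_call"].sum()) == 3

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            CovariationCriteria(mi_lo=9.0, mi_hi=8.0)
        with pytest.raises(ValueError):
            CovariationCriteria(select_fraction=0.0)
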