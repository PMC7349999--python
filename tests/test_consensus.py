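"""Consensus rules, region extraction and majority-zero subtraction."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ldrkit as lk
from ldrkit.consensus import ConsensusConfig, consensus_difference, extract_regions

from conftest import make_stack, make_track


def brute_force_vote(columns, rule):
    """Independent per-position vote counter over {O,M,N} columns."""
    out = []
    for col in columns:
        votes = [c for c in col if c != "N"]
        miss = sum(c == "M" for c in votes)
        if not votes:
            out.append("U")
        elif rule == "majority":
            out.append("D" if miss > len(votes) / 2 else "S")
        else:
            out.append("D" if miss == len(votes) else "S")
    return "".join(out)


def columns_of(rows):
    return ["".join(r[i] for r in rows) for i in range(len(rows[0]))]


class TestConsensusRules:
    def test_three_of_five_chains_is_majority_disordered(self):
        stack = make_stack(["M", "M", "M", "O", "O"])
        assert lk.majority_consensus(stack).states == "D"

    def test_exact_half_is_structured(self):
        stack = make_stack(["M", "M", "O", "O"])
        assert lk.majority_consensus(stack).states == "S"

    def test_uncovered_position_is_unknown(self):
        stack = make_stack(["N", "N", "N"])
        for rule in (lk.majority_consensus, lk.zero_consensus):
            track = rule(stack)
            assert track.states == "U"
            assert track.coverage[0] == 0

    def test_single_track_consensus_equals_track(self):
        stack = make_stack(["MONMO"])
        maj = lk.majority_consensus(stack)
        zero = lk.zero_consensus(stack)
        assert maj.states == "DSUDS"
        assert maj.states == zero.states

    def test_zero_requires_every_chain_missing(self):
        all_missing = make_stack(["M"] * 5)
        one_observed = make_stack(["M"] * 4 + ["O"])
        assert lk.zero_consensus(all_missing).states == "D"
        assert lk.zero_consensus(one_observed).states == "S"
        # the same position is still majority-disordered
        assert lk.majority_consensus(one_observed).states == "D"

    def test_uncovered_cells_do_not_vote(self):
        # 2 of 3 covering chains missing: D even though 2/5 of all tracks
        stack = make_stack(["M", "M", "O", "N", "N"])
        assert lk.majority_consensus(stack).states == "D"

    def test_exhaustive_columns_match_bruteforce(self):
        """Consensus is position-wise: checking every per-position column
        vector over {O,M,N} for 1-4 chains covers all stacks exactly."""
        for n_chains in range(1, 5):
            for col in product("OMN", repeat=n_chains):
                stack = make_stack(["".join(c) for c in zip(col)])
                for rule, fn in (("majority", lk.majority_consensus),
                                 ("zero", lk.zero_consensus)):
                    assert fn(stack).states == brute_force_vote([col], rule), (
                        n_chains, col, rule)

    def test_exhaustive_small_stacks_match_bruteforce(self):
        for rows in product(["".join(p) for p in product("OMN", repeat=3)],
                            repeat=2):
            stack = make_stack(list(rows))
            cols = columns_of(rows)
            assert lk.majority_consensus(stack).states == \
                brute_force_vote(cols, "majority")
            assert lk.zero_consensus(stack).states == brute_force_vote(cols, "zero")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_stacks_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(1, 5)), int(rng.integers(1, 7))
        rows = ["".join(rng.choice(list("OMN"), size=L)) for _ in range(n)]
        stack = make_stack(rows)
        cols = columns_of(rows)
        assert lk.majority_consensus(stack).states == brute_force_vote(cols, "majority")
        assert lk.zero_consensus(stack).states == brute_force_vote(cols, "zero")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_track_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("OMN"), size=8)) for _ in range(4)]
        stack = make_stack(rows)
        perm = make_stack([rows[i] for i in rng.permutation(4)])
        assert lk.majority_consensus(stack).states == \
            lk.majority_consensus(perm).states
        assert lk.zero_consensus(stack).states == lk.zero_consensus(perm).states

    def test_zero_disorder_subset_of_majority(self, small_stacks):
        for stack in small_stacks.values():
            maj = lk.majority_consensus(stack).states
            zero = lk.zero_consensus(stack).states
            for m, z in zip(maj, zero):
                if z == "D":
                    assert m == "D"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_duplicating_a_track_keeps_margin2_decisions(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("OMN"), size=10)) for _ in range(5)]
        stack = make_stack(rows)
        base = lk.majority_consensus(stack)
        dup_idx = int(rng.integers(0, 5))
        dup = make_stack(rows + [rows[dup_idx]])
        after = lk.majority_consensus(dup).states
        cov = stack.tracks != "N"
        miss = stack.tracks == "M"
        for i in range(10):
            if rows[dup_idx][i] == "N":
                continue
            margin = abs(2 * int(miss[:, i].sum()) - int(cov[:, i].sum()))
            if margin >= 2:
                assert after[i] == base.states[i]


class TestRegionExtraction:
    @pytest.mark.parametrize("run_len,expected", [
        (30, "LDR"), (29, "SDR"), (5, "SDR"), (4, None), (100, "LDR"),
    ])
    def test_length_thresholds(self, run_len, expected):
        track = make_track("S" * 3 + "D" * run_len + "S" * 3)
        regions = extract_regions(track)
        if expected is None:
            assert regions == []
        else:
            (r,) = regions
            assert (r.start, r.end, r.region_class) == (4, 3 + run_len, expected)

    def test_unknown_breaks_runs(self):
        track = make_track("D" * 40 + "U" + "D" * 40)
        regions = extract_regions(track)
        assert [(r.start, r.end) for r in regions] == [(1, 40), (42, 81)]
        assert all(r.region_class == "LDR" for r in regions)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_bruteforce_interval_scanner(self, seed):
        rng = np.random.default_rng(seed)
        states = "".join(rng.choice(list("DSU"), size=60, p=[0.5, 0.3, 0.2]))
        track = make_track(states)
        got = [(r.start, r.end, r.region_class) for r in extract_regions(track)]
        # oracle: scan every maximal D interval by position
        expect = []
        i = 0
        while i < len(states):
            if states[i] == "D":
                j = i
                while j < len(states) and states[j] == "D":
                    j += 1
                n = j - i
                if n >= 30:
                    expect.append((i + 1, j, "LDR"))
                elif n >= 5:
                    expect.append((i + 1, j, "SDR"))
                i = j
            else:
                i += 1
        assert got == expect

    def test_region_lengths_bounded_by_d_count(self, small_stacks):
        for stack in small_stacks.values():
            track = lk.majority_consensus(stack)
            regions = extract_regions(track)
            assert sum(r.length for r in regions) <= track.states.count("D")


class TestClassification:
    def test_ldr_takes_precedence(self):
        track = make_track("D" * 40 + "S" * 10 + "D" * 6 + "S" * 44)
        regions = extract_regions(track)
        pc = lk.classify_protein(regions, track)
        assert pc.category == "LDR-protein"

    def test_only_subthreshold_runs_is_structured(self):
        track = make_track(("D" * 4 + "S" * 10) * 5)
        pc = lk.classify_protein(extract_regions(track), track)
        assert pc.category == "structured"

    @pytest.mark.parametrize("n_d,expected", [(70, True), (69, False)])
    def test_fully_disordered_boundary_at_70_percent(self, n_d, expected):
        track = make_track("D" * n_d + "S" * (100 - n_d))
        pc = lk.classify_protein(extract_regions(track), track)
        assert pc.fully_disordered is expected


class TestConsensusDifference:
    def test_identical_consensus_gives_empty_difference(self):
        maj = make_track("D" * 40 + "S" * 10)
        zero = make_track("D" * 40 + "S" * 10, rule="zero")
        (cmp_,) = consensus_difference(extract_regions(maj), zero)
        assert cmp_.differences == ()
        assert cmp_.confirmed

    def test_partial_zero_support_confirmed(self):
        # majority LDR 1-60, zero D only at 1-35 -> difference 36-60, confirmed
        maj = make_track("D" * 60 + "S" * 10)
        zero = make_track("D" * 35 + "S" * 35, rule="zero")
        (cmp_,) = consensus_difference(extract_regions(maj), zero)
        assert [(d.start, d.end) for d in cmp_.differences] == [(36, 60)]
        assert cmp_.confirmed

    def test_short_zero_support_not_confirmed(self):
        # majority LDR 1-40, zero D only at 1-20 -> difference 21-40, unconfirmed
        maj = make_track("D" * 40 + "S" * 10)
        zero = make_track("D" * 20 + "S" * 30, rule="zero")
        (cmp_,) = consensus_difference(extract_regions(maj), zero)
        assert [(d.start, d.end) for d in cmp_.differences] == [(21, 40)]
        assert not cmp_.confirmed

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_interval_subtraction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        maj_states = "".join(rng.choice(list("DS"), size=80, p=[0.7, 0.3]))
        # zero D must be a subset of majority D
        zero_states = "".join(
            "D" if m == "D" and rng.random() < 0.6 else "S" for m in maj_states
        )
        maj = make_track(maj_states)
        zero = make_track(zero_states, rule="zero")
        for cmp_ in consensus_difference(extract_regions(maj), zero):
            r = cmp_.majority_region
            expect = set()
            for p in range(r.start, r.end + 1):
                if zero_states[p - 1] == "S":
                    expect.add(p)
            got = set()
            for d in cmp_.differences:
                got.update(range(d.start, d.end + 1))
            assert got == expect


def test_consensus_tsv_outputs(tmp_path, small_stacks):
    import pandas as pd

    pid, stack = next(iter(small_stacks.items()))
    maj = lk.majority_consensus(stack)
    zero = lk.zero_consensus(stack)
    from ldrkit.consensus import write_consensus_tsv, write_regions_tsv

    write_consensus_tsv(pid, stack.sequence, maj, zero, tmp_path / "c.tsv")
    df = pd.read_csv(tmp_path / "c.tsv", sep="\t")
    assert len(df) == stack.length
    assert "".join(df.majority_state) == maj.states

    regions = extract_regions(maj)
    write_regions_tsv(regions, tmp_path / "r.tsv")
    df = pd.read_csv(tmp_path / "r.tsv", sep="\t")
    assert len(df) == len(regions)
    if len(df):
        assert (df.length == df.end - df.start + 1).all()
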