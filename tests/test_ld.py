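"""LD computations: r², candidate expansion, block partition, haplotypes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from treesel.haplotypes import HaplotypeMatrix
from treesel.ld import (
    CandidateSNP,
    LDBlock,
    expand_candidates,
    ld_blocks,
    r_squared,
    r_squared_matrix,
    top_haplotypes,
)


def _haps(cols, ids=None):
    m = np.stack([np.asarray(c, dtype=np.int8) for c in cols], axis=1)
    return HaplotypeMatrix(
        matrix=m,
        positions=np.arange(1, m.shape[1] + 1) * 10,
        snp_ids=ids,
    )


class TestRSquared:
    def test_identical_columns_give_one(self):
        a = np.array([0, 1, 1, 0, 1])
        assert r_squared(a, a) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """Haplotypes {AB, AB, ab, aB}: D = 0.125, r² = 1/3."""
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 1, 0, 1])
        assert r_squared(a, b) == pytest.approx(1 / 3)

    def test_monomorphic_is_missing_not_zero(self):
        a = np.ones(6)
        b = np.array([0, 1, 0, 1, 0, 1])
        assert np.isnan(r_squared(a, b))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            r_squared(np.array([0, 1]), np.array([0, 1, 1]))

    @given(st.integers(0, 5000))
    def test_symmetry_and_allele_label_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        if a.var() == 0 or b.var() == 0:
            return
        r = r_squared(a, b)
        assert r == pytest.approx(r_squared(b, a))
        assert r == pytest.approx(r_squared(1 - a, b))
        assert r == pytest.approx(r_squared(a, 1 - b))
        assert 0.0 <= r <= 1.0 + 1e-12


class TestExpandCandidates:
    def test_no_linked_snps_returns_input(self, rng):
        cols = [rng.integers(0, 2, 60) for _ in range(3)]
        haps = _haps(cols, ids=["a", "b", "c"])
        reported = [CandidateSNP("a", 10, pics=0.5)]
        out = expand_candidates(reported, haps, r2_min=0.999)
        assert [c.snp_id for c in out] == ["a"]

    def test_duplicate_column_added_once_and_idempotent(self, rng):
        base = rng.integers(0, 2, 60)
        haps = _haps([base, base, 1 - base], ids=["a", "dup", "flip"])
        reported = [CandidateSNP("a", 10, pics=0.5)]
        out = expand_candidates(reported, haps)
        ids = [c.snp_id for c in out]
        assert ids.count("dup") == 1 and ids.count("flip") == 1  # r²=1 both
        again = expand_candidates(out, haps)
        assert {c.snp_id for c in again} == set(ids)
        assert {c.source for c in out if c.snp_id != "a"} == {"ld_expanded"}

    def test_candidate_set_bookkeeping_full_scale(self):
        """4331 reported + 6156 LD-linked novel SNPs -> 10487 candidates."""
        rng = np.random.default_rng(0)
        n_rep, n_new, n_hap = 4331, 6156, 24
        rep_cols = rng.integers(0, 2, size=(n_hap, n_rep)).astype(np.int8)
        # novel SNPs are exact copies of reported columns (r² = 1)
        new_cols = rep_cols[:, np.arange(n_new) % n_rep]
        matrix = np.concatenate([rep_cols, new_cols], axis=1)
        ids = [f"rep{i}" for i in range(n_rep)] + [f"new{i}" for i in range(n_new)]
        haps = HaplotypeMatrix(
            matrix=matrix,
            positions=np.arange(1, n_rep + n_new + 1),
            snp_ids=ids,
        )
        reported = [
            CandidateSNP(f"rep{i}", i + 1, pics=0.5) for i in range(n_rep)
        ]
        out = expand_candidates(reported, haps, r2_min=0.8)
        assert len(out) == 10_487

    def test_absent_reported_snp_skipped(self, rng):
        haps = _haps([rng.integers(0, 2, 30)], ids=["a"])
        reported = [CandidateSNP("missing", 99, pics=0.2)]
        out = expand_candidates(reported, haps)
        assert [c.snp_id for c in out] == ["missing"]


class TestLDBlocks:
    def test_all_linked_gives_one_block(self, rng):
        base = rng.integers(0, 2, 80)
        haps = _haps([base, base, base ^ (rng.random(80) < 0.02)], ids=list("abc"))
        blocks = ld_blocks(["a", "b", "c"], haps)
        assert len(blocks) == 1
        assert sorted(blocks[0].snp_ids) == ["a", "b", "c"]

    def test_all_unlinked_gives_singletons(self):
        rng = np.random.default_rng(4)
        cols = [rng.integers(0, 2, 400) for _ in range(4)]
        haps = _haps(cols, ids=list("abcd"))
        blocks = ld_blocks(list("abcd"), haps)
        assert len(blocks) == 4

    def test_chain_linkage_forms_single_block(self):
        """A-B and B-C linked, A-C weak: single-linkage joins all three
        (within-block pairs may fall below the cutoff)."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = rng.integers(0, 2, 300).astype(np.int8)
            b = (a ^ (rng.random(300) < 0.12)).astype(np.int8)
            c = (b ^ (rng.random(300) < 0.12)).astype(np.int8)
            r_ab, r_bc = r_squared(a, b), r_squared(b, c)
            r_ac = r_squared(a, c)
            if r_ab >= 0.6 and r_bc >= 0.6 and r_ac < 0.6:
                haps = _haps([a, b, c], ids=list("abc"))
                blocks = ld_blocks(list("abc"), haps)
                assert len(blocks) == 1
                return
        pytest.fail("could not realize the chain LD configuration")

    def test_partition_and_cross_block_property(self, rng):
        """Every SNP in exactly one block; all cross-block r² < cutoff."""
        cols = []
        for _ in range(6):
            base = rng.integers(0, 2, 200)
            cols.append(base)
            cols.append(base ^ (rng.random(200) < 0.05))
        ids = [f"s{i}" for i in range(len(cols))]
        haps = _haps(cols, ids=ids)
        blocks = ld_blocks(ids, haps, r2_cut=0.6)
        seen = [s for b in blocks for s in b.snp_ids]
        assert sorted(seen) == sorted(ids)  # partition
        r2 = r_squared_matrix(haps)
        lab = {}
        for b in blocks:
            for s in b.snp_ids:
                lab[s] = b.block_id
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if lab[ids[i]] != lab[ids[j]] and not np.isnan(r2[i, j]):
                    assert r2[i, j] < 0.6
        assert [b.block_id for b in blocks] == sorted(
            range(len(blocks)), key=lambda k: blocks[k].span[0]
        )


class TestTopHaplotypes:
    def test_all_identical(self):
        haps = _haps([[1, 1, 1, 1], [0, 0, 0, 0]], ids=["x", "y"])
        block = LDBlock(0, ["x", "y"], np.array([10, 20]))
        assert top_haplotypes(block, haps) == [("10", 1.0)]

    def test_counting_with_lexicographic_tiebreak(self):
        """2x'01', 1x'00', 1x'11': tie between 00 and 11 broken to 00."""
        haps = _haps([[0, 0, 0, 1], [1, 1, 0, 1]], ids=["x", "y"])
        block = LDBlock(0, ["x", "y"], np.array([10, 20]))
        assert top_haplotypes(block, haps, k=2) == [("01", 0.5), ("00", 0.25)]

    def test_frequencies_non_increasing(self, rng):
        cols = [rng.integers(0, 2, 50) for _ in range(4)]
        haps = _haps(cols, ids=list("wxyz"))
        block = LDBlock(0, list("wxyz"), np.array([10, 20, 30, 40]))
        tops = top_haplotypes(block, haps, k=5)
        freqs = [f for _, f in tops]
        assert all(a >= b for a, b in zip(freqs, freqs[1:]))
        assert sum(freqs) <= 1.0 + 1e-12

    def test_empty_block_rejected(self):
        haps = _haps([[0, 1]], ids=["x"])
        with pytest.raises(ValueError):
            top_haplotypes(LDBlock(0, [], np.array([])), haps)
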