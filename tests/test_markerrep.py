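"""Marker representations: D' confidence intervals, confidence-interval
haplotype blocks, HAP encoding, and PC features."""

import numpy as np
import pytest

from flaxgs import markerrep
from flaxgs.markerrep import (
    GabrielConfig,
    MarkerRepError,
    classify_pairs,
    dprime_ci,
    encode_hap_markers,
    find_blocks,
    pc_markers,
    snp_markers,
)

from conftest import make_gm


def _inbred_cols(cols):
    """Stack 0/2 dosage columns into a GenotypeMatrix."""
    return make_gm(np.column_stack(cols).astype(float))


class TestDprimeCI:
    def test_perfect_ld_strong(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 200) * 2.0
        gm = _inbred_cols([a, a])
        st = dprime_ci(gm, 0, 1)
        assert st.dprime == pytest.approx(1.0)
        assert st.ci_low >= 0.70 and st.ci_high >= 0.98
        assert st.classification == "strong_LD"

    def test_independent_loci_strong_recombination(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 500) * 2.0
            y = rng.integers(0, 2, 500) * 2.0
            st = dprime_ci(_inbred_cols([x, y]), 0, 1)
            hits += st.classification == "strong_recombination"
        assert hits >= 9

    def test_tiny_sample_wide_ci_inconclusive(self):
        # 4 lines consistent with complete LD: likelihood nearly flat
        gm = _inbred_cols([[0, 0, 2, 2], [0, 0, 2, 2]])
        st = dprime_ci(gm, 0, 1)
        assert st.ci_low < 0.70
        assert st.classification == "inconclusive"

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 100).astype(float)
        b = np.clip(a + rng.integers(-1, 2, 100), 0, 2).astype(float)
        gm = _inbred_cols([a, b])
        ij, ji = dprime_ci(gm, 0, 1), dprime_ci(gm, 1, 0)
        assert ij.dprime == pytest.approx(ji.dprime, abs=1e-12)
        assert (ij.ci_low, ij.ci_high) == (ji.ci_low, ji.ci_high)

    def test_monomorphic_rejected(self):
        gm = _inbred_cols([[0, 0, 0, 0], [0, 2, 0, 2]])
        with pytest.raises(MarkerRepError):
            dprime_ci(gm, 0, 1)


def oracle_blocks(gm, config):
    """Independent exhaustive block search: enumerate every interval, test
    the Gabriel conditions directly, then apply the same greedy resolution."""
    cfg = config or GabrielConfig()
    pairs = classify_pairs(gm, cfg)
    maf = gm.maf()
    chroms = gm.variants["chrom"].to_numpy()
    cands = []
    for a in range(gm.n_loci):
        for b in range(a + 1, gm.n_loci):
            if chroms[a] != chroms[b] or b - a > cfg.max_block_span_loci:
                continue
            if pairs.get((a, b)) != "strong_LD":
                continue
            inf = strong = 0
            for i in range(a, b + 1):
                for j in range(i + 1, b + 1):
                    informative = (
                        pairs.get((i, j)) is not None
                        and pairs[(i, j)] != "inconclusive"
                        and maf[i] >= cfg.min_informative_maf
                        and maf[j] >= cfg.min_informative_maf
                    )
                    if informative:
                        inf += 1
                        strong += pairs[(i, j)] == "strong_LD"
            if inf > 0 and strong / inf >= cfg.min_strong_fraction:
                cands.append((a, b))
    cands.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
    chosen, used = [], set()
    for a, b in cands:
        if any(i in used for i in range(a, b + 1)):
            continue
        used.update(range(a, b + 1))
        chosen.append((a, b))
    return sorted(chosen)


class TestFindBlocks:
    def test_single_cluster(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 2, 200) * 2.0
        free = [rng.integers(0, 2, 200) * 2.0 for _ in range(4)]
        gm = _inbred_cols(free[:2] + [base] * 5 + free[2:])
        blocks = find_blocks(gm)
        assert [(b.start_idx, b.end_idx) for b in blocks] == [(2, 6)]

    def test_all_unlinked_no_blocks(self):
        rng = np.random.default_rng(5)
        gm = _inbred_cols([rng.integers(0, 2, 400) * 2.0 for _ in range(6)])
        assert find_blocks(gm) == []

    def test_two_clusters(self):
        rng = np.random.default_rng(6)
        c1 = rng.integers(0, 2, 200) * 2.0
        c2 = rng.integers(0, 2, 200) * 2.0
        gm = _inbred_cols([c1, c1, c1, rng.integers(0, 2, 200) * 2.0, c2, c2, c2])
        blocks = find_blocks(gm)
        assert [(b.start_idx, b.end_idx) for b in blocks] == [(0, 2), (4, 6)]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_loci = rng.integers(3, 13)
        n = 120
        # random mix of correlated clusters and free loci
        cols = []
        base = rng.integers(0, 2, n) * 2.0
        for _ in range(n_loci):
            if rng.random() < 0.5:
                col = base.copy()
                flip = rng.random(n) < 0.05
                col[flip] = 2.0 - col[flip]
            else:
                col = rng.integers(0, 2, n) * 2.0
            if rng.random() < 0.2:
                base = rng.integers(0, 2, n) * 2.0
            cols.append(col)
        d = np.column_stack(cols)
        poly = d.min(axis=0) != d.max(axis=0)
        if poly.sum() < 3:
            pytest.skip("degenerate draw")
        gm = make_gm(d[:, poly])
        cfg = GabrielConfig()
        got = sorted((b.start_idx, b.end_idx) for b in find_blocks(gm, cfg))
        assert got == oracle_blocks(gm, cfg)

    def test_min_strong_fraction_monotone(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 2, 150) * 2.0
        cols = []
        for _ in range(8):
            col = base.copy()
            flip = rng.random(150) < 0.08
            col[flip] = 2.0 - col[flip]
            cols.append(col)
        gm = _inbred_cols(cols)
        prev_span = None
        for frac in (0.80, 0.90, 0.95, 1.0):
            cfg = GabrielConfig(min_strong_fraction=frac)
            span = sum(b.n_loci for b in find_blocks(gm, cfg))
            if prev_span is not None:
                assert span <= prev_span
            prev_span = span


class TestHapEncoding:
    def test_two_allele_closure(self):
        rng = np.random.default_rng(10)
        base = rng.integers(0, 2, 100) * 2.0
        gm = _inbred_cols([base, base, base])
        blocks = find_blocks(gm)
        ms = encode_hap_markers(gm, blocks)
        assert ms.n_features == 2
        np.testing.assert_allclose(ms.values.sum(axis=1), 2.0)

    def test_monomorphic_block_single_zero_variance_column(self):
        gm = _inbred_cols([[2, 2, 2, 2], [2, 2, 2, 2]])
        blk = markerrep.HaplotypeBlock(chrom="chr1", start_idx=0, end_idx=1)
        ms = encode_hap_markers(gm, [blk])
        assert ms.n_features == 1
        assert np.var(ms.values[:, 0]) == 0.0

    def test_column_accounting_identity(self, founder_panel):
        gm = founder_panel.to_genotype_matrix().take_loci(np.arange(60))
        blocks = find_blocks(gm)
        ms = encode_hap_markers(gm, blocks)
        in_block = sum(b.n_loci for b in blocks)
        assert ms.n_features == ms.provenance["n_block_allele_columns"] + (
            gm.n_loci - in_block
        )
        # closure over every block's columns
        col = 0
        for name_group in range(ms.provenance["n_blocks"]):
            cols = [
                k
                for k, nm in enumerate(ms.feature_names)
                if nm.startswith(f"HAP{name_group + 1}_")
            ]
            if cols:
                np.testing.assert_allclose(ms.values[:, cols].sum(axis=1), 2.0)
            col += len(cols)

    def test_het_lines_get_frequency_weighted_dosage(self):
        gm = make_gm(
            np.array([[0, 0], [0, 0], [2, 2], [2, 2], [1, 1]], dtype=float)
        )
        blk = markerrep.HaplotypeBlock(chrom="chr1", start_idx=0, end_idx=1)
        ms = encode_hap_markers(gm, [blk])
        np.testing.assert_allclose(ms.values[4], [1.0, 1.0])  # 2 * 0.5 each
        np.testing.assert_allclose(ms.values.sum(axis=1), 2.0)


class TestPCMarkers:
    def test_rank_two_needs_two_components(self):
        rng = np.random.default_rng(11)
        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 30))
        gm = make_gm(u @ v)
        pcs = pc_markers(gm)
        assert pcs.n_components == 2

    def test_projection_reproduces_training_scores(self, founder_panel):
        gm = founder_panel.to_genotype_matrix()
        pcs = pc_markers(gm, test_gm=gm)
        np.testing.assert_allclose(pcs.test.values, pcs.train.values, atol=1e-8)

    def test_minimal_component_count(self):
        rng = np.random.default_rng(12)
        gm = make_gm(rng.normal(size=(100, 300)))
        pcs = pc_markers(gm)
        cum = np.cumsum(pcs.explained_variance_ratio)
        assert cum[-1] >= 0.95
        assert pcs.n_components == 1 or cum[-2] < 0.95

    def test_requires_imputed(self):
        gm = make_gm(np.array([[0.0, np.nan], [2.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(MarkerRepError):
            pc_markers(gm)
        with pytest.raises(MarkerRepError):
            snp_markers(gm)
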