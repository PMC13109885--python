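"""File-format round-trips, the ordered marker-QC rules, windowed LD
pruning and genomic principal components."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gpeval.genio import (
    ParseError,
    compute_pcs,
    hwe_exact_p,
    ld_prune,
    qc_filter,
    read_dataset,
    read_plink,
    write_dataset,
    write_plink,
)
from gpeval.simdata import SimConfig, simulate_dataset

from conftest import geno_from_array, marker_frame


@pytest.fixture(scope="module")
def sim5x10(tmp_path_factory):
    cfg = SimConfig(n_founders=5, n_generations=1, n_markers=10, n_chromosomes=2, seed=4)
    ped, geno, pheno, _ = simulate_dataset(cfg)
    geno.dosages[0, 3] = np.nan  # one missing call
    return ped, geno, pheno


class TestIO:
    @pytest.mark.parametrize("dialect", ["tsv", "plink"])
    def test_round_trip_is_lossless(self, dialect, sim5x10, tmp_path):
        ped, geno, pheno = sim5x10
        write_dataset(tmp_path / dialect, geno, ped, pheno, dialect=dialect)
        geno2, ped2, pheno2 = read_dataset(tmp_path / dialect, dialect=dialect)
        np.testing.assert_array_equal(geno.dosages, geno2.dosages)
        assert geno.ids == geno2.ids
        assert list(geno.markers["marker"]) == list(geno2.markers["marker"])
        pd.testing.assert_frame_equal(ped.table, ped2.table)
        assert pheno2["trait"].tolist() == pytest.approx(pheno["trait"].tolist())

    def test_heterozygote_dosage_ignores_allele_order(self, tmp_path):
        (tmp_path / "t.map").write_text("1 m1 0 100\n")
        (tmp_path / "t.ped").write_text(
            "f1 i1 0 0 0 -9 A G\n"
            "f2 i2 0 0 0 -9 G A\n"
            "f3 i3 0 0 0 -9 A A\n"
        )
        geno = read_plink(tmp_path / "t")
        assert geno.dosages[:, 0].tolist() == [1.0, 1.0, 2.0]

    def test_missing_genotype_excluded_from_frequencies(self, tmp_path):
        (tmp_path / "t.map").write_text("1 m1 0 100\n")
        (tmp_path / "t.ped").write_text(
            "f1 i1 0 0 0 -9 0 0\n"
            "f2 i2 0 0 0 -9 A A\n"
            "f3 i3 0 0 0 -9 A G\n"
        )
        geno = read_plink(tmp_path / "t")
        assert np.isnan(geno.dosages[0, 0])
        assert geno.allele_freqs()[0] == pytest.approx(0.75)

    def test_parse_errors_name_file_and_line(self, tmp_path):
        (tmp_path / "t.map").write_text("1 m1 0 100\n1 m2 0 200\n")
        (tmp_path / "t.ped").write_text("f1 i1 0 0 0 -9 A A\n")
        with pytest.raises(ParseError, match=r"t\.ped:1"):
            read_plink(tmp_path / "t")
        (tmp_path / "t.ped").write_text(
            "f1 i1 0 0 0 -9 A A G G\nf1 i1 0 0 0 -9 A A G G\n"
        )
        with pytest.raises(ParseError, match="duplicated"):
            read_plink(tmp_path / "t")

    def test_writer_normalizes_allele_order(self, tmp_path):
        geno = geno_from_array([[0, 2], [2, 0]])
        geno.markers.loc[1, ["a1", "a2"]] = ["T", "C"]  # a1 lexicographically later
        write_plink(geno, tmp_path / "n")
        back = read_plink(tmp_path / "n")
        # marker 1 dosage flips to count the smaller allele C
        np.testing.assert_array_equal(back.dosages[:, 0], geno.dosages[:, 0])
        np.testing.assert_array_equal(back.dosages[:, 1], 2 - geno.dosages[:, 1])


def hwe_exact_oracle(n_het, n_hom1, n_hom2):
    """Brute-force exact test: enumerate heterozygote counts directly."""
    n = n_het + n_hom1 + n_hom2
    n_a = n_het + 2 * min(n_hom1, n_hom2)

    def prob(h):
        rare_hom = (n_a - h) // 2
        common_hom = n - h - rare_hom
        if rare_hom < 0 or common_hom < 0 or (n_a - h) % 2:
            return 0.0
        return (
            comb(n, rare_hom, exact=True)
            * comb(n - rare_hom, common_hom, exact=True)
            * comb(n - rare_hom - common_hom, h, exact=True)
            * 2**h
        )

    probs = {h: prob(h) for h in range(n_a + 1)}
    total = sum(probs.values())
    obs = probs[n_het]
    return sum(v for v in probs.values() if v <= obs) / total


class TestQC:
    @pytest.mark.parametrize(
        "counts",
        [(5, 3, 2), (50, 0, 50), (25, 25, 50), (0, 10, 0), (57, 14, 50)],
    )
    def test_hwe_exact_matches_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_exact_oracle(*counts), rel=1e-9)

    def test_qc_rules_apply_in_order(self):
        rng = np.random.default_rng(0)
        n = 100
        base = rng.integers(0, 3, size=(n, 6)).astype(float)
        base[:, 0] = rng.binomial(2, 0.5, n)  # healthy marker
        base[:4, 1] = np.nan  # call rate 0.96 -> rule 1
        base[:, 2] = 0.0
        base[:4, 2] = 1.0  # MAF 0.02 -> rule 2
        base[:, 3] = np.r_[np.zeros(50), np.full(50, 2.0)]  # (50,0,50) -> HWE
        base[:, 4] = rng.binomial(2, 0.4, n)
        base[:, 5] = rng.binomial(2, 0.5, n)  # healthy but unplaced
        geno = geno_from_array(base)
        geno.markers.loc[5, "chrom"] = "0"
        out, report = qc_filter(geno)
        assert report.removed_snp_call_rate == ["m1"]
        assert report.removed_maf == ["m2"]
        assert report.removed_hwe == ["m3"]
        assert report.removed_unplaced == ["m5"]
        assert out.n_markers == 2
        assert report.n_snps_in - out.n_markers == 4

    def test_maf_boundary_is_strict(self):
        n = 100
        col_low = np.r_[np.full(8, 1.0), np.zeros(92)]  # MAF 0.04
        col_edge = np.r_[np.full(10, 1.0), np.zeros(90)]  # MAF 0.05 exactly
        anchor = np.tile([0.0, 1.0, 2.0, 1.0], 25)
        geno = geno_from_array(np.c_[col_low, col_edge, anchor])
        out, report = qc_filter(geno, hwe_p=0)
        assert "m0" in report.removed_maf
        assert "m1" not in report.removed_maf
        assert "m1" in list(out.markers["marker"])

    def test_individual_call_rate_rule(self):
        arr = np.ones((10, 4))
        arr[0, :] = np.nan  # individual 0: call rate 0
        arr[:, 0] = np.tile([0, 1, 2, 1, 0], 2)
        geno = geno_from_array(arr)
        out, report = qc_filter(geno, snp_call_rate=0.5, maf=0.0, hwe_p=0.0)
        assert report.removed_individuals == ["i0"]
        assert out.n_individuals == 9

    def test_qc_is_idempotent(self, small_dataset):
        _, _, geno, _, _ = small_dataset
        once, _ = qc_filter(geno)
        twice, rep2 = qc_filter(once)
        assert twice.n_markers == once.n_markers
        assert twice.n_individuals == once.n_individuals
        assert not rep2.removed_maf and not rep2.removed_hwe

    def test_all_removed_raises(self):
        geno = geno_from_array(np.zeros((20, 3)))
        with pytest.raises(ValueError, match="empty panel"):
            qc_filter(geno)


class TestLDPrune:
    def test_duplicate_columns_collapse_to_one(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.5, 60).astype(float)
        geno = geno_from_array(np.c_[col, col])
        kept = ld_prune(geno, r2_threshold=0.2)
        assert len(kept) == 1

    def test_independent_markers_all_retained(self):
        rng = np.random.default_rng(2)
        n = 4000
        dos = rng.binomial(2, 0.5, size=(n, 12)).astype(float)
        geno = geno_from_array(dos)
        kept = ld_prune(geno, r2_threshold=0.2)
        assert len(kept) == 12

    def test_retained_counts_monotone_in_threshold(self, small_dataset):
        _, _, geno, _, _ = small_dataset
        geno_qc, _ = qc_filter(geno)
        sizes = [len(ld_prune(geno_qc, r2_threshold=t)) for t in (0.2, 0.4, 0.6)]
        assert sizes[0] <= sizes[1] <= sizes[2]
        assert sizes[0] < geno_qc.n_markers  # the simulator creates real LD

    def test_no_surviving_pair_above_threshold(self, small_dataset):
        _, _, geno, _, _ = small_dataset
        geno_qc, _ = qc_filter(geno)
        window, thr = 50, 0.4
        kept = ld_prune(geno_qc, window_snps=window, step_snps=5, r2_threshold=thr)
        dos = geno_qc.impute_mean().dosages[:, kept]
        r2 = np.corrcoef(dos.T) ** 2
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if kept[b] - kept[a] < window:
                    assert r2[a, b] <= thr + 1e-12

    def test_invariant_to_individual_order(self, small_dataset):
        _, _, geno, _, _ = small_dataset
        geno_qc, _ = qc_filter(geno)
        shuffled = geno_qc.subset(individuals=list(reversed(geno_qc.ids)))
        k1 = ld_prune(geno_qc, r2_threshold=0.3)
        k2 = ld_prune(shuffled, r2_threshold=0.3)
        np.testing.assert_array_equal(k1, k2)

    def test_threshold_validation(self):
        geno = geno_from_array(np.ones((4, 2)))
        with pytest.raises(ValueError):
            ld_prune(geno, r2_threshold=0.0)
        with pytest.raises(ValueError):
            ld_prune(geno, r2_threshold=1.5)


class TestPCs:
    def test_identical_individuals_share_scores(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.5, size=(10, 40)).astype(float)
        dos[1] = dos[0]
        geno = geno_from_array(dos)
        scores, frac = compute_pcs(geno, 3)
        np.testing.assert_allclose(
            scores.iloc[0, 1:].to_numpy(dtype=float),
            scores.iloc[1, 1:].to_numpy(dtype=float),
            atol=1e-8,
        )
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-12

    def test_matches_bruteforce_eigendecomposition(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(20, 50)).astype(float)
        geno = geno_from_array(dos)
        scores, _ = compute_pcs(geno, 4)
        p = dos.mean(axis=0) / 2
        Z = dos - 2 * p
        G = Z @ Z.T / np.sum(2 * p * (1 - p))
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1][:4]
        ref = vecs[:, order] * np.sqrt(vals[order])
        got = scores.iloc[:, 1:].to_numpy(dtype=float)
        for j in range(4):  # eigenvectors defined up to sign
            assert min(
                np.abs(got[:, j] - ref[:, j]).max(),
                np.abs(got[:, j] + ref[:, j]).max(),
            ) < 1e-8

    def test_diverged_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        m = 150
        p1 = rng.uniform(0.1, 0.9, m)
        p2 = np.clip(p1 + rng.choice([-0.4, 0.4], m), 0.05, 0.95)
        a = rng.binomial(2, p1, size=(40, m)).astype(float)
        b = rng.binomial(2, p2, size=(40, m)).astype(float)
        geno = geno_from_array(np.vstack([a, b]))
        scores, _ = compute_pcs(geno, 2)
        label = np.r_[np.zeros(40), np.ones(40)]
        r = np.corrcoef(scores["pc1"], label)[0, 1]
        assert abs(r) > 0.9

    def test_k_validation(self):
        geno = geno_from_array(np.ones((4, 6)))
        with pytest.raises(ValueError):
            compute_pcs(geno, 0)
        with pytest.raises(ValueError):
            compute_pcs(geno, 4)
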