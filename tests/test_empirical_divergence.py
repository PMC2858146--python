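"""Tests for pairwise differences, AMOVA Phi_st, bootstrap SEs, and MDS."""

import math

import numpy as np
import pytest

from serialcoal.empirical_divergence import (
    PopulationDataset,
    amova_phist,
    classical_mds,
    kruskal_stress1,
    pairwise_differences,
    pairwise_phist_matrix,
    read_fasta_with_metadata,
)
from serialcoal.sim_core import Demography, MutationModel, export_fasta, generate_structured_dataset


def _dataset(seqs, labels):
    return PopulationDataset(ids=[f"s{i}" for i in range(len(seqs))],
                             sequences=seqs, labels=labels)


def brute_force_phist(d2, codes, K):
    """Literal evaluation of the AMOVA sums, no matrix shortcuts."""
    N = len(codes)
    ssd_total = sum(d2[i][j] for i in range(N) for j in range(N)) / (2 * N)
    ssd_within = 0.0
    sizes = [sum(1 for c in codes if c == k) for k in range(K)]
    for k in range(K):
        idx = [i for i in range(N) if codes[i] == k]
        ssd_within += sum(d2[i][j] for i in idx for j in idx) / (2 * len(idx))
    ssd_among = ssd_total - ssd_within
    msd_among = ssd_among / (K - 1)
    msd_within = ssd_within / (N - K)
    n_prime = (N - sum(s * s for s in sizes) / N) / (K - 1)
    s2w = msd_within
    s2a = (msd_among - msd_within) / n_prime
    return s2a / (s2a + s2w), s2a, s2w


class TestIO:
    def test_round_trip_and_metadata_join(self, tmp_path):
        seqs = ["ACGTACGT", "ACGTACGA", "TCGTACGA"]
        aln, labels = (None, None)
        from serialcoal.sim_core import HaplotypeAlignment

        aln = HaplotypeAlignment(sample_ids=["x1", "x2", "x3"], sequences=seqs)
        fasta = tmp_path / "aln.fasta"
        export_fasta(aln, fasta)
        meta = tmp_path / "meta.csv"
        meta.write_text("id,population,age_bp\nx1,A,2000\nx2,A,3000\nx3,B,9000\n")
        ds = read_fasta_with_metadata(fasta, meta)
        assert ds.sequences == seqs
        assert ds.labels == ["A", "A", "B"]
        assert ds.ages_bp == [2000.0, 3000.0, 9000.0]

    def test_id_mismatch_names_offenders(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">x1\nACGT\n>x9\nACGA\n")
        meta = tmp_path / "meta.csv"
        meta.write_text("id,population\nx1,A\nx2,B\n")
        with pytest.raises(ValueError, match="x9"):
            read_fasta_with_metadata(fasta, meta)


class TestPairwiseDifferences:
    def test_counts_and_symmetry(self):
        ds = _dataset(["ACGT", "ACGA", "ACGT"], ["A", "A", "B"])
        d = pairwise_differences(ds)
        assert d[0, 1] == 1 and d[0, 2] == 0 and d[1, 2] == 1
        assert (d == d.T).all() and (np.diag(d) == 0).all()

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        ds = _dataset(["AC-T", "ACGA", "NCGA"], ["A", "A", "B"])
        d = pairwise_differences(ds)
        assert d[0, 1] == 1  # site 3 only; gap site dropped
        assert d[1, 2] == 0  # N site dropped


class TestAmova:
    def test_hand_computed_toy_components(self):
        # group A = {h1, h1, h2}, B = {h3 x3}; d(h1,h2)=1, d(h1,h3)=4, d(h2,h3)=5
        h1, h2, h3 = "AAAAA", "AAAAT", "TTTTA"
        ds = _dataset([h1, h1, h2, h3, h3, h3], ["A", "A", "A", "B", "B", "B"])
        res = amova_phist(ds, n_perm=0)
        assert res.sigma2_among == pytest.approx(2.0, abs=1e-12)
        assert res.sigma2_within == pytest.approx(1 / 6, abs=1e-12)
        assert res.phi_st == pytest.approx(12 / 13, abs=1e-12)

    def test_agrees_with_brute_force_on_random_data(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(6, 14))
            K = int(rng.integers(2, 4))
            codes = rng.integers(0, K, n)
            while len(set(codes)) < K:
                codes = rng.integers(0, K, n)
            seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 12)) for _ in range(n)]
            labels = [f"g{c}" for c in codes]
            ds = _dataset(seqs, labels)
            res = amova_phist(ds, grouping=[f"g{k}" for k in range(K)], n_perm=0)
            d2 = pairwise_differences(ds)
            want, s2a, s2w = brute_force_phist(d2.tolist(), list(codes), K)
            assert res.phi_st == pytest.approx(want, abs=1e-10)
            assert res.sigma2_among == pytest.approx(s2a, abs=1e-10)
            assert res.sigma2_within == pytest.approx(s2w, abs=1e-10)

    def test_invariant_under_relabeling_and_sample_order(self):
        rng = np.random.default_rng(1)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 15)) for _ in range(12)]
        labels = ["A"] * 5 + ["B"] * 7
        ds = _dataset(seqs, labels)
        base = amova_phist(ds, n_perm=0).phi_st
        # swap group names
        swapped = _dataset(seqs, ["B" if l == "A" else "A" for l in labels])
        assert amova_phist(swapped, n_perm=0).phi_st == pytest.approx(base, abs=1e-12)
        # permute sample order
        perm = rng.permutation(12)
        shuffled = _dataset([seqs[i] for i in perm], [labels[i] for i in perm])
        assert amova_phist(shuffled, n_perm=0).phi_st == pytest.approx(base, abs=1e-12)

    def test_identical_groups_near_zero(self):
        aln, labels = generate_structured_dataset(
            (12, 12), fixed_differences=0, demography=Demography(N0=100),
            model=MutationModel(mu_per_site_year=3e-5, L=100), seed=21)
        ds = _dataset(aln.sequences, labels)
        res = amova_phist(ds, n_perm=200, seed=1)
        assert abs(res.phi_st) <= 0.05
        assert res.p_perm > 0.05

    def test_fixed_monomorphic_groups_phist_one(self):
        aln, labels = generate_structured_dataset(
            (5, 5), fixed_differences=20, demography=Demography(N0=50),
            model=MutationModel(mu_per_site_year=0.0, L=20), seed=2)
        ds = _dataset(aln.sequences, labels)
        res = amova_phist(ds, n_perm=100, seed=3)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_perm < 0.05

    def test_phist_monotone_in_fixed_differences(self):
        means = []
        for fd in (0, 5, 20):
            vals = []
            for s in range(8):
                aln, labels = generate_structured_dataset(
                    (8, 8), fixed_differences=fd, demography=Demography(N0=100),
                    model=MutationModel(mu_per_site_year=3e-5, L=60), seed=100 + s)
                ds = _dataset(aln.sequences, labels)
                vals.append(amova_phist(ds, n_perm=0).phi_st)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_permutation_test_calibrated_under_null(self):
        # identical generating model for both groups: rejection rate at
        # alpha=0.05 should sit within 3 binomial SE of 5%
        rejections = 0
        n_sets = 200
        for s in range(n_sets):
            aln, labels = generate_structured_dataset(
                (10, 10), fixed_differences=0, demography=Demography(N0=100),
                model=MutationModel(mu_per_site_year=3e-5, L=80), seed=1000 + s)
            ds = _dataset(aln.sequences, labels)
            res = amova_phist(ds, n_perm=199, seed=s)
            rejections += res.p_perm <= 0.05
        rate = rejections / n_sets
        se = math.sqrt(0.05 * 0.95 / n_sets)
        assert rate <= 0.05 + 3 * se

    def test_single_group_rejected(self):
        ds = _dataset(["ACGT", "ACGA", "AGGA"], ["A", "A", "A"])
        with pytest.raises(ValueError):
            amova_phist(ds)


class TestPairwiseMatrix:
    def test_entry_count_and_symmetry(self):
        rng = np.random.default_rng(4)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 20)) for _ in range(12)]
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        phi, se = pairwise_phist_matrix(_dataset(seqs, labels), n_boot=50, seed=5)
        assert phi.shape == (3, 3)
        assert (phi.to_numpy() == phi.to_numpy().T).all()

    def test_bootstrap_se_zero_for_fixed_monomorphic_groups(self):
        ds = _dataset(["AAAA"] * 4 + ["TTTT"] * 4, ["A"] * 4 + ["B"] * 4)
        phi, se = pairwise_phist_matrix(ds, n_boot=100, seed=6)
        assert phi.loc["A", "B"] == pytest.approx(1.0)
        assert se.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_group_se_unavailable(self):
        ds = _dataset(["AAAA", "AATA", "TTTT"], ["A", "A", "B"])
        phi, se = pairwise_phist_matrix(ds, n_boot=50, seed=7)
        assert np.isnan(se.loc["A", "B"])
        assert np.isfinite(phi.loc["A", "B"])

    def test_bootstrap_se_shrinks_with_group_size(self):
        ses = []
        for n_per in (5, 25):
            vals = []
            for s in range(5):
                aln, labels = generate_structured_dataset(
                    (n_per, n_per), fixed_differences=3, demography=Demography(N0=100),
                    model=MutationModel(mu_per_site_year=3e-5, L=80), seed=300 + s)
                ds = _dataset(aln.sequences, labels)
                _, se = pairwise_phist_matrix(ds, n_boot=100, seed=s)
                vals.append(se.loc["A", "B"])
            ses.append(np.mean(vals))
        assert ses[1] < ses[0]


class TestMds:
    def test_zero_matrix_all_points_at_origin(self):
        with pytest.warns(UserWarning):
            res = classical_mds(np.zeros((4, 4)), dims=2)
        assert np.allclose(res.coordinates, 0)
        assert res.stress == pytest.approx(0.0)

    def test_collinear_points_recovered_in_1d(self):
        D = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        res = classical_mds(D, dims=1)
        x = np.sort(res.coordinates[:, 0])
        gaps = np.diff(x)
        assert gaps == pytest.approx([1.0, 1.0], abs=1e-9)
        assert res.stress <= 1e-9

    def test_euclidean_matrix_exact_recovery(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = classical_mds(D, dims=2)
        assert res.stress <= 1e-6
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_stress_reported_against_input(self):
        # a 4-point star metric that is not 2-D Euclidean: stress > 0
        D = np.array([[0, 2, 2, 2], [2, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0.0]])
        res = classical_mds(D, dims=2)
        assert res.stress > 0
        assert res.stress == pytest.approx(
            kruskal_stress1(D, np.sqrt((
                (res.coordinates[:, None] - res.coordinates[None, :]) ** 2).sum(-1))))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0, 1.0], [2.0, 0]]))
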