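"""Placement pipeline: self-placement, seeded determinism, read-simulation
statistics, convergence of sequence mode to genotype mode, and batch
semantics."""

import dataclasses

import numpy as np
import pytest

from pcaplace import (
    InsufficientSitesError,
    PlacementConfig,
    SimConfig,
    StudyGenotypes,
    place_all,
    place_genotype_sample,
    place_sequence_sample,
    simulate_reads,
    simulate_reference_reads,
    simulate_study,
)


def _as_study(panel, rows):
    return StudyGenotypes(
        genotypes=panel.genotypes[rows],
        sample_ids=np.array([f"copy{r}" for r in rows], dtype=object),
        site_index=np.arange(panel.n_sites, dtype=np.int64),
    )


class TestGenotypeMode:
    def test_self_placement(self, small_panel, small_space):
        """A full-data copy of a reference individual lands on its own
        coordinates (run at full joint rank, where the map is exact)."""
        panel, _ = small_panel
        cfg = PlacementConfig(K=4, K_prime=panel.n_samples, knn_k=10)
        study = _as_study(panel, [0, 40, 89])
        y_norm = np.linalg.norm(small_space.Y)
        for i, r in enumerate([0, 40, 89]):
            p = place_genotype_sample(panel, small_space, study, i, cfg)
            assert np.linalg.norm(p.coords - small_space.Y[r]) <= 1e-6 * y_norm
            assert p.t >= 0.999

    def test_identical_inputs_identical_outputs(self, small_panel, small_space, placement_cfg):
        panel, _ = small_panel
        study = _as_study(panel, [5, 5])
        p1 = place_genotype_sample(panel, small_space, study, 0, placement_cfg)
        p2 = place_genotype_sample(panel, small_space, study, 1, placement_cfg)
        assert np.array_equal(p1.coords, p2.coords)
        assert p1.t == p2.t and p1.Z == p2.Z

    def test_population_recovery(self, small_panel, small_space, small_cfg, placement_cfg):
        """Fresh study individuals from population 2 place nearest to
        population-2 references."""
        panel, truth = small_panel
        study = simulate_study(truth, small_cfg, assignments=[1] * 40, seed=31)
        hits = 0
        for i in range(40):
            p = place_genotype_sample(panel, small_space, study, i, placement_cfg)
            top = max(p.knn.items(), key=lambda kv: kv[1])[0]
            hits += top == "POP2"
        assert hits >= 38  # >= 95%

    def test_insufficient_overlap_names_counts(self, small_panel, small_space, placement_cfg):
        panel, _ = small_panel
        study = _as_study(panel, [0])
        study.genotypes[0, 50:] = np.nan
        with pytest.raises(InsufficientSitesError, match="50"):
            place_genotype_sample(panel, small_space, study, 0, placement_cfg)

    def test_k_prime_capped_at_rank(self, small_panel, small_space):
        panel, _ = small_panel
        cfg = PlacementConfig(K=4, K_prime=200, knn_k=10)
        study = _as_study(panel, [3])
        p = place_genotype_sample(panel, small_space, study, 0, cfg)
        assert np.isfinite(p.coords).all()

    def test_monotone_information_in_site_count(self, small_panel, small_space, small_cfg):
        """Median t does not decrease as the shared-site count grows."""
        panel, truth = small_panel
        study = simulate_study(truth, small_cfg, assignments=[0, 1, 2] * 5, seed=57)
        medians = []
        for l in (100, 300, 600):
            cfg = PlacementConfig(K=4, K_prime=20, knn_k=10)
            sub = StudyGenotypes(
                genotypes=study.genotypes[:, :l],
                sample_ids=study.sample_ids,
                site_index=study.site_index[:l],
            )
            ts = [
                place_genotype_sample(panel, small_space, sub, i, cfg).t
                for i in range(sub.n_samples)
            ]
            medians.append(np.median(ts))
        assert medians[0] <= medians[1] + 1e-12
        assert medians[1] <= medians[2] + 1e-12

    def test_split_site_placements_agree(self, small_panel, small_space, small_cfg):
        """Placements from disjoint site halves of the same individuals
        correlate strongly per PC."""
        panel, truth = small_panel
        study = simulate_study(truth, small_cfg, assignments=[0, 1, 2] * 10, seed=91)
        cfg = PlacementConfig(K=4, K_prime=20, knn_k=10)
        halves = []
        for cols in (np.arange(0, 600, 2), np.arange(1, 600, 2)):
            sub = StudyGenotypes(
                genotypes=study.genotypes[:, cols],
                sample_ids=study.sample_ids,
                site_index=study.site_index[cols],
            )
            halves.append(
                np.array([
                    place_genotype_sample(panel, small_space, sub, i, cfg).coords
                    for i in range(sub.n_samples)
                ])
            )
        for pc in range(2):  # structured PCs
            r = np.corrcoef(halves[0][:, pc], halves[1][:, pc])[0, 1]
            assert r > 0.9


class TestReadSimulation:
    def test_error_free_homozygotes(self, rng):
        g = np.array([[0.0, 2.0]])
        d = simulate_reference_reads(g, np.array([8, 8]), np.zeros(2), rng)
        assert d[0, 0] == 0.0 and d[0, 1] == 2.0

    def test_zero_depth_is_missing(self, rng):
        g = np.array([[1.0]])
        d = simulate_reference_reads(g, np.array([0]), np.zeros(1), rng)
        assert np.isnan(d[0, 0])

    def test_heterozygote_mean_dosage(self, rng):
        """g = 1, eps = 0.01, c = 10: mean simulated dosage is 1 within
        3 standard errors over 10^4 draws."""
        n = 10_000
        g = np.ones((n, 1))
        d = simulate_reference_reads(g, np.array([10]), np.array([0.01]), rng)
        se = np.sqrt(2 * 0.5 * 0.5 / 10 / n) * 2  # dosage var = 4 p(1-p)/c
        assert abs(d.mean() - 1.0) < 3 * se


class TestSequenceMode:
    def test_seeded_determinism(self, small_panel, small_space, small_study, small_cfg, placement_cfg):
        panel, _ = small_panel
        reads = simulate_reads(small_study, small_cfg, seed=12)
        cfg = dataclasses.replace(placement_cfg, mode="sequence", reps=3, seed=99)
        p1 = place_sequence_sample(panel, small_space, reads, 0, cfg)
        p2 = place_sequence_sample(panel, small_space, reads, 0, cfg)
        assert np.array_equal(p1.coords, p2.coords)
        assert p1.t == p2.t and p1.t_sd == p2.t_sd

    def test_reps_average_and_spread(self, small_panel, small_space, small_study, small_cfg, placement_cfg):
        panel, _ = small_panel
        reads = simulate_reads(small_study, small_cfg, seed=12)
        cfg = dataclasses.replace(placement_cfg, mode="sequence", reps=4)
        p = place_sequence_sample(panel, small_space, reads, 1, cfg)
        assert p.reps == 4 and p.t_sd > 0.0

    def test_high_coverage_converges_to_genotype_placement(self, small_panel, small_space, small_cfg, placement_cfg):
        """depth 200, eps = 0: sequence-mode coordinates approach the
        genotype-mode coordinates of the same individuals."""
        panel, truth = small_panel
        study = simulate_study(truth, small_cfg, assignments=[0, 1, 2], seed=44)
        deep_cfg = dataclasses.replace(small_cfg, depth_mean=200.0, error_rate=0.0)
        reads = simulate_reads(study, deep_cfg, seed=45)
        seq_cfg = dataclasses.replace(placement_cfg, mode="sequence")
        pc_range = small_space.Y.max(axis=0) - small_space.Y.min(axis=0)
        for i in range(3):
            pg = place_genotype_sample(panel, small_space, study, i, placement_cfg)
            ps = place_sequence_sample(panel, small_space, reads, i, seq_cfg)
            assert np.all(np.abs(pg.coords - ps.coords) <= 0.05 * pc_range)


class TestPlaceAll:
    def test_worker_count_does_not_change_results(self, small_panel, small_space, small_study, small_cfg):
        panel, _ = small_panel
        reads = simulate_reads(small_study, small_cfg, seed=12)
        cfg = PlacementConfig(K=4, K_prime=20, mode="sequence", seed=7, knn_k=10)
        p1, f1 = place_all(panel, small_space, reads, cfg, workers=1)
        p4, f4 = place_all(panel, small_space, reads, cfg, workers=4)
        assert not f1 and not f4
        assert [p.sample_id for p in p1] == [p.sample_id for p in p4]
        for a, b in zip(p1, p4):
            assert np.array_equal(a.coords, b.coords) and a.t == b.t

    def test_partial_failures_collected(self, small_panel, small_space, small_study, placement_cfg):
        panel, _ = small_panel
        geno = small_study.genotypes.copy()
        geno[2, 50:] = np.nan  # below min_loci
        study = StudyGenotypes(
            genotypes=geno, sample_ids=small_study.sample_ids, site_index=small_study.site_index
        )
        placements, failures = place_all(panel, small_space, study, placement_cfg)
        assert len(placements) == study.n_samples - 1
        assert len(failures) == 1 and failures[0].sample_id == str(study.sample_ids[2])

    def test_full_data_placements_have_high_t(self, small_panel, small_space, small_study, placement_cfg):
        panel, _ = small_panel
        placements, failures = place_all(panel, small_space, small_study, placement_cfg)
        assert not failures
        assert all(p.t > 0.9 for p in placements)
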