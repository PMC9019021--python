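"""Forward-model behavior: site packing, read mixtures, Ct and donor tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsbscape import (
    FactorKernel,
    GenomeSpec,
    make_sites,
    simulate_correlated_tracks,
    simulate_donors,
    simulate_qpcr,
    simulate_reads,
    toy_genome,
)


class TestMakeSites:
    def test_gaps_and_count(self, genome):
        sites = make_sites(genome, n_sites=80, min_gap=50_000, seed=1)
        assert len(sites) == 80
        pos = sorted(s.position for s in sites)
        assert min(np.diff(pos)) >= 50_000

    def test_infeasible_packing_raises(self):
        tiny = toy_genome(100_000)
        with pytest.raises(ValueError, match="cannot place"):
            make_sites(tiny, n_sites=80, min_gap=50_000, seed=1)

    def test_deterministic_per_seed(self, genome):
        a = make_sites(genome, n_sites=50, seed=5)
        b = make_sites(genome, n_sites=50, seed=5)
        assert [(s.contig, s.position, s.cleavage_score, s.transcription_score)
                for s in a] == [
            (s.contig, s.position, s.cleavage_score, s.transcription_score)
            for s in b
        ]
        c = make_sites(genome, n_sites=50, seed=6)
        assert [s.position for s in a] != [s.position for s in c]

    def test_cleavage_grades_cover_range(self, sites100):
        scores = sorted(s.cleavage_score for s in sites100)
        assert scores[0] == pytest.approx(0.1)
        assert scores[-1] == pytest.approx(1.0)
        assert len(set(scores)) == 100

    def test_multi_contig_genome(self):
        g = GenomeSpec(contigs=(("c1", 4_000_000), ("c2", 6_000_000)))
        sites = make_sites(g, n_sites=60, min_gap=20_000, seed=2)
        by_contig = {}
        for s in sites:
            by_contig.setdefault(s.contig, []).append(s.position)
        assert sum(len(v) for v in by_contig.values()) == 60
        for pos in by_contig.values():
            if len(pos) > 1:
                assert min(np.diff(sorted(pos))) >= 20_000


class TestSimulateReads:
    def test_count_conservation_and_sorted(self, sites100, exp_kernel, genome):
        reads = simulate_reads(
            sites100, exp_kernel, genome=genome, background_rate=1e-5,
            total_reads=20_000, seed=3,
        )
        assert len(reads) == 20_000
        keys = [(r.contig, r.start) for r in reads]
        assert keys == sorted(keys)

    def test_point_kernel_support(self, sites100, genome):
        kernel = FactorKernel(shape="point", amplitude=1.0)
        reads = simulate_reads(
            sites100, kernel, genome=genome, background_rate=0.0,
            total_reads=5_000, read_len=50, seed=4,
        )
        positions = {s.position for s in sites100}
        for r in reads:
            assert any(abs(r.start - p) <= 50 for p in positions)

    def test_exponential_mean_distance(self, genome):
        # one site, 1e5 reads: MLE of the exponential mean on |distance|
        site = make_sites(genome, n_sites=1, min_gap=1, seed=9)[0]
        kernel = FactorKernel(shape="exponential", decay_length_bp=2_000, amplitude=1.0)
        reads = simulate_reads(
            [site], kernel, genome=genome, background_rate=0.0,
            total_reads=100_000, seed=10,
        )
        dist = np.abs(np.array([r.start for r in reads]) - site.position)
        se = 2_000 / np.sqrt(len(dist))
        assert abs(dist.mean() - 2_000) < 3 * se + 0.5  # +0.5 for rounding

    def test_background_only_is_poisson(self, genome):
        # amplitude 0: per-bin counts ~ Poisson(rate * bin); chi-square GOF
        sites = make_sites(genome, n_sites=5, seed=12)
        kernel = FactorKernel(shape="point", amplitude=0.0)
        reads = simulate_reads(
            sites, kernel, genome=genome, background_rate=1e-3,
            total_reads=10_000, seed=13,
        )
        starts = np.array([r.start for r in reads])
        counts = np.bincount(starts // 10_000, minlength=1_000)
        mean = counts.mean()
        # bin observed counts into Poisson classes and compare expected freqs
        kmax = int(stats.poisson.ppf(0.999, mean))
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax + 1), mean)
        exp[-1] += stats.poisson.sf(kmax, mean)
        exp = exp * counts.size
        keep = exp >= 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 2)
        assert p > 0.001

    def test_edge_clipping_preserves_count(self):
        g = toy_genome(10_000)
        site = make_sites(g, n_sites=1, min_gap=1, seed=1)[0]
        kernel = FactorKernel(shape="exponential", decay_length_bp=5_000, amplitude=1.0)
        reads = simulate_reads(
            [site], kernel, genome=g, background_rate=0.0,
            total_reads=2_000, seed=2,
        )
        assert len(reads) == 2_000
        assert all(0 <= r.start and r.end <= 10_000 for r in reads)


class TestCorrelatedTracks:
    def test_r_one_identical_amplitudes(self, sites100, exp_kernel, genome):
        reads_a, reads_b = simulate_correlated_tracks(
            sites100, exp_kernel, 1.0, genome=genome, total_reads=10_000, seed=14
        )
        assert len(reads_a) == len(reads_b) == 10_000

    def test_invalid_r_raises(self, sites100, exp_kernel):
        with pytest.raises(ValueError, match="target_pearson"):
            simulate_correlated_tracks(sites100, exp_kernel, 1.5, seed=1)

    def test_null_r_gives_null_sample_correlation(self, genome, exp_kernel):
        from dsbscape import coverage, cpm_normalize, pearson, window_sum

        sites = make_sites(genome, n_sites=80, seed=15)
        reads_a, reads_b = simulate_correlated_tracks(
            sites, exp_kernel, 0.0, genome=genome, total_reads=200_000, seed=16
        )
        ta = cpm_normalize(coverage(reads_a, genome, 100))
        tb = cpm_normalize(coverage(reads_b, genome, 100))
        xs = [window_sum(ta, s, 10_000) for s in sites]
        ys = [window_sum(tb, s, 10_000) for s in sites]
        # Fisher-z 99.9% null band for n=80
        assert abs(np.arctanh(pearson(xs, ys))) < 3.29 / np.sqrt(77)


class TestSimulateQpcr:
    def test_unit_quantity_hits_ct_at_unit(self):
        tab = simulate_qpcr([1.0], ct_at_unit=28.0, noise_sd=0.0)
        assert tab["ct"][0] == pytest.approx(28.0)

    def test_doubling_drops_one_cycle(self):
        tab = simulate_qpcr([1.0, 2.0], efficiency=2.0, noise_sd=0.0)
        assert tab["ct"][0] - tab["ct"][1] == pytest.approx(1.0)

    def test_noise_sd_calibrated(self):
        tab = simulate_qpcr(np.ones(1_000), noise_sd=0.2, seed=17)
        assert np.std(tab["ct"], ddof=1) == pytest.approx(0.2, abs=0.02)

    def test_rejects_nonpositive_quantity(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_qpcr([1.0, 0.0])

    def test_labels_carried_through(self):
        labels = pd.DataFrame(
            {"sample": ["a", "b"], "target": "t", "condition": "x", "replicate": 1}
        )
        tab = simulate_qpcr([1.0, 2.0], labels=labels)
        assert list(tab["sample"]) == ["a", "b"]
        assert "ct" in tab.columns


class TestSimulateDonors:
    def test_poisson_limit_mean(self):
        expr, sv = simulate_donors(
            2_000, beta=(np.log(5), 0.0, 0.0, 0.0), dispersion=np.inf,
            n_decoys=0, seed=18,
        )
        counts = sv.groupby("donor_id").size()
        counts = counts.reindex(expr["donor_id"].unique(), fill_value=0)
        assert counts.mean() == pytest.approx(5.0, rel=0.05)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.15)

    def test_interaction_group_mean_ratio(self):
        b = (np.log(5), 0.3, 0.2, np.log(2))
        expr, sv = simulate_donors(4_000, beta=b, dispersion=np.inf, n_decoys=0, seed=19)
        wide = expr.pivot(index="donor_id", columns="gene", values="value")
        a = wide["SETX"] > wide["SETX"].median()
        bb = wide["POLD3"] > wide["POLD3"].median()
        counts = sv.groupby("donor_id").size().reindex(wide.index, fill_value=0)
        ratio = counts[a & bb].mean() / counts[~a & ~bb].mean()
        assert ratio == pytest.approx(np.exp(b[1] + b[2] + b[3]), rel=0.1)

    def test_determinism(self):
        e1, v1 = simulate_donors(100, seed=20)
        e2, v2 = simulate_donors(100, seed=20)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_decoys_do_not_pass_the_filter(self):
        from dsbscape import count_td

        _, sv = simulate_donors(50, beta=(np.log(3), 0, 0, 0), n_decoys=4, seed=21)
        decoys = sv[(sv["sv_type"] != "tandem_duplication") | (sv["size"] >= 100_000)]
        assert len(decoys) == 50 * 4
        assert count_td(zip(decoys["sv_type"], decoys["size"])) == 0


class TestKernelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape="blob"),
            dict(decay_length_bp=0),
            dict(dip_halfwidth_bp=30_000, plateau_halfwidth_bp=25_000),
            dict(amplitude=-1),
        ],
    )
    def test_bad_kernel_params(self, kwargs):
        with pytest.raises(ValueError):
            FactorKernel(**kwargs)

    def test_genome_validation(self):
        with pytest.raises(ValueError):
            GenomeSpec(contigs=(("c1", 100), ("c1", 200)))
        with pytest.raises(ValueError):
            GenomeSpec(contigs=(("c1", 0),))
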