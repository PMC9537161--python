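"""The maximum-likelihood engine: VAF fits, LRTs, deletions, filters, VCF."""

import numpy as np
import pysam
import pytest

from mitolong.caller import (
    CallerThresholds,
    DeletionAllele,
    FrequencyEstimate,
    VariantCall,
    call_variants,
    candidate_alleles,
    detect_long_deletions,
    estimate_vaf,
    filter_call,
    fit_frequencies,
    lrt_qualities,
    merge_indel_haplotypes,
    phred_from_lrt,
    write_vcf,
)
from mitolong.model import CutSite, MitoGenome, QualityModel
from mitolong.pileup import Pileup, SiteCounts, build_pileup
from mitolong.simulate import (
    Population,
    SimConfig,
    random_genome,
    simulate_pileup_counts,
    simulate_sample,
)

from oracles import grid_argmax, loglik_at, random_site


class TestFitFrequencies:
    def test_two_allele_single_quality_closed_form(self):
        counts = np.array([[95.0], [5.0]])
        errors = np.array([0.01])
        f, se, ll, conv, _ = fit_frequencies(counts, errors)
        assert conv
        assert f[1] == pytest.approx((0.05 - 0.01) / 0.98, abs=1e-9)

    def test_symmetric_counts_give_half(self):
        counts = np.array([[50.0], [50.0]])
        f, *_ = fit_frequencies(counts, np.array([0.01]))
        assert f[0] == pytest.approx(0.5, abs=1e-9)
        assert f[1] == pytest.approx(0.5, abs=1e-9)

    def test_below_error_rate_clips_to_zero(self):
        counts = np.array([[998.0], [2.0]])
        f, se, ll, conv, _ = fit_frequencies(counts, np.array([0.01]))
        assert f[1] == 0.0 and conv

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(2, 2001))
            k = int(rng.integers(0, n + 1))
            q = int(rng.integers(5, 41))
            e = 10.0 ** (-q / 10)
            counts = np.array([[float(n - k)], [float(k)]])
            f, *_ = fit_frequencies(counts, np.array([e]))
            expected = min(max((k / n - e) / (1 - 2 * e), 0.0), 1.0)
            assert f[1] == pytest.approx(expected, abs=1e-6)

    def test_grid_search_oracle_agreement(self, rng):
        """Fisher scoring lands on the brute-force grid optimum."""
        for _ in range(30):
            counts, errors = random_site(rng)
            f, se, ll, conv, _ = fit_frequencies(counts, errors)
            f_grid = grid_argmax(counts, errors)
            assert np.all(np.abs(f - f_grid) <= 1e-3)

    def test_optimum_invariants(self, rng):
        for _ in range(30):
            counts, errors = random_site(rng)
            total = counts.sum()
            f_init = counts.sum(axis=1) / total
            f, se, ll, conv, _ = fit_frequencies(counts, errors)
            assert f.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(f >= 0)
            assert ll >= loglik_at(f_init, counts, errors) - 1e-9

    def test_fixed_zero_constraint_respected(self):
        counts = np.array([[80.0], [15.0], [5.0]])
        errors = np.array([0.01])
        f, *_ = fit_frequencies(counts, errors, fixed_zero=[1])
        assert f[1] == 0.0 and f[2] > 0


class TestLrt:
    def _site(self, n_ref, n_alt, q=20):
        sc = SiteCounts(0)
        sc.add("A", "+", q, (n_ref + 1) // 2)
        sc.add("A", "-", q, n_ref // 2)
        sc.add("C", "+", q, (n_alt + 1) // 2)
        sc.add("C", "-", q, n_alt // 2)
        return sc

    def test_lrt_nonnegative_and_monotone_in_minor_count(self):
        th = CallerThresholds()
        qm = QualityModel()
        stats = []
        for k in (4, 8, 16, 32):
            site = self._site(200 - k, k)
            fit = estimate_vaf(site, qm, "A", th)
            ests = lrt_qualities(fit, site, qm, th)
            alt = [e for e in ests if e.allele == "C"][0]
            assert alt.lr_stat >= 0
            stats.append(alt.lr_stat)
        assert stats == sorted(stats)

    def test_phred_scaling(self):
        assert phred_from_lrt(0.0) == 0.0
        assert phred_from_lrt(10.83) == pytest.approx(30.0, abs=0.5)  # chi2 p ~ 1e-3
        assert phred_from_lrt(1e6) == 10000.0


class TestCandidateAlleles:
    def _site(self, fwd, rev, allele="C"):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 50)
        sc.add("A", "-", 30, 50)
        if fwd:
            sc.add(allele, "+", 30, fwd)
        if rev:
            sc.add(allele, "-", 30, rev)
        return sc

    def test_two_on_each_strand_retained(self):
        assert "C" in candidate_alleles(self._site(2, 2), "A")

    def test_one_sided_not_retained(self):
        assert "C" not in candidate_alleles(self._site(5, 0), "A")

    def test_one_each_not_retained(self):
        assert "C" not in candidate_alleles(self._site(1, 1), "A")

    def test_reference_always_baseline(self):
        sc = SiteCounts(0)
        sc.add("C", "+", 30, 10)
        sc.add("C", "-", 30, 10)
        assert candidate_alleles(sc, "A")[0] == "A"


def _two_pop_pile(genome, vaf, pos, alt, depth, seed, q=20):
    cfg = SimConfig(
        genome=genome,
        populations=[
            Population("wt", 1.0 - vaf),
            Population("mut", vaf, snvs={pos: alt}),
        ],
        cut_sites=[CutSite("c", "s", 50)],
        reads_per_sample=depth,
        quality_levels=(q,),
        quality_weights=(1.0,),
        seed=seed,
    )
    return cfg, simulate_sample(cfg)


class TestEndToEndCalling:
    def test_heteroplasmy_recovered_within_3se(self, tmp_path):
        genome = random_genome(1000, np.random.default_rng(1))
        pos = 499
        alt = "A" if genome.sequence[pos] != "A" else "G"
        cfg, res = _two_pop_pile(genome, 0.25, pos, alt, 400, seed=17)
        sams = res.write_sam(tmp_path)
        pile = build_pileup(list(sams.values()), genome.l, cfg.d, QualityModel())
        calls, dels, merged = call_variants(pile, genome)
        hits = [c for c in calls if c.position == pos]
        assert len(hits) == 1
        est = hits[0].estimates[1]
        assert est.allele == alt
        assert abs(est.f_hat - 0.25) <= 3 * est.se
        assert hits[0].filter_field == "PASS"

    def test_no_variant_null_gives_no_pass_calls(self, tmp_path):
        genome = random_genome(1000, np.random.default_rng(2))
        cfg = SimConfig(
            genome=genome,
            populations=[Population("wt", 1.0)],
            cut_sites=[CutSite("c", "s", 50)],
            reads_per_sample=200,
            quality_levels=(20,),
            quality_weights=(1.0,),
            seed=23,
        )
        res = simulate_sample(cfg)
        sams = res.write_sam(tmp_path)
        pile = build_pileup(list(sams.values()), genome.l, cfg.d, QualityModel())
        calls, dels, merged = call_variants(pile, genome)
        passing = [
            c
            for c in calls
            if c.filter_field == "PASS"
            and any(e.f_hat >= 0.005 for e in c.estimates[1:])
        ]
        assert passing == [] and dels == []


class TestLongDeletions:
    def test_no_deletions_empty_result(self, toy_genome, tmp_path):
        cfg = SimConfig(
            genome=toy_genome,
            populations=[Population("wt", 1.0)],
            cut_sites=[CutSite("c", "s", 50)],
            reads_per_sample=50,
            substitution_errors=False,
            seed=2,
        )
        res = simulate_sample(cfg)
        sams = res.write_sam(tmp_path)
        pile = build_pileup(list(sams.values()), toy_genome.l, cfg.d, QualityModel())
        dels, excl, regions = detect_long_deletions(pile, QualityModel())
        assert dels == [] and excl == {} and regions == []

    def test_mixture_disentangled(self, toy_genome, tmp_path):
        # two deletions plus wild type on a 2 kb toy circle
        cfg = SimConfig(
            genome=toy_genome,
            populations=[
                Population("wt", 0.2),
                Population("d1", 0.5, deletions=((500, 300),)),
                Population("d2", 0.3, deletions=((1200, 150),)),
            ],
            cut_sites=[CutSite("c", "s", 50)],
            reads_per_sample=300,
            quality_levels=(20,),
            quality_weights=(1.0,),
            seed=31,
        )
        res = simulate_sample(cfg)
        sams = res.write_sam(tmp_path)
        pile = build_pileup(list(sams.values()), toy_genome.l, cfg.d, QualityModel())
        th = CallerThresholds()
        dels, excl, regions = detect_long_deletions(pile, QualityModel(), th)
        assert len(dels) == 2
        by_start = sorted(dels, key=lambda a: a.start)
        assert abs(by_start[0].start - 500) <= th.merge_tol
        assert abs(by_start[0].length - 300) <= th.merge_tol
        assert abs(by_start[1].start - 1200) <= th.merge_tol
        assert abs(by_start[1].f_hat - 0.3) <= 3 * max(by_start[1].se, 0.01) + 0.05

    def test_all_reads_deleted_gives_frequency_one(self, toy_genome, tmp_path):
        cfg = SimConfig(
            genome=toy_genome,
            populations=[Population("d", 1.0, deletions=((500, 300),))],
            cut_sites=[CutSite("c", "s", 50)],
            reads_per_sample=60,
            substitution_errors=False,
            seed=5,
        )
        res = simulate_sample(cfg)
        sams = res.write_sam(tmp_path)
        pile = build_pileup(list(sams.values()), toy_genome.l, cfg.d, QualityModel())
        dels, excl, regions = detect_long_deletions(pile, QualityModel())
        assert len(dels) == 1
        assert dels[0].f_hat == pytest.approx(1.0, abs=0.02)


class TestMergedHaplotypes:
    def _pile_with_short_del(self, genome, n_ref=14, n_del=6):
        # reads covering [0, 40); n_del of them delete positions 10..11
        pile = Pileup(genome.l)
        seq = genome.sequence[:40]
        for i in range(n_ref):
            pile.add_read(
                f"ref{i}", "+" if i % 2 else "-", 0, [(0, 40)], seq, [30] * 40, d=0
            )
        del_seq = seq[:10] + seq[12:]
        for i in range(n_del):
            pile.add_read(
                f"del{i}",
                "+" if i % 2 else "-",
                0,
                [(0, 10), (2, 2), (0, 28)],
                del_seq,
                [30] * 38,
                d=0,
            )
        return pile

    def test_anchor_plus_deletion_run_merged(self, toy_genome):
        pile = self._pile_with_short_del(toy_genome)
        calls = merge_indel_haplotypes(pile, toy_genome, QualityModel())
        assert len(calls) == 1
        mc = calls[0]
        assert mc.start == 9  # anchor just before the deleted run
        ref_hap = toy_genome.sequence[9:12]
        del_hap = ref_hap[0] + "--"
        assert del_hap in mc.haplotypes
        est = mc.estimates[mc.haplotypes.index(del_hap)]
        assert est.f_hat == pytest.approx(6 / 20, abs=0.05)

    def test_uniform_reads_give_single_allele(self, toy_genome):
        pile = self._pile_with_short_del(toy_genome, n_ref=0, n_del=20)
        calls = merge_indel_haplotypes(pile, toy_genome, QualityModel())
        assert len(calls) == 1
        est = calls[0].estimates[0]
        assert est.f_hat == pytest.approx(1.0, abs=1e-6)


class TestFilters:
    def _call(self, site, f_hat=0.1, qual=60.0):
        ests = [
            FrequencyEstimate("A", 1 - f_hat, 0.01),
            FrequencyEstimate("C", f_hat, 0.01, 50.0, qual),
        ]
        return VariantCall(
            position=0,
            ref="A",
            alts=["C"],
            estimates=ests,
            depth_fwd={},
            depth_rev={},
            baseline="A",
        )

    def test_strand_bias_flagged(self):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 100)
        sc.add("A", "-", 30, 100)
        sc.add("C", "+", 30, 20)  # all minor observations on one strand
        call = filter_call(self._call(sc), sc)
        assert "strand_bias" in call.filters

    def test_balanced_minor_not_flagged(self):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 100)
        sc.add("A", "-", 30, 100)
        sc.add("C", "+", 30, 10)
        sc.add("C", "-", 30, 10)
        call = filter_call(self._call(sc), sc)
        assert call.filter_field == "PASS"

    def test_equal_qualities_no_base_qual_bias(self):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 50)
        sc.add("A", "-", 30, 50)
        sc.add("C", "+", 30, 5)
        sc.add("C", "-", 30, 5)
        call = filter_call(self._call(sc), sc)
        assert "base_qual_bias" not in call.filters

    def test_low_quality_minor_alleles_flagged(self):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 100)
        sc.add("A", "-", 30, 100)
        sc.add("C", "+", 6, 15)
        sc.add("C", "-", 6, 15)
        call = filter_call(self._call(sc), sc)
        assert "base_qual_bias" in call.filters

    def test_low_frequency_flag(self):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 1000)
        sc.add("A", "-", 30, 1000)
        sc.add("C", "+", 30, 3)
        sc.add("C", "-", 30, 3)
        call = filter_call(self._call(sc, f_hat=0.002), sc)
        assert "low_freq" in call.filters

    def test_low_lrt_quality_flag(self):
        sc = SiteCounts(0)
        sc.add("A", "+", 30, 50)
        sc.add("A", "-", 30, 50)
        sc.add("C", "+", 30, 2)
        sc.add("C", "-", 30, 2)
        call = filter_call(self._call(sc, qual=10.0), sc)
        assert "low_qual" in call.filters


class TestVcf:
    def test_header_only_vcf_parses(self, toy_genome, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], [], [], "sampleX", toy_genome, path)
        with pysam.VariantFile(str(path)) as vf:
            assert list(vf) == []
            assert toy_genome.name in vf.header.contigs

    def test_snv_record_round_trip(self, toy_genome, tmp_path):
        pos = 4170  # echoes a pathogenic site, 1-based 4171
        genome = random_genome(16569, np.random.default_rng(0))
        ref = genome.sequence[pos]
        alt = "A" if ref != "A" else "C"
        call = VariantCall(
            position=pos,
            ref=ref,
            alts=[alt],
            estimates=[
                FrequencyEstimate(ref, 0.75, 0.01),
                FrequencyEstimate(alt, 0.25, 0.01, 500.0, 1000.0),
            ],
            depth_fwd={ref: 300, alt: 100},
            depth_rev={ref: 300, alt: 100},
            baseline=ref,
        )
        path = tmp_path / "one.vcf"
        write_vcf([call], [], [], "s", genome, path)
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.pos == 4171 and rec.ref == ref and rec.alts == (alt,)
        assert rec.info["AF"][0] == pytest.approx(0.25)
        assert rec.filter.keys() == ["PASS"]
        assert rec.samples["s"]["HF"][0] == pytest.approx(0.25, abs=1e-6)

    def test_deletion_record_has_end(self, tmp_path):
        genome = random_genome(16569, np.random.default_rng(0))
        da = DeletionAllele(start=3263, length=16070 - 3264 + 1, n_reads=80, f_hat=0.076, se=0.01)
        assert da.name() == "m.3264_16070del"
        path = tmp_path / "del.vcf"
        write_vcf([], [da], [], "s", genome, path)
        with pysam.VariantFile(str(path)) as vf:
            rec = next(iter(vf))
        assert rec.pos == 3263  # anchor base before the deleted run
        assert rec.stop == 16070  # pysam exposes INFO END as .stop
        assert rec.info["SVLEN"] == -(16070 - 3264 + 1)
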