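"""Generator behaviour: determinism, planted structure, recoverable signal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from merip_enrich import io as mio
from merip_enrich.expression import differential_expression
from merip_enrich.kinetics import fit_course
from merip_enrich.simulate import (
    SimulationConfig,
    demethylated_sites,
    find_planted_sites,
    gene_base_expression,
    methylome_site_levels,
    simulate_dataset,
    simulate_decay_course,
    simulate_expression_matrix,
    simulate_libraries,
    simulate_methylome,
    simulate_transcriptome,
    write_simulation,
)

SMALL = dict(n_genes=30, depth_per_library=20_000, n_de_genes=5)


def test_zero_genes_gives_empty_transcriptome():
    assert simulate_transcriptome(SimulationConfig(seed=0, n_genes=0, n_de_genes=0)) == {}


def test_negative_gene_count_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, n_genes=-1, n_de_genes=0).validate()


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=5, n_genes=10, depth_per_library=5000, n_de_genes=3)
    for d in ("a", "b"):
        write_simulation(simulate_dataset(cfg), tmp_path / d)
    for rel in ("transcripts.fa", "models.gtf", "methylome.tsv",
                "reads/parental_IP_rep1.bed", "expression.tsv", "decay_ct.tsv"):
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_noncoding_count_within_binomial_interval():
    models = simulate_transcriptome(
        SimulationConfig(seed=3, n_genes=200, noncoding_fraction=0.1)
    )
    n_nc = sum(not m.coding for m in models.values())
    lo, hi = stats.binom.ppf([0.025, 0.975], 200, 0.1)
    assert lo <= n_nc <= hi


def test_planted_sites_sit_on_drach_motifs(study):
    sites = find_planted_sites(study.models)
    assert len(sites) > 0
    for row in sites.itertuples(index=False):
        seq = study.models[row.transcript_id].sequence
        assert seq[row.site_position : row.site_position + 5] == "GGACU"


class TestMethylome:
    def test_zero_rate_means_no_methylation_anywhere(self):
        cfg = SimulationConfig(seed=1, methylation_rate=0.0, **SMALL)
        meth = simulate_methylome(simulate_transcriptome(cfg), cfg)
        assert (meth["methylation_level"] == 0).all()

    def test_full_rate_no_demethylation_keeps_conditions_identical(self):
        cfg = SimulationConfig(
            seed=1, methylation_rate=1.0, demethylation_fraction=0.0, **SMALL
        )
        meth = simulate_methylome(simulate_transcriptome(cfg), cfg)
        piv = meth.pivot_table(
            index=["transcript_id", "site_position"],
            columns="condition",
            values="methylation_level",
        )
        assert (piv["parental"] == piv["resistant"]).all()
        assert (piv["parental"] == piv["resensitized"]).all()
        assert (piv["parental"] == 1.0).all()

    def test_demethylated_count_within_binomial_bounds(self):
        cfg = SimulationConfig(
            seed=2, n_genes=200, methylation_rate=1.0, demethylation_fraction=0.3
        )
        meth = simulate_methylome(simulate_transcriptome(cfg), cfg)
        n_meth = int(
            (meth[meth["condition"] == "parental"]["methylation_level"] > 0).sum()
        )
        n_lost = len(demethylated_sites(meth))
        lo, hi = stats.binom.ppf([0.001, 0.999], n_meth, 0.3)
        assert lo <= n_lost <= hi

    def test_model_without_sequence_rejected(self, coding_model):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError):
            simulate_methylome({"txA": coding_model}, cfg)


class TestLibraries:
    def test_zero_depth_gives_empty_libraries(self):
        cfg = SimulationConfig(seed=1, n_genes=10, depth_per_library=0, n_de_genes=3)
        models = simulate_transcriptome(cfg)
        libs = simulate_libraries(models, simulate_methylome(models, cfg), cfg)
        assert len(libs) == 12  # 3 conditions x 2 replicates x 2 assays
        assert all(l.n_reads == 0 for l in libs)

    def test_input_counts_track_expression(self, study):
        lib = next(
            l for l in study.libraries
            if l.assay == "input" and l.condition == "parental" and l.replicate == 1
        )
        expr = gene_base_expression(study.config)
        counts = pd.Series({tid: len(iv) for tid, iv in lib.reads.items()})
        counts = counts.reindex(expr.index, fill_value=0)
        r = np.corrcoef(counts, expr)[0, 1]
        assert r > 0.9

    def test_ip_over_input_ratio_near_enrichment_at_methylated_sites(self, study):
        """Mean read-count ratio at fully methylated sites ~ E / <w>, within 20%."""
        cfg = study.config
        ip = next(l for l in study.libraries
                  if l.assay == "IP" and l.condition == "parental" and l.replicate == 1)
        inp = next(l for l in study.libraries
                   if l.assay == "input" and l.condition == "parental" and l.replicate == 1)
        site_map = methylome_site_levels(study.methylome, "parental")
        expr = gene_base_expression(cfg)
        # library-wide normalizing constant: expression-weighted mean IP weight
        mean_w = {}
        for tid, m in study.models.items():
            s_max = m.length - cfg.fragment_length
            enriched = sum(
                min(pos + 2, s_max) - max(0, pos + 2 - cfg.fragment_length + 1) + 1
                for pos, lev in site_map.get(tid, [])
                if lev > 0
            )
            mean_w[tid] = 1.0 + (cfg.ip_enrichment - 1.0) * enriched / (s_max + 1)
        norm = sum(expr[t] * mean_w[t] for t in expr.index) / expr.sum()

        def count(lib, tid, lo, hi):
            iv = lib.reads.get(tid)
            if iv is None:
                return 0
            return int(np.count_nonzero((iv[:, 0] < hi) & (iv[:, 1] > lo)))

        ratios = []
        for tid, sites in site_map.items():
            for pos, lev in sites:
                if lev < 1.0:
                    continue
                a = count(ip, tid, pos, pos + 5)
                b = count(inp, tid, pos, pos + 5)
                if b >= 30:  # enough input reads for a stable per-site ratio
                    ratios.append(a / b)
        expected = cfg.ip_enrichment / norm
        assert len(ratios) > 20
        assert abs(np.mean(ratios) - expected) / expected < 0.2

    def test_resistant_ratio_drops_at_demethylated_sites(self, study):
        """Sign test: IP/input ratio falls from parental to resistant at lost sites."""
        lost = demethylated_sites(study.methylome)

        def site_ratio(cond, tid, pos):
            num = den = 0.0
            for lib in study.libraries:
                if lib.condition != cond or lib.replicate != 1:
                    continue
                iv = lib.reads.get(tid)
                c = (
                    0 if iv is None
                    else int(np.count_nonzero((iv[:, 0] < pos + 5) & (iv[:, 1] > pos)))
                )
                if lib.assay == "IP":
                    num = c
                else:
                    den = c
            return (num + 0.5) / (den + 0.5)

        drops = [
            site_ratio("parental", r.transcript_id, r.site_position)
            > site_ratio("resistant", r.transcript_id, r.site_position)
            for r in lost.itertuples(index=False)
        ]
        assert len(drops) >= 20
        p = stats.binomtest(sum(drops), len(drops), 0.5, alternative="greater").pvalue
        assert p < 1e-6

    def test_depth_scaling_preserves_cpm_profile(self):
        base = dict(seed=9, n_genes=20, dispersion=0.0, n_de_genes=5)
        cfg1 = SimulationConfig(depth_per_library=20_000, **base)
        cfg2 = SimulationConfig(depth_per_library=40_000, **base)
        models = simulate_transcriptome(cfg1)
        meth = simulate_methylome(models, cfg1)
        lib1 = simulate_libraries(models, meth, cfg1)[0]
        lib2 = simulate_libraries(models, meth, cfg2)[0]
        assert lib2.total_mapped == 2 * lib1.total_mapped
        cpm1 = pd.Series({t: len(v) for t, v in lib1.reads.items()}) / lib1.total_mapped
        cpm2 = pd.Series({t: len(v) for t, v in lib2.reads.items()}) / lib2.total_mapped
        cpm1, cpm2 = cpm1.align(cpm2, fill_value=0.0)
        assert np.corrcoef(cpm1, cpm2)[0, 1] > 0.99


class TestExpressionMatrix:
    def test_no_de_no_noise_gives_identical_group_means(self):
        cfg = SimulationConfig(seed=1, expression_noise_sd=0.0, **{**SMALL, 'n_de_genes': 0})
        models = simulate_transcriptome(cfg)
        expr, groups, truth = simulate_expression_matrix(
            models, simulate_methylome(models, cfg), cfg
        )
        par = [s for s, g in groups.items() if g == "parental"]
        res = [s for s, g in groups.items() if g == "resistant"]
        assert np.allclose(expr[par].mean(axis=1), expr[res].mean(axis=1))
        assert not truth["planted_up"].any()

    def test_noiseless_planted_genes_shift_exactly_one_log2(self):
        cfg = SimulationConfig(seed=1, de_fold=2.0, expression_noise_sd=0.0, **SMALL)
        models = simulate_transcriptome(cfg)
        expr, groups, truth = simulate_expression_matrix(
            models, simulate_methylome(models, cfg), cfg
        )
        par = [s for s, g in groups.items() if g == "parental"]
        res = [s for s, g in groups.items() if g == "resistant"]
        diff = expr[res].mean(axis=1) - expr[par].mean(axis=1)
        planted = truth.set_index("gene_id")["planted_up"]
        assert np.allclose(diff[planted.to_numpy()], 1.0)
        assert np.allclose(diff[~planted.to_numpy()], 0.0)

    def test_planted_genes_recovered_by_de_test(self):
        cfg = SimulationConfig(
            seed=4, n_genes=100, de_fold=2.0, expression_noise_sd=0.2, n_de_genes=20
        )
        models = simulate_transcriptome(cfg)
        expr, groups, truth = simulate_expression_matrix(
            models, simulate_methylome(models, cfg), cfg
        )
        de = differential_expression(expr, groups, "parental", "resistant")
        up = set(de.loc[de["call"] == "up", "gene_id"])
        planted = set(truth.loc[truth["planted_up"], "gene_id"])
        assert len(up & planted) / len(planted) >= 0.95

    def test_invalid_de_fold_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, de_fold=0.0).validate()


class TestDecaySimulation:
    def test_infinite_half_life_gives_constant_ct(self):
        (course,) = simulate_decay_course(
            ["stable"], [np.inf], [0, 3, 6], SimulationConfig(seed=0)
        )
        assert np.allclose(course.ct_target, course.ct_target[0])

    def test_one_half_life_raises_ct_by_one_cycle(self):
        (course,) = simulate_decay_course(
            ["g"], [3.0], [0, 3], SimulationConfig(seed=0)
        )
        assert course.ct_target[1] - course.ct_target[0] == pytest.approx(1.0)

    def test_noisy_course_recovered_within_ten_percent(self):
        cfg = SimulationConfig(seed=8, ct_noise_sd=0.1)
        (course,) = simulate_decay_course(["g"], [4.0], [0, 2, 4, 6, 8], cfg)
        est = fit_course(course)
        assert abs(est.t_half - 4.0) / 4.0 < 0.1

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            simulate_decay_course(["g"], [-1.0], [0, 3], SimulationConfig(seed=0))
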