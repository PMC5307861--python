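"""Synthetic-data generator: determinism, planted structure, guarantees."""

import numpy as np
import pandas as pd
import pytest

from lncpop import (SimulationConfig, simulate_expression, simulate_sequences,
                    simulate_trait, classify_candidates, TranscriptRecord,
                    population_stats, longest_orf)
from lncpop.errors import ConfigurationError
from lncpop.networks import spearman_rho
from scipy import stats as sps


def test_same_seed_is_bit_identical(small_config):
    m1, t1 = simulate_expression(small_config)
    m2, t2 = simulate_expression(small_config)
    assert m1.values.equals(m2.values)
    assert t1.de_features == t2.de_features
    assert t1.trait_genes == t2.trait_genes


def test_degenerate_no_noise_config_is_constant_within_environment():
    cfg = SimulationConfig(
        n_lncRNA=5, n_mRNA=5, n_individuals_per_env=6,
        feature_log_mean_sd=0.0, baseline_log_sd_mRNA=0.0,
        baseline_log_sd_lncRNA=0.0, dropout_prob_mRNA=0.0,
        dropout_prob_lncRNA=0.0, frac_DE=0.0, frac_diversity_inflated=0.0,
        n_modules_shared=0, n_modules_env_specific=0, n_trait_genes=0,
        seed=1)
    m, _ = simulate_expression(cfg)
    for env in m.env_names:
        sub = m.env_values(env).to_numpy()
        assert np.allclose(sub, sub[:, :1])


def test_invalid_config_names_offending_field():
    with pytest.raises(ConfigurationError, match="frac_DE"):
        SimulationConfig(frac_DE=1.5).validate()
    with pytest.raises(ConfigurationError, match="n_trait_genes"):
        SimulationConfig(n_mRNA=3, n_trait_genes=10, n_lncRNA=5,
                         n_modules_shared=0, n_modules_env_specific=0
                         ).validate()


def test_planted_log2_ratio_matches_closed_form_without_censoring():
    # with no dropout, E[log2 E_p ratio] of a planted feature equals the
    # signed de_log2fc (lognormal mean factors cancel between envs)
    cfg = SimulationConfig(
        n_lncRNA=400, n_mRNA=600, de_log2fc=1.0, frac_DE=0.1,
        dropout_prob_mRNA=0.0, dropout_prob_lncRNA=0.0,
        frac_diversity_inflated=0.0, seed=5)
    m, truth = simulate_expression(cfg)
    env1, env2 = m.env_names
    ep1 = m.env_values(env1).mean(axis=1)
    ep2 = m.env_values(env2).mean(axis=1)
    signs = pd.Series(truth.de_features)
    signed = np.log2(ep2[signs.index] / ep1[signs.index]) * signs
    assert abs(signed.mean() - 1.0) < 0.15


def test_class_contrasts_hold_at_default_config():
    m, _ = simulate_expression(SimulationConfig(seed=3))
    stats = population_stats(m)
    med = stats.groupby(["class", "env"])[["e_d", "freq"]].median()
    for env in m.env_names:
        assert med.loc[("lncRNA", env), "e_d"] > med.loc[("mRNA", env), "e_d"]
        assert med.loc[("lncRNA", env), "freq"] < med.loc[("mRNA", env), "freq"]


def test_module_members_correlate_within_scope(small_dataset):
    matrix, truth = small_dataset
    by_mod = {}
    for fid, (mod, scope) in truth.module_assignments.items():
        by_mod.setdefault((mod, scope), []).append(fid)
    rng = np.random.default_rng(0)
    for (mod, scope), members in by_mod.items():
        envs = list(matrix.env_names) if scope == "shared" else [scope]
        for env in envs:
            sub = matrix.env_values(env)
            within = [abs(spearman_rho(sub.loc[a], sub.loc[b]))
                      for i, a in enumerate(members)
                      for b in members[i + 1:]]
            others = [f for f in matrix.feature_ids
                      if f not in truth.module_assignments]
            pick = rng.choice(others, size=len(members), replace=False)
            between = [abs(spearman_rho(sub.loc[a], sub.loc[b]))
                       for a, b in zip(members, pick)]
            assert np.median(within) > np.median(between)


def test_coding_sequences_carry_long_orfs():
    seqs = simulate_sequences(n_noncoding=0, n_coding=5,
                              length_range=(600, 600), seed=1)
    assert len(seqs) == 5
    for _, s in seqs:
        assert len(s) == 600
        assert longest_orf(s) >= 150


def test_noncoding_sequences_all_pass_the_coding_rule():
    seqs = simulate_sequences(n_noncoding=50, n_coding=0,
                              length_range=(201, 600), seed=2)
    records = [TranscriptRecord.from_sequence(n, s) for n, s in seqs]
    out = classify_candidates(records)
    assert (out["decision"] == "candidate_lncRNA").all()


def test_sequence_gc_matches_target():
    seqs = simulate_sequences(n_noncoding=1, n_coding=0,
                              length_range=(10000, 10000),
                              gc_noncoding=0.46, seed=3)
    _, s = seqs[0]
    gc = (s.count("G") + s.count("C")) / len(s)
    assert abs(gc - 0.46) < 0.02


def test_sequence_generator_rejects_infeasible_orf():
    with pytest.raises(ConfigurationError):
        simulate_sequences(n_noncoding=0, n_coding=1, length_range=(100, 120),
                           seed=0)


def test_sequences_deterministic_under_seed():
    a = simulate_sequences(5, 5, seed=11)
    b = simulate_sequences(5, 5, seed=11)
    assert a == b


def test_trait_noise_free_single_gene_equals_log_expression(small_dataset):
    matrix, truth = small_dataset
    gene = next(iter(truth.trait_genes))
    cfg = SimulationConfig(trait_noise_sd=0.0, seed=0)
    solo = type(truth)(trait_genes={gene: 1.0})
    trait = simulate_trait(matrix, solo, cfg)
    expected = np.log(matrix.values.loc[gene].to_numpy() + 0.01)
    assert np.allclose(trait.to_numpy(), expected)


def test_trait_deterministic_and_correlated_with_its_gene(small_dataset):
    matrix, truth = small_dataset
    gene = next(iter(truth.trait_genes))
    cfg = SimulationConfig(trait_noise_sd=0.1, seed=9)
    solo = type(truth)(trait_genes={gene: 1.0})
    t1 = simulate_trait(matrix, solo, cfg)
    t2 = simulate_trait(matrix, solo, cfg)
    assert t1.equals(t2)
    rho = sps.spearmanr(t1.to_numpy(),
                        matrix.values.loc[gene].to_numpy()).statistic
    assert rho >= 0.9


def test_trait_requires_trait_genes(small_dataset):
    matrix, truth = small_dataset
    empty = type(truth)()
    with pytest.raises(ConfigurationError):
        simulate_trait(matrix, empty, SimulationConfig())
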