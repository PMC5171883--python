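import numpy as np
import pytest

from linedrift.behavior import score_gonogo_session
from linedrift.errors import ConfigError
from linedrift.pedigree import inbreeding_coefficients
from linedrift.summaries import read_trait_table, write_trait_table
from linedrift.synthetic import (
    BehaviorParams,
    SimConfig,
    generate_trait_table,
    simulate_breeding,
    simulate_gonogo_session,
)

SMALL = dict(n_families=6, offspring_per_family=4, generations=3)


def test_seed_determinism_of_breeding_and_sessions():
    a = simulate_breeding(SimConfig(seed=5, **SMALL))
    b = simulate_breeding(SimConfig(seed=5, **SMALL))
    assert np.array_equal(a.line_means, b.line_means)
    assert np.array_equal(a.realized_F, b.realized_F)
    assert a.pedigree.frame.equals(b.pedigree.frame)
    log1 = simulate_gonogo_session(BehaviorParams(seed=8))
    log2 = simulate_gonogo_session(BehaviorParams(seed=8))
    assert log1.events == log2.events


def test_non_psd_correlation_matrix_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ConfigError):
        simulate_breeding(SimConfig(genetic_correlations=bad, **SMALL))


def test_simulator_inbreeding_matches_pedigree_module():
    """The simulator's internal kinship recursion must agree exactly with
    Meuwissen-Luo F computed from the recorded pedigree."""
    sim = simulate_breeding(SimConfig(seed=2, **SMALL))
    coeffs = inbreeding_coefficients(sim.pedigree)
    frame = sim.pedigree.frame
    for gen in range(SMALL["generations"] + 1):
        for li, line in enumerate(("selected", "control")):
            mask = (frame["generation"] == gen) & (frame["line"] == line)
            ped_mean = np.mean([coeffs[i] for i in frame.loc[mask, "id"]])
            assert sim.realized_F[gen, li] == pytest.approx(ped_mean, abs=1e-12)


def test_no_response_without_additive_variance():
    """h2 = 0 on the selected trait: selection cannot produce a response."""
    responses = []
    for seed in range(200):
        cfg = SimConfig(
            n_families=5, offspring_per_family=4, generations=2,
            h2=(0.0, 0.33), seed=seed,
        )
        sim = simulate_breeding(cfg, record_pedigree=False)
        responses.append(sim.line_means[-1, 0, 0] - sim.line_means[0, 0, 0])
    mean = np.mean(responses)
    se = np.std(responses, ddof=1) / np.sqrt(len(responses))
    assert abs(mean) < 3 * se


def test_random_breeding_shows_no_systematic_response():
    responses = []
    for seed in range(150):
        cfg = SimConfig(
            n_families=5, offspring_per_family=4, generations=3,
            selection_mode="random", seed=seed,
        )
        sim = simulate_breeding(cfg, record_pedigree=False)
        responses.append(sim.line_means[-1, 0, 0] - sim.line_means[0, 0, 0])
    mean = np.mean(responses)
    se = np.std(responses, ddof=1) / np.sqrt(len(responses))
    assert abs(mean) < 3 * se


def test_within_family_selection_slows_inbreeding_vs_mass():
    """Paired seeds: within-family selection accumulates less F than mass
    selection at the same census size."""
    wf, mass = [], []
    for seed in range(100):
        for mode, acc in (("within_family", wf), ("mass", mass)):
            cfg = SimConfig(
                n_families=6, offspring_per_family=6, generations=6,
                selection_mode=mode, seed=seed,
            )
            sim = simulate_breeding(cfg, record_pedigree=False)
            acc.append(sim.realized_F[-1, 0])
    assert np.mean(wf) < np.mean(mass)


def test_random_within_family_breeding_inbreeding_rate():
    """Equal family contributions double Ne: dF/generation ~ 1/(8n)."""
    n_fam = 8
    rates = []
    for seed in range(40):
        cfg = SimConfig(
            n_families=n_fam, offspring_per_family=4, generations=10,
            selection_mode="random", seed=seed,
        )
        sim = simulate_breeding(cfg, record_pedigree=False)
        # slope over the linear accumulation phase (skip founder burn-in)
        rates.append((sim.realized_F[-1, 0] - sim.realized_F[2, 0]) / 8)
    expected = 1.0 / (8 * n_fam)
    assert np.mean(rates) == pytest.approx(expected, rel=0.3)


def test_one_generation_mass_selection_follows_breeders_equation():
    """Mean response ~ h2 * S over replicates (breeder's equation)."""
    h2 = 0.33
    responses, diffs = [], []
    for seed in range(300):
        cfg = SimConfig(
            n_families=8, offspring_per_family=6, generations=1,
            h2=(h2, h2), selection_mode="mass", seed=seed,
        )
        sim = simulate_breeding(cfg, record_pedigree=False)
        responses.append(sim.line_means[1, 0, 0] - sim.line_means[0, 0, 0])
        diffs.append(sim.selection_differentials[0, 0])
    mean_resp = np.mean(responses)
    expected = h2 * np.mean(diffs)
    se = np.std(responses, ddof=1) / np.sqrt(len(responses))
    assert mean_resp == pytest.approx(expected, abs=3 * se)


def test_simulated_sessions_recover_generating_probabilities():
    p_hit, p_fa = 0.8, 0.4
    hits, fas = [], []
    for seed in range(100):
        params = BehaviorParams(p_hit=p_hit, p_fa=p_fa,
                                background_poke_rate=0.0, seed=seed)
        s = score_gonogo_session(simulate_gonogo_session(params))
        hits.append(s.hits / s.n_go)
        fas.append(s.false_alarms / s.n_nogo)
    for est, p in ((np.mean(hits), p_hit), (np.mean(fas), p_fa)):
        se = np.sqrt(p * (1 - p) / (30 * 100))
        assert est == pytest.approx(p, abs=3 * se)


def test_trait_table_generation_matches_phenotypes_and_round_trips(tmp_path):
    cfg = SimConfig(seed=4, h2=(0.33, 0.4), trait_names=("activity", "hits"),
                    **SMALL)
    sim = simulate_breeding(cfg)
    records = generate_trait_table(sim)
    assert [r.trait_name for r in records] == ["activity", "hits"]
    for k, rec in enumerate(records):
        vals = sim.final_cohort["selected"]["phenotypes"][:, k]
        assert rec.high_active.mean == pytest.approx(vals.mean())
        assert rec.high_active.sem == pytest.approx(
            vals.std(ddof=1) / np.sqrt(len(vals))
        )
        assert rec.h2 == cfg.h2[k]
        assert rec.n_families == cfg.n_families
    path = tmp_path / "traits.csv"
    write_trait_table(records, path)
    assert read_trait_table(path) == records


def test_perfect_session_parameters_score_cleanly():
    params = BehaviorParams(p_hit=1.0, p_fa=0.0, background_poke_rate=0.0,
                            seed=3)
    s = score_gonogo_session(simulate_gonogo_session(params))
    assert s.hits == 30 and s.false_alarms == 0
    assert s.precue_responses == 0
    assert s.reinforcers == 60
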