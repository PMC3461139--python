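"""Wright-Fisher supplementation simulator: drift law, determinism, presets."""

import numpy as np
import pytest

from tempomon.popdata import BroodstockRecord, write_genepop
from tempomon.simulate import SimConfig, scenario_presets, simulate


def test_determinism_byte_identical_genepop(tmp_path):
    outs = []
    for run in range(2):
        cfg = scenario_presets("isolated_wf", seed=42)
        samples, _ = simulate(cfg)
        path = tmp_path / f"run{run}.gen"
        write_genepop([s.genotypes for s in samples], path)
        outs.append(path.read_bytes())
    assert outs[0] == outs[1]


def test_ideal_population_realized_ne_near_census():
    """phi=0 with Poisson-like reproduction gives Ne ~ Nc."""
    vals = []
    for seed in range(15):
        cfg = SimConfig(n_generations=1, Nc=400, true_Ne=None, L=1, seed=seed)
        _, truth = simulate(cfg)
        vals.append(truth.generations[0].realized_Ne)
    assert np.mean(vals) == pytest.approx(400, rel=0.15)


def test_drift_law_matches_target_ne():
    """Standardized frequency change over t gens follows 1-(1-1/(2Ne))^t."""
    t_gens, ne = 2, 100.0
    F = []
    for seed in range(150):
        cfg = SimConfig(n_generations=t_gens, Nc=1000, true_Ne=ne, L=3,
                        k_alleles=2, init_alpha=5.0, seed=seed)
        _, truth = simulate(cfg)
        f0 = truth.generations[0].allele_freqs
        ft = truth.generations[t_gens].allele_freqs
        for a, b in zip(f0, ft):
            if len(a) < 2 or len(b) < 2:
                continue
            z = (a[0] + b[0]) / 2
            if 0.1 < z < 0.9:
                F.append((a[0] - b[0]) ** 2 / (z * (1 - z)))
    expected = 1 - (1 - 1 / (2 * ne)) ** t_gens
    assert np.mean(F) == pytest.approx(expected, rel=0.15)


def test_heterozygosity_decay_law():
    """E[H_t] = H_0 (1 - 1/(2Ne))^t within Monte Carlo error."""
    ne, t_gens = 50.0, 6
    ratios = []
    for seed in range(60):
        cfg = SimConfig(n_generations=t_gens, Nc=500, true_Ne=ne, L=2,
                        k_alleles=4, init_alpha=5.0, seed=seed + 1)
        _, truth = simulate(cfg)

        def het(freqs):
            return np.mean([1 - np.sum(f**2) for f in freqs])

        h0 = het(truth.generations[0].allele_freqs)
        ht = het(truth.generations[t_gens].allele_freqs)
        ratios.append(ht / h0)
    expected = (1 - 1 / (2 * ne)) ** t_gens
    assert np.mean(ratios) == pytest.approx(expected, abs=0.02)


def test_offspring_frequencies_unbiased():
    """Mean offspring frequency equals the parental frequency (conservation)."""
    diffs = []
    for seed in range(100):
        cfg = SimConfig(n_generations=1, Nc=500, true_Ne=100.0, L=1,
                        k_alleles=2, init_alpha=5.0, seed=seed)
        _, truth = simulate(cfg)
        f0 = truth.generations[0].allele_freqs[0]
        f1 = truth.generations[1].allele_freqs[0]
        if len(f0) == len(f1):
            diffs.append(f1[0] - f0[0])
    assert abs(np.mean(diffs)) < 0.01


def test_ryman_laikre_direction():
    """A small-broodstock captive source lowers realized Ne vs phi=0."""
    def mean_ne(phi):
        vals = []
        for seed in range(12):
            lots = [BroodstockRecord("lot0", Nm=3, Nf=3, mating_design="paired")]
            cfg = SimConfig(
                n_generations=1, Nc=1000, true_Ne=None, L=1,
                supplementation={1: phi} if phi else {},
                broodstock=lots if phi else [], seed=seed,
            )
            _, truth = simulate(cfg)
            vals.append(truth.generations[0].realized_Ne)
        return np.mean(vals)

    assert mean_ne(0.5) < 0.6 * mean_ne(0.0)


def test_unsatisfiable_config_rejected():
    with pytest.raises(ValueError, match="exceeds Nc"):
        SimConfig(n_generations=1, Nc=100, true_Ne=200.0).validate()
    with pytest.raises(ValueError, match="sample size"):
        SimConfig(n_generations=1, Nc=100, sampling={0: 200}).validate()
    with pytest.raises(ValueError, match="unattainably small"):
        cfg = SimConfig(n_generations=1, Nc=10000, true_Ne=2.0, L=1)
        simulate(cfg)


def test_supplementation_requires_broodstock():
    cfg = SimConfig(n_generations=1, Nc=100, supplementation={1: 0.5})
    with pytest.raises(ValueError, match="broodstock"):
        simulate(cfg)


def test_preset_roundtrip_serialization():
    import yaml

    cfg = scenario_presets("supplemented_sink", seed=7)
    text = yaml.safe_dump(cfg.to_dict())
    back = SimConfig.from_dict(yaml.safe_load(text))
    assert back == cfg


def test_preset_isolated_wf_has_no_supplementation():
    cfg = scenario_presets("isolated_wf")
    assert all(cfg.phi(g) == 0 for g in range(cfg.n_generations + 1))


def test_unknown_preset_lists_options():
    with pytest.raises(ValueError, match="isolated_wf"):
        scenario_presets("nope")
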