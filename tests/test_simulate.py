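import numpy as np
import pandas as pd
import pytest

from sigcontext.catalog import build_catalog, group_by_sample
from sigcontext.intervals import ContextAnnotation
from sigcontext.refit import refit_exposures
from sigcontext.simulate import (
    PYR_TRINUCS,
    SimulationConfig,
    planted_hmm,
    simulate_cohort,
    simulate_expression_and_sv,
    simulate_genome,
    simulate_repliseq,
    simulate_tracks,
    synthetic_signatures,
)


def small_config(**kw):
    defaults = dict(seed=17, n_chroms=2, chrom_length=100_000)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_same_seed_identical_sequence(self, tmp_path):
        a = simulate_genome(small_config(), fasta_path=tmp_path / "a.fa")
        simulate_genome(small_config(), fasta_path=tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert a.total_length() == 200_000

    def test_requested_length_respected(self):
        g = simulate_genome(small_config(chrom_length=12_345))
        assert all(g.length(c) == 12_345 for c in g.chrom_names)

    def test_all_pyrimidine_trinucleotides_present(self):
        g = simulate_genome(small_config(seed=23))
        # exhaustive 3-mer scan of the emitted sequence
        seen = set()
        for chrom in g.chrom_names:
            seq = g.fetch(chrom, 0, g.length(chrom))
            for i in range(len(seq) - 2):
                tri = seq[i : i + 3]
                seen.add(tri)
        from sigcontext.catalog import revcomp

        pyr_seen = {t if t[1] in "CT" else revcomp(t) for t in seen if "N" not in t}
        assert set(PYR_TRINUCS) <= pyr_seen

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            small_config(chrom_length=5000)


class TestTracks:
    def test_same_seed_identical(self):
        a, pa, _ = simulate_tracks(small_config())
        b, pb, _ = simulate_tracks(small_config())
        for c in a:
            assert np.array_equal(a[c], b[c]) and np.array_equal(pa[c], pb[c])

    def test_deterministic_emissions_expose_path(self):
        cfg = small_config(emission_contrast=1.0, n_states=3, n_features=3)
        obs, paths, model = simulate_tracks(cfg)
        for c in obs:
            # with 0/1-deterministic emissions the active feature identifies the state
            decoded = obs[c].argmax(axis=1)
            active = model.emission.argmax(axis=1)
            assert np.array_equal(active[paths[c] - 1], decoded)

    def test_empirical_transitions_match_planted(self):
        cfg = SimulationConfig(seed=19, n_chroms=1, chrom_length=50_000_0 * 1000,
                               bin_size=10_000, n_states=3)
        obs, paths, model = simulate_tracks(cfg)  # 50k bins
        p = paths["chr1"] - 1
        emp = np.zeros((3, 3))
        np.add.at(emp, (p[:-1], p[1:]), 1.0)
        emp /= emp.sum(axis=1, keepdims=True)
        assert np.abs(emp - model.transition).max() < 0.05


class TestRepliseq:
    def test_single_centered_origin_splits_halves(self):
        cfg = SimulationConfig(seed=2, n_chroms=1, chrom_length=1_000_000,
                               origins_per_chrom=1, origin_sigma=100_000.0)
        pos, val, truth = simulate_repliseq(cfg)
        t = truth["chr1"]
        o = t["origins"][0]
        left = pos["chr1"] < o - 1
        right = pos["chr1"] > o + 1
        assert (t["direction"][left] == "left").all()
        assert (t["direction"][right] == "right").all()

    def test_noise_does_not_change_truth(self):
        base = dict(seed=3, n_chroms=1, chrom_length=1_000_000)
        _, _, clean = simulate_repliseq(SimulationConfig(**base, repliseq_noise=0.0))
        _, _, noisy = simulate_repliseq(SimulationConfig(**base, repliseq_noise=0.5))
        for key in ("timing", "direction", "speed"):
            assert np.array_equal(clean["chr1"][key], noisy["chr1"][key])

    def test_same_seed_identical_signal(self):
        a = simulate_repliseq(SimulationConfig(seed=4, n_chroms=1, chrom_length=500_000))
        b = simulate_repliseq(SimulationConfig(seed=4, n_chroms=1, chrom_length=500_000))
        assert np.array_equal(a[1]["chr1"], b[1]["chr1"])


@pytest.fixture(scope="module")
def world():
    cfg = SimulationConfig(
        seed=29, n_chroms=2, chrom_length=150_000,
        n_samples=4, mutations_per_sample=600,
        mixture_map={
            "late": {"SYN1": 0.4, "SYN2": 0.6},
            "early": {"SYN1": 0.1, "SYN2": 0.9},
        },
    )
    genome = simulate_genome(cfg)
    sigs = synthetic_signatures(4, seed=5)
    late = ContextAnnotation.from_tuples(
        "late", [(c, 0, 75_000) for c in genome.chrom_names], genome
    )
    early = late.complement(genome, "early")
    muts, truth = simulate_cohort(cfg, genome, [late, early], sigs)
    return cfg, genome, sigs, (late, early), muts, truth


class TestCohort:
    def test_single_signature_mixture_recovered(self):
        cfg = SimulationConfig(
            seed=31, n_chroms=1, chrom_length=150_000,
            n_samples=2, mutations_per_sample=800,
            mixture_map={"all": {"SYN1": 1.0}},
        )
        genome = simulate_genome(cfg)
        sigs = synthetic_signatures(4, seed=5)
        whole = ContextAnnotation.from_tuples("all", [("chr1", 0, 150_000)], genome)
        muts, _ = simulate_cohort(cfg, genome, [whole], sigs)
        cat = build_catalog(group_by_sample(muts)["S001"], genome)
        exp = refit_exposures(cat, sigs)
        assert exp.weight("SYN1") > 0.95

    def test_mutations_fall_inside_their_context(self, world):
        cfg, genome, sigs, (late, early), muts, truth = world
        from sigcontext.intervals import assign_points

        pts = [(m.chrom, m.pos) for m in muts]
        in_late = assign_points(pts, late)
        in_early = assign_points(pts, early)
        assert (in_late | in_early).all()

    def test_ref_matches_genome(self, world):
        cfg, genome, sigs, anns, muts, truth = world
        for m in muts[:200]:
            assert genome.fetch(m.chrom, m.pos - 1, m.pos) == m.ref

    def test_same_seed_identical_cohort(self, world):
        cfg, genome, sigs, anns, muts, truth = world
        muts2, _ = simulate_cohort(cfg, genome, list(anns), sigs)
        assert muts == muts2

    def test_truth_table_shape(self, world):
        cfg, genome, sigs, anns, muts, truth = world
        assert set(truth.columns) == {"sample", "context", "signature", "weight"}
        assert truth["sample"].nunique() == cfg.n_samples


class TestExpressionSV:
    def test_null_shift_gives_no_group_difference(self):
        from sigcontext.stats import rank_sum_test, tertile_grouping

        cfg = small_config(expression_shift=0.0, n_samples=60)
        rng = np.random.default_rng(0)
        weights = {f"S{i:03d}": float(w) for i, w in enumerate(rng.uniform(0.1, 0.5, 60))}
        table = simulate_expression_and_sv(cfg, weights)
        groups = tertile_grouping(table["expression"].to_numpy())
        w = np.array([weights[s] for s in table["sample"]])
        p = rank_sum_test(w[groups == "low"], w[groups == "high"])
        assert p > 0.05

    def test_monotone_link_gives_perfect_correlation(self):
        from sigcontext.stats import exposure_sv_correlation

        cfg = small_config(sv_noise=0.0)
        weights = {f"S{i}": 0.1 + 0.02 * i for i in range(20)}
        table = simulate_expression_and_sv(cfg, weights)
        rho, _ = exposure_sv_correlation(
            [weights[s] for s in table["sample"]], table["sv_count"].to_numpy()
        )
        assert rho == pytest.approx(1.0)

    def test_same_seed_identical_tables(self):
        cfg = small_config()
        weights = {f"S{i}": 0.2 for i in range(10)}
        a = simulate_expression_and_sv(cfg, weights)
        b = simulate_expression_and_sv(cfg, weights)
        pd.testing.assert_frame_equal(a, b)
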