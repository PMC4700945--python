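import numpy as np
import pytest
from scipy import stats as sps

from indelfit.io_formats import read_tree
from indelfit.simulator import (
    EvolvingSequence,
    IndelLengthDistribution,
    IndelParams,
    UniformReplacementSampler,
    _simulate_attributes_py,
    evolve_branch,
    sample_indel_length,
    simulate_attributes,
    simulate_true_msa,
    zipf_pmf,
)
from indelfit.stats import compute_attributes

from oracles import euler_indel_counts, replay_gap_matrix, truncated_power_pmf


class TestZipfPmf:
    def test_single_support_point(self):
        assert zipf_pmf(1, a=2.0, max_len=1) == 1.0

    def test_slope_must_exceed_one(self):
        with pytest.raises(ValueError):
            zipf_pmf(2, a=1.0, max_len=50)

    def test_out_of_range_length(self):
        with pytest.raises(ValueError):
            zipf_pmf(51, a=1.3, max_len=50)
        with pytest.raises(ValueError):
            zipf_pmf(0, a=1.3, max_len=50)

    def test_matches_bruteforce_normalizer(self):
        # frozen from explicit summation of j**-1.3 for j=1..50
        oracle = truncated_power_pmf(1.3, 50)
        assert zipf_pmf(1, 1.3, 50) == pytest.approx(oracle[0], abs=1e-14)
        assert zipf_pmf(17, 1.3, 50) == pytest.approx(oracle[16], abs=1e-14)

    @pytest.mark.parametrize("a", [1.1, 1.3, 1.7, 2.0])
    def test_pmf_sums_to_one_and_decreases(self, a):
        dist = IndelLengthDistribution(a=a, max_len=50)
        assert abs(dist.pmf.sum() - 1.0) < 1e-12
        assert np.all(np.diff(dist.pmf) < 0)


class TestSampleIndelLength:
    def test_degenerate_support(self, rng):
        dist = IndelLengthDistribution(a=1.5, max_len=1)
        assert all(sample_indel_length(dist, rng) == 1 for _ in range(100))

    def test_empirical_frequencies(self):
        dist = IndelLengthDistribution(a=1.3, max_len=50)
        rng = np.random.default_rng(4)
        n = 100_000
        draws = np.array([dist.sample(rng) for _ in range(n)])
        p1 = dist.pmf[0]
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs((draws == 1).mean() - p1) < 3 * se

    def test_histogram_chi_squared(self):
        """Drawn lengths are consistent with the pmf (GOF not rejected)."""
        dist = IndelLengthDistribution(a=1.3, max_len=50)
        rng = np.random.default_rng(7)
        n = 100_000
        draws = np.array([dist.sample(rng) for _ in range(n)])
        observed = np.bincount(draws, minlength=51)[1:]
        _, p = sps.chisquare(observed, dist.pmf * n)
        assert p > 0.01

    def test_seeded_reproducibility(self):
        dist = IndelLengthDistribution(a=1.3, max_len=50)
        d1 = [dist.sample(np.random.default_rng(5)) for _ in range(1)]
        d2 = [dist.sample(np.random.default_rng(5)) for _ in range(1)]
        assert d1 == d2


class TestIndelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(ir=-0.1, a=1.3, rl=100),
            dict(ir=0.1, a=1.0, rl=100),
            dict(ir=0.1, a=1.3, rl=0),
            dict(ir=0.1, a=1.3, rl=100, max_len=0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IndelParams(**kwargs)

    def test_ir_split_convention(self):
        assert IndelParams(ir=0.1, a=1.3, rl=10).per_side_rate == 0.05
        assert (
            IndelParams(ir=0.1, a=1.3, rl=10, ir_split="each").per_side_rate == 0.1
        )


class TestEvolveBranch:
    def test_zero_branch_length_is_identity(self, rng):
        seq = EvolvingSequence.root(50)
        out = evolve_branch(seq, 0.0, IndelParams(ir=0.5, a=1.3, rl=50), rng)
        assert out.ids == seq.ids

    def test_no_indel_limit_preserves_tokens(self, rng):
        seq = EvolvingSequence.root(80)
        out = evolve_branch(seq, 2.0, IndelParams(ir=0.0, a=1.3, rl=80), rng)
        assert out.ids == list(range(80))

    def test_input_not_mutated(self, rng):
        seq = EvolvingSequence.root(60)
        before = list(seq.ids)
        evolve_branch(seq, 1.0, IndelParams(ir=0.5, a=1.3, rl=60), rng)
        assert seq.ids == before

    def test_negative_branch_length_rejected(self, rng):
        seq = EvolvingSequence.root(10)
        with pytest.raises(ValueError):
            evolve_branch(seq, -1.0, IndelParams(ir=0.1, a=1.3, rl=10), rng)

    def test_length_stationarity(self):
        """Equal insertion/deletion rates keep the expected length at RL
        (up to the deletion-truncation edge effect)."""
        params = IndelParams(ir=0.1, a=1.3, rl=500)
        rng = np.random.default_rng(11)
        lengths = []
        for _ in range(1000):
            seq = EvolvingSequence.root(500)
            out = evolve_branch(seq, 0.2, params, rng)
            lengths.append(out.length)
        lengths = np.asarray(lengths, dtype=float)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 500) < 3 * se

    def test_event_counts_match_euler_oracle(self):
        """Gillespie indel event counts agree with an independent
        discretized-time simulator within Monte-Carlo error."""
        params = IndelParams(ir=0.02, a=1.3, rl=350)
        n = 10_000
        rng = np.random.default_rng(3)
        counts = np.empty(n)
        for i in range(n):
            record = []
            evolve_branch(EvolvingSequence.root(350), 0.5, params, rng, record=record)
            counts[i] = len(record)
        oracle = euler_indel_counts(
            L0=350, t=0.5, ir=0.02, a=1.3, max_len=50,
            n_reps=n, rng=np.random.default_rng(4), dt=1e-4,
        )
        se = np.sqrt(counts.var(ddof=1) / n + oracle.var(ddof=1) / n)
        assert abs(counts.mean() - oracle.mean()) < 3 * se + 0.01


class TestSimulateTrueMsa:
    def test_no_indels_gives_gapless_alignment(self, small_tree, rng):
        params = IndelParams(ir=0.0, a=1.3, rl=120)
        msa = simulate_true_msa(small_tree, params, rng)
        assert msa.n_cols == 120
        assert all("-" not in row for row in msa.rows)
        assert msa.n_rows == small_tree.n_leaves

    def test_zero_branch_lengths_give_identical_rows(self, rng):
        tree = read_tree("((A:0.0,B:0.0):0.0,C:0.0);")
        params = IndelParams(ir=0.3, a=1.3, rl=40)
        msa = simulate_true_msa(tree, params, rng)
        assert len(set(msa.rows)) == 1
        assert "-" not in msa.rows[0]

    def test_no_all_gap_columns(self, small_tree, rng):
        params = IndelParams(ir=0.1, a=1.3, rl=100)
        msa = simulate_true_msa(small_tree, params, rng)
        cols = np.array([list(r) for r in msa.rows])
        assert not np.any(np.all(cols == "-", axis=0))

    def test_gap_pattern_matches_replay_oracle(self, small_tree):
        """The true alignment equals an independent column-expansion
        reconstruction from the same event history, replicate by
        replicate."""
        ctree = small_tree.compile()
        params = IndelParams(ir=0.08, a=1.3, rl=120)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            record = []
            msa = simulate_true_msa(small_tree, params, rng, record=record)
            got = np.array([[c != "-" for c in row] for row in msa.rows])
            want = replay_gap_matrix(ctree, params.rl, record)
            assert got.shape == want.shape
            assert np.array_equal(got, want)

    def test_mean_gap_blocks_match_replay_oracle(self, bench_tree):
        """Mean total gap-block count over replicates agrees exactly with
        the column-expansion reference run on the same event logs."""
        params = IndelParams(ir=0.02, a=1.3, rl=350)
        ctree = bench_tree.compile()
        diffs = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            record = []
            msa = simulate_true_msa(bench_tree, params, rng, record=record)
            blocks_impl = compute_attributes(msa).n_gap_blocks
            mat = replay_gap_matrix(ctree, params.rl, record)
            gaps = ~mat
            starts = gaps[:, :1].sum() + (gaps[:, 1:] & ~gaps[:, :-1]).sum()
            diffs.append(blocks_impl - float(starts))
        assert diffs == [0.0] * len(diffs)

    def test_default_residues_are_conserved_per_column(self, small_tree):
        """Without a substitution layer each column carries one residue,
        conserved across every row that has it."""
        params = IndelParams(ir=0.05, a=1.3, rl=80)
        msa = simulate_true_msa(small_tree, params, np.random.default_rng(9))
        for col in zip(*msa.rows):
            chars = {c for c in col if c != "-"}
            assert len(chars) == 1

    def test_substitution_layer_mutates_residues(self, rng):
        """With the uniform replacement layer, long branches decorate the
        alignment with substitutions (rows differ beyond gaps)."""
        tree = read_tree("(A:1.0,B:1.0);")
        params = IndelParams(ir=0.0, a=1.3, rl=200)
        msa = simulate_true_msa(
            tree, params, rng, sampler=UniformReplacementSampler()
        )
        assert msa.n_cols == 200  # no indels
        diffs = sum(a != b for a, b in zip(*msa.rows))
        assert diffs > 0


class TestSimulateAttributes:
    def test_matches_full_msa_path(self, small_tree):
        """The attribute fast path agrees with attributes computed from
        the materialized alignment at the same seed."""
        params = IndelParams(ir=0.06, a=1.3, rl=150)
        for seed in range(10):
            fast = simulate_attributes(
                small_tree, params, np.random.default_rng(seed)
            )
            msa = simulate_true_msa(
                small_tree, params, np.random.default_rng(seed)
            )
            slow = compute_attributes(msa).as_array()
            assert np.array_equal(fast, slow)

    def test_jit_kernel_matches_python_reference(self, bench_tree):
        """The compiled kernel reproduces the pure-Python path
        bit-for-bit from the same seed."""
        for params in [
            IndelParams(ir=0.02, a=1.3, rl=350),
            IndelParams(ir=0.1, a=1.1, rl=100),
        ]:
            for seed in range(5):
                a1 = simulate_attributes(
                    bench_tree, params, np.random.Generator(np.random.PCG64(seed))
                )
                a2 = _simulate_attributes_py(
                    bench_tree, params, np.random.Generator(np.random.PCG64(seed))
                )
                assert np.array_equal(a1, a2)

    def test_conservation_at_zero_indel_rate(self, bench_tree, rng):
        attrs = simulate_attributes(
            bench_tree, IndelParams(ir=0.0, a=1.3, rl=350), rng
        )
        assert attrs.tolist() == [350.0, 0.0, 0.0, 350.0, 350.0]

    def test_seeded_determinism(self, bench_tree):
        params = IndelParams(ir=0.02, a=1.3, rl=350)
        a1 = simulate_attributes(bench_tree, params, np.random.default_rng(42))
        a2 = simulate_attributes(bench_tree, params, np.random.default_rng(42))
        assert np.array_equal(a1, a2)
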