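import numpy as np
import pytest

from cfmethsim.atlas import make_toy_atlas
from cfmethsim.errors import ValidationError
from cfmethsim.methprofile import extract_site_counts, global_methylation
from cfmethsim.simulate import (
    JagSpec,
    LengthSpec,
    RawFragment,
    SimConfig,
    apply_jagged_ends,
    convert_and_read,
    downsample,
    library_prep,
    sample_fragments,
    simulate_sample,
    simulate_spikeins,
)

from conftest import MIXTURE


def _calls(dataset):
    """Multiset of (site, call) pairs over all informative calls."""
    out = []
    for f in dataset.fragments:
        for pos, c in zip(f.cpg_positions, f.pattern):
            if c != ".":
                out.append((f.chrom, int(pos), c))
    return sorted(out)


class TestSampleFragments:
    def test_degenerate_bernoulli_all_methylated(self, site_atlas):
        atlas, _ = make_toy_atlas(2, 5, high_beta=1.0, low_beta=0.0)
        cfg = SimConfig(mixture={"tissueA": 1.0}, n_fragments=200, seed=3)
        rng = np.random.default_rng(0)
        # tissueA's own block is beta=0, all other sites beta=1
        frags = sample_fragments(cfg, atlas, rng)
        blockA = atlas.sites[:5]
        blockA_pos = {s.pos for s in blockA}
        for f in frags:
            for pos, m in zip(f.cpg_pos, f.meth):
                assert m == (pos not in blockA_pos)

    def test_mixture_counts_within_binomial_bounds(self, site_atlas):
        cfg = SimConfig(mixture={"tissueA": 0.5, "tissueB": 0.5}, n_fragments=10_000, seed=5)
        frags = sample_fragments(cfg, site_atlas, np.random.default_rng(5))
        n_a = sum(f.tissue == "tissueA" for f in frags)
        sd = np.sqrt(10_000 * 0.25)
        assert abs(n_a - 5_000) <= 3 * sd

    def test_deterministic_under_seed(self, site_atlas):
        cfg = SimConfig(mixture=MIXTURE, n_fragments=500, seed=11)
        f1 = sample_fragments(cfg, site_atlas, np.random.default_rng(11))
        f2 = sample_fragments(cfg, site_atlas, np.random.default_rng(11))
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert (a.start, a.end, a.tissue) == (b.start, b.end, b.tissue)
            np.testing.assert_array_equal(a.meth, b.meth)

    def test_unknown_tissue_rejected(self, site_atlas):
        cfg = SimConfig(mixture={"nosuch": 1.0}, n_fragments=10)
        with pytest.raises(ValidationError, match="unknown tissues"):
            sample_fragments(cfg, site_atlas, np.random.default_rng(0))

    def test_every_fragment_covers_a_site(self, site_atlas):
        cfg = SimConfig(mixture=MIXTURE, n_fragments=300, seed=2)
        for f in sample_fragments(cfg, site_atlas, np.random.default_rng(2)):
            assert len(f.cpg_pos) >= 1
            assert np.all((f.cpg_pos >= f.start) & (f.cpg_pos + 2 <= f.end))


class TestJaggedEnds:
    def _frag(self, length=200):
        return RawFragment("c", 0, length, "t", np.array([50]), np.array([True]))

    def test_jag_prob_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f = apply_jagged_ends(self._frag(), 0.0, JagSpec(mean=10), rng)
            assert f.j_left == 0 and f.j_right == 0

    def test_constant_length(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            f = apply_jagged_ends(self._frag(), 1.0, JagSpec(mean=20, kind="constant"), rng)
            assert f.j_left == 20 and f.j_right == 20

    def test_truncated_to_fragment_length(self):
        rng = np.random.default_rng(0)
        f = apply_jagged_ends(self._frag(length=5), 1.0, JagSpec(mean=500, kind="constant"), rng)
        assert f.j_left == 4 and f.j_right == 4

    def test_mean_overhang_matches_distribution(self):
        rng = np.random.default_rng(42)
        mean = 12.0
        draws = [
            apply_jagged_ends(self._frag(length=10_000), 1.0, JagSpec(mean=mean), rng).j_left
            for _ in range(10_000)
        ]
        # geometric: sd = sqrt(1-p)/p ~ mean; MC error on the mean ~ mean/sqrt(n)
        assert abs(np.mean(draws) - mean) < 4 * mean / np.sqrt(10_000)


class TestLibraryPrep:
    def _jagged_frag(self, n_cpg=6, j_left=0, j_right=0, meth=True):
        pos = np.arange(n_cpg) * 10 + 10
        f = RawFragment("c", 0, 100, "t", pos, np.full(n_cpg, meth))
        f.j_left, f.j_right = j_left, j_right
        return f

    def test_dslp_no_jag_no_repair(self):
        for mol in library_prep(self._jagged_frag(), "dsLP", emit="both"):
            assert not mol.repair.any()
            np.testing.assert_array_equal(mol.state, np.full(6, True))

    def test_dslp_fillin_flips_exactly_covered_cpgs(self):
        # left overhang of 35 bp spans CpGs at 10, 20, 30 -> 3 flips on the
        # minus strand (whose recessed 3' end is filled in); plus strand intact
        f = self._jagged_frag(j_left=35)
        plus, minus = library_prep(f, "dsLP", emit="both")
        assert plus.repair.sum() == 0 and plus.state.all()
        assert minus.repair.sum() == 3
        np.testing.assert_array_equal(minus.repair, [True, True, True, False, False, False])
        np.testing.assert_array_equal(minus.state, [False, False, False, True, True, True])

    def test_dslp_right_overhang_repairs_plus_strand(self):
        f = self._jagged_frag(j_right=45)  # spans CpGs at 60, (61..99): 60 only? end=100, pos>=55
        plus, minus = library_prep(f, "dsLP", emit="both")
        assert minus.repair.sum() == 0
        np.testing.assert_array_equal(plus.repair, plus.cpg_pos >= 55)

    def test_sslp_preserves_truth(self):
        f = self._jagged_frag(j_left=35, j_right=15)
        for mol in library_prep(f, "ssLP", emit="both"):
            assert not mol.repair.any()
            np.testing.assert_array_equal(mol.state, f.meth)

    def test_sslp_strand_lengths(self):
        f = self._jagged_frag(j_left=35, j_right=15)
        plus, minus = library_prep(f, "ssLP", emit="both")
        assert (plus.mstart, plus.mend) == (0, 85)
        assert (minus.mstart, minus.mend) == (35, 100)

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            library_prep(self._jagged_frag(), "bisulfite", emit="both")


class TestConvertAndRead:
    def _mol(self, meth=True, n=5):
        f = RawFragment("c", 0, 120, "t", np.arange(n) * 20 + 10, np.full(n, meth))
        f.j_left = f.j_right = 0
        return library_prep(f, "dsLP", emit="both")[0]

    def test_noiseless_limit(self):
        cfg = SimConfig(mixture={"t": 1.0}, conversion_rate=1.0, protection_rate=1.0)
        rec = convert_and_read(self._mol(meth=True), cfg, np.random.default_rng(0))
        assert rec.pattern == "CCCCC"
        rec = convert_and_read(self._mol(meth=False), cfg, np.random.default_rng(0))
        assert rec.pattern == "TTTTT"

    def test_inversion_limit(self):
        cfg = SimConfig(mixture={"t": 1.0}, conversion_rate=0.0, protection_rate=1.0)
        rec = convert_and_read(self._mol(meth=False), cfg, np.random.default_rng(0))
        assert rec.pattern == "CCCCC"  # every unconverted C reads as methylated

    def test_conversion_failure_rate_recovered(self):
        cfg = SimConfig(mixture={"t": 1.0}, conversion_rate=0.99, protection_rate=1.0)
        rng = np.random.default_rng(8)
        n_c = n_tot = 0
        for _ in range(20_000):
            rec = convert_and_read(self._mol(meth=False), cfg, rng)
            n_c += rec.pattern.count("C")
            n_tot += 5
        se = np.sqrt(0.01 * 0.99 / n_tot)
        assert abs(n_c / n_tot - 0.01) < 3 * se

    def test_read_positions(self):
        cfg = SimConfig(mixture={"t": 1.0}, read_length=50)
        mol = self._mol()  # molecule [0,120), CpGs at 10,30,50,70,90
        rec = convert_and_read(mol, cfg, np.random.default_rng(0))
        if mol.strand == "+":
            np.testing.assert_array_equal(rec.read1_pos, [10, 30, -1, -1, -1])
            np.testing.assert_array_equal(rec.read2_pos, [-1, -1, -1, 49, 29])
        else:
            np.testing.assert_array_equal(rec.read1_pos, [-1, -1, -1, 49, 29])
            np.testing.assert_array_equal(rec.read2_pos, [10, 30, -1, -1, -1])


class TestSpikeins:
    def test_perfect_channel(self):
        cfg = SimConfig(mixture={"t": 1.0}, conversion_rate=1.0, protection_rate=1.0)
        s = simulate_spikeins(cfg, 500, 500, np.random.default_rng(0))
        assert not s.lambda_is_c.any()  # all unmethylated lambda read as T
        assert s.puc19_is_c.all()  # all methylated pUC19 read as C

    def test_counts_must_be_positive(self):
        cfg = SimConfig(mixture={"t": 1.0})
        with pytest.raises(ValidationError):
            simulate_spikeins(cfg, 0, 100, np.random.default_rng(0))


class TestSimulateSample:
    def test_no_jag_sslp_dslp_identical(self, site_atlas):
        kw = dict(mixture=MIXTURE, n_fragments=2_000, jag_prob=0.0, seed=7)
        a = simulate_sample(SimConfig(library="ssLP", **kw), site_atlas)
        b = simulate_sample(SimConfig(library="dsLP", **kw), site_atlas)
        assert _calls(a) == _calls(b)

    def test_dslp_jag_lowers_global_methylation(self, sslp_sample, dslp_sample):
        g_ss = global_methylation(extract_site_counts(sslp_sample.fragments))
        g_ds = global_methylation(extract_site_counts(dslp_sample.fragments))
        assert g_ds < g_ss

    def test_global_methylation_monotone_in_jag(self, site_atlas):
        vals = []
        for jp in (0.0, 0.4, 0.8):
            cfg = SimConfig(
                mixture=MIXTURE, n_fragments=20_000, library="dsLP",
                jag_prob=jp, jag_length=JagSpec(mean=25.0), seed=13,
            )
            ds = simulate_sample(cfg, site_atlas)
            vals.append(global_methylation(extract_site_counts(ds.fragments)))
        assert vals[0] > vals[1] > vals[2]

    def test_repair_density_higher_in_read2_window(self, dslp_sample):
        r1 = r2 = t1 = t2 = 0
        for f in dslp_sample.fragments:
            for i, c in enumerate(f.pattern):
                if c == ".":
                    continue
                if 0 <= f.read1_pos[i] < 30:
                    t1 += 1
                    r1 += f.repair_mask[i]
                if 0 <= f.read2_pos[i] < 30:
                    t2 += 1
                    r2 += f.repair_mask[i]
        assert r2 / t2 > 10 * max(r1 / t1, 1e-9)

    def test_sslp_has_no_repair_flags(self, sslp_sample):
        assert not any(f.repair_mask.any() for f in sslp_sample.fragments)

    def test_empty_dataset(self, site_atlas):
        ds = simulate_sample(SimConfig(mixture=MIXTURE, n_fragments=0), site_atlas)
        assert ds.n_fragments == 0
        assert sum(ds.realized_counts.values()) == 0

    def test_realized_counts_sum(self, sslp_sample):
        assert sum(sslp_sample.realized_counts.values()) == sslp_sample.n_fragments

    def test_bit_identical_reruns(self, site_atlas):
        cfg = SimConfig(mixture=MIXTURE, n_fragments=1_000, library="dsLP",
                        jag_prob=0.5, seed=21)
        a = simulate_sample(cfg, site_atlas)
        b = simulate_sample(cfg, site_atlas)
        assert [f.pattern for f in a.fragments] == [f.pattern for f in b.fragments]
        np.testing.assert_array_equal(a.spikeins.lambda_is_c, b.spikeins.lambda_is_c)


class TestDownsample:
    def test_identity(self, sslp_sample):
        ds = downsample(sslp_sample, sslp_sample.n_fragments, seed=0)
        assert ds.fragments == sslp_sample.fragments

    def test_half(self, sslp_sample):
        half = sslp_sample.n_fragments // 2
        ds = downsample(sslp_sample, half, seed=0)
        assert ds.n_fragments == half
        assert ds.spikeins is sslp_sample.spikeins

    def test_too_large(self, sslp_sample):
        with pytest.raises(ValidationError):
            downsample(sslp_sample, sslp_sample.n_fragments + 1, seed=0)

    def test_composition_preserved_hypergeometric(self, sslp_sample):
        n, k = sslp_sample.n_fragments, sslp_sample.n_fragments // 2
        ds = downsample(sslp_sample, k, seed=3)
        for t, orig in sslp_sample.realized_counts.items():
            p = orig / n
            sd = np.sqrt(k * p * (1 - p) * (n - k) / (n - 1))
            assert abs(ds.realized_counts[t] - k * p) <= 3 * sd


class TestSimConfig:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SimConfig(mixture={"a": 0.5, "b": 0.4})

    def test_read_length_floor(self):
        with pytest.raises(ValidationError):
            SimConfig(mixture={"a": 1.0}, read_length=30)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(mixture=MIXTURE, n_fragments=123, jag_prob=0.4,
                        jag_length=JagSpec(mean=9.0), library="dsLP", seed=5)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg
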