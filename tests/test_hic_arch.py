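import numpy as np
import pytest

from chromarch.core_io import AlignmentBlock, GenomicInterval, revcomp
from chromarch.hic_arch import (
    BoundaryCall,
    ContactMatrix,
    MotifHit,
    ab_compartments,
    annotate_boundaries,
    boundary_f1,
    boundary_sharing,
    call_tad_boundaries,
    compartment_transitions,
    convergent_pairs,
    ice_normalize,
    insulation_score,
    scan_pwm,
)
from chromarch.simulate import SimParams, simulate_genome, simulate_hic


def _matrix(counts, bin_size=10_000, chrom="c"):
    return ContactMatrix(chrom, bin_size, np.asarray(counts, dtype=float))


def brute_force_pwm_scan(seq, pwm, background, threshold):
    """Independent per-position scorer (oracle for scan_pwm)."""
    assert (pwm > 0).all(), "oracle assumes a zero-free PWM"
    lo = np.log2(pwm / background[:, None])
    L = lo.shape[1]
    cutoff = threshold * lo.max(axis=0).sum()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand in "+-":
        for p in range(len(seq) - L + 1):
            window = seq[p : p + L]
            if strand == "-":
                window = revcomp(window)
            score = sum(
                lo[idx[b], j] if b in idx else 0.0 for j, b in enumerate(window)
            )
            if score >= cutoff:
                hits.append((p, strand, round(score, 9)))
    return sorted(hits)


class TestContactMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            _matrix([[1, 2], [3, 1]])

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            _matrix([[1, -1], [-1, 1]])


class TestIceNormalize:
    def test_two_by_two(self):
        bal, bias = ice_normalize(_matrix([[2, 1], [1, 2]]))
        rows = bal.counts.sum(axis=1)
        assert abs(rows[0] - rows[1]) / rows.mean() < 1e-5
        # symmetric matrix -> equal biases
        assert bias[0] == pytest.approx(bias[1], rel=1e-4)

    def test_already_balanced_unchanged_up_to_scale(self, rng):
        n = 20
        m = np.ones((n, n)) * 5
        bal, bias = ice_normalize(_matrix(m))
        np.testing.assert_allclose(bias, bias[0])
        ratio = bal.counts / m
        np.testing.assert_allclose(ratio, ratio[0, 0])

    def test_zero_row_masked(self):
        m = np.array([[0, 0, 0], [0, 4.0, 1], [0, 1, 2]])
        bal, bias = ice_normalize(_matrix(m))
        assert bal.mask[0] and np.isnan(bias[0])
        rows = bal.counts[1:, 1:].sum(axis=1)
        assert rows.std() / rows.mean() < 1e-5

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            ice_normalize(_matrix(np.zeros((3, 3))))

    def test_row_sum_cv_and_idempotence(self, rng):
        m = rng.poisson(10, size=(40, 40)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        bal, _ = ice_normalize(_matrix(m), tol=1e-7)
        rows = bal.counts[~bal.mask].sum(axis=1)
        assert rows.std() / rows.mean() < 1e-5
        twice, bias2 = ice_normalize(bal, tol=1e-7)
        np.testing.assert_allclose(
            twice.counts / twice.counts.max(), bal.counts / bal.counts.max(), atol=1e-4
        )


class TestInsulation:
    def test_uniform_matrix_scores_zero(self):
        m = _matrix(np.full((30, 30), 7.0))
        s = insulation_score(m, 5)
        defined = ~np.isnan(s)
        assert defined.sum() == 30 - 10
        np.testing.assert_allclose(s[defined], 0.0, atol=1e-12)

    def test_block_junction_is_unique_minimum(self):
        n = 30
        m = np.zeros((n, n))
        m[:15, :15] = 10.0
        m[15:, 15:] = 10.0
        s = insulation_score(_matrix(m), 5)
        # bins 14 and 15 both see a pure cross-block square: a 2-bin plateau
        assert int(np.nanargmin(s)) in (14, 15)
        calls = call_tad_boundaries(s, min_strength=0.1)
        assert len(calls) == 1 and calls[0].bin in (14, 15)

    def test_scaling_invariance(self, rng):
        m = rng.poisson(20, size=(40, 40)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        s1 = insulation_score(_matrix(m), 5)
        s2 = insulation_score(_matrix(m * 7.5), 5)
        np.testing.assert_allclose(s1, s2, equal_nan=True, atol=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            insulation_score(_matrix(np.ones((10, 10))), 5)


class TestBoundaries:
    def test_single_minimum(self):
        calls = call_tad_boundaries(np.array([0.0, -1.0, 0.0]), min_strength=0.5)
        assert len(calls) == 1
        assert calls[0].bin == 1 and calls[0].strength == pytest.approx(1.0)

    def test_monotone_no_boundaries(self):
        assert call_tad_boundaries(np.linspace(0, 1, 10)) == []

    def test_plateau_resolves_to_center(self):
        s = np.array([0.0, -1.0, -1.0, -1.0, 0.0])
        (call,) = call_tad_boundaries(s, min_strength=0.5)
        assert call.bin == 2

    def test_weak_minimum_dropped(self):
        assert call_tad_boundaries(np.array([0.0, -0.05, 0.0]), min_strength=0.1) == []

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            call_tad_boundaries(np.array([0.0, np.nan, 1.0]))

    def test_planted_tads_recovered(self):
        p = SimParams(seed=21, compartment_strength=0.0)
        _, truth = simulate_genome(p)
        m = simulate_hic(truth, p, "chr1")
        bal, _ = ice_normalize(ContactMatrix("chr1", p.hic_bin_size, m))
        scores = insulation_score(bal, 10)
        calls = call_tad_boundaries(scores, min_strength=0.1)
        _, _, f1 = boundary_f1([c.bin for c in calls], truth.tad_boundaries("chr1"))
        assert f1 >= 0.9


def _block_labels(sizes=(7, 5, 6, 8, 7, 7)):
    """Alternating A/B blocks of uneven size (even alternation would leave
    every diagonal constant and vanish under observed/expected)."""
    out = []
    lab = "A"
    for s in sizes:
        out += [lab] * s
        lab = "B" if lab == "A" else "A"
    return np.array(out)


class TestCompartments:
    def test_checkerboard_recovered(self):
        labels = _block_labels()
        same = labels[:, None] == labels[None, :]
        m = np.where(same, 10.0, 2.0)
        ori = (labels == "A").astype(float)
        values, got, degenerate = ab_compartments(_matrix(m), ori)
        assert not degenerate
        assert (got == labels).all()

    def test_uniform_degenerate(self):
        values, labels, degenerate = ab_compartments(
            _matrix(np.full((20, 20), 4.0)), np.arange(20.0)
        )
        assert degenerate and labels is None

    def test_orientation_flip_flips_labels(self):
        labels = _block_labels()
        same = labels[:, None] == labels[None, :]
        m = np.where(same, 10.0, 2.0)
        ori = (labels == "A").astype(float)
        _, l1, _ = ab_compartments(_matrix(m), ori)
        _, l2, _ = ab_compartments(_matrix(m), 1.0 - ori)
        flipped = np.where(l1 == "A", "B", "A")
        assert (l2 == flipped).all()

    def test_scaling_invariance(self):
        n = 40
        labels = np.array(["A"] * 20 + ["B"] * 20)
        same = labels[:, None] == labels[None, :]
        m = np.where(same, 10.0, 2.0)
        ori = (labels == "A").astype(float)
        v1, _, _ = ab_compartments(_matrix(m), ori)
        v2, _, _ = ab_compartments(_matrix(m * 3.0), ori)
        np.testing.assert_allclose(v1, v2, atol=1e-6)

    def test_transitions(self):
        labels = np.array(["A", "A", "B", "B", "A"])
        assert compartment_transitions(labels, bin_size=10) == [20, 40]


class TestPwmScan:
    @pytest.fixture
    def pwm(self):
        # information-rich 6-mer: consensus ACGTAC
        pwm = np.full((4, 6), 0.02)
        for j, b in enumerate("ACGTAC"):
            pwm["ACGT".index(b), j] = 0.94
        return pwm / pwm.sum(axis=0)

    def test_planted_consensus_max_score(self, pwm, rng):
        seq = "TTTTTTTTTT" + "ACGTAC" + "TTTTTTTTTT"
        hits = scan_pwm(seq, pwm, threshold=0.99)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.position == 10 for h in plus)

    def test_revcomp_symmetry(self, pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = scan_pwm(seq, pwm, threshold=0.7)
        rev = scan_pwm(revcomp(seq), pwm, threshold=0.7)
        L = pwm.shape[1]
        mirrored = sorted(
            (len(seq) - h.position - L, "+-"[h.strand == "+"], round(h.score, 6))
            for h in rev
        )
        assert mirrored == sorted(
            (h.position, h.strand, round(h.score, 6)) for h in fwd
        )

    def test_matches_brute_force(self, pwm, rng):
        seq = "".join(rng.choice(list("ACGTN"), 2_000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = sorted(
            (h.position, h.strand, round(h.score, 9))
            for h in scan_pwm(seq, pwm, threshold=0.6)
        )
        want = brute_force_pwm_scan(seq, pwm, np.full(4, 0.25), 0.6)
        assert got == want

    def test_column_sum_validated(self):
        with pytest.raises(ValueError):
            scan_pwm("ACGT", np.full((4, 3), 0.3))


class TestConvergentPairs:
    def _h(self, pos, strand):
        return MotifHit(pos, strand, 1.0)

    def test_one_pair(self):
        pairs = convergent_pairs([self._h(1_000, "+"), self._h(50_000, "-")], 100_000)
        assert len(pairs) == 1

    def test_divergent_no_pair(self):
        assert convergent_pairs([self._h(1_000, "-"), self._h(50_000, "+")], 100_000) == []

    def test_combinatorial_count(self):
        k, m = 4, 3
        hits = [self._h(1_000 * i, "+") for i in range(k)] + [
            self._h(10_000 + 1_000 * i, "-") for i in range(m)
        ]
        assert len(convergent_pairs(hits, 1_000_000)) == k * m

    def test_span_limit(self):
        assert convergent_pairs([self._h(0, "+"), self._h(50_000, "-")], 10_000) == []


class TestAnnotateBoundaries:
    def _boundary(self, pos, bin_size=10_000):
        return BoundaryCall(
            pos // bin_size,
            GenomicInterval("c", pos - pos % bin_size, pos - pos % bin_size + bin_size),
            1.0,
        )

    def test_single_ctcf_flag(self):
        flags, counts = annotate_boundaries(
            [self._boundary(100_000)], [MotifHit(103_000, "+", 5.0)], [], []
        )
        assert flags == [(True, False, False)]
        assert counts[(True, False, False)] == 1

    def test_empty_features_all_zero(self):
        flags, counts = annotate_boundaries(
            [self._boundary(100_000), self._boundary(300_000)], [], [], []
        )
        assert flags == [(False, False, False)] * 2
        assert counts[(False, False, False)] == 2

    def test_planted_enrichment_beats_random(self, rng):
        # CTCF planted at every boundary; random bins mostly unflagged
        boundary_pos = [int(p) for p in rng.integers(50_000, 950_000, 12)]
        boundaries = [self._boundary(p) for p in boundary_pos]
        hits = [MotifHit(p + 2_000, "+", 5.0) for p in boundary_pos]
        flags, _ = annotate_boundaries(boundaries, hits, [], [])
        frac_b = np.mean([f[0] for f in flags])
        perm_fracs = []
        for _ in range(200):
            rand = [self._boundary(int(p)) for p in rng.integers(0, 1_000_000, 12)]
            rf, _ = annotate_boundaries(rand, hits, [], [])
            perm_fracs.append(np.mean([f[0] for f in rf]))
        p = (1 + sum(f >= frac_b for f in perm_fracs)) / 201
        assert p < 0.05


class TestBoundarySharing:
    def _identity_map(self, length=1_000_000):
        return [AlignmentBlock("c", 0, length, "c", 0, length, "+", length, length)]

    def _b(self, pos, chrom="c", bin_size=10_000):
        b = pos // bin_size
        return BoundaryCall(b, GenomicInterval(chrom, b * bin_size, (b + 1) * bin_size), 1.0)

    def test_identical_sets_fraction_one(self):
        a = [self._b(100_000), self._b(500_000)]
        frac, pairs, n = boundary_sharing(a, a, self._identity_map())
        assert frac == 1.0 and n == 2

    def test_disjoint_sets_zero(self):
        a = [self._b(100_000)]
        b = [self._b(700_000)]
        frac, _, _ = boundary_sharing(a, b, self._identity_map())
        assert frac == 0.0

    def test_one_bin_shift_within_slack(self):
        a = [self._b(100_000)]
        b = [self._b(110_000)]
        frac, _, _ = boundary_sharing(a, b, self._identity_map(), slack_bins=1)
        assert frac == 1.0

    def test_gap_unprojectable_excluded(self):
        blocks = [AlignmentBlock("c", 0, 200_000, "c", 0, 200_000, "+", 200_000, 200_000)]
        a = [self._b(100_000), self._b(500_000)]  # second is in a gap
        frac, _, n = boundary_sharing(a, [self._b(100_000)], blocks)
        assert n == 1 and frac == 1.0

    def test_strand_aware_projection(self):
        # query [0, 100k) maps reversed onto target [0, 100k)
        blocks = [AlignmentBlock("c", 0, 100_000, "c", 0, 100_000, "-", 100_000, 100_000)]
        a = [self._b(20_000)]
        b = [self._b(75_000)]
        frac, _, _ = boundary_sharing(a, b, blocks, slack_bins=1)
        assert frac == 1.0
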