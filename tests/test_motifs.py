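"""PWM information content, trimming, similarity and clustering."""

import numpy as np
import pytest

from comotif.motifs import (
    EmptyMotifError,
    FLY_BACKGROUND,
    PWM,
    MotifCluster,
    cluster_pwms,
    column_ic,
    composition_assignment,
    composition_clusters,
    pwm_similarity,
    select_pwm_per_tf,
    trim_pwm,
)
from comotif.intervals import make_interval_set

from conftest import random_pwm, sharp_pwm

UNIFORM = [0.25, 0.25, 0.25, 0.25]


class TestColumnIC:
    @pytest.mark.parametrize(
        "freqs,expected",
        [(UNIFORM, 0.0), ([1, 0, 0, 0], 2.0), ([0.5, 0.5, 0, 0], 1.0)],
    )
    def test_known_values(self, freqs, expected):
        assert column_ic(freqs) == pytest.approx(expected, abs=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            column_ic([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            column_ic([1.2, -0.2, 0, 0])

    def test_range(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            assert 0.0 <= column_ic(p) <= 2.0


class TestTrim:
    def test_uniform_flanks_removed(self):
        pwm = PWM("x", "x", np.array([UNIFORM, [1, 0, 0, 0], UNIFORM]))
        t = trim_pwm(pwm)
        assert t.width == 1 and t.matrix[0, 0] == 1.0

    def test_identity_when_all_informative(self):
        pwm = sharp_pwm("ACGT")
        t = trim_pwm(pwm)
        np.testing.assert_array_equal(t.matrix, pwm.matrix)

    def test_low_ic_leading_column_by_formula(self):
        # IC(0.3,0.3,0.2,0.2) = 2 + 2*.3*log2(.3) + 2*.2*log2(.2) ~ 0.029 < 0.2
        col = [0.3, 0.3, 0.2, 0.2]
        assert column_ic(col) < 0.2
        pwm = PWM("x", "x", np.array([col, [1, 0, 0, 0]]))
        assert trim_pwm(pwm).width == 1

    def test_interior_untouched(self):
        pwm = PWM("x", "x", np.array([[1, 0, 0, 0], UNIFORM, [0, 1, 0, 0]]))
        assert trim_pwm(pwm).width == 3

    def test_all_trimmed_raises(self):
        with pytest.raises(EmptyMotifError):
            trim_pwm(PWM("x", "x", np.array([UNIFORM, UNIFORM])))

    def test_idempotent(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng)
            once = trim_pwm(pwm)
            np.testing.assert_array_equal(trim_pwm(once).matrix, once.matrix)


def _oracle_similarity(x: PWM, y: PWM, min_overlap=2):
    """Independent brute force over offsets/orientations of the IC-weighted PCC."""
    def ic(col):
        nz = col[col > 0]
        return 2 + float((nz * np.log2(nz)).sum())

    def pcc(u, v):
        u = u - u.mean()
        v = v - v.mean()
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return 0.0 if nu < 1e-12 or nv < 1e-12 else float(u @ v / (nu * nv))

    best = None
    for ym in (y.matrix, y.matrix[::-1, [3, 2, 1, 0]]):
        for off in range(-(len(ym) - 1), len(x.matrix)):
            pairs = [
                (i, i - off)
                for i in range(len(x.matrix))
                if 0 <= i - off < len(ym)
            ]
            if len(pairs) < min_overlap:
                continue
            num = den = 0.0
            for i, j in pairs:
                w = np.sqrt(ic(x.matrix[i]) * ic(ym[j]))
                num += w * pcc(x.matrix[i], ym[j])
                den += w
            matched_x = {i for i, _ in pairs}
            matched_y = {j for _, j in pairs}
            for i in set(range(len(x.matrix))) - matched_x:
                den += ic(x.matrix[i]) / 2
            for j in set(range(len(ym))) - matched_y:
                den += ic(ym[j]) / 2
            if den > 1e-12 and (best is None or num / den > best):
                best = num / den
    return 0.0 if best is None else best


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        for _ in range(10):
            p = random_pwm(rng)
            assert pwm_similarity(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_reverse_complement_is_one(self, rng):
        p = random_pwm(rng, width=6)
        assert pwm_similarity(p, p.reverse_complement()) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_pwm(rng), random_pwm(rng)
            assert pwm_similarity(a, b) == pytest.approx(pwm_similarity(b, a), abs=1e-9)

    def test_revcomp_pair_invariance(self, rng):
        for _ in range(10):
            a, b = random_pwm(rng), random_pwm(rng)
            assert pwm_similarity(a, b) == pytest.approx(
                pwm_similarity(a.reverse_complement(), b.reverse_complement()), abs=1e-12
            )

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            a, b = random_pwm(rng), random_pwm(rng)
            assert pwm_similarity(a, b) == pytest.approx(_oracle_similarity(a, b), abs=1e-10)

    def test_two_column_hand_case(self):
        a = PWM("a", "a", np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]]))
        b = PWM("b", "b", np.array([[0.6, 0.2, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1]]))
        assert pwm_similarity(a, b) == pytest.approx(_oracle_similarity(a, b), abs=1e-10)

    def test_uniform_pwms_zero_with_warning(self):
        u = PWM("u", "u", np.array([UNIFORM, UNIFORM]))
        with pytest.warns(UserWarning):
            assert pwm_similarity(u, u) == 0.0


class TestClustering:
    def test_identical_pwms_one_cluster(self):
        pwms = [sharp_pwm("ACGTAC", motif_id=f"m{i}") for i in range(3)]
        clusters = cluster_pwms(pwms)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_dissimilar_pwms_singletons(self):
        a, b = sharp_pwm("AAAAAA", motif_id="a"), sharp_pwm("CGCGCG", motif_id="b")
        assert pwm_similarity(a, b) < 0.8
        assert len(cluster_pwms([a, b])) == 2

    def test_near_duplicates_grouped(self):
        near1 = sharp_pwm("ACGTACGT", motif_id="n1")
        near2 = PWM("n2", "n2", 0.96 * near1.matrix + 0.01)
        others = [sharp_pwm(c, motif_id=f"o{i}") for i, c in enumerate(["AAAATTTT", "CCCCGGGG", "AGAGAGAG"])]
        assert pwm_similarity(near1, near2) > 0.95
        clusters = cluster_pwms([near1, near2] + others)
        assert len(clusters) == 4
        grouped = next(c for c in clusters if len(c.members) == 2)
        assert set(grouped.members) == {"n1", "n2"}

    def test_extreme_cuts(self, rng):
        pwms = [random_pwm(rng, motif_id=f"m{i}") for i in range(5)]
        assert len(cluster_pwms(pwms, cut=1.0 + 1e-9)) == 5
        assert len(cluster_pwms(pwms, cut=-1.0)) == 1

    def test_clusters_partition_input(self, rng):
        pwms = [random_pwm(rng, motif_id=f"m{i}") for i in range(8)]
        clusters = cluster_pwms(pwms)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(p.motif_id for p in pwms)
        for c in clusters:
            assert c.representative in c.members


def _mono_cluster(cid, base, n_cols=6):
    mat = np.full((n_cols, 4), 0.02)
    mat[:, base] = 0.94
    pwm = PWM(f"c{cid}", f"c{cid}", mat)
    return MotifCluster(cid, (f"c{cid}",), f"c{cid}", pwm)


class TestCompositionClusters:
    def test_fly_background_accepted(self):
        clusters = [_mono_cluster(i, i % 4) for i in range(12)]
        out = composition_clusters(clusters, background=FLY_BACKGROUND)
        assign = composition_assignment(out)
        assert sorted(assign) == list(range(12))  # partition

    def test_polyA_polyT_same_cluster(self):
        # A-rich and T-rich compositions are reverse complements: PCC 1.
        # A near-uniform cluster absorbs the bottom-10%-std exclusion.
        weak = MotifCluster(
            12, ("c12",), "c12",
            PWM("c12", "c12", np.full((6, 4), 0.25) + np.array([1e-3, -1e-3, 0, 0])),
        )
        clusters = [_mono_cluster(i, 0) for i in range(3)] + [
            _mono_cluster(i + 3, 3) for i in range(3)
        ] + [_mono_cluster(i + 6, 1) for i in range(6)] + [weak]
        out = composition_clusters(clusters, background=np.full(4, 0.25))
        assign = composition_assignment(out)
        at = {assign[i] for i in range(6)}
        assert len(at) == 1 and "others" not in at

    def test_planted_archetypes_recovered(self, rng):
        bases = [0, 1, 2]
        clusters = []
        truth = {}
        for k, base in enumerate(bases):
            for i in range(6):
                cid = k * 6 + i
                mat = np.full((6, 4), 0.1)
                mat[:, base] = 0.7
                mat += rng.dirichlet(np.ones(4), size=6) * 0.05
                mat /= mat.sum(axis=1, keepdims=True)
                clusters.append(MotifCluster(cid, (f"c{cid}",), f"c{cid}", PWM(f"c{cid}", f"c{cid}", mat)))
                truth[cid] = base
        out = composition_clusters(clusters, background=np.full(4, 0.25))
        assign = composition_assignment(out)
        for k in set(truth.values()):
            labels = {assign[c] for c, b in truth.items() if b == k and assign[c] != "others"}
            assert len(labels) <= 1  # archetype members never split across groups

    def test_min_members_and_partition(self, rng):
        clusters = [_mono_cluster(i, int(rng.integers(4))) for i in range(15)]
        out = composition_clusters(clusters, background=np.full(4, 0.25))
        assign = composition_assignment(out)
        assert sorted(assign) == list(range(15))
        for cc in out:
            if cc.comp_id != "others":
                assert len(cc.members) >= 5


class TestSelectPWM:
    def test_single_candidate_returned(self):
        p = sharp_pwm("ACGTAA", motif_id="only", tf_name="tf")
        out = select_pwm_per_tf([p], lambda pwm: [("chr1", 0, 6)], [make_interval_set([("chr1", 0, 100)])])
        assert out.motif_id == "only"

    def test_inside_beats_outside(self):
        inside = sharp_pwm("ACGTAA", motif_id="in", tf_name="tf")
        outside = sharp_pwm("ACGTAA", motif_id="out", tf_name="tf")
        regions = [make_interval_set([("chr1", 0, 100)])]

        def caller(pwm):
            return [("chr1", 10, 16)] if pwm.motif_id == "in" else [("chr1", 500, 506)]

        assert select_pwm_per_tf([inside, outside], caller, regions).motif_id == "in"

    def test_matches_overlap_oracle(self, rng):
        regions = make_interval_set([("chr1", int(s), int(s) + 50) for s in rng.integers(0, 2000, 8)])
        cands = [sharp_pwm("ACGTAA", motif_id=f"m{i}", tf_name="tf") for i in range(3)]
        sites = {
            f"m{i}": [("chr1", int(s), int(s) + 6) for s in rng.integers(0, 2000, 30)]
            for i in range(3)
        }
        merged = regions["chr1"]

        def frac(mid):
            hits = sum(
                any(s < e2 and e > s2 for s2, e2 in merged) for _, s, e in sites[mid]
            )
            return hits / len(sites[mid])

        best = select_pwm_per_tf(cands, lambda p: sites[p.motif_id], [regions])
        expect = max(sites, key=lambda m: (frac(m), tuple(-ord(c) for c in m)))
        assert best.motif_id == expect

    def test_zero_sites_warns(self):
        a = sharp_pwm("ACGTAA", motif_id="a", tf_name="tf")
        b = sharp_pwm("ACGTAA", motif_id="b", tf_name="tf")
        regions = [make_interval_set([("chr1", 0, 100)])]

        def caller(pwm):
            return [] if pwm.motif_id == "a" else [("chr1", 10, 16)]

        with pytest.warns(UserWarning):
            assert select_pwm_per_tf([a, b], caller, regions).motif_id == "b"
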