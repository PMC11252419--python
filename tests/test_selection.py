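"""Representative selection: distances, heterogeneity, passive/active
picks against brute-force oracles, membership updates, stop criteria."""

import numpy as np
import pytest

from semiprofile import (
    ConfigurationError,
    DataError,
    HeterogeneityConfig,
    active_select,
    bulk_distance,
    check_stop,
    passive_select,
    pb_distance,
    sample_heterogeneity,
    sc_distance,
    update_membership,
)
from semiprofile.bulk import BulkEmbedding, CohortState
from semiprofile.selection import cluster_heterogeneity_table, cohort_difficulty


def embedding_from(coords):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    ids = [f"S{i}" for i in range(coords.shape[0])]
    return BulkEmbedding(coords=coords, n_pcs=coords.shape[1],
                         explained_variance=np.ones(coords.shape[1]),
                         sample_ids=ids)


def state_from(emb, reps):
    assignment = {}
    for s in emb.sample_ids:
        d = [np.linalg.norm(emb.coord(s) - emb.coord(r)) for r in reps]
        assignment[s] = reps[int(np.argmin(d))]
    return CohortState(representatives=list(reps), assignment=assignment,
                       batch_size=len(reps))


class TestDistances:
    def test_bulk_distance_basics(self, rng):
        emb = embedding_from(rng.normal(size=(5, 3)))
        assert bulk_distance("S0", "S0", emb) == 0
        assert bulk_distance("S1", "S3", emb) == bulk_distance("S3", "S1", emb)
        want = np.linalg.norm(emb.coords[1] - emb.coords[3])
        assert bulk_distance("S1", "S3", emb) == pytest.approx(want)
        with pytest.raises(DataError):
            bulk_distance("S0", "NOPE", emb)

    def test_sc_distance_toy_and_properties(self):
        assert sc_distance(np.array([[0.0], [2.0]]),
                           np.array([[0.0], [2.0]]), K=1) == 0
        # 1-D toy: each cell's nearest cross-neighbour is at distance 1
        assert sc_distance(np.array([[0.0], [2.0]]),
                           np.array([[1.0], [3.0]]), K=1) == pytest.approx(1.0)
        with pytest.raises(ConfigurationError):
            sc_distance(np.ones((2, 1)), np.ones((2, 1)), K=3)

    def test_sc_distance_matches_brute_force(self, rng):
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(8, 3))
        K = 2
        d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        want = np.sort(d, axis=1)[:, :K].sum() / a.shape[0]
        assert sc_distance(a, b, K) == pytest.approx(want, rel=1e-9)

    def test_pb_distance(self, rng):
        pb = rng.gamma(2, 5, size=8)
        assert pb_distance(pb, pb) == 0
        other = rng.gamma(2, 5, size=8)
        assert pb_distance(pb, other) == pb_distance(other, pb)
        want = np.linalg.norm(np.log1p(pb) - np.log1p(other))
        assert pb_distance(pb, other) == pytest.approx(want)
        with pytest.raises(DataError):
            pb_distance(pb, other[:4])


class TestHeterogeneity:
    def setup_fixture(self, rng):
        emb = embedding_from(rng.normal(size=(4, 2)))
        state = state_from(emb, ["S0"])
        sc = {s: rng.normal(size=(5, 2)) for s in emb.sample_ids}
        pbs = {s: rng.gamma(2, 5, size=6) for s in emb.sample_ids}
        return emb, state, sc, pbs

    def test_representative_scores_zero(self, rng):
        emb, state, sc, pbs = self.setup_fixture(rng)
        assert sample_heterogeneity("S0", state, emb, sc, pbs) == 0

    def test_lambda_zero_reduces_to_bulk_distance(self, rng):
        emb, state, sc, pbs = self.setup_fixture(rng)
        cfg = HeterogeneityConfig(lambda_sc=0, lambda_pb=0)
        assert sample_heterogeneity("S2", state, emb, cfg=cfg) == pytest.approx(
            bulk_distance("S0", "S2", emb))

    def test_matches_sum_of_terms_oracle(self, rng):
        emb, state, sc, pbs = self.setup_fixture(rng)
        got = sample_heterogeneity("S3", state, emb, sc, pbs)
        want = (bulk_distance("S0", "S3", emb)
                + sc_distance(sc["S0"], sc["S3"], 1)
                + pb_distance(pbs["S0"], pbs["S3"]))
        assert got == pytest.approx(want, rel=1e-9)

    def test_missing_estimate_rejected(self, rng):
        emb, state, sc, pbs = self.setup_fixture(rng)
        with pytest.raises(DataError):
            sample_heterogeneity("S1", state, emb, None, pbs)


class TestPassiveSelect:
    def test_single_candidate_selected(self):
        emb = embedding_from([[0.0], [1.0]])
        state = state_from(emb, ["S0"])
        picked, new_state = passive_select(state, emb, B=1)
        assert picked == ["S1"]
        assert new_state.assignment["S1"] == "S1"

    def test_matches_iterated_argmax_oracle(self, rng):
        emb = embedding_from(rng.normal(size=(10, 2)))
        state = state_from(emb, ["S0"])
        picked, _ = passive_select(state, emb, B=3)
        # oracle: replay the iterated argmax by hand
        reps = ["S0"]
        expect = []
        for _ in range(3):
            assign = {s: min(reps, key=lambda r: np.linalg.norm(
                emb.coord(s) - emb.coord(r))) for s in emb.sample_ids}
            cands = [s for s in emb.sample_ids if s not in reps]
            pick = max(cands, key=lambda s: np.linalg.norm(
                emb.coord(s) - emb.coord(assign[s])))
            expect.append(pick)
            reps.append(pick)
        assert picked == expect

    def test_representatives_never_reselected(self, rng):
        emb = embedding_from(rng.normal(size=(6, 2)))
        state = state_from(emb, ["S0", "S1"])
        picked, _ = passive_select(state, emb, B=4)
        assert set(picked).isdisjoint({"S0", "S1"})

    def test_exhausted_cohort_warns(self):
        emb = embedding_from([[0.0], [1.0]])
        state = state_from(emb, ["S0"])
        with pytest.warns(UserWarning):
            picked, _ = passive_select(state, emb, B=5)
        assert picked == ["S1"]


class TestActiveSelect:
    def coords_two_clusters(self):
        return embedding_from([[0.0], [0.5], [10.0], [10.5], [11.5], [12.0]])

    def make_sc(self, emb, rng, scale=0.0):
        return {s: emb.coord(s) + rng.normal(0, 1e-3, size=(4, 1))
                for s in emb.sample_ids}

    def test_two_sample_cluster_picks_the_only_candidate(self, rng):
        emb = embedding_from([[0.0], [1.0]])
        state = state_from(emb, ["S0"])
        sc = self.make_sc(emb, rng)
        pbs = {s: np.abs(emb.coord(s)) + 1 for s in emb.sample_ids}
        rnd = active_select(state, emb, sc, pbs,
                            HeterogeneityConfig(batch_size=1))
        assert rnd.new_representatives == ["S1"]

    def test_six_sample_cluster_matches_exhaustive_split_oracle(self, rng):
        emb = self.coords_two_clusters()
        state = state_from(emb, ["S0", "S2"])
        sc = self.make_sc(emb, rng)
        pbs = {s: np.abs(emb.coord(s)) + 1 for s in emb.sample_ids}
        rnd = active_select(state, emb, sc, pbs,
                            HeterogeneityConfig(batch_size=1))
        # the right-hand cluster {S2..S5} is the most heterogeneous; oracle
        # enumerates all candidate splits scored by bulk distance
        members = ["S2", "S3", "S4", "S5"]
        best, best_j = np.inf, None
        for j in members[1:]:
            score = sum(min(np.linalg.norm(emb.coord(j) - emb.coord(i)),
                            np.linalg.norm(emb.coord("S2") - emb.coord(i)))
                        for i in members)
            if score < best:
                best, best_j = score, j
        assert rnd.new_representatives == [best_j]

    def test_singleton_clusters_never_chosen(self, rng):
        emb = embedding_from([[0.0], [5.0], [5.5], [6.0]])
        state = state_from(emb, ["S0", "S1"])  # S0 is a singleton cluster
        sc = self.make_sc(emb, rng)
        pbs = {s: np.abs(emb.coord(s)) + 1 for s in emb.sample_ids}
        rnd = active_select(state, emb, sc, pbs,
                            HeterogeneityConfig(batch_size=1))
        assert rnd.new_representatives and rnd.new_representatives[0] != "S0"

    def test_no_splittable_cluster_returns_empty(self, rng):
        emb = embedding_from([[0.0], [1.0]])
        state = state_from(emb, ["S0", "S1"])
        sc = self.make_sc(emb, rng)
        pbs = {s: np.abs(emb.coord(s)) + 1 for s in emb.sample_ids}
        with pytest.warns(UserWarning):
            rnd = active_select(state, emb, sc, pbs,
                                HeterogeneityConfig(batch_size=1))
        assert rnd.new_representatives == []


class TestMembership:
    def test_self_assignment_and_nearest_oracle(self, rng):
        emb = embedding_from(rng.normal(size=(8, 2)))
        state = CohortState(representatives=["S1", "S5"],
                            assignment={s: "S1" for s in emb.sample_ids},
                            batch_size=2)
        new = update_membership(state, emb)
        for s in emb.sample_ids:
            want = min(["S1", "S5"], key=lambda r: np.linalg.norm(
                emb.coord(s) - emb.coord(r)))
            assert new.assignment[s] == want
        assert new.assignment["S1"] == "S1" and new.assignment["S5"] == "S5"

    def test_equidistant_sample_goes_to_lower_index(self):
        emb = embedding_from([[0.0], [1.0], [2.0]])
        state = CohortState(representatives=["S2", "S0"],
                            assignment={"S0": "S0", "S1": "S0", "S2": "S2"},
                            batch_size=2)
        new = update_membership(state, emb)
        assert new.assignment["S1"] == "S0"

    def test_total_bulk_distance_never_increases(self, rng):
        emb = embedding_from(rng.normal(size=(9, 2)))
        reps = ["S0", "S4"]
        bad_assignment = {s: "S0" for s in emb.sample_ids}
        bad_assignment["S4"] = "S4"
        state = CohortState(representatives=reps, assignment=bad_assignment,
                            batch_size=2)
        before = sum(bulk_distance(r, s, emb)
                     for s, r in state.assignment.items())
        new = update_membership(state, emb)
        after = sum(bulk_distance(r, s, emb)
                    for s, r in new.assignment.items())
        assert after <= before + 1e-12


def test_difficulty_non_increasing_as_representatives_added(rng):
    """On separated blobs, adding representatives can only reduce the mean
    single-cell distance to the assigned representative."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
    coords = np.vstack([c + rng.normal(0, 0.2, size=(3, 2)) for c in centers])
    emb = embedding_from(coords)
    sc = {s: emb.coord(s) + rng.normal(0, 0.05, size=(6, 2))
          for s in emb.sample_ids}
    difficulties = []
    for reps in (["S0"], ["S0", "S3"], ["S0", "S3", "S6"],
                 ["S0", "S3", "S6", "S9"]):
        state = update_membership(
            CohortState(representatives=reps,
                        assignment={s: reps[0] for s in emb.sample_ids},
                        batch_size=len(reps)), emb)
        difficulties.append(cohort_difficulty(state, sc, K=1))
    assert all(b <= a + 1e-9 for a, b in zip(difficulties, difficulties[1:]))


class TestCheckStop:
    def test_identical_inputs_stop(self):
        data = {"S0": np.array([0.2, 0.5, 0.3]), "S1": np.array([0.1, 0.6, 0.3])}
        dec = check_stop(data, {k: v.copy() for k, v in data.items()}, level=1)
        assert dec.stop and dec.mean_correlation == pytest.approx(1.0)

    def test_threshold_is_inclusive(self, rng):
        a = rng.normal(size=6)
        b = a + rng.normal(0, 0.8, size=6)
        r = float(np.corrcoef(a, b)[0, 1])
        prev, new = {"S0": a}, {"S0": b}
        assert check_stop(prev, new, threshold=r).stop
        assert not check_stop(prev, new, threshold=r + 1e-9).stop

    def test_correlations_match_direct_pearson(self, rng):
        from scipy import stats

        prev = {f"S{i}": rng.normal(size=8) for i in range(3)}
        new = {f"S{i}": rng.normal(size=8) for i in range(3)}
        dec = check_stop(prev, new, level=2)
        for s in prev:
            assert dec.correlations[s] == pytest.approx(
                stats.pearsonr(prev[s], new[s])[0])

    def test_no_overlap_rejected(self):
        with pytest.raises(DataError):
            check_stop({"A": np.ones(3)}, {"B": np.ones(3)})
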