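import math

import numpy as np
import pytest

import latagg as lg
from latagg.mc import MoveKind, apply_proposal, propose_global, propose_local
from latagg.surface import generate_profile


def enumerate_local_proposals(state):
    """A-priori probability of every reachable local-move outcome.

    Independent re-derivation of the proposal rules: chain and bead picked
    uniformly; ends offer 6 anchor-neighbour targets at 1/6 each; interior
    beads split 1/2 corner flip (deterministic target) and 1/2 crankshaft
    (3 rotations at 1/3 each).  Occupied/out-of-range targets are null.
    Returns {frozen new coordinates of the moved chain: probability}.
    """
    box = state.box
    N, M = state.n_chains, state.chain_length
    out = {}

    def add(chain_idx, bead_idxs, new_sites, p):
        chain = state.chains[chain_idx].copy()
        for i, s in zip(bead_idxs, new_sites):
            if state.occupancy[s] != lg.lattice.EMPTY:
                return  # clash -> null proposal
            chain[i] = s
        key = (chain_idx, chain.tobytes())
        out[key] = out.get(key, 0.0) + p

    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for c in range(N):
        for i in range(M):
            p_bead = 1.0 / (N * M)
            chain = state.chains[c]
            if i in (0, M - 1):
                adj = 1 if i == 0 else M - 2
                for off in offs:
                    raw = chain[adj] + np.array(off)
                    if box.z_wall and not (box.z_min <= raw[2] <= box.z_max):
                        continue
                    t = tuple(box.wrap(raw))
                    if t == tuple(chain[i]):
                        continue
                    add(c, [i], [t], p_bead / 6)
            else:
                a, b = chain[i - 1], chain[i + 1]
                d = np.abs(box.min_image(b - a))
                if d.sum() == 2 and d.max() == 1:
                    raw = chain[i] + box.min_image(a - chain[i]) + box.min_image(
                        b - chain[i])
                    if not box.z_wall or box.z_min <= raw[2] <= box.z_max:
                        add(c, [i], [tuple(box.wrap(raw))], p_bead / 2)
                if i <= M - 3:
                    a2, b2 = chain[i - 1], chain[i + 2]
                    e = box.min_image(b2 - a2)
                    if np.abs(e).sum() == 1:
                        u = box.min_image(chain[i] - a2)
                        for v in (np.cross(e, u), -u, -np.cross(e, u)):
                            raw1, raw2 = a2 + v, b2 + v
                            if box.z_wall and not (
                                box.z_min <= raw1[2] <= box.z_max
                                and box.z_min <= raw2[2] <= box.z_max
                            ):
                                continue
                            add(c, [i, i + 1],
                                [tuple(box.wrap(raw1)), tuple(box.wrap(raw2))],
                                p_bead / 2 / 3)
    return out


class TestMetropolisAcceptance:
    def test_downhill_always_accepted(self, rng):
        assert all(lg.metropolis_accept(-0.5, 0.54, rng) for _ in range(100))
        assert all(lg.metropolis_accept(0.0, 0.54, rng) for _ in range(100))

    @pytest.mark.parametrize(
        "dE,T,expected",
        [(0.54 * math.log(2), 0.54, 0.5), (1.0, 0.54, math.exp(-1 / 0.54))],
    )
    def test_uphill_acceptance_probability(self, dE, T, expected):
        rng = np.random.default_rng(77)
        n = 40_000
        acc = sum(lg.metropolis_accept(dE, T, rng) for _ in range(n)) / n
        assert acc == pytest.approx(expected, abs=4 * math.sqrt(expected / n))

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            lg.metropolis_accept(0.1, 0.0, rng)


class TestProposalSymmetry:
    @pytest.mark.parametrize("z_wall", [False, True])
    def test_local_proposal_probabilities_are_symmetric(self, z_wall, rng):
        """P_propose(A->B) == P_propose(B->A) for every local move."""
        if z_wall:
            box = lg.SimulationBox(8, 8, 8, z_wall=True)
            surf = generate_profile("S", 0.2, (8, 8), "Ps", 5)
        else:
            box, surf = lg.SimulationBox(8, 8, 8), None
        state = lg.place_random_chains(2, lg.DEFAULT_SEQUENCE, box,
                                       surface=surf, rng_seed=21)
        model = lg.InteractionModel(eps_ps=1.0)
        checked = 0
        while checked < 25:
            prop = propose_local(state, rng)
            if prop.rejected_by_geometry or prop.is_null():
                continue
            fwd = enumerate_local_proposals(state)
            after = state.copy()
            apply_proposal(after, prop)
            after.validate()
            rev = enumerate_local_proposals(after)
            key_fwd = (prop.chain_index, after.chains[prop.chain_index].tobytes())
            key_rev = (prop.chain_index, state.chains[prop.chain_index].tobytes())
            assert key_fwd in fwd and key_rev in rev
            assert fwd[key_fwd] == pytest.approx(rev[key_rev], abs=1e-12)
            state = after
            checked += 1

    def test_global_rotation_fixes_pivot_and_reverses(self, rng):
        state = lg.place_random_chains(1, lg.DEFAULT_SEQUENCE,
                                       lg.SimulationBox(14, 14, 14), rng_seed=2)
        found = 0
        while found < 20:
            prop = propose_global(state, rng)
            if prop.rejected_by_geometry or prop.kind != MoveKind.RIGID_ROTATION:
                continue
            old, new = prop.old_pos, prop.new_pos
            # the pivot bead maps to itself
            assert any(np.array_equal(old[i], new[i]) for i in range(len(old)))
            found += 1

    def test_translation_of_isolated_chain_always_legal(self, rng):
        state = lg.place_random_chains(1, lg.DEFAULT_SEQUENCE,
                                       lg.SimulationBox(12, 12, 12), rng_seed=3)
        model = lg.InteractionModel()
        for _ in range(50):
            prop = propose_global(state, rng)
            if prop.kind == MoveKind.RIGID_TRANSLATION:
                assert not prop.rejected_by_geometry
                assert lg.delta_energy(state, prop, model) == 0.0

    def test_rotation_into_wall_rejected(self, rng):
        # a horizontal rod in the top layer cannot rotate upward
        box = lg.SimulationBox(8, 8, 8, z_wall=True)
        prof = generate_profile("smooth", 0.0, (8, 8), "Ps", 0)
        seq = lg.parse_sequence("HPPH")
        chains = np.array([[(2 + i, 4, 7) for i in range(4)]], dtype=np.int64)
        state = lg.SystemState(sequence=seq, chains=chains, box=box, surface=prof)
        saw_wall_rejection = False
        for _ in range(400):
            prop = propose_global(state, rng)
            if prop.kind == MoveKind.RIGID_ROTATION and prop.rejected_by_geometry:
                saw_wall_rejection = True
            if not prop.rejected_by_geometry:
                assert prop.new_pos[:, 2].max() <= box.z_max
                assert prop.new_pos[:, 2].min() >= box.z_min
        assert saw_wall_rejection


class TestTrajectories:
    def test_zero_budget_returns_initial_measurement_only(self, model):
        st = lg.place_random_chains(2, lg.DEFAULT_SEQUENCE,
                                    lg.SimulationBox(10, 10, 10), rng_seed=1)
        rec = lg.run_trajectory(st, model, lg.MCConfig(max_mcs=0, seed=0))
        assert list(rec.mcs) == [0]
        assert len(rec.energies) == 1

    def test_same_seed_identical_trajectory(self, model):
        st = lg.place_random_chains(3, lg.DEFAULT_SEQUENCE,
                                    lg.SimulationBox(10, 10, 10), rng_seed=4)
        cfg = lg.MCConfig(temperature=0.54, max_mcs=30_000, measure_every=500, seed=17)
        a = lg.run_trajectory(st, model, cfg)
        b = lg.run_trajectory(st, model, cfg)
        assert np.array_equal(a.final_state.chains, b.final_state.chains)
        assert [e.e_total for e in a.energies] == [e.e_total for e in b.energies]
        c = lg.run_trajectory(st, model, lg.MCConfig(
            temperature=0.54, max_mcs=30_000, measure_every=500, seed=18))
        assert not np.array_equal(a.final_state.chains, c.final_state.chains)

    def test_acceptance_rate_decreases_with_temperature(self, model):
        st = lg.place_random_chains(4, lg.DEFAULT_SEQUENCE,
                                    lg.SimulationBox(10, 10, 10), rng_seed=6)
        rates = []
        for T in (0.8, 0.54, 0.35, 0.2):
            accs = [
                lg.run_trajectory(st, model, lg.MCConfig(
                    temperature=T, max_mcs=40_000, measure_every=40_000, seed=s)
                ).acceptance_rate
                for s in (1, 2, 3)
            ]
            rates.append(np.mean(accs))
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_sweep_mode_attempt_accounting(self, model):
        st = lg.place_random_chains(2, lg.DEFAULT_SEQUENCE,
                                    lg.SimulationBox(10, 10, 10), rng_seed=4)
        cfg = lg.MCConfig(max_mcs=1000, measure_every=100, seed=5, sweep_mode=True)
        rec = lg.run_trajectory(st, model, cfg)
        assert rec.config.to_metadata()["mcs_mode"] == "sweep"
        rec.final_state.validate()


class TestBoltzmannSampling:
    def test_five_bead_chain_matches_exact_distribution(self):
        """Thinned MC occupancy of energy levels vs exact Boltzmann weights."""
        from scipy.stats import chisquare

        from latagg import _kernels

        L, T = 5, 0.5
        seq = lg.parse_sequence("+HPHH")
        model = lg.InteractionModel()
        mat = model.table.matrix

        def mi(d):
            d %= L
            return d - L if d > L // 2 else d

        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        states = []

        def grow(walk):
            if len(walk) == 5:
                states.append(list(walk))
                return
            x, y, z = walk[-1]
            for dx, dy, dz in offs:
                n = ((x + dx) % L, (y + dy) % L, (z + dz) % L)
                if n not in walk:
                    walk.append(n)
                    grow(walk)
                    walk.pop()

        grow([(0, 0, 0)])

        def energy(w):
            e = 0.0
            for i in range(5):
                for j in range(i + 2, 5):
                    d = sum(abs(mi(w[j][k] - w[i][k])) for k in range(3))
                    if d == 1:
                        e += mat[seq[i], seq[j]]
            return e

        es = np.array([energy(w) for w in states])
        levels = np.unique(np.round(es, 10))
        w = np.exp(-es / T)
        probs = np.array([w[np.isclose(es, lv)].sum() for lv in levels]) / w.sum()

        box = lg.SimulationBox(L, L, L)
        st = lg.SystemState(sequence=seq,
                            chains=np.array(states[0]).reshape(1, 5, 3), box=box)
        e_min = float(levels.min())
        n_bins = int(round((levels.max() - e_min) / 0.05)) + 1
        counts = _kernels.run_energy_histogram(
            st.chains.copy(), st.occupancy.copy(), st.sequence, mat, np.zeros(4),
            False, 0, T, 0.1, 1_500_000, 10_000, 150, 4242, e_min, n_bins)
        obs = np.array([counts[int(round((lv - e_min) / 0.05))] for lv in levels],
                       dtype=float)
        assert obs.sum() == counts.sum()  # every sample fell on a known level
        keep = probs * obs.sum() >= 5
        expected = probs[keep] * obs[keep].sum() / probs[keep].sum()
        _, p = chisquare(obs[keep], expected)
        assert p > 0.01
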