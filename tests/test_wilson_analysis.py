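"""Wilson loops, gauges, vibronic plaquettes, Lang-Firsov."""

import numpy as np
import pytest

import ciss_wilson as cw
from ciss_wilson.model_builder import ModeSpec, PeierlsCoupling
from ciss_wilson.spin_algebra import ID2, PAULI, pauli_dot, su2_from_axis_angle

Z = np.array([0.0, 0.0, 1.0])


class TestLinks:
    def test_no_soc_gives_identity_links(self):
        chain = cw.single_channel_chain(4, 0.1, 0.0)
        for u in cw.extract_links(chain).values():
            np.testing.assert_allclose(u.matrix, ID2, atol=1e-14)

    def test_reverse_orientation_is_inverse(self):
        chain, _ = cw.generate_random_model(12, 6)
        links = cw.extract_links(chain)
        for b in chain.bonds:
            prod = links[(b.i, b.j)].matrix @ links[(b.j, b.i)].matrix
            np.testing.assert_allclose(prod, ID2, atol=1e-13)

    def test_links_match_bond_decomposition(self):
        chain, _ = cw.generate_random_model(21, 6)
        links = cw.extract_links(chain)
        for b in chain.bonds:
            ref = cw.decompose_bond(b.t, b.lam, b.axis).rotation.matrix
            np.testing.assert_allclose(links[(b.i, b.j)].matrix, ref, atol=1e-14)


class TestLoopProduct:
    def test_back_and_forth_is_identity(self):
        chain, _ = cw.generate_random_model(4, 5)
        rep = cw.loop_product([1, 2, 3, 2, 1], cw.extract_links(chain))
        assert rep.trivial
        np.testing.assert_allclose(rep.loop_matrix, ID2, atol=1e-13)

    def test_open_path_rejected(self):
        chain, _ = cw.generate_random_model(4, 5)
        with pytest.raises(ValueError):
            cw.loop_product([1, 2, 3], cw.extract_links(chain))

    def test_missing_link_rejected(self):
        chain = cw.single_channel_chain(4, 0.1, 1e-3)
        with pytest.raises(KeyError):
            cw.loop_product([1, 3, 1], cw.extract_links(chain))

    def test_reversal_inverts_and_cyclic_shift_keeps_trace(self):
        chain = cw.multichannel_chain(6, 0.13, 2e-3, axes=np.array([0.3, -0.5, 0.9]))
        links = cw.extract_links(chain)
        fwd = cw.loop_product([2, 3, 4, 2], links)
        rev = cw.loop_product([2, 4, 3, 2], links)
        np.testing.assert_allclose(fwd.loop_matrix @ rev.loop_matrix, ID2, atol=1e-13)
        shifted = cw.loop_product([3, 4, 2, 3], links)
        assert shifted.trace == pytest.approx(fwd.trace, abs=1e-13)

    def test_trace_gauge_invariant_under_site_rotations(self):
        # conjugating every link by site-local rotations leaves |Tr W(C)|
        rng = np.random.default_rng(8)
        chain = cw.multichannel_chain(5, 0.1, 1e-3)
        links = cw.extract_links(chain)
        for _ in range(100):
            v = {
                s: su2_from_axis_angle(rng.uniform(0, np.pi), rng.normal(size=3)).matrix
                for s in range(1, 6)
            }
            rotated = {
                (i, j): cw.SpinRotation(
                    v[i].conj().T @ u.matrix @ v[j], u.angle, u.axis
                )
                for (i, j), u in links.items()
            }
            for j in (1, 2, 3):
                path = [j, j + 1, j + 2, j]
                t0 = cw.loop_product(path, links).trace
                t1 = cw.loop_product(path, rotated).trace
                assert abs(t1) == pytest.approx(abs(t0), abs=1e-12)


class TestElementaryLoops:
    def test_open_nn_chain_has_no_loops(self):
        assert cw.enumerate_elementary_loops(cw.single_channel_chain(6, 0.1, 1e-3)) == []

    def test_nn_nnn_chain_has_one_triangle_per_interior_site(self, benchmark_chain):
        loops = cw.enumerate_elementary_loops(benchmark_chain)
        assert len(loops) == 4
        assert {l.vertices for l in loops} == {
            (1, 2, 3, 1), (2, 3, 4, 2), (3, 4, 5, 3), (4, 5, 6, 4)
        }

    def test_ring_has_single_traversal_loop(self):
        ring = cw.single_channel_chain(6, 0.1, 1e-3, topology="ring")
        loops = cw.enumerate_elementary_loops(ring)
        assert len(loops) == 1 and loops[0].vertices == (1, 2, 3, 4, 5, 6, 1)


class TestPlaquette:
    def test_uniform_plaquette_has_zero_trace(self, benchmark_chain):
        rep = cw.plaquette_loop(2, benchmark_chain)
        assert not rep.trivial
        assert abs(rep.trace) < 1e-13
        # W = exp(i*(pi/2)*(n.sigma))
        assert rep.phase == pytest.approx(np.pi / 2, abs=1e-12)

    def test_no_soc_plaquette_is_identity(self):
        chain = cw.ChainSpec(
            3, (0.0,) * 3,
            (cw.Bond(1, 2, 0.1, 0.0), cw.Bond(2, 3, 0.1, 0.0), cw.Bond(1, 3, 0.05, 0.0)),
        )
        assert cw.plaquette_loop(1, chain).trivial

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            bonds = []
            for (i, j) in [(1, 2), (2, 3), (1, 3)]:
                bonds.append(
                    cw.Bond(i, j, rng.uniform(0.05, 0.2), rng.uniform(1e-4, 1e-2),
                            tuple(rng.normal(size=3)))
                )
            chain = cw.ChainSpec(3, (0.0,) * 3, tuple(bonds))
            links = cw.extract_links(chain)
            brute = (
                links[(1, 2)].matrix
                @ links[(2, 3)].matrix
                @ np.linalg.inv(links[(1, 3)].matrix)
            )
            np.testing.assert_allclose(
                cw.plaquette_loop(1, chain).loop_matrix, brute, atol=1e-13
            )

    def test_missing_bond_rejected(self):
        chain = cw.single_channel_chain(4, 0.1, 1e-3)
        with pytest.raises(KeyError):
            cw.plaquette_loop(1, chain)


class TestVibronicLoop:
    def test_manifold_is_trivial(self):
        rep = cw.vibronic_wilson_loop(0.1, 1e-3, Z, 0.02, 0.02 * 1e-3 / 0.1)
        assert rep.trivial and abs(rep.phase) < 1e-12

    def test_chi_zero_is_nontrivial(self):
        rep = cw.vibronic_wilson_loop(0.1, 1e-3, Z, 0.02, 0.0)
        assert not rep.trivial and abs(rep.phase) > 1e-3

    def test_no_phonon_path_rejected(self):
        with pytest.raises(ValueError, match="phonon-assisted"):
            cw.vibronic_wilson_loop(0.1, 1e-3, Z, 0.0, 0.0)

    def test_interference_on_manifold_is_one(self):
        assert cw.interference_term(0.1, 1e-3, Z, 0.03, 0.03 * 1e-3 / 0.1) == pytest.approx(1.0)

    def test_quarter_phase_gives_zero_interference(self):
        # phi_vib = 2*(phi_dir - phi_G) = pi/2 by construction
        t, lam = 0.1, 0.1  # phi_dir = pi/4
        g, chi = 1.0, 0.0  # phi_G = 0
        assert cw.interference_term(t, lam, Z, g, chi) == pytest.approx(0.0, abs=1e-12)

    def test_interference_matches_two_path_phases(self):
        # cos(Phi_vib) = cos(phi_dir + phi_bos) for random dimers
        rng = np.random.default_rng(23)
        for _ in range(100):
            t, lam = rng.uniform(0.05, 0.2), rng.uniform(1e-4, 1e-2)
            g, chi = rng.uniform(0, 0.04), rng.uniform(0, 0.02)
            if g == 0 and chi == 0:
                continue
            v = rng.normal(size=3)
            lhs = cw.interference_term(t, lam, v, g, chi)
            phi_dir, phi_bos = cw.dimer_phases(t, lam, v, g, chi)
            assert lhs == pytest.approx(np.cos(phi_dir + phi_bos), abs=1e-10)

    def test_manifold_factorization_of_bond_operator_strings(self):
        # on g/t = chi/lam every bond operator is T(X) = f(X)*T0 with real
        # f(X) = (t + g*X)/t, so a string of k of them is (prod f) * T0^k:
        # every vibronic trajectory carries the same SU(2) rotation
        rng = np.random.default_rng(31)
        t, lam, g = 0.12, 5e-3, 0.025
        chi = g * lam / t
        v = np.array([0.2, -0.4, 0.89])
        t0 = -t * ID2 + 1j * lam * pauli_dot(v)
        for k in (1, 2, 3, 4):
            for _ in range(20):
                xs = rng.uniform(-2, 2, size=k)
                m = ID2.copy()
                for x in xs:
                    m = m @ (-(t + g * x) * ID2 + 1j * (lam + chi * x) * pauli_dot(v))
                scalar = np.prod((t + g * xs) / t)
                ref = scalar * np.linalg.matrix_power(t0, k)
                np.testing.assert_allclose(m, ref, atol=1e-12)


class TestGauge:
    def test_identity_gauge_is_noop(self):
        chain, _ = cw.generate_random_model(2, 5)
        h = cw.build_electronic(chain)
        gauge = cw.GaugeMap(np.broadcast_to(ID2, (5, 2, 2)).copy())
        np.testing.assert_allclose(cw.apply_gauge(h, gauge).matrix, h.matrix, atol=1e-14)

    def test_two_site_gauge_is_inverse_link(self):
        chain = cw.single_channel_chain(2, 0.1, 5e-3, axes=np.array([1.0, 1.0, 0.0]))
        gauge = cw.build_site_gauge(chain)
        u = cw.extract_links(chain)[(1, 2)]
        np.testing.assert_allclose(gauge.rotations[1], u.matrix.conj().T, atol=1e-14)

    def test_gauge_removes_spin_dependence(self):
        chain, _ = cw.generate_random_model(42, 8)
        h = cw.build_electronic(chain)
        ht = cw.apply_gauge(h, cw.build_site_gauge(chain))
        # transformed NN blocks are -R_j * I
        links = cw.extract_links(chain)
        for b in chain.bonds:
            blk = ht.matrix[2 * (b.i - 1): 2 * b.i, 2 * (b.j - 1): 2 * b.j]
            r = cw.decompose_bond(b.t, b.lam, b.axis).amplitude
            np.testing.assert_allclose(blk, -r * ID2, atol=1e-13)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(h.matrix), np.linalg.eigvalsh(ht.matrix), atol=1e-12
        )

    def test_multichannel_gauge_rejected(self, benchmark_chain):
        with pytest.raises(ValueError):
            cw.build_site_gauge(benchmark_chain)

    def test_gauge_acts_through_boson_factor(self):
        chain, _ = cw.generate_random_model(6, 4)
        mode = ModeSpec(0.05, (), tuple(PeierlsCoupling(b.key, 0.01, 0.0) for b in chain.bonds))
        hv = cw.build_vibronic(chain, [mode], 3)
        ht = cw.apply_gauge(hv, cw.build_site_gauge(chain))
        np.testing.assert_allclose(
            np.linalg.eigvalsh(hv.matrix), np.linalg.eigvalsh(ht.matrix), atol=1e-12
        )


class TestSymmetryManifold:
    def test_tenth_couplings_on_manifold(self, bridge_chain):
        mode = ModeSpec(
            0.05, (), tuple(PeierlsCoupling(b.key, b.t / 10, b.lam / 10) for b in bridge_chain.bonds)
        )
        report = cw.check_gauge_condition(bridge_chain, [mode])
        assert report.on_manifold and all(ok for *_, ok in report.entries)

    def test_chi_zero_off_manifold(self, bridge_chain):
        mode = ModeSpec(0.05, (), (PeierlsCoupling((1, 2), 0.02, 0.0),))
        assert not cw.check_gauge_condition(bridge_chain, [mode]).on_manifold

    def test_no_peierls_trivially_on_manifold(self, bridge_chain):
        report = cw.check_gauge_condition(bridge_chain, [ModeSpec(0.05, (0.01,) * 4)])
        assert report.on_manifold and report.entries == ()

    def test_report_agrees_with_vibronic_loop_for_seeded_dimers(self):
        rng = np.random.default_rng(77)
        for k in range(100):
            t, lam = rng.uniform(0.05, 0.2), rng.uniform(1e-4, 1e-2)
            if k % 2:
                g = rng.uniform(0.005, 0.04)
                chi = g * lam / t  # exactly on-manifold
            else:
                g, chi = rng.uniform(0.005, 0.04), rng.uniform(0.001, 0.02)
            chain = cw.single_channel_chain(2, t, lam)
            mode = ModeSpec(0.05, (), (PeierlsCoupling((1, 2), g, chi),))
            flag = cw.check_gauge_condition(chain, [mode]).on_manifold
            loop = cw.vibronic_wilson_loop(t, lam, Z, g, chi)
            assert flag == loop.trivial

    def test_effective_soc_closed_form(self):
        v = np.array([0.1, 0.2, 0.97])
        np.testing.assert_allclose(
            cw.effective_dimer_soc(0.1, 1e-3, 0.02, 0.0, v), 1e-3 * 0.02 * v
        )
        g = 0.02
        chi = g * 1e-3 / 0.1
        assert np.all(cw.effective_dimer_soc(0.1, 1e-3, g, chi, v) == 0.0)
        plus = cw.effective_dimer_soc(0.1, 1e-3, g, chi + 0.003, v)
        minus = cw.effective_dimer_soc(0.1, 1e-3, g, chi - 0.003, v)
        np.testing.assert_allclose(plus, -minus, atol=1e-15)


class TestLangFirsov:
    def test_zero_coupling_is_identity(self):
        chain = cw.single_channel_chain(2, 0.1, 1e-3)
        h = cw.build_vibronic(chain, [ModeSpec(0.05, (0.0, 0.0))], 5)
        np.testing.assert_allclose(cw.lang_firsov(h).matrix, h.matrix, atol=1e-13)

    def test_onsite_shift_minus_g_squared_over_omega(self):
        # one coupled, nearly-decoupled site: vacuum diagonal shifts by -g^2/w
        chain = cw.ChainSpec(2, (0.0, 0.0), (cw.Bond(1, 2, 0.0, 1e-5),))
        g, w = 0.02, 0.05
        h = cw.build_vibronic(chain, [ModeSpec(w, (g, 0.0))], 30)
        ht = cw.lang_firsov(h)
        i = h.space.flat_index(1, 0, (0,))
        assert ht.matrix[i, i].real == pytest.approx(-g**2 / w + w / 2, abs=1e-10)

    def test_spectrum_preserved_seeded_dimers(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            chain = cw.single_channel_chain(
                2, rng.uniform(0.05, 0.2), rng.uniform(1e-4, 1e-2)
            )
            mode = ModeSpec(
                float(rng.uniform(0.025, 0.1)), tuple(rng.uniform(0, 0.04, size=2))
            )
            h = cw.build_vibronic(chain, [mode], 30)
            ht = cw.lang_firsov(h)
            np.testing.assert_allclose(
                np.linalg.eigvalsh(h.matrix), np.linalg.eigvalsh(ht.matrix), atol=1e-8
            )

    def test_peierls_rejected(self):
        chain = cw.single_channel_chain(2, 0.1, 1e-3)
        mode = ModeSpec(0.05, (0.01, 0.0), (PeierlsCoupling((1, 2), 0.01, 0.0),))
        h = cw.build_vibronic(chain, [mode], 4)
        with pytest.raises(ValueError, match="Holstein"):
            cw.lang_firsov(h)
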