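"""FEM operator properties, closed-form slab solutions and physical laws."""

import numpy as np
import pytest

from tesvox import fem
from tesvox.errors import BoundaryConditionError, ConfigurationError
from tesvox.phantoms import PhantomSpec, add_plate_electrodes, make_layered_sphere, make_slab
from tesvox.volumes import AIR, GM, SKULL, LabeledVolume


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

class TestElementStiffness:
    def test_rows_sum_to_zero(self):
        for h in ([1e-3] * 3, [1e-3, 2e-3, 0.5e-3]):
            K = fem.hex_stiffness(np.array(h))
            assert np.allclose(K.sum(axis=1), 0.0, atol=1e-18)
            assert np.allclose(K, K.T)

    def test_quadrature_is_exact(self):
        h = np.array([1.3e-3, 0.7e-3, 2.1e-3])
        K2 = fem.hex_stiffness(h, n_gauss=2)
        K4 = fem.hex_stiffness(h, n_gauss=4)
        assert np.allclose(K2, K4, rtol=1e-12)

    def test_tet_split_rows_sum_to_zero(self):
        K = fem.tet_equivalent_stiffness(np.array([1e-3, 1e-3, 1e-3]))
        assert np.allclose(K.sum(axis=1), 0.0, atol=1e-18)
        assert np.allclose(K, K.T)

    def test_linear_field_energy_agrees_between_discretizations(self):
        # both elements reproduce a linear voltage V = g . x exactly, so the
        # energy g^T K g must equal sigma |g|^2 * volume for both
        h = np.array([1e-3, 1.5e-3, 0.8e-3])
        corners = fem.CORNERS * h
        for g in (np.array([1.0, 0, 0]), np.array([0.3, -1.2, 0.7])):
            v = corners @ g
            vol = np.prod(h)
            for K in (fem.hex_stiffness(h), fem.tet_equivalent_stiffness(h)):
                assert v @ K @ v == pytest.approx(vol * g @ g, rel=1e-12)


# ---------------------------------------------------------------------------
# slab closed forms
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cube_solution(cube_slab):
    vol, plates = add_plate_electrodes(cube_slab)
    table = fem.ConductivityTable.default(gm=0.3, electrode=100.0)
    system = fem.assemble(vol, table)
    system = fem.apply_current_bc(system, plates, {"top": 1.0, "bottom": -1.0})
    sol = fem.solve(system, tol=1e-10)
    return vol, sol


class TestCubeClosedForm:
    def test_uniform_field_magnitude(self, cube_solution):
        # I / (sigma A) = 1e-3 / (0.3 * 0.05^2) = 1.3333... V/m in the tissue
        vol, sol = cube_solution
        # plate edges inject a little current through their side faces, so the
        # field is uniform to ~1%, not to machine precision
        mag = sol.E.magnitude()[vol.data == GM]
        expected = 1e-3 / (0.3 * 0.05**2)
        assert np.allclose(mag, expected, rtol=0.01)
        assert mag.mean() == pytest.approx(expected, rel=0.002)
        assert expected == pytest.approx(4.0 / 3.0, rel=1e-9)

    def test_field_is_axial(self, cube_solution):
        vol, sol = cube_solution
        E = sol.E.data[vol.data == GM]
        assert np.abs(E[:, :2]).max() < 0.005 * np.abs(E[:, 2]).max()

    def test_plane_current_equals_injected(self, cube_solution):
        vol, sol = cube_solution
        kz = np.nonzero((vol.data == GM).any(axis=(0, 1)))[0]
        mid = int(kz.mean())
        I = fem.current_through_plane(sol, axis=2, index=mid)
        assert abs(I) == pytest.approx(1e-3, rel=1e-6)

    def test_total_voltage_drop(self, cube_solution):
        # V = I R = I * L / (sigma A) across the 50 mm of tissue
        vol, sol = cube_solution
        v = sol.voltage_volume()
        gm = vol.data == GM
        kz = np.nonzero(gm.any(axis=(0, 1)))[0]
        top = v[:, :, kz.max()][gm[:, :, kz.max()]].mean()
        bot = v[:, :, kz.min()][gm[:, :, kz.min()]].mean()
        # voxel centers sit h/2 inside each face: 48 mm between sampled planes
        expected = 1e-3 * 0.048 / (0.3 * 0.05**2)
        assert abs(top - bot) == pytest.approx(expected, rel=1e-6)


@pytest.fixture(scope="module")
def layered_slab_solution():
    spec = PhantomSpec(
        kind="slab", thicknesses_mm=(20.0, 30.0), tissues=("gm", "skull"),
        voxel_mm=2.0, slab_size_mm=(40.0, 40.0), margin_voxels=3,
    )
    vol, plates = add_plate_electrodes(make_slab(spec))
    table = fem.ConductivityTable.default()
    system = fem.assemble(vol, table)
    system = fem.apply_current_bc(system, plates, {"top": 1.0, "bottom": -1.0})
    sol = fem.solve(system, tol=1e-10)
    return vol, sol, table


class TestLayeredSlab:
    def test_voltage_drop_ratio(self, layered_slab_solution):
        vol, sol, table = layered_slab_solution
        v = sol.voltage_volume()
        drops = {}
        for tissue, t_mm in ((GM, 20.0), (SKULL, 30.0)):
            mask = vol.data == tissue
            kz = np.nonzero(mask.any(axis=(0, 1)))[0]
            # per-layer mean voltage over the full cross-section
            col = [v[:, :, k][mask[:, :, k]].mean() for k in kz]
            # extrapolate the half-voxel at each end: uniform gradient inside
            # a layer makes drop = (span between centers) * n/(n-1) exact
            n = len(col)
            drops[tissue] = abs(col[-1] - col[0]) * n / (n - 1)
        expected = (20.0 / table[GM]) / (30.0 / table[SKULL])
        assert drops[GM] / drops[SKULL] == pytest.approx(expected, rel=1e-6)

    def test_field_jump_matches_conductivity_ratio(self, layered_slab_solution):
        # sigma_1 E_1n = sigma_2 E_2n across the interface
        vol, sol, table = layered_slab_solution
        Ez_gm = sol.E.data[vol.data == GM, 2].mean()
        Ez_sk = sol.E.data[vol.data == SKULL, 2].mean()
        assert Ez_gm * table[GM] == pytest.approx(Ez_sk * table[SKULL], rel=1e-6)
        assert abs(Ez_sk) > 5 * abs(Ez_gm)  # |E| genuinely discontinuous


# ---------------------------------------------------------------------------
# conservation, linearity, scaling, superposition
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sphere_system(small_sphere):
    from tesvox.electrodes import ElectrodeSpec, place_electrode
    from tesvox.validation import _surface_point

    vol = small_sphere
    voxmap = {}
    for name, direction, cur in (
        ("a", (0.0, 0.0, 1.0), 1.0),
        ("b", (0.0, 0.7, -0.7), -1.0),
    ):
        d = np.asarray(direction) / np.linalg.norm(direction)
        pos = _surface_point(vol, d)
        vol, body = place_electrode(
            vol, ElectrodeSpec(id=name, current_mA=cur), pos
        )
        voxmap[name] = body
    table = fem.ConductivityTable.default()
    system = fem.assemble(vol, table)
    return vol, system, voxmap, table


class TestConservationAndLinearity:
    TOL = 1e-9

    def _solve(self, system, voxmap, currents, tol=1e-9):
        s = fem.apply_current_bc(system, voxmap, currents)
        return fem.solve(s, tol=tol)

    def test_load_sums_to_zero(self, sphere_system):
        _, system, voxmap, _ = sphere_system
        s = fem.apply_current_bc(system, voxmap, {"a": 1.0, "b": -1.0})
        assert abs(s.load.sum()) < 1e-12

    def test_anode_load_is_exactly_the_current(self, sphere_system):
        _, system, voxmap, _ = sphere_system
        s = fem.apply_current_bc(system, voxmap, {"a": 1.0, "b": -1.0})
        assert s.load[s.load > 0].sum() == pytest.approx(1e-3, abs=1e-12)

    def test_current_linearity(self, sphere_system):
        _, system, voxmap, _ = sphere_system
        v1 = self._solve(system, voxmap, {"a": 1.0, "b": -1.0}).voltages
        v2 = self._solve(system, voxmap, {"a": 2.0, "b": -2.0}).voltages
        assert np.allclose(v2, 2.0 * v1, atol=10 * self.TOL * np.abs(v1).max())

    def test_conductivity_scaling(self, sphere_system):
        vol, system, voxmap, table = sphere_system
        v1 = self._solve(system, voxmap, {"a": 1.0, "b": -1.0}).voltages
        k = 3.0
        system_k = fem.assemble(vol, table.scaled(k))
        vk = self._solve(system_k, voxmap, {"a": 1.0, "b": -1.0}).voltages
        assert np.allclose(vk, v1 / k, atol=10 * self.TOL * np.abs(v1).max())

    def test_superposition(self, sphere_system):
        _, system, voxmap, _ = sphere_system
        va = self._solve(system, voxmap, {"a": 1.0, "b": -1.0}).voltages
        vb = self._solve(system, voxmap, {"a": 0.5, "b": -0.5}).voltages
        vc = self._solve(system, voxmap, {"a": 1.5, "b": -1.5}).voltages
        assert np.allclose(va + vb, vc, atol=10 * self.TOL * np.abs(vc).max())

    def test_unbalanced_currents_rejected(self, sphere_system):
        _, system, voxmap, _ = sphere_system
        with pytest.raises(ConfigurationError):
            fem.apply_current_bc(system, voxmap, {"a": 1.0, "b": -0.5})

    def test_buried_electrode_rejected(self, small_sphere):
        # a fully interior voxel set has no face exposed to background
        table = fem.ConductivityTable.default()
        system = fem.assemble(small_sphere, table)
        center = small_sphere.voxel_index(np.zeros(3)).reshape(1, 3)
        edge = np.argwhere(small_sphere.data == 5)[:1]
        with pytest.raises(BoundaryConditionError):
            fem.apply_current_bc(
                system, {"a": center, "b": edge}, {"a": 1.0, "b": -1.0}
            )


# ---------------------------------------------------------------------------
# domain handling and adapted meshes
# ---------------------------------------------------------------------------

class TestDomain:
    def test_air_cavities_excluded(self, small_sphere):
        vol = small_sphere.copy()
        center = vol.voxel_index(np.zeros(3))
        sl = tuple(slice(c - 1, c + 2) for c in center)
        vol.data[sl] = AIR
        system = fem.assemble(vol, fem.ConductivityTable.default())
        labs = vol.data[system.elem_ijk[:, 0], system.elem_ijk[:, 1],
                        system.elem_ijk[:, 2]]
        assert AIR not in labs
        assert len(system.elem_ijk) == int((vol.data != 0).sum() - 27)

    def test_missing_conductivity_raises(self, small_sphere):
        table = fem.ConductivityTable({GM: 0.3})
        with pytest.raises(ConfigurationError):
            fem.assemble(small_sphere, table)

    def test_nonpositive_conductivity_rejected(self):
        with pytest.raises(ConfigurationError):
            fem.ConductivityTable({GM: -1.0})

    def test_sigma_voxels_override(self, cube_slab):
        vol, plates = add_plate_electrodes(cube_slab)
        table = fem.ConductivityTable.default(gm=0.3)
        from tesvox.volumes import ELECTRODE

        # double every conductivity: the solution must exactly halve
        override = np.zeros(vol.data.shape)
        override[vol.data == GM] = 0.6
        override[vol.data == ELECTRODE] = 200.0
        s0 = fem.apply_current_bc(
            fem.assemble(vol, table), plates, {"top": 1.0, "bottom": -1.0})
        s1 = fem.apply_current_bc(
            fem.assemble(vol, table, sigma_voxels=override), plates,
            {"top": 1.0, "bottom": -1.0})
        E0 = fem.solve(s0, tol=1e-10).E.data[vol.data == GM, 2]
        E1 = fem.solve(s1, tol=1e-10).E.data[vol.data == GM, 2]
        assert np.allclose(E1, E0 / 2.0, rtol=1e-6)


class TestAdaptedMesh:
    def test_adapted_nodes_land_on_surfaces(self, small_sphere):
        from tesvox.validation import shell_projectors

        table = fem.ConductivityTable.default()
        system = fem.assemble(
            small_sphere, table,
            adapt_surfaces=shell_projectors((20.0, 24.0, 30.0)),
        )
        assert system.node_positions_mm is not None
        r = np.linalg.norm(system.node_world_mm(), axis=1)
        # many nodes now sit exactly on a shell radius
        on_surface = np.zeros(len(r), dtype=bool)
        for R in (20.0, 24.0, 30.0):
            on_surface |= np.abs(r - R) < 1e-9
        assert on_surface.sum() > 500

    def test_adapted_mesh_stays_valid(self, small_sphere):
        from tesvox.fem import _min_det_jacobian
        from tesvox.validation import shell_projectors

        table = fem.ConductivityTable.default()
        system = fem.assemble(
            small_sphere, table,
            adapt_surfaces=shell_projectors((20.0, 24.0, 30.0)),
        )
        mind = _min_det_jacobian(
            system.node_positions_mm / 1000.0, system.elem_nodes, 400_000
        )
        assert mind.min() > 0

    def test_adaptation_with_tet_rejected(self, small_sphere):
        from tesvox.validation import shell_projectors

        with pytest.raises(ConfigurationError):
            fem.assemble(small_sphere, fem.ConductivityTable.default(),
                         discretization="tet",
                         adapt_surfaces=shell_projectors((20.0,)))

    def test_isoparametric_matches_regular_when_unshifted(self, cube_slab):
        # projectors too far from every node: adaptation is a no-op and the
        # isoparametric assembly must reproduce the regular-grid operator
        def far_projector(points_mm):
            p = np.asarray(points_mm, float)
            return p + 500.0, np.full(len(p), 500.0)

        table = fem.ConductivityTable.default(gm=0.3)
        K0 = fem.assemble(cube_slab, table).matrix
        K1 = fem.assemble(cube_slab, table, adapt_surfaces=[far_projector]).matrix
        assert abs(K0 - K1).max() < 1e-9 * abs(K0).max()


class TestTetCrossCheck:
    def test_hex_and_tet_solutions_agree_on_cube(self, cube_slab):
        vol, plates = add_plate_electrodes(cube_slab)
        table = fem.ConductivityTable.default(gm=0.3)
        sols = {}
        for disc in ("hex", "tet"):
            s = fem.assemble(vol, table, discretization=disc)
            s = fem.apply_current_bc(s, plates, {"top": 1.0, "bottom": -1.0})
            sols[disc] = fem.solve(s, tol=1e-10)
        # near-uniform gradient: the two discretizations agree closely (they
        # differ only where the plate edges perturb the field)
        vh = sols["hex"].voltages
        vt = sols["tet"].voltages
        assert np.allclose(vh, vt, atol=1e-4 * np.abs(vh).max())


class TestSolver:
    def test_zero_load_gives_zero_solution(self, small_sphere):
        system = fem.assemble(small_sphere, fem.ConductivityTable.default())
        sol = fem.solve(system)
        assert np.all(sol.voltages == 0)
        assert sol.residual == 0.0

    def test_solution_is_zero_mean(self, sphere_system):
        _, system, voxmap, _ = sphere_system
        s = fem.apply_current_bc(system, voxmap, {"a": 1.0, "b": -1.0})
        sol = fem.solve(s, tol=1e-9)
        assert abs(sol.voltages.mean()) < 1e-15 * np.abs(sol.voltages).max()

    def test_tissue_summary_covers_domain(self, cube_solution):
        vol, sol = cube_solution
        df = fem.tissue_summary(sol, vol)
        assert set(df["tissue"]) == {"gm", "electrode"}
        assert df["voxels"].sum() == len(sol.system.elem_ijk)
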