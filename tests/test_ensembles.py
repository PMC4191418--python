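"""Ensemble metrics: block-averaged errors, grooves, overlaps, bends,
PCA, covariance ellipses and variability ordering.

Independent oracles: closed-form SEMs for iid and AR(1) series, Euclidean
distances for grooves, Monte-Carlo ray-casting for overlap areas, the
inscribed-angle formula for arcs, and the chi-square(2) quantile for
ellipse coverage.
"""

import numpy as np
import pandas as pd
import pytest

from triplexkit import (
    Atom,
    AtomicStructure,
    CANONICAL_B,
    EnsembleSpec,
    PairingAnnotation,
    StepParameterTarget,
    annotate_system,
    bend_angles,
    block_sem,
    covariance_ellipse,
    groove_widths,
    helix_step_table,
    overlap_areas,
    pca_ensemble,
    rebuild_helix,
    region_statistics,
    sample_step_ensemble,
    variability_summary,
)
from triplexkit.ensembles import points_inside_ellipse
from _oracles import _mc_union_overlap
from triplexkit.geometry import rotation_about_axis


class TestBlockSEM:
    def test_white_noise_matches_iid_formula(self, rng):
        sigma, n = 2.0, 4096
        x = rng.normal(0, sigma, n)
        sem, _ = block_sem(x)
        assert abs(sem - sigma / np.sqrt(n)) / (sigma / np.sqrt(n)) < 0.20

    def test_constant_series_zero(self):
        sem, _ = block_sem(np.full(256, 3.7))
        assert sem == 0.0

    def test_ar1_matches_correlated_formula(self, rng):
        phi, n = 0.9, 2**15
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0] / np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        sigma2 = 1.0 / (1 - phi**2)
        # exact large-n variance of the mean of an AR(1) series
        sem_true = np.sqrt(sigma2 / n * (1 + phi) / (1 - phi))
        sem, _ = block_sem(x)
        assert abs(sem - sem_true) / sem_true < 0.25

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_sem(np.arange(4.0))


class TestRegionStatistics:
    def test_two_stage_average_and_three_regions(self, study_system):
        spec = EnsembleSpec(
            sequence=study_system.duplex_seq,
            means=CANONICAL_B.as_array(),
            covariances=np.diag([0.1, 0.1, 0.05, 1.0, 2.0, 2.0]) ** 2,
            n_frames=32,
            seed=6,
        )
        ens = sample_step_ensemble(spec)
        tab = helix_step_table(ens, annotate_system(ens, study_system))
        rs = region_statistics(tab)
        assert set(rs.region) == {"first duplex", "homo-purine", "second duplex"}
        # region mean equals the mean of per-step time averages
        sub = tab[tab.region == "homo-purine"]
        want = sub.groupby("step").twist.mean().mean()
        got = rs[(rs.region == "homo-purine") & (rs.parameter == "twist")]["mean"].iloc[0]
        assert abs(got - want) < 1e-12
        assert (rs["sem"] >= 0).all()


def _phosphate_ladder(n, separation=10.0, rise=3.0):
    """Two parallel straight strands of P atoms, a fixed distance apart."""
    atoms, coords = [], []
    for i in range(1, n + 1):  # leading strand
        atoms.append(Atom("P", "P", i, "DA"))
        coords.append([0.0, 0.0, i * rise])
    for i in range(1, n + 1):  # complementary strand residues n+1..2n
        atoms.append(Atom("P", "P", n + i, "DT"))
        coords.append([separation, 0.0, (n + 1 - i) * rise])
    ann = PairingAnnotation(
        wc_pairs=[(i, 2 * n + 1 - i) for i in range(1, n + 1)],
        hoogsteen_pairs=[],
        regions={"helix": (1, n)},
    )
    return AtomicStructure(atoms, np.array(coords)), ann


class TestGrooveWidths:
    def test_parallel_strands_with_matched_offsets(self):
        """With zero cross-strand stagger, the +-2 offsets reach phosphates
        displaced 2 rise steps along the ladder: widths follow Pythagoras
        exactly (Euclidean oracle)."""
        st, ann = _phosphate_ladder(9, separation=10.0, rise=3.0)
        gw = groove_widths(st, ann)
        inner = gw.dropna()
        want = np.hypot(10.0, 2 * 3.0)
        assert np.allclose(inner.minor, want)
        assert np.allclose(inner.major, want)

    def test_zero_offsets_give_plain_separation(self):
        st, ann = _phosphate_ladder(6, separation=10.0)
        gw = groove_widths(st, ann, minor_offset=0, major_offset=0)
        assert np.allclose(gw.dropna().minor, 10.0)
        assert np.allclose(gw.dropna().major, 10.0)

    def test_terminal_positions_flagged_absent(self, fiber_duplex_b, duplex_annotation):
        gw = groove_widths(fiber_duplex_b, duplex_annotation)
        assert gw[gw.position == 1].minor.isna().all()
        assert gw.dropna().shape[0] > 0

    def test_rigid_motion_invariance(self, fiber_duplex_b, duplex_annotation):
        gw0 = groove_widths(fiber_duplex_b, duplex_annotation)
        R = rotation_about_axis([1, 1, 0], 1.1)
        moved = AtomicStructure(
            fiber_duplex_b.atoms, fiber_duplex_b.coords @ R.T + np.array([3, -4, 7.0])
        )
        gw1 = groove_widths(moved, duplex_annotation)
        assert np.allclose(
            gw0.dropna()[["minor", "major"]], gw1.dropna()[["minor", "major"]],
            atol=1e-9,
        )


class TestOverlapAreas:
    def test_coincident_pairs_give_full_polygon_area(self, fiber_duplex_b,
                                                     duplex_annotation):
        # a zero-twist, tiny-rise stack: pair polygons nearly coincide
        st = rebuild_helix("GG", StepParameterTarget(0, 0, 0.05, 0, 0, 0))
        seq_sys = __import__("triplexkit").SystemDefinition(duplex_seq="GG")
        ann = annotate_system(st, seq_sys)
        ov = overlap_areas(st, ann, 1)
        from shapely.geometry import Polygon
        from triplexkit.bases import RING_ATOMS, standard_geometry

        g = standard_geometry("G")
        ring = Polygon(g.coords_of(RING_ATOMS["G"])[:, :2])
        c = standard_geometry("C")
        ringc = Polygon(c.coords_of(RING_ATOMS["C"])[:, :2])
        expect = ring.area + ringc.area  # disjoint rings of one pair
        assert abs(ov["endocyclic"] - expect) < 0.05 * expect

    def test_laterally_separated_zero(self):
        st = rebuild_helix("GG", StepParameterTarget(25.0, 0, 3.3, 0, 0, 0))
        ann = annotate_system(st, __import__("triplexkit").SystemDefinition(duplex_seq="GG"))
        ov = overlap_areas(st, ann, 1)
        assert ov["endocyclic"] == 0.0 and ov["exocyclic"] == 0.0

    def test_matches_monte_carlo_oracle(self, fiber_duplex_b, duplex_annotation, rng):
        ov = overlap_areas(fiber_duplex_b, duplex_annotation, 15)
        # rebuild the projected ring polygons independently
        from triplexkit.bases import RING_ATOMS
        from triplexkit.frames import fit_base_frame, pair_frame, step_parameters

        pairs = dict(duplex_annotation.wc_pairs)
        pfs = {}
        for i in (15, 16):
            ni, ci = fiber_duplex_b.residue_coords(i)
            nj, cj = fiber_duplex_b.residue_coords(pairs[i])
            pfs[i] = pair_frame(
                fit_base_frame(ni, ci, fiber_duplex_b.residue_base(i)),
                fit_base_frame(nj, cj, fiber_duplex_b.residue_base(pairs[i])),
            )
        sp = step_parameters(pfs[15], pfs[16])
        mo, mr = sp.mid_frame.origin, sp.mid_frame.rotation

        def ring_xy(res):
            base = fiber_duplex_b.residue_base(res)
            names = RING_ATOMS[base]
            got, c = fiber_duplex_b.residue_coords(res, names=set(names))
            order = [got.index(n) for n in names]
            return ((c - mo) @ mr)[order][:, :2]

        A = [ring_xy(15), ring_xy(pairs[15])]
        B = [ring_xy(16), ring_xy(pairs[16])]
        mc = _mc_union_overlap(A, B, 1_000_000, rng)
        assert abs(mc - ov["endocyclic"]) < 0.01 * max(ov["endocyclic"], 1.0)

    def test_symmetric_and_rigid_motion_invariant(self, fiber_duplex_b,
                                                  duplex_annotation):
        ov = overlap_areas(fiber_duplex_b, duplex_annotation, 10)
        R = rotation_about_axis([0.3, 1, 2], 0.9)
        moved = AtomicStructure(
            fiber_duplex_b.atoms, fiber_duplex_b.coords @ R.T + 11.0
        )
        ov2 = overlap_areas(moved, duplex_annotation, 10)
        assert abs(ov["endocyclic"] - ov2["endocyclic"]) < 1e-6
        assert abs(ov["exocyclic"] - ov2["exocyclic"]) < 1e-6


def _com_circle_structure(n, radius, arc_step_deg):
    """Base pairs whose COMs sit exactly on a circle (all atoms of each
    pair collapsed to one point), for the inscribed-angle oracle."""
    atoms, coords = [], []
    for i in range(1, n + 1):
        th = np.radians(arc_step_deg * i)
        p = [radius * np.cos(th), radius * np.sin(th), 0.0]
        for res, base in ((i, "DA"), (2 * n + 1 - i, "DT")):
            for name in ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4", "N6") if base == "DA" else ("N1", "C2", "N3", "C4", "C5", "C6", "O2", "O4", "C7"):
                atoms.append(Atom(name, name[0] if name[0] in "NCO" else "C", res, base))
                coords.append(p)
    order = np.argsort([a.residue_index for a in atoms], kind="stable")
    atoms = [atoms[i] for i in order]
    coords = np.array(coords)[order]
    ann = PairingAnnotation(
        wc_pairs=[(i, 2 * n + 1 - i) for i in range(1, n + 1)],
        hoogsteen_pairs=[],
        regions={"helix": (1, n)},
    )
    return AtomicStructure(atoms, coords), ann


class TestBendAngles:
    def test_straight_stack_gives_180(self, study_system):
        """Pure-rise stacking of identical pairs puts every pair COM on one
        line: the bend angle is 180 deg for every distance."""
        seq = "A" * 21
        st = rebuild_helix(seq, StepParameterTarget(0, 0, 3.32, 0, 0, 0))
        ann = annotate_system(st, type(study_system)(duplex_seq=seq))
        ba = bend_angles(st, ann, vertex=11)
        assert np.abs(ba.angle - 180.0).max() < 1e-6

    def test_planar_arc_matches_inscribed_angle_formula(self):
        arc = 12.0  # degrees between successive COMs on the circle
        st, ann = _com_circle_structure(9, radius=40.0, arc_step_deg=arc)
        ba = bend_angles(st, ann, vertex=5, distances=[1, 2, 3, 4])
        for _, row in ba.iterrows():
            want = 180.0 - row.distance * arc
            assert abs(row.angle - want) < 1e-8

    def test_rigid_motion_invariance(self, fiber_duplex_b, duplex_annotation):
        ba0 = bend_angles(fiber_duplex_b, duplex_annotation, vertex=15, distances=[7])
        R = rotation_about_axis([1, 0, 1], 2.0)
        moved = AtomicStructure(
            fiber_duplex_b.atoms, fiber_duplex_b.coords @ R.T - 5.0
        )
        ba1 = bend_angles(moved, duplex_annotation, vertex=15, distances=[7])
        assert abs(ba0.angle.iloc[0] - ba1.angle.iloc[0]) < 1e-9

    def test_a_and_b_fibers_give_distinct_reference_angles(
        self, fiber_duplex_b, fiber_duplex_a, duplex_annotation, study_system
    ):
        ann_a = annotate_system(fiber_duplex_a, study_system)
        b = bend_angles(fiber_duplex_b, duplex_annotation, 15, [7]).angle.iloc[0]
        a = bend_angles(fiber_duplex_a, ann_a, 15, [7]).angle.iloc[0]
        assert abs(a - b) > 10.0

    def test_out_of_range_distance_rejected(self, fiber_duplex_b, duplex_annotation):
        with pytest.raises(ValueError):
            bend_angles(fiber_duplex_b, duplex_annotation, vertex=15, distances=[20])


class TestPCA:
    def _line_ensemble(self, rng, n_frames=40, n_atoms=30):
        base = rng.normal(size=(n_atoms, 3)) * 5
        direction = rng.normal(size=3 * n_atoms)
        direction /= np.linalg.norm(direction)
        amps = rng.normal(size=n_frames)
        coords = base.ravel()[None, :] + amps[:, None] * direction[None, :]
        atoms = [Atom("C1'", "C", i + 1, "DA") for i in range(n_atoms)]
        return AtomicStructure(atoms, coords.reshape(n_frames, n_atoms, 3)), direction

    def test_single_mode_recovered(self, rng):
        st, direction = self._line_ensemble(rng)
        pca = pca_ensemble(st, annotation=None, fit_region=None, superpose=False)
        assert pca.variance_fractions[0] > 1 - 1e-9
        overlap = abs(np.dot(pca.eigenvectors[0], direction))
        assert overlap > 1 - 1e-9

    def test_eigenvector_count_is_three_per_atom(self, rng):
        st, _ = self._line_ensemble(rng, n_frames=10, n_atoms=12)
        pca = pca_ensemble(st, annotation=None, fit_region=None)
        assert pca.eigenvalues.shape[0] == 3 * 12
        assert pca.eigenvectors.shape == (36, 36)

    def test_fractions_sum_to_one_and_eigsum_matches_trace(self, rng):
        st, _ = self._line_ensemble(rng, n_frames=25, n_atoms=8)
        st = AtomicStructure(st.atoms, st.coords + rng.normal(scale=0.1, size=st.coords.shape))
        pca = pca_ensemble(st, annotation=None, fit_region=None)
        assert abs(pca.variance_fractions.sum() - 1.0) < 1e-9
        X = st.coords.reshape(st.n_frames, -1)
        # trace check only valid without superposition (identity fit here is
        # near-identity since fit uses all atoms of an uncorrelated cloud)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)

    def test_projections_zero_mean(self, rng):
        st, _ = self._line_ensemble(rng, n_frames=30, n_atoms=10)
        pca = pca_ensemble(st, annotation=None, fit_region=None)
        assert np.abs(pca.projections.mean(axis=0)).max() < 1e-9

    def test_known_two_mode_covariance_recovered(self, rng):
        n_atoms, n_frames = 20, 4000
        base = rng.normal(size=(n_atoms, 3)) * 8
        v1 = rng.normal(size=3 * n_atoms)
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=3 * n_atoms)
        v2 -= v1 * (v1 @ v2)
        v2 /= np.linalg.norm(v2)
        s1, s2 = 3.0, 1.5
        amps = rng.normal(size=(n_frames, 2)) * [s1, s2]
        X = base.ravel()[None, :] + amps @ np.vstack([v1, v2])
        atoms = [Atom("C1'", "C", i + 1, "DA") for i in range(n_atoms)]
        st = AtomicStructure(atoms, X.reshape(n_frames, n_atoms, 3))
        pca = pca_ensemble(st, annotation=None, fit_region=None, superpose=False)
        tol = 4.0 * np.sqrt(2.0 / n_frames)
        assert abs(pca.eigenvalues[0] - s1**2) < tol * s1**2
        assert abs(pca.eigenvalues[1] - s2**2) < tol * s2**2
        assert pca.eigenvalues[2] < 1e-9
        assert abs(np.dot(pca.eigenvectors[0], v1)) > 0.99

    def test_single_frame_rejected(self, rng):
        atoms = [Atom("C1'", "C", 1, "DA")]
        with pytest.raises(ValueError):
            pca_ensemble(AtomicStructure(atoms, np.zeros((1, 1, 3))),
                         annotation=None, fit_region=None)


class TestCovarianceEllipse:
    def test_isotropic_circle_radius_3_sigma(self, rng):
        X = rng.normal(0, 2.0, size=(40000, 2))
        ell = covariance_ellipse(X, score=3.0)
        assert np.allclose(ell.semi_axes, 6.0, rtol=0.05)

    def test_diagonal_closed_form(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200000, 2)) * [2.0, 1.0]
        ell = covariance_ellipse(X, score=3.0)
        assert abs(ell.semi_axes[0] - 6.0) < 0.1
        assert abs(ell.semi_axes[1] - 3.0) < 0.05

    def test_three_sigma_coverage_matches_chi2(self, rng):
        from scipy.stats import chi2

        cov = np.array([[4.0, 1.5], [1.5, 2.0]])
        L = np.linalg.cholesky(cov)
        X = rng.normal(size=(200000, 2)) @ L.T
        ell = covariance_ellipse(X, score=3.0)
        frac = points_inside_ellipse(X, ell)
        assert abs(frac - chi2(df=2).cdf(9.0)) < 0.005  # ~0.9889

    def test_degenerate_flagged(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        assert covariance_ellipse(X).degenerate


class TestVariability:
    def test_constant_ensemble_zero_sd(self, study_system):
        spec = EnsembleSpec(
            sequence="GACT", means=CANONICAL_B.as_array(),
            covariances=np.zeros((6, 6)), n_frames=5, seed=0,
        )
        ens = sample_step_ensemble(spec)
        tab = helix_step_table(ens, annotate_system(
            ens, type(study_system)(duplex_seq="GACT")))
        v = variability_summary(tab)
        assert (v.roll_sd < 1e-9).all() and (v.slide_sd < 1e-9).all()

    def test_class_ordering_recovered(self, study_system):
        """A generator with YR > RR > RY roll/slide spreads must show the
        same ordering in the measured per-step variabilities."""
        seq = "TAGC"  # steps: TA (YR), AG (RR), GC (RY)
        scales = {"YR": 3.0, "RR": 2.0, "RY": 1.0}
        base_sd = np.array([0.1, 0.25, 0.1, 1.0, 2.0, 2.0])
        covs = []
        for cls in ("YR", "RR", "RY"):
            sd = base_sd.copy()
            sd[[1, 4]] *= scales[cls]
            covs.append(np.diag(sd**2))
        spec = EnsembleSpec(sequence=seq, means=CANONICAL_B.as_array(),
                            covariances=np.stack(covs), n_frames=400, seed=17)
        ens = sample_step_ensemble(spec)
        tab = helix_step_table(ens, annotate_system(
            ens, type(study_system)(duplex_seq=seq)))
        v = variability_summary(tab).set_index("step_class")
        assert v.loc["YR", "roll_sd"] > v.loc["RR", "roll_sd"] > v.loc["RY", "roll_sd"]
        assert v.loc["YR", "slide_sd"] > v.loc["RR", "slide_sd"] > v.loc["RY", "slide_sd"]
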