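"""Basin classification, near-manifold extraction, separatrix fitting."""

import numpy as np
import pytest

import statswitch as sw
from conftest import stables_sorted


def test_grid_fractions_sum_to_one(grid_u4):
    total = (grid_u4.fraction("motile") + grid_u4.fraction("stationary")
             + grid_u4.fraction("unresolved"))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_high_upd_grid_mostly_motile(grid_u4):
    assert grid_u4.fraction("motile") > 0.5


def test_grid_covers_both_attractors(grid_u4):
    for s in stables_sorted(grid_u4.equilibria):
        assert np.all(s.state > [grid_u4.spec.s_min, grid_u4.spec.a_min,
                                 grid_u4.spec.b_min])
        assert np.all(s.state < [grid_u4.spec.s_max, grid_u4.spec.a_max,
                                 grid_u4.spec.b_max])


def test_grid_of_attractor_copies_is_trivial(p, eq_u4):
    motile = stables_sorted(eq_u4)[1]
    lab = sw.fate_of_initial(motile.state, 4.0, p, eq_u4)
    assert lab.tag == "motile" and lab.t_converge == 0.0


def test_near_manifold_points_bracket_the_saddle(grid_u4):
    pts = sw.near_manifold_points(grid_u4)
    assert len(pts) >= 10
    sad = next(s for s in grid_u4.equilibria if not s.is_stable)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    assert np.all(sad.state >= lo - 1e-9) and np.all(sad.state <= hi + 1e-9)


def test_near_manifold_empty_when_monostable(p):
    # build a tiny grid at monostable UPD by classifying against the sole
    # attractor twice (classify_grid refuses monostable conditions)
    with pytest.raises(ValueError):
        sw.classify_grid(15.0, p, spec=sw.GridSpec(n=3))


def test_plane_fit_exact_on_planar_points(rng):
    n = rng.normal(size=3)
    n /= np.linalg.norm(n)
    basis = np.linalg.svd(np.eye(3) - np.outer(n, n))[0][:, :2]
    pts = (rng.uniform(-1, 1, size=(40, 2)) @ basis.T) * 30 + 50
    fit = sw.fit_manifold(pts, form="plane")
    assert fit.rms_residual < 1e-9


def test_plane_fit_degenerate_cloud_rejected():
    pts = np.tile([1.0, 2.0, 3.0], (20, 1))
    with pytest.raises(ValueError):
        sw.fit_manifold(pts, form="plane")
    with pytest.raises(ValueError):
        sw.fit_manifold(pts[:4], form="plane")


def test_separatrix_plane_quality(grid_u4):
    """The fitted plane sides >90% of resolved points correctly and passes
    within two grid-cell diagonals of the saddle."""
    pts = sw.near_manifold_points(grid_u4)
    fit = sw.fit_manifold(pts, form="plane", grid=grid_u4)
    assert fit.sided_accuracy > 0.9
    sad = next(s for s in grid_u4.equilibria if not s.is_stable)
    n = fit.plane_normal()
    dist = abs(float(fit.evaluate(sad.state)[0]))
    assert dist <= 2 * grid_u4.spec.cell_diagonal()


def test_quadric_fit_runs(grid_u4):
    pts = sw.near_manifold_points(grid_u4)
    fit = sw.fit_manifold(pts, form="quadratic", grid=grid_u4)
    assert fit.sided_accuracy > 0.9


def test_displacement_across_plane_separates_fates(p, grid_u4):
    """Stepping ±1% of the box diagonal along the plane normal from points
    on the separatrix near the saddle yields opposite fates.

    Separatrix points are pinned by bisecting grid edges whose endpoints
    reached opposite fates."""
    pts = sw.near_manifold_points(grid_u4)
    fit = sw.fit_manifold(pts, form="plane", grid=grid_u4)
    sad = next(s for s in grid_u4.equilibria if not s.is_stable)
    n_axes = grid_u4.spec.n
    fates = grid_u4.fates.reshape(n_axes, n_axes, n_axes)
    gridpts = grid_u4.points.reshape(n_axes, n_axes, n_axes, 3)
    pairs = []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        fa, fb = fates[tuple(a)], fates[tuple(b)]
        opp = ((fa == "motile") & (fb == "stationary")) | \
              ((fa == "stationary") & (fb == "motile"))
        pa, pb = gridpts[tuple(a)][opp], gridpts[tuple(b)][opp]
        pairs.extend(zip(pa, pb))
    mids = np.array([(0.5 * (a + b)) for a, b in pairs])
    order = np.argsort(np.linalg.norm(mids - sad.state, axis=1))
    diag = np.linalg.norm([grid_u4.spec.s_max, grid_u4.spec.a_max,
                           grid_u4.spec.b_max])
    eps = 0.01 * diag * fit.plane_normal()

    def fate(x):
        return sw.fate_of_initial(np.clip(x, 0, None), 4.0, p,
                                  grid_u4.equilibria).tag

    hits = trials = 0
    for i in order[:10]:
        lo, hi = pairs[i]
        f_lo = fate(lo)
        for _ in range(10):                  # bisect to the true boundary
            mid = 0.5 * (lo + hi)
            if fate(mid) == f_lo:
                lo = mid
            else:
                hi = mid
        x = 0.5 * (lo + hi)
        up, dn = fate(x + eps), fate(x - eps)
        trials += 1
        if {up, dn} == {"motile", "stationary"}:
            hits += 1
    assert hits >= 0.9 * trials


def test_plane_normal_aligns_with_saddle_stable_eigenplane(p, grid_u4):
    """The fitted plane approximates the saddle's 2-D stable manifold: its
    normal is within 25 degrees of the normal of the stable eigenplane."""
    pts = sw.near_manifold_points(grid_u4)
    fit = sw.fit_manifold(pts, form="plane", grid=grid_u4)
    sad = next(s for s in grid_u4.equilibria if not s.is_stable)
    J = sw.jacobian_three_var(sad.state, 4.0, p)
    ev, V = np.linalg.eig(J)
    stable = V[:, ev.real < 0]
    if np.iscomplexobj(stable) and np.abs(stable.imag).max() > 1e-12:
        # complex-conjugate pair: the eigenplane is span(Re v, Im v)
        basis = np.stack([stable[:, 0].real, stable[:, 0].imag], axis=1)
    else:
        basis = stable.real
    n_tan = np.cross(basis[:, 0], basis[:, 1])
    n_tan /= np.linalg.norm(n_tan)
    cosang = abs(float(n_tan @ fit.plane_normal()))
    assert np.degrees(np.arccos(min(cosang, 1.0))) < 25.0


def test_grid_refinement_stability(p):
    """Doubling grid resolution moves the basin fractions by < 5 points."""
    f = []
    for n in (9, 17):
        g = sw.classify_grid(4.0, p, spec=sw.GridSpec(n=n))
        f.append(g.fraction("motile") + 0.5 * g.fraction("unresolved"))
    assert abs(f[0] - f[1]) < 0.05


def test_manifold_shift_with_upd(p):
    """The motile basin grows monotonically across the bistable window."""
    rep = sw.manifold_shift_report(p, U_values=(0.0133, 0.133, 4.0),
                                   spec=sw.GridSpec(n=7))
    frac = rep["motile_fraction"].to_numpy()
    assert np.all(np.diff(frac) > 0)
    assert rep["regime"].eq("bistable").all()
    # identical conditions give identical fits
    rep2 = sw.manifold_shift_report(p, U_values=(4.0, 4.0),
                                    spec=sw.GridSpec(n=7))
    assert rep2["probe_value"].iloc[0] == rep2["probe_value"].iloc[1]


def test_probe_side_flips_across_the_stop_boundary(p):
    """Raising the miRNA strength moves the separatrix past the reference
    initial condition: the probe's side flips between a converging and a
    non-converging strength."""
    rep = sw.manifold_shift_report(p, deltaAsigma_values=(0.05, 0.25),
                                   U_fixed=4.0, spec=sw.GridSpec(n=7))
    assert rep["probe_side"].tolist() == ["motile", "stationary"]
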