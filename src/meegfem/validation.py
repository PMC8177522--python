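"""End-to-end validation studies on self-generated sphere fixtures.

Each function runs one complete study — generating the conductor,
sensors and sources it needs, executing the forward machinery, and
measuring the result against its oracle (analytic sphere series, Sarvas
field, linear-search localization, direct-vs-transfer equivalence,
Monte-Carlo scan recovery).  The returned dictionaries carry the
measured quantities plus the problem size; the test suite asserts them
and ``scripts/acceptance.py`` reports them.

Study conditions: three-shell sphere 0.092/0.086/0.080 m at
0.33/0.0042/0.33 S/m (voxelized at 4-8 mm), the homogeneous 0.092 m
sphere for convergence ladders (8/4/2 mm) and cross-model comparisons
(2 mm), 32 sensors, dipole moments of 1 nA*m.
"""

from __future__ import annotations

import numpy as np

from .eeg import Assembly, apply_transfer, compute_eeg_transfer, solve_eeg_forward
from .fixtures import (
    DEFAULT_CONDUCTIVITIES,
    DEFAULT_RADII,
    brain_dipole,
    electrode_cap,
    hex_sphere_model,
    hex_to_tet,
    interior_source_space,
    magnetometer_shell,
    noise_sd_for_snr,
    synthetic_measurement,
)
from .locate import build_center_index, edge_hop, linear_locate, locate
from .meg import assemble_secondary_coupling, solve_meg_forward
from .mesh import Dipole, VolumeConductor, build_face_neighbors
from .scan import dipole_scan
from .sources import represented_moment, venant_rhs
from .sphere import SphereModel, rdm, sarvas_meg, sphere_eeg

R_OUTER = DEFAULT_RADII[0]
R_BRAIN = DEFAULT_RADII[-1]
SIGMA_BRAIN = DEFAULT_CONDUCTIVITIES[-1]
TOL = 1e-8
N_ELECTRODES = 32
MOMENT = 1e-9  # A*m


def _three_shell(voxel_size: float) -> VolumeConductor:
    vc = hex_sphere_model(voxel_size=voxel_size)
    build_face_neighbors(vc.mesh)
    return vc


def _homogeneous(voxel_size: float) -> VolumeConductor:
    vc = hex_sphere_model(radii=(R_OUTER,), conductivities=(SIGMA_BRAIN,),
                          voxel_size=voxel_size)
    build_face_neighbors(vc.mesh)
    return vc


def _random_brain_dipoles(rng, n, r_max):
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = r_max * rng.uniform(0.1, 1.0, size=n) ** (1 / 3)
    moms = rng.normal(size=(n, 3))
    moms *= MOMENT / np.linalg.norm(moms, axis=1, keepdims=True)
    return [Dipole(r * d, m) for r, d, m in zip(radii, dirs, moms)]


def transfer_consistency(seed: int = 0, voxel_size: float = 0.004,
                         n_dipoles: int = 10) -> dict:
    """Transfer-vs-direct equivalence for all four source models.

    Partial integration, St. Venant and subtraction run on the
    three-shell hexahedral sphere; the (tet-only) Whitney model runs on
    the same-resolution tetrahedral subdivision.  Reports the largest
    |T b - R A^-1 b| over sensors/dipoles/models relative to the output
    scale, to be compared with 10x the solver tolerance.
    """
    rng = np.random.default_rng(seed)
    electrodes = electrode_cap(N_ELECTRODES, R_OUTER)
    dipoles = _random_brain_dipoles(rng, n_dipoles, 0.8 * R_BRAIN)
    worst = 0.0
    per_model = {}
    vc_hex = _three_shell(voxel_size)
    asm = Assembly(vc_hex, scheme="cg", tol=TOL)
    T = compute_eeg_transfer(vc_hex, electrodes, assembly=asm)
    for name in ("partial_integration", "venant", "subtraction"):
        model = asm.source_model(name)
        via = apply_transfer(T, model, dipoles, electrodes)
        direct = solve_eeg_forward(vc_hex, dipoles, electrodes,
                                   assembly=asm, model=model)
        dev = float(np.abs(via - direct).max() / np.abs(direct).max())
        per_model[name] = dev
        worst = max(worst, dev)
    vc_tet = hex_to_tet(vc_hex)
    build_face_neighbors(vc_tet.mesh)
    asm_t = Assembly(vc_tet, scheme="cg", tol=TOL)
    T_t = compute_eeg_transfer(vc_tet, electrodes, assembly=asm_t)
    model = asm_t.source_model("whitney")
    via = apply_transfer(T_t, model, dipoles, electrodes)
    direct = solve_eeg_forward(vc_tet, dipoles, electrodes,
                               assembly=asm_t, model=model)
    dev = float(np.abs(via - direct).max() / np.abs(direct).max())
    per_model["whitney"] = dev
    worst = max(worst, dev)
    return {
        "max_rel_deviation": worst,
        "per_model": per_model,
        "bound": 10.0 * TOL,
        "n": vc_hex.mesh.n_elements,
    }


def cg_convergence(seed: int = 0,
                   voxel_sizes=(0.008, 0.004, 0.002)) -> dict:
    """Surface-potential RDM of CG against the closed-form central-dipole
    potential u(R, theta) = 3 q cos(theta) / (4 pi sigma R^2), per
    resolution of the homogeneous sphere."""
    dip = Dipole([0.0, 0.0, 0.0], [0.0, 0.0, MOMENT])
    electrodes = electrode_cap(N_ELECTRODES, R_OUTER)
    model = SphereModel([0, 0, 0], [R_OUTER], [SIGMA_BRAIN])
    rdms = {}
    n_by_voxel = {}
    for h in voxel_sizes:
        vc = _homogeneous(h)
        asm = Assembly(vc, scheme="cg", tol=TOL)
        pots = solve_eeg_forward(vc, [dip], electrodes, assembly=asm)
        R = asm.restriction(electrodes)
        ana = sphere_eeg(model, dip, R.projected)
        rdms[h] = float(rdm(pots[:, 0], ana))
        n_by_voxel[h] = vc.mesh.n_elements
    vals = [rdms[h] for h in voxel_sizes]
    return {
        "rdm_by_voxel": rdms,
        "n_by_voxel": n_by_voxel,
        "rdm_finest": vals[-1],
        "rdm_coarsest": vals[0],
        "monotone": bool(all(b < a for a, b in zip(vals, vals[1:]))),
        "n": n_by_voxel[voxel_sizes[-1]],
    }


def sphere_series_selfconsistency(seed: int = 0) -> dict:
    """Equal-conductivity multilayer = homogeneous; outer Neumann
    residual; truncation-doubling stability."""
    dip = Dipole([0.0, 0.01, 0.05], [MOMENT, 0.0, MOMENT])
    pts = electrode_cap(N_ELECTRODES, R_OUTER)
    multi = SphereModel([0, 0, 0], DEFAULT_RADII,
                        [SIGMA_BRAIN] * len(DEFAULT_RADII))
    homo = SphereModel([0, 0, 0], [R_OUTER], [SIGMA_BRAIN])
    u_multi = sphere_eeg(multi, dip, pts)
    u_homo = sphere_eeg(homo, dip, pts)
    equal_dev = float(np.abs(u_multi - u_homo).max() / np.abs(u_homo).max())

    # second-order one-sided radial derivative at the outer surface
    shell = SphereModel([0, 0, 0], DEFAULT_RADII, DEFAULT_CONDUCTIVITIES)
    delta = 1e-5 * R_OUTER
    u0 = sphere_eeg(shell, dip, pts, demean=False)
    u1 = sphere_eeg(shell, dip, pts * (1 - delta / R_OUTER), demean=False)
    u2 = sphere_eeg(shell, dip, pts * (1 - 2 * delta / R_OUTER), demean=False)
    dudr = (3 * u0 - 4 * u1 + u2) / (2 * delta)
    neumann = float(np.abs(dudr).max() / (np.abs(u0).max() / R_OUTER))

    u_long = sphere_eeg(shell, dip, pts, n_max=400, rtol=0.0)
    u_short = sphere_eeg(shell, dip, pts, n_max=200, rtol=0.0)
    trunc = float(np.abs(u_long - u_short).max() / np.abs(u_short).max())
    return {
        "equal_conductivity_deviation": equal_dev,
        "neumann_residual": neumann,
        "truncation_doubling_change": trunc,
        "n": len(pts),
    }


def localization_consistency(seed: int = 0, voxel_size: float = 0.008,
                             n_points: int = 1000) -> dict:
    """locate() vs the linear-search oracle for uniform random interior
    points on hex and tet fixtures; hop counts bounded by element count."""
    rng = np.random.default_rng(seed)
    out = {}
    for kind in ("hexahedron", "tetrahedron"):
        vc = _homogeneous(voxel_size)
        if kind == "tetrahedron":
            vc = hex_to_tet(vc)
            build_face_neighbors(vc.mesh)
        mesh = vc.mesh
        index = build_center_index(mesh)
        # uniform in the 0.9 R ball: every such point lies in a retained
        # voxel (voxel centers within half a diagonal stay below R)
        pts = rng.normal(size=(n_points, 3))
        pts *= (0.9 * R_OUTER * rng.uniform(0, 1, n_points) ** (1 / 3)
                / np.linalg.norm(pts, axis=1))[:, None]
        agree = 0
        max_hops = 0
        for p in pts:
            found = locate(mesh, index, p)
            ref = linear_locate(mesh, p)
            status, elem, hops = edge_hop(mesh, index.nearest(p), p,
                                          count_hops=True)
            max_hops = max(max_hops, hops)
            if found == ref and found is not None:
                agree += 1
        out[kind] = {
            "agreement": agree / n_points,
            "max_hops": max_hops,
            "n_elements": mesh.n_elements,
        }
    return {
        "agreement_min": min(out[k]["agreement"] for k in out),
        "hops_within_bound": bool(
            all(out[k]["max_hops"] <= out[k]["n_elements"] for k in out)
        ),
        "per_kind": out,
        "n": n_points,
    }


def conservation_invariants(seed: int = 0, voxel_size: float = 0.008) -> dict:
    """Discrete conservation: A 1 = 0 (CG and DG), restriction rows sum
    to 1, direct source vectors sum to 0, Venant recovers the moment."""
    rng = np.random.default_rng(seed)
    vc = _three_shell(voxel_size)
    electrodes = electrode_cap(N_ELECTRODES, R_OUTER)
    asm_cg = Assembly(vc, scheme="cg", tol=TOL)
    asm_dg = Assembly(vc, scheme="dg", tol=TOL, eta=4.0,
                      preconditioner="jacobi")
    one_cg = np.ones(asm_cg.A.shape[0])
    one_dg = np.ones(asm_dg.A.shape[0])
    kern_cg = float(np.abs(asm_cg.A @ one_cg).max() / np.abs(asm_cg.A.data).max())
    kern_dg = float(np.abs(asm_dg.A @ one_dg).max() / np.abs(asm_dg.A.data).max())
    R = asm_cg.restriction(electrodes)
    rowsum = float(np.abs(np.asarray(R.matrix.sum(axis=1)) - 1.0).max())

    vc_tet = hex_to_tet(vc)
    build_face_neighbors(vc_tet.mesh)
    dipoles = _random_brain_dipoles(rng, 5, 0.8 * R_BRAIN)
    from .sources import partial_integration_rhs, whitney_rhs

    bsum = 0.0
    moment_err = 0.0
    for dip in dipoles:
        for b in (partial_integration_rhs(vc, dip), venant_rhs(vc, dip),
                  whitney_rhs(vc_tet, dip)):
            bsum = max(bsum, abs(b.total()) / b.norm1())
        bv = venant_rhs(vc, dip)
        m1 = bv.values @ (vc.mesh.vertices[bv.indices] - dip.position)
        moment_err = max(
            moment_err,
            float(np.linalg.norm(m1 - dip.moment) / np.linalg.norm(dip.moment)),
        )
        mw = represented_moment(vc_tet, dip)
        moment_err = max(
            moment_err,
            float(np.linalg.norm(mw - dip.moment) / np.linalg.norm(dip.moment)),
        )
    return {
        "stiffness_kernel_cg": kern_cg,
        "stiffness_kernel_dg": kern_dg,
        "restriction_rowsum_error": rowsum,
        "rhs_sum_max": bsum,
        "moment_recovery_error": moment_err,
        "n": vc.mesh.n_elements,
    }


def meg_vs_sarvas(seed: int = 0, voxel_size: float = 0.004,
                  n_coils: int = 32) -> dict:
    """Tangential dipole at eccentricity 0.5 vs the Sarvas closed form;
    radial-dipole suppression relative to the tangential maximum."""
    vc = _homogeneous(voxel_size)
    coils = magnetometer_shell(n_coils, R_OUTER + 0.028)
    asm = Assembly(vc, scheme="cg", tol=TOL)
    pos = [0.0, 0.0, 0.5 * R_OUTER]
    dip_t = Dipole(pos, [MOMENT, 0.0, 0.0])
    dip_r = Dipole(pos, [0.0, 0.0, MOMENT])
    S = assemble_secondary_coupling(vc, coils)
    B = solve_meg_forward(vc, [dip_t, dip_r], coils, assembly=asm,
                          secondary_coupling=S)
    ana = sarvas_meg([0, 0, 0], dip_t, coils)
    return {
        "tangential_rdm": float(rdm(B[:, 0], ana)),
        "radial_suppression": float(np.abs(B[:, 1]).max() / np.abs(B[:, 0]).max()),
        "n": vc.mesh.n_elements,
    }


def scan_recovery(seed: int = 0, voxel_size: float = 0.008,
                  n_sources: int = 500, n_replicates: int = 100,
                  snr_db: float = 20.0) -> dict:
    """Deviation-scan recovery on the three-shell sphere.

    Noise-free: the measurement is one leadfield column; the scan must
    return that column with GOF = 1.  Noisy: Gaussian noise at the given
    SNR, success = best index within the top-1% GOF neighborhood of the
    true location (the locations whose noise-free GOF against the clean
    signal ranks in the top percentile)."""
    rng = np.random.default_rng(seed)
    vc = _three_shell(voxel_size)
    electrodes = electrode_cap(N_ELECTRODES, R_OUTER)
    asm = Assembly(vc, scheme="cg", tol=TOL)
    T = compute_eeg_transfer(vc, electrodes, assembly=asm)
    space = interior_source_space(n_sources, 0.8 * R_BRAIN, seed=seed)
    model = asm.source_model("partial_integration")
    dipoles = [Dipole(p, MOMENT * n)
               for p, n in zip(space.positions, space.normals)]
    L = apply_transfer(T, model, dipoles, electrodes)

    jstar = int(rng.integers(0, n_sources))
    clean = L[:, jstar].copy()
    res0 = dipole_scan(L, clean)
    exact = res0.best == jstar and abs(res0.gof[res0.best] - 1.0) < 1e-12

    k_top = max(1, int(np.ceil(0.01 * n_sources)))
    top = set(np.argsort(res0.gof)[-k_top:].tolist())
    sd = noise_sd_for_snr(clean, snr_db)
    hits = 0
    for rep in range(n_replicates):
        m = synthetic_measurement(clean, 1.0, sd, seed=seed * 100003 + rep)
        r = dipole_scan(L, m)
        hits += int(r.best in top)
    return {
        "noise_free_exact": bool(exact),
        "noise_free_gof": float(res0.gof[res0.best]),
        "recovery_rate": hits / n_replicates,
        "n": n_sources,
    }


def cross_model_agreement(seed: int = 0, voxel_size: float = 0.002,
                          eccentricities=(0.4, 0.8)) -> dict:
    """Pairwise RDM between all four source models on the refined
    homogeneous tetrahedral sphere for dipoles of eccentricity <= 0.8
    (mixed radial/tangential moments)."""
    vc = hex_to_tet(_homogeneous(voxel_size))
    build_face_neighbors(vc.mesh)
    electrodes = electrode_cap(N_ELECTRODES, R_OUTER)
    asm = Assembly(vc, scheme="cg", tol=TOL)
    dipoles = [
        brain_dipole(ecc, [0.3, 0.2, 1.0], [MOMENT, 0.0, MOMENT],
                     radii=(R_OUTER,))
        for ecc in eccentricities
    ]
    names = ("partial_integration", "venant", "subtraction", "whitney")
    pots = {}
    for name in names:
        model = asm.source_model(name)
        pots[name] = solve_eeg_forward(vc, dipoles, electrodes,
                                       assembly=asm, model=model)
    worst = 0.0
    pairs = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            val = max(
                float(rdm(pots[a][:, k], pots[b][:, k]))
                for k in range(len(dipoles))
            )
            pairs[f"{a}|{b}"] = val
            worst = max(worst, val)
    return {"max_pairwise_rdm": worst, "pairs": pairs,
            "n": vc.mesh.n_elements}
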