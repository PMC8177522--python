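import numpy as np
import pytest

import meegfem as mf
from meegfem.mesh import Dipole


@pytest.fixture(scope="module")
def transfer(homog_sphere_8mm, electrodes32, homog_assembly):
    return mf.compute_eeg_transfer(homog_sphere_8mm, electrodes32,
                                   assembly=homog_assembly)


def test_forward_columns_are_demeaned(homog_sphere_8mm, electrodes32,
                                      homog_assembly):
    dips = [Dipole([0, 0, 0.02], [1e-9, 0, 0]),
            Dipole([0.01, 0, 0.03], [0, 1e-9, 1e-9])]
    pots = mf.solve_eeg_forward(homog_sphere_8mm, dips, electrodes32,
                                assembly=homog_assembly)
    assert pots.shape == (32, 2)
    assert np.abs(pots.mean(axis=0)).max() < 1e-12 * np.abs(pots).max()


def test_forward_linear_in_moment(homog_sphere_8mm, electrodes32,
                                  homog_assembly):
    pos = [0.005, -0.01, 0.025]
    q1, q2 = np.array([1e-9, 0, 0]), np.array([0, 0.5e-9, -1e-9])
    p = mf.solve_eeg_forward(
        homog_sphere_8mm,
        [Dipole(pos, q1), Dipole(pos, q2), Dipole(pos, q1 + q2)],
        electrodes32, assembly=homog_assembly,
    )
    assert np.abs(p[:, 0] + p[:, 1] - p[:, 2]).max() <= 1e-5 * np.abs(
        p[:, 2]
    ).max()


def test_transfer_shape_and_duplicate_rows(homog_sphere_8mm, homog_assembly,
                                           electrodes32):
    dup = np.vstack([electrodes32[:4], electrodes32[:1]])
    T = mf.compute_eeg_transfer(homog_sphere_8mm, dup,
                                assembly=homog_assembly)
    assert T.shape == (5, homog_assembly.space.ndof)
    assert np.allclose(T.matrix[4], T.matrix[0], atol=1e-12)


def test_electrode_swap_permutes_rows(homog_sphere_8mm, homog_assembly,
                                      electrodes32):
    T = mf.compute_eeg_transfer(homog_sphere_8mm, electrodes32[:6],
                                assembly=homog_assembly)
    swapped = electrodes32[:6][[1, 0, 2, 3, 4, 5]]
    T2 = mf.compute_eeg_transfer(homog_sphere_8mm, swapped,
                                 assembly=homog_assembly)
    assert np.allclose(T2.matrix[0], T.matrix[1], atol=1e-14)
    assert np.allclose(T2.matrix[1], T.matrix[0], atol=1e-14)


@pytest.mark.parametrize("model_name",
                         ["partial_integration", "venant", "subtraction"])
def test_transfer_equals_direct(transfer, homog_sphere_8mm, electrodes32,
                                homog_assembly, model_name):
    rng = np.random.default_rng(11)
    dips = [Dipole(rng.uniform(-0.03, 0.03, 3), rng.normal(size=3) * 1e-9)
            for _ in range(3)]
    model = homog_assembly.source_model(model_name)
    via = mf.apply_transfer(transfer, model, dips, electrodes32)
    direct = mf.solve_eeg_forward(homog_sphere_8mm, dips, electrodes32,
                                  assembly=homog_assembly, model=model)
    assert np.abs(via - direct).max() <= 10 * homog_assembly.tol * np.abs(
        direct
    ).max()


def test_transfer_provenance_checked(transfer, coarse_three_shell):
    model = mf.make_source_model("partial_integration", coarse_three_shell)
    with pytest.raises(ValueError, match="provenance"):
        mf.apply_transfer(transfer, model,
                          [Dipole([0, 0, 0.02], [1e-9, 0, 0])])


def test_sparse_apply_touches_few_columns(transfer, homog_assembly):
    """Cost per dipole for direct models is O(nnz), independent of n."""
    model = homog_assembly.source_model("venant")
    dip = Dipole([0.005, 0.01, 0.02], [0, 0, 1e-9])
    model.bind(dip)
    b = model.assemble_rhs(dip)
    assert b.storage == "sparse"
    assert b.nnz <= 40  # bounded by the vertex-star size, not by n
    assert b.nnz < transfer.shape[1] // 100


def test_zero_moment_guard():
    with pytest.raises(ValueError, match="moment"):
        Dipole([0, 0, 0.02], [0, 0, 0])
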