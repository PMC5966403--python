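"""Ensemble geometry: superposition, RMSD/RMSF, distances, loop states."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tsl2screen import hairpinstruct as hs
from tsl2screen import synthio
from tsl2screen.errors import EnsembleFormatError, InsufficientDataError


def quaternion_rmsd(X, Y):
    """Independent superposition oracle: Horn's closed-form quaternion
    method for the least-squares proper rotation."""
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    S = X0.T @ Y0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(X0 ** 2) + np.sum(Y0 ** 2) - 2.0 * lam) / X.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def test_kabsch_recovers_rigid_transform():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 3))
    R0 = Rotation.random(random_state=2).as_matrix()
    Y = X @ R0.T + np.array([3.0, -1.0, 2.0])
    sup = hs.kabsch(X, Y)
    assert sup.rmsd < 1e-9
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
    np.testing.assert_allclose(sup.apply(X), Y, atol=1e-9)


def test_kabsch_rejects_improper_rotation():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 3))
    mirror = X * np.array([-1.0, 1.0, 1.0])
    sup = hs.kabsch(X, mirror)
    assert sup.rmsd > 0.1
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


def test_kabsch_symmetric():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(8, 3))
    Y = rng.normal(size=(8, 3))
    assert hs.kabsch(X, Y).rmsd == pytest.approx(hs.kabsch(Y, X).rmsd,
                                                 abs=1e-10)


def test_kabsch_matches_quaternion_oracle():
    rng = np.random.default_rng(5)
    for _ in range(25):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 3))
        assert hs.kabsch(X, Y).rmsd == pytest.approx(quaternion_rmsd(X, Y),
                                                     abs=1e-8)


def test_kabsch_too_few_atoms():
    with pytest.raises(InsufficientDataError):
        hs.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def test_kabsch_flags_collinear_sets():
    X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    sup = hs.kabsch(X, X.copy())
    assert sup.degenerate


# ---------------------------------------------------------------------------
# pairwise bundle RMSD
# ---------------------------------------------------------------------------

def _jittered_bundle(n_models, sigma, seed=0):
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=seed, n_frames=n_models, p_triloop=0.0, sigma=sigma))
    return ens


def test_bundle_rmsd_identical_models():
    ens = _jittered_bundle(5, sigma=0.0)
    mean, sd = hs.pairwise_bundle_rmsd(ens, "all_heavy")
    assert mean == pytest.approx(0.0, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_bundle_rmsd_two_models_equals_single_pair():
    ens = _jittered_bundle(2, sigma=0.4)
    mean, sd = hs.pairwise_bundle_rmsd(ens, "all_heavy")
    idx = ens.select("all_heavy")
    single = hs.kabsch(ens.coords[0, idx], ens.coords[1, idx]).rmsd
    assert mean == pytest.approx(single)
    assert sd == pytest.approx(0.0)


def test_metrics_invariant_under_global_rigid_motion(two_state_ensemble):
    ens, _ = two_state_ensemble
    small = hs.HairpinEnsemble(coords=ens.coords[:30], atoms=ens.atoms)
    rng = np.random.default_rng(9)
    moved = small.coords.copy()
    for f in range(moved.shape[0]):
        R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
        moved[f] = moved[f] @ R.T + rng.normal(0, 5.0, 3)
    ens2 = hs.HairpinEnsemble(coords=moved, atoms=small.atoms)
    m1, s1 = hs.pairwise_bundle_rmsd(small, "all_heavy")
    m2, s2 = hs.pairwise_bundle_rmsd(ens2, "all_heavy")
    assert m2 == pytest.approx(m1, abs=1e-6)
    r1, _ = hs.rmsf(small)
    r2, _ = hs.rmsf(ens2)
    np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-6)
    d1, _, _ = hs.residue_distance_series(small, 1, 19, "c1")
    d2, _, _ = hs.residue_distance_series(ens2, 1, 19, "c1")
    np.testing.assert_allclose(d1, d2, atol=1e-6)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_rmsf_static_trajectory_is_zero():
    ens = _jittered_bundle(10, sigma=0.0)
    per_res, per_atom = hs.rmsf(ens)
    assert np.all(per_atom < 1e-12)


def test_rmsf_isotropic_jitter_analytic_value():
    """Pure sigma-jitter about one reference: per-atom RMSF -> sigma*sqrt(3)."""
    sigma = 0.5
    ens = _jittered_bundle(10_000, sigma=sigma, seed=13)
    _, per_atom = hs.rmsf(ens)
    assert per_atom.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.02)


def test_rmsf_loop_exceeds_stem_in_two_state_mixture(two_state_ensemble):
    ens, _ = two_state_ensemble
    per_res, _ = hs.rmsf(ens)
    loop = per_res.loc[[8, 9, 10, 11, 12]].mean()
    stem = per_res.loc[[3, 4, 5, 6]].mean()
    assert loop > stem


# ---------------------------------------------------------------------------
# distances and loop states
# ---------------------------------------------------------------------------

def test_distance_series_single_atom_residue(toy_ensemble):
    d, mean, sd = hs.residue_distance_series(toy_ensemble, 1, 2, mode="c1")
    np.testing.assert_allclose(d, [5.0, 5.0])
    # a one-atom residue's centre of mass is the atom position
    d_com, _, _ = hs.residue_distance_series(toy_ensemble, 1, 2, mode="com")
    com1 = (30.974 * np.array([0, 0, 0]) + 12.011 * np.array([1, 0, 0])
            + 14.007 * np.array([2, 0, 0])) / (30.974 + 12.011 + 14.007)
    assert d_com[0] == pytest.approx(6.0 - com1[0])


def test_distance_series_matches_reference_construction():
    ens, truth = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=3, n_frames=300, p_triloop=1.0, sigma=0.1))
    ref = truth.attrs["reference"]
    _, mean, _ = hs.residue_distance_series(ens, 8, 12, "c1")
    assert mean == pytest.approx(ref["d_loop_c1_triloop"], abs=0.1)


def test_loop_state_classification_pure_states():
    ens, truth = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=4, n_frames=50, p_triloop=1.0, sigma=0.0))
    ref = truth.attrs["reference"]
    thr = hs.loop_state_threshold(ref["d_loop_com_triloop"],
                                  ref["d_loop_com_pentaloop"])
    res = hs.classify_loop_state(ens, threshold=thr)
    assert res.fraction_triloop == 1.0


def test_loop_state_boundary_is_pentaloop(toy_ensemble):
    # frame distance exactly at the threshold: strict inequality
    d, _, _ = hs.residue_distance_series(toy_ensemble, 1, 2, mode="c1")
    res = hs.classify_loop_state(toy_ensemble, threshold=float(d[0]),
                                 mode="c1", res_a=1, res_b=2)
    assert set(res.states) == {"pentaloop"}


def test_loop_state_mixture_recovery():
    ens, truth = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=6, n_frames=5000, p_triloop=0.7))
    ref = truth.attrs["reference"]
    thr = hs.loop_state_threshold(ref["d_loop_com_triloop"],
                                  ref["d_loop_com_pentaloop"])
    res = hs.classify_loop_state(ens, threshold=thr)
    assert res.fraction_triloop == pytest.approx(0.7, abs=0.02)
    assert res.ci_low < res.fraction_triloop < res.ci_high
    # fractions invariant to frame order
    rev = hs.HairpinEnsemble(coords=ens.coords[::-1].copy(), atoms=ens.atoms)
    res2 = hs.classify_loop_state(rev, threshold=thr)
    assert res2.fraction_triloop == res.fraction_triloop


def test_loop_state_threshold_validation(toy_ensemble):
    with pytest.raises(ValueError):
        hs.classify_loop_state(toy_ensemble, threshold=-1.0, mode="c1",
                               res_a=1, res_b=2)


# ---------------------------------------------------------------------------
# opening shift
# ---------------------------------------------------------------------------

def test_opening_shift_identical_ensembles():
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=8, n_frames=400, p_triloop=0.5))
    res = hs.opening_shift(ens, ens)
    assert res.delta_mean == pytest.approx(0.0)
    assert res.ci_low <= 0.0 <= res.ci_high


def test_opening_shift_recovers_planted_opening():
    free, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=9, n_frames=800, p_triloop=0.5))
    bound, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=10, n_frames=800, p_triloop=0.5, terminal_opening_extra=2.0))
    res = hs.opening_shift(free, bound)
    assert 1.5 <= res.delta_mean <= 2.5
    assert res.ci_low > 0.0
    # built-in coupling: terminal opening anticorrelates with loop closure
    assert res.corr_free < 0 and res.corr_bound < 0


def test_opening_shift_needs_one_block():
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=12, n_frames=20))
    with pytest.raises(InsufficientDataError):
        hs.opening_shift(ens, ens, block_length=50)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def test_pdb_round_trip(tmp_path):
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=2, n_frames=4))
    path = tmp_path / "ens.pdb"
    hs.write_ensemble(ens, path)
    back = hs.read_ensemble(path)
    assert back.n_frames == 4
    assert back.atoms["res_seq"].tolist() == ens.atoms["res_seq"].tolist()
    np.testing.assert_allclose(back.coords, ens.coords, atol=1e-3)


def test_pdb_star_dialect_accepted(tmp_path):
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=2, n_frames=2))
    path = tmp_path / "ens.pdb"
    hs.write_ensemble(ens, path)
    text = path.read_text().replace("C1'", "C1*")
    star = tmp_path / "star.pdb"
    star.write_text(text)
    back = hs.read_ensemble(star)
    assert (back.atoms["atom_name"] == "C1'").sum() == 19


def test_pdb_inconsistent_roster_names_model_and_atom(tmp_path):
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=2, n_frames=3))
    path = tmp_path / "ens.pdb"
    hs.write_ensemble(ens, path)
    lines = path.read_text().splitlines(keepends=True)
    # drop the first C1' atom record inside MODEL 2
    out, in_model2, dropped = [], False, False
    for ln in lines:
        if ln.startswith("MODEL"):
            in_model2 = "2" == ln.split()[1]
        if in_model2 and not dropped and " C1' " in ln:
            dropped = True
            continue
        out.append(ln)
    bad = tmp_path / "bad.pdb"
    bad.write_text("".join(out))
    with pytest.raises(EnsembleFormatError, match="model 2"):
        hs.read_ensemble(bad)


def test_trajectory_tsv_round_trip(tmp_path, toy_ensemble):
    rows = []
    for f in range(toy_ensemble.n_frames):
        for i, row in toy_ensemble.atoms.iterrows():
            x, y, z = toy_ensemble.coords[f, i]
            rows.append((f, row["res_seq"], row["res_name"],
                         row["atom_name"], row["element"], x, y, z))
    df = pd.DataFrame(rows, columns=["frame", "res_seq", "res_name",
                                     "atom_name", "element", "x", "y", "z"])
    path = tmp_path / "traj.tsv"
    df.to_csv(path, sep="\t", index=False)
    back = hs.read_trajectory_tsv(path)
    assert back.n_frames == toy_ensemble.n_frames
    d, _, _ = hs.residue_distance_series(back, 1, 2, mode="c1")
    np.testing.assert_allclose(d, [5.0, 5.0])
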