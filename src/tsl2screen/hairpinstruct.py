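"""Geometry analytics over stem-loop structure ensembles.

Works on a 19-residue RNA hairpin (helical stem residues 1-7 paired with
13-19, loop residues 8-12) represented as an ensemble of frames with an
identical atom roster: NMR bundles read from multi-model PDB files, MD
trajectory snapshots, or synthetic ensembles from
:mod:`tsl2screen.synthio`.

Provides Kabsch least-squares superposition (proper rotations only),
average pairwise bundle RMSD (the NMR precision statistic), per-residue
RMSF about an iteratively refined mean structure, internal distance
observables — terminal opening d(C1' res 1, C1' res 19) and loop closure
d(res 8, res 12) — two-state pentaloop/triloop classification of frames,
and free-vs-bound terminal opening shifts with a moving-block bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

from .errors import EnsembleFormatError, InsufficientDataError

STEM_RESIDUES = tuple(range(1, 8)) + tuple(range(13, 20))
LOOP_RESIDUES = tuple(range(8, 13))

#: fallback loop-closure threshold (Angstrom, centre-of-mass mode) when no
#: reference-state distances are available; calibration constant
DEFAULT_LOOP_THRESHOLD = 7.0


# ---------------------------------------------------------------------------
# ensemble container and I/O
# ---------------------------------------------------------------------------

@dataclass
class HairpinEnsemble:
    """Frames x atoms x 3 coordinates plus an atom table.

    ``atoms`` has one row per atom with columns ``res_seq`` (1-based,
    contiguous), ``res_name``, ``atom_name``, ``element`` and ``mass``
    (Da); the roster is identical across frames by construction.
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    atoms: pd.DataFrame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleFormatError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise EnsembleFormatError(
                f"{self.coords.shape[1]} coordinate columns but "
                f"{len(self.atoms)} atom rows")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleFormatError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selection) -> np.ndarray:
        """Atom indices for a named selection (``all_heavy``,
        ``stem_heavy``, ``loop_heavy``) or an explicit boolean mask /
        integer index array."""
        if isinstance(selection, str):
            heavy = self.atoms["element"].str.upper() != "H"
            if selection == "all_heavy":
                mask = heavy
            elif selection == "stem_heavy":
                mask = heavy & self.atoms["res_seq"].isin(STEM_RESIDUES)
            elif selection == "loop_heavy":
                mask = heavy & self.atoms["res_seq"].isin(LOOP_RESIDUES)
            else:
                raise ValueError(f"unknown selection {selection!r}")
            idx = np.flatnonzero(mask.to_numpy())
        else:
            idx = np.atleast_1d(np.asarray(selection))
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        if idx.size == 0:
            raise EnsembleFormatError(f"selection {selection!r} matches no atoms")
        return idx

    def residue_atoms(self, res_seq: int, heavy_only: bool = True) -> np.ndarray:
        mask = self.atoms["res_seq"] == res_seq
        if heavy_only:
            mask &= self.atoms["element"].str.upper() != "H"
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise EnsembleFormatError(f"no atoms for residue {res_seq}")
        return idx

    def atom_index(self, res_seq: int, atom_name: str) -> int:
        name = _normalise_atom_name(atom_name)
        mask = (self.atoms["res_seq"] == res_seq) \
            & (self.atoms["atom_name"] == name)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise EnsembleFormatError(
                f"atom {atom_name!r} missing from residue {res_seq}")
        return int(idx[0])


def _normalise_atom_name(name: str) -> str:
    # accept both prime dialects: C1' and C1*
    return name.strip().replace("*", "'").replace("′", "'")


def read_ensemble(path) -> HairpinEnsemble:
    """Read a (multi-)model PDB file into a :class:`HairpinEnsemble`.

    MODEL/ENDMDL blocks become frames.  Atom names are normalised to the
    apostrophe dialect (C1* -> C1').  For alternate locations the first
    conformer encountered is kept; hydrogens are kept in the roster and
    excluded by the ``*_heavy`` selections.  Models whose atom rosters
    disagree raise :class:`EnsembleFormatError` naming the model and atom.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EnsembleFormatError(f"{path}: no models found")

    rosters, frames = [], []
    for model in st:
        keys, xyz = [], []
        seen = set()
        for chain in model:
            for residue in chain:
                for atom in residue:
                    key = (residue.seqid.num, residue.name.strip(),
                           _normalise_atom_name(atom.name))
                    if key in seen:  # alternate location: keep first
                        continue
                    seen.add(key)
                    keys.append(key + (atom.element.name,
                                       float(atom.element.weight)))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        rosters.append(keys)
        frames.append(np.asarray(xyz, dtype=float))

    ref = rosters[0]
    ref_set = {k[:3] for k in ref}
    for m, roster in enumerate(rosters[1:], start=2):
        cur = {k[:3] for k in roster}
        if cur != ref_set:
            missing = sorted(ref_set - cur)
            extra = sorted(cur - ref_set)
            detail = []
            if missing:
                r, n, a = missing[0]
                detail.append(f"missing atom {a!r} of residue {n}{r}")
            if extra:
                r, n, a = extra[0]
                detail.append(f"unexpected atom {a!r} of residue {n}{r}")
            raise EnsembleFormatError(
                f"model {m} roster differs from model 1: " + "; ".join(detail))
        # order may differ between models: map onto model-1 order
        if [k[:3] for k in roster] != [k[:3] for k in ref]:
            order = {k[:3]: i for i, k in enumerate(roster)}
            frames[m - 1] = frames[m - 1][[order[k[:3]] for k in ref]]

    atoms = pd.DataFrame(ref, columns=["res_seq", "res_name", "atom_name",
                                       "element", "mass"])
    return HairpinEnsemble(coords=np.stack(frames), atoms=atoms)


def write_ensemble(ensemble: HairpinEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records,
    single chain A, coordinates at the PDB's 3-decimal precision)."""
    st = gemmi.Structure()
    st.name = "tsl2screen ensemble"
    for f in range(ensemble.n_frames):
        model = gemmi.Model(f + 1)
        chain = gemmi.Chain("A")
        for res_seq, sub in ensemble.atoms.groupby("res_seq", sort=True):
            res = gemmi.Residue()
            res.name = str(sub["res_name"].iloc[0])
            res.seqid = gemmi.SeqId(int(res_seq), " ")
            for i, row in sub.iterrows():
                atom = gemmi.Atom()
                atom.name = str(row["atom_name"])
                atom.element = gemmi.Element(str(row["element"]))
                x, y, z = ensemble.coords[f, i]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_trajectory_tsv(path) -> HairpinEnsemble:
    """Read a plain trajectory table with columns
    ``frame, res_seq, res_name, atom_name, element, x, y, z``."""
    df = pd.read_csv(path, sep="\t")
    df["atom_name"] = df["atom_name"].map(_normalise_atom_name)
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values(["res_seq", "atom_name"])
    atoms = first[["res_seq", "res_name", "atom_name", "element"]].copy()
    atoms["mass"] = [float(gemmi.Element(e).weight) for e in atoms["element"]]
    coords = np.empty((len(frames), len(atoms), 3))
    key_order = list(zip(first["res_seq"], first["atom_name"]))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values(["res_seq", "atom_name"])
        if list(zip(sub["res_seq"], sub["atom_name"])) != key_order:
            raise EnsembleFormatError(f"frame {f}: atom roster differs")
        coords[fi] = sub[["x", "y", "z"]].to_numpy(dtype=float)
    return HairpinEnsemble(coords=coords, atoms=atoms.reset_index(drop=True))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    degenerate: bool = False

    def apply(self, coords) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(X, Y) -> Superposition:
    """Optimal proper-rotation least-squares superposition of X onto Y.

    Returns the rotation R (det = +1, enforced by the SVD sign
    correction, so mirror images are never matched), translation t with
    ``X @ R.T + t ~ Y``, and the minimised RMSD.  Near-collinear atom
    sets are superposed but flagged ``degenerate``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise InsufficientDataError("kabsch needs >= 3 atoms")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = X0 @ R.T - Y0
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    scale = S[0] if S[0] > 0 else 1.0
    degenerate = bool(S[1] / scale < 1e-8)
    t = yc - xc @ R.T
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         degenerate=degenerate)


def pairwise_bundle_rmsd(ensemble: HairpinEnsemble,
                         selection="all_heavy"):
    """Average pairwise RMSD of a structure bundle.

    Every unordered model pair is superposed independently on the
    selected atoms and the minimised RMSD recorded; returns
    ``(mean, sd)`` over all N(N-1)/2 pairs (population SD, matching the
    usual bundle-precision statistic).
    """
    idx = ensemble.select(selection)
    n = ensemble.n_frames
    if n < 2:
        raise InsufficientDataError("need >= 2 models for pairwise RMSD")
    sub = ensemble.coords[:, idx, :]
    vals = [kabsch(sub[i], sub[j]).rmsd
            for i in range(n) for j in range(i + 1, n)]
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std())


def rmsf(ensemble: HairpinEnsemble, selection="all_heavy",
         n_iterations: int = 3):
    """Per-residue RMSF about an iteratively refined mean structure.

    All frames are superposed (on the selected atoms) onto the running
    mean structure, the mean is recomputed, and the cycle repeats
    ``n_iterations`` times.  Per-atom RMSF is the root mean squared
    displacement from the final mean position; the per-residue value is
    the unweighted mean over that residue's selected atoms.  Returns
    ``(per_residue: Series, per_atom: ndarray)``.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("RMSF needs >= 2 frames")
    idx = ensemble.select(selection)
    frames = ensemble.coords[:, idx, :].copy()
    ref = frames[0]
    for _ in range(n_iterations):
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            aligned[f] = kabsch(frames[f], ref).apply(frames[f])
        ref = aligned.mean(axis=0)
        frames = aligned
    disp2 = np.sum((frames - ref) ** 2, axis=2)  # (F, A)
    per_atom = np.sqrt(disp2.mean(axis=0))
    res = ensemble.atoms["res_seq"].to_numpy()[idx]
    per_residue = pd.Series(per_atom).groupby(res).mean()
    per_residue.index.name = "res_seq"
    return per_residue, per_atom


# ---------------------------------------------------------------------------
# distance observables
# ---------------------------------------------------------------------------

def residue_distance_series(ensemble: HairpinEnsemble, res_a: int,
                            res_b: int, mode: str = "c1"):
    """Per-frame distance between two residues, in Angstrom.

    ``mode='c1'`` uses the C1' atoms; ``mode='com'`` the mass-weighted
    centre of each residue's heavy atoms.  Internal coordinates: no
    superposition is involved.  Returns ``(series, mean, sd)``.
    """
    if mode == "c1":
        pa = ensemble.coords[:, ensemble.atom_index(res_a, "C1'"), :]
        pb = ensemble.coords[:, ensemble.atom_index(res_b, "C1'"), :]
    elif mode == "com":
        pa = _residue_com(ensemble, res_a)
        pb = _residue_com(ensemble, res_b)
    else:
        raise ValueError(f"mode must be 'c1' or 'com', got {mode!r}")
    d = np.linalg.norm(pa - pb, axis=1)
    return d, float(d.mean()), float(d.std())


def _residue_com(ensemble: HairpinEnsemble, res_seq: int) -> np.ndarray:
    idx = ensemble.residue_atoms(res_seq, heavy_only=True)
    masses = ensemble.atoms["mass"].to_numpy()[idx]
    w = masses / masses.sum()
    return np.einsum("fad,a->fd", ensemble.coords[:, idx, :], w)


@dataclass
class LoopStateResult:
    states: np.ndarray  # 'triloop' / 'pentaloop' per frame
    fraction_triloop: float
    ci_low: float
    ci_high: float
    threshold: float
    d_loop: np.ndarray


def loop_state_threshold(d_loop_triloop_ref: float,
                         d_loop_pentaloop_ref: float) -> float:
    """Midpoint of the two reference-state loop-closure distances."""
    return 0.5 * (float(d_loop_triloop_ref) + float(d_loop_pentaloop_ref))


def classify_loop_state(ensemble: HairpinEnsemble,
                        threshold: float | None = None,
                        mode: str = "com", res_a: int = 8,
                        res_b: int = 12) -> LoopStateResult:
    """Per-frame pentaloop/triloop assignment from the loop-closure
    distance d(res 8, res 12).

    A frame is a triloop iff d_loop is strictly below ``threshold``
    (frames exactly at the threshold are pentaloops).  With no threshold
    given the calibration default of 7.0 A (centre-of-mass mode) is
    used; prefer :func:`loop_state_threshold` when reference-state
    distances are known.  The triloop fraction is reported with a
    Wilson 95% binomial CI.
    """
    if threshold is None:
        threshold = DEFAULT_LOOP_THRESHOLD
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    d, _, _ = residue_distance_series(ensemble, res_a, res_b, mode=mode)
    tri = d < threshold
    k, n = int(tri.sum()), int(tri.size)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95,
                                             method="wilson")
    states = np.where(tri, "triloop", "pentaloop")
    return LoopStateResult(states=states, fraction_triloop=k / n,
                           ci_low=float(ci.low), ci_high=float(ci.high),
                           threshold=float(threshold), d_loop=d)


# ---------------------------------------------------------------------------
# free-vs-bound shifts
# ---------------------------------------------------------------------------

def _block_bootstrap_mean(x: np.ndarray, block_length: int, n_boot: int,
                          rng: np.random.Generator) -> np.ndarray:
    n = x.size
    if n < block_length:
        raise InsufficientDataError(
            f"series of {n} frames shorter than one block ({block_length})")
    n_blocks = int(np.ceil(n / block_length))
    starts = rng.integers(0, n - block_length + 1, size=(n_boot, n_blocks))
    # moving blocks, concatenated and trimmed to the original length
    offsets = np.arange(block_length)
    samples = x[(starts[:, :, None] + offsets).reshape(n_boot, -1)[:, :n]]
    return samples.mean(axis=1)


@dataclass
class OpeningShift:
    delta_mean: float  # Angstrom, bound - free
    ci_low: float
    ci_high: float
    corr_free: float  # Pearson corr(d_term, d_loop) within each ensemble
    corr_bound: float


def opening_shift(ensemble_free: HairpinEnsemble,
                  ensemble_bound: HairpinEnsemble,
                  term=(1, 19), loop=(8, 12), loop_mode: str = "com",
                  block_length: int = 50, n_boot: int = 1000,
                  seed: int = 0) -> OpeningShift:
    """Ligand-induced terminal-opening shift with a bootstrap CI.

    Delta = mean d_term(bound) - mean d_term(free), where d_term is the
    C1'-C1' distance between the terminal residues.  The 95% CI comes
    from a moving-block bootstrap (default block length 50 frames) of
    each series independently, which respects short-range frame
    autocorrelation.  The Pearson correlation between terminal opening
    and loop closure across frames is reported for each ensemble; a
    negative value reflects the coupled open-terminus/closed-loop motion.
    """
    rng = np.random.default_rng(seed)
    d_free, _, _ = residue_distance_series(ensemble_free, *term, mode="c1")
    d_bound, _, _ = residue_distance_series(ensemble_bound, *term, mode="c1")
    delta = float(d_bound.mean() - d_free.mean())
    bf = _block_bootstrap_mean(d_free, block_length, n_boot, rng)
    bb = _block_bootstrap_mean(d_bound, block_length, n_boot, rng)
    lo, hi = np.percentile(bb - bf, [2.5, 97.5])

    def _corr(ens):
        dt, _, _ = residue_distance_series(ens, *term, mode="c1")
        dl, _, _ = residue_distance_series(ens, *loop, mode=loop_mode)
        if np.ptp(dt) == 0 or np.ptp(dl) == 0:
            return float("nan")
        return float(stats.pearsonr(dt, dl)[0])

    return OpeningShift(delta_mean=delta, ci_low=float(lo), ci_high=float(hi),
                        corr_free=_corr(ensemble_free),
                        corr_bound=_corr(ensemble_bound))
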