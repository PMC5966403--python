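"""Seeded synthetic-data generators for every pipeline input.

Each generator emits the data table a pipeline stage consumes *plus* a
ground-truth table, so every downstream statistic can be scored against
what was planted.  All randomness flows through one
``numpy.random.default_rng(seed)`` per call: identical config, identical
seed, identical bytes.

What is emulated, per generator:

* :func:`gen_plate` — a focused-library fluorescence-displacement screen
  (default 304 compounds in quadruplicate) with the four control roles
  (A: dye+RNA+compound, B: dye+compound, C: dye+RNA, D: dye alone),
  multiplicative lognormal plate-reader noise, a planted binder fraction
  with displacement effects, and a fraction of autofluorescent compounds
  whose intrinsic emission inflates their A and B wells.
* :func:`gen_dose` — replicated 4PL dose-response series.
* :func:`gen_junction_table` — beta-binomially overdispersed
  inclusion/skipping junction counts with planted dPSI effects between a
  treated and a control group.
* :func:`gen_hairpin_ensemble` — an idealised 19-residue stem-loop
  coordinate trajectory mixing two reference conformations, "pentaloop"
  (loop residues 8-12 splayed, terminus closed) and "triloop" (residues
  8 and 12 closed together, terminus opened), so terminal opening and
  loop closure are anticorrelated across frames by construction.
* :func:`gen_probe_panel`, :func:`gen_cd_spectrum`, :func:`gen_gel_bands`,
  :func:`gen_ct_table` — probe-panel fixtures with planted correlation to
  exon inclusion, signed-Gaussian CD spectra, gel band pairs consistent
  with a stated true inclusion, and Ct tables consistent with a stated
  fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .hairpinstruct import HairpinEnsemble

# Pinned residue identities of the 19-nt stem-loop (1-based).  Positions
# not pinned default to adenosine and can be overridden per config.
PINNED_SEQUENCE = {1: "A", 2: "U", 8: "A", 9: "A", 10: "A", 11: "U",
                   12: "U", 15: "G", 18: "G", 19: "U"}


def _check(cond, msg):
    if not cond:
        raise ConfigError(msg)


def _lognormal_factors(rng, cv, size):
    """Mean-one multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# plate generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateConfig:
    """Fluorescence-displacement plate conditions.

    Signal levels follow the worked Eq.-1 scale: dye-alone background
    ``dye_level`` = 200 a.u. and full dye+RNA signal 1000 a.u.
    ``n_control_replicates`` defaults to 16 (two dedicated control
    columns of a 96-well plate) for a stable plate-mean window.
    """

    seed: int
    n_compounds: int = 304
    n_replicates: int = 4
    n_control_replicates: int = 16
    n_dmso: int = 8
    binder_fraction: float = 0.18
    mean_displacement: float = 40.0  # % activity of a true binder
    sd_displacement: float = 10.0
    autofluor_fraction: float = 0.02
    autofluor_scale: float = 0.5  # x full signal, added to A and B wells
    cv: float = 0.05
    dye_level: float = 200.0
    rna_window: float = 800.0  # C - D before noise
    concentration_uM: float = 100.0

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        for name in ("binder_fraction", "autofluor_fraction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _check(self.cv >= 0, f"cv must be >= 0, got {self.cv}")
        _check(self.n_compounds >= 1, "n_compounds must be >= 1")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")


def gen_plate(config: PlateConfig):
    """Generate one screening plate set.

    Returns ``(wells, truth)``: a well table with columns
    ``plate_id, well_id, role, compound_id, concentration_uM, replicate,
    fluorescence`` and a truth table with one row per compound
    (``entity_id, true_label, true_effect, autofluorescent``).  DMSO
    control pseudo-compounds (label ``control``) are included for hit
    calling; the shared C and D control wells carry no compound id.
    """
    rng = np.random.default_rng(config.seed)
    n, r = config.n_compounds, config.n_replicates
    d0, c0 = config.dye_level, config.dye_level + config.rna_window

    compound_ids = [f"CMP{i + 1:04d}" for i in range(n)]
    is_binder = rng.random(n) < config.binder_fraction
    effect = np.where(
        is_binder,
        np.clip(rng.normal(config.mean_displacement,
                           config.sd_displacement, n), 0.0, 100.0),
        0.0)
    is_auto = rng.random(n) < config.autofluor_fraction
    auto_offset = np.where(
        is_auto, config.autofluor_scale * c0 * rng.uniform(0.5, 1.5, n), 0.0)

    # clean per-replicate signals; DMSO pseudo-compounds behave as
    # zero-effect, non-fluorescent compounds
    dmso_ids = [f"DMSO{i + 1:02d}" for i in range(config.n_dmso)]
    all_ids = compound_ids + dmso_ids
    eff_all = np.concatenate([effect, np.zeros(config.n_dmso)])
    auto_all = np.concatenate([auto_offset, np.zeros(config.n_dmso)])
    m = len(all_ids)

    b_clean = np.tile((d0 + auto_all)[:, None], (1, r))
    a_clean = b_clean + (1.0 - eff_all[:, None] / 100.0) * (c0 - d0)
    a_wells = a_clean * _lognormal_factors(rng, config.cv, (m, r))
    b_wells = b_clean * _lognormal_factors(rng, config.cv, (m, r))
    c_wells = c0 * _lognormal_factors(rng, config.cv, config.n_control_replicates)
    d_wells = d0 * _lognormal_factors(rng, config.cv, config.n_control_replicates)

    recs = []
    wid = 1
    for role, block in (("A", a_wells), ("B", b_wells)):
        for ci, cid in enumerate(all_ids):
            for rep in range(r):
                recs.append(("P01", f"W{wid:05d}", role, cid,
                             config.concentration_uM, rep + 1,
                             block[ci, rep]))
                wid += 1
    for role, block in (("C", c_wells), ("D", d_wells)):
        for rep in range(block.size):
            recs.append(("P01", f"W{wid:05d}", role, "", 0.0, rep + 1,
                         block[rep]))
            wid += 1
    wells = pd.DataFrame(recs, columns=[
        "plate_id", "well_id", "role", "compound_id", "concentration_uM",
        "replicate", "fluorescence"])

    truth = pd.DataFrame({
        "entity_id": all_ids,
        "true_label": (["binder" if b else "non-binder" for b in is_binder]
                       + ["control"] * config.n_dmso),
        "true_effect": eff_all,
        "autofluorescent": np.concatenate(
            [is_auto, np.zeros(config.n_dmso, dtype=bool)]),
    })
    return wells, truth


# ---------------------------------------------------------------------------
# dose-response generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseConfig:
    """Replicated 4PL dose series.  Default truth echoes the primary
    binding assay: EC50 16 uM, hill 1, 8 half-log-spaced doses x 4
    replicates, 5% multiplicative noise."""

    seed: int
    bottom: float = 10.0
    top: float = 100.0
    ec50: float = 16.0
    hill: float = 1.0
    n_doses: int = 8
    n_replicates: int = 4
    cv: float = 0.05
    dose_span: float = 1.5  # doses span ec50 * 10^(+-dose_span)

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(self.ec50 > 0, "ec50 must be positive")
        _check(self.hill > 0, "hill must be positive")
        _check(self.n_doses >= 4, "need >= 4 concentrations spanning ec50")
        _check(self.cv >= 0, "cv must be >= 0")


def four_pl(x, bottom, top, ec50, hill):
    """The 4PL closed form y = bottom + (top-bottom)/(1+(ec50/x)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def gen_dose(config: DoseConfig):
    """Returns ``(table, truth)``: a dose table with columns
    ``concentration_uM, replicate, response`` and the true 4PL
    parameters as a one-row DataFrame."""
    rng = np.random.default_rng(config.seed)
    doses = config.ec50 * np.logspace(-config.dose_span, config.dose_span,
                                      config.n_doses)
    _check(np.all(doses > 0), "concentrations must be positive")
    mu = four_pl(doses, config.bottom, config.top, config.ec50, config.hill)
    resp = mu[:, None] * _lognormal_factors(
        rng, config.cv, (config.n_doses, config.n_replicates))
    table = pd.DataFrame({
        "concentration_uM": np.repeat(doses, config.n_replicates),
        "replicate": np.tile(np.arange(1, config.n_replicates + 1),
                             config.n_doses),
        "response": resp.ravel(),
    })
    truth = pd.DataFrame([{
        "bottom": config.bottom, "top": config.top,
        "ec50": config.ec50, "hill": config.hill,
        "n_replicates": config.n_replicates,
    }])
    return table, truth


# ---------------------------------------------------------------------------
# junction-count generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionConfig:
    """Cassette-exon junction counts for a treated-vs-control contrast.

    ``depth`` is the junction-read total per (event, sample); counts are
    beta-binomial with intraclass correlation ``rho`` (one value per
    dataset).  A fraction of events carries a planted |dPSI| between
    groups, signed so the treated PSI stays inside [0, 1].
    """

    seed: int
    n_events: int = 200
    n_samples_per_group: int = 4
    depth: int = 200
    rho: float = 0.01
    affected_fraction: float = 0.15
    dpsi: float = 0.5

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(self.depth > 0, "depth must be positive")
        _check(0.0 <= self.rho < 1.0, f"rho must be in [0, 1), got {self.rho}")
        _check(0.0 <= self.affected_fraction <= 1.0,
               "affected_fraction must be in [0, 1]")
        _check(0.0 <= self.dpsi <= 1.0, "dpsi must be in [0, 1]")


def _beta_binomial(rng, n, q, rho, size):
    """Beta-binomial draws with mean n*q and intraclass correlation rho."""
    q = np.broadcast_to(q, size)
    if rho == 0:
        return rng.binomial(n, q)
    nu = (1.0 - rho) / rho  # a + b
    a = np.clip(q * nu, 1e-12, None)
    b = np.clip((1.0 - q) * nu, 1e-12, None)
    p = rng.beta(a, b)
    return rng.binomial(n, p)


def gen_junction_table(config: JunctionConfig):
    """Returns ``(junctions, truth)``.

    ``junctions`` has one row per (event, sample) with columns
    ``event_id, gene_id, sample_id, group, incl_counts, skip_counts``
    where ``incl_counts`` is the summed two-junction inclusion count.
    With true PSI p, the inclusion-junction proportion of the junction
    reads is 2p/(1+p), so the (I/2)/((I/2)+S) estimator is centred on p.
    Some genes host two events, mimicking multi-event genes in the
    roll-up.  ``truth`` has per-event labels and true dPSI.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    event_ids = [f"EV{i + 1:05d}" for i in range(n)]
    # every fourth event shares its gene with the previous event
    gene_idx = [i - 1 if (i % 4 == 3) else i for i in range(n)]
    gene_ids = [f"GENE{g + 1:05d}" for g in gene_idx]

    affected = rng.random(n) < config.affected_fraction
    psi_control = rng.uniform(0.1, 0.9, n)
    sign = np.where(psi_control + config.dpsi <= 0.98, 1.0, -1.0)
    true_dpsi = np.where(affected, sign * config.dpsi, 0.0)
    psi_treated = np.clip(psi_control + true_dpsi, 0.0, 1.0)

    rows = []
    for group, psis in (("control", psi_control), ("treated", psi_treated)):
        q = 2.0 * psis / (1.0 + psis)
        for s in range(config.n_samples_per_group):
            incl = _beta_binomial(rng, config.depth, q, config.rho, (n,))
            skip = config.depth - incl
            sample_id = f"{group}_{s + 1}"
            rows.append(pd.DataFrame({
                "event_id": event_ids, "gene_id": gene_ids,
                "sample_id": sample_id, "group": group,
                "incl_counts": incl, "skip_counts": skip,
            }))
    junctions = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({
        "entity_id": event_ids,
        "gene_id": gene_ids,
        "true_label": np.where(affected, "affected", "unaffected"),
        "true_effect": true_dpsi,
        "psi_control": psi_control,
        "psi_treated": psi_treated,
    })
    return junctions, truth


# ---------------------------------------------------------------------------
# hairpin ensemble generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinConfig:
    """Two-state 19-residue stem-loop trajectory.

    The idealised geometry (helical rise 2.8 A, twist 33 deg/residue,
    C1'-C1' pair span 10.4 A) is a stand-in convention; only the residue
    indexing semantics (terminal pair 1/19, loop 8-12, triloop 9-11) are
    meaningful.  Frame states are i.i.d. Bernoulli(p_triloop) — no
    Markov dwell times — with isotropic Gaussian jitter sigma per axis.
    ``terminal_opening_extra`` shifts the terminal C1'-C1' distance of
    both reference states, emulating a ligand-bound ensemble.
    """

    seed: int
    n_frames: int = 1000
    p_triloop: float = 0.5
    sigma: float = 0.3  # A per axis
    terminal_opening_extra: float = 0.0  # A, added to d_term of both states
    sequence_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(0.0 <= self.p_triloop <= 1.0,
               f"p_triloop must be in [0, 1], got {self.p_triloop}")
        _check(self.sigma >= 0, f"sigma must be >= 0, got {self.sigma}")
        _check(self.n_frames >= 1, "n_frames must be >= 1")


_RISE = 2.8       # A per residue along the stem helix
_TWIST = np.deg2rad(33.0)
_RADIUS = 5.4     # chosen so the paired C1'-C1' span is ~10.4 A
_PAIR_PHASE = np.deg2rad(150.0)
_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}


def _sequence(config: HairpinConfig):
    seq = {i: "A" for i in range(1, 20)}
    seq.update(PINNED_SEQUENCE)
    for k, v in config.sequence_overrides.items():
        _check(1 <= int(k) <= 19, f"sequence override position {k} out of range")
        seq[int(k)] = str(v)
    return seq


def _reference_coords(state: str, terminal_extra: float):
    """C1' positions of the 19 residues for one reference state, plus the
    local inward unit vector used to place the other atoms."""
    pos = np.zeros((20, 3))  # 1-based
    axis_xy = np.zeros((20, 2))
    for j in range(1, 8):  # 5' strand
        th = _TWIST * (j - 1)
        pos[j] = [_RADIUS * np.cos(th), _RADIUS * np.sin(th), _RISE * (j - 1)]
        axis_xy[j] = [np.cos(th), np.sin(th)]
    for k in range(13, 20):  # 3' strand, antiparallel, paired with 20-k
        j = 20 - k
        th = _TWIST * (j - 1) + _PAIR_PHASE
        pos[k] = [_RADIUS * np.cos(th), _RADIUS * np.sin(th), _RISE * (j - 1)]
        axis_xy[k] = [np.cos(th), np.sin(th)]

    p7, p13 = pos[7], pos[13]
    centre = 0.5 * (p7 + p13)
    e1 = (p13 - p7) / np.linalg.norm(p13 - p7)
    up = np.array([0.0, 0.0, 1.0])
    if state == "pentaloop":
        # five residues splayed on a wide arc above the stem
        radius = 0.6 * np.linalg.norm(p13 - p7) * 1.2
        for i, res in enumerate(range(8, 13)):
            phi = np.pi * (i + 1) / 6.0
            pos[res] = centre + radius * (-np.cos(phi) * e1 + np.sin(phi) * up)
            axis_xy[res] = axis_xy[7]
    elif state == "triloop":
        # residues 8 and 12 close into a pair; 9-11 bulge on a tight arc
        pos[8] = centre - 2.5 * e1 + 1.5 * up
        pos[12] = centre + 2.5 * e1 + 1.5 * up
        for i, res in enumerate(range(9, 12)):
            phi = np.pi * (i + 1) / 4.0
            pos[res] = centre + 3.5 * (-np.cos(phi) * e1 + np.sin(phi) * up) \
                + 1.5 * up
            axis_xy[res] = axis_xy[7]
        axis_xy[8] = axis_xy[7]
        axis_xy[12] = axis_xy[13]
        # loop closing couples to terminal opening: splay the closing pair
        open_axis = pos[19] - pos[1]
        open_axis = open_axis / np.linalg.norm(open_axis)
        pos[1] -= 2.0 * open_axis
        pos[19] += 2.0 * open_axis
    else:  # pragma: no cover
        raise ValueError(f"unknown state {state!r}")

    if terminal_extra != 0.0:
        open_axis = pos[19] - pos[1]
        open_axis = open_axis / np.linalg.norm(open_axis)
        pos[1] -= 0.5 * terminal_extra * open_axis
        pos[19] += 0.5 * terminal_extra * open_axis
    return pos, axis_xy


def _build_atoms(seq):
    rows = []
    for res in range(1, 20):
        base = seq[res]
        n_name = "N9" if base in ("A", "G") else "N1"
        for atom, elem in (("P", "P"), ("C4'", "C"), ("C1'", "C"),
                           (n_name, "N")):
            rows.append((res, base, atom, elem, _MASS[elem]))
    return pd.DataFrame(rows, columns=["res_seq", "res_name", "atom_name",
                                       "element", "mass"])


def _expand_reference(pos, axis_xy):
    """Place P, C4', C1' and the base nitrogen around each C1' anchor."""
    coords = []
    for res in range(1, 20):
        q = pos[res]
        w = np.array([-axis_xy[res][0], -axis_xy[res][1], 0.0])  # inward
        coords.append(q + np.array([0, 0, 0]) - 2.5 * w - np.array([0, 0, 1.4]))  # P
        coords.append(q - 1.5 * w + np.array([0, 0, 1.2]))  # C4'
        coords.append(q)  # C1'
        coords.append(q + 2.0 * w)  # base N
    return np.asarray(coords)


def reference_hairpin(state: str, terminal_extra: float = 0.0,
                      config: HairpinConfig | None = None):
    """Noise-free reference coordinates (n_atoms x 3) and atom table for
    one loop state (``'pentaloop'`` or ``'triloop'``)."""
    cfg = config or HairpinConfig(seed=0)
    seq = _sequence(cfg)
    pos, axis_xy = _reference_coords(state, terminal_extra)
    return _expand_reference(pos, axis_xy), _build_atoms(seq)


def gen_hairpin_ensemble(config: HairpinConfig):
    """Returns ``(ensemble, truth)``.

    ``truth`` has one row per frame (``entity_id, true_label,
    true_effect``) where ``true_effect`` is the reference loop-closure
    distance (C1' 8-12) of that frame's state; the attached
    ``truth.attrs['reference']`` dict carries the reference d_loop /
    d_term values of both states in both distance modes.
    """
    rng = np.random.default_rng(config.seed)
    refs, atoms = {}, None
    ref_meta = {}
    for state in ("pentaloop", "triloop"):
        coords, atoms = reference_hairpin(state,
                                          config.terminal_opening_extra,
                                          config)
        refs[state] = coords
        one = HairpinEnsemble(coords=coords[None, :, :], atoms=atoms)
        from .hairpinstruct import residue_distance_series
        for mode in ("c1", "com"):
            _, dl, _ = residue_distance_series(one, 8, 12, mode=mode)
            _, dt, _ = residue_distance_series(one, 1, 19, mode="c1")
            ref_meta[f"d_loop_{mode}_{state}"] = dl
            ref_meta[f"d_term_{state}"] = dt

    states = np.where(rng.random(config.n_frames) < config.p_triloop,
                      "triloop", "pentaloop")
    n_atoms = refs["pentaloop"].shape[0]
    coords = np.empty((config.n_frames, n_atoms, 3))
    for i, s in enumerate(states):
        coords[i] = refs[s]
    coords += rng.normal(0.0, config.sigma, coords.shape)

    ensemble = HairpinEnsemble(coords=coords, atoms=atoms)
    truth = pd.DataFrame({
        "entity_id": [f"frame{i + 1:05d}" for i in range(config.n_frames)],
        "true_label": states,
        "true_effect": [ref_meta[f"d_loop_c1_{s}"] for s in states],
    })
    truth.attrs["reference"] = ref_meta
    return ensemble, truth


# ---------------------------------------------------------------------------
# probe-panel fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeConfig:
    """2AP-style probe panel with a planted probe-vs-inclusion
    correlation across stem-loop variants.

    Default variants and inclusion levels follow the minigene panel:
    non-mutated baseline at 16% inclusion, stem mismatches up to 62%.
    """

    seed: int
    r_true: float = 0.9
    n_replicates: int = 8
    baseline_signal: float = 100.0
    signal_span: float = 80.0
    noise_sd: float = 5.0
    variants: tuple = ("n.m.", "2C", "3C", "4G", "6C", "9C")
    inclusion: tuple = (16.0, 5.0, 40.0, 45.0, 62.0, 55.0)

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(-1.0 <= self.r_true <= 1.0, "r_true must be in [-1, 1]")
        _check(len(self.variants) == len(self.inclusion),
               "variants and inclusion must have equal length")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")


def gen_probe_panel(config: ProbeConfig):
    """Returns ``(panel, truth)`` with one panel row per variant per
    replicate (``variant_id, probe_signal, e7_inclusion``).

    Variant-level signals are built from standardised inclusion as
    ``z = r*x + sqrt(1-r^2)*eps`` so the expected Pearson correlation
    between mean signal and inclusion equals ``r_true`` (exactly
    ``r_true`` = +-1 when noiseless).
    """
    rng = np.random.default_rng(config.seed)
    incl = np.asarray(config.inclusion, dtype=float)
    x = (incl - incl.mean()) / incl.std()
    r = config.r_true
    eps = rng.standard_normal(len(incl)) if abs(r) < 1.0 else np.zeros(len(incl))
    z = r * x + np.sqrt(max(0.0, 1.0 - r ** 2)) * eps
    mean_signal = config.baseline_signal + config.signal_span * z
    rows = []
    for v, mu, inc in zip(config.variants, mean_signal, incl):
        sig = mu + rng.normal(0.0, config.noise_sd, config.n_replicates)
        for s in sig:
            rows.append((v, float(s), float(inc)))
    panel = pd.DataFrame(rows, columns=["variant_id", "probe_signal",
                                        "e7_inclusion"])
    truth = pd.DataFrame({
        "entity_id": config.variants,
        "true_label": ["reference" if v == "n.m." else "variant"
                       for v in config.variants],
        "true_effect": incl,
        "mean_signal": mean_signal,
        "r_true": r,
    })
    return panel, truth


@dataclass(frozen=True)
class CdConfig:
    """CD spectrum as a sum of signed Gaussians: a positive band near
    265 nm (base stacking) and a negative band near 210 nm (helicity)."""

    seed: int
    positive_peak_nm: float = 265.0
    positive_amp: float = 8.0
    positive_width: float = 12.0
    negative_peak_nm: float = 210.0
    negative_amp: float = -10.0
    negative_width: float = 9.0
    noise_sd: float = 0.0
    wavelength_min: float = 200.0
    wavelength_max: float = 320.0
    step_nm: float = 1.0
    variant_id: str = "n.m."

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(self.positive_amp > 0 and self.negative_amp < 0,
               "positive_amp must be > 0 and negative_amp < 0")


def gen_cd_spectrum(config: CdConfig):
    """Returns ``(spectrum, truth)`` with columns
    ``wavelength_nm, molar_cd, variant_id``."""
    rng = np.random.default_rng(config.seed)
    wl = np.arange(config.wavelength_min, config.wavelength_max + 1e-9,
                   config.step_nm)
    y = (config.positive_amp
         * np.exp(-0.5 * ((wl - config.positive_peak_nm)
                          / config.positive_width) ** 2)
         + config.negative_amp
         * np.exp(-0.5 * ((wl - config.negative_peak_nm)
                          / config.negative_width) ** 2))
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, wl.size)
    spectrum = pd.DataFrame({"wavelength_nm": wl, "molar_cd": y,
                             "variant_id": config.variant_id})
    truth = pd.DataFrame([{
        "entity_id": config.variant_id,
        "true_label": "cd_spectrum",
        "true_effect": config.positive_peak_nm,
        "negative_peak_nm": config.negative_peak_nm,
    }])
    return spectrum, truth


@dataclass(frozen=True)
class GelConfig:
    """Inclusion/skipping band pairs consistent with stated true percent
    inclusion per sample (before multiplicative noise)."""

    seed: int
    inclusion_pct: tuple = (16.0, 72.0)
    conditions: tuple = ("DMSO", "compound@40uM")
    total_intensity: float = 1000.0
    cv: float = 0.05
    n_replicates: int = 3

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(len(self.inclusion_pct) == len(self.conditions),
               "inclusion_pct and conditions must have equal length")
        _check(all(0 <= v <= 100 for v in self.inclusion_pct),
               "inclusion_pct values must be in [0, 100]")
        _check(self.cv >= 0, "cv must be >= 0")


def gen_gel_bands(config: GelConfig):
    """Returns ``(bands, truth)`` with columns
    ``sample_id, condition, inc_intensity, skip_intensity``."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond, inc_pct in zip(config.conditions, config.inclusion_pct):
        inc0 = config.total_intensity * inc_pct / 100.0
        skip0 = config.total_intensity * (1.0 - inc_pct / 100.0)
        for rep in range(config.n_replicates):
            f = _lognormal_factors(rng, config.cv, 2)
            rows.append((f"{cond}_r{rep + 1}", cond,
                         inc0 * f[0], skip0 * f[1]))
    bands = pd.DataFrame(rows, columns=["sample_id", "condition",
                                        "inc_intensity", "skip_intensity"])
    truth = pd.DataFrame({
        "entity_id": config.conditions,
        "true_label": ["gel_condition"] * len(config.conditions),
        "true_effect": config.inclusion_pct,
    })
    return bands, truth


@dataclass(frozen=True)
class CtConfig:
    """qPCR Ct table consistent with a stated target fold change between
    treated and control, with a stable reference gene."""

    seed: int
    fold: float = 2.0
    ct_target_control: float = 26.0
    ct_ref: float = 20.0
    noise_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self):
        _check(isinstance(self.seed, (int, np.integer)), "seed is mandatory")
        _check(self.fold > 0, "fold must be positive")
        _check(self.noise_sd >= 0, "noise_sd must be >= 0")


def gen_ct_table(config: CtConfig):
    """Returns ``(ct, truth)`` with columns
    ``sample_id, condition, gene, is_reference, ct``.  The treated target
    Ct is shifted by -log2(fold) so 2^-ddCt recovers ``fold``."""
    rng = np.random.default_rng(config.seed)
    ct_target_treated = config.ct_target_control - np.log2(config.fold)
    rows = []
    for cond, ct_t in (("control", config.ct_target_control),
                       ("treated", ct_target_treated)):
        for rep in range(config.n_replicates):
            noise = rng.normal(0.0, config.noise_sd, 2)
            rows.append((f"{cond}_r{rep + 1}", cond, "target", False,
                         ct_t + noise[0]))
            rows.append((f"{cond}_r{rep + 1}", cond, "reference", True,
                         config.ct_ref + noise[1]))
    ct = pd.DataFrame(rows, columns=["sample_id", "condition", "gene",
                                     "is_reference", "ct"])
    truth = pd.DataFrame([{
        "entity_id": "target", "true_label": "fold_change",
        "true_effect": config.fold,
    }])
    return ct, truth
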