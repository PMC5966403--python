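"""Generator contracts: determinism, truth recovery, type invariants."""

import numpy as np
import pytest

from tsl2screen import screenstats, synthio
from tsl2screen.errors import ConfigError


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def test_generators_are_byte_deterministic(tmp_path):
    """Identical (config, seed) reproduces identical serialised bytes for
    every generator, including the PDB ensemble."""
    from tsl2screen import hairpinstruct

    def plate():
        return synthio.gen_plate(synthio.PlateConfig(seed=42, n_compounds=30))

    def dose():
        return synthio.gen_dose(synthio.DoseConfig(seed=42))

    def junctions():
        return synthio.gen_junction_table(
            synthio.JunctionConfig(seed=42, n_events=40))

    def probe():
        return synthio.gen_probe_panel(synthio.ProbeConfig(seed=42))

    def gel():
        return synthio.gen_gel_bands(synthio.GelConfig(seed=42))

    def ct():
        return synthio.gen_ct_table(synthio.CtConfig(seed=42))

    def cd():
        return synthio.gen_cd_spectrum(synthio.CdConfig(seed=42, noise_sd=0.5))

    for gen in (plate, dose, junctions, probe, gel, ct, cd):
        (d1, t1), (d2, t2) = gen(), gen()
        assert d1.to_csv(index=False) == d2.to_csv(index=False)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    cfg = synthio.HairpinConfig(seed=42, n_frames=3)
    e1, _ = synthio.gen_hairpin_ensemble(cfg)
    e2, _ = synthio.gen_hairpin_ensemble(cfg)
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    hairpinstruct.write_ensemble(e1, p1)
    hairpinstruct.write_ensemble(e2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ():
    w1, _ = synthio.gen_plate(synthio.PlateConfig(seed=1, n_compounds=10))
    w2, _ = synthio.gen_plate(synthio.PlateConfig(seed=2, n_compounds=10))
    assert not np.allclose(w1["fluorescence"], w2["fluorescence"])


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"binder_fraction": 1.5}, {"autofluor_fraction": -0.1}, {"cv": -0.05},
    {"n_compounds": 0},
])
def test_plate_config_validation(kwargs):
    with pytest.raises(ConfigError):
        synthio.PlateConfig(seed=1, **kwargs)


@pytest.mark.parametrize("cfg, kwargs", [
    (synthio.DoseConfig, {"ec50": -1.0}),
    (synthio.DoseConfig, {"n_doses": 3}),
    (synthio.JunctionConfig, {"rho": 1.0}),
    (synthio.JunctionConfig, {"depth": 0}),
    (synthio.HairpinConfig, {"sigma": -0.1}),
    (synthio.HairpinConfig, {"p_triloop": 1.2}),
    (synthio.CtConfig, {"fold": 0.0}),
])
def test_generator_config_validation(cfg, kwargs):
    with pytest.raises(ConfigError):
        cfg(seed=1, **kwargs)


# ---------------------------------------------------------------------------
# plate truth recovery
# ---------------------------------------------------------------------------

def test_null_plate_mean_activity_unbiased():
    """Monte Carlo over seeds: with no binders planted, the plate-mean
    Eq.-1 activity is within 3 SE of zero."""
    means = []
    for seed in range(300):
        wells, _ = synthio.gen_plate(synthio.PlateConfig(
            seed=20_000 + seed, n_compounds=60, binder_fraction=0.0))
        acts = screenstats.plate_activities(wells)
        keep = ~acts["compound_id"].str.startswith("DMSO")
        means.append(acts.loc[keep, "mean_activity"].mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(means.size)
    assert abs(means.mean()) <= 3 * se


def test_binder_count_within_binomial_interval():
    """n = 304, fraction 0.18: the planted binder count behaves as a
    Binomial(304, 0.18) draw around the expected 54.7."""
    from scipy import stats

    _, truth = synthio.gen_plate(synthio.PlateConfig(seed=1))
    n1 = int((truth["true_label"] == "binder").sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], 304, 0.18)
    assert lo <= n1 <= hi
    # aggregate over 40 plates: Binomial(304*40, 0.18) at the 99.9% level
    total = sum(int((synthio.gen_plate(synthio.PlateConfig(seed=s))[1]
                     ["true_label"] == "binder").sum()) for s in range(40))
    lo, hi = stats.binom.ppf([0.0005, 0.9995], 304 * 40, 0.18)
    assert lo <= total <= hi


def test_plate_tables_satisfy_consumer_invariants(default_plate):
    wells, truth = default_plate
    assert (wells["fluorescence"] >= 0).all()
    assert set(wells["role"]) == {"A", "B", "C", "D"}
    has_cid = wells["compound_id"] != ""
    assert (wells.loc[has_cid, "role"].isin(["A", "B"])).all()
    assert (~wells.loc[~has_cid, "role"].isin(["A", "B"])).all()
    assert truth["entity_id"].is_unique


def test_autofluorescent_compounds_are_flagged_downstream():
    wells, truth = synthio.gen_plate(synthio.PlateConfig(
        seed=123, autofluor_fraction=0.3))
    acts = screenstats.plate_activities(wells)
    merged = acts.merge(truth, left_on="compound_id", right_on="entity_id")
    auto = merged["autofluorescent"].astype(bool)
    assert (merged.loc[auto, "autofluor_flag"]).mean() > 0.95
    assert (merged.loc[~auto, "autofluor_flag"]).mean() < 0.05


# ---------------------------------------------------------------------------
# dose generator
# ---------------------------------------------------------------------------

def test_dose_noiseless_matches_closed_form():
    cfg = synthio.DoseConfig(seed=1, cv=0.0)
    table, truth = synthio.gen_dose(cfg)
    expected = synthio.four_pl(table["concentration_uM"], cfg.bottom,
                               cfg.top, cfg.ec50, cfg.hill)
    np.testing.assert_allclose(table["response"], expected)


def test_dose_midpoint_identity():
    assert synthio.four_pl(16.0, 0.0, 100.0, 16.0, 2.3) == pytest.approx(50.0)


def test_dose_recovery_rate():
    """4PL refits recover the planted EC50 within 15% in >= 90% of seeds
    (8 doses x 4 replicates, CV 5%)."""
    ok = 0
    for seed in range(200):
        table, truth = synthio.gen_dose(synthio.DoseConfig(seed=seed))
        fit = screenstats.fit_4pl(table["concentration_uM"],
                                  table["response"])
        if fit.converged and abs(fit.ec50 - 16.0) / 16.0 <= 0.15:
            ok += 1
    assert ok / 200 >= 0.90


# ---------------------------------------------------------------------------
# junction generator
# ---------------------------------------------------------------------------

def test_junction_counts_are_integral_and_bounded():
    j, _ = synthio.gen_junction_table(synthio.JunctionConfig(seed=3))
    assert (j["incl_counts"] >= 0).all() and (j["skip_counts"] >= 0).all()
    assert np.issubdtype(j["incl_counts"].dtype, np.integer)
    assert ((j["incl_counts"] + j["skip_counts"]) == 200).all()


def test_junction_sample_psi_converges_to_group_psi():
    from tsl2screen import psidiff
    j, truth = synthio.gen_junction_table(synthio.JunctionConfig(
        seed=4, n_events=50, depth=10_000, rho=0.0, affected_fraction=0.0))
    j = j.assign(psi=psidiff.psi_from_counts(j["incl_counts"],
                                             j["skip_counts"]))
    merged = j.merge(truth, left_on="event_id", right_on="entity_id")
    assert np.abs(merged["psi"] - merged["psi_control"]).max() < 0.02


# ---------------------------------------------------------------------------
# hairpin generator
# ---------------------------------------------------------------------------

def test_hairpin_pure_state_no_jitter_is_reference():
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=5, n_frames=6, p_triloop=1.0, sigma=0.0))
    ref, _ = synthio.reference_hairpin("triloop")
    for f in range(6):
        np.testing.assert_allclose(ens.coords[f], ref)


def test_hairpin_state_fraction_recovery():
    _, truth = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=6, n_frames=5000, p_triloop=0.7))
    frac = (truth["true_label"] == "triloop").mean()
    assert frac == pytest.approx(0.7, abs=0.02)


def test_hairpin_terminal_loop_anticorrelation():
    from tsl2screen import hairpinstruct as hs
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=7, n_frames=1000, p_triloop=0.5))
    d_term, _, _ = hs.residue_distance_series(ens, 1, 19, "c1")
    d_loop, _, _ = hs.residue_distance_series(ens, 8, 12, "com")
    assert np.corrcoef(d_term, d_loop)[0, 1] < 0


def test_hairpin_pinned_sequence():
    ens, _ = synthio.gen_hairpin_ensemble(synthio.HairpinConfig(
        seed=1, n_frames=1))
    by_res = ens.atoms.drop_duplicates("res_seq").set_index("res_seq")
    for pos, base in synthio.PINNED_SEQUENCE.items():
        assert by_res.loc[pos, "res_name"] == base
    assert ens.coords.shape[1] == 19 * 4  # >= 3 labelled atoms incl. C1'


# ---------------------------------------------------------------------------
# remaining fixtures
# ---------------------------------------------------------------------------

def test_probe_panel_noiseless_perfect_correlation():
    from scipy import stats
    panel, truth = synthio.gen_probe_panel(synthio.ProbeConfig(
        seed=1, r_true=1.0, noise_sd=0.0))
    agg = panel.groupby("variant_id").mean(numeric_only=True)
    r, _ = stats.pearsonr(agg["probe_signal"], agg["e7_inclusion"])
    assert r == pytest.approx(1.0)


def test_gel_bands_reflect_true_inclusion():
    bands, truth = synthio.gen_gel_bands(synthio.GelConfig(
        seed=1, inclusion_pct=(72.0,), conditions=("X",), cv=0.0))
    assert bands["inc_intensity"].iloc[0] == pytest.approx(720.0)
    assert bands["skip_intensity"].iloc[0] == pytest.approx(280.0)


def test_ct_table_reproduces_planted_fold():
    from tsl2screen import splicequant
    ct, truth = synthio.gen_ct_table(synthio.CtConfig(seed=1, fold=4.0))
    mean_ct = ct.groupby(["condition", "is_reference"])["ct"].mean()
    rec = splicequant.DdctRecord(
        ct_target_treated=mean_ct[("treated", False)],
        ct_ref_treated=mean_ct[("treated", True)],
        ct_target_control=mean_ct[("control", False)],
        ct_ref_control=mean_ct[("control", True)])
    assert splicequant.ddct_fold(rec) == pytest.approx(4.0)
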