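"""End-to-end orchestration: YAML configuration, stage sequencing,
deterministic sub-seeding and a consolidated plain-text report.

Stages run in the fixed order ``simulate -> screen -> splicing -> psi ->
struct``; each stage reads either a user-supplied input path or the
table the ``simulate`` stage produced.  One global seed fans out to
per-stage sub-seeds by stable hashing of the stage name, so toggling
one stage never perturbs another stage's random stream.  Identical
config + seed reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hairpinstruct, psidiff, screenstats, splicequant, synthio
from .errors import ConfigError, Tsl2ScreenError

STAGES = ("simulate", "screen", "splicing", "psi", "struct")

_FLOAT_FMT = "%.10g"


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable 31-bit sub-seed for a stage derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _require_keys(section: str, given: dict, allowed: dict):
    for key in given:
        if key not in allowed:
            raise ConfigError(f"unknown key {section}.{key!r}")
    for key, (typ, check, msg) in allowed.items():
        if key not in given:
            continue
        v = given[key]
        if v is None:
            continue
        if typ is float and isinstance(v, int) and not isinstance(v, bool):
            v = float(v)
            given[key] = v
        if not isinstance(v, typ) or isinstance(v, bool) and typ is not bool:
            raise ConfigError(
                f"key {section}.{key!r} must be {typ.__name__}, "
                f"got {type(v).__name__} ({v!r})")
        if check is not None and not check(v):
            raise ConfigError(f"key {section}.{key!r} out of range: {msg}")


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "tsl2screen_out"
    stages: tuple = STAGES
    screen: dict = field(default_factory=dict)
    splicing: dict = field(default_factory=dict)
    psi: dict = field(default_factory=dict)
    struct: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        out = {
            "seed": self.seed, "outdir": self.outdir,
            "stages": list(self.stages),
            "screen": {"wells": None, "cutoff": 20.0, "alpha": 0.05},
            "splicing": {"bands": None, "ct": None, "probe": None},
            "psi": {"junctions": None, "t1": 0.4, "t2": 0.65,
                    "affected_fasta": None, "background_fasta": None,
                    "motif": "AGGTAAG", "max_mismatch": 0},
            "struct": {"pdb": None, "selection": "all_heavy",
                       "loop_mode": "com", "loop_threshold": None},
            "simulate": {"plate": {}, "dose": {}, "junctions": {},
                         "hairpin": {}, "probe": {}, "gel": {}, "ct": {}},
        }
        out["screen"].update(self.screen)
        out["splicing"].update(self.splicing)
        out["psi"].update(self.psi)
        out["struct"].update(self.struct)
        out["simulate"].update(self.simulate)
        return out


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration.

    Unknown keys are rejected and every violation names the offending
    key.  Referenced input files must exist at validation time.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level YAML must be a mapping")

    top = {"seed": (int, None, ""),
           "outdir": (str, None, ""),
           "stages": (list, None, ""),
           "screen": (dict, None, ""), "splicing": (dict, None, ""),
           "psi": (dict, None, ""), "struct": (dict, None, ""),
           "simulate": (dict, None, "")}
    _require_keys("<top>", raw, top)

    stages = raw.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r} in 'stages'")

    screen = dict(raw.get("screen") or {})
    _require_keys("screen", screen, {
        "wells": (str, None, ""),
        "cutoff": (float, lambda v: 0 <= v <= 100, "cutoff in [0, 100]"),
        "alpha": (float, lambda v: 0 < v < 1, "alpha in (0, 1)")})
    splicing = dict(raw.get("splicing") or {})
    _require_keys("splicing", splicing, {
        "bands": (str, None, ""), "ct": (str, None, ""),
        "probe": (str, None, "")})
    psi = dict(raw.get("psi") or {})
    _require_keys("psi", psi, {
        "junctions": (str, None, ""),
        "t1": (float, lambda v: 0 < v <= 1, "t1 in (0, 1]"),
        "t2": (float, lambda v: 0 < v <= 1, "t2 in (0, 1]"),
        "affected_fasta": (str, None, ""),
        "background_fasta": (str, None, ""),
        "motif": (str, None, ""),
        "max_mismatch": (int, lambda v: v >= 0, "max_mismatch >= 0")})
    t1 = psi.get("t1", 0.4)
    t2 = psi.get("t2", 0.65)
    if t2 < t1:
        raise ConfigError(f"key psi.t2 ({t2}) must be >= psi.t1 ({t1})")
    struct = dict(raw.get("struct") or {})
    _require_keys("struct", struct, {
        "pdb": (str, None, ""),
        "selection": (str, lambda v: v in ("all_heavy", "stem_heavy",
                                           "loop_heavy"), "known selection"),
        "loop_mode": (str, lambda v: v in ("c1", "com"), "'c1' or 'com'"),
        "loop_threshold": (float, lambda v: v > 0, "positive")})
    simulate = dict(raw.get("simulate") or {})
    _require_keys("simulate", simulate, {
        k: (dict, None, "") for k in
        ("plate", "dose", "junctions", "hairpin", "probe", "gel", "ct")})

    cfg = PipelineConfig(
        seed=int(raw.get("seed", 1)), outdir=str(raw.get("outdir",
                                                         "tsl2screen_out")),
        stages=tuple(stages), screen=screen, splicing=splicing, psi=psi,
        struct=struct, simulate=simulate)

    for section, key in (("screen", "wells"), ("splicing", "bands"),
                         ("splicing", "ct"), ("splicing", "probe"),
                         ("psi", "junctions"), ("psi", "affected_fasta"),
                         ("psi", "background_fasta"), ("struct", "pdb")):
        path = getattr(cfg, section).get(key)
        if path is not None and not Path(path).exists():
            raise ConfigError(f"key {section}.{key!r}: file {path!r} not found")
    return cfg


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _run_simulate(cfg: dict, seed: int, outdir: Path, summary: list):
    sim = cfg["simulate"]
    out = {}
    wells, wtruth = synthio.gen_plate(
        synthio.PlateConfig(seed=stage_seed(seed, "plate"), **sim["plate"]))
    dose, dtruth = synthio.gen_dose(
        synthio.DoseConfig(seed=stage_seed(seed, "dose"), **sim["dose"]))
    junc, jtruth = synthio.gen_junction_table(
        synthio.JunctionConfig(seed=stage_seed(seed, "junctions"),
                               **sim["junctions"]))
    gel, gtruth = synthio.gen_gel_bands(
        synthio.GelConfig(seed=stage_seed(seed, "gel"), **sim["gel"]))
    ct, ctruth = synthio.gen_ct_table(
        synthio.CtConfig(seed=stage_seed(seed, "ct"), **sim["ct"]))
    probe, ptruth = synthio.gen_probe_panel(
        synthio.ProbeConfig(seed=stage_seed(seed, "probe"), **sim["probe"]))
    ens, etruth = synthio.gen_hairpin_ensemble(
        synthio.HairpinConfig(seed=stage_seed(seed, "hairpin"),
                              **sim["hairpin"]))
    simdir = outdir / "simulated"
    for name, df in (("wells", wells), ("dose", dose), ("junctions", junc),
                     ("bands", gel), ("ct", ct), ("probe", probe)):
        _write(df, simdir / f"{name}.tsv")
    for name, df in (("plate", wtruth), ("dose", dtruth),
                     ("junctions", jtruth), ("gel", gtruth), ("ct", ctruth),
                     ("probe", ptruth), ("hairpin", etruth.drop(
                         columns=[], errors="ignore"))):
        _write(df, simdir / f"truth_{name}.tsv")
    simdir.mkdir(parents=True, exist_ok=True)
    hairpinstruct.write_ensemble(ens, simdir / "ensemble.pdb")
    out.update(wells=wells, dose=dose, junctions=junc, bands=gel, ct=ct,
               probe=probe, ensemble=ens, hairpin_truth=etruth)
    summary.append(f"simulate: {len(wtruth)} compounds, "
                   f"{jtruth.shape[0]} splicing events, "
                   f"{ens.n_frames} hairpin frames -> {simdir}")
    return out


def _run_screen(cfg: dict, outdir: Path, sim: dict, summary: list):
    sc = cfg["screen"]
    if sc["wells"] is not None:
        wells = pd.read_csv(sc["wells"], sep="\t",
                            dtype={"compound_id": str}, keep_default_na=False)
    elif "wells" in sim:
        wells = sim["wells"]
    else:
        raise ConfigError("screen stage: no wells table (set screen.wells "
                          "or enable the simulate stage)")
    acts = screenstats.plate_activities(wells)
    is_ctrl = acts["compound_id"].str.startswith("DMSO")
    ctrl = np.concatenate(acts.loc[is_ctrl, "activities"].to_list()) \
        if is_ctrl.any() else None
    if ctrl is None:
        raise ConfigError("screen stage: no DMSO control wells found")
    hits = screenstats.call_hits(acts[~is_ctrl], ctrl,
                                 cutoff=sc["cutoff"], alpha=sc["alpha"])
    _write(hits, outdir / "hits.tsv")
    qc_rows = []
    for plate_id, plate in wells.groupby("plate_id"):
        qc = screenstats.zfactor(
            plate.loc[plate["role"] == "C", "fluorescence"],
            plate.loc[plate["role"] == "D", "fluorescence"])
        qc_rows.append((plate_id, qc.mu_pos, qc.mu_neg, qc.sigma_pos,
                        qc.sigma_neg, qc.z_factor))
    _write(pd.DataFrame(qc_rows, columns=[
        "plate_id", "mu_pos", "mu_neg", "sigma_pos", "sigma_neg",
        "z_factor"]), outdir / "qc.tsv")
    if "dose" in sim:
        fit = screenstats.fit_4pl(sim["dose"]["concentration_uM"],
                                  sim["dose"]["response"])
        _write(pd.DataFrame([{
            "compound_id": "SIM", "bottom": fit.bottom, "top": fit.top,
            "ec50_uM": fit.ec50, "hill": fit.hill,
            "sse": fit.residual_sse, "converged": fit.converged}]),
            outdir / "ec50.tsv")
    n_hits = int(hits["is_hit"].sum())
    summary.append(f"screen: {n_hits} hits of {len(hits)} compounds "
                   f"(cutoff {sc['cutoff']}%, alpha {sc['alpha']}, "
                   f"Bonferroni m={len(hits)})")
    return {"hits": hits}


def _run_splicing(cfg: dict, outdir: Path, sim: dict, summary: list):
    sp = cfg["splicing"]
    bands = pd.read_csv(sp["bands"], sep="\t") if sp["bands"] \
        else sim.get("bands")
    if bands is None:
        raise ConfigError("splicing stage: no band table (set "
                          "splicing.bands or enable the simulate stage)")
    bands = bands.assign(percent_inclusion=[
        splicequant.percent_inclusion(i, s)
        for i, s in zip(bands["inc_intensity"], bands["skip_intensity"])])
    _write(bands, outdir / "splicing.tsv")
    cond = bands.groupby("condition")["percent_inclusion"].mean()
    mip_rows = []
    if "DMSO" in cond.index:
        base = float(cond["DMSO"])
        for c, v in cond.items():
            if c != "DMSO" and base < 100:
                mip_rows.append((c, float(v), base,
                                 splicequant.mip(float(v), base)))
    if mip_rows:
        _write(pd.DataFrame(mip_rows, columns=[
            "condition", "e7_treated", "e7_dmso", "mip_pct"]),
            outdir / "mip.tsv")
    ct = pd.read_csv(sp["ct"], sep="\t") if sp["ct"] else sim.get("ct")
    if ct is not None:
        mean_ct = ct.groupby(["condition", "is_reference"])["ct"].mean()
        rec = splicequant.DdctRecord(
            ct_target_treated=float(mean_ct[("treated", False)]),
            ct_ref_treated=float(mean_ct[("treated", True)]),
            ct_target_control=float(mean_ct[("control", False)]),
            ct_ref_control=float(mean_ct[("control", True)]))
        fold = splicequant.ddct_fold(rec)
        _write(pd.DataFrame([{"fold_2_neg_ddct": fold}]),
               outdir / "qpcr_fold.tsv")
        summary.append(f"splicing: qPCR fold change {fold:.3g}")
    probe = pd.read_csv(sp["probe"], sep="\t") if sp["probe"] \
        else sim.get("probe")
    if probe is not None:
        per_variant, r, p = splicequant.probe_delta_and_correlation(probe)
        _write(per_variant, outdir / "probe_deltas.tsv")
        _write(pd.DataFrame([{"pearson_r": r, "p_two_tailed": p}]),
               outdir / "probe_corr.tsv")
        summary.append(f"splicing: probe-vs-inclusion Pearson r = {r:.3f} "
                       f"(p = {p:.2g})")
    if mip_rows:
        summary.append("splicing: %MIP " + ", ".join(
            f"{c}: {m:.1f}%" for c, _, _, m in mip_rows))
    return {}


def _run_psi(cfg: dict, outdir: Path, sim: dict, summary: list):
    ps = cfg["psi"]
    junc = pd.read_csv(ps["junctions"], sep="\t") if ps["junctions"] \
        else sim.get("junctions")
    if junc is None:
        raise ConfigError("psi stage: no junction table (set psi.junctions "
                          "or enable the simulate stage)")
    res = psidiff.psi_table(junc, t1=ps["t1"], t2=ps["t2"])
    _write(res, outdir / "psi.tsv")
    filt = psidiff.delta_psi_filter(res, t1=ps["t1"], t2=ps["t2"])
    _write(filt["modified"], outdir / "dpsi_modified.tsv")
    summary.append(
        f"psi: {filt['n_modified_events']} events (|dPSI| > {ps['t1']}) in "
        f"{filt['n_modified_genes']} genes; {filt['n_strong_events']} "
        f"strongly affected (> {ps['t2']})")
    if ps["affected_fasta"] and ps["background_fasta"]:
        affected = _read_fasta(ps["affected_fasta"])
        background = _read_fasta(ps["background_fasta"])
        enr = psidiff.motif_enrichment(affected, background,
                                       motif=ps["motif"],
                                       max_mismatch=ps["max_mismatch"])
        _write(pd.DataFrame([{
            "motif": enr.motif, "k_affected": enr.k_affected,
            "n_affected": enr.n_affected, "k_background": enr.k_background,
            "n_background": enr.n_background, "p": enr.p}]),
            outdir / "motif.tsv")
        summary.append(f"psi: motif {enr.motif} enrichment p = {enr.p:.3g}")
    return {}


def _read_fasta(path) -> list:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def _run_struct(cfg: dict, outdir: Path, sim: dict, summary: list):
    st = cfg["struct"]
    if st["pdb"] is not None:
        ens = hairpinstruct.read_ensemble(st["pdb"])
        threshold = st["loop_threshold"]
    elif "ensemble" in sim:
        ens = sim["ensemble"]
        ref = sim["hairpin_truth"].attrs.get("reference", {})
        threshold = st["loop_threshold"]
        if threshold is None and ref:
            threshold = hairpinstruct.loop_state_threshold(
                ref[f"d_loop_{st['loop_mode']}_triloop"],
                ref[f"d_loop_{st['loop_mode']}_pentaloop"])
    else:
        raise ConfigError("struct stage: no ensemble (set struct.pdb or "
                          "enable the simulate stage)")
    per_res, _ = hairpinstruct.rmsf(ens, selection=st["selection"])
    _write(per_res.rename("rmsf_A").reset_index(), outdir / "rmsf.tsv")
    d_term, _, _ = hairpinstruct.residue_distance_series(ens, 1, 19, "c1")
    d_loop, _, _ = hairpinstruct.residue_distance_series(
        ens, 8, 12, st["loop_mode"])
    states = hairpinstruct.classify_loop_state(
        ens, threshold=threshold, mode=st["loop_mode"])
    _write(pd.DataFrame({
        "frame": np.arange(1, ens.n_frames + 1),
        "d_term_A": d_term, "d_loop_A": d_loop, "state": states.states}),
        outdir / "metrics.tsv")
    # bundle statistics over (at most) the first 40 models, the usual
    # NMR bundle size; pairwise cost grows quadratically in frames
    nb = min(ens.n_frames, 40)
    bundle = hairpinstruct.HairpinEnsemble(coords=ens.coords[:nb],
                                           atoms=ens.atoms)
    stats_rows = []
    for sel in ("all_heavy", "stem_heavy", "loop_heavy"):
        mean, sd = hairpinstruct.pairwise_bundle_rmsd(bundle, sel)
        stats_rows.append((sel, nb, mean, sd))
    _write(pd.DataFrame(stats_rows, columns=[
        "selection", "n_models", "mean_pairwise_rmsd_A", "sd_A"]),
        outdir / "bundle_stats.tsv")
    summary.append(
        f"struct: triloop fraction {states.fraction_triloop:.3f} "
        f"[{states.ci_low:.3f}, {states.ci_high:.3f}] at threshold "
        f"{states.threshold:.2f} A; mean d_term {d_term.mean():.2f} A")
    return {}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order and write per-stage TSVs, a run
    log (resolved config, seed, versions) and a plain-text summary.

    A stage failure aborts the run with the stage name attached.
    Returns the summary lines.
    """
    cfg = config.resolved()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    summary: list[str] = [f"tsl2screen pipeline (seed {cfg['seed']})"]
    sim: dict = {}
    runners = {"simulate": _run_simulate, "screen": _run_screen,
               "splicing": _run_splicing, "psi": _run_psi,
               "struct": _run_struct}
    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        try:
            if stage == "simulate":
                sim = runners[stage](cfg, cfg["seed"], outdir, summary)
            else:
                runners[stage](cfg, outdir, sim, summary)
        except Tsl2ScreenError as exc:
            raise Tsl2ScreenError(f"stage {stage!r} failed: {exc}") from exc
    log = {
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2,
                                                    default=str) + "\n")
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return {"summary": summary, "outdir": outdir}
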