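"""Junction-count differential splicing and donor-motif enrichment.

Percent spliced-in (PSI) of a cassette exon is estimated from junction
read counts.  A cassette event has two inclusion junctions (upstream
exon-cassette and cassette-downstream exon) but only one skipping
junction, so the summed inclusion count ``I`` is halved before
normalisation::

    psi = (I/2) / (I/2 + S)

dPSI = mean PSI(treated) - mean PSI(control) is thresholded on its
absolute value (|dPSI| > 0.4 for "modified", > 0.65 for "strongly
affected"), since treatments both promote and reduce inclusion.

The module also classifies gene-level treatment responses into
target-pathway-mediated vs off-target by contrasting disease-background
and wild-type cells, and tests a splice-donor motif (default AGGTAAG)
for over-representation among affected donors with an exact
hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .screenstats import welch_test

logger = logging.getLogger(__name__)

JUNCTION_COLUMNS = ["event_id", "gene_id", "sample_id", "group",
                    "incl_counts", "skip_counts"]


# ---------------------------------------------------------------------------
# PSI / dPSI
# ---------------------------------------------------------------------------

def psi_from_counts(incl_counts, skip_counts):
    """Per-sample PSI = (I/2)/((I/2)+S) from summed inclusion-junction and
    skipping-junction counts.  Samples with I + S = 0 get NaN (undefined,
    excluded downstream)."""
    i = np.asarray(incl_counts, dtype=float)
    s = np.asarray(skip_counts, dtype=float)
    if np.any(i < 0) or np.any(s < 0):
        raise ValueError("junction counts must be non-negative")
    tot = i / 2.0 + s
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(tot > 0, (i / 2.0) / tot, np.nan)
    return psi


def psi_table(junctions: pd.DataFrame, treated: str = "treated",
              control: str = "control", t1: float = 0.4,
              t2: float = 0.65) -> pd.DataFrame:
    """Per-event PSI and dPSI between two sample groups.

    ``junctions`` has one row per (event, sample) with columns
    ``event_id, gene_id, sample_id, group, incl_counts, skip_counts``.
    Samples with zero total counts for an event are excluded from that
    event's group means (logged); events undefined in every sample of a
    group are dropped with a warning.  Returns one row per event with
    ``psi_treated``, ``psi_control``, ``dpsi``, ``pass_04``-style flags
    named ``modified`` (|dPSI| > t1) and ``strongly_affected`` (> t2).
    """
    _check_thresholds(t1, t2)
    df = junctions.copy()
    df["psi"] = psi_from_counts(df["incl_counts"].to_numpy(),
                                df["skip_counts"].to_numpy())
    n_undef = int(df["psi"].isna().sum())
    if n_undef:
        logger.info("%d (event, sample) pairs with zero coverage excluded",
                    n_undef)
    rows = []
    for (event_id, gene_id), ev in df.groupby(["event_id", "gene_id"],
                                              sort=True):
        mt = ev.loc[ev["group"] == treated, "psi"].dropna()
        mc = ev.loc[ev["group"] == control, "psi"].dropna()
        if mt.empty or mc.empty:
            logger.warning("event %s dropped: no defined PSI in a group",
                           event_id)
            continue
        dpsi = float(mt.mean() - mc.mean())
        rows.append((event_id, gene_id, float(mt.mean()), float(mc.mean()),
                     dpsi, len(mt), len(mc),
                     abs(dpsi) > t1, abs(dpsi) > t2))
    return pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "psi_treated", "psi_control", "dpsi",
        "n_treated", "n_control", "modified", "strongly_affected"])


def _check_thresholds(t1, t2):
    for name, t in (("t1", t1), ("t2", t2)):
        if not 0.0 < t <= 1.0:
            raise ValueError(f"threshold {name} must be in (0, 1], got {t}")
    if t2 < t1:
        raise ValueError(f"t2 ({t2}) must be >= t1 ({t1})")


def delta_psi_filter(results: pd.DataFrame, t1: float = 0.4,
                     t2: float = 0.65) -> dict:
    """Classify events by |dPSI| and roll up to genes.

    ``results`` must carry ``event_id``, ``gene_id`` and ``dpsi``.
    Returns a dict with the ``modified`` (|dPSI| > t1) and
    ``strongly_affected`` (|dPSI| > t2) event tables plus distinct-gene
    counts for each tier.  t2 >= t1 guarantees the strong set is a
    subset of the modified set.
    """
    _check_thresholds(t1, t2)
    r = results.copy()
    r["modified"] = r["dpsi"].abs() > t1
    r["strongly_affected"] = r["dpsi"].abs() > t2
    modified = r[r["modified"]]
    strong = r[r["strongly_affected"]]
    return {
        "events": r,
        "modified": modified.reset_index(drop=True),
        "strongly_affected": strong.reset_index(drop=True),
        "n_modified_events": int(len(modified)),
        "n_modified_genes": int(modified["gene_id"].nunique()),
        "n_strong_events": int(len(strong)),
        "n_strong_genes": int(strong["gene_id"].nunique()),
    }


# ---------------------------------------------------------------------------
# disease-background vs wild-type response classification
# ---------------------------------------------------------------------------

@dataclass
class ResponseClassification:
    gene_id: str
    sma_p: float
    wt_p: float
    sma_direction: int  # sign of treated - control mean
    wt_direction: int
    label: str  # smn_mediated | off_target | wt_only | non_responsive


def classify_smn_dependence(measurements: pd.DataFrame,
                            alpha: float = 0.05) -> list[ResponseClassification]:
    """Label each gene's treatment response as SMN-recovery-mediated or
    off-target by contrasting SMA-background and wild-type cells.

    ``measurements`` has columns ``gene_id``, ``background`` (``sma`` or
    ``wt``), ``condition`` (``treated`` or ``control``) and ``value``
    (any per-sample splicing readout).  Per background a two-tailed Welch
    test compares treated vs control.  Decision rule:

    * significant in SMA only                       -> ``smn_mediated``
    * significant in both, same direction           -> ``off_target``
    * significant in WT only                        -> ``wt_only``
    * anything else                                 -> ``non_responsive``

    No multiplicity correction is applied across the (small) validation
    panel; ``alpha`` is configurable.
    """
    out = []
    for gene_id, g in measurements.groupby("gene_id", sort=True):
        ps, dirs = {}, {}
        for bg in ("sma", "wt"):
            b = g[g["background"] == bg]
            x = b.loc[b["condition"] == "treated", "value"].to_numpy(float)
            y = b.loc[b["condition"] == "control", "value"].to_numpy(float)
            if x.size < 2 or y.size < 2:
                raise InsufficientDataError(
                    f"gene {gene_id!r}, background {bg!r}: need >= 2 "
                    "replicates per condition"
                )
            _, _, p = welch_test(x, y)
            ps[bg] = p
            dirs[bg] = int(np.sign(x.mean() - y.mean()))
        sig_sma = ps["sma"] < alpha
        sig_wt = ps["wt"] < alpha
        if sig_sma and not sig_wt:
            label = "smn_mediated"
        elif sig_sma and sig_wt and dirs["sma"] == dirs["wt"]:
            label = "off_target"
        elif sig_wt and not sig_sma:
            label = "wt_only"
        else:
            label = "non_responsive"
        out.append(ResponseClassification(
            gene_id=str(gene_id), sma_p=ps["sma"], wt_p=ps["wt"],
            sma_direction=dirs["sma"], wt_direction=dirs["wt"], label=label))
    return out


# ---------------------------------------------------------------------------
# donor-motif enrichment
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class MotifEnrichment:
    motif: str
    k_affected: int
    n_affected: int
    k_background: int
    n_background: int
    p: float


def hamming_to_motif(window: str, motif: str) -> int:
    """Minimum mismatch count of ``motif`` against ``window`` over all
    offsets, with IUPAC degeneracy allowed in the motif."""
    best = len(motif)
    for off in range(len(window) - len(motif) + 1):
        mism = sum(1 for m, b in zip(motif, window[off:off + len(motif)])
                   if b not in IUPAC[m])
        best = min(best, mism)
    return best


def motif_contains(window: str, motif: str, max_mismatch: int = 0) -> bool:
    """True iff some offset of ``window`` matches ``motif`` with Hamming
    distance <= ``max_mismatch`` (IUPAC codes allowed in the motif)."""
    return hamming_to_motif(window, motif) <= max_mismatch


def _validate_windows(windows, motif):
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in motif")
    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"donor windows have unequal lengths {sorted(lengths)}")
    (wlen,) = lengths or {0}
    if wlen < len(motif):
        raise ValueError(
            f"motif length {len(motif)} exceeds window length {wlen}")
    clean = []
    for w in windows:
        w = w.upper().replace("U", "T")
        if any(b not in "ACGTN" for b in w):
            raise ValueError(f"non-DNA character in donor window {w!r}")
        clean.append(w)
    return clean, motif


def motif_enrichment(affected_donors, background_donors,
                     motif: str = "AGGTAAG",
                     max_mismatch: int = 0) -> MotifEnrichment:
    """Over-representation of a donor motif among affected events.

    Donor windows are 9-mers spanning the exon/intron boundary (last 3
    exonic + first 6 intronic bases, plus strand, exon first); any equal
    window length >= the motif length is accepted.  A window "contains"
    the motif iff some offset matches with <= ``max_mismatch``
    mismatches.  The p-value is the one-sided hypergeometric upper tail
    for the number of containing windows among the affected set drawn
    from the pooled (affected + background) population.
    """
    affected, motif = _validate_windows(list(affected_donors), motif)
    background, _ = _validate_windows(list(background_donors), motif)
    if len({len(w) for w in affected + background}) > 1:
        raise ValueError("affected and background windows differ in length")
    k_aff = sum(motif_contains(w, motif, max_mismatch) for w in affected)
    k_bg = sum(motif_contains(w, motif, max_mismatch) for w in background)
    n_aff, n_bg = len(affected), len(background)
    N = n_aff + n_bg  # pooled population
    K = k_aff + k_bg  # containing windows in the pool
    p = float(stats.hypergeom.sf(k_aff - 1, N, K, n_aff))
    return MotifEnrichment(motif=motif, k_affected=k_aff, n_affected=n_aff,
                           k_background=k_bg, n_background=n_bg, p=min(p, 1.0))
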