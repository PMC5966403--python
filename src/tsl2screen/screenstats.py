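"""Plate-level fluorescence-displacement analytics.

The screen reads a dye (TO-PRO-1) whose emission increases when bound to a
target RNA; a compound that displaces the dye lowers the signal.  Each
compound is measured against four control roles on the plate:

====  =========================================
role  contents
====  =========================================
A     dye + RNA + compound
B     dye + compound (compound background)
C     dye + RNA     (full signal)
D     dye alone     (dye background)
====  =========================================

Displacement activity of one replicate is::

    activity (%) = 100 - ((A - B) / (C - D)) * 100

so a compound that leaves the RNA-dependent signal untouched scores 0 and a
compound that abolishes it scores 100.  Values outside [0, 100] are
meaningful (fluorescence enhancers score negative) and are never clamped.

The module also provides the screening-window quality coefficient
(Z'-factor), Welch two-sample tests, Bonferroni-corrected hit calling
against DMSO controls, a compound-autofluorescence flag, and a
four-parameter-logistic (4PL) dose-response model in the usual
model/results idiom: ``FourParamLogistic(conc, response).fit()`` returns a
:class:`DoseResponseResults` with the estimates, their standard errors and
a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    AssayWindowError,
    DegenerateControlsError,
    InsufficientDataError,
    InsufficientDosesError,
    MissingControlError,
)

WELL_COLUMNS = [
    "plate_id",
    "well_id",
    "role",
    "compound_id",
    "concentration_uM",
    "replicate",
    "fluorescence",
]

#: minimum relative RNA-dependent window (C - D) > ASSAY_WINDOW_EPS * D
ASSAY_WINDOW_EPS = 0.05


# ---------------------------------------------------------------------------
# Eq.-1 activity
# ---------------------------------------------------------------------------

def activity_percent(a, b, c, d):
    """Fluorescence-displacement activity of one (or many) replicates.

    Parameters are the four control-role readings (arrays broadcast).
    Raises :class:`AssayWindowError` when the RNA window ``c - d`` is not
    comfortably positive (``(c - d) <= ASSAY_WINDOW_EPS * d``).
    """
    a, b, c, d = (np.asarray(v, dtype=float) for v in (a, b, c, d))
    window = c - d
    if np.any(window <= ASSAY_WINDOW_EPS * d):
        raise AssayWindowError(
            "RNA-dependent window (C - D) is too small relative to the dye "
            f"background: min(C - D) = {float(np.min(window)):.4g}"
        )
    return 100.0 - (a - b) / window * 100.0


@dataclass
class ActivityResult:
    """Per-compound displacement summary.

    ``p_value`` / ``p_adj`` / ``is_hit`` are filled in by
    :func:`call_hits`; they are ``None`` until then.
    """

    compound_id: str
    activities: np.ndarray  # per-replicate %
    mean_activity: float
    sd: float
    n: int
    autofluor_flag: bool = False
    p_value: float | None = None
    p_adj: float | None = None
    is_hit: bool | None = None


def compute_activity(wells: pd.DataFrame, compound_id: str | None = None,
                     autofluor_threshold: float = 0.2) -> ActivityResult:
    """Eq.-1 activity for one compound from its A/B wells plus the plate
    C/D control wells.

    ``wells`` must contain the compound's A and B wells and the plate's C
    and D wells.  When the number of C/D control replicates matches the
    number of compound replicates the ratio is formed replicate-by-
    replicate; otherwise the plate-mean window ``mean(C) - mean(D)`` is
    used for every replicate (the usual design with dedicated control
    columns).
    """
    w = wells
    if compound_id is None:
        cids = w.loc[w["role"].isin(["A", "B"]), "compound_id"].dropna().unique()
        if len(cids) != 1:
            raise ValueError(
                "wells contain several compounds; pass compound_id explicitly"
            )
        compound_id = cids[0]

    def _readings(role, cid=None):
        m = w["role"] == role
        if cid is not None:
            m &= w["compound_id"] == cid
        sub = w.loc[m].sort_values("replicate")
        if sub.empty:
            raise MissingControlError(
                f"no wells with role {role!r}"
                + (f" for compound {cid!r}" if cid else "")
            )
        return sub["fluorescence"].to_numpy(dtype=float)

    a = _readings("A", compound_id)
    b = _readings("B", compound_id)
    c = _readings("C")
    d = _readings("D")
    if len(a) != len(b):
        raise MissingControlError(
            f"compound {compound_id!r}: {len(a)} A wells but {len(b)} B wells"
        )
    if len(c) == len(a) and len(d) == len(a):
        act = activity_percent(a, b, c, d)
    else:
        act = activity_percent(a, b, float(np.mean(c)), float(np.mean(d)))
    flag = flag_autofluorescence(b, d, rel_threshold=autofluor_threshold)
    return ActivityResult(
        compound_id=str(compound_id),
        activities=act,
        mean_activity=float(np.mean(act)),
        sd=float(np.std(act, ddof=1)) if len(act) > 1 else 0.0,
        n=len(act),
        autofluor_flag=flag,
    )


def plate_activities(wells: pd.DataFrame,
                     autofluor_threshold: float = 0.2) -> pd.DataFrame:
    """Vectorised Eq.-1 activity for every compound on every plate.

    Returns one row per compound with columns ``compound_id``,
    ``mean_activity``, ``sd``, ``n``, ``autofluor_flag`` and the
    per-replicate activities in ``activities`` (list).  DMSO control
    pseudo-compounds are rows like any other; the caller separates them.
    """
    out = []
    for plate_id, plate in wells.groupby("plate_id", sort=True):
        cw = plate[plate["role"] == "C"]["fluorescence"].to_numpy(dtype=float)
        dw = plate[plate["role"] == "D"]["fluorescence"].to_numpy(dtype=float)
        if cw.size == 0 or dw.size == 0:
            raise MissingControlError(f"plate {plate_id!r}: missing C or D wells")
        cbar, dbar = float(np.mean(cw)), float(np.mean(dw))
        if cbar - dbar <= ASSAY_WINDOW_EPS * dbar:
            raise AssayWindowError(
                f"plate {plate_id!r}: window C - D = {cbar - dbar:.4g} too small"
            )
        ab = plate[plate["role"].isin(["A", "B"])]
        piv = ab.pivot_table(index=["compound_id", "replicate"], columns="role",
                             values="fluorescence", aggfunc="first")
        if piv.isna().any().any():
            missing = piv[piv.isna().any(axis=1)].index[0]
            raise MissingControlError(
                f"plate {plate_id!r}: compound {missing[0]!r} replicate "
                f"{missing[1]} lacks a paired A or B well"
            )
        act = 100.0 - (piv["A"] - piv["B"]) / (cbar - dbar) * 100.0
        bflag = (piv["B"].groupby(level=0).mean() - dbar) / dbar > autofluor_threshold
        g = act.groupby(level=0)
        out.append(pd.DataFrame({
            "plate_id": plate_id,
            "compound_id": g.mean().index,
            "mean_activity": g.mean().to_numpy(),
            "sd": g.std(ddof=1).fillna(0.0).to_numpy(),
            "n": g.size().to_numpy(),
            "autofluor_flag": bflag.reindex(g.mean().index).to_numpy(),
            "activities": [v.to_numpy() for _, v in g],
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# assay QC
# ---------------------------------------------------------------------------

@dataclass
class QcResult:
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float
    z_factor: float


def zfactor(pos, neg) -> QcResult:
    """Screening-window coefficient Z' = 1 - 3(sd+ + sd-) / |mu+ - mu-|.

    Uses the control wells only (sample SDs, ddof=1).  Z' <= 1 always; an
    assay near 0.5-1 separates its controls well enough to screen.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientDataError("zfactor needs >= 2 readings per control group")
    mu_p, mu_n = float(np.mean(pos)), float(np.mean(neg))
    if mu_p == mu_n:
        raise DegenerateControlsError(
            "positive and negative control means are equal; Z' undefined"
        )
    s_p = float(np.std(pos, ddof=1))
    s_n = float(np.std(neg, ddof=1))
    z = 1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n)
    return QcResult(mu_p, mu_n, s_p, s_n, z)


# ---------------------------------------------------------------------------
# Welch test
# ---------------------------------------------------------------------------

def welch_test(x, y):
    """Two-tailed Welch t-test.

    Returns ``(t, df, p)`` with the Satterthwaite degrees of freedom.  By
    convention two groups with zero variance and equal means give
    ``(0, n1+n2-2, 1)``; zero variance with unequal means gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("welch_test needs n >= 2 in each group")
    v1 = float(np.var(x, ddof=1))
    v2 = float(np.var(y, ddof=1))
    m1, m2 = float(np.mean(x)), float(np.mean(y))
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return math.copysign(math.inf, m1 - m2), float(n1 + n2 - 2), 0.0
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------

def call_hits(activities: pd.DataFrame, control_activities,
              cutoff: float = 20.0, alpha: float = 0.05,
              m: int | None = None) -> pd.DataFrame:
    """Call screening hits against pooled DMSO-control activities.

    A compound is a hit iff its mean activity strictly exceeds ``cutoff``
    (percent displacement) AND its Bonferroni-adjusted two-tailed Welch
    p-value against the DMSO activities is below ``alpha``.  The
    screening is sequential — the cutoff is applied first, followed by
    the t-tests — so the Bonferroni family ``m`` defaults to the number
    of compounds that pass the cutoff (at least 1); pass ``m``
    explicitly to correct over the whole library instead.  Output is
    sorted by mean activity descending, ties broken by compound_id.
    """
    if len(activities) == 0:
        raise InsufficientDataError("no compound activities supplied")
    ctrl = np.asarray(control_activities, dtype=float)
    if ctrl.size < 2:
        raise InsufficientDataError("need >= 2 DMSO control activities")
    if m is None:
        m = max(1, int((activities["mean_activity"] > cutoff).sum()))

    rows = []
    for _, r in activities.iterrows():
        t, df, p = welch_test(np.asarray(r["activities"], dtype=float), ctrl)
        p_adj = min(1.0, m * p)
        rows.append((r["compound_id"], r["mean_activity"], r["sd"], r["n"],
                     bool(r.get("autofluor_flag", False)), p, p_adj,
                     bool(r["mean_activity"] > cutoff and p_adj < alpha)))
    out = pd.DataFrame(rows, columns=[
        "compound_id", "mean_activity", "sd", "n", "autofluor_flag",
        "p_value", "p_adj", "is_hit"])
    return out.sort_values(
        ["mean_activity", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)


def flag_autofluorescence(b_readings, d_readings,
                          rel_threshold: float = 0.2) -> bool:
    """Flag a compound whose intrinsic fluorescence inflates its B wells.

    Flagged iff ``(mean(B) - mean(D)) / mean(D)`` strictly exceeds
    ``rel_threshold``.  A reading exactly at the threshold is not flagged.
    """
    b = np.asarray(b_readings, dtype=float)
    d = np.asarray(d_readings, dtype=float)
    if b.size == 0 or d.size == 0:
        raise InsufficientDataError("need >= 1 B and >= 1 D reading")
    mean_d = float(np.mean(d))
    if mean_d == 0.0:
        raise DegenerateControlsError("mean dye-alone (D) reading is zero")
    return bool((float(np.mean(b)) - mean_d) / mean_d > rel_threshold)


def secondary_screen_rate(n_active: int, n_tested: int) -> int:
    """Active rate of a follow-up screen as the integer percent
    ``round(100 * n_active / n_tested)``."""
    if n_tested <= 0 or n_active < 0 or n_active > n_tested:
        raise ValueError("need 0 <= n_active <= n_tested with n_tested > 0")
    return int(round(100.0 * n_active / n_tested))


# ---------------------------------------------------------------------------
# 4PL dose-response model
# ---------------------------------------------------------------------------

def _fpl(logx, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logx)))


@dataclass
class DoseResponseResults:
    """Results of a 4PL fit: y = bottom + (top-bottom)/(1+(ec50/x)^hill).

    ``ec50`` is only reported when the optimiser converged and the
    estimate lies within the tested concentration range scaled by
    [0.1, 10]; otherwise ``converged`` is False and ``ec50`` is None.
    """

    bottom: float
    top: float
    ec50: float | None
    hill: float
    residual_sse: float
    converged: bool
    n_obs: int
    bse: dict = field(default_factory=dict)  # standard errors where available
    message: str = ""
    _conc: np.ndarray | None = None
    _response: np.ndarray | None = None

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        ec50 = self.ec50 if self.ec50 is not None else float("nan")
        return _fpl(np.log10(conc), self.bottom, self.top,
                    math.log10(ec50), self.hill)

    def summary(self) -> str:
        lines = ["4PL dose-response fit", "-" * 42]
        lines.append(f"{'n obs':<12}{self.n_obs}")
        lines.append(f"{'converged':<12}{self.converged}")
        for name in ("bottom", "top", "ec50", "hill"):
            val = getattr(self, name)
            se = self.bse.get(name)
            txt = "   (not reported)" if val is None else f"{val:12.4g}"
            if se is not None and val is not None:
                txt += f"  (se {se:.3g})"
            lines.append(f"{name:<12}{txt}")
        lines.append(f"{'SSE':<12}{self.residual_sse:12.4g}")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the data and the fitted curve on a log-concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self._conc is not None:
            ax.semilogx(self._conc, self._response, "o", alpha=0.6, label="data")
            if self.converged and self.ec50 is not None:
                grid = np.geomspace(self._conc.min(), self._conc.max(), 200)
                ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
                ax.axvline(self.ec50, ls=":", color="grey")
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


class FourParamLogistic:
    """Four-parameter logistic dose-response model.

    Fit in log10-concentration space by trust-region least squares with
    hill > 0 enforced; initialised at top = max(y), bottom = min(y),
    EC50 = geometric mid-concentration, hill = 1.
    """

    def __init__(self, conc, response):
        conc = np.asarray(conc, dtype=float)
        response = np.asarray(response, dtype=float)
        if conc.shape != response.shape:
            raise ValueError("conc and response must have the same length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(response)):
            raise ValueError("responses must be finite")
        if np.unique(conc).size < 4:
            raise InsufficientDosesError(
                f"4PL needs >= 4 distinct concentrations, got {np.unique(conc).size}"
            )
        self.conc = conc
        self.response = response

    def fit(self) -> DoseResponseResults:
        logx = np.log10(self.conc)
        y = self.response
        lmin, lmax = float(logx.min()), float(logx.max())
        x0 = np.array([float(y.min()), float(y.max()),
                       0.5 * (lmin + lmax), 1.0])
        lo = np.array([-np.inf, -np.inf, lmin - 2.0, 1e-3])
        hi = np.array([np.inf, np.inf, lmax + 2.0, 50.0])

        def resid(theta):
            return _fpl(logx, *theta) - y

        sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                     method="trf", xtol=1e-12, ftol=1e-12,
                                     gtol=1e-12)
        bottom, top, lec50, hill = (float(v) for v in sol.x)
        sse = float(np.sum(sol.fun ** 2))
        ec50 = 10.0 ** lec50
        converged = bool(sol.success)
        message = ""
        # an essentially flat response carries no dose information
        if np.ptp(y) < 1e-9 * max(1.0, abs(float(np.mean(y)))):
            converged, message = False, "response is constant across doses"
        in_range = 0.1 * 10.0 ** lmin <= ec50 <= 10.0 * 10.0 ** lmax
        if converged and not in_range:
            converged = False
            message = (f"EC50 estimate {ec50:.3g} uM lies outside the tested "
                       "range x[0.1, 10]; not reported")
        bse = {}
        if converged:
            dof = y.size - 4
            if dof > 0:
                try:
                    jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
                    perr = np.sqrt(np.diag(jtj_inv) * sse / dof)
                    bse = {"bottom": float(perr[0]), "top": float(perr[1]),
                           "ec50": float(perr[2] * ec50 * math.log(10)),
                           "hill": float(perr[3])}
                except np.linalg.LinAlgError:
                    pass
        return DoseResponseResults(
            bottom=bottom, top=top,
            ec50=ec50 if converged else None, hill=hill,
            residual_sse=sse, converged=converged, n_obs=int(y.size),
            bse=bse, message=message, _conc=self.conc, _response=y)


def fit_4pl(conc, response) -> DoseResponseResults:
    """Functional wrapper: ``FourParamLogistic(conc, response).fit()``."""
    return FourParamLogistic(conc, response).fit()
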