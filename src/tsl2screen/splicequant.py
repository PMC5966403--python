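"""Exon-inclusion quantification and structural-probe analytics.

Covers the low-throughput splicing readouts around the screen: percent
exon-7 inclusion from gel band densitometry, the percent-of-maximum-
increment-possible (%MIP) normalisation of a treatment effect, 2^-ddCt
qPCR fold changes, 2-aminopurine / native-PAGE / circular-dichroism probe
panels correlated against inclusion, and 4PL dose-response fits of
inclusion versus compound concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError
from .screenstats import DoseResponseResults, FourParamLogistic


def percent_inclusion(inc, skip, background: float = 0.0) -> float:
    """Percent inclusion 100*inc/(inc+skip) from the two isoform band
    intensities, after optional constant background subtraction (floored
    at zero) applied to both bands."""
    inc = max(float(inc) - background, 0.0)
    skip = max(float(skip) - background, 0.0)
    if inc < 0 or skip < 0:
        raise ValueError("band intensities must be non-negative")
    total = inc + skip
    if total <= 0:
        raise UndefinedStatisticError(
            "both band intensities are zero after background subtraction"
        )
    return 100.0 * inc / total


def mip(e7_treated: float, e7_dmso: float) -> float:
    """Percent of the maximum inclusion increment possible:

        %MIP = 100 * (E7_treated - E7_dmso) / (100 - E7_dmso)

    i.e. the treatment effect normalised by the remaining headroom above
    the vehicle baseline.  Negative when treatment reduces inclusion.
    """
    for name, v in (("e7_treated", e7_treated), ("e7_dmso", e7_dmso)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if e7_dmso == 100.0:
        raise UndefinedStatisticError(
            "baseline inclusion is 100%; no headroom, %MIP undefined"
        )
    return 100.0 * (e7_treated - e7_dmso) / (100.0 - e7_dmso)


@dataclass
class DdctRecord:
    """One 2^-ddCt comparison: target and reference gene Ct values in the
    treated and control conditions."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def ddct(self) -> float:
        return ((self.ct_target_treated - self.ct_ref_treated)
                - (self.ct_target_control - self.ct_ref_control))


def ddct_fold(record: DdctRecord) -> float:
    """Relative expression fold change 2^-ddCt."""
    cts = (record.ct_target_treated, record.ct_ref_treated,
           record.ct_target_control, record.ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-record.ddct()))


# ---------------------------------------------------------------------------
# structural probe panels
# ---------------------------------------------------------------------------

def probe_delta_and_correlation(panel: pd.DataFrame,
                                reference: str = "n.m."):
    """Per-variant probe-signal change versus the reference variant, and
    its Pearson correlation with exon inclusion across variants.

    ``panel`` has one row per variant per replicate with columns
    ``variant_id``, ``probe_signal``, ``e7_inclusion``.  The probe signal
    can be 2AP fluorescence, a native-PAGE hairpin fraction or a CD band
    magnitude.  Returns ``(per_variant, r, p)`` where ``per_variant`` has
    the mean signal, mean inclusion and delta_pct = 100*(F - F_ref)/F_ref.
    """
    required = {"variant_id", "probe_signal", "e7_inclusion"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    agg = panel.groupby("variant_id", sort=True).agg(
        probe_signal=("probe_signal", "mean"),
        e7_inclusion=("e7_inclusion", "mean"),
        n=("probe_signal", "size"),
    )
    if reference not in agg.index:
        raise ValueError(f"reference variant {reference!r} not in panel")
    if len(agg) < 3:
        raise UndefinedStatisticError(
            "need >= 3 variants for a probe-inclusion correlation"
        )
    f_ref = float(agg.loc[reference, "probe_signal"])
    if f_ref == 0:
        raise UndefinedStatisticError("reference probe signal is zero")
    agg = agg.assign(delta_pct=100.0 * (agg["probe_signal"] - f_ref) / f_ref)
    x = agg["delta_pct"].to_numpy(dtype=float)
    y = agg["e7_inclusion"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "probe signal or inclusion constant across variants; "
            "correlation undefined"
        )
    r, p = stats.pearsonr(x, y)
    return agg.reset_index(), float(r), float(p)


def hairpin_fraction(hairpin_band: float, duplex_band: float) -> float:
    """Fraction of RNA folded as the hairpin on a native gel:
    hairpin / (hairpin + duplex)."""
    h, d = float(hairpin_band), float(duplex_band)
    if h < 0 or d < 0:
        raise ValueError("band intensities must be non-negative")
    if h + d == 0:
        raise UndefinedStatisticError("both native-PAGE bands are zero")
    return h / (h + d)


# ---------------------------------------------------------------------------
# circular dichroism
# ---------------------------------------------------------------------------

@dataclass
class CdExtrema:
    lambda_max: float  # nm, positive band
    mag_max: float
    lambda_min: float  # nm, negative band
    mag_min: float


def _refined_extremum(wl, y, idx):
    """3-point parabolic refinement of a grid extremum at index ``idx``."""
    if idx == 0 or idx == len(y) - 1:
        return float(wl[idx]), float(y[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wl[idx]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    step = wl[idx + 1] - wl[idx]
    return float(wl[idx] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def cd_extrema(spectrum: pd.DataFrame,
               positive_window=(240.0, 300.0),
               negative_window=(200.0, 235.0)) -> CdExtrema:
    """Locate the positive (~265 nm, base stacking) and negative
    (~210 nm, helicity) CD bands of an RNA spectrum.

    ``spectrum`` has columns ``wavelength_nm`` and ``molar_cd``.  The grid
    argmax/argmin in each window is refined by 3-point parabolic
    interpolation, so peak positions are reported at sub-nm resolution.
    """
    s = spectrum.sort_values("wavelength_nm")
    wl = s["wavelength_nm"].to_numpy(dtype=float)
    y = s["molar_cd"].to_numpy(dtype=float)
    out = {}
    for name, (lo, hi), sign in (("max", positive_window, +1),
                                 ("min", negative_window, -1)):
        m = (wl >= lo) & (wl <= hi)
        if m.sum() < 5:
            raise ValueError(
                f"window [{lo}, {hi}] nm covered by only {int(m.sum())} points"
            )
        wlw, yw = wl[m], y[m]
        idx = int(np.argmax(sign * yw))
        if sign * yw[idx] <= 0:
            raise UndefinedStatisticError(
                f"no {'positive' if sign > 0 else 'negative'} extremum in "
                f"window [{lo}, {hi}] nm"
            )
        out[name] = _refined_extremum(wlw, yw, idx)
    return CdExtrema(lambda_max=out["max"][0], mag_max=out["max"][1],
                     lambda_min=out["min"][0], mag_min=out["min"][1])


def cd_peak_shift(variant: pd.DataFrame, reference: pd.DataFrame,
                  **kwargs) -> float:
    """Positive-band wavelength shift of a variant spectrum versus a
    reference spectrum, lambda_max(variant) - lambda_max(reference), in nm."""
    return cd_extrema(variant, **kwargs).lambda_max \
        - cd_extrema(reference, **kwargs).lambda_max


# ---------------------------------------------------------------------------
# dose-response of splicing
# ---------------------------------------------------------------------------

def splicing_dose_response(doses, inclusion) -> DoseResponseResults:
    """4PL fit of percent exon inclusion against compound concentration
    (same contract as :class:`tsl2screen.screenstats.FourParamLogistic`)."""
    return FourParamLogistic(doses, inclusion).fit()
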