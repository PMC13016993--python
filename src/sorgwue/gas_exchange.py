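"""Derived leaf physiology and Ball-Woodrow-Berry model fitting.

The Ball-Woodrow-Berry (BWB) model describes stomatal conductance as a
linear function of the "ball index" An * Hs / Cs:

    gsw = m * (An * Hs / Cs) + g0

where m (dimensionless, the stomatal sensitivity) is the slope and g0
(mol m-2 s-1) the residual conductance as An approaches zero.  Fits are
ordinary least squares of gsw on the ball index over one light-response
curve (one accession x treatment x replicate); treatment effects on m
are compared at the replicate level with Student's t-tests per accession
and an overall two-way ANOVA (accession x treatment).

Also here: intrinsic water-use efficiency iWUE = An / gsw and the
dark-adapted fluorescence yield Fv/Fm = (Fm - F0) / Fm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InputError, ValidationError
from .io_formats import GasExchangeRecord

logger = logging.getLogger(__name__)


def iwue(An: float, gsw: float) -> float:
    """Intrinsic water-use efficiency An/gsw (umol CO2 per mol H2O)."""
    if gsw <= 0:
        raise InputError(f"gsw must be > 0, got {gsw}")
    return An / gsw


def ball_index(An: float, Hs: float, Cs: float) -> float:
    """The BWB regressor An * Hs / Cs (mol m-2 s-1).

    Hs must be a relative-humidity *fraction*; a value above 1 almost
    certainly means percent was passed and raises a unit error.
    """
    if Hs > 1:
        raise InputError(
            f"Hs={Hs} looks like percent relative humidity; pass a fraction in (0, 1]"
        )
    if not (0 < Hs):
        raise InputError(f"Hs must be in (0, 1], got {Hs}")
    if Cs <= 0:
        raise InputError(f"Cs must be > 0, got {Cs}")
    return An * Hs / Cs


def fv_fm(F0: float, Fm: float) -> float:
    """Maximum quantum yield of PSII from dark-adapted fluorescence."""
    if not (Fm > F0 > 0):
        raise InputError(f"need Fm > F0 > 0, got F0={F0}, Fm={Fm}")
    return (Fm - F0) / Fm


@dataclass(frozen=True)
class FluorescenceRecord:
    """Dark-adapted chlorophyll fluorescence: F0, Fm and derived yield."""

    F0: float
    Fm: float

    def __post_init__(self) -> None:
        if not (self.Fm > self.F0 > 0):
            raise ValidationError(f"need Fm > F0 > 0, got F0={self.F0}, Fm={self.Fm}")

    @property
    def Fv(self) -> float:
        return self.Fm - self.F0

    @property
    def FvFm(self) -> float:
        return self.Fv / self.Fm


@dataclass
class BWBFit:
    """OLS fit of one light-response curve to the BWB relation."""

    accession_id: str
    treatment: str
    replicate: int
    m: float
    g0: float
    r2: float
    n_points: int
    mean_iwue: float  # mean An/gsw across the curve's records
    negative_g0: bool = False
    low_n: bool = False


def fit_bwb(records: Sequence[GasExchangeRecord]) -> BWBFit:
    """Fit gsw = m * ball_index + g0 by OLS over one curve.

    Requires >= 3 records from a single accession x treatment x
    replicate with non-degenerate ball-index spread.  g0 is
    unconstrained; a negative intercept is flagged, not rejected.
    """
    if len(records) < 3:
        raise InputError(f"need >= 3 records to fit, got {len(records)}")
    keys = {(r.accession_id, r.treatment, r.replicate) for r in records}
    if len(keys) != 1:
        raise InputError(f"records mix curves: {sorted(keys)}")
    x = np.array([ball_index(r.An, r.Hs, r.Cs) for r in records])
    y = np.array([r.gsw for r in records])
    if np.ptp(x) <= 0 or np.allclose(x, x[0]):
        raise FitError("degenerate ball-index spread; cannot fit a slope")
    res = stats.linregress(x, y)
    acc, treatment, rep = next(iter(keys))
    fit = BWBFit(
        accession_id=acc, treatment=treatment, replicate=rep,
        m=float(res.slope), g0=float(res.intercept),
        r2=float(res.rvalue**2), n_points=len(records),
        mean_iwue=float(np.mean([iwue(r.An, r.gsw) for r in records])),
        negative_g0=res.intercept < 0, low_n=len(records) < 5,
    )
    if fit.negative_g0:
        logger.info("fit_bwb: negative g0=%.4f for %s/%s rep %d",
                    fit.g0, acc, treatment, rep)
    return fit


def fit_bwb_by_curve(records: Sequence[GasExchangeRecord]) -> list[BWBFit]:
    """Group records by (accession, treatment, replicate) and fit each curve."""
    df = pd.DataFrame([r.__dict__ for r in records])
    fits = []
    by_rec = {(r.accession_id, r.treatment, r.replicate): [] for r in records}
    for r in records:
        by_rec[(r.accession_id, r.treatment, r.replicate)].append(r)
    for key in sorted(by_rec):
        fits.append(fit_bwb(by_rec[key]))
    return fits


def pooled_treatment_fit(
    records: Sequence[GasExchangeRecord], treatment: str
) -> tuple[float, float, float, int]:
    """Reporting mode pooling accessions per treatment: records are
    replicate-averaged per accession x PPFD, then one regression is fit
    across all accessions (one point per accession x PPFD level).
    Returns (m, g0, r2, n_points)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    df = df[df["treatment"] == treatment]
    if df.empty:
        raise InputError(f"no records for treatment {treatment}")
    avg = (
        df.groupby(["accession_id", "ppfd"], as_index=False)
        .agg({"An": "mean", "gsw": "mean", "Hs": "mean", "Cs": "mean"})
    )
    x = (avg["An"] * avg["Hs"] / avg["Cs"]).to_numpy()
    y = avg["gsw"].to_numpy()
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), len(avg)


@dataclass
class SlopeContrast:
    """WW vs WS comparison of BWB slopes."""

    per_accession: pd.DataFrame  # accession, m_ww, m_ws, t, p, direction
    anova: pd.DataFrame  # two-way ANOVA table (accession, treatment, interaction)
    interaction_p: float
    treatment_p: float
    r_m_iwue: float  # Pearson r between m and curve-level iWUE across fits
    r_m_iwue_p: float


def compare_slopes(
    fits_ww: Sequence[BWBFit], fits_ws: Sequence[BWBFit]
) -> SlopeContrast:
    """Treatment contrast of the BWB slope at the replicate level.

    Per accession: two-sample t-test of replicate slopes WW vs WS.
    Overall: two-way fixed-effects ANOVA of m on accession x treatment
    (type-I sums of squares, appropriate for the balanced design; cells
    missing replicates are used as available with a warning).  Also
    reports the Pearson correlation between m and curve-level iWUE
    across all fits.
    """
    if len(fits_ww) < 2 or len(fits_ws) < 2:
        raise InputError("need >= 2 fits per treatment")
    df = pd.DataFrame(
        [
            {"accession": f.accession_id, "treatment": f.treatment,
             "replicate": f.replicate, "m": f.m, "iwue": f.mean_iwue}
            for f in list(fits_ww) + list(fits_ws)
        ]
    )
    cell_sizes = df.groupby(["accession", "treatment"]).size()
    if cell_sizes.nunique() > 1:
        logger.warning("compare_slopes: unbalanced cells; ANOVA on available data")

    rows = []
    for acc, sub in df.groupby("accession"):
        ww = sub.loc[sub["treatment"] == "WW", "m"].to_numpy()
        ws = sub.loc[sub["treatment"] == "WS", "m"].to_numpy()
        if len(ww) < 2 or len(ws) < 2:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(ww, ws)
        rows.append(
            {
                "accession": acc,
                "m_ww": ww.mean() if len(ww) else np.nan,
                "m_ws": ws.mean() if len(ws) else np.nan,
                "t": t, "p": p,
                "direction": "WW>WS" if ww.mean() > ws.mean() else "WS>=WW",
            }
        )
    per_acc = pd.DataFrame(rows)

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("m ~ C(accession) * C(treatment)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    interaction_p = float(anova.loc["C(accession):C(treatment)", "PR(>F)"])
    treatment_p = float(anova.loc["C(treatment)", "PR(>F)"])

    r, rp = stats.pearsonr(df["m"], df["iwue"])
    return SlopeContrast(
        per_accession=per_acc, anova=anova,
        interaction_p=interaction_p, treatment_p=treatment_p,
        r_m_iwue=float(r), r_m_iwue_p=float(rp),
    )
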