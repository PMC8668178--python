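"""Linear and linear-plateau dose–response fitting on treatment LSMeans.

Five competing mean-response shapes over the dose range 0–22 mg·kg⁻¹ DM are
fitted to the four dose least-squares means:

1. linear over the whole range 0 → 22;
2. linear 0 → 1.38, plateau 1.38 → 22;
3. linear 0 → 5.5, plateau 5.5 → 22;
4. flat 0 → 1.38, linear 1.38 → 5.5, plateau 5.5 → 22;
5. flat 0 → 1.38, linear 1.38 → 22.

Every candidate has two free parameters (intercept and slope) and is
continuous across its breakpoints by construction.  Candidates are ranked by
the nominal significance of their dose slope: the slope is estimated by
ordinary least squares over the means lying on the sloped segment (plateau
means inform the fit only through the candidate's continuity constraints),
and is scaled by the candidate's full-design dose spread in SEM units,

    t = b_segment * sqrt(Sxx_full) / SEM,

referred to a t distribution on the ANOVA residual df.  This scores each
candidate by the magnitude of the dose signal it implies across the whole
design relative to the precision of a treatment mean; the candidate with the
smallest p is selected, with ties broken toward fewer segments.  The exact
test behind the original selection procedure is not fully identified by its
description, so these p-values are a documented reconstruction meant for
ranking, not calibrated tail probabilities (see docs/methods.md).

The join point of the selected plateau model is the maximum effective dose;
the minimum effective dose is the smallest dose whose planned contrast with
the control is significant after a significant overall F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DOSES",
    "CandidateFit",
    "DoseResponseFit",
    "fit_candidates",
    "min_effective_dose",
    "max_effective_dose",
]

DOSES = (0.0, 1.38, 5.5, 22.0)


def _x1(d):
    return np.asarray(d, dtype=float)


def _x2(d):
    return np.minimum(np.asarray(d, dtype=float), 1.38)


def _x3(d):
    return np.minimum(np.asarray(d, dtype=float), 5.5)


def _x4(d):
    return np.clip(np.asarray(d, dtype=float), 1.38, 5.5)


def _x5(d):
    return np.maximum(np.asarray(d, dtype=float), 1.38)


# (id, description, x-map, sloped-segment doses, join point, n segments)
_CANDIDATES = (
    (1, "linear 0-22", _x1, (0.0, 1.38, 5.5, 22.0), None, 1),
    (2, "linear 0-1.38, plateau", _x2, (0.0, 1.38), 1.38, 2),
    (3, "linear 0-5.5, plateau", _x3, (0.0, 1.38, 5.5), 5.5, 2),
    (4, "flat 0-1.38, linear 1.38-5.5, plateau", _x4, (1.38, 5.5), 5.5, 3),
    (5, "flat 0-1.38, linear 1.38-22", _x5, (1.38, 5.5, 22.0), None, 2),
)


@dataclass
class CandidateFit:
    model_id: int
    description: str
    intercept: float
    slope: float  # segment-estimated slope (response units per mg/kg)
    slope_full: float  # slope from the full 4-mean least-squares fit
    t: float
    p: float
    sse: float
    join_point: Optional[float]
    n_segments: int
    _xfun: Callable = None

    def predict(self, dose):
        """Fitted mean response at arbitrary dose(s) (full-LS parameters)."""
        return self.intercept + self.slope_full * self._xfun(dose)


@dataclass
class DoseResponseFit:
    doses: np.ndarray
    means: np.ndarray
    sem: float
    df_resid: int
    candidates: list
    selected: CandidateFit
    responsive: bool  # selected slope nominally significant

    @property
    def selected_model(self) -> int:
        return self.selected.model_id


def _ols_line(x: np.ndarray, y: np.ndarray):
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        return ybar, 0.0, 0.0
    slope = float(((x - xbar) * (y - ybar)).sum() / sxx)
    return ybar - slope * xbar, slope, sxx


def fit_candidates(
    means: Sequence[float],
    sem: float,
    doses: Sequence[float] = DOSES,
    df_resid: int = 14,
) -> DoseResponseFit:
    """Fit and rank the five candidate shapes.

    Parameters
    ----------
    means
        The four dose LSMeans, ordered as ``doses``.
    sem
        Standard error of a treatment mean from the pooled ANOVA.
    doses
        The dose levels; all five canonical breakpoints assume the standard
        set {0, 1.38, 5.5, 22.0}.
    df_resid
        Residual df of the ANOVA that produced the means (14 in the full
        three-cycle design).
    """
    doses = np.asarray(doses, dtype=float)
    means = np.asarray(means, dtype=float)
    if doses.shape != (4,) or means.shape != (4,):
        raise ValueError("exactly four dose levels with means are required")
    if not np.allclose(np.sort(doses), DOSES):
        raise ValueError(f"expected dose levels {DOSES}, got {tuple(doses)}")
    if sem <= 0:
        raise ValueError("sem must be positive")
    order = np.argsort(doses)
    doses, means = doses[order], means[order]

    fits = []
    for mid, desc, xfun, seg, join, nseg in _CANDIDATES:
        xfull = xfun(doses)
        a_full, b_full, sxx_full = _ols_line(xfull, means)
        fitted = a_full + b_full * xfull
        sse = float(((means - fitted) ** 2).sum())

        seg_mask = np.isin(doses, seg)
        _, b_seg, _ = _ols_line(xfun(doses[seg_mask]), means[seg_mask])

        t = b_seg * np.sqrt(sxx_full) / sem
        p = float(2 * stats.t.sf(abs(t), df_resid))
        fits.append(
            CandidateFit(
                model_id=mid,
                description=desc,
                intercept=a_full,
                slope=b_seg,
                slope_full=b_full,
                t=float(t),
                p=p,
                sse=sse,
                join_point=join,
                n_segments=nseg,
                _xfun=xfun,
            )
        )

    # |t| is monotone in p on a common df and keeps discriminating where the
    # p-values underflow; exact ties break toward fewer segments
    selected = min(fits, key=lambda f: (-abs(f.t), f.n_segments, f.model_id))
    return DoseResponseFit(
        doses=doses,
        means=means,
        sem=float(sem),
        df_resid=int(df_resid),
        candidates=fits,
        selected=selected,
        responsive=selected.p <= 0.05,
    )


def min_effective_dose(
    dose_f_p: float, contrasts: pd.DataFrame, alpha: float = 0.05
):
    """Smallest dose whose planned contrast with control is significant.

    Requires a significant overall dose F-test first; returns ``(dose,
    reason)`` where dose is ``None`` when the F-test or every contrast fails.
    ``contrasts`` needs columns ``dose`` and ``p``.
    """
    if dose_f_p >= alpha:
        return None, f"overall dose F-test not significant (p = {dose_f_p:.3g})"
    sig = contrasts.loc[contrasts["p"] < alpha, "dose"]
    if sig.empty:
        return None, "no dose differed from control in the planned contrasts"
    return float(sig.min()), "smallest dose differing from control"


def max_effective_dose(fit: DoseResponseFit, dose_f_p: Optional[float] = None):
    """Join point of the selected plateau model, gated on significance.

    Returns ``(dose, reason)``.  The selected candidate must contain a
    plateau segment (models 1 and 5 are monotone to the top dose and yield
    ``None``), and the dose response must be significant.  Significance is
    judged by the overall ANOVA dose F-test when supplied — the reconstructed
    slope p-values rank the candidates but their absolute scale is not that
    of the original procedure — else by the selected slope's nominal p.
    """
    gate_p = dose_f_p if dose_f_p is not None else fit.selected.p
    if gate_p > 0.05:
        return None, f"dose response not significant (p = {gate_p:.3g})"
    if fit.selected.join_point is None:
        return None, (
            f"selected model {fit.selected.model_id} has no plateau; response "
            "is monotone to the top dose"
        )
    return float(fit.selected.join_point), "join point of the selected plateau model"
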