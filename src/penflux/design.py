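"""Balanced randomized-complete-block analysis for dose × sex trials.

The design has ``b`` time blocks (cycles), ``d`` dose levels and two sexes,
with exactly one enclosure per dose × sex cell per block.  In this balanced
layout the classical sums-of-squares decomposition with cycle as a block
stratum yields the same treatment F-tests, least-squares means and contrasts
as a REML mixed model with random cycle, so the closed form is used.

Planned contrasts compare each dose with the zero-dose control, unadjusted
for multiplicity.  When the dose × sex interaction is significant the same
contrasts are evaluated within each sex instead of pooled.

Sparse categorical outcomes fall back from a logit-link binomial model to a
conditional exact (Fisher) test on the control-versus-treated margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "rcbd_fit",
    "rcbd_fit_cube",
    "interaction_gate",
    "significance_label",
    "fisher_exact_2xk",
    "binomial_category_fit",
]

ALPHA = 0.05
TENDENCY = 0.10


def significance_label(p: float) -> str:
    """'significant' (p ≤ 0.05), 'tendency' (0.05 < p ≤ 0.10) or 'ns'."""
    if p <= ALPHA:
        return "significant"
    if p <= TENDENCY:
        return "tendency"
    return "ns"


@dataclass
class AnovaResult:
    """Fit of a balanced block × dose × sex ANOVA."""

    doses: np.ndarray
    sexes: list
    anova_table: pd.DataFrame  # source, df, ss, ms, F, p
    lsmeans_dose: pd.Series
    lsmeans_sex: pd.Series
    cell_means: pd.DataFrame  # dose × sex
    sem_dose: float
    sem_sex: float
    mse: float
    df_resid: int
    contrasts: pd.DataFrame  # each dose vs control, pooled over sex
    within_sex_contrasts: pd.DataFrame
    dose_p: float = field(init=False)
    sex_p: float = field(init=False)
    interaction_p: float = field(init=False)

    def __post_init__(self) -> None:
        t = self.anova_table.set_index("source")
        self.dose_p = float(t.loc["dose", "p"])
        self.sex_p = float(t.loc["sex", "p"])
        self.interaction_p = float(t.loc["dose:sex", "p"])


def rcbd_fit_cube(y: np.ndarray, doses=None, sexes=("steer", "heifer")) -> AnovaResult:
    """Fit from a response cube of shape (blocks, doses, sexes).

    The array form is the fast path used by simulation studies; NaNs are not
    allowed (the design must be complete).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("response cube must be (blocks, doses, sexes)")
    b, d, s = y.shape
    if s != 2:
        raise ValueError("exactly two sexes expected")
    if b < 2 or d < 2:
        raise ValueError("need at least two blocks and two doses")
    if np.isnan(y).any():
        raise ValueError("unbalanced table: missing cells")
    if doses is None:
        doses = np.arange(d, dtype=float)
    doses = np.asarray(doses, dtype=float)

    grand = y.mean()
    block_m = y.mean(axis=(1, 2))
    dose_m = y.mean(axis=(0, 2))
    sex_m = y.mean(axis=(0, 1))
    cell_m = y.mean(axis=0)  # (d, s)

    ss_total = float(((y - grand) ** 2).sum())
    ss_block = float(d * s * ((block_m - grand) ** 2).sum())
    ss_dose = float(b * s * ((dose_m - grand) ** 2).sum())
    ss_sex = float(b * d * ((sex_m - grand) ** 2).sum())
    inter_dev = cell_m - dose_m[:, None] - sex_m[None, :] + grand
    ss_int = float(b * (inter_dev**2).sum())
    ss_resid = ss_total - ss_block - ss_dose - ss_sex - ss_int

    df_block, df_dose, df_sex, df_int = b - 1, d - 1, 1, d - 1
    df_resid = (b - 1) * (2 * d - 1)
    mse = ss_resid / df_resid

    def frow(source, df, ss):
        if source in ("residual",):
            return {"source": source, "df": df, "ss": ss, "ms": ss / df, "F": np.nan, "p": np.nan}
        ms = ss / df
        if mse == 0:
            F = np.inf if ms > 0 else 0.0
            p = 0.0 if ms > 0 else 1.0
        else:
            F = ms / mse
            p = float(stats.f.sf(F, df, df_resid))
        return {"source": source, "df": df, "ss": ss, "ms": ms, "F": F, "p": p}

    table = pd.DataFrame(
        [
            frow("block", df_block, ss_block),
            frow("dose", df_dose, ss_dose),
            frow("sex", df_sex, ss_sex),
            frow("dose:sex", df_int, ss_int),
            frow("residual", df_resid, ss_resid),
        ]
    )

    n_per_dose = b * s
    sem_dose = math.sqrt(mse / n_per_dose)
    sem_sex = math.sqrt(mse / (b * d))

    def _contrast(diff, n):
        se = math.sqrt(2 * mse / n)
        if se == 0:
            t = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), df_resid))
        return se, t, p

    ctr_rows = []
    for j in range(1, d):
        diff = dose_m[j] - dose_m[0]
        se, t, p = _contrast(diff, n_per_dose)
        ctr_rows.append(
            {"dose": doses[j], "diff": diff, "se": se, "t": t, "p": p,
             "label": significance_label(p)}
        )
    contrasts = pd.DataFrame(ctr_rows)

    ws_rows = []
    for k, sex in enumerate(sexes):
        for j in range(1, d):
            diff = cell_m[j, k] - cell_m[0, k]
            se, t, p = _contrast(diff, b)
            ws_rows.append(
                {"sex": sex, "dose": doses[j], "diff": diff, "se": se, "t": t, "p": p,
                 "label": significance_label(p)}
            )
    within = pd.DataFrame(ws_rows)

    return AnovaResult(
        doses=doses,
        sexes=list(sexes),
        anova_table=table,
        lsmeans_dose=pd.Series(dose_m, index=doses, name="lsmean"),
        lsmeans_sex=pd.Series(sex_m, index=list(sexes), name="lsmean"),
        cell_means=pd.DataFrame(cell_m, index=doses, columns=list(sexes)),
        sem_dose=sem_dose,
        sem_sex=sem_sex,
        mse=mse,
        df_resid=df_resid,
        contrasts=contrasts,
        within_sex_contrasts=within,
    )


def rcbd_fit(table: pd.DataFrame, response: str = "value") -> AnovaResult:
    """Fit from a long table with columns cycle, dose, sex and a response.

    The table must be balanced: exactly one observation per cycle × dose ×
    sex cell; anything else raises (the design is balanced by construction
    and unbalanced generalisations are out of scope).
    """
    req = {"cycle", "dose", "sex", response}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    blocks = np.sort(table["cycle"].unique())
    doses = np.sort(table["dose"].unique().astype(float))
    sexes = sorted(table["sex"].unique(), reverse=True)  # steer, heifer
    counts = table.groupby(["cycle", "dose", "sex"]).size()
    if len(counts) != len(blocks) * len(doses) * len(sexes) or (counts != 1).any():
        raise ValueError("unbalanced table: need exactly one row per cycle x dose x sex")
    cube = np.full((len(blocks), len(doses), len(sexes)), np.nan)
    bi = {v: i for i, v in enumerate(blocks)}
    di = {v: i for i, v in enumerate(doses)}
    si = {v: i for i, v in enumerate(sexes)}
    for row in table.itertuples(index=False):
        cube[bi[row.cycle], di[float(row.dose)], si[row.sex]] = getattr(row, response)
    return rcbd_fit_cube(cube, doses=doses, sexes=sexes)


@dataclass
class GateDecision:
    route: str  # "pooled" or "within_sex"
    interaction_p: float
    contrasts: pd.DataFrame


def interaction_gate(result: AnovaResult) -> GateDecision:
    """Route reporting by the dose × sex interaction test.

    A non-significant interaction (p > 0.05) pools the dose means across
    sexes; p ≤ 0.05 (ties included) routes to within-sex contrasts.
    """
    if result.interaction_p <= ALPHA:
        return GateDecision("within_sex", result.interaction_p, result.within_sex_contrasts)
    return GateDecision("pooled", result.interaction_p, result.contrasts)


def fisher_exact_2xk(counts) -> float:
    """Two-sided conditional exact test for a 2 × k contingency table.

    Enumerates all tables with the observed margins; the p-value is the total
    probability of tables no more probable than the observed one (the
    standard two-sided convention, which for 2 × 2 matches Fisher's test).
    """
    obs = np.asarray(counts, dtype=int)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    row1 = int(obs[0].sum())
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())

    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])

    def log_comb(a, b):
        return log_fact[a] - log_fact[b] - log_fact[a - b]

    denom = log_comb(n, row1)

    def table_logp(top):
        return sum(log_comb(int(c), int(a)) for c, a in zip(col_sums, top)) - denom

    obs_log_num = table_logp(obs[0]) + denom  # numerator only
    k = len(col_sums)

    total = 0.0
    # enumerate first-row entries column by column under the margin constraints
    def rec(j, remaining, logp):
        nonlocal total
        if j == k - 1:
            a = remaining
            if 0 <= a <= col_sums[j]:
                lp = logp + log_comb(int(col_sums[j]), a)
                if lp <= obs_log_num + 1e-9:
                    total += math.exp(lp - denom)
            return
        tail_capacity = int(col_sums[j + 1 :].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(col_sums[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, logp + log_comb(int(col_sums[j]), a))

    rec(0, row1, 0.0)
    return float(min(1.0, total))


@dataclass
class CategoricalResult:
    method: str  # "binomial_glm" or "fisher_fallback"
    probs_by_dose: Optional[pd.Series]
    contrasts: Optional[pd.DataFrame]
    fallback_p: Optional[float]
    fallback_table: Optional[np.ndarray] = None


def binomial_category_fit(counts: pd.DataFrame) -> CategoricalResult:
    """Dose effect on a binary pen-level category frequency.

    ``counts`` has one row per enclosure: cycle, dose, sex, k (animals in the
    category) and n (animals graded).  Fits a logit-link binomial GLM with
    dose, sex, dose × sex and cycle as fixed effects (the fixed-block
    approximation of the random-cycle model) and Wald contrasts of each dose
    against the control on the logit scale, averaged over sexes.

    When the data are sparse — some dose arm with zero (or saturated) counts,
    or a non-converging fit — the model is abandoned for a conditional exact
    test of control vs. treated pooled over the positive doses.
    """
    import statsmodels.api as sm

    req = {"cycle", "dose", "sex", "k", "n"}
    if req - set(counts.columns):
        raise ValueError(f"missing columns: {sorted(req - set(counts.columns))}")
    doses = np.sort(counts["dose"].unique().astype(float))
    arm = counts.groupby("dose")[["k", "n"]].sum()

    def _fallback() -> CategoricalResult:
        con = arm.loc[0.0]
        lub = arm.drop(index=0.0).sum()
        table = np.array(
            [[int(con["k"]), int(con["n"] - con["k"])],
             [int(lub["k"]), int(lub["n"] - lub["k"])]]
        )
        return CategoricalResult(
            "fisher_fallback", None, None, fisher_exact_2xk(table), table
        )

    sparse = (arm["k"] == 0).any() or (arm["k"] == arm["n"]).any()
    if sparse:
        return _fallback()

    df = counts.copy()
    df["dose"] = df["dose"].astype(float)
    sexes = sorted(df["sex"].unique(), reverse=True)
    cycles = np.sort(df["cycle"].unique())
    # treatment-coded design built by hand (reference: control dose, first
    # sex, first cycle)
    cols = {}
    for d in doses[1:]:
        cols[f"dose_{d}"] = (df["dose"] == d).astype(float)
    for s in sexes[1:]:
        cols[f"sex_{s}"] = (df["sex"] == s).astype(float)
    for d in doses[1:]:
        for s in sexes[1:]:
            cols[f"dose_{d}:sex_{s}"] = cols[f"dose_{d}"] * cols[f"sex_{s}"]
    for c in cycles[1:]:
        cols[f"cycle_{c}"] = (df["cycle"] == c).astype(float)
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    endog = np.column_stack([df["k"], df["n"] - df["k"]])
    import warnings

    try:
        with warnings.catch_warnings():
            # sparse pen counts routinely separate; such fits are discarded
            # below in favour of the exact test, so the noise is suppressed
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not fit.converged or not np.isfinite(fit.bse).all() or (fit.bse > 1e3).any():
            return _fallback()
    except Exception:
        return _fallback()

    names = list(X.columns)
    rows = []
    probs = {}
    # mean logit per dose averaged over sexes at the average cycle level
    cyc_cols = [f"cycle_{c}" for c in cycles[1:]]
    base = {nm: 0.0 for nm in names}
    base["const"] = 1.0
    for nm in cyc_cols:
        base[nm] = 1.0 / len(cycles)

    def dose_logit_vec(d):
        v = dict(base)
        if d != doses[0]:
            v[f"dose_{d}"] = 1.0
        for s in sexes[1:]:
            v[f"sex_{s}"] = 1.0 / len(sexes)
            if d != doses[0]:
                v[f"dose_{d}:sex_{s}"] = 1.0 / len(sexes)
        return np.array([v[nm] for nm in names])

    cov = fit.cov_params().to_numpy() if hasattr(fit.cov_params(), "to_numpy") else fit.cov_params()
    params = np.asarray(fit.params)
    for d in doses:
        eta = dose_logit_vec(d) @ params
        probs[d] = float(1 / (1 + np.exp(-eta)))
    for d in doses[1:]:
        L = dose_logit_vec(d) - dose_logit_vec(doses[0])
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append({"dose": d, "logit_diff": est, "se": se, "z": z, "p": p})
    return CategoricalResult(
        "binomial_glm", pd.Series(probs, name="prob"), pd.DataFrame(rows), None
    )
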