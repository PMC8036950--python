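"""Two-way repeated-measures ANOVA with Greenhouse-Geisser correction, plus
Holm-adjusted paired contrasts between measurement ranges.

The comparison design is fully within-subject: every subject contributes one
response value (per-subject F1 or MAE from leave-one-subject-out evaluation)
in each cell of the model-family x measurement-range crossing.  The standard
balanced within-subject decomposition is used: each effect (factor A, factor
B, their interaction) is tested against its own subject-by-effect error term.
Sphericity of a within factor with more than two levels is never assumed;
the Greenhouse-Geisser epsilon (Box's sample-covariance estimator, computed
from orthonormal contrast scores) multiplies both degrees of freedom before
the p-value is taken, which leaves the F statistic itself unchanged.  For a
two-level factor epsilon is exactly 1 and the correction is a no-op.

Marginal contrasts between the high-g and low-g ranges are paired
within-subject differences; with a balanced design these coincide with
model-estimated marginal-mean contrasts.  Families of contrasts are adjusted
with the step-down Holm method.  Alpha is fixed at 0.05 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import BalanceError, ContractError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Effect table plus the full sum-of-squares decomposition."""

    effects: pd.DataFrame   # index: effect name; SS, df1, df2, eps, F, p_unc, p_gg, error_ss
    ss_subject: float
    ss_total: float
    factor_levels: dict

    def decomposition_total(self) -> float:
        """Sum of every effect SS, error SS and the subject SS."""
        return float(
            self.effects["ss"].sum() + self.effects["error_ss"].sum() + self.ss_subject
        )


def _check_balance(tbl, subject, factors, response):
    cells = tbl.groupby([subject, *factors], observed=True).size()
    subjects = tbl[subject].unique()
    levels = [sorted(tbl[f].unique()) for f in factors]
    expected = {(s, *combo) for s in subjects
                for combo in pd.MultiIndex.from_product(levels)}
    got = set(cells.index)
    missing = expected - got
    if missing or (cells != 1).any():
        dup = [idx for idx, k in cells.items() if k != 1]
        raise BalanceError(sorted(missing) + [(*d, "duplicated") for d in dup])
    if not np.isfinite(tbl[response].to_numpy(dtype=float)).all():
        raise ContractError("responses must be finite")
    return subjects, levels


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, sum zero)."""
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1.0)
        H[i] /= np.linalg.norm(H[i])
    return H


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from per-subject orthonormal contrast scores.

    ``scores`` is n_subjects x (effect df); epsilon = tr(S)^2 / (df * tr(S@S))
    with S the sample covariance of the scores, bounded to [1/df, 1].
    """
    df = scores.shape[1]
    if df <= 1:
        return 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(S)
    denom = df * np.trace(S @ S)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(1.0 / df, eps)))


def rm_anova_two_way(
    tbl: pd.DataFrame,
    subject: str = "subject_id",
    factors: tuple[str, str] = ("family", "range"),
    response: str = "value",
) -> AnovaResult:
    """Balanced two-way fully-within-subject ANOVA with GG-corrected p-values."""
    fa, fb = factors
    subjects, (lev_a, lev_b) = _check_balance(tbl, subject, factors, response)
    n, a, b = len(subjects), len(lev_a), len(lev_b)
    if n < 3:
        raise ContractError("need at least 3 subjects")

    # y[s, i, j] cube in fixed level order
    piv = tbl.pivot_table(index=subject, columns=list(factors), values=response, observed=True)
    piv = piv.reindex(index=subjects, columns=pd.MultiIndex.from_product([lev_a, lev_b]))
    y = piv.to_numpy(dtype=float).reshape(n, a, b)

    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_subj = a * b * np.sum((m_s - g) ** 2)
    ss_a = n * b * np.sum((m_a - g) ** 2)
    ss_b = n * a * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    err_a = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    err_b = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - g
    )
    err_ab = np.sum(resid**2)
    ss_total = np.sum((y - g) ** 2)

    Ca, Cb = _helmert(a), _helmert(b)
    scores_a = y.mean(axis=2) @ Ca.T                       # n x (a-1)
    scores_b = y.mean(axis=1) @ Cb.T                       # n x (b-1)
    scores_ab = np.einsum("pi,nij,qj->npq", Ca, y, Cb).reshape(n, (a - 1) * (b - 1))

    rows = {}
    for name, ss, err, df1, df2, scores in (
        (fa, ss_a, err_a, a - 1, (a - 1) * (n - 1), scores_a),
        (fb, ss_b, err_b, b - 1, (b - 1) * (n - 1), scores_b),
        (f"{fa}:{fb}", ss_ab, err_ab, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), scores_ab),
    ):
        if err <= 0:
            F = np.inf if ss > 0 else np.nan
        else:
            F = (ss / df1) / (err / df2)
        eps = _gg_epsilon(scores)
        p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else (0.0 if ss > 0 else np.nan)
        p_gg = (
            float(sps.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else (0.0 if ss > 0 else np.nan)
        )
        rows[name] = {
            "ss": float(ss),
            "df1": df1,
            "df2": df2,
            "error_ss": float(err),
            "F": float(F),
            "eps": eps,
            "df1_gg": eps * df1,
            "df2_gg": eps * df2,
            "p_unc": p_unc,
            "p_gg": p_gg,
            "sphericity_assumed": df1 <= 1,
        }
    effects = pd.DataFrame(rows).T
    result = AnovaResult(
        effects=effects,
        ss_subject=float(ss_subj),
        ss_total=float(ss_total),
        factor_levels={fa: lev_a, fb: lev_b},
    )
    return result


def marginal_means(
    tbl: pd.DataFrame,
    subject: str = "subject_id",
    factors: tuple[str, str] = ("family", "range"),
    response: str = "value",
) -> dict[str, pd.Series]:
    """Cell means and per-factor margin means (arithmetic = model-estimated
    when the design is balanced, which ``_check_balance`` enforces)."""
    _check_balance(tbl, subject, factors, response)
    out = {"cell": tbl.groupby(list(factors), observed=True)[response].mean()}
    for f in factors:
        out[f] = tbl.groupby(f, observed=True)[response].mean()
    out["grand"] = tbl[response].mean()
    return out


def holm_adjust(p: list[float]) -> list[float]:
    """Step-down Holm adjustment, returned in the input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ContractError("p must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj.tolist()


def paired_range_contrast(
    tbl: pd.DataFrame,
    strata: str = "family",
    range_col: str = "range",
    high: str = "high_g",
    low: str = "low_g",
    subject: str = "subject_id",
    response: str = "value",
) -> pd.DataFrame:
    """Per-stratum paired high-minus-low contrasts, Holm-adjusted across strata.

    Within each stratum (e.g. each model family) the subject-wise high-g minus
    low-g differences feed a paired t-test; subjects missing either level in a
    stratum are dropped with a log entry.
    """
    rows = []
    for level, sub in tbl.groupby(strata, observed=True):
        wide = sub.pivot_table(index=subject, columns=range_col, values=response, observed=True)
        if high not in wide.columns or low not in wide.columns:
            raise ContractError(f"stratum {level!r} lacks a range level")
        complete = wide.dropna(subset=[high, low])
        dropped = len(wide) - len(complete)
        if dropped:
            logger.info("stratum %s: dropped %d subject(s) missing a range level", level, dropped)
        d = (complete[high] - complete[low]).to_numpy(dtype=float)
        if d.size < 2:
            raise ContractError(f"stratum {level!r}: need >= 2 paired subjects")
        if np.allclose(d, d[0]):
            # zero-variance differences: t undefined; p = 1 when all-zero else -> 0
            p = 1.0 if np.allclose(d, 0.0) else 0.0
            t = np.nan
        else:
            t, p = sps.ttest_rel(complete[high], complete[low])
        rows.append(
            {
                strata: level,
                "estimate": float(d.mean()),
                "n_pairs": int(d.size),
                "t": float(t),
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].tolist())
    return out
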