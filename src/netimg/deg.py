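"""Differential expression: moderated t-statistic, BH adjustment, DEG union.

Per cancer type, tumors are compared with their matched normal tissues on
log2(x+1)-transformed expression. The per-gene residual variance is shrunk
toward a common prior by empirical Bayes: the prior degrees of freedom d0 and
prior variance s0^2 are fit by method of moments on the log sample variances,
the shrunken variance is the df-weighted average

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

and the moderated t uses s_tilde with df + d0 degrees of freedom. A gene is a
DEG when |fold change| >= 2 and BH-adjusted p < 0.01 in at least one cancer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = ["moderated_t", "adjust_p", "deg_union", "deg_table", "fit_prior"]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from sample variances.

    Models log(s^2) as a scaled-F deviate around log(s0^2); matches the mean
    and variance of e = log(s^2) - digamma(df/2) + log(df/2). When the
    observed spread of log variances does not exceed its sampling expectation,
    d0 is infinite (all genes share s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        return np.inf, 0.0
    e = np.log(positive) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if positive.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene fold change and moderated t between two sample groups.

    Parameters
    ----------
    group_a, group_b
        Genes x samples matrices of non-negative expression values (rows
        aligned). DataFrames keep their gene index in the result.
    prior_df
        Override the fitted prior degrees of freedom: ``0`` gives the
        ordinary pooled-variance t, ``numpy.inf`` uses the prior variance
        s0^2 for every gene, ``None`` (default) fits d0 from the data.

    Returns
    -------
    DataFrame with columns ``log2_fc``, ``t_mod``, ``p_raw``.
    """
    index = group_a.index if isinstance(group_a, pd.DataFrame) else None
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    if a.shape[0] != b.shape[0]:
        raise ValueError("group matrices must cover the same genes")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")

    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    log2_fc = la.mean(axis=1) - lb.mean(axis=1)

    df = float(n_a + n_b - 2)
    ss = ((la - la.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (lb - lb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df

    if prior_df is None:
        d0, s0_sq = fit_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_prior(s2, df)

    if np.isinf(d0):
        s2_shrunk = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_shrunk = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_shrunk * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2_fc / np.where(se > 0, se, 1.0), 0.0)
    # no variance anywhere and no difference: declare null (t=0, p=1);
    # no variance with a difference cannot be scored -> infinite t, p=0
    degenerate = (se == 0) & (log2_fc != 0)
    if degenerate.any():
        t_mod = np.where(degenerate, np.where(log2_fc > 0, np.inf, -np.inf), t_mod)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.where((se == 0) & (log2_fc == 0), 1.0, p_raw)

    return pd.DataFrame(
        {"log2_fc": log2_fc, "t_mod": t_mod, "p_raw": p_raw}, index=index
    )


def adjust_p(p_raw: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_table(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Run tumor-vs-normal moderated t per cancer type.

    ``expression`` is genes x samples; ``metadata`` has columns ``sample_id``,
    ``cancer``, ``status`` (``tumor``/``normal``). Adjustment is applied
    within each cancer's comparison. Returns the long-format DEG table with
    columns ``gene``, ``cancer``, ``log2_fc``, ``t_mod``, ``p_raw``, ``p_adj``.
    """
    required = {"sample_id", "cancer", "status"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    frames = []
    for cancer, grp in metadata.groupby("cancer", sort=True):
        tumors = grp.loc[grp["status"] == "tumor", "sample_id"]
        normals = grp.loc[grp["status"] == "normal", "sample_id"]
        if len(tumors) < 2 or len(normals) < 2:
            raise ValueError(
                f"cancer {cancer!r} needs >=2 tumor and >=2 normal samples"
            )
        res = moderated_t(
            expression[list(tumors)], expression[list(normals)], prior_df=prior_df
        )
        res["p_adj"] = adjust_p(res["p_raw"].to_numpy())
        res.insert(0, "cancer", cancer)
        res.insert(0, "gene", expression.index)
        frames.append(res.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def deg_union(
    records: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> set[str]:
    """Genes with |FC| >= fc_threshold and adjusted p < p_threshold somewhere.

    ``records`` is the long table from :func:`deg_table` (needs ``gene``,
    ``log2_fc``, ``p_adj``). The fold-change bound is inclusive and applied
    on the log2 scale (|log2_fc| >= log2(fc_threshold)); the p bound is
    strict, matching the filter "|FC| >= 2 and adjusted p < 0.01".
    """
    if records.empty:
        return set()
    lfc = np.log2(fc_threshold)
    hit = (records["log2_fc"].abs() >= lfc) & (records["p_adj"] < p_threshold)
    return set(records.loc[hit, "gene"])
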