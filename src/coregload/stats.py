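"""Within-subject statistics layer.

Repeated-measures ANOVA (one or two within factors) with Greenhouse-Geisser
correction and partial eta squared; Holm-corrected paired post hocs;
subject-level sign-flip permutation tests per electrode with
Benjamini-Hochberg FDR; repeated-measures correlation; and the Morey
within-subject standard error used for condition-mean error bars.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PairedTResult",
    "TopoTestResult",
    "RmCorrResult",
    "rm_anova",
    "rm_anova_oneway",
    "posthoc_paired_t",
    "holm",
    "benjamini_hochberg",
    "permutation_topo_test",
    "rmcorr",
    "within_subject_sem",
]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[float, float]
    p: float
    gg_epsilon: float
    p_gg: float
    eta_p2: float
    degenerate: bool = False
    sphericity_flag: bool = False  # True when epsilon < 0.75


@dataclass
class PairedTResult:
    level_a: str
    level_b: str
    t: float
    df: int
    p_raw: float
    p_adj: float
    degenerate: bool = False


@dataclass
class TopoTestResult:
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_perm: int
    exact: bool


@dataclass
class RmCorrResult:
    r: float
    df: int
    p: float
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# p-value adjustments
# ---------------------------------------------------------------------------

def holm(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty_like(p)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _gg_epsilon(cell_data: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast-projected sample covariance."""
    S = np.cov(cell_data, rowvar=False, ddof=1)
    M = contrasts @ np.atleast_2d(S) @ contrasts.T
    d = M.shape[0]
    tr = np.trace(M)
    denom = d * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova_oneway(data: np.ndarray, effect: str = "factor") -> AnovaResult:
    """One-way repeated-measures ANOVA on an (N subjects x k levels) array."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need >= 2 levels")
    if n < 3:
        raise ValueError("need >= 3 subjects")
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return _assemble_result(effect, ss_cond, ss_err, df1, df2, data)


def _assemble_result(
    effect: str,
    ss_eff: float,
    ss_err: float,
    df1: int,
    df2: int,
    cell_data: np.ndarray,
    contrasts: np.ndarray | None = None,
) -> AnovaResult:
    ss_err = max(ss_err, 0.0)
    if contrasts is None:
        contrasts = _orthonormal_contrasts(cell_data.shape[1])
    if ss_err <= 1e-12 * max(ss_eff, 1.0):
        f = 0.0 if ss_eff <= 1e-12 else math.inf
        return AnovaResult(
            effect, f, (df1, df2), math.nan, 1.0, math.nan,
            0.0 if ss_eff <= 1e-12 else 1.0, degenerate=True,
        )
    f = (ss_eff / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    eps = _gg_epsilon(cell_data, contrasts)
    p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
    eta = ss_eff / (ss_eff + ss_err)
    return AnovaResult(
        effect, float(f), (df1, df2), p, eps, p_gg, float(eta),
        sphericity_flag=eps < 0.75,
    )


def rm_anova(
    table,
    dv: str = "value",
    subject: str = "subject",
    within: list[str] | None = None,
) -> list[AnovaResult]:
    """Repeated-measures ANOVA from a tidy table (one or two within factors).

    ``table`` is a pandas DataFrame with one row per subject x cell; the
    design must be complete and balanced (exactly one observation per
    subject per cell).  Returns main effects (and the interaction for two
    factors), each with the uncorrected p, the Greenhouse-Geisser epsilon
    and corrected p, and partial eta squared.
    """
    import pandas as pd

    if within is None or not within:
        raise ValueError("name at least one within factor")
    if len(within) > 2:
        raise ValueError("at most two within factors supported")
    df = pd.DataFrame(table)
    subjects = sorted(df[subject].unique())
    n = len(subjects)
    if n < 3:
        raise ValueError("need >= 3 subjects")
    levels = [sorted(df[f].unique()) for f in within]
    counts = df.groupby([subject, *within], sort=True)[dv].count()
    n_cells = n * int(np.prod([len(lv) for lv in levels]))
    if (counts != 1).any() or len(counts) != n_cells:
        raise ValueError("design must be complete and balanced (one obs per cell)")

    if len(within) == 1:
        k = len(levels[0])
        wide = (
            df.pivot_table(index=subject, columns=within[0], values=dv)
            .loc[subjects, levels[0]]
            .to_numpy()
        )
        return [rm_anova_oneway(wide, effect=within[0])]

    fa, fb = within
    a, b = len(levels[0]), len(levels[1])
    cells = (
        df.pivot_table(index=subject, columns=within, values=dv)
        .loc[subjects, list(itertools.product(levels[0], levels[1]))]
        .to_numpy()
        .reshape(n, a, b)
    )
    grand = cells.mean()
    m_s = cells.mean(axis=(1, 2))
    m_a = cells.mean(axis=(0, 2))
    m_b = cells.mean(axis=(0, 1))
    m_sa = cells.mean(axis=2)
    m_sb = cells.mean(axis=1)
    m_ab = cells.mean(axis=0)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        cells
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    ua = np.ones((1, a)) / np.sqrt(a)
    ub = np.ones((1, b)) / np.sqrt(b)
    flat = cells.reshape(n, a * b)
    results = [
        _assemble_result(
            fa, ss_a, ss_sa, a - 1, (a - 1) * (n - 1), flat, np.kron(ca, ub)
        ),
        _assemble_result(
            fb, ss_b, ss_sb, b - 1, (b - 1) * (n - 1), flat, np.kron(ua, cb)
        ),
        _assemble_result(
            f"{fa}:{fb}",
            ss_ab,
            ss_sab,
            (a - 1) * (b - 1),
            (a - 1) * (b - 1) * (n - 1),
            flat,
            np.kron(ca, cb),
        ),
    ]
    return results


# ---------------------------------------------------------------------------
# post hoc paired t-tests
# ---------------------------------------------------------------------------

def posthoc_paired_t(
    table,
    dv: str = "value",
    subject: str = "subject",
    within: str = "condition",
    correction: str = "holm",
) -> list[PairedTResult]:
    """All pairwise two-tailed paired t-tests with Holm correction."""
    import pandas as pd

    df = pd.DataFrame(table)
    levels = sorted(df[within].unique())
    subjects = sorted(df[subject].unique())
    wide = (
        df.pivot_table(index=subject, columns=within, values=dv)
        .loc[subjects, levels]
        .to_numpy()
    )
    pairs = list(itertools.combinations(range(len(levels)), 2))
    raw = []
    results = []
    for i, j in pairs:
        d = wide[:, i] - wide[:, j]
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                t, p, degenerate = 0.0, 1.0, True
            else:
                t, p, degenerate = math.inf, math.nan, True
        else:
            t, p = sps.ttest_rel(wide[:, i], wide[:, j])
            degenerate = False
        raw.append(p)
        results.append(
            PairedTResult(
                levels[i], levels[j], float(t), len(subjects) - 1, float(p),
                math.nan, degenerate,
            )
        )
    if correction == "holm":
        finite = np.array([not r.degenerate or not math.isnan(r.p_raw) for r in results])
        adj = np.full(len(results), math.nan)
        if finite.any():
            adj[finite] = holm(np.asarray(raw)[finite])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    elif correction == "none":
        for r in results:
            r.p_adj = r.p_raw
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return results


# ---------------------------------------------------------------------------
# permutation topographic test
# ---------------------------------------------------------------------------

def _paired_t(d: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 of an (N x C) difference matrix; 0/0 -> 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def permutation_topo_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TopoTestResult:
    """Per-channel paired t with subject-level sign-flip permutations + BH.

    When ``2**N <= n_perm`` all sign patterns are enumerated and p-values
    are exact (``#{|t*| >= |t|} / 2**N``); otherwise ``n_perm`` random flips
    are drawn and ``p = (1 + #{|t*| >= |t|}) / (1 + n_perm)``.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("paired inputs must have identical shape")
    D = A - B
    n, n_ch = D.shape
    t_obs = _paired_t(D)
    tol = 1e-12

    exact = 2**n <= n_perm
    if exact:
        signs = np.array(
            list(itertools.product([1.0, -1.0], repeat=n)), dtype=float
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    # permuted means; Σd² is sign-invariant, so sd follows from the mean
    sum_sq = (D**2).sum(axis=0)
    means = signs @ D / n  # (n_perm, n_ch)
    var = (sum_sq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
    count = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - tol).sum(axis=0)
    if exact:
        p = count / signs.shape[0]
    else:
        p = (1.0 + count) / (1.0 + n_perm)
    q = benjamini_hochberg(p)
    return TopoTestResult(
        t=t_obs,
        p=p,
        q=q,
        significant=q < alpha,
        n_perm=signs.shape[0],
        exact=exact,
    )


# ---------------------------------------------------------------------------
# repeated-measures correlation
# ---------------------------------------------------------------------------

def rmcorr(subject, x, y) -> RmCorrResult:
    """Repeated-measures correlation: the common within-subject association.

    Both variables are centered within subject; r is the Pearson correlation
    of the centered values (which carries the common-slope sign), with
    ``df = n_obs - n_subjects - 1`` and p from the t transform of r.  The
    95% CI uses the Fisher z transform at that df.
    """
    subject = np.asarray(subject)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subject.size == x.size == y.size):
        raise ValueError("subject, x, y must have equal length")
    subjects, inverse, counts = np.unique(
        subject, return_inverse=True, return_counts=True
    )
    if subjects.size < 2:
        raise ValueError("need >= 2 subjects")
    if counts.min() < 2:
        raise ValueError("need >= 2 observations per subject")
    xm = np.bincount(inverse, weights=x) / counts
    ym = np.bincount(inverse, weights=y) / counts
    xc = x - xm[inverse]
    yc = y - ym[inverse]
    sxx, syy = np.sum(xc**2), np.sum(yc**2)
    if sxx <= 0 or syy <= 0:
        raise ValueError("zero within-subject variance")
    r = float(np.sum(xc * yc) / np.sqrt(sxx * syy))
    r = float(np.clip(r, -1.0, 1.0))
    df = int(x.size - subjects.size - 1)
    if df < 1:
        raise ValueError("not enough observations for the rmcorr df")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = abs(r) * math.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(t, df))
    se = 1.0 / math.sqrt(max(df - 1, 1))
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    zcrit = sps.norm.ppf(0.975)
    ci = (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))
    return RmCorrResult(r, df, p, ci)


# ---------------------------------------------------------------------------
# within-subject SEM
# ---------------------------------------------------------------------------

def within_subject_sem(data: np.ndarray) -> np.ndarray:
    """Morey-corrected within-subject SEM per condition.

    ``data`` is (N subjects x M conditions).  Cousineau normalization
    removes subject offsets (subtract the subject mean, add the grand
    mean); per-condition SEMs of the normalized data are then scaled by
    ``sqrt(M / (M - 1))``.
    """
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    if m < 2:
        raise ValueError("need >= 2 conditions")
    normalized = data - data.mean(axis=1, keepdims=True) + data.mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(m / (m - 1))
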