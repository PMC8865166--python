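"""Within-subject inferential machinery, implemented from first principles.

Covers the analyses an event-locked cardiac/speed study needs:

* two-way fully within-subject ANOVA (condition-type x time) with the
  complete sums-of-squares decomposition, partial eta-squared, Mauchly's
  sphericity test and Greenhouse-Geisser epsilon-corrected p-values;
* Bonferroni-corrected per-time-point paired comparisons;
* orthonormal polynomial trend contrasts (linear/quadratic/cubic) over the
  post-baseline time grid, tested with one-sample t on per-subject scores —
  a significant quadratic trend is the signature of a biphasic
  deceleration-then-acceleration cardiac response;
* paired t-tests with Cohen's d on AUC summaries.

Each statistic is computed explicitly (cell means and sums over cells);
nothing is delegated to a packaged ANOVA routine, so the implementation can
be cross-checked against independent oracles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class EffectResult:
    """One within-subject effect of the ANOVA table."""

    name: str
    ss: float
    df: float
    ms: float
    ss_error: float
    df_error: float
    ms_error: float
    F: float
    p_uncorrected: float
    partial_eta_sq: float
    mauchly_W: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    df_gg: tuple[float, float] | None = None
    p_gg: float | None = None

    @property
    def sphericity_violated(self) -> bool:
        return self.mauchly_p is not None and self.mauchly_p < ALPHA

    @property
    def p_report(self) -> float:
        """Corrected p when sphericity is violated, uncorrected otherwise."""
        if self.sphericity_violated and self.p_gg is not None:
            return self.p_gg
        return self.p_uncorrected


@dataclass
class RmAnovaResult:
    effects: dict[str, EffectResult]
    n_subjects: int
    ss_subject: float

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


@dataclass
class ContrastResult:
    order: str  # linear / quadratic / cubic
    weights: np.ndarray
    scores: np.ndarray  # per-subject
    t: float
    df: int
    p: float


@dataclass
class PairedResult:
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    cohens_d: float


# ---------------------------------------------------------------------------
# sphericity helpers
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each summing to zero (Helmert-style)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def gg_epsilon(samples: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from an n x k matrix of repeated measures.

    epsilon = tr(C S C')^2 / ((k-1) tr((C S C')^2)) with C orthonormal
    contrasts and S the sample covariance; bounded in [1/(k-1), 1].
    """
    samples = np.asarray(samples, dtype=float)
    n, k = samples.shape
    C = _orthonormal_contrasts(k)
    S = np.cov(samples, rowvar=False, ddof=1)
    E = C @ S @ C.T
    tr = np.trace(E)
    tr2 = np.trace(E @ E)
    if tr2 <= 0 or tr <= 0:  # degenerate (e.g. constant data): no violation
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(samples: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on an n x k repeated-measures matrix.

    Returns (W, p) via the chi-square approximation. Degenerate covariance
    (constant data) is reported as W=1, p=1 (nothing to violate).
    """
    samples = np.asarray(samples, dtype=float)
    n, k = samples.shape
    d = k - 1
    C = _orthonormal_contrasts(k)
    S = np.cov(samples, rowvar=False, ddof=1)
    E = C @ S @ C.T
    tr = np.trace(E)
    if tr <= 1e-300:
        return 1.0, 1.0
    sign, logdet = np.linalg.slogdet(E)
    if sign <= 0:
        return 0.0, 0.0
    logW = logdet - d * np.log(tr / d)
    W = float(np.exp(logW))
    # chi-square approximation with the usual second-order term
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    chi2 = max(-(n - 1) * f * logW, 0.0)
    df = d * (d + 1) // 2 - 1
    if df <= 0:
        return W, 1.0
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    return W, float(p1 + w2 * (p2 - p1))


# ---------------------------------------------------------------------------
# two-way within-subject ANOVA
# ---------------------------------------------------------------------------

def _effect(
    name: str,
    ss: float,
    df: float,
    ss_err: float,
    df_err: float,
    sphericity_samples: np.ndarray | None = None,
) -> EffectResult:
    ms = ss / df
    ms_err = ss_err / df_err
    tiny = 1e-12
    if ss_err < tiny:
        if ss < tiny:  # all cells equal for this effect: no signal, no noise
            F, p, eta = 0.0, 1.0, 0.0
        else:
            raise ZeroDivisionError(
                f"zero error variance for effect '{name}' with nonzero effect SS"
            )
    else:
        F = ms / ms_err
        p = float(sps.f.sf(F, df, df_err))
        eta = ss / (ss + ss_err)
    res = EffectResult(name, ss, df, ms, ss_err, df_err, ms_err, F, p, eta)
    if sphericity_samples is not None and sphericity_samples.shape[1] > 2:
        res.mauchly_W, res.mauchly_p = mauchly_test(sphericity_samples)
        eps = gg_epsilon(sphericity_samples)
        res.gg_epsilon = eps
        res.df_gg = (df * eps, df_err * eps)
        if ss_err < tiny:
            res.p_gg = p
        else:
            res.p_gg = float(sps.f.sf(F, df * eps, df_err * eps))
    return res


def rm_anova_2x_k(matrix_exp: np.ndarray, matrix_ctrl: np.ndarray) -> RmAnovaResult:
    """2 (condition-type) x k (time) fully within-subject ANOVA.

    Inputs are row-aligned n x k matrices (experimental and control change
    values for the same participants). Error terms are the effect-by-subject
    interactions: F_A = MS_A / MS_AxS and so on. Greenhouse-Geisser epsilon
    and Mauchly's test are computed for the time and interaction effects
    from the appropriately collapsed per-subject data (mean over condition
    types for time; their difference for the interaction).
    """
    A = 2
    Y = np.stack([np.asarray(matrix_exp, float), np.asarray(matrix_ctrl, float)], axis=1)
    if Y.ndim != 3 or Y.shape[1] != A:
        raise ValueError("expected two row-aligned n x k matrices")
    n, _, k = Y.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if matrix_exp.shape != matrix_ctrl.shape:
        raise ValueError("matrices must share the same shape")

    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))  # subject
    m_a = Y.mean(axis=(0, 2))  # condition-type
    m_b = Y.mean(axis=(0, 1))  # time
    m_ab = Y.mean(axis=0)  # A x k
    m_sa = Y.mean(axis=2)  # n x A
    m_sb = Y.mean(axis=1)  # n x k

    ss_s = A * k * np.sum((m_s - grand) ** 2)
    ss_a = n * k * np.sum((m_a - grand) ** 2)
    ss_b = n * A * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = k * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = A * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_sab = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    df_a, df_b, df_ab = A - 1, k - 1, (A - 1) * (k - 1)
    df_sa, df_sb, df_sab = (n - 1) * df_a, (n - 1) * df_b, (n - 1) * df_ab

    time_samples = Y.mean(axis=1)  # n x k, collapsed over condition-type
    inter_samples = Y[:, 0, :] - Y[:, 1, :]  # n x k difference

    effects = {
        "condition_type": _effect("condition_type", ss_a, df_a, ss_sa, df_sa),
        "time": _effect("time", ss_b, df_b, ss_sb, df_sb, time_samples),
        "interaction": _effect(
            "interaction", ss_ab, df_ab, ss_sab, df_sab, inter_samples
        ),
    }
    return RmAnovaResult(effects, n, float(ss_s))


def bonferroni_posthoc(
    matrix_exp: np.ndarray, matrix_ctrl: np.ndarray, alpha: float = ALPHA
) -> list[dict]:
    """Paired t at each time point, Bonferroni-adjusted over the k points."""
    X = np.asarray(matrix_exp, float)
    Y = np.asarray(matrix_ctrl, float)
    if X.shape != Y.shape:
        raise ValueError("matrices must share the same shape")
    k = X.shape[1]
    out = []
    for j in range(k):
        r = paired_test(X[:, j], Y[:, j])
        p_adj = min(1.0, r.p * k)
        out.append(
            {
                "time_index": j,
                "t": r.t,
                "p": r.p,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return out


# ---------------------------------------------------------------------------
# polynomial trend contrasts
# ---------------------------------------------------------------------------

def polynomial_weights(k: int, max_order: int = 3) -> dict[str, np.ndarray]:
    """Orthonormal polynomial contrast weights over k equally spaced points.

    Gram-Schmidt on {t, t^2, t^3, ...} after removing the intercept; each
    vector sums to zero, has unit norm, and its leading polynomial
    coefficient is positive, so a positive quadratic score means a U-shaped
    (decelerate-then-accelerate) time course.
    """
    if k < max_order + 1:
        raise ValueError(f"{k} time points cannot support order-{max_order} contrasts")
    t = np.arange(k, dtype=float)
    basis = [np.ones(k)]
    names = ["linear", "quadratic", "cubic", "quartic", "quintic"]
    out: dict[str, np.ndarray] = {}
    for order in range(1, max_order + 1):
        v = t**order
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        v = v / np.linalg.norm(v)
        basis.append(v)
        out[names[order - 1]] = v
    return out


def polynomial_contrast(
    matrix: np.ndarray, orders: tuple[int, ...] = (1, 2, 3)
) -> dict[str, ContrastResult]:
    """Trend tests on an n x k matrix of post-baseline change values.

    Per-subject score = weights . subject curve; one-sample t against 0 with
    df = n - 1.
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    names = {1: "linear", 2: "quadratic", 3: "cubic"}
    weights = polynomial_weights(k, max(orders))
    out: dict[str, ContrastResult] = {}
    for order in orders:
        name = names[order]
        w = weights[name]
        scores = X @ w
        mean = scores.mean()
        sd = scores.std(ddof=1)
        if sd < 1e-12:
            t_val, p = (0.0, 1.0) if abs(mean) < 1e-12 else (np.inf * np.sign(mean), 0.0)
        else:
            t_val = mean / (sd / np.sqrt(n))
            p = float(2 * sps.t.sf(abs(t_val), n - 1))
        out[name] = ContrastResult(name, w, scores, float(t_val), n - 1, p)
    return out


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------

def paired_test(x: np.ndarray, y: np.ndarray) -> PairedResult:
    """Paired t-test with Cohen's d for paired data (mean diff / SD of diffs).

    Degenerate zero-variance differences are reported explicitly: d = 0,
    p = 1 when the difference is identically zero, d = +/-inf, p = 0 when a
    nonzero constant difference leaves nothing to test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and aligned")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd < 1e-12:
        if abs(mean) < 1e-12:
            return PairedResult(n, mean, 0.0, 0.0, n - 1, 1.0, 0.0)
        s = float(np.sign(mean))
        return PairedResult(n, mean, 0.0, s * np.inf, n - 1, 0.0, s * np.inf)
    t_val = mean / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t_val), n - 1))
    return PairedResult(n, mean, sd, float(t_val), n - 1, p, mean / sd)


def paired_auc_test(auc_exp: np.ndarray, auc_ctrl: np.ndarray) -> PairedResult:
    """Experimental vs. control AUC comparison for one group of participants."""
    return paired_test(auc_exp, auc_ctrl)
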