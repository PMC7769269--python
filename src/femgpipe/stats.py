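"""Inferential machinery for the mimicry analysis.

The centerpiece is a balanced mixed-design ANOVA with one between-subjects
factor (group, 2 levels) and two crossed within-subjects factors (emotion,
6 levels; time bin, 6 levels). The decomposition is the classical
univariate sums-of-squares approach with subjects nested in groups, three
within-subject error strata, Mauchly's sphericity test per stratum, and
Greenhouse-Geisser (GG) degrees-of-freedom correction applied when
Mauchly's test rejects at the analysis alpha and the GG epsilon falls
below 0.75.

Planned group contrasts compare the two groups' mean amplitude for a
single emotion (pooled over time bins) against the emotion x time x
subject-within-group error stratum, with the GG-corrected error df; their
effect size is the correlation coefficient r = sqrt(F / (F + df_err)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .types import EMOTIONS, GROUPS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sphericity

@dataclass
class SphericityResult:
    """Mauchly's W with its chi-square approximation and the GG epsilon."""

    W: float
    chi2: float
    df: float
    pval: float
    epsilon: float


def orthonormal_contrasts(m: int) -> np.ndarray:
    """An (m, m-1) matrix of orthonormal contrasts (Helmert-style)."""
    C = np.zeros((m, m - 1))
    for j in range(m - 1):
        C[: j + 1, j] = 1.0
        C[j + 1, j] = -(j + 1)
        C[:, j] /= np.linalg.norm(C[:, j])
    return C


def gg_epsilon(cov: np.ndarray, m: int | None = None) -> float:
    """Greenhouse-Geisser epsilon from a condition covariance matrix.

    Computed as (sum lambda)^2 / ((m-1) * sum lambda^2) on the eigenvalues
    of the covariance projected onto orthonormal contrasts; bounded in
    [1/(m-1), 1].
    """
    cov = np.asarray(cov, dtype=float)
    m = m if m is not None else cov.shape[0]
    C = orthonormal_contrasts(m)
    M = C.T @ cov @ C
    lam = np.linalg.eigvalsh(M)
    lam = np.clip(lam, 0.0, None)
    denom = (m - 1) * np.sum(lam**2)
    if denom == 0.0:
        return 1.0
    eps = np.sum(lam) ** 2 / denom
    return float(np.clip(eps, 1.0 / (m - 1), 1.0))


def mauchly_test(scores: np.ndarray, groups: np.ndarray | None = None) -> SphericityResult:
    """Mauchly's test of sphericity on subjects x conditions scores.

    ``groups`` optionally assigns each subject to a between-subjects
    group; the condition covariance is then pooled within groups with
    error df n - n_groups (n - 1 for a single group). With m = 2
    conditions sphericity holds vacuously (W = 1, epsilon = 1). A
    singular contrast covariance yields W = 0 with a warning.
    """
    X = np.asarray(scores, dtype=float).copy()
    n, m = X.shape
    if groups is None:
        groups = np.zeros(n, dtype=int)
    labels = np.unique(groups)
    for g in labels:
        X[groups == g] -= X[groups == g].mean(axis=0)
    d = n - labels.size
    if m < 2 or d < 1:
        raise ValueError("need >= 2 conditions and error df >= 1")
    C = orthonormal_contrasts(m)
    S = (X.T @ X) / d
    M = C.T @ S @ C
    eps = None
    lam = np.linalg.eigvalsh(M)
    lam_pos = np.clip(lam, 0.0, None)
    denom = (m - 1) * np.sum(lam_pos**2)
    eps = 1.0 if denom == 0 else float(np.clip(np.sum(lam_pos) ** 2 / denom,
                                               1.0 / (m - 1), 1.0))
    if m == 2:
        return SphericityResult(W=1.0, chi2=0.0, df=0.0, pval=1.0, epsilon=1.0)
    p = m - 1
    tr = np.sum(lam_pos)
    if np.any(lam_pos <= 0) or tr <= 0:
        warnings.warn("singular contrast covariance in Mauchly's test; W set to 0")
        return SphericityResult(W=0.0, chi2=np.inf, df=p * (p + 1) / 2 - 1,
                                pval=0.0, epsilon=eps)
    W = float(np.prod(lam_pos) / (tr / p) ** p)
    W = min(W, 1.0)
    chi2 = -(d - (2 * p**2 + p + 2) / (6.0 * p)) * np.log(W)
    dfc = p * (p + 1) / 2 - 1
    pval = float(st.chi2.sf(chi2, dfc))
    return SphericityResult(W=W, chi2=float(chi2), df=dfc, pval=pval, epsilon=eps)


# ---------------------------------------------------------------------------
# mixed ANOVA

@dataclass
class StratumInfo:
    """Error-stratum bookkeeping for one within (or between) stratum."""

    ss_err: float
    df_err: float               # uncorrected
    epsilon: float              # 1.0 for the between stratum
    corrected: bool
    sphericity: SphericityResult | None = None

    @property
    def df_err_eff(self) -> float:
        return self.df_err * self.epsilon if self.corrected else self.df_err

    @property
    def ms_err(self) -> float:
        return self.ss_err / self.df_err


@dataclass
class AnovaResult:
    """Mixed-ANOVA output: the printed table plus stratum internals."""

    table: pd.DataFrame
    strata: dict[str, StratumInfo]
    cell_means: np.ndarray      # (n_groups, n_emotions, n_bins)
    group_sizes: np.ndarray
    alpha: float


def _pivot_binned(binned: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Long-format (participant, group, emotion, bin, amplitude) table for
    one muscle -> y[s, e, t] array, group index per subject, subject ids."""
    need = {"participant", "group", "emotion", "bin", "amplitude"}
    missing = need - set(binned.columns)
    if missing:
        raise ValueError(f"binned table missing column(s) {sorted(missing)}")
    bins = np.sort(binned["bin"].unique())
    wide = binned.pivot_table(index=["group", "participant"], columns=["emotion", "bin"],
                              values="amplitude", sort=True)
    cols = [(e, b) for e in EMOTIONS for b in bins]
    try:
        wide = wide[cols]
    except KeyError as exc:
        raise ValueError(f"incomplete within-subject cells: {exc}") from None
    if wide.isna().any().any():
        raise ValueError("incomplete design: every participant needs all emotion x bin cells")
    groups = wide.index.get_level_values("group").to_numpy()
    subjects = wide.index.get_level_values("participant").tolist()
    gidx = np.array([list(GROUPS).index(g) for g in groups])
    order = np.argsort(gidx, kind="stable")
    y = wide.to_numpy()[order].reshape(len(subjects), len(EMOTIONS), len(bins))
    return y, gidx[order], [subjects[i] for i in order]


def mixed_anova(binned: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Balanced 2 (group) x 6 (emotion) x 6 (time bin) mixed ANOVA.

    ``binned`` is the long-format table for a single muscle. The design
    must be complete and balanced (equal group sizes); this mirrors the
    balanced cohort the analysis was built around and keeps the classical
    sums-of-squares decomposition exact.

    GG correction is applied per within stratum when Mauchly's p < alpha
    and epsilon < 0.75; partial eta squared is computed per effect against
    its own error stratum.
    """
    y, gidx, _ = _pivot_binned(binned)
    n_subj, E, T = y.shape
    k = int(gidx.max()) + 1
    counts = np.bincount(gidx, minlength=k)
    if k < 2 or np.unique(counts).size != 1:
        raise ValueError(f"design must be balanced with 2 groups (group sizes {counts.tolist()})")
    n = int(counts[0])
    if n < 2:
        raise ValueError("need >= 2 participants per group")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))                       # subject means
    m_g = np.array([y[gidx == g].mean() for g in range(k)])
    m_e = y.mean(axis=(0, 2))
    m_t = y.mean(axis=(0, 1))
    m_ge = np.stack([y[gidx == g].mean(axis=(0, 2)) for g in range(k)])
    m_gt = np.stack([y[gidx == g].mean(axis=(0, 1)) for g in range(k)])
    m_et = y.mean(axis=0)
    m_get = np.stack([y[gidx == g].mean(axis=0) for g in range(k)])
    m_se = y.mean(axis=2)
    m_st = y.mean(axis=1)

    ss_total = ((y - grand) ** 2).sum()
    ss_A = n * E * T * ((m_g - grand) ** 2).sum()
    ss_S = E * T * ((m_s - m_g[gidx]) ** 2).sum()
    ss_B = n_subj * T * ((m_e - grand) ** 2).sum()
    ss_AB = n * T * ((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2).sum()
    ss_BS = T * ((m_se - m_s[:, None] - m_ge[gidx] + m_g[gidx, None]) ** 2).sum()
    ss_C = n_subj * E * ((m_t - grand) ** 2).sum()
    ss_AC = n * E * ((m_gt - m_g[:, None] - m_t[None, :] + grand) ** 2).sum()
    ss_CS = E * ((m_st - m_s[:, None] - m_gt[gidx] + m_g[gidx, None]) ** 2).sum()
    ss_BC = n_subj * ((m_et - m_e[:, None] - m_t[None, :] + grand) ** 2).sum()
    ss_ABC = n * ((m_get - m_ge[:, :, None] - m_gt[:, None, :] - m_et[None]
                   + m_g[:, None, None] + m_e[None, :, None] + m_t[None, None, :]
                   - grand) ** 2).sum()
    ss_BCS = ss_total - (ss_A + ss_S + ss_B + ss_AB + ss_BS + ss_C + ss_AC
                         + ss_CS + ss_BC + ss_ABC)

    df_A, df_S = k - 1, k * (n - 1)
    df_B, df_AB, df_BS = E - 1, (k - 1) * (E - 1), k * (n - 1) * (E - 1)
    df_C, df_AC, df_CS = T - 1, (k - 1) * (T - 1), k * (n - 1) * (T - 1)
    df_BC = (E - 1) * (T - 1)
    df_ABC = (k - 1) * (E - 1) * (T - 1)
    df_BCS = k * (n - 1) * (E - 1) * (T - 1)

    # sphericity per within stratum, covariance pooled within groups
    sph_B = mauchly_test(m_se, groups=gidx)
    sph_C = mauchly_test(m_st, groups=gidx)
    sph_BC = mauchly_test(y.reshape(n_subj, E * T), groups=gidx)

    def _stratum(ss_err, df_err, sph):
        corrected = bool(sph is not None and sph.pval < alpha and sph.epsilon < 0.75)
        return StratumInfo(ss_err=ss_err, df_err=df_err,
                           epsilon=sph.epsilon if sph is not None else 1.0,
                           corrected=corrected, sphericity=sph)

    strata = {
        "between": _stratum(ss_S, df_S, None),
        "emotion": _stratum(ss_BS, df_BS, sph_B),
        "time": _stratum(ss_CS, df_CS, sph_C),
        "emotion_x_time": _stratum(ss_BCS, df_BCS, sph_BC),
    }

    rows = []

    def _effect(name, ss, df, stratum_key):
        s = strata[stratum_key]
        factor = s.epsilon if s.corrected else 1.0
        df_eff, df_err = df * factor, s.df_err * factor
        ms_eff = ss / df_eff if df_eff > 0 else np.nan
        ms_err = s.ss_err / df_err
        F = ms_eff / ms_err
        p = float(st.f.sf(F, df_eff, df_err))
        eta = ss / (ss + s.ss_err) if (ss + s.ss_err) > 0 else 0.0
        rows.append({"effect": name, "df": df_eff, "MS": ms_eff, "F": F,
                     "eta_p2": eta, "p": p,
                     "epsilon": s.epsilon if stratum_key != "between" else np.nan})

    def _error(name, stratum_key):
        s = strata[stratum_key]
        factor = s.epsilon if s.corrected else 1.0
        rows.append({"effect": name, "df": s.df_err * factor,
                     "MS": s.ss_err / (s.df_err * factor), "F": np.nan,
                     "eta_p2": np.nan, "p": np.nan, "epsilon": np.nan})

    _effect("Group", ss_A, df_A, "between")
    _error("Error (between)", "between")
    _effect("Emotion", ss_B, df_B, "emotion")
    _effect("Emotion x Group", ss_AB, df_AB, "emotion")
    _error("Error (Emotion)", "emotion")
    _effect("Time", ss_C, df_C, "time")
    _effect("Time x Group", ss_AC, df_AC, "time")
    _error("Error (Time)", "time")
    _effect("Emotion x Time", ss_BC, df_BC, "emotion_x_time")
    _effect("Emotion x Time x Group", ss_ABC, df_ABC, "emotion_x_time")
    _error("Error (Emotion x Time)", "emotion_x_time")

    table = pd.DataFrame(rows, columns=["effect", "df", "MS", "F", "eta_p2", "p", "epsilon"])
    cell_means = m_get
    return AnovaResult(table=table, strata=strata, cell_means=cell_means,
                       group_sizes=counts, alpha=alpha)


# ---------------------------------------------------------------------------
# planned contrasts and simple tests

@dataclass
class ContrastResult:
    """A 1-df planned group contrast for one (muscle, emotion)."""

    muscle: str
    emotion: str
    F: float
    df_num: float
    df_err: float
    p: float
    r: float


def effect_size_r(F: float, df_err: float) -> float:
    """Contrast effect size r = sqrt(F / (F + df_err))."""
    if F < 0 or df_err <= 0:
        raise ValueError("need F >= 0 and df_err > 0")
    return float(np.sqrt(F / (F + df_err)))


def planned_group_contrast(anova: AnovaResult, emotion: str, muscle: str = "?") -> ContrastResult:
    """Group difference for one emotion, pooled over the 6 time bins.

    The contrast mean square is tested against the emotion x time x
    subject-within-group error stratum of the full mixed ANOVA; the error
    df is that stratum's GG-corrected df. Alpha is left unadjusted across
    the contrast family.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    e = EMOTIONS.index(emotion)
    means = anova.cell_means[:, e, :].mean(axis=1)      # per-group mean over bins
    n1, n2 = anova.group_sizes[:2]
    T = anova.cell_means.shape[2]
    L = float(means[0] - means[1])
    ss_contrast = L**2 / (1.0 / (n1 * T) + 1.0 / (n2 * T))
    s = anova.strata["emotion_x_time"]
    F = ss_contrast / s.ms_err
    df_err = s.df_err_eff
    p = float(st.f.sf(F, 1.0, df_err))
    return ContrastResult(muscle=muscle, emotion=emotion, F=float(F), df_num=1.0,
                          df_err=float(df_err), p=p, r=effect_size_r(F, df_err))


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with a two-tailed p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    p = correlation_pvalue(r, n)
    return CorrelationResult(r=r, n=n, p=p)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a sample correlation of size n (t on n-2 df)."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return float(2.0 * st.t.sf(abs(t), n - 2))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def independent_t_test(a, b) -> TTestResult:
    """Pooled-variance two-sample t-test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per sample")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=na + nb - 2, p=1.0)
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    return TTestResult(t=float(t), df=df, p=float(2.0 * st.t.sf(abs(t), df)))


def format_p(p: float, decimals: int = 3) -> str:
    """Report p to 3 decimals, with '<0.001' formatting below that."""
    lim = 10.0 ** (-decimals)
    if p < lim:
        return f"<{lim:.{decimals}f}"
    return f"{p:.{decimals}f}"
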