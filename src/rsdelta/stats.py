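"""Group statistics: transformation, mixed ANOVA, Duncan post-hoc, Grubbs
outlier control, demographic/clinical marker batteries, ROC discrimination.

The central design is a mixed Group x Band x ROI ANOVA on log10-transformed
normalized regional source activities (subjects nested in groups; Band and
ROI are repeated measures), with Mauchly sphericity checks and
Greenhouse-Geisser correction, Duncan's multiple range test for post-hoc
group contrasts under a Bonferroni family threshold of 0.05/25 = 0.002,
and an iterative Grubbs test (alpha = 0.001) guarding against outliers.
Patient-level discrimination is summarized by ROC indices (sensitivity,
specificity, case/control-weighted accuracy, PPV, NPV, AUROC).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.diagnostic import lilliefors

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")
ROI_ORDER = ("frontal", "central", "parietal", "occipital", "temporal")


# ---------------------------------------------------------------------------
# transformation and normality
# ---------------------------------------------------------------------------

def log10_and_check(regional: pd.DataFrame, value_col: str = "value",
                    alpha: float = 0.05
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log10-transform cell values and test each cell for normality.

    The Kolmogorov-Smirnov test uses Lilliefors-corrected critical values
    because the cell mean and SD are estimated from the data. Returns the
    transformed frame (column ``log10_value``) and a per-cell report with
    the normality p-value and a flag for cells rejected at ``alpha``.
    """
    vals = regional[value_col].to_numpy(dtype=float)
    if np.any(vals <= 0):
        bad = regional.loc[vals <= 0]
        first = bad.iloc[0]
        raise ValueError(
            "non-positive value for subject "
            f"{first.get('subject_id', '?')} in cell "
            f"({first.get('band', '?')}, {first.get('roi', '?')})")
    out = regional.copy()
    out["log10_value"] = np.log10(vals)
    rows = []
    for (band, roi), cell in out.groupby(["band", "roi"], sort=False):
        x = cell["log10_value"].to_numpy()
        if len(x) >= 4 and np.ptp(x) > 0:
            _, p = lilliefors(x, dist="norm")
        else:
            p = np.nan
        rows.append({"band": band, "roi": roi, "n": len(x),
                     "ks_p": p, "non_normal": bool(p < alpha)
                     if np.isfinite(p) else False})
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed ANOVA (between: Group; within: Band, ROI)
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float = 1.0
    df1_gg: float = np.nan
    df2_gg: float = np.nan
    p_gg: float = np.nan
    mauchly_p: float = np.nan

    @property
    def p_corrected(self) -> float:
        """GG-corrected p when sphericity is rejected, else the raw p."""
        if np.isfinite(self.mauchly_p) and self.mauchly_p < 0.05 \
                and np.isfinite(self.p_gg):
            return self.p_gg
        return self.p


def _cube_from_frame(df: pd.DataFrame, value_col: str,
                     bands=BAND_ORDER, rois=ROI_ORDER):
    """(groups, per-group subject cubes) from a tidy frame; errors on
    missing cells."""
    groups = list(dict.fromkeys(df["group"]))
    cubes = []
    for g in groups:
        sub = df[df["group"] == g]
        subjects = list(dict.fromkeys(sub["subject_id"]))
        cube = np.full((len(subjects), len(bands), len(rois)), np.nan)
        piv = sub.set_index(["subject_id", "band", "roi"])[value_col]
        for i, s in enumerate(subjects):
            for j, b in enumerate(bands):
                for k, r in enumerate(rois):
                    try:
                        cube[i, j, k] = piv.loc[(s, b, r)]
                    except KeyError:
                        raise ValueError(
                            f"missing cell ({s}, {b}, {r}); mixed ANOVA "
                            "requires complete within-subject data"
                        ) from None
        cubes.append(cube)
    return groups, cubes


def _centering_contrast(k: int) -> np.ndarray:
    """Orthonormal (k x k-1) contrast spanning the deviation space."""
    return np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]


def _sphericity(deviations: np.ndarray, df_error: int,
                contrast: np.ndarray | None = None) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon and Mauchly p from within-group subject
    deviations (n_subjects x k repeated measures).

    ``contrast`` restricts the test to an effect subspace (e.g. the
    Kronecker contrast of an interaction stratum); by default the full
    k-1 dimensional deviation space is used.
    """
    k = deviations.shape[1]
    C = _centering_contrast(k) if contrast is None else contrast
    d = C.shape[1]
    if d < 1:
        return 1.0, np.nan
    S = deviations.T @ deviations / max(df_error, 1)
    E = C.T @ S @ C
    tr = np.trace(E)
    tr2 = np.trace(E @ E)
    eps = tr ** 2 / (d * tr2) if tr2 > 0 else 1.0
    eps = float(min(max(eps, 1.0 / d), 1.0))
    mauchly_p = np.nan
    if df_error > d:
        sign, logdet = np.linalg.slogdet(E)
        if sign > 0 and tr > 0:
            logw = logdet - d * np.log(tr / d)
            f = df_error
            rho = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * f)
            chi2 = -f * rho * logw
            dfc = d * (d + 1) // 2 - 1
            mauchly_p = float(sst.chi2.sf(chi2, dfc)) if dfc > 0 else np.nan
    return eps, mauchly_p


def mixed_anova(regional: pd.DataFrame, value_col: str = "log10_value",
                bands=BAND_ORDER, rois=ROI_ORDER) -> list[AnovaResult]:
    """Univariate mixed ANOVA: Group (between) x Band x ROI (within).

    Classical sums-of-squares decomposition with subjects nested in
    groups; each within stratum (Band, ROI, Band x ROI) has its own error
    term, Greenhouse-Geisser epsilon and Mauchly test. Unequal group sizes
    enter through the per-group subject counts.
    """
    groups, cubes = _cube_from_frame(regional, value_col, bands, rois)
    a = len(groups)
    b, c = len(bands), len(rois)
    ns = [cube.shape[0] for cube in cubes]
    N = sum(ns)
    if a < 2 or min(ns) < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    allx = np.concatenate(cubes, axis=0)          # (N, b, c)
    GM = allx.mean()

    subj_means = allx.mean(axis=(1, 2))           # (N,)
    grp_of = np.repeat(np.arange(a), ns)
    A_g = np.array([subj_means[grp_of == g].mean() for g in range(a)])
    ss_subj_tot = b * c * np.sum((subj_means - GM) ** 2)
    ss_A = b * c * np.sum([ns[g] * (A_g[g] - GM) ** 2 for g in range(a)])
    ss_S = ss_subj_tot - ss_A
    df_S = N - a

    results: list[AnovaResult] = []
    F_A = (ss_A / (a - 1)) / (ss_S / df_S)
    results.append(AnovaResult("Group", float(F_A), a - 1, df_S,
                               float(sst.f.sf(F_A, a - 1, df_S))))

    def within_stratum(name, axis_means, cell_means_g, d, reps):
        """Generic within-factor stratum (factor main + interaction with
        Group + its error)."""
        # axis_means: (levels,) grand means per level (weighted)
        # cell_means_g: (a, levels) per-group level means
        # reps: observations per (subject, level) = product of other
        #       within sizes
        levels = len(axis_means)
        ss_main = reps * N * np.sum((axis_means - GM) ** 2)
        ss_inter = reps * np.sum(
            [ns[g] * np.sum((cell_means_g[g] - A_g[g]
                             - axis_means + GM) ** 2) for g in range(a)])
        return ss_main, ss_inter, levels

    # --- Band stratum
    band_subj = allx.mean(axis=2)                 # (N, b)
    B_j = band_subj.mean(axis=0)
    B_gj = np.array([band_subj[grp_of == g].mean(axis=0) for g in range(a)])
    ss_B, ss_AB, _ = within_stratum("Band", B_j, B_gj, b - 1, c)
    dev_B = np.vstack([band_subj[grp_of == g] - B_gj[g] for g in range(a)])
    dev_B = dev_B - dev_B.mean(axis=1, keepdims=True) * 0  # keep raw devs
    ss_BS = c * np.sum((band_subj - B_gj[grp_of]
                        - subj_means[:, None] + A_g[grp_of, None]) ** 2)
    df_BS = (b - 1) * (N - a)
    eps_B, mau_B = _sphericity(band_subj - B_gj[grp_of], N - a)

    # --- ROI stratum
    roi_subj = allx.mean(axis=1)                  # (N, c)
    C_k = roi_subj.mean(axis=0)
    C_gk = np.array([roi_subj[grp_of == g].mean(axis=0) for g in range(a)])
    ss_C, ss_AC, _ = within_stratum("ROI", C_k, C_gk, c - 1, b)
    ss_CS = b * np.sum((roi_subj - C_gk[grp_of]
                        - subj_means[:, None] + A_g[grp_of, None]) ** 2)
    df_CS = (c - 1) * (N - a)
    eps_C, mau_C = _sphericity(roi_subj - C_gk[grp_of], N - a)

    # --- Band x ROI stratum
    M_jk = allx.mean(axis=0)                      # (b, c)
    M_gjk = np.array([allx[grp_of == g].mean(axis=0) for g in range(a)])
    ss_BC = N * np.sum((M_jk - B_j[:, None] - C_k[None, :] + GM) ** 2)
    ss_ABC = np.sum([ns[g] * np.sum(
        (M_gjk[g] - B_gj[g][:, None] - C_gk[g][None, :] + A_g[g]
         - M_jk + B_j[:, None] + C_k[None, :] - GM) ** 2)
        for g in range(a)])
    ss_total = np.sum((allx - GM) ** 2)
    ss_BCS = ss_total - (ss_A + ss_S + ss_B + ss_AB + ss_BS
                         + ss_C + ss_AC + ss_CS + ss_BC + ss_ABC)
    ss_BCS = max(ss_BCS, 0.0)
    df_BCS = (b - 1) * (c - 1) * (N - a)
    flat = (allx - M_gjk[grp_of]).reshape(N, b * c)
    kron_contrast = np.kron(_centering_contrast(b), _centering_contrast(c))
    eps_BC, mau_BC = _sphericity(flat, N - a, contrast=kron_contrast)

    def add(effect, ss, df1, ss_err, df_err, eps, mau):
        ms = ss / df1
        mse = ss_err / df_err
        F = ms / mse if mse > 0 else np.inf
        p = float(sst.f.sf(F, df1, df_err))
        d1g, d2g = eps * df1, eps * df_err
        p_gg = float(sst.f.sf(F, d1g, d2g))
        results.append(AnovaResult(effect, float(F), df1, df_err, p,
                                   float(eps), d1g, d2g, p_gg, mau))

    if b > 1:
        add("Band", ss_B, b - 1, ss_BS, df_BS, eps_B, mau_B)
        add("Group x Band", ss_AB, (a - 1) * (b - 1), ss_BS, df_BS,
            eps_B, mau_B)
    if c > 1:
        add("ROI", ss_C, c - 1, ss_CS, df_CS, eps_C, mau_C)
        add("Group x ROI", ss_AC, (a - 1) * (c - 1), ss_CS, df_CS,
            eps_C, mau_C)
    if b > 1 and c > 1:
        add("Band x ROI", ss_BC, (b - 1) * (c - 1), ss_BCS, df_BCS,
            eps_BC, mau_BC)
        add("Group x Band x ROI", ss_ABC, (a - 1) * (b - 1) * (c - 1),
            ss_BCS, df_BCS, eps_BC, mau_BC)
    return results


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class PosthocResult:
    band: str
    roi: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    p: float
    significant: bool        # under the 0.05/25 family threshold
    direction: str           # "a>b" or "a<b"


def duncan_pairwise(means: dict[str, float], n_per_group: dict[str, int],
                    ms_error: float, df_error: float,
                    ) -> dict[tuple[str, str], float]:
    """Duncan multiple-range p-value for every group pair.

    Means are ranked; a pair spanning r steps of the ordering is referred
    to the studentized range with r means, and the range-dependent
    protection level 1-(1-a)^(r-1) is inverted to report an adjusted
    p-value p_Duncan = 1-(1-p_range)^(1/(r-1)). For r = 2 this is exactly
    the studentized-range p.
    """
    if df_error <= 0:
        raise ValueError("error degrees of freedom must be positive")
    order = sorted(means, key=means.get)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            ga, gb = order[i], order[j]
            r = j - i + 1
            nh = 2.0 / (1.0 / n_per_group[ga] + 1.0 / n_per_group[gb])
            se = np.sqrt(ms_error / nh)
            q = abs(means[gb] - means[ga]) / se if se > 0 else np.inf
            p_range = float(sst.studentized_range.sf(q, r, df_error))
            p = 1.0 - (1.0 - p_range) ** (1.0 / (r - 1)) if r > 2 else p_range
            out[(ga, gb)] = min(max(p, 0.0), 1.0)
    return out


def duncan_posthoc(regional: pd.DataFrame, value_col: str = "log10_value",
                   family_size: int = 25, alpha: float = 0.05,
                   bands=BAND_ORDER, rois=ROI_ORDER) -> pd.DataFrame:
    """Duncan contrasts between groups in every band x ROI cell.

    The error term of a cell is the pooled within-group variance of that
    cell. The family threshold is ``alpha / family_size`` (0.05/25 = 0.002
    for 5 bands x 5 ROIs).
    """
    threshold = alpha / family_size
    rows = []
    for band in bands:
        for roi in rois:
            cell = regional[(regional["band"] == band)
                            & (regional["roi"] == roi)]
            if cell.empty:
                continue
            groups = list(dict.fromkeys(cell["group"]))
            means, ns, ss, df_err = {}, {}, 0.0, 0
            for g in groups:
                x = cell.loc[cell["group"] == g, value_col].to_numpy()
                means[g], ns[g] = float(x.mean()), len(x)
                ss += np.sum((x - x.mean()) ** 2)
                df_err += len(x) - 1
            if df_err <= 0:
                continue
            mse = ss / df_err
            pvals = duncan_pairwise(means, ns, mse, df_err)
            for (ga, gb), p in pvals.items():
                rows.append(PosthocResult(
                    band=band, roi=roi, group_a=ga, group_b=gb,
                    mean_a=means[ga], mean_b=means[gb], p=p,
                    significant=bool(p < threshold),
                    direction="a>b" if means[ga] > means[gb] else "a<b"))
    return pd.DataFrame([r.__dict__ for r in rows])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold achieving family-wise alpha: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Grubbs outlier screening
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = sst.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_iterative(values: np.ndarray, alpha: float = 0.001) -> list[int]:
    """Iterative (leave-one-out) Grubbs test; returns removed indices in
    removal order. Requires n >= 3; stops when the most extreme value no
    longer exceeds the critical value at ``alpha``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    active = list(range(len(x)))
    removed: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(sub - sub.mean()) / sd
        i_max = int(np.argmax(g))
        if g[i_max] > grubbs_critical(len(sub), alpha):
            removed.append(active.pop(i_max))
        else:
            break
    return removed


# ---------------------------------------------------------------------------
# exact contingency tests (enumeration)
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a 2xC table under fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (sum(lgamma(r + 1) for r in rows)
          + sum(lgamma(c + 1) for c in cols)
          - lgamma(n + 1)
          - sum(lgamma(v + 1) for v in table.ravel()))
    return lp


def fisher_freeman_halton(table) -> float:
    """Two-sided exact test for a 2xC contingency table by enumeration.

    For C = 2 this is Fisher's exact test; for C > 2 the Freeman-Halton
    extension. Two-sided by the point-probability method: the p-value sums
    the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table. Accepts a
    2 x C or C x 2 table (e.g. male/female counts per group).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if t.shape[0] != 2 and t.shape[1] == 2:
        t = t.T
    if t.shape[0] != 2:
        raise ValueError("one dimension of the table must have size 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    cols = t.sum(axis=0)
    r0 = t.sum(axis=1)[0]
    lp_obs = _log_table_prob(t)
    total = 0.0
    p = 0.0

    def rec(col: int, remaining: int, current: list[int]):
        nonlocal total, p
        if col == len(cols) - 1:
            if remaining > cols[col]:
                return
            cells = current + [remaining]
            cand = np.array([cells, cols - cells])
            if np.any(cand < 0):
                return
            lp = _log_table_prob(cand)
            prob = np.exp(lp)
            total += prob
            if lp <= lp_obs + 1e-9:
                p += prob
            return
        for v in range(min(cols[col], remaining) + 1):
            rec(col + 1, remaining - v, current + [v])

    rec(0, r0, [])
    return float(min(p / total, 1.0))


# ---------------------------------------------------------------------------
# marker battery
# ---------------------------------------------------------------------------

def marker_battery(subjects: pd.DataFrame, family: list[dict],
                   group_col: str = "group", alpha: float = 0.05
                   ) -> pd.DataFrame:
    """Run the declared univariate test per marker with a per-family
    Bonferroni threshold.

    ``family`` is a list of dicts with keys ``marker`` (column name or, for
    count tests, a 2xC array under key ``table``) and ``test`` in
    {"anova", "kruskal", "ttest", "ttest_log10", "fisher",
    "freeman_halton"}. The threshold is alpha / len(family).
    """
    if not family:
        raise ValueError("empty marker family")
    thr = bonferroni_threshold(alpha, len(family))
    rows = []
    for spec_row in family:
        test = spec_row["test"]
        name = spec_row.get("marker", test)
        if test in ("fisher", "freeman_halton"):
            p = fisher_freeman_halton(spec_row["table"])
        else:
            col = spec_row["marker"]
            if not np.issubdtype(subjects[col].dtype, np.number):
                raise ValueError(f"marker {col!r} is not numeric for a "
                                 f"parametric test")
            groups = [g[col].dropna().to_numpy()
                      for _, g in subjects.groupby(group_col, sort=False)]
            if test == "anova":
                p = float(sst.f_oneway(*groups).pvalue)
            elif test == "kruskal":
                p = float(sst.kruskal(*groups).pvalue)
            elif test in ("ttest", "ttest_log10"):
                if len(groups) != 2:
                    raise ValueError("t-test requires exactly two groups")
                a_, b_ = groups
                if test == "ttest_log10":
                    if np.any(a_ <= 0) or np.any(b_ <= 0):
                        raise ValueError(f"marker {col!r} has non-positive "
                                         "values; log10 undefined")
                    a_, b_ = np.log10(a_), np.log10(b_)
                p = float(sst.ttest_ind(a_, b_).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
        rows.append({"marker": name, "test": test, "p": p,
                     "threshold": thr, "significant": bool(p < thr)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC discrimination
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auroc: float
    sensitivity: float
    specificity: float
    accuracy: float          # weighted by the number of cases and controls
    ppv: float
    npv: float
    threshold: float
    direction: str           # "higher" scores indicate the positive class


def roc_classify(scores, labels, positive, direction: str = "higher"
                 ) -> ROCResult:
    """ROC analysis of a single score for a two-class problem.

    AUROC is the trapezoidal area (equal to the Mann-Whitney probability
    of correct pairwise ranking); the operating point maximizes Youden's
    J = sensitivity + specificity - 1, and sensitivity, specificity,
    weighted accuracy, PPV and NPV are reported at that point.
    """
    from sklearn.metrics import roc_curve, auc

    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == positive else 0 for lab in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    s = scores if direction == "higher" else -scores
    fpr, tpr, thresholds = roc_curve(y, s)
    auroc = float(auc(fpr, tpr))
    j = tpr - fpr
    i = int(np.argmax(j))
    thr = float(thresholds[i])
    pred = s >= thr
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    n_cases, n_controls = tp + fn, tn + fp
    acc = (sens * n_cases + spec * n_controls) / (n_cases + n_controls)
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return ROCResult(auroc=auroc, sensitivity=sens, specificity=spec,
                     accuracy=acc, ppv=ppv, npv=npv,
                     threshold=thr if direction == "higher" else -thr,
                     direction=direction)
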