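"""Group-level statistics for embryo feature tables.

Covers Welch's unequal-variance t-tests with Benjamini–Hochberg correction,
the permutation-calibrated effect-size/significance screen (a feature passes
when its relative effect exceeds a threshold AND its Welch p falls below an
alpha chosen so the label-shuffle false-discovery estimate stays below the
target FDR), per-cell SD/CV variability summaries with ANOVA + Tukey HSD,
the robustness screen (mean unchanged, variance increased), and the relative
AB-size bin/lethality and correlation analyses.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError

log = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    effect_threshold: float = 0.15
    target_fdr: float = 0.10
    n_shuffles: int = 100
    min_embryos_per_group: int = 5
    alpha_grid: tuple[float, ...] = (0.05, 0.02, 0.01, 0.008, 0.005, 0.002, 0.001)
    effect_mode: str = "relative"  # or "absolute"
    seed: int = 0

    def validate(self) -> None:
        if self.effect_mode not in ("relative", "absolute"):
            raise ArgumentError(f"unknown effect mode {self.effect_mode!r}")
        if not 0 < self.effect_threshold < 1:
            raise ArgumentError("effect_threshold must be in (0, 1)")
        if not 0 < self.target_fdr < 1:
            raise ArgumentError("target_fdr must be in (0, 1)")
        if self.n_shuffles < 1:
            raise ArgumentError("n_shuffles must be >= 1")
        if list(self.alpha_grid) != sorted(self.alpha_grid, reverse=True):
            raise ArgumentError("alpha_grid must be descending")


# ---------------------------------------------------------------------------
# Welch + BH
# ---------------------------------------------------------------------------

def _welch_arrays(
    X: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    min_n: int,
    effect_mode: str = "relative",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nan-aware Welch test per column.

    Returns (effect, t, p, tested); the effect is the relative mean
    difference (mean_a - mean_b) / mean_b, or the plain difference with
    ``effect_mode="absolute"``.
    """
    A, B = X[mask_a], X[mask_b]
    na = np.sum(~np.isnan(A), axis=0).astype(float)
    nb = np.sum(~np.isnan(B), axis=0).astype(float)
    tested = (na >= min_n) & (nb >= min_n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(A, axis=0), np.nanmean(B, axis=0)
        va = np.nanvar(A, axis=0, ddof=1)
        vb = np.nanvar(B, axis=0, ddof=1)
        sa, sb = va / na, vb / nb
        denom = np.sqrt(sa + sb)
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
        effect = (ma - mb) if effect_mode == "absolute" else (ma - mb) / mb
    zero_var = tested & (va == 0) & (vb == 0)
    if zero_var.any():
        p = np.where(zero_var & (ma == mb), 1.0, p)
        p = np.where(zero_var & (ma != mb), 0.0, p)
        t = np.where(zero_var, 0.0, t)
    p = np.where(tested, p, np.nan)
    return effect, t, p, tested


def welch_bh(
    table: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    min_embryos_per_group: int = 2,
) -> pd.DataFrame:
    """Per-feature Welch test between two groups with BH adjustment.

    The effect size is the relative mean difference versus group_b
    (the control/alive group by convention).
    """
    labels = labels.reindex(table.index)
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ArgumentError(f"empty group among {group_a!r}, {group_b!r}")
    X = table.to_numpy(dtype=float)
    effect, t, p, tested = _welch_arrays(X, mask_a, mask_b, min_embryos_per_group)
    out = pd.DataFrame(
        {
            "feature": table.columns,
            "mean_a": np.nanmean(np.where(mask_a[:, None], X, np.nan), axis=0),
            "mean_b": np.nanmean(np.where(mask_b[:, None], X, np.nan), axis=0),
            "n_a": np.sum(~np.isnan(X[mask_a]), axis=0),
            "n_b": np.sum(~np.isnan(X[mask_b]), axis=0),
            "effect": effect,
            "t": t,
            "p": p,
        }
    )
    dropped = out[~tested]
    if len(dropped):
        log.info("%d features excluded (insufficient coverage)", len(dropped))
    out = out[tested].reset_index(drop=True)
    if len(out):
        zero_both = (out["p"] == 1.0) & (out["mean_a"] == out["mean_b"])
        if zero_both.any():
            log.warning("%d features with zero variance in both groups", int(zero_both.sum()))
        out["p_adj"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


# ---------------------------------------------------------------------------
# permutation-calibrated FDR screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    table: pd.DataFrame  # feature, effect, p, p_adj, passes
    alpha_star: float
    alpha_table: pd.DataFrame  # alpha, observed, expected, fdr
    config: ScreenConfig = field(default_factory=ScreenConfig)

    @property
    def passing_features(self) -> list[str]:
        return self.table.loc[self.table["passes"], "feature"].tolist()


def permutation_fdr_alpha(
    table: pd.DataFrame,
    labels: pd.Series,
    config: ScreenConfig | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> tuple[float, ScreenResult]:
    """Choose the p-value cut-off alpha by label-shuffle FDR calibration.

    For each alpha on the descending grid, the expected false-positive count
    is the mean number of features passing (|effect| >= threshold AND
    p < alpha) over ``n_shuffles`` random label permutations; the estimated
    FDR is expected / max(observed, 1); alpha* is the largest grid alpha
    with FDR <= target.  The same shuffle set is reused across the grid.
    """
    config = config or ScreenConfig()
    config.validate()
    labels = labels.reindex(table.index)
    values = labels.dropna().unique()
    if group_a is None or group_b is None:
        if len(values) != 2:
            raise ArgumentError("labels must be binary or groups given explicitly")
        group_a, group_b = sorted(map(str, values))
    keep = labels.isin([group_a, group_b]).to_numpy()
    X = table.to_numpy(dtype=float)[keep]
    lab = labels.to_numpy()[keep]
    mask_a = lab == group_a

    thr = config.effect_threshold
    min_n = config.min_embryos_per_group
    effect, t, p, tested = _welch_arrays(X, mask_a, ~mask_a, min_n, config.effect_mode)
    with np.errstate(invalid="ignore"):
        obs_pass = tested & (np.abs(effect) >= thr)

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_a = int(mask_a.sum())
    alphas = np.asarray(config.alpha_grid)
    perm_counts = np.zeros((config.n_shuffles, alphas.size))
    for s in range(config.n_shuffles):
        perm = rng.permutation(n)
        pm = np.zeros(n, dtype=bool)
        pm[perm[:n_a]] = True
        eff_s, _, p_s, tested_s = _welch_arrays(X, pm, ~pm, min_n, config.effect_mode)
        with np.errstate(invalid="ignore"):
            base = tested_s & (np.abs(eff_s) >= thr)
            for k, a in enumerate(alphas):
                perm_counts[s, k] = np.sum(base & (p_s < a))

    expected = perm_counts.mean(axis=0)
    observed = np.array(
        [np.sum(obs_pass & (p < a)) for a in alphas], dtype=float
    )
    fdr = expected / np.maximum(observed, 1.0)
    ok = fdr <= config.target_fdr
    if ok.any():
        alpha_star = float(alphas[np.argmax(ok)])  # largest alpha meeting the bound
    else:
        alpha_star = float(alphas[-1])
        log.warning(
            "no alpha on the grid meets FDR <= %.2f; using smallest (%g); "
            "nothing may pass",
            config.target_fdr,
            alpha_star,
        )
    passes = obs_pass & (p < alpha_star)
    p_adj = np.full_like(p, np.nan)
    if tested.any():
        p_adj[tested] = multipletests(
            np.nan_to_num(p[tested], nan=1.0), method="fdr_bh"
        )[1]
    result_table = pd.DataFrame(
        {
            "feature": table.columns,
            "effect": effect,
            "p": p,
            "p_adj": p_adj,
            "passes": passes,
        }
    )
    alpha_table = pd.DataFrame(
        {"alpha": alphas, "observed": observed, "expected": expected, "fdr": fdr}
    )
    return alpha_star, ScreenResult(
        table=result_table, alpha_star=alpha_star, alpha_table=alpha_table,
        config=config,
    )


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------

def variability_stats(
    table: pd.DataFrame, groups: pd.Series, min_embryos: int = 2
) -> pd.DataFrame:
    """Per-group, per-column sample SD and CV (CV only for positive means)."""
    groups = groups.reindex(table.index)
    rows = []
    for g, sub in table.groupby(groups):
        n = sub.notna().sum()
        mean = sub.mean()
        sd = sub.std(ddof=1)
        for col in table.columns:
            if n[col] < min_embryos:
                continue
            m, s = mean[col], sd[col]
            cv = s / m if m > 0 else np.nan
            rows.append(
                {
                    "group": g,
                    "feature": col,
                    "n": int(n[col]),
                    "mean": m,
                    "sd": s,
                    "cv": cv,
                }
            )
    return pd.DataFrame(rows)


def anova_tukey(values: pd.Series, groups: pd.Series):
    """One-way ANOVA plus Tukey HSD across groups.

    Returns (anova p-value, Tukey summary DataFrame).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    samples = [sub["value"].to_numpy() for _, sub in df.groupby("group")]
    if len(samples) < 2:
        raise ArgumentError("need >= 2 groups for ANOVA")
    f, p = sps.f_oneway(*samples)
    tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy())
    summary = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return float(p), summary


def robustness_screen(
    table: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    mean_alpha: float = 0.05,
    var_alpha: float = 0.05,
    min_embryos_per_group: int = 5,
    variance_test: str = "f",
) -> pd.DataFrame:
    """Features whose mean is unchanged but whose variability increased.

    A feature is flagged when the Welch test finds no mean difference
    (p >= mean_alpha) and a one-sided variance test finds the group_b
    variance significantly larger (p < var_alpha).  ``variance_test`` is the
    variance-ratio F test by default, with Brown–Forsythe Levene as the
    robust alternative; the test pairing is a design decision of this
    package.
    """
    if variance_test not in ("f", "levene"):
        raise ArgumentError(f"unknown variance test {variance_test!r}")
    labels = labels.reindex(table.index)
    A = table[labels == group_a]
    B = table[labels == group_b]
    rows = []
    for col in table.columns:
        a = A[col].dropna().to_numpy()
        b = B[col].dropna().to_numpy()
        if len(a) < min_embryos_per_group or len(b) < min_embryos_per_group:
            continue
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            continue
        _, p_mean = sps.ttest_ind(a, b, equal_var=False)
        f = vb / va if va > 0 else np.inf
        if variance_test == "levene":
            _, p_two = sps.levene(a, b, center="median")
            # one-sided: significant only when group_b is the inflated one
            p_var = float(p_two / 2.0) if vb > va else 1.0
        else:
            p_var = float(sps.f.sf(f, len(b) - 1, len(a) - 1))
        rows.append(
            {
                "feature": col,
                "p_mean": float(p_mean),
                "var_ratio": f,
                "p_var": p_var,
                "flagged": bool(p_mean >= mean_alpha and p_var < var_alpha),
            }
        )
    df = pd.DataFrame(
        rows, columns=["feature", "p_mean", "var_ratio", "p_var", "flagged"]
    )
    return df


# ---------------------------------------------------------------------------
# AB-size analyses
# ---------------------------------------------------------------------------

def bin_lethality(
    metadata: pd.DataFrame, bin_width: float = 2.0, lo: float = 42.0, hi: float = 62.0
) -> pd.DataFrame:
    """Lethality fraction in half-open relative-AB-size bins.

    Bins are labelled in interval notation, e.g. ``(56-54]`` contains sizes
    s with 54 <= s < 56 (the square bracket marks the included endpoint).
    Empty bins are reported with n = 0, not dropped.
    """
    if "relative_AB_size" not in metadata or "outcome" not in metadata:
        raise ArgumentError("metadata must have relative_AB_size and outcome")
    edges = np.arange(hi, lo - bin_width / 2, -bin_width)
    rows = []
    for high, low in zip(edges[:-1], edges[1:]):
        sel = metadata[
            (metadata["relative_AB_size"] >= low)
            & (metadata["relative_AB_size"] < high)
        ]
        n = len(sel)
        dead = int((sel["outcome"] == "dead").sum())
        rows.append(
            {
                "bin": f"({high:g}-{low:g}]",
                "low": low,
                "high": high,
                "n": n,
                "n_dead": dead,
                "lethality": dead / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def size_correlation(
    metadata: pd.DataFrame, quantity: pd.Series
) -> tuple[float, float, int]:
    """Pearson r between relative AB size and a per-embryo quantity.

    The two-sided p-value comes from the asymptotic t approximation with
    n - 2 degrees of freedom.
    """
    df = pd.DataFrame(
        {"size": metadata["relative_AB_size"], "q": quantity.reindex(metadata.index)}
    ).dropna()
    n = len(df)
    if n < 3:
        raise ArgumentError("need >= 3 paired observations")
    r, p = sps.pearsonr(df["size"], df["q"])
    return float(r), float(p), n
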