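"""Cross-site land-use statistics.

Spearman correlations of genus relative abundance with land use and soil
covariates (exact permutation p for n <= 8, t approximation otherwise),
arcsine-square-root transform for ANOVA, one-/two-way ANOVA, the 0.05%
site-wide abundance filter, three-set Venn partitioning, the cross-site
signature rule (|rho| >= 0.5 and p <= 0.001 at every site), and ratio /
integer fold-change reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnalysisConfig:
    abundance_floor: float = 0.0005  # 0.05% of site-wide reads
    rho_floor: float = 0.5
    p_ceiling: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.abundance_floor < 1):
            raise ValueError("abundance_floor must be in (0,1)")
        if not (0 < self.rho_floor <= 1) or not (0 < self.p_ceiling < 1):
            raise ValueError("bad rho_floor or p_ceiling")


EXACT_P_MAX_N = 8


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho on average ranks with a two-sided p.

    Exact permutation enumeration for n <= 8, t approximation with
    df = n - 2 otherwise.  Constant input is an undefined correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation for a constant vector")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= EXACT_P_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    perms = np.array(list(permutations(ry)))
    cx = rx - rx.mean()
    cy = perms - perms.mean(axis=1, keepdims=True)
    denom = math.sqrt((cx @ cx)) * np.sqrt((cy * cy).sum(axis=1))
    rhos = (cy @ cx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def arcsine_sqrt(p):
    """Variance-stabilizing asin(sqrt(p)) transform for proportions."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if out.ndim == 0 else out


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """Classical between/within decomposition; returns (F, (df1, df2), p)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least 2 values")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    df1 = len(gs) - 1
    df2 = all_vals.size - len(gs)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, (df1, df2), 1.0
        return math.inf, (df1, df2), 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), (df1, df2), float(sps.f.sf(f, df1, df2))


def two_way_anova(
    values: Sequence[float], factor_a: Sequence, factor_b: Sequence
) -> pd.DataFrame:
    """Balanced two-way ANOVA with interaction (main effects A, B, A:B).

    Requires a complete balanced design with >= 2 replicates per cell;
    unbalanced input raises with an instruction to subsample to balance.
    Returns a DataFrame indexed by effect with F, df and p columns.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, float), "a": factor_a, "b": factor_b})
    cells = df.groupby(["a", "b"]).size()
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    if len(cells) != n_a * n_b or cells.nunique() != 1:
        raise ValueError("unbalanced design: subsample to a balanced complete layout first")
    if cells.iloc[0] < 2:
        raise ValueError("need >= 2 replicates per cell")
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    out = tab.rename(
        index={"C(a)": "A", "C(b)": "B", "C(a):C(b)": "A:B", "Residual": "residual"}
    )[["df", "sum_sq", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})
    # zero-variance degeneracies: an effect with no sum of squares has F = 0;
    # a real effect over zero residual variance is reported below any floor
    ms_res = out.loc["residual", "sum_sq"] / out.loc["residual", "df"]
    for eff in ("A", "B", "A:B"):
        if out.loc[eff, "sum_sq"] < 1e-12:
            out.loc[eff, ["F", "p"]] = [0.0, 1.0]
        elif ms_res < 1e-12:
            out.loc[eff, ["F", "p"]] = [math.inf, 0.0]
    return out.drop(columns="sum_sq")


def abundance_filter(
    counts_by_site: Mapping[str, pd.DataFrame],
    denominators: Mapping[str, int],
    floor: float,
) -> dict[str, set[str]]:
    """Per site: genera whose site-wide relative abundance reaches the floor.

    Site-wide abundance = total genus pair count at the site / total
    trimmed-pair denominator over the site's samples.
    """
    out: dict[str, set[str]] = {}
    for site, counts in counts_by_site.items():
        denom = sum(denominators[s] for s in counts.columns)
        if denom <= 0:
            raise ValueError(f"site {site}: zero total trimmed pairs")
        frac = counts.sum(axis=1) / denom
        out[site] = set(frac.index[frac >= floor - 1e-15])
    return out


def venn_partition(sets: Mapping[str, set]) -> tuple[dict[str, int], float]:
    """Counts for the 7 regions of a 3-set Venn plus |∩| / |∪|."""
    if len(sets) != 3:
        raise ValueError("venn_partition needs exactly 3 sets")
    (ka, a), (kb, b), (kc, c) = sets.items()
    union = a | b | c
    regions = {
        ka: len(a - b - c),
        kb: len(b - a - c),
        kc: len(c - a - b),
        f"{ka}&{kb}": len((a & b) - c),
        f"{ka}&{kc}": len((a & c) - b),
        f"{kb}&{kc}": len((b & c) - a),
        f"{ka}&{kb}&{kc}": len(a & b & c),
    }
    shared = len(a & b & c) / len(union) if union else 0.0
    return regions, shared


def signature_genera(
    corr_by_site: Mapping[str, pd.DataFrame],
    abundant_by_site: Mapping[str, set[str]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Genera correlated with land use in the same direction at every site.

    A genus is a positive (negative) signature iff it passes the abundance
    filter at all sites and has rho >= rho_floor (<= -rho_floor) with
    p <= p_ceiling at every site.  ``corr_by_site`` maps site -> DataFrame
    indexed by genus with ``rho`` and ``p`` columns.
    """
    config = config or AnalysisConfig()
    sites = list(corr_by_site)
    common = set.intersection(*(abundant_by_site[s] for s in sites)) if sites else set()
    rows = []
    for genus in sorted(common):
        rhos = {}
        ok_pos = ok_neg = True
        for site in sites:
            tab = corr_by_site[site]
            if genus not in tab.index:
                ok_pos = ok_neg = False
                break
            rho, p = float(tab.loc[genus, "rho"]), float(tab.loc[genus, "p"])
            rhos[site] = rho
            sig = p <= config.p_ceiling + 1e-15
            ok_pos &= sig and rho >= config.rho_floor - 1e-12
            ok_neg &= sig and rho <= -config.rho_floor + 1e-12
        if ok_pos or ok_neg:
            rows.append(
                {"genus": genus, "direction": "positive" if ok_pos else "negative", **rhos}
            )
    cols = ["genus", "direction", *sites]
    return pd.DataFrame(rows, columns=cols).set_index("genus")


def fold_change(mean_a: float, mean_b: float) -> tuple[float, int, int]:
    """Ratio of the larger mean to the smaller plus a nearest-integer fold.

    Returns (ratio, fold, direction) with direction +1 if mean_a > mean_b,
    -1 if mean_a < mean_b, 0 if equal.  Fold rounds half away from zero.
    """
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("undefined fold: both means must be positive")
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    ratio = hi / lo
    fold = int(math.floor(ratio + 0.5))
    direction = (mean_a > mean_b) - (mean_a < mean_b)
    return float(ratio), fold, direction
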