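"""Trial statistics: nested ANOVA, LSD mean separation, Pearson matrix.

The trial model is the additive fixed-effects linear model

    y_ijk = b0 + b1 (crop_i) + b2 (cultivar_j within crop_i) + b3 (block_k) + e_ijk

fitted by OLS with Type-I (sequential) sums of squares in the order
crop -> cultivar(crop) -> block.  Because every cultivar name belongs to
exactly one crop, fitting the plain cultivar factor *after* crop yields
exactly the cultivar-within-crop sequential SS.  Crop means are separated
by Fisher's LSD at alpha = 0.05; phenotype-trait associations are Pearson
correlations over cultivar-averaged values with t-distribution stars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "fit_nested_anova",
    "lsd_separation",
    "pearson_matrix",
    "sequential_f",
    "permutation_pvalue",
]


@dataclass
class AnovaResult:
    """Nested ANOVA fit: coefficient table, sequential ANOVA table, residuals."""

    response: str
    anova_table: pd.DataFrame  # rows: crop, cultivar(crop), block, residual
    coefficients: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    df_error: int
    mse: float
    group_means: pd.Series  # crop-level means of the response
    group_sizes: pd.Series
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def p_values(self) -> dict:
        return {
            term: float(self.anova_table.loc[term, "PR(>F)"])
            for term in ("crop", "cultivar(crop)", "block")
        }

    def ss_partition_error(self) -> float:
        """Relative gap between summed sequential SS and total SS."""
        total = float(((self.fitted + self.residuals)
                       - (self.fitted + self.residuals).mean()).__pow__(2).sum())
        parts = float(self.anova_table["sum_sq"].sum())
        return abs(parts - total) / max(total, 1e-300)


def _prepare(records, response: str) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        from .morphotypes import trials_to_dataframe

        df = trials_to_dataframe(records)
    if response not in df.columns:
        raise ValueError(f"response {response!r} not in columns {list(df.columns)}")
    df = df.dropna(subset=[response, "crop", "cultivar", "block"])
    return df


def fit_nested_anova(records, response: str) -> AnovaResult:
    """Fit the additive crop + cultivar(crop) + block model with Type-I SS.

    The underlying OLS fit (coefficients, fitted values, residuals) comes
    from statsmodels; the sequential table is assembled from explicit
    projections onto the nested design spaces, because the nesting makes the
    dummy design exactly collinear (crop indicators are sums of their
    cultivar indicators) and generic sequential-ANOVA helpers then miscount
    the cultivar-within-crop degrees of freedom (7 instead of 8 - 2 = 6).
    """
    from statsmodels.formula.api import ols

    df = _prepare(records, response)
    if df["crop"].nunique() < 2:
        raise ValueError("need at least 2 crops")
    n = len(df)
    df = df.assign(
        _y=df[response].astype(float),
        block=df["block"].astype(str),
    )
    k_crop = df["crop"].nunique()
    k_cult = df["cultivar"].nunique()
    k_block = df["block"].nunique()
    df_terms = {
        "crop": k_crop - 1,
        "cultivar(crop)": k_cult - k_crop,
        "block": k_block - 1,
    }
    df_err = n - 1 - sum(df_terms.values())
    if df_err < 1:
        raise ValueError(
            f"singular design: {n} observations leave {df_err} error df"
        )

    model = ols("_y ~ C(crop) + C(cultivar) + C(block)", data=df).fit()

    y = df["_y"].to_numpy()
    yc = y - y.mean()
    proj = [float(((U.T @ yc) ** 2).sum()) for U in _sequential_bases(df)]
    ss = {
        "crop": proj[0],
        "cultivar(crop)": proj[1] - proj[0],
        "block": proj[2] - proj[1],
    }
    sse = float((yc**2).sum()) - proj[2]
    mse = sse / df_err
    rows = {}
    for term in ("crop", "cultivar(crop)", "block"):
        dft = max(df_terms[term], 1)
        if ss[term] <= 1e-30:  # constant responses: no effect, p = 1
            f_stat, p = 0.0, 1.0
        elif mse <= 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ss[term] / dft / mse
            p = float(sps.f.sf(f_stat, dft, df_err))
        rows[term] = {
            "df": float(df_terms[term]), "sum_sq": ss[term],
            "mean_sq": ss[term] / dft, "F": f_stat, "PR(>F)": p,
        }
    rows["residual"] = {
        "df": float(df_err), "sum_sq": sse, "mean_sq": mse,
        "F": np.nan, "PR(>F)": np.nan,
    }
    table = pd.DataFrame(rows).T

    return AnovaResult(
        response=response,
        anova_table=table,
        coefficients=model.params,
        fitted=np.asarray(model.fittedvalues),
        residuals=np.asarray(model.resid),
        df_error=df_err,
        mse=mse,
        group_means=df.groupby("crop")["_y"].mean(),
        group_sizes=df.groupby("crop")["_y"].size(),
        data=df,
    )


def lsd_separation(result: AnovaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher's LSD letters for crop means.

    Two means differ iff |difference| strictly exceeds
    t(1 - alpha/2, df_error) * SE(difference), with the SE built from the
    ANOVA error mean square.  Separation is computed (and flagged) whether
    or not the crop F-test is significant.
    """
    if result.df_error <= 0:
        raise ValueError("zero error degrees of freedom: LSD undefined")
    means = result.group_means.sort_values(ascending=False)
    sizes = result.group_sizes[means.index]
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, result.df_error)

    levels = list(means.index)
    n = len(levels)
    differs = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            se = np.sqrt(result.mse * (1.0 / sizes.iloc[i] + 1.0 / sizes.iloc[j]))
            differs[i, j] = differs[j, i] = (
                abs(means.iloc[i] - means.iloc[j]) > tcrit * se
            )

    # letter assignment: greedily merge non-differing runs (means sorted)
    letters = [""] * n
    current = 0
    for i in range(n):
        if i == 0:
            letters[i] = chr(ord("a") + current)
            continue
        if differs[i, i - 1]:
            current += 1
        letters[i] = chr(ord("a") + current)
    # a level also inherits earlier letters it does not differ from
    for i in range(n):
        for j in range(i):
            if not differs[i, j] and letters[j][-1] not in letters[i]:
                letters[i] = letters[i] + letters[j][-1]
        letters[i] = "".join(sorted(set(letters[i])))

    crop_p = result.p_values["crop"]
    return pd.DataFrame({
        "mean": means,
        "n": sizes,
        "group": letters,
        "factor_significant": crop_p < alpha,
    })


def pearson_matrix(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations over cultivar-averaged values, with stars.

    Returns (r matrix, star matrix); stars at 0.05 / 0.01 / 0.001 from the
    t-distribution.  Zero-variance variables yield missing entries for their
    pairs, reported as NaN / ''.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 cultivar averages")
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    stars = pd.DataFrame("", index=variables, columns=variables, dtype=object)
    for i, a in enumerate(variables):
        for j in range(i + 1, k):
            b = variables[j]
            xa = table[a].to_numpy(dtype=float)
            xb = table[b].to_numpy(dtype=float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rv, pv = sps.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = rv
            s = "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""
            stars.loc[a, b] = stars.loc[b, a] = s
    return r, stars


def _sequential_bases(df: pd.DataFrame):
    """Orthonormal bases of the nested cumulative design spaces.

    Returns ``[U1, U2, U3]`` spanning [1 | crop], [... | cultivar],
    [... | block] column spaces, built directly from indicator matrices —
    independent of any model-fitting machinery.
    """
    from scipy.linalg import orth

    n = len(df)
    blocks = [np.ones((n, 1))]
    for col in ("crop", "cultivar", "block"):
        blocks.append(pd.get_dummies(df[col].astype(str)).to_numpy(dtype=float))
    bases = []
    for k in range(1, 4):
        bases.append(orth(np.hstack(blocks[: k + 1])))
    return bases


def sequential_f(df: pd.DataFrame, y: np.ndarray, bases=None) -> dict:
    """Sequential (Type-I) F statistics for crop, cultivar(crop), block.

    Computed from projection norms onto the nested design spaces; this is
    the brute-force definition of sequential SS, used both directly and as
    the statistic of the permutation oracle.
    """
    if bases is None:
        bases = _sequential_bases(df)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    proj = [float(((U.T @ yc) ** 2).sum()) for U in bases]
    ss_crop = proj[0]
    ss_cult = proj[1] - proj[0]
    ss_block = proj[2] - proj[1]
    sse = float((yc**2).sum()) - proj[2]
    df_crop = df["crop"].nunique() - 1
    df_cult = df["cultivar"].nunique() - df["crop"].nunique()
    df_block = df["block"].nunique() - 1
    df_err = len(df) - 1 - df_crop - df_cult - df_block
    mse = sse / df_err
    return {
        "crop": ss_crop / max(df_crop, 1) / mse,
        "cultivar(crop)": ss_cult / max(df_cult, 1) / mse,
        "block": ss_block / max(df_block, 1) / mse,
    }


def permutation_pvalue(
    records, response: str, term: str = "crop", n_perm: int = 10000, seed: int = 0
) -> float:
    """Permutation-test p-value for an ANOVA term's F statistic.

    Independent oracle for the parametric p-values: the response is permuted
    (freely for the crop term; within crops for the nested cultivar term)
    and the sequential F recomputed from design-space projections.
    """
    df = _prepare(records, response)
    bases = _sequential_bases(df)
    y = df[response].to_numpy(dtype=float)
    f_obs = sequential_f(df, y, bases)[term]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if term == "crop":
            yp = rng.permutation(y)
        else:
            perm = np.arange(len(y))
            for idx in df.groupby("crop").indices.values():
                perm[idx] = rng.permutation(idx)
            yp = y[perm]
        if sequential_f(df, yp, bases)[term] >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)
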