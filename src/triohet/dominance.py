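"""Per-gene trio ANOVA and dominance-ratio pattern classification.

Each gene's log2 expression at one stage is modelled as
``y = u + a * x_a + d * x_d + replicate block + e`` with x_a = +1 for P1,
-1 for P2, 0 for F1 and x_d = 1 for F1 only, so ``u`` is the mid-parent
level, ``a`` the composite additive effect and ``d`` the F1 deviation
from the mid-parent.  Classification of the dominance ratio h_p uses a
confidence interval for [d] - [a] when [d] > 0 (and [d] + [a] when
[d] < 0, with [a] = |a|): an interval containing zero pins the hybrid to
the nearer parent's level (HPL / LPL), an interval beyond it calls
over-/under-dominance (AHP / BLP), and an interval on the mid-parent
side calls partial dominance (MPL).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "TrioEffects",
    "fit_trio_anova",
    "classify_hp",
    "summarize_patterns",
    "PATTERN_CLASSES",
]

PATTERN_CLASSES = ("AHP", "HPL", "MPL", "LPL", "BLP", "none")
UP_CLASSES = ("AHP", "HPL")
DOWN_CLASSES = ("LPL", "BLP")

# pseudo degrees of freedom lent by pooling residual variances across genes
POOLING_PRIOR_DF = 20.0


@dataclass
class TrioEffects:
    """Fitted per-gene effects for one stage.

    ``table`` has one row per gene: u, a_raw, abs_a, d, rep_effect,
    resid_var; after :func:`classify_hp` also estimate, ci_low, ci_high
    and hp_class.  ``cov_unit`` holds the unit-variance design constants
    (entries of (X'X)^-1 for the a and d coefficients).
    """

    table: pd.DataFrame
    stage: str
    resid_df: int
    cov_unit: dict
    level: Optional[float] = None
    variance_mode: Optional[str] = None


def _design(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Rows follow ``samples``; columns: 1, x_a, x_d, sum-to-zero replicate dummies."""
    genos = samples["genotype"].to_numpy()
    for g in ("P1", "P2", "F1"):
        if (genos == g).sum() == 0:
            raise ValueError(f"missing genotype {g} at this stage")
    reps = sorted(samples["replicate"].unique())
    x_a = np.where(genos == "P1", 1.0, np.where(genos == "P2", -1.0, 0.0))
    x_d = np.where(genos == "F1", 1.0, 0.0)
    cols = [np.ones(len(samples)), x_a, x_d]
    names = ["u", "a", "d"]
    last = reps[-1]
    for r in reps[:-1]:
        col = np.where(
            samples["replicate"] == r, 1.0, np.where(samples["replicate"] == last, -1.0, 0.0)
        )
        cols.append(col)
        names.append(f"rep_{r}")
    return np.column_stack(cols), names


def fit_trio_anova(
    log_expr: pd.DataFrame, samples: pd.DataFrame, stage: str
) -> TrioEffects:
    """Least-squares fit of the trio model for every gene at one stage.

    ``log_expr`` is genes x samples on the log2 scale; ``samples`` the
    metadata table (genotype, stage, replicate) indexed by sample id.
    """
    meta = samples.loc[list(log_expr.columns)]
    meta = meta[meta["stage"].astype(str) == str(stage)]
    if len(meta) == 0:
        raise ValueError(f"no samples at stage {stage!r}")
    Y = log_expr[list(meta.index)].to_numpy(dtype=float)
    X, names = _design(meta)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ (xtx_inv @ X.T).T  # genes x p
    resid = Y - coef @ X.T
    rss = np.einsum("gs,gs->g", resid, resid)
    resid_var = rss / df

    ia, idx_d = names.index("a"), names.index("d")
    a_raw = coef[:, ia]
    d = coef[:, idx_d]
    table = pd.DataFrame(
        {
            "u": coef[:, names.index("u")],
            "a_raw": a_raw,
            "abs_a": np.abs(a_raw),
            "d": d,
            "rep_effect": coef[:, names.index(f"rep_{sorted(meta['replicate'].unique())[0]}")]
            if any(nm.startswith("rep_") for nm in names)
            else 0.0,
            "resid_var": resid_var,
        },
        index=log_expr.index,
    )
    cov_unit = {
        "aa": float(xtx_inv[ia, ia]),
        "dd": float(xtx_inv[idx_d, idx_d]),
        "ad": float(xtx_inv[ia, idx_d]),
    }
    return TrioEffects(table=table, stage=str(stage), resid_df=df, cov_unit=cov_unit)


def classify_hp(
    effects: TrioEffects,
    level: float = 0.998,
    variance_mode: str = "pooled",
    prior_df: float = POOLING_PRIOR_DF,
    atol: float = 1e-10,
) -> TrioEffects:
    """Assign the dominance-ratio pattern class per gene.

    For [d] > 0 a two-sided CI for [d] - [a] at ``level``: containing 0
    -> HPL, entirely positive -> AHP, entirely negative -> MPL; for
    [d] < 0 symmetric on [d] + [a] (LPL / BLP / MPL); [d] == 0 -> none.

    ``variance_mode="pooled"`` moderates each gene's residual variance
    toward the across-gene median with ``prior_df`` pseudo-df (t quantile
    on resid_df + prior_df); ``"per_gene"`` uses the raw fit variance.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    tab = effects.table
    s2 = tab["resid_var"].to_numpy(dtype=float)
    df = effects.resid_df
    if variance_mode == "pooled":
        prior = float(np.median(s2))
        s2_used = (df * s2 + prior_df * prior) / (df + prior_df)
        t_df = df + prior_df
    elif variance_mode == "per_gene":
        s2_used = s2
        t_df = df
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    a_raw = tab["a_raw"].to_numpy()
    abs_a = tab["abs_a"].to_numpy()
    d = tab["d"].to_numpy()
    sign_a = np.where(a_raw >= 0, 1.0, -1.0)
    sign_d = np.sign(d)

    # combination d - sign(d) * |a| = d - sign(d) * sign(a) * a
    cu = effects.cov_unit
    w = sign_d * sign_a  # coefficient of a in the combination (negated)
    est = d - sign_d * abs_a
    var_unit = cu["dd"] + cu["aa"] - 2.0 * w * cu["ad"]
    se = np.sqrt(var_unit * s2_used)
    tq = stats.t.ppf(0.5 + level / 2.0, t_df)
    ci_low = est - tq * se
    ci_high = est + tq * se

    # atol guards exact-tie genes (noiseless fits) against fp jitter
    classes = np.full(len(tab), "none", dtype=object)
    pos = d > atol
    neg = d < -atol
    contains0 = (ci_low <= atol) & (ci_high >= -atol)
    # d > 0: CI of d - |a|
    classes[pos & contains0] = "HPL"
    classes[pos & (ci_low > atol)] = "AHP"
    classes[pos & (ci_high < -atol)] = "MPL"
    # d < 0: CI of d + |a|
    classes[neg & contains0] = "LPL"
    classes[neg & (ci_high < -atol)] = "BLP"
    classes[neg & (ci_low > atol)] = "MPL"

    out = tab.copy()
    out["estimate"] = est
    out["ci_low"] = ci_low
    out["ci_high"] = ci_high
    out["hp_class"] = classes
    return replace(
        effects, table=out, level=level, variance_mode=variance_mode
    )


def summarize_patterns(effects: TrioEffects, dg_hp: Iterable) -> pd.DataFrame:
    """Class counts and fractions restricted to the DG_HP set.

    Returns one row per class plus ``up_regulated`` (AHP + HPL) and
    ``down_regulated`` (LPL + BLP) rows; fractions are over classified
    DG_HP genes and absent (NaN) when the set is empty.
    """
    if "hp_class" not in effects.table.columns:
        raise ValueError("effects not classified; run classify_hp first")
    dg_hp = list(dg_hp)
    missing = set(dg_hp) - set(effects.table.index)
    if missing:
        raise ValueError(f"DG_HP genes missing a class: {sorted(missing)[:5]}")
    classes = effects.table.loc[dg_hp, "hp_class"]
    n = len(classes)
    rows = []
    for cls in PATTERN_CLASSES:
        k = int((classes == cls).sum())
        rows.append({"group": cls, "count": k, "fraction": (k / n) if n else np.nan})
    up = int(classes.isin(UP_CLASSES).sum())
    down = int(classes.isin(DOWN_CLASSES).sum())
    rows.append({"group": "up_regulated", "count": up, "fraction": (up / n) if n else np.nan})
    rows.append(
        {"group": "down_regulated", "count": down, "fraction": (down / n) if n else np.nan}
    )
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["stage"] = effects.stage
    out.attrs["n_dg_hp"] = n
    return out
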