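"""Full-factorial parameter screening with ANOVA + Tukey HSD.

The bucketing workflow has a handful of discrete knobs — bucket sizes in
RT and m/z, normalization strategy, fragment-block inclusion, data
fusion — and the screening machinery here expands a full factorial over
them, runs the pipeline once per combination on a fixed, already-aligned
dataset, records the classifier response (OOB error by default), and
analyzes factor effects with a main-effects ANOVA followed by Tukey's
honest significant difference on every factor's level pairs.

The ANOVA is an additive OLS model over the factors (no interactions:
the screening reports per-factor pairwise differences).  Tukey p-values
use the studentized range on the additive model's residual mean square,
i.e. the same error term for every factor — the behaviour of running
TukeyHSD on a multi-way aov fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .errors import ConfigError

__all__ = [
    "DOEDesign",
    "DOEResult",
    "DOE1_DESIGN",
    "DOE2_DESIGN",
    "expand_design",
    "run_doe",
    "anova_tukey",
]


@dataclass(frozen=True)
class DOEDesign:
    """Ordered factors -> levels map plus the response to record."""

    factors: dict[str, tuple]
    response: str = "oob_error"

    def __post_init__(self):
        if not self.factors:
            raise ConfigError("a design needs at least one factor")
        object.__setattr__(
            self, "factors", {k: tuple(v) for k, v in self.factors.items()}
        )
        for name, levels in self.factors.items():
            if len(levels) < 2:
                raise ConfigError(f"factor {name!r} needs >= 2 levels")


#: The two published screening designs: initial optimization (60
#: combinations) and long-term validation (288 combinations).
DOE1_DESIGN = DOEDesign(factors={
    "rt_size": (5, 20, 80),
    "mz_size": (2, 5, 10, 20),
    "normalization": ("BPC", "BPC_RT", "TIC", "TIC_RT", "ISTD_add"),
})

DOE2_DESIGN = DOEDesign(factors={
    "rt_size": (5, 20, 80),
    "mz_size": (2, 5),
    "fragments": ("yes_small", "yes_large", "no"),
    "data_fusion": ("yes_full", "yes_full_frag_small", "yes_full_frag_large", "no"),
    "normalization": ("BPC", "BPC_RT", "TIC", "TIC_RT"),
})


def expand_design(design: DOEDesign) -> pd.DataFrame:
    """Cartesian product of factor levels, last factor varying fastest."""
    names = list(design.factors)
    combos = list(itertools.product(*design.factors.values()))
    return pd.DataFrame(combos, columns=names)


@dataclass
class DOEResult:
    responses: pd.DataFrame          # one row per combination (+ replicate)
    anova: pd.DataFrame              # per-factor sum_sq, df, F, p
    tukey: pd.DataFrame              # per factor-level-pair comparisons
    response_name: str = "oob_error"

    def to_tsvs(self, prefix) -> tuple:
        from pathlib import Path
        prefix = Path(prefix)
        rp = prefix.with_name(prefix.name + "_responses.tsv")
        tp = prefix.with_name(prefix.name + "_tukey.tsv")
        self.responses.to_csv(rp, sep="\t", index=False)
        self.tukey.to_csv(tp, sep="\t", index=False)
        return rp, tp


def _tukey_factor(
    df: pd.DataFrame, factor: str, response: str, mse: float, df_resid: float,
    levels: Sequence,
) -> list[dict]:
    """Tukey HSD comparisons for one factor on a shared error term."""
    groups = df.groupby(factor, sort=False)[response]
    means = {lvl: groups.get_group(lvl).mean() for lvl in levels}
    ns = {lvl: len(groups.get_group(lvl)) for lvl in levels}
    k = len(levels)
    rows = []
    unreliable = any(n < 2 for n in ns.values())
    for l1, l2 in itertools.combinations(levels, 2):
        diff = means[l2] - means[l1]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[l1] + 1.0 / ns[l2]))
        if se == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(np.clip(studentized_range.sf(q, k, df_resid), 0.0, 1.0))
        rows.append({
            "factor": factor,
            "pair": f"{l2}-{l1}",
            "difference": float(diff),
            "p_adj": p,
            "reliable": not unreliable,
        })
    return rows


def anova_tukey(
    responses: pd.DataFrame,
    factors: Sequence[str],
    response: str = "response",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main-effects ANOVA plus Tukey HSD tables for each factor.

    Degenerate inputs are handled explicitly: a factor with zero
    between-level variance gets F = 0 and p = 1; levels observed only
    once make that factor's Tukey p-values unreliable (flagged).
    """
    df = responses.copy()
    df["_y"] = df[response].astype(float)
    for f in factors:
        if df[f].nunique() < 2:
            raise ConfigError(f"factor {f!r} has fewer than 2 observed levels")
        counts = df[f].value_counts()
        if (counts < 2).any():
            warnings.warn(f"factor {f!r}: level(s) with a single observation; "
                          "Tukey p-values unreliable")
    terms = " + ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"_y ~ {terms}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on zero residual df edge cases
        table = sm.stats.anova_lm(model, typ=2)
    anova_rows = []
    resid_ss = float(table.loc["Residual", "sum_sq"])
    df_resid = float(table.loc["Residual", "df"])
    mse = resid_ss / df_resid if df_resid > 0 else 0.0
    total_ss = float(((df["_y"] - df["_y"].mean()) ** 2).sum())
    # numerically-zero effects (identical group values) get F=0, p=1
    zero_tol = 1e-12 * max(total_ss, 1.0)
    for f in factors:
        row = table.loc[f"C(Q('{f}'))"]
        ss, fdf = float(row["sum_sq"]), float(row["df"])
        if ss <= zero_tol:
            F, p = 0.0, 1.0
        elif not np.isfinite(row["F"]) or resid_ss <= zero_tol:
            F, p = float("inf"), 0.0
        else:
            F, p = float(row["F"]), float(row["PR(>F)"])
        anova_rows.append({"factor": f, "sum_sq": ss, "df": fdf, "F": F, "p": p})
    anova_rows.append({"factor": "Residual", "sum_sq": resid_ss, "df": df_resid,
                       "F": float("nan"), "p": float("nan")})
    anova = pd.DataFrame(anova_rows)

    tukey_rows = []
    for f in factors:
        levels = list(dict.fromkeys(df[f]))
        tukey_rows.extend(_tukey_factor(df, f, "_y", mse, df_resid, levels))
    tukey = pd.DataFrame(tukey_rows)
    return anova, tukey


def run_doe(
    pipeline: Callable[[dict, int], float],
    design: DOEDesign,
    *,
    replicate_seeds: Sequence[int] = (0,),
) -> DOEResult:
    """Execute the pipeline for every factor combination.

    ``pipeline(combination, seed) -> response`` runs bucketing,
    normalization, fusion and training for one combination (alignment is
    combination-independent and is expected to have happened already —
    callers close over the aligned dataset and their caches).  A failing
    combination records an NA response with its error message; the DOE
    never aborts.
    """
    grid = expand_design(design)
    rows = []
    for seed in replicate_seeds:
        for _, combo in grid.iterrows():
            combo_dict = combo.to_dict()
            rec = dict(combo_dict)
            rec["seed"] = seed
            try:
                rec["response"] = float(pipeline(combo_dict, int(seed)))
                rec["error"] = ""
            except Exception as exc:  # record, keep going
                rec["response"] = float("nan")
                rec["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(rec)
    responses = pd.DataFrame(rows)
    ok = responses.dropna(subset=["response"])
    factors = [f for f in design.factors if ok[f].nunique() > 1]
    if len(ok) >= 3 and factors:
        anova, tukey = anova_tukey(ok, factors)
    else:
        anova = pd.DataFrame(columns=["factor", "sum_sq", "df", "F", "p"])
        tukey = pd.DataFrame(columns=["factor", "pair", "difference", "p_adj", "reliable"])
    return DOEResult(responses=responses, anova=anova, tukey=tukey,
                     response_name=design.response)
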