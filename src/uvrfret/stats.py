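"""Experiment-level inference for the FRET study design.

The replication unit is the independent experiment (or photobleaching
replicate), not pooled pixels or regions.  The design is a genotype x UV-B
factorial analysed with a fixed-effects two-way ANOVA (Type II sums of
squares, so mildly unbalanced data are handled) followed by Šídák-adjusted
pairwise comparisons of cell means using the residual mean square.

Summary output mirrors the field's figure convention: group mean ± SE with
either significance stars on the within-genotype ±UV contrasts or a compact
letter display over all tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DesignError",
    "AnovaResult",
    "make_table",
    "two_way_anova",
    "default_comparisons",
    "sidak_adjust",
    "sidak_posthoc",
    "compact_letter_display",
    "summarize",
]


class DesignError(ValueError):
    """The factorial design is unusable (empty cells, single level, ...)."""


REQUIRED_COLUMNS = ("experiment", "genotype", "uv", "value")


def make_table(rows, **extra) -> pd.DataFrame:
    """Build a measurement table with columns (experiment, genotype, uv, value)."""
    df = pd.DataFrame(rows, **extra)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"measurement table lacks columns {missing}")
    if not np.isfinite(df["value"]).all():
        raise DesignError("non-finite response values in measurement table")
    return df


def _validate_design(df: pd.DataFrame, factors=("genotype", "uv"),
                     min_reps: int = 2) -> None:
    for f in factors:
        if df[f].nunique() < 2:
            raise DesignError(f"factor {f!r} needs >= 2 levels")
    counts = df.groupby(list(factors), observed=True).size()
    full = pd.MultiIndex.from_product([df[f].unique() for f in factors],
                                      names=list(factors))
    for cell in full:
        n = counts.get(cell, 0)
        if n == 0:
            raise DesignError(f"empty design cell {cell}")
        if n < min_reps:
            raise DesignError(f"design cell {cell} has {n} replicate(s); need >= {min_reps}")


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition with the residual variance needed post hoc."""

    table: pd.DataFrame  # index: genotype, uv, interaction, residual
    ss_total: float
    ms_resid: float
    df_resid: float

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def two_way_anova(df: pd.DataFrame, response: str = "value",
                  factors: tuple[str, str] = ("genotype", "uv")) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction (Type II sums of squares)."""
    _validate_design(df, factors)
    a, b = factors
    data = df.copy()
    data[a] = data[a].astype(str)
    data[b] = data[b].astype(str)
    model = smf.ols(f"{response} ~ C({a}) * C({b})", data=data).fit()
    raw = anova_lm(model, typ=2)
    rename = {
        f"C({a})": a,
        f"C({b})": b,
        f"C({a}):C({b})": "interaction",
        "Residual": "residual",
    }
    table = raw.rename(index=rename)
    table = table.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p_value"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    y = data[response].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if np.allclose(y, y[0]):
        # constant response: every effect SS is 0, F ratios are undefined
        table["sum_sq"] = 0.0
        table["mean_sq"] = 0.0
        table.loc[table.index != "residual", ["F", "p_value"]] = np.nan
        ss_total = 0.0
    ms_resid = float(table.loc["residual", "mean_sq"])
    df_resid = float(table.loc["residual", "df"])
    return AnovaResult(table=table, ss_total=ss_total,
                       ms_resid=ms_resid, df_resid=df_resid)


def default_comparisons(df: pd.DataFrame) -> list[tuple[tuple, tuple]]:
    """The m=6 default Šídák family for the 3-genotype x ±UV design.

    Three within-genotype ±UV pairs plus the three between-genotype pairs in
    the no-UV state — the contrasts conventionally annotated on the bar plots.
    """
    genos = list(pd.unique(df["genotype"]))
    uvs = sorted(pd.unique(df["uv"]), key=str)
    comps: list[tuple[tuple, tuple]] = []
    if len(uvs) == 2:
        for g in genos:
            comps.append(((g, uvs[0]), (g, uvs[1])))
        no_uv = uvs[0]
        for i in range(len(genos)):
            for j in range(i + 1, len(genos)):
                comps.append(((genos[i], no_uv), (genos[j], no_uv)))
    return comps


def sidak_adjust(p_raw, m: int | None = None):
    """Šídák multiple-comparison adjustment ``1 - (1 - p)**m``."""
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("raw p-values must be within [0, 1]")
    if m is None:
        m = p.size
    adj = 1.0 - (1.0 - p) ** m
    return adj if np.ndim(p_raw) else float(adj)


def sidak_posthoc(df: pd.DataFrame, comparisons=None,
                  anova: AnovaResult | None = None,
                  factors: tuple[str, str] = ("genotype", "uv"),
                  response: str = "value") -> pd.DataFrame:
    """Pairwise cell-mean t tests on the ANOVA residual MS, Šídák-adjusted.

    Each comparison is a pair of factor-level tuples ``((g1, uv1), (g2, uv2))``.
    Returns a DataFrame with means, t, raw and adjusted p-values; adjusted
    p is ``1 - (1 - p_raw)**m`` for the family size m, preserving the raw
    ordering.
    """
    if comparisons is None:
        comparisons = default_comparisons(df)
    if len(comparisons) == 0:
        return pd.DataFrame(columns=["cell_a", "cell_b", "diff", "t",
                                     "p_raw", "p_adj"])
    if anova is None:
        anova = two_way_anova(df, response=response, factors=factors)
    a, b = factors
    groups = df.groupby([a, b], observed=True)[response]
    means, counts = groups.mean(), groups.size()
    rows = []
    m = len(comparisons)
    for cell_a, cell_b in comparisons:
        for cell in (cell_a, cell_b):
            if tuple(cell) not in means.index:
                raise DesignError(f"comparison references missing cell {cell}")
        ma, mb = means[tuple(cell_a)], means[tuple(cell_b)]
        na, nb = counts[tuple(cell_a)], counts[tuple(cell_b)]
        se = np.sqrt(anova.ms_resid * (1.0 / na + 1.0 / nb))
        if se == 0:
            t = np.inf if ma != mb else 0.0
            p_raw = 0.0 if ma != mb else 1.0
        else:
            t = (ma - mb) / se
            p_raw = 2.0 * sps.t.sf(abs(t), anova.df_resid)
        rows.append({
            "cell_a": tuple(cell_a), "cell_b": tuple(cell_b),
            "mean_a": ma, "mean_b": mb, "diff": ma - mb,
            "t": t, "df": anova.df_resid,
            "p_raw": p_raw, "p_adj": sidak_adjust(p_raw, m),
        })
    return pd.DataFrame(rows)


def compact_letter_display(groups, posthoc: pd.DataFrame,
                           alpha: float = 0.05) -> dict:
    """Greedy compact letter display from a pairwise adjusted-p table.

    Groups sharing at least one letter are not significantly different at
    ``alpha`` for any tested pair; pairs absent from ``posthoc`` are treated
    as not significantly different.
    """
    groups = [tuple(g) for g in groups]
    sig = set()
    for _, row in posthoc.iterrows():
        if row["p_adj"] < alpha:
            sig.add(frozenset((tuple(row["cell_a"]), tuple(row["cell_b"]))))
    letters: list[set] = []  # each letter = set of mutually compatible groups
    assignment = {g: "" for g in groups}
    for g in groups:
        placed = False
        for letter_set in letters:
            if all(frozenset((g, other)) not in sig for other in letter_set):
                letter_set.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # Drop letter sets wholly contained in another (absorption).
    keep = []
    for i, s in enumerate(letters):
        if not any(i != j and s < other for j, other in enumerate(letters)):
            if s not in keep:
                keep.append(s)
    for i, s in enumerate(keep):
        ch = chr(ord("a") + i)
        for g in s:
            assignment[g] += ch
    return {g: "".join(sorted(v)) for g, v in assignment.items()}


def summarize(df: pd.DataFrame, factors: tuple[str, str] = ("genotype", "uv"),
              response: str = "value", threshold: float = 0.05,
              annotate: str = "stars", comparisons=None) -> pd.DataFrame:
    """Group mean ± SE across experiments with significance annotations.

    ``annotate="stars"`` marks each within-genotype ±UV contrast on the UV
    member of the pair; ``annotate="letters"`` produces a compact letter
    display over the default (or given) comparison family.  Single-experiment
    groups get an SE of NaN with a warning.
    """
    import warnings

    a, b = factors
    g = df.groupby([a, b], observed=True)[response]
    out = g.agg(mean="mean", n="size").reset_index()
    sd = g.std(ddof=1).reset_index(drop=True)
    out["se"] = sd.to_numpy() / np.sqrt(out["n"].to_numpy())
    if (out["n"] < 2).any():
        warnings.warn("groups with a single experiment: SE reported as NaN")
    out["annotation"] = ""
    try:
        ph = sidak_posthoc(df, comparisons=comparisons, factors=factors,
                           response=response)
    except DesignError:
        return out
    if annotate == "stars":
        for _, row in ph.iterrows():
            (g1, u1), (g2, u2) = row["cell_a"], row["cell_b"]
            if g1 == g2 and row["p_adj"] < threshold:
                star = "**" if row["p_adj"] < 0.01 else "*"
                sel = (out[a].astype(str) == str(g1)) & \
                      (out[b].astype(str) == str(max(u1, u2, key=str)))
                out.loc[sel, "annotation"] = star
    elif annotate == "letters":
        cells = list(zip(out[a], out[b]))
        cld = compact_letter_display(cells, ph, alpha=threshold)
        out["annotation"] = [cld.get(c, "") for c in cells]
    else:
        raise ValueError(f"unknown annotation style {annotate!r}")
    return out
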