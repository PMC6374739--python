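"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the kinetic
Monte-Carlo donor simulates competing exponential decay/transfer clocks, and
the ANOVA oracle evaluates the textbook balanced-design partition formulas
directly from group means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def mc_transfer_efficiency(paths, n_trials: int, rng: np.random.Generator,
                           survive_p: float = 1.0) -> float:
    """Kinetic Monte-Carlo transfer efficiency of one donor.

    The donor decays radiatively at unit rate and transfers to acceptor ``i``
    at rate ``o_i = e_i / (1 - e_i)``; each acceptor is present with
    probability ``survive_p`` (bleaching removes it otherwise).  Efficiency is
    the fraction of trials in which some transfer clock fires before decay.
    """
    e = np.asarray(paths, dtype=float)
    if e.size == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        odds = e / (1.0 - e)
        t_tr = rng.exponential(1.0, (n_trials, e.size)) / odds
    present = rng.random((n_trials, e.size)) < survive_p
    t_tr = np.where(present, t_tr, np.inf)
    t_decay = rng.exponential(1.0, n_trials)
    return float(np.mean(t_tr.min(axis=1) < t_decay))


def mc_bleach_percent(paths, completeness: float, n_trials: int,
                      rng: np.random.Generator) -> float:
    """Monte-Carlo percent donor-intensity increase after partial bleaching.

    Donor intensity is proportional to the radiative fraction ``1 - E``; the
    bleach removes each acceptor independently with probability
    ``completeness``.
    """
    pre = 1.0 - mc_transfer_efficiency(paths, n_trials, rng, 1.0)
    post = 1.0 - mc_transfer_efficiency(paths, n_trials, rng,
                                        1.0 - completeness)
    return 100.0 * (post - pre) / pre


def brute_force_two_way_anova(df: pd.DataFrame) -> dict:
    """Balanced two-way ANOVA from the classical partition formulas."""
    a_levels = sorted(df["genotype"].astype(str).unique())
    b_levels = sorted(df["uv"].astype(str).unique())
    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    ns = df.groupby([df["genotype"].astype(str), df["uv"].astype(str)]).size()
    n = int(ns.iloc[0])
    assert (ns == n).all(), "oracle requires a balanced design"
    a_means = {a: df.loc[df["genotype"].astype(str) == a, "value"].mean()
               for a in a_levels}
    b_means = {b: df.loc[df["uv"].astype(str) == b, "value"].mean()
               for b in b_levels}
    cell_means = {
        (a, b): df.loc[(df["genotype"].astype(str) == a)
                       & (df["uv"].astype(str) == b), "value"].mean()
        for a in a_levels for b in b_levels
    }
    I, J = len(a_levels), len(b_levels)
    ss_a = n * J * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n * I * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (cell_means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels for b in b_levels
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_a - ss_b - ss_ab
    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_resid = I * J * (n - 1)
    ms_resid = ss_resid / df_resid
    return {
        "ss": {"genotype": ss_a, "uv": ss_b, "interaction": ss_ab,
               "residual": ss_resid, "total": ss_total},
        "f": {"genotype": (ss_a / df_a) / ms_resid,
              "uv": (ss_b / df_b) / ms_resid,
              "interaction": (ss_ab / df_ab) / ms_resid if df_ab else np.nan},
        "df_resid": df_resid,
    }
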