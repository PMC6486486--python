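"""Per-protein differential statistics across age groups and the filtering gates.

Each protein is tested with a one-way fixed-effects ANOVA over the ordered age
groups of one region, on the normalized scale. Post-hoc power is computed at
the observed effect size from the noncentral F distribution (noncentrality
lambda = N * f^2, with f^2 = eta^2 / (1 - eta^2) and eta^2 = SSB/SST). The
maximum fold change is the largest pairwise ratio of back-transformed group
means, i.e. on the raw intensity scale where "1.2-fold" is meaningful.

A protein is retained when it clears every gate: p <= alpha, max fold change
>= fc_min, post-hoc power >= power_min, and unique peptides >= the minimum.
No multiple-testing correction gates by default; a Benjamini-Hochberg FDR
column is emitted for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable


@dataclass(frozen=True)
class FilterParams:
    alpha: float = 0.05
    fc_min: float = 1.2
    power_min: float = 0.8
    min_unique_peptides: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_min <= 1:
            raise ValueError("fc_min must be > 1")
        if not 0 < self.power_min < 1:
            raise ValueError("power_min must be in (0, 1)")


@dataclass
class ProteinStat:
    """Differential statistics for one protein in one region."""

    protein: str
    region: str
    means: tuple[float, ...]  # normalized scale, young -> old
    raw_means: tuple[float, ...]  # back-transformed scale
    f_statistic: float
    p_value: float
    eta_squared: float
    sst: float
    df: tuple[int, int]
    n_total: int
    unique_peptides: int
    power: float | None = None
    max_fc: float | None = None
    gates_failed: list[str] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        return not self.gates_failed


def anova_by_age(table: AbundanceTable, region: str) -> list[ProteinStat]:
    """One-way ANOVA across the three age groups, vectorized over proteins.

    Degenerate proteins with zero within- and between-group variance get
    F = 0, p = 1 (no evidence of change); zero within-group variance with a
    real between-group effect gives p = 0.
    """
    if not table.normalized:
        raise ValueError("table must be normalized before ANOVA")
    groups = [table.replicate_values(region, age).to_numpy() for age in table.age_order]
    for age, g in zip(table.age_order, groups):
        if g.shape[1] < 2:
            raise ValueError(f"age group {age!r} in region {region!r} has < 2 replicates")
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())
    gmeans = np.column_stack([g.mean(axis=1) for g in groups])
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ssb = (ns * (gmeans - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, m in zip(groups, gmeans.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    sst = ssb + ssw
    df1, df2 = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / df1) / (ssw / df2)
        eta = np.where(sst > 0, ssb / sst, 0.0)
    # degenerate cases
    both_zero = (ssw <= 0) & (ssb <= 1e-300)
    f_stat = np.where(both_zero, 0.0, f_stat)
    p = stats.f.sf(f_stat, df1, df2)
    p = np.where(both_zero, 1.0, p)
    p = np.where(np.isinf(f_stat), 0.0, p)

    means_norm = gmeans
    raw = np.sinh(means_norm) if table.normalized else means_norm
    out = []
    for i, pid in enumerate(table.protein_ids):
        out.append(
            ProteinStat(
                protein=pid,
                region=region,
                means=tuple(float(v) for v in means_norm[i]),
                raw_means=tuple(float(v) for v in raw[i]),
                f_statistic=float(f_stat[i]),
                p_value=float(p[i]),
                eta_squared=float(min(eta[i], 1.0)),
                sst=float(sst[i]),
                df=(df1, df2),
                n_total=n_total,
                unique_peptides=int(table.unique_peptides.loc[pid]),
            )
        )
    return out


def posthoc_power(stat: ProteinStat, alpha: float = 0.05) -> float:
    """Power of the one-way ANOVA at the protein's observed effect size.

    Uses the noncentral F distribution: with eta^2 = 0 the test runs at its
    size (power = alpha); as the noncentrality grows the power tends to 1.
    Zero total variance yields 0 with a warning.
    """
    df1, df2 = stat.df
    eta = stat.eta_squared
    if stat.n_total <= df1 + 1:
        raise ValueError("not enough samples for power computation")
    if stat.sst <= 0:
        warnings.warn(
            f"protein {stat.protein}: zero total variance, power undefined (0)", stacklevel=2
        )
        return 0.0
    f_crit = stats.f.isf(alpha, df1, df2)
    if eta >= 1.0 - 1e-12:
        return 1.0
    lam = stat.n_total * eta / (1.0 - eta)
    if lam == 0:
        return float(alpha)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def max_fold_change(stat: ProteinStat) -> float:
    """Max over unordered age pairs of (larger mean / smaller mean), raw scale."""
    means = np.asarray(stat.raw_means, dtype=float)
    if (means <= 0).any():
        raise ValueError(f"protein {stat.protein}: nonpositive back-transformed mean")
    return float(means.max() / means.min())


def apply_filters(
    stats_list: list[ProteinStat], params: FilterParams = FilterParams()
) -> tuple[list[ProteinStat], list[ProteinStat]]:
    """Partition proteins into (kept, dropped) by the four gates.

    Fills in ``power`` and ``max_fc`` where missing; every dropped protein
    carries the list of gates it failed (subset of
    {"p", "fc", "power", "peptides"}).
    """
    kept, dropped = [], []
    for st in stats_list:
        if st.power is None:
            st.power = posthoc_power(st, params.alpha)
        if st.max_fc is None:
            st.max_fc = max_fold_change(st)
        failed = []
        if st.p_value > params.alpha:
            failed.append("p")
        if st.max_fc < params.fc_min:
            failed.append("fc")
        if st.power < params.power_min:
            failed.append("power")
        if st.unique_peptides < params.min_unique_peptides:
            failed.append("peptides")
        st.gates_failed = failed
        (kept if not failed else dropped).append(st)
    return kept, dropped


def stats_to_frame(stats_list: list[ProteinStat], fdr: bool = True) -> pd.DataFrame:
    """One row per protein with all gate values; optional BH-FDR column
    (informational — never used as a gate)."""
    rows = []
    for st in stats_list:
        rows.append(
            {
                "protein_id": st.protein,
                "region": st.region,
                "mean_young": st.means[0],
                "mean_mid": st.means[1],
                "mean_old": st.means[2],
                "F": st.f_statistic,
                "p_value": st.p_value,
                "eta_squared": st.eta_squared,
                "power": st.power,
                "max_fold_change": st.max_fc,
                "unique_peptides": st.unique_peptides,
                "passes": st.passes,
                "gates_failed": ",".join(st.gates_failed),
            }
        )
    df = pd.DataFrame(rows).set_index("protein_id")
    if fdr and len(df):
        from statsmodels.stats.multitest import multipletests

        df["bh_fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
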