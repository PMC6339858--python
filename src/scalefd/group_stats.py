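"""Group-level statistics on cohort tables of fractal dimensions.

Sensor-wise two-sample t tests with Benjamini-Hochberg FDR control, a mixed
two-way repeated-measures ANOVA (group as between-subjects factor, electrode
as within-subjects factor) with Greenhouse-Geisser sphericity adjustment, and
per-channel Pearson correlations between fractal dimension and a cognitive
covariate.

Fractal dimensions are log-transformed before the group tests because their
sampling distribution is right-skewed; correlations with the covariate use
the untransformed dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "CohortTable",
    "TestResult",
    "RmAnovaResult",
    "log_transform",
    "sensorwise_ttests",
    "bh_fdr",
    "rm_anova",
    "covariate_correlation",
]


@dataclass(frozen=True)
class TestResult:
    """One inferential result: a t, F or r statistic with its p (and q) value.

    ``df`` may be non-integer after a sphericity adjustment.
    """

    statistic: float
    p: float
    effect: str
    df: tuple[float, ...] | float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise InputError(f"p = {self.p} outside [0, 1]")
        if self.q is not None and not (0.0 <= self.q <= 1.0):
            raise InputError(f"q = {self.q} outside [0, 1]")


@dataclass(frozen=True)
class CohortTable:
    """Per-(subject, channel, band) fractal dimensions with subject metadata.

    ``data`` columns: subject, channel, band, D.
    ``meta`` columns: subject, group, covariate.  ``group_order`` fixes which
    group is "A" (first) for the sign convention of the t statistic: positive
    t means group A > group B.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    group_order: tuple[str, str] = None  # type: ignore[assignment]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        need = {"subject", "channel", "band", "D"}
        if not need.issubset(self.data.columns):
            raise InputError(f"data must have columns {sorted(need)}")
        if not {"subject", "group"}.issubset(self.meta.columns):
            raise InputError("meta must have columns subject, group")
        groups = list(pd.unique(self.meta["group"]))
        if len(groups) != 2:
            raise InputError(f"exactly two groups required, got {groups}")
        if self.group_order is None:
            object.__setattr__(self, "group_order", (groups[0], groups[1]))
        # identical channel x band coverage per subject
        cover = self.data.groupby("subject").apply(
            lambda g: frozenset(zip(g["channel"], g["band"])), include_groups=False
        )
        if cover.nunique() != 1:
            raise InputError("all subjects must share identical channel x band coverage")

    @property
    def channels(self) -> list[str]:
        return list(pd.unique(self.data["channel"]))

    @property
    def bands(self) -> list[str]:
        return list(pd.unique(self.data["band"]))

    def band_matrix(self, band: str) -> pd.DataFrame:
        """Wide subject x channel matrix of D for one band, with group labels."""
        sub = self.data[self.data["band"] == band]
        if sub.empty:
            raise InputError(f"band {band!r} absent from table")
        wide = sub.pivot(index="subject", columns="channel", values="D")
        wide = wide[self.channels]  # preserve channel order
        meta = self.meta.set_index("subject").loc[wide.index]
        wide.insert(0, "group", meta["group"])
        if "covariate" in meta:
            wide.insert(1, "covariate", meta["covariate"])
        return wide


def log_transform(table: CohortTable) -> CohortTable:
    """Replace D by its natural log (metadata untouched).

    The operation is marked on the table; applying it twice is an error, as
    is any non-positive dimension.
    """
    if table.log_transformed:
        raise InputError("table is already log-transformed")
    if (table.data["D"] <= 0).any():
        raise InputError("log transform requires all D > 0")
    data = table.data.copy()
    data["D"] = np.log(data["D"])
    return replace(table, data=data, log_transformed=True)


def _group_values(wide: pd.DataFrame, order: tuple[str, str]):
    a = wide[wide["group"] == order[0]]
    b = wide[wide["group"] == order[1]]
    if len(a) < 2 or len(b) < 2:
        raise InputError("need >= 2 subjects per group")
    return a, b


def sensorwise_ttests(
    table: CohortTable, band: str, variant: str = "student"
) -> list[TestResult]:
    """Independent two-tailed t test per channel for one band.

    ``variant='student'`` is the classical pooled-variance test;
    ``variant='welch'`` drops the equal-variance assumption.  Positive t means
    the first group of ``table.group_order`` is larger.
    """
    wide = table.band_matrix(band)
    a, b = _group_values(wide, table.group_order)
    out = []
    for ch in table.channels:
        xa, xb = a[ch].to_numpy(float), b[ch].to_numpy(float)
        if np.var(xa) == 0 and np.var(xb) == 0:
            raise InputError(f"zero variance in both groups at channel {ch!r}")
        res = sstats.ttest_ind(xa, xb, equal_var=(variant == "student"))
        out.append(
            TestResult(
                statistic=float(res.statistic),
                p=float(res.pvalue),
                effect=ch,
                df=float(res.df),
            )
        )
    return out


def bh_fdr(p_values: Sequence[float], q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one comparison family.

    Returns ``(adjusted, reject)``.  The family should contain *all*
    comparisons made together: 16 for sensor-wise tests of one dimension, 48
    for the three band-specific dimensions pooled, 896 for the binned PSD
    grid (56 bins x 16 channels).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return adj, reject


def attach_fdr(results: list[TestResult], q_level: float = 0.05) -> list[TestResult]:
    """Return copies of ``results`` with BH-adjusted q values filled in."""
    adj, _ = bh_fdr([r.p for r in results], q_level)
    return [replace(r, q=float(qv)) for r, qv in zip(results, adj)]


@dataclass(frozen=True)
class RmAnovaResult:
    """Mixed two-way ANOVA summary: group main effect and group x channel
    interaction (Greenhouse-Geisser adjusted), plus the full SS table."""

    group: TestResult
    interaction: TestResult
    epsilon: float
    table: pd.DataFrame = field(repr=False)


def _gg_epsilon(pooled_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-subject covariance matrix.

    ``eps = tr(C S C)^2 / ((b-1) tr((C S C)^2))`` with C the centering matrix;
    bounded by ``1/(b-1) <= eps <= 1``.
    """
    b = pooled_cov.shape[0]
    c = np.eye(b) - np.ones((b, b)) / b
    s = c @ pooled_cov @ c
    num = np.trace(s) ** 2
    den = (b - 1) * np.trace(s @ s)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (b - 1), num / den)))


def rm_anova(table: CohortTable, band: str) -> RmAnovaResult:
    """Mixed repeated-measures ANOVA for one band.

    Group (2 levels) is the between-subjects factor and channel the
    within-subjects factor.  The group x channel interaction's degrees of
    freedom are multiplied by the Greenhouse-Geisser epsilon estimated from
    the pooled within-group covariance of the channel measures.  Requires a
    balanced design (every channel present for every subject).
    """
    wide = table.band_matrix(band)
    chans = table.channels
    y = wide[chans].to_numpy(float)  # subjects x channels
    if np.isnan(y).any():
        raise InputError("unbalanced design: missing channel values")
    groups = wide["group"].to_numpy()
    order = table.group_order
    n_per = np.array([(groups == g).sum() for g in order])
    if np.any(n_per < 2):
        raise InputError("need >= 2 subjects per group")
    n_total, b = y.shape
    a = 2

    gm = y.mean()
    subj_means = y.mean(axis=1)
    chan_means = y.mean(axis=0)
    grp_masks = [groups == g for g in order]
    grp_means = np.array([y[m].mean() for m in grp_masks])
    cell_means = np.vstack([y[m].mean(axis=0) for m in grp_masks])  # a x b

    ss_total = ((y - gm) ** 2).sum()
    ss_between_subj = b * ((subj_means - gm) ** 2).sum()
    ss_group = b * (n_per * (grp_means - gm) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_chan = n_total * ((chan_means - gm) ** 2).sum()
    ss_inter = (
        n_per[:, None] * (cell_means - grp_means[:, None] - chan_means[None, :] + gm) ** 2
    ).sum()
    ss_error = ss_total - ss_between_subj - ss_chan - ss_inter

    df_group, df_subj = a - 1, n_total - a
    df_chan = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (n_total - a) * (b - 1)

    ms = lambda ss, df: ss / df
    f_group = ms(ss_group, df_group) / ms(ss_subj_within, df_subj)
    f_chan = ms(ss_chan, df_chan) / ms(ss_error, df_err)
    f_inter = ms(ss_inter, df_inter) / ms(ss_error, df_err)

    # pooled within-group covariance of the channel measures
    covs = [np.cov(y[m], rowvar=False, ddof=1) for m in grp_masks]
    pooled = sum((n - 1) * c for n, c in zip(n_per, covs)) / (n_total - a)
    eps = _gg_epsilon(np.atleast_2d(pooled))

    p_group = float(sstats.f.sf(f_group, df_group, df_subj))
    p_inter = float(sstats.f.sf(f_inter, eps * df_inter, eps * df_err))

    tab = pd.DataFrame(
        {
            "effect": ["group", "subjects_within", "channel", "group_x_channel", "error"],
            "SS": [ss_group, ss_subj_within, ss_chan, ss_inter, ss_error],
            "df": [df_group, df_subj, df_chan, df_inter, df_err],
            "F": [f_group, np.nan, f_chan, f_inter, np.nan],
        }
    )
    return RmAnovaResult(
        group=TestResult(float(f_group), p_group, effect="group", df=(float(df_group), float(df_subj))),
        interaction=TestResult(
            float(f_inter), p_inter, effect="group_x_channel",
            df=(float(eps * df_inter), float(eps * df_err)),
        ),
        epsilon=eps,
        table=tab,
    )


def covariate_correlation(
    table: CohortTable, band: str, group: str | None = None
) -> list[TestResult]:
    """Pearson correlation of D with the covariate, per channel, in one group.

    Defaults to the second group of ``group_order`` (the clinical group in the
    emulated design).  Uses untransformed dimensions by convention; pass a
    transformed table explicitly if log-D correlations are wanted.
    """
    if "covariate" not in table.meta.columns:
        raise InputError("table has no covariate column")
    group = table.group_order[1] if group is None else group
    wide = table.band_matrix(band)
    sub = wide[wide["group"] == group]
    if len(sub) < 3:
        raise InputError("need >= 3 subjects for a correlation")
    cov = sub["covariate"].to_numpy(float)
    if np.var(cov) == 0:
        raise InputError("constant covariate")
    out = []
    for ch in table.channels:
        r, p = sstats.pearsonr(sub[ch].to_numpy(float), cov)
        out.append(TestResult(float(r), float(p), effect=ch, df=float(len(sub) - 2)))
    return out
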