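"""Methylation statistics: beta/M values, detection p-values, DMP calling.

The beta value is ``M / (M + U + 100)`` after a negative-control background
subtraction; detection p-values are empirical ranks of total intensity in
the negative-control distribution. Differential methylation uses per-probe
two-group least squares on M-values with empirical-Bayes variance
moderation: a scaled inverse-chi-square prior is fitted to the residual
variances by method of moments on the log scale, residual variances are
shrunk towards the prior, and moderated t statistics are referred to a t
distribution with augmented degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import IntegrityError

__all__ = [
    "BetaMatrix",
    "DmpResult",
    "AgreementSummary",
    "compute_beta",
    "beta_to_m",
    "m_to_beta",
    "fit_variance_prior",
    "call_dmps",
    "dmp_agreement",
    "distribution_summary",
    "platform_correlation",
]

BETA_OFFSET = 100.0
M_CAP = (0.01, 0.99)


@dataclass
class BetaMatrix:
    """Probe x sample beta values with per-cell detection p-values."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    meth: pd.DataFrame | None = None
    unmeth: pd.DataFrame | None = None


@dataclass
class AgreementSummary:
    n_dmps_a: int
    n_dmps_b: int
    n_a_probes_on_b: int
    n_confirmed_at_primary_threshold: int
    n_confirmed_at_relaxed_threshold: int
    spearman_rho: float


#: Row shape of the frame returned by :func:`call_dmps`.
DmpResult = ["probe_id", "delta_beta", "moderated_t", "p_value", "is_dmp"]


def compute_beta(
    meth: pd.DataFrame,
    unmeth: pd.DataFrame,
    control_meth: pd.DataFrame | None = None,
    control_unmeth: pd.DataFrame | None = None,
    background_percentile: float = 50.0,
    offset: float = BETA_OFFSET,
) -> BetaMatrix:
    """Background-correct intensities and compute beta values.

    The per-sample background is the given percentile of the pooled
    negative-control intensities (methylated and unmethylated channels
    together); it is subtracted from both channels, flooring at zero.
    Detection p is the one-sided empirical rank of the probe's raw total
    intensity within the control total-intensity distribution, with the
    smallest attainable value ``1 / (n_controls + 1)``.
    """
    if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
        raise IntegrityError("methylated/unmethylated matrices are not aligned")
    if (meth.to_numpy() < 0).any() or (unmeth.to_numpy() < 0).any():
        raise IntegrityError("negative raw intensities")
    have_controls = control_meth is not None and control_unmeth is not None
    if have_controls:
        background = pd.Series(
            {
                s: np.percentile(
                    np.concatenate(
                        [control_meth[s].to_numpy(), control_unmeth[s].to_numpy()]
                    ),
                    background_percentile,
                )
                for s in meth.columns
            }
        )
    else:
        background = pd.Series(0.0, index=meth.columns)
    m_corr = (meth - background).clip(lower=0.0)
    u_corr = (unmeth - background).clip(lower=0.0)
    beta = m_corr / (m_corr + u_corr + offset)
    detection_p = None
    if have_controls:
        totals = (meth + unmeth).to_numpy()
        dp = np.empty_like(totals, dtype=float)
        for j, s in enumerate(meth.columns):
            ctrl = np.sort(
                control_meth[s].to_numpy() + control_unmeth[s].to_numpy()
            )
            n = ctrl.size
            # controls with total >= probe total
            ge = n - np.searchsorted(ctrl, totals[:, j], side="left")
            dp[:, j] = (1.0 + ge) / (n + 1.0)
        detection_p = pd.DataFrame(dp, index=meth.index, columns=meth.columns)
    return BetaMatrix(beta=beta, detection_p=detection_p, meth=meth, unmeth=unmeth)


def beta_to_m(beta, cap: tuple[float, float] = M_CAP):
    """Logit-2 transform with beta clamped to ``cap`` to avoid infinities."""
    b = np.clip(np.asarray(beta, dtype=float), cap[0], cap[1])
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    m_arr = np.asarray(m, dtype=float)
    return 2.0**m_arr / (1.0 + 2.0**m_arr)


def _trigamma_inverse(x: np.ndarray, iterations: int = 60) -> np.ndarray:
    """Newton solve of ``trigamma(y) = x`` (monotone decreasing)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(iterations):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif)) < 1e-12:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior.

    Works on ``log(s2)`` whose mean and excess variance (beyond the
    chi-square sampling noise ``trigamma(df/2)``) identify the prior
    degrees of freedom ``d0`` and scale ``s0^2``. Returns
    ``(inf, exp(mean))`` when the observed spread is at or below the
    sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.var(e, ddof=0) * n / (n - 1.0)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = float(_trigamma_inverse(np.array([e_var]))[0])
    d0 = 2.0 * half_d0
    s0_sq = float(
        np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0))
    )
    return d0, s0_sq


def call_dmps(
    beta: pd.DataFrame,
    groups,
    p_thresh: float = 1e-3,
    db_thresh: float = 0.1,
    detection_p: pd.DataFrame | None = None,
    detection_thresh: float = 0.01,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group differential methylation with moderated t statistics.

    ``groups`` maps sample name to one of two labels. Probes failing the
    detection filter in any sample are dropped before testing (when
    ``detection_p`` is given). ``prior_df`` overrides the estimated prior
    degrees of freedom; 0 reproduces the ordinary t-test.

    Returns a frame indexed by probe id with ``delta_beta`` (mean of the
    second label group minus the first, labels sorted), ``moderated_t``,
    ``p_value`` and ``is_dmp``.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.reindex(beta.columns)
    if groups.isna().any():
        raise IntegrityError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise IntegrityError(f"exactly two groups required, got {labels}")
    cols_a = beta.columns[groups == labels[0]]
    cols_b = beta.columns[groups == labels[1]]
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise IntegrityError("each group needs >= 2 samples (no residual df)")
    kept = beta
    if detection_p is not None:
        mask = (detection_p < detection_thresh).all(axis=1)
        kept = beta.loc[mask]
    m = beta_to_m(kept)
    ma = m[cols_a].to_numpy()
    mb = m[cols_b].to_numpy()
    mean_a, mean_b = ma.mean(axis=1), mb.mean(axis=1)
    rss = ((ma - mean_a[:, None]) ** 2).sum(axis=1) + (
        (mb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = rss / df_resid
    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb.mean(axis=1) - ma.mean(axis=1)) / se
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    delta_beta = (
        kept[cols_b].mean(axis=1) - kept[cols_a].mean(axis=1)
    ).to_numpy()
    out = pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "moderated_t": t,
            "p_value": p,
            "is_dmp": (p < p_thresh) & (np.abs(delta_beta) > db_thresh),
        },
        index=kept.index,
    )
    out.index.name = "probe_id"
    out.attrs["prior_df"] = d0
    out.attrs["prior_s2"] = s0_sq
    return out


def dmp_agreement(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    relaxed_p: float = 0.01,
    db_thresh: float = 0.1,
) -> AgreementSummary:
    """Cross-platform confirmation of platform-a DMPs on platform b.

    Confirmation at the relaxed threshold re-tests platform-b p-values at
    ``relaxed_p`` (keeping the delta-beta criterion). The Spearman rho is
    computed on delta-beta over platform-a DMPs present on platform b.
    """
    shared = results_a.index.intersection(results_b.index)
    if len(shared) == 0:
        raise IntegrityError("probe universes are disjoint")
    a_dmps = results_a.index[results_a["is_dmp"]]
    b_dmps = results_b.index[results_b["is_dmp"]]
    a_on_b = a_dmps.intersection(results_b.index)
    confirmed = a_on_b.intersection(b_dmps)
    relaxed_mask = (results_b.loc[a_on_b, "p_value"] < relaxed_p) & (
        results_b.loc[a_on_b, "delta_beta"].abs() > db_thresh
    )
    if len(a_on_b) >= 2:
        rho = float(
            stats.spearmanr(
                results_a.loc[a_on_b, "delta_beta"],
                results_b.loc[a_on_b, "delta_beta"],
            ).statistic
        )
    else:
        rho = float("nan")
    return AgreementSummary(
        n_dmps_a=int(len(a_dmps)),
        n_dmps_b=int(len(b_dmps)),
        n_a_probes_on_b=int(len(a_on_b)),
        n_confirmed_at_primary_threshold=int(len(confirmed)),
        n_confirmed_at_relaxed_threshold=int(relaxed_mask.sum()),
        spearman_rho=rho,
    )


def distribution_summary(
    beta: pd.DataFrame,
    probe_subsets: dict[str, pd.Index] | None = None,
    bin_width: float = 0.02,
) -> pd.DataFrame:
    """Histogram densities of beta per sample per probe subset.

    Bins are a fixed grid on [0, 1]; densities integrate to 1. Empty
    subsets produce no rows and a warning.
    """
    import warnings

    if probe_subsets is None:
        probe_subsets = {"all": beta.index}
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    rows = []
    for name, ids in probe_subsets.items():
        ids = beta.index.intersection(pd.Index(ids))
        if len(ids) == 0:
            warnings.warn(f"probe subset {name!r} is empty")
            continue
        sub = beta.loc[ids]
        for sample in beta.columns:
            vals = sub[sample].dropna().to_numpy()
            dens, _ = np.histogram(vals, bins=edges, density=True)
            for left, d in zip(edges[:-1], dens):
                rows.append(
                    {
                        "subset": name,
                        "sample": sample,
                        "bin_left": round(float(left), 10),
                        "density": float(d),
                    }
                )
    return pd.DataFrame(rows, columns=["subset", "sample", "bin_left", "density"])


def platform_correlation(
    beta_a: pd.DataFrame,
    beta_b: pd.DataFrame,
    pairing: list[tuple[str, str]],
) -> pd.Series:
    """Spearman rho per paired sample over shared, pairwise-unmasked probes."""
    shared = beta_a.index.intersection(beta_b.index)
    out = {}
    for sa, sb in pairing:
        x = beta_a.loc[shared, sa]
        y = beta_b.loc[shared, sb]
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise IntegrityError(
                f"fewer than 3 shared unmasked probes for pair ({sa}, {sb})"
            )
        out[(sa, sb)] = float(stats.spearmanr(x[ok], y[ok]).statistic)
    return pd.Series(out, name="spearman_rho")
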