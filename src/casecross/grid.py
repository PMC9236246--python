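"""Enumeration and execution of the full model array.

The analysis runs one conditional quasi-Poisson model per combination of
exposure metric (5 pollutants + O3H8 + 2 composite indices = 8), single-day
lag (0-14) and analysis stratum (18), i.e. 2,160 models per outcome block.
Each model regresses the stratum's daily counts on one lagged exposure with
natural-spline temperature and humidity adjustment, conditioning on the
year x month x day-of-week cluster totals.

Results are summarized as association-count arrays — how many models per
stratum/exposure/lag cell reached a significant positive association
(lower 95% CI above 1 at the exposure's IQR increment).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design as dz
from .conditional import DesignMatrix, NonIdentifiableError, fit, rr_from_fit
from .design import StratumSpec, WHOLE_CHAPTER, attach_lags, get_count_series, season_labels
from .exposure import EXPOSURE_COLUMNS, compute_iqr
from .splines import natural_spline_basis

log = logging.getLogger(__name__)

LAGS = tuple(range(15))


@dataclass(frozen=True)
class ModelSpec:
    exposure: str
    lag: int
    stratum: StratumSpec
    block: str = WHOLE_CHAPTER

    def __post_init__(self):
        if self.exposure not in EXPOSURE_COLUMNS:
            raise ValueError(
                f"unknown exposure {self.exposure!r}; expected one of {EXPOSURE_COLUMNS}"
            )
        if self.lag not in LAGS:
            raise ValueError(f"lag must be in 0..14, got {self.lag}")


def enumerate_models(
    exposures=EXPOSURE_COLUMNS,
    lags=LAGS,
    strata=None,
    blocks=(WHOLE_CHAPTER,),
) -> list[ModelSpec]:
    """Full model cross-product in deterministic (exposure, lag, stratum) order.

    With the defaults this yields 8 x 15 x 18 = 2,160 specs per outcome
    block.
    """
    if strata is None:
        strata = dz.enumerate_strata()
    strata = list(strata)
    specs = [
        ModelSpec(exposure=e, lag=l, stratum=s, block=b)
        for b in blocks
        for e, l, s in itertools.product(exposures, lags, strata)
    ]
    return specs


def _fit_one(spec: ModelSpec, counts, daily, iqr, level=0.95):
    """Fit one model spec; returns a result row dict (never raises)."""
    row = {
        "exposure": spec.exposure,
        "lag": spec.lag,
        "stratum": spec.stratum.label,
        "block": spec.block,
        "converged": False,
        "beta": np.nan,
        "se": np.nan,
        "dispersion": np.nan,
        "rr": np.nan,
        "rr_lower": np.nan,
        "rr_upper": np.nan,
        "iqr": iqr,
        "n_days": 0,
        "n_clusters": 0,
        "significant_positive": False,
        "error": "",
    }
    try:
        series = get_count_series(counts, spec.stratum, spec.block)
        if spec.stratum.season != "all":
            seasons = season_labels(series.index)
            series = series[(seasons == spec.stratum.season).to_numpy()]
        frame = attach_lags(series, daily, spec.exposure, spec.lag)
        clusters = dz.build_clusters(frame.index.min(), frame.index.max())
        cl = clusters.cluster_ids(frame.index)
        # spline bases from this fitted subset's covariate quantiles
        bt = natural_spline_basis(frame["temperature"].to_numpy(), df=3)
        bh = natural_spline_basis(frame["humidity"].to_numpy(), df=3)
        X = np.column_stack([frame["x"].to_numpy(), bt.matrix, bh.matrix])
        names = ("x",) + tuple(f"temp_ns{i}" for i in (1, 2, 3)) + tuple(
            f"rh_ns{i}" for i in (1, 2, 3)
        )
        dm = DesignMatrix(X=X, y=frame["count"].to_numpy(), cluster=cl, names=names)
        res = fit(dm)
        row.update(
            converged=res.converged,
            beta=res.coef(),
            se=res.stderr(),
            dispersion=res.dispersion,
            n_days=res.n_days,
            n_clusters=res.n_clusters,
        )
        if res.converged and iqr > 0:
            rr = rr_from_fit(res, delta=iqr, level=level)
            row.update(
                rr=rr.rr,
                rr_lower=rr.lower,
                rr_upper=rr.upper,
                significant_positive=rr.significant_positive,
            )
    except (NonIdentifiableError, ValueError, KeyError, np.linalg.LinAlgError) as exc:
        row["error"] = f"{type(exc).__name__}: {exc}"
        log.warning("model %s lag %s %s failed: %s", spec.exposure, spec.lag,
                    spec.stratum.label, exc)
    return row


def run_grid(
    specs,
    counts: pd.DataFrame,
    daily: pd.DataFrame,
    level: float = 0.95,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Run every model spec; one result row per spec, failures kept.

    Parameters
    ----------
    specs : sequence of ModelSpec
    counts : long count table from :func:`casecross.design.build_counts`
    daily : date-indexed exposure + weather table
    bh_adjust : bool
        If true, append a Benjamini-Hochberg adjusted p-value column
        (``p_bh``) over the grid's converged models. Off by default — the
        primary analysis, like common practice in this literature, reports
        unadjusted per-model tests.

    RR scaling uses each exposure's IQR computed from the all-days series
    (the study-period IQR), not per-stratum.
    """
    iqrs = {
        e: compute_iqr(daily[e]) for e in {s.exposure for s in specs} if e in daily
    }
    rows = [
        _fit_one(spec, counts, daily, iqrs.get(spec.exposure, np.nan), level=level)
        for spec in specs
    ]
    out = pd.DataFrame(rows)
    if not out.empty:
        from scipy import stats

        z = out["beta"] / out["se"]
        out["p_value"] = 2 * stats.norm.sf(np.abs(z))
        if bh_adjust:
            from statsmodels.stats.multitest import multipletests

            out["p_bh"] = np.nan
            ok = out["p_value"].notna()
            if ok.any():
                out.loc[ok, "p_bh"] = multipletests(
                    out.loc[ok, "p_value"], method="fdr_bh"
                )[1]
    return out


@dataclass
class AssociationArray:
    """Counts of significant positive associations in three arrangements."""

    by_stratum_exposure: pd.DataFrame
    by_exposure_lag: pd.DataFrame
    by_stratum_lag: pd.DataFrame
    total: int


def significance_counts(results: pd.DataFrame) -> AssociationArray:
    """Aggregate flagged models into strata x exposures, exposures x lags and
    strata x lags count arrays; each arrangement's cells sum to the number
    of flagged results."""
    flagged = results["significant_positive"].fillna(False).astype(bool)
    r = results.assign(flag=flagged.astype(int))

    def pivot(rows, cols):
        return (
            r.pivot_table(index=rows, columns=cols, values="flag", aggfunc="sum", fill_value=0)
            .astype(int)
        )

    return AssociationArray(
        by_stratum_exposure=pivot("stratum", "exposure"),
        by_exposure_lag=pivot("exposure", "lag"),
        by_stratum_lag=pivot("stratum", "lag"),
        total=int(flagged.sum()),
    )


def plot_association_heatmap(array: pd.DataFrame, ax=None, **kwargs):
    """Render one association-count arrangement as a heatmap (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * array.shape[1] + 2, 0.4 * array.shape[0] + 1))
    im = ax.imshow(array.to_numpy(), cmap=kwargs.pop("cmap", "Greens"), **kwargs)
    ax.set_xticks(range(array.shape[1]), array.columns, rotation=90)
    ax.set_yticks(range(array.shape[0]), array.index)
    for (i, j), v in np.ndenumerate(array.to_numpy()):
        ax.text(j, i, str(v), ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
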