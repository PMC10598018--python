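"""Summary tables aggregating coupling maps by functional systems.

All functions here are pure: identical inputs give identical outputs, and
every table round-trips through the text writers in :mod:`eigencoupling.io`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .coupling import CouplingMap, pearson_r
from .nulls import NullEnsemble, z_from_null

__all__ = [
    "aggregate_by_network",
    "well_predicted_distribution",
    "network_z_map",
    "intersubject_variability",
    "one_way_anova",
]

logger = logging.getLogger(__name__)


def _check_labels(labels, n: int) -> np.ndarray:
    labels = np.asarray([str(x) for x in labels])
    if labels.size != n:
        raise ValueError(f"expected {n} labels, got {labels.size}")
    return labels


def aggregate_by_network(coupling: CouplingMap, labels) -> pd.DataFrame:
    """Descriptive statistics of coupling R per network.

    Median, interquartile range, and min-max match the usual boxplot
    definition; member counts sum to the region count.
    """
    labels = _check_labels(labels, len(coupling))
    R = coupling.R
    rows = []
    for net in sorted(set(labels)):
        vals = R[labels == net]
        if vals.size == 0:
            raise ValueError(f"network {net!r} has no members")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({
            "network": net,
            "n_members": int(vals.size),
            "mean_R": float(vals.mean()),
            "median_R": float(med),
            "iqr_low": float(q1),
            "iqr_high": float(q3),
            "min_R": float(vals.min()),
            "max_R": float(vals.max()),
        })
    table = pd.DataFrame(rows).set_index("network")
    assert table["n_members"].sum() == len(coupling)
    return table


def well_predicted_distribution(coupling: CouplingMap, labels) -> pd.DataFrame:
    """Share of well-predicted regions per network vs. network-size share.

    A region is well predicted when its R is strictly above the grand mean
    (unweighted over regions). Each share column sums to 1; if no region
    exceeds the mean the well-predicted shares are NaN and a warning is
    logged.
    """
    labels = _check_labels(labels, len(coupling))
    R = coupling.R
    threshold = R.mean()
    well = R > threshold
    n_well = int(well.sum())
    networks = sorted(set(labels))
    rows = []
    for net in networks:
        mask = labels == net
        rows.append({
            "network": net,
            "well_predicted_share": (well & mask).sum() / n_well if n_well else np.nan,
            "network_size_share": mask.sum() / R.size,
            "n_well_predicted": int((well & mask).sum()),
            "n_members": int(mask.sum()),
        })
    if n_well == 0:
        logger.warning("well_predicted_distribution: no region exceeds the grand mean")
    return pd.DataFrame(rows).set_index("network")


def network_z_map(
    coupling: CouplingMap, labels, network_nulls: dict[str, NullEnsemble]
) -> np.ndarray:
    """Per-region z of coupling R against its own network's null ensemble."""
    labels = _check_labels(labels, len(coupling))
    missing = set(labels) - set(network_nulls)
    if missing:
        raise ValueError(f"no null ensemble for network(s): {sorted(missing)}")
    return np.array([
        z_from_null(r, network_nulls[lab]) for r, lab in zip(coupling.R, labels)
    ])


def intersubject_variability(R_matrix: np.ndarray) -> dict:
    """Per-region spread of coupling across subjects.

    Returns standard deviation and coefficient of variation maps plus their
    Pearson correlations with the mean map (the floor-effect diagnostics).
    CV is NaN (flagged) where the mean is not positive.
    """
    R = np.asarray(R_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("R_matrix must be subjects x regions with >= 2 subjects")
    mean = R.mean(axis=0)
    sd = R.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    if np.any(mean <= 0):
        logger.warning("intersubject_variability: %d regions have non-positive mean R",
                       int((mean <= 0).sum()))
    finite_cv = np.isfinite(cv)

    def _safe_corr(x, y):
        try:
            return pearson_r(x, y)
        except ValueError:
            return np.nan

    return {
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "corr_sd_mean": _safe_corr(sd, mean),
        "corr_cv_mean": (
            _safe_corr(cv[finite_cv], mean[finite_cv]) if finite_cv.sum() > 2 else np.nan
        ),
    }


def one_way_anova(R_matrix: np.ndarray) -> dict:
    """One-way ANOVA with region as the factor and subjects as replicates.

    Computed from explicit sums of squares; F follows an F(df_between,
    df_within) distribution under the null of equal region means. A zero
    within-group variance with nonzero between-group variance is flagged by
    an infinite F.
    """
    from scipy import stats

    R = np.asarray(R_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("R_matrix must be subjects x regions, both >= 2")
    n_subj, n_reg = R.shape
    grand = R.mean()
    group_means = R.mean(axis=0)
    ss_between = n_subj * float(((group_means - grand) ** 2).sum())
    ss_within = float(((R - group_means) ** 2).sum())
    df_between = n_reg - 1
    df_within = n_reg * (n_subj - 1)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        F = 0.0 if ms_between == 0 else np.inf
        p = 1.0 if ms_between == 0 else 0.0
    else:
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_between, df_within))
    return {
        "F": float(F),
        "df_between": df_between,
        "df_within": df_within,
        "p": p,
        "ss_between": ss_between,
        "ss_within": ss_within,
    }
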