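"""Group comparison with lobar repeated measures, FDR and dose-response.

Responder vs non-responder differences in normalized connectivity are
tested per band with a linear mixed-effects model: the observation unit
is a subject's mean connection z-score within each lobar region (lobe x
hemisphere), the group is a fixed effect, and a per-subject random
intercept absorbs the within-subject correlation across regions.  P-values
are adjusted across the five frequency bands with the Benjamini-Hochberg
step-up procedure (5% FDR family).  The continuous association between a
connectivity feature and percent seizure reduction is quantified by the
Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .features import NormalizedFC, _pair_mask
from .parcellation import Parcellation

__all__ = [
    "lobar_mean_table",
    "group_compare",
    "fdr_adjust",
    "spearman_association",
    "subset_analysis",
]


def lobar_mean_table(
    nfcs: Sequence[NormalizedFC],
    group_by_id: Mapping[str, str],
    parcellation: Parcellation,
) -> pd.DataFrame:
    """Repeated-measures table: one row per subject x lobar region x band.

    ``group_by_id`` maps subject_id -> "R" | "NR".  The z value is the
    mean connection z-score within the region (both endpoints inside it).
    """
    regions = []
    for lobe in parcellation.lobes:
        for h in ("L", "R"):
            members = set(parcellation.modules_in(lobe=lobe, hemisphere=h))
            if members:
                regions.append((f"{lobe}_{h}", members))
    rows = []
    for nfc in nfcs:
        if nfc.subject_id not in group_by_id:
            continue
        masks = {name: _pair_mask(nfc.pairs, members, "both_endpoint")
                 for name, members in regions}
        for band, z in nfc.z.items():
            for name, mask in masks.items():
                if not mask.any():
                    continue
                rows.append(
                    {
                        "subject_id": nfc.subject_id,
                        "group": group_by_id[nfc.subject_id],
                        "lobe": name,
                        "band": band,
                        "z": float(z[mask].mean()),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Result of one band's responder vs non-responder comparison."""

    p_value: float
    ls_means: dict[str, tuple[float, float, float]]  # group -> (est, lo, hi)
    method: str  # "mixed_lm" | "ttest_fallback"


def _mixedlm_band(df: pd.DataFrame, random_slope_lobe: bool) -> GroupComparison:
    df = df.copy()
    df["grp"] = (df["group"] == "R").astype(float)
    re_formula = "~lobe" if random_slope_lobe else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("z ~ grp", df, groups=df["subject_id"],
                            re_formula=re_formula)
        fit = model.fit(reml=True)
    p = float(fit.pvalues["grp"])
    if not np.isfinite(p):
        raise np.linalg.LinAlgError("singular mixed-model fit")
    b0, b1 = float(fit.params["Intercept"]), float(fit.params["grp"])
    cov = fit.cov_params().loc[["Intercept", "grp"], ["Intercept", "grp"]].to_numpy()
    zcrit = sps.norm.ppf(0.975)
    se_nr = np.sqrt(cov[0, 0])
    se_r = np.sqrt(cov.sum())
    ls = {
        "NR": (b0, b0 - zcrit * se_nr, b0 + zcrit * se_nr),
        "R": (b0 + b1, b0 + b1 - zcrit * se_r, b0 + b1 + zcrit * se_r),
    }
    return GroupComparison(p_value=p, ls_means=ls, method="mixed_lm")


def _ttest_fallback(df: pd.DataFrame) -> GroupComparison:
    means = df.groupby(["subject_id", "group"], observed=True)["z"].mean().reset_index()
    ls = {}
    for g in ("NR", "R"):
        v = means.loc[means["group"] == g, "z"].to_numpy()
        m, se = v.mean(), v.std(ddof=1) / np.sqrt(len(v))
        tcrit = sps.t.ppf(0.975, len(v) - 1)
        ls[g] = (float(m), float(m - tcrit * se), float(m + tcrit * se))
    r = means.loc[means["group"] == "R", "z"]
    nr = means.loc[means["group"] == "NR", "z"]
    p = float(sps.ttest_ind(r, nr, equal_var=False).pvalue)
    return GroupComparison(p_value=p, ls_means=ls, method="ttest_fallback")


def group_compare(
    table: pd.DataFrame, random_slope_lobe: bool = False
) -> dict[str, GroupComparison]:
    """Per-band mixed-effects group comparison on the lobar table.

    Falls back (flagged via ``method``) to a Welch t-test on subject-level
    means when the mixed model is singular.
    """
    for g in ("R", "NR"):
        if table.loc[table["group"] == g, "subject_id"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    if table["lobe"].nunique() < 2:
        raise ValueError("need >= 2 lobar regions for a repeated-measures model")
    out: dict[str, GroupComparison] = {}
    for band, df in table.groupby("band", sort=False, observed=True):
        try:
            out[band] = _mixedlm_band(df, random_slope_lobe)
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn(
                f"mixed model singular for band {band!r}; falling back to a "
                "subject-level Welch t-test",
                stacklevel=2,
            )
            out[band] = _ttest_fallback(df)
    return out


def fdr_adjust(pvals: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    keys = list(pvals)
    arr = np.asarray([pvals[k] for k in keys], dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError(f"p-values must lie in [0, 1], got {arr.tolist()}")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    return dict(zip(keys, adjusted.astype(float)))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rhos = []
    for perm in itertools.permutations(range(len(ry))):
        rhos.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
    rhos = np.asarray(rhos)
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_association(
    feature: np.ndarray, reductions: np.ndarray, exact: bool = False
) -> tuple[float, float]:
    """Spearman rank correlation between a feature and percent reduction.

    Ties get average ranks; the p-value uses the t approximation, or the
    exact permutation distribution when ``exact`` is set (n <= 10 only).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(reductions, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if exact:
        if x.size > 10:
            raise ValueError("exact permutation p-value supported only for n <= 10")
        return rho, _exact_spearman_p(x, y, rho)
    return rho, float(res.pvalue)


SUBSET_FILTERS = ("all", "no_resection", "intention_to_treat")


def subset_analysis(
    nfcs: Sequence[NormalizedFC],
    outcomes: Sequence,
    parcellation: Parcellation,
    which: str = "all",
    band: str = "alpha",
) -> dict:
    """Re-run the group comparison and dose-response on a cohort subset.

    ``which`` selects patients: ``all`` (stimulation enabled, the primary
    cohort), ``no_resection`` (drops concurrent resective surgery) or
    ``intention_to_treat`` (every implanted patient regardless of
    stimulation status).
    """
    if which not in SUBSET_FILTERS:
        raise ValueError(f"filter must be one of {SUBSET_FILTERS}, got {which!r}")
    if which == "all":
        keep = [o for o in outcomes if o.stim_enabled]
    elif which == "no_resection":
        keep = [o for o in outcomes if o.stim_enabled and not o.concurrent_resection]
    else:
        keep = list(outcomes)
    ids = {o.subject_id for o in keep}
    groups = {o.subject_id: ("R" if o.responder else "NR") for o in keep}
    if len(set(groups.values())) < 2:
        raise ValueError(f"subset {which!r} lost a response class")
    sub_nfcs = [n for n in nfcs if n.subject_id in ids]
    table = lobar_mean_table(sub_nfcs, groups, parcellation)
    comparisons = group_compare(table)
    by_id = {n.subject_id: n for n in sub_nfcs}
    feat = np.array([by_id[o.subject_id].z[band].mean() for o in keep])
    red = np.array([o.percent_reduction for o in keep])
    rho, p = spearman_association(feat, red)
    return {
        "filter": which,
        "n": len(keep),
        "n_responders": sum(o.responder for o in keep),
        "n_nonresponders": sum(not o.responder for o in keep),
        "group_compare": comparisons,
        "fdr": fdr_adjust({b: c.p_value for b, c in comparisons.items()}),
        "spearman": {"band": band, "rho": rho, "p": p},
    }
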