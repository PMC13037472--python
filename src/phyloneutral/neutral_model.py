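"""Occupancy-abundance neutral model: predicted occurrence curve, least-squares
fit of the dispersal parameter mN, and exact-binomial selection classification.

The occupancy curve is the beta approximation for large local communities: a
taxon with metacommunity relative abundance p has local relative abundance
Beta(mN*p, mN*(1-p)), and its predicted occurrence is the probability that
this abundance exceeds the detection limit d. Taxa whose observed occupancy
deviates from the fitted curve (two-tailed exact binomial test on N hosts at
success probability F_fit) are labelled ecologically selected (above the
curve) or not ecologically selected (below); everything else is neutral.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import FeatureTable, SampleMetadata

__all__ = [
    "NCMFit",
    "SelectionClassification",
    "predicted_occurrence",
    "fit_ncm",
    "fit_ncm_per_group",
    "classify_selection",
    "exact_binomial_pvalue",
    "CATEGORY_SELECTED",
    "CATEGORY_NEUTRAL",
    "CATEGORY_NOT_SELECTED",
]

CATEGORY_SELECTED = "ecologically_selected"
CATEGORY_NEUTRAL = "neutral"
CATEGORY_NOT_SELECTED = "not_ecologically_selected"

_MN_BOUNDS = (1e-6, 1e7)


def predicted_occurrence(p, mN: float, d: float):
    """Probability that a Beta(mN*p, mN*(1-p)) local abundance exceeds the
    detection limit d. Accepts scalar or array p; F(0)=0 and F(1)=1 by
    continuity."""
    if mN <= 0:
        raise ValueError(f"mN must be positive, got {mN}")
    if not 0 < d < 1:
        raise ValueError(f"detection limit must be in (0,1), got {d}")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("relative abundance p must be in [0,1]")
    with np.errstate(invalid="ignore"):
        out = stats.beta.sf(d, mN * p_arr, mN * (1.0 - p_arr))
    out = np.where(p_arr == 0.0, 0.0, out)
    out = np.where(p_arr == 1.0, 1.0, out)
    if np.isscalar(p) or p_arr.ndim == 0:
        return float(out)
    return out


@dataclasses.dataclass
class NCMFit:
    mN: float
    detection_limit: float
    n_hosts: int
    taxon_ids: list[str]
    p: np.ndarray  # mean relative abundance per taxon
    f_obs: np.ndarray  # observed occupancy fraction
    f_fit: np.ndarray  # predicted occurrence at fitted mN
    k: np.ndarray  # hosts where detected (int)
    r_squared: float
    sse: float
    bound_hit: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "p": self.p,
                "f_obs": self.f_obs,
                "f_fit": self.f_fit,
                "k": self.k,
            }
        )

    def summary(self) -> dict:
        return {
            "mN": self.mN,
            "detection_limit": self.detection_limit,
            "n_hosts": self.n_hosts,
            "n_taxa": len(self.taxon_ids),
            "r_squared": self.r_squared,
            "sse": self.sse,
            "bound_hit": self.bound_hit,
        }


def fit_mn_curve(p: np.ndarray, f_obs: np.ndarray, d: float) -> tuple[float, float]:
    """Least-squares mN for given (abundance, occupancy) pairs.

    A coarse log-spaced SSE scan brackets the optimum before bounded
    refinement: the SSE surface flattens for huge mN, which can strand a
    plain bracketing search far from the minimum.
    """

    def sse(mN: float) -> float:
        return float(np.sum((f_obs - predicted_occurrence(p, mN, d)) ** 2))

    grid = np.geomspace(_MN_BOUNDS[0], _MN_BOUNDS[1], 120)
    best = int(np.argmin([sse(m) for m in grid]))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6, "maxiter": 500}
    )
    return float(res.x), sse(float(res.x))


def fit_ncm(table: FeatureTable, d: float | None = None) -> NCMFit:
    """Fit the dispersal parameter mN by least squares on occupancy.

    p_i is each taxon's mean within-sample relative abundance, F_obs_i the
    fraction of samples where it is detected (count > 0). mN minimizes
    sum_i (F_obs_i - F_fit_i(mN))^2 over a bounded interval. The detection
    limit defaults to 1/depth when every sample has the same total (i.e. the
    table was rarefied); otherwise it must be given.
    """
    if table.is_transformed:
        raise ValueError("fit_ncm requires raw counts")
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa to fit")
    totals = table.counts.sum(axis=0)
    if np.any(totals == 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero total counts: {empty}")
    if d is None:
        if len(set(totals.tolist())) != 1:
            raise ValueError(
                "detection limit d not given and sample depths are unequal; "
                "rarefy first or pass d explicitly"
            )
        d = 1.0 / float(totals[0])

    rel = table.counts / totals[None, :]
    p = rel.mean(axis=1)
    detected = table.counts > 0
    k = detected.sum(axis=1)
    f_obs = k / table.n_samples

    if np.allclose(f_obs, f_obs[0]):
        raise ValueError("R^2 undefined: observed occupancy has zero variance")

    mN, sse_val = fit_mn_curve(p, f_obs, d)
    bound_hit = bool(
        mN - _MN_BOUNDS[0] < 1e-3 or _MN_BOUNDS[1] - mN < _MN_BOUNDS[1] * 1e-4
    )
    if bound_hit:
        warnings.warn(f"mN optimizer near bound: {mN:.4g}", stacklevel=2)
    f_fit = predicted_occurrence(p, mN, d)
    ss_tot = float(np.sum((f_obs - f_obs.mean()) ** 2))
    return NCMFit(
        mN=mN,
        detection_limit=d,
        n_hosts=table.n_samples,
        taxon_ids=list(table.taxon_ids),
        p=p,
        f_obs=f_obs,
        f_fit=f_fit,
        k=k.astype(int),
        r_squared=1.0 - sse_val / ss_tot,
        sse=sse_val,
        bound_hit=bound_hit,
    )


def fit_ncm_per_group(
    table: FeatureTable, metadata: SampleMetadata, d: float | None = None
) -> dict[str, NCMFit]:
    """Fit one model per metadata group (samples subset per group)."""
    fits = {}
    for group in sorted(set(metadata.groups.values())):
        samples = [s for s in table.sample_ids if metadata.groups.get(s) == group]
        if len(samples) < 2:
            warnings.warn(f"group {group!r} has <2 samples; skipped", stacklevel=2)
            continue
        sub = table.select_samples(samples)
        nonzero = sub.counts.sum(axis=1) > 0
        sub = FeatureTable(
            [t for t, ok in zip(sub.taxon_ids, nonzero) if ok],
            sub.sample_ids,
            sub.counts[nonzero, :],
        )
        fits[group] = fit_ncm(sub, d=d)
    return fits


def exact_binomial_pvalue(k: int, n: int, prob: float) -> float:
    """Two-tailed exact binomial p-value by the minimum-likelihood method:
    the sum of P(X=j) over all j whose probability does not exceed P(X=k).

    Degenerate success probabilities follow the forced-outcome rule: p=1 when
    k matches the only possible outcome, else p=0.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if prob <= 0.0:
        return 1.0 if k == 0 else 0.0
    if prob >= 1.0:
        return 1.0 if k == n else 0.0
    return float(stats.binomtest(k, n, prob, alternative="two-sided").pvalue)


@dataclasses.dataclass
class SelectionClassification:
    taxon_ids: list[str]
    k: np.ndarray
    n_hosts: int
    p_value: np.ndarray
    category: list[str]
    alpha: float
    fdr: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "k": self.k,
                "p_value": self.p_value,
                "category": self.category,
            }
        )

    def by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {
            CATEGORY_SELECTED: [], CATEGORY_NEUTRAL: [], CATEGORY_NOT_SELECTED: []
        }
        for t, c in zip(self.taxon_ids, self.category):
            out[c].append(t)
        return out


def classify_selection(
    fit: NCMFit, alpha: float = 0.05, fdr: bool = False
) -> SelectionClassification:
    """Three-way per-taxon selection labels from exact binomial deviation tests.

    A taxon is ecologically selected when its deviation is significant and its
    observed occupancy exceeds the fitted curve; not ecologically selected when
    significant and below; neutral otherwise. ``fdr=True`` applies
    Benjamini-Hochberg before thresholding.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    pvals = np.array(
        [
            exact_binomial_pvalue(int(k), fit.n_hosts, float(f))
            for k, f in zip(fit.k, fit.f_fit)
        ]
    )
    effective = pvals
    if fdr:
        from statsmodels.stats.multitest import multipletests

        effective = multipletests(pvals, method="fdr_bh")[1]
    categories = []
    for p_eff, fo, ff in zip(effective, fit.f_obs, fit.f_fit):
        if p_eff < alpha and fo > ff:
            categories.append(CATEGORY_SELECTED)
        elif p_eff < alpha and fo < ff:
            categories.append(CATEGORY_NOT_SELECTED)
        else:
            categories.append(CATEGORY_NEUTRAL)
    return SelectionClassification(
        taxon_ids=list(fit.taxon_ids),
        k=fit.k.copy(),
        n_hosts=fit.n_hosts,
        p_value=pvals,
        category=categories,
        alpha=alpha,
        fdr=fdr,
    )
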