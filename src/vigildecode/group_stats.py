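"""Group-level mass-univariate statistics on decoding scores.

Every TGM cell gets a two-sided Mann-Whitney U test comparing the
per-subject observed accuracies against per-subject null accuracies
(from re-running the identical decoding with labels permuted within
subject); the resulting p-value matrix is corrected per
(train-state, test-state) family with the Benjamini-Hochberg step-up
procedure at q = 0.01.  Two-sided testing keeps below-chance cells
(polarity-reversal transfer) detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .decoding import TemporalGeneralizationMatrix

__all__ = ["StatResult", "mann_whitney_cell", "bh_fdr", "mass_univariate"]


@dataclass
class StatResult:
    """Per-cell p-values, the BH significance mask, and bookkeeping."""

    pvals: np.ndarray
    mask: np.ndarray
    q: float
    test_name: str
    n_subjects: int
    family_size: int


def mann_whitney_cell(obs: Sequence[float], null: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value for one TGM cell.

    Uses the exact distribution when both groups have <= 20 values and
    the pooled sample is tie-free; otherwise the normal approximation
    with tie correction (and continuity correction).  Degenerate cells
    where the statistic has zero variance (all values identical) return
    p = 1.
    """
    obs = np.asarray(obs, dtype=float)
    null = np.asarray(null, dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([obs, null])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(obs.size, null.size) <= 20 and not has_ties) else "asymptotic"
    p = mannwhitneyu(obs, null, alternative="two-sided", method=method).pvalue
    if np.isnan(p):  # zero-variance cell (e.g. every accuracy identical)
        return 1.0
    return float(min(p, 1.0))


def bh_fdr(pvals: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q.

    Plain step-up rule: sort ascending, find the largest k with
    p_(k) <= k q / m, reject hypotheses 1..k.
    """
    pvals = np.asarray(pvals, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def mass_univariate(
    tgms: Sequence[TemporalGeneralizationMatrix],
    null_tgms: Sequence[TemporalGeneralizationMatrix],
    q: float = 0.01,
) -> StatResult:
    """Cell-wise Mann-Whitney + BH over one state-pair matrix family.

    ``tgms`` and ``null_tgms`` are per-subject matrices of identical
    shape; the FDR family is all cells of this one matrix.
    """
    if len(tgms) == 0 or len(null_tgms) == 0:
        raise ValueError("need at least one observed and one null TGM")
    obs = np.stack([t.scores for t in tgms])
    null = np.stack([t.scores for t in null_tgms])
    if obs.shape[1:] != null.shape[1:]:
        raise ValueError("observed and null TGM shapes differ")
    n_tr, n_te = obs.shape[1], obs.shape[2]
    # Vectorized asymptotic pass over all cells, then redo the (usually
    # few) tie-free small-sample cells with the exact distribution so
    # every cell matches mann_whitney_cell.
    fo = obs.reshape(obs.shape[0], -1)
    fn = null.reshape(null.shape[0], -1)
    with np.errstate(invalid="ignore"):
        pflat = mannwhitneyu(
            fo, fn, alternative="two-sided", method="asymptotic", axis=0
        ).pvalue
    pflat = np.where(np.isnan(pflat), 1.0, np.minimum(pflat, 1.0))
    if max(fo.shape[0], fn.shape[0]) <= 20:
        pooled = np.sort(np.concatenate([fo, fn], axis=0), axis=0)
        tie_free = ~np.any(np.diff(pooled, axis=0) == 0, axis=0)
        for k in np.flatnonzero(tie_free):
            pflat[k] = mann_whitney_cell(fo[:, k], fn[:, k])
    pvals = pflat.reshape(n_tr, n_te)
    mask = bh_fdr(pvals.ravel(), q).reshape(n_tr, n_te)
    return StatResult(
        pvals=pvals,
        mask=mask,
        q=q,
        test_name="mann-whitney-u (two-sided) vs label-permutation null",
        n_subjects=len(tgms),
        family_size=n_tr * n_te,
    )
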