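"""Concordance between statistical maps and between region activation tables.

Treating one thresholded group map as ground truth, a second map's t values
are swept over all thresholds to build an ROC curve (hit rate vs false-alarm
rate) whose area summarizes threshold-free agreement; single hit/false-alarm
figures are evaluated at the test map's own FDR + cluster threshold.  At the
region level, an atlas labels each region active when at least 5% of its
voxels are significant, and tables from two maps are compared by
correlation and by ROC over regions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core import StatMap
from .grouplevel import GroupResult

__all__ = [
    "ConcordanceResult",
    "RegionTable",
    "roc_curve_from_scores",
    "roc_between_maps",
    "region_activation_table",
    "table_concordance",
]

ACTIVE_PCT_THRESHOLD = 5.0


@dataclass
class ConcordanceResult:
    """ROC summary of one ordered (test, reference) map pair."""

    auc: float
    hit_rate: float | None
    fa_rate: float | None
    curve: np.ndarray               # (n, 2) columns (fa, hit), sorted
    reference_name: str = ""
    test_name: str = ""


def roc_curve_from_scores(scores: np.ndarray, truth: np.ndarray
                          ) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for continuous scores against binary truth.

    Thresholds sweep the unique score values; ties receive half credit
    (the trapezoid over tied blocks equals rank-based pair counting).
    Endpoints (0,0) and (1,1) are always included.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative voxels")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted, t_sorted = scores[order], truth[order]
    # group tied scores so ties are handled as one step
    _, first_idx = np.unique(-s_sorted, return_index=True)
    boundaries = np.append(first_idx[1:], len(s_sorted))
    tp = np.cumsum(t_sorted)[boundaries - 1]
    fp = np.cumsum(~t_sorted)[boundaries - 1]
    hit = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fa = np.concatenate([[0.0], fp / n_neg, [1.0]])
    auc = float(np.trapezoid(hit, fa))
    return np.column_stack([fa, hit]), auc


def roc_between_maps(test: StatMap | np.ndarray, ref: GroupResult,
                     mask: np.ndarray,
                     test_sig_mask: np.ndarray | None = None,
                     test_name: str = "", reference_name: str = ""
                     ) -> ConcordanceResult:
    """Compare a test t map against a thresholded reference group result.

    Positives for the threshold-free ROC sweep are the reference's
    positively activated FDR survivors (before cluster filtering) — an
    upper level set of the reference t map, so an identical test map
    separates perfectly.  The single hit/false-alarm rates are evaluated at
    ``test_sig_mask`` (the test map thresholded at its own FDR + cluster
    rule) against the same truth.
    """
    if ref.sig_mask is None:
        raise ValueError("reference group result must be thresholded")
    mask = mask.astype(bool)
    tvals = (test.values if isinstance(test, StatMap) else np.asarray(test))
    scores = tvals[mask]
    pos = (ref.fdr_mask if ref.fdr_mask is not None else ref.sig_mask)
    truth = (pos & (ref.tmap.values > 0))[mask]
    curve, auc = roc_curve_from_scores(scores, truth)
    hit = fa = None
    if test_sig_mask is not None:
        declared = test_sig_mask[mask]
        hit = float((declared & truth).sum() / truth.sum())
        fa = float((declared & ~truth).sum() / (~truth).sum())
    return ConcordanceResult(auc=auc, hit_rate=hit, fa_rate=fa, curve=curve,
                             reference_name=reference_name, test_name=test_name)


@dataclass
class RegionTable:
    """Per-region activation percentages with the 5% activity flag."""

    table: pd.DataFrame             # columns region_id, n_voxels, pct_active, active

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def pct_active(self) -> np.ndarray:
        return self.table["pct_active"].to_numpy()

    @property
    def active_flags(self) -> np.ndarray:
        return self.table["active"].to_numpy()


def region_activation_table(sig_mask: np.ndarray, atlas_labels: np.ndarray,
                            mask: np.ndarray) -> RegionTable:
    """Percentage of significant voxels per atlas region.

    A region counts as activated when at least 5% of its in-mask voxels are
    significant.  Regions with no in-mask voxels are dropped with a warning.
    """
    mask = mask.astype(bool)
    sig = sig_mask.astype(bool) & mask
    labels = np.asarray(atlas_labels)
    rows = []
    for rid in np.unique(labels[labels > 0]):
        region = (labels == rid) & mask
        n = int(region.sum())
        if n == 0:
            warnings.warn(f"region {rid} empty inside mask; dropped",
                          stacklevel=2)
            continue
        pct = 100.0 * (sig & region).sum() / n
        rows.append(dict(region_id=int(rid), n_voxels=n, pct_active=pct,
                         active=pct >= ACTIVE_PCT_THRESHOLD))
    return RegionTable(table=pd.DataFrame(rows))


def table_concordance(a: RegionTable, b: RegionTable) -> dict:
    """Agreement between two region tables.

    Returns Pearson correlation of activation percentages, correlation of
    the binary 5% flags, and the ROC area treating ``b``'s flags as truth
    scored by ``a``'s percentages.
    """
    if not np.array_equal(a.region_ids, b.region_ids):
        raise ValueError("tables must cover the same region set")
    pa, pb = a.pct_active, b.pct_active
    if pa.std() == 0 or pb.std() == 0:
        raise ValueError("degenerate (constant) percentage vector")
    corr_pct = float(np.corrcoef(pa, pb)[0, 1])
    fa_flags, fb_flags = a.active_flags.astype(float), b.active_flags.astype(float)
    if fa_flags.std() == 0 or fb_flags.std() == 0:
        corr_bin = float("nan")
    else:
        corr_bin = float(np.corrcoef(fa_flags, fb_flags)[0, 1])
    if fb_flags.any() and not fb_flags.all():
        _, roc = roc_curve_from_scores(pa, fb_flags.astype(bool))
    else:
        roc = float("nan")
    return {"correlation_pct": corr_pct, "correlation_binary": corr_bin,
            "roc_over_regions": roc}
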