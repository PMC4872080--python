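"""Regularized logistic classification of extreme-stability transcripts.

Transcripts (or 3'UTR segments) are ranked by half-life or abundance, the
top-k are labelled stable (1) and the bottom-k unstable (0), and an
L2-regularized logistic regression predicts the label from 16 overlapping
dinucleotide counts plus counts of binding sites grouped as miRNAs,
activators and repressors.  Performance is the AU-ROC over repeated
stratified k-fold cross-validation (10 x 10-fold by default, 100 AUCs);
the ridge penalty is chosen per outer fold by an inner cross-validation
maximizing validation AUC.  Models are compared by a two-sided Wilcoxon
signed-rank test on the paired per-fold AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import RunConfig
from .sites import Site
from .structure import AccessibilityProfile, site_accessibility

logger = logging.getLogger(__name__)

BASES = "ACGU"
DINUCLEOTIDES = [a + b for a in BASES for b in BASES]
GROUP_NAMES = ("mirnas", "activators", "repressors")
VARIANTS = ("plain", "clip_only", "accessibility_weighted", "overlap_penalized")

# RBPs with literature support for stabilizing / destabilizing their targets
DEFAULT_ACTIVATORS = frozenset(
    {"HNRNPL", "PABPC1", "PABPC3", "PABPC4", "PABPC5", "PABPN1",
     "RBFOX1", "HuR", "IGF2BP2", "IGF2BP3"}
)
DEFAULT_REPRESSORS = frozenset(
    {"CUGBP1", "MBNL1", "HNRNPC", "KHSRP", "ZFP36", "AUF1", "TIA1", "PUM1", "PUM2"}
)


@dataclass(frozen=True)
class FactorGroups:
    """Disjoint factor rosters used for the three site-count features.
    miRNA membership is decided by ``factor_class`` unless listed."""

    activators: frozenset[str] = DEFAULT_ACTIVATORS
    repressors: frozenset[str] = DEFAULT_REPRESSORS
    mirnas: frozenset[str] | None = None  # None = every factor of class miRNA

    def __post_init__(self) -> None:
        if self.activators & self.repressors:
            raise ValueError("activators and repressors must be disjoint")

    def group_of(self, site: Site) -> str | None:
        if self.mirnas is not None and site.factor_id in self.mirnas:
            return "mirnas"
        if self.mirnas is None and site.factor_class == "miRNA":
            return "mirnas"
        if site.factor_id in self.activators:
            return "activators"
        if site.factor_id in self.repressors:
            return "repressors"
        return None


def dinucleotide_counts(seq: str) -> np.ndarray:
    """Overlapping dimer counts in fixed AA..UU order (sum = len - 1)."""
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGU characters {sorted(bad)}")
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    idx = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    counts = np.zeros(16, dtype=int)
    for i in range(len(seq) - 1):
        counts[idx[seq[i : i + 2]]] += 1
    return counts


def group_site_counts(
    sites: Sequence[Site],
    groups: FactorGroups,
    variant: str = "plain",
    *,
    all_sites: Sequence[Site] | None = None,
    profile: AccessibilityProfile | None = None,
) -> np.ndarray:
    """(mirnas, activators, repressors) feature triple for one sequence.

    Variants: ``plain`` counts sites; ``clip_only`` counts only CLIP- or
    gPARCLIP-supported sites; ``accessibility_weighted`` sums site
    accessibility (requires ``profile``); ``overlap_penalized`` counts a
    site as 0.5 instead of 1 when it overlaps any other factor's site
    (overlap set = ``all_sites`` if given, else ``sites``).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant == "accessibility_weighted" and profile is None:
        raise ValueError("accessibility_weighted variant requires an accessibility profile")
    pool = list(all_sites) if all_sites is not None else list(sites)
    out = dict.fromkeys(GROUP_NAMES, 0.0)
    for s in sites:
        group = groups.group_of(s)
        if group is None:
            continue
        if variant == "clip_only":
            if not (s.clip_supported or s.gparclip_supported):
                continue
            value = 1.0
        elif variant == "accessibility_weighted":
            value = site_accessibility(s, profile)  # type: ignore[arg-type]
        elif variant == "overlap_penalized":
            overlapped = any(
                o.factor_id != s.factor_id and s.overlaps(o) for o in pool
            )
            value = 0.5 if overlapped else 1.0
        else:
            value = 1.0
        out[group] += value
    return np.array([out[g] for g in GROUP_NAMES])


def label_extremes(
    values: Mapping[str, float],
    has_site: Mapping[str, bool],
    k: int = 500,
) -> dict[str, int]:
    """Top-k = 1, bottom-k = 0, middle discarded; ids without any miRNA or
    RBP site are removed before ranking.  Ties at a boundary are broken by
    id order (logged)."""
    eligible = [
        (v, tid) for tid, v in values.items() if has_site.get(tid, False) and v is not None
    ]
    if len(eligible) < 2 * k:
        raise ValueError(
            f"need >= {2 * k} site-bearing ids to label extremes, have {len(eligible)}"
        )
    ranked = sorted(eligible, key=lambda item: (-item[0], item[1]))
    if len(ranked) > 2 * k and (
        ranked[k - 1][0] == ranked[k][0] or ranked[-k][0] == ranked[-k - 1][0]
    ):
        logger.info("label_extremes: ties at a class boundary broken by id order")
    labels = {tid: 1 for _, tid in ranked[:k]}
    labels.update({tid: 0 for _, tid in ranked[-k:]})
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (midranks under ties): U / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class CVResult:
    """Repeated-CV outcome: one AUC per (repeat, fold), the vertically
    averaged ROC on a fixed FPR grid, chosen penalties, and the coefficient
    vector of a final full-data fit (for sign inspection)."""

    per_run_auc: np.ndarray            # cv_repeats * cv_folds values
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    chosen_lambda: np.ndarray
    coef: np.ndarray
    feature_names: list[str]

    @property
    def mean_auc(self) -> float:
        return float(self.per_run_auc.mean())


def _make_estimator(lambdas: np.ndarray, inner_cv: int, seed: int) -> Pipeline:
    # glmnet-style: pure L2 (alpha=0), penalty chosen by inner CV on AUC
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logreg",
                LogisticRegressionCV(
                    Cs=1.0 / lambdas,
                    cv=StratifiedKFold(inner_cv, shuffle=True, random_state=seed),
                    l1_ratios=(0.0,),  # pure L2, glmnet alpha=0
                    scoring="roc_auc",
                    solver="lbfgs",
                    max_iter=2000,
                    refit=True,
                    use_legacy_attributes=False,
                ),
            ),
        ]
    )


def ridge_logistic_cv(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    config: RunConfig,
    *,
    seed: int | None = None,
    lambda_grid: np.ndarray | None = None,
    inner_cv: int = 3,
    fpr_points: int = 101,
) -> CVResult:
    """Repeated stratified k-fold CV of the ridge logistic model.

    Standardization and penalty selection happen inside each training fold
    (no leakage into held-out data).  The default penalty grid is 50
    log-spaced values in [1e-4, 1e4] on the standardized scale.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if seed is None:
        seed = config.seed
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 4, 50)

    fpr_grid = np.linspace(0, 1, fpr_points)
    aucs, lambdas_chosen, tprs = [], [], []
    for repeat in range(config.cv_repeats):
        outer = StratifiedKFold(
            config.cv_folds, shuffle=True, random_state=seed * 1000 + repeat
        )
        for fold, (tr, te) in enumerate(outer.split(X, y)):
            est = _make_estimator(lambda_grid, inner_cv, seed * 1000 + repeat)
            est.fit(X[tr], y[tr])
            scores = est.decision_function(X[te])
            aucs.append(roc_auc(scores, y[te]))
            lambdas_chosen.append(1.0 / float(np.atleast_1d(est["logreg"].C_)[0]))
            fpr, tpr, _ = roc_curve(y[te], scores)
            tprs.append(np.interp(fpr_grid, fpr, tpr))
    final = _make_estimator(lambda_grid, inner_cv, seed)
    final.fit(X, y)
    coef = final["logreg"].coef_.ravel().copy()
    return CVResult(
        per_run_auc=np.array(aucs),
        fpr_grid=fpr_grid,
        mean_tpr=np.mean(tprs, axis=0),
        chosen_lambda=np.array(lambdas_chosen),
        coef=coef,
        feature_names=feature_names,
    )


def length_only_baseline(
    utr_lengths: Sequence[float],
    y: Sequence[int],
    config: RunConfig,
    *,
    seed: int | None = None,
) -> CVResult:
    """The ridge CV run with 3'UTR length as the single feature."""
    X = np.asarray(utr_lengths, dtype=float).reshape(-1, 1)
    result = ridge_logistic_cv(X, y, config, seed=seed)
    result.feature_names = ["utr_length"]
    return result


def compare_models(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p on paired per-fold AUCs (zeros
    dropped); p = 1 when every difference is zero."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC vectors must be paired (same shape)")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Feature-table assembly
# ---------------------------------------------------------------------------

def build_feature_table(
    sequences: Mapping[str, str],
    sites_by_id: Mapping[str, Sequence[Site]],
    groups: FactorGroups,
    *,
    variant: str = "plain",
    profiles: Mapping[str, AccessibilityProfile] | None = None,
    labels: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One row per sequence: 16 dinucleotide counts, 3 group counts, and a
    ``label`` column when labels are supplied (labelled rows only)."""
    ids = sorted(labels) if labels is not None else sorted(sequences)
    rows = []
    for tid in ids:
        seq = sequences[tid]
        counts = dinucleotide_counts(seq)
        gcounts = group_site_counts(
            sites_by_id.get(tid, ()),
            groups,
            variant,
            profile=None if profiles is None else profiles.get(tid),
        )
        row = {"transcript_id": tid}
        row.update(dict(zip(DINUCLEOTIDES, counts.tolist())))
        row.update(dict(zip(GROUP_NAMES, gcounts.tolist())))
        if labels is not None:
            row["label"] = labels[tid]
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")
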