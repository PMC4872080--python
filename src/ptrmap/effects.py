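"""Group analyses of knockdown / transfection log fold changes.

Transcripts are stratified by properties of a factor's binding sites --
in vivo (CLIP) support, competition with overlapping sites of other factors,
co-occurrence with a second factor within a distance, or participation in a
predicted stem-loop -- and the LFC distributions of the groups are compared
with one-tailed Mann-Whitney U tests.  Confounding by 3'UTR length and
baseline expression is handled either by residualising LFCs on the two
covariates or by covariate-matched resampling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Transcript
from .sites import Site
from .structure import StemPairCandidate

logger = logging.getLogger(__name__)

EXACT_LIMIT = 12  # n_x + n_y up to which the exact MW null is enumerated


@dataclass
class TestResult:
    comparison: tuple[str, str]
    statistic: float
    p: float
    direction: str
    n_x: int
    n_y: int
    degenerate: bool = False


@dataclass
class GroupAssignment:
    transcript_id: str
    analysis: str
    label: str


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x against y from midranks: U_x = R_x - n_x(n_x+1)/2."""
    nx = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2)


def mann_whitney_one_tailed(
    x: Sequence[float], y: Sequence[float], direction: str = "less"
) -> TestResult:
    """One-tailed Mann-Whitney U (Wilcoxon rank-sum) test.

    ``direction='less'`` tests whether x tends to be smaller than y
    (alternative hypothesis).  The null distribution is enumerated exactly
    (all rank assignments, midranks under ties) when n_x + n_y <=
    ``EXACT_LIMIT``; otherwise the normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if direction not in {"less", "greater"}:
        raise ValueError("direction must be 'less' or 'greater'")
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(("x", "y"), u, 1.0, direction, len(x), len(y), degenerate=True)

    nx, ny = len(x), len(y)
    if nx + ny <= EXACT_LIMIT:
        # exact: U is a rank statistic, so enumerating which pooled ranks go
        # to x reproduces the permutation null even under ties
        ranks = stats.rankdata(pooled)
        us = [
            sum(ranks[i] for i in combo) - nx * (nx + 1) / 2
            for combo in itertools.combinations(range(nx + ny), nx)
        ]
        us = np.asarray(us)
        eps = 1e-9
        if direction == "less":
            p = np.mean(us <= u + eps)
        else:
            p = np.mean(us >= u - eps)
    else:
        alternative = direction  # scipy's alternative matches our direction
        p = stats.mannwhitneyu(
            x, y, alternative=alternative, use_continuity=True, method="asymptotic"
        ).pvalue
    return TestResult(("x", "y"), u, float(p), direction, nx, ny)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho = Pearson correlation of midranks (complete pairs only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def _sites_by_transcript(sites: Sequence[Site]) -> dict[str, list[Site]]:
    by_tid: dict[str, list[Site]] = {}
    for s in sites:
        by_tid.setdefault(s.transcript_id, []).append(s)
    return by_tid


def classify_clip_groups(
    transcripts: Sequence[Transcript],
    factor_sites: Sequence[Site],
    *,
    excluded_transcripts: Sequence[str] | None = None,
) -> list[GroupAssignment]:
    """CLIP / other / no_site per transcript for one factor.

    ``excluded_transcripts`` (e.g. carriers of intronic sites of the factor)
    are removed before grouping.
    """
    excluded = set(excluded_transcripts or ())
    by_tid = _sites_by_transcript(factor_sites)
    out = []
    for t in transcripts:
        if t.id in excluded:
            continue
        sites = by_tid.get(t.id, [])
        if any(s.clip_supported for s in sites):
            label = "CLIP"
        elif sites:
            label = "other"
        else:
            label = "no_site"
        out.append(GroupAssignment(t.id, "clip", label))
    return out


def classify_competition(
    transcripts: Sequence[Transcript],
    factor_sites: Sequence[Site],
    other_sites: Sequence[Site],
    *,
    excluded_transcripts: Sequence[str] | None = None,
) -> list[GroupAssignment]:
    """Competition grouping for one factor.

    no_competition: >= 1 CLIP-supported factor site overlapping no other
    factor's site; competition: >= 1 CLIP-supported site but every factor
    site overlaps some other factor's site; no_site: no factor sites;
    excluded: factor sites present but none CLIP-supported (reported for
    transparency, omitted from the comparison).  Overlap = >= 1 shared UTR
    position.
    """
    excl = set(excluded_transcripts or ())
    by_tid = _sites_by_transcript(factor_sites)
    others = _sites_by_transcript(other_sites)
    out = []
    for t in transcripts:
        if t.id in excl:
            continue
        sites = by_tid.get(t.id, [])
        if not sites:
            out.append(GroupAssignment(t.id, "competition", "no_site"))
            continue
        if not any(s.clip_supported for s in sites):
            out.append(GroupAssignment(t.id, "competition", "excluded"))
            continue
        comp = others.get(t.id, [])
        overlapped = [any(s.overlaps(o) for o in comp) for s in sites]
        clip_free = any(
            s.clip_supported and not olap for s, olap in zip(sites, overlapped)
        )
        if clip_free:
            label = "no_competition"
        elif all(overlapped):
            label = "competition"
        else:
            # a non-CLIP factor site escapes overlap: falls outside the
            # standard three-group scheme; treat as no_competition only if
            # CLIP-free, else competition requires every site overlapped
            label = "excluded"
        out.append(GroupAssignment(t.id, "competition", label))
    return out


def classify_cooperation(
    transcripts: Sequence[Transcript],
    sites_a: Sequence[Site],
    sites_b: Sequence[Site],
    *,
    selected_pairs: Sequence[StemPairCandidate] = (),
    distance: int | None = None,
    require_clip_a: bool = False,
) -> list[GroupAssignment]:
    """Five-group cooperation labels, or the two-group distance variant.

    With ``distance=None``: None / OnlyA / OnlyB / Both_not_stemloop /
    Both_stemloop (a selected stem pair on the transcript wins).  With a
    distance, transcripts carrying both factors are split into within_<d> /
    beyond_<d> by the minimal edge-to-edge gap between an A site and a B
    site.
    """
    by_a = _sites_by_transcript(
        [s for s in sites_a if not require_clip_a or s.clip_supported]
    )
    by_b = _sites_by_transcript(sites_b)
    stem_tids = {p.site_a.transcript_id for p in selected_pairs}
    analysis = "cooperation5" if distance is None else "distance2"
    out = []
    for t in transcripts:
        has_a = bool(by_a.get(t.id))
        has_b = bool(by_b.get(t.id))
        if distance is None:
            if not has_a and not has_b:
                label = "None"
            elif has_a and not has_b:
                label = "OnlyA"
            elif has_b and not has_a:
                label = "OnlyB"
            elif t.id in stem_tids:
                label = "Both_stemloop"
            else:
                label = "Both_not_stemloop"
        else:
            if not (has_a and has_b):
                label = "no_pair"
            else:
                gap = min(
                    max(b.start - a.end, a.start - b.end, 0)
                    for a in by_a[t.id]
                    for b in by_b[t.id]
                )
                label = f"within_{distance}" if gap <= distance else f"beyond_{distance}"
        out.append(GroupAssignment(t.id, analysis, label))
    return out


# ---------------------------------------------------------------------------
# Covariate adjustment
# ---------------------------------------------------------------------------

def residualize_lfc(
    lfc: Mapping[str, float],
    utr_length: Mapping[str, float],
    expression: Mapping[str, float],
) -> dict[str, float]:
    """Residuals of OLS: lfc ~ 1 + utr_length + expression.

    Rows with a missing covariate or response are dropped.  Raises on a
    rank-deficient design, naming the collinear column.
    """
    ids = [
        tid
        for tid in lfc
        if lfc.get(tid) is not None
        and utr_length.get(tid) is not None
        and expression.get(tid) is not None
    ]
    if len(ids) < 3:
        raise ValueError("need >= 3 complete rows for residualization")
    y = np.array([lfc[tid] for tid in ids], dtype=float)
    X = np.column_stack(
        [
            np.ones(len(ids)),
            np.array([utr_length[tid] for tid in ids], dtype=float),
            np.array([expression[tid] for tid in ids], dtype=float),
        ]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for col, name in ((1, "utr_length"), (2, "expression")):
            if np.linalg.matrix_rank(np.delete(X, col, axis=1)) == rank:
                raise ValueError(f"rank-deficient design: column '{name}' is collinear")
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return dict(zip(ids, resid.tolist()))


def matched_resample_test(
    group_small: Sequence[str],
    group_large: Sequence[str],
    covariates: Mapping[str, tuple[float, float]],
    lfc: Mapping[str, float],
    *,
    n_rep: int = 1000,
    alpha: float = 0.05,
    direction: str = "less",
    rng: np.random.Generator,
) -> float:
    """Covariate-matched resampling comparison of two groups' LFCs.

    Each repetition bootstrap-resamples ``group_large`` (with replacement,
    same size), matches every member of ``group_small`` to its nearest
    neighbour in the resample on z-scored covariates (ties random), and runs
    a one-tailed Mann-Whitney test of the small group's LFCs against the
    matched sample.  Returns the empirical p: the fraction of repetitions
    NOT significant at ``alpha``.
    """
    if not group_large:
        raise ValueError("group_large must be nonempty")
    small = [t for t in group_small if t in covariates and lfc.get(t) is not None]
    large = [t for t in group_large if t in covariates and lfc.get(t) is not None]
    if not small or not large:
        raise ValueError("no complete cases in one of the groups")
    all_cov = np.array([covariates[t] for t in small + large], dtype=float)
    mu, sd = all_cov.mean(axis=0), all_cov.std(axis=0)
    sd[sd == 0] = 1.0
    z_small = (np.array([covariates[t] for t in small]) - mu) / sd
    z_large = (np.array([covariates[t] for t in large]) - mu) / sd
    lfc_small = np.array([lfc[t] for t in small], dtype=float)
    lfc_large = np.array([lfc[t] for t in large], dtype=float)

    n_not_significant = 0
    for _ in range(n_rep):
        boot = rng.integers(0, len(large), size=len(large))
        zb = z_large[boot]
        d2 = ((z_small[:, None, :] - zb[None, :, :]) ** 2).sum(axis=2)
        jitter = rng.random(d2.shape) * 1e-9  # random tie-breaking
        matched = lfc_large[boot[np.argmin(d2 + jitter, axis=1)]]
        res = mann_whitney_one_tailed(lfc_small, matched, direction)
        if res.p >= alpha:
            n_not_significant += 1
    return n_not_significant / n_rep


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

def group_lfc_frame(
    assignments: Sequence[GroupAssignment], lfc: Mapping[str, float]
) -> pd.DataFrame:
    """Long table (transcript_id, analysis, label, lfc), complete cases."""
    rows = [
        {
            "transcript_id": a.transcript_id,
            "analysis": a.analysis,
            "label": a.label,
            "lfc": lfc[a.transcript_id],
        }
        for a in assignments
        if lfc.get(a.transcript_id) is not None
    ]
    return pd.DataFrame(rows)


def compare_groups(
    frame: pd.DataFrame, label_x: str, label_y: str, direction: str = "less"
) -> TestResult:
    """One-tailed Mann-Whitney between two labelled groups of a frame."""
    x = frame.loc[frame["label"] == label_x, "lfc"].to_numpy()
    y = frame.loc[frame["label"] == label_y, "lfc"].to_numpy()
    res = mann_whitney_one_tailed(x, y, direction)
    res.comparison = (label_x, label_y)
    return res
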