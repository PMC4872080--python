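"""Permutation test for binding-site co-occurrence.

For an anchor factor, partner sites are counted in 50-nt windows spanning
200 nt on either side of each anchor site (8 windows: 4 upstream of the site
start, 4 downstream of the site end).  The observed count per (partner,
window) is compared with its distribution under shuffles of the factor
identities -- site positions stay fixed -- stratified three ways: within
chromosomes, within AU-content classes of the matched k-mer (<3, 3-5, >=6
A/U bases), and within deciles of relative position along the UTR.  A pair
of factors is called interacting when at least one window reaches q < alpha
under all three shuffling schemes.

Two biases are handled before counting: factors with near-identical motifs
are excluded from each other's partner sets, and homotypic clusters must be
collapsed to their most upstream site (see ``collapse_homotypic``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import Transcript
from .motifs import Motif, motif_similarity
from .sites import Site

logger = logging.getLogger(__name__)

SHUFFLE_KINDS = ("chromosome", "au_content", "position_decile")


@dataclass(frozen=True)
class WindowScheme:
    """Disjoint fixed-width windows flanking an anchor site.

    Upstream offsets are measured from the anchor start, downstream offsets
    from the anchor end; the anchor body itself belongs to no window.
    Window indices run upstream-to-downstream: with the 50/200 defaults,
    index 0 is [-200,-150) before the start and index 7 is [150,200) past
    the end.
    """

    window_size: int = 50
    span: int = 200

    def __post_init__(self) -> None:
        if self.span % self.window_size != 0:
            raise ValueError("span must be divisible by window_size")

    @property
    def per_side(self) -> int:
        return self.span // self.window_size

    @property
    def n_windows(self) -> int:
        return 2 * self.per_side

    def window_index(
        self, anchor_start: int, anchor_end: int, partner_start: int
    ) -> int | None:
        """Window holding the partner site's start, or None (too far away or
        inside the anchor body)."""
        if partner_start < anchor_start:
            d = anchor_start - partner_start  # 1..span
            if d > self.span:
                return None
            return self.per_side - 1 - (d - 1) // self.window_size
        if partner_start >= anchor_end:
            d = partner_start - anchor_end  # 0..span-1
            if d >= self.span:
                return None
            return self.per_side + d // self.window_size
        return None  # inside the anchor body


def exclude_similar_factors(
    anchor: str,
    motifs: Mapping[str, Sequence[Motif]],
    explicit_list: Iterable[tuple[str, str]] | None = None,
    *,
    threshold: float = 0.8,
) -> set[str]:
    """Factors whose motifs are too similar to the anchor's to be counted as
    partners: either listed explicitly or exceeding ``threshold`` best
    ungapped-offset mean column Pearson correlation."""
    excluded: set[str] = set()
    for a, b in explicit_list or ():
        if a == anchor:
            excluded.add(b)
        elif b == anchor:
            excluded.add(a)
    anchor_motifs = motifs.get(anchor, ())
    for factor, fmotifs in motifs.items():
        if factor == anchor or factor in excluded:
            continue
        for ma in anchor_motifs:
            if any(motif_similarity(ma, mb) > threshold for mb in fmotifs):
                excluded.add(factor)
                break
    return excluded


# ---------------------------------------------------------------------------
# Counting machinery
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Precomputed site-pair geometry: which window each ordered site pair
    falls in.  Positions never change under identity shuffling, so this is
    built once and reused for every permutation."""

    factor_ids: list[str]
    site_factor: np.ndarray      # int factor label per site
    sites: list[Site]
    anchor_idx: np.ndarray       # per pair: site index of the anchor
    partner_idx: np.ndarray
    window: np.ndarray
    scheme: WindowScheme

    @property
    def n_factors(self) -> int:
        return len(self.factor_ids)

    def counts(self, labels: np.ndarray | None = None) -> np.ndarray:
        """Count matrix [anchor_factor, partner_factor, window]."""
        if labels is None:
            labels = self.site_factor
        nf, nw = self.n_factors, self.scheme.n_windows
        if len(self.window) == 0:
            return np.zeros((nf, nf, nw))
        combined = (
            labels[self.anchor_idx] * nf + labels[self.partner_idx]
        ) * nw + self.window
        return np.bincount(combined, minlength=nf * nf * nw).reshape(nf, nf, nw).astype(float)


def build_pair_table(
    sites: Sequence[Site], scheme: WindowScheme | None = None
) -> PairTable:
    """Index every ordered same-transcript site pair by its window.

    Expects homotypically collapsed sites (see ``collapse_homotypic``)."""
    scheme = scheme or WindowScheme()
    factor_ids = sorted({s.factor_id for s in sites})
    fidx = {f: i for i, f in enumerate(factor_ids)}
    site_factor = np.array([fidx[s.factor_id] for s in sites], dtype=np.intp)

    by_tid: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_tid.setdefault(s.transcript_id, []).append(i)

    anchors, partners, windows = [], [], []
    for idxs in by_tid.values():
        for ia in idxs:
            sa = sites[ia]
            for ip in idxs:
                if ia == ip:
                    continue
                w = scheme.window_index(sa.start, sa.end, sites[ip].start)
                if w is not None:
                    anchors.append(ia)
                    partners.append(ip)
                    windows.append(w)
    return PairTable(
        factor_ids=factor_ids,
        site_factor=site_factor,
        sites=list(sites),
        anchor_idx=np.array(anchors, dtype=np.intp),
        partner_idx=np.array(partners, dtype=np.intp),
        window=np.array(windows, dtype=np.intp),
        scheme=scheme,
    )


def window_counts(
    anchor_factor: str, pair_table: PairTable
) -> dict[str, np.ndarray]:
    """Observed partner counts per window for one anchor factor."""
    counts = pair_table.counts()
    ai = pair_table.factor_ids.index(anchor_factor)
    return {
        partner: counts[ai, pi]
        for pi, partner in enumerate(pair_table.factor_ids)
        if partner != anchor_factor
    }


# ---------------------------------------------------------------------------
# Shuffling schemes
# ---------------------------------------------------------------------------

def au_content_group(kmer: str) -> int:
    """AU class of a matched k-mer: 0 (<3 A/U), 1 (3-5), 2 (>=6)."""
    au = sum(1 for b in kmer if b in "AU")
    return 0 if au < 3 else (1 if au < 6 else 2)


def shuffle_groups(
    sites: Sequence[Site],
    transcripts: Mapping[str, Transcript],
    kind: str,
) -> np.ndarray:
    """Stratification labels for one shuffling scheme (one label per site)."""
    if kind == "chromosome":
        labels = [transcripts[s.transcript_id].chrom for s in sites]
    elif kind == "au_content":
        labels = [au_content_group(s.matched_kmer) for s in sites]
    elif kind == "position_decile":
        labels = []
        for s in sites:
            utr_len = len(transcripts[s.transcript_id].utr_seq)
            mid = (s.start + s.end) / 2.0
            labels.append(min(9, int(10 * mid / utr_len)))
    else:
        raise ValueError(f"unknown shuffle kind {kind!r}; choose from {SHUFFLE_KINDS}")
    _, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    return codes.astype(np.intp)


def permute_and_count(
    pair_table: PairTable,
    group_labels: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null count distributions: ``n`` independent shuffles of factor
    identities within each stratum, positions fixed.

    Returns an array of shape (n, n_factors, n_factors, n_windows).  The
    per-stratum factor multiset is conserved by construction; single-site
    strata reduce to the identity permutation (logged once)."""
    group_members = [
        np.flatnonzero(group_labels == g) for g in np.unique(group_labels)
    ]
    n_singleton = sum(1 for m in group_members if len(m) == 1)
    if n_singleton:
        logger.info("permute_and_count: %d single-site strata shuffle trivially", n_singleton)
    labels = pair_table.site_factor.copy()
    out = np.empty(
        (n, pair_table.n_factors, pair_table.n_factors, pair_table.scheme.n_windows)
    )
    for it in range(n):
        for members in group_members:
            labels[members] = labels[rng.permutation(members)]
        out[it] = pair_table.counts(labels)
    return out


def empirical_pvalue(observed: float, null_counts: np.ndarray) -> float:
    """Enrichment-sided add-one estimator: (1 + #{null >= obs}) / (1 + n)."""
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("null_counts must be nonempty")
    return float((1 + np.sum(null_counts >= observed)) / (1 + null_counts.size))


def qvalues(p: Sequence[float], method: str = "bh", *, storey_lambda: float = 0.5) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; optionally scaled by Storey's
    pi0 estimate at a single lambda."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "storey":
        pi0 = min(1.0, np.mean(p > storey_lambda) / (1.0 - storey_lambda))
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    return q


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def cooccurrence_analysis(
    sites: Sequence[Site],
    transcripts: Sequence[Transcript] | Mapping[str, Transcript],
    config: RunConfig,
    *,
    anchors: Sequence[str] | None = None,
    motifs: Mapping[str, Sequence[Motif]] | None = None,
    explicit_similar: Iterable[tuple[str, str]] | None = None,
    rng: np.random.Generator | None = None,
    qvalue_method: str = "bh",
) -> pd.DataFrame:
    """Full permutation analysis over all (anchor, partner, window) cells.

    ``sites`` must already be homotypically collapsed.  Returns a long-format
    table with observed counts, per-scheme expected counts / empirical p /
    q-values, the min-over-schemes enrichment ratio and the interaction
    call.  q-values are BH-adjusted per (anchor, partner) across its
    windows, separately per scheme.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.id: t for t in transcripts}
    if rng is None:
        rng = config.rng("cooccurrence")
    scheme = WindowScheme(config.cooccur_window, config.cooccur_span)
    table = build_pair_table(sites, scheme)
    factor_ids = table.factor_ids
    anchors = list(anchors) if anchors is not None else factor_ids
    observed = table.counts()

    nulls = {}
    for kind in SHUFFLE_KINDS:
        groups = shuffle_groups(table.sites, transcripts, kind)
        nulls[kind] = permute_and_count(table, groups, config.n_permutations, rng)

    excluded = {
        a: exclude_similar_factors(
            a, motifs, explicit_similar, threshold=config.motif_similarity_threshold
        )
        if motifs is not None or explicit_similar is not None
        else set()
        for a in anchors
    }

    rows = []
    for anchor in anchors:
        ai = factor_ids.index(anchor)
        for pi, partner in enumerate(factor_ids):
            if partner == anchor or partner in excluded[anchor]:
                continue
            obs = observed[ai, pi]  # per window
            per_scheme_p = {}
            per_scheme_exp = {}
            for kind in SHUFFLE_KINDS:
                null = nulls[kind][:, ai, pi, :]  # (n_perm, n_windows)
                per_scheme_exp[kind] = null.mean(axis=0)
                per_scheme_p[kind] = np.array(
                    [empirical_pvalue(obs[w], null[:, w]) for w in range(scheme.n_windows)]
                )
            per_scheme_q = {
                kind: qvalues(per_scheme_p[kind], qvalue_method) for kind in SHUFFLE_KINDS
            }
            ratios = np.full(scheme.n_windows, np.inf)
            for kind in SHUFFLE_KINDS:
                exp = per_scheme_exp[kind].copy()
                o = obs.copy()
                zero = exp == 0
                o[zero] += 0.5
                exp[zero] += 0.5
                ratios = np.minimum(ratios, o / exp)
            q_stack = np.stack([per_scheme_q[k] for k in SHUFFLE_KINDS])
            interacting = bool((q_stack < config.q_alpha).all(axis=0).any())
            for w in range(scheme.n_windows):
                row = {
                    "anchor": anchor,
                    "partner": partner,
                    "window": w,
                    "observed": int(obs[w]),
                    "enrichment": ratios[w],
                    "interacting": interacting,
                }
                for kind in SHUFFLE_KINDS:
                    row[f"expected_{kind}"] = per_scheme_exp[kind][w]
                    row[f"p_{kind}"] = per_scheme_p[kind][w]
                    row[f"q_{kind}"] = per_scheme_q[kind][w]
                rows.append(row)
    return pd.DataFrame(rows)


def interacting_pairs(results: pd.DataFrame) -> list[tuple[str, str]]:
    """Unique (anchor, partner) pairs flagged interacting."""
    if results.empty:
        return []
    flagged = results[results["interacting"]]
    return sorted({(r.anchor, r.partner) for r in flagged.itertuples()})


def heatmap_table(results: pd.DataFrame, anchor: str) -> pd.DataFrame:
    """Log min-over-schemes enrichment ratios for one anchor: rows =
    partners, columns = windows (upstream to downstream)."""
    sub = results[results["anchor"] == anchor]
    mat = sub.pivot(index="partner", columns="window", values="enrichment")
    return np.log(mat)
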