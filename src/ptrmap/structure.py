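"""RNA secondary-structure accessibility and stem-loop cooperation scoring.

The built-in folding backend is a Boltzmann-weighted Nussinov model: nested
structures only, every legal pair (Watson-Crick + GU wobble) contributes one
unit of stability, a structure with ``p`` pairs has Boltzmann weight
``exp(p / temperature_weight)``, and hairpin loops contain at least three
unpaired bases.  Exact per-base unpaired probabilities come from the
inside-outside algorithm over this grammar and structures are drawn by
stochastic traceback, so the model is small enough to verify against
exhaustive enumeration yet behaves like a thermodynamic ensemble.  External
folding engines can be plugged in through the ``FoldBackend`` protocol or the
file adapters at the bottom of this module.

Accessibility of a site is the mean probability of being unpaired across the
site, computed on the 3'UTR concatenated with its upstream coding flank and
averaged over all local folding windows that contain each base (window
length W, maximum pair span L).  Candidate cooperating site pairs are
screened by ungapped reverse complementarity (>= ``min_bp`` base pairs),
scored by the average number of inter-site base pairs over sampled window
structures, and selected greedily so that each site joins at most one pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .config import RunConfig
from .io import Transcript
from .sites import Site

logger = logging.getLogger(__name__)

_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})
MIN_HAIRPIN = 3  # unpaired bases enclosed by any pair


def can_pair(a: str, b: str) -> bool:
    return a + b in _PAIRS


class FoldBackend(Protocol):
    """Minimal folding interface the pipeline depends on."""

    def unpaired_probabilities(
        self, seq: str, window_length: int, max_span: int, step: int = 1
    ) -> np.ndarray: ...

    def sample_structures(
        self, seq: str, n: int, rng: np.random.Generator, max_span: int | None = None
    ) -> list[set[tuple[int, int]]]: ...


# ---------------------------------------------------------------------------
# Built-in partition-function backend
# ---------------------------------------------------------------------------

class NussinovBackend:
    """Exact partition function, base-pair probabilities and Boltzmann
    sampling under the weighted Nussinov model described above."""

    def __init__(self, temperature_weight: float = 1.0):
        if temperature_weight <= 0:
            raise ValueError("temperature_weight must be positive")
        self.temperature_weight = temperature_weight
        self.pair_weight = float(np.exp(1.0 / temperature_weight))

    # -- partition function -------------------------------------------------

    def _partners(self, seq: str, max_span: int | None) -> list[np.ndarray]:
        """For each i, the sorted array of admissible partners k > i."""
        m = len(seq)
        span = max_span if max_span is not None else m
        out = []
        for i in range(m):
            ks = [
                k
                for k in range(i + MIN_HAIRPIN + 1, min(m, i + span + 1))
                if can_pair(seq[i], seq[k])
            ]
            out.append(np.array(ks, dtype=np.intp))
        return out

    def inside(self, seq: str, max_span: int | None = None) -> np.ndarray:
        """E[i, j] = partition function of the half-open segment [i, j)."""
        m = len(seq)
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"non-ACGU characters {sorted(bad)} in sequence")
        partners = self._partners(seq, max_span)
        w = self.pair_weight
        E = np.ones((m + 2, m + 2))
        for length in range(2, m + 1):
            for i in range(m - length + 1):
                j = i + length
                ks = partners[i]
                ks = ks[ks < j]
                total = E[i + 1, j]
                if len(ks):
                    total += w * float(E[i + 1, ks] @ E[ks + 1, j])
                E[i, j] = total
        return E

    def pair_probabilities(self, seq: str, max_span: int | None = None) -> np.ndarray:
        """P[i, k] = probability that bases i and k are paired (i < k)."""
        m = len(seq)
        E = self.inside(seq, max_span)
        partners = self._partners(seq, max_span)
        w = self.pair_weight
        O = np.zeros((m + 2, m + 2))
        O[0, m] = 1.0
        P = np.zeros((m, m))
        for length in range(m, 1, -1):
            for i in range(m - length + 1):
                j = i + length
                o = O[i, j]
                if o == 0.0:
                    continue
                O[i + 1, j] += o
                ks = partners[i]
                ks = ks[ks < j]
                if len(ks):
                    inner = E[i + 1, ks]      # E of [i+1, k)
                    outer = E[ks + 1, j]      # E of [k+1, j)
                    contrib = o * w * inner * outer
                    np.add.at(P[i], ks, contrib)
                    np.add.at(O[i + 1], ks, o * w * outer)
                    np.add.at(O[:, j], ks + 1, o * w * inner)
        return P / E[0, m]

    def exact_unpaired(self, seq: str, max_span: int | None = None) -> np.ndarray:
        """Exact per-base unpaired probability for one global fold."""
        P = self.pair_probabilities(seq, max_span)
        return 1.0 - (P.sum(axis=0) + P.sum(axis=1))

    # -- FoldBackend protocol -----------------------------------------------

    def unpaired_probabilities(
        self, seq: str, window_length: int, max_span: int, step: int = 1
    ) -> np.ndarray:
        """Per-base unpaired probability, averaged over the length-W windows
        containing the base (single global fold when |seq| <= W).

        ``step`` strides the window starts; the default 1 averages over
        every window, larger strides trade resolution for speed on long
        sequences (the final window is always included so all bases are
        covered)."""
        m = len(seq)
        if m <= window_length:
            return self.exact_unpaired(seq, max_span)
        if step < 1:
            raise ValueError("step must be >= 1")
        sums = np.zeros(m)
        counts = np.zeros(m)
        starts = list(range(0, m - window_length + 1, step))
        if starts[-1] != m - window_length:
            starts.append(m - window_length)
        for s in starts:
            p = self.exact_unpaired(seq[s : s + window_length], max_span)
            sums[s : s + window_length] += p
            counts[s : s + window_length] += 1
        return sums / counts

    def sample_structures(
        self,
        seq: str,
        n: int,
        rng: np.random.Generator,
        max_span: int | None = None,
    ) -> list[set[tuple[int, int]]]:
        """Draw ``n`` structures from the Boltzmann distribution by
        stochastic traceback through the inside matrix."""
        m = len(seq)
        E = self.inside(seq, max_span)
        partners = self._partners(seq, max_span)
        w = self.pair_weight
        out: list[set[tuple[int, int]]] = []
        for _ in range(n):
            pairs: set[tuple[int, int]] = set()
            stack = [(0, m)]
            while stack:
                i, j = stack.pop()
                while j - i >= 2:
                    r = rng.random() * E[i, j]
                    if r < E[i + 1, j]:
                        i += 1
                        continue
                    ks = partners[i]
                    ks = ks[ks < j]
                    weights = w * E[i + 1, ks] * E[ks + 1, j]
                    r -= E[i + 1, j]
                    k = int(ks[np.searchsorted(np.cumsum(weights), r, side="right")])
                    pairs.add((i, k))
                    stack.append((k + 1, j))
                    i, j = i + 1, k
            out.append(pairs)
        return out


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityProfile:
    """Windowed unpaired probabilities over flank + UTR of one transcript."""

    transcript_id: str
    values: np.ndarray  # length = |flank| + |UTR|
    window_length: int
    max_span: int
    flank_length: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < -1e-9) | (self.values > 1 + 1e-9)).any():
            raise ValueError("unpaired probabilities outside [0,1]")


def accessibility_profile(
    transcript: Transcript, backend: FoldBackend, config: RunConfig
) -> AccessibilityProfile:
    """Fold flank + UTR with local windows of length W and pair span <= L."""
    seq = transcript.folded_seq
    values = backend.unpaired_probabilities(
        seq, config.window_length, config.max_pair_span, config.window_step
    )
    return AccessibilityProfile(
        transcript_id=transcript.id,
        values=values,
        window_length=config.window_length,
        max_span=config.max_pair_span,
        flank_length=len(transcript.flank_seq),
    )


def site_accessibility(site: Site, profile: AccessibilityProfile) -> float:
    """Mean unpaired probability across the site (UTR coordinates)."""
    lo = site.start + profile.flank_length
    hi = site.end + profile.flank_length
    if lo < 0 or hi > len(profile.values):
        raise ValueError(
            f"site [{site.start},{site.end}) outside accessibility profile "
            f"({len(profile.values) - profile.flank_length} UTR bases)"
        )
    return float(np.mean(profile.values[lo:hi]))


# ---------------------------------------------------------------------------
# Stem-loop pair scoring
# ---------------------------------------------------------------------------

def revcomp_bp_count(site_a_seq: str, site_b_seq: str) -> int:
    """Maximum base pairs over all ungapped antiparallel registers.

    GU wobble counts as a pair, consistent with the thermodynamic model."""
    if not site_a_seq or not site_b_seq:
        raise ValueError("both site sequences must be non-empty")
    rb = site_b_seq[::-1]
    best = 0
    for offset in range(-(len(rb) - 1), len(site_a_seq)):
        count = 0
        for i in range(max(0, offset), min(len(site_a_seq), offset + len(rb))):
            if can_pair(site_a_seq[i], rb[i - offset]):
                count += 1
        best = max(best, count)
    return best


def _coords(site: Site | tuple[int, int], offset: int) -> tuple[int, int]:
    if isinstance(site, tuple):
        start, end = site
    else:
        start, end = site.start, site.end
    return start + offset, end + offset


def enumerate_stem_windows(
    site_a: Site | tuple[int, int],
    site_b: Site | tuple[int, int],
    seq_length: int,
    window_length: int,
    *,
    offset: int = 0,
) -> list[int]:
    """Start positions of every length-W window fully containing both sites.

    For an unclipped pair the count is W - span + 1 with span = end_b -
    start_a; windows truncated by the sequence boundaries are dropped.
    ``offset`` shifts UTR coordinates into the folded (flank + UTR) sequence.
    """
    start_a, _ = _coords(site_a, offset)
    start_b, end_b = _coords(site_b, offset)
    if start_a > start_b:
        raise ValueError("site_a must start before site_b")
    lo = max(0, end_b - window_length)
    hi = min(start_a, seq_length - window_length)
    return list(range(lo, hi + 1)) if hi >= lo else []


@dataclass
class StemPairCandidate:
    """A pair of sites screened for stem-loop formation potential."""

    site_a: Site
    site_b: Site
    bp_count: int = 0
    stem_score: float = 0.0
    selected: bool = False

    def __post_init__(self) -> None:
        if self.site_a.start > self.site_b.start:
            raise ValueError("site_a must start before site_b")
        if self.stem_score < 0:
            raise ValueError("stem_score must be >= 0")


def stem_score(
    site_a: Site,
    site_b: Site,
    transcript: Transcript,
    backend: FoldBackend,
    config: RunConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Average number of base pairs formed between the two sites.

    For every window containing both sites, ``n_structure_samples``
    structures are drawn and the inter-site pair count averaged; the final
    score is the mean over windows.  It estimates the Boltzmann expectation
    of the inter-site pair count and can exceed 1.
    """
    if rng is None:
        rng = config.rng("stem_score")
    seq = transcript.folded_seq
    offset = len(transcript.flank_seq)
    windows = enumerate_stem_windows(
        site_a, site_b, len(seq), config.window_length, offset=offset
    )
    if not windows:
        warnings.warn(
            f"no folding window contains both sites [{site_a.start},{site_a.end}) "
            f"and [{site_b.start},{site_b.end}) on {transcript.id}; score 0"
        )
        return 0.0
    a_lo, a_hi = site_a.start + offset, site_a.end + offset
    b_lo, b_hi = site_b.start + offset, site_b.end + offset
    window_means = []
    for s in windows:
        wseq = seq[s : s + config.window_length]
        structures = backend.sample_structures(
            wseq, config.n_structure_samples, rng, max_span=config.max_pair_span
        )
        counts = []
        for pairs in structures:
            n_inter = 0
            for i, j in pairs:
                gi, gj = s + i, s + j
                in_a = (a_lo <= gi < a_hi), (a_lo <= gj < a_hi)
                in_b = (b_lo <= gi < b_hi), (b_lo <= gj < b_hi)
                if (in_a[0] and in_b[1]) or (in_b[0] and in_a[1]):
                    n_inter += 1
            counts.append(n_inter)
        window_means.append(float(np.mean(counts)))
    return float(np.mean(window_means))


def expected_inter_site_pairs(
    site_a: Site,
    site_b: Site,
    transcript: Transcript,
    backend: NussinovBackend,
    config: RunConfig,
) -> float:
    """Exact counterpart of :func:`stem_score`: the Boltzmann expectation of
    the inter-site pair count from base-pair probabilities, no sampling."""
    seq = transcript.folded_seq
    offset = len(transcript.flank_seq)
    windows = enumerate_stem_windows(
        site_a, site_b, len(seq), config.window_length, offset=offset
    )
    if not windows:
        return 0.0
    a_lo, a_hi = site_a.start + offset, site_a.end + offset
    b_lo, b_hi = site_b.start + offset, site_b.end + offset
    means = []
    for s in windows:
        P = backend.pair_probabilities(
            seq[s : s + config.window_length], config.max_pair_span
        )
        total = 0.0
        for gi in range(a_lo, a_hi):
            for gj in range(b_lo, b_hi):
                i, j = gi - s, gj - s
                total += P[min(i, j), max(i, j)]
        means.append(total)
    return float(np.mean(means))


def select_stem_pairs(
    candidates: Sequence[StemPairCandidate], config: RunConfig
) -> list[StemPairCandidate]:
    """Greedy matching: drop scores below threshold, sort by score (desc),
    then bp_count (desc), then leftmost pair; accept a pair only when neither
    site already belongs to an accepted pair."""

    def sitekey(s: Site) -> tuple:
        return (s.transcript_id, s.factor_id, s.start, s.end)

    eligible = [c for c in candidates if c.stem_score >= config.stem_score_threshold]
    eligible.sort(
        key=lambda c: (
            -c.stem_score,
            -c.bp_count,
            c.site_a.start,
            c.site_b.start,
            sitekey(c.site_a),
            sitekey(c.site_b),
        )
    )
    used: set[tuple] = set()
    selected: list[StemPairCandidate] = []
    for c in eligible:
        ka, kb = sitekey(c.site_a), sitekey(c.site_b)
        if ka in used or kb in used:
            continue
        used.update((ka, kb))
        c.selected = True
        selected.append(c)
    return selected


def screen_stem_candidates(
    sites_a: Sequence[Site],
    sites_b: Sequence[Site],
    transcript: Transcript,
    config: RunConfig,
) -> list[StemPairCandidate]:
    """All ordered (upstream, downstream) pairs passing the >= min_bp
    reverse-complementarity filter, not yet structure-scored."""
    seq = transcript.utr_seq
    out = []
    for sa in sites_a:
        for sb in sites_b:
            first, second = (sa, sb) if sa.start <= sb.start else (sb, sa)
            if first is second or first.overlaps(second):
                continue
            bp = revcomp_bp_count(
                seq[first.start : first.end], seq[second.start : second.end]
            )
            if bp >= config.min_bp:
                out.append(StemPairCandidate(site_a=first, site_b=second, bp_count=bp))
    return out


# ---------------------------------------------------------------------------
# External-backend adapters
# ---------------------------------------------------------------------------

def read_unpaired_table(path: str | Path, length: int) -> np.ndarray:
    """RNAplfold ``_lunp``-style table: 1-based position, single-base
    unpaired probability in the second column.  Comment lines ignored."""
    values = np.full(length, np.nan)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            pos = int(fields[0]) - 1
            if 0 <= pos < length:
                values[pos] = float(fields[1])
    if np.isnan(values).any():
        raise ValueError(f"unpaired table {path} does not cover all {length} positions")
    return values


def parse_dotbracket(structure: str) -> set[tuple[int, int]]:
    """Dot-bracket string -> set of (i, j) pairs, 0-based, i < j."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket string")
    return pairs


def read_dotbracket_samples(path: str | Path) -> list[set[tuple[int, int]]]:
    """One dot-bracket structure per line, e.g. an external sampler's output."""
    with open(path) as fh:
        return [parse_dotbracket(line.strip()) for line in fh if line.strip()]


class PrecomputedBackend:
    """Serve externally computed unpaired probabilities and/or structure
    samples (e.g. imported RNAplfold / Boltzmann-sampler output) behind the
    FoldBackend interface."""

    def __init__(
        self,
        unpaired: np.ndarray | None = None,
        samples: Sequence[set[tuple[int, int]]] | None = None,
    ):
        self.unpaired = None if unpaired is None else np.asarray(unpaired, dtype=float)
        self.samples = list(samples) if samples is not None else None

    def unpaired_probabilities(self, seq, window_length, max_span, step=1):
        if self.unpaired is None or len(self.unpaired) != len(seq):
            raise ValueError("no precomputed unpaired probabilities for this sequence")
        return self.unpaired

    def sample_structures(self, seq, n, rng, max_span=None):
        if self.samples is None:
            raise ValueError("no precomputed structure samples")
        idx = rng.integers(0, len(self.samples), size=n)
        return [self.samples[i] for i in idx]
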