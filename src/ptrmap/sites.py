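"""Binding-site calling on 3'UTRs and site-level annotation.

A site is an exact match of one of a factor's k-mers (or IUPAC consensus) on
the UTR.  Each site carries flags for in vivo support (CLIP / gPAR-CLIP peak
overlap), prediction sources (miRNA sites only) and the mean conservation
score across the matched positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Interval, Transcript
from .motifs import IUPAC, Motif, motif_kmers

logger = logging.getLogger(__name__)


@dataclass
class Site:
    transcript_id: str
    factor_id: str
    start: int
    end: int
    factor_class: str = "RBP"
    matched_kmer: str = ""
    clip_supported: bool = False
    clip_percentile: float | None = None
    gparclip_supported: bool = False
    conservation_mean: float | None = None
    pred_targetscan: bool = False
    pred_pictar: bool = False
    pred_mirtarbase: bool = False
    pred_agoclip: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid site [{self.start},{self.end})")
        if self.matched_kmer and self.end - self.start != len(self.matched_kmer):
            raise ValueError("site width must equal matched k-mer length")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Site") -> bool:
        """Share >= 1 position on the same transcript (half-open)."""
        return (
            self.transcript_id == other.transcript_id
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _kmer_matches(seq: str, kmer: str) -> Iterable[int]:
    """All (overlapping) exact-match start positions of kmer in seq."""
    pos = seq.find(kmer)
    while pos != -1:
        yield pos
        pos = seq.find(kmer, pos + 1)


def _consensus_matches(seq: str, consensus: str) -> Iterable[int]:
    k = len(consensus)
    allowed = [frozenset(IUPAC[ch]) for ch in consensus]
    for pos in range(len(seq) - k + 1):
        if all(seq[pos + j] in allowed[j] for j in range(k)):
            yield pos


def scan_sites(
    transcript: Transcript,
    motifs: Motif | Sequence[Motif],
    *,
    top_n: int = 10,
) -> list[Site]:
    """Exact-match scan of one factor's motif(s) against a 3'UTR.

    PFMs are resolved to their top-``top_n`` k-mers; all representations of
    the same factor are scanned independently and pooled.  Overlapping
    matches are all reported; sites are sorted by (start, end).
    """
    if isinstance(motifs, Motif):
        motifs = [motifs]
    if not motifs:
        return []
    factor_ids = {m.factor_id for m in motifs}
    if len(factor_ids) != 1:
        raise ValueError(f"scan_sites expects one factor, got {sorted(factor_ids)}")
    factor_id = motifs[0].factor_id
    factor_class = motifs[0].factor_class
    seq = transcript.utr_seq

    hits: dict[tuple[int, int], str] = {}
    # explicit k-mers (PFM top-n and literal sets) in one pooled pass
    kmers = motif_kmers([m for m in motifs if m.consensus is None], n=top_n)
    for kmer in kmers:
        if len(kmer) > len(seq):
            continue
        for pos in _kmer_matches(seq, kmer):
            hits.setdefault((pos, pos + len(kmer)), kmer)
    for m in motifs:
        if m.consensus is None or len(m.consensus) > len(seq):
            continue
        for pos in _consensus_matches(seq, m.consensus):
            span = (pos, pos + len(m.consensus))
            hits.setdefault(span, seq[span[0] : span[1]])

    return [
        Site(
            transcript_id=transcript.id,
            factor_id=factor_id,
            factor_class=factor_class,
            start=start,
            end=end,
            matched_kmer=kmer,
        )
        for (start, end), kmer in sorted(hits.items())
    ]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_clip(
    sites: Sequence[Site], peaks: Sequence[Interval], source: str = "clip"
) -> list[Site]:
    """Flag sites overlapping a (background-subtracted) peak by >= 1 nt.

    For CLIP, ``clip_percentile`` becomes the numerically smallest (best)
    percentile among overlapping peaks.  Existing flags are never unset.
    """
    if source not in {"clip", "gparclip"}:
        raise ValueError("source must be 'clip' or 'gparclip'")
    by_tid: dict[str, list[Interval]] = {}
    for p in peaks:
        by_tid.setdefault(p.transcript_id, []).append(p)
    out: list[Site] = []
    for site in sites:
        overlapping = [
            p
            for p in by_tid.get(site.transcript_id, [])
            if p.start < site.end and site.start < p.end
        ]
        site = replace(site)
        if overlapping:
            if source == "clip":
                site.clip_supported = True
                pcts = [p.score_percentile for p in overlapping if p.score_percentile is not None]
                if pcts:
                    best = min(pcts)
                    if site.clip_percentile is None or best < site.clip_percentile:
                        site.clip_percentile = best
            else:
                site.gparclip_supported = True
        out.append(site)
    return out


def annotate_conservation(
    sites: Sequence[Site], conservation: Mapping[str, np.ndarray] | None
) -> list[Site]:
    """Attach the mean per-base conservation over [start, end) to each site.

    A missing track leaves ``conservation_mean`` unset (never zero)."""
    out = []
    for site in sites:
        site = replace(site)
        track = None if conservation is None else conservation.get(site.transcript_id)
        if track is not None:
            if site.end > len(track):
                raise ValueError(
                    f"site [{site.start},{site.end}) outside conservation track "
                    f"of length {len(track)} on {site.transcript_id}"
                )
            site.conservation_mean = float(np.mean(track[site.start : site.end]))
        out.append(site)
    return out


def assemble_mirna_sites(
    predicted: Mapping[str, Sequence[Site]],
    validated_pairs: Iterable[tuple[str, str]],
    ago_peaks: Sequence[Interval],
    *,
    known_transcripts: set[str] | None = None,
) -> list[Site]:
    """Merge per-source miRNA site predictions into one flagged site list.

    ``predicted`` maps source name ('targetscan' / 'pictar') to site lists.
    Same-miRNA sites from different sources that overlap are merged into one
    site spanning their union, carrying both source flags.  Pair-level
    validation (miRTarBase-style) sets ``pred_mirtarbase`` on every site of
    that miRNA on that transcript; Ago-CLIP support requires >= 1 nt peak
    overlap.
    """
    flag_for = {"targetscan": "pred_targetscan", "pictar": "pred_pictar"}
    pool: list[Site] = []
    n_skipped = 0
    for source, sites in predicted.items():
        if source not in flag_for:
            raise ValueError(f"unknown miRNA prediction source {source!r}")
        for s in sites:
            if known_transcripts is not None and s.transcript_id not in known_transcripts:
                n_skipped += 1
                continue
            s = replace(s, factor_class="miRNA")
            setattr(s, flag_for[source], True)
            pool.append(s)
    if n_skipped:
        logger.warning("assemble_mirna_sites: skipped %d sites on unknown transcripts", n_skipped)

    # merge overlapping same-miRNA, same-transcript sites (union span, OR flags)
    merged: list[Site] = []
    keyfn = lambda s: (s.transcript_id, s.factor_id, s.start, s.end)
    for s in sorted(pool, key=keyfn):
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.transcript_id == s.transcript_id
            and last.factor_id == s.factor_id
            and s.start < last.end
        ):
            last.end = max(last.end, s.end)
            last.matched_kmer = ""
            last.pred_targetscan |= s.pred_targetscan
            last.pred_pictar |= s.pred_pictar
        else:
            merged.append(replace(s))

    validated = {(mirna, tid) for mirna, tid in validated_pairs}
    for s in merged:
        if (s.factor_id, s.transcript_id) in validated:
            s.pred_mirtarbase = True

    by_tid: dict[str, list[Interval]] = {}
    for p in ago_peaks:
        by_tid.setdefault(p.transcript_id, []).append(p)
    for s in merged:
        s.pred_agoclip = any(
            p.start < s.end and s.start < p.end for p in by_tid.get(s.transcript_id, [])
        )
    return merged


def collapse_homotypic(sites: Sequence[Site]) -> list[Site]:
    """Collapse homotypic clusters: within each (transcript, factor), group
    sites by transitive overlap and keep only the most upstream member.

    Guards co-occurrence counting against U-rich regions producing many
    overlapping same-factor matches.
    """
    out: list[Site] = []
    groups: dict[tuple[str, str], list[Site]] = {}
    for s in sites:
        groups.setdefault((s.transcript_id, s.factor_id), []).append(s)
    for key in groups:
        chain_end = -1
        for s in sorted(groups[key], key=lambda s: (s.start, s.end)):
            if s.start >= chain_end:  # new transitive-overlap chain
                out.append(s)
                chain_end = s.end
            else:
                chain_end = max(chain_end, s.end)
    out.sort(key=lambda s: (s.transcript_id, s.start, s.end, s.factor_id))
    return out


# ---------------------------------------------------------------------------
# Site table I/O (extended BED)
# ---------------------------------------------------------------------------

_FLAGS = (
    "clip_supported",
    "gparclip_supported",
    "pred_targetscan",
    "pred_pictar",
    "pred_mirtarbase",
    "pred_agoclip",
)


def write_sites(sites: Iterable[Site], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#transcript_id\tstart\tend\tfactor_id\tfactor_class\tmatched_kmer\t"
            "flags\tclip_percentile\tconservation_mean\n"
        )
        for s in sites:
            flags = ",".join(f for f in _FLAGS if getattr(s, f)) or "."
            pct = "." if s.clip_percentile is None else f"{s.clip_percentile:g}"
            cons = "." if s.conservation_mean is None else f"{s.conservation_mean:.4f}"
            fh.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.factor_id}\t"
                f"{s.factor_class}\t{s.matched_kmer or '.'}\t{flags}\t{pct}\t{cons}\n"
            )


def read_sites(path: str | Path) -> list[Site]:
    out: list[Site] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            (tid, start, end, factor, fclass, kmer, flags, pct, cons) = line.split("\t")
            site = Site(
                transcript_id=tid,
                factor_id=factor,
                factor_class=fclass,
                start=int(start),
                end=int(end),
                matched_kmer="" if kmer == "." else kmer,
                clip_percentile=None if pct == "." else float(pct),
                conservation_mean=None if cons == "." else float(cons),
            )
            if flags != ".":
                for f in flags.split(","):
                    setattr(site, f, True)
            out.append(site)
    return out
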