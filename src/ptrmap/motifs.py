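"""Motif representations and k-mer generation.

A factor's binding preference arrives as one of three representations:
a position frequency matrix (k columns of A/C/G/U probabilities), an IUPAC
consensus string, or an explicit k-mer set.  PFMs are scanned via their top-n
most probable k-mers (n = 10 by default), which lets motifs longer than the
measured 7-mers be represented exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


@dataclass
class Motif:
    """One motif representation for one factor.

    Exactly one of ``pfm`` (k x 4 array over A,C,G,U), ``consensus`` (IUPAC
    string) or ``kmers`` (explicit list) is set.  A factor may own several
    Motif records (e.g. multiple in vitro-derived PFMs); their k-mer sets are
    pooled before scanning.
    """

    factor_id: str
    factor_class: str = "RBP"  # or "miRNA"
    pfm: np.ndarray | None = None
    consensus: str | None = None
    kmers: list[str] | None = None

    def __post_init__(self) -> None:
        reps = sum(x is not None for x in (self.pfm, self.consensus, self.kmers))
        if reps != 1:
            raise ValueError(
                f"motif {self.factor_id}: exactly one representation required, got {reps}"
            )
        if self.pfm is not None:
            self.pfm = np.asarray(self.pfm, dtype=float)
            if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
                raise ValueError(f"motif {self.factor_id}: PFM must be k x 4")
            if not (4 <= self.pfm.shape[0] <= 12):
                raise ValueError(f"motif {self.factor_id}: PFM length outside [4,12]")
            sums = self.pfm.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"motif {self.factor_id}: PFM columns must sum to 1")
        if self.consensus is not None:
            self.consensus = self.consensus.upper().replace("T", "U")
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"motif {self.factor_id}: non-IUPAC characters {sorted(bad)}")
        if self.kmers is not None:
            self.kmers = [k.upper().replace("T", "U") for k in self.kmers]
            for k in self.kmers:
                bad = set(k) - set(BASES)
                if bad:
                    raise ValueError(f"motif {self.factor_id}: non-ACGU k-mer {k}")

    @property
    def width(self) -> int:
        if self.pfm is not None:
            return self.pfm.shape[0]
        if self.consensus is not None:
            return len(self.consensus)
        return max(len(k) for k in self.kmers)  # type: ignore[arg-type]


def top_n_kmers(pfm: np.ndarray, n: int = 10) -> list[str]:
    """The ``n`` k-mers with highest product probability under a PFM.

    Ties are broken lexicographically.  If fewer than ``n`` k-mers exist
    (4^k < n), all are returned.  Uses a beam of width ``n`` over prefixes;
    because every extension multiplies all prefixes by column factors drawn
    from the same set, the top-n prefixes at each column suffice.
    """
    pfm = np.asarray(pfm, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    beam: list[tuple[float, str]] = [(1.0, "")]
    for col in pfm:
        extended = [
            (prob * col[BASE_INDEX[b]], prefix + b) for prob, prefix in beam for b in BASES
        ]
        extended.sort(key=lambda item: (-item[0], item[1]))
        beam = extended[:n]
    return [kmer for _, kmer in beam]


def consensus_to_kmers(consensus: str, *, max_expansion: int = 65536) -> list[str]:
    """Expand an IUPAC consensus into its explicit k-mer set."""
    kmers = [""]
    for ch in consensus.upper().replace("T", "U"):
        options = IUPAC[ch]
        kmers = [k + b for k in kmers for b in options]
        if len(kmers) > max_expansion:
            raise ValueError(f"consensus {consensus} expands past {max_expansion} k-mers")
    return kmers


def motif_kmers(motifs: Iterable[Motif], n: int = 10) -> list[str]:
    """Pooled, deduplicated k-mer set for one factor's motif records."""
    pooled: list[str] = []
    seen: set[str] = set()
    for m in motifs:
        if m.pfm is not None:
            kmers = top_n_kmers(m.pfm, n)
        elif m.consensus is not None:
            kmers = consensus_to_kmers(m.consensus)
        else:
            kmers = list(m.kmers or [])
        for k in kmers:
            if k not in seen:
                seen.add(k)
                pooled.append(k)
    return pooled


def motif_to_pfm(motif: Motif) -> np.ndarray:
    """Any representation -> PFM.  Consensus columns become uniform over the
    allowed bases; k-mer sets become per-position empirical frequencies."""
    if motif.pfm is not None:
        return motif.pfm
    if motif.consensus is not None:
        cols = []
        for ch in motif.consensus:
            col = np.zeros(4)
            for b in IUPAC[ch]:
                col[BASE_INDEX[b]] = 1.0 / len(IUPAC[ch])
            cols.append(col)
        return np.array(cols)
    kmers = motif.kmers or []
    width = max(len(k) for k in kmers)
    pfm = np.zeros((width, 4))
    counts = np.zeros(width)
    for k in kmers:
        for j, b in enumerate(k):
            pfm[j, BASE_INDEX[b]] += 1
            counts[j] += 1
    counts[counts == 0] = 1
    return pfm / counts[:, None]


def motif_similarity(a: Motif | np.ndarray, b: Motif | np.ndarray, *, min_overlap: int = 4) -> float:
    """Best ungapped-offset mean column Pearson correlation between two PFMs.

    Columns with zero variance contribute correlation 0.  Overlaps shorter
    than ``min_overlap`` columns (or the shorter motif) are not considered.
    """
    pa = motif_to_pfm(a) if isinstance(a, Motif) else np.asarray(a, dtype=float)
    pb = motif_to_pfm(b) if isinstance(b, Motif) else np.asarray(b, dtype=float)
    ka, kb = pa.shape[0], pb.shape[0]
    need = min(min_overlap, ka, kb)
    best = -1.0
    for offset in range(-(kb - need), ka - need + 1):
        a_lo, a_hi = max(0, offset), min(ka, offset + kb)
        if a_hi - a_lo < need:
            continue
        cols_a = pa[a_lo:a_hi]
        cols_b = pb[a_lo - offset : a_hi - offset]
        corrs = []
        for ca, cb in zip(cols_a, cols_b):
            sa, sb = ca.std(), cb.std()
            if sa < 1e-12 or sb < 1e-12:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(ca, cb)[0, 1]))
        best = max(best, float(np.mean(corrs)))
    return best


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_pfm_motifs(path: str | Path) -> list[Motif]:
    """Minimal PFM blocks::

        >FACTOR_ID RBP
        0.7  0.1  0.1  0.1
        ...  (k rows, columns A C G U)
    """
    motifs: list[Motif] = []
    factor: str | None = None
    fclass = "RBP"
    rows: list[list[float]] = []

    def _flush() -> None:
        if factor is not None:
            motifs.append(Motif(factor_id=factor, factor_class=fclass, pfm=np.array(rows)))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split()
                factor, fclass = parts[0], parts[1] if len(parts) > 1 else "RBP"
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
        _flush()
    return motifs


def read_kmer_motifs(path: str | Path) -> list[Motif]:
    """TSV: ``factor_id  factor_class  {consensus|kmers}  STRING[,STRING...]``."""
    motifs: list[Motif] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            factor, fclass, rep, payload = line.split("\t")[:4]
            if rep == "consensus":
                motifs.append(Motif(factor_id=factor, factor_class=fclass, consensus=payload))
            elif rep == "kmers":
                motifs.append(Motif(factor_id=factor, factor_class=fclass, kmers=payload.split(",")))
            else:
                raise ValueError(f"unknown motif representation {rep!r} for {factor}")
    return motifs


def write_pfm_motifs(motifs: Iterable[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            pfm = motif_to_pfm(m)
            fh.write(f">{m.factor_id} {m.factor_class}\n")
            for row in pfm:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")
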