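"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emits the exact artefacts the analysis consumes -- UTR FASTA,
site and CLIP-peak BED, conservation bedGraph, expression/half-life TSV --
with a ground-truth record for parameter-recovery tests.  It emulates:

* random-composition 3'UTRs (log-normal lengths, AU-rich base composition)
  with upstream coding flanks;
* planted motif instances (exact k-mer copies, non-self-overlapping per
  factor) plus optional cross-factor overlaps that create competition;
* CLIP peaks covering a configurable fraction of planted sites (padded,
  with rank percentiles) and decoy peaks on empty regions;
* conservation elevated at a fraction of functional sites (Beta(8,2) over a
  Beta(1,3) baseline);
* co-localized partner sites within a gap of an anchor factor's sites, and
  stem-loop partners planted as exact reverse complements;
* knockdown log fold changes with CLIP / competition / cooperation /
  stem-loop effects and optional length/expression confounding;
* half-lives driven by activator / repressor / miRNA site counts plus
  dinucleotide composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionRecord, Interval, Transcript
from .sites import Site
from .stability import FactorGroups, dinucleotide_counts, group_site_counts

RNA = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FactorSpec:
    """One synthetic factor: id, class and the exact k-mers it binds."""

    factor_id: str
    kmers: tuple[str, ...]
    factor_class: str = "RBP"
    density: float = 2.0  # planted sites per kb of UTR


@dataclass(frozen=True)
class ColocSpec:
    """Planted co-localization: for each site of ``factor_a``, with
    probability ``prob_per_site`` plant a ``factor_b`` site whose start lies
    within ``max_gap`` nt downstream of the anchor's end."""

    factor_a: str
    factor_b: str
    max_gap: int = 50
    prob_per_site: float = 0.4


@dataclass(frozen=True)
class StemSpec:
    """Planted stem-loop partners: per transcript, with probability ``prob``
    plant a ``factor_a`` site and, ``min_sep``..``max_sep`` nt downstream,
    a ``factor_b`` site that is its exact reverse complement."""

    factor_a: str
    factor_b: str
    prob: float = 0.3
    min_sep: int = 20
    max_sep: int = 100


def default_roster() -> list[FactorSpec]:
    """Five RBP-like factors with 7-mer sets of mixed (3-5) AU content, so
    AU-stratified shuffling mixes factor identities within strata."""
    return [
        FactorSpec("FACA", ("UGUAGCU", "UGUAGCA")),
        FactorSpec("FACB", ("ACCUGUG", "GCAUCAU")),
        FactorSpec("FACC", ("CAUGCUA", "CCAUGUU")),
        FactorSpec("FACD", ("GGUAUCU", "GGACUAU")),
        FactorSpec("FACE", ("AGGCAUA", "UCCGUAU")),
    ]


def halflife_roster() -> list[FactorSpec]:
    """Activator / repressor / miRNA factors named after the default
    stability-model rosters."""
    specs = [
        FactorSpec("HuR", ("UUUAGUU", "UUUCAUU"), density=1.5),
        FactorSpec("HNRNPL", ("ACACGAC", "ACACAGC"), density=1.5),
        FactorSpec("PABPC1", ("AGAAGAC", "AAGACGA"), density=1.5),
        FactorSpec("IGF2BP2", ("CGGACUC", "CAGGACU"), density=1.5),
        FactorSpec("PUM1", ("UGUACAG", "UGUACCG"), density=1.5),
        FactorSpec("TIA1", ("UCCCGAU", "UCCCUGA"), density=1.5),
        FactorSpec("HNRNPC", ("GUUUCGC", "CGUUUCG"), density=1.5),
        FactorSpec("ZFP36", ("UAUUCGC", "AUUCGCA"), density=1.5),
    ]
    mirnas = [
        FactorSpec("miR-901", ("GCACUUC",), factor_class="miRNA", density=1.5),
        FactorSpec("miR-902", ("CUGGAUC",), factor_class="miRNA", density=1.5),
        FactorSpec("miR-903", ("GACGGUC",), factor_class="miRNA", density=1.5),
        FactorSpec("miR-904", ("CCGAAGU",), factor_class="miRNA", density=1.5),
    ]
    return specs + mirnas


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Effect sizes follow the structure of RBP-knockdown experiments: a
    negative ``delta_clip`` emulates a stabilizer (targets destabilized on
    knockdown), ``delta_other`` is the weaker effect of sites lacking in
    vivo support, and ``competition_attenuation`` scales the effect when
    every site of the knocked-down factor is overlapped by another factor's
    site.
    """

    n_transcripts: int = 1000
    utr_length_median: float = 1000.0
    utr_length_sigma: float = 0.5   # log-normal sigma of UTR lengths
    min_utr_length: int = 250
    au_fraction: float = 0.55
    flank_length: int = 200
    n_chromosomes: int = 10
    factors: list[FactorSpec] = field(default_factory=default_roster)
    coloc_pairs: list[ColocSpec] = field(default_factory=list)
    stem_pairs: list[StemSpec] = field(default_factory=list)
    knockdown_factor: str | None = None  # default: first factor in roster
    overlap_prob: float = 0.3    # chance an anchor-factor site gets an overlapping competitor
    clip_coverage: float = 0.5
    clip_peak_pad: int = 10
    decoy_peak_density: float = 0.5  # peaks per kb on empty regions
    conservation_boost_fraction: float = 0.7
    # knockdown LFC effects
    delta_clip: float = -1.0
    delta_other: float = -0.5
    delta_nosite: float = 0.0
    competition_attenuation: float = 0.5
    coop_boost: float = 0.0
    stemloop_boost: float = 0.0
    noise_sigma: float = 0.5
    confounded: bool = False     # add length/expression confounding to LFC
    length_coef: float = -0.0004  # per-nt LFC shift when confounded
    expression_coef: float = 0.1  # per-log-expression-unit shift when confounded
    # half-life model
    beta_activators: float = 0.5
    beta_repressors: float = 0.5
    beta_mirnas: float = 0.5
    gamma_dinuc_sigma: float = 0.1
    halflife_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.competition_attenuation <= 1):
            raise ValueError("competition_attenuation must be in [0,1]")
        if self.noise_sigma <= 0 or self.halflife_sigma <= 0:
            raise ValueError("noise sigmas must be positive")
        for spec in self.factors:
            if spec.density < 0:
                raise ValueError(f"negative site density for {spec.factor_id}")
        if self.knockdown_factor is None and self.factors:
            self.knockdown_factor = self.factors[0].factor_id

    def rng(self, stage: str) -> np.random.Generator:
        digest = np.frombuffer(stage.encode(), dtype=np.uint8)
        return np.random.default_rng([self.seed, *digest.tolist()])


def stability_config(seed: int = 0, n_transcripts: int = 2000) -> SynthConfig:
    """Study conditions for the half-life / stability experiment.

    Mirrors a fixed-length 3'UTR-segment stability assay: near-constant
    300-nt segments (so composition, not length, drives dinucleotide
    features), the activator/repressor/miRNA roster, balanced group effects
    (beta = 0.5 per site) and measurement noise sized so that classification
    of the extremes is informative but imperfect.
    """
    return SynthConfig(
        n_transcripts=n_transcripts,
        factors=halflife_roster(),
        overlap_prob=0.0,
        utr_length_median=300.0,
        utr_length_sigma=0.02,
        min_utr_length=160,
        halflife_sigma=3.0,
        seed=seed,
    )


@dataclass
class PlantedSite:
    """Ground-truth record aligned with one emitted site."""

    planted: bool = True
    intended_clip: bool = False
    intact: bool = True        # sequence still carries the exact k-mer
    coloc_partner: bool = False
    stem_partner: bool = False


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    site_info: list[PlantedSite] = field(default_factory=list)
    transcript: dict[str, dict] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_info": [asdict(s) for s in self.site_info],
            "transcript": self.transcript,
            "effects": self.effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Generation stages
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, au_fraction: float) -> str:
    p_au = au_fraction / 2.0
    p_cg = (1.0 - au_fraction) / 2.0
    bases = rng.choice(list("AUCG"), size=length, p=[p_au, p_au, p_cg, p_cg])
    return "".join(bases)


def gen_transcripts(config: SynthConfig, rng: np.random.Generator | None = None) -> list[Transcript]:
    """I.i.d.-composition UTRs + flanks with Beta(1,3) baseline conservation."""
    if rng is None:
        rng = config.rng("transcripts")
    out = []
    for i in range(config.n_transcripts):
        length = int(
            np.exp(np.log(config.utr_length_median) + config.utr_length_sigma * rng.standard_normal())
        )
        length = max(length, config.min_utr_length)
        out.append(
            Transcript(
                id=f"T{i:05d}",
                chrom=f"chr{1 + rng.integers(config.n_chromosomes)}",
                utr_seq=_random_seq(rng, length, config.au_fraction),
                flank_seq=_random_seq(rng, config.flank_length, config.au_fraction),
                conservation=rng.beta(1, 3, size=length),
            )
        )
    return out


def _place_nonoverlapping(
    rng: np.random.Generator, utr_len: int, width: int, occupied: list[tuple[int, int]], tries: int = 30
) -> int | None:
    for _ in range(tries):
        start = int(rng.integers(0, utr_len - width + 1))
        if all(start + width <= lo or start >= hi for lo, hi in occupied):
            return start
    return None


def plant_sites(
    transcripts: Sequence[Transcript],
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Site], list[Interval], GroundTruth]:
    """Embed motif instances, competition overlaps, co-localized and
    stem-loop partners; emit CLIP peaks and elevate conservation.

    Mutates the transcripts' sequences and conservation in place.  Emitted
    sites carry no CLIP flags -- support is annotated downstream from the
    peak list, closing the loop with the real pipeline.
    """
    if rng is None:
        rng = config.rng("sites")
    kd = config.knockdown_factor
    spec_by_id = {f.factor_id: f for f in config.factors}
    truth = GroundTruth(
        effects={
            "delta_clip": config.delta_clip,
            "delta_other": config.delta_other,
            "delta_nosite": config.delta_nosite,
            "competition_attenuation": config.competition_attenuation,
            "coop_boost": config.coop_boost,
            "stemloop_boost": config.stemloop_boost,
            "noise_sigma": config.noise_sigma,
        }
    )
    all_sites: list[Site] = []
    all_info: list[PlantedSite] = []
    clip_peaks: list[Interval] = []

    for t in transcripts:
        seq = list(t.utr_seq)
        utr_len = len(seq)
        occupied: list[tuple[int, int]] = []   # spans of all planted sites
        per_factor: dict[str, list[tuple[int, int]]] = {f: [] for f in spec_by_id}
        t_sites: list[Site] = []
        t_info: list[PlantedSite] = []

        def _write(factor: str, fclass: str, kmer: str, start: int, **info_kw) -> None:
            end = start + len(kmer)
            seq[start:end] = kmer
            occupied.append((start, end))
            per_factor.setdefault(factor, []).append((start, end))
            t_sites.append(
                Site(
                    transcript_id=t.id,
                    factor_id=factor,
                    factor_class=fclass,
                    start=start,
                    end=end,
                    matched_kmer=kmer,
                )
            )
            t_info.append(PlantedSite(**info_kw))

        # baseline sites per factor, non-overlapping across all factors
        for spec in config.factors:
            n = rng.poisson(spec.density * utr_len / 1000.0)
            placed = 0
            for _ in range(n):
                kmer = spec.kmers[rng.integers(len(spec.kmers))]
                start = _place_nonoverlapping(rng, utr_len, len(kmer), occupied)
                if start is None:
                    continue
                _write(spec.factor_id, spec.factor_class, kmer, start)
                placed += 1
            if n >= 5 and placed < n / 2:
                raise ValueError(
                    f"factor {spec.factor_id}: density {spec.density}/kb too high to "
                    "place sites without overlap; lower the density"
                )

        # competition: overlap some anchor-factor sites with another factor
        if kd is not None and config.overlap_prob > 0 and len(config.factors) > 1:
            competitors = [f for f in config.factors if f.factor_id != kd]
            for start, end in list(per_factor.get(kd, [])):
                if rng.random() >= config.overlap_prob:
                    continue
                comp = competitors[rng.integers(len(competitors))]
                kmer = comp.kmers[rng.integers(len(comp.kmers))]
                shift = int(rng.integers(1, max(2, len(kmer) - 1)))
                c_start = start + shift if rng.random() < 0.5 else start - shift
                if c_start < 0 or c_start + len(kmer) > utr_len:
                    continue
                _write(comp.factor_id, comp.factor_class, kmer, c_start)

        # planted co-localization
        for spec in config.coloc_pairs:
            partner = spec_by_id[spec.factor_b]
            for start, end in list(per_factor.get(spec.factor_a, [])):
                if rng.random() >= spec.prob_per_site:
                    continue
                kmer = partner.kmers[rng.integers(len(partner.kmers))]
                b_start = end + int(rng.integers(0, spec.max_gap + 1))
                if b_start + len(kmer) > utr_len:
                    continue
                if not all(b_start + len(kmer) <= lo or b_start >= hi for lo, hi in occupied):
                    continue
                _write(partner.factor_id, partner.factor_class, kmer, b_start,
                       coloc_partner=True)

        # planted stem-loop partners (site_b = exact reverse complement)
        for spec in config.stem_pairs:
            if rng.random() >= spec.prob:
                continue
            fa, fb = spec_by_id[spec.factor_a], spec_by_id[spec.factor_b]
            kmer = fa.kmers[rng.integers(len(fa.kmers))]
            a_start = _place_nonoverlapping(rng, utr_len, len(kmer), occupied)
            if a_start is None:
                continue
            sep = int(rng.integers(spec.min_sep, spec.max_sep + 1))
            b_start = a_start + len(kmer) + sep
            if b_start + len(kmer) > utr_len:
                continue
            if not all(b_start + len(kmer) <= lo or b_start >= hi for lo, hi in occupied):
                continue
            _write(fa.factor_id, fa.factor_class, kmer, a_start, stem_partner=True)
            _write(fb.factor_id, fb.factor_class, reverse_complement(kmer), b_start,
                   stem_partner=True)

        # CLIP peaks over a fraction of planted sites; decoys elsewhere
        for site, info in zip(t_sites, t_info):
            if rng.random() < config.clip_coverage:
                info.intended_clip = True
                clip_peaks.append(
                    Interval(
                        t.id,
                        max(0, site.start - config.clip_peak_pad),
                        min(utr_len, site.end + config.clip_peak_pad),
                        name=f"peak_{site.factor_id}",
                        score_percentile=float(rng.uniform(1, 100)),
                    )
                )
        n_decoys = rng.poisson(config.decoy_peak_density * utr_len / 1000.0)
        for _ in range(n_decoys):
            start = _place_nonoverlapping(rng, utr_len, 20, occupied)
            if start is not None:
                clip_peaks.append(
                    Interval(t.id, start, start + 20, name="decoy",
                             score_percentile=float(rng.uniform(1, 100)))
                )

        # conservation boost at functional sites
        for site in t_sites:
            if rng.random() < config.conservation_boost_fraction:
                t.conservation[site.start : site.end] = rng.beta(
                    8, 2, size=len(site)
                )

        new_seq = "".join(seq)
        for site, info in zip(t_sites, t_info):
            info.intact = new_seq[site.start : site.end] == site.matched_kmer
        t.utr_seq = new_seq

        # transcript-level truth for the knockdown factor
        kd_sites = [s for s in t_sites if s.factor_id == kd]
        other = [s for s in t_sites if s.factor_id != kd]
        all_overlapped = bool(kd_sites) and all(
            any(s.overlaps(o) for o in other) for s in kd_sites
        )
        has_clip = any(
            info.intended_clip
            for s, info in zip(t_sites, t_info)
            if s.factor_id == kd
        )
        truth.transcript[t.id] = {
            "has_site": bool(kd_sites),
            "has_clip": has_clip,
            "all_overlapped": all_overlapped,
            "coloc": any(i.coloc_partner for i in t_info),
            "stemloop": any(i.stem_partner for i in t_info),
        }
        all_sites.extend(t_sites)
        all_info.extend(t_info)

    truth.site_info = all_info
    return all_sites, clip_peaks, truth


def gen_lfc(
    transcripts: Sequence[Transcript],
    ground_truth: GroundTruth,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, ExpressionRecord]:
    """Knockdown log fold changes with planted CLIP / competition /
    cooperation effects, optional confounding, and Gaussian noise.

    Sets ``lfc`` and ``expression`` on the transcripts and records each
    transcript's expected (noise-free) LFC in the ground truth.
    """
    if rng is None:
        rng = config.rng("lfc")
    out: dict[str, ExpressionRecord] = {}
    for t in transcripts:
        info = ground_truth.transcript[t.id]
        if info["has_clip"]:
            base = config.delta_clip
        elif info["has_site"]:
            base = config.delta_other
        else:
            base = config.delta_nosite
        if info["all_overlapped"]:
            base *= config.competition_attenuation
        mean = base
        if info["coloc"]:
            mean += config.coop_boost
        if info["stemloop"]:
            mean += config.stemloop_boost
        log_expr = float(rng.normal(2.0, 1.0))
        expression = float(np.exp(log_expr))
        if config.confounded:
            mean += config.length_coef * len(t.utr_seq)
            mean += config.expression_coef * log_expr
        lfc = float(mean + rng.normal(0.0, config.noise_sigma))
        info["expected_lfc"] = mean
        t.lfc = lfc
        t.expression = expression
        out[t.id] = ExpressionRecord(
            lfc=lfc, expression=expression, utr_length=float(len(t.utr_seq))
        )
    return out


def gen_halflife(
    transcripts: Sequence[Transcript],
    sites: Sequence[Site],
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    groups: FactorGroups | None = None,
) -> dict[str, float]:
    """Half-lives from group site counts and dinucleotide composition.

    The latent stability score is
    ``h = b+ * activators - b- * repressors - bm * mirnas + sum_d g_d *
    dinuc_d + N(0, sigma)`` with dinucleotide weights ``g_d`` drawn once per
    dataset from N(0, gamma_dinuc_sigma); the stored half-life is exp(h /
    sd(h)), a positive, rank-preserving transform.  Sets ``half_life`` on
    the transcripts.
    """
    if rng is None:
        rng = config.rng("halflife")
    if groups is None:
        groups = FactorGroups()
    gamma = rng.normal(0.0, config.gamma_dinuc_sigma, size=16)
    by_tid: dict[str, list[Site]] = {}
    for s in sites:
        by_tid.setdefault(s.transcript_id, []).append(s)
    scores = {}
    for t in transcripts:
        mir, act, rep = group_site_counts(by_tid.get(t.id, ()), groups, "plain")
        dinuc = dinucleotide_counts(t.utr_seq)
        h = (
            config.beta_activators * act
            - config.beta_repressors * rep
            - config.beta_mirnas * mir
            + float(gamma @ dinuc)
            + float(rng.normal(0.0, config.halflife_sigma))
        )
        scores[t.id] = h
    values = np.array(list(scores.values()))
    scale = values.std() or 1.0
    out = {}
    for t in transcripts:
        t.half_life = float(np.exp(scores[t.id] / scale))
        out[t.id] = t.half_life
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SynthDataset:
    config: SynthConfig
    transcripts: list[Transcript]
    sites: list[Site]
    clip_peaks: list[Interval]
    ground_truth: GroundTruth


def generate_dataset(
    config: SynthConfig,
    *,
    with_lfc: bool = True,
    with_halflife: bool = False,
    halflife_groups: FactorGroups | None = None,
) -> SynthDataset:
    """Run all generation stages with per-stage streams off ``config.seed``."""
    transcripts = gen_transcripts(config)
    sites, peaks, truth = plant_sites(transcripts, config)
    if with_lfc:
        gen_lfc(transcripts, truth, config)
    if with_halflife:
        gen_halflife(transcripts, sites, config, groups=halflife_groups)
    return SynthDataset(config, transcripts, sites, peaks, truth)


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> None:
    """Emit FASTA, BED, bedGraph, TSV and the ground-truth JSON."""
    from . import io as _io
    from .sites import write_sites

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(dataset.transcripts, outdir / "utrs.fa")
    with open(outdir / "flanks.fa", "w") as fh:
        for t in dataset.transcripts:
            if t.flank_seq:
                fh.write(f">{t.id}\n{t.flank_seq}\n")
    write_sites(dataset.sites, outdir / "sites.bed")
    _io.write_intervals(dataset.clip_peaks, outdir / "clip_peaks.bed")
    _io.write_conservation(dataset.transcripts, outdir / "conservation.bedgraph")
    records = {
        t.id: ExpressionRecord(
            lfc=t.lfc,
            expression=t.expression,
            half_life=t.half_life,
            utr_length=float(len(t.utr_seq)),
        )
        for t in dataset.transcripts
    }
    _io.write_expression_table(records, outdir / "expression.tsv")
    dataset.ground_truth.to_json(outdir / "ground_truth.json")
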