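"""Synthetic seasonal/diel microbial community generator.

Emulates the statistical structure of a temperate coastal time series sampled across
seasons and across the day/night cycle: a lognormal rank-abundance distribution, higher
winter than summer richness, a single dominant taxon holding a fixed share of the
community (~25%), partial taxon turnover between seasons, and multiplicative night-time
fold-changes on selected taxa. The generator also emits multiplexed amplicon reads
(MID + primers + taxon subsequence, with injected errors) and shotgun protein-coding
fragments, so that every downstream stage — read filtering, ORF calling, clustering,
rarefaction and community comparison — can be exercised without external data.

All randomness flows from explicit integer seeds; identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ReadRecord, revcomp

Season = str
Phase = str  # "day" | "night"

_NT = np.array(list("ACGT"))

# codons without stop codons (TAA, TAG, TGA), used for stop-free references
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class DielEffect:
    """Night-time multiplicative fold-change on one taxon within one season."""

    taxon: str
    season: Season
    fold: float

    def validate(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"diel fold-change must be > 0, got {self.fold}")


@dataclass
class CommunitySpec:
    """Parameters of the simulated community.

    richness_by_season gives the number of taxa active in each season; turnover is the
    proportion of active taxa replaced between adjacent seasons. dominant_fraction is
    the community share reassigned to the designated dominant taxon. planted_base pins
    the base (day-time) share of named taxa — used to plant diel-responsive taxa at a
    known abundance.
    """

    n_taxa_pool: int
    richness_by_season: Dict[Season, int]
    lognormal_sigma: float = 1.5
    dominant_fraction: float = 0.25
    dominant_taxon: str = "taxon_0000"
    diel_effects: List[DielEffect] = field(default_factory=list)
    planted_base: Dict[str, float] = field(default_factory=dict)
    turnover: float = 0.7
    depth: int = 4070
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa_pool <= 0:
            raise ValueError("n_taxa_pool must be positive")
        for season, s in self.richness_by_season.items():
            if not 1 <= s <= self.n_taxa_pool:
                raise ValueError(
                    f"richness for season {season!r} must be in [1, n_taxa_pool]"
                )
        if not 0 < self.lognormal_sigma:
            raise ValueError("lognormal_sigma must be > 0")
        if not 0 < self.dominant_fraction < 1:
            raise ValueError("dominant_fraction must be in (0,1)")
        if not 0 <= self.turnover <= 1:
            raise ValueError("turnover must be in [0,1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        pool = set(self.taxon_pool())
        for eff in self.diel_effects:
            eff.validate()
            if eff.taxon not in pool:
                raise ValueError(f"diel effect references unknown taxon {eff.taxon!r}")
            if eff.season not in self.richness_by_season:
                raise ValueError(f"diel effect references unknown season {eff.season!r}")
        for taxon, frac in self.planted_base.items():
            if taxon not in pool:
                raise ValueError(f"planted_base references unknown taxon {taxon!r}")
            if not 0 < frac < 1:
                raise ValueError("planted base shares must be in (0,1)")

    def taxon_pool(self) -> List[str]:
        return [f"taxon_{i:04d}" for i in range(self.n_taxa_pool)]


@dataclass
class GeneratedDataset:
    """Counts, per-sample metadata and generation truth."""

    counts: pd.DataFrame  # features x samples, ints, column sums == spec.depth
    metadata: pd.DataFrame  # index = sample ids; columns season, phase, timestamp
    spec: CommunitySpec
    proportions: pd.DataFrame  # realized per-sample taxon proportions (pre-multinomial)

    def validate(self) -> None:
        if list(self.metadata.index) != list(self.counts.columns):
            raise ValueError("metadata rows must match count columns")
        sums = self.counts.sum(axis=0)
        if not (sums == self.spec.depth).all():
            raise ValueError("column sums must equal the requested depth")


def _season_taxon_sets(
    spec: CommunitySpec, seasons: Sequence[Season], rng: np.random.Generator
) -> Dict[Season, List[str]]:
    """Active taxon set per season, honouring turnover and forced (dominant/diel) taxa."""
    pool = spec.taxon_pool()
    forced_by_season: Dict[Season, List[str]] = {s: [spec.dominant_taxon] for s in seasons}
    for eff in spec.diel_effects:
        if eff.season in forced_by_season and eff.taxon not in forced_by_season[eff.season]:
            forced_by_season[eff.season].append(eff.taxon)

    sets: Dict[Season, List[str]] = {}
    prev: Optional[List[str]] = None
    for season in seasons:
        s = spec.richness_by_season[season]
        forced = forced_by_season[season]
        if prev is None:
            kept: List[str] = []
        else:
            carry = [t for t in prev if t not in forced]
            n_keep = min(len(carry), int(round((1.0 - spec.turnover) * s)))
            kept = list(rng.choice(carry, size=n_keep, replace=False)) if n_keep else []
        chosen = forced + kept
        remaining = [t for t in pool if t not in chosen]
        n_new = s - len(chosen)
        if n_new < 0:  # richness smaller than forced set
            chosen = chosen[:s]
            n_new = 0
        if n_new > len(remaining):
            raise ValueError("taxon pool too small for requested richness/turnover")
        new = list(rng.choice(remaining, size=n_new, replace=False))
        active = sorted(chosen + new)
        sets[season] = active
        prev = active
    return sets


def _base_proportions(
    spec: CommunitySpec, active: Sequence[str], rng: np.random.Generator
) -> pd.Series:
    """Lognormal rank abundances with post-hoc mass pinning for dominant/planted taxa."""
    w = np.exp(spec.lognormal_sigma * rng.standard_normal(len(active)))
    p = pd.Series(w / w.sum(), index=list(active))
    pinned: Dict[str, float] = {}
    if spec.dominant_taxon in p.index:
        pinned[spec.dominant_taxon] = spec.dominant_fraction
    for taxon, frac in spec.planted_base.items():
        if taxon in p.index:
            pinned[taxon] = frac
    if pinned:
        total_pin = sum(pinned.values())
        if total_pin >= 1:
            raise ValueError("pinned shares sum to >= 1")
        others = [t for t in p.index if t not in pinned]
        p.loc[others] *= (1.0 - total_pin) / p.loc[others].sum()
        for taxon, frac in pinned.items():
            p.loc[taxon] = frac
    return p


def _apply_diel(
    p: pd.Series, effects: Sequence[DielEffect], season: Season, phase: Phase
) -> pd.Series:
    """Multiply the named taxa at night; rescale the rest so the named taxa's
    proportion ratio night:day equals the fold exactly."""
    if phase != "night":
        return p
    hits = [e for e in effects if e.season == season and e.taxon in p.index]
    if not hits:
        return p
    q = p.copy()
    old_mass = sum(p[e.taxon] for e in hits)
    new_mass = sum(min(e.fold * p[e.taxon], 1.0) for e in hits)
    if new_mass >= 1:
        raise ValueError("diel fold-changes exceed the available community mass")
    affected = {e.taxon for e in hits}
    others = [t for t in p.index if t not in affected]
    q.loc[others] *= (1.0 - new_mass) / (1.0 - old_mass)
    for e in hits:
        q.loc[e.taxon] = e.fold * p[e.taxon]
    return q


def generate_community_series(
    spec: CommunitySpec, samples: Sequence[Tuple[Season, Phase]]
) -> GeneratedDataset:
    """Simulate a multi-season day/night count table at fixed sequencing depth.

    Counts are drawn multinomially so column sums equal ``spec.depth`` exactly.
    """
    spec.validate()
    if not samples:
        raise ValueError("at least one sample must be requested")
    for season, phase in samples:
        if season not in spec.richness_by_season:
            raise ValueError(f"unknown season label {season!r}")
        if phase not in ("day", "night"):
            raise ValueError(f"phase must be 'day' or 'night', got {phase!r}")

    rng = np.random.default_rng(spec.seed)
    seasons: List[Season] = []
    for season, _ in samples:
        if season not in seasons:
            seasons.append(season)

    active = _season_taxon_sets(spec, seasons, rng)
    base = {s: _base_proportions(spec, active[s], rng) for s in seasons}

    sample_ids: List[str] = []
    seen: Dict[str, int] = {}
    for season, phase in samples:
        stem = f"{season}_{phase}"
        seen[stem] = seen.get(stem, 0) + 1
        sample_ids.append(stem if seen[stem] == 1 else f"{stem}_{seen[stem]}")

    all_taxa = sorted({t for s in seasons for t in active[s]})
    counts = pd.DataFrame(0, index=all_taxa, columns=sample_ids, dtype=int)
    props = pd.DataFrame(0.0, index=all_taxa, columns=sample_ids)
    for (season, phase), sid in zip(samples, sample_ids):
        p = _apply_diel(base[season], spec.diel_effects, season, phase)
        draws = rng.multinomial(spec.depth, p.values)
        counts.loc[p.index, sid] = draws
        props.loc[p.index, sid] = p.values

    metadata = pd.DataFrame(
        {
            "season": [s for s, _ in samples],
            "phase": [ph for _, ph in samples],
            "timestamp": np.arange(len(samples)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ds = GeneratedDataset(counts=counts, metadata=metadata, spec=spec, proportions=props)
    ds.validate()
    return ds


def seasonal_preset(seed: int = 0) -> Tuple[CommunitySpec, List[Tuple[Season, Phase]]]:
    """Default study conditions: three seasons x day/night at depth 4070.

    Winter richness 550 vs summer 180, one dominant taxon at 25% of the community, and
    one winter taxon with a 15-fold night increase planted at a 3% day-time share.
    """
    spec = CommunitySpec(
        n_taxa_pool=1100,
        richness_by_season={"winter": 550, "spring": 200, "summer": 180},
        lognormal_sigma=1.5,
        dominant_fraction=0.25,
        dominant_taxon="taxon_0000",
        diel_effects=[DielEffect("taxon_0001", "winter", 15.0)],
        planted_base={"taxon_0001": 0.03},
        turnover=0.7,
        depth=4070,
        seed=seed,
    )
    samples = [
        ("winter", "day"),
        ("winter", "night"),
        ("spring", "day"),
        ("spring", "night"),
        ("summer", "day"),
        ("summer", "night"),
    ]
    return spec, samples


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def taxon_references(
    taxa: Sequence[str], length: int, seed: int
) -> Dict[str, str]:
    """Deterministic per-taxon reference sequences (one RNG stream, taxon order)."""
    rng = np.random.default_rng(seed)
    return {t: _random_nt(rng, length) for t in sorted(taxa)}


def generate_amplicon_reads(
    dataset: GeneratedDataset,
    mids: Dict[str, str],
    primers: Tuple[str, str],
    read_len: int = 60,
    err_rate: float = 0.0,
    n_frac: float = 0.0,
    seed: int = 0,
    corrupt_frac: float = 0.0,
    corrupt_mode: str = "mixed",  # wrong_mid | short | low_quality | mixed
) -> List[ReadRecord]:
    """Multiplexed amplicon reads: MID + fwd primer + taxon subsequence + rev primer.

    Substitutions are injected into the insert at ``err_rate`` and Ns at ``n_frac``;
    a ``corrupt_frac`` fraction of reads is damaged (wrong MID / short insert /
    low mean quality) to exercise the filters. Per-sample read counts equal the
    dataset depth.
    """
    if len(set(mids.values())) != len(mids):
        raise ValueError("duplicate MIDs")
    if not (0 <= err_rate < 1 and 0 <= n_frac < 1):
        raise ValueError("err_rate and n_frac must be in [0,1)")
    fwd, rev = primers
    rng = np.random.default_rng(seed)
    refs = taxon_references(dataset.counts.index, read_len + 20, seed=seed)
    modes = ("wrong_mid", "short", "low_quality")

    reads: List[ReadRecord] = []
    for sample in dataset.counts.columns:
        mid = mids[sample]
        col = dataset.counts[sample]
        idx = 0
        for taxon, n in col.items():
            for _ in range(int(n)):
                insert = list(refs[taxon][:read_len])
                if err_rate > 0:
                    for i in np.nonzero(rng.random(len(insert)) < err_rate)[0]:
                        insert[i] = str(rng.choice([b for b in "ACGT" if b != insert[i]]))
                if n_frac > 0:
                    for i in np.nonzero(rng.random(len(insert)) < n_frac)[0]:
                        insert[i] = "N"
                read_mid = mid
                qual_mean = 38
                corrupted = corrupt_frac > 0 and rng.random() < corrupt_frac
                if corrupted:
                    mode = corrupt_mode if corrupt_mode != "mixed" else modes[rng.integers(3)]
                    if mode == "wrong_mid":
                        first = "T" if mid[0] != "T" else "G"
                        read_mid = first + mid[1:]
                    elif mode == "short":
                        insert = insert[:30]
                    elif mode == "low_quality":
                        qual_mean = 25
                seq = read_mid + fwd + "".join(insert) + rev
                qual = np.clip(
                    rng.normal(qual_mean, 2, size=len(seq)).round().astype(int), 2, 40
                )
                reads.append(
                    ReadRecord(
                        id=f"{sample}_r{idx:05d}",
                        seq=seq,
                        qual=qual.tolist(),
                        sample=sample,
                    )
                )
                idx += 1
    return reads


# ---------------------------------------------------------------------------
# Shotgun / transcript fragments
# ---------------------------------------------------------------------------

def gene_references(
    gene_pool: int, n_codons: int, seed: int
) -> Dict[str, str]:
    """Stop-free (frame 1) protein-coding reference sequences."""
    if gene_pool <= 0:
        raise ValueError("empty gene pool")
    rng = np.random.default_rng(seed)
    codons = np.array(_SENSE_CODONS)
    return {
        f"gene_{g:04d}": "".join(codons[rng.integers(0, len(codons), size=n_codons)])
        for g in range(gene_pool)
    }


def generate_shotgun_fragments(
    dataset: GeneratedDataset,
    gene_pool: int = 50,
    frag_len_range: Tuple[int, int] = (120, 300),
    seed: int = 0,
    expression_multipliers: Optional[Dict[str, float]] = None,
    depth: Optional[int] = None,
) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Per-sample protein-coding fragments drawn proportionally to gene abundances.

    Gene weights are lognormal per season; in the metatranscriptome variant,
    ``expression_multipliers`` (gene -> fold) multiply the named genes' weights in
    night samples. Fragments start on codon boundaries so frame +1 is stop-free by
    construction. Returns the reads and a truth table (fragment -> gene, sample).
    """
    if gene_pool <= 0:
        raise ValueError("empty gene pool")
    lo, hi = frag_len_range
    if lo > hi or lo <= 0:
        raise ValueError("invalid fragment length range")
    rng = np.random.default_rng(seed)
    n_codons = max(120, hi // 3 + 40)
    refs = gene_references(gene_pool, n_codons, seed=seed)
    genes = sorted(refs)
    n_frags = depth if depth is not None else dataset.spec.depth

    season_weights: Dict[str, np.ndarray] = {}
    for season in dataset.metadata["season"].unique():
        season_weights[season] = np.exp(1.5 * rng.standard_normal(len(genes)))

    reads: List[ReadRecord] = []
    truth_rows = []
    for sample in dataset.counts.columns:
        season = dataset.metadata.loc[sample, "season"]
        phase = dataset.metadata.loc[sample, "phase"]
        w = season_weights[season].copy()
        if expression_multipliers and phase == "night":
            for gene, fold in expression_multipliers.items():
                w[genes.index(gene)] *= fold
        p = w / w.sum()
        picks = rng.choice(len(genes), size=n_frags, p=p)
        lengths = rng.integers(lo, hi + 1, size=n_frags)
        for i, (gi, length) in enumerate(zip(picks, lengths)):
            ref = refs[genes[gi]]
            max_start = (len(ref) - int(length)) // 3
            start = 3 * int(rng.integers(0, max(1, max_start + 1)))
            frag = ref[start : start + int(length)]
            rid = f"{sample}_f{i:05d}"
            reads.append(ReadRecord(id=rid, seq=frag, sample=sample))
            truth_rows.append({"fragment_id": rid, "sample": sample, "gene": genes[gi]})
    truth = pd.DataFrame(truth_rows).set_index("fragment_id")
    return reads, truth
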