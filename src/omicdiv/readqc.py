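"""Quality filtering for amplicon reads and shotgun/transcript fragments.

Two procedures are implemented. Amplicon (16S V6-style) reads must carry an exact
multiplex-identifier (MID) prefix and an exact proximal primer, a near match to the
distal primer, no Ns, and after trimming be at least 50 nt with mean Phred quality of
at least 30. Shotgun/transcript fragments are rejected for >10% Ns, length <75 bp,
>60% of any single base, or being an exact duplicate of an earlier fragment.

Rules are applied in a fixed order and every rejection is attributed to the first
failing rule, so the report always conserves reads: input = passed + sum(rejections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .records import ReadRecord

AMPLICON_RULES = ("mid", "proximal_primer", "distal_primer", "n_bases", "length", "quality")
SHOTGUN_RULES = ("n_fraction", "length", "base_composition", "duplicate")


@dataclass
class AmpliconFilterParams:
    mid_map: Dict[str, str]  # sample -> MID
    fwd_primer: str
    rev_primer: str
    min_len_post_trim: int = 50
    min_mean_quality: float = 30.0
    distal_mismatch_tolerance: int = 1

    def validate(self) -> None:
        if self.min_len_post_trim <= 0:
            raise ValueError("min_len_post_trim must be positive")
        mids = list(self.mid_map.values())
        if len(set(mids)) != len(mids):
            raise ValueError("MIDs must be unique")
        if any("N" in m for m in mids):
            raise ValueError("MIDs must be N-free")
        for a in mids:
            for b in mids:
                if a != b and b.startswith(a):
                    raise ValueError(f"ambiguous MID map: {a!r} is a prefix of {b!r}")


@dataclass
class ShotgunFilterParams:
    max_n_fraction: float = 0.10
    min_len: int = 75
    max_single_base_fraction: float = 0.60
    drop_exact_duplicates: bool = True

    def validate(self) -> None:
        if not 0 < self.max_n_fraction <= 1:
            raise ValueError("max_n_fraction must be in (0,1]")
        if not 0 < self.max_single_base_fraction <= 1:
            raise ValueError("max_single_base_fraction must be in (0,1]")
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")


@dataclass
class FilterReport:
    n_input: int = 0
    n_passed: int = 0
    rejections: Dict[str, int] = field(default_factory=dict)
    per_sample_passed: Dict[str, int] = field(default_factory=dict)
    n_quality_skipped: int = 0  # reads without qualities: quality rule not applied

    def conserve(self) -> bool:
        return self.n_input == self.n_passed + sum(self.rejections.values())

    def to_rows(self) -> List[Dict[str, object]]:
        rows = [{"metric": "input", "count": self.n_input},
                {"metric": "passed", "count": self.n_passed}]
        rows += [{"metric": f"rejected_{r}", "count": n} for r, n in self.rejections.items()]
        rows += [{"metric": f"passed_{s}", "count": n} for s, n in self.per_sample_passed.items()]
        return rows


def _find_distal(seq: str, primer: str, tolerance: int) -> int:
    """Rightmost start of a <=tolerance-mismatch, indel-free match to the distal primer
    within the terminal 1.5x primer-length window; -1 if absent."""
    k = len(primer)
    window = int(np.ceil(1.5 * k))
    lo = max(0, len(seq) - window)
    for start in range(len(seq) - k, lo - 1, -1):
        mism = sum(1 for a, b in zip(seq[start : start + k], primer) if a != b)
        if mism <= tolerance:
            return start
    return -1


def filter_amplicon_reads(
    reads: Iterable[ReadRecord], params: AmpliconFilterParams
) -> Tuple[Dict[str, List[ReadRecord]], FilterReport]:
    """Demultiplex and filter amplicon reads; MID and both primers are trimmed.

    Rule order (first failing rule is charged): exact MID prefix -> exact proximal
    primer -> near-match distal primer -> no Ns in the insert -> post-trim length ->
    post-trim mean quality. Reads without quality values skip the quality rule and are
    counted in the report.
    """
    params.validate()
    by_sample: Dict[str, List[ReadRecord]] = {s: [] for s in params.mid_map}
    report = FilterReport(rejections={r: 0 for r in AMPLICON_RULES})
    mid_to_sample = {m: s for s, m in params.mid_map.items()}
    fwd, rev = params.fwd_primer, params.rev_primer

    for read in reads:
        report.n_input += 1
        seq = read.seq
        sample = None
        for mid, samp in mid_to_sample.items():
            if seq.startswith(mid):
                sample = samp
                mid_len = len(mid)
                break
        if sample is None:
            report.rejections["mid"] += 1
            continue
        if not seq[mid_len:].startswith(fwd):
            report.rejections["proximal_primer"] += 1
            continue
        insert_start = mid_len + len(fwd)
        distal = _find_distal(seq, rev, params.distal_mismatch_tolerance)
        if distal < insert_start:
            report.rejections["distal_primer"] += 1
            continue
        insert = seq[insert_start:distal]
        if "N" in insert:
            report.rejections["n_bases"] += 1
            continue
        if len(insert) < params.min_len_post_trim:
            report.rejections["length"] += 1
            continue
        if read.qual is not None:
            q = read.qual[insert_start:distal]
            if float(np.mean(q)) < params.min_mean_quality:
                report.rejections["quality"] += 1
                continue
            qual = list(q)
        else:
            report.n_quality_skipped += 1
            qual = None
        report.n_passed += 1
        report.per_sample_passed[sample] = report.per_sample_passed.get(sample, 0) + 1
        by_sample[sample].append(
            ReadRecord(id=read.id, seq=insert, qual=qual, sample=sample)
        )
    return by_sample, report


def filter_shotgun_reads(
    reads: Iterable[ReadRecord], params: Optional[ShotgunFilterParams] = None
) -> Tuple[List[ReadRecord], FilterReport]:
    """Filter shotgun/transcript fragments, preserving input order of survivors.

    Rule order: N fraction (>10% rejects) -> length (<75 rejects) -> single-base
    composition (>60% rejects) -> exact sequence duplicates (first occurrence kept).
    """
    params = params or ShotgunFilterParams()
    params.validate()
    report = FilterReport(rejections={r: 0 for r in SHOTGUN_RULES})
    passed: List[ReadRecord] = []
    seen: set = set()
    for read in reads:
        report.n_input += 1
        seq = read.seq
        length = len(seq)
        if length and seq.count("N") / length > params.max_n_fraction:
            report.rejections["n_fraction"] += 1
            continue
        if length < params.min_len:
            report.rejections["length"] += 1
            continue
        if max(seq.count(b) for b in "ACGT") / length > params.max_single_base_fraction:
            report.rejections["base_composition"] += 1
            continue
        if params.drop_exact_duplicates:
            if seq in seen:
                report.rejections["duplicate"] += 1
                continue
            seen.add(seq)
        report.n_passed += 1
        if read.sample is not None:
            report.per_sample_passed[read.sample] = (
                report.per_sample_passed.get(read.sample, 0) + 1
            )
        passed.append(read)
    return passed, report
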