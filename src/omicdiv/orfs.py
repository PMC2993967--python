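"""Six-frame translation and predicted-ORF (pORF) extraction.

A pORF is a maximal stop-free translated segment of more than ``min_aa`` amino acids
in any of the six reading frames. No start codon is required: shotgun fragments rarely
contain gene starts. Codons containing any non-ACGT base translate to 'X' and count
toward the length (upstream QC already caps N content).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from Bio.Data import CodonTable

from .records import ReadRecord, revcomp

FRAMES = (1, 2, 3, -1, -2, -3)


def _codon_map() -> Dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    m = dict(table.forward_table)
    for stop in table.stop_codons:
        m[stop] = "*"
    return m


_CODONS = _codon_map()


def translate_frame(seq: str, offset: int) -> str:
    """Translate one forward frame; non-ACGT codons become 'X', stops '*'."""
    n = (len(seq) - offset) // 3
    return "".join(
        _CODONS.get(seq[offset + 3 * i : offset + 3 * i + 3], "X") for i in range(n)
    )


@dataclass
class Porf:
    """A predicted ORF with forward-strand, 0-based half-open coordinates."""

    id: str
    fragment_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    start: int
    end: int
    aa: str
    sample: Optional[str] = None

    def __len__(self) -> int:
        return len(self.aa)


def six_frame_porfs(
    fragment: str | ReadRecord, min_aa: int = 40, fragment_id: str = "frag",
    sample: Optional[str] = None,
) -> List[Porf]:
    """All maximal stop-free segments strictly longer than ``min_aa`` amino acids,
    from all six frames, ordered by (frame, start)."""
    if isinstance(fragment, ReadRecord):
        fragment_id = fragment.id
        sample = fragment.sample
        fragment = fragment.seq
    seq = fragment.upper()
    length = len(seq)
    rc = revcomp(seq)
    porfs: List[Porf] = []
    for frame in FRAMES:
        strand_seq = seq if frame > 0 else rc
        offset = abs(frame) - 1
        aa = translate_frame(strand_seq, offset)
        pos = 0
        for segment in aa.split("*"):
            if len(segment) > min_aa:
                # codon coordinates on the translated strand
                nt_start = offset + 3 * pos
                nt_end = nt_start + 3 * len(segment)
                if frame > 0:
                    start, end = nt_start, nt_end
                else:
                    start, end = length - nt_end, length - nt_start
                porfs.append(
                    Porf(
                        id=f"{fragment_id}|{frame:+d}|{start}",
                        fragment_id=fragment_id,
                        frame=frame,
                        start=start,
                        end=end,
                        aa=segment,
                        sample=sample,
                    )
                )
            pos += len(segment) + 1  # +1 for the stop codon
    porfs.sort(key=lambda p: (FRAMES.index(p.frame), p.start))
    return porfs


def porfs_from_reads(reads, min_aa: int = 40) -> List[Porf]:
    out: List[Porf] = []
    for read in reads:
        out.extend(six_frame_porfs(read, min_aa=min_aa))
    return out
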