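"""Bipartite zipcode motif scanner.

The zipcode is the bipartite cis-element in the β-actin 3'UTR bound by the
KH34 domains of Igf2bp1/ZBP1: a GGACT followed, after a short spacer, by ACA.
The scanner reports every (GGACT, ACA) pair whose spacer — the number of
nucleotides strictly between the end of GGACT and the start of ACA — lies in
the configured range, on the sense strand only (3'UTRs are mRNA-sense).
Overlapping hits are all reported; IUPAC wildcards never match.
"""

from __future__ import annotations

from dataclasses import dataclass

from .image_io import SequenceRecord

__all__ = ["ZipcodeHit", "scan_zipcode", "MOTIF_5P", "MOTIF_3P"]

MOTIF_5P = "GGACT"
MOTIF_3P = "ACA"

#: default spacer range (nt strictly between the two parts); the zebrafish
#: β-actin element has spacer 7, other vertebrate zipcodes vary.
DEFAULT_SPACER_MIN = 5
DEFAULT_SPACER_MAX = 15

_VALID = set("ACGT")


@dataclass
class ZipcodeHit:
    """One bipartite match; coordinates are 0-based on the normalized sequence."""

    record_id: str
    pos_ggact: int
    pos_aca: int
    spacer_nt: int
    matched_substring: str

    def __post_init__(self) -> None:
        if self.pos_aca != self.pos_ggact + len(MOTIF_5P) + self.spacer_nt:
            raise ValueError("inconsistent hit coordinates")


def scan_zipcode(
    record: SequenceRecord,
    spacer_min: int = DEFAULT_SPACER_MIN,
    spacer_max: int = DEFAULT_SPACER_MAX,
) -> list[ZipcodeHit]:
    """All (GGACT, spacer, ACA) matches with spacer in [spacer_min, spacer_max].

    The sequence is normalized (uppercase, U→T) before matching; characters
    outside A/C/G/T (including IUPAC wildcards) never match and anything
    outside the IUPAC alphabet raises.  Hits are ordered by GGACT position,
    then spacer length.
    """
    if spacer_min < 0 or spacer_min > spacer_max:
        raise ValueError("need 0 <= spacer_min <= spacer_max")
    seq = record.normalized()
    bad = [i for i, c in enumerate(seq) if c not in _VALID and c not in set("RYSWKMBDHVN")]
    if bad:
        raise ValueError(f"invalid alphabet characters at positions {bad[:10]}")

    hits: list[ZipcodeHit] = []
    k5 = len(MOTIF_5P)
    k3 = len(MOTIF_3P)
    pos = seq.find(MOTIF_5P)
    while pos != -1:
        for spacer in range(spacer_min, spacer_max + 1):
            start3 = pos + k5 + spacer
            if start3 + k3 > len(seq):
                break
            if seq[start3 : start3 + k3] == MOTIF_3P:
                hits.append(
                    ZipcodeHit(
                        record_id=record.id,
                        pos_ggact=pos,
                        pos_aca=start3,
                        spacer_nt=spacer,
                        matched_substring=seq[pos : start3 + k3],
                    )
                )
        pos = seq.find(MOTIF_5P, pos + 1)
    return hits
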