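"""Spliced-transcript reconstruction, ORF scanning, and Kozak-context scoring.

The Kozak context is the 10-nucleotide window from position -6 to +4 around
a start codon (AUG occupying positions +1..+3, i.e. characters 7-9 of the
window).  Strong contexts carry a purine at -3 and a G at +4; the default
translation-initiation-site (TIS) scorer is an explicit position-weight
table over the six upstream positions and +4, normalized so the Kozak
consensus GCCRCC AUG G scores exactly 1.0 and the least-similar context 0.0.
Any callable with the same signature can be plugged in instead (e.g. a
wrapper around an external TIS predictor).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .io_formats import TranscriptModel

__all__ = [
    "ORFCandidate",
    "KozakWeightScorer",
    "DEFAULT_SCORER",
    "revcomp",
    "splice_transcript",
    "find_orfs",
    "extract_kozak_context",
    "score_tis",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = ("TAA", "TAG", "TGA")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ORFCandidate:
    """An ATG-to-stop open reading frame in transcript coordinates.

    ``start`` is the 0-based position of the A of the ATG; ``end`` is one
    past the stop codon; ``kozak_context`` is the -6..+4 window as RNA with
    AUG at characters 7-9 (5'-truncated positions padded with N).
    """

    transcript_id: str
    start: int
    end: int
    frame: int
    peptide: str
    kozak_context: str
    tis_score: float | None = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        n_codons = (self.end - self.start) // 3
        # n_codons - 1 peptide residues with a stop codon; n_codons without
        # (stopless ORFs are only produced when explicitly requested)
        if len(self.peptide) not in (n_codons - 1, n_codons):
            raise ValueError("peptide length inconsistent with coordinates")
        if self.kozak_context[6:9] != "AUG":
            raise ValueError("kozak_context must have AUG at positions 7-9")


def splice_transcript(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenate exon sequences 5'->3'; reverse-complement on minus strand."""
    chrom_seq = genome[model.chrom]
    parts = []
    for s, e in model.exons:
        if s < 0 or e > len(chrom_seq):
            raise ValueError(
                f"transcript {model.transcript_id}: exon ({s}, {e}) outside "
                f"{model.chrom} (length {len(chrom_seq)})"
            )
        block = chrom_seq[s:e].upper()
        parts.append(revcomp(block) if model.strand == "-" else block)
    return "".join(parts)


def translate(cds: str) -> str:
    """Translate an in-frame CDS, excluding the stop symbol."""
    peptide = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            break
        peptide.append(CODON_TABLE[codon])
    return "".join(peptide)


def find_orfs(
    sequence: str,
    min_peptide_length: int = 10,
    transcript_id: str = "",
    require_stop: bool = True,
    scorer: Callable[[str], float] | None = None,
) -> list[ORFCandidate]:
    """Scan the forward strand of a transcript sequence for ATG...stop ORFs.

    Every ATG with an in-frame stop downstream yields a candidate (nested
    ATGs inside a found ORF are reported as separate candidates); codon spans
    containing N are skipped.  ORFs running off the 3' end without a stop are
    excluded unless ``require_stop`` is False (their ``end`` then marks the
    last complete codon).  Results are sorted by start position.
    """
    seq = sequence.upper()
    orfs: list[ORFCandidate] = []
    for m in re.finditer("ATG", seq):
        start = m.start()
        end = None
        hit_n = False
        for i in range(start, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                hit_n = True
                break
            if codon in STOP_CODONS:
                end = i + 3
                break
        if hit_n:
            continue
        if end is None:
            if require_stop:
                continue
            end = start + 3 * ((len(seq) - start) // 3)  # last complete codon
        peptide = translate(seq[start:end])
        if len(peptide) < min_peptide_length:
            continue
        context = extract_kozak_context(seq, start)
        orfs.append(
            ORFCandidate(
                transcript_id=transcript_id,
                start=start,
                end=end,
                frame=start % 3,
                peptide=peptide,
                kozak_context=context,
                tis_score=score_tis(context, scorer) if scorer else None,
            )
        )
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def extract_kozak_context(sequence: str, start: int) -> str:
    """The -6..+4 window around an ATG at ``start``, rendered as RNA.

    Ten characters: six upstream of the ATG, the AUG itself, and the +4
    base.  Positions upstream of the transcript 5' end are padded with N;
    a missing +4 base (ATG at the very 3' end) likewise becomes N.
    """
    seq = sequence.upper()
    if seq[start : start + 3] != "ATG":
        raise ValueError(f"no ATG at position {start}")
    upstream = seq[max(0, start - 6) : start].rjust(6, "N")
    plus4 = seq[start + 3 : start + 4] or "N"
    return (upstream + "ATG" + plus4).replace("T", "U")


class KozakWeightScorer:
    """Position-weight similarity of a -6..+4 context to the Kozak consensus.

    Scored positions are -6..-1 and +4 (the AUG itself is fixed).  Each
    position has a base->weight mapping; the -3 purine and the +4 G — the
    canonical strong-context determinants — get double weight.  The raw sum
    is min-max normalized so the consensus GCCACCAUGG scores 1.0 and the
    lowest-weight context 0.0.  N contributes the position's minimum weight.
    """

    #: per-position base weights, order -6, -5, -4, -3, -2, -1, +4
    DEFAULT_WEIGHTS: tuple[dict[str, float], ...] = (
        {"G": 1.0, "A": 0.7, "C": 0.5, "U": 0.3},  # -6
        {"C": 1.0, "A": 0.6, "G": 0.6, "U": 0.4},  # -5
        {"C": 1.0, "A": 0.6, "G": 0.5, "U": 0.4},  # -4
        {"A": 2.0, "G": 1.8, "C": 0.4, "U": 0.2},  # -3 (purine, double weight)
        {"C": 1.0, "A": 0.6, "G": 0.5, "U": 0.4},  # -2
        {"C": 1.0, "A": 0.7, "G": 0.6, "U": 0.5},  # -1
        {"G": 2.0, "A": 0.6, "C": 0.5, "U": 0.4},  # +4 (G, double weight)
    )

    def __init__(self, weights: Sequence[Mapping[str, float]] | None = None) -> None:
        self.weights = tuple(dict(w) for w in (weights or self.DEFAULT_WEIGHTS))
        if len(self.weights) != 7:
            raise ValueError("need weights for 7 positions (-6..-1 and +4)")
        self._max = sum(max(w.values()) for w in self.weights)
        self._min = sum(min(w.values()) for w in self.weights)

    def __call__(self, context: str) -> float:
        context = context.upper().replace("T", "U")
        if len(context) != 10 or context[6:9] != "AUG":
            raise ValueError(
                f"malformed context {context!r}: need 10 chars with AUG at 7-9"
            )
        bases = context[:6] + context[9]
        raw = 0.0
        for base, w in zip(bases, self.weights):
            raw += w.get(base, min(w.values()))
        return (raw - self._min) / (self._max - self._min)


DEFAULT_SCORER = KozakWeightScorer()


def score_tis(context: str, scorer: Callable[[str], float] | None = None) -> float:
    """Score a -6..+4 initiation context in [0, 1] with a pluggable scorer."""
    score = (scorer or DEFAULT_SCORER)(context)
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"scorer returned {score} outside [0, 1]")
    return float(score)
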