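"""Translation of transcript models and block-level protein comparison.

Translation splices the annotated CDS in transcript orientation (reverse
complement on the minus strand), starts at the annotated start codon and runs
to the first in-frame stop, reading through the annotated CDS end into the
3' UTR if no stop is met earlier (as happens after frameshifting deletions).
When the annotated start codon has been removed by the event, the spliced
mRNA is rescanned for the first AUG opening a reading frame of at least 30
codons.  A stop codon falling more than 50 nt upstream of the last exon–exon
junction sets an informational premature-stop (NMD-candidate) flag; the flag
feeds no downstream filter.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

from Bio.Seq import Seq

from .models import GenomeInterval, ProteinRecord, ResidueDiff, TranscriptModel

MIN_RESCAN_ORF_CODONS = 30
NMD_WINDOW_NT = 50

_VALID = set("ACGT")


def _clean(seq: str) -> str:
    seq = seq.upper()
    if set(seq) - _VALID:
        warnings.warn("unknown nucleotide symbol(s) translated as X")
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def splice(transcript: TranscriptModel, genome, spans=None) -> str:
    """Concatenate exonic sequence in transcript orientation."""
    spans = transcript.exon_spans if spans is None else spans
    chrom = genome[transcript.chrom]
    seq = "".join(str(chrom[s:e]) for s, e in spans)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return _clean(seq)


def genomic_to_mrna(transcript: TranscriptModel, pos: int) -> int:
    """Map a genomic position (on an exon) to its mRNA offset."""
    offset = 0
    spans = transcript.exon_spans
    if transcript.strand == "+":
        for s, e in spans:
            if s <= pos < e:
                return offset + (pos - s)
            offset += e - s
    else:
        for s, e in reversed(spans):
            if s <= pos < e:
                return offset + (e - 1 - pos)
            offset += e - s
    raise ValueError(f"position {pos} not exonic in {transcript.transcript_id}")


def mrna_to_genomic(
    transcript: TranscriptModel, start: int, end: int
) -> List[GenomeInterval]:
    """Map an mRNA interval back to genomic interval(s)."""
    out: List[Tuple[int, int]] = []
    offset = 0
    spans = transcript.exon_spans
    ordered = spans if transcript.strand == "+" else list(reversed(spans))
    for s, e in ordered:
        length = e - s
        lo = max(start, offset)
        hi = min(end, offset + length)
        if lo < hi:
            if transcript.strand == "+":
                out.append((s + (lo - offset), s + (hi - offset)))
            else:
                out.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return [
        GenomeInterval(transcript.chrom, s, e, transcript.strand)
        for s, e in sorted(out)
    ]


def _junction_offsets(transcript: TranscriptModel) -> List[int]:
    """mRNA offsets of exon–exon junctions (position of first base after each)."""
    lengths = [e - s for s, e in transcript.exon_spans]
    if transcript.strand == "-":
        lengths = list(reversed(lengths))
    offsets, acc = [], 0
    for ln in lengths[:-1]:
        acc += ln
        offsets.append(acc)
    return offsets


def _first_stop(mrna: str, start: int) -> Optional[int]:
    """mRNA offset of the first in-frame stop codon at/after ``start``."""
    for i in range(start, len(mrna) - 2, 3):
        if mrna[i : i + 3] in ("TAA", "TAG", "TGA"):
            return i
    return None


def _orf_codons(mrna: str, start: int) -> int:
    stop = _first_stop(mrna, start)
    end = stop if stop is not None else start + (len(mrna) - start) // 3 * 3
    return (end - start) // 3


def translate(
    transcript: TranscriptModel,
    genome,
    min_orf_codons: int = MIN_RESCAN_ORF_CODONS,
    nmd_window: int = NMD_WINDOW_NT,
) -> ProteinRecord:
    """Translate one transcript into a :class:`ProteinRecord`."""
    if not transcript.cds:
        return ProteinRecord(sequence="", coding_status="non_coding")
    mrna = splice(transcript, genome)
    cds_first = (
        min(s for s, _ in transcript.cds_spans)
        if transcript.strand == "+"
        else max(e for _, e in transcript.cds_spans) - 1
    )
    start = genomic_to_mrna(transcript, cds_first)
    if mrna[start : start + 3] != "ATG":
        # annotated start removed by the event: rescan for a usable AUG
        start = next(
            (
                i
                for i in range(len(mrna) - 2)
                if mrna[i : i + 3] == "ATG"
                and _orf_codons(mrna, i) >= min_orf_codons
            ),
            None,
        )
        if start is None:
            return ProteinRecord(sequence="", coding_status="non_coding")
    stop = _first_stop(mrna, start)
    end = stop if stop is not None else start + (len(mrna) - start) // 3 * 3
    if end == start:
        return ProteinRecord(sequence="", coding_status="non_coding")
    aa = str(Seq(mrna[start:end]).translate())
    status = "coding"
    junctions = _junction_offsets(transcript)
    if stop is not None and junctions and junctions[-1] - stop > nmd_window:
        status = "premature_stop_flagged"
    cds_used = mrna_to_genomic(
        transcript, start, end + (3 if stop is not None else 0)
    )
    return ProteinRecord(sequence=aa, coding_status=status, cds_used=cds_used)


def diff(p_incl: ProteinRecord, p_excl: ProteinRecord) -> ResidueDiff:
    """Block difference between the inclusion and exclusion proteins.

    Longest common prefix, then longest common suffix of the remainders
    (capped so prefix + suffix never exceeds the shorter length).
    """
    a, b = p_incl.sequence, p_excl.sequence
    la, lb = len(a), len(b)
    prefix = 0
    while prefix < min(la, lb) and a[prefix] == b[prefix]:
        prefix += 1
    max_suffix = min(la, lb) - prefix
    suffix = 0
    while suffix < max_suffix and a[la - 1 - suffix] == b[lb - 1 - suffix]:
        suffix += 1
    return ResidueDiff(prefix_len=prefix, suffix_len=suffix, len_incl=la, len_excl=lb)
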