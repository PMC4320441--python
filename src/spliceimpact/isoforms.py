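"""Construction of inclusion/exclusion transcript pairs for splicing events.

For each event the *inclusion* transcript contains the alternative region and
the *exclusion* transcript lacks it.  Which of the two equals the annotated
host depends on the event class: for exon skipping and alternative splice
sites the host carries the region and the exclusion form is synthesized by
excision; for intron retention the host lacks the intron and the inclusion
form is synthesized by merging it in; alternative promoters/polyadenylation
additionally drop everything transcript-upstream/-downstream of the region.
``complex`` events are never synthesized — both transcripts must be annotated
and are named explicitly as ``"INCLUSION_ID|EXCLUSION_ID"`` in the event's
``host_transcript_id`` field.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from . import intervals as iv
from .models import (
    AltExonEvent,
    GenomeInterval,
    TranscriptModel,
    TranscriptPair,
)


class PairBuildError(ValueError):
    """Raised when an event cannot be paired with its host transcript."""


def pick_host(
    event: AltExonEvent, transcripts: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Resolve the host transcript for an event.

    An explicit ``host_transcript_id`` wins.  Without one, the fallback is the
    transcript of the event's gene with the longest CDS, ties broken by
    lexicographically smallest transcript id — a deterministic stand-in for a
    manual "most representative transcript" choice.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    if event.host_transcript_id:
        hid = event.host_transcript_id.split("|")[0]
        if hid not in by_id:
            raise PairBuildError(
                f"{event.probeset_id}: host transcript {hid!r} not found"
            )
        return by_id[hid]
    sym = event.gene_symbol.strip().upper()
    candidates = [t for t in transcripts if t.gene_symbol.strip().upper() == sym]
    if not candidates:
        raise PairBuildError(
            f"{event.probeset_id}: no transcript for gene {event.gene_symbol!r}"
        )
    return min(candidates, key=lambda t: (-t.cds_length(), t.transcript_id))


def _derived(
    host: TranscriptModel, suffix: str, exon_spans, cds_spans
) -> TranscriptModel:
    mk = lambda spans: [
        GenomeInterval(host.chrom, s, e, host.strand) for s, e in spans
    ]
    t = TranscriptModel(
        transcript_id=host.transcript_id + suffix,
        gene_id=host.gene_id,
        gene_symbol=host.gene_symbol,
        chrom=host.chrom,
        strand=host.strand,
        exons=mk(exon_spans),
        cds=mk(cds_spans),
    )
    t.validate()
    return t


def _excise(host: TranscriptModel, region: GenomeInterval) -> TranscriptModel:
    """Host minus the region, exon boundaries trimmed (never re-merged)."""
    exons = iv.subtract(host.exon_spans, region.span)
    cds = iv.subtract(host.cds_spans, region.span)
    if not exons:
        raise PairBuildError("region excision leaves no exons")
    return _derived(host, "-excl", exons, cds)


def _drop_flank(
    host: TranscriptModel, region: GenomeInterval, side: str
) -> TranscriptModel:
    """Drop the region plus all exonic sequence 5' or 3' of it (transcript
    orientation)."""
    upstream_genomic_left = (side == "5p") == (host.strand == "+")
    if upstream_genomic_left:
        cut = (0, region.end)
    else:
        cut = (region.start, max(e for _, e in host.exon_spans))
    exons = iv.subtract(host.exon_spans, cut)
    cds = iv.subtract(host.cds_spans, cut)
    if not exons:
        raise PairBuildError("flank drop leaves no exons")
    return _derived(host, "-excl", exons, cds)


def _retain_intron(host: TranscriptModel, region: GenomeInterval) -> TranscriptModel:
    """Merge a fully intronic region into its flanking exons.

    The region becomes coding when both its endpoints abut CDS, i.e. the CDS
    of the flanking exons runs all the way to the intron boundaries.
    """
    spans = host.exon_spans
    intronic = not iv.overlaps(spans, region.span) and (
        spans[0][0] < region.start and region.end <= spans[-1][1]
    )
    if not intronic:
        raise PairBuildError("intron_retention region is not fully intronic")
    exons = iv.merge(spans + [region.span])
    cds_spans = host.cds_spans
    left_ok = any(e == region.start for _, e in cds_spans)
    right_ok = any(s == region.end for s, _ in cds_spans)
    if left_ok and right_ok:
        cds = iv.merge(cds_spans + [region.span])
    else:
        cds = cds_spans
    return _derived(host, "+IR", exons, cds)


def build_pair(
    event: AltExonEvent,
    host: TranscriptModel,
    transcripts_by_id: Optional[Dict[str, TranscriptModel]] = None,
) -> TranscriptPair:
    """Build the inclusion/exclusion transcript pair for one event."""
    region = event.region
    if region.chrom != host.chrom or region.strand != host.strand:
        raise PairBuildError(
            f"{event.probeset_id}: region on {region.chrom}{region.strand}, "
            f"host on {host.chrom}{host.strand}"
        )
    cls = event.event_class

    if cls == "complex":
        parts = event.host_transcript_id.split("|")
        if len(parts) != 2 or not transcripts_by_id:
            raise PairBuildError(
                f"{event.probeset_id}: complex events need "
                "'INCLUSION_ID|EXCLUSION_ID' in host_transcript_id"
            )
        try:
            incl, excl = (transcripts_by_id[p] for p in parts)
        except KeyError as exc:
            raise PairBuildError(
                f"{event.probeset_id}: unknown transcript {exc}"
            ) from exc
        return TranscriptPair(event=event, inclusion=incl, exclusion=excl)

    if cls == "intron_retention":
        inclusion = _retain_intron(host, region)
        return TranscriptPair(event=event, inclusion=inclusion, exclusion=host)

    if not iv.overlaps(host.exon_spans, region.span):
        raise PairBuildError(
            f"{event.probeset_id}: region does not overlap host exons"
        )
    if cls in ("skipped_exon", "alt_5ss", "alt_3ss"):
        exclusion = _excise(host, region)
    elif cls == "alt_promoter":
        exclusion = _drop_flank(host, region, "5p")
    elif cls == "alt_polyA":
        exclusion = _drop_flank(host, region, "3p")
    else:  # pragma: no cover - vocabulary enforced upstream
        raise PairBuildError(f"unhandled event class {cls!r}")
    return TranscriptPair(event=event, inclusion=host, exclusion=exclusion)


def classify_region(event: AltExonEvent, pair: TranscriptPair) -> str:
    """Classify the event region against the inclusion CDS projection.

    coding = region entirely inside the CDS union; utr_only = entirely
    outside; mixed = straddling a CDS boundary; not_determined when the
    inclusion transcript has no CDS.
    """
    if not pair.inclusion.is_coding:
        return "not_determined"
    cds = pair.inclusion.cds_spans
    covered = iv.total_length(iv.intersect(iv.merge(cds), [event.region.span]))
    if covered == len(event.region):
        return "coding"
    if covered == 0:
        return "utr_only"
    return "mixed"
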